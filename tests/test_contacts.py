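import itertools

import numpy as np
import pytest

from cellcontacts import (
    ContactCriteria,
    PeriodicBox,
    build_adjacency_table,
    candidate_pairs,
    compare_methods,
    compute_grid,
    contacts_frame,
    contacts_trajectory,
    naive_contacts,
    pair_distance,
    probe_pair_system,
    random_system,
    random_trajectory,
    stride_select,
)
from cellcontacts.synth import validation_sweep

from conftest import assert_contacts_valid, compact_cloud, make_trajectory


# ---------------------------------------------------------------------------
# stride selection


def test_stride_select_examples():
    assert stride_select([0, 250, 500, 750, 1000], 500) == [0, 500, 1000]
    steps = [3, 17, 21, 400]
    assert stride_select(steps, 1) == steps
    with pytest.raises(ValueError):
        stride_select([0], 0)


def test_stride_select_numpy_path_preserves_order():
    steps = np.array([1000, 0, 750, 500])
    assert stride_select(steps, 500) == [1000, 0, 500]


# ---------------------------------------------------------------------------
# distances


def test_pair_distance_examples(box50):
    assert pair_distance((1, 2, 3), (1, 2, 3), box50) == 0.0
    assert pair_distance((1, 0, 0), (49, 0, 0), box50, "minimum_image") == pytest.approx(2.0)
    assert pair_distance((1, 0, 0), (49, 0, 0), box50, "raw") == pytest.approx(48.0)
    with pytest.raises(ValueError):
        pair_distance((0, 0, 0), (1, 1, 1), box50, "chebyshev")


def test_minimum_image_distance_never_exceeds_half_diagonal(box50):
    rng = np.random.default_rng(11)
    half_diag = np.linalg.norm(box50.lengths / 2)
    for p, q in rng.uniform(-100, 150, size=(200, 2, 3)):
        assert pair_distance(p, q, box50, "minimum_image") <= half_diag + 1e-9


# ---------------------------------------------------------------------------
# candidate enumeration


def test_candidate_pairs_same_and_far_bins(box50):
    grid = compute_grid(box50, 5.4)
    table = build_adjacency_table(grid)
    same = make_trajectory([[1.0, 1.0, 1.0], [2.0, 2.0, 2.0]], box50)
    assert candidate_pairs(same.frames[0], same.atoms, grid, table) == {(1, 2)}
    far = make_trajectory([[1.0, 1.0, 1.0], [25.0, 25.0, 25.0]], box50)
    assert candidate_pairs(far.frames[0], far.atoms, grid, table) == set()


def test_candidate_pairs_match_adjacency_filter_oracle(box50):
    """The grid enumeration equals a brute-force bin-adjacency filter on all pairs."""
    grid = compute_grid(box50, 5.4)
    table = build_adjacency_table(grid)
    traj = random_system(20, box50, hydrogen_fraction=0.0, seed=13)
    frame = traj.frames[0]
    from cellcontacts.grid import assign_bins

    bins = assign_bins(frame, grid)
    expected = set()
    for i, j in itertools.combinations(range(20), 2):
        if bins[i] == bins[j] or bins[j] in table[bins[i]]:
            a, b = traj.atoms[i].atom_number, traj.atoms[j].atom_number
            expected.add((min(a, b), max(a, b)))
    assert candidate_pairs(frame, traj.atoms, grid, table) == expected


def test_candidate_pairs_superset_of_contact_pairs(box50):
    grid = compute_grid(box50, 5.4)
    table = build_adjacency_table(grid)
    criteria = ContactCriteria(stride_modulus=None, min_residue_gap=0, heavy_only=False)
    traj = random_system(400, box50, hydrogen_fraction=0.0, seed=29)
    cand = candidate_pairs(traj.frames[0], traj.atoms, grid, table)
    hits = naive_contacts(traj.frames[0], traj.atoms, box50, criteria)
    assert {(c.atom_a, c.atom_b) for c in hits} <= cand


# ---------------------------------------------------------------------------
# predicate set


def _single_frame(coords, box, **kw):
    return make_trajectory(coords, box, **kw)


def test_contact_within_cutoff_detected(box50, criteria_single_frame):
    traj = _single_frame([[10, 10, 10], [15.3, 10, 10]], box50, residues=[1, 3])
    out = contacts_trajectory(traj, criteria_single_frame)
    assert len(out) == 1
    c = out.contacts[0]
    assert (c.atom_a, c.atom_b) == (1, 2)
    assert c.distance == pytest.approx(5.3)
    assert_contacts_valid(out, criteria_single_frame)


def test_adjacent_residues_excluded(box50, criteria_single_frame):
    traj = _single_frame([[10, 10, 10], [13, 10, 10]], box50, residues=[4, 5])
    assert len(contacts_trajectory(traj, criteria_single_frame)) == 0
    # same pair across instances is distance-eligible
    traj2 = _single_frame([[10, 10, 10], [13, 10, 10]], box50, residues=[4, 5], instances=[1, 2])
    assert len(contacts_trajectory(traj2, criteria_single_frame)) == 1


def test_hydrogen_excluded_when_heavy_only(box50, criteria_single_frame):
    traj = _single_frame(
        [[10, 10, 10], [12, 10, 10]], box50, residues=[1, 10], heavy=[True, False]
    )
    assert len(contacts_trajectory(traj, criteria_single_frame)) == 0
    all_atoms = ContactCriteria(stride_modulus=None, heavy_only=False)
    assert len(contacts_trajectory(traj, all_atoms)) == 1


def test_cutoff_boundary_is_inclusive(box50):
    criteria = ContactCriteria(stride_modulus=None)
    traj = _single_frame([[10, 10, 10], [15.4, 10, 10]], box50, residues=[1, 4])
    out = contacts_trajectory(traj, criteria)
    assert len(out) == 1 and out.contacts[0].distance <= 5.4


def test_naive_contacts_collinear_example(box50):
    criteria = ContactCriteria(stride_modulus=None, distance_mode="raw")
    traj = _single_frame(
        [[0, 0, 0], [5, 0, 0], [10, 0, 0]], box50, residues=[1, 5, 9]
    )
    out = naive_contacts(traj.frames[0], traj.atoms, box50, criteria)
    assert {(c.atom_a, c.atom_b) for c in out} == {(1, 2), (2, 3)}
    assert all(c.distance == pytest.approx(5.0) for c in out)


def test_empty_and_singleton_systems(box50, criteria_single_frame):
    empty = probe_pair_system([], box50)
    assert len(contacts_trajectory(empty, criteria_single_frame)) == 0
    single = _single_frame([[1, 1, 1]], box50)
    assert len(naive_contacts(single.frames[0], single.atoms, box50, criteria_single_frame)) == 0


# ---------------------------------------------------------------------------
# trajectory plumbing


def test_trajectory_stride_selection(box50):
    base = random_system(50, box50, seed=3)
    traj = random_trajectory(base, n_frames=5, step_stride=250, seed=4)
    assert traj.steps == [250, 500, 750, 1000, 1250]
    criteria = ContactCriteria(stride_modulus=500)
    out = contacts_trajectory(traj, criteria)
    assert {c.step for c in out} <= {500, 1000}
    per_frame = ContactCriteria(stride_modulus=None)
    every2 = contacts_trajectory(traj, per_frame, frame_every=2)
    assert {c.step for c in every2} <= {250, 750, 1250}


def test_single_frame_trajectory_equals_contacts_frame(box50, criteria_single_frame):
    traj = random_system(300, box50, seed=17)
    grid = compute_grid(box50, criteria_single_frame.min_bin_edge)
    table = build_adjacency_table(grid)
    via_traj = contacts_trajectory(traj, criteria_single_frame)
    via_frame = contacts_frame(
        traj.frames[0], traj.atoms, grid, table, criteria_single_frame
    )
    assert via_traj.equivalent(via_frame, 0.0)


def test_trajectory_union_equals_per_frame_oracle(box50):
    base = random_system(500, box50, seed=21)
    traj = random_trajectory(base, n_frames=10, step_stride=500, seed=22)
    criteria = ContactCriteria(stride_modulus=None)
    indexed = contacts_trajectory(traj, criteria)
    per_frame = [
        naive_contacts(f, traj.atoms, box50, criteria).contacts for f in traj.frames
    ]
    from cellcontacts import ContactSet

    oracle = ContactSet(tuple(itertools.chain.from_iterable(per_frame)))
    assert indexed.equivalent(oracle, 0.0)
    assert_contacts_valid(indexed, criteria)


# ---------------------------------------------------------------------------
# engine equivalence and monotonicity


def test_indexed_equals_oracle_over_seeded_sweep():
    """Spot-check of the oracle-equivalence property (full sweep in acceptance)."""
    for traj, criteria in validation_sweep(seed=1234, n_systems=24):
        indexed = contacts_trajectory(traj, criteria)
        naive = contacts_trajectory(traj, criteria, use_spatial_index=False)
        assert indexed.equivalent(naive, 1e-9)
        assert_contacts_valid(indexed, criteria)


def test_contacts_monotone_in_cutoff(box50):
    traj = random_system(400, box50, seed=31)
    keys = {}
    for cutoff in (3.0, 5.4, 8.0):
        criteria = ContactCriteria(cutoff=cutoff, stride_modulus=None)
        keys[cutoff] = set(contacts_trajectory(traj, criteria).keys())
    assert keys[3.0] <= keys[5.4] <= keys[8.0]


def test_degenerate_grid_falls_back_to_all_pairs():
    box = PeriodicBox(12.0, 12.0, 12.0)  # 2x2x2 cells of 6 Å
    criteria = ContactCriteria(stride_modulus=None)
    traj = random_system(150, box, seed=37)
    indexed = contacts_trajectory(traj, criteria)
    naive = contacts_trajectory(traj, criteria, use_spatial_index=False)
    assert indexed.equivalent(naive, 0.0)
    assert len(indexed) > 0


# ---------------------------------------------------------------------------
# compare_methods


def test_compare_methods_reports_equality(box50):
    traj = random_system(1000, box50, seed=41)
    report = compare_methods(traj, ContactCriteria(stride_modulus=None))
    assert report.equal
    assert report.n_frames == 1
    assert report.candidate_pairs < report.all_pairs
    assert 0.0 < report.pair_reduction_percent < 100.0


def test_compare_methods_two_atom_system(box50):
    traj = make_trajectory([[1, 1, 1], [2, 2, 2]], box50)
    report = compare_methods(traj, ContactCriteria(stride_modulus=None))
    assert report.all_pairs == 1
    assert report.candidate_pairs <= 1


def test_compact_cloud_examines_27_bins(box50):
    """A protein-sized cloud inside one bin is covered by a single 27-bin chunk."""
    traj = compact_cloud(box50, center=(25.0, 25.0, 25.0), radius=1.5, n_atoms=30, seed=5)
    report = compare_methods(traj, ContactCriteria(stride_modulus=None))
    assert report.bins_examined == 27
    assert report.equal
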