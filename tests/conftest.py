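import numpy as np
import pytest

from cellcontacts import (
    AtomRecord,
    ContactCriteria,
    ContactSet,
    Frame,
    PeriodicBox,
    Trajectory,
)

BOX50 = PeriodicBox(50.0, 50.0, 50.0)


@pytest.fixture
def box50():
    return BOX50


@pytest.fixture
def criteria_single_frame():
    """Default predicate set, every frame selected."""
    return ContactCriteria(stride_modulus=None)


def make_atoms(n, residues=None, instances=None, heavy=None):
    """Hand-built atom list with explicit residue/instance/heavy control."""
    residues = residues if residues is not None else [10 * i + 1 for i in range(n)]
    instances = instances if instances is not None else [1] * n
    heavy = heavy if heavy is not None else [True] * n
    return tuple(
        AtomRecord(
            atom_number=i + 1,
            name="C1" if heavy[i] else "H1",
            element="C" if heavy[i] else "H",
            residue_id=residues[i],
            instance=instances[i],
            heavy=heavy[i],
        )
        for i in range(n)
    )


def make_trajectory(coords, box, step=0, **atom_kwargs):
    coords = np.asarray(coords, dtype=np.float64)
    atoms = make_atoms(len(coords), **atom_kwargs)
    return Trajectory(atoms=atoms, frames=(Frame(step=step, coords=coords),), box=box)


def compact_cloud(box, center, radius, n_atoms, seed=0):
    """A cloud of heavy atoms inside a sphere far smaller than one bin."""
    rng = np.random.default_rng(seed)
    offsets = rng.uniform(-radius, radius, size=(n_atoms, 3))
    return make_trajectory(np.asarray(center) + offsets, box)


def assert_contacts_valid(contact_set: ContactSet, criteria: ContactCriteria):
    """Every emitted contact satisfies the full predicate set's invariants."""
    seen = set()
    for c in contact_set:
        assert c.atom_a < c.atom_b
        assert c.distance <= criteria.cutoff
        if c.instance_a == c.instance_b:
            lo, hi = sorted((c.residue_a, c.residue_b))
            assert hi - lo >= criteria.min_residue_gap
        assert c.key not in seen
        seen.add(c.key)
    assert list(contact_set.keys()) == sorted(contact_set.keys())
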