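# Methods

## Problem and model

Given a trajectory of N atoms in a fixed orthorhombic periodic box, find for
each selected frame every pair of atoms satisfying a contact predicate set:
heavy (non-hydrogen) atoms, separated by at least a minimum residue gap when
they belong to the same monomer instance, at an inter-atomic distance no
greater than a cutoff. The method is the classical cell-index (cell-list)
scheme specialised to a constant-volume setting: because the box never
changes, the grid geometry and the 26-neighbor adjacency table are computed
once per system and reused for every frame, and the per-atom bin index can
be stored alongside the coordinates (in memory or in a database column) as a
precomputed spatial hash.

Assumptions:

* the box is orthorhombic; triclinic cells are out of scope;
* box dimensions are constant across frames (NVE-style trajectories);
* coordinates are finite; they need not lie inside the primary image — they
  are wrapped before binning;
* atom numbering is unique per system; residue identifiers are bare
  integers comparable only within one instance.

## Grid construction

Per axis, `count = max(1, floor(L / min_edge))` and `edge = L / count`, so
the edge is the smallest value ≥ `min_edge` that tiles the axis evenly. A
small relative guard (1e-12) bumps the count when `L` is a floating-point
near-multiple of `min_edge`; consequently, at exact multiples the edge can
sit below `min_edge` by one part in 1e12, which is inside every tolerance
used downstream. Axes shorter than `min_edge` collapse to a single cell and
are flagged degenerate. The linear bin index is `ix + nx*(iy + ny*iz)`
(x fastest); any fixed order works, this one is documented and tested. Bin
indices are kept below 2^32 − 1 so they fit a 32-bit database integer.

Cells are half-open intervals `[i*edge, (i+1)*edge)` with a clamp to
`count − 1`, which makes the assignment total: a coordinate that wraps or
divides onto the upper box face cannot produce an out-of-range cell.
Wrapping maps `x = L` (and every multiple) to 0.

## Adjacency

Neighbors are the 26 cells at offsets {−1, 0, 1}³ minus the origin, wrapped
modulo the per-axis counts (the box is periodic; every bin then has exactly
26 distinct neighbors once each axis has ≥ 3 cells). On axes with fewer than
3 cells the wrapped offsets collide and the neighbor set deduplicates —
a 2×2×2 grid yields 7 neighbors per bin, a 1×1×1 grid none. A non-periodic
mode that truncates at the walls is provided for non-wrapped point clouds;
the periodic mode is the default since wrapped adjacency is what makes
minimum-image candidate enumeration complete.

## Candidate enumeration and fallback

Within-bin pairs are emitted with the first index below the second;
cross-bin pairs only when the home bin index is below the neighbor's, so
each pair is enumerated exactly once. The spatial index is trusted only when
every axis has ≥ 3 cells of edge ≥ cutoff; otherwise (tiny boxes, or a
deliberately coarse `min_bin_edge`) the engine transparently evaluates all
pairs. This keeps the contract purely predicate-defined for every input:
small systems reduce to the naive search rather than risking missed
contacts, and pay essentially nothing for the indexing machinery.

## Distances and the cutoff boundary

Two distance modes are exposed because trajectory conventions differ:

* `minimum_image` (default): per-axis signed differences are folded into
  (−L/2, L/2] before the Euclidean norm. Self-consistent with periodic
  adjacency, and correct for solvated systems where molecules cross faces.
* `raw`: plain Euclidean distance of the stored coordinates, matching
  contact queries written directly against unwrapped solute coordinates.
  With in-box coordinates the candidate set still covers every raw-mode
  contact, since a raw distance ≤ cutoff implies per-axis differences ≤ one
  bin edge; for coordinates far outside the box, raw mode should be used
  with the brute-force engine.

The cutoff comparison is inclusive (`distance ≤ cutoff`), reading the cutoff
as an attained maximum. Comparisons are made on squared distances, and the
square root is taken only for reporting.

Both engines, and the SQL path, compute the wrapped delta as
`d − L·round(d/L)` with identical expression shape, so the three paths
produce bit-identical squared distances and therefore identical contact
sets; the only divergence is the half-integer tie `d = ±L/2`, where the two
rounding conventions pick opposite signs of the same magnitude and the
square is unaffected.

## Predicates

* `heavy_only` (default true): hydrogen is identified by the element field
  when present, else by the atom-name heuristic (strip leading digits, an
  initial `H` means hydrogen) — PDB files frequently omit the element
  columns, and names like `1HB` are hydrogens.
* `min_residue_gap` (default 2): within one instance, after ordering the two
  residues, require `residue_b − residue_a ≥ 2`; this excludes same-residue
  and adjacent-residue pairs. The exclusion is deliberately *not* applied
  across instances: residue numbering of distinct monomers is not
  comparable, so inter-monomer pairs are always distance-eligible.
* canonical output order: `atom_a < atom_b` by atom number (the reflexivity
  trim), contacts sorted by (step, atom_a, atom_b).
* `stride_modulus` (default 500): frames whose step counter is divisible by
  the modulus; 500 steps is 1 ps at the 2 fs integration steps these
  trajectories use. An `every-k-frames` alternative exists for trajectories
  whose step numbering is uninformative.

## Relational storage

Each simulation id gets `Coord_{id}` (x, y, z, atom_number, step, struct_id,
instance, bin; primary key (step, atom_number); covering index (step, bin,
atom_number)), `Box_{id}`, `Bins_{id}` and `Atoms_{id}`. Choices made where
the layout was open:

* the bins table is normalized (bin, neighbor) rows rather than one wide
  26-column row per bin, so degenerate grids with fewer than 26 neighbors
  are represented exactly;
* the covering index column list is an assumption: (step, bin, atom_number)
  serves the spatial self-join;
* `struct_id` is carried as an opaque integer and used by no predicate;
* no join-order or join-type hints: SQLite plans from the declared indexes,
  and correctness — not plan shape — is the tested contract. The query
  restricts the coordinate self-join to same-or-adjacent bins via the bins
  table (dropped for degenerate grids, mirroring the in-memory fallback).

The storage report measures per-table sizes (via SQLite's `dbstat` when
available) and the size of a canonical little-endian packed export of the
coordinate table — field order (step i64, atom_number i32, struct_id i32,
instance i32, bin u32, x f64, y f64, z f64) — raw and zlib-compressed
(level 6), reporting percent saved. This is a generic, platform-neutral
analogue of engine-specific row/page compression studies, not a
reproduction of any engine's figures.

## Synthetic data

The generator places atoms uniformly at random in the box — it emulates
system *scale* (atom count, box size, hydrogen fraction, residue blocks,
monomer instances), not physics. Defaults, chosen once: residue blocks of 8
atoms (≈ heavy atoms per amino acid), hydrogen fraction 0.5 (≈ protein
stoichiometry), one instance, Gaussian frame-to-frame displacement of 0.5 Å
per axis. What uniform placement does not reproduce: excluded volume,
bonded geometry, water structure, and density inhomogeneity (a real solvated
protein concentrates contacts in the solute). Passing tests therefore
demonstrate the *combinatorial and geometric* correctness of the search on
arbitrary point sets — which is the property that transfers to real data —
not anything about biological contact statistics. The probe-pair builder
places pairs at exact requested separations (optionally straddling a box
face so minimum-image and raw modes disagree) for boundary-condition tests.

The standard validation sweep runs 100 seeded single-frame systems of
10-2000 atoms in 20-80 Å cubic boxes (every fourth with a deliberately
coarse grid to force the fallback), both distance modes; the protein-scale
pruning fixture is 6,000 heavy atoms in a 50 Å box, the size of a large
single-domain protein system. All randomness uses NumPy's PCG64
(`default_rng`), so seeds reproduce across platforms. These sizes keep the
full validation suite under a minute while covering every code path; the
engines scale to larger systems linearly in occupied bins.

## Known limitations

* Orthorhombic boxes only; no triclinic support.
* One fixed box per trajectory; NPT trajectories with fluctuating volume
  would need per-frame grids.
* The SQL path materialises the self-join per step; it is meant as a
  correctness-equivalent relational expression of the query, not as a
  performance benchmark of any database engine.
* No contact classification (hydrogen bonds, salt bridges) — generic
  heavy-atom proximity only.
* Single-threaded; no distributed execution.
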