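"""Relational (SQLite) storage of trajectories and the declarative contact query.

Each simulation is persisted in per-simulation tables named by its integer
identifier — ``Coord_{id}`` (coordinates plus the precomputed bin index),
``Box_{id}`` (periodic box dimensions) and ``Bins_{id}`` (the bin adjacency
table) — plus an ``Atoms_{id}`` metadata table carrying the heavy flag and
residue/instance identifiers that the contact query's structural joins need,
and a small ``Sims`` registry recording the grid parameters used at load
time.

The bin adjacency is stored normalized as (bin, neighbor) rows rather than
one 26-column row per bin, so degenerate grids with fewer than 26 neighbors
are represented exactly.

``sql_contacts`` evaluates the full contact predicate set as a declarative
self-join of the coordinate table constrained by the bins table. The wrapped
per-axis deltas and the squared-distance comparison use the same expression
shape as the in-memory engine, so the two paths agree bit-for-bit.
"""

from __future__ import annotations

import math
import sqlite3
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .contacts import _grid_usable
from .grid import assign_bins, build_adjacency_table, compute_grid
from .model import Contact, ContactCriteria, ContactSet, PeriodicBox, Trajectory

__all__ = [
    "ContactStore",
    "StorageReport",
    "create_simulation_tables",
    "load_trajectory",
    "sql_contacts",
    "storage_report",
]

#: Canonical little-endian record layout of one coordinate row, used for the
#: binary export in the storage report.
EXPORT_DTYPE = np.dtype(
    [
        ("step", "<i8"),
        ("atom_number", "<i4"),
        ("struct_id", "<i4"),
        ("instance", "<i4"),
        ("bin", "<u4"),
        ("x", "<f8"),
        ("y", "<f8"),
        ("z", "<f8"),
    ]
)


class ContactStore:
    """Single-file embedded relational store (SQLite) for trajectories."""

    def __init__(self, path: str | Path = ":memory:"):
        self.path = str(path)
        self.conn = sqlite3.connect(self.path)
        self.conn.execute(
            "CREATE TABLE IF NOT EXISTS Sims ("
            " sim_id INTEGER PRIMARY KEY,"
            " min_bin_edge REAL,"
            " periodic INTEGER,"
            " nx INTEGER, ny INTEGER, nz INTEGER,"
            " loaded INTEGER NOT NULL DEFAULT 0)"
        )
        self.conn.commit()

    def close(self) -> None:
        self.conn.close()

    def __enter__(self) -> "ContactStore":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    def table_names(self, sim_id: int) -> tuple[str, str, str, str]:
        return (f"Coord_{sim_id}", f"Box_{sim_id}", f"Bins_{sim_id}", f"Atoms_{sim_id}")

    def has_simulation(self, sim_id: int) -> bool:
        row = self.conn.execute("SELECT 1 FROM Sims WHERE sim_id = ?", (sim_id,)).fetchone()
        return row is not None


@dataclass(frozen=True)
class StorageReport:
    """Table sizes plus raw-vs-compressed size of the canonical binary export."""

    sim_id: int
    table_rows: dict[str, int]
    table_bytes: dict[str, int | None]
    export_raw_bytes: int
    export_compressed_bytes: int
    codec: str = "zlib-6"

    @property
    def percent_saved(self) -> float:
        if self.export_raw_bytes == 0:
            return 0.0
        return 100.0 * (1.0 - self.export_compressed_bytes / self.export_raw_bytes)


def create_simulation_tables(store: ContactStore, sim_id: int) -> tuple[str, ...]:
    """Create the per-simulation tables; the id must be new.

    The coordinate table carries a clustered-style primary key (step,
    atom_number) and a secondary covering index over (step, bin,
    atom_number) serving the spatial join.
    """
    if sim_id <= 0:
        raise ValueError(f"simulation id must be a positive integer, got {sim_id}")
    if store.has_simulation(sim_id):
        raise ValueError(f"simulation {sim_id} already exists in this store")
    coord, box, bins, atoms = store.table_names(sim_id)
    cur = store.conn
    cur.execute(
        f"CREATE TABLE {coord} ("
        " x REAL NOT NULL, y REAL NOT NULL, z REAL NOT NULL,"
        " atom_number INTEGER NOT NULL,"
        " step INTEGER NOT NULL,"
        " struct_id INTEGER NOT NULL,"
        " instance INTEGER NOT NULL,"
        " bin INTEGER NOT NULL,"
        " PRIMARY KEY (step, atom_number))"
    )
    cur.execute(f"CREATE INDEX idx_{coord}_cover ON {coord} (step, bin, atom_number)")
    cur.execute(f"CREATE TABLE {box} (step INTEGER PRIMARY KEY, x REAL, y REAL, z REAL)")
    cur.execute(
        f"CREATE TABLE {bins} ("
        " bin INTEGER NOT NULL, neighbor INTEGER NOT NULL,"
        " PRIMARY KEY (bin, neighbor))"
    )
    cur.execute(
        f"CREATE TABLE {atoms} ("
        " atom_number INTEGER PRIMARY KEY,"
        " name TEXT, element TEXT,"
        " residue_id INTEGER NOT NULL,"
        " instance INTEGER NOT NULL,"
        " heavy INTEGER NOT NULL)"
    )
    cur.execute("INSERT INTO Sims (sim_id, loaded) VALUES (?, 0)", (sim_id,))
    store.conn.commit()
    return (coord, box, bins, atoms)


def load_trajectory(
    store: ContactStore,
    sim_id: int,
    traj: Trajectory,
    criteria: ContactCriteria,
    struct_id: int = 0,
) -> dict[str, int]:
    """Load a trajectory: coordinates with precomputed bin indices, the box
    row, atom metadata, and the full bin adjacency table.

    Returns rows written per table plus the bin count of the grid.
    """
    coord, box_t, bins_t, atoms_t = store.table_names(sim_id)
    if not store.has_simulation(sim_id):
        raise ValueError(f"simulation {sim_id} has no tables; call create_simulation_tables first")
    (n_rows,) = store.conn.execute(f"SELECT COUNT(*) FROM {coord}").fetchone()
    if n_rows:
        raise ValueError(f"simulation {sim_id} is already loaded")
    grid = compute_grid(traj.box, criteria.min_bin_edge)
    adjacency = build_adjacency_table(grid, periodic=criteria.periodic_adjacency)
    cur = store.conn
    numbers = traj.atom_numbers()
    coord_rows = 0
    for frame in traj.frames:
        bins = assign_bins(frame, grid)
        cur.executemany(
            f"INSERT INTO {coord} (x, y, z, atom_number, step, struct_id, instance, bin)"
            " VALUES (?, ?, ?, ?, ?, ?, ?, ?)",
            [
                (
                    float(frame.coords[i, 0]),
                    float(frame.coords[i, 1]),
                    float(frame.coords[i, 2]),
                    int(numbers[i]),
                    frame.step,
                    struct_id,
                    traj.atoms[i].instance,
                    int(bins[i]),
                )
                for i in range(traj.n_atoms)
            ],
        )
        coord_rows += traj.n_atoms
    cur.execute(f"INSERT INTO {box_t} (step, x, y, z) VALUES (0, ?, ?, ?)",
                (traj.box.lx, traj.box.ly, traj.box.lz))
    bin_rows = 0
    for b, neighbors in adjacency.items():
        cur.executemany(
            f"INSERT INTO {bins_t} (bin, neighbor) VALUES (?, ?)",
            [(b, nb) for nb in sorted(neighbors)],
        )
        bin_rows += len(neighbors)
    cur.executemany(
        f"INSERT INTO {atoms_t} (atom_number, name, element, residue_id, instance, heavy)"
        " VALUES (?, ?, ?, ?, ?, ?)",
        [
            (a.atom_number, a.name, a.element, a.residue_id, a.instance, int(a.heavy))
            for a in traj.atoms
        ],
    )
    cur.execute(
        "UPDATE Sims SET min_bin_edge = ?, periodic = ?, nx = ?, ny = ?, nz = ?, loaded = 1"
        " WHERE sim_id = ?",
        (criteria.min_bin_edge, int(criteria.periodic_adjacency), *grid.counts, sim_id),
    )
    store.conn.commit()
    return {
        coord: coord_rows,
        box_t: 1,
        bins_t: bin_rows,
        atoms_t: traj.n_atoms,
        "n_bins": grid.n_bins,
    }


def _load_box(store: ContactStore, sim_id: int) -> PeriodicBox:
    box_t = store.table_names(sim_id)[1]
    row = store.conn.execute(f"SELECT x, y, z FROM {box_t} LIMIT 1").fetchone()
    if row is None:
        raise ValueError(f"simulation {sim_id} is not loaded (empty box table)")
    return PeriodicBox(*row)


def sql_contacts(
    store: ContactStore,
    sim_id: int,
    criteria: ContactCriteria,
    step_window: tuple[int, int] | None = None,
) -> ContactSet:
    """Contact query evaluated declaratively inside the relational store.

    A self-join of the coordinate table within one step, restricted by the
    bins table to same-or-adjacent bins (the spatial-index join), joined to
    the atom metadata table for the heavy and residue predicates, with the
    squared-distance cutoff applied on wrapped (or raw) per-axis deltas.
    For degenerate grids the spatial restriction is omitted — the relational
    analogue of the in-memory all-pairs fallback.
    """
    if not store.has_simulation(sim_id):
        raise ValueError(f"simulation {sim_id} is not present in this store")
    coord, _box_t, bins_t, atoms_t = store.table_names(sim_id)
    box = _load_box(store, sim_id)
    grid = compute_grid(box, criteria.min_bin_edge)

    params: dict[str, float | int] = {
        "cut2": criteria.cutoff * criteria.cutoff,
        "gap": criteria.min_residue_gap,
        "lx": box.lx,
        "ly": box.ly,
        "lz": box.lz,
    }
    join_terms = ["b.step = a.step", "b.atom_number > a.atom_number"]
    if _grid_usable(grid, criteria.cutoff):
        join_terms.append(
            f"(b.bin = a.bin OR EXISTS (SELECT 1 FROM {bins_t} n"
            "  WHERE n.bin = a.bin AND n.neighbor = b.bin))"
        )
    where_terms = []
    if criteria.stride_modulus is not None:
        where_terms.append("a.step % :mod = 0")
        params["mod"] = criteria.stride_modulus
    if step_window is not None:
        where_terms.append("a.step BETWEEN :lo AND :hi")
        params["lo"], params["hi"] = step_window
    if criteria.heavy_only:
        where_terms.append("ca.heavy = 1 AND cb.heavy = 1")
    where_terms.append(
        "(ca.instance <> cb.instance OR ABS(ca.residue_id - cb.residue_id) >= :gap)"
    )
    if criteria.distance_mode == "minimum_image":
        dx = "((a.x - b.x) - :lx * ROUND((a.x - b.x) / :lx))"
        dy = "((a.y - b.y) - :ly * ROUND((a.y - b.y) / :ly))"
        dz = "((a.z - b.z) - :lz * ROUND((a.z - b.z) / :lz))"
    else:
        dx, dy, dz = "(a.x - b.x)", "(a.y - b.y)", "(a.z - b.z)"
    where = (" WHERE " + " AND ".join(where_terms)) if where_terms else ""
    query = (
        "SELECT a.step, a.atom_number, b.atom_number,"
        " ca.residue_id, cb.residue_id, ca.instance, cb.instance,"
        f" {dx}*{dx} + {dy}*{dy} + {dz}*{dz} AS d2"
        f" FROM {coord} a"
        f" JOIN {coord} b ON {' AND '.join(join_terms)}"
        f" JOIN {atoms_t} ca ON ca.atom_number = a.atom_number"
        f" JOIN {atoms_t} cb ON cb.atom_number = b.atom_number"
        f"{where}"
    )
    cut2 = params["cut2"]
    contacts = [
        Contact(
            step=int(step),
            atom_a=int(aa),
            atom_b=int(ab),
            residue_a=int(ra),
            residue_b=int(rb),
            instance_a=int(ia),
            instance_b=int(ib),
            distance=math.sqrt(d2),
        )
        for step, aa, ab, ra, rb, ia, ib, d2 in store.conn.execute(query, params)
        if d2 <= cut2
    ]
    return ContactSet(tuple(contacts))


def _table_bytes(store: ContactStore, name: str) -> int | None:
    """On-disk size of one table via the dbstat virtual table, when compiled in."""
    try:
        row = store.conn.execute(
            "SELECT SUM(pgsize) FROM dbstat WHERE name = ?", (name,)
        ).fetchone()
        return int(row[0]) if row and row[0] is not None else 0
    except sqlite3.OperationalError:
        return None


def storage_report(store: ContactStore, sim_id: int) -> StorageReport:
    """Row counts, table byte sizes, and raw-vs-zlib sizes of the canonical
    binary export of the coordinate table."""
    if not store.has_simulation(sim_id):
        raise ValueError(f"simulation {sim_id} is not present in this store")
    names = store.table_names(sim_id)
    rows = {}
    sizes = {}
    for name in names:
        (rows[name],) = store.conn.execute(f"SELECT COUNT(*) FROM {name}").fetchone()
        sizes[name] = _table_bytes(store, name)
    coord = names[0]
    data = store.conn.execute(
        f"SELECT step, atom_number, struct_id, instance, bin, x, y, z FROM {coord}"
        " ORDER BY step, atom_number"
    ).fetchall()
    packed = np.zeros(len(data), dtype=EXPORT_DTYPE)
    if data:
        cols = list(zip(*data))
        for i, field in enumerate(EXPORT_DTYPE.names):
            packed[field] = cols[i]
    raw = packed.tobytes()
    compressed = zlib.compress(raw, level=6)
    return StorageReport(
        sim_id=sim_id,
        table_rows=rows,
        table_bytes=sizes,
        export_raw_bytes=len(raw),
        export_compressed_bytes=len(compressed),
    )
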