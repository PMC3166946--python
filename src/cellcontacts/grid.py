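"""Spatial bin grid over a periodic orthorhombic box.

Implements the cell-index (spatial hashing) structure: the box is split per
axis into the largest number of equal cells whose edge is at least a minimum
length (by default the contact cutoff, 5.4 Å), cells are numbered
consecutively into a one-dimensional hash (x fastest, then y, then z), and a
precomputed adjacency table maps every bin to its 26 surrounding bins,
wrapped across the periodic faces.

With bin edges >= the cutoff, any two atoms within the cutoff are guaranteed
to sit in the same bin or in adjacent bins, so near-neighbor search only
needs to inspect 27 bins per atom.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .model import Frame, PeriodicBox

__all__ = [
    "BinGrid",
    "AdjacencyTable",
    "compute_grid",
    "wrap_coordinate",
    "bin_index",
    "adjacent_bins",
    "build_adjacency_table",
    "assign_bins",
]

#: Bin indices are stored as 32-bit integers downstream.
MAX_BINS = 2**32 - 1

#: bin -> frozenset of neighboring bin indices.
AdjacencyTable = dict[int, frozenset[int]]


@dataclass(frozen=True)
class BinGrid:
    """Per-axis cell counts and edge lengths for one periodic box.

    ``degenerate_axes`` flags axes whose box length is shorter than the
    requested minimum edge (a single cell narrower than the cutoff);
    downstream code must not rely on adjacency completeness there.
    """

    box: PeriodicBox
    counts: tuple[int, int, int]
    edges: tuple[float, float, float]
    degenerate_axes: tuple[bool, bool, bool]

    def __post_init__(self) -> None:
        lengths = (self.box.lx, self.box.ly, self.box.lz)
        for c, e, L in zip(self.counts, self.edges, lengths):
            if c < 1:
                raise ValueError(f"cell count must be >= 1, got {c}")
            if not math.isclose(c * e, L, rel_tol=1e-9):
                raise ValueError(f"edge*count = {c * e} does not reconstruct box length {L}")
        if self.n_bins > MAX_BINS:
            raise ValueError(f"{self.n_bins} bins exceeds the 2^32-1 bin-index limit")

    @property
    def n_bins(self) -> int:
        nx, ny, nz = self.counts
        return nx * ny * nz

    @property
    def degenerate(self) -> bool:
        """True when any axis has fewer than 3 cells or a sub-minimum edge."""
        return any(self.degenerate_axes) or any(c < 3 for c in self.counts)

    def cell_of(self, index: int) -> tuple[int, int, int]:
        """Invert the linearization: index -> (ix, iy, iz)."""
        nx, ny, _ = self.counts
        ix = index % nx
        iy = (index // nx) % ny
        iz = index // (nx * ny)
        return ix, iy, iz

    def linear(self, ix: int, iy: int, iz: int) -> int:
        nx, ny, _ = self.counts
        return ix + nx * (iy + ny * iz)


def compute_grid(box: PeriodicBox, min_edge: float) -> BinGrid:
    """Split ``box`` into the most cells per axis with edge >= ``min_edge``.

    Per axis: ``count = max(1, floor(L / min_edge))`` and ``edge = L / count``,
    so ``edge >= min_edge`` whenever ``L >= min_edge``. Axes shorter than
    ``min_edge`` collapse to a single sub-minimum cell and are flagged
    degenerate.
    """
    if not (math.isfinite(min_edge) and min_edge > 0):
        raise ValueError(f"min_edge must be positive and finite, got {min_edge}")
    counts: list[int] = []
    edges: list[float] = []
    degenerate: list[bool] = []
    for L in (box.lx, box.ly, box.lz):
        c = int(math.floor(L / min_edge))
        # guard floating error at exact multiples, e.g. L = k * min_edge
        while (c + 1) * min_edge <= L * (1 + 1e-12):
            c += 1
        while c > 1 and c * min_edge > L * (1 + 1e-12):
            c -= 1
        c = max(1, c)
        counts.append(c)
        edges.append(L / c)
        degenerate.append(L / c < min_edge * (1 - 1e-12))
    return BinGrid(box=box, counts=tuple(counts), edges=tuple(edges), degenerate_axes=tuple(degenerate))


def wrap_coordinate(x: float, length: float) -> float:
    """Wrap a coordinate into the primary image [0, L).

    ``x`` exactly equal to ``L`` (or any multiple) maps to 0.
    """
    if not (math.isfinite(length) and length > 0):
        raise ValueError(f"box length must be positive, got {length}")
    if not math.isfinite(x):
        raise ValueError(f"coordinate must be finite, got {x}")
    r = x % length
    if r >= length:  # float mod can round up to L for tiny negative x
        r -= length
    return r


def _wrap_array(coords: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    wrapped = np.mod(coords, lengths)
    np.subtract(wrapped, lengths, out=wrapped, where=wrapped >= lengths)
    return wrapped


def _bins_for_coords(coords: np.ndarray, grid: BinGrid) -> np.ndarray:
    """Vectorized bin assignment for an (n, 3) coordinate array."""
    coords = np.asarray(coords, dtype=np.float64)
    if coords.size and not np.isfinite(coords).all():
        bad = int(np.flatnonzero(~np.isfinite(coords).all(axis=1))[0])
        raise ValueError(f"non-finite coordinate at atom position {bad}")
    lengths = grid.box.lengths
    counts = np.array(grid.counts, dtype=np.int64)
    edges = np.array(grid.edges, dtype=np.float64)
    wrapped = _wrap_array(coords, lengths)
    cells = np.floor(wrapped / edges).astype(np.int64)
    np.clip(cells, 0, counts - 1, out=cells)  # guard x/edge rounding at the upper face
    nx, ny, _ = grid.counts
    return cells[:, 0] + nx * (cells[:, 1] + ny * cells[:, 2])


def bin_index(point: tuple[float, float, float], grid: BinGrid) -> int:
    """Linear bin index of one point (wrapping into the box first).

    Cells are half-open intervals ``[i*edge, (i+1)*edge)`` per axis with a
    clamp to ``count - 1`` guarding floating-point edge cases at the upper
    box face; linearization is x fastest, then y, then z.
    """
    arr = np.asarray(point, dtype=np.float64).reshape(1, 3)
    return int(_bins_for_coords(arr, grid)[0])


def adjacent_bins(index: int, grid: BinGrid, periodic: bool = True) -> frozenset[int]:
    """The set of bins at cell offsets {-1, 0, 1}^3 (minus the home cell).

    Offsets wrap modulo the per-axis counts when ``periodic``; otherwise
    neighbors beyond a wall are dropped. Wrapping duplicates on axes with
    fewer than 3 cells collapse, so degenerate grids yield fewer than 26
    neighbors; the home bin itself is never included.
    """
    if not (0 <= index < grid.n_bins):
        raise ValueError(f"bin index {index} out of range [0, {grid.n_bins})")
    ix, iy, iz = grid.cell_of(index)
    counts = grid.counts
    out: set[int] = set()
    for dx, dy, dz in itertools.product((-1, 0, 1), repeat=3):
        if dx == dy == dz == 0:
            continue
        cell = []
        ok = True
        for i, d, n in ((ix, dx, counts[0]), (iy, dy, counts[1]), (iz, dz, counts[2])):
            j = i + d
            if periodic:
                j %= n
            elif not (0 <= j < n):
                ok = False
                break
            cell.append(j)
        if ok:
            out.add(grid.linear(*cell))
    out.discard(index)
    return frozenset(out)


def build_adjacency_table(grid: BinGrid, periodic: bool = True) -> AdjacencyTable:
    """Precompute the neighbor sets for every bin of the grid."""
    return {b: adjacent_bins(b, grid, periodic=periodic) for b in range(grid.n_bins)}


def assign_bins(frame: Frame, grid: BinGrid) -> np.ndarray:
    """Bin index for every atom of a frame (one index per coordinate row)."""
    try:
        return _bins_for_coords(frame.coords, grid)
    except ValueError as exc:
        raise ValueError(f"frame {frame.step}: {exc}") from exc
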