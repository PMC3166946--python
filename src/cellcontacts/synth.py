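"""Seeded synthetic systems and trajectories.

Stands in for real solvated-protein trajectories so every engine is testable
without external structure downloads: atoms are placed uniformly at random
in the periodic box (no water-like packing or force field), residues are
assigned in fixed-size blocks per monomer instance, and frames evolve by
independent Gaussian displacements wrapped back into the box.

All randomness flows through ``numpy.random.default_rng`` (the PCG64
generator), so a given seed reproduces the same system on any platform.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from .grid import _wrap_array
from .model import AtomRecord, Frame, PeriodicBox, Trajectory

__all__ = [
    "random_system",
    "random_trajectory",
    "probe_pair_system",
    "validation_sweep",
]

#: ~ heavy atoms per amino-acid residue.
DEFAULT_RESIDUE_SIZE = 8
#: roughly half the atoms of a protein are hydrogens.
DEFAULT_HYDROGEN_FRACTION = 0.5
#: r.m.s. per-axis displacement (Å) between consecutive stored frames.
DEFAULT_DISPLACEMENT = 0.5


def random_system(
    n_atoms: int,
    box: PeriodicBox,
    residue_size: int = DEFAULT_RESIDUE_SIZE,
    hydrogen_fraction: float = DEFAULT_HYDROGEN_FRACTION,
    n_instances: int = 1,
    seed: int = 0,
) -> Trajectory:
    """Uniform random single-frame system.

    Atoms are split into ``n_instances`` consecutive equal blocks (monomers);
    within each instance residue numbering restarts at 1 and advances every
    ``residue_size`` atoms. Hydrogen flags are independent draws at
    ``hydrogen_fraction``.
    """
    if n_atoms < 0:
        raise ValueError(f"n_atoms must be >= 0, got {n_atoms}")
    if residue_size < 1:
        raise ValueError(f"residue_size must be >= 1, got {residue_size}")
    if n_instances < 1:
        raise ValueError(f"n_instances must be >= 1, got {n_instances}")
    if not (0.0 <= hydrogen_fraction <= 1.0):
        raise ValueError(f"hydrogen_fraction must be in [0, 1], got {hydrogen_fraction}")
    rng = np.random.default_rng(seed)
    coords = rng.uniform(0.0, 1.0, size=(n_atoms, 3)) * box.lengths
    is_h = rng.random(n_atoms) < hydrogen_fraction
    per_instance = math.ceil(n_atoms / n_instances) if n_atoms else 0
    atoms = []
    for i in range(n_atoms):
        inst = i // per_instance if per_instance else 0
        within = i - inst * per_instance
        element = "H" if is_h[i] else "C"
        atoms.append(
            AtomRecord(
                atom_number=i + 1,
                name=f"{element}{within % residue_size + 1}",
                element=element,
                residue_id=within // residue_size + 1,
                instance=inst + 1,
                heavy=not is_h[i],
            )
        )
    return Trajectory(
        atoms=tuple(atoms),
        frames=(Frame(step=0, coords=coords),),
        box=box,
    )


def random_trajectory(
    system: Trajectory,
    n_frames: int,
    step_stride: int = 500,
    displacement_scale: float = DEFAULT_DISPLACEMENT,
    seed: int = 0,
) -> Trajectory:
    """Random-walk trajectory grown from a single-frame base system.

    Frames are stored at steps ``step_stride, 2*step_stride, ...``; each
    frame adds seeded isotropic Gaussian displacements to the previous one
    and wraps the result into the box.
    """
    if n_frames < 1:
        raise ValueError(f"n_frames must be >= 1, got {n_frames}")
    if step_stride < 1:
        raise ValueError(f"step_stride must be >= 1, got {step_stride}")
    if displacement_scale < 0:
        raise ValueError(f"displacement_scale must be >= 0, got {displacement_scale}")
    rng = np.random.default_rng(seed)
    lengths = system.box.lengths
    current = system.frames[0].coords.copy()
    frames = []
    for k in range(1, n_frames + 1):
        if displacement_scale > 0:
            current = _wrap_array(
                current + rng.normal(0.0, displacement_scale, size=current.shape), lengths
            )
        frames.append(Frame(step=k * step_stride, coords=current.copy()))
    return Trajectory(atoms=system.atoms, frames=tuple(frames), box=system.box)


def validation_sweep(
    seed: int,
    n_systems: int = 100,
    n_range: tuple[int, int] = (10, 2000),
    box_range: tuple[float, float] = (20.0, 80.0),
):
    """Standard conditions for validating the indexed engine against the oracle.

    Yields ``(trajectory, criteria)`` pairs: single-frame uniform systems of
    10-2000 atoms in cubic boxes of 20-80 Å (by default), hydrogen fractions
    0-0.6, one to three instances, alternating minimum-image and raw distance
    modes. Every fourth system widens the minimum bin edge to nearly half the
    box so the grid degenerates (fewer than 3 cells per axis) and the
    all-pairs fallback is exercised.
    """
    from .model import ContactCriteria

    rng = np.random.default_rng(seed)
    for k in range(n_systems):
        n = int(rng.integers(n_range[0], n_range[1] + 1))
        L = float(rng.uniform(*box_range))
        hf = float(rng.uniform(0.0, 0.6))
        inst = int(rng.integers(1, 4))
        system_seed = int(rng.integers(0, 2**31 - 1))
        traj = random_system(
            n,
            PeriodicBox(L, L, L),
            hydrogen_fraction=hf,
            n_instances=inst,
            seed=system_seed,
        )
        criteria = ContactCriteria(
            min_bin_edge=L / 2.2 if k % 4 == 3 else None,
            stride_modulus=None,
            distance_mode="minimum_image" if k % 2 == 0 else "raw",
        )
        yield traj, criteria


def probe_pair_system(
    distances: Sequence[float],
    box: PeriodicBox,
    across_boundary: bool = False,
) -> Trajectory:
    """Heavy-atom pairs at exactly the requested separations (one frame).

    Pair ``k`` sits on its own y-lane; within a pair the atoms are separated
    along x by the requested distance and carry residues 4 apart in one
    instance, so only the distance predicate decides whether the pair is a
    contact. With ``across_boundary`` the pair straddles the x = 0 face:
    the minimum-image separation equals the request while the raw separation
    is ``lx - distance``.
    """
    half_min = box.min_length / 2.0
    for d in distances:
        if not (0 < d < half_min):
            raise ValueError(
                f"probe distance {d} must be in (0, min(box)/2 = {half_min})"
            )
    n = len(distances)
    if n == 0:
        return Trajectory(atoms=(), frames=(Frame(step=0, coords=np.empty((0, 3))),), box=box)
    lane = box.ly / n
    if n > 1 and lane <= 2.0 * max(distances):
        raise ValueError(f"{n} probe pairs do not fit in a {box.ly} Å box without interacting")
    atoms = []
    rows = []
    for k, d in enumerate(distances):
        y = (k + 0.5) * lane
        z = box.lz / 2.0
        if across_boundary:
            xa, xb = box.lx - d / 2.0, d / 2.0
        else:
            xa, xb = box.lx / 4.0, box.lx / 4.0 + d
        for i, x in enumerate((xa, xb)):
            atoms.append(
                AtomRecord(
                    atom_number=2 * k + i + 1,
                    name="C1",
                    element="C",
                    residue_id=10 * k + 1 + 4 * i,
                    instance=1,
                    heavy=True,
                )
            )
            rows.append((x, y, z))
    return Trajectory(
        atoms=tuple(atoms),
        frames=(Frame(step=0, coords=np.array(rows, dtype=np.float64)),),
        box=box,
    )
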