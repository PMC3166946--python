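"""Domain types for periodic-box contact analysis.

The types here are deliberately algorithm-free: a fixed orthorhombic
periodic box (NVE ensemble, constant volume), static per-atom metadata,
time-ordered coordinate frames, and the contact-filter criteria applied
by the search engines in :mod:`cellcontacts.contacts`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "PeriodicBox",
    "AtomRecord",
    "Frame",
    "Trajectory",
    "ContactCriteria",
    "Contact",
    "ContactSet",
    "is_hydrogen_name",
    "DISTANCE_MODES",
]

DISTANCE_MODES = ("minimum_image", "raw")

#: Default contact cutoff in Å — the maximum distance at which a pair of
#: heavy atoms is considered to be in contact.
DEFAULT_CUTOFF = 5.4

#: Default step stride: simulations advance 500 integration steps per
#: picosecond, so ``step % 500 == 0`` selects frames at 1 ps granularity.
DEFAULT_STRIDE_MODULUS = 500


def is_hydrogen_name(name: str) -> bool:
    """Heuristic hydrogen test for atom names lacking an element column.

    Strips leading digits (PDB names like ``1HB``) and tests whether the
    first alphabetic character is ``H``.
    """
    stripped = name.strip().lstrip("0123456789")
    return bool(stripped) and stripped[0].upper() == "H"


@dataclass(frozen=True)
class PeriodicBox:
    """Orthorhombic periodic box with fixed edge lengths in Å.

    The box is constant across all frames of a trajectory (NVE ensemble:
    fixed volume).
    """

    lx: float
    ly: float
    lz: float

    def __post_init__(self) -> None:
        for label, value in (("lx", self.lx), ("ly", self.ly), ("lz", self.lz)):
            if not (isinstance(value, (int, float)) and math.isfinite(value) and value > 0):
                raise ValueError(f"box length {label} must be positive and finite, got {value!r}")

    @property
    def lengths(self) -> np.ndarray:
        """Edge lengths as a float64 array ``[lx, ly, lz]``."""
        return np.array([self.lx, self.ly, self.lz], dtype=np.float64)

    @property
    def min_length(self) -> float:
        return min(self.lx, self.ly, self.lz)


@dataclass(frozen=True)
class AtomRecord:
    """Static metadata for one atom of the system.

    ``instance`` identifies the monomer within a multimeric system;
    ``residue_id`` is a bare integer with no chain semantics attached.
    ``heavy`` must be consistent with ``element`` when the element is known:
    every non-hydrogen atom is heavy.
    """

    atom_number: int
    name: str
    element: str
    residue_id: int
    instance: int
    heavy: bool

    def __post_init__(self) -> None:
        if self.atom_number <= 0:
            raise ValueError(f"atom_number must be positive, got {self.atom_number}")
        el = self.element.strip()
        if el:
            expected = el.upper() != "H"
            if self.heavy != expected:
                raise ValueError(
                    f"atom {self.atom_number}: heavy={self.heavy} inconsistent "
                    f"with element {el!r}"
                )


@dataclass(frozen=True)
class Frame:
    """One time point of a trajectory: a step counter and (n, 3) coordinates in Å."""

    step: int
    coords: np.ndarray

    def __post_init__(self) -> None:
        if self.step < 0:
            raise ValueError(f"step must be non-negative, got {self.step}")
        coords = np.asarray(self.coords, dtype=np.float64)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError(f"coords must have shape (n, 3), got {coords.shape}")
        if coords.size and not np.isfinite(coords).all():
            raise ValueError(f"frame {self.step}: non-finite coordinates")
        object.__setattr__(self, "coords", coords)

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]


@dataclass(frozen=True)
class Trajectory:
    """Atom metadata plus an ordered list of coordinate frames in one fixed box."""

    atoms: tuple[AtomRecord, ...]
    frames: tuple[Frame, ...]
    box: PeriodicBox

    def __post_init__(self) -> None:
        atoms = tuple(self.atoms)
        frames = tuple(self.frames)
        object.__setattr__(self, "atoms", atoms)
        object.__setattr__(self, "frames", frames)
        numbers = [a.atom_number for a in atoms]
        if len(set(numbers)) != len(numbers):
            raise ValueError("atom_number values must be unique within a system")
        steps = [f.step for f in frames]
        if any(b <= a for a, b in zip(steps, steps[1:])):
            raise ValueError(f"frame steps must be strictly increasing, got {steps}")
        for f in frames:
            if f.n_atoms != len(atoms):
                raise ValueError(
                    f"frame {f.step} has {f.n_atoms} coordinates for {len(atoms)} atoms"
                )

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def steps(self) -> list[int]:
        return [f.step for f in self.frames]

    # Cached-per-call array views of atom metadata, used by the engines.
    def atom_numbers(self) -> np.ndarray:
        return np.array([a.atom_number for a in self.atoms], dtype=np.int64)

    def heavy_mask(self) -> np.ndarray:
        return np.array([a.heavy for a in self.atoms], dtype=bool)

    def residue_ids(self) -> np.ndarray:
        return np.array([a.residue_id for a in self.atoms], dtype=np.int64)

    def instances(self) -> np.ndarray:
        return np.array([a.instance for a in self.atoms], dtype=np.int64)


@dataclass(frozen=True)
class ContactCriteria:
    """The contact-filter predicate set.

    Parameters
    ----------
    cutoff:
        Maximum inter-atomic distance (Å) for a contact; the comparison is
        inclusive (``distance <= cutoff``). Default 5.4 Å.
    min_bin_edge:
        Minimum spatial-bin edge length (Å); must be >= cutoff so a bin and
        its 26 neighbors cover the cutoff sphere. Defaults to the cutoff.
    heavy_only:
        Consider only non-hydrogen atoms (default True).
    min_residue_gap:
        Within one instance, require ``residue_b - residue_a >= gap`` after
        ordering residues. The default of 2 excludes same-residue and
        adjacent-residue pairs, which are through-bond or uninformative.
    stride_modulus:
        Select frames whose step counter is divisible by this value
        (default 500: 1 ps granularity at 500 steps/ps). ``None`` selects
        every frame.
    distance_mode:
        ``"minimum_image"`` wraps per-axis differences into (-L/2, L/2];
        ``"raw"`` uses plain Euclidean distance of the stored coordinates.
    periodic_adjacency:
        Whether bin adjacency wraps across the periodic faces (default True).
    """

    cutoff: float = DEFAULT_CUTOFF
    min_bin_edge: float | None = None
    heavy_only: bool = True
    min_residue_gap: int = 2
    stride_modulus: int | None = DEFAULT_STRIDE_MODULUS
    distance_mode: str = "minimum_image"
    periodic_adjacency: bool = True

    def __post_init__(self) -> None:
        if not (math.isfinite(self.cutoff) and self.cutoff > 0):
            raise ValueError(f"cutoff must be positive, got {self.cutoff}")
        if self.min_bin_edge is None:
            object.__setattr__(self, "min_bin_edge", float(self.cutoff))
        if self.min_bin_edge < self.cutoff:
            raise ValueError(
                f"min_bin_edge ({self.min_bin_edge}) must be >= cutoff ({self.cutoff})"
            )
        if self.min_residue_gap < 0:
            raise ValueError(f"min_residue_gap must be >= 0, got {self.min_residue_gap}")
        if self.stride_modulus is not None and self.stride_modulus < 1:
            raise ValueError(f"stride_modulus must be >= 1, got {self.stride_modulus}")
        if self.distance_mode not in DISTANCE_MODES:
            raise ValueError(
                f"distance_mode must be one of {DISTANCE_MODES}, got {self.distance_mode!r}"
            )


@dataclass(frozen=True, slots=True)
class Contact:
    """One detected contact, canonically ordered so atom_a < atom_b.

    residue/instance fields are reported in the order induced by the atoms.
    """

    step: int
    atom_a: int
    atom_b: int
    residue_a: int
    residue_b: int
    instance_a: int
    instance_b: int
    distance: float

    def __post_init__(self) -> None:
        if self.atom_a >= self.atom_b:
            raise ValueError(
                f"contact atoms must satisfy atom_a < atom_b, got {self.atom_a}, {self.atom_b}"
            )
        if not (math.isfinite(self.distance) and self.distance >= 0):
            raise ValueError(f"contact distance must be finite and >= 0, got {self.distance}")

    @property
    def key(self) -> tuple[int, int, int]:
        return (self.step, self.atom_a, self.atom_b)


@dataclass(frozen=True)
class ContactSet:
    """Deduplicated, deterministically ordered collection of contacts.

    Ordering is by (step, atom_a, atom_b); duplicate keys are rejected.
    """

    contacts: tuple[Contact, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        ordered = tuple(sorted(self.contacts, key=lambda c: c.key))
        keys = [c.key for c in ordered]
        if len(set(keys)) != len(keys):
            seen: set[tuple[int, int, int]] = set()
            dup = next(k for k in keys if k in seen or seen.add(k))  # type: ignore[func-returns-value]
            raise ValueError(f"duplicate contact key {dup}")
        object.__setattr__(self, "contacts", ordered)

    def __len__(self) -> int:
        return len(self.contacts)

    def __iter__(self) -> Iterator[Contact]:
        return iter(self.contacts)

    def keys(self) -> list[tuple[int, int, int]]:
        return [c.key for c in self.contacts]

    def equivalent(self, other: "ContactSet", distance_tol: float = 1e-9) -> bool:
        """True when both sets hold the same (step, atom_a, atom_b) keys with
        all per-contact fields equal and distances within ``distance_tol``."""
        if len(self) != len(other):
            return False
        for a, b in zip(self.contacts, other.contacts):
            if a.key != b.key:
                return False
            if (a.residue_a, a.residue_b, a.instance_a, a.instance_b) != (
                b.residue_a,
                b.residue_b,
                b.instance_a,
                b.instance_b,
            ):
                return False
            if abs(a.distance - b.distance) > distance_tol:
                return False
        return True

    def symmetric_difference_keys(self, other: "ContactSet") -> list[tuple[int, int, int]]:
        return sorted(set(self.keys()) ^ set(other.keys()))

    def to_dataframe(self):
        """Contacts as a pandas DataFrame in canonical order."""
        import pandas as pd

        return pd.DataFrame(
            {
                "step": [c.step for c in self.contacts],
                "atom_a": [c.atom_a for c in self.contacts],
                "atom_b": [c.atom_b for c in self.contacts],
                "residue_a": [c.residue_a for c in self.contacts],
                "residue_b": [c.residue_b for c in self.contacts],
                "instance_a": [c.instance_a for c in self.contacts],
                "instance_b": [c.instance_b for c in self.contacts],
                "distance": [c.distance for c in self.contacts],
            }
        )
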