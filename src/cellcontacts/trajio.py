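"""Trajectory and contact I/O.

Readers produce fully validated :class:`~cellcontacts.model.Trajectory`
objects or fail loudly; nothing is silently coerced.

Formats:

* PDB (read): ATOM/HETATM fixed columns; multiple MODEL blocks become
  frames; CRYST1 a/b/c become the box.
* Internal tabular trajectory (read/write): three CSV files — atom metadata,
  per-frame coordinate rows, and the box — mirroring the relational
  coordinate/box table layout.
* Contacts (read/write): one CSV with canonical column order.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .model import AtomRecord, Contact, ContactSet, Frame, PeriodicBox, Trajectory, is_hydrogen_name

__all__ = [
    "read_pdb",
    "read_table_trajectory",
    "write_table_trajectory",
    "write_contacts",
    "read_contacts",
]

#: Synthetic step assigned to MODEL ordinal m (0-based) is ``m * PDB_MODEL_STRIDE``,
#: mirroring 500 integration steps per stored picosecond.
PDB_MODEL_STRIDE = 500

#: Padding (Å) added per axis when a PDB lacks CRYST1 and the box must be
#: inferred from the coordinate extent.
BOX_PADDING = 10.0

ATOMS_COLUMNS = ["atom_number", "name", "element", "residue_id", "instance", "heavy"]
COORDS_COLUMNS = ["step", "atom_number", "x", "y", "z"]
BOX_COLUMNS = ["lx", "ly", "lz"]
CONTACT_COLUMNS = [
    "step",
    "atom_a",
    "atom_b",
    "residue_a",
    "residue_b",
    "instance_a",
    "instance_b",
    "distance",
]


def _pdb_atom_line(line: str) -> tuple[str, str, int, float, float, float, str]:
    """(name, chain, resseq, x, y, z, element) from one ATOM/HETATM record."""
    name = line[12:16]
    chain = line[21] if len(line) > 21 else " "
    resseq = int(line[22:26])
    x = float(line[30:38])
    y = float(line[38:46])
    z = float(line[46:54])
    element = line[76:78].strip() if len(line) >= 77 else ""
    return name, chain, resseq, x, y, z, element


def read_pdb(path: str | Path) -> Trajectory:
    """Read a (possibly multi-MODEL) PDB file as a trajectory.

    MODEL blocks become frames at synthetic steps ``ordinal * 500``; CRYST1
    a/b/c define the box. The element is taken from columns 77-78 when
    present, otherwise inferred from the atom name (leading digits stripped,
    initial ``H`` means hydrogen). Chain IDs map to instances in order of
    first appearance (A -> 1, B -> 2, ...). Without CRYST1 the box is
    inferred from the coordinate extent plus padding, with a warning.
    """
    path = Path(path)
    box: PeriodicBox | None = None
    models: list[list[tuple]] = []
    current: list[tuple] = []
    in_model = False
    serials: list[int] = []
    with path.open() as fh:
        for line in fh:
            rec = line[:6]
            if rec == "CRYST1":
                box = PeriodicBox(float(line[6:15]), float(line[15:24]), float(line[24:33]))
            elif rec == "MODEL ":
                if in_model and current:
                    models.append(current)
                current = []
                in_model = True
            elif rec == "ENDMDL":
                models.append(current)
                current = []
                in_model = False
            elif rec in ("ATOM  ", "HETATM"):
                current.append(_pdb_atom_line(line))
                if not models:  # atom serials of the first model only
                    try:
                        serials.append(int(line[6:11]))
                    except ValueError:
                        serials.append(-1)
    if current:
        models.append(current)
    models = [m for m in models if m]
    if not models:
        raise ValueError(f"{path}: no ATOM/HETATM records")
    n = len(models[0])
    for m, model in enumerate(models):
        if len(model) != n:
            raise ValueError(
                f"{path}: MODEL {m + 1} has {len(model)} atoms, expected {n}"
            )

    chain_map: dict[str, int] = {}
    atoms: list[AtomRecord] = []
    use_serials = len(set(serials)) == n and all(s > 0 for s in serials)
    if not use_serials and serials:
        warnings.warn(f"{path}: atom serials unusable; renumbering 1..{n}", stacklevel=2)
    for i, (name, chain, resseq, _x, _y, _z, element) in enumerate(models[0]):
        if chain not in chain_map:
            chain_map[chain] = len(chain_map) + 1
        hydrogen = element.upper() == "H" if element else is_hydrogen_name(name)
        atoms.append(
            AtomRecord(
                atom_number=serials[i] if use_serials else i + 1,
                name=name.strip(),
                element=element,
                residue_id=resseq,
                instance=chain_map[chain],
                heavy=not hydrogen,
            )
        )
    frames = tuple(
        Frame(
            step=m * PDB_MODEL_STRIDE,
            coords=np.array([(x, y, z) for _, _, _, x, y, z, _ in model], dtype=np.float64),
        )
        for m, model in enumerate(models)
    )
    if box is None:
        extent = frames[0].coords.max(axis=0) - frames[0].coords.min(axis=0)
        box = PeriodicBox(*(extent + 2 * BOX_PADDING))
        warnings.warn(
            f"{path}: no CRYST1 record; inferred box "
            f"({box.lx:.1f}, {box.ly:.1f}, {box.lz:.1f}) Å from coordinate extent",
            stacklevel=2,
        )
    return Trajectory(atoms=tuple(atoms), frames=frames, box=box)


def _require_columns(df: pd.DataFrame, columns: Sequence[str], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")


def read_table_trajectory(
    atoms_path: str | Path, coords_path: str | Path, box_path: str | Path
) -> Trajectory:
    """Read the internal three-file tabular trajectory format.

    ``atoms``: atom_number, name, element, residue_id, instance, heavy;
    ``coords``: step, atom_number, x, y, z (one row per atom per frame);
    ``box``: lx, ly, lz (single mandatory row). Coordinates are parsed in
    round-trip float precision, so write -> read is bit-exact.
    """
    atoms_df = pd.read_csv(atoms_path, dtype={"name": str, "element": str}, keep_default_na=False)
    _require_columns(atoms_df, ATOMS_COLUMNS, atoms_path)
    coords_df = pd.read_csv(coords_path, float_precision="round_trip")
    _require_columns(coords_df, COORDS_COLUMNS, coords_path)
    box_df = pd.read_csv(box_path, float_precision="round_trip")
    _require_columns(box_df, BOX_COLUMNS, box_path)
    if len(box_df) == 0:
        raise ValueError(f"{box_path}: box row is mandatory")
    box = PeriodicBox(*(float(box_df.iloc[0][c]) for c in BOX_COLUMNS))

    atoms = tuple(
        AtomRecord(
            atom_number=int(r.atom_number),
            name=str(r.name_),
            element=str(r.element),
            residue_id=int(r.residue_id),
            instance=int(r.instance),
            heavy=bool(r.heavy),
        )
        for r in atoms_df.rename(columns={"name": "name_"}).itertuples(index=False)
    )
    known = {a.atom_number for a in atoms}
    unknown = set(coords_df["atom_number"].unique()) - known
    if unknown:
        raise ValueError(
            f"{coords_path}: coordinate rows reference unknown atom_number(s) {sorted(unknown)[:5]}"
        )
    order = {a.atom_number: i for i, a in enumerate(atoms)}
    frames = []
    for step, grp in coords_df.groupby("step", sort=True):
        if len(grp) != len(atoms) or set(grp["atom_number"]) != known:
            raise ValueError(f"{coords_path}: step {step} does not cover every atom exactly once")
        coords = np.empty((len(atoms), 3), dtype=np.float64)
        rows = grp["atom_number"].map(order).to_numpy()
        coords[rows] = grp[["x", "y", "z"]].to_numpy(dtype=np.float64)
        frames.append(Frame(step=int(step), coords=coords))
    return Trajectory(atoms=atoms, frames=tuple(frames), box=box)


def write_table_trajectory(
    traj: Trajectory,
    atoms_path: str | Path,
    coords_path: str | Path,
    box_path: str | Path,
) -> None:
    """Write the three-file tabular format (see :func:`read_table_trajectory`)."""
    pd.DataFrame(
        {
            "atom_number": [a.atom_number for a in traj.atoms],
            "name": [a.name for a in traj.atoms],
            "element": [a.element for a in traj.atoms],
            "residue_id": [a.residue_id for a in traj.atoms],
            "instance": [a.instance for a in traj.atoms],
            "heavy": [a.heavy for a in traj.atoms],
        }
    ).to_csv(atoms_path, index=False)
    numbers = traj.atom_numbers()
    parts = [
        pd.DataFrame(
            {
                "step": f.step,
                "atom_number": numbers,
                "x": f.coords[:, 0],
                "y": f.coords[:, 1],
                "z": f.coords[:, 2],
            }
        )
        for f in traj.frames
    ]
    frame_df = (
        pd.concat(parts, ignore_index=True)
        if parts
        else pd.DataFrame(columns=COORDS_COLUMNS)
    )
    frame_df.to_csv(coords_path, index=False)
    pd.DataFrame({"lx": [traj.box.lx], "ly": [traj.box.ly], "lz": [traj.box.lz]}).to_csv(
        box_path, index=False
    )


def write_contacts(contacts: ContactSet, path: str | Path) -> int:
    """Write a contact set as CSV (distance to 3 decimals); returns row count."""
    df = contacts.to_dataframe()
    if df.empty:
        df = pd.DataFrame(columns=CONTACT_COLUMNS)
    df.to_csv(path, index=False, float_format="%.3f")
    return len(df)


def read_contacts(path: str | Path) -> ContactSet:
    """Re-read a contacts CSV written by :func:`write_contacts`."""
    df = pd.read_csv(path)
    _require_columns(df, CONTACT_COLUMNS, path)
    return ContactSet(
        tuple(
            Contact(
                step=int(r.step),
                atom_a=int(r.atom_a),
                atom_b=int(r.atom_b),
                residue_a=int(r.residue_a),
                residue_b=int(r.residue_b),
                instance_a=int(r.instance_a),
                instance_b=int(r.instance_b),
                distance=float(r.distance),
            )
            for r in df.itertuples(index=False)
        )
    )
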