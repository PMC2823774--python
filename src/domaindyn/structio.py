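"""Structures, trajectories, atom selections and optimal superposition.

The in-memory model is deliberately small: a :class:`Structure` is a set of
parallel numpy arrays over atoms (names, residues, chains, coordinates,
masses) and a :class:`Trajectory` is a reference structure plus a stack of
coordinate frames.  PDB files are read by fixed columns (v3.3 layout), with
alternate locations resolved to the highest-occupancy conformer (ties keep
the first encountered) so parsing is deterministic on real crystal files.
Hydrogens absent from the input are never added; masses come from a built-in
element table.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import (
    AlignmentError,
    EmptyInputError,
    GeometryError,
    GroupDefinitionError,
    InputError,
    ParseError,
    SelectionError,
)

__all__ = [
    "Structure",
    "Trajectory",
    "SegmentDef",
    "AtomGroup",
    "ATOMIC_MASSES",
    "read_pdb",
    "write_pdb",
    "select",
    "named_group",
    "superpose",
    "apply_transform",
]

# Standard atomic weights (amu), heavy elements found in protein crystal
# files plus hydrogen for completeness.
ATOMIC_MASSES = {
    "H": 1.008, "D": 2.014, "C": 12.011, "N": 14.007, "O": 15.999,
    "P": 30.974, "S": 32.06, "F": 18.998, "NA": 22.990, "MG": 24.305,
    "CL": 35.45, "K": 39.098, "CA": 40.078, "MN": 54.938, "FE": 55.845,
    "CO": 58.933, "NI": 58.693, "CU": 63.546, "ZN": 65.38, "SE": 78.971,
    "BR": 79.904, "I": 126.904,
}

BACKBONE_NAMES = ("N", "CA", "C", "O")

# Six carbons of the tryptophan indole six-membered ring.
TRP_RING6 = ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2")


@dataclass
class Structure:
    """An ordered, indexable set of atoms with coordinates in Å."""

    names: np.ndarray          # atom names, str
    elements: np.ndarray       # element symbols, upper case, str
    resids: np.ndarray         # residue numbers, int
    resnames: np.ndarray       # residue names, str
    chains: np.ndarray         # chain identifiers, str
    coords: np.ndarray         # (n_atoms, 3) float, Å
    masses: np.ndarray         # (n_atoms,) float, amu
    hetero: np.ndarray = None  # bool, True for HETATM records
    title: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.hetero is None:
            self.hetero = np.zeros(len(self.names), dtype=bool)
        if not np.all(np.isfinite(self.coords)):
            raise ParseError("non-finite coordinates in structure")
        if np.any(np.asarray(self.masses) <= 0):
            raise ParseError("every atom must have positive mass")

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    def copy(self) -> "Structure":
        return Structure(
            names=self.names.copy(), elements=self.elements.copy(),
            resids=self.resids.copy(), resnames=self.resnames.copy(),
            chains=self.chains.copy(), coords=self.coords.copy(),
            masses=self.masses.copy(), hetero=self.hetero.copy(),
            title=self.title, meta=dict(self.meta),
        )

    def take(self, indices: Sequence[int]) -> "Structure":
        """Sub-structure over the given atom indices (order preserved)."""
        idx = np.asarray(indices, dtype=int)
        return Structure(
            names=self.names[idx], elements=self.elements[idx],
            resids=self.resids[idx], resnames=self.resnames[idx],
            chains=self.chains[idx], coords=self.coords[idx],
            masses=self.masses[idx], hetero=self.hetero[idx],
            title=self.title,
        )

    def with_coords(self, coords: np.ndarray) -> "Structure":
        out = self.copy()
        out.coords = np.asarray(coords, dtype=float)
        return out


@dataclass
class Trajectory:
    """Ordered coordinate frames sharing the reference's atom order."""

    reference: Structure
    frames: np.ndarray   # (n_frames, n_atoms, 3) float, Å
    times: np.ndarray    # (n_frames,) float, ns, strictly increasing

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[1] != self.reference.n_atoms:
            raise AlignmentError(
                f"frames shape {self.frames.shape} incompatible with "
                f"{self.reference.n_atoms}-atom reference"
            )
        if len(self.times) != len(self.frames):
            raise AlignmentError("times length must equal frame count")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise InputError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)


@dataclass(frozen=True)
class SegmentDef:
    """A contiguous residue range on one chain with an atom policy."""

    name: str
    first_residue: int
    last_residue: int
    chain: Optional[str] = None      # None: match any chain
    atom_policy: str = "backbone"    # backbone | heavy | all | alpha_carbon

    def __post_init__(self):
        if self.first_residue > self.last_residue:
            raise SelectionError(
                f"segment {self.name!r}: first_residue > last_residue"
            )
        if self.atom_policy not in ("backbone", "heavy", "all", "alpha_carbon"):
            raise SelectionError(
                f"segment {self.name!r}: unknown atom policy {self.atom_policy!r}"
            )


@dataclass
class AtomGroup:
    """Indices into a Structure's atom list."""

    indices: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.indices = np.asarray(self.indices, dtype=int)
        if len(np.unique(self.indices)) != len(self.indices):
            raise SelectionError(f"group {self.label!r}: duplicate indices")

    def __len__(self) -> int:
        return len(self.indices)


# ---------------------------------------------------------------------------
# PDB reading / writing (fixed columns, PDB v3.3)
# ---------------------------------------------------------------------------

_TWO_LETTER = {k for k in ATOMIC_MASSES if len(k) == 2}


def _element_from_name(name: str, resname: str) -> str:
    """Infer an element symbol when the element column is blank."""
    stripped = name.strip().lstrip("0123456789")
    if not stripped:
        raise ParseError(f"cannot infer element from atom name {name!r}")
    two = stripped[:2].upper()
    # Two-letter symbols only when the name starts in column 13 (ions such
    # as 'NA  ', 'CL  ', 'FE  '); 'CA' in a protein residue is a carbon.
    if two in _TWO_LETTER and len(name) >= 2 and name[0] != " " and resname.strip().upper() == two:
        return two
    return stripped[0].upper()


def _parse_atom_line(line: str, lineno: int):
    try:
        name = line[12:16]
        altloc = line[16]
        resname = line[17:20].strip()
        chain = line[21].strip() or " "
        resid = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        occ_field = line[54:60].strip()
        occupancy = float(occ_field) if occ_field else 1.0
        element = line[76:78].strip().upper() if len(line) >= 78 else ""
    except (ValueError, IndexError) as exc:
        raise ParseError(f"malformed ATOM/HETATM record at line {lineno}: {exc}") from exc
    if not element:
        element = _element_from_name(name, resname)
    return {
        "name": name.strip(), "altloc": altloc, "resname": resname,
        "chain": chain, "resid": resid, "xyz": (x, y, z),
        "occupancy": occupancy, "element": element,
        "hetero": line.startswith("HETATM"),
    }


def _model_to_arrays(atoms: list, title: str) -> Structure:
    masses = []
    for a in atoms:
        m = ATOMIC_MASSES.get(a["element"])
        if m is None:
            m = ATOMIC_MASSES.get(a["element"][:1])
        if m is None or m <= 0:
            raise ParseError(f"no mass for element {a['element']!r}")
        masses.append(m)
    return Structure(
        names=np.array([a["name"] for a in atoms]),
        elements=np.array([a["element"] for a in atoms]),
        resids=np.array([a["resid"] for a in atoms], dtype=int),
        resnames=np.array([a["resname"] for a in atoms]),
        chains=np.array([a["chain"] for a in atoms]),
        coords=np.array([a["xyz"] for a in atoms], dtype=float),
        masses=np.array(masses, dtype=float),
        hetero=np.array([a["hetero"] for a in atoms], dtype=bool),
        title=title,
    )


def _reduce_altlocs(atoms: list) -> list:
    """Keep the highest-occupancy alternate location; ties keep the first."""
    out, best = [], {}
    for a in atoms:
        if a["altloc"] == " ":
            out.append(a)
            continue
        key = (a["chain"], a["resid"], a["resname"], a["name"])
        if key not in best:
            best[key] = len(out)
            out.append(a)
        elif a["occupancy"] > out[best[key]]["occupancy"]:
            out[best[key]] = a
    return out


def read_pdb(
    source: Union[str, Path, io.TextIOBase],
    frame_dt_ns: float = 1.0,
) -> Union[Structure, Trajectory]:
    """Read a PDB file; multi-model input yields a :class:`Trajectory`.

    HETATM records (ligands, ions, waters) are retained and addressable by
    residue name.  ``frame_dt_ns`` sets the spacing of the synthetic frame
    clock for multi-model input (PDB carries no time stamps).
    """
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
        title = Path(source).stem
    else:
        text = source.read()
        title = ""
    models, current = [], []
    in_model = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6]
        if rec == "MODEL ":
            if current:
                models.append(current)
            current, in_model = [], True
        elif rec == "ENDMDL":
            models.append(current)
            current, in_model = [], False
        elif rec in ("ATOM  ", "HETATM"):
            current.append(_parse_atom_line(line.ljust(80), lineno))
        elif line.startswith("TITLE"):
            title = (title + " " + line[10:80].strip()).strip()
    if current:
        models.append(current)
    models = [m for m in models if m]
    if not models:
        raise EmptyInputError("PDB input contains no atoms")
    models = [_reduce_altlocs(m) for m in models]
    first = _model_to_arrays(models[0], title)
    if len(models) == 1:
        return first
    n = first.n_atoms
    frames = np.empty((len(models), n, 3))
    for i, m in enumerate(models):
        if len(m) != n:
            raise ParseError(
                f"model {i + 1} has {len(m)} atoms, expected {n}"
            )
        frames[i] = [a["xyz"] for a in m]
    times = np.arange(len(models), dtype=float) * float(frame_dt_ns)
    return Trajectory(reference=first, frames=frames, times=times)


def _format_atom_line(i, s: Structure, xyz) -> str:
    name = s.names[i]
    # PDB convention: 1-letter elements start in column 14 for short names.
    if len(name) < 4 and len(s.elements[i]) == 1:
        name_field = f" {name:<3s}"
    else:
        name_field = f"{name:<4s}"
    rec = "HETATM" if s.hetero[i] else "ATOM  "
    return (
        f"{rec}{(i % 99999) + 1:5d} {name_field} {s.resnames[i]:<3s} "
        f"{s.chains[i]:1s}{s.resids[i]:4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
        f"          {s.elements[i]:>2s}"
    )


def write_pdb(obj: Union[Structure, Trajectory], path: Union[str, Path]) -> None:
    """Round-trip PDB writer (multi-model for trajectories)."""
    lines = []
    if isinstance(obj, Trajectory):
        s = obj.reference
        if s.title:
            lines.append(f"TITLE     {s.title[:70]}")
        for f, frame in enumerate(obj.frames, start=1):
            lines.append(f"MODEL     {f:4d}")
            lines.extend(_format_atom_line(i, s, frame[i]) for i in range(s.n_atoms))
            lines.append("ENDMDL")
    else:
        s = obj
        if s.title:
            lines.append(f"TITLE     {s.title[:70]}")
        lines.extend(_format_atom_line(i, s, s.coords[i]) for i in range(s.n_atoms))
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Selections
# ---------------------------------------------------------------------------

def select(structure: Structure, segment: SegmentDef) -> AtomGroup:
    """Atoms of a residue range filtered by the segment's atom policy."""
    mask = (structure.resids >= segment.first_residue) & (
        structure.resids <= segment.last_residue
    )
    if segment.chain is not None:
        mask &= structure.chains == segment.chain
    if segment.atom_policy == "backbone":
        mask &= np.isin(structure.names, BACKBONE_NAMES)
    elif segment.atom_policy == "alpha_carbon":
        mask &= structure.names == "CA"
    elif segment.atom_policy == "heavy":
        mask &= structure.elements != "H"
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        raise SelectionError(
            f"segment {segment.name!r} (chain={segment.chain!r}, "
            f"{segment.first_residue}-{segment.last_residue}, "
            f"{segment.atom_policy}) selects no atoms"
        )
    return AtomGroup(indices=idx, label=segment.name)


def _residue_mask(structure, chain, resid, resname):
    mask = np.ones(structure.n_atoms, dtype=bool)
    if chain is not None:
        mask &= structure.chains == chain
    if resid is not None:
        mask &= structure.resids == resid
    if resname is not None:
        mask &= structure.resnames == resname
    return mask


def named_group(
    structure: Structure,
    kind: str,
    chain: Optional[str] = None,
    resid: Optional[int] = None,
    resname: Optional[str] = None,
) -> AtomGroup:
    """Binding-site atom groups used by the distance collective variables.

    kinds
    -----
    ``trp_ring6``
        The six carbons of the tryptophan indole six-membered ring
        (CD2, CE2, CE3, CZ2, CZ3, CH2).
    ``tyr_oh``
        The tyrosine hydroxyl oxygen (OH).
    ``phc_n``
        The phosphorylcholine quaternary ammonium nitrogen (the single
        nitrogen of the ligand residue; named N1 in the CCD entry).
    ``phc_phosphate_o``
        The three anionic phosphate oxygens: oxygens within bonding
        distance of the ligand phosphorus that are not bonded to carbon
        (excludes the choline ester oxygen).
    """
    mask = _residue_mask(structure, chain, resid, resname)
    idx = np.flatnonzero(mask)
    where = f"chain={chain!r} resid={resid!r} resname={resname!r}"
    if len(idx) == 0:
        raise GroupDefinitionError(f"no residue matches {where}")
    names = structure.names[idx]
    label = f"{kind}:{where}"
    if kind == "trp_ring6":
        missing = [n for n in TRP_RING6 if n not in names]
        if missing:
            raise GroupDefinitionError(
                f"{label}: missing indole ring atoms {missing}"
            )
        order = {n: i for i, n in enumerate(TRP_RING6)}
        sel = sorted(
            (i for i in idx if structure.names[i] in order),
            key=lambda i: order[structure.names[i]],
        )
        return AtomGroup(indices=np.array(sel), label=label)
    if kind == "tyr_oh":
        sel = idx[names == "OH"]
        if len(sel) != 1:
            raise GroupDefinitionError(f"{label}: hydroxyl oxygen 'OH' absent")
        return AtomGroup(indices=sel, label=label)
    if kind == "phc_n":
        sel = idx[structure.elements[idx] == "N"]
        if len(sel) != 1:
            raise GroupDefinitionError(
                f"{label}: expected exactly one nitrogen, found {len(sel)}"
            )
        return AtomGroup(indices=sel, label=label)
    if kind == "phc_phosphate_o":
        p_idx = idx[structure.elements[idx] == "P"]
        o_idx = idx[structure.elements[idx] == "O"]
        if len(p_idx) == 1 and len(o_idx) >= 3:
            p_xyz = structure.coords[p_idx[0]]
            c_xyz = structure.coords[idx[structure.elements[idx] == "C"]]
            sel = []
            for i in o_idx:
                o = structure.coords[i]
                if np.linalg.norm(o - p_xyz) > 1.75:
                    continue  # not bonded to P
                if len(c_xyz) and np.min(np.linalg.norm(c_xyz - o, axis=1)) < 1.6:
                    continue  # ester oxygen
                sel.append(i)
        elif len(o_idx) == 3:
            sel = list(o_idx)  # minimal marker ligand without explicit P
        else:
            sel = []
        if len(sel) != 3:
            raise GroupDefinitionError(
                f"{label}: could not identify the three anionic phosphate "
                f"oxygens (found {len(sel)}; residue has atoms {sorted(set(names))})"
            )
        return AtomGroup(indices=np.array(sorted(sel)), label=label)
    raise GroupDefinitionError(f"unknown group kind {kind!r}")


# ---------------------------------------------------------------------------
# Superposition
# ---------------------------------------------------------------------------

def superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: Optional[np.ndarray] = None,
):
    """Weighted least-squares rigid fit of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` best matches ``reference`` and
    the rotation is proper (determinant +1).  RMSD is the weighted
    root-mean-square deviation after the fit, in Å.
    """
    mob = np.asarray(mobile, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if mob.shape != ref.shape or mob.ndim != 2 or mob.shape[1] != 3:
        raise GeometryError("superpose requires matching (n, 3) arrays")
    n = len(mob)
    if n < 3:
        raise GeometryError("superpose requires at least 3 points")
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
            raise GeometryError("invalid superposition weights")
    wsum = w.sum()
    mc = (w[:, None] * mob).sum(0) / wsum
    rc = (w[:, None] * ref).sum(0) / wsum
    mob0, ref0 = mob - mc, ref - rc
    sv = np.linalg.svd(mob0 * np.sqrt(w)[:, None], compute_uv=False)
    if sv[1] <= 1e-8 * max(sv[0], 1.0):
        raise GeometryError("degenerate (collinear) point configuration")
    rot, _ = Rotation.align_vectors(ref0, mob0, weights=w)
    R = rot.as_matrix()
    t = rc - R @ mc
    fitted = mob @ R.T + t
    rmsd = float(np.sqrt((w * ((fitted - ref) ** 2).sum(1)).sum() / wsum))
    return R, t, rmsd


def apply_transform(coords: np.ndarray, rotation: np.ndarray, translation: np.ndarray) -> np.ndarray:
    return np.asarray(coords, dtype=float) @ np.asarray(rotation).T + translation
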