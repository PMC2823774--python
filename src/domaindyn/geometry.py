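"""Per-frame collective variables and flexibility measures.

Implements the observables used to follow a two-domain protein with a
flexible linker: binding-site distances (tryptophan-ring/ammonium and
tyrosine-hydroxyl/phosphate conventions), the inter-domain orientation
cosine cos(theta) between two intra-domain C-alpha displacement vectors,
the inter-domain center-of-mass distance D, segmental RMSD time series
against a reference structure, per-atom RMSF with per-segment
normalization, and the per-residue segmental RMSD between two protomers
of a crystal dimer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

from .errors import (
    AlignmentError,
    DegenerateInputError,
    GeometryError,
    SelectionError,
)
from .structio import (
    AtomGroup,
    SegmentDef,
    Structure,
    Trajectory,
    apply_transform,
    select,
    superpose,
)

__all__ = [
    "OrientationSpec",
    "CVSeries",
    "FlexibilityReport",
    "cos_theta",
    "interdomain_distance",
    "site_distance",
    "segmental_rmsd_series",
    "rmsf",
    "protomer_segmental_rmsd",
]


@dataclass(frozen=True)
class OrientationSpec:
    """Four residue locators whose C-alphas define vectors V1 and V2.

    V1 = r(v1_to) - r(v1_from), V2 = r(v2_to) - r(v2_from); each locator is
    ``(chain or None, resid)``.  The direction convention (second minus
    first) is arbitrary but recorded; cos(theta) is symmetric under
    simultaneous flips of both vectors.
    """

    v1_from: Tuple[Optional[str], int]
    v1_to: Tuple[Optional[str], int]
    v2_from: Tuple[Optional[str], int]
    v2_to: Tuple[Optional[str], int]

    def __post_init__(self):
        locs = (self.v1_from, self.v1_to, self.v2_from, self.v2_to)
        if len(set(locs)) != 4:
            raise GeometryError("orientation residues must be distinct")


@dataclass
class CVSeries:
    """A named scalar collective variable sampled per frame."""

    name: str
    values: np.ndarray
    units: str
    times: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if len(self.values) != len(self.times):
            raise AlignmentError("CVSeries values/times length mismatch")
        if not np.all(np.isfinite(self.values)):
            raise GeometryError(f"CVSeries {self.name!r} has non-finite values")


@dataclass
class FlexibilityReport:
    """Per-atom RMSF and its per-segment summaries (Å)."""

    per_atom: np.ndarray        # Å per atom of the segment
    segment_mean: float         # mean over atoms, Å
    normalized: float           # segment_mean / residue count
    n_residues: int
    reference_coords: np.ndarray
    atom_indices: np.ndarray


def _ca_index(structure: Structure, locator) -> int:
    chain, resid = locator
    mask = (structure.resids == resid) & (structure.names == "CA")
    if chain is not None:
        mask &= structure.chains == chain
    idx = np.flatnonzero(mask)
    if len(idx) != 1:
        raise SelectionError(
            f"alpha-carbon of residue {locator} resolves to {len(idx)} atoms"
        )
    return int(idx[0])


def cos_theta(coords: np.ndarray, structure: Structure, spec: OrientationSpec) -> float:
    """Cosine of the angle between the two inter-residue C-alpha vectors."""
    coords = np.asarray(coords, dtype=float)
    r = lambda loc: coords[_ca_index(structure, loc)]
    v1 = r(spec.v1_to) - r(spec.v1_from)
    v2 = r(spec.v2_to) - r(spec.v2_from)
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        raise GeometryError("zero-length orientation vector")
    return float(np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0))


def _com(structure: Structure, coords: np.ndarray, group: AtomGroup) -> np.ndarray:
    m = structure.masses[group.indices]
    return (m[:, None] * coords[group.indices]).sum(0) / m.sum()


def interdomain_distance(
    coords: np.ndarray,
    structure: Structure,
    segA: SegmentDef,
    segB: SegmentDef,
) -> float:
    """Distance between mass-weighted backbone centers of two segments, Å."""
    ga = select(structure, SegmentDef(segA.name, segA.first_residue,
                                      segA.last_residue, segA.chain, "backbone"))
    gb = select(structure, SegmentDef(segB.name, segB.first_residue,
                                      segB.last_residue, segB.chain, "backbone"))
    coords = np.asarray(coords, dtype=float)
    return float(np.linalg.norm(_com(structure, coords, ga) - _com(structure, coords, gb)))


def site_distance(
    coords: np.ndarray,
    site: AtomGroup,
    ligand: AtomGroup,
    site_mode: str = "cog",
    ligand_mode: str = "single",
) -> float:
    """Binding-site distance between a protein group and a ligand group.

    Tryptophan convention: site_mode='cog' over the six indole ring carbons
    versus ligand_mode='single' (the quaternary ammonium nitrogen).
    Tyrosine convention: site_mode='single' (the hydroxyl oxygen) versus
    ligand_mode='mean' over the three anionic phosphate oxygens.
    """
    coords = np.asarray(coords, dtype=float)
    if len(site) == 0 or len(ligand) == 0:
        raise GeometryError("empty atom group")
    if site_mode == "cog":
        p_site = coords[site.indices].mean(0)
    elif site_mode == "single":
        if len(site) != 1:
            raise GeometryError(
                f"site_mode='single' needs a 1-atom group, got {len(site)}"
            )
        p_site = coords[site.indices[0]]
    else:
        raise GeometryError(f"unknown site_mode {site_mode!r}")
    if ligand_mode == "mean":
        p_lig = coords[ligand.indices].mean(0)
    elif ligand_mode == "single":
        if len(ligand) != 1:
            raise GeometryError(
                f"ligand_mode='single' needs a 1-atom group, got {len(ligand)}"
            )
        p_lig = coords[ligand.indices[0]]
    else:
        raise GeometryError(f"unknown ligand_mode {ligand_mode!r}")
    return float(np.linalg.norm(p_lig - p_site))


def _backbone(seg: SegmentDef) -> SegmentDef:
    return SegmentDef(seg.name, seg.first_residue, seg.last_residue,
                      seg.chain, "backbone")


def segmental_rmsd_series(
    traj: Trajectory,
    reference: Structure,
    segment: SegmentDef,
    fit_segment: Optional[SegmentDef] = None,
) -> CVSeries:
    """Backbone RMSD of a segment after a least-squares fit on fit_segment.

    Each frame is superposed onto the reference using the backbone atoms of
    ``fit_segment`` (default: the segment itself), then the RMSD is
    evaluated over the segment's backbone atoms.
    """
    if fit_segment is None:
        fit_segment = segment
    if traj.reference.n_atoms != reference.n_atoms:
        raise AlignmentError("trajectory and reference atom counts differ")
    seg_idx = select(reference, _backbone(segment)).indices
    fit_idx = select(reference, _backbone(fit_segment)).indices
    ref_fit = reference.coords[fit_idx]
    ref_seg = reference.coords[seg_idx]
    out = np.empty(traj.n_frames)
    for f, frame in enumerate(traj.frames):
        R, t, _ = superpose(frame[fit_idx], ref_fit)
        fitted = apply_transform(frame[seg_idx], R, t)
        out[f] = np.sqrt(((fitted - ref_seg) ** 2).sum(1).mean())
    return CVSeries(
        name=f"rmsd:{segment.name}", values=out, units="Å", times=traj.times,
        meta={"fit_segment": fit_segment.name},
    )


def rmsf(
    traj: Trajectory,
    segment: SegmentDef,
    fit: bool = True,
    max_iter: int = 5,
) -> FlexibilityReport:
    """Per-atom RMSF about the trajectory-average segment structure.

    Frames are iteratively superposed onto the running average structure of
    the segment (the average is the fixed point of fit-then-average).  The
    segment RMSF is the mean over member atoms; the normalized RMSF divides
    by the residue count, following the convention of normalizing segmental
    fluctuation by segment length.
    """
    if traj.n_frames < 2:
        raise DegenerateInputError("RMSF requires at least 2 frames")
    idx = select(traj.reference, segment).indices
    X = traj.frames[:, idx, :].copy()
    if fit:
        mean = X[0]
        for _ in range(max_iter):
            for f in range(len(X)):
                R, t, _ = superpose(X[f], mean)
                X[f] = apply_transform(X[f], R, t)
            new_mean = X.mean(0)
            if np.max(np.abs(new_mean - mean)) < 1e-10:
                mean = new_mean
                break
            mean = new_mean
    mean = X.mean(0)
    per_atom = np.sqrt(((X - mean) ** 2).sum(2).mean(0))
    resids = traj.reference.resids[idx]
    chains = traj.reference.chains[idx]
    n_res = len(set(zip(chains.tolist(), resids.tolist())))
    seg_mean = float(per_atom.mean())
    return FlexibilityReport(
        per_atom=per_atom,
        segment_mean=seg_mean,
        normalized=seg_mean / n_res,
        n_residues=n_res,
        reference_coords=mean,
        atom_indices=idx,
    )


def protomer_segmental_rmsd(
    structA: Structure,
    structB: Structure,
    segment: SegmentDef,
    fit: bool = True,
) -> float:
    """Per-residue segmental RMSD between two protomers of a dimer.

    The segment's backbone atoms of A are least-squares superposed onto the
    corresponding atoms of B (per-segment fit), the backbone RMSD is
    computed, and the result is divided by the residue count (Å per
    residue).  ``fit=False`` skips the superposition.
    """
    ga = select(structA, _backbone(segment))
    gb = select(structB, _backbone(segment))
    if len(ga) != len(gb):
        raise AlignmentError(
            f"segment {segment.name!r}: {len(ga)} vs {len(gb)} backbone atoms"
        )
    namesA = structA.names[ga.indices]
    namesB = structB.names[gb.indices]
    if not np.array_equal(namesA, namesB):
        raise AlignmentError(f"segment {segment.name!r}: atom name mismatch")
    a = structA.coords[ga.indices]
    b = structB.coords[gb.indices]
    if fit:
        R, t, rmsd = superpose(a, b)
    else:
        rmsd = float(np.sqrt(((a - b) ** 2).sum(1).mean()))
    n_res = segment.last_residue - segment.first_residue + 1
    return rmsd / n_res
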