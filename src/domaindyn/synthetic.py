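"""Seeded generators with planted ground truth for every pipeline stage.

Each generator is a pure function of its parameters and seed: identical
inputs give bit-identical outputs.  The generators emulate

* a two-rigid-domain pseudo-protein joined by a flexible linker, carrying
  tryptophan-like ring markers, tyrosine-like hydroxyl markers and a
  phosphorylcholine-like ligand per domain, so every named atom group and
  collective variable can be exercised without a real crystal file;
* trajectories posed so the inter-domain orientation cosine and the
  center-of-mass distance follow prescribed schedules;
* Gaussian fluctuation trajectories with planted orthonormal mode
  directions and variances (the PCA oracle);
* windowed mean-force samples drawn from an analytic double-well potential
  of mean force with AR(1)-correlated noise (the ABF/stitching oracle);
* a harmonic bead-spring chain with a closed-form vibrational spectrum
  (the NMA oracle).

Default planted-PMF parameters follow the published two-well profile for
the N-terminal Fn2 domain: wells at 3.0 and 5.6 Å with depths 1.0 and
2.1 kcal/mol; a preset for the C-terminal domain (3.0/5.7 Å, 1.1/2.0
kcal/mol) is also provided.  Well widths of 0.5 Å are a package choice
(typical for a binding PMF resolved at 0.05 Å bins).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.signal import lfilter
from scipy.spatial.transform import Rotation

from .errors import FeasibilityError, InputError
from .pmf import ForceWindow, correlation_length, write_force_window
from .structio import SegmentDef, Structure, Trajectory
from .geometry import OrientationSpec
from .modes import FREQ_CM_PER_SQRT_KCAL

__all__ = [
    "PlantedPMF",
    "PDC109_A_WELLS",
    "PDC109_B_WELLS",
    "PlantedModes",
    "ScheduleSpec",
    "TwoDomainLayout",
    "make_two_domain_structure",
    "random_internal_directions",
    "gaussian_mode_trajectory",
    "schedule_trajectory",
    "abf_windows",
    "harmonic_chain",
]

PDC109_A_WELLS = ((3.0, 1.0, 0.5), (5.6, 2.1, 0.5))
PDC109_B_WELLS = ((3.0, 1.1, 0.5), (5.7, 2.0, 0.5))


@dataclass(frozen=True)
class PlantedPMF:
    """Analytic double-well PMF: sum of inverted Gaussians plus a wall.

    W(xi) = -sum_i depth_i exp(-(xi - pos_i)^2 / (2 width_i^2))
            + wall_k (wall_pos - xi)^2 for xi < wall_pos.

    W -> 0 at large xi, so anchoring at a distant xi0 leaves the planted
    depths intact.  ``gradient`` is the exact analytic derivative.
    """

    wells: Tuple[Tuple[float, float, float], ...] = PDC109_A_WELLS
    wall_pos: float = 2.5
    wall_k: float = 5.0

    def w(self, xi) -> np.ndarray:
        xi = np.asarray(xi, dtype=float)
        out = np.zeros_like(xi)
        for pos, depth, width in self.wells:
            out -= depth * np.exp(-((xi - pos) ** 2) / (2.0 * width**2))
        wall = np.where(xi < self.wall_pos,
                        self.wall_k * (self.wall_pos - xi) ** 2, 0.0)
        return out + wall

    def gradient(self, xi) -> np.ndarray:
        xi = np.asarray(xi, dtype=float)
        out = np.zeros_like(xi)
        for pos, depth, width in self.wells:
            out += depth * (xi - pos) / width**2 * np.exp(
                -((xi - pos) ** 2) / (2.0 * width**2)
            )
        out += np.where(xi < self.wall_pos,
                        -2.0 * self.wall_k * (self.wall_pos - xi), 0.0)
        return out


@dataclass
class PlantedModes:
    """Orthonormal mode directions with target variances (PCA oracle)."""

    reference: Structure
    directions: np.ndarray     # (k, 3N), orthonormal rows
    variances: np.ndarray      # (k,), Å^2
    seed: int = 0

    def __post_init__(self):
        D = np.asarray(self.directions, dtype=float)
        if D.ndim != 2 or D.shape[1] != 3 * self.reference.n_atoms:
            raise InputError("directions must be (k, 3N)")
        if not np.allclose(D @ D.T, np.eye(len(D)), atol=1e-10):
            raise InputError("planted directions must be orthonormal to 1e-10")
        self.directions = D
        self.variances = np.asarray(self.variances, dtype=float)


@dataclass
class ScheduleSpec:
    """Target cos(theta) and inter-domain distance D per frame.

    ``cos_theta`` and ``distance`` may be scalars, arrays of length
    n_frames, or callables of the fractional time t in [0, 1].
    """

    cos_theta: Union[float, Sequence[float], Callable] = 0.8
    distance: Union[float, Sequence[float], Callable] = 25.0
    noise_sd: float = 0.0     # Å, isotropic per-coordinate Gaussian
    seed: int = 0

    def resolve(self, which: str, n_frames: int) -> np.ndarray:
        tgt = self.cos_theta if which == "cos_theta" else self.distance
        if callable(tgt):
            vals = np.array([tgt(t) for t in np.linspace(0, 1, n_frames)])
        else:
            vals = np.broadcast_to(np.asarray(tgt, dtype=float), (n_frames,)).copy()
        if which == "cos_theta" and np.any(np.abs(vals) > 1):
            raise InputError("cos(theta) targets must lie in [-1, 1]")
        if which == "distance" and np.any(vals <= 0):
            raise InputError("distance targets must be positive")
        return vals


@dataclass
class TwoDomainLayout:
    """Bookkeeping emitted alongside the two-domain pseudo-protein."""

    domain_a: SegmentDef
    linker: SegmentDef
    domain_b: SegmentDef
    orientation: OrientationSpec
    trp_resids: Tuple[int, int, int, int]
    tyr_resids: Tuple[int, int]
    ligand_resids: Tuple[int, int]      # ligand of domain a, of domain b


_HELIX_RISE = 1.5
_HELIX_RADIUS = 2.3
_HELIX_TURN = np.deg2rad(100.0)
# backbone offsets relative to the CA position (arbitrary but fixed)
_BB_OFFSETS = {
    "N": np.array([-1.2, 0.4, -0.5]),
    "CA": np.zeros(3),
    "C": np.array([1.2, 0.4, 0.5]),
    "O": np.array([1.6, 1.5, 0.5]),
}
_BB_ELEMENTS = {"N": "N", "CA": "C", "C": "C", "O": "O"}


def _helix_ca(n: int) -> np.ndarray:
    i = np.arange(n)
    return np.stack([
        _HELIX_RADIUS * np.cos(i * _HELIX_TURN),
        _HELIX_RADIUS * np.sin(i * _HELIX_TURN),
        _HELIX_RISE * i,
    ], axis=1)


def make_two_domain_structure(
    residues_per_domain: int = 10,
    linker_residues: int = 4,
    domain_separation: float = 25.0,
) -> Structure:
    """Deterministic two-domain pseudo-protein with marker groups.

    Each domain is a compact helix of N/CA/C/O backbone residues; the
    linker is an extended strand between them.  Two residues per domain
    are tryptophan-like (six indole-ring-named carbons), one per domain is
    tyrosine-like (an OH oxygen), and one phosphorylcholine-like ligand
    (quaternary N, choline C, phosphorus, ester O and three anionic O)
    sits near the first ring of each domain.  The layout (segments,
    orientation spec, marker residue numbers) is stored in
    ``structure.meta['two_domain']``.
    """
    nd, nl = int(residues_per_domain), int(linker_residues)
    if nd < 3 or nl < 3:
        raise InputError("domains and linker need at least 3 residues each")

    def domain_atoms(ca, first_resid, trp_pair, tyr_res, tag):
        names, elements, resids, resnames, het, xyz = [], [], [], [], [], []
        for j, c in enumerate(ca):
            rid = first_resid + j
            rname = "TRP" if rid in trp_pair else ("TYR" if rid == tyr_res else "GLY")
            for nm in ("N", "CA", "C", "O"):
                names.append(nm)
                elements.append(_BB_ELEMENTS[nm])
                resids.append(rid)
                resnames.append(rname)
                het.append(False)
                xyz.append(c + _BB_OFFSETS[nm])
            if rname == "TRP":
                ring_center = c + np.array([0.0, 2.6, 0.0])
                for k, nm in enumerate(("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2")):
                    ang = k * np.pi / 3.0
                    names.append(nm)
                    elements.append("C")
                    resids.append(rid)
                    resnames.append(rname)
                    het.append(False)
                    xyz.append(ring_center + 1.4 * np.array(
                        [np.cos(ang), 0.0, np.sin(ang)]))
            elif rname == "TYR":
                names.append("OH")
                elements.append("O")
                resids.append(rid)
                resnames.append(rname)
                het.append(False)
                xyz.append(c + np.array([0.0, -2.2, 1.0]))
        return names, elements, resids, resnames, het, xyz

    trp_a = (1 + nd // 3, 1 + (2 * nd) // 3)
    tyr_a = 2
    first_b = nd + nl + 1
    trp_b = (first_b + nd // 3 - 1, first_b + (2 * nd) // 3 - 1)
    tyr_b = first_b + 1

    ca_a = _helix_ca(nd)
    ca_a -= ca_a.mean(0)
    rot_b = Rotation.from_euler("zyx", [40.0, 25.0, -30.0], degrees=True).as_matrix()
    ca_b = (_helix_ca(nd) - _helix_ca(nd).mean(0)) @ rot_b.T
    ca_b += np.array([domain_separation, 0.0, 0.0])
    # extended linker between domain ends
    start = ca_a[-1] + np.array([1.0, 0.0, 0.0])
    end = ca_b[0] - np.array([1.0, 0.0, 0.0])
    ca_l = start + (end - start) * ((np.arange(nl) + 1.0) / (nl + 1.0))[:, None]

    names, elements, resids, resnames, het, xyz = domain_atoms(
        ca_a, 1, trp_a, tyr_a, "a")
    for j, c in enumerate(ca_l):
        rid = nd + 1 + j
        for nm in ("N", "CA", "C", "O"):
            names.append(nm)
            elements.append(_BB_ELEMENTS[nm])
            resids.append(rid)
            resnames.append("GLY")
            het.append(False)
            xyz.append(c + _BB_OFFSETS[nm])
    parts_b = domain_atoms(ca_b, first_b, trp_b, tyr_b, "b")
    for lst, new in zip((names, elements, resids, resnames, het, xyz), parts_b):
        lst.extend(new)

    # phosphorylcholine-like ligands near the first ring of each domain
    def ligand(ring_center, rid):
        n_pos = ring_center + np.array([0.0, 4.2, 0.0])
        c_pos = n_pos + np.array([1.5, 0.0, 0.0])
        o_ester = c_pos + np.array([1.4, 0.0, 0.0])
        p_pos = o_ester + np.array([1.6, 0.0, 0.0])
        out = [("N1", "N", n_pos), ("C1", "C", c_pos), ("O4", "O", o_ester),
               ("P", "P", p_pos)]
        for k in range(3):
            ang = 2.0 * np.pi * k / 3.0
            u = np.array([0.5, np.cos(ang), np.sin(ang)])
            out.append((f"O{k + 1}", "O", p_pos + 1.5 * u / np.linalg.norm(u)))
        for nm, el, pos in out:
            names.append(nm)
            elements.append(el)
            resids.append(rid)
            resnames.append("PHC")
            het.append(True)
            xyz.append(pos)

    ring_a = ca_a[trp_a[0] - 1] + np.array([0.0, 2.6, 0.0])
    ring_b = ca_b[trp_b[0] - first_b] + np.array([0.0, 2.6, 0.0])
    lig_a, lig_b = 901, 902
    ligand(ring_a, lig_a)
    ligand(ring_b, lig_b)

    from .structio import ATOMIC_MASSES
    struct = Structure(
        names=np.array(names), elements=np.array(elements),
        resids=np.array(resids, dtype=int), resnames=np.array(resnames),
        chains=np.array(["A"] * len(names)),
        coords=np.array(xyz, dtype=float),
        masses=np.array([ATOMIC_MASSES[e] for e in elements]),
        hetero=np.array(het, dtype=bool),
        title="synthetic two-domain pseudo-protein",
    )
    layout = TwoDomainLayout(
        domain_a=SegmentDef("domain_a", 1, nd, "A", "backbone"),
        linker=SegmentDef("linker", nd + 1, nd + nl, "A", "backbone"),
        domain_b=SegmentDef("domain_b", first_b, first_b + nd - 1, "A", "backbone"),
        orientation=OrientationSpec(
            v1_from=("A", trp_a[0]), v1_to=("A", trp_a[1]),
            v2_from=("A", trp_b[0]), v2_to=("A", trp_b[1]),
        ),
        trp_resids=(trp_a[0], trp_a[1], trp_b[0], trp_b[1]),
        tyr_resids=(tyr_a, tyr_b),
        ligand_resids=(lig_a, lig_b),
    )
    struct.meta["two_domain"] = layout
    return struct


def random_internal_directions(
    reference: Structure,
    n_directions: int,
    seed: int = 0,
) -> np.ndarray:
    """Random orthonormal directions orthogonal to rigid-body motions.

    Sampling frames along such directions leaves the PCA fit (which removes
    net translation and rotation) with the full planted variance, so they
    serve as recoverable planted modes.
    """
    n = reference.n_atoms
    rng = np.random.default_rng(seed)
    com = reference.coords.mean(0)
    rel = reference.coords - com
    rigid = []
    for ax in np.eye(3):
        t = np.tile(ax, n)
        rigid.append(t / np.linalg.norm(t))
        r = np.cross(ax, rel).ravel()
        rigid.append(r / np.linalg.norm(r))
    rigid = np.linalg.qr(np.array(rigid).T)[0]  # (3n, 6)
    raw = rng.normal(size=(3 * n, n_directions))
    raw -= rigid @ (rigid.T @ raw)
    q, _ = np.linalg.qr(raw)
    return q.T[:n_directions]


def gaussian_mode_trajectory(
    planted: PlantedModes,
    n_frames: int,
    seed: Optional[int] = None,
    rigid_transforms: bool = False,
    frame_dt_ns: float = 1.0,
) -> Trajectory:
    """Frames sampled along planted orthonormal directions.

    frame = reference + sum_i c_i direction_i with c_i ~ N(0, variance_i);
    optionally composed with a random rigid transform per frame.
    """
    if n_frames < 2:
        raise InputError("need at least 2 frames")
    rng = np.random.default_rng(planted.seed if seed is None else seed)
    k = len(planted.variances)
    coeffs = rng.normal(size=(n_frames, k)) * np.sqrt(planted.variances)
    disp = coeffs @ planted.directions
    frames = planted.reference.coords[None, :, :] + disp.reshape(
        n_frames, -1, 3)
    if rigid_transforms:
        for f in range(n_frames):
            R = Rotation.random(random_state=np.random.RandomState(
                rng.integers(0, 2**31 - 1))).as_matrix()
            t = rng.uniform(-5.0, 5.0, size=3)
            centroid = frames[f].mean(0)
            frames[f] = (frames[f] - centroid) @ R.T + centroid + t
    times = np.arange(n_frames, dtype=float) * frame_dt_ns
    return Trajectory(reference=planted.reference, frames=frames, times=times)


def _rotation_between(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Proper rotation mapping unit vector u onto unit vector v."""
    c = float(np.clip(np.dot(u, v), -1.0, 1.0))
    axis = np.cross(u, v)
    norm = np.linalg.norm(axis)
    if norm < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate pi about any axis perpendicular to u
        perp = np.cross(u, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(u, [0.0, 1.0, 0.0])
        perp /= np.linalg.norm(perp)
        return Rotation.from_rotvec(np.pi * perp).as_matrix()
    axis /= norm
    return Rotation.from_rotvec(np.arccos(c) * axis).as_matrix()


def schedule_trajectory(
    structure: Structure,
    spec: ScheduleSpec,
    n_frames: int,
    frame_dt_ns: float = 1.0,
) -> Trajectory:
    """Pose domain B so cos(theta) and D follow the schedule exactly.

    Domain B (with its ligand) is rigidly rotated about its backbone
    center of mass so the second orientation vector makes the scheduled
    angle with the first, then translated so the inter-domain
    center-of-mass distance equals the scheduled D.  Linker atoms are
    interpolated between the two domain transforms, so a varying schedule
    deforms the linker.  Gaussian coordinate noise is added after posing.
    """
    layout: TwoDomainLayout = structure.meta.get("two_domain")
    if layout is None:
        raise InputError("structure must come from make_two_domain_structure")
    from .geometry import _ca_index
    from .structio import select

    cos_t = spec.resolve("cos_theta", n_frames)
    d_t = spec.resolve("distance", n_frames)
    X0 = structure.coords
    ca = lambda loc: X0[_ca_index(structure, loc)]
    v1 = ca(layout.orientation.v1_to) - ca(layout.orientation.v1_from)
    u1 = v1 / np.linalg.norm(v1)
    v2 = ca(layout.orientation.v2_to) - ca(layout.orientation.v2_from)
    u2 = v2 / np.linalg.norm(v2)

    ga = select(structure, layout.domain_a)
    gb = select(structure, layout.domain_b)
    mA = structure.masses[ga.indices]
    mB = structure.masses[gb.indices]
    comA = (mA[:, None] * X0[ga.indices]).sum(0) / mA.sum()
    comB = (mB[:, None] * X0[gb.indices]).sum(0) / mB.sum()
    n_hat = comB - comA
    n_hat /= np.linalg.norm(n_hat)
    # fixed in-plane perpendicular used to realize the scheduled angle
    e = n_hat - np.dot(n_hat, u1) * u1
    if np.linalg.norm(e) < 1e-8:
        e = np.cross(u1, [0.0, 0.0, 1.0])
    e /= np.linalg.norm(e)

    ext_a = np.max(np.linalg.norm(X0[ga.indices] - comA, axis=1))
    ext_b = np.max(np.linalg.norm(X0[gb.indices] - comB, axis=1))
    if np.any(d_t <= ext_a + ext_b):
        raise FeasibilityError(
            f"scheduled D as small as {d_t.min():.3g} Å would overlap domains "
            f"(extents {ext_a:.3g} + {ext_b:.3g} Å)"
        )

    moving = np.flatnonzero(
        (structure.resids >= layout.domain_b.first_residue)
        & (structure.resids <= layout.domain_b.last_residue)
        | (structure.resids == layout.ligand_resids[1])
    )
    linker_idx = np.flatnonzero(
        (structure.resids >= layout.linker.first_residue)
        & (structure.resids <= layout.linker.last_residue)
    )
    nl = layout.linker.last_residue - layout.linker.first_residue + 1
    frac = (structure.resids[linker_idx] - layout.linker.first_residue + 0.5) / nl

    rng = np.random.default_rng(spec.seed)
    frames = np.empty((n_frames, structure.n_atoms, 3))
    for f in range(n_frames):
        theta = np.arccos(np.clip(cos_t[f], -1.0, 1.0))
        target_dir = np.cos(theta) * u1 + np.sin(theta) * e
        R = _rotation_between(u2, target_dir)
        com_target = comA + d_t[f] * n_hat
        frame = X0.copy()
        frame[moving] = (X0[moving] - comB) @ R.T + com_target
        moved_linker_anchor = (X0[linker_idx] - comB) @ R.T + com_target
        frame[linker_idx] = (
            (1.0 - frac)[:, None] * X0[linker_idx]
            + frac[:, None] * moved_linker_anchor
        )
        frames[f] = frame
    if spec.noise_sd > 0:
        frames += rng.normal(0.0, spec.noise_sd, size=frames.shape)
    times = np.arange(n_frames, dtype=float) * frame_dt_ns
    return Trajectory(reference=structure, frames=frames, times=times)


def abf_windows(
    planted: PlantedPMF,
    lo: float = 2.0,
    hi: float = 14.0,
    window_width: float = 4.0,
    overlap: float = 2.0,
    bin_width: float = 0.05,
    samples_per_bin: int = 1000,
    noise_sd: float = 1.0,
    ar1_phi: float = 0.9,
    seed: int = 0,
    out_dir: Optional[Union[str, Path]] = None,
):
    """Windowed mean-force bins sampled from the planted analytic PMF.

    The default window layout follows the published protocol: windows of
    4 Å along xi with 2 Å overlap covering 2-14 Å, forces accumulated in
    0.05 Å bins.  Per-window force series are AR(1) with coefficient
    ``ar1_phi`` and marginal standard deviation ``noise_sd``; each bin's
    mean gradient is the exact bin-average of dW/dxi plus the mean of its
    noise chunk, and per-bin variances and the per-window correlation
    length are measured from the generated samples.  With ``out_dir`` the
    windows are written as TSV files plus a JSON truth sidecar.
    """
    step = window_width - overlap
    if step <= 0:
        raise InputError("overlap must be smaller than window width")
    starts = []
    s = lo
    while s + window_width <= hi + 1e-9:
        starts.append(round(s, 10))
        s += step
    if not starts or abs(starts[-1] + window_width - hi) > 1e-9:
        raise InputError(
            f"windows of width {window_width} with overlap {overlap} do not "
            f"tile [{lo}, {hi}]"
        )
    rng = np.random.default_rng(seed)
    windows = []
    for w_lo in starts:
        w_hi = w_lo + window_width
        n_bins = int(round(window_width / bin_width))
        edges = w_lo + np.arange(n_bins + 1) * bin_width
        centers = 0.5 * (edges[:-1] + edges[1:])
        w_edges = planted.w(edges)
        exact = (w_edges[1:] - w_edges[:-1]) / bin_width
        counts = np.full(n_bins, float(samples_per_bin))
        if noise_sd > 0:
            n_tot = n_bins * samples_per_bin
            innov = rng.normal(size=n_tot + 1000)
            innov[0] /= np.sqrt(1.0 - ar1_phi**2) if abs(ar1_phi) < 1 else 1.0
            chain = lfilter([1.0], [1.0, -ar1_phi],
                            np.sqrt(1.0 - ar1_phi**2) * noise_sd * innov)
            chain = chain[1000:]
            chunks = chain.reshape(n_bins, samples_per_bin)
            grad = exact + chunks.mean(axis=1)
            var = chunks.var(axis=1, ddof=1)
            kappa = correlation_length(chain)
        else:
            grad = exact.copy()
            var = np.zeros(n_bins)
            kappa = None
        windows.append(ForceWindow(
            lo=w_lo, hi=w_hi, bin_width=bin_width, bin_centers=centers,
            mean_gradient=grad, sample_count=counts, force_variance=var,
            kappa=kappa,
        ))
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for i, w in enumerate(windows):
            write_force_window(w, out / f"window_{i:02d}.tsv")
        truth = {
            "wells": [list(w) for w in planted.wells],
            "wall_pos": planted.wall_pos, "wall_k": planted.wall_k,
            "lo": lo, "hi": hi, "window_width": window_width,
            "overlap": overlap, "bin_width": bin_width,
            "samples_per_bin": samples_per_bin, "noise_sd": noise_sd,
            "ar1_phi": ar1_phi, "seed": seed,
        }
        (out / "truth.json").write_text(json.dumps(truth, indent=1))
    return windows


def harmonic_chain(n_beads: int, k: float = 1.0, m: float = 1.0):
    """1D bead-spring chain along x with a closed-form spectrum.

    Returns ``(structure, potential, analytic_frequencies_cm)`` where the
    potential couples only x coordinates (so transverse degrees of freedom
    are exact zero modes) and the analytic nonzero frequencies are
    2 sqrt(k/m) sin(j pi / 2n), j = 1..n-1, converted to cm^-1.
    """
    if n_beads < 2:
        raise InputError("need at least 2 beads")
    from .structio import Structure as _S
    n = int(n_beads)
    coords = np.zeros((n, 3))
    coords[:, 0] = np.arange(n, dtype=float)
    struct = _S(
        names=np.array(["CA"] * n), elements=np.array(["C"] * n),
        resids=np.arange(1, n + 1), resnames=np.array(["GLY"] * n),
        chains=np.array(["A"] * n), coords=coords,
        masses=np.full(n, float(m)), title=f"harmonic chain n={n}",
    )

    def potential(flat: np.ndarray) -> float:
        x = np.asarray(flat, dtype=float).reshape(-1, 3)[:, 0]
        return float(0.5 * k * np.sum((np.diff(x) - 1.0) ** 2))

    j = np.arange(1, n)
    freqs = FREQ_CM_PER_SQRT_KCAL * 2.0 * np.sqrt(k / m) * np.sin(
        j * np.pi / (2.0 * n))
    return struct, potential, freqs
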