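"""Normal modes, principal components, and involvement spectra.

Normal-mode analysis diagonalizes the mass-weighted Hessian
M^(-1/2) H M^(-1/2); eigenvalues in kcal/mol/Å^2/amu convert to vibrational
wavenumbers via omega[cm^-1] = 108.593 * sqrt(lambda).  Principal
components diagonalize the mass-weighted covariance of a trajectory after
removing net translation and rotation by superposition onto a reference.
The two bases are compared by projecting PCs onto normal modes, and the
conformational change between a ligand-free and a ligand-bound reference is
quantified per mode by involvement coefficients I_n = |v_n . dr| and their
thermally weighted analogue T_n, in which a mode's contribution is scaled
by its thermal amplitude (1/omega_n for normal modes, sqrt(lambda_p) for
principal components) and renormalized so the squared coefficients sum to
one.

Hessians come either from an anisotropic elastic network (a desk-scale
stand-in for force-field Hessians) or from central differences of an
arbitrary analytic potential.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Tuple

import numpy as np
from scipy.linalg import eigh

from .errors import (
    BasisError,
    ConnectivityWarning,
    DecompositionError,
    DegenerateInputError,
    GeometryError,
    InputError,
    NormalizationError,
    SaddlePointWarning,
)
from .structio import (
    BACKBONE_NAMES,
    Structure,
    Trajectory,
    apply_transform,
    superpose,
)

__all__ = [
    "FREQ_CM_PER_SQRT_KCAL",
    "save_modeset",
    "load_modeset",
    "HessianMatrix",
    "ModeSet",
    "DifferenceVector",
    "InvolvementSpectrum",
    "elastic_network_hessian",
    "numerical_hessian",
    "normal_modes",
    "pca",
    "project",
    "difference_vector",
    "involvement",
    "residue_decomposition",
    "best_fit_scale",
]

# sqrt(kcal/mol/Å^2/amu) expressed as a wavenumber:
# sqrt(4184 J / (N_A * 1e-20 m^2 * 1 amu)) / (2 pi c), c in cm/s.
_KCAL = 4184.0
_NA = 6.02214076e23
_AMU = 1.66053906660e-27
_C_CM = 2.99792458e10
FREQ_CM_PER_SQRT_KCAL = float(
    np.sqrt(_KCAL / (_NA * 1e-20 * _AMU)) / (2.0 * np.pi * _C_CM)
)  # = 108.59...


@dataclass
class HessianMatrix:
    """Symmetric 3N x 3N second-derivative matrix, kcal/mol/Å^2."""

    matrix: np.ndarray
    source: str  # "elastic_network" | "numerical"

    def __post_init__(self):
        H = np.asarray(self.matrix, dtype=float)
        if H.ndim != 2 or H.shape[0] != H.shape[1] or H.shape[0] % 3:
            raise InputError("Hessian must be square with 3N rows")
        if not np.allclose(H, H.T, atol=1e-8 * max(1.0, np.abs(H).max())):
            raise InputError("Hessian must be symmetric")
        self.matrix = H

    @property
    def n_atoms(self) -> int:
        return self.matrix.shape[0] // 3


@dataclass
class ModeSet:
    """Eigenvectors over mass-weighted 3N coordinates.

    Normal modes carry frequencies (cm^-1, ascending); principal components
    carry variances (Å^2 amu, descending).  Near-zero rigid-body modes are
    discarded and counted in ``n_discarded_rigid``.
    """

    kind: str                          # "NM" | "PC"
    vectors: np.ndarray                # (3N, k), orthonormal columns
    masses: np.ndarray                 # amu per atom
    reference: Optional[Structure] = None
    frequencies: Optional[np.ndarray] = None   # cm^-1 (NM)
    variances: Optional[np.ndarray] = None     # Å^2 amu (PC)
    n_discarded_rigid: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        V = np.asarray(self.vectors, dtype=float)
        G = V.T @ V
        if not np.allclose(G, np.eye(V.shape[1]), atol=1e-8):
            raise BasisError("mode vectors are not orthonormal to 1e-8")
        self.vectors = V

    @property
    def n_modes(self) -> int:
        return self.vectors.shape[1]

    @property
    def dim(self) -> int:
        return self.vectors.shape[0]


@dataclass
class DifferenceVector:
    """Unit conformational-change direction in mass-weighted coordinates."""

    components: np.ndarray
    ref_free: Optional[Structure] = None
    ref_bound: Optional[Structure] = None

    def __post_init__(self):
        v = np.asarray(self.components, dtype=float)
        n = np.linalg.norm(v)
        if abs(n - 1.0) > 1e-10:
            raise InputError("difference vector must have unit norm")
        self.components = v


@dataclass
class InvolvementSpectrum:
    """Per-mode involvement I_n and thermal involvement T_n."""

    involvement: np.ndarray        # I_n in [0, 1]
    thermal: np.ndarray            # T_n in [0, 1], sum of squares = 1
    cumulative_sq: np.ndarray      # running sum of I_n^2
    thermal_cumulative_sq: np.ndarray


# ---------------------------------------------------------------------------
# Hessians
# ---------------------------------------------------------------------------

def elastic_network_hessian(
    structure: Structure,
    cutoff: float = 12.0,
    spring_k: float = 1.0,
) -> HessianMatrix:
    """Anisotropic-network Hessian with uniform springs inside a cutoff.

    For each atom pair within ``cutoff`` the off-diagonal 3x3 block is
    -k (d x d)/|d|^2 with d the equilibrium separation; diagonal blocks
    are minus the sum of the row's off-diagonal blocks, which enforces
    translational invariance exactly.
    """
    if cutoff <= 0:
        raise InputError("cutoff must be positive")
    X = structure.coords
    n = structure.n_atoms
    if n < 2:
        raise InputError("need at least 2 atoms")
    H = np.zeros((3 * n, 3 * n))
    diff = X[:, None, :] - X[None, :, :]
    dist = np.linalg.norm(diff, axis=2)
    neighbor = (dist <= cutoff) & (dist > 0)
    isolated = np.flatnonzero(~neighbor.any(axis=1))
    if len(isolated):
        warnings.warn(
            f"atoms without neighbors inside cutoff {cutoff} Å: "
            f"{isolated.tolist()}",
            ConnectivityWarning,
        )
    for i in range(n):
        for j in range(i + 1, n):
            if not neighbor[i, j]:
                continue
            d = diff[i, j]
            block = -spring_k * np.outer(d, d) / (dist[i, j] ** 2)
            H[3*i:3*i+3, 3*j:3*j+3] += block
            H[3*j:3*j+3, 3*i:3*i+3] += block
            H[3*i:3*i+3, 3*i:3*i+3] -= block
            H[3*j:3*j+3, 3*j:3*j+3] -= block
    return HessianMatrix(matrix=H, source="elastic_network")


def anm_energy(structure: Structure, cutoff: float, spring_k: float) -> Callable:
    """The pair-spring energy whose Hessian the ANM block formula gives."""
    X0 = structure.coords
    dist0 = np.linalg.norm(X0[:, None] - X0[None, :], axis=2)
    ii, jj = np.where(np.triu((dist0 > 0) & (dist0 <= cutoff), k=1))
    d0 = dist0[ii, jj]

    def energy(coords: np.ndarray) -> float:
        X = np.asarray(coords, dtype=float).reshape(-1, 3)
        d = np.linalg.norm(X[ii] - X[jj], axis=1)
        return float(0.5 * spring_k * np.sum((d - d0) ** 2))

    return energy


def numerical_hessian(
    potential: Callable[[np.ndarray], float],
    coords: np.ndarray,
    step: float = 1e-4,
) -> HessianMatrix:
    """Central-difference Hessian of an analytic potential, symmetrized."""
    x0 = np.asarray(coords, dtype=float).ravel()
    n = len(x0)
    if n % 3:
        raise InputError("coordinates must be 3N")
    e0 = float(potential(x0))
    if not np.isfinite(e0):
        raise InputError("potential non-finite at the expansion point")

    def e(dx):
        v = float(potential(x0 + dx))
        if not np.isfinite(v):
            raise InputError("potential non-finite at displaced point")
        return v

    H = np.empty((n, n))
    for i in range(n):
        ei = np.zeros(n)
        ei[i] = step
        H[i, i] = (e(ei) - 2.0 * e0 + e(-ei)) / step**2
        for j in range(i + 1, n):
            ej = np.zeros(n)
            ej[j] = step
            H[i, j] = H[j, i] = (
                e(ei + ej) - e(ei - ej) - e(-ei + ej) + e(-ei - ej)
            ) / (4.0 * step**2)
    H = 0.5 * (H + H.T)
    return HessianMatrix(matrix=H, source="numerical")


# ---------------------------------------------------------------------------
# Diagonalization
# ---------------------------------------------------------------------------

def normal_modes(
    hessian: HessianMatrix,
    masses: np.ndarray,
    rigid_tol: float = 1e-6,
) -> ModeSet:
    """Diagonalize the mass-weighted Hessian and convert to wavenumbers.

    Eigenvalues with |lambda| < rigid_tol * max(lambda) are treated as
    rigid-body modes and discarded (six for a non-linear isolated
    molecule).  Negative eigenvalues beyond the tolerance trigger a
    saddle-point warning and are dropped from the returned set.
    """
    m = np.asarray(masses, dtype=float)
    if np.any(m <= 0):
        raise InputError("masses must be positive")
    if 3 * len(m) != hessian.matrix.shape[0]:
        raise BasisError("mass vector does not match Hessian dimension")
    sqrtm = np.sqrt(np.repeat(m, 3))
    Hmw = hessian.matrix / np.outer(sqrtm, sqrtm)
    lam, vec = eigh(0.5 * (Hmw + Hmw.T))
    scale = max(np.abs(lam).max(), 1e-300)
    rigid = np.abs(lam) < rigid_tol * scale
    negative = (lam < 0) & ~rigid
    if np.any(negative):
        warnings.warn(
            f"{int(negative.sum())} imaginary mode(s): eigenvalues "
            f"{lam[negative].tolist()}",
            SaddlePointWarning,
        )
    keep = ~rigid & ~negative
    lam_k, vec_k = lam[keep], vec[:, keep]
    order = np.argsort(lam_k)
    lam_k, vec_k = lam_k[order], vec_k[:, order]
    freqs = FREQ_CM_PER_SQRT_KCAL * np.sqrt(lam_k)
    return ModeSet(
        kind="NM", vectors=vec_k, masses=m,
        frequencies=freqs,
        n_discarded_rigid=int(rigid.sum()),
        meta={"n_imaginary": int(negative.sum()), "source": hessian.source},
    )


def _mean_structure(frames, weights, n_iter=5):
    mean = frames[0]
    for _ in range(n_iter):
        fitted = np.empty_like(frames)
        for f in range(len(frames)):
            R, t, _ = superpose(frames[f], mean, weights)
            fitted[f] = apply_transform(frames[f], R, t)
        new_mean = fitted.mean(0)
        if np.max(np.abs(new_mean - mean)) < 1e-12:
            return new_mean, fitted
        mean = new_mean
    return mean, fitted


def pca(
    traj: Trajectory,
    masses: Optional[np.ndarray] = None,
    reference: Optional[Structure] = None,
    n_modes: Optional[int] = None,
    span: Optional[Tuple[float, float]] = None,
) -> ModeSet:
    """Principal components of the mass-weighted coordinate covariance.

    Frames (optionally restricted to a time ``span`` in ns) are
    mass-weighted superposed onto the reference (default: the iteratively
    fitted mean structure), displacements are mass-weighted, and the
    covariance matrix is diagonalized.  Variances are returned descending,
    in Å^2 amu.
    """
    if traj.n_frames < 2:
        raise DegenerateInputError("PCA requires at least 2 frames")
    frames = traj.frames
    if span is not None:
        sel = (traj.times >= span[0]) & (traj.times <= span[1])
        frames = frames[sel]
        if len(frames) < 2:
            raise DegenerateInputError("selected span has fewer than 2 frames")
    m = traj.reference.masses if masses is None else np.asarray(masses, float)
    if reference is None:
        ref_coords, fitted = _mean_structure(frames, m)
        ref_struct = traj.reference.with_coords(ref_coords)
    else:
        ref_struct = reference
        ref_coords = reference.coords
        fitted = np.empty_like(frames)
        for f in range(len(frames)):
            R, t, _ = superpose(frames[f], ref_coords, m)
            fitted[f] = apply_transform(frames[f], R, t)
    sqrtm = np.sqrt(np.repeat(m, 3))
    Q = fitted.reshape(len(fitted), -1) * sqrtm
    Q = Q - Q.mean(0)
    k = Q.shape[1] if n_modes is None else int(n_modes)
    if n_modes is not None and n_modes > len(fitted) - 1:
        warnings.warn(
            f"requested {n_modes} modes from {len(fitted)} frames "
            "(rank-deficient covariance)",
            UserWarning,
        )
    cov = (Q.T @ Q) / (len(Q) - 1)
    lam, vec = eigh(cov)
    lam, vec = lam[::-1], vec[:, ::-1]
    lam = np.clip(lam, 0.0, None)
    return ModeSet(
        kind="PC", vectors=vec[:, :k], masses=m, reference=ref_struct,
        variances=lam[:k], n_discarded_rigid=0,
        meta={"n_frames": len(fitted)},
    )


# ---------------------------------------------------------------------------
# Projections and involvement
# ---------------------------------------------------------------------------

def project(pc_vector: np.ndarray, nms: ModeSet) -> np.ndarray:
    """Squared overlaps of one PC eigenvector with each normal mode."""
    v = np.asarray(pc_vector, dtype=float)
    if v.shape != (nms.dim,):
        raise BasisError(
            f"vector dimension {v.shape} does not match mode dimension {nms.dim}"
        )
    return (nms.vectors.T @ v) ** 2


def difference_vector(
    ref_free: Structure,
    ref_bound: Structure,
    masses: Optional[np.ndarray] = None,
    mass_weighted: bool = True,
) -> DifferenceVector:
    """Normalized conformational-change direction bound - free.

    The bound reference is superposed onto the free one (optimal
    heavy-atom/mass-weighted fit removes net translation and rotation);
    the coordinate difference is mass-weighted and normalized to unit
    length.
    """
    if ref_free.n_atoms != ref_bound.n_atoms:
        raise GeometryError("reference structures differ in atom count")
    m = ref_free.masses if masses is None else np.asarray(masses, float)
    R, t, _ = superpose(ref_bound.coords, ref_free.coords, m)
    fitted = apply_transform(ref_bound.coords, R, t)
    d = (fitted - ref_free.coords).ravel()
    if mass_weighted:
        d = d * np.sqrt(np.repeat(m, 3))
    norm = np.linalg.norm(d)
    if norm < 1e-12:
        raise DegenerateInputError("structures are identical; no difference direction")
    return DifferenceVector(components=d / norm,
                            ref_free=ref_free, ref_bound=ref_bound)


def involvement(modes: ModeSet, diff: DifferenceVector) -> InvolvementSpectrum:
    """Involvement I_n = |v_n . dr| and thermal involvement T_n.

    For normal modes the thermal weight is I_n / omega_n (mode amplitudes
    scale as 1/omega); for principal components it is I_p * sqrt(lambda_p).
    T is renormalized so that sum T_n^2 = 1.
    """
    v = diff.components
    if v.shape != (modes.dim,):
        raise BasisError("difference vector dimension does not match modes")
    I = np.abs(modes.vectors.T @ v)
    if modes.kind == "NM":
        if modes.frequencies is None or np.any(modes.frequencies <= 0):
            raise NormalizationError(
                "thermal involvement undefined with zero/absent frequencies"
            )
        w = I / modes.frequencies
    else:
        if modes.variances is None:
            raise NormalizationError("PC mode set lacks variances")
        w = I * np.sqrt(modes.variances)
    norm = np.linalg.norm(w)
    T = w / norm if norm > 0 else np.zeros_like(w)
    return InvolvementSpectrum(
        involvement=I,
        thermal=T,
        cumulative_sq=np.cumsum(I**2),
        thermal_cumulative_sq=np.cumsum(T**2),
    )


def residue_decomposition(
    vector: np.ndarray,
    structure: Structure,
    atom_policy: str = "backbone",
) -> np.ndarray:
    """Per-residue amplitude: Euclidean norm over each residue's atoms."""
    v = np.asarray(vector, dtype=float)
    if v.shape != (3 * structure.n_atoms,):
        raise BasisError("vector dimension does not match structure")
    comp = v.reshape(-1, 3)
    residues = []
    seen = set()
    for c, r in zip(structure.chains, structure.resids):
        if (c, r) not in seen:
            seen.add((c, r))
            residues.append((c, r))
    out = np.empty(len(residues))
    for k, (c, r) in enumerate(residues):
        mask = (structure.chains == c) & (structure.resids == r)
        if atom_policy == "backbone":
            mask &= np.isin(structure.names, BACKBONE_NAMES)
        elif atom_policy == "alpha_carbon":
            mask &= structure.names == "CA"
        if not mask.any():
            raise DecompositionError(
                f"residue {c}:{r} has no {atom_policy} atoms"
            )
        out[k] = np.linalg.norm(comp[mask])
    return out


def save_modeset(modes: ModeSet, path) -> None:
    """TSV (one eigenvector per column) plus a JSON sidecar."""
    import hashlib
    import json
    from pathlib import Path

    path = Path(path)
    scale = modes.frequencies if modes.kind == "NM" else modes.variances
    header = "\t".join(f"{s:.10g}" for s in scale)
    label = "#omega_cm" if modes.kind == "NM" else "#lambda_A2amu"
    lines = [f"#kind\t{modes.kind}", f"{label}\t{header}"]
    for row in modes.vectors:
        lines.append("\t".join(f"{x:.17g}" for x in row))
    path.write_text("\n".join(lines) + "\n")
    ref_hash = ""
    if modes.reference is not None:
        ref_hash = hashlib.sha256(
            np.ascontiguousarray(modes.reference.coords).tobytes()
        ).hexdigest()[:16]
    sidecar = {
        "kind": modes.kind,
        "masses": modes.masses.tolist(),
        "n_discarded_rigid": modes.n_discarded_rigid,
        "reference_coord_hash": ref_hash,
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=1))


def load_modeset(path) -> ModeSet:
    import json
    from pathlib import Path

    path = Path(path)
    kind, scale, rows = None, None, []
    for line in path.read_text().splitlines():
        if line.startswith("#kind"):
            kind = line.split("\t")[1]
        elif line.startswith(("#omega_cm", "#lambda_A2amu")):
            scale = np.array([float(x) for x in line.split("\t")[1:]])
        elif line and not line.startswith("#"):
            rows.append([float(x) for x in line.split("\t")])
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    V = np.array(rows)
    return ModeSet(
        kind=kind, vectors=V, masses=np.array(sidecar["masses"]),
        frequencies=scale if kind == "NM" else None,
        variances=scale if kind == "PC" else None,
        n_discarded_rigid=sidecar["n_discarded_rigid"],
    )


def best_fit_scale(a: np.ndarray, b: np.ndarray) -> float:
    """argmin_s ||s a - b|| = (a . b) / (a . a)."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise BasisError("profiles must have the same length")
    denom = float(np.dot(a, a))
    if denom == 0:
        raise DegenerateInputError("zero reference profile")
    return float(np.dot(a, b) / denom)
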