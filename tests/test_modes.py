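"""Normal modes, PCA, projections and involvement coefficients."""

import numpy as np
import pytest

from domaindyn import modes
from domaindyn.errors import (
    BasisError,
    DegenerateInputError,
    NormalizationError,
    SaddlePointWarning,
)
from domaindyn.structio import ATOMIC_MASSES, Structure, Trajectory
from domaindyn.synthetic import (
    PlantedModes,
    gaussian_mode_trajectory,
    harmonic_chain,
    random_internal_directions,
)

from conftest import random_rigid


def cloud_structure(rng, n=8, spread=4.0):
    pts = rng.normal(scale=spread, size=(n, 3))
    return Structure(
        names=np.array(["CA"] * n), elements=np.array(["C"] * n),
        resids=np.arange(1, n + 1), resnames=np.array(["GLY"] * n),
        chains=np.array(["A"] * n), coords=pts,
        masses=np.full(n, 12.011),
    )


class TestElasticNetworkHessian:
    def test_two_atom_block(self):
        s = Structure(
            names=np.array(["CA", "CA"]), elements=np.array(["C", "C"]),
            resids=np.array([1, 2]), resnames=np.array(["GLY", "GLY"]),
            chains=np.array(["A", "A"]),
            coords=np.array([[0.0, 0, 0], [1.0, 0, 0]]),
            masses=np.array([12.0, 12.0]))
        k = 2.5
        H = modes.elastic_network_hessian(s, cutoff=2.0, spring_k=k).matrix
        block = H[0:3, 3:6]
        expected = np.zeros((3, 3))
        expected[0, 0] = -k
        np.testing.assert_allclose(block, expected, atol=1e-12)

    def test_translational_invariance(self, rng):
        s = cloud_structure(rng, n=12)
        H = modes.elastic_network_hessian(s, cutoff=8.0).matrix
        n = s.n_atoms
        rows = H.reshape(n, 3, n, 3).sum(axis=2)
        np.testing.assert_allclose(rows, 0.0, atol=1e-10)

    def test_matches_numerical_second_derivative(self, rng):
        """ANM block formula equals the Hessian of the pair-spring energy."""
        s = cloud_structure(rng, n=20, spread=3.0)
        cutoff, k = 7.0, 1.3
        analytic = modes.elastic_network_hessian(s, cutoff, k).matrix
        energy = modes.anm_energy(s, cutoff, k)
        numeric = modes.numerical_hessian(energy, s.coords, step=1e-4).matrix
        np.testing.assert_allclose(numeric, analytic, atol=1e-6)

    def test_isolated_atom_warns(self, rng):
        s = cloud_structure(rng, n=4)
        s.coords[3] += 100.0
        with pytest.warns(Warning, match="without neighbors"):
            modes.elastic_network_hessian(s, cutoff=20.0)


class TestNumericalHessian:
    def test_1d_harmonic(self):
        k = 3.7
        pot = lambda x: 0.5 * k * float(np.asarray(x).ravel()[0] ** 2)
        H = modes.numerical_hessian(pot, np.zeros(3), step=1e-3).matrix
        assert H[0, 0] == pytest.approx(k, abs=1e-6)

    def test_symmetrized_output(self, rng):
        A = rng.normal(size=(6, 6))
        pot = lambda x: float(x @ A @ x)
        H = modes.numerical_hessian(pot, np.zeros(6), step=1e-3).matrix
        np.testing.assert_allclose(H, H.T, atol=1e-20)


class TestNormalModes:
    def test_unit_conversion_constant(self):
        # unit mass-weighted curvature -> 108.59... cm^-1
        H = modes.HessianMatrix(np.eye(3), "numerical")
        ms = modes.normal_modes(H, np.ones(1), rigid_tol=0.0)
        np.testing.assert_allclose(ms.frequencies, 108.6, atol=0.05)
        assert modes.FREQ_CM_PER_SQRT_KCAL == pytest.approx(108.59, abs=0.01)

    @pytest.mark.parametrize("n,k,m", [(2, 1.0, 1.0), (8, 2.0, 3.0),
                                       (15, 0.7, 12.0)])
    def test_harmonic_chain_dispersion(self, n, k, m):
        struct, pot, analytic = harmonic_chain(n, k, m)
        H = modes.numerical_hessian(pot, struct.coords, step=1e-3)
        ms = modes.normal_modes(H, struct.masses)
        assert len(ms.frequencies) == n - 1
        np.testing.assert_allclose(ms.frequencies, analytic, rtol=1e-4)

    def test_enm_has_exactly_six_rigid_modes(self, rng):
        s = cloud_structure(rng, n=10)
        H = modes.elastic_network_hessian(s, cutoff=30.0)
        ms = modes.normal_modes(H, s.masses)
        assert ms.n_discarded_rigid == 6
        assert np.all(ms.frequencies > 0)

    def test_saddle_point_warns(self):
        H = modes.HessianMatrix(np.diag([-2.0, 1.0, 1.0]), "numerical")
        with pytest.warns(SaddlePointWarning):
            ms = modes.normal_modes(H, np.ones(1), rigid_tol=1e-9)
        assert len(ms.frequencies) == 2

    def test_eigenvectors_orthonormal(self, rng):
        s = cloud_structure(rng, n=10)
        ms = modes.normal_modes(
            modes.elastic_network_hessian(s, cutoff=30.0), s.masses)
        G = ms.vectors.T @ ms.vectors
        np.testing.assert_allclose(G, np.eye(ms.n_modes), atol=1e-10)


class TestPCA:
    def planted(self, rng, variances=(4.0, 1.0), n_atoms=8):
        ref = cloud_structure(rng, n=n_atoms)
        ref.masses[:] = 1.0
        # internal (rigid-free) directions survive the PCA superposition
        dirs = random_internal_directions(ref, len(variances), seed=5)
        return PlantedModes(reference=ref, directions=dirs,
                            variances=np.array(variances), seed=5)

    def test_static_trajectory_zero_variance(self, rng):
        ref = cloud_structure(rng)
        traj = Trajectory(ref, np.stack([ref.coords] * 4), np.arange(4.0))
        ms = modes.pca(traj, masses=np.ones(ref.n_atoms), reference=ref)
        np.testing.assert_allclose(ms.variances, 0.0, atol=1e-12)

    def test_recovers_planted_directions_and_variances(self, rng):
        planted = self.planted(rng)
        traj = gaussian_mode_trajectory(planted, 5000)
        ms = modes.pca(traj, masses=np.ones(planted.reference.n_atoms),
                       reference=planted.reference)
        np.testing.assert_allclose(ms.variances[:2], [4.0, 1.0], rtol=0.05)
        for i in range(2):
            dot = abs(np.dot(ms.vectors[:, i], planted.directions[i]))
            assert dot > 0.99
        assert ms.variances[2] < 0.05 * ms.variances[1]

    def test_rigid_transform_invariant_spectrum(self, rng):
        planted = self.planted(rng)
        plain = gaussian_mode_trajectory(planted, 2000, seed=9)
        moved = gaussian_mode_trajectory(planted, 2000, seed=9,
                                         rigid_transforms=True)
        m1 = modes.pca(plain, masses=np.ones(8), reference=planted.reference)
        m2 = modes.pca(moved, masses=np.ones(8), reference=planted.reference)
        np.testing.assert_allclose(m2.variances[:5], m1.variances[:5],
                                   atol=1e-6 * m1.variances[0])

    def test_too_few_frames(self, rng):
        ref = cloud_structure(rng)
        traj = Trajectory(ref, ref.coords[None], np.zeros(1))
        with pytest.raises(DegenerateInputError):
            modes.pca(traj)


class TestProjection:
    def nm_basis(self, rng):
        s = cloud_structure(rng, n=6)
        H = modes.elastic_network_hessian(s, cutoff=30.0)
        return modes.normal_modes(H, s.masses)

    def test_pc_equal_to_one_nm(self, rng):
        nms = self.nm_basis(rng)
        shares = modes.project(nms.vectors[:, 2], nms)
        assert shares[2] == pytest.approx(1.0, abs=1e-10)
        assert shares.sum() == pytest.approx(1.0, abs=1e-10)

    def test_mixture_shares(self, rng):
        nms = self.nm_basis(rng)
        v = 0.6 * nms.vectors[:, 0] + 0.8 * nms.vectors[:, 1]
        shares = modes.project(v, nms)
        assert shares[0] == pytest.approx(0.36, abs=1e-10)
        assert shares[1] == pytest.approx(0.64, abs=1e-10)

    def test_complete_basis_sums_to_one(self, rng):
        nms = self.nm_basis(rng)
        v = rng.normal(size=nms.dim)
        # restrict to the non-rigid subspace spanned by the modes
        v = nms.vectors @ (nms.vectors.T @ v)
        v /= np.linalg.norm(v)
        assert modes.project(v, nms).sum() == pytest.approx(1.0, abs=1e-8)

    def test_dimension_mismatch(self, rng):
        nms = self.nm_basis(rng)
        with pytest.raises(BasisError):
            modes.project(np.ones(nms.dim + 3), nms)

    def test_sign_invariance(self, rng):
        nms = self.nm_basis(rng)
        v = rng.normal(size=nms.dim)
        v /= np.linalg.norm(v)
        s1 = modes.project(v, nms)
        flipped = modes.ModeSet(
            kind="NM", vectors=-nms.vectors, masses=nms.masses,
            frequencies=nms.frequencies,
            n_discarded_rigid=nms.n_discarded_rigid)
        np.testing.assert_allclose(modes.project(v, flipped), s1, atol=1e-12)


class TestDifferenceVector:
    def test_unit_norm_and_rigid_invariance(self, rng):
        a = cloud_structure(rng)
        b = a.with_coords(a.coords + rng.normal(scale=0.3, size=a.coords.shape))
        d0 = modes.difference_vector(a, b)
        assert np.linalg.norm(d0.components) == pytest.approx(1.0, abs=1e-12)
        R, t = random_rigid(rng)
        b2 = b.with_coords(b.coords @ R.T + t)
        d1 = modes.difference_vector(a, b2)
        np.testing.assert_allclose(np.abs(np.dot(d0.components, d1.components)),
                                   1.0, atol=1e-9)

    def test_identical_structures_error(self, rng):
        a = cloud_structure(rng)
        with pytest.raises(DegenerateInputError):
            modes.difference_vector(a, a.copy())


class TestInvolvement:
    def manual_modeset(self, freqs):
        dim = 3 * len(freqs)  # arbitrary; use identity columns
        k = len(freqs)
        V = np.eye(dim)[:, :k]
        return modes.ModeSet(kind="NM", vectors=V, masses=np.ones(dim // 3),
                             frequencies=np.array(freqs, dtype=float))

    def test_single_mode_difference(self):
        ms = self.manual_modeset([1.0, 2.0, 3.0])
        d = modes.DifferenceVector(ms.vectors[:, 1])
        spec = modes.involvement(ms, d)
        np.testing.assert_allclose(spec.involvement, [0, 1, 0], atol=1e-12)
        np.testing.assert_allclose(spec.thermal, [0, 1, 0], atol=1e-12)

    def test_equal_mixture(self):
        ms = self.manual_modeset([1.0, 1.0])
        v = (ms.vectors[:, 0] + ms.vectors[:, 1]) / np.sqrt(2)
        spec = modes.involvement(ms, modes.DifferenceVector(v))
        np.testing.assert_allclose(spec.involvement, 1 / np.sqrt(2), atol=1e-12)

    def test_thermal_weighting_quarters(self):
        """Equal I with omega2 = 2*omega1 gives T1^2/T2^2 = 4."""
        ms = self.manual_modeset([1.0, 2.0])
        v = (ms.vectors[:, 0] + ms.vectors[:, 1]) / np.sqrt(2)
        spec = modes.involvement(ms, modes.DifferenceVector(v))
        assert spec.thermal[0] ** 2 / spec.thermal[1] ** 2 == \
            pytest.approx(4.0, rel=1e-10)
        assert np.sum(spec.thermal**2) == pytest.approx(1.0, abs=1e-12)

    def test_completeness_over_full_basis(self, rng):
        """Sum of I_n^2 = 1 when the mode basis spans the deformation."""
        s = cloud_structure(rng, n=10)
        H = modes.elastic_network_hessian(s, cutoff=30.0)
        nms = modes.normal_modes(H, s.masses)
        # small internal deformation along a mixture of modes (Cartesian
        # displacement = M^(-1/2) q, masses here uniform)
        q = nms.vectors @ rng.normal(size=nms.n_modes)
        disp = (q / np.sqrt(np.repeat(s.masses, 3))).reshape(-1, 3)
        b = s.with_coords(s.coords + 1e-3 * disp)
        d = modes.difference_vector(s, b)
        spec = modes.involvement(nms, d)
        assert np.sum(spec.involvement**2) == pytest.approx(1.0, abs=1e-8)

    def test_zero_frequency_rejected(self):
        ms = self.manual_modeset([1.0, 2.0])
        ms.frequencies = np.array([0.0, 2.0])
        v = ms.vectors[:, 1]
        with pytest.raises(NormalizationError):
            modes.involvement(ms, modes.DifferenceVector(v))


class TestPCANMAConsistency:
    def test_boltzmann_sampling_matches_equipartition(self, rng):
        """PCs of harmonic Boltzmann sampling converge to the normal modes,
        with variances k_B T / lambda_n (mass-weighted units)."""
        s = cloud_structure(rng, n=7)
        s.masses[:] = 1.0
        H = modes.elastic_network_hessian(s, cutoff=30.0, spring_k=1.0)
        nms = modes.normal_modes(H, s.masses)
        lam = (nms.frequencies / modes.FREQ_CM_PER_SQRT_KCAL) ** 2
        kt = 0.0019872 * 300.0
        n_frames = 20000
        coeffs = rng.normal(size=(n_frames, nms.n_modes)) * np.sqrt(kt / lam)
        disp = coeffs @ nms.vectors.T
        frames = s.coords[None] + disp.reshape(n_frames, -1, 3)
        traj = Trajectory(s, frames, np.arange(float(n_frames)))
        pcs = modes.pca(traj, masses=s.masses, reference=s)
        expected = np.sort(kt / lam)[::-1]
        got = pcs.variances[:nms.n_modes]
        np.testing.assert_allclose(got, expected, rtol=0.10)
        # softest normal mode dominates the first PC
        overlap = abs(np.dot(pcs.vectors[:, 0], nms.vectors[:, 0]))
        assert overlap > 0.9


class TestResidueDecomposition:
    def test_amplitudes_and_error(self, toy_chain):
        v = np.zeros(3 * toy_chain.n_atoms)
        # displace residue 30's CA by (3, 4, 0) -> amplitude 5
        idx = np.flatnonzero((toy_chain.resids == 30) &
                             (toy_chain.names == "CA"))[0]
        v[3 * idx:3 * idx + 2] = [3.0, 4.0]
        amps = modes.residue_decomposition(v, toy_chain)
        assert amps[30 - 24] == pytest.approx(5.0)
        assert np.count_nonzero(amps) == 1

    def test_ligand_residue_without_backbone_errors(self, two_domain):
        from domaindyn.errors import DecompositionError
        v = np.zeros(3 * two_domain.n_atoms)
        v[0] = 1.0
        with pytest.raises(DecompositionError):
            modes.residue_decomposition(v, two_domain)


class TestBestFitScale:
    @pytest.mark.parametrize("factor", [2.0, -0.5, 0.0])
    def test_exact_scalings(self, rng, factor):
        a = rng.normal(size=40)
        assert modes.best_fit_scale(a, factor * a) == pytest.approx(factor)

    def test_orthogonal_profiles_scale_zero(self):
        a = np.array([1.0, 0.0, 1.0, 0.0])
        b = np.array([0.0, 1.0, 0.0, 1.0])
        assert modes.best_fit_scale(a, b) == 0.0

    def test_noisy_least_squares_closed_form(self, rng):
        a = rng.normal(size=100)
        b = 2.36 * a + rng.normal(scale=0.1, size=100)
        assert modes.best_fit_scale(a, b) == pytest.approx(
            np.dot(a, b) / np.dot(a, a), rel=1e-12)


class TestModeSetIO:
    def test_save_load_roundtrip(self, rng, tmp_path):
        s = cloud_structure(rng, n=6)
        nms = modes.normal_modes(
            modes.elastic_network_hessian(s, cutoff=30.0), s.masses)
        nms.reference = s
        p = tmp_path / "modes.tsv"
        modes.save_modeset(nms, p)
        back = modes.load_modeset(p)
        assert back.kind == "NM"
        np.testing.assert_allclose(back.vectors, nms.vectors, atol=1e-15)
        np.testing.assert_allclose(back.frequencies, nms.frequencies,
                                   rtol=1e-9)
        assert back.n_discarded_rigid == 6
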