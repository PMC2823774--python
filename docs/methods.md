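# Methods

This note documents the models, conventions and numerical choices behind
the package, what the synthetic generators do and do not emulate, and the
known limitations.

## System and coordinates

The target system is a two-domain protein with a flexible linker — the
PDC109 layout, with an N-terminal Fn2 domain (residues 24–61), a linker
(62–68) and a C-terminal Fn2 domain (69–109), each Fn2 domain binding one
phosphorylcholine (PhC). All analyses operate on plain coordinate arrays
in Å with per-atom masses in amu; structures come from fixed-column PDB
parsing (v3.3 layout). Alternate locations are resolved to the
highest-occupancy conformer, ties keeping the first encountered, so real
crystal files parse deterministically. Hydrogens absent from the input are
never added; masses come from a built-in standard-atomic-weight table.
Heavy-atom analyses are the default throughout (mode analysis in
particular excludes hydrogens).

## Collective variables

* **Binding-site distances.** Tryptophan convention: distance from the
  ligand quaternary ammonium nitrogen to the unweighted center of geometry
  of the six indole-ring carbons (CD2, CE2, CE3, CZ2, CZ3, CH2). Tyrosine
  convention: distance from the hydroxyl oxygen to the mean position of
  the three anionic phosphate oxygens. The phosphate oxygens are
  identified geometrically (O within 1.75 Å of the ligand phosphorus and
  not within 1.6 Å of a carbon), which excludes the choline ester oxygen
  without relying on author-specific atom names (in the CCD entry for PhC
  these are O1/O3/O4, with O2 the ester oxygen and N1 the nitrogen).
* **Orientation cosine.** cos θ between V₁ = r(W58)−r(W47) and
  V₂ = r(W106)−r(W93) (Cα positions). The vector direction convention
  (second-listed minus first-listed residue) is arbitrary; cos θ is
  invariant under simultaneous flips and the convention is fixed in the
  orientation spec. On the crystal structure this gives ≈0.8 (≈37°).
* **Inter-domain distance D.** Euclidean distance between mass-weighted
  centers of the two domains' backbone (N, CA, C, O) atoms. Center of mass
  is mass-weighted; center of geometry is unweighted — both are exposed
  because the two distance conventions above use one each.
* **Segmental RMSD.** Each frame is least-squares superposed on the
  backbone atoms of a fit segment, then RMSD is evaluated over the
  analysis segment's backbone. For per-domain and linker series the fit
  segment defaults to the segment itself (internal deformation); for the
  whole molecule the fit is the whole backbone, so relative domain motion
  shows up in the whole-molecule series but not in the per-domain ones.
* **RMSF.** Frames are iteratively superposed onto the running mean
  structure of the segment (fit–average fixed point, ≤5 iterations,
  1e-10 convergence); per-atom RMSF is the 3D root-mean-square deviation
  from the mean position. The segment RMSF is the mean over member atoms;
  the normalized RMSF divides by the residue count. The normalization
  convention ("per residue") is not uniquely determined by its verbal
  description; division by N (not √N) is the package convention, kept
  configurable by using the unnormalized value and residue count that the
  report also carries.
* **Protomer segmental RMSD.** For each segment, protomer A's backbone is
  superposed onto protomer B's (per-segment fit, backbone atoms), the
  backbone RMSD is divided by residue count (Å per residue). Per-segment
  backbone fitting is the default; whether the published convention fit
  per segment or per protomer, backbone or heavy-atom, is not
  determinable from the printed values alone, so `fit=False` and custom
  atom policies remain available. Units are Å per residue.

## Superposition

Weighted least-squares rigid fit (Kabsch via `scipy`'s
`Rotation.align_vectors`), proper rotation guaranteed. Degenerate inputs
(<3 points, collinear sets, by singular-value ratio < 1e-8) are rejected.
Weights default to uniform; mass weighting is used by the mode analyses.

## PMF from force windows

A window holds per-bin estimates of dW/dξ over [lo, hi] tiled by 0.05 Å
bins (the published protocol: five 4 Å windows with 2 Å overlaps covering
2–14 Å). **Gradient convention:** `mean_gradient` is the *bin-average* of
dW/dξ — which is what an adaptive-biasing-force estimator accumulates —
so the cumulative sum g·Δξ reproduces W at bin edges exactly for any
smooth profile. This makes stitching machine-precision exact on noise-free
windows, which a midpoint/trapezoid convention cannot achieve (its
O(h²) bias is ~0.01 kcal/mol on these wells); the stitched profile
therefore lives on bin edges.

Overlapping windows are reconciled by the constant offset minimizing the
squared disagreement over shared grid points (windows must share a bin
lattice; gaps are an error); multiply covered points are averaged. The
profile is anchored so W(ξ₀)=0, ξ₀ = 14 Å by default (the far end of the
sampled range, a lower-bound convention for binding constants).

**Errors.** The per-point standard deviation uses
SD[ΔW] = |ξ−ξ₀|·√(2κσ_F²/N) with the pooled force variance σ_F², total
sample count N and correlation length κ of the window covering the point
(the best-sampled one in overlaps). κ is the statistical inefficiency
1 + 2Σρ(t), autocorrelations summed to the first non-positive value. A
50-replicate Monte-Carlo calibration in the test suite confirms the
estimate is within a factor of two of the empirical spread (it
over-estimates by ≈√2 on AR(1) noise, the safe side).

**Minima.** Strict local minima of the (optionally moving-average
smoothed, default none) grid profile; depth is −W since W(ξ₀)=0; the
global minimum is the deepest well.

**Association constants.** The printed form of the defining equation is
typographically lost in the source material, so both plausible readings
are implemented and the mode is recorded in every output:

* `two_state` (default): K_a = e^(−ΔG/RT)/(C·w), ΔG the depth of the
  global minimum inside the bound region relative to W(ξ₀), C the
  reference concentration, w the `dimer_weight` (4 when comparing a
  per-Fn2-domain profile against measurements on the two-domain dimer —
  a pure bookkeeping convention, not an inference).
* `volume_integral`: K_a = N_A·10⁻²⁷·∫ 4πξ² e^(−W/RT) dξ over the bound
  region (Å³→L), divided by the dimer weight. Quadrature is per-interval
  16-point Gauss–Legendre on the piecewise-linear profile, matching the
  square-well closed form to 1e-6 relative.

The effective K_a over several sites is the Boltzmann-weighted mean
Σ K_i·e^(−ΔG_i/RT) / Σ e^(−ΔG_i/RT); with the published per-domain pair
(28.2 M⁻¹ at −2.1 kcal/mol, 27.7 M⁻¹ at −2.0 kcal/mol) it reproduces the
printed effective value of 28 M⁻¹. R = 1.98720425864×10⁻³ kcal/mol/K,
T = 300 K by default.

## Mode analysis

* **Hessians.** The anisotropic elastic network (pair springs k inside a
  cutoff; off-diagonal 3×3 blocks −k·(d⊗d)/|d|², diagonal blocks enforcing
  translational invariance) is the desk-scale stand-in for force-field
  Hessians, which are out of scope. A central-difference numerical Hessian
  of an arbitrary potential (symmetrized) supports analytic test systems.
* **Normal modes.** Diagonalization of M^(−1/2)·H·M^(−1/2). Eigenvalues in
  kcal/mol/Å²/amu convert to wavenumbers by ω[cm⁻¹] = 108.5914·√λ (from
  CODATA constants: √(4184 J/(N_A·10⁻²⁰ m²·amu))/(2πc)). Rigid-body modes
  are discarded by the tolerance |λ| < 1e-6·max|λ| and counted (exactly 6
  for a 3D non-linear molecule); negative eigenvalues beyond tolerance
  raise a saddle-point warning and are dropped.
* **PCA.** Frames are mass-weighted superposed onto a reference (default:
  the iteratively fitted mean structure; a time-span restriction
  reproduces tail-averaged references), displacements are mass-weighted,
  and the covariance is diagonalized; variances (Å²·amu) descend. For a
  trajectory Boltzmann-sampled from a harmonic network at temperature T,
  PC directions converge to the normal modes with variances k_BT/λ_n
  (verified to 10 % at 20 000 frames in the tests).
* **Difference vector.** The bound reference is superposed onto the free
  one (mass-weighted heavy-atom fit removes net translation/rotation);
  the coordinate difference is mass-weighted and normalized. Residual
  rigid-body content after the fit is second order in the deformation.
* **Involvement.** I_n = |v_n·Δr̂|; with a complete basis Σ I_n² = 1. The
  printed formula for the thermal variant is garbled in the source; the
  implementation follows the stated 1/ω amplitude scaling: T_n ∝ I_n/ω_n
  for normal modes (I_p·√λ_p for PCs), renormalized so Σ T_n² = 1, and is
  isolated in one function for easy revision. Outputs report I, T and
  cumulative squared percentages, since published percentage accountings
  are most consistent with squared shares.
* **Residue decomposition.** Per-residue amplitude is the Euclidean norm
  of the vector's components over that residue's backbone atoms; the
  best-fit scale between two profiles is the least-squares (a·b)/(a·a).

## Synthetic generators (what a green test establishes)

All generators are pure functions of (parameters, seed) — identical inputs
give bit-identical outputs — and emit planted-truth JSON sidecars when
writing files, so tests never re-derive truth from the artifact.

* **Planted PMF.** Sum of inverted Gaussians plus a harmonic wall below
  2.5 Å. Default wells follow the published two-well profile of the
  N-terminal domain (3.0 Å/1.0 kcal/mol, 5.6 Å/2.1 kcal/mol); the
  C-terminal preset is 3.0/1.1 and 5.7/2.0. Well widths of 0.5 Å are a
  package choice — neither stated in the source material nor critical; it
  is a typical width for a binding PMF resolved at 0.05 Å bins and keeps
  the two wells cleanly separated. The wall stiffness 5 kcal/mol/Å²
  likewise just provides the expected repulsive rise at short range.
* **Force windows.** Per-window AR(1) force noise (default coefficient
  0.9, marginal SD 1.0 kcal/mol/Å, 1000 samples/bin) directly exercises
  the correlation-length machinery (κ→(1+φ)/(1−φ)=19). Bin means,
  variances and κ are measured from the generated samples, not assumed.
  What this does *not* emulate: non-stationary sampling, bin-boundary
  effects of a real ABF estimator, or Jacobian corrections.
* **Two-domain pseudo-protein.** Helical domains, extended linker,
  marker residues carrying ring/hydroxyl atoms and a PhC-like ligand
  (N1, choline C, P, ester O, three anionic O) per domain. Chemically
  unrealistic by design: the geometry stages consume only named groups,
  so marker topology is sufficient for correctness tests — green tests
  say nothing about force-field realism.
* **Schedule trajectories.** Domain B is rigidly re-posed per frame so the
  emitted cos θ and D match their targets exactly before noise; linker
  atoms interpolate between the domain transforms (so a varying schedule
  deforms only the linker — the planted analogue of hinge motion);
  Gaussian coordinate noise is added after posing. Infeasible distances
  (domain overlap) are rejected.
* **Gaussian-mode trajectories.** Frames sampled along planted orthonormal
  directions; for PCA recovery the directions are drawn orthogonal to the
  rigid-body subspace (`random_internal_directions`), because the PCA fit
  removes net translation/rotation and would otherwise absorb part of a
  generic direction's variance.
* **Harmonic chain.** Springs couple x-coordinates only, so transverse
  degrees of freedom are exact zero modes and the nonzero spectrum is the
  closed form 2√(k/m)·sin(jπ/2n).

## Numerical choices

* Stitching offsets: least-squares constant per window over overlap
  points (edge anchoring would propagate single-bin noise).
* W(ξ₀)=0 is exact at the nearest grid point when ξ₀ lies on the grid
  (within 1e-9), interpolated otherwise.
* Rigid-mode tolerance 1e-6·max|λ|; orthonormality checks at 1e-8;
  unit-norm checks at 1e-10.
* Gauss–Legendre order 16 per profile interval for the volume integral.
* Minima are strict (no plateaus); smoothing is off by default and
  exposed as a bin-count flag.
* PDB coordinates are written at the format's 3-decimal precision; file
  round-trip tests use 5e-4 Å tolerances accordingly.

## Limitations

* No molecular dynamics, minimization or force fields: Hessians are
  elastic-network or analytic, and trajectories are synthetic. Published
  values that require the original multi-hundred-ns trajectories (PMF
  depths from explicit-solvent sampling, K_a ≈ 28 M⁻¹, time series,
  involvement percentages) are out of desk reach; the test suite instead
  verifies the machinery on planted ground truth at matched protocol
  parameters.
* The crystal-geometry regression requires the 1h8p structure file, which
  must be supplied by the user (`tests/data/1h8p.pdb`).
* mmCIF and compressed trajectory formats are not read; no hydrogen
  placement or bond perception.
* The volume-integral K_a applies the dimer weight as a plain divisor;
  box-volume standard-state corrections beyond the 4πξ² factor are out of
  scope.
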