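# Methods

## Scope and data flow

`spinrelax` computes dipole-dipole induced spin-lattice relaxation for
hydrogen nuclei partitioned into a water pool (WP) and a macromolecule pool
(MP). The pipeline is

trajectory → pair displacement (minimum image) → rank-2 spherical harmonics
F₂,q → lag autocorrelation G_q(τ) → spectral density J_q(ω) → rate assembly
(intra-pool R1; cross-pool auto/cross) → pool averages → effective rates →
power-law field fit → weighted sheath average.

Positions are kept in nm and times in ps throughout; conversion to SI
(m⁻⁶ s for spectral densities) happens exactly once, at the rate kernels,
and is enforced by a units tag on every `SpectralDensity` — passing an
internal-unit density into a rate kernel raises `UnitsError` rather than
silently producing rates off by 10⁴².

## Relaxation model and assumptions

The rates follow the semiclassical dipolar framework: classical motion, a
quantum dipolar Hamiltonian, and no secondary mechanisms (J-coupling,
chemical-shift anisotropy, spin-rotation). The spin-operator algebra is
absorbed into the numeric prefactors of the rate expressions (see README),
with K = (μ₀/4π) γ_H² ħ ≈ 7.55·10⁻²⁵ m³/s. All intra-pool partner sums use
the general (non-isotropic) form — no assumption that tumbling is isotropic
is made for analysed data; the isotropic closed form (BPP Lorentzian) is
kept only as an independent oracle (`rates.bpp_r1`).

The cross rate (1/16)K²Σ[9J₂(2ω_L) − J₀(0)] is signed: in the slow-motion
regime J₀(0) dominates and cross-relaxation transfers inverted
magnetization. Averages never take absolute values. Because both pools'
cross-rate averages are the same pairwise double sum divided by the
respective pool size, detailed balance N_WP·R̄_cross,WP = N_MP·R̄_cross,MP
holds to machine precision whenever both sides are computed from one shared
pairwise spectral-density set, and `cross_pool_rates` is structured to
guarantee exactly that.

## Correlation and spectral-density estimators

* Autocorrelation: FFT-based with zero padding to ≥ 2N (no circular wrap),
  real part, unbiased per-lag divisor N−k. An O(N²) direct-sum twin
  (`autocorrelate_direct`) exists purely as a cross-check; the two agree to
  1e−10 relative on random series.
* Truncation: the lag grid is cut at a configurable fraction of the series
  duration (default 0.3) because the tail of a finite-trajectory estimate is
  noise-dominated. For synthetic fixtures with known τ_c the analyses
  truncate near 30 τ_c — beyond that the exponential has decayed to e⁻³⁰
  while the noise variance keeps accumulating linearly in the integration
  window.
* Spectral density: trapezoidal integration of 2·G_q(τ)cos(ωτ) on the
  uniform lag grid; no tail extrapolation (slowly decaying correlations are
  the model-free path's job). Frequencies with ω·dt > π/4 are refused since
  the grid cannot resolve the oscillation; at the 0.5 ps sampling typical of
  membrane simulations this admits all proton Larmor frequencies well beyond
  7 T.

## Model-free fitting

Normalized correlations are fitted per q (independently — the closed form
is stated per q; no joint fit) to S²e^(−τ/τ_M) + (1−S²)e^(−τ/τ_i) by bounded
least squares: S² ∈ [0,1], timescales in [10⁻³ dt, 100 τ_max]. Multi-start
over S² ∈ {0.2, 0.5, 0.8} × three τ_M decades, τ_i seeded from the initial
10% decay; best residual wins, so the reported residual is non-increasing
over starts. The two exponentials are symmetric under
(S², τ_M) ↔ (1−S², τ_i); after fitting, the slower timescale is relabelled
τ_M. Two degeneracies are handled explicitly: if τ_i and τ_M collapse within
1% the curve is a single exponential and the rigid limit S² = 1 is reported;
if the fast amplitude 1−S² < 0.01, τ_i is flagged unidentifiable.
Convergence: xtol 1e−10, max 10⁴ evaluations. Noiseless two-exponential
curves are recovered to 1e−6 relative.

The MP analysis path uses model-free spectral densities (macromolecular
correlations need not decay within the trajectory); WP and cross-pool paths
integrate numerically — correlations there converge. This split is exposed
as `method=` on `intra_pool_rates`.

## Synthetic generators (what they emulate, what they don't)

All generators draw from one counter-based Philox stream per master seed
(bitwise reproducible), emit rigid H–H pairs (default separation 0.158 nm)
on widely spaced centres (50 nm grid, making inter-molecular dipolar terms
~10⁻¹⁶ of intra-pair ones, so isolated-pair oracles survive all-pair sums),
and record their ground truth in the trajectory metadata.

* `isotropic_rotor`: orientation performs rotational Brownian motion,
  D_r = 1/(6τ_c), via per-step random axis-angle rotations with per-axis
  variance 2·D_r·dt. Step variances above 0.1 rad² are refused (coarse steps
  bias the decay). Oracle: ⟨P₂(u(0)·u(τ))⟩ = e^(−τ/τ_c) and uniform-sphere
  harmonic magnitudes A₀:A₁:A₂ = 12:2:8.
* `cone_restricted_rotor`: wobble in a cone (reflected spherical diffusion
  inside half-angle β, with [cosβ(1+cosβ)/2]² = S²) composed with global
  isotropic tumbling at τ_M. The stationary within-cone distribution is
  uniform, so the plateau order parameter is exact by construction; the
  effective internal time is of order τ_i but not exactly τ_i, which is why
  recovery tests assert S² and τ_M, not τ_i. S² = 1 delegates to a pure
  global rotor.
* `translational_brownian`: Gaussian displacement steps, variance 2·D·dt
  per axis; Einstein relation MSD = 6Dt is the oracle. The mean-squared-
  displacement fit, not a viscosity/radius (Stokes–Einstein) model, defines
  D here.
* `water_slab`: Brownian centres between reflecting walls with local D(z),
  orientations tumbling with local τ_c(z); slower mobility near the walls
  emulates water at membrane surfaces and produces the characteristic
  parabola-like R1 profile (high at the walls, low mid-slab). Centres stay
  half a pair length clear of the walls so hydrogens never leave the slab.
  Limitation: the position-dependent-D update ignores the spurious-drift
  (∇D) correction of inhomogeneous diffusion, and molecules do not interact;
  profile tests are therefore qualitative (shape and ordering), not
  quantitative Boltzmann-level checks.

None of the generators contain forces, water models or lipid chemistry.
Passing tests therefore demonstrate that the *analysis* is correct on motion
with known statistics — not that any particular membrane simulation is
faithful to real myelin.

## Spatial profiles

`windowed_profile` repeats the rate computation on short windows with random
start frames and random molecules, recording each window's rate and mean
position, plus an MSD-slope diffusion estimate of the pair centre; binning
by position yields R1(z) and D(z) with standard errors. Windows must be
short against the slab-crossing time for the position label to mean
anything; the reference protocol value (1.5 ns windows, 2000 windows) is the
default in `AnalysisConfig`. The MSD fit uses the early-lag window
(0.2%–2% of the maximum lag) where every frame contributes a time origin;
long lags carry few independent displacements and are excluded.

## Defaults and problem sizes

`AnalysisConfig` defaults: fields 1.5/3/7 T, truncation 0.3, 1.5 ns windows,
2000 windows, 10% MP subsampling, seed 0. Test and validation ensembles are
desk-scale by design: 32 pairs × 10⁵ steps for the closed-form equivalence
(agreement within 5% at all τ_c ∈ {2.5, 100, 5000} ps and all three
fields), 24 pairs × 4·10⁴ steps for order-parameter recovery (S² within
±0.05, τ_M within ±15%), 100 molecules × 10⁴ steps for diffusion recovery
(within 5%), 150 molecules × 8·10³ steps for the slab profile (wall bins
exceed centre bins by > 3 SE).

## Reference inputs

`spinrelax.reference` carries the published averaged-rate table
(per pool: intrinsic, cross, auto at the three fields), the pool sizes
(N_WP = 9398 water hydrogens, of which 9397 act as partners to a selected
proton; N_MP = 13810, which the bundled lipid formulas reproduce exactly),
the membrane composition (whose water mass fraction evaluates to 40%), and
the printed effective-rate fit coefficients. The arithmetic-reproduction
path reports the 7 T sheath average both from fits of the tabulated
effective rates (1.85 Hz) and from the printed fit functions (1.82 Hz); the
difference traces to print rounding of the tabulated MP rates, which shifts
the fitted MP prefactor from 5.98 to ≈ 6.11.

## Known limitations

* Orthorhombic boxes only; no frame alignment or drift removal.
* No chemical-exchange kinetics: the exchange decomposition takes the
  chemical-exchange rate as external input.
* Membrane-normal orientation dependence of MP rates is not modelled.
* The per-partner model-free path fits every pair independently and is
  expensive for dense systems; use the partner cutoff (r⁻⁶-bounded error)
  for large pools.
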