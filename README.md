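# spinrelax

Dipolar spin-lattice relaxation analysis for two-pool water/macromolecule
hydrogen systems, from trajectories to field-dependent R1.

## The problem

In myelin-rich white matter, the longitudinal (R1) relaxation of hydrogen
nuclei is driven by fluctuating ^1H-^1H dipole-dipole couplings. Water
confined between the lipid membranes of the myelin sheath (the *water pool*,
WP) and the lipid-bound hydrogens (the *macromolecule pool*, MP) relax at
very different rates, exchange magnetization through dipolar
cross-relaxation, and both contribute to the MR signal. Experimental
separation of the two pools is notoriously uncertain, which motivates
computing the rates directly from hydrogen trajectories. This package
implements that computation — and, because re-running a cluster-scale
membrane simulation is out of desk scope, it ships statistically controlled
synthetic trajectory generators with known motional ground truth so every
stage of the analysis has an oracle.

## The model

For a spin pair at separation r with orientation (θ, φ) relative to B0 ∥ z,
the lattice functions are the rank-2 spherical harmonics
F₂,₀ = (1 − 3cos²θ)/r³, F₂,₁ = sinθ cosθ e^(−iφ)/r³, F₂,₂ = sin²θ e^(−2iφ)/r³.
Their lag autocorrelations G_q(τ) = Re⟨F_q(t)F_q*(t+τ)⟩ give spectral
densities J_q(ω) = 2∫₀^∞ G_q(τ) cos(ωτ) dτ, and with
K = (μ₀/4π) γ_H² ħ the rates are

- intra-pool: R₁ = (9/8) K² Σᵢ [J₁(ω_L) + J₂(2ω_L)]
- cross-pool: R₁^auto = (1/16) K² Σᵢ [J₀(0) + 18 J₁(ω_L) + 9 J₂(2ω_L)],
  R₁^cross = (1/16) K² Σᵢ [9 J₂(2ω_L) − J₀(0)]

with ω_L = γ_H B0 and the sums over partner nuclei in the same or the other
pool respectively. Macromolecular correlations that do not decay within the
trajectory are handled by the two-timescale model-free form
Ĝ(τ) = S² e^(−τ/τ_M) + (1 − S²) e^(−τ/τ_i) and its two-Lorentzian spectral
density. Effective rates R₁^ef = R₁ + R₁^auto are fitted across field
strengths as n₀·B0^n1, and the whole-sheath average is the hydrogen-count-
weighted mean of the two pools' effective-rate functions.

## Worked example

Generate isotropically tumbling spin pairs with a 10 ps rotational
correlation time and push them through the full numeric pipeline:

```
$ spinrelax generate --kind isotropic_rotor --tau-c 10 --dt 0.5 \
      --n-steps 20000 --n-pairs 8 --seed 6 --out iso.sptrj
$ spinrelax rates --input iso.sptrj --outdir out --fields 1.5,3,7 \
      --truncation 0.03 --cutoff-nm 1.0
            mean        se   n
R1_1.5  0.541452  0.033127  16
R1_3    0.541808  0.032060  16
R1_7    0.543704  0.026356  16
```

The 16 protons (8 pairs) average to R1 ≈ 0.54 s⁻¹ at all three fields —
with ω_L τ_c ≪ 1 the motion is in the extreme-narrowing regime, so the rate
is field-independent. The run also writes `bpp_comparison.csv` comparing the
pipeline against the closed-form BPP rate for the generator's ground truth:

```
 B0  pipeline_R1  closed_form_R1  relative_difference
1.5     0.541452        0.549182            -0.014077
3.0     0.541808        0.549092            -0.013266
7.0     0.543704        0.548558            -0.008849
```

The published two-pool arithmetic (effective rates, field-dependence fits,
whole-sheath average) is reproduced from the bundled averaged-rate table:

```
$ spinrelax published-arithmetic
     R1_WP  R1_WP_cross  R1_WP_auto  R1_MP  R1_MP_cross  R1_MP_auto  R1_WP_ef  R1_MP_ef
B0
1.5  1.175        0.061       0.165   4.95        0.042       0.112     1.340     5.062
3.0  0.978        0.039       0.132   3.72        0.027       0.090     1.110     3.810
7.0  0.718        0.016       0.095   2.43        0.011       0.065     0.813     2.495
WP power law: n0=1.537 n1=-0.318
MP power law: n0=6.113 n1=-0.450
sheath average at 7 T (table fits): 1.851 Hz
sheath average at 7 T (published fits): 1.821 Hz
```

The water pool relaxes at 1.34 Hz effective at 1.5 T falling to 0.81 Hz at
7 T (n₀ ≈ 1.53, n₁ ≈ −0.32); the lipid pool follows ≈ 6·B0^−0.45; weighting
the two fitted functions by pool size gives a whole-sheath rate of ≈ 1.8 Hz
at 7 T.

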