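# Methods

This note documents the models implemented in `ppixquant`, the tunable
parameters that matter, the synthetic phantom generator used for
validation, and the numerical and design choices made where the design was
genuinely open.

## Signal model and pre-processing

Emission scans are photon counts on a uniform wavelength grid, by default
450–800 nm with a 1 nm step (351 samples, both endpoints included); all
internal computation happens on this grid and coarser inputs (reflectance,
optical properties) are linearly interpolated onto it. Pre-processing
divides raw counts by dwell time × scan repeats × per-wavelength emission
filter transmission, yielding counts/s. Filter compensation is applied per
emission wavelength rather than as a band average — the per-wavelength form
is exact when the transmission curve is known on the grid. Dark-noise and
source-fluctuation corrections are assumed already applied upstream by the
instrument.

Spectra tables are delimited text in two dialects (wavelengths as header
row or as first column), auto-detected and overridable, since no standard
file format exists for this kind of data.

## Optical properties

Total reflectance from an integrating sphere includes a specular (Fresnel)
component; at normal incidence between media of indices n₁, n₂ it is
((n₁−n₂)/(n₁+n₂))², exactly 0.04 for air/glass (1.0/1.5), and it is
subtracted as a constant with clamping at zero. Reduced scattering spectra
are summarised by the mixed Rayleigh–Mie model

    μs′(λ) = a′ ( f_Ray (λ/λ₀)⁻⁴ + (1−f_Ray)(λ/λ₀)^(−b_Mie) ),  λ₀ = 500 nm,

fitted by trust-region bounded least squares over 450–1000 nm with bounds
a′ > 0, f_Ray ∈ [0, 1], b_Mie ∈ [0, 4] (the upper bound keeps the Mie
exponent below the Rayleigh exponent, the physical ordering), initialised
at a′ = μs′(λ₀), f_Ray = 0.1, b_Mie = 1. Both f_Ray and the Mie fraction
1−f_Ray are reported explicitly to avoid ambiguity. Inversion of sphere
measurements to μa/μs′ (adding-doubling, Monte-Carlo transport) is out of
scope; the package consumes tabulated coefficients.

## Blind unmixing

The factorisation V ≈ WH (all non-negative) is fitted by the classical
multiplicative updates, interleaved H-then-W, under three objectives:

* **euclidean** — ‖V−WH‖²; homoscedastic Gaussian noise assumption.
* **divergence** — Σ(V log(V/WH) − V + WH); the Poisson-count objective.
  The printed form of the classical KL update rule carries an ambiguous
  denominator index; the standard column/row-sum normalisation
  (Σₗ W_{li} for H, Σₗ H_{jl} for W) is implemented.
* **hellinger** — ‖√V−√(WH)‖²; implemented literally as the Euclidean
  machinery applied to √V, so the two code paths agree element-wise under
  a shared seed. The square root stabilises Poisson variance at high
  counts, giving an approximately homoscedastic problem.

Numerical choices: an ε-floor of 1e-12 on W, H and WH inside ratios and
logarithms (zeros are otherwise absorbing states of multiplicative
updates); initialisation from a seeded uniform(ε, 1) draw scaled so
mean(WH) = mean(V); convergence when the relative change of the
(regularised) objective drops below 1e-6, capped at 2000 iterations; 5
random restarts by default, keeping the lowest objective. After fitting,
endmembers are rescaled to unit area on the grid with abundances rescaled
inversely — the product WH is unchanged; this fixes the scale degeneracy
of NMF so abundances are comparable across runs.

**Smoothness.** Endmember spectra should be smooth in λ, encoded as a
Tikhonov penalty α_Γ‖ΓH‖² with Γ the (m−1)×m first-difference operator.
Rather than deriving a new multiplicative rule, a projected gradient step
H ← max(0, H_mult − α_Γ ΓᵀΓH) follows each multiplicative update; the
learning rate is folded into α_Γ. The alternation is inexact by design: the
combined objective decreases in ≥ 95 % of iterations rather than strictly.
Because the step is linear in H, a dimensionless weight is scale-free;
`alpha_gamma="auto"` resolves to 0.02, which shrinks high-frequency
content by a few percent per iteration while leaving convergence intact.
Values approaching 0.25 destabilise the step (the spectral norm of ΓᵀΓ
is ≤ 4).

**System-noise endmember.** Spectra exhibit a sharp instrumental spike near
690 nm. One additional endmember is initialised as a unit-peak Gaussian at
690 nm (FWHM 4 nm — the width is a free choice; any width narrow compared
with fluorophore emission works) and exempted from the smoothness step, so
it can stay sharp and absorb the spike instead of contaminating the smooth
endmembers. On planted-spike data the exempt endmember captures ≥ 90 % of
the spike energy.

Reconstruction quality is reported uniformly as the normalised L2 error
‖V−WH‖²/‖V‖² in the raw intensity domain; for Hellinger models the
reconstruction is (WH)² element-wise.

## Reflectance-based distortion correction

Tissue absorption and scattering attenuate both the excitation light and
the emitted fluorescence. With diffuse reflectance as an empirical
surrogate for the optical properties, three corrections are implemented:

* **valdes** (baseline dual-band): V′ = V/(R_ex·R_em^α), with R_ex the mean
  reflectance over 430–450 nm (close to the 405 nm excitation, where data
  are robust) and R_em over 625–645 nm (primary PpIX emission peak).
* **spectral**: V′(λ) = V(λ)/(R_ex·R(λ)^α), wavelength-dependent, applied
  before unmixing.
* **abundance**: W′ᵢ = Wᵢ/(R_ex·R̄_em,i^α) applied after unmixing, with
  R̄_em,i = ∫R(λ)Hᵢ(λ)dλ / ∫Hᵢ(λ)dλ the reflectance averaged with the
  endmember spectrum as weight — each fluorophore gets the correction
  matched to its own emission shape.

Band "integration" is implemented as the band mean (trapezoidal integral /
width) so both factors stay in [0, 1] and α is comparable across bands.
Reflectance is floored at 1e-4 before exponentiation to avoid blow-ups in
deep absorption bands. Because a constant per-sample factor commutes with
a linear unmixing, scaling spectra before unmixing and scaling abundances
after are mathematically equivalent for a fixed basis; this equivalence is
asserted to 1e-8 in the tests.

The exponent α is calibrated by sweeping a grid over [−2, 2] (default step
0.1), scoring each value by the R² of the full
correction → unmixing → calibration chain against ground truth (R² after
κ calibration was chosen as the goodness-of-fit; a free linear fit would
reward affine rather than proportional agreement). Ties break toward
smaller |α|. For the abundance method the unmixing of uncorrected spectra
is computed once and reused across the sweep (the correction is post hoc);
pre-unmixing methods re-run the unmixing per α.

## PpIX identification and calibration

Blind endmembers arrive unordered, so PpIX-bearing components are
identified by the KL divergence between each endmember and simplified
bi-Gaussian templates of the two emission states (unit-sum normalised on
the grid): primary peak at 620 or 635 nm with 25 nm FWHM, shared secondary
peak at 705 nm with relative amplitude 0.2 and 45 nm FWHM. All template
parameters are configuration; the values are generic literature-style
shapes, not fits. The system-noise endmember is never selectable.

The selection threshold (default 13.5) was tuned on the synthetic suite.
Two facts drive the choice: blind endmembers always carry some background
admixture — no phantom is background-free, so the extreme rays of the data
cone are impure — which places PpIX-bearing endmembers at KL ≈ 1–12
against the templates while pure background humps score ≈ 13–15; and the
costs are asymmetric — dropping a true PpIX endmember discards one
emission state and collapses concentration recovery (the dual-state bias
the method exists to remove), whereas an occasionally admitted background
endmember is neutralised by the least-squares calibration (its weight
fits to ≈ 0). The default therefore sits just below the background
cluster.

Calibration solves min_κ‖y − W^ppix κ‖² by ordinary least squares
(minimum-norm on rank deficiency); the ground truth y is the *total* PpIX
concentration, and κ absorbs the per-state quantum efficiencies and the
counts-to-concentration scale, which is exactly why a weighted
recombination of both states can be calibrated against total concentration
even though the states are never observed separately. Predictions
ŷ = W^ppix κ are reported as-is (negative values flagged with a warning,
not clipped). For Hellinger models, W and H are squared element-wise back
to the intensity domain before template matching, abundance correction and
calibration: root-domain abundances scale like √concentration and would
make a linear calibration systematically concave (on the synthetic panel
this caps R² near 0.87), whereas the squared abundances restore the linear
relation and one calibration form applies across all objectives. The
squaring is exact for a component where it dominates and an approximation
in mixtures.

Metrics are R² = 1 − Σ(y−ŷ)²/Σ(y−ȳ)² and RMSE (µg/ml), evaluated
per-measurement (replicates share y), aggregated as mean ± sd over five
seeded unmixing runs by default because the factorisation is stochastic.

## Synthetic phantom panel

The generator emulates a gelatin phantom panel with intralipid (IL) as
scatterer, haemoglobin (Hb) as absorber and PpIX as fluorophore: the full
factorial crossing IL ∈ {1, 3, 5} %, Hb ∈ {0.5, 1.25, 2} mg/ml,
PpIX ∈ {0, 5, 10, 15} µg/ml × 3 replicates = 108 samples.

* **Reflectance** is the albedo-like ratio μs′/(μs′+μa) on a 400–800 nm,
  2 nm grid (coarser than emission, as in practice). The Hb absorption
  template has a dominant Soret band at 415 nm, Q bands at 540/576 nm and
  a red baseline, with amplitudes placing μa at ≈ 0.9–3.4 /mm near 400 nm
  and ≈ 0.06–0.24 /mm at 630 nm over the design range; IL scattering
  follows the Rayleigh–Mie law with μs′(500) = 0.55 /mm per % IL,
  f_Ray = 0.1, b_Mie = 0.9. These ranges mirror brain-tissue-mimicking
  phantoms; the ratio form is *not* a radiative-transport solution and
  only aims at plausible spectral shape and composition dependence.
* **Emission** mixes the two PpIX states with a 620-state fraction
  f = clip(0.1 + 0.15·IL − 0.05·Hb, 0, 0.8) — a monotone surrogate for the
  lipid-driven blue shift (more intralipid → more 620 nm emission), not a
  quantitative photochemical model — a 620-state quantum efficiency of 0.3
  relative to the 635 state, a broad log-normal background hump at 520 nm
  whose amplitude grows with IL (gelatin + intralipid autofluorescence),
  and a 4 nm-FWHM spike at 690 nm scaling with IL.
* **Distortion** multiplies the clean spectrum by R_ex·R(λ)^α_true with
  α_true = −1.0 by default — the exact inverse of the spectral correction,
  which makes exponent recovery well-posed and echoes the calibrated
  optimum reported for this correction family.
* **Noise** is Poisson counting noise; `counts_scale` (default 1e4) sets
  the expected peak counts of the brightest design point, a realistic
  photomultiplier-count regime.

The generator returns clean and noisy spectra, per-component ground-truth
amplitudes and total concentrations, and writes/reads the same delimited
formats the rest of the package consumes (byte-identical output under a
fixed seed).

**What passing tests do and do not show.** The panel reproduces the
features that make dual-state quantification hard — overlapping states
with unequal quantum efficiency, composition-dependent spectral shape,
background fluorescence, a sharp instrumental artefact, reflectance-coupled
intensity distortion, Poisson noise — but its distortion is exactly
invertible by construction, its endmember shapes are clean parametric
curves, and it has no pH effects, photobleaching, inter-batch variability
or reflectance measurement error. Recovery results on this panel validate
the pipeline's correctness and internal consistency, not its accuracy on
measured tissue spectra.

## Default configuration summary

| parameter | default | meaning |
|---|---|---|
| grid | 450–800 nm, 1 nm | emission wavelength grid (351 points) |
| r | 4 (+1 noise EM) | content endmembers |
| alpha_gamma | auto → 0.02 | smoothness step weight (dimensionless) |
| tol / max_iter | 1e-6 / 2000 | convergence of the objective |
| restarts | 5 | random initialisations per unmixing |
| seeds | (0,…,4) | pipeline repetitions for mean ± sd |
| ex_band / em_band | 430–450 / 625–645 nm | dual-band correction windows |
| α grid | −2…2, step 0.1 | exponent calibration sweep |
| KL threshold | 13.5 | PpIX endmember selection |
| templates | 620/635 nm, FWHM 25; 705 nm ×0.2, FWHM 45 | bi-Gaussian PpIX shapes |

Problem sizes used by the test suite and the acceptance script (108 × 351
spectra, 3–5 restarts, ≤ 1500 iterations) were chosen so a full validation
pass completes in about a minute on one CPU; all results quoted in the
README are produced by those runs.

## Known limitations

* NMF on this data class is not identifiable up to rotation: endmembers
  carry background admixture, and quantification relies on the
  least-squares calibration spanning the PpIX subspace rather than on
  recovering pure spectra.
* The Hellinger intensity-domain squaring is exact only for dominant
  components; mixed pixels incur a cross-term error.
* The abundance correction uses the endmember-weighted reflectance as a
  constant per endmember; it cannot undo wavelength-dependent distortion
  *within* an endmember's band.
* Replicate spectra are treated as independent samples sharing one ground
  truth; an `--average-replicates` style aggregation is deliberately not
  applied by default.
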