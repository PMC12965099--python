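# ppixquant

Quantification of dual-state protoporphyrin IX (PpIX) fluorescence for
fluorescence-guided neurosurgery research: blind spectral unmixing of
emission spectra, reflectance-based correction of tissue optical
distortion, and calibration of unmixed abundances to absolute PpIX
concentration. A forward simulator of tissue-mimicking phantom panels
provides ground truth for validating every stage.

## The problem

5-ALA-induced PpIX accumulates selectively in glioma, but measuring *how
much* is hard: in tissue PpIX exists in two photochemical states with
primary emission peaks at 620 nm and 635 nm, markedly different quantum
efficiencies, and spectra that overlap each other and tissue
autofluorescence. On top of that, tissue absorption and scattering distort
the detected intensity. Quantifying only the 635 nm state, or ignoring the
optical distortion, biases the estimated concentration.

## The method

Emission spectra (counts vs wavelength, 450–800 nm at 1 nm) for *n*
samples form a non-negative matrix **V** (n × m), factorised blindly as

```
V ≈ W H ,   W ≥ 0 (n × r abundances),  H ≥ 0 (r × m endmember spectra)
```

by multiplicative-update NMF under one of three objectives: Euclidean
‖V − WH‖², generalised Kullback–Leibler divergence (the Poisson-count
objective), or the Hellinger distance ‖√V − √(WH)‖² (Euclidean updates on
square-root-transformed counts, variance-stabilising for Poisson data).
Two regularisation devices target spectroscopy structure: a Tikhonov
penalty α_Γ‖ΓH‖² on spectral first differences (smooth endmembers), and a
dedicated smoothing-exempt endmember initialised as a sharp 690 nm peak
that absorbs a systematic instrumental spike.

Optical distortion is corrected empirically from paired diffuse
reflectance R(λ): dividing by R_ex·R_em^α (constant dual-band),
R_ex·R(λ)^α (wavelength-dependent, pre-unmixing), or per-endmember
R_ex·R̄_em,i^α with R̄_em,i the endmember-weighted mean reflectance
(post-unmixing). The exponent α is calibrated by sweeping [−2, 2] against
known concentrations.

PpIX-bearing endmembers are identified by thresholding the KL divergence
against bi-Gaussian templates of the two emission states, and a weight
vector κ (fitted by least squares, min‖y − W^ppix κ‖²) recombines their
abundances into total PpIX concentration in µg/ml, absorbing the per-state
quantum efficiencies.

## Worked example

Simulate the default 108-phantom panel (intralipid 1/3/5 %, haemoglobin
0.5/1.25/2 mg/ml, PpIX 0/5/10/15 µg/ml, 3 replicates, Poisson noise,
distortion exponent −1.0) and run the best-performing configuration:

```
$ ppixquant simulate --seed 3 --out panel/
wrote 108 samples; manifest: panel/manifest.yaml

$ ppixquant calibrate panel/manifest.yaml --objective hellinger \
      --correction abundance --alpha -1.0
R2 = 0.9289 ± 0.0185; RMSE = 1.4791 ± 0.1859 ug/ml over 5 runs
```

R² is the coefficient of determination between predicted and true total
PpIX concentration over the 108 samples; RMSE is in µg/ml on the 0–15
µg/ml design range. The mean ± sd aggregates five seeded unmixing runs.
The same chain is available from Python:

```python
from ppixquant import (ForwardModelParams, simulate_dataset,
                       PipelineConfig, CorrectionConfig, run_pipeline)

ds = simulate_dataset(params=ForwardModelParams(seed=3))
cfg = PipelineConfig(objective="hellinger",
                     correction=CorrectionConfig(method="abundance", alpha=-1.0))
print(run_pipeline(ds, cfg).summary)
```

`ppixquant sweep-alpha` calibrates the correction exponent,
`ppixquant compare` renders the 3 objectives × 5 treatments comparison
grid, and `ppixquant fit-scattering` fits the mixed Rayleigh–Mie model
μs′(λ) = a′·(f_Ray·(λ/λ₀)⁻⁴ + (1−f_Ray)·(λ/λ₀)^(−b_Mie)) to reduced
scattering spectra.

## Limitations

Validation uses a synthetic phantom generator, not measured spectra; see
`docs/methods.md` for what the generator does and does not emulate, the
meaning of every tunable parameter, and the numerical choices made.
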