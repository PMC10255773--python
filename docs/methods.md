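# Methods

## Problem and scope

`ftirq` implements a complete quantitative-calibration protocol for FT-IR
spectra of pet food spiked with melamine or cyanuric acid: synthetic spectrum
generation, Dirichlet data augmentation, spectral pretreatments, three linear
multivariate calibrations (PLS1, PCR, NAS-based HLA/GO), a fixed-architecture
1D convolutional network, and the evaluation metrics used to compare them.
No instrument data ships with the package: the raw measurements behind the
original study are not public, so the synthetic generator stands in for the
spectrometer and all quantitative results in the test suite refer to that
synthetic system.

## Synthetic spectra

Each pure component (pet-food matrix, melamine, cyanuric acid) is a sum of
Gaussian/Lorentzian bands with literature peak positions: matrix protein
amide bands at 3288/1643/1538 cm⁻¹ and lipid C–H stretches at 2921/2852 cm⁻¹;
melamine's broad N–H envelope over 3000–3500 cm⁻¹, triazine modes at 1643,
1022 and 810 cm⁻¹ and the C–N region at 1433–1533 cm⁻¹; cyanuric acid's
carbonyl doublet at 1777/1752 cm⁻¹, ring stretches at 1400/1418/1464 cm⁻¹ and
the 778 cm⁻¹ out-of-plane mode. Band *positions* are physically grounded;
band *widths and amplitudes* are package choices (broad envelopes for H-bonded
stretches, FWHM 12–22 cm⁻¹ for sharp ring modes, peak absorbances 0.3–0.9
a.u.), because no reference prints them. The spectra are therefore
structurally realistic but not photometrically calibrated to any instrument;
tests that pass on this generator demonstrate the correctness of the
algorithms and the achievable accuracy under these controlled conditions, not
the accuracy obtainable on real extracts.

A sample at mass fraction c (% w/w) mixes the pure spectra by Beer–Lambert
superposition, `(1 − c/100)·matrix + (c/100)·adulterant`, then receives three
degradations per replicate: a multiplicative scatter factor ~ N(1, 0.05), a
random degree-2 polynomial baseline with coefficient scale 0.01 a.u., and
white noise with σ = 0.002 a.u. These defaults are typical of bench ATR
FT-IR practice: scatter of a few percent from repacking powder, baseline
drift an order of magnitude above the noise floor, and point noise well below
the 0.3–0.9 a.u. band amplitudes. They are exactly what makes SNV/MSC
pretreatment non-trivial. The design grid is the study's: concentrations
0, 0.1, 0.5, 0.8, 1, 2, 3, 4 % w/w with ten replicates each.

The wavenumber axis is 3800 → 500 cm⁻¹ (descending, spectroscopic
convention) with **1803 points** (≈1.83 cm⁻¹ spacing). The published layer
table of the network fixes kernel size 5 and first-conv output length 1799,
which forces input length 1803 even though the surrounding text prints
"1804"; we adopt 1803 so the architecture arithmetic is exactly checkable,
and the resolution is configurable for other uses.

## Dirichlet augmentation

For each concentration class with k replicates, artificial spectra are drawn
as convex combinations Σ wᵢ·rᵢ with w ~ Dirichlet(α·1ₖ), α = 1 (uniform on
the simplex; the original recipe's α is not published). Mixing never crosses
classes by default, so labels transfer exactly and each artificial spectrum
lies in the per-wavenumber [min, max] envelope of its class — both are
tested invariants. 169 draws per class × 8 classes reproduce the study's
1352 samples. Cross-class mixing (continuous labels Σ wᵢ·cᵢ) exists behind
an explicit flag for experimentation.

Augmentation runs on the raw replicates and preprocessing afterwards,
matching the reading that the artificial data were generated first and
pretreated second.

## Pretreatments

* **SNV** — per spectrum, subtract the mean and divide by the sample
  standard deviation.
* **MSC** — per spectrum, OLS fit x ≈ a + b·reference and correct to
  (x − a)/b; the reference is the calibration-set mean and is frozen into
  the fitted model so prediction data can never influence it.
* **Savitzky–Golay derivatives** — scipy's filter, window 11, polynomial
  order 2 by default (the conventional chemometrics setting; no reference
  value exists), scaled by the physical axis spacing so d(A)/d(ν̃) is
  comparable across resolutions; edges use the polynomial fit on the
  truncated window.
* **Range normalization** — per spectrum min-max scaling onto [0, 1].

All methods are sample-wise; only MSC carries fitted state.

## Linear calibrations

All three engines mean-center X and y internally and predict
ŷ = ȳ + (x − x̄)ᵀb.

* **PLS1 (NIPALS)** — weights w = Xᵀy/‖Xᵀy‖, scores t = Xw, loadings
  p = Xᵀt/tᵀt, q = yᵀt/tᵀt, deflation of X and y; b = W(PᵀW)⁻¹q. Scores are
  mutually orthogonal to 1e-10 (tested), and at full rank the predictions
  coincide with the pseudo-inverse OLS solution to 1e-8 (tested, including
  against scikit-learn's PLSRegression as an independent implementation).
* **PCR** — SVD of centered X, regression of y on the leading score
  columns, coefficients mapped back through the right singular vectors.
* **HLA/GO** — least-squares pure-analyte signal ŝ = Xᵀy/(yᵀy); background
  matrix X − y ŝᵀ truncated to rank A by SVD; net analyte signal
  s* = (I − V_A V_Aᵀ)ŝ; prediction ĉ = s*ᵀ(r − x̄)/(s*ᵀs*) + ȳ. This is the
  standard hybrid-linear-analysis construction; on noiseless two-component
  mixtures with A = 1 it recovers concentrations to 1e-8 (tested). A
  vanishing ‖s*‖ means the analyte is indistinguishable from background and
  raises an error.

The factor count is chosen by 10-fold cross-validation stratified by
concentration class (the selection criterion — minimum pooled RMS of the
held-out predictions — is prescribed; the fold scheme is ours). Ties take
the smallest count. Candidate counts beyond a fold's effective rank reuse
the last attainable coefficient vector, so the tie rule resolves them to the
smaller model instead of failing. For continuous labels the stratification
degrades gracefully to a round-robin over sorted values.

The pipeline treats the choice of pretreatment the same way: each candidate
is scored by its best cross-validated RMS inside the calibration set only,
and the winner is refit and evaluated once on the held-out split. Nothing is
hardcoded to "SNV wins"; on other data another pretreatment may be selected.

## 1D CNN

Architecture (fixed by the published layer table): three valid stride-1
convolutions with kernel 5 and 64/32/16 filters (ReLU each), dropout 0.5
after the first convolution, max-pool 2, flatten (14 320 features), dense
64/32/1 with ReLU on the first two and a linear output. With input length
1803 the per-layer trainable parameters are 384 / 10 272 / 2 576 / 916 544 /
2 080 / 33 — total 931 889 — and the test suite checks these from the actual
weight-tensor shapes, with feature lengths 1799/1795/1791/895 read off a real
forward pass.

The network is implemented directly in numpy: the multi-channel
convolutions run as K shifted batched matrix products (BLAS), the
memory-bound glue (single-channel first convolution, ReLU/dropout masks,
max-pooling) as fused single-pass numba kernels, and backpropagation is
explicit (verified against central-difference numerical gradients on a
small configuration and against a brute-force triple-loop convolution
oracle). Inputs are standardized per wavenumber — subtract the
calibration-set column mean, divide by the column standard deviation, with
the statistics frozen into the model and reapplied at prediction time.
Without this the tiny concentration-dependent band changes ride on large
constant matrix bands and gradient descent spends its budget on the
uninformative directions; with it the same architecture converges an order
of magnitude faster in validation error.

The optimizer is Adam (β₁ 0.9, β₂ 0.999, ε 1e-8) at the published rate
0.001 with a short linear warmup (first 5 % of epochs), cosine decay to
zero over the remaining budget, global gradient-norm clipping at 5, and the
output bias initialized at the label mean. The optimizer identity, the
schedule, the clipping and the batch size (32) are unstated in the source
protocol and are package choices, each answering an observed failure mode:
with a constant rate the 931k parameters keep taking fixed-size Adam steps
after the fit has formed and the validation error oscillates by a factor of
two between late epochs (the decay settles the weights); and without
warmup and clipping the first large updates can commit the network to a
basin that fits the calibration set but attenuates validation predictions
toward the mean — across data realizations, warmup plus clipping turned
the occasional stuck run (validation R² ≈ 0.66–0.89) into steadily
converging ones (≥ 0.9 by epoch 30 on the worst realization tested, still
improving). Arithmetic is float32; one seeded generator drives
initialization (He for all layers), shuffling and dropout, so training is
bit-reproducible at a fixed thread configuration. The validation set is
monitored only — no early stopping; the epoch budget is fixed in advance.

The default epoch count is 500, matching the study protocol. The test
suite and the acceptance script train **100 epochs**, the package's
desk-scale benchmark; on the synthetic fixture the network crosses
prediction R² 0.95 well before that budget and ends around R² 0.95–0.97
(RMSEP ≈ 0.2–0.3 % w/w) depending on the data realization, with the
remaining 400 epochs of the full protocol left to polish the fit. The
network's prediction error remains well above the linear methods' on this
synthetic system — unsurprising, since the generator is exactly the linear
Beer–Lambert model that PLSR assumes; the protocol reports both without
asserting an ordering.

The 1148/204 split is not divisible evenly by 8 classes; per-class
calibration counts are 144/143 with the four classes carrying the extra
sample chosen by the seeded generator.

## Metrics and reporting

R² is the standard 1 − SSres/SStot. (The source formula as printed reduces
to SSres/SStot, which would be ≈0 for the good fits it reports as ≈0.99; the
raw ratio is exposed as `r2_printed` for transparency.) RMSE is the plain
root-mean-square residual, and bias is mean(y − ŷ) — positive bias means
under-prediction. The identity rmse² = bias² + var(residuals) is tested to
1e-10. The comparison table mirrors the conventional layout (R²cal, RMSEC,
R²pre, RMSEP, LVs, bias), sorted by RMSEP with stable ties.

## Reproducibility and numerics

Every stochastic stage (noise, Dirichlet draws, folds, splits, network
training) takes an explicit integer seed; the pipeline derives all stage
seeds from one global seed via `numpy.random.SeedSequence` spawning, and the
provenance JSON written with each run is sufficient to reproduce every
output file. CSV round-trips are exact (17-significant-digit writes,
round-trip float parsing on read).

Numerical guards: NIPALS stops when the residual covariance norm drops below
1e-12 (rank exhausted); MSC rejects slopes |b| < 1e-12; HLA rejects
‖s*‖² < 1e-24; constant rows are rejected by SNV/range normalization with
the offending sample named.

## Known limitations

* Band widths/amplitudes and the noise magnitudes are package choices; the
  synthetic system is easier than real extracts (no moisture bands,
  instrument drift, or matrix variability between batches), so the near-unity
  R² values on the fixture should not be read as expected field performance.
* The generator does not model ATR penetration-depth effects, Mie scatter or
  instrument line-shape convolution.
* HLA/GO is the standard construction; variant formulations from the
  broader NAS literature are out of scope.
* PLS2, variable-selection methods (VIP, CARS) and support-vector regression
  are out of scope.

One pipeline-level caveat belongs here: the cross-validated pretreatment
ranking of the linear models does not transfer to the network. On the
synthetic system MSC can beat SNV by linear CV error while the network
trained on the same MSC spectra generalizes clearly worse than on SNV
spectra. The pipeline therefore selects pretreatments by CV for the linear
methods only and trains the network on SNV by default (``cnn_preprocess``),
rather than reusing a linear model's winner as a proxy.
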