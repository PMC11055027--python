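# Methods

This note records the scientific and numerical choices behind brixspec: what
each stage assumes, which parameters matter, what the simulator does and does
not emulate, and where the design was genuinely open.

## The problem setting

A pushbroom hyperspectral camera images fruit across a few hundred narrow
bands in the visible/NIR (here 387–1034 nm, 256 bands). Sugar-related
absorption (pigments, O–H overtones of water/sugar solutions) depresses
reflectance in localised wavelength regions, so soluble-solids content can be
regressed on the spectrum. The practical obstacles are (i) per-sample
multiplicative/additive scatter from surface geometry, (ii) detector noise at
the spectral extremes, and (iii) strong collinearity across bands, which makes
full-spectrum models slow and noisy. The pipeline addresses these with
scatter/noise preprocessing, data-driven wavelength selection, and a
regularised nonlinear regressor, in that order.

## Synthetic data generator

`generate_spectra` draws, per sample:

- Brix `y ~ U[brix_min, brix_max]` (default 7.4–12.5 °Brix). Only the range of
  plausible field values is known, so a uniform draw is the least-committal
  choice.
- a clean spectrum `baseline(λ) − Σ_j gain·(y − brix_min)·exp(−(λ−c_j)²/2w_j²)`.
  The baseline is the fixed quadratic `0.30 + 1.40u − 1.10u²` in normalised
  wavelength `u`, giving a reflectance envelope ≈0.30–0.75 that rises from the
  blue end, peaks near 800 nm and eases into the NIR — the typical shape of
  fruit reflectance. Three default absorption centers sit at 680, 760 and
  960 nm (chlorophyll, O–H third overtone, water second overtone) with widths
  20/15/30 nm.
- an affine scatter distortion `(1+s)·x + o` with `s ~ N(0, 0.05²)`,
  `o ~ N(0, 0.02²)` — exactly the model MSC assumes — and i.i.d. band noise
  `N(0, 0.01²)` (roughly 1–3% of the envelope, a plausible single-acquisition
  noise floor for a CCD system near its spectral edges).
- `signal_gain = 0.02` reflectance per °Brix, i.e. a maximum valley depth of
  ≈0.10 over the 5.1 °Brix range, comparable to the pigment/water features in
  real fruit spectra.

The truth object records the labels, the per-sample scatter terms, and the
*informative band indices* — bands within one width of any absorption center —
which recovery tests compare selections against.

`generate_image_stack` inverts black/white calibration by construction
(`raw = black + truth·(white − black)`, `white > black` everywhere), so the
calibration stage can be verified to machine precision.

**What the simulator does not emulate:** wavelength-correlated (pink) noise,
detector nonlinearity and saturation, specular highlights, fruit-geometry
shading beyond the affine model, temperature drift, and any nonlinearity of
the Brix–depth relationship. Passing recovery tests therefore demonstrate the
algorithms' correctness under their stated assumptions, not instrument-grade
performance on real fruit.

## Preprocessing

- **Black/white correction** is the elementwise `(I0 − B)/(W − B)`; a pixel
  where `W = B` is reported as a degenerate calibration, not silently patched.
- **Band trimming** keeps the closed interval `[lo, hi]`; a 256-point linear
  axis over 387–1034 nm keeps 236 bands in 400–1000 nm.
- **Train/test split** is a seeded uniform partition with
  `|train| = round-half-up(n·ratio)`, so `168 × 0.7 → 118:50`.
- **SG**: the smoothing weights are derived from the least-squares projection
  on the window design rather than looked up, and are validated in tests
  against both an explicit normal-equations solve and `scipy.signal.
  savgol_coeffs`. Defaults window 11, order 2 — a standard chemometrics
  setting at ~2.5 nm band spacing (window ≈ 25 nm, wider than the noise
  scale, narrower than the absorption features). Edge handling defaults to
  `truncate_fit` (re-fit the polynomial on the truncated window), which
  reproduces polynomials of degree ≤ order *everywhere*, not only at interior
  bands; `reflect` padding is available as an alternative.
- **SNV** uses the sample SD (n−1 denominator); the choice is pinned by tests.
- **MSC** regresses each spectrum on a reference and inverts the fitted
  affine map. The pipeline uses the calibration-set mean as reference so no
  test-set statistics leak into preprocessing; a fitted slope below 1e−8 is a
  degenerate-fit error rather than a near-division-by-zero.

## Wavelength selection

**CARS.** `p` is the full band count, `N` the number of Monte-Carlo runs
(default 50), cross-validation 10-fold, at most 10 latent PLS components, and
an 80% calibration subsample per run (customary in the CARS literature; the
fraction is configurable). Each run fits PLS on the currently retained bands
of a fresh subsample, forms `ω_i = |b_i|/Σ|b_j|`, truncates to the top
`⌈p·r_i⌉` weights (ties broken toward the lower band index), then resamples
that many bands with replacement in proportion to ω and deduplicates — so the
retained count is non-increasing and never below 2 (clamped). RMSECV is
scored by PLS on the full calibration set under one fold assignment drawn
from the seed and shared by all runs (and by the all-band reference model),
making the trace internally comparable. Ceiling rather than floor in the
schedule guarantees survival of at least two bands.

**SPA.** Chains are built on autoscaled columns (projection norms comparable
across bands) from every candidate start band; prefix scoring regresses Brix
on the original columns by OLS under the same style of fixed CV folds.
A duplicated column has zero residual after its twin is chosen and can never
be co-selected; rank deficiency terminates a chain early.

## Modeling

The ε-SVR uses the RBF kernel `exp(−g‖x−x'‖²)` on features standardised by
calibration-set mean/SD (so `g` has a comparable meaning across
preprocessors). ε defaults to 0.1 °Brix — the resolution of a typical digital
refractometer, below which fitting residuals is meaningless. The quadratic
program is solved by scikit-learn's libsvm binding; brixspec owns the
parameterisation and tuning.

The GA searches `(log₁₀C, log₁₀g)` in `C ∈ [0.01, 100]`, `g ∈ [0.001, 10]` —
wide enough to contain the optima reported for comparable NIR sugar models.
Chromosomes are real-valued pairs; selection is roulette over inverse-RMSE
ranks, crossover an arithmetic blend (rate 0.8), mutation a Gaussian step
with σ = 10% of each gene's log-range (rate 0.1), clamped to the bounds, with
elitism 1, population 20, 30 generations. Fitness is the k-fold
cross-validated RMSE on the calibration set (the quantity the evaluation
tables report); folds are fixed once per call, so fitness is deterministic,
the best-so-far history non-increasing, and the whole search reproducible
from its seed. A budget-matched log-grid search is kept as an independent
oracle in tests, never as the implementation.

## Evaluation

`Rc²`/`Rp²` are `1 − SS_res/SS_tot` with the mean taken over the evaluated set
itself (calibration mean for `Rc²`, prediction-set mean for `Rp²`). This is
deliberately *not* the squared Pearson correlation: the two coincide only for
unbiased predictions, and the sum-of-squares form is the one that penalises
bias. Reports render at 4 decimals. `evaluate` refuses overlapping train/test
indices outright.

## Reproducibility

One global seed fans out to per-stage seeds via `seed XOR crc32(stage_name)`,
so any stage can be re-run in isolation with the stream it had inside the full
pipeline, and every artifact in an output directory is regenerable from the
config alone. Test and acceptance problem sizes (e.g. 200×100 recovery tasks,
a 70-sample configuration grid) are chosen as the smallest sets on which the
tested effects are comfortably observable.

## Known limitations

- PLS inside CARS uses scikit-learn's NIPALS; coefficient signs are
  convention-dependent (weights use absolute values, so selection is
  unaffected).
- SPA scores every chain prefix by a fresh OLS solve; for very large band
  counts an incremental QR update would be cheaper.
- The GA optimises only `(C, g)`; ε is fixed, as its natural scale is set by
  the reference instrument rather than the data.
- With fewer calibration samples than bands the linear baseline interpolates
  its training set (`Rc² = 1`); only its prediction-set columns are
  informative in comparisons.
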