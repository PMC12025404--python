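# Methods

## Signal model and preprocessing

The package assumes mono hydrophone audio sampled at 1 kHz containing
low-frequency baleen-whale calls over coloured background noise. Antarctic
blue-whale song occupies roughly 15–30 Hz, so preprocessing applies a
fourth-order Butterworth bandpass with 15 and 30 Hz edges. The filter is
run forward-backward (`sosfiltfilt`), which doubles the effective
attenuation but keeps zero phase so call onsets in annotations stay
aligned with the waveform; the single-pass design has the textbook 3 dB
points at the band edges. The filtered recording is divided by its maximum
absolute value (one normalisation per recording, not per window — the
normalisation is defined on the whole filtered signal) and then cut into
non-overlapping, half-open, fixed-duration windows; trailing samples that
do not fill a window are discarded. Windows inherit labels from
annotations by largest temporal overlap, with ties and empty windows
labelled `noise`; this mapping is a package choice, since selection-table
annotations carry no window semantics of their own.

Because the analysis band ends at 30 Hz, the pipeline decimates the
filtered signal by an integer factor (default 10, i.e. 1 kHz → 100 Hz,
anti-aliased FIR, zero phase) before feature extraction. This leaves the
band of interest untouched (Nyquist 50 Hz) and reduces the quadratic
pairwise-matching cost of sample entropy by two orders of magnitude; all
defaults below refer to the decimated rate.

## Multiscale sample entropy

For each window `F_k` of length `L`, coarse-graining at scale `τ` replaces
consecutive non-overlapping blocks of `τ` samples by their mean (1-based
block arithmetic, partial trailing block dropped), giving `⌊L/τ⌋` points.
Sample entropy of a coarse-grained series is
`SE = −ln(P_{m+1}/P_m)` with `P_m = C_m/T_m`: `C_m` counts unordered pairs
of `m`-point templates whose Chebyshev distance is at most `r`, and
`C_{m+1}` the same among the `(m+1)`-point templates (a match at `m+1`
implies one at `m`, so `C_{m+1} ≤ C_m` always).

Two normalisers are provided because the published ones are not pair
counts:

* `norm_mode="paper"` (default): `T_m = m·M/2` and
  `T_{m+1} = (m+1)(M−1)/2` with `M = ⌊L/τ⌋ − m + 1`. These can make the
  "probabilities" exceed 1; the entropy is still well defined and
  monotone in `r`, and this is the published convention, so it is the
  default.
* `norm_mode="standard"`: the classical `M(M−1)/2` and `(M−1)(M−2)/2`
  pair counts, under which a constant series has entropy exactly 0.

The tolerance is anchored to the **scale-1** window: `r = r_coef·σ(F_k)`,
reused at every scale. This is canonical multiscale practice — rescaling
`r` per scale would remove exactly the variance decay that distinguishes
white from correlated noise. Defaults: `m = 2`, `r_coef = 0.2`
(0.2–0.5 is the accepted range), `τ_max = 12`, window 26 s (chosen to
cover one full Z call; Z calls run 18–26 s).

Undefined entropies (zero matches at either template length, e.g. for very
regular windows at tiny tolerances) are returned as NaN and imputed with
the column maximum of the finite entries before modelling: no matches
means "at least as irregular as anything observed", and the imputation
preserves that semantics without propagating non-finite values. The
degenerate all-zero window yields a fully imputed row.

The implementation counts matches with chunked vectorised Chebyshev
distances (row blocks of 128 bound peak memory); the test suite pins it,
case by case, to a literal double-loop transcription of the defining
equations, in both normalisation modes.

## Baseline features

All baselines produce one row per analysis window from the same window
matrix, so the mixture back-end is identical across methods and the
comparison isolates feature extraction.

* **PCA** — mean-centred SVD scores of the `s × L` window matrix,
  `τ_max` components (behind the scenes: scikit-learn's exact solver).
* **DMD** — windows are treated as successive snapshots of one matrix;
  the best-fit linear one-step operator `A = X₂VΣ⁻¹U*` is estimated from
  the truncated SVD of the first `T−1` snapshots, its eigenpairs give
  modes `φ = X₁VΣ⁻¹ω`, and each window's features are its coefficient
  magnitudes `|Φ⁺F_k|` in the retained mode basis (rank = feature count,
  default 12). Default rank selection elsewhere keeps singular values
  above `1e−10·σ₁`.
* **Wavelet features** — complex-Morlet CWT on 24 log-spaced scales
  mapped to 10–120 Hz (clipped to 0.45·rate); per frame, the smoothed
  energy (moving average over 0.5 s — the regularisation span is not
  specified anywhere, so half a second of frames is the package default),
  the energy-weighted spectral centroid, and the base-2 entropy of the
  across-scale energy distribution. The per-frame energy is z-scored
  ("robust range normalisation" and z-scoring are different things; the
  z-score is implemented). Window features are the frame averages of
  (E, F, H), NaN frames (zero energy) excluded.

## Mixture modelling and feature reduction

The mixture uses full covariances with a `1e−6` diagonal ridge
(covariance structure is unspecified in the source method; full is the
least restrictive choice at these dimensionalities). EM starts from a
seeded k-means hard assignment, stops when the relative log-likelihood
change falls below `1e−6` (cap 500 iterations), and keeps the best of 5
restarts. The component count is chosen by BIC
(`−2 log L + k log n`, `k = K−1 + Kd + Kd(d+1)/2`) over `K = 1..8`, ties
to the smaller `K`.

Feature ranking: with responsibilities `P(j|x_i)` from a mixture fitted to
the standardised log-entropy matrix, `MPP(j,f)` is the posterior-weighted
mean of standardised feature `f` under component `j`. Standardisation
matters — on raw features the statistic rewards magnitude, not
discrimination. The printed statistic scores components, not features, so
an aggregation rule is needed; the package uses
`score(f) = max_j |MPP(j,f)|` and sorts descending (documented package
choice). Per-component averages are reported as diagnostics.
Zero-variance features (up to rounding noise) are excluded from ranking.
Defaults for the retained count: ζ = 4 (MSE), 7 (PCA), 5 (DMD), 3 (WF).

The detector then refits a mixture with the **same** `K` on the reduced
training matrix `Ψ_t` (whether `K` should be re-selected on `Ψ_t` is
ambiguous; reusing it keeps the reduction and classification models
aligned), clusters training rows by the MAP rule, maps each component to
the majority class of its members (empty components map to `noise` — the
original method never specifies how components acquire class meaning), and
labels test rows by the weight-free maximum-likelihood rule with ties to
the lowest component index. Detection is the binary call-vs-noise
decision; multiclass call-type evaluation is available as one-vs-rest
counts with a micro-average. Note that accuracy and error rate share a
denominator and therefore sum to exactly 1 in every report; published
comparison tables in this literature sometimes do not have this property,
which implies an additional, undescribed evaluation detail there.

Trials (`fit_multi`) vary only the stratified 70/30 split and the EM
seeds; features are extracted once per dataset. Everything downstream of a
`(config, seed)` pair is deterministic.

## Synthetic scenes

The generator renders calls as linear-FM chirps with 0.5 s raised-cosine
tapers — the simplest waveform consistent with the calls' published verbal
description (no call-synthesis model exists in the source literature):

* `BmAntA`: tonal 25–27 Hz, 8–12 s;
* `BmAntB`: the tonal part plus a 2 s 27→20 Hz downsweep;
* `BmAntZ`: the full three-part Z call (adds the 20→18 Hz tonal,
  8–12 s; total 18–26 s);
* `BmD`: a 1–4 s downsweep from 60–106 Hz down to 22–40 Hz.

Scenes sum calls onto seeded white (default) or 1/f noise, with the noise
scaled so the **in-band (15–30 Hz)** signal-to-noise ratio — measured by
periodogram integration over the band — equals the requested value
exactly. In-band SNR is used because the detector only ever sees that
band; a D call's full-band SNR is much lower since most of its sweep lies
above 30 Hz. The default benchmark is 100 single-window scenes at 10 dB
in-band SNR, half noise, half calls (20 A, 15 Z, 15 D), preprocessed
exactly like real recordings and split 70/30 by largest-remainder
stratification.

What the generator does **not** emulate: propagation loss, multipath,
dispersion, transient interference (icebergs, airguns, ship noise),
overlapping choruses, clock drift, or amplitude fading within a call.
Passing tests on this benchmark therefore demonstrate the pipeline's
mechanics and the discriminative power of entropy profiles for tonal
calls in stationary noise — not field-grade detection performance, which
in the literature is measured on annotated Antarctic recordings and is
substantially harder (published mean accuracies are in the mid-80s
percent).

## Numerical choices and edge cases

* Chebyshev matching uses `≤ r` (inclusive), matching the defining
  inequality; distances are never materialised as a full `M × M` matrix.
* Integer PCM WAV input is scaled by the type's full negative scale so a
  full-scale square wave maps to ±1.0 exactly; multi-channel files keep
  channel 0 with a warning; unreadable files raise an I/O error naming
  the path.
* All-zero recordings cannot be normalised (explicit error); all-zero
  windows produce fully imputed entropy rows.
* EM log-likelihood is monotone up to `1e−8` (the ridge added in each
  M step can introduce rounding-level dips); fits are reproducible bit
  for bit under a fixed seed.
* Tie-breaks everywhere go to the lowest index (argmax semantics); a tie
  in window labelling goes to `noise`.
* The benchmark problem sizes used by the test suite and the acceptance
  script — 100 scenes, 10 trials, 26-s windows at 100 Hz decimated rate,
  entropy scales to 12 — were chosen so a full run stays comfortably
  within desk-scale compute while keeping ≥30 windows per evaluated
  class.

## Known limitations

* The `paper` normalisers make `P_m` scale-dependent in a way the
  `standard` ones do not; comparisons across different `m` should use
  `standard`.
* MPP ranking is only as good as the reduction-stage mixture; with
  heavily overlapping components the max-|MPP| aggregation can pick
  redundant scales (inter-feature correlation among neighbouring scales
  is high).
* The DMD baseline treats windows as snapshots of a single linear system,
  which is a modelling fiction for a heterogeneous recording; it is
  included as a comparison feature extractor, not as a dynamical model.
* Component-to-class mapping by training majority can silently absorb a
  rare call type into a noise-dominated component when `K` is small.
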