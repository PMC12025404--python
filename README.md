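# bluecall

Detection and classification of Antarctic blue-whale (*Balaenoptera
musculus intermedia*) vocalizations in continuous passive acoustic
recordings, using **multiscale sample entropy (MSE)** features and
**Gaussian mixture model (GMM)** clustering/classification, with PCA,
dynamic mode decomposition (DMD) and continuous-wavelet feature baselines
and a synthetic call simulator so the whole pipeline can be exercised
without field recordings.

## Who this is for

Bioacousticians and ecological-monitoring engineers who need an automatic,
threshold-free detector for low-frequency baleen-whale song — stereotyped
three-part Z calls (≈26 Hz tonal, ~2 s downsweep to 20 Hz, ≈18–20 Hz tonal;
18–26 s total) and short variable D-call downsweeps (22–106 Hz, 1–4 s) — in
long 1 kHz hydrophone recordings.

## The method

A recording `x(t)` is bandpass-filtered to the 15–30 Hz call band
(fourth-order Butterworth, zero phase), normalised by its maximum absolute
value, and cut into non-overlapping fixed windows `F_k` (26 s by default).
For each window and each scale factor `τ = 1..τ_max`:

1. **coarse-grain**: `c_j(τ) = (1/τ) Σ_{i=(j−1)τ+1}^{jτ} w_i` — block
   means of length τ;
2. **sample entropy**: `SE_k(τ) = −ln(P_{m+1}/P_m)`, where `P_m` is the
   (normalised) count of pairs of `m`-length templates within a Chebyshev
   tolerance `r = 0.2 σ(F_k)`, and `P_{m+1}` the same at length `m+1`.

The `s × τ_max` entropy matrix is log-transformed (`ln(1+SE)`), a GMM with
BIC-selected component count `K` is fitted by EM, and features are ranked
by their **mean posterior probability** statistic
`MPP(j, f) = (1/s) Σ_i P(j|x_i)·z_i(f)` on standardised features; the top
`ζ` columns form the reduced matrix `Ψ`. A second GMM fitted on the
training rows of `Ψ` assigns windows to components by the MAP rule
`C(s) = argmax_j P(j|s)`; components are mapped to classes (call vs noise)
by training-label majority, and test windows are labelled by the
maximum-likelihood rule `C_ML(s) = argmax_j p(s|θ_j)`. Performance is
reported as accuracy `(TP+TN)/(TP+FP+TN+FN)` and error rate
`(FN+FP)/(TP+FP+TN+FN)`, which sum to 1 by construction.

## Worked example

```python
import numpy as np
from bluecall import make_benchmark, CallDetector

bench = make_benchmark(n_scenes=100, snr_db=10.0, seed=1)
det = CallDetector.from_benchmark(bench, method="mse")
res = det.fit(seed=0)
print(res.summary())
```

```
MSE-GMM detection trial (seed 0)
====================================================
windows train/test:  70/30
mixture components:  5 (BIC-selected)
features kept:       4 of 12 (columns [3, 7, 4, 10])
TP/TN/FP/FN:         15/15/0/0
accuracy:            1.0000
error rate:          0.0000
```

The benchmark synthesizes 100 26-s scenes at 10 dB in-band SNR (half
noise-only, half containing one Z-type or D call), preprocesses them
exactly as real recordings, and splits them 70/30 stratified by class. The
summary shows one trial: BIC chose 5 mixture components on the 12
log-entropy features, the MPP ranking kept 4 scale columns, and all 30
held-out windows were labelled correctly. Averaging over 10 trials
(`det.fit_multi(range(10))`) gives the mean/highest/lowest accuracy table;
on this benchmark the entropy features average ≈99% detection accuracy
while the PCA baseline stays near chance, with DMD and wavelet features in
between — the same ordering reported for field recordings.

A `bluecall` console script wires the same workflow from the shell:

```bash
bluecall simulate --out-dir scenes --n-scenes 20 --seed 11
bluecall extract  --audio scenes --method mse --out feat.tsv
bluecall train    --features feat.tsv --out model.json --k-range 1-4
bluecall classify --model model.json --features feat.tsv --out pred.csv
bluecall evaluate --predictions pred.csv --truth feat.tsv --out report.json
```

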