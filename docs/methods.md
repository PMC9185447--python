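# Methods note

This note records the scientific model implemented by `falladl`, the
conventions and parameters it fixes, and the reasoning behind the main design
decisions. Everything here is deterministic given a seed.

## 1. Canonical representation

* **Axes.** All processing happens in a canonical body frame: AP
  (anterior–posterior), ML (medio-lateral), V (vertical). A per-dataset
  manifest maps native sensor axes onto canonical ones as a signed
  permutation (e.g. `AP <- +y`, `ML <- -x`); the induced 3×3 matrix must be a
  proper signed permutation (each native axis used once). Unit conversion
  supports `m/s²`/`g` (g = 9.81 m/s²) and `deg/s`/`rad/s`.
* **Resampling.** Streams are linearly interpolated onto a 50 Hz grid
  anchored at the first timestamp, `t_k = t_0 + k/50`,
  `k = 0 … floor(T·50) − 1`. Labels are categorical and transfer from the
  nearest input sample; exact midpoints go to the earlier sample. The
  comparison uses a `1e-9 ×` sample-spacing tolerance so float rounding
  cannot flip an exact tie.
* **Windows.** Window length `L = round(window_s · 50)` samples, hop
  `H = max(1, round(L · (1 − overlap)))`; defaults `window_s = 1`,
  `overlap = 0.8` give `L = 50`, `H = 10`. The number of windows over `N`
  samples is the closed form `floor((N − L)/H) + 1` for `N ≥ L`, else 0.
  Windows never span recording boundaries. A window's label is the modal
  sample label; ties are broken toward the tied label whose **last**
  occurrence in the window is latest (bias toward the activity being
  entered, which matters for transitions and falls). Windows whose mode is
  the unlabeled marker are dropped.

## 2. Feature bank (199 features)

Features are computed per window over eight channels — six axis channels
(acc/gyr × AP/ML/V) and two vector magnitudes (SumVM = per-sample Euclidean
norm of the acc or gyr triple) — in 14 fixed groups (group sizes
6+2+16+40+6+14+24+9+2+15+24+32+5+4 = 199), ordered statistic-major inside
each group. They cover first- to fourth-order moments, order statistics and
ranges, RMS and waveform length, zero/mean crossings, signal-magnitude area,
slope and regression statistics, inter-axis Pearson correlations (six pairs;
degenerate cases return 0), autocorrelation summaries, and spectral
quantities (energy, entropy, centroid/mean frequency, peak frequency and
amplitude, band measures) from the magnitude spectrum of the de-meaned
signal. One feature (`rotational_angle_acc_SumVM`) is a tilt angle
`acos(acc_V / ‖acc‖)` and is tagged cross-channel since it depends on the V
axis, not on the magnitude alone. The exponential moving average uses
`alpha = 0.1`. Every feature has a stable integer id (1…199); rankings and
CSVs refer to these ids.

## 3. Scaling and feature selection

* **Min–max scaling** maps each feature to [0, 1]. Two groupings:
  `per_dataset` (each virtual dataset scaled on its own pooled data — the
  historically common but leaky default, kept for comparability) and
  `train_fit` (parameters `lo`, `span` fitted on training rows only, applied
  with clipping to any other partition — the leakage-safe mode used by the
  final hold-out evaluation). Constant features map to 0.
* **Relief-F**: k = 10 nearest hits/misses per class, all instances used,
  L1 feature differences (features are already unit-range), miss
  contributions weighted by `P(c) / (1 − P(class(x_i)))`; neighbor ties are
  resolved by instance index for determinism.
* **Mutual information / mRMR**: 20 equal-width bins per feature, entropies
  in nats; mRMR uses the difference criterion (relevance − mean pairwise
  redundancy) with greedy forward selection.
* **CFS**: greedy forward search on the merit
  `k·r̄_cf / sqrt(k + k(k−1)·r̄_ff)` with the correlation ratio as
  feature–class association and Pearson correlation between features.
* **LASSO path order**: one-vs-rest L1 logistic regression over
  `C ∈ logspace(−3, 2, 16)`; a feature's score is how early any class
  coefficient becomes non-zero along the path (liblinear solver, wrapped in
  an explicit one-vs-rest meta-estimator).
* **PCA resultant procedure**: keep the minimal m components whose cumulative
  explained variance reaches 70%; form per-feature resultant loadings as the
  variance-weighted mean of absolute loadings, normalized to sum to 1; count
  features strictly above the uniform level 1/F (with a 1e−9 relative
  tolerance so an exactly uniform loading does not count) and cap selection
  at twice that count. The procedure also yields a full feature ordering by
  resultant loading.

All rankers return a full permutation of the 199 ids with scores;
score ties break toward the lower feature id. Methods are pluggable via a
registry.

## 4. Benchmark protocol

* **Hold-out**: stratified 70/30 split; per class, `round(0.7·n_c)` windows
  go to training. A class with a single window goes to training with a
  warning. A subject-wise mode assigns whole subjects greedily instead.
* **Cross-validation**: stratified k-fold built per class by dealing the
  shuffled class indices as `idx[f::k]`; each window is tested once per
  repeat; per-repeat metrics come from the pooled fold confusion matrix and
  repeats are summarized as mean ± std.
* **Metrics**: per-class one-vs-rest sensitivity, specificity, precision and
  F1 plus their unweighted macro means; accuracy = trace/total; multiclass
  MCC via the covariance (Gorodkin) formulation. All reported ×100.
* **Models**: distance-weighted k-NN (default 1 neighbor, Minkowski
  exponent 0.5, squared-inverse weights; fractional exponents force the
  brute-force neighbor search and scikit-learn's "not a metric" warning is
  expected; zero-distance neighbors take all the weight), decision tree,
  LDA, and bagging/boosting ensembles (default 37 cycles). Grid search
  covers 5 neighbor counts × 4 distances × 3 weightings for k-NN and cycle
  counts {10,…,100} ∪ {37} for ensembles, ties resolved toward the simpler
  model.
* **Progressive sweep**: evaluate the top n = stride, 2·stride, … ≤ cap
  features for each model × ranking and keep the n with the best CV MCC.
* **Window-size study**: the full pipeline (segmentation → extraction →
  scaling → ranking on the training partition → hold-out test) re-runs at
  0.5/1/1.5/2 s windows for chosen (model, ranking, n) triples.
* **Neural models**: CNN, LSTM, BiLSTM and CNN-LSTM implemented in numpy
  with manual backpropagation (no deep-learning framework dependency). The
  selected feature vector is treated as a length-F single-channel sequence.
  Fixed training regime: 100 epochs, batch size 64, Adam at 0.001,
  cross-entropy, 20-way softmax; 150 hidden units by default. Gradients are
  verified against finite differences in the test suite.

## 5. Synthetic corpus generator

Three virtual datasets emulate real-world heterogeneity: `synthA` (200 Hz,
g and deg/s, ±16 g clip, identity axes), `synthB` (100 Hz, m/s² and rad/s,
axis remap `AP <- +y`, `ML <- −x`), `synthC` (20 Hz, g, ±8 g clip, full axis
permutation). Class mix is walking-dominant (≈29.7%), lying ≈18.5%, syncope
rarest (≈0.27%). Sessions are random activity scripts; a class is drawn with
probability ∝ mix/mean-duration so the emitted per-sample share converges to
the mix; classes with fewer than 3 segments corpus-wide are topped up.
Cyclical activities and postures are held in long bouts (8–14 s), transitions
last 1–3 s, falls 3–4 s.

Per-class signal models: static postures are the gravity reaction along a
posture direction plus noise and slow sway; gait is gravity plus harmonic
components at a step frequency in 1.5–2.5 Hz with class-specific amplitude
and asymmetry (downstairs adds sharpened heel-strike pulses); jumping is
high-amplitude periodic vertical bursts; transitions rotate the gravity
vector between postures (spherical interpolation, with compound paths such
as stand → sit → tilted lying for stand-to-lying) with correlated gyro
activity, sustained vertical unloading/loading over the movement and a
direction-breaking pulse (settle bump near the end of descents, push-off
near the start of ascents); falls have a lead-in with a growing lean along
the eventual fall direction, a partially unloaded descent, an impact spike,
and a post-impact damped settling oscillation on the final lying posture.
The impact-spike amplitude is solved exactly so the acceleration magnitude
at the pulse-peak sample equals the configured peak (easy preset: fixed
per-class peaks ≥ 3.2 g; realistic preset: drawn from 3–8 g), which
guarantees the ≥ 3 g impact floor by construction. Syncope is a vertical
collapse onto a crumpled posture.

Two presets: `easy` (low noise: 0.05 m/s², 0.5 deg/s; fixed per-class
parameters) is engineered so the 20 classes are cleanly separable end to
end — the study condition for recovery checks; `realistic` (0.35 m/s²,
3 deg/s, jittered parameters) deliberately overlaps neighboring classes
(e.g. stand-to-sit vs bending) to exercise confusion behavior.

**Generator limitations.** The signals are phenomenological, not
biomechanical: no soft-tissue artifacts, no sensor drift or bias, no
orientation change within non-transition segments, falls always complete and
always start from standing, and class difficulty is controlled by noise and
parameter jitter rather than by realistic inter-subject variability.
Because activity scripts are composed of whole bouts, empirical class shares
concentrate at the bout level — ±2 percentage-point convergence needs
hundreds of bouts per class, i.e. hours of scripted recording, not merely
50 k samples.

## 6. Numerical conventions

* Gravity constant 9.81 m/s²; angles in degrees for gyro channels.
* Spectra come from the DFT of the de-meaned window without tapering;
  spectral energy equals de-meaned time-domain energy (Parseval).
* Correlation, skewness, kurtosis and z-scores return 0 in degenerate
  (zero-variance) cases rather than NaN.
* All stochastic steps (generation, splits, shuffles, model seeds, network
  initialization) take explicit integer seeds; repeated runs are
  bit-identical on the same platform.
* The test suite verifies the feature bank, Relief-F, the multiclass MCC and
  the windowing count against independently coded plain-Python oracles
  (direct DFT, explicit O(W²) loops) at 1e−9 relative tolerance or better.

## 7. Design decisions and limitations

* `per_dataset` scaling is retained as the default because it reflects
  common practice in pooled-corpus studies, although it leaks test
  information; the leakage-safe `train_fit` mode is used wherever a final
  generalization estimate is reported, and a dedicated test corrupts test
  rows and asserts that nothing fitted on training rows changes.
* Fractional-exponent Minkowski dissimilarity (p = 0.5) is kept despite not
  being a metric because distance-weighted 1-NN with it is the strongest
  classical configuration on this feature bank.
* The neural stack is intentionally small and CPU-bound; it demonstrates the
  architectures and the fixed training regime rather than competing with the
  classical models, and its accuracy on the separable preset (> 90%) is
  asserted at a reduced hidden width chosen for runtime.
* Headline numbers from real multi-dataset corpora are out of scope: every
  quantitative claim in this repository is computed on the synthetic corpora
  described above and is reproducible from a seed.
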