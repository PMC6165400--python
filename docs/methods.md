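# Methods

`enosecp` analyses electronic-nose (e-nose) data: multichannel voltage
transients from a panel of metal-oxide-semiconductor (MOS) gas sensors exposed
to a sample's headspace, used to discriminate between product categories
(the motivating application is herbal-medicine quality screening with a
16-sensor Taguchi-type panel and 12 medicine categories).  Because no such
dataset is publicly deposited, the package ships a synthetic generator that
reproduces the *structure* of those records, and every downstream method is
validated on that generator plus analytic and brute-force oracles.

## Signal model (synthetic generator)

One acquisition is modelled per sensor as

    Vs(t) = b + m*t + r(t) + e(t)

* `b` — clean-air baseline level (default 0.5 V),
* `m` — per-sample drift slope, `m ~ N(0, 1e-4 V/s)`: slow sensor drift,
* `e(t)` — i.i.d. Gaussian noise, sd 0.01 V,
* `r(t)` — the gas response: 0 during the baseline phase; after injection a
  first-order rise `A (1 - exp(-(t - t_inj)/tau_r))` for the reaction phase;
  then exponential recovery `r_end * exp(-(t - t_dec)/tau_d)` once clean air
  is pumped in.

Phase durations follow the acquisition protocol: 20 s baseline, 180 s
rise/stabilize, 140 s decline (340 s records at 100 Hz, 34,000 points,
injection at index 2000).  The test suite and the analysis scripts default to
a 10x shorter, 10x coarser version (10 Hz, 34 s, identical phase proportions
and proportionally scaled time constants) purely to keep iteration fast; the
full resolution is one flag away (`SimulationConfig.full_scale()`).

Class identity enters only through the amplitude pattern: sensor `s` has a
base amplitude `base_s ~ U(0.8, 2.5) V` and class `c` responds with
`A_cs = base_s * exp(separation * delta_cs)`, `delta_cs ~ N(0, 0.4)`.  This
keeps amplitudes positive, makes `separation = 0` collapse all classes onto
one profile, and for a fixed seed makes between-class distances monotone in
`separation`.  Per-sample amplitude jitter (sd 0.05 V) provides within-class
spread on top of noise and drift.  Kinetic constants are per-sensor,
`tau_r ~ U(20, 60) s` and `tau_d ~ U(40, 120) s` at full scale.

Sampling is i.i.d. within class and balanced across classes, so a pooled
labelled dataset is exchangeable — exactly the hypothesis under which
conformal prediction promises coverage, which is what the validity tests
check.

What the generator does *not* emulate: sensor chemistry (humidity and
temperature dependence, poisoning, cross-sensitivity structure between
specific volatiles), long-term drift across sessions, or heavy-tailed noise.
Passing tests therefore demonstrate correctness of the algorithms under the
stated statistical assumptions, not field performance on real instruments.

Seeding: a dataset has one master seed; record `i` uses
`SeedSequence([seed, i])`, so datasets are bit-reproducible and any record can
be regenerated in isolation.

## Feature extraction

Each sensor trace is calibrated by subtracting its baseline, `V = Vs - V0`,
where `V0` is the per-sensor mean over the pre-injection window (the protocol
does not pin down the estimator; the mean over the full 20 s baseline phase
is the default and is configurable).  Eight features per sensor follow:

1. `Vmax = max |V|` over the record;
2. `Vint = trapezoid integral of V(t) dt` over the record, volt-seconds.
   The trapezoid rule is exact for piecewise-linear signals.  Note that a
   record of `n = T * SR` samples spans `T - 1/SR` seconds, so on simulated
   records `Vint` integrates over 339.99 s rather than 340 s — a negligible
   (< 0.003%) difference retained so record length matches the protocol's
   sample-index conventions.  Analytic tests use inclusive-endpoint grids
   where exactness statements are meaningful;
3.-8. min and max of the exponential moving average of the first difference,
   `y(1) = a V(1)`, `y(k) = (1-a) y(k-1) + a (V(k) - V(k-1))` (1-based k),
   at smoothing factors `a = 1/(100 SR), 1/(10 SR), 1/SR` — at 100 Hz these
   are 1e-4, 1e-3, 1e-2.  The extrema are taken over the post-injection index
   window with strict bounds, `injection_index < k < n` (at full scale:
   `2000 < k < 34000`).  `V(1)` refers to the calibrated trace (calibration
   precedes feature extraction).

Column order per sensor is `[max, int, min@a1, max@a1, min@a2, max@a2,
min@a3, max@a3]` with `a1 < a2 < a3`; any fixed order would do — this one is
stable and named.  A 16-sensor record yields 128 columns.  No scaling or
normalization is applied at this stage; standardization is an opt-in flag in
the conformal and benchmark modules (fitted on training data only).

The EMA recurrence is evaluated with a linear IIR filter; a brute-force loop
re-implementation serves as its oracle in the tests.

## Conformal prediction

The nonconformity of a bag member `(x, y)` is the KNN distance ratio

    alpha = sum_{s=1..k} d(x, s-th nearest same-label neighbour)
          / sum_{s=1..k} d(x, s-th nearest different-label neighbour),

neighbours taken within the bag excluding the member itself.  Scoring a new
object under a hypothesized label augments the bag, re-scores every member
leave-one-out, and ranks `alpha_new`:

* `strict` mode: `p_y = #{i : alpha_i > alpha_new} / n` — a strict count over
  the augmented bag of size n.  This can reach p = 0 for all labels.
* `standard` mode: `p_y = #{i : alpha_i >= alpha_new} / n`, including the
  test member itself, so `p >= 1/n`.  This is the conventional transductive
  p-value and carries the finite-sample guarantee
  `P(true label excluded from Gamma^eps) <= eps` under exchangeability.

Both are provided because the strict-count variant is the formulation used
in the motivating e-nose application, while the standard variant is the one
whose validity can be (and is) tested.  Prediction sets are `{y : p_y > eps}`,
nested in eps by construction.  Forced prediction returns `argmax_y p_y`
(ties broken toward the smallest label — deterministic), with
`confidence = 1 - second-largest p` and `credibility = largest p`.

Numerical/degenerate conventions, all exercised by tests:

* k-smallest distance sums are accumulated in ascending order, which makes
  the optimized leave-one-out path bit-identical to a naive per-fold
  recomputation (float addition is order-sensitive for k > 1);
* zero numerator gives `alpha = 0` regardless of the denominator; a positive
  numerator over a zero denominator gives `alpha = +inf`;
* a member with fewer than k same-label (resp. different-label) companions
  has the missing distances padded with +inf, i.e. `alpha = +inf` (resp. 0;
  `inf/inf` is scored 1, neutral).  This keeps minimal datasets (e.g. 2
  classes x 2 samples) evaluable; for every p-value to be backed by k real
  neighbours, give each class at least k + 2 members;
* distances are `scipy.spatial.distance.cdist` (Euclidean by default), whose
  per-pair values do not depend on the surrounding matrix — a requirement for
  the shared-distance-matrix LOO optimization to be exact.

Leave-one-out evaluation exploits the identity that "train on n-1, augment
with the held-out point under a candidate label" is the full bag with one
label replaced, so a single n x n distance matrix serves all folds; a test
asserts exact agreement with the naive path for both modes and k in {1, 3}.
With `standardize=True` the scaler must be refit per fold, so the naive path
is used.

The calibration curve reports, per significance level, the fraction of LOO
samples whose true label falls outside the prediction set; on exchangeable
synthetic data in standard mode this stays below `eps` up to binomial noise
(LOO folds are weakly coupled, so the test allows 3 standard errors).

## Benchmark harness

Classifiers (decision tree, KNN, LDA, SVM, Gaussian naive Bayes, one-hidden-
layer MLP trained by back-propagation) are scikit-learn estimators behind a
declarative spec; the harness contributes the leave-one-out protocol, the PCA
sweep and the report. Deterministic families are seeded; `standardize=True`
inserts a per-fold standard scaler.  PCA components have their sign fixed by
"largest-magnitude loading positive", making projections reproducible; an
eigendecomposition of the sample covariance is the oracle for the explained
variances.  By default PCA is fitted on the full matrix before the LOO loop —
the protocol commonly used in this literature, which leaks a small amount of
held-out information into the projection; `pca_in_fold=True` refits PCA
inside each fold.  Wall-clock timing is reported for orientation and is the
one column exempt from byte-level reproducibility.

## Problem sizes

The working set for the analysis scripts and the acceptance script is 12
classes x 10-20 samples x 16 sensors at the scaled record resolution —
chosen so that each LOO sweep completes in seconds while keeping the class
count, feature count (128) and balance of the motivating application.  The
structural full-resolution run (12 x 50 at 100 Hz / 340 s, streamed one
record at a time to bound memory) verifies the 600 x 128 feature-matrix
shape.

## Known limitations

* The generator's amplitude-pattern class model is far kinder than real
  volatile chemistry; absolute accuracy numbers on synthetic data say nothing
  about accuracy on real panels (expect the synthetic ones to be higher at
  the default separation).
* `strict`-mode p-values have no coverage guarantee; use `standard` mode
  whenever prediction-set validity matters.
* Euclidean distance on raw features is dominated by the integral feature
  (largest dynamic range); this mirrors the unscaled protocol, and
  standardization is available but off by default.
* LOO conformal validity is only approximate (folds share data); the
  guarantee is exact for a fresh exchangeable test point.
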