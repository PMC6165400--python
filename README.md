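# enosecp

Electronic-nose (e-nose) sensor-array analysis: synthetic MOS gas-sensor
record simulation, transient-response feature extraction, a from-scratch
transductive conformal predictor with per-sample reliability, and a
leave-one-out classifier / PCA benchmark harness.

## The problem

An e-nose is an array of partially selective gas sensors (here: a panel of
Taguchi-type metal-oxide sensors) plus pattern recognition.  Each measurement
is a multichannel voltage transient: a clean-air baseline, a headspace
injection, a rise to a compound- and sensor-specific plateau, and a decline
under clean carrier gas.  Classifying such records — e.g. telling 12
near-identical-looking herbal-medicine categories apart — is routine for
standard classifiers, but point predictions alone are risky when the
downstream decision affects treatment: one also wants to know *how reliable
each individual prediction is*.  That is what conformal prediction adds.

The pipeline:

1. **simulate** — per-sensor records `Vs(t) = baseline + drift·t + response + noise`
   with class identity encoded in the amplitude pattern across the panel;
2. **extract** — calibrate `V = Vs − V0` (baseline subtraction) and compute 8
   features per sensor: `Vmax = max|V|`, `Vint = ∫V dt`, and min/max of the
   exponential moving average of the derivative,
   `y(k) = (1−a)·y(k−1) + a·(V(k)−V(k−1))`, at `a = 1/(100·SR), 1/(10·SR), 1/SR`
   → a samples × 128 feature matrix for 16 sensors;
3. **conformal** — KNN nonconformity
   `α = Σ dist to k nearest same-label / Σ dist to k nearest other-label`;
   for each candidate label, augment the bag, re-score everything
   leave-one-out, and report the p-value rank of the test point.  Prediction
   set `Γ^ε = {y : p_y > ε}`; forced prediction `argmax p` with
   `confidence = 1 − second-largest p` and `credibility = largest p`;
4. **benchmark** — leave-one-out accuracy for decision tree, KNN, LDA, SVM,
   naive Bayes and an MLP, at full dimension and after PCA.

See `docs/methods.md` for the model, conventions and limitations.

## Worked example

```python
from enosecp import (CPConfig, SimulationConfig, build_feature_matrix,
                     loo_evaluate, make_class_profiles, simulate_dataset,
                     format_prediction_row)

sim = SimulationConfig(samples_per_class=10, seed=7)      # 10 Hz / 34 s records
profiles = make_class_profiles(12, 16, separation=1.0, seed=7,
                               timescale=sim.timescale)
fm = build_feature_matrix(simulate_dataset(profiles, sim))
print(fm.values.shape)

preds, acc = loo_evaluate(fm, CPConfig(k=1, p_value_mode="strict"))
print(f"CP-1NN forced accuracy: {acc:.4f}")
print(format_prediction_row(0, fm.labels[0], preds[0]))
```

prints

```
(120, 128)
CP-1NN forced accuracy: 0.9917
0, 1, 1, 1.0000, 0.3667
```

i.e. 120 samples × (8 × 16) features; 119/120 forced predictions correct;
sample 0's true class 1 is predicted with confidence 1.0000 (all rival labels
have p-value 0) and credibility 0.3667 (its own label's p-value — well away
from 0, so the prediction is trustworthy).

The same run, step by step with artifacts written under `results/`, is in the
numbered scripts:

```bash
python analysis/01_simulate.py             # raw records -> scratch/analysis/
python analysis/02_extract_features.py     # results/features.csv (120 x 128)
python analysis/03_benchmark_classifiers.py  # results/benchmark.csv + PCA plot
python analysis/04_conformal_prediction.py   # CP reports, calibration curve
```

There is also a CLI over the same library (`enosecp simulate | extract |
conformal | benchmark | report | pipeline`), e.g.

```bash
enosecp simulate --classes 12 --per-class 10 --sensors 16 --seed 7 --out ds/
enosecp extract --in ds/ --out features.csv
enosecp conformal --features features.csv --k 1 --epsilons 0.05,0.1 --out cp.csv
```

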