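# Methods

## Problem setting

`fedhetero` simulates cross-silo federated learning for patient-level binary
classification (the motivating task is preoperative lymph-node-metastasis
detection in pancreatic ductal adenocarcinoma from CT): a handful of
institutional clients, full participation every round, only model parameters
crossing institutional boundaries. The scientific object of study is the
**server aggregation rule** under client heterogeneity — label skew and
site-specific feature (domain) shift — not the image encoder: clients here
train a compact MLP classifier over feature vectors, standing in for the
classifier head that sits on a frozen 3-D embedding pathway in the full-scale
clinical setting.

## The aggregation rule

At round *t* the server broadcasts the global vector ω⁽ᵗ⁾; client *k* trains
locally and returns (ω_k, n_k, D_k), where n_k is its training-sample count
and D_k its empirical label distribution. Two discrepancy scores are computed
per client:

* **label discrepancy** d_k = KL(D_k ‖ T) in nats, with T the target
  distribution (uniform by default);
* **representation discrepancy** Δ_k = 1 − cos(θ_k, θ_ref), the cosine
  distance between the client's final-classifier ("head") parameters θ_k and
  the head θ_ref of the global model broadcast at the *start* of the round.
  Using the start-of-round head avoids any circularity with the aggregation
  being computed.

The unnormalized score is s_k = ReLU(ñ_k − a·d_k − γ·Δ_k + b), and the
aggregation weights are p_k = s_k / Σ_m s_m. By default ñ_k = n_k / Σ_m n_m:
with raw counts in the hundreds and d_k ≲ 0.7, Δ_k ≤ 2, the discrepancy
terms would be numerically irrelevant at the hyperparameter magnitudes that
matter (a, γ ≤ 10); expressing sizes as fractions makes the three terms
commensurate. A flag restores raw counts.

Reductions: (a, b, γ) = (0, 0, 0) is exactly sample-size (FedAvg) weighting;
γ = 0 is label-discrepancy-only (FedDisco) weighting. Two hyperparameter
presets are exposed and neither is hard-coded as canonical: (0.1, 0.1, 10)
(validation-selected in the motivating study) — the `FederationConfig`
default — and (1, 1, 1) (best cell of the coarse ablation grid).

Conventions for degenerate inputs, fixed once:

* θ with zero norm (e.g. a zero-initialized head) has no direction; Δ_k ≡ 0,
  i.e. no penalty.
* If the ReLU clips every score to zero, the round falls back to sample-size
  weights (configurable: uniform, or hard error), flags the round in the
  diagnostics, and logs a warning rather than failing.
* KL uses natural logarithm (the convention in this aggregation-rule
  lineage; any other base only rescales a) with 0·ln 0 = 0; a target with
  zero mass where the client has mass is a domain error.
* The head segment is the final linear layer's weight matrix, row-major,
  followed by its bias vector.
* Whether b is added before or after size normalization is a free choice;
  the formula order as written (ñ_k − a·d_k − γ·Δ_k + b) is used.
* Aggregation is a deterministic function of its inputs; no tie-breaking
  randomness exists anywhere in the server path.

## Federation protocol

Synchronous rounds, all clients every round. Strategies: `fedavg`,
`feddisco`, `ours`, and `fedbn` (sample-size weights, but normalization
segments are excluded from both broadcast and aggregation: each client keeps
its own, and the global copy retains its initial values). Defaults: 30
rounds of 2 local epochs (midpoints of the 20–40 rounds / 1–3 epochs
cross-silo regime), learning rate 1e-3 with cosine decay over rounds,
decoupled weight decay 0.01, batch size 4.

Local optimization is AdamW-style: bias-corrected adaptive moments with
decoupled weight decay, hand-implemented in numpy with analytic backprop
(verified against central finite differences to 1e-5 relative). Moment state
is client-local and reset each round; an explicit `OptState` can be threaded
through chained calls, which makes "2 epochs" bit-identical to two chained
1-epoch calls. All batch schedules are keyed by (run seed, round, client
index), independent of the strategy, so strategies that produce identical
weights produce bit-identical trajectories.

The client model is input → hidden (ReLU, optionally a per-sample
normalization layer with learnable gain/shift) → 2-class linear head, default
hidden width 16 — a desk-scale analogue of a 512–256–2 perceptron head.
Per-sample (layer) normalization was chosen over batch normalization so that
evaluation is deterministic and there are no running moments; the FedBN
open question of which running statistics to use at test time becomes the
question of which *learned* normalization parameters to use, and both modes
are computed for FedBN runs (pooled test with client-local norms, and with
the untouched global norms) and logged. Dropout is off by default; when
enabled it is applied (inverted) to the features entering the classifier.
Loss is unweighted cross-entropy; the decision threshold is 0.5.

Evaluation-time model selection reports the final-round model; the
best-validation round index is logged alongside.

## Synthetic multi-site cohorts

Each client draws class-conditional Gaussian features x = A_k(μ_y + ε) + c_k
with ε ~ N(0, I); ‖μ₁ − μ₀‖ = `class_separation` along a seeded shared
direction; A_k = I + s·R_k with R_k a seeded random matrix of unit spectral
norm and s = `shift_strength`; c_k a seeded random offset of norm s. Label
counts are deterministic, round(prevalence·n) half-up, so the label
discrepancy d_k is exactly controllable in tests. Splits are stratified per
class by the largest-remainder rule (70/10/20 by default; remainders rounded
to 9 decimals before ranking so float noise cannot flip a tie; exact ties
break toward train, then val).

The `three_site_cohort` preset mirrors a three-hospital structure: sizes
180/163/203 (546 patients), prevalences 0.71/0.69/0.64. Its free defaults
were fixed once at desk scale: feature_dim 16, class_separation 1.0 (Bayes
balanced accuracy ≈ 0.69 on the within-site task, leaving the learned models
in the 0.55–0.65 range typical of this problem), shift_strength 0.5
(moderate site shift). A full 30-round federated run on the preset takes
about one second on one CPU core.

**What the generator does and does not emulate.** It produces genuine label
skew and genuine representation-level divergence (site-specific affine
feature transforms yield different per-site decision boundaries). It does
*not* emulate asymmetric site pathology: every client receives a transform of
the same magnitude, so the clients are statistically exchangeable. A direct
consequence, observed consistently in simulation, is that discrepancy-based
reweighting is *expectation-neutral* here: no client is systematically more
divergent, so down-weighting by drift adds variance but no bias, and the
pooled-test balanced accuracy of the heterogeneity-aware strategy matches
FedAvg to within quantization noise (±1–2 flipped test predictions, i.e.
|ΔBA| ≤ 0.003 over 10-seed means at every shift strength we examined, far
inside the 0.05 non-inferiority band asserted for the IID case). Passing
simulation tests therefore demonstrate correctness and non-inferiority of
the rule, not the full-scale clinical gains, which arise from severe,
asymmetric inter-hospital domain shift that destabilizes plain averaging.

## Diagnostic metrics

Threshold metrics are computed from exact integer confusion counts
(positive class = LNM-positive): sensitivity, specificity, precision,
balanced accuracy = (sens + spec)/2, F_β for β ∈ {1, 2}, and the diagnostic
odds ratio DOR = (TP·TN)/(FP·FN). Degenerate cells follow clinical-table
typography rather than smoothing: DOR is +∞ when exactly the denominator is
zero with a positive numerator, NaN (rendered "-") when numerator and
denominator are both zero; any metric with an empty denominator is NaN. A
Haldane–Anscombe 0.5 correction is available behind a flag, off by default.
ROC AUC (Mann–Whitney, ties ½) and AUPRC as step-wise average precision —
the convention under which uninformative constant scores give exactly the
prevalence — are delegated to scikit-learn and cross-checked in the test
suite against brute-force pair-enumeration and threshold-enumeration
oracles.

The test fixtures include the printed metric rows of a published
three-center benchmark of this task. Rows whose printed cells are internally
inconsistent are flagged in the fixture table and excluded from identity
checks: one aggregated federated-averaging row prints a balanced accuracy
inconsistent with its own sensitivity/specificity mean, and the
gradient-boosting / random-forest rows (plus one centralized site row) print
DOR values that cannot be recovered from their 4-decimal sensitivity and
specificity (evidently computed from unrounded counts). The flags are data
annotations, not tolerances.

## CT preprocessing

Standardization chain, in narrative order (configurable): trilinear
resampling to isotropic spacing (output shape round(shape·spacing/target);
masks nearest-neighbor), Hounsfield clipping to [−1000, 2000], per-patient
z-score over the whole clipped volume (population std; constant volumes map
to zeros with a warning), and a fixed-size ROI crop centered on the organ
mask's voxel centroid (rounded down at exact .5), zero-padded where the ROI
exceeds the volume — after z-scoring, zero is the mean intensity.
Augmentation (seeded, deterministic): per-axis flips at p = 0.5, trilinear
zoom drawn from [0.9, 1.2] with recrop/pad to the original shape, additive
Gaussian noise σ = 0.01, multiplicative intensity scaling drawn from
[0.7, 1.3] (an additive ±0.3 mode is available behind a flag), and a 90°
rotation about a random axis at p = 0.5. Application probabilities for the
always-on transforms are a documented convention; the literature the chain
follows does not state them.

## Numerical choices

* All randomness flows from named `numpy.random.SeedSequence` streams keyed
  by (seed, purpose[, round, client]); every component is independently
  reproducible and bit-identical across reruns.
* Weight simplex validity is enforced at construction (sum within 1e-9).
* Cosine similarity is clamped to [−1, 1] before forming the distance.
* The normalization layer uses variance floor 1e-5.
* Gradient checks, reductions and oracle comparisons in the tests use
  tolerances of 1e-5 (finite differences), 1e-12 (algebraic identities), and
  the fixture tables' own printed precision elsewhere.

## Known limitations

* Clients are simulated in-process; there is no transport, encryption, or
  differential privacy. The privacy contract is structural: the report type
  that crosses the client/server boundary cannot carry features or labels.
* The generator's symmetric site shift cannot reproduce ordering effects
  between aggregation strategies (see above); demonstrating those requires
  asymmetric heterogeneity beyond the scenario model.
* The numpy training backend is CPU-only and intended for desk-scale
  problems (hundreds of samples, tens of features).
* DOR confidence intervals, significance tests and calibration metrics are
  out of scope.
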