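# Methods

## Adaptation dynamics

Intrinsic suppression is activation-based: a per-unit state integrates the
unit's own rectified output and is subtracted, scaled by β, from the
pooled drive before the ReLU. Within a model step the activation is
computed from the *current* state and the state is then updated from that
activation, so suppression at step t reflects activity strictly before t.
The power-law mechanism keeps one independent state channel per decay
factor α_k, each updated with its own (1 − α_k) input weight; the
effective suppression is the channel sum, which is why its β (0.15) is far
below the single-exponential β (0.7). States are stored pre-β so β can be
swept without re-simulating.

Consequences used as oracles in the tests:

- open loop (fixed activation sequence, s₀ = 0):
  s_T = (1 − α) Σ_{k<T} α^{T−1−k} a_k;
- closed loop under constant drive x with exponential adaptation:
  a* = s* = x / (1 + β), so x = 1, β = 0.7 settles at 1/1.7;
- β = 0 is arithmetically identical to disabling adaptation (asserted
  bitwise);
- a single-α "power-law" model is exactly the exponential model;
- at the presets, long-horizon activation loss is strictly smaller for the
  power-law mechanism (its fast channel α = 0.75 saturates low).

## Network

The simulator is a stack of rectified layers — dense or small same-padded
convolutions — with optional lateral recurrence per layer
(drive = b + W_ff·x_t + W_lat·h_{t−1}, one pooled term before the
suppression subtraction) and adaptation attached to every rectifier. The
readout is linear: no softmax, no rectifier, hence no adaptation on it.
Weights are seeded Gaussian draws (He-scaled); nothing is trained by
backpropagation. Normalization is a fixed per-channel affine frozen from a
calibration batch (statistics collected at a configurable step, default 4),
making the network time-translation invariant; the exact statistics that a
large pretrained recurrent recognition network would use are out of scope
here, so synthetic networks compute their own once and freeze them.

The "toy classifier" used in end-to-end runs is a single dense recurrent
layer whose linear readout is solved in closed form (ridge regression from
single-step feedforward hidden states to one-hot category labels). This is
a readout fit, not network training, and it keeps identically-seeded builds
deterministic.

Modes: *sequential* carries recurrent and adaptation state across image
boundaries (the first step of a run is a pure feedforward pass);
*single-image* zeroes state before each image and is exactly equivalent to
a one-image sequential run.

## Prototype readout

Exemplar readout states are taken from single-image runs at their final
step (the assumption adopted where the exemplar time point is otherwise
unspecified). Relevance ranking uses Pearson correlation between each
exemplar's state and the reference vector (mean of the target- and
foil-image states); Euclidean distance is available behind a flag since
the similarity metric for ranking is a genuinely open choice — correlation
was preferred to keep the module on a single similarity measure. The
prototype is the plain mean of the top-k ranked states (k = 10 by default;
10/50/100 are all computable from one exemplar set).

Representational strength p_t is the Pearson correlation between the
readout state y_t and the target vector. Zero-variance readout rows (which
a rectified toy network can produce) yield NaN sentinels meaning "no
evidence": they are skipped by peak-taking and excluded, with a logged
count, from d′ — never imputed and never an exception mid-trial.

## Signal detection

PPC = max p over the trial (sequential) or over per-image values
(single-image). AUC over present/absent PPC distributions uses the midrank
Mann–Whitney estimator — chosen over literal criterion integration for
exact tie handling and O(n log n) determinism; equivalence to the
threshold-sweep ROC integral is asserted in tests, including under heavy
ties. d′ = √2·Φ⁻¹(AUC), with AUC clipped to [1/(2n+2), 1 − 1/(2n+2)]
(configurable) so perfect separation maps to a finite value. Human d′ adds
0.5 to every SDT cell (log-linear correction), which keeps it finite at 0%
and 100% rates.

## Model–human comparison

Report rate RR = yes-responses / subjects per trial, over *all* trials
(target-absent included). Predictivity is midrank Spearman ρ between PPC
and RR per (model steps × duration) cell; constant inputs give a NaN
sentinel. Bootstrap CIs resample subjects only (trial resampling exists
behind a flag, off by default), 95% percentile bounds, bit-reproducible
given a seed.

Noise ceilings are computed per presentation duration (matching per-panel
ceilings in the analyses this supports): upper = mean over subjects of
Spearman(subject, group-mean RR), lower = the same with the focal subject
excluded from the mean. Note the upper ceiling carries a self-inclusion
bias of order 1/√S under independent subjects — it is a ceiling, not an
unbiased null statistic; the leave-one-out lower ceiling is the null-clean
quantity.

Temporal correspondence is the argmax of ρ over steps per duration, ties
resolved to the *smallest* step (the more parsimonious temporal mapping,
and reproducible); the per-bootstrap argmax distribution gives its CI.
Explanatory power is mean over durations of best-ρ / lower-ceiling;
values above 1 are legal and durations with non-positive ceilings are
excluded with a warning.

## Synthetic world

Defaults state the emulated experiment: 176 trials (8 blocks × 22),
36 subjects, 6 images per trial from distinct categories, exactly 25%
target-absent (stratified as round(n·p), not sampled — stable fixtures),
targets uniform over interior positions (never first or last),
presentation durations 13/40/80 ms. The desk-scale choices not fixed by
the emulated experiment: 180 categories × 12 exemplars (enough for unique
trial cues), 8×8 single-channel images in [0,1] built as a per-category
uniform template plus Gaussian pixel noise (σ = 0.25 — templates stay
nearest-template decodable but exemplars vary visibly), model steps grid
(1, 2, 4, 8), and a duration→steps map {13→2, 40→4, 80→8} used to pick
which model evidence drives the observers.

Observers answer yes with probability
logistic(gain·(evidence − median) + bias_s + noise), bias and noise
N(0, σ_subj); gain 6 and σ_subj 0.5 give panels with realistic
inter-subject agreement (lower ceilings ≈ 0.3–0.5). By default the latent
evidence is the toy model's own PPC, enabling self-consistency tests in
which the generating model should reach the lower noise ceiling.

What a green end-to-end test establishes: the pipeline is internally
consistent — evidence generated by the model is recovered as predictivity
at the planted duration→steps correspondence. What it does not establish:
anything about real images, pretrained representations, or human
behaviour; synthetic categories are linearly separable templates with
i.i.d. noise, far easier than natural-image statistics.

## Numerical choices

- Recursion checks at relative 1e−10; anything downstream of rectification
  chains at 1e−6; correlation oracles at 1e−12.
- Top-k ties break toward the smallest category index (stable argsort of
  the negated row).
- Per-image accuracy within a presentation window defaults to the mean of
  per-step correctness; scoring only the window's final step is available
  behind a flag, since the aggregation is a genuinely open choice.
- All randomness flows through `numpy.random.default_rng` seeds carried in
  configs; identical seeds give byte-identical CSV outputs.

## Known limitations

- No training: hidden weights are random, so absolute accuracies and d′
  levels are far below what pretrained recognition weights would give, and
  no absolute performance figure here is comparable to published curves.
- Dense toy networks are the default; the conv path is exercised but small.
- Divisive normalization, feedback (top-down) recurrence and
  criterion/bias estimation are out of scope.
- The subject bootstrap treats trials as fixed; generalisation across
  stimulus sets is not addressed.
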