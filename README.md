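# rsvpsim

Sequential object-recognition models with intrinsic suppression, and the
psychophysics pipeline that compares them with human rapid serial visual
presentation (RSVP) behaviour.

## The problem

In RSVP experiments, observers view a stream of six photographs — each shown
for 13–160 ms — and report whether an image matching a cued category was
present. Standard feedforward recognition models see each image in
isolation and vastly outperform humans at short durations; they have no
notion of time. This package implements the modelling framework needed to
study recognition *in sequence*: recurrent rate networks whose internal
state persists across images, rapid neural adaptation that suppresses
recently active units, a prototype-based readout of how strongly a target
category is represented at each moment, and the signal-detection and
trial-by-trial statistics that link model evidence to human reports.

It is intended for computational-neuroscience and model-based-psychophysics
work where the full pipeline — stimulus sequence → network dynamics →
evidence time course → sensitivity and single-trial predictivity — must be
reproducible end to end on synthetic data, without large pretrained
weights.

## The model

**Dynamics.** Each rectified unit carries an intrinsic suppression state
*s* driven by its own past activation and subtracted from its drive:

    a_t = ReLU(b + W x_t + W_lat h_{t-1} − β Σ_k s_t^(k))
    s_{t+1}^(k) = α_k s_t^(k) + (1 − α_k) a_t

One decay factor α gives exponential adaptation (preset `exponential-vinken`:
α = 0.96, β = 0.7); a sum of exponentials approximates power-law adaptation
(preset `powerlaw-paper`: α = [0.96, 0.75], β = 0.15), which matches the
exponential mechanism at short timescales but suppresses much less over long
ones. Presentation duration is emulated by repeating an image for *n* model
steps; "sequential" mode carries recurrent and adaptation state across image
boundaries, "single-image" mode resets it.

**Readout.** The category readout is linear (no softmax). A trial's target
category is represented by a prototype φ — the geometric centre of the
readout states of its most relevant exemplars, ranked against the mean
target/foil representation. Representational strength is
p_t = r(φ, y_t) (Pearson), and the trial's evidence is its peak, PPC = max p.

**Statistics.** Model sensitivity is d′ = √2·z(AUC) with AUC the midrank
Mann–Whitney estimator over target-present vs target-absent PPC
distributions; human d′ uses the log-linear (+0.5) correction. Single-trial
predictivity is the Spearman ρ between PPC and the human report rate
RR = P/N per (model steps × presentation duration) cell, with 95% CIs from
subject bootstraps, leave-one-out/full-group noise ceilings, the most
predictive model step per duration (temporal correspondence), and best-ρ /
lower-ceiling averaged over durations (explanatory power).

## Worked example

```python
import numpy as np
from rsvpsim import get_preset, simulate_unit

trace = simulate_unit(np.ones(600), get_preset("exponential-vinken"))
print(round(trace.activation[-1], 4))   # 0.5882 = 1/(1+β): adapted steady state
```

A constant unit drive settles at 1/1.7 ≈ 0.588 — adaptation gives away ~41%
of the response. The full synthetic experiment:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

prints (seed 1):

```
d' per model steps per image:
 steps_per_image   dprime   n
               1 1.683745 176
               2 1.428850 176
               4 1.604568 176
               8 2.063014 176

most predictive model step per presentation duration:
 duration  best_step  best_step_ci_low  best_step_ci_high
       13          2               2.0                2.0
       40          4               4.0                8.0
       80          8               8.0                8.0

explanatory power (fraction of lower noise ceiling): 2.554
```

Reading this: the toy sequential model separates target-present from
target-absent trials at every duration (d′ well above 0); the most
predictive model step grows monotonically with the human presentation
duration, recovering the duration→steps mapping the synthetic observers
were built from (13→2, 40→4, 80→8 ms→steps); and because those observers
were generated from this very model's evidence, its predictivity exceeds
the lower noise ceiling (explanatory power > 1).

The script regenerates everything from scratch under `--seed`: synthetic
image bank → RSVP trials (6 images, 25% target-absent, interior targets) →
recurrent network with power-law suppression → prototypes and PPC →
simulated observer panel → d′, predictivity, ceilings, correspondence.

## Command line

```bash
rsvpsim synth    --out runs/world --seed 0           # bank + trial table
rsvpsim simulate --preset powerlaw-paper --steps 1,2,4,8 --out runs/sim
rsvpsim analyze  --ppc runs/sim/ppc.csv --out runs/dprime
rsvpsim compare  --ppc runs/sim/ppc.csv --reports runs/reports.csv \
                 --out runs/cmp --plot
```

Every command writes a `manifest.json` with the resolved configuration,
seed and warning counts; identical manifests give byte-identical outputs.

See `docs/methods.md` for modelling assumptions, parameter choices and
limitations.
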