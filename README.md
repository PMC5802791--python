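# memloop

Closed-loop memory decoding and stimulation analysis for intracranial EEG
(iEEG) experiments on verbal memory.

During delayed free recall, the brain state at word encoding predicts whether
the word will later be recalled: successful encoding shows increased
high-frequency spectral power together with decreased low-frequency power.
A per-subject classifier trained on this subsequent-memory effect (SME) can
decode the probability of recall online, word by word, and trigger electrical
stimulation precisely when encoding is predicted to fail. `memloop`
implements that entire analysis as a tested, reusable pipeline, exercised end
to end on a synthetic-data generator that emulates the structure of such a
study — so every stage is verifiable without any patient data.

## What the package computes

**Decoding.** Raw multichannel iEEG is band-stop filtered around 60 Hz
(4th-order Butterworth, 57.5–62.5 Hz, zero-phase), re-referenced to a bipolar
montage of adjacent contacts, and decomposed with Morlet wavelets (wave
number 5) at 8 frequencies geometrically spaced over 3–180 Hz. Power over the
word-encoding epoch ([0, 1366) ms from onset, with 1365 ms analysis buffers)
is log-transformed, time-averaged and z-scored, giving one feature per
(electrode pair × frequency). A recall classifier is trained per subject by
L2-penalized logistic regression (LIBLINEAR convention, C = 2.4 × 10⁻⁴,
class weights inverse to class frequency):

    p(recalled | x) = logistic(x·W + b)

Performance is summarized by ROC AUC (chance 0.50) with a label-permutation
significance test, and feature attributions use the forward-model
(activation-pattern) transform **A** = Σₓ**W** / σ²_logit(ŷ).

**Closed loop.** In a simulated closed-loop session (1 practice + 25 task
lists of 12 words; lists 1–3 baseline; lists 4–25 an interleave of 11 Stim
and 11 NoStim lists), features are normalized against baseline-list
statistics — refit after each completed NoStim list — and decoded online. On
Stim lists a decoded probability below 0.5 triggers 500 ms of stimulation;
on NoStim lists below-threshold words are flagged as matched controls.

**Effect estimation.** Trial-level recall of stimulated vs matched words is
modeled with a binomial mixed-effects logistic model (random intercepts and
condition slopes per subject and per stimulation site, Laplace approximation
to the marginal likelihood), reporting the stimulation odds ratio; a
log-binomial companion model reports the relative risk as a percent change;
a linear mixed model of consecutive-word classifier-output changes
(w₍ᵢ₊₁₎ − wᵢ) estimates the post-stimulation shift in decoded brain state;
and group-balance checks compare trigger proportions and record-only recall
across study arms.

## Worked example

```python
import numpy as np
from memloop import synthgen, sigproc, decoder, loopsim, stimstats
from memloop.config import profile_config

cfg = profile_config("lateral_temporal", n_subjects=1, seed=11)
profile = synthgen.make_subject(cfg, 0)

# three record-only sessions -> per-subject recall classifier
X, y = [], []
for s in range(cfg.n_record_sessions):
    events, feats = synthgen.simulate_record_session(cfg, profile, s)
    z = sigproc.normalize_features(feats, "within_session")
    X.append(z.values); y.append(events["recalled"].to_numpy())
model = decoder.train(np.vstack(X), np.concatenate(y),
                      pair_labels=profile.pair_labels,
                      freqs=sigproc.analysis_freqs())

# one closed-loop session with threshold-triggered stimulation
sched = synthgen.make_schedule(cfg, cfg.seed_for("loop", profile.site, "sched"))
events = synthgen.simulate_recall(sched, cfg,
                                  seed=cfg.seed_for("loop", profile.site, "recall"),
                                  profile=profile, session=3)
feats = synthgen.simulate_features(events, cfg,
                                   seed=cfg.seed_for("loop", profile.site, "feats"),
                                   profile=profile)
log, out = loopsim.run_closed_loop_session(model, feats, sched, events,
                                           config=cfg, profile=profile)

nostim = out[out.list_role == "NoStim"]
print("held-out NoStim AUC:", round(decoder.auc(nostim.classifier_prob,
                                                nostim.recalled), 3))
print("trigger fraction on Stim lists:",
      round(out[out.list_role == "Stim"].stimulated.mean(), 3))
```

Output:

```
held-out NoStim AUC: 0.575
trigger fraction on Stim lists: 0.47
```

The classifier trained on record-only sessions generalizes to the new
session (AUC well above the 0.50 chance level), and — because decoded
probabilities center near the 0.5 threshold — about half of the Stim-list
words trigger stimulation, which is what makes NoStim below-threshold words
valid matched controls.

A full multi-subject run, from simulation through the effect models, is one
command:

```sh
memloop simulate --seed 1 --out run/   # then: preprocess, train, loop, stats
memloop report --out run/
```

## Layout

| module | role |
| --- | --- |
| `memloop.config` | study parameters, group profiles, seed derivation |
| `memloop.synthgen` | schedules, recall model, spectral features, raw iEEG |
| `memloop.sigproc` | notch filter, bipolar montage, Morlet power, z-scoring |
| `memloop.decoder` | classifier training/scoring, AUC, permutation test, forward model |
| `memloop.loopsim` | closed-loop session simulation, target/parameter selection, matching |
| `memloop.stimstats` | mixed-effects and log-binomial effect models, balance checks |
| `memloop.glmm` | Laplace-approximation logistic mixed-model fitter |
| `memloop.io`, `memloop.pipeline`, `memloop.cli` | formats, orchestration, command line |

See `docs/methods.md` for the modeling assumptions, parameter defaults and
known limitations.
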