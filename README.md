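# dnfreach

An adaptive dynamic neural field (DNF) model of context-dependent
reach-goal selection.  The package is for computational neuroscientists who
want a compact, fully reproducible simulation of how a single
frontoparietal-style substrate can integrate sensorimotor mapping,
working memory, reward-driven association learning, and competitive action
selection — and how the learning history then biases free-choice behavior.

## The model in brief

Five interconnected components evolve under Amari field dynamics

    tau du/dt = -u + h + s + k * f(u) + noise,    f(u) = 1/(1+e^(-beta u)),

with local excitatory / globally inhibitory interaction kernels `k`:
a spatial input field (visible cues and their decaying sensory trace),
discrete latching context nodes (the rule cue), a two-dimensional
association field (direction x context; a single self-sustained peak is the
working memory and the substrate of learning), a motor preparation field
(soft competition between candidate reach plans), and a gated
winner-take-all motor field (the decision).  Two projections are plastic
and updated once per trial from a binary reward signal `R = +-1` (reach
within +-8 degrees of the rewarded goal):

* instar rule, context -> association:  dW = eps(R) f_assoc (f_ctx - W)
* outstar rule, association -> preparation:  dW = eps(R) f_assoc (f_prep - W)

with failure variants that weaken co-active connections (normalized so
rewarded and failed trials produce comparable total change).  The model
learns the arbitrary "direct" (reach to the cue) versus "inferred" (reach
opposite the cue) mapping from a staged training protocol in which an
explicit target cue fades out linearly, and it can then be probed with
memory-guided (DMG), late-instruction (PMG-CI) and free-choice (PMG-NC)
trials under equal-probability or bias-minimizing reward schedules.

See `docs/methods.md` for the full model description, parameter meanings,
design decisions, and known limitations.

## Worked example

```python
import numpy as np
from dnfreach import (ModelConfig, SessionConfig, init_model, run_session,
                      percent_correct)

cfg = ModelConfig()                       # two contexts: direct / inferred
model = init_model(cfg, np.random.default_rng(1))

# stage 1: inferred-reach training, 1000 trials, 80% inferred,
# target-cue salience fading linearly from 1 to 0
model, log = run_session(model, SessionConfig.ir_training(n_trials=1000,
                                                          seed=2))

# stage 2: definite-motor-goal probe, learning off
model, probe = run_session(model, SessionConfig.dmg_probe(n_trials=400,
                                                          seed=3))
print(f"DMG percent correct: {percent_correct(probe):.1f}%")
print("index shift at a trained inferred patch:",
      model.index_shift_map()[18].max(), "degrees")
```

Output:

```
DMG percent correct: 100.0%
index shift at a trained inferred patch: 180.0 degrees
```

That is: after training, the model reaches the context-specified goal in
every probe trial, and the association-field regions that learned to prefer
the inferred context have rewired their output projection by 180 degrees —
the learned inverse mapping — while the rest of the map keeps its original
(direct) topology.

A command-line interface wraps the same pipelines:

```bash
dnfreach train-ir --seed 1 --out model.h5
dnfreach probe --model model.h5 --task dmg --n-trials 400
dnfreach run schedules --seed 1 --out out/schedules
```

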