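# caselect

Reliable inference of task-state selectivity for calcium-imaged neurons —
and an objective way to choose the analysis parameters that make that
inference trustworthy.

## The problem

In assays with animal-controlled state transitions (here: open-arm vs
closed-arm occupancy of an elevated zero maze, imaged with a head-mounted
miniscope), each neuron is assigned a selectivity label from its
selectivity index

    SI = (avg(OA) − avg(CA)) / (avg(OA) + avg(CA)),

tested against a shuffle null: OA-selective if the true SI exceeds the
97.5th percentile of 1,000 shuffled SIs, CA-selective below the 2.5th,
nonselective otherwise.  But the label depends on five analysis choices —
neural datatype (events / 2 s- or 4 s-convolved events / drift-subtracted
traces), behavioral datatype (head or body centroid), bin width (50 ms or
1 s), open/closed-arm sample matching, and shuffle method (randperm,
partial/full events-chunking, circshift) — a 2×4×2×2×4 grid of 128
combinations of which 120 are valid.  `caselect` quantifies how strongly
labels depend on these choices (pairwise label-consistency matrices with
bootstrap CIs), attributes disagreement to SI changes versus null-width
changes (robust-regression congruence), scores every setting by accuracy
on template neurons and by combined robustness, and validates the selected
optimum by stratified bootstrap, holdout cross-validation, and a
Poisson-GLM cross-check.

Because no public dataset accompanies this design, the package ships a
first-class synthetic-session generator (`caselect.synthetic`) with known
per-neuron ground truth; see `docs/methods.md` for what it does and does
not emulate.

## Worked example

```python
import numpy as np
import caselect as cs

# a 20 min synthetic session: 3 stationary neurons
# (OA-preferring, flat, CA-preferring)
cfg = cs.SimConfig(n_neurons=3, session_duration=1200.0,
                   rate_oa=[0.5, 0.3, 0.1], rate_ca=[0.1, 0.3, 0.5],
                   rate_modulation_sd=0.0, transition_gain=1.0)
session = cs.generate_session(cfg, seed=42)
print(np.round(session.truth.truth_si.to_numpy(), 3))

# label the neurons under one parameter setting
setting = [s for s in cs.enumerate_settings()[0]
           if s.tuple == ("conv2s", "head", "native", "nonmatched", "randperm")][0]
res = cs.label_cohort(session, [setting], n_iterations=1000, seed=0)
print(res.label_names(0), np.round(res.true_si[0], 3), np.round(res.null_sd[0], 3))
```

prints

```
[ 0.667  0.    -0.667]
['OA' 'NS' 'CA'] [ 0.484 -0.088 -0.43 ] [0.069 0.058 0.05 ]
```

The analytic ground-truth SIs are ±2/3 and 0, and all three labels are
recovered.  The estimated SIs are attenuated toward zero (±0.43–0.48)
because the 2 s convolution kernel smears activity across the
animal-controlled state transitions — exactly the kind of
parameter-induced distortion the consistency analysis quantifies — while
the randperm null SD (~0.05–0.07 at these event counts) sets the
detection resolution.

A command-line interface wraps the same library for shell use:

```bash
caselect simulate --out sim --seed 1 --n-neurons 20
caselect selectivity --session sim --out sel --seed 1 --setting-id 37
caselect optimize --session sim --out opt --seed 1
```

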