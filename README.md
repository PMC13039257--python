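# histbias

Analyses of trial-history bias in two-stimulus magnitude discrimination,
with a ground-truth synthetic generator so every stage is verifiable by
parameter recovery.

In the task this package models, a subject compares two distances presented
in sequence: S1 (8–48 mm in 8 mm steps, shown 1000 ms, a blue circle or red
square above or below a reference point) and then S2, always a different
distance with the complementary colour and position. The subject reports
which stimulus was farther. Choices in such tasks are not driven by the
current pair alone: the remembered S1 regresses toward the mean of the
stimulus distribution (contraction bias, ⟨S⟩ = 28 mm), and the *previous*
trial's S2 attracts the current percept (serial dependence). `histbias` is
for researchers who want to quantify these effects behaviourally and in
simultaneously or separately recorded spiking data.

The package implements:

- **S2-ward bias** — for the 10 ordered pairs at |S1 − S2| = 8 mm and each
  of the 6 previous-S2 magnitudes: P(choose S2) minus the pair's overall
  P(choose S2); its linear trend against the previous S2 (negative under
  attraction), and a paired permutation rank test for the colour
  match/mismatch asymmetry.
- **Choice GLMs** — four binomial-logit models of P(choose S2) per cell:
  stimulus ratio sign(S2−S1)·max(S1,S2)/min(S1,S2); + contraction bias
  S1 − ⟨S⟩; + previous S2; + previous S1; compared by test-set r² over
  300 + 300 session resamples × 200 repeats with ANOVA/Tukey.
- **Pseudo-population decoding** — linear SVM (l2, C = 1) on trials×neurons
  rate matrices in 200 ms windows stepped by 25 ms, 75/25 stratified splits,
  z-scored on the training set; sliding curves, cross-temporal
  generalisation matrices, within-session label-permutation nulls, and
  history-conditioned decoding (one decoder per previous-S2 class,
  evaluated within and across history conditions, with marginal
  class-assignment shifts).
- **Ensemble spike-train HMM** — Bernoulli emissions on 5 ms bins,
  Baum–Welch with 10 restarts scored by 3-fold held-out likelihood, state
  count chosen by BIC = −2LL + [M(M−1) + MN]·ln T over M ∈ {2, …, N−1},
  state assignment by the posterior > 0.8 for ≥ 50 ms rule, and
  coding-state detection via occupancy Mann–Whitney tests with
  Benjamini–Hochberg correction.
- **Synthetic generator** — task-conformant trial sequences, a probit
  observer with contraction and colour-gated attraction, and latent-state
  ensemble spike trains with tuning to S1 magnitude, S1 colour and the
  previous S2 (gated off in early S1 to emulate activity-silent
  maintenance). See `docs/methods.md` for the model and its limits.

## Worked example

```python
import numpy as np
from histbias import (
    BehaviourParams, attach_previous_trial, compute_s2ward_bias,
    fit_bias_slope, split_by_feature_match, generate_behaviour_dataset,
)

params = BehaviourParams()          # sigma=6 mm, lambda=0.2,
                                    # beta_mismatch=0.15, beta_match=0.05
trials = generate_behaviour_dataset(50, 1000, params, seed=1)
paired = attach_previous_trial(trials)

table = compute_s2ward_bias(paired)
fit = fit_bias_slope(table)
split = split_by_feature_match(paired, "colour", rng=2)
print(f"cells: {len(table)}")
print(f"slope: {fit.slope:.3f} (p = {fit.p_value:.2e})")
print(f"mismatch slope: {fit_bias_slope(split.table_mismatch).slope:.3f}")
print(f"match slope:    {fit_bias_slope(split.table_match).slope:.3f}")
print(f"colour split: U = {split.u_statistic:.0f}, p = {split.p_value:.4f}")
```

prints

```
cells: 60
slope: -0.156 (p = 2.86e-16)
mismatch slope: -0.233
match slope:    -0.082
colour split: U = 1364, p = 0.0005
```

All 60 (pair × previous-S2) cells are populated. The bias falls by ~0.16
(in choice-probability units) as the previous S2 goes from its smallest to
its largest value — an attractive history effect — and the trend is steeper
when the previous S2 and current S1 differ in colour, with the paired
permutation test rejecting equality of the two conditions.

The same generator feeds the neural analyses:

```python
from histbias import NeuralParams, WindowGrid, generate_neural_dataset, conditional_decode

sessions, truth = generate_neural_dataset(
    8, 300, params, NeuralParams(n_neurons=8, history_shift_eta=-0.35), seed=4)
res = conditional_decode(sessions, grid=WindowGrid(step_ms=100.0), repeats=4, rng=0)
f, p, tukey = res.tier_anova("early_s1")
acc = {t: v.mean() for t, v in res.tier_samples("early_s1").items()}
print({k: round(v, 3) for k, v in acc.items()}, f"p = {p:.2g}")
```

prints

```
{'within': 0.863, 'low_delta': 0.822, 'high_delta': 0.744} p = 2.6e-05
```

showing the signature history interaction: S1 is decoded best when training
and test trials share the same previous-S2 class, and accuracy drops as the
history gap grows.

A command-line interface wraps the pipeline:

```bash
histbias simulate --out-dir data --seed 7 --n-sessions 6
histbias behavior --trials data/trials.csv --out behaviour.json
histbias decode   --trials data/trials.csv --spikes data/spikes.csv \
                  --target prevs2class --out decode_out --seed 7
histbias hmm      --trials data/trials.csv --spikes data/spikes.csv \
                  --out hmm_out --seed 7
histbias run      --config run.yaml
```

where `run.yaml` holds a master seed and any stage overrides, e.g.

```yaml
seed: 11
out_dir: full_run
n_sessions: 6
trials_per_session: 240
n_neurons: 8
decode_repeats: 100
n_perm: 1000
```

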