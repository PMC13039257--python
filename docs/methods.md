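# Methods

`histbias` implements the analysis chain for trial-history bias in a
two-stimulus distance-discrimination task: a subject sees a first stimulus S1
(one of six distances, 8–48 mm in 8 mm steps, shown for 1000 ms as a blue
circle or red square above or below a reference point), then after a delay a
second stimulus S2 with the complementary colour and position and a different
distance, and must report which was farther. The package quantifies how the
*previous* trial's S2 magnitude pulls current-trial choices and neural codes,
using four stages: behavioural bias statistics, a choice-GLM comparison,
pseudo-population decoding, and ensemble hidden Markov models. A synthetic
generator with known ground truth makes every stage testable by parameter
recovery; no recorded data are required or bundled.

## Behavioural model and statistics

**S2-ward bias.** For the 10 ordered stimulus pairs at the smallest relative
distance (|S1 − S2| = 8 mm) and each of the 6 possible previous-S2
magnitudes, the bias is P(choose S2) in that cell minus the pair's overall
P(choose S2). Pair means are trial-weighted, so the weighted mean bias within
a pair is exactly zero (enforced to 1e-12 in tests). Only trials that are
complete and follow a complete trial enter. The trend of bias against the
previous S2 is an OLS fit with the previous S2 rescaled to [0, 1] over its
six values (the per-mm slope is also reported); an attractive history effect
makes the slope negative.

**Feature-match comparison.** Trials are split by whether the previous S2
shared the current S1's colour (or position). Because the per-pair
normalisation forces both partitions' bias sets to zero mean, a rank test on
raw bias values cannot see a difference in history *strength*; the
comparison therefore uses history-aligned scores, bias × (28 − prev_S2)/40
(positive = attraction), with a Mann–Whitney U statistic whose p-value comes
from randomly swapping the match/mismatch values within each
(pair, previous-S2) cell pairing. The paired swap respects the dependence the
normalisation induces; its null calibration is verified at 500 repetitions
(rejection rate in [0.03, 0.07] at α = 0.05).

**Choice GLM.** Four binomial-logit models of P(choose S2) at the
(current pair × previous pair) cell level: stimulus ratio alone
(sign(S2−S1)·max/min); + contraction bias (cb = S1 − ⟨S⟩, ⟨S⟩ = 28 mm, signed
so positive favours S2 — an S1 above the mean is contracted downward); +
previous S2; + previous S1. Regressors are min–max normalised on the
training cells. Per repeat, 300 training and 300 disjoint test sessions are
sampled (resampling with replacement, flagged, when fewer sessions exist);
r² is the squared Pearson correlation between predicted and observed cell
probabilities; 200 repeats feed a one-way ANOVA with Tukey HSD across
models. Non-convergent repeats are dropped; more than 10% drops is an error.

**Generative observer (synthetic data).** Choices come from a probit
observer: perceived S1 = S1 + λ(28 − S1) + β(prev S2 − S1), with β chosen by
the colour relation (default β_mismatch = 0.15, β_match = 0.05, λ = 0.2);
P(choose S2) = (1 − lapse)·Φ((S2 − perceived S1)/σ) + lapse/2 with σ = 6 mm
and lapse = 0.02. The probit form gives closed-form oracle checks; the
defaults are the recovery-study conditions used throughout the tests.

## Pseudo-population decoding

Firing rates are computed in half-open 200 ms windows advanced in 25 ms
steps from −300 to +1400 ms around S1 onset (69 windows). Per neuron, 75% of
eligible trials (stratified by class) form a training pool and 25% a test
pool; pseudo-trials pair randomly drawn same-class trials across neurons
without replacement, truncated to the smallest per-neuron pool so rows are
i.i.d. within class. Rates are z-scored with training-set parameters
(degenerate SD → 1). The decoder is a linear SVM (l2 penalty, squared hinge
solved in the primal for determinism, C = 1, one-vs-rest). Stimulus
magnitudes are decoded as three classes (low {8,16}, medium {24,32}, high
{40,48} mm). Curves average 100 random-split repeats (±SD across repeats);
cross-temporal matrices train at window i and test at window j, each window
z-scored with its own training parameters so the diagonal reproduces the
same-window curve exactly.

**Permutation null.** Class labels are permuted within session before
assembly (1000 permutations at full scale; reduced sizes are stated with
each experiment); a window is significant when the observed mean accuracy
exceeds the null's 95th percentile. Note a small intrinsic property: because
labels are permuted *before* the train/test split, each permuted class pool
is shared by both sides, and pool-level count fluctuations generalise — the
3-class null averages ≈ 0.336 rather than exactly 1/3. The observed
statistic carries the identical offset under the null hypothesis, so the
test is calibrated (measured flag rate 0.054 at α = 0.05 over no-signal
data), which is the reason for testing against a permutation null rather
than nominal chance in the first place.

**History-conditioned decoding.** One S1-class decoder is trained per
previous-S2 class on neurons with at least five trials in every
(condition × class) cell, so all decoders share one feature space; each is
evaluated on every condition's held-out trials (z-scored with the training
condition's parameters). Accuracies pool into tiers by the history gap
between train and test (within, low Δ = adjacent classes, high Δ =
low↔high) for early S1 ([0, 500) ms) and late S1 ([500, 1000) ms), compared
by ANOVA with Tukey HSD. Marginal assignment fractions — the share of test
trials predicted as each class, with the within-condition case as reference
— quantify prediction bias; no probability calibration is applied since the
max-margin decoder has no native posteriors.

## Spike-train hidden Markov model

Ensemble spike trains are binned at 5 ms over a span from the previous
trial's S2 onset to the end of the current S1 presentation (default −2600 to
+1400 ms) and clipped to spike/no-spike (clipped bins are counted and
reported). Emissions are independent Bernoulli per neuron per bin, so the
emission matrix is M states × N neurons of spike probabilities — the shape
implied by the standard initialisation: transition = |I + N(0, 0.02)|
row-normalised; emission rows = permuted per-neuron mean rates + N(0, 0.02),
clipped to [1e-4, 1 − 1e-4]. The latent chain restarts independently each
trial, which lets the scaled forward–backward recursions run batched across
equal-length trials (the likelihood is verified against exhaustive path
enumeration to 1e-8 and against an independent categorical-HMM embedding).

Fitting is Baum–Welch (EM) to ΔLL < 1e-6 per observation or 500 iterations,
10 restarts; restarts are scored by 3-fold cross-validated held-out
log-likelihood at the trial level and the winning initialisation is refit on
all trials. The state count M is selected over {2, …, N−1} by
BIC = −2·LL + [M(M−1) + M·N]·ln T with T = trials × bins (natural log).
The initial state distribution is uniform and re-estimated by EM. A state is
*assigned* where its posterior exceeds 0.8 (strictly) for at least 50
consecutive ms (≥ 10 bins); mean state occupancy is the assigned time within
a window. *Coding states* are states whose per-trial occupancy differs
between task-variable groups (Mann–Whitney U, Benjamini–Hochberg across
states, groups under 3 trials skipped with a warning).

## Synthetic neural generator

Each session's ensemble is driven by a latent Markov chain (default 2
states, diagonal transition mass 0.985 per 5 ms step) with per-state,
per-neuron base rates drawn from 3–12 spk/s. During S1 presentation, rates
multiply by a graded S1-class gain (each neuron prefers one class: ×g there,
×1 adjacent, ×1/g opposite; g = 2) and a colour gain (g = 1.5). A
previous-S2-class gain (g = 1.8) acts only inside the *silent gate*
intervals — the pre-S1 span and late S1 ([500, 1000) ms) — emulating the
activity-silent gap in which the previous S2 is decodable before S1 onset
and again late in S1 but not early, without claiming a synaptic mechanism.
Spikes are inhomogeneous Poisson per 5 ms bin (times uniform within bins).

The history shift of the tuning input is signed:
effective S1 = S1 + η·(prev S2 − S1). A positive η (attraction) geometrically
forces a decoder trained on low-history trials to over-predict *high* S1
classes on high-history trials; reproducing the observed phenomenology —
accuracy falling with the train/test history gap *and* predictions biased
toward the decoder's own training history — requires the sensory code to
shift *away* from the previous S2 (adaptation), so the default is η = −0.25
(recovery experiments use −0.35). Attractive behavioural bias and adaptive
sensory-code shift coexist in the generator, mirroring the standard
encoder-adaptation account of serial dependence. An optional
`colour_state_bias` parameter biases the latent chain's initial state by S1
colour to create detectable colour-coding states.

What the generator does *not* emulate: spike-history dependence
(refractoriness), cross-trial latent-state carryover, inter-areal structure,
non-Poisson count dispersion, and realistic inter-trial timing jitter of the
previous-trial events (the previous S2 is anchored at a fixed −2600 ms).
Passing recovery tests therefore demonstrates correctness of the analysis
chain under these idealised conditions, not performance on recorded data.

## Problem sizes and numerical choices

Recovery experiments run at desk scale, chosen as the package's study
conditions: behavioural recovery on 50,000 trials; the GLM suite on 600
sessions × 100 trials with 200 repeats; conditional decoding on 20 sessions
× 8 neurons × 250 trials with 10 repeats at 50 ms window steps; permutation
experiments with 100–200 permutations; HMM recovery on 20 synthetic sessions
of 5 neurons, 60 trials × 300 bins with 2 restarts and 2 folds. Determinism
is enforced end to end: every stage draws from a child seed spawned at a
fixed position from the master seed, so toggling one stage never perturbs
another, and repeated runs are byte-identical.

Ties and degenerate cases: half-open windows make spike assignment
unambiguous; one-vs-rest ties resolve by highest decision value then lowest
class index (the linear solver is deterministic in the primal); zero-SD
z-score columns are left unscaled; emission probabilities are floored at
1e-4 against log(0); all-tied occupancy comparisons return p = 1; empty
(condition × class) cells and single-class training sets are rejected with
the offending cell named.

## Known limitations

- The Mann–Whitney comparison of match vs mismatch bias uses aligned scores
  with a paired permutation p-value (see above); the plain rank test on raw
  bias values is provably insensitive under the per-pair normalisation.
- BIC state-count recovery depends on state separation and data volume;
  with weakly separated states BIC prefers fewer states by design.
- r² for the binomial GLM is a cell-level correlation measure, not a
  likelihood-based pseudo-r².
- The Bernoulli emission model treats neurons as conditionally independent
  given the state; the emission law is isolated behind the estimator so a
  multinomial variant could be swapped in.
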