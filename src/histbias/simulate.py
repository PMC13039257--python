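"""Synthetic task sequences, biased choices and ensemble spike trains.

The generator defines the study conditions for every parameter-recovery test:
it produces trial tables that satisfy the task's pseudo-randomisation
constraints, choices from a signal-detection (probit) observer with
contraction bias and an attractive pull of perceived S1 toward the previous
trial's S2 (stronger under colour mismatch), and ensemble spike trains driven
by a latent Markov chain with multiplicative tuning to current S1 magnitude,
S1 colour and previous-S2 magnitude.  The previous-S2 tuning is gated off
during early S1 presentation to emulate an activity-silent gap: the variable
is decodable before S1 onset and again in late S1, but not in between.

Every public entry point is deterministic given its seed, and all generated
data pass the validation rules of :mod:`histbias.task`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.stats import norm

from .task import (
    COLOURS,
    D1_CHOICES_MS,
    D2_CHOICES_MS,
    MAGNITUDES_MM,
    MEAN_MAGNITUDE_MM,
    POSITIONS,
    PRE_S_CHOICES_MS,
    S1_DURATION_MS,
    DEFAULT_SPAN_MS,
    MAGNITUDE_CLASSES,
    PairedTrial,
    SessionEnsemble,
    TrialRecord,
    attach_previous_trial,
    bin_magnitude_continuous,
    class_index,
)


@dataclass
class BehaviourParams:
    """Parameters of the probit choice observer.

    perceived_s1 = s1 + lambda*(28 - s1) + beta*(prev_s2 - s1), with beta
    chosen by the colour relation between the previous S2 and the current S1;
    P(choose S2) = (1-lapse)*Phi((s2 - perceived_s1)/sigma) + lapse/2.
    """

    sensory_noise_sigma: float = 6.0  # mm
    contraction_lambda: float = 0.2
    attract_beta_mismatch: float = 0.15
    attract_beta_match: float = 0.05
    lapse_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sensory_noise_sigma <= 0:
            raise ValueError("sensory_noise_sigma must be > 0")
        if not (0 <= self.contraction_lambda < 1):
            raise ValueError("contraction_lambda must be in [0, 1)")
        if self.attract_beta_mismatch < 0 or self.attract_beta_match < 0:
            raise ValueError("attraction weights must be >= 0")
        if not (0 <= self.lapse_rate <= 0.2):
            raise ValueError("lapse_rate must be in [0, 0.2]")


@dataclass
class NeuralParams:
    """Parameters of the latent-state ensemble spike generator.

    Gains are multiplicative tuning depths: a neuron preferring class ``c``
    multiplies its rate by ``gain`` on class-``c`` trials, by 1 on the
    adjacent class and by ``1/gain`` on the farthest class.  ``silent_gate``
    lists the ms intervals (relative to S1 onset) in which the previous-S2
    gain acts; the default leaves early S1 ungated, reproducing the
    activity-silent gap.  ``history_shift_eta`` shifts the S1 magnitude that
    drives the tuning by ``eta * (prev_s2 - s1)`` mm: positive values shift
    the sensory code toward the previous S2 (attraction), negative values
    away from it (adaptation).  The adaptive default is what reproduces the
    observed decoder phenomenology — accuracy falling with the history gap
    between train and test trials AND predictions biased toward the
    decoder's own training history.
    """

    n_neurons: int = 12
    n_states_true: int = 2
    transition_stickiness: float = 0.985  # per 5 ms step
    base_rate_range: tuple[float, float] = (3.0, 12.0)  # spk/s
    s1_gain: float = 2.0
    colour_gain: float = 1.5
    prev_s2_gain: float = 1.8
    history_shift_eta: float = -0.25
    silent_gate: tuple[tuple[float, float], ...] = ((-2600.0, 0.0), (500.0, 1000.0))
    span_ms: tuple[float, float] = DEFAULT_SPAN_MS
    bin_ms: float = 5.0
    colour_state_bias: float = 0.0  # biases the initial latent state by S1 colour
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_neurons < 4:
            raise ValueError("n_neurons must be >= 4")
        if self.n_states_true < 1:
            raise ValueError("n_states_true must be >= 1")
        if not (0 < self.transition_stickiness <= 1):
            raise ValueError("transition_stickiness must be in (0, 1]")
        lo, hi = self.base_rate_range
        if lo < 0 or hi < lo:
            raise ValueError("base_rate_range must be a non-negative interval")
        for g in (self.s1_gain, self.colour_gain, self.prev_s2_gain):
            if g <= 0:
                raise ValueError("tuning gains must be > 0 (rates stay >= 0)")
        if not (0 <= self.colour_state_bias <= 1):
            raise ValueError("colour_state_bias must be in [0, 1]")


def generate_task_sequence(
    n_trials: int,
    seed: int | np.random.Generator,
    session_id: str = "sim",
    p_incomplete: float = 0.0,
) -> list[TrialRecord]:
    """Pseudo-randomised trial sequence with choices unset.

    Ordered (s1, s2) magnitude pairs are drawn uniformly from the 30 unequal
    pairs; colours, positions and delays are drawn independently from their
    task sets, so the previous-S2 colour and the current-S1 colour match on
    about half of consecutive trials.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mags = np.asarray(MAGNITUDES_MM)
    s1 = rng.choice(mags, size=n_trials)
    # draw s2 uniformly among the five magnitudes different from s1
    offs = rng.integers(1, len(mags), size=n_trials)
    s2 = mags[(np.searchsorted(mags, s1) + offs) % len(mags)]
    colour = rng.choice(COLOURS, size=n_trials)
    position = rng.choice(POSITIONS, size=n_trials)
    pre_s = rng.choice(PRE_S_CHOICES_MS, size=n_trials)
    d1 = rng.choice(D1_CHOICES_MS, size=n_trials)
    d2 = rng.choice(D2_CHOICES_MS, size=n_trials)
    complete = rng.random(n_trials) >= p_incomplete
    return [
        TrialRecord(
            session_id=session_id,
            trial_index=i,
            s1_mm=int(s1[i]),
            s2_mm=int(s2[i]),
            s1_colour=str(colour[i]),
            s1_position=str(position[i]),
            pre_s_ms=int(pre_s[i]),
            d1_ms=int(d1[i]),
            d2_ms=int(d2[i]),
            choice="none",
            complete=bool(complete[i]),
        )
        for i in range(n_trials)
    ]


def p_choose_s2(
    trial: TrialRecord, previous: Optional[TrialRecord], params: BehaviourParams
) -> float:
    """Probability the probit observer chooses S2 on this trial."""
    perceived = trial.s1_mm + params.contraction_lambda * (
        MEAN_MAGNITUDE_MM - trial.s1_mm
    )
    if previous is not None and previous.complete:
        beta = (
            params.attract_beta_match
            if previous.s2_colour == trial.s1_colour
            else params.attract_beta_mismatch
        )
        perceived += beta * (previous.s2_mm - trial.s1_mm)
    p = norm.cdf((trial.s2_mm - perceived) / params.sensory_noise_sigma)
    return float((1 - params.lapse_rate) * p + params.lapse_rate / 2)


def simulate_choice(
    trial: TrialRecord,
    previous: Optional[TrialRecord],
    params: BehaviourParams,
    rng: np.random.Generator,
) -> str:
    return "S2" if rng.random() < p_choose_s2(trial, previous, params) else "S1"


def simulate_choices(
    trials: Sequence[TrialRecord],
    params: BehaviourParams,
    rng: np.random.Generator | None = None,
) -> list[TrialRecord]:
    """Fill in choices for a task sequence (vectorised; incomplete trials keep
    choice='none')."""
    rng = np.random.default_rng(params.seed) if rng is None else rng
    paired = attach_previous_trial(trials)
    s1 = np.array([p.trial.s1_mm for p in paired], dtype=float)
    s2 = np.array([p.trial.s2_mm for p in paired], dtype=float)
    perceived = s1 + params.contraction_lambda * (MEAN_MAGNITUDE_MM - s1)
    beta = np.zeros(len(paired))
    prev_s2 = np.zeros(len(paired))
    for i, p in enumerate(paired):
        if p.previous is not None and p.previous.complete:
            beta[i] = (
                params.attract_beta_match
                if p.previous.s2_colour == p.trial.s1_colour
                else params.attract_beta_mismatch
            )
            prev_s2[i] = p.previous.s2_mm
    perceived += beta * (prev_s2 - s1)
    p_s2 = (1 - params.lapse_rate) * norm.cdf(
        (s2 - perceived) / params.sensory_noise_sigma
    ) + params.lapse_rate / 2
    draw = rng.random(len(paired)) < p_s2
    out = []
    for i, p in enumerate(paired):
        if p.trial.complete:
            out.append(replace(p.trial, choice="S2" if draw[i] else "S1"))
        else:
            out.append(p.trial)
    return out


def generate_behaviour_dataset(
    n_sessions: int,
    trials_per_session: int,
    params: BehaviourParams,
    seed: int | None = None,
    p_incomplete: float = 0.02,
    session_prefix: str = "sim",
) -> list[TrialRecord]:
    """Multi-session trial table with simulated choices."""
    master = np.random.default_rng(params.seed if seed is None else seed)
    out: list[TrialRecord] = []
    for s in range(n_sessions):
        trials = generate_task_sequence(
            trials_per_session,
            master,
            session_id=f"{session_prefix}{s:04d}",
            p_incomplete=p_incomplete,
        )
        out.extend(simulate_choices(trials, params, master))
    return out


# ---------------------------------------------------------------------------
# ensemble spike trains


def _graded_gains(gain: float, pref: np.ndarray) -> np.ndarray:
    """(n_neurons, 3) multiplicative gain profile: gain at the preferred class,
    1 adjacent, 1/gain at distance two."""
    dist = np.abs(np.arange(3)[None, :] - pref[:, None])
    return gain ** (1.0 - dist)


def _sample_states(
    n_trials: int,
    n_bins: int,
    params: NeuralParams,
    rng: np.random.Generator,
    init_probs: np.ndarray,
) -> np.ndarray:
    """Latent Markov chain per trial (independent restart each trial)."""
    M = params.n_states_true
    if M == 1:
        return np.zeros((n_trials, n_bins), dtype=int)
    stay = params.transition_stickiness
    states = np.empty((n_trials, n_bins), dtype=int)
    cum_init = np.cumsum(init_probs, axis=1)
    states[:, 0] = (rng.random((n_trials, 1)) > cum_init).sum(axis=1)
    switch = rng.random((n_trials, n_bins)) >= stay
    jump = rng.integers(1, M, size=(n_trials, n_bins))
    for b in range(1, n_bins):
        s = states[:, b - 1].copy()
        moved = switch[:, b]
        s[moved] = (s[moved] + jump[moved, b]) % M
        states[:, b] = s
    return states


def simulate_session_spikes(
    trials: Sequence[TrialRecord],
    params: NeuralParams,
    seed: int | np.random.Generator | None = None,
) -> tuple[SessionEnsemble, np.ndarray]:
    """Ensemble spike trains for one session's trials.

    Returns the ensemble and the ground-truth latent state per (trial, 5 ms
    bin) for recovery tests.  Rates are state base rates multiplied by the
    S1-class gain and colour gain during S1 presentation and by the
    previous-S2-class gain inside the silent-gate intervals; spike counts are
    Poisson per bin, spike times uniform within their bin.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(params.seed if seed is None else seed)
    )
    paired = attach_previous_trial(trials)
    n_trials = len(paired)
    lo, hi = params.span_ms
    n_bins = int(round((hi - lo) / params.bin_ms))
    centers = lo + (np.arange(n_bins) + 0.5) * params.bin_ms
    M, N = params.n_states_true, params.n_neurons

    base = rng.uniform(*params.base_rate_range, size=(M, N))
    pref_s1 = rng.permuted(np.arange(N) % 3)
    pref_prev = rng.permuted(np.arange(N) % 3)
    pref_colour = rng.permuted(np.arange(N) % 2)
    g_s1 = _graded_gains(params.s1_gain, pref_s1)          # (N, 3)
    g_prev = _graded_gains(params.prev_s2_gain, pref_prev)  # (N, 3)
    g_col = np.where(
        pref_colour[:, None] == np.arange(2)[None, :],
        params.colour_gain,
        1.0 / params.colour_gain,
    )  # (N, 2)

    in_s1 = (centers >= 0) & (centers < S1_DURATION_MS)
    in_gate = np.zeros(n_bins, dtype=bool)
    for a, b in params.silent_gate:
        in_gate |= (centers >= a) & (centers < b)

    # per-trial initial state distribution, optionally biased by S1 colour
    init = np.full((n_trials, max(M, 1)), 1.0 / max(M, 1))
    if params.colour_state_bias > 0 and M >= 2:
        for i, p in enumerate(paired):
            k = 0 if p.trial.s1_colour == "blue" else 1
            init[i] = (1 - params.colour_state_bias) / M
            init[i, k % M] += params.colour_state_bias
    states = _sample_states(n_trials, n_bins, params, rng, init)

    rates = base[states]  # (trials, bins, N)
    gains = np.ones((n_trials, n_bins, N))
    for i, p in enumerate(paired):
        t = p.trial
        s1_eff = float(t.s1_mm)
        if p.previous is not None and p.previous.complete:
            s1_eff += params.history_shift_eta * (p.previous.s2_mm - t.s1_mm)
            prev_cls = class_index(bin_magnitude_continuous(p.previous.s2_mm))
            gains[i, in_gate] *= g_prev[:, prev_cls]
        s1_cls = class_index(bin_magnitude_continuous(s1_eff))
        col = 0 if t.s1_colour == "blue" else 1
        gains[i, in_s1] *= g_s1[:, s1_cls] * g_col[:, col]
    rates = rates * gains
    if np.any(rates < 0):
        raise ValueError("negative firing rate after gains")

    counts = rng.poisson(rates * (params.bin_ms / 1000.0))
    session_id = paired[0].trial.session_id if n_trials else "sim"
    spikes: dict[str, dict[int, np.ndarray]] = {}
    neuron_ids = [f"n{j:03d}" for j in range(N)]
    for j, nid in enumerate(neuron_ids):
        per_trial = {}
        for i, p in enumerate(paired):
            c = counts[i, :, j]
            nz = np.nonzero(c)[0]
            if nz.size == 0:
                per_trial[p.trial.trial_index] = np.empty(0)
                continue
            reps = c[nz]
            starts = lo + np.repeat(nz, reps) * params.bin_ms
            times = starts + rng.random(reps.sum()) * params.bin_ms
            per_trial[p.trial.trial_index] = np.sort(times)
        spikes[nid] = per_trial
    ensemble = SessionEnsemble(
        session_id=session_id,
        neuron_ids=neuron_ids,
        spikes=spikes,
        trials=list(trials),
    )
    return ensemble, states


def generate_neural_dataset(
    n_sessions: int,
    trials_per_session: int,
    behaviour: BehaviourParams,
    neural: NeuralParams,
    seed: int = 0,
    p_incomplete: float = 0.02,
    session_prefix: str = "sim",
) -> tuple[list[SessionEnsemble], dict[str, np.ndarray]]:
    """Full synthetic dataset: sessions with choices, spikes and true states."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_sessions)
    sessions, truth = [], {}
    for s in range(n_sessions):
        rng = np.random.default_rng(children[s])
        sid = f"{session_prefix}{s:04d}"
        trials = generate_task_sequence(
            trials_per_session, rng, session_id=sid, p_incomplete=p_incomplete
        )
        trials = simulate_choices(trials, behaviour, rng)
        ensemble, states = simulate_session_spikes(trials, neural, rng)
        sessions.append(ensemble)
        truth[sid] = states
    return sessions, truth
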