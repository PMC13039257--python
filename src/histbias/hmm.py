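"""Hidden Markov models on binned ensemble spike trains.

The ensemble observation is the population spike train binned at 5 ms and
clipped to spike/no-spike; emissions are independent Bernoulli per neuron per
bin, so the emission matrix is M states x N neurons of spike probabilities —
the shape implied by the standard initialisation (permuted per-neuron mean
rates plus Gaussian noise).  Fitting is Baum-Welch with multiple restarts
scored by cross-validated held-out log-likelihood; the number of states is
selected by BIC = -2 LL + [M(M-1) + M N] ln T over M in {2, ..., N-1}.

State sequences are decoded from the posteriors with the occupancy rule
"posterior > 0.8 for at least 50 consecutive ms"; *coding states* are states
whose per-trial occupancy in a window differs between task-variable groups
(Mann-Whitney U with Benjamini-Hochberg correction across states).

Trials are treated as independent restarts of the latent chain, which allows
the forward-backward recursions to be batched across trials of equal length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .task import DEFAULT_SPAN_MS, PairedTrial, SessionEnsemble

EMISSION_FLOOR = 1e-4


def bin_spikes(
    session: SessionEnsemble,
    bin_ms: float = 5.0,
    span: tuple[float, float] = DEFAULT_SPAN_MS,
    trial_indices: Optional[Sequence[int]] = None,
) -> tuple[np.ndarray, int, list[int]]:
    """Binary (trials, bins, neurons) observation array.

    Bins are half-open [edge, edge + bin_ms).  Multi-spike bins are clipped to
    1 and counted; the clip count is returned so heavy clipping is visible.
    """
    lo, hi = span
    n_bins = int(round((hi - lo) / bin_ms))
    if trial_indices is None:
        trial_indices = [
            p.trial.trial_index
            for p in session.paired()
            if p.eligible and p.trial.complete
        ]
    trial_indices = list(trial_indices)
    obs = np.zeros((len(trial_indices), n_bins, len(session.neuron_ids)), dtype=np.int8)
    clipped = 0
    for j, nid in enumerate(session.neuron_ids):
        for i, ti in enumerate(trial_indices):
            times = session.spike_times(nid, ti)
            if not len(times):
                continue
            sel = times[(times >= lo) & (times < hi)]
            bins = ((sel - lo) // bin_ms).astype(int)
            counts = np.bincount(bins, minlength=n_bins)
            clipped += int((counts > 1).sum())
            obs[i, :, j] = counts > 0
    return obs, clipped, trial_indices


def init_hmm(
    M: int,
    N: int,
    mean_rates: np.ndarray,
    rng: np.random.Generator,
    noise_std: float = 0.02,
) -> tuple[np.ndarray, np.ndarray]:
    """Standard initialisation of the transition and emission matrices.

    Transition: |identity + N(0, noise_std)| row-normalised.  Emission rows:
    independent random permutations of the per-neuron mean spike probability
    per bin, plus N(0, noise_std), clipped away from {0, 1}.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    trans = np.abs(np.eye(M) + rng.normal(0.0, noise_std, size=(M, M)))
    trans /= trans.sum(axis=1, keepdims=True)
    emis = np.empty((M, N))
    for m in range(M):
        emis[m] = rng.permutation(np.asarray(mean_rates, dtype=float))
    emis += rng.normal(0.0, noise_std, size=(M, N))
    emis = np.clip(emis, EMISSION_FLOOR, 1 - EMISSION_FLOOR)
    return trans, emis


def _log_emission(obs: np.ndarray, emission: np.ndarray) -> np.ndarray:
    """(trials, bins, M) log P(obs_bin | state)."""
    p = np.clip(emission, EMISSION_FLOOR, 1 - EMISSION_FLOOR)
    x = obs.astype(float)
    return x @ np.log(p).T + (1.0 - x) @ np.log1p(-p).T


def forward_backward(
    obs: np.ndarray,
    transition: np.ndarray,
    emission: np.ndarray,
    initial: Optional[np.ndarray] = None,
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Scaled forward-backward over a batch of equal-length trials.

    Returns (total log-likelihood in nats, posteriors (trials, bins, M),
    expected transition counts (M, M), expected initial-state counts (M,)).
    """
    if obs.ndim == 2:
        obs = obs[None]
    R, T, _ = obs.shape
    M = transition.shape[0]
    if initial is None:
        initial = np.full(M, 1.0 / M)
    logB = _log_emission(obs, emission)
    off = logB.max(axis=2, keepdims=True)
    B = np.exp(logB - off)  # (R, T, M), scaled per (trial, bin)

    alpha = np.empty((R, T, M))
    c = np.empty((R, T))
    a = initial[None, :] * B[:, 0]
    c[:, 0] = a.sum(axis=1)
    alpha[:, 0] = a / c[:, 0][:, None]
    for t in range(1, T):
        a = (alpha[:, t - 1] @ transition) * B[:, t]
        c[:, t] = a.sum(axis=1)
        alpha[:, t] = a / c[:, t][:, None]
    ll = float(np.sum(np.log(c)) + np.sum(off))

    beta = np.empty((R, T, M))
    beta[:, T - 1] = 1.0
    xi_sum = np.zeros((M, M))
    for t in range(T - 2, -1, -1):
        bb = B[:, t + 1] * beta[:, t + 1]
        # expected transitions t -> t+1, normalised per trial
        u = np.einsum("rm,rn->mn", alpha[:, t], bb / c[:, t + 1][:, None])
        xi_sum += transition * u
        beta[:, t] = (bb / c[:, t + 1][:, None]) @ transition.T
    gamma = alpha * beta
    gamma /= gamma.sum(axis=2, keepdims=True)
    return ll, gamma, xi_sum, gamma[:, 0].sum(axis=0)


class BernoulliSpikeHMM:
    """Hidden Markov model with per-neuron Bernoulli emissions on 5 ms bins.

    sklearn-style estimator: ``fit`` runs Baum-Welch with ``restarts``
    initialisations, scoring each by fold-averaged held-out log-likelihood
    (``cv_folds``-fold split at the trial level) and refitting the winning
    initialisation on all trials.  Fitted attributes carry a trailing
    underscore; ``bic_`` uses T = trials x bins observations.
    """

    def __init__(
        self,
        n_states: int = 2,
        *,
        max_iter: int = 500,
        tol: float = 1e-6,
        restarts: int = 10,
        cv_folds: int = 3,
        random_state: int | np.random.Generator | None = None,
    ) -> None:
        self.n_states = n_states
        self.max_iter = max_iter
        self.tol = tol
        self.restarts = restarts
        self.cv_folds = cv_folds
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {
            "n_states": self.n_states,
            "max_iter": self.max_iter,
            "tol": self.tol,
            "restarts": self.restarts,
            "cv_folds": self.cv_folds,
            "random_state": self.random_state,
        }

    def set_params(self, **params) -> "BernoulliSpikeHMM":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    # -- EM core ----------------------------------------------------------

    def _em(
        self,
        obs: np.ndarray,
        trans: np.ndarray,
        emis: np.ndarray,
        init: np.ndarray,
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, list[float]]:
        R, T, N = obs.shape
        history: list[float] = []
        x = obs.astype(float).reshape(R * T, N)
        for _ in range(self.max_iter):
            ll, gamma, xi_sum, init_counts = forward_backward(obs, trans, emis, init)
            history.append(ll)
            if len(history) > 1 and history[-1] - history[-2] < self.tol * (R * T):
                break
            g = gamma.reshape(R * T, self.n_states)
            weight = g.sum(axis=0)
            if np.any(weight <= 0):
                raise _DegenerateFit(self.n_states)
            emis = np.clip(
                (g.T @ x) / weight[:, None], EMISSION_FLOOR, 1 - EMISSION_FLOOR
            )
            if self.n_states > 1:
                rows = xi_sum.sum(axis=1, keepdims=True)
                if np.any(rows <= 0):
                    raise _DegenerateFit(self.n_states)
                trans = xi_sum / rows
            init = init_counts / init_counts.sum()
        return trans, emis, init, history[-1], history

    def fit(self, X: np.ndarray) -> "BernoulliSpikeHMM":
        """Fit on X with shape (trials, bins, neurons), binary entries."""
        obs = np.asarray(X)
        if obs.ndim != 3:
            raise ValueError("X must be (trials, bins, neurons)")
        R, T, N = obs.shape
        rng = (
            self.random_state
            if isinstance(self.random_state, np.random.Generator)
            else np.random.default_rng(self.random_state)
        )
        mean_rates = obs.reshape(R * T, N).mean(axis=0)
        folds = np.arange(R) % max(self.cv_folds, 1)
        folds = rng.permutation(folds)

        best_score, best_init_mats, best_history = -np.inf, None, None
        n_degenerate = 0
        for _ in range(self.restarts):
            trans0, emis0 = init_hmm(self.n_states, N, mean_rates, rng)
            init0 = np.full(self.n_states, 1.0 / self.n_states)
            try:
                if self.cv_folds > 1 and R >= self.cv_folds:
                    scores = []
                    for f in range(self.cv_folds):
                        tr, te = obs[folds != f], obs[folds == f]
                        t_f, e_f, i_f, _, _ = self._em(tr, trans0, emis0, init0)
                        ll_te, _, _, _ = forward_backward(te, t_f, e_f, i_f)
                        scores.append(ll_te / te.shape[0])
                    score = float(np.mean(scores))
                else:
                    _, _, _, ll_all, _ = self._em(obs, trans0, emis0, init0)
                    score = ll_all / R
            except _DegenerateFit:
                n_degenerate += 1
                continue
            if score > best_score:
                best_score, best_init_mats = score, (trans0, emis0, init0)
        if best_init_mats is None:
            raise RuntimeError(
                f"all {self.restarts} restarts degenerate for M={self.n_states}"
            )
        trans0, emis0, init0 = best_init_mats
        trans, emis, init, ll, history = self._em(obs, trans0, emis0, init0)

        self.transition_ = trans
        self.emission_ = emis
        self.initial_ = init
        self.log_likelihood_ = ll
        self.history_ = history
        self.cv_score_ = best_score
        self.n_obs_ = R * T
        self.n_neurons_ = N
        self.n_degenerate_restarts_ = n_degenerate
        M = self.n_states
        self.n_parameters_ = M * (M - 1) + M * N
        self.bic_ = -2.0 * ll + self.n_parameters_ * np.log(R * T)
        return self

    def score(self, X: np.ndarray) -> float:
        ll, _, _, _ = forward_backward(
            np.asarray(X), self.transition_, self.emission_, self.initial_
        )
        return ll

    def predict_posteriors(self, X: np.ndarray) -> np.ndarray:
        """(trials, bins, M) posterior state probabilities."""
        _, gamma, _, _ = forward_backward(
            np.asarray(X), self.transition_, self.emission_, self.initial_
        )
        return gamma


class _DegenerateFit(RuntimeError):
    pass


def bic_score(log_likelihood: float, M: int, N: int, T: int) -> float:
    """-2 LL + [M(M-1) + M N] ln T."""
    return -2.0 * log_likelihood + (M * (M - 1) + M * N) * np.log(T)


def sample_hmm(
    transition: np.ndarray,
    emission: np.ndarray,
    n_trials: int,
    n_bins: int,
    rng: np.random.Generator | int = 0,
    initial: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample observations from a known Bernoulli-emission HMM.

    The latent chain restarts independently on every trial.  Returns
    (observations (trials, bins, neurons), true states (trials, bins)).
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    transition = np.asarray(transition, dtype=float)
    emission = np.asarray(emission, dtype=float)
    M, N = emission.shape
    initial = np.full(M, 1.0 / M) if initial is None else np.asarray(initial, float)
    states = np.empty((n_trials, n_bins), dtype=int)
    cum0 = np.cumsum(initial)
    cum = np.cumsum(transition, axis=1)
    states[:, 0] = np.searchsorted(cum0, rng.random(n_trials), side="right")
    u = rng.random((n_trials, n_bins))
    for b in range(1, n_bins):
        c = cum[states[:, b - 1]]
        states[:, b] = (u[:, b, None] >= c).sum(axis=1)
    obs = (rng.random((n_trials, n_bins, N)) < emission[states]).astype(np.int8)
    return obs, states


def baum_welch(
    obs_set: np.ndarray,
    M: int,
    rng: np.random.Generator | int = 0,
    max_iter: int = 500,
    restarts: int = 10,
    cv_folds: int = 3,
    tol: float = 1e-6,
) -> BernoulliSpikeHMM:
    """Fit an M-state ensemble HMM (functional wrapper over the estimator)."""
    model = BernoulliSpikeHMM(
        n_states=M,
        max_iter=max_iter,
        tol=tol,
        restarts=restarts,
        cv_folds=cv_folds,
        random_state=rng,
    )
    return model.fit(obs_set)


def select_n_states(
    obs_set: np.ndarray,
    rng: np.random.Generator | int = 0,
    m_values: Optional[Sequence[int]] = None,
    **fit_kwargs,
) -> tuple[BernoulliSpikeHMM, pd.DataFrame]:
    """BIC model selection over M in {2, ..., N-1} (N = ensemble size).

    Returns the BIC-minimising model and the full BIC trace.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    N = obs_set.shape[2]
    if m_values is None:
        if N < 4:
            raise ValueError(f"need at least 4 neurons for the 2..N-1 range, got {N}")
        m_values = range(2, N)
    models, rows = [], []
    for M in m_values:
        model = baum_welch(obs_set, M, rng, **fit_kwargs)
        models.append(model)
        rows.append(
            {
                "n_states": M,
                "log_likelihood": model.log_likelihood_,
                "bic": model.bic_,
                "cv_score": model.cv_score_,
            }
        )
    trace = pd.DataFrame(rows)
    best = models[int(trace["bic"].idxmin())]
    return best, trace


# ---------------------------------------------------------------------------
# state assignment and coding states


@dataclass
class StateInterval:
    trial_index: int
    state: int
    start_ms: float
    end_ms: float


def assign_states(
    posteriors: np.ndarray,
    threshold: float = 0.8,
    min_dur_ms: float = 50.0,
    bin_ms: float = 5.0,
    span_start_ms: float = DEFAULT_SPAN_MS[0],
    trial_indices: Optional[Sequence[int]] = None,
) -> list[StateInterval]:
    """Decode assigned-state intervals from posterior probabilities.

    A state is assigned over a maximal run of bins where its posterior is
    strictly greater than ``threshold`` and the run lasts at least
    ``min_dur_ms`` (>= 10 bins at 5 ms).  Intervals from different states
    cannot overlap since posteriors sum to one and threshold >= 0.5.
    """
    if posteriors.ndim == 2:
        posteriors = posteriors[None]
    R, T, M = posteriors.shape
    if trial_indices is None:
        trial_indices = list(range(R))
    min_bins = int(np.ceil(min_dur_ms / bin_ms))
    out: list[StateInterval] = []
    for r in range(R):
        for m in range(M):
            above = posteriors[r, :, m] > threshold
            edges = np.diff(np.r_[0, above.astype(int), 0])
            starts = np.nonzero(edges == 1)[0]
            ends = np.nonzero(edges == -1)[0]
            for a, b in zip(starts, ends):
                if b - a >= min_bins:
                    out.append(
                        StateInterval(
                            trial_index=trial_indices[r],
                            state=m,
                            start_ms=span_start_ms + a * bin_ms,
                            end_ms=span_start_ms + b * bin_ms,
                        )
                    )
    return out


def state_occupancy(
    intervals: Sequence[StateInterval],
    trial_indices: Sequence[int],
    n_states: int,
    window: tuple[float, float],
) -> pd.DataFrame:
    """Per (trial, state) assigned time (ms) inside ``window``."""
    lo, hi = window
    occ = {(ti, m): 0.0 for ti in trial_indices for m in range(n_states)}
    for iv in intervals:
        overlap = min(iv.end_ms, hi) - max(iv.start_ms, lo)
        if overlap > 0 and (iv.trial_index, iv.state) in occ:
            occ[(iv.trial_index, iv.state)] += overlap
    rows = [
        {"trial_index": ti, "state": m, "occupancy_ms": occ[(ti, m)]}
        for ti in trial_indices
        for m in range(n_states)
    ]
    return pd.DataFrame(rows)


def detect_coding_states(
    occupancy: pd.DataFrame,
    groups: dict[int, object],
    alpha: float = 0.05,
    min_group_size: int = 3,
) -> pd.DataFrame:
    """Coding-state test: per state, Mann-Whitney U of occupancy between the
    two trial groups, Benjamini-Hochberg corrected across states.

    ``groups`` maps trial_index -> group label (exactly two labels).  States
    whose smaller group has fewer than ``min_group_size`` trials are skipped
    with a warning.
    """
    df = occupancy.copy()
    df["group"] = df["trial_index"].map(groups)
    df = df.dropna(subset=["group"])
    labels = sorted(df["group"].unique(), key=str)
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 groups, got {labels}")
    rows = []
    for state, g in df.groupby("state"):
        a = g.loc[g.group == labels[0], "occupancy_ms"].to_numpy()
        b = g.loc[g.group == labels[1], "occupancy_ms"].to_numpy()
        if min(len(a), len(b)) < min_group_size:
            warnings.warn(
                f"state {state}: a group has fewer than {min_group_size} trials; skipped",
                stacklevel=2,
            )
            continue
        if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
            u, p = len(a) * len(b) / 2.0, 1.0  # all-tied degenerate case
        else:
            res = stats.mannwhitneyu(a, b, alternative="two-sided")
            u, p = float(res.statistic), float(res.pvalue)
        rows.append(
            {
                "state": state,
                "u_statistic": u,
                "p_raw": p,
                "mean_occ_a": a.mean(),
                "mean_occ_b": b.mean(),
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["state", "u_statistic", "p_raw", "mean_occ_a", "mean_occ_b", "p_fdr", "coding"]
        )
    out = pd.DataFrame(rows)
    reject, p_adj, _, _ = multipletests(out["p_raw"], alpha=alpha, method="fdr_bh")
    out["p_fdr"] = p_adj
    out["coding"] = reject
    return out
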