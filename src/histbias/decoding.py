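"""Pseudo-population decoding with sliding windows and permutation nulls.

Neurons recorded in different sessions are combined into a pseudo-population:
per neuron, 75% of its eligible trials (stratified by class) go to a training
pool and 25% to a test pool, pseudo-trials are assembled per class by pairing
randomly drawn same-class trials across neurons, and firing rates in a 200 ms
window are z-scored with training-set parameters.  A linear SVM (l2 penalty,
C = 1, one-vs-rest) is trained per window; accuracy curves are averaged over
random-split repeats, cross-temporal matrices evaluate every (train window,
test window) pair, and significance comes from within-session label
permutations.

History-conditioned decoding trains one decoder per previous-S2 class and
evaluates it within and across conditions; the drop in accuracy with the
history gap between train and test trials, and the shift of the predicted
class toward the decoder's own training history, quantify the attractive
bias at the population level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.svm import LinearSVC
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .task import (
    MAGNITUDE_CLASSES,
    PairedTrial,
    SessionEnsemble,
    bin_magnitude,
    eligible_labelled_trials,
    filter_neurons,
)

LabelFn = Callable[[PairedTrial], Optional[object]]


def label_s1_class(p: PairedTrial) -> str:
    return bin_magnitude(p.trial.s1_mm)


def label_prev_s2_class(p: PairedTrial) -> Optional[str]:
    return bin_magnitude(p.previous.s2_mm) if p.previous is not None else None


def label_s1_colour(p: PairedTrial) -> str:
    return p.trial.s1_colour


def colour_match(p: PairedTrial) -> Optional[bool]:
    if p.previous is None:
        return None
    return p.previous.s2_colour == p.trial.s1_colour


def _class_sort_key(c: object):
    """Magnitude classes sort low < medium < high; anything else lexically."""
    if isinstance(c, str) and c in MAGNITUDE_CLASSES:
        return (0, MAGNITUDE_CLASSES.index(c))
    return (1, str(c))


@dataclass
class WindowGrid:
    """Sliding 200 ms windows advanced in 25 ms steps.

    Windows are half-open [center - width/2, center + width/2).  The default
    grid runs from 300 ms before S1 onset to 1400 ms after (end of the
    shortest post-S1 delay), 69 centers.  Early/late S1 are the two
    half-periods of the 1000 ms presentation.
    """

    start_ms: float = -300.0
    stop_ms: float = 1400.0
    step_ms: float = 25.0
    width_ms: float = 200.0
    early_s1: tuple[float, float] = (0.0, 500.0)
    late_s1: tuple[float, float] = (500.0, 1000.0)

    @property
    def centers(self) -> np.ndarray:
        n = int(round((self.stop_ms - self.start_ms) / self.step_ms)) + 1
        return self.start_ms + self.step_ms * np.arange(n)

    def __len__(self) -> int:
        return len(self.centers)

    def window_indices(self, interval: tuple[float, float]) -> np.ndarray:
        c = self.centers
        return np.nonzero((c >= interval[0]) & (c < interval[1]))[0]


def window_rates(
    session: SessionEnsemble,
    center_ms: float,
    trial_indices: Sequence[int],
    neuron_ids: Optional[Sequence[str]] = None,
    width_ms: float = 200.0,
) -> np.ndarray:
    """trials x neurons firing-rate matrix (spk/s) in one half-open window."""
    neuron_ids = session.neuron_ids if neuron_ids is None else neuron_ids
    lo, hi = center_ms - width_ms / 2, center_ms + width_ms / 2
    cols = [
        session.count_in_window(nid, trial_indices, lo, hi) for nid in neuron_ids
    ]
    return np.column_stack(cols) / (width_ms / 1000.0)


def _zscore_params(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)  # degenerate columns left unscaled
    return mu, sd


class WindowRateCache:
    """Per-(session, neuron, trial) spike counts for every grid window.

    Spike trains are immutable within an analysis, so counts are computed
    once per (unit, trial) for all window centers and reused across split
    repeats and label permutations.
    """

    def __init__(
        self,
        sessions: Sequence[SessionEnsemble],
        centers_ms: np.ndarray,
        width_ms: float = 200.0,
    ) -> None:
        self.sessions = list(sessions)
        self.centers_ms = np.asarray(centers_ms, dtype=float)
        self.width_ms = float(width_ms)
        self._lo = self.centers_ms - width_ms / 2
        self._hi = self.centers_ms + width_ms / 2
        self._cache: dict[tuple[int, str, int], np.ndarray] = {}

    def window_index(self, center_ms: float, width_ms: float) -> Optional[int]:
        if width_ms != self.width_ms:
            return None
        hit = np.nonzero(self.centers_ms == center_ms)[0]
        return int(hit[0]) if hit.size else None

    def counts(self, si: int, nid: str, ti: int) -> np.ndarray:
        key = (si, nid, ti)
        out = self._cache.get(key)
        if out is None:
            times = self.sessions[si].spike_times(nid, ti)
            out = (
                np.searchsorted(times, self._hi, "left")
                - np.searchsorted(times, self._lo, "left")
            ).astype(float)
            self._cache[key] = out
        return out


class PseudoAssembly:
    """One random train/test pseudo-trial composition.

    Fixing the composition per repeat and reading out rates per window keeps
    the cross-temporal matrix consistent with the same-window curve: the same
    pseudo-trials are evaluated at every window.
    """

    def __init__(
        self,
        sessions: Sequence[SessionEnsemble],
        label_fn: LabelFn,
        rng: np.random.Generator,
        split: float = 0.75,
        min_trials_per_class: int = 5,
        units: Optional[Sequence[tuple[int, str]]] = None,
        label_override: Optional[dict[tuple[int, int], object]] = None,
        rate_cache: Optional[WindowRateCache] = None,
    ) -> None:
        if not (0 < split < 1):
            raise ValueError("split must be in (0, 1)")
        self.sessions = list(sessions)
        per_session: dict[int, tuple[list[int], list[object]]] = {}
        for si, s in enumerate(self.sessions):
            idx, labels = eligible_labelled_trials(s, label_fn)
            if label_override is not None:
                labels = [label_override[(si, ti)] for ti in idx]
            per_session[si] = (idx, labels)
        if units is None:
            units = []
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                for si, s in enumerate(self.sessions):
                    if label_override is not None:
                        over = {
                            ti: label_override[(si, ti)]
                            for ti in per_session[si][0]
                        }
                        fn: LabelFn = lambda p, _o=over: _o.get(p.trial.trial_index)
                    else:
                        fn = label_fn
                    for nid in filter_neurons(
                        s, fn, min_trials_per_class=min_trials_per_class
                    ):
                        units.append((si, nid))
        self.units: list[tuple[int, str]] = list(units)
        if not self.units:
            raise ValueError("no eligible neurons for this labelling")
        classes = sorted(
            {lab for si, _ in self.units for lab in per_session[si][1]},
            key=_class_sort_key,
        )
        if len(classes) < 2:
            raise ValueError("need at least 2 classes to decode")
        self.classes: list[object] = classes

        # per unit, per class: independent stratified 75/25 split
        train_pools: dict[object, list[np.ndarray]] = {c: [] for c in classes}
        test_pools: dict[object, list[np.ndarray]] = {c: [] for c in classes}
        for si, nid in self.units:
            idx, labels = per_session[si]
            idx_arr = np.asarray(idx)
            lab_arr = np.asarray(labels, dtype=object)
            for c in classes:
                pool = idx_arr[lab_arr == c]
                if len(pool) < min_trials_per_class:
                    raise ValueError(
                        f"unit {(self.sessions[si].session_id, nid)} has "
                        f"{len(pool)} trials of class {c!r} (< {min_trials_per_class})"
                    )
                perm = rng.permutation(pool)
                n_tr = int(len(pool) * split)
                train_pools[c].append(perm[:n_tr])
                test_pools[c].append(perm[n_tr:])
        self.train_sel = {
            c: self._stack(train_pools[c], rng) for c in classes
        }
        self.test_sel = {c: self._stack(test_pools[c], rng) for c in classes}
        self.rate_cache = rate_cache
        self._rate_cache: dict[tuple[float, float], tuple[np.ndarray, ...]] = {}
        self._tensors: Optional[tuple[np.ndarray, np.ndarray]] = None

    @staticmethod
    def _stack(pools: list[np.ndarray], rng: np.random.Generator) -> np.ndarray:
        """(n_pseudo, n_units) trial indices, n_pseudo = min pool size."""
        n = min(len(p) for p in pools)
        return np.column_stack([rng.permutation(p)[:n] for p in pools])

    def labels(self, sel: dict[object, np.ndarray]) -> np.ndarray:
        return np.concatenate(
            [np.repeat(i, len(sel[c])) for i, c in enumerate(self.classes)]
        )

    def _rates_for(self, sel: dict[object, np.ndarray], center: float, width: float) -> np.ndarray:
        blocks = []
        for c in self.classes:
            mat = np.empty(sel[c].shape, dtype=float)
            for u, (si, nid) in enumerate(self.units):
                mat[:, u] = self.sessions[si].count_in_window(
                    nid, sel[c][:, u], center - width / 2, center + width / 2
                )
            blocks.append(mat / (width / 1000.0))
        return np.vstack(blocks)

    def _all_window_tensors(self) -> tuple[np.ndarray, np.ndarray]:
        """(rows, units, n_windows) rate tensors for train and test."""
        assert self.rate_cache is not None
        out = []
        for sel in (self.train_sel, self.test_sel):
            blocks = []
            for c in self.classes:
                block = np.empty((*sel[c].shape, len(self.rate_cache.centers_ms)))
                for u, (si, nid) in enumerate(self.units):
                    for r, ti in enumerate(sel[c][:, u]):
                        block[r, u] = self.rate_cache.counts(si, nid, ti)
                blocks.append(block)
            out.append(np.vstack(blocks) / (self.rate_cache.width_ms / 1000.0))
        return out[0], out[1]

    def matrices(
        self, center_ms: float, width_ms: float = 200.0
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(X_train, y_train, X_test, y_test) for one window, not yet z-scored."""
        w = (
            self.rate_cache.window_index(center_ms, width_ms)
            if self.rate_cache is not None
            else None
        )
        if w is not None:
            if self._tensors is None:
                self._tensors = self._all_window_tensors()
            Xtr, Xte = self._tensors[0][:, :, w], self._tensors[1][:, :, w]
        else:
            key = (center_ms, width_ms)
            if key not in self._rate_cache:
                self._rate_cache[key] = (
                    self._rates_for(self.train_sel, center_ms, width_ms),
                    self._rates_for(self.test_sel, center_ms, width_ms),
                )
            Xtr, Xte = self._rate_cache[key]
        return Xtr, self.labels(self.train_sel), Xte, self.labels(self.test_sel)


@dataclass
class PseudoPopulationSet:
    """z-scored train/test rate matrices for one window."""

    X_train: np.ndarray
    y_train: np.ndarray
    X_test: np.ndarray
    y_test: np.ndarray
    classes: list[object]
    mean_: np.ndarray
    sd_: np.ndarray
    split_fraction: float
    repeat_index: int = 0


def build_pseudopopulation(
    sessions: Sequence[SessionEnsemble],
    label_fn: LabelFn,
    window_center_ms: float,
    split: float = 0.75,
    rng: np.random.Generator | int = 0,
    width_ms: float = 200.0,
    repeat_index: int = 0,
) -> PseudoPopulationSet:
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    asm = PseudoAssembly(sessions, label_fn, rng, split=split)
    Xtr, ytr, Xte, yte = asm.matrices(window_center_ms, width_ms)
    mu, sd = _zscore_params(Xtr)
    return PseudoPopulationSet(
        (Xtr - mu) / sd,
        ytr,
        (Xte - mu) / sd,
        yte,
        asm.classes,
        mu,
        sd,
        split,
        repeat_index,
    )


def _classifier(C: float) -> LinearSVC:
    # primal solve: deterministic, one-vs-rest multiclass, squared-hinge/l2
    return LinearSVC(C=C, penalty="l2", dual=False)


def decode_window(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    y_test: np.ndarray,
    C: float = 1.0,
) -> tuple[float, np.ndarray]:
    """Linear max-margin decoding of one window: accuracy and predictions."""
    if len(np.unique(y_train)) < 2:
        raise ValueError("training set contains a single class")
    clf = _classifier(C).fit(X_train, y_train)
    pred = clf.predict(X_test)
    return float(np.mean(pred == y_test)), pred


@dataclass
class DecodeResult:
    """Accuracies over windows (and repeats), with optional permutation null."""

    centers_ms: np.ndarray
    accuracy: np.ndarray            # (repeats, W) or (repeats, W, W)
    classes: list[object]
    null: Optional[np.ndarray] = None       # (n_perm, W)
    alpha: float = 0.05

    @property
    def mean_accuracy(self) -> np.ndarray:
        return self.accuracy.mean(axis=0)

    @property
    def sd_accuracy(self) -> np.ndarray:
        return self.accuracy.std(axis=0)

    @property
    def chance(self) -> float:
        return 1.0 / len(self.classes)

    @property
    def null_quantile(self) -> Optional[np.ndarray]:
        if self.null is None:
            return None
        return np.quantile(self.null, 1 - self.alpha, axis=0)

    @property
    def significant(self) -> Optional[np.ndarray]:
        q = self.null_quantile
        if q is None:
            return None
        return self.mean_accuracy > q

    @property
    def p_values(self) -> Optional[np.ndarray]:
        if self.null is None:
            return None
        obs = self.mean_accuracy
        n = self.null.shape[0]
        return (1 + (self.null >= obs[None, :]).sum(axis=0)) / (n + 1)

    def frame(self) -> pd.DataFrame:
        d = {
            "center_ms": self.centers_ms,
            "mean_acc": self.mean_accuracy,
            "sd_acc": self.sd_accuracy,
        }
        if self.null is not None:
            d["null_q95"] = self.null_quantile
            d["significant"] = self.significant
            d["p_value"] = self.p_values
        return pd.DataFrame(d)


def sliding_curve(
    sessions: Sequence[SessionEnsemble],
    label_fn: LabelFn,
    grid: WindowGrid = WindowGrid(),
    repeats: int = 100,
    rng: np.random.Generator | int = 0,
    C: float = 1.0,
    units: Optional[Sequence[tuple[int, str]]] = None,
) -> DecodeResult:
    """Mean +/- SD decoding accuracy per window over random-split repeats."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if units is None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            units = [
                (si, nid)
                for si, s in enumerate(sessions)
                for nid in filter_neurons(s, label_fn)
            ]
    centers = grid.centers
    cache = WindowRateCache(sessions, centers, grid.width_ms)
    acc = np.zeros((repeats, len(centers)))
    classes: list[object] = []
    for r in range(repeats):
        asm = PseudoAssembly(sessions, label_fn, rng, units=units, rate_cache=cache)
        classes = asm.classes
        for w, c in enumerate(centers):
            Xtr, ytr, Xte, yte = asm.matrices(c, grid.width_ms)
            mu, sd = _zscore_params(Xtr)
            acc[r, w], _ = decode_window(
                (Xtr - mu) / sd, ytr, (Xte - mu) / sd, yte, C=C
            )
    return DecodeResult(centers, acc, classes)


def cross_temporal(
    sessions: Sequence[SessionEnsemble],
    label_fn: LabelFn,
    grid: WindowGrid = WindowGrid(),
    repeats: int = 100,
    rng: np.random.Generator | int = 0,
    C: float = 1.0,
) -> DecodeResult:
    """Full train-window x test-window generalisation matrix.

    Each window's rates are z-scored with that window's training parameters;
    the diagonal therefore reproduces the same-window sliding curve exactly.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    centers = grid.centers
    cache = WindowRateCache(sessions, centers, grid.width_ms)
    W = len(centers)
    acc = np.zeros((repeats, W, W))
    classes: list[object] = []
    for r in range(repeats):
        asm = PseudoAssembly(sessions, label_fn, rng, rate_cache=cache)
        classes = asm.classes
        Ztr, Zte, ytr, yte = [], [], None, None
        for c in centers:
            Xtr, ytr, Xte, yte = asm.matrices(c, grid.width_ms)
            mu, sd = _zscore_params(Xtr)
            Ztr.append((Xtr - mu) / sd)
            Zte.append((Xte - mu) / sd)
        for i in range(W):
            clf = _classifier(C).fit(Ztr[i], ytr)
            for j in range(W):
                acc[r, i, j] = np.mean(clf.predict(Zte[j]) == yte)
    return DecodeResult(centers, acc, classes)


def _permuted_labels(
    sessions: Sequence[SessionEnsemble],
    label_fn: LabelFn,
    rng: np.random.Generator,
) -> dict[tuple[int, int], object]:
    """Within-session permutation of trial class labels."""
    out: dict[tuple[int, int], object] = {}
    for si, s in enumerate(sessions):
        idx, labels = eligible_labelled_trials(s, label_fn)
        perm = rng.permutation(len(labels))
        for ti, k in zip(idx, perm):
            out[(si, ti)] = labels[k]
    return out


def permutation_null(
    sessions: Sequence[SessionEnsemble],
    label_fn: LabelFn,
    grid: WindowGrid = WindowGrid(),
    n_perm: int = 1000,
    rng: np.random.Generator | int = 0,
    C: float = 1.0,
    units: Optional[Sequence[tuple[int, str]]] = None,
) -> np.ndarray:
    """(n_perm, W) null accuracies from within-session label permutations.

    Labels are shuffled within each session before pseudo-population assembly;
    each permutation uses a single random train/test split.  The neuron set is
    fixed to the unpermuted filtering (permutation preserves per-session class
    counts).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if units is None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            units = [
                (si, nid)
                for si, s in enumerate(sessions)
                for nid in filter_neurons(s, label_fn)
            ]
    centers = grid.centers
    cache = WindowRateCache(sessions, centers, grid.width_ms)
    null = np.zeros((n_perm, len(centers)))
    for p in range(n_perm):
        override = _permuted_labels(sessions, label_fn, rng)
        asm = PseudoAssembly(
            sessions,
            label_fn,
            rng,
            units=units,
            label_override=override,
            rate_cache=cache,
        )
        for w, c in enumerate(centers):
            Xtr, ytr, Xte, yte = asm.matrices(c, grid.width_ms)
            mu, sd = _zscore_params(Xtr)
            null[p, w], _ = decode_window(
                (Xtr - mu) / sd, ytr, (Xte - mu) / sd, yte, C=C
            )
    return null


def decode_with_null(
    sessions: Sequence[SessionEnsemble],
    label_fn: LabelFn,
    grid: WindowGrid = WindowGrid(),
    repeats: int = 100,
    n_perm: int = 1000,
    rng: np.random.Generator | int = 0,
    C: float = 1.0,
    alpha: float = 0.05,
) -> DecodeResult:
    """Sliding curve plus permutation-null significance mask."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    res = sliding_curve(sessions, label_fn, grid, repeats, rng, C)
    res.null = permutation_null(sessions, label_fn, grid, n_perm, rng, C)
    res.alpha = alpha
    return res


# ---------------------------------------------------------------------------
# history-conditioned decoding

TIER_NAMES = ("within", "low_delta", "high_delta")


@dataclass
class ConditionalDecodeResult:
    """Within/across-condition decoding by history gap.

    ``accuracy[r, w, i, j]`` is the accuracy of the decoder trained on
    condition i tested on condition j's held-out trials at window w of
    ``centers_ms``; tiers pool (i, j) pairs by |i - j| (0 within, 1 low
    gap, 2 high gap).  ``marginals[r, w, i, j, k]`` is the fraction of
    condition-j test trials assigned to class k by the condition-i decoder.
    """

    centers_ms: np.ndarray
    window_sets: dict[str, np.ndarray]     # name -> indices into centers_ms
    conditions: list[object]
    classes: list[object]
    accuracy: np.ndarray
    marginals: np.ndarray

    def tier_samples(self, window_set: str) -> dict[str, np.ndarray]:
        w = self.window_sets[window_set]
        n = len(self.conditions)
        out = {}
        for tier, gap in zip(TIER_NAMES, (0, 1, 2)):
            pairs = [
                (i, j) for i in range(n) for j in range(n) if abs(i - j) == gap
            ]
            out[tier] = np.concatenate(
                [self.accuracy[:, w, i, j].ravel() for i, j in pairs]
            )
        return out

    def tier_anova(self, window_set: str) -> tuple[float, float, pd.DataFrame]:
        samples = self.tier_samples(window_set)
        f, p = stats.f_oneway(*[samples[t] for t in TIER_NAMES])
        values = np.concatenate([samples[t] for t in TIER_NAMES])
        groups = np.concatenate([[t] * len(samples[t]) for t in TIER_NAMES])
        tk = pairwise_tukeyhsd(values, groups)
        frame = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
        frame["p-adj"] = np.asarray(tk.pvalues, dtype=float)
        return float(f), float(p), frame

    def marginal_deltas(self, window_set: str) -> np.ndarray:
        """(train cond, test cond, class) deviation of assignment fractions
        from the within-condition reference, averaged over repeats/windows."""
        w = self.window_sets[window_set]
        m = self.marginals[:, w].mean(axis=(0, 1))  # (i, j, k)
        ref = np.stack([m[i, i] for i in range(m.shape[0])])  # (i, k)
        return m - ref[:, None, :]


def conditional_decode(
    sessions: Sequence[SessionEnsemble],
    target_fn: LabelFn = label_s1_class,
    condition_fn: LabelFn = label_prev_s2_class,
    grid: WindowGrid = WindowGrid(),
    repeats: int = 100,
    rng: np.random.Generator | int = 0,
    C: float = 1.0,
    min_trials_per_class: int = 5,
    window_sets: Optional[dict[str, tuple[float, float]]] = None,
) -> ConditionalDecodeResult:
    """Decode the target separately per condition and generalise across.

    One decoder is trained per condition (previous-S2 class by default) on
    that condition's trials labelled by the target (current-S1 class); each
    decoder is evaluated on every condition's held-out test trials, z-scored
    with the training condition's parameters.  The neuron set is restricted
    to units with enough trials in every (condition x class) cell so all
    decoders share one feature space.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if window_sets is None:
        window_sets = {"early_s1": grid.early_s1, "late_s1": grid.late_s1}

    def joint(p: PairedTrial) -> Optional[tuple]:
        c, t = condition_fn(p), target_fn(p)
        return None if c is None or t is None else (c, t)

    # verify every (condition, class) cell is populated somewhere
    all_joint: set[tuple] = set()
    conds: set[object] = set()
    targs: set[object] = set()
    for s in sessions:
        _, labs = eligible_labelled_trials(s, joint)
        all_joint.update(labs)
        conds.update(c for c, _ in labs)
        targs.update(t for _, t in labs)
    conditions = sorted(conds, key=_class_sort_key)
    classes = sorted(targs, key=_class_sort_key)
    for c in conditions:
        for t in classes:
            if (c, t) not in all_joint:
                raise ValueError(f"empty (condition, class) cell: ({c!r}, {t!r})")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        units = [
            (si, nid)
            for si, s in enumerate(sessions)
            for nid in filter_neurons(
                s, joint, min_trials_per_class=min_trials_per_class
            )
        ]
    if not units:
        raise ValueError("no neurons satisfy the per-(condition x class) trial counts")

    centers_all = grid.centers
    wsets = {k: grid.window_indices(v) for k, v in window_sets.items()}
    used = np.unique(np.concatenate(list(wsets.values())))
    centers = centers_all[used]
    wsets = {
        k: np.searchsorted(used, v) for k, v in wsets.items()
    }
    n_c, n_k, W = len(conditions), len(classes), len(centers)
    cache = WindowRateCache(sessions, centers, grid.width_ms)
    acc = np.zeros((repeats, W, n_c, n_c))
    marg = np.zeros((repeats, W, n_c, n_c, n_k))

    def make_label_fn(cond: object) -> LabelFn:
        def fn(p: PairedTrial) -> Optional[object]:
            return target_fn(p) if condition_fn(p) == cond else None

        return fn

    for r in range(repeats):
        asms = [
            PseudoAssembly(
                sessions,
                make_label_fn(cond),
                rng,
                units=units,
                min_trials_per_class=min_trials_per_class,
                rate_cache=cache,
            )
            for cond in conditions
        ]
        for w, cen in enumerate(centers):
            mats = [a.matrices(cen, grid.width_ms) for a in asms]
            for i in range(n_c):
                Xtr, ytr, _, _ = mats[i]
                mu, sd = _zscore_params(Xtr)
                clf = _classifier(C).fit((Xtr - mu) / sd, ytr)
                for j in range(n_c):
                    _, _, Xte, yte = mats[j]
                    pred = clf.predict((Xte - mu) / sd)
                    acc[r, w, i, j] = np.mean(pred == yte)
                    for k in range(n_k):
                        marg[r, w, i, j, k] = np.mean(pred == k)
    return ConditionalDecodeResult(
        centers_ms=centers,
        window_sets=wsets,
        conditions=conditions,
        classes=classes,
        accuracy=acc,
        marginals=marg,
    )


def decode_feature(
    sessions: Sequence[SessionEnsemble],
    grid: WindowGrid = WindowGrid(),
    repeats: int = 100,
    rng: np.random.Generator | int = 0,
    C: float = 1.0,
    split_by_match: bool = False,
) -> dict[str, DecodeResult]:
    """Binary decoding of the current S1 colour (chance 0.5).

    With ``split_by_match`` the analysis runs separately on trials whose
    previous S2 colour matches / differs from the current S1 colour.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if not split_by_match:
        return {"all": sliding_curve(sessions, label_s1_colour, grid, repeats, rng, C)}

    def match_fn(p: PairedTrial):
        return label_s1_colour(p) if colour_match(p) else None

    def mismatch_fn(p: PairedTrial):
        return label_s1_colour(p) if colour_match(p) is False else None

    return {
        "match": sliding_curve(sessions, match_fn, grid, repeats, rng, C),
        "mismatch": sliding_curve(sessions, mismatch_fn, grid, repeats, rng, C),
    }
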