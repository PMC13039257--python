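"""Behavioural history-bias statistics and choice GLMs.

The central statistic is the *S2-ward bias*: for each of the 10 ordered
current stimulus pairs with |S1 - S2| = 8 mm, and each of the 6 possible
previous-trial S2 magnitudes, the probability of choosing S2 minus the pair's
overall probability of choosing S2.  Positive values mean the previous trial
pushed choices toward S2.  An attractive effect of the previous S2 on the
perceived S1 shows up as a negative linear trend of bias against the previous
S2 magnitude, stronger when the previous S2 and the current S1 differ in
colour.

A four-model binomial (logit) GLM comparison quantifies the same effect at
the level of cell probabilities: stimulus ratio alone, + contraction bias,
+ previous S2, + previous S1, compared by test-set r² across session
resamples with one-way ANOVA and Tukey HSD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .task import (
    MAGNITUDES_MM,
    MEAN_MAGNITUDE_MM,
    PairedTrial,
    attach_previous_trial,
)

#: regressor sets of the four standard choice models
MODEL_SPECS: tuple[tuple[str, ...], ...] = (
    ("stim_ratio",),
    ("stim_ratio", "cb"),
    ("stim_ratio", "cb", "prev_s2"),
    ("stim_ratio", "cb", "prev_s2", "prev_s1"),
)

BIAS_COLUMNS = ["s1_mm", "s2_mm", "prev_s2_mm", "n_trials", "p_choose_s2", "bias"]


def _analysable(paired: Sequence[PairedTrial], delta_mm: int = 8) -> list[PairedTrial]:
    return [
        p
        for p in paired
        if p.eligible
        and p.trial.complete
        and p.trial.choice in ("S1", "S2")
        and abs(p.trial.s1_mm - p.trial.s2_mm) == delta_mm
    ]


def compute_s2ward_bias(paired: Sequence[PairedTrial]) -> pd.DataFrame:
    """S2-ward bias table over (current pair, previous S2) cells.

    Restricted to current pairs with |S1 - S2| = 8 mm and trials preceded by a
    complete trial.  Per pair, the bias of each previous-S2 cell is the cell's
    P(choose S2) minus the pair's trial-weighted mean P(choose S2), so the
    trial-weighted mean bias within a pair is exactly zero.  Cells with no
    trials are omitted (at most 60 rows).
    """
    rows = _analysable(paired)
    if not rows:
        warnings.warn("no eligible trials for the S2-ward bias", stacklevel=2)
        return pd.DataFrame(columns=BIAS_COLUMNS)
    df = pd.DataFrame(
        {
            "s1_mm": [p.trial.s1_mm for p in rows],
            "s2_mm": [p.trial.s2_mm for p in rows],
            "prev_s2_mm": [p.previous.s2_mm for p in rows],
            "chose_s2": [1.0 if p.trial.choice == "S2" else 0.0 for p in rows],
        }
    )
    cells = (
        df.groupby(["s1_mm", "s2_mm", "prev_s2_mm"])["chose_s2"]
        .agg(n_trials="size", p_choose_s2="mean")
        .reset_index()
    )
    pair_mean = (
        cells.assign(w=cells.n_trials * cells.p_choose_s2)
        .groupby(["s1_mm", "s2_mm"])
        .apply(lambda g: g.w.sum() / g.n_trials.sum(), include_groups=False)
        .rename("pair_mean")
    )
    cells = cells.join(pair_mean, on=["s1_mm", "s2_mm"])
    cells["bias"] = cells.p_choose_s2 - cells.pair_mean
    return cells[BIAS_COLUMNS]


@dataclass
class SlopeFit:
    """OLS trend of S2-ward bias against previous-S2 magnitude."""

    slope: float          # bias per normalised previous-S2 unit (prev_s2 in [0,1])
    intercept: float
    p_value: float
    slope_per_mm: float   # same fit on the raw mm scale
    n_cells: int


def fit_bias_slope(table: pd.DataFrame) -> SlopeFit:
    """Ordinary least squares of cell bias against previous-S2 magnitude.

    The previous S2 is rescaled to [0, 1] across its six task values; the raw
    per-mm slope is also reported.  Two-sided t-test on the slope.
    """
    if table["prev_s2_mm"].nunique() < 2:
        raise ValueError("need at least 2 distinct previous-S2 values")
    lo, hi = min(MAGNITUDES_MM), max(MAGNITUDES_MM)
    x = (table["prev_s2_mm"].to_numpy(dtype=float) - lo) / (hi - lo)
    y = table["bias"].to_numpy(dtype=float)
    res = stats.linregress(x, y)
    return SlopeFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        p_value=float(res.pvalue),
        slope_per_mm=float(res.slope / (hi - lo)),
        n_cells=len(table),
    )


@dataclass
class FeatureSplit:
    table_match: pd.DataFrame
    table_mismatch: pd.DataFrame
    u_statistic: float
    p_value: float
    n_units: int = 0


def _mwu(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney U: exact below 20 per group (no ties), else
    normal approximation with tie correction."""
    exact = len(a) < 20 and len(b) < 20 and len(np.unique(np.r_[a, b])) == len(a) + len(b)
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return float(res.statistic), float(res.pvalue)


def _aligned_scores(table: pd.DataFrame) -> pd.DataFrame:
    """History-aligned bias per cell: bias x (28 - prev_s2)/40.

    Positive scores mean the cell's choices moved toward the previous S2
    (attraction); the per-pair demeaning makes raw bias values mean-zero in
    every partition, so a rank test must act on these aligned scores to see
    a slope difference at all.
    """
    out = table[["s1_mm", "s2_mm", "prev_s2_mm"]].copy()
    out["score"] = table["bias"] * (MEAN_MAGNITUDE_MM - table["prev_s2_mm"]) / 40.0
    return out


def split_by_feature_match(
    paired: Sequence[PairedTrial],
    feature: str = "colour",
    n_perm: int = 2000,
    rng: np.random.Generator | int = 0,
) -> FeatureSplit:
    """Bias tables split by whether the previous S2 shares ``feature`` with
    the current S1, with a rank test for a history-strength difference.

    The test statistic is the Mann-Whitney U between the two partitions'
    history-aligned cell scores; its p-value comes from pairing the
    partitions' cells on (current pair, previous S2) and randomly swapping
    within each pairing, which respects the within-pair dependence the
    per-pair normalisation induces.
    """
    if feature not in ("colour", "position"):
        raise ValueError(f"feature must be 'colour' or 'position', got {feature!r}")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    attr = "s2_colour" if feature == "colour" else "s2_position"
    cur = "s1_colour" if feature == "colour" else "s1_position"
    rows = _analysable(paired)
    match = [p for p in rows if getattr(p.previous, attr) == getattr(p.trial, cur)]
    mismatch = [p for p in rows if getattr(p.previous, attr) != getattr(p.trial, cur)]
    for name, part in (("match", match), ("mismatch", mismatch)):
        if not part:
            raise ValueError(f"no eligible trials in the {name} partition")
    t_match = compute_s2ward_bias(match)
    t_mismatch = compute_s2ward_bias(mismatch)
    merged = _aligned_scores(t_match).merge(
        _aligned_scores(t_mismatch),
        on=["s1_mm", "s2_mm", "prev_s2_mm"],
        suffixes=("_match", "_mismatch"),
    )
    a = merged["score_match"].to_numpy()
    b = merged["score_mismatch"].to_numpy()
    u_obs, _ = _mwu(a, b)
    K = len(a)
    # paired swap permutations: exchangeable under "feature plays no role"
    flips = rng.random((n_perm, K)) < 0.5
    av = np.where(flips, b[None, :], a[None, :])
    bv = np.where(flips, a[None, :], b[None, :])
    both = np.concatenate([av, bv], axis=1)
    ranks = stats.rankdata(both, axis=1)
    u_perm = ranks[:, :K].sum(axis=1) - K * (K + 1) / 2
    mid = K * K / 2.0
    p = float((1 + np.sum(np.abs(u_perm - mid) >= abs(u_obs - mid))) / (n_perm + 1))
    return FeatureSplit(t_match, t_mismatch, u_obs, p, n_units=K)


# ---------------------------------------------------------------------------
# choice GLM


def stim_ratio(s1_mm: float, s2_mm: float) -> float:
    """sign(S2 - S1) * max(S1, S2) / min(S1, S2); positive favours choosing S2."""
    return float(np.sign(s2_mm - s1_mm) * max(s1_mm, s2_mm) / min(s1_mm, s2_mm))


def build_glm_design(
    paired: Sequence[PairedTrial],
    regressors: Sequence[str] = ("stim_ratio", "cb", "prev_s2", "prev_s1"),
    normalise: bool = True,
    ranges: Optional[dict[str, tuple[float, float]]] = None,
) -> tuple[pd.DataFrame, np.ndarray, dict[str, tuple[float, float]]]:
    """Trial-level design matrix and S2-choice response.

    Raw regressors: stim_ratio; cb = S1 - 28 mm (signed so that positive
    favours choosing S2: an S1 above the mean is contracted downward);
    prev_s2 and prev_s1 magnitudes in mm.  With ``normalise`` each column is
    min-max scaled to [0, 1] using ``ranges`` (fitted on this data when not
    supplied, to be reused on test data).  Returns (X, y, ranges).
    """
    rows = _analysable(paired)
    if not rows:
        raise ValueError("no eligible trials for the GLM design")
    raw = pd.DataFrame(
        {
            "stim_ratio": [stim_ratio(p.trial.s1_mm, p.trial.s2_mm) for p in rows],
            "cb": [p.trial.s1_mm - MEAN_MAGNITUDE_MM for p in rows],
            "prev_s2": [float(p.previous.s2_mm) for p in rows],
            "prev_s1": [float(p.previous.s1_mm) for p in rows],
        }
    )[list(regressors)]
    y = np.array([1.0 if p.trial.choice == "S2" else 0.0 for p in rows])
    if normalise:
        if ranges is None:
            ranges = {c: (raw[c].min(), raw[c].max()) for c in raw.columns}
        for c in raw.columns:
            lo, hi = ranges[c]
            if hi == lo:
                raise ValueError(f"regressor {c!r} is constant over the design")
            raw[c] = (raw[c] - lo) / (hi - lo)
    else:
        ranges = {c: (0.0, 1.0) for c in raw.columns}
    return raw, y, ranges


_CELL_KEYS = ["s1_mm", "s2_mm", "prev_s1_mm", "prev_s2_mm"]


def _cell_table(paired: Sequence[PairedTrial]) -> pd.DataFrame:
    """Aggregate eligible trials into (current pair x previous pair) cells."""
    rows = _analysable(paired)
    df = pd.DataFrame(
        {
            "s1_mm": [p.trial.s1_mm for p in rows],
            "s2_mm": [p.trial.s2_mm for p in rows],
            "prev_s1_mm": [p.previous.s1_mm for p in rows],
            "prev_s2_mm": [p.previous.s2_mm for p in rows],
            "chose_s2": [1.0 if p.trial.choice == "S2" else 0.0 for p in rows],
        }
    )
    cells = (
        df.groupby(_CELL_KEYS)["chose_s2"].agg(n="size", k="sum").reset_index()
    )
    cells["p_obs"] = cells.k / cells.n
    return cells


def _cell_design(cells: pd.DataFrame, regressors: Sequence[str]) -> pd.DataFrame:
    X = pd.DataFrame(
        {
            "stim_ratio": [
                stim_ratio(a, b) for a, b in zip(cells.s1_mm, cells.s2_mm)
            ],
            "cb": cells.s1_mm - MEAN_MAGNITUDE_MM,
            "prev_s2": cells.prev_s2_mm.astype(float),
            "prev_s1": cells.prev_s1_mm.astype(float),
        },
        index=cells.index,
    )
    return X[list(regressors)]


@dataclass
class GlmSuiteResult:
    """Coefficients and train/test r² of the four choice models."""

    model_names: list[str]
    coefficients: dict[str, pd.DataFrame]   # per model: repeats x terms
    r2_train: dict[str, np.ndarray]
    r2_test: dict[str, np.ndarray]
    anova_f: float
    anova_p: float
    tukey: pd.DataFrame                     # pairwise comparisons on test r²
    n_dropped: int
    resampled_with_replacement: bool = False

    def tukey_p(self, model_a: str, model_b: str) -> float:
        t = self.tukey
        m = ((t.group1 == model_a) & (t.group2 == model_b)) | (
            (t.group1 == model_b) & (t.group2 == model_a)
        )
        return float(t.loc[m, "p-adj"].iloc[0])


def _fit_one(
    train_cells: pd.DataFrame,
    test_cells: pd.DataFrame,
    regressors: Sequence[str],
) -> tuple[np.ndarray, float, float]:
    Xtr = _cell_design(train_cells, regressors)
    ranges = {c: (Xtr[c].min(), Xtr[c].max()) for c in Xtr.columns}
    for c in Xtr.columns:
        lo, hi = ranges[c]
        if hi == lo:
            raise ValueError(f"regressor {c!r} is constant over the training cells")
    Xte = _cell_design(test_cells, regressors)
    for c in Xtr.columns:
        lo, hi = ranges[c]
        Xtr[c] = (Xtr[c] - lo) / (hi - lo)
        Xte[c] = (Xte[c] - lo) / (hi - lo)
    endog = np.c_[train_cells.k, train_cells.n - train_cells.k]
    model = sm.GLM(endog, sm.add_constant(Xtr, has_constant="add"), family=sm.families.Binomial())
    fit = model.fit()
    if not fit.converged:
        raise RuntimeError("GLM did not converge")
    p_tr = fit.predict(sm.add_constant(Xtr, has_constant="add"))
    p_te = fit.predict(sm.add_constant(Xte, has_constant="add"))
    r2_tr = float(np.corrcoef(p_tr, train_cells.p_obs)[0, 1] ** 2)
    r2_te = float(np.corrcoef(p_te, test_cells.p_obs)[0, 1] ** 2)
    return fit.params.to_numpy(), r2_tr, r2_te


def fit_glm_suite(
    trials,
    seed: int = 0,
    n_train: int = 300,
    n_test: int = 300,
    n_repeats: int = 200,
    model_specs: Sequence[Sequence[str]] = MODEL_SPECS,
) -> GlmSuiteResult:
    """Four-model choice-GLM comparison over session resamples.

    Per repeat, ``n_train`` + ``n_test`` disjoint sessions are sampled (without
    replacement when enough sessions exist, otherwise with replacement and
    flagged); each binomial-logit model is fitted on the train cells and r² is
    the squared Pearson correlation between predicted and observed cell
    probabilities.  Across models, one-way ANOVA and Tukey HSD on test r².
    Repeats with a non-convergent fit are dropped; more than 10% drops is an
    error.
    """
    paired = trials if trials and isinstance(trials[0], PairedTrial) else attach_previous_trial(trials)
    rows = _analysable(paired)
    by_session: dict[str, list[PairedTrial]] = {}
    for p in rows:
        by_session.setdefault(p.trial.session_id, []).append(p)
    session_ids = sorted(by_session)
    rng = np.random.default_rng(seed)
    with_replacement = len(session_ids) < n_train + n_test
    if with_replacement:
        warnings.warn(
            f"only {len(session_ids)} sessions for {n_train}+{n_test}; "
            "resampling with replacement",
            stacklevel=2,
        )
    names = ["+".join(spec) for spec in model_specs]
    coefs: dict[str, list[np.ndarray]] = {n: [] for n in names}
    r2_tr: dict[str, list[float]] = {n: [] for n in names}
    r2_te: dict[str, list[float]] = {n: [] for n in names}
    dropped = 0
    for _ in range(n_repeats):
        if with_replacement:
            train_ids = rng.choice(session_ids, size=n_train, replace=True)
            test_ids = rng.choice(session_ids, size=n_test, replace=True)
        else:
            picked = rng.choice(session_ids, size=n_train + n_test, replace=False)
            train_ids, test_ids = picked[:n_train], picked[n_train:]
        train_cells = _cell_table(
            [p for sid in train_ids for p in by_session[sid]]
        )
        test_cells = _cell_table([p for sid in test_ids for p in by_session[sid]])
        try:
            for name, spec in zip(names, model_specs):
                c, a, b = _fit_one(train_cells, test_cells, spec)
                coefs[name].append(c)
                r2_tr[name].append(a)
                r2_te[name].append(b)
        except (RuntimeError, ValueError, np.linalg.LinAlgError):
            dropped += 1
            k = min(len(r2_te[n]) for n in names)
            for name in names:  # discard any partial results of this repeat
                coefs[name] = coefs[name][:k]
                r2_tr[name] = r2_tr[name][:k]
                r2_te[name] = r2_te[name][:k]
    if dropped > 0.1 * n_repeats:
        raise RuntimeError(f"{dropped}/{n_repeats} repeats failed to converge")
    r2_te_arr = {n: np.asarray(v) for n, v in r2_te.items()}
    values = np.concatenate([r2_te_arr[n] for n in names])
    groups = np.concatenate([[n] * len(r2_te_arr[n]) for n in names])
    f, p = stats.f_oneway(*[r2_te_arr[n] for n in names])
    tk = pairwise_tukeyhsd(values, groups)
    tukey = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
    tukey["p-adj"] = np.asarray(tk.pvalues, dtype=float)  # unrounded
    coef_frames = {
        n: pd.DataFrame(np.vstack(v), columns=["const", *spec])
        for (n, spec), v in zip(zip(names, model_specs), coefs.values())
    }
    return GlmSuiteResult(
        model_names=names,
        coefficients=coef_frames,
        r2_train={n: np.asarray(v) for n, v in r2_tr.items()},
        r2_test=r2_te_arr,
        anova_f=float(f),
        anova_p=float(p),
        tukey=tukey,
        n_dropped=dropped,
        resampled_with_replacement=with_replacement,
    )
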