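"""Domain model for the two-stimulus distance-discrimination task.

A trial presents a first stimulus S1 (a blue circle or a red square, above or
below a reference point, at one of six distances 8–48 mm in 8 mm steps) for
1000 ms, then after a delay a second stimulus S2 with the complementary colour
and position and a *different* distance.  After a second delay the subject
chooses which of the two stimuli was farther from the reference.

This module holds the task constants, the trial/spike containers, plain-CSV
readers and writers, and the trial/neuron/session eligibility filters shared
by the behavioural, decoding and latent-state analyses.  All within-trial
times are milliseconds relative to current-trial S1 onset; events of the
previous trial carry negative times.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

MAGNITUDES_MM: tuple[int, ...] = (8, 16, 24, 32, 40, 48)
#: mean of the stimulus-magnitude distribution, the attractor of contraction bias
MEAN_MAGNITUDE_MM: float = 28.0
COLOURS: tuple[str, str] = ("blue", "red")
POSITIONS: tuple[str, str] = ("above", "below")
PRE_S_CHOICES_MS: tuple[int, ...] = (400, 800)
D1_CHOICES_MS: tuple[int, ...] = (400, 800)
D2_CHOICES_MS: tuple[int, ...] = (0, 400, 800)
CHOICES: tuple[str, ...] = ("S1", "S2", "none")
MAGNITUDE_CLASSES: tuple[str, str, str] = ("low", "medium", "high")
S1_DURATION_MS: float = 1000.0
#: default spike alignment span: previous-trial S2 onset .. end of current D1
DEFAULT_SPAN_MS: tuple[float, float] = (-2600.0, 1400.0)

_OTHER_COLOUR = {"blue": "red", "red": "blue"}
_OTHER_POSITION = {"above": "below", "below": "above"}

TRIALS_COLUMNS = [
    "session_id", "trial_index", "s1_mm", "s2_mm", "s1_colour", "s1_position",
    "pre_s_ms", "d1_ms", "d2_ms", "choice", "complete",
]
SPIKES_COLUMNS = ["session_id", "neuron_id", "trial_index", "time_ms"]


def other_colour(colour: str) -> str:
    return _OTHER_COLOUR[colour]


def other_position(position: str) -> str:
    return _OTHER_POSITION[position]


def bin_magnitude(mm: float) -> str:
    """Map a task magnitude onto its low/medium/high class.

    low = {8, 16} mm, medium = {24, 32} mm, high = {40, 48} mm.  Magnitudes
    outside the six-value task set are rejected.
    """
    if mm not in MAGNITUDES_MM:
        raise ValueError(
            f"magnitude {mm!r} mm is not in the task set {MAGNITUDES_MM}"
        )
    return MAGNITUDE_CLASSES[0 if mm <= 16 else (1 if mm <= 32 else 2)]


def class_index(name: str) -> int:
    return MAGNITUDE_CLASSES.index(name)


def bin_magnitude_continuous(mm: float) -> str:
    """Class of an arbitrary (possibly off-grid) magnitude.

    Boundaries sit midway between class-adjacent task magnitudes (20 and
    36 mm).  Used for *effective* magnitudes shifted by trial history, which
    need not lie on the 8 mm grid.
    """
    return MAGNITUDE_CLASSES[0 if mm < 20 else (1 if mm < 36 else 2)]


@dataclass
class TrialRecord:
    """One behavioural trial.

    ``s2_colour``/``s2_position`` are always the complements of the S1
    attributes and are exposed as properties.  ``correct`` derives from the
    choice and the magnitude order.
    """

    session_id: str
    trial_index: int
    s1_mm: int
    s2_mm: int
    s1_colour: str
    s1_position: str
    pre_s_ms: int
    d1_ms: int
    d2_ms: int
    choice: str = "none"
    complete: bool = True

    def __post_init__(self) -> None:
        if self.trial_index < 0:
            raise ValueError(f"trial_index {self.trial_index} must be >= 0")
        for name in ("s1_mm", "s2_mm"):
            mm = getattr(self, name)
            if mm not in MAGNITUDES_MM:
                raise ValueError(f"{name}={mm!r} is not in the task set {MAGNITUDES_MM}")
        if self.s1_mm == self.s2_mm:
            raise ValueError(f"s1_mm and s2_mm must differ (both {self.s1_mm} mm)")
        if self.s1_colour not in COLOURS:
            raise ValueError(f"s1_colour={self.s1_colour!r} not in {COLOURS}")
        if self.s1_position not in POSITIONS:
            raise ValueError(f"s1_position={self.s1_position!r} not in {POSITIONS}")
        if self.pre_s_ms not in PRE_S_CHOICES_MS:
            raise ValueError(f"pre_s_ms={self.pre_s_ms!r} not in {PRE_S_CHOICES_MS}")
        if self.d1_ms not in D1_CHOICES_MS:
            raise ValueError(f"d1_ms={self.d1_ms!r} not in {D1_CHOICES_MS}")
        if self.d2_ms not in D2_CHOICES_MS:
            raise ValueError(f"d2_ms={self.d2_ms!r} not in {D2_CHOICES_MS}")
        if self.choice not in CHOICES:
            raise ValueError(f"choice={self.choice!r} not in {CHOICES}")
        if not self.complete and self.choice != "none":
            raise ValueError("incomplete trial must have choice='none'")

    @property
    def s2_colour(self) -> str:
        return _OTHER_COLOUR[self.s1_colour]

    @property
    def s2_position(self) -> str:
        return _OTHER_POSITION[self.s1_position]

    @property
    def correct(self) -> bool:
        if self.choice == "S2":
            return self.s2_mm > self.s1_mm
        if self.choice == "S1":
            return self.s1_mm > self.s2_mm
        return False


@dataclass
class PairedTrial:
    """A trial together with its immediate predecessor in the same session.

    ``eligible`` means the predecessor exists and was complete — the entry
    condition for every history-conditioned analysis.  Analyses that need the
    current choice additionally require ``trial.complete``.
    """

    trial: TrialRecord
    previous: Optional[TrialRecord]
    eligible: bool


def attach_previous_trial(trials: Sequence[TrialRecord]) -> list[PairedTrial]:
    """Pair each trial with its predecessor within the session.

    Trials must be ordered by ``trial_index`` within each session; duplicate
    indices within a session are rejected.  The first trial of a session (no
    predecessor) and successors of incomplete trials are flagged ineligible.
    """
    out: list[PairedTrial] = []
    prev_by_session: dict[str, TrialRecord] = {}
    seen: dict[str, set[int]] = {}
    for t in trials:
        idx_seen = seen.setdefault(t.session_id, set())
        if t.trial_index in idx_seen:
            raise ValueError(
                f"duplicate trial_index {t.trial_index} in session {t.session_id!r}"
            )
        idx_seen.add(t.trial_index)
        prev = prev_by_session.get(t.session_id)
        if prev is not None and t.trial_index <= prev.trial_index:
            raise ValueError(
                f"trials of session {t.session_id!r} are not ordered by trial_index"
            )
        out.append(PairedTrial(t, prev, prev is not None and prev.complete))
        prev_by_session[t.session_id] = t
    return out


@dataclass
class SessionEnsemble:
    """Simultaneously recorded neurons of one session plus trial alignment.

    ``spikes`` maps neuron id -> trial_index -> sorted spike times in ms
    relative to the current trial's S1 onset.
    """

    session_id: str
    neuron_ids: list[str]
    spikes: dict[str, dict[int, np.ndarray]]
    trials: list[TrialRecord]
    _paired: Optional[list[PairedTrial]] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        valid = {t.trial_index for t in self.trials}
        for nid in self.neuron_ids:
            per_trial = self.spikes.setdefault(nid, {})
            for ti, times in per_trial.items():
                if ti not in valid:
                    raise ValueError(
                        f"spikes of neuron {nid!r} reference unknown trial {ti}"
                    )
                arr = np.asarray(times, dtype=float)
                if np.any(np.diff(arr) < 0):
                    raise ValueError(
                        f"spike times of neuron {nid!r}, trial {ti} are not non-decreasing"
                    )
                per_trial[ti] = arr

    def paired(self) -> list[PairedTrial]:
        if self._paired is None:
            self._paired = attach_previous_trial(self.trials)
        return self._paired

    def spike_times(self, neuron_id: str, trial_index: int) -> np.ndarray:
        return self.spikes.get(neuron_id, {}).get(trial_index, np.empty(0))

    def count_in_window(
        self, neuron_id: str, trial_indices: Sequence[int], lo_ms: float, hi_ms: float
    ) -> np.ndarray:
        """Spike counts per trial in the half-open window [lo_ms, hi_ms)."""
        counts = np.zeros(len(trial_indices), dtype=float)
        per_trial = self.spikes.get(neuron_id, {})
        for i, ti in enumerate(trial_indices):
            times = per_trial.get(ti)
            if times is not None and times.size:
                counts[i] = np.searchsorted(times, hi_ms, "left") - np.searchsorted(
                    times, lo_ms, "left"
                )
        return counts

    def mean_rate(
        self, neuron_id: str, trial_indices: Sequence[int], span: tuple[float, float]
    ) -> float:
        """Total spikes in ``span`` over the given trials divided by total time (spk/s)."""
        if not len(trial_indices):
            return 0.0
        total = self.count_in_window(neuron_id, trial_indices, span[0], span[1]).sum()
        return float(total) / (len(trial_indices) * (span[1] - span[0]) / 1000.0)


LabelFn = Callable[[PairedTrial], Optional[object]]


def eligible_labelled_trials(
    session: SessionEnsemble, label_fn: LabelFn
) -> tuple[list[int], list[object]]:
    """Trial indices (and labels) that are complete, follow a complete trial
    and receive a non-None label."""
    idx, labels = [], []
    for p in session.paired():
        if not (p.eligible and p.trial.complete):
            continue
        lab = label_fn(p)
        if lab is None:
            continue
        idx.append(p.trial.trial_index)
        labels.append(lab)
    return idx, labels


def filter_neurons(
    session: SessionEnsemble,
    label_fn: LabelFn,
    min_rate: float = 1.0,
    min_trials_per_class: int = 5,
    span: tuple[float, float] = DEFAULT_SPAN_MS,
) -> list[str]:
    """Neurons eligible for decoding a given labelling.

    Retained iff mean firing rate over eligible trials is at least ``min_rate``
    spk/s and every class of ``label_fn`` has at least ``min_trials_per_class``
    eligible trials.  Both bounds are inclusive.
    """
    idx, labels = eligible_labelled_trials(session, label_fn)
    if not idx:
        warnings.warn(
            f"session {session.session_id!r}: no eligible trials for this labelling",
            stacklevel=2,
        )
        return []
    counts = pd.Series(labels).value_counts()
    if counts.empty or counts.min() < min_trials_per_class:
        return []
    return [
        nid
        for nid in session.neuron_ids
        if session.mean_rate(nid, idx, span) >= min_rate
    ]


def filter_sessions_for_hmm(
    sessions: Iterable[SessionEnsemble],
    min_neurons: int = 4,
    min_rate: float = 1.0,
    min_trials: int = 25,
    span: tuple[float, float] = DEFAULT_SPAN_MS,
) -> list[SessionEnsemble]:
    """Sessions eligible for ensemble latent-state fitting.

    A session is kept iff at least ``min_neurons`` neurons have a mean rate of
    at least ``min_rate`` spk/s over the eligible trials and at least
    ``min_trials`` trials are complete and preceded by a complete trial.  The
    returned ensembles contain only the qualifying neurons.
    """
    kept = []
    for s in sessions:
        idx = [
            p.trial.trial_index
            for p in s.paired()
            if p.eligible and p.trial.complete
        ]
        if len(idx) < min_trials:
            continue
        good = [n for n in s.neuron_ids if s.mean_rate(n, idx, span) >= min_rate]
        if len(good) < min_neurons:
            continue
        kept.append(
            SessionEnsemble(
                session_id=s.session_id,
                neuron_ids=good,
                spikes={n: s.spikes[n] for n in good},
                trials=s.trials,
            )
        )
    return kept


# ---------------------------------------------------------------------------
# plain-CSV I/O


def _reject(row: int, rule: str) -> ValueError:
    return ValueError(f"trials file row {row}: {rule}")


def trials_to_frame(trials: Sequence[TrialRecord]) -> pd.DataFrame:
    rows = [
        {
            "session_id": t.session_id,
            "trial_index": t.trial_index,
            "s1_mm": t.s1_mm,
            "s2_mm": t.s2_mm,
            "s1_colour": t.s1_colour,
            "s1_position": t.s1_position,
            "pre_s_ms": t.pre_s_ms,
            "d1_ms": t.d1_ms,
            "d2_ms": t.d2_ms,
            "choice": t.choice,
            "complete": t.complete,
        }
        for t in trials
    ]
    return pd.DataFrame(rows, columns=TRIALS_COLUMNS)


def write_trials(trials: Sequence[TrialRecord], path) -> None:
    trials_to_frame(trials).to_csv(path, index=False, lineterminator="\n")


def read_trials(path) -> list[TrialRecord]:
    """Read and validate a trials CSV; any schema violation names row and rule."""
    df = pd.read_csv(path)
    missing = [c for c in TRIALS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trials file is missing columns {missing}")
    out = []
    for i, row in enumerate(df.itertuples(index=False)):
        d = row._asdict()
        if "s1_colour" in d and "s2_colour" in df.columns:
            if d["s1_colour"] == getattr(row, "s2_colour"):
                raise _reject(i, f"s1_colour equals s2_colour ({d['s1_colour']!r})")
        if "s2_position" in df.columns and d["s1_position"] == getattr(row, "s2_position"):
            raise _reject(i, f"s1_position equals s2_position ({d['s1_position']!r})")
        kwargs = {k: d[k] for k in TRIALS_COLUMNS}
        kwargs["complete"] = bool(kwargs["complete"])
        kwargs["trial_index"] = int(kwargs["trial_index"])
        for k in ("s1_mm", "s2_mm", "pre_s_ms", "d1_ms", "d2_ms"):
            kwargs[k] = int(kwargs[k])
        try:
            out.append(TrialRecord(**kwargs))
        except ValueError as e:
            raise _reject(i, str(e)) from e
    return out


def write_spikes(sessions: Iterable[SessionEnsemble], path) -> None:
    frames = []
    for s in sessions:
        for nid in s.neuron_ids:
            for ti, times in sorted(s.spikes[nid].items()):
                if not len(times):
                    continue
                frames.append(
                    pd.DataFrame(
                        {
                            "session_id": s.session_id,
                            "neuron_id": nid,
                            "trial_index": ti,
                            "time_ms": np.asarray(times, dtype=float),
                        }
                    )
                )
    df = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=SPIKES_COLUMNS)
    )
    df.to_csv(path, index=False, lineterminator="\n")


def read_spikes(path) -> dict[str, dict[str, dict[int, np.ndarray]]]:
    """Read a spikes CSV into session -> neuron -> trial -> sorted times (ms)."""
    df = pd.read_csv(path)
    missing = [c for c in SPIKES_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"spikes file is missing columns {missing}")
    out: dict[str, dict[str, dict[int, np.ndarray]]] = {}
    for (sid, nid, ti), grp in df.groupby(
        ["session_id", "neuron_id", "trial_index"], sort=True
    ):
        out.setdefault(str(sid), {}).setdefault(str(nid), {})[int(ti)] = np.sort(
            grp["time_ms"].to_numpy(dtype=float)
        )
    return out


def build_sessions(
    trials: Sequence[TrialRecord],
    spikes: Mapping[str, Mapping[str, Mapping[int, np.ndarray]]],
) -> list[SessionEnsemble]:
    """Assemble per-session ensembles from a trial list and a spikes mapping."""
    by_session: dict[str, list[TrialRecord]] = {}
    for t in trials:
        by_session.setdefault(t.session_id, []).append(t)
    out = []
    for sid, sess_trials in by_session.items():
        sess_spikes = {k: dict(v) for k, v in spikes.get(sid, {}).items()}
        out.append(
            SessionEnsemble(
                session_id=sid,
                neuron_ids=sorted(sess_spikes),
                spikes=sess_spikes,
                trials=sorted(sess_trials, key=lambda t: t.trial_index),
            )
        )
    return out
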