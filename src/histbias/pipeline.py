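"""End-to-end orchestration: simulate -> behaviour -> decoding -> HMM.

A run is described by a :class:`RunConfig` (YAML-serialisable); every
stochastic stage receives a deterministic child seed spawned from the master
seed at a fixed position, so toggling one stage never perturbs another's
randomness.  Outputs are plain CSV tables plus one machine-readable JSON
report with a config hash and per-stage summaries, including pass/fail of
built-in parameter-recovery checks.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import behavior, decoding, hmm, simulate, task

log = logging.getLogger("histbias")

#: fixed spawn positions per stage (new stages append; existing never move)
_STAGE_KEYS = {"simulate": 0, "behavior": 1, "decode": 2, "hmm": 3}


class ConfigError(ValueError):
    """Invalid run configuration; message lists every violation by key path."""


@dataclass
class RunConfig:
    """Validated configuration of a full pipeline run."""

    seed: int = 0
    out_dir: str = "histbias_run"
    # stage toggles
    run_behavior: bool = True
    run_decode: bool = True
    run_hmm: bool = True
    # generator
    n_sessions: int = 6
    trials_per_session: int = 240
    n_neurons: int = 8
    behaviour_params: dict = field(default_factory=dict)
    neural_params: dict = field(default_factory=dict)
    # behaviour stage
    glm_n_train: int = 300
    glm_n_test: int = 300
    glm_repeats: int = 200
    # decoding stage
    split: float = 0.75
    svm_c: float = 1.0
    decode_repeats: int = 100
    n_perm: int = 1000
    grid_step_ms: float = 25.0
    # hmm stage
    hmm_bin_ms: float = 5.0
    hmm_threshold: float = 0.8
    hmm_min_dur_ms: float = 50.0
    hmm_restarts: int = 10
    hmm_cv_folds: int = 3
    hmm_max_iter: int = 500
    hmm_max_sessions: Optional[int] = None
    hmm_max_states: Optional[int] = None  # cap on the 2..N-1 BIC range

    def child_seed(self, stage: str) -> int:
        ss = np.random.SeedSequence(self.seed, spawn_key=(_STAGE_KEYS[stage],))
        return int(ss.generate_state(1)[0] % (2**31))


_ALLOWED_KEYS = set(RunConfig.__dataclass_fields__)


def validate_config(raw: dict) -> RunConfig:
    """Normalise a raw mapping into a RunConfig, collecting all violations."""
    errors = []
    unknown = set(raw) - _ALLOWED_KEYS
    for k in sorted(unknown):
        errors.append(f"{k}: unknown key")
    cfg = RunConfig(**{k: v for k, v in raw.items() if k in _ALLOWED_KEYS})
    if not isinstance(cfg.seed, int) or cfg.seed < 0:
        errors.append("seed: must be a non-negative integer")
    if not (0 < cfg.split < 1):
        errors.append("split: must be in (0, 1)")
    if cfg.svm_c <= 0:
        errors.append("svm_c: must be > 0")
    if not (0 < cfg.hmm_threshold < 1):
        errors.append("hmm_threshold: must be in (0, 1)")
    if cfg.hmm_min_dur_ms < cfg.hmm_bin_ms:
        errors.append("hmm_min_dur_ms: must cover at least one bin")
    if cfg.n_sessions < 1 or cfg.trials_per_session < 2:
        errors.append("n_sessions/trials_per_session: too small")
    if cfg.grid_step_ms <= 0 or 200.0 % cfg.grid_step_ms != 0:
        errors.append("grid_step_ms: must be > 0 and divide the 200 ms window")
    if cfg.n_perm < 100:
        errors.append("n_perm: must be >= 100")
    if errors:
        raise ConfigError("; ".join(errors))
    return cfg


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    return validate_config(raw)


def config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(asdict(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON serialisable: {type(o)}")


def write_true_states(truth: dict, sessions, path) -> None:
    """Ground-truth latent states, one row per trial, states space-joined."""
    rows = []
    for s in sessions:
        states = truth[s.session_id]
        for i, t in enumerate(s.trials):
            rows.append(
                {
                    "session_id": s.session_id,
                    "trial_index": t.trial_index,
                    "states": " ".join(map(str, states[i])),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False, lineterminator="\n")


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages in dependency order.

    Writes per-stage CSV tables and a JSON report under ``cfg.out_dir``.
    A stage failure is recorded in the report (and re-raised by the CLI as a
    nonzero exit); completed stages keep their outputs.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "config": asdict(cfg),
        "config_hash": config_hash(cfg),
        "stages": {},
        "checks": {},
        "failures": [],
    }

    bp = simulate.BehaviourParams(**cfg.behaviour_params)
    npr = {"n_neurons": cfg.n_neurons, **cfg.neural_params}
    np_ = simulate.NeuralParams(**npr)

    # --- simulate ---------------------------------------------------------
    t0 = time.perf_counter()
    sessions, truth = simulate.generate_neural_dataset(
        cfg.n_sessions,
        cfg.trials_per_session,
        bp,
        np_,
        seed=cfg.child_seed("simulate"),
    )
    trials = [t for s in sessions for t in s.trials]
    task.write_trials(trials, out / "trials.csv")
    task.write_spikes(sessions, out / "spikes.csv")
    write_true_states(truth, sessions, out / "true_states.csv")
    report["stages"]["simulate"] = {
        "n_sessions": cfg.n_sessions,
        "n_trials": len(trials),
        "elapsed_s": round(time.perf_counter() - t0, 3),
    }
    log.info("simulate: %d sessions, %d trials", cfg.n_sessions, len(trials))

    paired = task.attach_previous_trial(trials)

    # --- behaviour --------------------------------------------------------
    if cfg.run_behavior:
        t0 = time.perf_counter()
        try:
            bias = behavior.compute_s2ward_bias(paired)
            bias.to_csv(out / "bias_table.csv", index=False, lineterminator="\n")
            slope = behavior.fit_bias_slope(bias)
            split = behavior.split_by_feature_match(paired, "colour")
            slope_mm = behavior.fit_bias_slope(split.table_mismatch)
            slope_m = behavior.fit_bias_slope(split.table_match)
            report["stages"]["behavior"] = {
                "slope": slope.slope,
                "slope_p": slope.p_value,
                "mismatch_slope": slope_mm.slope,
                "match_slope": slope_m.slope,
                "colour_mwu_u": split.u_statistic,
                "colour_mwu_p": split.p_value,
                "elapsed_s": round(time.perf_counter() - t0, 3),
            }
            report["checks"]["bias_slope_negative"] = bool(
                slope.slope < 0 and slope.p_value < 0.05
            )
            report["checks"]["mismatch_stronger_than_match"] = bool(
                slope_mm.slope < slope_m.slope
            )
        except Exception as e:  # noqa: BLE001 - partial report contract
            report["failures"].append({"stage": "behavior", "error": str(e)})
            log.exception("behavior stage failed")

    # --- decoding ---------------------------------------------------------
    if cfg.run_decode:
        t0 = time.perf_counter()
        try:
            grid = decoding.WindowGrid(step_ms=cfg.grid_step_ms)
            rng = np.random.default_rng(cfg.child_seed("decode"))
            res = decoding.decode_with_null(
                sessions,
                decoding.label_s1_class,
                grid,
                repeats=cfg.decode_repeats,
                n_perm=cfg.n_perm,
                rng=rng,
                C=cfg.svm_c,
            )
            res.frame().to_csv(out / "decode_s1class.csv", index=False, lineterminator="\n")
            in_s1 = grid.window_indices((0.0, 1000.0))
            report["stages"]["decode"] = {
                "n_windows": len(grid),
                "mean_acc_s1_presentation": float(res.mean_accuracy[in_s1].mean()),
                "frac_significant_s1": float(np.mean(res.significant[in_s1])),
                "elapsed_s": round(time.perf_counter() - t0, 3),
            }
            report["checks"]["s1_decodable_during_presentation"] = bool(
                np.mean(res.significant[in_s1]) > 0.5
            )
        except Exception as e:  # noqa: BLE001
            report["failures"].append({"stage": "decode", "error": str(e)})
            log.exception("decode stage failed")

    # --- hmm --------------------------------------------------------------
    if cfg.run_hmm:
        t0 = time.perf_counter()
        try:
            eligible = task.filter_sessions_for_hmm(sessions)
            if cfg.hmm_max_sessions is not None:
                eligible = eligible[: cfg.hmm_max_sessions]
            rng = np.random.default_rng(cfg.child_seed("hmm"))
            rows, interval_rows = [], []
            for s in eligible:
                obs, clipped, idx = hmm.bin_spikes(s, bin_ms=cfg.hmm_bin_ms)
                n_neurons = obs.shape[2]
                m_hi = n_neurons if cfg.hmm_max_states is None else min(
                    cfg.hmm_max_states + 1, n_neurons
                )
                model, trace = hmm.select_n_states(
                    obs,
                    rng,
                    m_values=range(2, m_hi),
                    restarts=cfg.hmm_restarts,
                    cv_folds=cfg.hmm_cv_folds,
                    max_iter=cfg.hmm_max_iter,
                )
                post = model.predict_posteriors(obs)
                ivals = hmm.assign_states(
                    post,
                    threshold=cfg.hmm_threshold,
                    min_dur_ms=cfg.hmm_min_dur_ms,
                    bin_ms=cfg.hmm_bin_ms,
                    trial_indices=idx,
                )
                for iv in ivals:
                    interval_rows.append(
                        {
                            "session_id": s.session_id,
                            "trial_index": iv.trial_index,
                            "state": iv.state,
                            "start_ms": iv.start_ms,
                            "end_ms": iv.end_ms,
                        }
                    )
                rows.append(
                    {
                        "session_id": s.session_id,
                        "n_neurons": len(s.neuron_ids),
                        "n_trials": len(idx),
                        "n_states": model.n_states,
                        "log_likelihood": model.log_likelihood_,
                        "bic": model.bic_,
                        "clipped_bins": clipped,
                    }
                )
            pd.DataFrame(rows).to_csv(out / "hmm_models.csv", index=False, lineterminator="\n")
            pd.DataFrame(interval_rows).to_csv(
                out / "hmm_state_intervals.csv", index=False, lineterminator="\n"
            )
            report["stages"]["hmm"] = {
                "n_sessions_fit": len(rows),
                "selected_states": [r["n_states"] for r in rows],
                "elapsed_s": round(time.perf_counter() - t0, 3),
            }
            report["checks"]["hmm_sessions_fit"] = bool(rows)
        except Exception as e:  # noqa: BLE001
            report["failures"].append({"stage": "hmm", "error": str(e)})
            log.exception("hmm stage failed")

    report["all_checks_pass"] = bool(report["checks"]) and all(
        report["checks"].values()
    )
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")
    return report
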