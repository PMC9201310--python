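"""Generate -> estimate -> diagnose -> report, as one reproducible run.

A pipeline run takes either an existing trial log or a generator config,
groups sessions into conditions (by reinforcement probability, ITI and
time-out by default), and for each condition writes the pooled count /
probability / expected matrices (CSV, start states as rows, end states as
columns, canonical order), the order diagnostics (JSON), per-session
summaries (CSV), a flat diagnostics table for plotting, and a manifest.
Identical config + seed give byte-identical output (no timestamps).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .diagnostics import (
    SplitHalfReport,
    TestResult,
    chi2_into_state,
    split_half_homogeneity,
    w_statistic,
    y_deviation,
)
from .estimation import count_transitions, estimate_first_order, estimate_zeroth_order
from .io import read_trial_log, write_trial_log
from .metrics import summarize_session
from .outcomes import OUTCOME_LABELS, Outcome, parse_outcome
from .sessions import Session, SessionMeta
from .simulate import (
    BehaviorPolicy,
    independence_policy,
    premature_carryover_policy,
    simulate_cohort,
)

log = logging.getLogger("trialchain.pipeline")


@dataclass(frozen=True)
class PipelineConfig:
    """Fully specifies one pipeline run.

    Exactly one of ``input_path`` (a trial log) or ``generator`` (a config
    mapping for :func:`build_cohort`) must be set.
    """

    output_dir: str
    input_path: Optional[str] = None
    generator: Optional[Mapping[str, Any]] = None
    group_keys: tuple[str, ...] = ("p_reward", "iti_s", "timeout_s")
    alpha: float = 0.05
    target: Outcome = Outcome.PREMATURE
    seed: int = 0
    per_subject: bool = False

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.generator is None):
            raise ValueError("exactly one of input_path / generator must be set")
        bad = [k for k in self.group_keys if k not in ("p_reward", "iti_s", "timeout_s", "subject_id")]
        if bad:
            raise ValueError(f"unknown group keys {bad}")

    @classmethod
    def from_file(cls, path: str | Path, **overrides: Any) -> "PipelineConfig":
        """Load a YAML/JSON config file; keyword overrides win."""
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        if "target" in raw:
            raw["target"] = parse_outcome(raw["target"])
        if "group_keys" in raw:
            raw["group_keys"] = tuple(raw["group_keys"])
        return cls(**raw)


def build_policy(cfg: Mapping[str, Any]) -> BehaviorPolicy:
    """Build a behaviour policy from a config mapping.

    ``kind: independence`` takes an optional ``action_probs`` vector
    (correct, incorrect, omission, premature).  ``kind: first_order`` takes
    either an explicit 5x4 ``conditional_probs`` matrix (rows in canonical
    outcome order) or ``premature_excess`` / ``nr_excess`` boosts applied to
    ``action_probs``.
    """
    kind = cfg.get("kind", "independence")
    if kind == "independence":
        probs = cfg.get("action_probs")
        return independence_policy(probs) if probs is not None else independence_policy()
    if kind == "first_order":
        if "conditional_probs" in cfg:
            return BehaviorPolicy(
                kind="first_order",
                conditional_probs=np.asarray(cfg["conditional_probs"], float),
                initial_action_probs=cfg.get("initial_action_probs"),
            )
        from .simulate import DEFAULT_ACTION_PROBS

        return premature_carryover_policy(
            base_action_probs=cfg.get("action_probs", DEFAULT_ACTION_PROBS),
            excess=float(cfg.get("premature_excess", 0.25)),
            nr_excess=float(cfg.get("nr_excess", 0.0)),
        )
    raise ValueError(f"unknown policy kind {kind!r}")


def build_cohort(generator: Mapping[str, Any], seed: int) -> list[Session]:
    """Simulate a cohort from a generator config mapping.

    Keys: ``n_subjects``, ``between_subject_sd``, ``block_size``, ``policy``
    (see :func:`build_policy`) and ``conditions`` — a list of mappings with
    ``p_reward``, ``iti_s``, ``timeout_s`` and optional ``n_trials``
    (default 100) and ``session_id``.
    """
    policy = build_policy(generator.get("policy", {}))
    metas = []
    for m, cond in enumerate(generator["conditions"]):
        metas.append(
            SessionMeta(
                subject_id="TBD",
                session_id=cond.get("session_id", f"cond{m:02d}"),
                p_reward=float(cond["p_reward"]),
                iti_s=float(cond.get("iti_s", 5.0)),
                timeout_s=float(cond.get("timeout_s", 5.0)),
                max_trials=int(cond.get("n_trials", 100)),
            )
        )
    return simulate_cohort(
        n_subjects=int(generator.get("n_subjects", 24)),
        base_policy=policy,
        between_subject_sd=float(generator.get("between_subject_sd", 0.0)),
        metas=metas,
        master_seed=seed,
        block_size=int(generator.get("block_size", 20)),
    )


def _matrix_frame(mat: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame(mat, index=list(OUTCOME_LABELS), columns=list(OUTCOME_LABELS))


def _result_dict(r: TestResult) -> dict[str, Any]:
    return dataclasses.asdict(r)


def _split_half_dict(rep: SplitHalfReport) -> dict[str, Any]:
    return {
        "max_abs_diff_into_target": rep.max_abs_diff_into_target,
        "degenerate": rep.degenerate,
        "first_half_test": _result_dict(rep.first_half[1]),
        "second_half_test": _result_dict(rep.second_half[1]),
    }


def analyze_condition(
    sessions: Sequence[Session], alpha: float = 0.05, target: Outcome = Outcome.PREMATURE
) -> dict[str, Any]:
    """Pooled first-order/independence fits and diagnostics for one condition."""
    counts = count_transitions(sessions, pool=True)
    tm = estimate_first_order(counts)
    fit = estimate_zeroth_order(counts)
    w = w_statistic(counts, fit, alpha)
    chi2 = chi2_into_state(counts, fit, target, alpha)
    profile = y_deviation(counts, fit, target)
    split = split_half_homogeneity(sessions, target, alpha)
    summaries = [summarize_session(s) for s in sessions]
    return {
        "counts": counts,
        "transition_matrix": tm,
        "independence_fit": fit,
        "w": w,
        "chi2_target": chi2,
        "y": profile,
        "split_half": split,
        "summaries": summaries,
    }


def _condition_label(key: tuple) -> str:
    return "_".join(str(k).replace(".", "p") for k in key) or "all"


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute one run; returns the report bundle and writes it to disk."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.generator is not None:
        sessions = build_cohort(config.generator, config.seed)
        write_trial_log(sessions, outdir / "simulated_trials.csv")
        log.info("simulated %d sessions", len(sessions))
    else:
        sessions = read_trial_log(config.input_path)
        log.info("read %d sessions from %s", len(sessions), config.input_path)

    keys = list(config.group_keys)
    if config.per_subject and "subject_id" not in keys:
        keys.append("subject_id")

    groups: dict[tuple, list[Session]] = {}
    for s in sessions:
        key = tuple(getattr(s.meta, k) for k in keys)
        groups.setdefault(key, []).append(s)

    report: dict[str, Any] = {}
    flat_rows = []
    for key in sorted(groups, key=str):
        members = groups[key]
        label = _condition_label(key)
        if not members:  # pragma: no cover - defensive
            log.warning("condition %s empty; skipped", label)
            continue
        res = analyze_condition(members, alpha=config.alpha, target=config.target)
        report[label] = res

        cdir = outdir / label
        cdir.mkdir(exist_ok=True)
        _matrix_frame(res["counts"].counts).to_csv(cdir / "counts.csv")
        _matrix_frame(res["transition_matrix"].probs).to_csv(cdir / "transition_probs.csv")
        _matrix_frame(res["independence_fit"].expected).to_csv(cdir / "expected.csv")
        diag = {
            "condition": dict(zip(keys, [_json_safe(v) for v in key])),
            "n_sessions": len(members),
            "n_transitions": int(res["counts"].n_transitions),
            "W": _result_dict(res["w"]),
            "chi2_target": _result_dict(res["chi2_target"]),
            "target_state": res["y"].target_state.value,
            "Y": {
                lab: (None if not d else float(v))
                for lab, v, d in zip(OUTCOME_LABELS, res["y"].y, res["y"].defined)
            },
            "split_half": _split_half_dict(res["split_half"]),
        }
        (cdir / "diagnostics.json").write_text(json.dumps(diag, indent=2))
        pd.DataFrame(
            [
                {
                    "subject": sm.subject_id,
                    "session": sm.session_id,
                    **dict(zip(OUTCOME_LABELS, sm.counts)),
                    "n_trials": sm.n_trials,
                    "mean_correct_latency_ms": sm.mean_correct_latency_ms,
                }
                for sm in res["summaries"]
            ]
        ).to_csv(cdir / "summaries.csv", index=False)

        flat_rows.append(
            {
                "condition": label,
                "n_sessions": len(members),
                "n_transitions": int(res["counts"].n_transitions),
                "W": res["w"].statistic,
                "W_reject": res["w"].reject,
                "chi2_target": res["chi2_target"].statistic,
                "chi2_reject": res["chi2_target"].reject,
                **{
                    f"Y_{lab}": (float(v) if d else np.nan)
                    for lab, v, d in zip(OUTCOME_LABELS, res["y"].y, res["y"].defined)
                },
                "split_half_max_abs_diff": res["split_half"].max_abs_diff_into_target,
            }
        )

    pd.DataFrame(flat_rows).to_csv(outdir / "diagnostics_flat.csv", index=False)
    manifest = {
        "package": "trialchain",
        "version": __version__,
        "seed": config.seed,
        "alpha": config.alpha,
        "target": config.target.value,
        "group_keys": keys,
        "input": config.input_path or "<generator>",
        "n_sessions": len(sessions),
        "conditions": [_condition_label(k) for k in sorted(groups, key=str)],
    }
    (outdir / "manifest.txt").write_text(
        "".join(f"{k}: {v}\n" for k, v in manifest.items())
    )
    return report


def _json_safe(v: Any) -> Any:
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    return v
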