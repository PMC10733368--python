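"""End-to-end workflow: simulate (or load) -> collapse -> fit single-cursor ->
predict held-out conditions -> derived statistics.

The workflow mirrors the validation logic of the study: model parameters are
identified ONLY from the single-cursor (or sigma = 0) conditions; every
multi-cursor and cursor-cloud condition is strictly held out and predicted
with the fitted parameters, so prediction R^2 is a genuine out-of-condition
test (and may be negative).
"""

from __future__ import annotations

import json
import platform
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator

from .conditions import CloudSpec, ErrorSet
from .dn import DNParams, analytic_single, nonlinearity_index, peak_error
from .mle import MLEParams, ordinary_mle_decline_ratio
from .fitting import FitResult, fit_dn_single, fit_mle_single, predict_conditions, r_squared
from .schedules import (
    PerturbationSchedule,
    build_exp1_schedule,
    build_exp23_schedule,
    condition_id,
)
from .simulate import collapse_symmetric, condition_means, simulate_responses
from . import stats as _stats

__all__ = ["AnalysisConfig", "SyntheticConfig", "run", "default_true_params"]

# Ground-truth DN parameter sets for the synthetic generator: the published
# single-cursor fit for each experiment and response type (w, k); s = 22 deg.
REFERENCE_DN_FITS: dict[tuple[str, str], tuple[float, float]] = {
    ("exp1", "learning"): (5.3271e-4, 7.7806e-7),
    ("exp1", "feedback"): (4.0541e-4, 9.2642e-5),
    ("exp2", "learning"): (2.0002e-4, 2.1434e-6),
    ("exp2", "feedback"): (2.3700e-4, 1.2071e-5),
    ("exp3", "learning"): (4.7525e-4, 2.1102e-6),
}

# Analysis sample sizes of the three experiments.
DEFAULT_N_PARTICIPANTS = {"exp1": 8, "exp2": 15, "exp3": 10}


def default_true_params(experiment: str, response_type: str, M: int = 3601, s: float = 22.0) -> DNParams:
    key = (experiment, response_type)
    if key not in REFERENCE_DN_FITS:
        raise KeyError(f"no reference parameter set for {key}")
    w, k = REFERENCE_DN_FITS[key]
    return DNParams(w=w, k=k, s=s, M=M)


class SyntheticConfig(BaseModel):
    """Ground-truth generator settings; ``None`` fields fall back to the
    experiment's reference values."""

    true_w: Optional[float] = None
    true_k: Optional[float] = None
    noise_sd: Optional[float] = None  # response units; default 15% of peak response
    noise_frac_of_peak: float = 0.15
    n_participants: Optional[int] = None


class AnalysisConfig(BaseModel):
    experiment: Literal["exp1", "exp2", "exp3"] = "exp1"
    response_type: Literal["learning", "feedback"] = "learning"
    model: Literal["dn", "mle", "both"] = "both"
    M: int = 3601
    s: float = Field(default=22.0, gt=0)
    n_draws: int = Field(default=20_000, ge=1)
    seed: int = 12345
    input_responses: Optional[str] = None  # ResponseTable CSV; None -> simulate
    out_dir: str = "results/run"
    synthetic: SyntheticConfig = SyntheticConfig()

    @field_validator("M")
    @classmethod
    def _odd_m(cls, v: int) -> int:
        if v < 3 or v % 2 == 0:
            raise ValueError("M must be an odd integer >= 3")
        return v


def _build_schedule(cfg: AnalysisConfig) -> PerturbationSchedule:
    if cfg.experiment == "exp1":
        return build_exp1_schedule()
    mode = "online" if cfg.experiment == "exp2" else "endpoint"
    return build_exp23_schedule(mode)


def _resolve_synthetic(cfg: AnalysisConfig) -> tuple[DNParams, float, int]:
    syn = cfg.synthetic
    if syn.true_w is not None and syn.true_k is not None:
        true = DNParams(w=syn.true_w, k=syn.true_k, s=cfg.s, M=cfg.M)
    else:
        true = default_true_params(cfg.experiment, cfg.response_type, cfg.M, cfg.s)
    if syn.noise_sd is not None:
        noise = syn.noise_sd
    else:
        peak = abs(analytic_single(peak_error(true), true))
        noise = syn.noise_frac_of_peak * peak
    n_part = syn.n_participants or DEFAULT_N_PARTICIPANTS[cfg.experiment]
    return true, noise, n_part


def _collapsed_conditions(schedule: PerturbationSchedule) -> list[tuple[str, ErrorSet | CloudSpec]]:
    """(rep_id, perturbation) for each collapse representative, in id order."""
    reps = {}
    rep_of = schedule.mirror_pairs()
    for cond in schedule.conditions:
        if rep_of[cond.condition_id] == cond.condition_id:
            reps[cond.condition_id] = cond.perturbation
    return sorted(reps.items())


def _single_cursor_points(
    means: pd.Series, conds: list[tuple[str, ErrorSet | CloudSpec]]
) -> list[tuple[float, float]]:
    """(error, response) pairs for the fit: collapsed single-cursor conditions
    (ErrorSets of one cursor) or sigma = 0 clouds."""
    pts = []
    for cid, p in conds:
        if isinstance(p, ErrorSet) and p.n_cursors == 1:
            pts.append((p.errors[0], float(means[cid])))
        elif isinstance(p, CloudSpec) and p.sigma == 0.0:
            pts.append((p.mu, float(means[cid])))
    return sorted(pts)


def _held_out_ids(conds: list[tuple[str, ErrorSet | CloudSpec]]) -> list[str]:
    out = []
    for cid, p in conds:
        if isinstance(p, ErrorSet) and p.n_cursors > 1:
            out.append(cid)
        elif isinstance(p, CloudSpec) and p.sigma > 0:
            out.append(cid)
    return out


def _derived_stats(
    cfg: AnalysisConfig,
    conds: list[tuple[str, ErrorSet | CloudSpec]],
    predictions: dict[str, dict[str, float]],
    data_means: pd.Series,
) -> dict:
    stats: dict = {}
    if cfg.experiment == "exp1":
        stats["averaged_response_by_e2"] = {}
        for model, pred in predictions.items():
            stats["averaged_response_by_e2"][model] = {
                str(k): v for k, v in _stats.averaged_response(pred).items()
            }
        try:
            stats["averaged_response_by_e2"]["data"] = {
                str(k): v for k, v in _stats.averaged_response(dict(data_means)).items()
            }
        except KeyError:
            pass
    else:
        mus = (14.0, 40.0)
        stats["declining_rate"] = {}
        stats["decline_ratio_small_over_large"] = {}
        stats["decline_ratio_large_over_small"] = {}
        sources = dict(predictions)
        sources["data"] = dict(data_means)
        for label, values in sources.items():
            rates = {}
            ok = True
            for mu in mus:
                by_sigma = {}
                for sigma in (0.0, 7.0, 20.0):
                    cid = condition_id(CloudSpec(mu=mu, sigma=sigma, n_cursors=5))
                    if cid not in values:
                        ok = False
                        break
                    by_sigma[sigma] = values[cid]
                if not ok:
                    break
                rates[mu] = _stats.declining_rate(by_sigma)
            if not ok:
                continue
            ratio = _stats.decline_ratio(rates[mus[0]], rates[mus[1]])
            stats["declining_rate"][label] = {
                str(mu): {str(s): r for s, r in rmap.items()} for mu, rmap in rates.items()
            }
            stats["decline_ratio_small_over_large"][label] = {str(s): r for s, r in ratio.items()}
            stats["decline_ratio_large_over_small"][label] = {
                str(s): (1.0 / r if r != 0 else float("inf")) for s, r in ratio.items()
            }
        # the ordinary-MLE foil: constant observation noise pins the ratio at 1
        foil = ordinary_mle_decline_ratio(
            14.0, 40.0, (7.0, 20.0), MLEParams(c=1.0, ratio_sv=1.0, constant_sigma_mode=True)
        )
        stats["decline_ratio_small_over_large"]["ordinary_mle"] = {
            str(s): r for s, r in foil.items()
        }
    return stats


def run(cfg: AnalysisConfig) -> dict:
    """Execute the configured workflow and write the result bundle to
    ``cfg.out_dir``; returns the bundle as a dict."""
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    schedule = _build_schedule(cfg)
    schedule.to_frame().to_csv(out_dir / "schedule.csv", index=False)

    if cfg.input_responses is not None:
        table = pd.read_csv(cfg.input_responses)
        generator_info: dict = {"source": cfg.input_responses}
    else:
        true, noise_sd, n_part = _resolve_synthetic(cfg)
        table = simulate_responses(
            schedule, true, noise_sd, n_part, cfg.seed, cfg.response_type
        )
        generator_info = {
            "source": "synthetic",
            "true_w": true.w,
            "true_k": true.k,
            "noise_sd": noise_sd,
            "n_participants": n_part,
        }
    table.to_csv(out_dir / "responses.csv", index=False)

    collapsed = collapse_symmetric(table, schedule)
    collapsed.to_csv(out_dir / "responses_collapsed.csv", index=False)
    means_df = condition_means(collapsed)
    means = means_df.set_index("condition_id")["response"]

    conds = _collapsed_conditions(schedule)
    points = _single_cursor_points(means, conds)

    fits: dict[str, FitResult] = {}
    if cfg.model in ("dn", "both"):
        fits["dn"] = fit_dn_single(points, s=cfg.s, M=cfg.M)
    if cfg.model in ("mle", "both"):
        fits["mle"] = fit_mle_single(points)

    cond_objects = [p for _, p in conds]
    cond_ids = [cid for cid, _ in conds]
    held_out = _held_out_ids(conds)
    predictions: dict[str, dict[str, float]] = {}
    pred_rows = []
    for model, fit in fits.items():
        pred = predict_conditions(fit.params, cond_objects, n_draws=cfg.n_draws, seed=cfg.seed)
        predictions[model] = dict(zip(cond_ids, pred.tolist()))
        for cid, val in predictions[model].items():
            pred_rows.append((model, cid, val, float(means[cid])))
    pred_df = pd.DataFrame(pred_rows, columns=["model", "condition_id", "predicted", "observed"])
    pred_df.to_csv(out_dir / "predictions.csv", index=False)

    scores: dict[str, dict[str, float]] = {}
    for model, fit in fits.items():
        sc = {"r2_fit": fit.r_squared}
        obs = [float(means[cid]) for cid in held_out]
        pred = [predictions[model][cid] for cid in held_out]
        if len(obs) >= 2:
            sc["r2_prediction_held_out"] = r_squared(obs, pred)
        if cfg.experiment == "exp1":
            dbl = [cid for cid in held_out if cid.startswith("double")]
            sc["r2_prediction_double"] = r_squared(
                [float(means[c]) for c in dbl], [predictions[model][c] for c in dbl]
            )
        if model == "dn":
            p = fit.params
            sc["nonlinearity_index"] = nonlinearity_index(p.w, p.k)
        scores[model] = sc

    derived = _derived_stats(cfg, conds, predictions, means)

    for model, fit in fits.items():
        (out_dir / f"fit_{model}.json").write_text(json.dumps(fit.to_dict(), indent=2))
    (out_dir / "derived_stats.json").write_text(json.dumps(derived, indent=2))
    log = {
        "config": json.loads(cfg.model_dump_json()),
        "generator": generator_info,
        "seed": cfg.seed,
        "n_draws": cfg.n_draws,
        "scores": scores,
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    (out_dir / "run_log.json").write_text(json.dumps(log, indent=2))
    return {
        "schedule": schedule,
        "responses": table,
        "collapsed": collapsed,
        "means": means,
        "fits": fits,
        "predictions": predictions,
        "scores": scores,
        "derived_stats": derived,
    }
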