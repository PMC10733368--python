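"""Nonlinear least-squares fitting of the single-cursor models, and
out-of-condition prediction.

Both models are fit to condition-mean responses (response vs error size) by
bounded least squares in log10 parameter space with multi-start over a
log-spaced grid — the parameters span several orders of magnitude and a single
start is unreliable.  Goodness of fit is the ordinary coefficient of
determination R^2 = 1 - SS_res / SS_tot (SS_tot about the observed mean);
prediction R^2 is computed without refitting, so it can be negative when a
model's out-of-condition predictions are worse than the observed mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .conditions import CloudSpec, ErrorSet
from . import dn as _dn
from . import mle as _mle
from .dn import DNParams, analytic_single
from .mle import MLEParams, mle_multi, mle_single

__all__ = [
    "FitResult",
    "fit_dn_single",
    "fit_mle_single",
    "r_squared",
    "predict_conditions",
]

_FTOL = 1e-12
_MAX_NFEV = 10_000


@dataclass
class FitResult:
    """Outcome of a single-cursor model fit."""

    model_tag: str  # "DN", "MLE", or "DN-no-norm"
    params: DNParams | MLEParams
    r_squared: float
    residuals: np.ndarray
    loss: float
    n_restarts_used: int
    converged: bool
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        if isinstance(self.params, DNParams):
            p = {"w": self.params.w, "k": self.params.k, "s": self.params.s, "M": self.params.M}
        else:
            p = {
                "c": self.params.c,
                "ratio_sv": self.params.ratio_sv,
                "ratio_kv": self.params.ratio_kv,
                "constant_sigma_mode": self.params.constant_sigma_mode,
            }
        return {
            "model_tag": self.model_tag,
            "params": p,
            "r_squared": self.r_squared,
            "loss": self.loss,
            "n_restarts_used": self.n_restarts_used,
            "converged": self.converged,
            "residuals": [float(r) for r in self.residuals],
        }

    @staticmethod
    def from_dict(d: dict) -> "FitResult":
        p = d["params"]
        if d["model_tag"].startswith("DN"):
            params: DNParams | MLEParams = DNParams(w=p["w"], k=p["k"], s=p["s"], M=p["M"])
        else:
            params = MLEParams(
                c=p["c"],
                ratio_sv=p["ratio_sv"],
                ratio_kv=p["ratio_kv"],
                constant_sigma_mode=p.get("constant_sigma_mode", False),
            )
        return FitResult(
            model_tag=d["model_tag"],
            params=params,
            r_squared=d["r_squared"],
            residuals=np.asarray(d["residuals"], dtype=float),
            loss=d["loss"],
            n_restarts_used=d["n_restarts_used"],
            converged=d["converged"],
        )


def r_squared(observed: Sequence[float], predicted: Sequence[float]) -> float:
    """Coefficient of determination, 1 - SS_res / SS_tot (SS_tot about the mean).

    Unbounded below: negative values mean the prediction is worse than the
    observed mean.  Raises if the observations carry no variance.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.size < 2:
        raise ValueError("observed and predicted must be equal-length vectors of size >= 2")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("observed values are all equal; R^2 undefined")
    ss_res = float(np.sum((obs - pred) ** 2))
    return 1.0 - ss_res / ss_tot


def _check_points(points) -> tuple[np.ndarray, np.ndarray]:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be a sequence of (error, response) pairs")
    e, y = pts[:, 0], pts[:, 1]
    if len(set(np.abs(e[e != 0]))) < 2:
        raise ValueError("need responses at >= 2 distinct non-zero error magnitudes")
    if np.all(y == 0):
        raise ValueError("all responses are zero; fit is degenerate")
    return e, y


def _multistart(residual_fn, starts, bounds):
    """Best-of-restarts bounded least squares over log10 parameters."""
    best = None
    n_used = 0
    for x0 in starts:
        n_used += 1
        try:
            sol = least_squares(
                residual_fn,
                x0,
                bounds=bounds,
                method="trf",
                ftol=_FTOL,
                xtol=_FTOL,
                gtol=_FTOL,
                max_nfev=_MAX_NFEV,
            )
        except Exception:  # a bad start must not sink the fit
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("all restarts failed")
    return best, n_used


def fit_dn_single(
    points,
    s: float = 22.0,
    M: int = 3601,
    n_grid: int = 5,
    starts=None,
) -> FitResult:
    """Fit the closed-form single-cursor DN response to (error, response) pairs.

    Minimizes squared error over (w, k), both positive, with the tuning width
    s fixed (22 deg) and M fixed.  Multi-start over a log-spaced grid
    w in [1e-5, 1e-2] x k in [1e-8, 1e-4] (n_grid x n_grid starts).
    """
    e, y = _check_points(points)

    def resid(x):
        p = DNParams(w=10.0 ** x[0], k=10.0 ** x[1], s=s, M=M)
        return analytic_single(e, p) - y

    if starts is None:
        w_grid = np.linspace(-5.0, -2.0, n_grid)
        k_grid = np.linspace(-8.0, -4.0, n_grid)
        starts = [(lw, lk) for lw in w_grid for lk in k_grid]
    best, n_used = _multistart(resid, starts, bounds=([-10.0, -12.0], [0.0, 0.0]))
    params = DNParams(w=10.0 ** best.x[0], k=10.0 ** best.x[1], s=s, M=M)
    res = analytic_single(e, params) - y
    return FitResult(
        model_tag="DN",
        params=params,
        r_squared=r_squared(y, y + res) if np.any(y != y.mean()) else float("nan"),
        residuals=res,
        loss=float(np.sum(res**2)),
        n_restarts_used=n_used,
        converged=bool(best.status > 0),
    )


def fit_mle_single(points, n_grid: int = 3, starts=None) -> FitResult:
    """Fit the single-cursor MLE response (signal-dependent noise) to data.

    Minimizes squared error over (c, sigma_v/sigma_p, k_v/sigma_p), all
    positive, multi-start over c in [1e3, 1e7] x sv in [10, 1e3] x
    kv in [0.1, 1e2] (log-spaced, n_grid each).
    """
    e, y = _check_points(points)

    def resid(x):
        p = MLEParams(c=10.0 ** x[0], ratio_sv=10.0 ** x[1], ratio_kv=10.0 ** x[2])
        return mle_single(e, p) - y

    if starts is None:
        c_grid = np.linspace(3.0, 7.0, n_grid)
        sv_grid = np.linspace(1.0, 3.0, n_grid)
        kv_grid = np.linspace(-1.0, 2.0, n_grid)
        starts = [(lc, lsv, lkv) for lc in c_grid for lsv in sv_grid for lkv in kv_grid]
    best, n_used = _multistart(
        resid, starts, bounds=([-2.0, -2.0, -12.0], [12.0, 6.0, 4.0])
    )
    params = MLEParams(
        c=10.0 ** best.x[0], ratio_sv=10.0 ** best.x[1], ratio_kv=10.0 ** best.x[2]
    )
    res = np.asarray(mle_single(e, params)) - y
    return FitResult(
        model_tag="MLE",
        params=params,
        r_squared=r_squared(y, y + res),
        residuals=res,
        loss=float(np.sum(res**2)),
        n_restarts_used=n_used,
        converged=bool(best.status > 0),
    )


def predict_conditions(
    params: DNParams | MLEParams,
    conditions: Sequence[ErrorSet | CloudSpec],
    n_draws: int = _dn.DEFAULT_N_DRAWS,
    seed: int = _dn.DEFAULT_SEED,
) -> np.ndarray:
    """Predicted responses for a list of conditions under fitted parameters.

    ErrorSets are evaluated exactly; CloudSpecs by the Monte-Carlo expectation
    (deterministic given ``seed``; each condition draws independently from its
    own seeded stream).
    """
    out = np.empty(len(conditions))
    for i, cond in enumerate(conditions):
        if isinstance(cond, ErrorSet):
            if isinstance(params, DNParams):
                out[i] = _dn.dn_response(cond, params)
            else:
                out[i] = mle_multi(cond, params)
        elif isinstance(cond, CloudSpec):
            rng = np.random.default_rng([seed, i])
            if isinstance(params, DNParams):
                out[i] = _dn.expected_cloud_response(cond, params, n_draws, rng=rng)[0]
            else:
                out[i] = _mle.expected_cloud_response(cond, params, n_draws, rng=rng)[0]
        else:
            raise TypeError(f"unsupported condition type: {type(cond)!r}")
    return out
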