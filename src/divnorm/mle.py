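"""Maximum-likelihood-estimation (MLE) cue-combination model of the learning
response, with signal-dependent observation noise.

The learner combines the visually observed error (variance sigma(e)^2, with
sigma(e) = sigma_v + k_v |e| growing linearly with error size) with the
motor-prediction prior (mean 0, variance sigma_p^2) and responds proportionally
to the posterior-mean error estimate:

    x(e) = c * sigma_p^2 / (sigma_p^2 + sigma(e)^2) * e            (single cursor)
    x(e) = c * (1/sigma_p^2 + sum_i 1/sigma(e_i)^2)^-1 * sum_i e_i/sigma(e_i)^2

Only the ratios sigma_v/sigma_p and k_v/sigma_p (and the gain c) are
identifiable, so parameters are stored as those ratios.  Setting k_v = 0
("ordinary MLE", constant observation noise) makes the single-cursor response
exactly linear in e.

A key qualitative contrast with the divisive-normalization model: duplicating
a cursor strictly increases the MLE response (extra independent evidence)
whereas it leaves the DN response unchanged (max operation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .conditions import CloudSpec, ErrorSet

__all__ = [
    "MLEParams",
    "sd_ratio",
    "mle_single",
    "mle_multi",
    "expected_cloud_response",
    "ordinary_mle_cloud_response",
    "ordinary_mle_decline_ratio",
]


@dataclass(frozen=True)
class MLEParams:
    """Identifiable MLE parameters.

    c : positive response gain (response units per degree).
    ratio_sv : sigma_v / sigma_p, dimensionless baseline observation noise.
    ratio_kv : k_v / sigma_p, per-degree slope of the signal-dependent noise.
    constant_sigma_mode : if True, the "ordinary MLE" variant; ratio_kv must
        be 0 (observation noise independent of error size).
    """

    c: float
    ratio_sv: float
    ratio_kv: float = 0.0
    constant_sigma_mode: bool = False

    def __post_init__(self) -> None:
        if self.c <= 0:
            raise ValueError("gain c must be positive")
        if not (np.isfinite(self.ratio_sv) and self.ratio_sv >= 0):
            raise ValueError("ratio_sv must be finite and >= 0")
        if not (np.isfinite(self.ratio_kv) and self.ratio_kv >= 0):
            raise ValueError("ratio_kv must be finite and >= 0")
        if self.constant_sigma_mode and self.ratio_kv != 0.0:
            raise ValueError("constant_sigma_mode requires ratio_kv = 0")

    @classmethod
    def from_absolute(
        cls,
        c: float,
        sigma_p: float,
        sigma_v: float,
        k_v: float = 0.0,
        constant_sigma_mode: bool = False,
    ) -> "MLEParams":
        """Construct from absolute noise SDs; normalizes to ratios immediately."""
        if sigma_p <= 0:
            raise ValueError("sigma_p must be positive")
        return cls(c, sigma_v / sigma_p, k_v / sigma_p, constant_sigma_mode)

    def as_ordinary(self) -> "MLEParams":
        return replace(self, ratio_kv=0.0, constant_sigma_mode=True)


def sd_ratio(e: float | np.ndarray, params: MLEParams) -> float | np.ndarray:
    """sigma(e)/sigma_p = sigma_v/sigma_p + (k_v/sigma_p) |e|; even in e."""
    out = params.ratio_sv + params.ratio_kv * np.abs(np.asarray(e, dtype=float))
    return float(out) if out.ndim == 0 else out


def mle_single(e: float | np.ndarray, params: MLEParams) -> float | np.ndarray:
    """Single-cursor MLE response x = c e / (1 + (sigma(e)/sigma_p)^2); odd in e."""
    e = np.asarray(e, dtype=float)
    r = sd_ratio(e, params)
    out = params.c * e / (1.0 + np.square(r))
    return float(out) if np.ndim(out) == 0 else out


def mle_multi(error_set: ErrorSet | np.ndarray, params: MLEParams) -> float:
    """Multi-cursor MLE response (precision-weighted combination of cursors).

    With weights w_i = 1 / (sigma(e_i)/sigma_p)^2:
    x = c (1 + sum_i w_i)^-1 sum_i w_i e_i.  Reduces to :func:`mle_single`
    for a single cursor; every duplicated cursor adds precision.
    """
    if isinstance(error_set, ErrorSet):
        e = error_set.as_array()
    else:
        e = np.atleast_1d(np.asarray(error_set, dtype=float))
        if e.size == 0:
            raise ValueError("empty error set")
    w = 1.0 / np.square(sd_ratio(e, params))
    return float(params.c * (w * e).sum() / (1.0 + w.sum()))


def expected_cloud_response(
    spec: CloudSpec,
    params: MLEParams,
    n_draws: int = 100_000,
    seed: int = 20231220,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Monte-Carlo expected multi-cursor MLE response to a cursor cloud.

    Applies the precision-weighted combination to each drawn cloud; same
    sampling scheme (draw count, seeding) as the DN cloud expectation so the
    two models see identical study conditions.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    if spec.sigma == 0.0:
        return mle_multi(np.full(spec.n_cursors, spec.mu), params), 0.0
    if rng is None:
        rng = np.random.default_rng(seed)
    e = spec.draw(rng, size=n_draws)  # (n_draws, n_cursors)
    w = 1.0 / np.square(params.ratio_sv + params.ratio_kv * np.abs(e))
    vals = params.c * (w * e).sum(axis=1) / (1.0 + w.sum(axis=1))
    mean = float(vals.mean())
    se = float(vals.std(ddof=1) / math.sqrt(n_draws)) if n_draws > 1 else 0.0
    return mean, se


def ordinary_mle_cloud_response(
    mu: float,
    sigma: float,
    params: MLEParams,
    sigma_p: float = 1.0,
) -> float:
    """Expected ordinary-MLE (constant-noise) response to a cursor cloud.

    Under the conventional cue-combination account, feedback uncertainty adds
    to the observed-error variance: sigma_obs^2 = sigma_v^2 + sigma_cloud^2,
    so the response is c * mu / (1 + ratio_sv^2 + (sigma/sigma_p)^2).  The
    shrinkage factor depends on sigma but not on mu.  ``sigma_p`` (degrees)
    sets the scale at which cloud dispersion loads on the unidentifiable
    prior SD; declining-rate *ratios* across mu are invariant to it.
    """
    if not params.constant_sigma_mode and params.ratio_kv != 0.0:
        raise ValueError("ordinary-MLE cloud response requires constant-sigma parameters")
    if sigma_p <= 0:
        raise ValueError("sigma_p must be positive")
    shrink = 1.0 / (1.0 + params.ratio_sv**2 + (sigma / sigma_p) ** 2)
    return params.c * shrink * mu


def ordinary_mle_decline_ratio(
    mu_small: float,
    mu_large: float,
    sigma_grid,
    params: MLEParams,
    sigma_p: float = 1.0,
) -> dict[float, float]:
    """Ratio of declining rates (mu_small vs mu_large) under the ordinary MLE.

    For each sigma in ``sigma_grid``, the declining rate of the expected
    response relative to sigma = 0 is computed at both mean error sizes and
    their ratio returned.  Because the shrinkage factor is independent of mu,
    the rates at the two means are identical and the ratio is analytically 1
    for every sigma — the model predicts no relative suppression of the
    decline at large errors, regardless of feedback uncertainty.
    """
    out: dict[float, float] = {}
    for mu in (mu_small, mu_large):
        if ordinary_mle_cloud_response(mu, 0.0, params, sigma_p) == 0.0:
            raise ZeroDivisionError(
                f"sigma = 0 response at mu = {mu} is zero; declining rate undefined"
            )
    for sigma in sigma_grid:
        rates = []
        for mu in (mu_small, mu_large):
            r0 = ordinary_mle_cloud_response(mu, 0.0, params, sigma_p)
            rs = ordinary_mle_cloud_response(mu, float(sigma), params, sigma_p)
            rates.append((r0 - rs) / r0)
        if rates[1] == 0.0:
            raise ZeroDivisionError(f"declining rate at mu = {mu_large} is zero for sigma = {sigma}")
        out[float(sigma)] = rates[0] / rates[1]
    return out
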