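"""Divisive-normalization (DN) population model of single-trial motor learning.

A bank of M direction-tuned units encodes the visual error(s).  Each unit's
Gaussian tuning is driven by the cursor nearest its preferred direction (a max
operation over cursors), its output is w * phi_j * f_j, and the population is
integrated with divisive normalization:

    X(e) = sum_j x_j(e) / (k M + sum_j x_j(e)^2)

For a single cursor the sums have closed forms (Gaussian integrals over the
preferred-direction grid), giving

    X(e) = 2 sqrt(2 pi) w s e / (720 k + sqrt(pi) w^2 s (s^2 + 2 e^2))

and, with normalization absent, the linear law X(e) = sqrt(2 pi) w s e / (360 k).
The ratio w^2 / k indexes the strength of the nonlinearity.

All angles are degrees; responses are in arbitrary force-impulse units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .conditions import CloudSpec, ErrorSet
from .population import NeuralPopulation, make_population

__all__ = [
    "DNParams",
    "tuning",
    "dn_response",
    "linear_response_single",
    "analytic_single",
    "nonlinearity_index",
    "peak_error",
    "expected_cloud_response",
]

#: Monte-Carlo defaults for cursor-cloud expectations.
DEFAULT_N_DRAWS = 100_000
DEFAULT_SEED = 20231220


@dataclass(frozen=True)
class DNParams:
    """Parameters of the DN model.

    w : positive integration gain (response units per degree of weighted
        tuning output).
    k : positive normalization constant.
    s : Gaussian tuning width, degrees (22 deg throughout this work).
    M : number of units; odd and >= 3 so 0 deg is a preferred direction.
    """

    w: float
    k: float
    s: float = 22.0
    M: int = 3601

    def __post_init__(self) -> None:
        if self.w <= 0:
            raise ValueError("gain w must be positive")
        if self.k <= 0:
            raise ValueError("normalization constant k must be positive")
        if self.s <= 0:
            raise ValueError("tuning width s must be positive")
        if self.M < 3 or self.M % 2 == 0:
            raise ValueError("M must be an odd integer >= 3")

    def population(self) -> NeuralPopulation:
        return make_population(self.M, self.s)


def tuning(error_set: ErrorSet, pop: NeuralPopulation) -> np.ndarray:
    """Gaussian tuning gains f_j in (0, 1] under the max-over-cursors rule.

    f_j = max_i exp(-(e_i - phi_j)^2 / (2 s^2)), evaluated as a plain (not
    circular) Gaussian in degrees.
    """
    e = error_set.as_array()
    phi = pop.preferred_directions
    d = e[:, None] - phi[None, :]
    f = np.exp(-(d * d) / (2.0 * pop.tuning_width_s**2))
    return f.max(axis=0)


def _paired_sums(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """sum_j x_j and sum_j x_j^2 along the last axis, pairing unit j with its
    mirror M-1-j before summing.

    Pairing makes the population sum an exactly odd function of the error set
    in floating point (negating all errors reverses and negates x; each pair
    term then negates exactly), so X(0) = 0 and X(-e) = -X(e) hold exactly.
    """
    half = x.shape[-1] // 2
    lo = x[..., :half]
    hi = x[..., :half:-1]  # mirror partners: hi[i] = x[M-1-i]
    sx = (lo + hi).sum(axis=-1) + x[..., half]
    sx2 = (lo * lo + hi * hi).sum(axis=-1) + x[..., half] ** 2
    return sx, sx2


def _sums(errors: np.ndarray, params: DNParams, phi: np.ndarray) -> tuple[float, float]:
    """sum_j x_j and sum_j x_j^2 for one error set (errors: 1-D array)."""
    d = errors[:, None] - phi[None, :]
    f = np.exp(-(d * d) / (2.0 * params.s**2)).max(axis=0)
    x = params.w * phi * f
    sx, sx2 = _paired_sums(x)
    return float(sx), float(sx2)


def dn_response(
    error_set: ErrorSet | np.ndarray,
    params: DNParams,
    *,
    normalize: bool = True,
) -> float:
    """Learning (or feedback) response of the DN population to an error set.

    ``normalize=False`` drops the pooled-activity term from the denominator
    (the no-DN linear limit; the denominator is then k*M alone).
    """
    if isinstance(error_set, ErrorSet):
        errors = error_set.as_array()
    else:
        errors = np.atleast_1d(np.asarray(error_set, dtype=float))
        if errors.size == 0:
            raise ValueError("empty error set")
    phi = params.population().preferred_directions
    sx, sx2 = _sums(errors, params, phi)
    # k scales with the number of distinct preferred directions, M - 1 (the
    # inclusive grid's endpoints -180 and +180 are the same direction); this
    # keeps the response invariant to grid refinement and convergent to the
    # closed-form single-cursor solution.
    denom = params.k * (params.M - 1) + (sx2 if normalize else 0.0)
    return sx / denom


def linear_response_single(e: float, params: DNParams) -> float:
    """Closed-form single-cursor response without normalization (linear in e)."""
    return math.sqrt(2.0 * math.pi) * params.w * params.s * e / (360.0 * params.k)


def analytic_single(e: float | np.ndarray, params: DNParams) -> float | np.ndarray:
    """Closed-form single-cursor DN response.

    X(e) = 2 sqrt(2 pi) w s e / (720 k + sqrt(pi) w^2 s (s^2 + 2 e^2));
    odd in e, saturating, with an interior peak at :func:`peak_error`.
    """
    e = np.asarray(e, dtype=float)
    num = 2.0 * math.sqrt(2.0 * math.pi) * params.w * params.s * e
    den = 720.0 * params.k + math.sqrt(math.pi) * params.w**2 * params.s * (
        params.s**2 + 2.0 * e**2
    )
    out = num / den
    return float(out) if out.ndim == 0 else out


def nonlinearity_index(w: float, k: float) -> float:
    """Strength of the DN nonlinearity, w^2 / k.

    Larger values mean stronger saturation of the response with error size.
    """
    if k == 0:
        raise ValueError("k must be nonzero")
    return w * w / k


def peak_error(params: DNParams) -> float:
    """Error size at which the closed-form single-cursor response peaks.

    From dX/de = 0:  e* = sqrt((720 k + sqrt(pi) w^2 s^3) / (2 sqrt(pi) w^2 s)).
    """
    spi = math.sqrt(math.pi)
    return math.sqrt(
        (720.0 * params.k + spi * params.w**2 * params.s**3)
        / (2.0 * spi * params.w**2 * params.s)
    )


def dn_response_batch(error_sets: np.ndarray, params: DNParams, chunk: int = 512) -> np.ndarray:
    """DN responses for many error sets at once.

    ``error_sets`` has shape (n_sets, n_cursors); returns shape (n_sets,).
    Work is chunked so the (chunk, n_cursors, M) intermediate stays small.
    """
    error_sets = np.asarray(error_sets, dtype=float)
    phi = params.population().preferred_directions
    two_s2 = 2.0 * params.s**2
    kM = params.k * (params.M - 1)  # distinct directions; see dn_response
    out = np.empty(error_sets.shape[0])
    for lo in range(0, error_sets.shape[0], chunk):
        block = error_sets[lo : lo + chunk]
        d = block[:, :, None] - phi[None, None, :]
        f = np.exp(-(d * d) / two_s2).max(axis=1)  # (chunk, M)
        x = params.w * phi[None, :] * f
        sx, sx2 = _paired_sums(x)
        out[lo : lo + block.shape[0]] = sx / (kM + sx2)
    return out


def expected_cloud_response(
    spec: CloudSpec,
    params: DNParams,
    n_draws: int = DEFAULT_N_DRAWS,
    seed: int = DEFAULT_SEED,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Monte-Carlo expected DN response to a cursor cloud.

    Draws ``n_draws`` independent clouds of ``spec.n_cursors`` errors from
    N(mu, sigma^2), evaluates the DN response on each, and returns the sample
    mean and its standard error.  ``sigma = 0`` short-circuits to the exact
    deterministic response (duplicated cursors are inert under the max rule).
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    if spec.sigma == 0.0:
        return dn_response(np.full(spec.n_cursors, spec.mu), params), 0.0
    if rng is None:
        rng = np.random.default_rng(seed)
    draws = spec.draw(rng, size=n_draws)
    vals = dn_response_batch(draws, params)
    mean = float(vals.mean())
    se = float(vals.std(ddof=1) / math.sqrt(n_draws)) if n_draws > 1 else 0.0
    return mean, se
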