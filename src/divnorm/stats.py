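"""Derived descriptive statistics of the fit-then-predict workflow.

- ``averaged_response``: mean learning response over e1 = 15, 30, 45 deg for
  each second-cursor direction e2, summarizing how an added cursor shifts the
  response relative to the single-cursor reference.
- ``declining_rate``: fractional reduction of the cloud response at feedback
  uncertainty sigma relative to sigma = 0, at a fixed mean error mu.
- ``decline_ratio``: ratio of declining rates between a small and a large mean
  error.  Reported in both orientations (small/large and its reciprocal); a
  small/large value below 1 means the decline is relatively suppressed at
  large errors — the signature that separates divisive normalization from the
  ordinary MLE account (which pins the ratio at exactly 1).
"""

from __future__ import annotations

import warnings
from typing import Mapping

from .conditions import ErrorSet
from .schedules import canonical_id, condition_id

__all__ = ["averaged_response", "declining_rate", "decline_ratio"]

E1_AVERAGE = (15.0, 30.0, 45.0)
E2_LEVELS = (-45.0, -30.0, -15.0, 0.0, 15.0, 30.0, 45.0)


def _pair_value(values: Mapping[str, float], e1: float, e2: float) -> float:
    """Collapsed response for the double-cursor cell (e1, e2).

    The |e1| = |e2| diagonal is excluded from the experimental design; it is
    filled by its exact model-level equivalent: for e2 = +e1 the single-cursor
    condition at e1 (a duplicated cursor is inert under the max operation),
    and for e2 = -e1 the value 0 (odd symmetry of the collapsed response).
    """
    if e2 == e1:
        return values[condition_id(ErrorSet((e1,)))]
    if e2 == -e1:
        return 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cid = canonical_id(ErrorSet((e1, e2)))
    if cid not in values:
        raise KeyError(f"incomplete design: missing collapsed condition {cid}")
    return values[cid]


def averaged_response(values: Mapping[str, float]) -> dict[float, float]:
    """Mean response over e1 in {15, 30, 45} per e2 level, plus the
    single-cursor reference under key ``"single"``.

    ``values`` maps collapsed condition ids to responses (data means or model
    predictions).  Raises KeyError on an incomplete design.
    """
    out: dict = {}
    for e2 in E2_LEVELS:
        vals = [_pair_value(values, e1, e2) for e1 in E1_AVERAGE]
        out[e2] = sum(vals) / len(vals)
    singles = []
    for e1 in E1_AVERAGE:
        cid = condition_id(ErrorSet((e1,)))
        if cid not in values:
            raise KeyError(f"incomplete design: missing single-cursor condition {cid}")
        singles.append(values[cid])
    out["single"] = sum(singles) / len(singles)
    return out


def declining_rate(responses: Mapping[float, float]) -> dict[float, float]:
    """Fractional decline relative to the sigma = 0 response.

    ``responses`` maps sigma (deg) to the expected response at a fixed mu.
    rate(sigma) = (r(0) - r(sigma)) / r(0); rate(0) = 0.  A negative rate
    means the response increased with uncertainty.
    """
    if 0.0 not in responses:
        raise ValueError("responses must include the sigma = 0 baseline")
    r0 = responses[0.0]
    if r0 == 0.0:
        raise ZeroDivisionError("sigma = 0 response is zero; declining rate undefined")
    return {float(s): (r0 - r) / r0 for s, r in responses.items()}


def decline_ratio(
    rates_small_mu: Mapping[float, float],
    rates_large_mu: Mapping[float, float],
) -> dict[float, float]:
    """Ratio of declining rates (small-mu / large-mu) per sigma > 0."""
    sigmas = sorted(set(rates_small_mu) & set(rates_large_mu))
    out: dict[float, float] = {}
    for s in sigmas:
        if s == 0.0:
            continue
        if rates_large_mu[s] == 0.0:
            raise ZeroDivisionError(f"large-mu declining rate is zero at sigma = {s}")
        out[s] = rates_small_mu[s] / rates_large_mu[s]
    return out
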