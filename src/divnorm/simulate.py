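"""Synthetic condition- and participant-level response tables.

Responses are generated from a ground-truth DN model: for every participant x
condition x cycle, the cursor errors are realized (fixed for ErrorSet
conditions; drawn fresh from the cloud distribution each perturbation trial,
as in the experiments), the noiseless DN response is computed, and independent
Gaussian noise (between-trial/participant variability) is added; cycles are
then averaged within participant.  The result mimics the deposited behavioral
tables: one row per participant and condition.

``collapse_symmetric`` applies the sign-symmetric collapsing used in the
analysis: the responses of a mirrored condition pair (C, -C) are combined as
(r(C) - r(-C)) / 2 and assigned to the pair's canonical (positively-labeled)
representative; self-mirrored conditions pass through unchanged.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .conditions import CloudSpec, ErrorSet
from .dn import DNParams, dn_response, dn_response_batch
from .schedules import PerturbationSchedule, mirror_id

__all__ = ["simulate_responses", "collapse_symmetric", "condition_means"]

RESPONSE_COLUMNS = ["participant_id", "condition_id", "response_type", "response"]


def simulate_responses(
    schedule: PerturbationSchedule,
    true_params: DNParams,
    noise_sd: float,
    n_participants: int,
    seed: int,
    response_type: str = "learning",
) -> pd.DataFrame:
    """Simulate a ResponseTable (participant_id, condition_id, response_type, response).

    ``noise_sd`` is the SD of the additive Gaussian trial noise, in response
    units; cycle means are returned per participant.  Deterministic given
    ``seed``.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    if response_type not in ("learning", "feedback"):
        raise ValueError("response_type must be 'learning' or 'feedback'")
    rng = np.random.default_rng(seed)
    cycles = schedule.cycles
    rows = []
    for cond in schedule.conditions:
        p = cond.perturbation
        stochastic = isinstance(p, CloudSpec) and p.sigma > 0.0
        if stochastic:
            draws = p.draw(rng, size=n_participants * cycles)
            base = dn_response_batch(draws, true_params).reshape(n_participants, cycles)
        elif isinstance(p, ErrorSet):
            base = dn_response(p, true_params)
        elif isinstance(p, CloudSpec):  # sigma = 0: n identical cursors, inert
            base = dn_response(np.full(p.n_cursors, p.mu), true_params)
        else:  # pragma: no cover
            raise TypeError(f"unsupported condition type {type(p)!r}")
        if noise_sd > 0:
            noise = rng.normal(0.0, noise_sd, size=(n_participants, cycles))
            per_participant = (base + noise).mean(axis=1) if stochastic else base + noise.mean(axis=1)
        else:
            # avoid averaging identical values (inexact in the last ulp)
            per_participant = base.mean(axis=1) if stochastic else np.full(n_participants, base)
        for pid in range(n_participants):
            rows.append((pid + 1, cond.condition_id, response_type, per_participant[pid]))
    return pd.DataFrame(rows, columns=RESPONSE_COLUMNS)


def collapse_symmetric(table: pd.DataFrame, schedule: PerturbationSchedule) -> pd.DataFrame:
    """Sign-symmetric collapsing of a ResponseTable.

    For each mirrored condition pair the collapsed response is
    (response(C) - response(-C)) / 2, assigned to the canonical representative;
    this both averages the two sign conditions (responses are odd in the
    perturbation) and cancels any direction-independent offset.  Self-mirrored
    conditions (e.g. the all-zero perturbation) pass through unchanged.
    """
    rep_of = schedule.mirror_pairs()
    missing = set(table["condition_id"]) - set(rep_of)
    if missing:
        raise ValueError(f"conditions not in schedule: {sorted(missing)}")
    wide = table.pivot_table(
        index=["participant_id", "response_type"],
        columns="condition_id",
        values="response",
    )
    groups: dict[str, list[str]] = {}
    for cid, rep in rep_of.items():
        groups.setdefault(rep, []).append(cid)
    by_id = schedule.by_id()
    for rep, members in groups.items():
        if len(members) == 1:
            cond = by_id[members[0]].perturbation
            if mirror_id(cond) != members[0]:
                raise ValueError(f"mirror partner missing for condition {members[0]}")
    rows = []
    for (pid, rtype), series in wide.iterrows():
        for rep in sorted(groups):
            members = groups[rep]
            if len(members) == 1:  # self-mirrored (e.g. all-zero perturbation)
                val = series[members[0]]
            else:
                pos, neg = (members[0], members[1]) if members[0] == rep else (members[1], members[0])
                if pos not in series.index or neg not in series.index:
                    raise ValueError(f"mirror partner missing for collapsed condition {rep}")
                val = (series[pos] - series[neg]) / 2.0
            rows.append((pid, rep, rtype, val))
    return pd.DataFrame(rows, columns=RESPONSE_COLUMNS)


def condition_means(table: pd.DataFrame) -> pd.DataFrame:
    """Across-participant mean and standard error per condition."""
    g = table.groupby(["condition_id", "response_type"])["response"]
    out = g.agg(["mean", "sem", "count"]).reset_index()
    return out.rename(columns={"mean": "response", "sem": "se", "count": "n"})
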