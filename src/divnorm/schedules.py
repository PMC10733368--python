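"""Perturbation schedules of the three experiments.

Experiment 1 (multi-cursor, online feedback): 39 perturbation types —
9 single-cursor (e1 in {0, +/-7.5, +/-15, +/-30, +/-45} deg), 18 double-cursor
(unordered pairs from {0, +/-15, +/-30, +/-45} excluding |e1| = |e2|), and
12 triple-cursor (e1 in {-45, -30, -15, 0, 15, 22.5} with (e2, e3) = (30, 45),
plus the 6 sign-mirrored patterns).  Each condition is run for 9 cycles of
4 trials (perturbation, probe, 2 null washouts): 4 x 9 x 39 = 1404 trials.

Experiments 2 (online) and 3 (endpoint feedback): 15 cursor-cloud conditions,
mu in {0, +/-14, +/-40} x sigma in {0, 7, 20} deg, 5 cursors drawn fresh each
perturbation trial, 12 cycles: 4 x 12 x 15 = 720 trials.

Sign-mirrored condition pairs (every error negated) are collapsed in analysis;
each pair's canonical representative is the variant whose sorted error tuple
is lexicographically largest (i.e. the positively-labeled one).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .conditions import CloudSpec, ErrorSet

__all__ = [
    "Condition",
    "PerturbationSchedule",
    "build_exp1_schedule",
    "build_exp23_schedule",
    "condition_id",
    "mirror_id",
    "canonical_id",
]

TRIALS_PER_SET = 4  # perturbation, probe, 2 null trials


def _fmt(x: float) -> str:
    if x == 0:
        x = 0.0  # avoid a distinct "-0" label for the mirrored zero
    return f"{x:+g}"


def condition_id(cond: ErrorSet | CloudSpec) -> str:
    """Stable identifier for a condition.

    ErrorSets are labeled by their errors sorted in descending order (the set
    is unordered); clouds by (mu, sigma).
    """
    if isinstance(cond, CloudSpec):
        return f"cloud_mu{_fmt(cond.mu)}_sd{cond.sigma:g}"
    errs = sorted(cond.errors, reverse=True)
    kind = {1: "single", 2: "double", 3: "triple"}.get(len(errs), f"n{len(errs)}")
    return f"{kind}_" + "_".join(_fmt(e) for e in errs)


def mirror_id(cond: ErrorSet | CloudSpec) -> str:
    return condition_id(cond.mirrored())


def canonical_id(cond: ErrorSet | CloudSpec) -> str:
    """Identifier of the collapse representative of ``cond``'s mirror pair.

    The representative is the sign variant with the lexicographically larger
    sorted-descending error tuple (for clouds: non-negative mu).  Self-mirrored
    conditions are their own representative.
    """
    if isinstance(cond, CloudSpec):
        rep = cond if cond.mu >= 0 else cond.mirrored()
        return condition_id(rep)
    fwd = tuple(sorted(cond.errors, reverse=True))
    bwd = tuple(sorted((-e for e in cond.errors), reverse=True))
    return condition_id(cond if fwd >= bwd else cond.mirrored())


@dataclass(frozen=True)
class Condition:
    condition_id: str
    perturbation: ErrorSet | CloudSpec
    feedback_mode: str  # "online" or "endpoint"


@dataclass(frozen=True)
class PerturbationSchedule:
    conditions: tuple[Condition, ...]
    cycles: int
    trials_per_set: int = TRIALS_PER_SET

    @property
    def n_conditions(self) -> int:
        return len(self.conditions)

    @property
    def n_trials(self) -> int:
        return self.trials_per_set * self.cycles * self.n_conditions

    def by_id(self) -> dict[str, Condition]:
        return {c.condition_id: c for c in self.conditions}

    def mirror_pairs(self) -> dict[str, str]:
        """Map condition_id -> id of its collapse representative."""
        return {c.condition_id: canonical_id(c.perturbation) for c in self.conditions}

    def to_frame(self) -> pd.DataFrame:
        """Schedule table: condition_id, n_cursors, e1..e3, mu, sigma, feedback_mode."""
        rows = []
        for c in self.conditions:
            row: dict = {"condition_id": c.condition_id, "feedback_mode": c.feedback_mode}
            p = c.perturbation
            if isinstance(p, CloudSpec):
                row.update(n_cursors=p.n_cursors, mu=p.mu, sigma=p.sigma)
            else:
                row.update(n_cursors=p.n_cursors, mu=None, sigma=None)
                for i, e in enumerate(sorted(p.errors, reverse=True), start=1):
                    row[f"e{i}"] = e
            rows.append(row)
        cols = ["condition_id", "n_cursors", "e1", "e2", "e3", "mu", "sigma", "feedback_mode"]
        df = pd.DataFrame(rows)
        for col in cols:
            if col not in df.columns:
                df[col] = None
        return df[cols]


def _error_conditions(error_sets: Iterable[tuple[float, ...]], feedback_mode: str) -> list[Condition]:
    out = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # schedule errors never exceed 90 deg anyway
        for errs in error_sets:
            es = ErrorSet(tuple(errs))
            out.append(Condition(condition_id(es), es, feedback_mode))
    return out


def build_exp1_schedule() -> PerturbationSchedule:
    """The 39-condition multi-cursor schedule (experiment 1), 9 cycles."""
    singles = [(e,) for e in (0.0, 7.5, -7.5, 15.0, -15.0, 30.0, -30.0, 45.0, -45.0)]
    pool = (0.0, 15.0, -15.0, 30.0, -30.0, 45.0, -45.0)
    doubles = [
        pair
        for pair in itertools.combinations(pool, 2)
        if abs(pair[0]) != abs(pair[1])
    ]
    e1_triples = (-45.0, -30.0, -15.0, 0.0, 15.0, 22.5)
    triples = [(e1, 30.0, 45.0) for e1 in e1_triples]
    triples += [(-e1, -30.0, -45.0) for e1 in e1_triples]
    conds = _error_conditions(singles + doubles + triples, "online")
    return PerturbationSchedule(conditions=tuple(conds), cycles=9)


def build_exp23_schedule(feedback_mode: str = "online") -> PerturbationSchedule:
    """The 15-condition cursor-cloud schedule (experiments 2/3), 12 cycles.

    ``feedback_mode`` is "online" (experiment 2: cursors visible throughout
    the movement) or "endpoint" (experiment 3: visible only after movement
    end); the schedule geometry is identical.
    """
    if feedback_mode not in ("online", "endpoint"):
        raise ValueError("feedback_mode must be 'online' or 'endpoint'")
    conds = []
    for mu in (0.0, 14.0, -14.0, 40.0, -40.0):
        for sigma in (0.0, 7.0, 20.0):
            spec = CloudSpec(mu=mu, sigma=sigma, n_cursors=5)
            conds.append(Condition(condition_id(spec), spec, feedback_mode))
    return PerturbationSchedule(conditions=tuple(conds), cycles=12)
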