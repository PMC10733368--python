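"""Perturbation conditions: concrete cursor-error sets and cursor-cloud specs.

A perturbation trial shows the participant one or more cursors whose movement
directions are rotated away from the hand direction.  A condition is either a
fixed set of cursor direction errors (degrees) or a normal-distribution spec
from which the cursor errors are drawn fresh on every trial.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["ErrorSet", "CloudSpec"]

# Beyond ~90 deg the planar-Gaussian approximation of the circular tuning
# function is no longer trustworthy.
GAUSSIAN_APPROX_LIMIT_DEG = 90.0


@dataclass(frozen=True)
class ErrorSet:
    """A fixed set of cursor direction errors, in degrees.

    Errors must be finite and within +/-180 deg.  Errors beyond +/-90 deg are
    accepted but flagged (``approx_warning``): the Gaussian tuning used here
    approximates a circular tuning function and the approximation holds only
    for relatively small errors.
    """

    errors: tuple[float, ...]
    approx_warning: bool = field(init=False, default=False)

    def __post_init__(self) -> None:
        errs = tuple(float(e) for e in np.atleast_1d(np.asarray(self.errors, dtype=float)))
        if len(errs) == 0:
            raise ValueError("ErrorSet requires at least one cursor error")
        arr = np.array(errs)
        if not np.all(np.isfinite(arr)):
            raise ValueError("cursor errors must be finite")
        if np.any(np.abs(arr) > 180.0):
            raise ValueError("cursor errors must lie within [-180, 180] degrees")
        object.__setattr__(self, "errors", errs)
        if np.any(np.abs(arr) > GAUSSIAN_APPROX_LIMIT_DEG):
            object.__setattr__(self, "approx_warning", True)
            warnings.warn(
                "cursor error beyond +/-90 deg: the Gaussian approximation of "
                "the circular tuning function degrades for large errors",
                stacklevel=2,
            )

    @property
    def n_cursors(self) -> int:
        return len(self.errors)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.errors, dtype=float)

    def mirrored(self) -> "ErrorSet":
        """The sign-flipped condition (every cursor error negated)."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return ErrorSet(tuple(-e for e in self.errors))


@dataclass(frozen=True)
class CloudSpec:
    """A cursor cloud: ``n_cursors`` directions drawn i.i.d. from N(mu, sigma^2).

    Parameters are in degrees. ``sigma = 0`` collapses to ``n_cursors``
    identical cursors at ``mu``.
    """

    mu: float
    sigma: float
    n_cursors: int = 5

    def __post_init__(self) -> None:
        if not np.isfinite(self.mu):
            raise ValueError("mu must be finite")
        if self.sigma < 0 or not np.isfinite(self.sigma):
            raise ValueError("sigma must be finite and >= 0")
        if self.n_cursors < 1:
            raise ValueError("n_cursors must be >= 1")

    def draw(self, rng: np.random.Generator, size: int = 1) -> np.ndarray:
        """Draw ``size`` independent clouds; shape ``(size, n_cursors)``."""
        return rng.normal(self.mu, self.sigma, size=(size, self.n_cursors))

    def mirrored(self) -> "CloudSpec":
        return CloudSpec(-self.mu, self.sigma, self.n_cursors)
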