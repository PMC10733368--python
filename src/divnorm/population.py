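"""Bank of direction-tuned neural units.

Preferred directions are laid out on a symmetric inclusive grid spanning
[-180, +180] deg so that 0 deg is always a grid point and the grid is exactly
odd-symmetric (for every preferred direction phi, -phi is also on the grid).
With M = 3601 the spacing is 0.1 deg.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["NeuralPopulation", "make_population"]


@dataclass(frozen=True)
class NeuralPopulation:
    """M direction-tuned units with Gaussian tuning of width ``tuning_width_s``."""

    preferred_directions: np.ndarray  # degrees, length M
    tuning_width_s: float  # degrees
    grid_spacing: float  # degrees

    def __post_init__(self) -> None:
        phi = np.asarray(self.preferred_directions, dtype=float)
        object.__setattr__(self, "preferred_directions", phi)
        if self.tuning_width_s <= 0:
            raise ValueError("tuning width s must be positive")

    @property
    def n_units(self) -> int:
        return self.preferred_directions.size


def make_population(M: int, s: float) -> NeuralPopulation:
    """Build the symmetric inclusive preferred-direction grid.

    phi_j = -180 + (j - 1) * 360 / (M - 1) for j = 1..M, so the grid contains
    -180, 0 and +180 exactly.

    Parameters
    ----------
    M : odd integer >= 3, number of units.
    s : tuning width in degrees, > 0.
    """
    if not isinstance(M, (int, np.integer)):
        raise ValueError("M must be an integer")
    if M < 3 or M % 2 == 0:
        raise ValueError("M must be an odd integer >= 3 so that 0 deg is a grid point")
    if s <= 0:
        raise ValueError("tuning width s must be positive")
    spacing = 360.0 / (M - 1)
    phi = -180.0 + spacing * np.arange(M, dtype=float)
    # enforce exact symmetry: phi reversed equals -phi
    phi = (phi - phi[::-1]) / 2.0
    return NeuralPopulation(preferred_directions=phi, tuning_width_s=float(s), grid_spacing=spacing)
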