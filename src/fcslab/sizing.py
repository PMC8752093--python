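"""Stokes-Einstein size inference from diffusion coefficients.

For a compact diffusing entity D scales with the inverse hydrodynamic
radius, i.e. with the inverse cube root of its volume or molecular mass.
Two consequences used here: a measured D can be rescaled between species of
known mass, D_target = D_known * (M_known / M_target)^(1/3), and a ratio of
measured D values converts into a relative complex volume,
(D_fast / D_slow)^3.  Pure arithmetic on ensemble medians; no
hydrodynamic-shape corrections.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["SizeComparison", "mass_scaled_diffusion", "volume_ratio"]


def mass_scaled_diffusion(D_known: float, M_known: float, M_target: float) -> float:
    """Rescale a diffusion coefficient by the cube root of a mass ratio."""
    if D_known <= 0 or M_known <= 0 or M_target <= 0:
        raise ValueError("all inputs must be positive")
    return D_known * (M_known / M_target) ** (1.0 / 3.0)


def volume_ratio(D_fast: float, D_slow: float) -> float:
    """Relative volume (or mass) of the slow entity: (D_fast / D_slow)^3."""
    if D_fast <= 0 or D_slow <= 0:
        raise ValueError("diffusion coefficients must be positive")
    return (D_fast / D_slow) ** 3


@dataclass(frozen=True)
class SizeComparison:
    """Relative size of two diffusing entities from their D values."""

    D_a: float
    D_b: float
    volume_ratio: float       # (D_a / D_b)^3; > 1 means b is larger
    M_a: float | None = None  # kDa, optional
    M_b: float | None = None

    @classmethod
    def from_diffusion(cls, D_a: float, D_b: float,
                       M_a: float | None = None,
                       M_b: float | None = None) -> "SizeComparison":
        return cls(D_a=D_a, D_b=D_b, volume_ratio=volume_ratio(D_a, D_b),
                   M_a=M_a, M_b=M_b)
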