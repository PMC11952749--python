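"""Apparent temporal discounting of a reward-rate-optimal agent.

Normalizing the subjective value-time function by the outcome magnitude
gives the agent's apparent discounting function

    D(t) = sv(r, t) / r = (1 - rho_out * t / r) / (1 + t / t_out),

a hyperbola (curvature set by 1/t_out, the apportionment of time) scaled
by a linear numerator (the opportunity cost).  With no outside reward the
function is the pure hyperbola 1/(1 + t/t_out), i.e. the standard
hyperbolic form 1/(1 + k t) with k = 1/t_out.  The Magnitude and Sign
effects fall out of the same expression: the opportunity-cost term is
divided by the outcome, so larger rewards discount apparently more
shallowly, and punishments more shallowly than rewards (for a positive
outside rate; the ordering inverts with a negative outside rate and
vanishes at zero).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
from scipy.optimize import curve_fit

from .world import OutsideContext, Pursuit
from .valuation import subjective_value_in_out

__all__ = [
    "DiscountCurve",
    "discount_function",
    "sv_time_curve",
    "fit_hyperbolic_k",
    "magnitude_effect_curves",
    "sign_effect_curves",
]


@dataclass(frozen=True)
class DiscountCurve:
    """Magnitude-normalized subjective values over a delay grid.

    ``values[i] == sv(outcome, delays[i]) / outcome``; value 1 at zero
    delay.  Values may go negative at long delays (the opportunity cost
    eventually exceeds the outcome), which the standard hyperbola cannot
    express.
    """

    delays: np.ndarray
    values: np.ndarray
    outcome: float
    context: OutsideContext

    def __post_init__(self) -> None:
        object.__setattr__(self, "delays", np.asarray(self.delays, dtype=float))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.delays.shape != self.values.shape:
            raise ValueError("delays and values must have matching shapes")


def sv_time_curve(
    outcome: float, outside: OutsideContext, delays: Sequence[float]
) -> np.ndarray:
    """Subjective value of an outcome at each temporal displacement.

    sv(t) = (r - rho_out t) * t_out / (t + t_out); crosses zero at
    t = r / rho_out when rho_out > 0.
    """
    delays = np.asarray(delays, dtype=float)
    if np.any(delays < 0):
        raise ValueError("delays must be >= 0")
    return np.array(
        [
            subjective_value_in_out(Pursuit(outcome, t), outside).subjective_value
            for t in delays
        ]
    )


def discount_function(
    outcome: float, outside: OutsideContext, delays: Sequence[float]
) -> DiscountCurve:
    """The apparent discounting curve sv(t)/outcome over a delay grid."""
    if outcome == 0:
        raise ValueError("outcome must be nonzero to normalize subjective value")
    values = sv_time_curve(outcome, outside, delays) / outcome
    return DiscountCurve(np.asarray(delays, dtype=float), values, outcome, outside)


def fit_hyperbolic_k(curve: DiscountCurve) -> float:
    """Least-squares fit of the standard hyperbola 1/(1 + k t) to a curve.

    Unweighted least squares on the value scale, k constrained >= 0.
    When the curve was generated with a zero outside rate the fit recovers
    k = 1/t_out exactly (to solver tolerance).  A constant curve cannot
    identify k and raises ValueError.
    """
    t = curve.delays
    v = curve.values
    if np.unique(t).size < 3:
        raise ValueError("need at least 3 distinct delays to fit k")
    if np.allclose(v, v[0]):
        raise ValueError("degenerate (constant) curve: k is unidentifiable")
    k0 = 1.0 / curve.context.outside_time
    popt, _ = curve_fit(
        lambda tt, k: 1.0 / (1.0 + k * tt), t, v, p0=[k0], bounds=(0.0, np.inf)
    )
    return float(popt[0])


def magnitude_effect_curves(
    r_small: float,
    r_large: float,
    outside: OutsideContext,
    delays: Sequence[float],
) -> Tuple[DiscountCurve, DiscountCurve]:
    """Discount curves for a small and a large reward in the same context.

    With a positive outside rate the larger reward's curve lies strictly
    above the smaller's at every positive delay (the Magnitude effect);
    with no outside reward the curves coincide.
    """
    if not 0 < r_small < r_large:
        raise ValueError("need 0 < r_small < r_large")
    return (
        discount_function(r_small, outside, delays),
        discount_function(r_large, outside, delays),
    )


def sign_effect_curves(
    magnitude: float, outside: OutsideContext, delays: Sequence[float]
) -> Tuple[DiscountCurve, DiscountCurve]:
    """Discount curves for a reward (+magnitude) and a punishment (-magnitude).

    For a positive outside rate the punishment appears to discount more
    shallowly than the reward (the Sign effect); the curves coincide at a
    zero outside rate and the ordering inverts when the outside rate is
    negative.
    """
    if not magnitude > 0:
        raise ValueError("magnitude must be > 0")
    return (
        discount_function(magnitude, outside, delays),
        discount_function(-magnitude, outside, delays),
    )
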