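"""Parameter-misestimation agents and the Malapportionment agent.

Six misestimation models each multiply one quantity entering the global
reward rate by an error term omega (underestimation for omega < 1,
overestimation for omega > 1):

======================================  ==========================================
variable                                misestimated global rate
======================================  ==========================================
``outside_time``                        (r_in + rho_out t_out) / (t_in + w t_out)
``outside_reward``                      (r_in + w rho_out t_out) / (t_in + t_out)
``outside_both_rate_preserved``         (r_in + w rho_out t_out) / (t_in + w t_out)
``inside_time``                         (r_in + rho_out t_out) / (w t_in + t_out)
``inside_reward``                       (w r_in + rho_out t_out) / (t_in + t_out)
``inside_both_rate_preserved``          (w r_in + rho_out t_out) / (w t_in + t_out)
======================================  ==========================================

The rate-preserved variants leave the perceived local rates equal to the
true ones, so Forgo behaviour stays optimal while Choice is distorted.
The *Malapportionment* agent is ``outside_both_rate_preserved`` with
omega < 1 (equivalently ``inside_both_rate_preserved`` with omega > 1):
it underweights time outside relative to inside the considered pursuit
while correctly estimating both reward rates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from .world import OutsideContext, Pursuit

__all__ = [
    "VARIABLES",
    "MisestimationSpec",
    "misestimated_global_rate",
    "misestimated_outside_rate",
    "misestimated_inside_rate",
    "perceived_outside",
    "perceived_reversal_delay",
    "MalapportionmentPredictions",
    "malapportionment_curves",
]

VARIABLES = (
    "none",
    "outside_time",
    "outside_reward",
    "outside_both_rate_preserved",
    "inside_time",
    "inside_reward",
    "inside_both_rate_preserved",
)


@dataclass(frozen=True)
class MisestimationSpec:
    """Which quantity is misestimated and by what factor omega > 0."""

    variable: str
    omega: float = 1.0

    def __post_init__(self) -> None:
        if self.variable not in VARIABLES:
            raise ValueError(
                f"unknown misestimation variable {self.variable!r}; "
                f"expected one of {VARIABLES}"
            )
        if not self.omega > 0:
            raise ValueError(f"omega must be > 0, got {self.omega}")


def misestimated_global_rate(
    pursuit: Pursuit, outside: OutsideContext, spec: MisestimationSpec
) -> float:
    """Global reward rate as perceived by the misestimating agent."""
    r_in, t_in = pursuit.reward, pursuit.duration
    r_out, t_out = outside.outside_reward, outside.outside_time
    w = spec.omega
    v = spec.variable
    if v == "none":
        pass
    elif v == "outside_time":
        t_out = w * t_out
    elif v == "outside_reward":
        r_out = w * r_out
    elif v == "outside_both_rate_preserved":
        r_out, t_out = w * r_out, w * t_out
    elif v == "inside_time":
        t_in = w * t_in
    elif v == "inside_reward":
        r_in = w * r_in
    elif v == "inside_both_rate_preserved":
        r_in, t_in = w * r_in, w * t_in
    total = t_in + t_out
    if total <= 0:
        raise ValueError("perceived traversal time must be > 0")
    return (r_in + r_out) / total


def misestimated_outside_rate(outside: OutsideContext, spec: MisestimationSpec) -> float:
    """Outside reward rate as perceived by the agent.

    Misestimating the outside time divides the perceived rate by omega;
    misestimating the outside reward multiplies it; the rate-preserved
    variants and all inside variants leave it untouched.
    """
    rho = outside.rate
    if spec.variable == "outside_time":
        return rho / spec.omega
    if spec.variable == "outside_reward":
        return spec.omega * rho
    return rho


def misestimated_inside_rate(pursuit: Pursuit, spec: MisestimationSpec) -> float:
    """Local reward rate of the pursuit as perceived by the agent."""
    rho = pursuit.rate
    if spec.variable == "inside_time":
        return rho / spec.omega
    if spec.variable == "inside_reward":
        return spec.omega * rho
    return rho


def perceived_outside(outside: OutsideContext, omega: float) -> OutsideContext:
    """The Malapportionment agent's outside: (omega r_out, omega t_out).

    Rate preserved; only the weight of the outside shrinks (omega < 1).
    """
    return outside.scaled(omega)


def perceived_reversal_delay(
    ss: Pursuit, ll: Pursuit, outside: OutsideContext, omega: float = 1.0
) -> Optional[float]:
    """Common front-end delay at which the agent's preference reverses SS -> LL.

    The delay is an unrewarded interval common to both choice policies, so
    it belongs to the time spent outside the considered pursuits; the
    Malapportionment agent underweights it along with the rest of the
    outside.  The perceived rates under choosing pursuit X are
    (r_X + omega r_out) / (t_X + omega (t_out + d)); equating them over d
    is linear with root

        d* = x / omega - t_out,
        x = [(r_SS + omega r_out) t_LL - (r_LL + omega r_out) t_SS]
            / (r_LL - r_SS).

    At omega = 1 this is the true reward-rate-optimal reversal delay (for
    the optimal agent the placement of a common additive delay is
    irrelevant).  Returns None when no positive reversal delay exists.
    """
    if not omega > 0:
        raise ValueError(f"omega must be > 0, got {omega}")
    if ll.reward == ss.reward:
        return None
    r_out, t_out = outside.outside_reward, outside.outside_time
    x = ((ss.reward + omega * r_out) * ll.duration - (ll.reward + omega * r_out) * ss.duration) / (
        ll.reward - ss.reward
    )
    d = x / omega - t_out
    return d if d > 0 else None


@dataclass(frozen=True)
class MalapportionmentPredictions:
    """Optimal-vs-perceived behavioural signatures of time malapportionment.

    For omega < 1 the perceived discounting curve is more curved than the
    optimal one, the Magnitude- and Sign-effect gaps are smaller, and the
    preference-reversal delay is larger.
    """

    omega: float
    delays: np.ndarray
    discount_optimal: np.ndarray
    discount_perceived: np.ndarray
    magnitude_gap_optimal: np.ndarray
    magnitude_gap_perceived: np.ndarray
    sign_gap_optimal: np.ndarray
    sign_gap_perceived: np.ndarray
    reversal_delay_optimal: Optional[float]
    reversal_delay_perceived: Optional[float]


def malapportionment_curves(
    ss: Pursuit,
    ll: Pursuit,
    outside: OutsideContext,
    omega: float,
    delays: Optional[Sequence[float]] = None,
    sign_magnitude: Optional[float] = None,
) -> MalapportionmentPredictions:
    """Predictions of the Malapportionment agent against the optimal agent.

    Every perceived quantity is obtained by substituting the underweighted
    outside (omega r_out, omega t_out) into the corresponding optimal-agent
    operation.  ``ll.reward`` parameterizes the discounting curve,
    (``ss.reward``, ``ll.reward``) the Magnitude-effect pair, and
    ``sign_magnitude`` (default the mean of the two rewards) the
    Sign-effect pair.
    """
    from . import discounting  # local import; discounting is independent of this module

    if not omega > 0:
        raise ValueError(f"omega must be > 0, got {omega}")
    if delays is None:
        delays = np.linspace(0.0, 4.0 * outside.outside_time, 41)
    delays = np.asarray(delays, dtype=float)
    seen = perceived_outside(outside, omega)
    if sign_magnitude is None:
        sign_magnitude = 0.5 * (abs(ss.reward) + abs(ll.reward))

    def gap(pair) -> np.ndarray:
        a, b = pair
        return np.asarray(a.values) - np.asarray(b.values)

    disc_opt = discounting.discount_function(ll.reward, outside, delays)
    disc_hat = discounting.discount_function(ll.reward, seen, delays)
    mag_opt = discounting.magnitude_effect_curves(ss.reward, ll.reward, outside, delays)
    mag_hat = discounting.magnitude_effect_curves(ss.reward, ll.reward, seen, delays)
    sign_opt = discounting.sign_effect_curves(sign_magnitude, outside, delays)
    sign_hat = discounting.sign_effect_curves(sign_magnitude, seen, delays)
    return MalapportionmentPredictions(
        omega=omega,
        delays=delays,
        discount_optimal=np.asarray(disc_opt.values),
        discount_perceived=np.asarray(disc_hat.values),
        magnitude_gap_optimal=gap((mag_opt[1], mag_opt[0])),
        magnitude_gap_perceived=gap((mag_hat[1], mag_hat[0])),
        sign_gap_optimal=gap((sign_opt[1], sign_opt[0])),
        sign_gap_perceived=gap((sign_hat[1], sign_hat[0])),
        reversal_delay_optimal=perceived_reversal_delay(ss, ll, outside, 1.0),
        reversal_delay_perceived=perceived_reversal_delay(ss, ll, outside, omega),
    )
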