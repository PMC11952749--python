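"""Subjective value of a pursuit and the decomposition of time's cost.

The subjective value (sv) of a pursuit is the immediate reward magnitude
an agent should treat as equivalent to initiating the pursuit: the amount
that, taken instead, yields the same global reward rate.  Two algebraically
equivalent forms are provided:

* from the global rate achieved under a policy of accepting the pursuit,
  ``sv = r_in - rho_g * t_in``;
* from the reward and time outside the considered pursuit type,
  ``sv = (r_in - rho_out * t_in) * t_out / (t_in + t_out)``.

The second form splits time's cost ``rho_g * t_in`` into an *opportunity
cost* ``rho_out * t_in`` (what a policy of not taking the pursuit would
earn over its duration) and an *apportionment cost*
``(rho_g - rho_out) * t_in`` (the remainder, driven by the fraction of
traversal time the pursuit occupies).
"""

from __future__ import annotations

from dataclasses import dataclass

from .world import OutsideContext, Pursuit, global_rate_in_out, occupancy_weight

__all__ = [
    "ValuationBreakdown",
    "subjective_value_from_global_rate",
    "subjective_value_in_out",
    "subjective_value_nonexclusive",
]


@dataclass(frozen=True)
class ValuationBreakdown:
    """sv of one pursuit-in-context with the full time-cost decomposition.

    Invariants (up to float tolerance):
    opportunity_cost + apportionment_cost == time_cost,
    subjective_value == pursuit reward - time_cost,
    time_cost == global_rate * pursuit duration.
    """

    subjective_value: float
    global_rate: float
    occupancy_weight: float
    time_cost: float
    opportunity_cost: float
    apportionment_cost: float


def subjective_value_from_global_rate(pursuit: Pursuit, global_rate: float) -> float:
    """sv = r_in - rho_g * t_in (global reward-rate-equivalent immediate reward)."""
    return pursuit.reward - global_rate * pursuit.duration


def subjective_value_in_out(pursuit: Pursuit, outside: OutsideContext) -> ValuationBreakdown:
    """Subjective value and time-cost breakdown from the in/outside parcellation.

    The sv is computed in the outside form
    ``(r_in - rho_out * t_in) * t_out / (t_in + t_out)`` whose two factors
    are the opportunity-cost-subtracted reward and the apportionment
    scaling (the weight of the outside).  A zero-duration pursuit is legal
    and values to its own reward.
    """
    t_in = pursuit.duration
    rho_out = outside.rate
    rho_g = global_rate_in_out(pursuit, outside)
    w_in = occupancy_weight(pursuit, outside)
    sv = (pursuit.reward - rho_out * t_in) * (1.0 - w_in)
    return ValuationBreakdown(
        subjective_value=sv,
        global_rate=rho_g,
        occupancy_weight=w_in,
        time_cost=rho_g * t_in,
        opportunity_cost=rho_out * t_in,
        apportionment_cost=(rho_g - rho_out) * t_in,
    )


def subjective_value_nonexclusive(pursuit: Pursuit, outside: OutsideContext) -> float:
    """sv when engaging the pursuit does not forfeit the outside reward stream.

    When the agent keeps receiving rewards at the outside rate during the
    pursuit, the opportunity cost drops out and only the apportionment
    scaling remains: sv = r_in / (1 + t_in/t_out).  Independent of r_out,
    and equal to ``subjective_value_in_out`` when r_out = 0.
    """
    return pursuit.reward / (1.0 + pursuit.duration / outside.outside_time)
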