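"""Reward-rate-optimal Forgo and Choice policies and policy-region maps.

Forgo: take an offered pursuit iff its local rate exceeds its outside
rate (equivalently, iff its subjective value is positive).  Choice between
a smaller-sooner (SS) and larger-later (LL) pursuit: pick the policy with
the greater resulting global rate, which coincides with comparing the
marginal rate (r_LL - r_SS)/(t_LL - t_SS) to the optimal global rate, and
with comparing subjective values.  All comparisons carry an indifference
tolerance ``tol`` (absolute, on rates) so exact-equality cases are
reported as "indifferent" rather than resolved by float noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import misestimation as mis
from .world import ForgoWorld, OutsideContext, Pursuit, global_rate_in_out, parcel_world
from .valuation import subjective_value_in_out

__all__ = [
    "DEFAULT_TOL",
    "BehaviorTriplet",
    "forgo_decision",
    "optimal_accept_set",
    "choice_decision",
    "behavior_triplet",
    "critical_outside_rate_for_choice",
    "critical_outside_time_for_choice",
    "preference_reversal_delay",
    "RegionMap",
    "policy_region_map",
]

DEFAULT_TOL = 1e-9

TAKE, FORGO, INDIFFERENT = "take", "forgo", "indifferent"
SS, LL = "SS", "LL"


@dataclass(frozen=True)
class BehaviorTriplet:
    """The agent's pattern across the three decisions posed by an SS/LL pair:
    choose between them, take-or-forgo LL alone, take-or-forgo SS alone.
    Each field is set by its own comparison; no cross-field constraint.
    """

    choice: str
    forgo_ll: str
    forgo_ss: str

    def astuple(self) -> Tuple[str, str, str]:
        return (self.choice, self.forgo_ll, self.forgo_ss)


def _compare(a: float, b: float, tol: float, gt: str, lt: str) -> str:
    if a > b + tol:
        return gt
    if a < b - tol:
        return lt
    return INDIFFERENT


def forgo_decision(
    pursuit: Pursuit, outside: OutsideContext, tol: float = DEFAULT_TOL
) -> str:
    """Take when rho_in > rho_out, forgo when rho_in < rho_out, else indifferent.

    Agrees with the sign of the pursuit's subjective value.
    """
    return _compare(pursuit.rate, outside.rate, tol, TAKE, FORGO)


def optimal_accept_set(world: ForgoWorld, tol: float = DEFAULT_TOL) -> frozenset:
    """Reward-rate-maximal accept set by iterative removal.

    Starting from accepting everything, repeatedly drop the lowest-rate
    accepted pursuit whose local rate falls below its current outside rate
    (computed by parcelling over the current accept set; ties broken by
    index) until no accepted pursuit violates rho_in >= rho_out - tol.
    The surviving set attains the maximum of the global rate over all 2^n
    subsets, which :func:`pursuitval.simulate.brute_force_optimal_accept_set`
    verifies exhaustively.
    """
    accepted = set(range(world.n))
    while accepted:
        violators = []
        for i in sorted(accepted):
            pursuit, outside = parcel_world(world, accepted, i)
            if pursuit.rate < outside.rate - tol:
                violators.append(i)
        if not violators:
            break
        accepted.remove(min(violators, key=lambda i: (world.pursuits[i].rate, i)))
    return frozenset(accepted)


def choice_decision(
    ss: Pursuit, ll: Pursuit, outside: OutsideContext, tol: float = DEFAULT_TOL
) -> str:
    """LL iff the global rate under choosing LL beats choosing SS, SS if reversed."""
    rate_ss = global_rate_in_out(ss, outside)
    rate_ll = global_rate_in_out(ll, outside)
    return _compare(rate_ll, rate_ss, tol, LL, SS)


def behavior_triplet(
    ss: Pursuit,
    ll: Pursuit,
    outside: OutsideContext,
    spec: Optional[mis.MisestimationSpec] = None,
    tol: float = DEFAULT_TOL,
) -> BehaviorTriplet:
    """Choice and both Forgo decisions for one SS/LL pair in one context.

    With a misestimation spec, every comparison uses the agent's perceived
    quantities: Choice compares misestimated global rates, Forgo compares
    the misestimated local rate against the misestimated outside rate.
    """
    if spec is None or spec.variable == "none" or spec.omega == 1.0:
        return BehaviorTriplet(
            choice=choice_decision(ss, ll, outside, tol),
            forgo_ll=forgo_decision(ll, outside, tol),
            forgo_ss=forgo_decision(ss, outside, tol),
        )
    rate_ss = mis.misestimated_global_rate(ss, outside, spec)
    rate_ll = mis.misestimated_global_rate(ll, outside, spec)
    rho_out_hat = mis.misestimated_outside_rate(outside, spec)
    return BehaviorTriplet(
        choice=_compare(rate_ll, rate_ss, tol, LL, SS),
        forgo_ll=_compare(mis.misestimated_inside_rate(ll, spec), rho_out_hat, tol, TAKE, FORGO),
        forgo_ss=_compare(mis.misestimated_inside_rate(ss, spec), rho_out_hat, tol, TAKE, FORGO),
    )


def critical_outside_rate_for_choice(
    ss: Pursuit, ll: Pursuit, t_out: float
) -> Optional[float]:
    """Outside reward rate at which choosing SS and choosing LL tie.

    Solves (r_SS + rho t_out)/(t_SS + t_out) = (r_LL + rho t_out)/(t_LL + t_out),
    linear in rho.  At the root the tied global rate equals the marginal
    rate (r_LL - r_SS)/(t_LL - t_SS).  Returns None when no crossing
    exists at a nonnegative rate.
    """
    if t_out <= 0:
        raise ValueError("t_out must be > 0")
    if ll.duration == ss.duration:
        raise ValueError("critical rate undefined for equal durations")
    rho = (
        ll.reward * (ss.duration + t_out) - ss.reward * (ll.duration + t_out)
    ) / (t_out * (ll.duration - ss.duration))
    return rho if rho >= 0 else None


def critical_outside_time_for_choice(
    ss: Pursuit,
    ll: Pursuit,
    r_out: float,
    t_min: float = 1e-6,
    t_max: float = 1e6,
) -> Optional[float]:
    """Outside time at which sv_SS = sv_LL, holding the outside reward fixed.

    Brackets a sign change of sv_SS - sv_LL on a log grid over
    (t_min, t_max) and polishes it with Brent's method to |dt| < 1e-10.
    Returns None when the difference never changes sign on the interval.
    """

    def diff(t_out: float) -> float:
        ctx = OutsideContext(r_out, t_out)
        return (
            subjective_value_in_out(ss, ctx).subjective_value
            - subjective_value_in_out(ll, ctx).subjective_value
        )

    grid = np.geomspace(t_min, t_max, 200)
    vals = np.array([diff(t) for t in grid])
    sign = np.sign(vals)
    idx = np.nonzero(sign[:-1] * sign[1:] < 0)[0]
    if idx.size == 0:
        return None
    lo, hi = grid[idx[0]], grid[idx[0] + 1]
    return float(brentq(diff, lo, hi, xtol=1e-10))


def preference_reversal_delay(
    ss: Pursuit, ll: Pursuit, outside: OutsideContext
) -> Optional[float]:
    """Common added delay d* at which preference reverses from SS to LL.

    Both pursuit durations are extended by d (the outside is unchanged);
    the global rates under the two choice policies tie when

        d* = [(r_LL + r_out)(t_SS + t_out) - (r_SS + r_out)(t_LL + t_out)]
             / (r_SS - r_LL).

    Requires rho_SS > rho_LL for the SS-first ordering; returns None when
    no positive root exists (no reversal).
    """
    if ll.reward == ss.reward:
        return None
    num = (ll.reward + outside.outside_reward) * (ss.duration + outside.outside_time) - (
        ss.reward + outside.outside_reward
    ) * (ll.duration + outside.outside_time)
    d = num / (ss.reward - ll.reward)
    return d if d > 0 else None


@dataclass(frozen=True)
class RegionMap:
    """Long-format triplet table over (outside rate, omega) and the
    boundary rates between adjacent distinct triplets within each omega row."""

    table: pd.DataFrame
    boundaries: pd.DataFrame


def policy_region_map(
    ss: Pursuit,
    ll: Pursuit,
    t_out: float,
    outside_rates: Sequence[float],
    variable: str = "none",
    omegas: Sequence[float] = (1.0,),
    tol: float = DEFAULT_TOL,
) -> RegionMap:
    """Behaviour triplet per (outside rate, omega) grid cell.

    The omega = 1 row of any variable reproduces the optimal map.  The
    boundary table records, per omega, the pair of adjacent grid rates
    between which the triplet changes (midpoint reported as the boundary
    estimate).
    """
    rates = list(outside_rates)
    rows: List[dict] = []
    bounds: List[dict] = []
    for omega in omegas:
        spec = mis.MisestimationSpec(variable, omega) if variable != "none" else None
        prev: Optional[BehaviorTriplet] = None
        prev_rate: Optional[float] = None
        for rho in rates:
            outside = OutsideContext.from_rate(rho, t_out)
            trip = behavior_triplet(ss, ll, outside, spec, tol)
            rows.append(
                {
                    "outside_rate": rho,
                    "omega": omega,
                    "choice": trip.choice,
                    "forgo_ll": trip.forgo_ll,
                    "forgo_ss": trip.forgo_ss,
                }
            )
            if prev is not None and trip != prev:
                bounds.append(
                    {
                        "omega": omega,
                        "boundary_rate": 0.5 * (prev_rate + rho),
                        "below": "|".join(prev.astuple()),
                        "above": "|".join(trip.astuple()),
                    }
                )
            prev, prev_rate = trip, rho
    return RegionMap(
        table=pd.DataFrame(rows),
        boundaries=pd.DataFrame(bounds, columns=["omega", "boundary_rate", "below", "above"]),
    )
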