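"""Pursuit worlds and the global reward-rate algebra.

A temporal decision-making world is a recurrent environment composed of
*pursuits*: paths that cost a fixed duration, yield a (possibly negative)
reward, and return the agent to a *default pursuit* from which new pursuit
opportunities are encountered at fixed frequencies.  Everything in this
module is exact rate arithmetic; stochastic and exhaustive oracles for it
live in :mod:`pursuitval.simulate`.

Units are abstract: rewards in "reward units", times in "time units", and
every rate is reward per unit time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Tuple

__all__ = [
    "Pursuit",
    "ForgoWorld",
    "OutsideContext",
    "global_rate_forgo_world",
    "parcel_world",
    "global_rate_in_out",
    "occupancy_weight",
]


@dataclass(frozen=True)
class Pursuit:
    """A single rewarding path: reward magnitude over a required duration.

    The local reward rate is always derived from the stored fields
    (never stored separately), so the pair (reward, duration) is the
    single source of truth.  Rewards may be negative (punishments);
    durations may not.
    """

    reward: float
    duration: float
    label: Optional[str] = None

    def __post_init__(self) -> None:
        if not _finite(self.reward) or not _finite(self.duration):
            raise ValueError("pursuit reward and duration must be finite numbers")
        if self.duration < 0:
            raise ValueError(f"pursuit duration must be >= 0, got {self.duration}")

    @property
    def rate(self) -> float:
        """Local reward rate, reward/duration. Requires duration > 0."""
        if self.duration <= 0:
            raise ValueError("local rate undefined for zero-duration pursuit")
        return self.reward / self.duration

    def delayed(self, delay: float) -> "Pursuit":
        """The same pursuit with ``delay`` added to its duration."""
        return Pursuit(self.reward, self.duration + delay, self.label)


@dataclass(frozen=True)
class ForgoWorld:
    """n pursuit types encountered from a default pursuit.

    ``frequencies[i]`` is the encounter rate of pursuit i in events per
    unit of default-pursuit time; ``default_rate`` is the reward rate
    accrued while in the default pursuit.
    """

    pursuits: Tuple[Pursuit, ...]
    frequencies: Tuple[float, ...]
    default_rate: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "pursuits", tuple(self.pursuits))
        object.__setattr__(self, "frequencies", tuple(float(f) for f in self.frequencies))
        if len(self.pursuits) != len(self.frequencies):
            raise ValueError(
                f"{len(self.pursuits)} pursuits but {len(self.frequencies)} frequencies"
            )
        if not _finite(self.default_rate):
            raise ValueError("default_rate must be a finite number")
        for i, f in enumerate(self.frequencies):
            if not _finite(f) or f <= 0:
                raise ValueError(f"frequency of pursuit {i} must be > 0, got {f}")
        for i, p in enumerate(self.pursuits):
            if p.duration <= 0:
                raise ValueError(f"pursuit {i} must have duration > 0 in a ForgoWorld")

    @property
    def n(self) -> int:
        return len(self.pursuits)

    def all_indices(self) -> frozenset:
        return frozenset(range(self.n))


@dataclass(frozen=True)
class OutsideContext:
    """Everything outside a considered pursuit type.

    ``outside_reward`` (r_out) is the average reward collected outside the
    pursuit per traversal; ``outside_time`` (t_out) the average time spent
    outside per traversal.  The outside reward rate r_out/t_out is derived.
    """

    outside_reward: float
    outside_time: float

    def __post_init__(self) -> None:
        if not _finite(self.outside_reward) or not _finite(self.outside_time):
            raise ValueError("outside reward and time must be finite numbers")
        if self.outside_time <= 0:
            raise ValueError(f"outside_time must be > 0, got {self.outside_time}")

    @property
    def rate(self) -> float:
        """Outside reward rate rho_out = r_out / t_out."""
        return self.outside_reward / self.outside_time

    @classmethod
    def from_rate(cls, rate: float, outside_time: float) -> "OutsideContext":
        """Build from an outside reward *rate* and an outside time."""
        return cls(rate * outside_time, outside_time)

    def scaled(self, omega: float) -> "OutsideContext":
        """Outside with both reward and time scaled by ``omega`` (rate preserved)."""
        if omega <= 0:
            raise ValueError("scale factor must be > 0")
        return OutsideContext(omega * self.outside_reward, omega * self.outside_time)


def _finite(x) -> bool:
    try:
        x = float(x)
    except (TypeError, ValueError):
        return False
    return x == x and abs(x) != float("inf")


def _as_index_set(world: ForgoWorld, accept_set: Iterable[int]) -> frozenset:
    idx = frozenset(int(i) for i in accept_set)
    bad = [i for i in idx if not 0 <= i < world.n]
    if bad:
        raise ValueError(f"accept_set indices out of range: {sorted(bad)}")
    return idx


def global_rate_forgo_world(world: ForgoWorld, accept_set: Iterable[int]) -> float:
    """Long-run global reward rate under a policy accepting ``accept_set``.

    rho_g = (sum_{i in A} f_i r_i + rho_d) / (sum_{i in A} f_i t_i + 1),
    where the "+1" is the unit of default-pursuit time per normalization
    cycle over which the encounter frequencies are defined.  Rejected
    pursuits contribute nothing to either sum.
    """
    idx = _as_index_set(world, accept_set)
    num = world.default_rate
    den = 1.0
    for i in idx:
        p = world.pursuits[i]
        if p.duration <= 0:
            raise ValueError(f"accepted pursuit {i} has non-positive duration")
        num += world.frequencies[i] * p.reward
        den += world.frequencies[i] * p.duration
    return num / den


def parcel_world(
    world: ForgoWorld, accept_set: Iterable[int], focal: int
) -> Tuple[Pursuit, OutsideContext]:
    """Split the world into the focal pursuit and its outside.

    Returns the focal pursuit unchanged together with the average time
    spent (t_out) and reward collected (r_out) outside the focal pursuit
    type for each instance the focal pursuit is experienced:

        t_out = (sum_{i in A, i != focal} f_i t_i + 1) / f_focal
        r_out = (sum_{i in A, i != focal} f_i r_i + rho_d) / f_focal

    The in/out parcellation is exact: the global rate of (pursuit, outside)
    equals the direct accept-set rate.
    """
    idx = _as_index_set(world, accept_set)
    focal = int(focal)
    if focal not in idx:
        raise ValueError(f"focal pursuit {focal} is not in the accept set")
    f_focal = world.frequencies[focal]
    t_out = 1.0
    r_out = world.default_rate
    for i in idx:
        if i == focal:
            continue
        t_out += world.frequencies[i] * world.pursuits[i].duration
        r_out += world.frequencies[i] * world.pursuits[i].reward
    return world.pursuits[focal], OutsideContext(r_out / f_focal, t_out / f_focal)


def global_rate_in_out(pursuit: Pursuit, outside: OutsideContext) -> float:
    """Global reward rate of the parcellated world: (r_in + r_out)/(t_in + t_out)."""
    total_time = pursuit.duration + outside.outside_time
    if total_time <= 0:
        raise ValueError("total traversal time must be > 0")
    return (pursuit.reward + outside.outside_reward) / total_time


def occupancy_weight(pursuit: Pursuit, outside: OutsideContext) -> float:
    """Fraction of traversal time spent inside the pursuit, w_in = t_in/(t_in+t_out).

    Satisfies the weighted-average identity
    w_in * rho_in + (1 - w_in) * rho_out = global_rate_in_out(pursuit, outside).
    """
    if pursuit.duration < 0:
        raise ValueError("duration must be >= 0")
    return pursuit.duration / (pursuit.duration + outside.outside_time)
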