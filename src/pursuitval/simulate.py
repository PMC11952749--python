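"""Independent oracles: stochastic traversal simulation and exhaustive search.

``simulate_traversals`` realizes a pursuit world as a renewal-reward
process (exponential waits in the default pursuit, multinomial encounter
types) so its empirical long-run rate can be checked against the closed
-form global-rate expression.  ``brute_force_optimal_accept_set``
enumerates every accept policy so the iterative Forgo policy can be
checked against the true optimum.  Neither stands in for the analytic
path; both exist to verify it.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Tuple

import numpy as np

from .world import ForgoWorld, global_rate_forgo_world

__all__ = ["SimulationResult", "simulate_traversals", "brute_force_optimal_accept_set"]

_N_BATCHES = 100  # batch means absorb renewal correlation in the SE


@dataclass(frozen=True)
class SimulationResult:
    total_reward: float
    total_time: float
    empirical_rate: float
    standard_error: float
    n_encounters: int
    seed: int


def simulate_traversals(
    world: ForgoWorld,
    accept_set: Iterable[int],
    n_encounters: int,
    seed: int,
) -> SimulationResult:
    """Simulate ``n_encounters`` pursuit encounters under an accept policy.

    The agent waits in the default pursuit for an exponential time with
    total rate sum(f_i) (accruing default reward), then encounters pursuit
    i with probability f_i / sum(f_j).  Accepted encounters add the
    pursuit's reward and duration; rejected encounters add nothing.
    Encounters arriving mid-pursuit are not modelled (the agent only
    encounters pursuits from the default).  Deterministic given ``seed``.
    """
    if n_encounters < 1:
        raise ValueError("n_encounters must be >= 1")
    accept = frozenset(int(i) for i in accept_set)
    bad = [i for i in accept if not 0 <= i < world.n]
    if bad:
        raise ValueError(f"accept_set indices out of range: {sorted(bad)}")
    if world.n == 0:
        raise ValueError("cannot simulate encounters in a world with no pursuits")
    freq = np.asarray(world.frequencies, dtype=float)
    total_freq = freq.sum()
    if total_freq <= 0:
        raise ValueError("total encounter frequency must be > 0")

    rng = np.random.default_rng(seed)
    waits = rng.exponential(1.0 / total_freq, size=n_encounters)
    kinds = rng.choice(world.n, size=n_encounters, p=freq / total_freq)

    rewards_by_kind = np.array([p.reward for p in world.pursuits])
    durations_by_kind = np.array([p.duration for p in world.pursuits])
    accepted = np.isin(kinds, sorted(accept))
    step_reward = waits * world.default_rate + np.where(accepted, rewards_by_kind[kinds], 0.0)
    step_time = waits + np.where(accepted, durations_by_kind[kinds], 0.0)

    total_reward = float(step_reward.sum())
    total_time = float(step_time.sum())
    rate = total_reward / total_time

    n_batches = min(_N_BATCHES, n_encounters)
    usable = (n_encounters // n_batches) * n_batches
    br = step_reward[:usable].reshape(n_batches, -1).sum(axis=1)
    bt = step_time[:usable].reshape(n_batches, -1).sum(axis=1)
    batch_rates = br / bt
    se = float(batch_rates.std(ddof=1) / np.sqrt(n_batches)) if n_batches > 1 else float("nan")

    return SimulationResult(
        total_reward=total_reward,
        total_time=total_time,
        empirical_rate=rate,
        standard_error=se,
        n_encounters=n_encounters,
        seed=seed,
    )


def brute_force_optimal_accept_set(world: ForgoWorld) -> Tuple[frozenset, float]:
    """Exhaustive argmax of the global rate over all 2^n accept sets.

    Ties are broken toward the smaller subset, then lexicographically.
    Guarded at n <= 20 to keep enumeration tractable.
    """
    if world.n > 20:
        raise ValueError(f"refusing exhaustive search over 2^{world.n} subsets (n > 20)")
    best_set: frozenset = frozenset()
    best_rate = global_rate_forgo_world(world, ())
    for size in range(1, world.n + 1):
        for subset in combinations(range(world.n), size):
            rate = global_rate_forgo_world(world, subset)
            if rate > best_rate:
                best_set, best_rate = frozenset(subset), rate
    return best_set, best_rate
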