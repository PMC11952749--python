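"""World-spec file I/O and random-world generation.

Three spec layouts are accepted, in YAML or JSON (chosen by extension;
YAML is a superset so either parser reads both):

full Forgo world::

    pursuits:
      - {label: A, reward: 2.0, duration: 1.0, frequency: 0.5}
      - {label: B, reward: 4.0, duration: 2.0, frequency: 0.25}
    default_rate: 0.0

reduced pursuit-in-context (r_in/t_in inside, r_out/t_out outside)::

    {r_in: 4.0, t_in: 4.0, r_out: 0.7, t_out: 3.0}

choice (SS vs LL sharing one outside)::

    ss: {reward: 2.5, duration: 2.5}
    ll: {reward: 5.0, duration: 8.5}
    outside: {r_out: 0.0, t_out: 6.0}

Exactly one layout must be present; validation errors name the offending
field and constraint.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Tuple, Union

import numpy as np
import yaml

from .world import ForgoWorld, OutsideContext, Pursuit

__all__ = [
    "ChoiceSpec",
    "load_world_spec",
    "save_world_spec",
    "generate_random_world",
]


@dataclass(frozen=True)
class ChoiceSpec:
    ss: Pursuit
    ll: Pursuit
    outside: OutsideContext


WorldLike = Union[ForgoWorld, Tuple[Pursuit, OutsideContext], ChoiceSpec]

_REDUCED_KEYS = {"r_in", "t_in", "r_out", "t_out"}

# generator defaults: moderate laboratory-scale worlds with mixed-sign
# rewards, sub-unit to ~10 time-unit durations and sub-unit default rates
_DEFAULT_RANGES: Mapping[str, Tuple[float, float]] = {
    "duration": (0.1, 10.0),
    "reward": (-5.0, 10.0),
    "frequency": (0.05, 2.0),
    "default_rate": (0.0, 1.0),
}


class SpecError(ValueError):
    """A world-spec file violated the schema."""


def _require_number(mapping: Mapping, key: str, where: str) -> float:
    if key not in mapping:
        raise SpecError(f"{where}: missing required field {key!r}")
    value = mapping[key]
    try:
        value = float(value)
    except (TypeError, ValueError):
        raise SpecError(f"{where}: field {key!r} must be a number, got {value!r}") from None
    if not np.isfinite(value):
        raise SpecError(f"{where}: field {key!r} must be finite, got {value!r}")
    return value


def _parse_pursuit(mapping: Mapping, where: str) -> Pursuit:
    if not isinstance(mapping, Mapping):
        raise SpecError(f"{where}: expected a mapping with reward/duration")
    reward = _require_number(mapping, "reward", where)
    duration = _require_number(mapping, "duration", where)
    if duration <= 0:
        raise SpecError(f"{where}: field 'duration' must be > 0, got {duration}")
    return Pursuit(reward, duration, mapping.get("label"))


def _parse_outside(mapping: Mapping, where: str) -> OutsideContext:
    r_out = _require_number(mapping, "r_out", where)
    t_out = _require_number(mapping, "t_out", where)
    if t_out <= 0:
        raise SpecError(f"{where}: field 't_out' must be > 0, got {t_out}")
    return OutsideContext(r_out, t_out)


def _load_raw(path: Union[str, Path]) -> Mapping:
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json":
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    if not isinstance(raw, Mapping):
        raise SpecError(f"{path}: top level must be a mapping")
    return raw


def load_world_spec(path: Union[str, Path]) -> WorldLike:
    """Load and validate a world-spec file (see module docstring for layouts)."""
    raw = _load_raw(path)
    where = str(path)
    forms = [
        "pursuits" in raw,
        _REDUCED_KEYS <= set(raw),
        "ss" in raw or "ll" in raw,
    ]
    if sum(forms) != 1:
        raise SpecError(
            f"{where}: exactly one of the full ('pursuits'), reduced "
            f"(r_in/t_in/r_out/t_out) or choice (ss/ll/outside) layouts must be present"
        )
    if forms[0]:
        entries = raw["pursuits"]
        if not isinstance(entries, (list, tuple)) or not entries:
            raise SpecError(f"{where}: 'pursuits' must be a non-empty list")
        pursuits, freqs = [], []
        for i, entry in enumerate(entries):
            p = _parse_pursuit(entry, f"{where}: pursuits[{i}]")
            f = _require_number(entry, "frequency", f"{where}: pursuits[{i}]")
            if f <= 0:
                raise SpecError(f"{where}: pursuits[{i}]: 'frequency' must be > 0, got {f}")
            pursuits.append(p)
            freqs.append(f)
        default_rate = _require_number(raw, "default_rate", where) if "default_rate" in raw else 0.0
        return ForgoWorld(tuple(pursuits), tuple(freqs), default_rate)
    if forms[1]:
        t_in = _require_number(raw, "t_in", where)
        if t_in < 0:
            raise SpecError(f"{where}: field 't_in' must be >= 0, got {t_in}")
        pursuit = Pursuit(_require_number(raw, "r_in", where), t_in)
        return pursuit, _parse_outside(raw, where)
    for key in ("ss", "ll", "outside"):
        if key not in raw:
            raise SpecError(f"{where}: choice layout requires field {key!r}")
    return ChoiceSpec(
        ss=_parse_pursuit(raw["ss"], f"{where}: ss"),
        ll=_parse_pursuit(raw["ll"], f"{where}: ll"),
        outside=_parse_outside(raw["outside"], f"{where}: outside"),
    )


def save_world_spec(obj: WorldLike, path: Union[str, Path]) -> None:
    """Write a world back to disk in the matching layout (YAML or JSON by extension)."""
    if isinstance(obj, ForgoWorld):
        data = {
            "pursuits": [
                {
                    **({"label": p.label} if p.label is not None else {}),
                    "reward": p.reward,
                    "duration": p.duration,
                    "frequency": f,
                }
                for p, f in zip(obj.pursuits, obj.frequencies)
            ],
            "default_rate": obj.default_rate,
        }
    elif isinstance(obj, ChoiceSpec):
        data = {
            "ss": {"reward": obj.ss.reward, "duration": obj.ss.duration},
            "ll": {"reward": obj.ll.reward, "duration": obj.ll.duration},
            "outside": {"r_out": obj.outside.outside_reward, "t_out": obj.outside.outside_time},
        }
    else:
        pursuit, outside = obj
        data = {
            "r_in": pursuit.reward,
            "t_in": pursuit.duration,
            "r_out": outside.outside_reward,
            "t_out": outside.outside_time,
        }
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2), encoding="utf-8")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False), encoding="utf-8")


def generate_random_world(
    n_pursuits: int,
    seed: int,
    ranges: Optional[Mapping[str, Tuple[float, float]]] = None,
) -> ForgoWorld:
    """Random valid Forgo world for property tests; deterministic given seed.

    Durations, rewards, frequencies and the default rate are drawn
    uniformly from ``ranges`` (defaults in ``_DEFAULT_RANGES``; rewards
    may be negative, durations and frequencies are positive).
    ``n_pursuits = 0`` yields a default-only world.
    """
    if n_pursuits < 0:
        raise ValueError("n_pursuits must be >= 0")
    bounds = dict(_DEFAULT_RANGES)
    if ranges:
        bounds.update(ranges)
    rng = np.random.default_rng(seed)
    pursuits = tuple(
        Pursuit(
            reward=float(rng.uniform(*bounds["reward"])),
            duration=float(rng.uniform(*bounds["duration"])),
            label=f"p{i}",
        )
        for i in range(n_pursuits)
    )
    freqs = tuple(float(rng.uniform(*bounds["frequency"])) for _ in range(n_pursuits))
    return ForgoWorld(pursuits, freqs, float(rng.uniform(*bounds["default_rate"])))
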