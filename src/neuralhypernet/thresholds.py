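"""Loading and evaluation of the vertex/antivertex risk-range map.

Each analysis variable is split into two boolean descriptors: ``var[1]``
("the observed value is a risk sign") and its antivertex ``var[0]`` ("the
observed value is not a risk sign").  The ranges live in an editable YAML
file — they are clinical data, not code — and :func:`load_threshold_map`
parses them into :class:`Interval` pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

_RANGE_KEYS = {"equals", "min", "max", "min_exclusive", "max_exclusive"}


@dataclass(frozen=True)
class Interval:
    """A one-dimensional range with optionally exclusive bounds."""

    equals: float | None = None
    min: float = -math.inf
    max: float = math.inf
    min_exclusive: bool = False
    max_exclusive: bool = False

    def contains(self, value: float) -> bool:
        if self.equals is not None:
            return value == self.equals
        lo_ok = value > self.min if self.min_exclusive else value >= self.min
        hi_ok = value < self.max if self.max_exclusive else value <= self.max
        return lo_ok and hi_ok


#: variable name -> (antivertex range, vertex range)
ThresholdMap = dict[str, tuple[Interval, Interval]]


def _parse_range(variable: str, polarity: str, spec: dict) -> Interval:
    unknown = set(spec) - _RANGE_KEYS
    if unknown:
        raise ValueError(
            f"threshold map entry {variable}[{polarity}]: unknown keys {sorted(unknown)}"
        )
    return Interval(
        equals=spec.get("equals"),
        min=spec.get("min", -math.inf),
        max=spec.get("max", math.inf),
        min_exclusive=bool(spec.get("min_exclusive", False)),
        max_exclusive=bool(spec.get("max_exclusive", False)),
    )


def load_threshold_map(path: str | Path | None = None) -> ThresholdMap:
    """Read a YAML risk-range map; the packaged default when *path* is None."""
    if path is None:
        text = (
            resources.files("neuralhypernet").joinpath("data/thresholds.yaml").read_text()
        )
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ValueError("threshold map must be a mapping of variable -> ranges")
    out: ThresholdMap = {}
    for variable, ranges in raw.items():
        if not isinstance(ranges, dict) or set(ranges) != {"0", "1"}:
            raise ValueError(
                f"threshold map entry {variable!r} must define exactly the "
                f"'0' and '1' ranges"
            )
        out[variable] = (
            _parse_range(variable, "0", ranges["0"]),
            _parse_range(variable, "1", ranges["1"]),
        )
    return out
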