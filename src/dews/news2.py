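"""NEWS-2 aggregate score and per-parameter sub-scores.

The scorer is table-driven: the published band chart ships as a versioned
CSV resource (``resources/news2_bands.csv``) and all banding decisions are
lookups into that table. SpO2 scale 2 (chronic respiratory disease, target
saturations 88-92%) is selected at episode level via the ``chronic_resp``
argument; the high-saturation scale-2 bands differ on air vs on oxygen and
are encoded with a ``condition`` column.

Measured values are compared to band edges after rounding to the chart's
granularity: respiration, pulse, SBP and SpO2 to the nearest integer,
temperature to one decimal.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources as importlib_resources

from .data_model import (
    ACVPU_ORDINAL,
    AdmissionEpisode,
    ObservationSet,
    filter_complete,
)

_EPS = 1e-9

COMPONENTS = (
    "resp_rate",
    "spo2",
    "supplemental_o2",
    "sbp",
    "heart_rate",
    "consciousness",
    "temperature",
)


@dataclass(frozen=True)
class News2Result:
    components: dict[str, int]
    total: int
    scale_used: str  # "scale1" | "scale2"


@dataclass(frozen=True)
class _Band:
    lower: float
    upper: float
    condition: str  # "", "air" or "oxygen"
    points: int

    def contains(self, value: float, on_oxygen: bool) -> bool:
        if self.condition == "air" and on_oxygen:
            return False
        if self.condition == "oxygen" and not on_oxygen:
            return False
        return self.lower - _EPS <= value <= self.upper + _EPS


@lru_cache(maxsize=None)
def _load_bands() -> dict[tuple[str, str], tuple[_Band, ...]]:
    table: dict[tuple[str, str], list[_Band]] = {}
    ref = importlib_resources.files("dews.resources").joinpath("news2_bands.csv")
    with ref.open(newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            key = (row["parameter"], row["scale"])
            lower = float(row["lower"]) if row["lower"] else -math.inf
            upper = float(row["upper"]) if row["upper"] else math.inf
            table.setdefault(key, []).append(
                _Band(lower, upper, row["condition"], int(row["points"]))
            )
    return {k: tuple(v) for k, v in table.items()}


def _lookup(parameter: str, scale: str, value: float, on_oxygen: bool) -> int:
    bands = _load_bands().get((parameter, scale)) or _load_bands().get(
        (parameter, "all")
    )
    if bands is None:
        raise KeyError(f"no bands for parameter {parameter!r}")
    for band in bands:
        if band.contains(value, on_oxygen):
            return band.points
    raise ValueError(f"value {value} outside all {parameter} bands")


def news2_score(obs: ObservationSet, chronic_resp: bool) -> News2Result:
    """Score one complete observation set against the NEWS-2 chart.

    ``chronic_resp`` selects SpO2 scale 2; it is an episode-level flag,
    not a per-observation one.
    """
    if not obs.is_complete:
        raise ValueError("news2_score requires a complete observation set")
    scale = "2" if chronic_resp else "1"
    on_o2 = obs.on_oxygen
    components = {
        "resp_rate": _lookup("resp_rate", "all", round(obs.resp_rate), on_o2),
        "spo2": _lookup("spo2", scale, round(obs.spo2), on_o2),
        "supplemental_o2": _lookup(
            "supplemental_o2", "all", 1.0 if on_o2 else 0.0, on_o2
        ),
        "sbp": _lookup("sbp", "all", round(obs.sbp), on_o2),
        "heart_rate": _lookup("heart_rate", "all", round(obs.heart_rate), on_o2),
        "consciousness": _lookup(
            "consciousness", "all", ACVPU_ORDINAL[obs.acvpu], on_o2
        ),
        "temperature": _lookup(
            "temperature", "all", round(obs.temperature, 1), on_o2
        ),
    }
    return News2Result(
        components=components,
        total=sum(components.values()),
        scale_used=f"scale{scale}",
    )


def max_news2(episode: AdmissionEpisode) -> int:
    """Maximum NEWS-2 total over the episode's complete observation sets."""
    complete = filter_complete(episode.observations)
    if not complete:
        raise ValueError(
            f"episode {episode.episode_id} has no complete observation sets"
        )
    chronic = episode.chronic_resp_flag
    return max(news2_score(o, chronic).total for o in complete)
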