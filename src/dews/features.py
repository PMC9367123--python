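"""38-dimensional raw + engineered feature vectors for scoring rows.

Manifest (38 features):

* 11 static — hinge splits above/below the normal band for the four
  U-shaped vitals (heart rate, respiratory rate, SBP, temperature), a
  low-side hinge for SpO2, the inspired-oxygen ordinal (0-5) and the
  ACVPU ordinal (Alert=0 .. Unresponsive=4);
* 21 dynamic — difference from the previous observation, rolling mean and
  rolling sample SD (window 5, minimum 3) for each of 7 channels;
* 6 slope categories — 0 normal-stable, 1 normal-unstable, 2
  outside-improving, 3 outside-stable, 4 outside-worsening, for the 6
  continuous channels (ACVPU excluded).

Normal bands are the NEWS-2 zero-score bands; SpO2 uses the scale-2 band
(88-92) for chronic-respiratory episodes. Bands, slope/SD tolerances and
the inspired-oxygen mapping ship as editable resource files.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources as importlib_resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .data_model import (
    ACVPU_ORDINAL,
    AdmissionEpisode,
    O2Mode,
    ObservationSet,
    scoring_history,
)
from .news2 import news2_score

logger = logging.getLogger(__name__)

MANIFEST_VERSION = "1.0"

#: (channel key, observation attribute) pairs; fio2/acvpu are derived.
CHANNELS = ("hr", "rr", "sbp", "temp", "spo2", "fio2", "acvpu")
SLOPE_CHANNELS = ("hr", "rr", "sbp", "temp", "spo2", "fio2")

STATIC_FEATURES = (
    "hr_high",
    "hr_low",
    "rr_high",
    "rr_low",
    "sbp_high",
    "sbp_low",
    "temp_high",
    "temp_low",
    "spo2_low",
    "fio2",
    "acvpu",
)

DYNAMIC_FEATURES = tuple(
    f"{ch}_{stat}" for ch in CHANNELS for stat in ("delta", "rollmean", "rollsd")
)

SLOPE_FEATURES = tuple(f"{ch}_slopecat" for ch in SLOPE_CHANNELS)

FEATURE_NAMES = STATIC_FEATURES + DYNAMIC_FEATURES + SLOPE_FEATURES

assert len(FEATURE_NAMES) == 38

_CHANNEL_TO_BAND = {
    "hr": "heart_rate",
    "rr": "resp_rate",
    "sbp": "sbp",
    "temp": "temperature",
    "spo2": "spo2",
    "fio2": "fio2",
}


@dataclass(frozen=True)
class NormalBand:
    parameter: str
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not self.lower <= self.upper:
            raise ValueError(f"band for {self.parameter}: lower > upper")

    def contains(self, value: float) -> bool:
        return self.lower <= value <= self.upper


@dataclass(frozen=True)
class ChannelConfig:
    band: NormalBand
    slope_tol: float  # units per hour
    sd_tol: float  # same units as the channel


@lru_cache(maxsize=None)
def load_channel_config() -> dict[str, ChannelConfig]:
    ref = importlib_resources.files("dews.resources").joinpath("normal_bands.csv")
    out: dict[str, ChannelConfig] = {}
    with ref.open(newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            out[row["channel"]] = ChannelConfig(
                band=NormalBand(
                    row["channel"], float(row["lower"]), float(row["upper"])
                ),
                slope_tol=float(row["slope_tol"]),
                sd_tol=float(row["sd_tol"]),
            )
    return out


@lru_cache(maxsize=None)
def _fio2_table() -> dict[str, list[tuple[float, float, int]]]:
    ref = importlib_resources.files("dews.resources").joinpath("fio2_mapping.csv")
    table: dict[str, list[tuple[float, float, int]]] = {}
    with ref.open(newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            lower = float(row["lower"])
            upper = float(row["upper"]) if row["upper"] else math.inf
            table.setdefault(row["mode"], []).append(
                (lower, upper, int(row["ordinal"]))
            )
    return table


def encode_fio2(o2_mode: O2Mode, o2_value: Optional[float]) -> int:
    """Ordinal inspired-oxygen level: 0 (none) .. 5 (very high).

    Flow bands are L/min; concentration bands are percent. Lower edges are
    exclusive, upper edges inclusive.
    """
    if o2_mode == O2Mode.AIR:
        return 0
    if o2_value is None:
        raise ValueError(f"o2_value required for mode {o2_mode}")
    for lower, upper, ordinal in _fio2_table()[o2_mode.value]:
        if lower < o2_value <= upper:
            return ordinal
    return 0  # below the lowest band (e.g. 21% "concentration" = air)


def hinge_split(value: float, band: NormalBand) -> tuple[float, float]:
    """Split into (low, high) exceedances; at most one is nonzero."""
    return max(0.0, band.lower - value), max(0.0, value - band.upper)


def delta(history: Sequence[float]) -> float:
    """Current minus previous value; 0 when no previous observation exists."""
    if len(history) < 2:
        return 0.0
    return history[-1] - history[-2]


def rolling_stats(
    history: Sequence[float], window: int = 5, min_n: int = 3
) -> Optional[tuple[float, float]]:
    """Mean and sample SD of the up-to-``window`` most recent values.

    Returns ``None`` when fewer than ``min_n`` values are available.
    """
    tail = np.asarray(history[-window:], dtype=float)
    if tail.size < min_n:
        return None
    return float(tail.mean()), float(tail.std(ddof=1))


def _ls_slope(times_h: np.ndarray, values: np.ndarray) -> float:
    t = times_h - times_h.mean()
    denom = float(t @ t)
    if denom == 0.0:
        return 0.0
    return float(t @ (values - values.mean())) / denom


def slope_category(
    times_h: Sequence[float],
    values: Sequence[float],
    band: NormalBand,
    slope_tol: float,
    sd_tol: float,
    window: int = 5,
    min_n: int = 3,
) -> int:
    """Categorise recent values relative to the normal band.

    0 normal-stable, 1 normal-unstable, 2 outside-improving,
    3 outside-stable, 4 outside-worsening. Fewer than ``min_n`` values in
    the window yields 0 by convention.
    """
    t = np.asarray(times_h[-window:], dtype=float)
    v = np.asarray(values[-window:], dtype=float)
    if v.size < min_n:
        return 0
    current = v[-1]
    if band.contains(current):
        return 0 if v.std(ddof=1) <= sd_tol else 1
    s = _ls_slope(t, v)
    if abs(s) <= slope_tol:
        return 3
    toward = s < 0 if current > band.upper else s > 0
    return 2 if toward else 4


# ---------------------------------------------------------------------------
# Feature assembly


@dataclass
class FeatureVector:
    episode_id: str
    timestamp: object
    values: dict[str, float]
    label: Optional[int] = None

    def __post_init__(self) -> None:
        if tuple(self.values) != FEATURE_NAMES:
            raise ValueError("feature vector does not match the manifest")


def _channel_value(obs: ObservationSet, channel: str) -> float:
    if channel == "hr":
        return float(obs.heart_rate)
    if channel == "rr":
        return float(obs.resp_rate)
    if channel == "sbp":
        return float(obs.sbp)
    if channel == "temp":
        return float(obs.temperature)
    if channel == "spo2":
        return float(obs.spo2)
    if channel == "fio2":
        return float(encode_fio2(obs.o2_mode, obs.o2_value))
    if channel == "acvpu":
        return float(ACVPU_ORDINAL[obs.acvpu])
    raise KeyError(channel)


def _band_for(channel: str, chronic_resp: bool) -> ChannelConfig:
    cfg = load_channel_config()
    if channel == "spo2" and chronic_resp:
        return cfg["spo2_scale2"]
    return cfg[_CHANNEL_TO_BAND[channel]]


def build_features(
    episode: AdmissionEpisode,
    at: int,
    k: int = 2,
    truncate_at_terminal: bool = True,
) -> FeatureVector:
    """Build the 38-feature vector for the observation at index ``at``.

    ``at`` indexes the episode's complete (and, by default, pre-terminal)
    observation list; it must be a scoring-eligible index (``at >= k``).
    Only observations up to and including ``at`` are used.
    """
    history, start = scoring_history(episode, k, truncate_at_terminal)
    if not 0 <= at < len(history):
        raise IndexError(f"observation index {at} out of range")
    if at < start:
        raise ValueError(
            f"observation index {at} is excluded from scoring (first {start})"
        )
    window = history[: at + 1]
    return _features_from_window(episode, window)


def _features_from_window(
    episode: AdmissionEpisode, window: Sequence[ObservationSet]
) -> FeatureVector:
    chronic = episode.chronic_resp_flag
    obs = window[-1]
    t0 = window[0].timestamp
    times_h = [(o.timestamp - t0).total_seconds() / 3600.0 for o in window]
    series = {ch: [_channel_value(o, ch) for o in window] for ch in CHANNELS}

    values: dict[str, float] = {}
    for ch, feat in (("hr", "hr"), ("rr", "rr"), ("sbp", "sbp"), ("temp", "temp")):
        low, high = hinge_split(series[ch][-1], _band_for(ch, chronic).band)
        values[f"{feat}_high"] = high
        values[f"{feat}_low"] = low
    # supranormal saturation carries no risk: low-side hinge only
    values["spo2_low"] = hinge_split(
        series["spo2"][-1], _band_for("spo2", chronic).band
    )[0]
    values["fio2"] = series["fio2"][-1]
    values["acvpu"] = series["acvpu"][-1]

    for ch in CHANNELS:
        hist = series[ch]
        values[f"{ch}_delta"] = delta(hist)
        stats = rolling_stats(hist)
        if stats is None:
            # undefined rolling window: encoded as 0 on the raw scale
            values[f"{ch}_rollmean"] = 0.0
            values[f"{ch}_rollsd"] = 0.0
        else:
            values[f"{ch}_rollmean"], values[f"{ch}_rollsd"] = stats

    for ch in SLOPE_CHANNELS:
        cfg = _band_for(ch, chronic)
        values[f"{ch}_slopecat"] = float(
            slope_category(times_h, series[ch], cfg.band, cfg.slope_tol, cfg.sd_tol)
        )

    ordered = {name: values[name] for name in FEATURE_NAMES}
    return FeatureVector(
        episode_id=episode.episode_id, timestamp=obs.timestamp, values=ordered
    )


def build_feature_table(
    episodes: Sequence[AdmissionEpisode],
    k: int = 2,
    truncate_at_terminal: bool = True,
    include_news2: bool = True,
) -> pd.DataFrame:
    """Feature rows for every scoring-eligible observation in the cohort.

    Columns: episode_id, timestamp, (news2_total,) then the 38 manifest
    features in order.
    """
    rows = []
    for ep in episodes:
        history, start = scoring_history(ep, k, truncate_at_terminal)
        chronic = ep.chronic_resp_flag
        for at in range(start, len(history)):
            fv = _features_from_window(ep, history[: at + 1])
            row = {"episode_id": ep.episode_id, "timestamp": fv.timestamp}
            if include_news2:
                row["news2_total"] = news2_score(history[at], chronic).total
            row.update(fv.values)
            rows.append(row)
    columns = ["episode_id", "timestamp"]
    if include_news2:
        columns.append("news2_total")
    columns.extend(FEATURE_NAMES)
    return pd.DataFrame(rows, columns=columns)


# ---------------------------------------------------------------------------
# Normalization


@dataclass
class Normalizer:
    """Per-feature zero-mean/unit-variance transform with stored constants."""

    feature_names: tuple[str, ...]
    means: np.ndarray
    sds: np.ndarray
    constant_features: tuple[str, ...] = field(default_factory=tuple)

    @classmethod
    def fit(cls, matrix: np.ndarray, feature_names: Sequence[str]) -> "Normalizer":
        x = np.asarray(matrix, dtype=float)
        if x.ndim != 2 or x.shape[0] < 2:
            raise ValueError("need at least two training vectors")
        means = x.mean(axis=0)
        sds = x.std(axis=0, ddof=1)
        constant = sds <= 0
        names = tuple(feature_names)
        constant_names = tuple(n for n, c in zip(names, constant) if c)
        if constant_names:
            logger.warning(
                "constant features normalized with SD=1: %s",
                ", ".join(constant_names),
            )
        sds = np.where(constant, 1.0, sds)
        return cls(names, means, sds, constant_names)

    def transform(self, matrix: np.ndarray) -> np.ndarray:
        x = np.asarray(matrix, dtype=float)
        return (x - self.means) / self.sds

    def to_dict(self) -> dict:
        return {
            "feature_names": list(self.feature_names),
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "constant_features": list(self.constant_features),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Normalizer":
        return cls(
            tuple(d["feature_names"]),
            np.asarray(d["means"], dtype=float),
            np.asarray(d["sds"], dtype=float),
            tuple(d.get("constant_features", ())),
        )
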