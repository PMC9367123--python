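"""Seeded generator of ward-like vital-sign cohorts.

Episodes are sequences of roughly 4-hourly observation sets. Each vital
follows a stationary AR(1) process around a per-episode baseline drawn
from a truncated normal; deteriorating episodes superimpose a linear ramp
(with noise) on one of several archetypes (respiratory, septic, cardiac,
bradycardic) over a lead-time window that ends at the outcome event. A
configurable fraction of episodes carries the chronic-respiratory
(SpO2 scale 2) label with a lower saturation baseline.

``generate_from_logistic_truth`` instead draws row labels from a known
logistic model on the engineered features, so that model training can be
checked against a ground-truth coefficient vector.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from datetime import datetime, timedelta, timezone
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .data_model import (
    Acvpu,
    AdmissionEpisode,
    EventKind,
    O2Mode,
    ObservationSet,
    OutcomeEvent,
)
from .features import FEATURE_NAMES, Normalizer, build_feature_table

_EPOCH = datetime(2021, 1, 1, tzinfo=timezone.utc)


class ConfigError(ValueError):
    """The simulation configuration is invalid or infeasible."""


#: per-vital (baseline mean, baseline sd, AR noise sd, clip lo, clip hi)
VITAL_PARAMS = {
    "heart_rate": (78.0, 9.0, 4.0, 45.0, 150.0),
    "resp_rate": (16.0, 2.2, 1.2, 8.0, 40.0),
    "sbp": (125.0, 14.0, 6.0, 70.0, 210.0),
    "temperature": (36.8, 0.35, 0.15, 34.0, 40.5),
    "spo2": (96.5, 1.2, 0.8, 75.0, 100.0),
}

#: archetype -> ramp magnitudes added linearly over the lead window
ARCHETYPES = {
    "respiratory": {
        "resp_rate": 9.0,
        "spo2": -7.0,
        "heart_rate": 14.0,
        "o2_flow": 6.0,
    },
    "septic": {"heart_rate": 28.0, "sbp": -28.0, "temperature": 1.8},
    "cardiac": {"heart_rate": 32.0, "sbp": -24.0, "spo2": -3.0},
    "bradycardic": {"heart_rate": -32.0, "temperature": -1.6},
}

ARCHETYPE_CSD_CODES = {
    "respiratory": "resp_failure",
    "septic": "sepsis",
    "cardiac": "arrhythmia",
    "bradycardic": "bradycardia",
}


@dataclass
class SimConfig:
    n_episodes: int = 500
    mean_obs_per_episode: float = 14.0
    min_obs_per_episode: int = 9
    interval_hours: float = 4.0
    interval_jitter_hours: float = 1.0
    ar_coef: float = 0.7
    p_deteriorate: float = 0.12
    lead_time_hours: tuple[float, float] = (12.0, 28.0)
    archetype_mix: dict[str, float] = field(
        default_factory=lambda: {
            "respiratory": 0.35,
            "septic": 0.30,
            "cardiac": 0.25,
            "bradycardic": 0.10,
        }
    )
    event_kind_probs: dict[str, float] = field(
        default_factory=lambda: {"csd": 0.60, "icu_admission": 0.25, "death": 0.15}
    )
    chronic_resp_fraction: float = 0.15
    missing_rate: float = 0.005
    start_spread_days: float = 365.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_episodes < 1:
            raise ConfigError("n_episodes must be >= 1")
        for name, probs in (
            ("archetype_mix", self.archetype_mix),
            ("event_kind_probs", self.event_kind_probs),
        ):
            if any(p < 0 for p in probs.values()) or not math.isclose(
                sum(probs.values()), 1.0, abs_tol=1e-9
            ):
                raise ConfigError(f"{name} must be nonnegative and sum to 1")
        if not 0.0 <= self.p_deteriorate <= 1.0:
            raise ConfigError("p_deteriorate must be in [0, 1]")
        span = (self.min_obs_per_episode - 1) * self.interval_hours
        if self.lead_time_hours[1] > span:
            raise ConfigError(
                f"max lead time {self.lead_time_hours[1]} h exceeds the "
                f"minimum episode span {span} h"
            )

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "lead_time_hours" in raw:
            raw["lead_time_hours"] = tuple(raw["lead_time_hours"])
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(f"bad simulation config: {exc}") from None

    def to_dict(self) -> dict:
        d = asdict(self)
        d["lead_time_hours"] = list(self.lead_time_hours)
        return d


def _truncnorm(rng: np.random.Generator, mean, sd, lo, hi) -> float:
    for _ in range(100):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(min(max(mean, lo), hi))


def _simulate_episode(
    rng: np.random.Generator, config: SimConfig, index: int
) -> AdmissionEpisode:
    episode_id = f"ep{index:05d}"
    chronic = rng.random() < config.chronic_resp_fraction
    n_obs = max(
        config.min_obs_per_episode, int(rng.poisson(config.mean_obs_per_episode))
    )
    start = _EPOCH + timedelta(
        days=float(rng.uniform(0, config.start_spread_days))
    )
    gaps = np.maximum(
        1.0,
        rng.normal(config.interval_hours, config.interval_jitter_hours, n_obs - 1),
    )
    times_h = np.concatenate([[0.0], np.cumsum(gaps)])

    baselines = {}
    for vital, (mean, sd, _, lo, hi) in VITAL_PARAMS.items():
        if vital == "spo2" and chronic:
            mean, sd, lo, hi = 91.0, 1.5, 82.0, 96.0
        baselines[vital] = _truncnorm(rng, mean, sd, lo, hi)

    deteriorates = rng.random() < config.p_deteriorate
    archetype = None
    event_time_h = None
    lead = None
    if deteriorates:
        names = sorted(config.archetype_mix)
        probs = np.array([config.archetype_mix[n] for n in names])
        archetype = names[rng.choice(len(names), p=probs / probs.sum())]
        lead = float(rng.uniform(*config.lead_time_hours))
        event_time_h = float(times_h[-1] + rng.uniform(0.5, 2.0))

    series = {}
    for vital, (_, _, noise_sd, lo, hi) in VITAL_PARAMS.items():
        base = baselines[vital]
        if vital == "spo2" and chronic:
            lo, hi = 75.0, 100.0
        x = np.empty(n_obs)
        level = base + rng.normal(0, noise_sd)
        for i in range(n_obs):
            level = base + config.ar_coef * (level - base) + rng.normal(0, noise_sd)
            x[i] = level
        if deteriorates and vital in ARCHETYPES[archetype]:
            onset = event_time_h - lead
            frac = np.clip((times_h - onset) / lead, 0.0, 1.0)
            x = x + frac * ARCHETYPES[archetype][vital]
        series[vital] = np.clip(x, lo, hi)

    o2_flow = np.zeros(n_obs)
    if chronic and rng.random() < 0.5:
        o2_flow += 1.0  # long-term low-flow oxygen
    if deteriorates and "o2_flow" in ARCHETYPES[archetype]:
        onset = event_time_h - lead
        frac = np.clip((times_h - onset) / lead, 0.0, 1.0)
        o2_flow = o2_flow + frac * ARCHETYPES[archetype]["o2_flow"]
    o2_flow = np.round(o2_flow * 2) / 2  # charted to the half litre

    observations = []
    for i in range(n_obs):
        acvpu = Acvpu.ALERT
        if deteriorates and event_time_h is not None:
            frac = (times_h[i] - (event_time_h - lead)) / lead
            if frac > 0.7 and rng.random() < 0.3:
                acvpu = Acvpu.CONFUSED if rng.random() < 0.6 else Acvpu.VOICE
        flow = float(o2_flow[i])
        obs = ObservationSet(
            episode_id=episode_id,
            timestamp=start + timedelta(hours=float(times_h[i])),
            heart_rate=round(float(series["heart_rate"][i]), 0),
            resp_rate=round(float(series["resp_rate"][i]), 0),
            sbp=round(float(series["sbp"][i]), 0),
            temperature=round(float(series["temperature"][i]), 1),
            spo2=round(float(series["spo2"][i]), 0),
            o2_mode=O2Mode.FLOW if flow > 0 else O2Mode.AIR,
            o2_value=flow if flow > 0 else None,
            acvpu=acvpu,
            scale2_label=chronic,
        )
        if rng.random() < config.missing_rate:
            dropped = rng.choice(
                ["heart_rate", "resp_rate", "sbp", "temperature", "spo2"]
            )
            setattr(obs, dropped, None)
        observations.append(obs)

    events = []
    if deteriorates:
        kinds = sorted(config.event_kind_probs)
        probs = np.array([config.event_kind_probs[k] for k in kinds])
        kind = EventKind(kinds[rng.choice(len(kinds), p=probs / probs.sum())])
        events.append(
            OutcomeEvent(
                episode_id=episode_id,
                timestamp=start + timedelta(hours=event_time_h),
                kind=kind,
                csd_code=(
                    ARCHETYPE_CSD_CODES[archetype]
                    if kind == EventKind.CSD
                    else None
                ),
            )
        )

    return AdmissionEpisode(
        episode_id=episode_id,
        observations=observations,
        events=events,
        age=_truncnorm(rng, 66.0, 17.0, 18.0, 100.0),
        sex="F" if rng.random() < 0.53 else "M",
    )


def generate_cohort(config: SimConfig) -> list[AdmissionEpisode]:
    """Generate a seed-reproducible ward-like cohort."""
    rng = np.random.default_rng(config.seed)
    return [_simulate_episode(rng, config, i) for i in range(config.n_episodes)]


def default_truth(
    intercept: float = -3.5, magnitude: float = 0.9
) -> tuple[dict[str, float], float]:
    """A reference ground-truth coefficient vector on the 38-feature manifest.

    Signs follow clinical direction: high heart/respiratory rate, low blood
    pressure, low saturation, rising oxygen requirement and adverse slope
    categories increase risk.
    """
    truth = {name: 0.0 for name in FEATURE_NAMES}
    for name, sign in [
        ("hr_high", +1),
        ("rr_high", +1),
        ("sbp_low", +1),
        ("temp_low", +1),
        ("spo2_low", +1),
        ("fio2", +1),
        ("acvpu", +1),
        ("hr_delta", +1),
        ("rr_delta", +1),
        ("sbp_delta", -1),
        ("hr_rollsd", +1),
        ("hr_slopecat", +1),
        ("rr_slopecat", +1),
    ]:
        truth[name] = sign * magnitude
    return truth, intercept


def generate_from_logistic_truth(
    config: SimConfig,
    truth: Optional[dict[str, float]] = None,
    intercept: Optional[float] = None,
) -> tuple[pd.DataFrame, list[AdmissionEpisode], dict[str, float], float]:
    """Cohort whose row labels are drawn from a known logistic model.

    A stationary (non-deteriorating) cohort is generated, its feature table
    built and normalised on itself, and each scoring row labelled
    Bernoulli(sigmoid(intercept + truth . z)). Returns
    ``(table, episodes, truth, intercept)`` with the truth stored beside
    the cohort for oracle use; the table carries the true probability in a
    ``true_prob`` column.
    """
    if truth is None or intercept is None:
        default_w, default_b = default_truth()
        truth = truth if truth is not None else default_w
        intercept = intercept if intercept is not None else default_b
    if tuple(truth) != FEATURE_NAMES:
        raise ValueError("truth coefficients do not match the 38-feature manifest")

    base = SimConfig(**{**config.to_dict(), "p_deteriorate": 0.0})
    episodes = generate_cohort(base)
    table = build_feature_table(episodes, include_news2=False)
    x = table[list(FEATURE_NAMES)].to_numpy(dtype=float)
    normalizer = Normalizer.fit(x, FEATURE_NAMES)
    z = normalizer.transform(x)
    w = np.array([truth[name] for name in FEATURE_NAMES])
    prob = 1.0 / (1.0 + np.exp(-(intercept + z @ w)))
    rng = np.random.default_rng(config.seed + 1)
    table = table.copy()
    table["true_prob"] = prob
    table["label"] = (rng.random(len(prob)) < prob).astype(int)
    return table, episodes, dict(truth), float(intercept)
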