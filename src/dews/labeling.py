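"""Outcome labels for scoring rows and episode-level train/validation splits.

Two outcome definitions are built in: death or ICU admission within 24 h
(``D_ICU``) and clinically significant deterioration within 4 h (``CSD``).
A row is positive when any qualifying event falls strictly after the
observation and no later than the horizon:  t_obs < t_e <= t_obs + horizon
(an event at the instant of observation is a concurrent detection, not a
prediction).

Episodes are truncated at the first death/ICU event — no scoring rows are
produced afterwards — and observations after an earlier CSD event remain
in the data, re-labelled against later events.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import datetime, timedelta
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .data_model import AdmissionEpisode, EventKind, scoring_history

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OutcomeSpec:
    name: str
    horizon: timedelta
    kinds: tuple[EventKind, ...]

    def __post_init__(self) -> None:
        if self.horizon <= timedelta(0):
            raise ValueError("horizon must be positive")


D_ICU = OutcomeSpec(
    "d_icu", timedelta(hours=24), (EventKind.DEATH, EventKind.ICU_ADMISSION)
)
CSD = OutcomeSpec("csd", timedelta(hours=4), (EventKind.CSD,))

OUTCOMES = {"d_icu": D_ICU, "csd": CSD}


def label_observations(
    episode: AdmissionEpisode,
    spec: OutcomeSpec,
    k: int = 2,
    truncate_at_terminal: bool = True,
) -> list[int]:
    """Binary label per scoring-eligible observation set, in time order."""
    history, start = scoring_history(episode, k, truncate_at_terminal)
    event_times = _qualifying_event_times(episode, spec)
    return [
        _label_one(o.timestamp, event_times, spec.horizon)
        for o in history[start:]
    ]


def _qualifying_event_times(
    episode: AdmissionEpisode, spec: OutcomeSpec
) -> list[datetime]:
    times = [e.timestamp for e in episode.events if e.kind in spec.kinds]
    if episode.observations:
        first_obs = episode.observations[0].timestamp
        ignored = [t for t in times if t < first_obs]
        if ignored:
            logger.warning(
                "episode %s: %d %s event(s) before the first observation "
                "ignored for labelling",
                episode.episode_id,
                len(ignored),
                spec.name,
            )
            times = [t for t in times if t >= first_obs]
    return times


def _label_one(
    t_obs: datetime, event_times: Sequence[datetime], horizon: timedelta
) -> int:
    return int(any(t_obs < t_e <= t_obs + horizon for t_e in event_times))


def label_table(
    table: pd.DataFrame,
    episodes: Sequence[AdmissionEpisode],
    spec: OutcomeSpec,
) -> pd.DataFrame:
    """Append a ``label`` column to a feature table (episode_id, timestamp)."""
    by_id = {ep.episode_id: ep for ep in episodes}
    labels = np.zeros(len(table), dtype=int)
    for i, (episode_id, t_obs) in enumerate(
        zip(table["episode_id"], table["timestamp"])
    ):
        ep = by_id.get(episode_id)
        if ep is None:
            continue
        labels[i] = _label_one(
            t_obs, _qualifying_event_times(ep, spec), spec.horizon
        )
    out = table.copy()
    out["label"] = labels
    return out


def split_cohort(
    episodes: Sequence[AdmissionEpisode],
    n_train: Optional[int] = None,
    seed: Optional[int] = None,
    cutoff: Optional[datetime] = None,
) -> tuple[list[AdmissionEpisode], list[AdmissionEpisode]]:
    """Episode-level train/validation split.

    Exactly one of ``n_train`` (random mode, seed-reproducible) or
    ``cutoff`` (temporal mode, by last-observation time) must be given.
    No episode ever straddles both sides.
    """
    episodes = list(episodes)
    if (n_train is None) == (cutoff is None):
        raise ValueError("specify exactly one of n_train or cutoff")
    if cutoff is not None:
        train = [e for e in episodes if _last_time(e) <= cutoff]
        valid = [e for e in episodes if _last_time(e) > cutoff]
        if not train or not valid:
            logger.warning("temporal cutoff %s leaves one side empty", cutoff)
        return train, valid
    if not 0 <= n_train <= len(episodes):
        raise ValueError(
            f"n_train={n_train} outside [0, {len(episodes)}]"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(episodes))
    train_idx = set(order[:n_train].tolist())
    train = [e for i, e in enumerate(episodes) if i in train_idx]
    valid = [e for i, e in enumerate(episodes) if i not in train_idx]
    return train, valid


def _last_time(episode: AdmissionEpisode) -> datetime:
    if not episode.observations:
        raise ValueError(f"episode {episode.episode_id} has no observations")
    return episode.observations[-1].timestamp
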