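from __future__ import annotations

from datetime import datetime, timedelta, timezone

import pytest

from dews.data_model import (
    Acvpu,
    AdmissionEpisode,
    EventKind,
    O2Mode,
    ObservationSet,
    OutcomeEvent,
)

T0 = datetime(2021, 3, 1, 8, 0, tzinfo=timezone.utc)


@pytest.fixture
def make_obs():
    """Factory for a complete, all-normal observation set with overrides."""

    def factory(episode_id="ep1", hours=0.0, **overrides):
        fields = dict(
            heart_rate=70.0,
            resp_rate=16.0,
            sbp=120.0,
            temperature=37.0,
            spo2=97.0,
            o2_mode=O2Mode.AIR,
            o2_value=None,
            acvpu=Acvpu.ALERT,
            scale2_label=False,
        )
        fields.update(overrides)
        return ObservationSet(
            episode_id=episode_id,
            timestamp=T0 + timedelta(hours=hours),
            **fields,
        )

    return factory


@pytest.fixture
def make_episode(make_obs):
    """Factory for an episode of n complete 4-hourly observation sets."""

    def factory(episode_id="ep1", n=5, events=(), interval=4.0, **obs_overrides):
        observations = [
            make_obs(episode_id=episode_id, hours=i * interval, **obs_overrides)
            for i in range(n)
        ]
        return AdmissionEpisode(
            episode_id=episode_id,
            observations=observations,
            events=list(events),
            age=70.0,
            sex="F",
        )

    return factory


@pytest.fixture
def make_event():
    def factory(episode_id="ep1", hours=0.0, kind=EventKind.CSD, csd_code="sepsis"):
        if kind != EventKind.CSD:
            csd_code = None
        return OutcomeEvent(
            episode_id=episode_id,
            timestamp=T0 + timedelta(hours=hours),
            kind=kind,
            csd_code=csd_code,
        )

    return factory
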