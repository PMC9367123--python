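"""Domain types, delimited-text I/O and row-level exclusion filters.

The atomic unit is the :class:`ObservationSet` — one time-stamped group of
vital signs. Observation sets belong to an :class:`AdmissionEpisode`, which
also carries the episode's outcome events and a derived chronic-respiratory
flag (true when any observation set was recorded on oxygen-saturation
scale 2).

All timestamps are handled as absolute instants: ISO-8601 strings with an
explicit UTC offset are parsed to timezone-aware datetimes; naive inputs
are interpreted as UTC. Horizon arithmetic (4 h / 24 h) is therefore
DST-safe.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Sequence

logger = logging.getLogger(__name__)

CLINICAL_FIELDS = (
    "heart_rate",
    "resp_rate",
    "sbp",
    "temperature",
    "spo2",
    "oxygen",  # mode plus, for flow/concentration, the value
    "acvpu",
)

OBS_COLUMNS = [
    "episode_id",
    "timestamp",
    "heart_rate",
    "resp_rate",
    "sbp",
    "temperature",
    "spo2",
    "o2_mode",
    "o2_value",
    "acvpu",
    "scale2_label",
]

EVENT_COLUMNS = ["episode_id", "timestamp", "kind", "csd_code"]

META_COLUMNS = ["episode_id", "age", "sex"]


class SchemaError(ValueError):
    """An input file does not conform to the expected schema."""


class CohortError(ValueError):
    """A cohort-level contract violation (e.g. too many bad rows)."""


class O2Mode(str, Enum):
    AIR = "air"
    FLOW = "flow"
    CONCENTRATION = "concentration"


class Acvpu(str, Enum):
    ALERT = "Alert"
    CONFUSED = "Confused"
    VOICE = "Voice"
    PAIN = "Pain"
    UNRESPONSIVE = "Unresponsive"


ACVPU_ORDINAL = {
    Acvpu.ALERT: 0,
    Acvpu.CONFUSED: 1,
    Acvpu.VOICE: 2,
    Acvpu.PAIN: 3,
    Acvpu.UNRESPONSIVE: 4,
}


class EventKind(str, Enum):
    DEATH = "death"
    ICU_ADMISSION = "icu_admission"
    CSD = "csd"


#: Event kinds that terminate scoring for an episode.
TERMINAL_KINDS = (EventKind.DEATH, EventKind.ICU_ADMISSION)


@dataclass(frozen=True)
class RowError:
    line: int
    message: str


def parse_timestamp(text: str) -> datetime:
    """Parse an ISO-8601 timestamp; naive values are taken as UTC."""
    ts = datetime.fromisoformat(text.strip())
    if ts.tzinfo is None:
        ts = ts.replace(tzinfo=timezone.utc)
    return ts


def format_timestamp(ts: datetime) -> str:
    if ts.tzinfo is None:
        ts = ts.replace(tzinfo=timezone.utc)
    return ts.isoformat()


@dataclass
class ObservationSet:
    """One time-stamped set of vital signs; missing fields are ``None``."""

    episode_id: str
    timestamp: datetime
    heart_rate: Optional[float] = None
    resp_rate: Optional[float] = None
    sbp: Optional[float] = None
    temperature: Optional[float] = None
    spo2: Optional[float] = None
    o2_mode: Optional[O2Mode] = None
    o2_value: Optional[float] = None
    acvpu: Optional[Acvpu] = None
    scale2_label: bool = False

    @property
    def on_oxygen(self) -> bool:
        return self.o2_mode is not None and self.o2_mode != O2Mode.AIR

    @property
    def is_complete(self) -> bool:
        """All seven clinical fields present.

        ``o2_mode=air`` is a valid (non-missing) oxygen state; a flow or
        concentration mode without a value is incomplete.
        """
        if None in (
            self.heart_rate,
            self.resp_rate,
            self.sbp,
            self.temperature,
            self.spo2,
            self.acvpu,
            self.o2_mode,
        ):
            return False
        if self.o2_mode != O2Mode.AIR and self.o2_value is None:
            return False
        return True


@dataclass
class OutcomeEvent:
    episode_id: str
    timestamp: datetime
    kind: EventKind
    csd_code: Optional[str] = None

    def __post_init__(self) -> None:
        if (self.kind == EventKind.CSD) != (self.csd_code is not None):
            raise ValueError(
                "csd_code must be present exactly when kind is 'csd' "
                f"(episode {self.episode_id})"
            )


@dataclass
class AdmissionEpisode:
    episode_id: str
    observations: list[ObservationSet] = field(default_factory=list)
    events: list[OutcomeEvent] = field(default_factory=list)
    age: Optional[float] = None
    sex: Optional[str] = None

    def __post_init__(self) -> None:
        # Stable sort keeps file order for duplicate timestamps.
        self.observations.sort(key=lambda o: o.timestamp)
        self.events.sort(key=lambda e: e.timestamp)
        n_death = sum(1 for e in self.events if e.kind == EventKind.DEATH)
        if n_death > 1:
            raise ValueError(
                f"episode {self.episode_id} has {n_death} death events"
            )
        ts = [o.timestamp for o in self.observations]
        for a, b in zip(ts, ts[1:]):
            if a == b:
                logger.info(
                    "episode %s: duplicate observation timestamp %s kept in "
                    "file order",
                    self.episode_id,
                    a,
                )
                break

    @property
    def chronic_resp_flag(self) -> bool:
        """True iff any observation set was recorded on SpO2 scale 2."""
        return any(o.scale2_label for o in self.observations)

    def terminal_time(self) -> Optional[datetime]:
        """Timestamp of the first death/ICU event, if any."""
        times = [e.timestamp for e in self.events if e.kind in TERMINAL_KINDS]
        return min(times) if times else None


# ---------------------------------------------------------------------------
# Filters


def filter_complete(obs: Sequence[ObservationSet]) -> list[ObservationSet]:
    """Keep only complete observation sets, preserving order."""
    return [o for o in obs if o.is_complete]


def exclude_initial(
    episode: AdmissionEpisode, k: int = 2
) -> list[ObservationSet]:
    """Scoring-eligible observations: complete sets minus the first ``k``.

    The dropped sets are not returned but remain part of the episode and
    feed history windows for the retained sets.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    return filter_complete(episode.observations)[k:]


def scoring_history(
    episode: AdmissionEpisode,
    k: int = 2,
    truncate_at_terminal: bool = True,
) -> tuple[list[ObservationSet], int]:
    """Return ``(history, start)`` for scoring an episode.

    ``history`` is the complete-case observation list (optionally truncated
    at the first death/ICU event); rows ``history[start:]`` are the
    scoring-eligible observation sets, while earlier rows serve only as
    history for rolling-window features.
    """
    complete = filter_complete(episode.observations)
    if truncate_at_terminal:
        t_term = episode.terminal_time()
        if t_term is not None:
            complete = [o for o in complete if o.timestamp < t_term]
    return complete, min(k, len(complete))


# ---------------------------------------------------------------------------
# Delimited-text I/O


def _parse_float(text: str) -> Optional[float]:
    text = text.strip()
    return float(text) if text else None


def _parse_bool(text: str) -> bool:
    return text.strip().lower() in ("true", "1", "yes")


def _check_columns(header: Sequence[str], required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in header]
    if missing:
        raise SchemaError(f"{what} file is missing columns: {', '.join(missing)}")


def _parse_obs_row(row: dict, line: int) -> ObservationSet:
    mode_text = (row.get("o2_mode") or "").strip()
    mode = O2Mode(mode_text) if mode_text else None
    acvpu_text = (row.get("acvpu") or "").strip()
    acvpu = Acvpu(acvpu_text) if acvpu_text else None
    return ObservationSet(
        episode_id=row["episode_id"].strip(),
        timestamp=parse_timestamp(row["timestamp"]),
        heart_rate=_parse_float(row.get("heart_rate") or ""),
        resp_rate=_parse_float(row.get("resp_rate") or ""),
        sbp=_parse_float(row.get("sbp") or ""),
        temperature=_parse_float(row.get("temperature") or ""),
        spo2=_parse_float(row.get("spo2") or ""),
        o2_mode=mode,
        o2_value=_parse_float(row.get("o2_value") or ""),
        acvpu=acvpu,
        scale2_label=_parse_bool(row.get("scale2_label") or ""),
    )


def read_cohort(
    obs_path: str | Path,
    events_path: str | Path,
    meta_path: str | Path | None = None,
    max_error_fraction: float = 0.10,
) -> tuple[list[AdmissionEpisode], list[RowError]]:
    """Assemble episodes from observation/event (and optional metadata) files.

    Malformed rows are collected as :class:`RowError` with their line
    numbers; the read fails only when more than ``max_error_fraction`` of
    rows are malformed.
    """
    errors: list[RowError] = []
    obs_by_episode: dict[str, list[ObservationSet]] = {}
    n_rows = 0

    with open(obs_path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError(f"observations file {obs_path} is empty")
        _check_columns(reader.fieldnames, OBS_COLUMNS, "observations")
        for line, row in enumerate(reader, start=2):
            n_rows += 1
            try:
                obs = _parse_obs_row(row, line)
            except (ValueError, KeyError) as exc:
                errors.append(RowError(line, f"observations: {exc}"))
                continue
            obs_by_episode.setdefault(obs.episode_id, []).append(obs)

    events_by_episode: dict[str, list[OutcomeEvent]] = {}
    with open(events_path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError(f"events file {events_path} is empty")
        _check_columns(reader.fieldnames, EVENT_COLUMNS, "events")
        for line, row in enumerate(reader, start=2):
            n_rows += 1
            try:
                event = OutcomeEvent(
                    episode_id=row["episode_id"].strip(),
                    timestamp=parse_timestamp(row["timestamp"]),
                    kind=EventKind(row["kind"].strip()),
                    csd_code=(row.get("csd_code") or "").strip() or None,
                )
            except (ValueError, KeyError) as exc:
                errors.append(RowError(line, f"events: {exc}"))
                continue
            events_by_episode.setdefault(event.episode_id, []).append(event)

    meta: dict[str, tuple[Optional[float], Optional[str]]] = {}
    if meta_path is not None:
        with open(meta_path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None:
                raise SchemaError(f"metadata file {meta_path} is empty")
            _check_columns(reader.fieldnames, META_COLUMNS, "metadata")
            for line, row in enumerate(reader, start=2):
                try:
                    meta[row["episode_id"].strip()] = (
                        _parse_float(row.get("age") or ""),
                        (row.get("sex") or "").strip() or None,
                    )
                except (ValueError, KeyError) as exc:
                    errors.append(RowError(line, f"metadata: {exc}"))

    if n_rows and len(errors) > max_error_fraction * n_rows:
        raise CohortError(
            f"{len(errors)} of {n_rows} rows malformed "
            f"(> {max_error_fraction:.0%}); first: {errors[0].message}"
        )

    episodes = []
    for episode_id in sorted(obs_by_episode):
        age, sex = meta.get(episode_id, (None, None))
        episodes.append(
            AdmissionEpisode(
                episode_id=episode_id,
                observations=obs_by_episode[episode_id],
                events=events_by_episode.pop(episode_id, []),
                age=age,
                sex=sex,
            )
        )
    for episode_id in events_by_episode:
        logger.warning("events for unknown episode %s ignored", episode_id)
    return episodes, errors


def _fmt(value: Optional[float]) -> str:
    if value is None:
        return ""
    return repr(value) if isinstance(value, float) else str(value)


def write_cohort(
    episodes: Iterable[AdmissionEpisode],
    obs_path: str | Path,
    events_path: str | Path,
    meta_path: str | Path | None = None,
) -> None:
    """Write a cohort back to delimited text (round-trips bit-exactly)."""
    episodes = list(episodes)
    with open(obs_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(OBS_COLUMNS)
        for ep in episodes:
            for o in ep.observations:
                writer.writerow(
                    [
                        o.episode_id,
                        format_timestamp(o.timestamp),
                        _fmt(o.heart_rate),
                        _fmt(o.resp_rate),
                        _fmt(o.sbp),
                        _fmt(o.temperature),
                        _fmt(o.spo2),
                        o.o2_mode.value if o.o2_mode else "",
                        _fmt(o.o2_value),
                        o.acvpu.value if o.acvpu else "",
                        str(o.scale2_label).lower(),
                    ]
                )
    with open(events_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(EVENT_COLUMNS)
        for ep in episodes:
            for e in ep.events:
                writer.writerow(
                    [
                        e.episode_id,
                        format_timestamp(e.timestamp),
                        e.kind.value,
                        e.csd_code or "",
                    ]
                )
    if meta_path is not None:
        with open(meta_path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(META_COLUMNS)
            for ep in episodes:
                writer.writerow([ep.episode_id, _fmt(ep.age), ep.sex or ""])
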