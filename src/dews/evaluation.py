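"""ROC/PR metrics, bootstrap intervals, matched cut-points and 4-hour
event-window detection.

Conventions
-----------
* A positive call is ``score >= threshold``.
* AUROC is the Mann-Whitney probability that a random positive outscores a
  random negative, ties counted one half (equivalently the trapezoidal ROC
  integral); computed from ranks.
* AUPRC is average precision: a step-function sum over descending scores,
  with tied scores handled as a block (no linear interpolation, which is
  optimistic on heavily unbalanced data).
* False-positive and false-negative rates are expressed as a percentage of
  ALL observation sets, not of a single class.
* An event is detected when any observation of its episode scored at or
  above threshold within the 4 hours up to and including the event time.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from datetime import timedelta
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .data_model import OutcomeEvent

logger = logging.getLogger(__name__)


class UndefinedMetricError(ValueError):
    """The requested metric is undefined on the given data."""


def _as_arrays(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be 1-D and aligned")
    return s, y


def auroc(scores, labels) -> float:
    """Area under the ROC curve via the rank (Mann-Whitney) identity."""
    s, y = _as_arrays(scores, labels)
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("AUROC requires both classes")
    ranks = rankdata(s)
    rank_sum = ranks[y == 1].sum()
    return (rank_sum - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def auprc(scores, labels) -> float:
    """Average precision with tied scores handled as a block."""
    s, y = _as_arrays(scores, labels)
    n_pos = int(y.sum())
    if n_pos == 0:
        raise UndefinedMetricError("AUPRC requires at least one positive")
    order = np.argsort(-s, kind="stable")
    s, y = s[order], y[order]
    ap = 0.0
    tp = 0
    n_seen = 0
    i = 0
    n = s.size
    while i < n:
        j = i
        while j < n and s[j] == s[i]:
            j += 1
        block_pos = int(y[i:j].sum())
        tp += block_pos
        n_seen = j
        if block_pos:
            precision = tp / n_seen
            ap += precision * (block_pos / n_pos)
        i = j
    return ap


def bootstrap_ci(
    metric: Callable[[np.ndarray, np.ndarray], float],
    scores,
    labels,
    B: int = 500,
    level: float = 0.95,
    seed: Optional[int] = None,
    max_undefined_fraction: float = 0.20,
) -> tuple[float, float]:
    """Percentile bootstrap interval over resampled observation sets."""
    s, y = _as_arrays(scores, labels)
    metric(s, y)  # must be defined on the full data
    rng = np.random.default_rng(seed)
    values = []
    n_undefined = 0
    n = s.size
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        try:
            values.append(metric(s[idx], y[idx]))
        except UndefinedMetricError:
            n_undefined += 1
    if n_undefined > max_undefined_fraction * B:
        raise UndefinedMetricError(
            f"metric undefined in {n_undefined}/{B} bootstrap resamples"
        )
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(values, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


@dataclass(frozen=True)
class ThresholdRow:
    score_name: str
    threshold: float
    sensitivity: float  # percent
    specificity: float  # percent
    fp_rate_pct_all_obs: float
    fn_rate_pct_all_obs: float

    def to_dict(self) -> dict:
        return {
            "score": self.score_name,
            "threshold": self.threshold,
            "sensitivity_pct": self.sensitivity,
            "specificity_pct": self.specificity,
            "fp_rate_pct_all_obs": self.fp_rate_pct_all_obs,
            "fn_rate_pct_all_obs": self.fn_rate_pct_all_obs,
        }


def threshold_metrics(
    scores, labels, threshold: float, score_name: str = "score"
) -> ThresholdRow:
    s, y = _as_arrays(scores, labels)
    call = s >= threshold
    tp = int(np.sum(call & (y == 1)))
    fp = int(np.sum(call & (y == 0)))
    fn = int(np.sum(~call & (y == 1)))
    tn = int(np.sum(~call & (y == 0)))
    n = s.size
    sens = 100.0 * tp / (tp + fn) if (tp + fn) else math.nan
    spec = 100.0 * tn / (tn + fp) if (tn + fp) else math.nan
    return ThresholdRow(
        score_name=score_name,
        threshold=float(threshold),
        sensitivity=sens,
        specificity=spec,
        fp_rate_pct_all_obs=100.0 * fp / n,
        fn_rate_pct_all_obs=100.0 * fn / n,
    )


def matched_threshold(
    ref_scores,
    cand_scores,
    labels,
    ref_threshold: float,
    mode: str,
    score_name: str = "candidate",
) -> tuple[float, ThresholdRow]:
    """Candidate threshold matching a reference operating point.

    ``mode='specificity'``: smallest candidate threshold whose specificity
    is at least the reference's (maximises sensitivity at matched
    specificity). ``mode='sensitivity'``: largest candidate threshold whose
    sensitivity is at least the reference's. The search runs over observed
    candidate scores plus +inf; an unattainable target returns the extreme
    threshold with a warning.
    """
    if mode not in ("sensitivity", "specificity"):
        raise ValueError("mode must be 'sensitivity' or 'specificity'")
    ref_row = threshold_metrics(ref_scores, labels, ref_threshold)
    target = getattr(ref_row, mode)
    candidates = np.concatenate(
        [np.unique(np.asarray(cand_scores, dtype=float)), [np.inf]]
    )
    feasible = [
        t
        for t in candidates
        if getattr(threshold_metrics(cand_scores, labels, t), mode) >= target
    ]
    if not feasible:
        logger.warning(
            "matched_threshold: target %s %.1f%% unattainable; returning -inf",
            mode,
            target,
        )
        chosen = -math.inf
    else:
        chosen = min(feasible) if mode == "specificity" else max(feasible)
    return chosen, threshold_metrics(cand_scores, labels, chosen, score_name)


# ---------------------------------------------------------------------------
# Event-level detection


@dataclass(frozen=True)
class DetectionCrossTab:
    both_detected: int
    only_a: int
    only_b: int
    neither: int

    @property
    def total(self) -> int:
        return self.both_detected + self.only_a + self.only_b + self.neither

    def to_dict(self) -> dict:
        return {
            "both_detected": self.both_detected,
            "only_a": self.only_a,
            "only_b": self.only_b,
            "neither": self.neither,
            "total_events": self.total,
        }


def event_detection(
    events: Sequence[OutcomeEvent],
    scored: pd.DataFrame,
    threshold: float,
    score_column: str = "score",
    window: timedelta = timedelta(hours=4),
) -> list[bool]:
    """Per-event detection flag.

    An event is detected iff any observation of its episode with timestamp
    in [t_event - window, t_event] has ``score >= threshold``. Events with
    no observation in the window count as not detected (flagged in the
    log).
    """
    out = []
    grouped = dict(tuple(scored.groupby("episode_id", sort=False)))
    for event in events:
        rows = grouped.get(event.episode_id)
        if rows is None:
            logger.warning(
                "event in episode %s has no scored observations",
                event.episode_id,
            )
            out.append(False)
            continue
        in_window = rows[
            (rows["timestamp"] >= event.timestamp - window)
            & (rows["timestamp"] <= event.timestamp)
        ]
        if in_window.empty:
            logger.warning(
                "event at %s in episode %s has no observations within %s",
                event.timestamp,
                event.episode_id,
                window,
            )
            out.append(False)
        else:
            out.append(bool((in_window[score_column] >= threshold).any()))
    return out


def cross_tab(
    events: Sequence[OutcomeEvent],
    scored_a: pd.DataFrame,
    threshold_a: float,
    scored_b: pd.DataFrame,
    threshold_b: float,
    score_column_a: str = "score",
    score_column_b: str = "score",
    window: timedelta = timedelta(hours=4),
) -> DetectionCrossTab:
    """Partition events by which of two scoring systems detected them."""
    det_a = event_detection(events, scored_a, threshold_a, score_column_a, window)
    det_b = event_detection(events, scored_b, threshold_b, score_column_b, window)
    both = sum(a and b for a, b in zip(det_a, det_b))
    only_a = sum(a and not b for a, b in zip(det_a, det_b))
    only_b = sum(b and not a for a, b in zip(det_a, det_b))
    neither = sum(not a and not b for a, b in zip(det_a, det_b))
    return DetectionCrossTab(both, only_a, only_b, neither)


# ---------------------------------------------------------------------------
# Report assembly


def score_summary(
    scores, labels, B: int = 500, seed: Optional[int] = None
) -> dict:
    """AUROC and AUPRC with percentile bootstrap CIs."""
    out = {}
    for name, metric in (("auroc", auroc), ("auprc", auprc)):
        value = metric(scores, labels)
        lo, hi = bootstrap_ci(metric, scores, labels, B=B, seed=seed)
        out[name] = {"value": value, "ci_lo": lo, "ci_hi": hi}
    return out


def evaluate_scores(
    table: pd.DataFrame,
    events: Sequence[OutcomeEvent] | None = None,
    dews_column: str = "dews",
    news2_column: Optional[str] = "news2_total",
    news2_thresholds: Sequence[float] = (5, 7),
    B: int = 500,
    seed: Optional[int] = None,
    window: timedelta = timedelta(hours=4),
) -> dict:
    """Full evaluation report for one (or two) scores on a labelled table.

    Mirrors the study's reporting: area summaries with bootstrap CIs, a
    threshold table at the reference cut-points with matched candidate
    cut-points (both matching modes), and — when events are supplied — the
    two-score event-detection cross-tab at the first reference cut-point
    and its matched-specificity candidate threshold.
    """
    labels = table["label"].to_numpy()
    dews_scores = table[dews_column].to_numpy()
    report: dict = {
        "n_observation_sets": int(len(table)),
        "n_positive": int(labels.sum()),
        "scores": {"dews": score_summary(dews_scores, labels, B=B, seed=seed)},
        "thresholds": [],
    }
    if news2_column is None or news2_column not in table.columns:
        return report

    news2_scores = table[news2_column].to_numpy()
    report["scores"]["news2"] = score_summary(news2_scores, labels, B=B, seed=seed)

    matched_spec_first: Optional[float] = None
    for ref_thr in news2_thresholds:
        ref_row = threshold_metrics(news2_scores, labels, ref_thr, "news2")
        report["thresholds"].append(ref_row.to_dict())
        for mode in ("specificity", "sensitivity"):
            thr, row = matched_threshold(
                news2_scores, dews_scores, labels, ref_thr, mode, "dews"
            )
            entry = row.to_dict()
            entry["matched_to"] = {"score": "news2", "threshold": ref_thr,
                                   "mode": mode}
            report["thresholds"].append(entry)
            if matched_spec_first is None and mode == "specificity":
                matched_spec_first = thr

    if events is not None and matched_spec_first is not None:
        scored = table[["episode_id", "timestamp", news2_column, dews_column]]
        tab = cross_tab(
            events,
            scored,
            news2_thresholds[0],
            scored,
            matched_spec_first,
            score_column_a=news2_column,
            score_column_b=dews_column,
            window=window,
        )
        report["event_cross_tab"] = tab.to_dict()
        report["event_cross_tab"]["thresholds"] = {
            "news2": news2_thresholds[0],
            "dews": matched_spec_first,
        }
    return report
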