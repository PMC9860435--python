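"""Score a finished deployment against simulator ground truth, and the
capture-economics comparison between triggered and timed acquisition.

Triggers are matched one-to-one to truth windows greedily in time order;
a trigger counts as matching a window when it falls within the window
widened by one motion-detect interval on each side (the engine samples
the scene at that granularity). Windows the engine provably could not
catch — those fully inside the rest shadow of an earlier trigger — are
excluded from the sensitivity denominator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

from .simulate import TruthWindow

__all__ = [
    "TriggerMetrics",
    "match_events",
    "score_deployment",
    "intervalometer_equivalent",
    "metrics_report",
]


@dataclass
class TriggerMetrics:
    """Trigger-performance summary for one deployment."""

    expected_events: int
    matchable_events: int
    matched_events: int
    sensitivity: float  # matched / matchable
    false_triggers: int  # triggers overlapping no truth window
    false_trigger_rate_per_hour: float
    images_captured: int
    intervalometer_equivalent_count: int
    duration_hours: float
    matches: list[tuple[float, int]] = field(default_factory=list)  # (trigger_t, window idx)


def match_events(
    trigger_times: list[float],
    windows: list[TruthWindow],
    tolerance: float,
) -> tuple[list[tuple[float, int]], list[float]]:
    """Greedy one-to-one matching of triggers to truth windows.

    Triggers are processed in time order; each is assigned to the
    earliest-ending unmatched window whose widened interval
    ``[start - tolerance, end + tolerance]`` contains it (this greedy
    rule attains the maximum matching for interval overlap). Returns
    (matches, false_triggers) where false triggers overlap *no* window
    at all, matched or not.
    """
    order = sorted(range(len(windows)), key=lambda i: windows[i].end_s)
    taken = [False] * len(windows)
    matches: list[tuple[float, int]] = []
    false: list[float] = []
    for t in sorted(trigger_times):
        overlapping = [
            i for i in order
            if windows[i].start_s - tolerance <= t <= windows[i].end_s + tolerance
        ]
        if not overlapping:
            false.append(t)
            continue
        for i in overlapping:
            if not taken[i]:
                taken[i] = True
                matches.append((t, i))
                break
        # overlaps only already-matched windows: neither matched nor false
    return matches, false


def score_deployment(
    rec,
    truth_windows: list[TruthWindow],
    *,
    detect_interval: float | None = None,
) -> TriggerMetrics:
    """Compute trigger metrics for a finished deployment record.

    ``rec`` is a :class:`~octotrigger.deployment.DeploymentRecord` (or any
    object with ``trigger_times``, ``images_captured``, ``duration_s``
    and ``settings``). Truth must share the deployment clock: windows
    beyond the deployment duration raise an error.
    """
    duration_s = rec.duration_s
    for w in truth_windows:
        if w.start_s < 0 or w.start_s > duration_s + 1e-9:
            raise ValueError(
                f"truth window at {w.start_s} s lies outside the deployment "
                f"clock [0, {duration_s:.0f} s]; clocks are misaligned"
            )
    s = rec.settings
    if detect_interval is None:
        detect_interval = float(s.motion.motion_detect_interval)
    matches, false = match_events(
        list(rec.trigger_times), truth_windows, tolerance=detect_interval
    )
    matchable = [w for w in truth_windows if w.matchable]
    matched_matchable = sum(1 for _, i in matches if truth_windows[i].matchable)
    n_matchable = len(matchable)
    sensitivity = matched_matchable / n_matchable if n_matchable else 1.0
    duration_h = duration_s / 3600.0
    rate = len(false) / duration_h if duration_h > 0 else 0.0
    return TriggerMetrics(
        expected_events=len(truth_windows),
        matchable_events=n_matchable,
        matched_events=matched_matchable,
        sensitivity=sensitivity,
        false_triggers=len(false),
        false_trigger_rate_per_hour=rate,
        images_captured=rec.images_captured,
        intervalometer_equivalent_count=intervalometer_equivalent(
            duration_h, detect_interval
        ),
        duration_hours=duration_h,
        matches=matches,
    )


def intervalometer_equivalent(duration_hours: float, interval_seconds: float) -> int:
    """Images a fixed-interval time-lapse would take over the same span.

    ``floor(duration_hours * 3600 / interval_seconds)`` — the yardstick
    for how much capture (and later screening) effort triggering saves.
    """
    if interval_seconds <= 0:
        raise ValueError("interval_seconds must be > 0")
    if duration_hours < 0:
        raise ValueError("duration_hours must be >= 0")
    return math.floor(duration_hours * 3600.0 / interval_seconds)


def metrics_report(m: TriggerMetrics) -> str:
    """Human-readable summary of a metrics object."""
    lines = [
        f"expected events:            {m.expected_events}",
        f"matchable events:           {m.matchable_events}",
        f"matched events:             {m.matched_events}",
        f"sensitivity:                {m.sensitivity:.3f}",
        f"false triggers:             {m.false_triggers}",
        f"false-trigger rate (/h):    {m.false_trigger_rate_per_hour:.3f}",
        f"images captured:            {m.images_captured}",
        f"intervalometer equivalent:  {m.intervalometer_equivalent_count}",
        f"duration (h):               {m.duration_hours:.2f}",
    ]
    return "\n".join(lines)


def metrics_to_csv(m: TriggerMetrics, path: str | Path) -> None:
    """Write the metrics as a one-row CSV."""
    import pandas as pd

    row = {k: v for k, v in m.__dict__.items() if k != "matches"}
    pd.DataFrame([row]).to_csv(path, index=False)
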