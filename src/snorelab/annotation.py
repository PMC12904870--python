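"""Event timeline: episode construction, third-sound measurement, labeling.

The selection logic mirrors how preapneic and continuous/simple snores are
identified clinically from an annotated sleep-endoscopy recording:

* a snoring *episode* is a run of at least three similar snoring events in a
  row (similar = close in time and without a level jump between them);
* the *third* sound of an episode is the one measured;
* if an apnea (>= 10 s cessation, AASM) immediately follows the measured
  episode, that third sound is *preapneic*; if more snoring follows, it is
  *continuous* (also called simple);
* the opening snore right after an apnea is acoustically atypical and is
  excluded; the episode count restarts at the next event;
* sounds overlapping examination maneuvers or exhibiting level jumps are
  excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "MarkerKind",
    "EventMarker",
    "SnoreEpisode",
    "LabeledEvent",
    "AnnotationConfig",
    "read_markers",
    "write_labels",
    "build_episodes",
    "label_measured_events",
    "annotate",
]

MARKER_KINDS = ("snore", "apnea", "maneuver", "level_jump")

LABEL_PREAPNEIC = "preapneic"
LABEL_CONTINUOUS = "continuous"
LABEL_EXCLUDED = "excluded"

REASON_NOT_THIRD = "not_third"
REASON_OPENING = "opening_snore"
REASON_MANEUVER = "maneuver"
REASON_LEVEL_JUMP = "level_jump"
REASON_ISOLATED = "isolated_event"


@dataclass
class EventMarker:
    """One annotated interval on the recording timeline."""

    onset_s: float
    offset_s: float
    kind: str
    level_db: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in MARKER_KINDS:
            raise ValueError(f"unknown marker kind {self.kind!r}")
        if not self.offset_s > self.onset_s:
            raise ValueError(
                f"marker offset ({self.offset_s}) must exceed onset ({self.onset_s})"
            )

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s

    def overlaps(self, other: "EventMarker") -> bool:
        return self.onset_s < other.offset_s and other.onset_s < self.offset_s


@dataclass
class SnoreEpisode:
    """A maximal run of similar snores, after opening-snore removal.

    ``opening_event`` is the atypical first snore after an apnea; it sits
    outside ``events`` so the episode counter restarts at the next snore.
    ``terminal`` is ``"apnea"`` when an apnea immediately follows the run's
    last snore, else ``"none"``.
    """

    events: list
    terminal: str = "none"
    opening_event: Optional[EventMarker] = None

    @property
    def measurable(self) -> bool:
        return len(self.events) >= 3

    def n_events(self) -> int:
        return len(self.events)


@dataclass
class LabeledEvent:
    """A snore marker with its measurement label."""

    event: EventMarker
    label: str
    reason: Optional[str] = None


@dataclass
class AnnotationConfig:
    """Thresholds of the selection logic.

    apnea_min_gap_s
        Minimum apnea duration (AASM definition: 10 s cessation of airflow).
    max_interonset_s
        Largest onset-to-onset gap between "similar snoring events in a
        row"; one slow breathing cycle is an upper bound.
    level_jump_db
        Largest RMS level difference between consecutive snores of one
        episode; a larger step is a level jump (e.g. velum to tongue
        snoring) and splits the run.
    min_episode_events / measured_index
        An episode needs at least three events; the third one is measured.
    infer_apnea_from_gaps
        When True, an unmarked silent gap >= apnea_min_gap_s after a run is
        treated as apnea evidence.  Off by default: apneas are expected as
        explicit, audio-visually confirmed markers.
    """

    apnea_min_gap_s: float = 10.0
    max_interonset_s: float = 10.0
    level_jump_db: float = 8.0
    min_episode_events: int = 3
    measured_index: int = 3
    infer_apnea_from_gaps: bool = False

    def __post_init__(self) -> None:
        if min(self.apnea_min_gap_s, self.max_interonset_s, self.level_jump_db) <= 0:
            raise ValueError("annotation thresholds must be positive")
        if self.measured_index > self.min_episode_events:
            raise ValueError("measured_index cannot exceed min_episode_events")


def read_markers(path) -> list:
    """Read an event-marker CSV (columns onset_s, offset_s, kind[, level_db]).

    Markers are returned sorted by onset.  Overlapping snore markers are
    merged (with a warning); apnea rows shorter than the 10 s AASM minimum
    are rejected (dropped with a warning naming the row).
    """
    df = pd.read_csv(path)
    required = {"onset_s", "offset_s", "kind"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: marker CSV needs columns {sorted(required)}")
    markers = []
    for i, row in df.iterrows():
        kind = str(row["kind"]).strip()
        if kind not in MARKER_KINDS:
            raise ValueError(f"{path}: row {i}: unknown marker kind {kind!r}")
        onset, offset = float(row["onset_s"]), float(row["offset_s"])
        if not offset > onset:
            raise ValueError(f"{path}: row {i}: offset_s must exceed onset_s")
        level = None
        if "level_db" in df.columns and pd.notna(row.get("level_db")):
            level = float(row["level_db"])
        if kind == "apnea" and offset - onset < 10.0:
            logger.warning(
                "%s: row %d: apnea of %.1f s rejected: below AASM minimum of 10 s",
                path, i, offset - onset,
            )
            continue
        markers.append(EventMarker(onset, offset, kind, level))
    markers.sort(key=lambda m: (m.onset_s, m.offset_s))
    return _merge_overlapping_snores(markers)


def _merge_overlapping_snores(markers: list) -> list:
    out = []
    for m in markers:
        if out and m.kind == "snore" and out[-1].kind == "snore" and out[-1].overlaps(m):
            prev = out[-1]
            logger.warning(
                "merging overlapping snore markers at %.2f-%.2f and %.2f-%.2f s",
                prev.onset_s, prev.offset_s, m.onset_s, m.offset_s,
            )
            out[-1] = EventMarker(
                prev.onset_s,
                max(prev.offset_s, m.offset_s),
                "snore",
                prev.level_db if prev.level_db is not None else m.level_db,
            )
        else:
            out.append(m)
    return out


def _similar(prev: EventMarker, cur: EventMarker, cfg: AnnotationConfig) -> bool:
    if cur.onset_s - prev.onset_s > cfg.max_interonset_s:
        return False
    if prev.level_db is not None and cur.level_db is not None:
        if abs(cur.level_db - prev.level_db) > cfg.level_jump_db:
            return False
    return True


def build_episodes(markers: list, cfg: Optional[AnnotationConfig] = None) -> list:
    """Group sorted markers into snore episodes.

    A run breaks when consecutive snores stop being similar (inter-onset gap
    or level jump) or when a non-snore marker intervenes.  A run whose first
    snore directly follows an apnea has that snore set aside as the opening
    snore, restarting the episode count at the next event.  Runs shorter
    than ``min_episode_events`` are still returned (non-measurable).
    """
    cfg = cfg or AnnotationConfig()
    episodes: list = []
    run: list = []
    after_apnea = False  # run[0] (or the pending snore) directly follows an apnea

    def close_run(terminal: str) -> None:
        nonlocal run, after_apnea
        if not run:
            return
        opening = None
        events = run
        if after_apnea:
            opening, events = run[0], run[1:]
        episodes.append(SnoreEpisode(events=events, terminal=terminal, opening_event=opening))
        run = []
        after_apnea = False

    snores = [m for m in markers if m.kind == "snore"]
    others = [m for m in markers if m.kind != "snore"]

    def blocking_between(a: float, b: float):
        """First apnea/maneuver marker starting in (a, b), if any."""
        for m in others:
            if m.kind in ("apnea",) and a <= m.onset_s < b:
                return m
        return None

    if snores and any(
        m.kind == "apnea" and m.onset_s < snores[0].onset_s for m in others
    ):
        after_apnea = True  # recording opens mid-night, right after an apnea

    for i, snore in enumerate(snores):
        if run:
            prev = run[-1]
            apnea_between = blocking_between(prev.offset_s, snore.onset_s)
            gap_apnea = (
                cfg.infer_apnea_from_gaps
                and snore.onset_s - prev.offset_s >= cfg.apnea_min_gap_s
            )
            if apnea_between is not None or gap_apnea:
                close_run("apnea")
                after_apnea = True
            elif not _similar(prev, snore, cfg):
                close_run("none")
        run.append(snore)

    if run:
        last = run[-1]
        trailing = blocking_between(last.offset_s, np.inf)
        terminal = "apnea" if trailing is not None else "none"
        close_run(terminal)
    return episodes


def label_measured_events(
    episodes: list,
    cfg: Optional[AnnotationConfig] = None,
    exclusion_markers: Optional[list] = None,
) -> list:
    """Assign preapneic/continuous/excluded labels to every snore event.

    Exactly zero or one event per episode is measured: the event at
    ``measured_index`` of a measurable episode, unless it overlaps a
    maneuver or level-jump marker.  All other events carry an exclusion
    reason.
    """
    cfg = cfg or AnnotationConfig()
    exclusion_markers = [
        m for m in (exclusion_markers or []) if m.kind in ("maneuver", "level_jump")
    ]

    def overlap_reason(ev: EventMarker) -> Optional[str]:
        for m in exclusion_markers:
            if m.overlaps(ev):
                return REASON_MANEUVER if m.kind == "maneuver" else REASON_LEVEL_JUMP
        return None

    labeled = []
    for ep in episodes:
        if ep.opening_event is not None:
            labeled.append(LabeledEvent(ep.opening_event, LABEL_EXCLUDED, REASON_OPENING))
        measurable = len(ep.events) >= cfg.min_episode_events
        for idx, ev in enumerate(ep.events, start=1):
            reason = overlap_reason(ev)
            if reason is not None:
                labeled.append(LabeledEvent(ev, LABEL_EXCLUDED, reason))
            elif not measurable:
                labeled.append(LabeledEvent(ev, LABEL_EXCLUDED, REASON_ISOLATED))
            elif idx == cfg.measured_index:
                label = LABEL_PREAPNEIC if ep.terminal == "apnea" else LABEL_CONTINUOUS
                labeled.append(LabeledEvent(ev, label))
            else:
                labeled.append(LabeledEvent(ev, LABEL_EXCLUDED, REASON_NOT_THIRD))
    labeled.sort(key=lambda le: le.event.onset_s)
    return labeled


def annotate(markers: list, cfg: Optional[AnnotationConfig] = None) -> list:
    """Convenience: episodes + labeling in one call on a sorted marker list."""
    cfg = cfg or AnnotationConfig()
    episodes = build_episodes(markers, cfg)
    return label_measured_events(episodes, cfg, exclusion_markers=markers)


def labels_to_frame(labeled: list) -> pd.DataFrame:
    rows = [
        {
            "onset_s": le.event.onset_s,
            "offset_s": le.event.offset_s,
            "kind": le.event.kind,
            "level_db": le.event.level_db,
            "label": le.label,
            "reason": le.reason,
        }
        for le in labeled
    ]
    return pd.DataFrame(rows, columns=["onset_s", "offset_s", "kind", "level_db", "label", "reason"])


def write_labels(labeled: list, path) -> None:
    labels_to_frame(labeled).to_csv(path, index=False)
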