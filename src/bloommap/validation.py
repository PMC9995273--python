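"""Validation against event records and labelled pixels.

Event matching mirrors how in-situ harmful-algal-event records (location +
bloom period) are compared with daily satellite detections: for each event,
every dated mask inside its period is a *valid* scene when enough of the
pixels within the matching radius are unmasked, and a *detected* scene when
at least one bloom pixel lies within the radius.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .scene import BLOOM, INVALID, BloomMask


@dataclass
class MatchReport:
    """Per-event matchups plus the aggregate detection statistics.

    ``scene_ratio``: bloom-detected scenes over valid scenes, pooled across
    events with at least one valid scene.  ``n_s``: events with at least one
    successful detection.  ``event_fraction``: n_s over all events.
    """

    per_event: pd.DataFrame
    scene_ratio: float
    n_s: int
    event_fraction: float


def merge_duplicate_events(
    events: pd.DataFrame, distance_deg: float = 0.1
) -> pd.DataFrame:
    """Drop events duplicating an earlier one (centres within
    ``distance_deg`` and overlapping periods)."""
    keep = []
    kept_rows: list[pd.Series] = []
    for _, row in events.iterrows():
        dup = False
        for prev in kept_rows:
            close = (
                abs(row["lat"] - prev["lat"]) <= distance_deg
                and abs(row["lon"] - prev["lon"]) <= distance_deg
            )
            overlap = row["start"] <= prev["end"] and prev["start"] <= row["end"]
            if close and overlap:
                dup = True
                break
        keep.append(not dup)
        if not dup:
            kept_rows.append(row)
    return events[np.asarray(keep)].reset_index(drop=True)


def match_events(
    events: pd.DataFrame,
    masks: list[BloomMask],
    radius: float = 0.5,
    min_valid_fraction: float = 0.1,
) -> MatchReport:
    """Match an event table (event_id, lat, lon, start, end) against dated
    bloom masks.

    Events with zero valid scenes are excluded from the scene-level ratio
    and flagged in the per-event report.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    rows = []
    total_valid = 0
    total_detected = 0
    for _, ev in events.iterrows():
        start, end = _as_date(ev["start"]), _as_date(ev["end"])
        if start > end:
            raise ValueError(f"event {ev['event_id']}: start after end")
        n_valid_scenes = 0
        n_detected_scenes = 0
        for mask in masks:
            if not (start <= mask.date <= end):
                continue
            near = _near(mask, float(ev["lat"]), float(ev["lon"]), radius)
            if not near.any():
                continue
            states = mask.state[near]
            frac_valid = float((states != INVALID).mean())
            if frac_valid >= min_valid_fraction:
                n_valid_scenes += 1
                if (states == BLOOM).any():
                    n_detected_scenes += 1
        rows.append(
            {
                "event_id": ev["event_id"],
                "n_valid_scenes": n_valid_scenes,
                "n_detected_scenes": n_detected_scenes,
                "detected": n_detected_scenes > 0,
                "no_valid_scenes": n_valid_scenes == 0,
            }
        )
        total_valid += n_valid_scenes
        total_detected += n_detected_scenes
    per_event = pd.DataFrame(rows)
    scene_ratio = total_detected / total_valid if total_valid else float("nan")
    n_s = int(per_event["detected"].sum()) if len(per_event) else 0
    event_fraction = n_s / len(per_event) if len(per_event) else float("nan")
    return MatchReport(per_event, scene_ratio, n_s, event_fraction)


def _near(mask: BloomMask, lat: float, lon: float, radius: float) -> np.ndarray:
    dlat = np.abs(mask.grid.lat - lat)
    dlon = np.abs(mask.grid.lon - lon)
    return (dlat[:, None] <= radius) & (dlon[None, :] <= radius)


def _as_date(v) -> _dt.date:
    if isinstance(v, _dt.datetime):
        return v.date()
    if isinstance(v, _dt.date):
        return v
    return pd.Timestamp(v).date()


@dataclass
class ConfusionReport:
    """Pixel confusion counts over mutually valid pixels.

    Producer accuracy = TP/(TP+FN) (blooms found among true blooms); user
    accuracy = TP/(TP+FP) (true blooms among predicted blooms).
    """

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def producer_accuracy(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else float("nan")

    @property
    def user_accuracy(self) -> float:
        d = self.tp + self.fp
        return self.tp / d if d else float("nan")

    @property
    def n_valid(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def pixel_confusion(predicted: BloomMask, labels: np.ndarray) -> ConfusionReport:
    """Confusion counts of a predicted mask against a ground-truth raster
    (1 bloom, 0 no-bloom, 255 invalid/unlabelled).  Only pixels valid in
    both rasters are counted."""
    labels = np.asarray(labels)
    if labels.shape != predicted.state.shape:
        raise ValueError("label raster shape does not match mask")
    valid = (predicted.state != INVALID) & (labels != INVALID)
    pred = predicted.state[valid] == BLOOM
    truth = labels[valid] == BLOOM
    return ConfusionReport(
        tp=int((pred & truth).sum()),
        fp=int((pred & ~truth).sum()),
        fn=int((~pred & truth).sum()),
        tn=int((~pred & ~truth).sum()),
    )
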