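"""Nuclei tracking: greedy mutual-nearest-neighbour linking, mitosis
detection as track splits, and the per-well MitosisCount.

A mitosis is counted when one track ends and two fresh tracks begin close
by shortly after.  For the parent track to actually end at the division,
the linker refuses to extend a track whose gating radius contains two or
more objects that both claim it as their nearest track (division
ambiguity); the two daughters then start new tracks that the split
detector pairs back to the parent.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

TRACK_COLUMNS = ["track_id", "frame", "label", "x", "y", "area"]


@dataclass
class TrackSet:
    """Linked tracks: one row per (track, frame) observation."""

    points: pd.DataFrame
    parents: dict[int, int] = field(default_factory=dict)  # daughter -> parent

    def __post_init__(self) -> None:
        self.points = pd.DataFrame(self.points, columns=TRACK_COLUMNS)

    @property
    def n_tracks(self) -> int:
        return self.points["track_id"].nunique()

    def track_ids(self) -> np.ndarray:
        return np.sort(self.points["track_id"].unique())

    def endpoints(self) -> pd.DataFrame:
        """First/last frame and position per track."""
        pts = self.points.sort_values(["track_id", "frame"], kind="stable")
        first = pts.groupby("track_id").first()
        last = pts.groupby("track_id").last()
        n = pts.groupby("track_id").size()
        return pd.DataFrame({
            "start_frame": first["frame"], "start_x": first["x"], "start_y": first["y"],
            "end_frame": last["frame"], "end_x": last["x"], "end_y": last["y"],
            "length": n,
        })

    def track_length_mean(self) -> float:
        if self.points.empty:
            return 0.0
        return float(self.points.groupby("track_id").size().mean())


@dataclass(frozen=True)
class MitosisEvent:
    """One detected track split."""

    frame: int
    parent: int
    daughter_a: int
    daughter_b: int
    x: float
    y: float


def link(
    tables: Sequence[pd.DataFrame],
    max_dist: float = 8.0,
    max_gap: int = 1,
) -> TrackSet:
    """Link per-frame object tables into tracks.

    Objects in consecutive frames are joined when each is the other's
    nearest neighbour within ``max_dist`` px (mutual nearest neighbour);
    tracks survive up to ``max_gap`` missed frames.  A track claimed as
    nearest by >=2 in-gate objects is not extended (potential division).
    Unmatched objects start new tracks.  Ties break by (distance, id).

    The default gate (8 px, one nucleus radius) is deliberately much
    tighter than the split-detection radius: frame-to-frame Brownian
    motion is a few px, while daughters appear ~1.2 radii from the parent,
    so a division ends the parent track rather than linking through one
    daughter.
    """
    if max_dist <= 0:
        raise ValueError("max_dist must be positive")
    rows: list[tuple] = []
    open_tracks: list[dict] = []  # {"id", "x", "y", "last_frame"}
    next_id = 0
    for f, tab in enumerate(tables):
        tab = tab.sort_values("label", kind="stable") if len(tab) else tab
        open_tracks = [t for t in open_tracks if f - t["last_frame"] <= max_gap + 1]
        assigned: dict[int, int] = {}  # object row position -> track id
        if len(tab) and open_tracks:
            opts = np.array([[t["x"], t["y"]] for t in open_tracks])
            objs = tab[["x", "y"]].to_numpy(dtype=float)
            d = cdist(opts, objs)
            in_gate = d <= max_dist
            nearest_track = np.where(in_gate.any(axis=0), d.argmin(axis=0), -1)
            # division ambiguity is judged in a wider radius than the link
            # gate: daughters appear ~1.2 radii away, beyond the gate but
            # both still nearest to the parent track
            in_claim = d <= 2.0 * max_dist
            claim_track = np.where(in_claim.any(axis=0), d.argmin(axis=0), -1)
            claims = np.bincount(claim_track[claim_track >= 0],
                                 minlength=len(open_tracks))
            nearest_obj = np.where(in_gate.any(axis=1), d.argmin(axis=1), -1)
            for ti, t in enumerate(open_tracks):
                if claims[ti] >= 2:
                    continue  # ambiguous: likely a division, let the track end
                oj = nearest_obj[ti]
                if oj >= 0 and nearest_track[oj] == ti:
                    assigned[int(oj)] = t["id"]
        still_open: list[dict] = []
        matched_ids = set(assigned.values())
        for t in open_tracks:
            if t["id"] not in matched_ids:
                still_open.append(t)
        for pos in range(len(tab)):
            row = tab.iloc[pos]
            if pos in assigned:
                tid = assigned[pos]
                for t in open_tracks:
                    if t["id"] == tid:
                        t.update(x=float(row["x"]), y=float(row["y"]), last_frame=f)
                        still_open.append(t)
                        break
            else:
                tid = next_id
                next_id += 1
                still_open.append({"id": tid, "x": float(row["x"]),
                                   "y": float(row["y"]), "last_frame": f})
            rows.append((tid, f, int(row["label"]), float(row["x"]),
                         float(row["y"]), float(row.get("area", np.nan))))
        open_tracks = sorted(still_open, key=lambda t: t["id"])
    return TrackSet(pd.DataFrame(rows, columns=TRACK_COLUMNS))


def detect_splits(
    tracks: TrackSet,
    radius: float = 16.0,
    window: int = 2,
) -> list[MitosisEvent]:
    """Detect mitoses: a track ends at frame f and >=2 new tracks begin in
    (f, f+window] within ``radius`` px of its last position.

    The two nearest candidates become the daughters (ties by distance then
    track id); each new track is consumed by at most one event.  Parents
    are processed in (end frame, track id) order, deterministically.
    """
    if tracks.points.empty:
        return []
    ep = tracks.endpoints()
    consumed: set[int] = set()
    events: list[MitosisEvent] = []
    for parent in ep.sort_values("end_frame", kind="stable").index:
        pend = ep.loc[parent]
        f = int(pend["end_frame"])
        cand = ep[(ep["start_frame"] > f) & (ep["start_frame"] <= f + window)]
        cand = cand[~cand.index.isin(consumed) & (cand.index != parent)]
        if len(cand) < 2:
            continue
        dist = np.hypot(cand["start_x"] - pend["end_x"], cand["start_y"] - pend["end_y"])
        cand = cand.assign(dist=dist)
        cand = cand[cand["dist"] <= radius]
        if len(cand) < 2:
            continue
        picked = sorted(cand.index, key=lambda i: (cand.loc[i, "dist"], i))[:2]
        d1, d2 = sorted(picked)
        consumed.update((d1, d2))
        events.append(MitosisEvent(
            frame=int(min(ep.loc[d1, "start_frame"], ep.loc[d2, "start_frame"])),
            parent=int(parent), daughter_a=int(d1), daughter_b=int(d2),
            x=float(pend["end_x"]), y=float(pend["end_y"]),
        ))
        tracks.parents[int(d1)] = int(parent)
        tracks.parents[int(d2)] = int(parent)
    return events


def mitosis_count(events: Sequence[MitosisEvent]) -> int:
    """The per-well MitosisCount: total track splits over all timepoints."""
    return len(events)


def apoptotic_terminations(
    tracks: TrackSet,
    events: Sequence[MitosisEvent],
    last_frame: int | None = None,
    collapse: float = 0.5,
) -> int:
    """Track ends with an area collapse (> ``1-collapse`` loss over the last
    two observations) and no split: the fragmenting-nucleus signature."""
    if tracks.points.empty:
        return 0
    split_parents = {e.parent for e in events}
    if last_frame is None:
        last_frame = int(tracks.points["frame"].max())
    n = 0
    for tid, pts in tracks.points.groupby("track_id"):
        if tid in split_parents:
            continue
        pts = pts.sort_values("frame")
        if int(pts["frame"].iloc[-1]) >= last_frame:
            continue  # censored, not a death
        areas = pts["area"].to_numpy(dtype=float)
        if len(areas) >= 3 and np.isfinite(areas[-1]) and np.isfinite(areas[-3]) \
                and areas[-3] > 0 and areas[-1] < collapse * areas[-3]:
            n += 1
    return n


@dataclass(frozen=True)
class WellSummary:
    """Per-well tracking summary feeding the screen-scoring stage."""

    plate: str
    well: str
    mitosis_count: int
    apoptotic_terminations: int
    n_tracks: int
    mean_track_length: float

    def __post_init__(self) -> None:
        if self.mitosis_count < 0:
            raise ValueError("MitosisCount must be non-negative")


def summarize_well(
    plate: str,
    well: str,
    tracks: TrackSet,
    events: Sequence[MitosisEvent],
) -> WellSummary:
    last = int(tracks.points["frame"].max()) if len(tracks.points) else 0
    return WellSummary(
        plate=plate, well=well,
        mitosis_count=mitosis_count(events),
        apoptotic_terminations=apoptotic_terminations(tracks, events, last),
        n_tracks=tracks.n_tracks,
        mean_track_length=tracks.track_length_mean(),
    )


def track_movie(
    stack: np.ndarray,
    *,
    smooth_sigma: float = 2.0,
    min_area: int | None = None,
    max_dist: float = 8.0,
    max_gap: int = 1,
    split_radius: float = 16.0,
    split_window: int = 2,
) -> tuple[TrackSet, list[MitosisEvent]]:
    """Full imaging path for one movie: segment every frame, link, detect
    splits.  Convenience wrapper used by the pipeline and benchmarks."""
    from .nuclei_imaging import DEFAULT_MIN_AREA, segment_movie

    tables = segment_movie(stack, smooth_sigma=smooth_sigma,
                           min_area=DEFAULT_MIN_AREA if min_area is None else min_area)
    tracks = link(tables, max_dist=max_dist, max_gap=max_gap)
    events = detect_splits(tracks, radius=split_radius, window=split_window)
    return tracks, events
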