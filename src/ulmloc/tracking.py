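"""Two-step linear-assignment tracking.

Step one links detections between consecutive frames by minimum-total-
distance one-to-one assignment with a distance gate, producing track
segments.  Step two joins segment ends to segment starts across gaps of
up to ``max_gap`` frames, rejecting joins whose linking angle (between
the segment's terminal velocity and the end-to-start displacement)
exceeds 45 degrees.  Tracks shorter than the minimum persistence are
discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .config import ImagingConfig
from .decode import Localization

_BIG = 1e9


@dataclass
class Track:
    id: int
    points: list[Localization] = field(default_factory=list)

    def __post_init__(self):
        frames = [p.frame for p in self.points]
        if any(b <= a for a, b in zip(frames, frames[1:])):
            raise ValueError("track frames must strictly increase")

    @property
    def span(self) -> int:
        return self.points[-1].frame - self.points[0].frame + 1

    def coords(self) -> np.ndarray:
        return np.array([(p.row, p.col) for p in self.points])

    def mean_speed_mm_s(self, cfg: ImagingConfig) -> float:
        """Mean step speed; coordinates are fine-grid pixels."""
        if len(self.points) < 2:
            return 0.0
        c = self.coords()
        frames = np.array([p.frame for p in self.points])
        d = np.linalg.norm(np.diff(c, axis=0), axis=1) / np.diff(frames)
        return float(d.mean() * cfg.fine_pixel_um * cfg.frame_rate_hz / 1000.0)

    @property
    def direction_sign(self) -> int:
        """+1 for net motion toward the transducer (decreasing row)."""
        dr = self.points[-1].row - self.points[0].row
        return 1 if dr < 0 else -1


def link_frames(locs_t: list[Localization], locs_t1: list[Localization],
                max_dist: float) -> list[tuple[int, int]]:
    """Optimal one-to-one assignment between two frames' detections,
    restricted to pairs within ``max_dist``."""
    if max_dist <= 0:
        raise ValueError("max_dist must be positive")
    if not locs_t or not locs_t1:
        return []
    a = np.array([(p.row, p.col) for p in locs_t])
    b = np.array([(p.row, p.col) for p in locs_t1])
    d = cdist(a, b)
    cost = np.where(d <= max_dist, d, _BIG)
    ri, ci = linear_sum_assignment(cost)
    return [(int(i), int(j)) for i, j in zip(ri, ci) if d[i, j] <= max_dist]


def build_segments(locs: list[Localization], max_dist: float) -> list[Track]:
    """Frame-to-frame linking over a whole acquisition -> track segments."""
    by_frame: dict[int, list[Localization]] = {}
    for p in locs:
        by_frame.setdefault(p.frame, []).append(p)
    frames = sorted(by_frame)
    segments: list[Track] = []
    open_segs: dict[int, Track] = {}       # index into current frame's locs
    next_id = 0
    prev_frame: int | None = None
    for t in frames:
        cur = by_frame[t]
        new_open: dict[int, Track] = {}
        if prev_frame is not None and t == prev_frame + 1 and open_segs:
            links = link_frames(by_frame[prev_frame], cur, max_dist)
            matched_prev = {}
            for i, j in links:
                if i in open_segs:
                    matched_prev[j] = open_segs[i]
            for j, seg in matched_prev.items():
                seg.points.append(cur[j])
                new_open[j] = seg
        for j, p in enumerate(cur):
            if j not in new_open:
                seg = Track(next_id, [p])
                next_id += 1
                segments.append(seg)
                new_open[j] = seg
        open_segs = new_open
        prev_frame = t
    return segments


def _terminal_velocity(seg: Track, tail: int = 3) -> np.ndarray:
    """Displacement per frame over the last min(tail, len-1) steps."""
    c = seg.coords()
    frames = np.array([p.frame for p in seg.points])
    k = min(tail, len(seg.points) - 1)
    if k < 1:
        return np.zeros(2)
    return (c[-1] - c[-1 - k]) / (frames[-1] - frames[-1 - k])


def link_segments(segments: list[Track], max_dist: float, max_gap: int = 2,
                  max_angle_deg: float = 45.0) -> list[Track]:
    """Gap-closing by linear assignment between segment ends and starts."""
    if not segments:
        return []
    ends = [(s.points[-1].frame, s.points[-1].row, s.points[-1].col)
            for s in segments]
    starts = [(s.points[0].frame, s.points[0].row, s.points[0].col)
              for s in segments]
    n = len(segments)
    cost = np.full((n, n), _BIG)
    cos_gate = np.cos(np.deg2rad(max_angle_deg))
    for i, (et, er, ec) in enumerate(ends):
        vel = _terminal_velocity(segments[i])
        for j, (st, sr, sc) in enumerate(starts):
            if i == j:
                continue
            gap = st - et
            if gap < 1 or gap > max_gap:
                continue
            disp = np.array([sr - er, sc - ec])
            dist = np.linalg.norm(disp)
            if dist > max_dist * gap:
                continue
            if dist > 1e-12 and np.linalg.norm(vel) > 1e-12:
                cosang = float(vel @ disp) / (np.linalg.norm(vel) * dist)
                if cosang < cos_gate:
                    continue           # linking angle beyond the gate
            cost[i, j] = dist
    ri, ci = linear_sum_assignment(cost)
    succ = {int(i): int(j) for i, j in zip(ri, ci) if cost[i, j] < _BIG}
    has_pred = set(succ.values())
    merged: list[Track] = []
    next_id = 0
    for i, seg in enumerate(segments):
        if i in has_pred:
            continue
        points = list(seg.points)
        k = i
        while k in succ:
            k = succ[k]
            points.extend(segments[k].points)
        merged.append(Track(next_id, points))
        next_id += 1
    return merged


def filter_tracks(tracks: list[Track], min_persistence: int = 10) -> list[Track]:
    """Drop tracks spanning fewer than ``min_persistence`` frames."""
    return [t for t in tracks if t.span >= min_persistence]


def default_max_dist(cfg: ImagingConfig, headroom: float = 1.5,
                     max_speed_mm_s: float = 25.0) -> float:
    """Gate: headroom x the fastest bubble's per-frame displacement (fine px)."""
    return headroom * cfg.fine_px_per_frame(max_speed_mm_s)


def track_localizations(locs: list[Localization], cfg: ImagingConfig,
                        max_dist: float | None = None, max_gap: int = 2,
                        max_angle_deg: float = 45.0,
                        min_persistence: int = 10) -> list[Track]:
    """Full tracker: frame linking, gap closing, persistence filtering.
    Coordinates are fine-grid pixels."""
    if max_dist is None:
        max_dist = default_max_dist(cfg)
    segments = build_segments(locs, max_dist)
    tracks = link_segments(segments, max_dist, max_gap, max_angle_deg)
    return filter_tracks(tracks, min_persistence)
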