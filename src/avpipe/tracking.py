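"""Linking per-frame detections into per-punctum tracks.

Frame-to-frame association is greedy globally-nearest-neighbour: candidate
(track, detection) pairs are sorted by distance and linked smallest first,
subject to a per-frame displacement bound.  Tracks survive up to ``max_gap``
missing frames (gap closing) before terminating.  Greedy assignment is
adequate at the low punctum densities of axon-tip recordings and is simple
to verify; it is not globally optimal (documented limitation).
"""

from __future__ import annotations

import dataclasses
from typing import Iterable

import numpy as np

from .detection import SpotDetection

__all__ = ["TrackingParams", "Track", "link_tracks", "residence_time"]


@dataclasses.dataclass(frozen=True)
class TrackingParams:
    max_disp_um: float = 0.5  # allowed displacement per elapsed frame
    max_gap: int = 2          # missing frames bridged by gap closing


@dataclasses.dataclass
class Track:
    """Time-linked detections of one punctum in one channel."""

    track_id: int
    channel: str
    detections: list[SpotDetection]
    censored_start: bool = False  # present in the first frame
    censored_end: bool = False    # present in the last frame

    @property
    def birth_frame(self) -> int:
        return self.detections[0].frame

    @property
    def death_frame(self) -> int:
        return self.detections[-1].frame

    @property
    def n_frames(self) -> int:
        return len(self.detections)

    def positions(self) -> dict[int, tuple[float, float]]:
        return {d.frame: (d.x, d.y) for d in self.detections}

    def intensities(self) -> np.ndarray:
        return np.array([d.intensity for d in self.detections])

    def frames(self) -> np.ndarray:
        return np.array([d.frame for d in self.detections])


def _group_by_frame(detections, n_frames: int) -> list[list[SpotDetection]]:
    frames: list[list[SpotDetection]] = [[] for _ in range(n_frames)]
    for item in detections:
        if isinstance(item, SpotDetection):
            frames[item.frame].append(item)
        else:  # already per-frame lists
            for d in item:
                frames[d.frame].append(d)
    # canonical within-frame order so the result is independent of input order
    for lst in frames:
        lst.sort(key=lambda d: (d.y, d.x))
    return frames


def link_tracks(detections: Iterable, *, n_frames: int,
                pixel_size_um: float,
                params: TrackingParams = TrackingParams()) -> list[Track]:
    """Link detections (flat list or per-frame lists) into tracks.

    A track whose last detection is ``g`` frames back may claim a detection
    within ``max_disp_um × g`` (displacement budget scales across closed
    gaps); unmatched detections seed new tracks.  Every detection belongs to
    exactly one track.  The result is invariant to within-frame input order.
    """
    per_frame = _group_by_frame(detections, n_frames)
    tracks: list[Track] = []
    active: list[Track] = []
    for f in range(n_frames):
        dets = per_frame[f]
        # drop tracks whose gap budget is exhausted
        active = [t for t in active if f - t.death_frame <= params.max_gap + 1]
        candidates = []
        for ti, tr in enumerate(active):
            last = tr.detections[-1]
            elapsed = f - last.frame
            budget = params.max_disp_um * elapsed
            for di, d in enumerate(dets):
                dist = np.hypot(d.x - last.x, d.y - last.y) * pixel_size_um
                if dist <= budget:
                    candidates.append((dist, ti, di))
        candidates.sort()
        used_t: set[int] = set()
        used_d: set[int] = set()
        for dist, ti, di in candidates:
            if ti in used_t or di in used_d:
                continue
            used_t.add(ti)
            used_d.add(di)
            active[ti].detections.append(dets[di])
        for di, d in enumerate(dets):
            if di not in used_d:
                tr = Track(track_id=len(tracks), channel=d.channel,
                           detections=[d])
                tracks.append(tr)
                active.append(tr)
    last_frame = n_frames - 1
    for tr in tracks:
        tr.censored_start = tr.birth_frame == 0
        tr.censored_end = tr.death_frame == last_frame
    return tracks


def residence_time(track: Track, video_duration_s: float,
                   frame_interval_s: float) -> tuple[float, bool]:
    """Observed residence time (s) of a punctum and its censoring flag.

    The residence is the observed time span of the track; endpoints clipped
    by the acquisition window are extended to the window boundary, so a
    punctum present in every frame of a 600-s video scores exactly 600 s.
    The value is capped at the video duration; censored means the track
    touches either end of the recording (the true residence may be longer).
    """
    if not track.detections:
        raise ValueError("track has no detections")
    start = 0.0 if track.censored_start else track.birth_frame * frame_interval_s
    end = video_duration_s if track.censored_end \
        else track.death_frame * frame_interval_s
    res = min(max(0.0, end - start), video_duration_s)
    return res, bool(track.censored_start or track.censored_end)
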