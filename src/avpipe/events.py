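"""Assembling multi-channel tracks into biogenesis events and classifying them.

The classification rules follow the live-imaging conventions for axonal
autophagosome biogenesis:

* stalled — an early-marker (ATG13/ATG5) punctum visible for at least 5 min
  (300 s, inclusive) that never recruits LC3B;
* productive — a marker punctum persisting less than 5 min whose paired
  LC3B signal rises after pairing;
* markers still present at the video end with < 300 s of visibility are
  right-censored and excluded from classification; short-lived markers with
  no LC3B are reported as ambiguous rather than forced into either class.

The biogenesis rate counts de-novo LC3B tracks per minute; LC3B puncta
already present in frame 0 count only if their intensity or area shows a
significant increasing trend (one-sided permutation test on the early
least-squares slope).
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .tracking import Track, TrackingParams, residence_time

__all__ = ["ClassificationParams", "CandidateEvent", "AVEvent",
           "NeuronSummary", "pair_channels", "classify_event",
           "biogenesis_rate", "atg9_association", "assemble_events",
           "increasing_trend"]

MARKER_CHANNELS = ("ATG13", "ATG5", "WIPI2B")


@dataclasses.dataclass(frozen=True)
class ClassificationParams:
    coloc_dist_um: float = 0.3       # object-based colocalization radius
    min_overlap_frames: int = 3      # common close frames required to pair
    stall_threshold_s: float = 300.0  # "at least 5 min", inclusive
    min_track_frames: int = 3        # shortest track counted as a punctum
    slope_window_s: float = 60.0     # early window for trend tests
    n_permutations: int = 200
    slope_alpha: float = 0.05
    seed: int = 0


@dataclasses.dataclass
class CandidateEvent:
    """A marker track with optionally paired LC3B / ATG9 tracks."""

    marker_track: Track
    lc3b_track: Track | None = None
    atg9_track: Track | None = None


@dataclasses.dataclass
class AVEvent:
    """One classified biogenesis event."""

    event_id: int
    marker_track: Track
    lc3b_track: Track | None
    atg9_track: Track | None
    event_class: str  # productive | stalled | ambiguous
    onset_s: float
    marker_dwell_s: float
    lc3b_recruited: bool
    atg9_associated: bool
    censored: bool


@dataclasses.dataclass
class NeuronSummary:
    """Per-video (per-neuron) event counts and biogenesis rate."""

    neuron_id: int
    duration_s: float
    n_denovo_lc3b: int
    biogenesis_rate_per_min: float
    n_productive: int
    n_stalled: int
    n_ambiguous: int
    events: list[AVEvent]


def _close_frames(a: Track, b: Track, coloc_dist_um: float,
                  pixel_size_um: float) -> list[tuple[int, float]]:
    """Common frames where the two centroids are within the threshold."""
    pa, pb = a.positions(), b.positions()
    out = []
    for f in sorted(set(pa) & set(pb)):
        d = math.hypot(pa[f][0] - pb[f][0], pa[f][1] - pb[f][1]) * pixel_size_um
        if d <= coloc_dist_um:
            out.append((f, d))
    return out


def _greedy_pair(markers: list[Track], others: list[Track],
                 params: ClassificationParams,
                 pixel_size_um: float) -> dict[int, int]:
    """Closest-pairing-first assignment, each track used at most once."""
    cands = []
    for mi, m in enumerate(markers):
        for oi, o in enumerate(others):
            close = _close_frames(m, o, params.coloc_dist_um, pixel_size_um)
            if len(close) >= params.min_overlap_frames:
                mean_d = float(np.mean([d for _, d in close]))
                cands.append((mean_d, mi, oi))
    cands.sort()
    used_m: set[int] = set()
    used_o: set[int] = set()
    pairing: dict[int, int] = {}
    for _, mi, oi in cands:
        if mi in used_m or oi in used_o:
            continue
        used_m.add(mi)
        used_o.add(oi)
        pairing[mi] = oi
    return pairing


def pair_channels(tracks_by_channel: dict[str, list[Track]],
                  marker_channel: str, pixel_size_um: float,
                  params: ClassificationParams = ClassificationParams()
                  ) -> list[CandidateEvent]:
    """Build candidate events around each marker track.

    A marker track is paired with an LC3B (and, independently, an ATG9)
    track iff their centroids lie within ``coloc_dist_um`` in at least
    ``min_overlap_frames`` common frames; pairs are assigned closest first
    and each track joins at most one event.
    """
    markers = [t for t in tracks_by_channel.get(marker_channel, [])
               if t.n_frames >= params.min_track_frames]
    lc3b = [t for t in tracks_by_channel.get("LC3B", [])
            if t.n_frames >= params.min_track_frames]
    atg9 = [t for t in tracks_by_channel.get("ATG9", [])
            if t.n_frames >= params.min_track_frames]
    lc3b_pairs = _greedy_pair(markers, lc3b, params, pixel_size_um)
    atg9_pairs = _greedy_pair(markers, atg9, params, pixel_size_um)
    return [CandidateEvent(marker_track=m,
                           lc3b_track=lc3b[lc3b_pairs[mi]]
                           if mi in lc3b_pairs else None,
                           atg9_track=atg9[atg9_pairs[mi]]
                           if mi in atg9_pairs else None)
            for mi, m in enumerate(markers)]


def _lc3b_rises_after_pairing(candidate: CandidateEvent,
                              frame_interval_s: float,
                              params: ClassificationParams) -> bool:
    """Least-squares slope of paired-LC3B intensity after pairing is > 0."""
    lc = candidate.lc3b_track
    if lc is None:
        return False
    marker_frames = set(candidate.marker_track.positions())
    frames = lc.frames()
    vals = lc.intensities()
    common = [i for i, f in enumerate(frames) if f in marker_frames]
    start = common[0] if common else 0
    n = max(3, int(round(params.slope_window_s / frame_interval_s)))
    f = frames[start:start + n].astype(float)
    v = vals[start:start + n]
    if len(f) < 3:
        f, v = frames.astype(float)[:n], vals[:n]
    if len(f) < 2 or np.ptp(f) == 0:
        return False
    slope = np.polyfit(f, v, 1)[0]
    return bool(slope > 0)


def classify_event(candidate: CandidateEvent, video_duration_s: float,
                   frame_interval_s: float, pixel_size_um: float,
                   params: ClassificationParams = ClassificationParams(),
                   event_id: int = 0) -> AVEvent:
    """Apply the 5-min stall / LC3B-recruitment rules to one candidate."""
    marker = candidate.marker_track
    if marker is None or not marker.detections:
        raise ValueError("candidate has no marker track")
    dwell, _ = residence_time(marker, video_duration_s, frame_interval_s)
    recruited = _lc3b_rises_after_pairing(candidate, frame_interval_s, params)
    stalled_long = dwell >= params.stall_threshold_s
    censored = marker.censored_end and not stalled_long
    if censored:
        event_class = "ambiguous"
    elif stalled_long and not recruited:
        event_class = "stalled"
    elif not stalled_long and recruited:
        event_class = "productive"
    else:
        event_class = "ambiguous"
    atg9_assoc = atg9_association(candidate, pixel_size_um, params)
    return AVEvent(event_id=event_id, marker_track=marker,
                   lc3b_track=candidate.lc3b_track,
                   atg9_track=candidate.atg9_track,
                   event_class=event_class,
                   onset_s=marker.birth_frame * frame_interval_s,
                   marker_dwell_s=dwell, lc3b_recruited=recruited,
                   atg9_associated=atg9_assoc, censored=censored)


def atg9_association(candidate: CandidateEvent, pixel_size_um: float,
                     params: ClassificationParams = ClassificationParams()
                     ) -> bool:
    """ATG9 overlaps the marker within the colocalization radius for at
    least half of the marker's visible frames."""
    marker = candidate.marker_track
    atg9 = candidate.atg9_track
    if atg9 is None:
        return False
    n_close = len(_close_frames(marker, atg9, params.coloc_dist_um,
                                pixel_size_um))
    return n_close >= 0.5 * marker.n_frames


def increasing_trend(values: np.ndarray, frame_interval_s: float,
                     params: ClassificationParams,
                     rng: np.random.Generator) -> bool:
    """One-sided permutation test for a positive early slope.

    Operationalizes "increased in fluorescence intensity and/or area with
    time" for puncta already present at the start of the recording: the
    least-squares slope over the first ``slope_window_s`` must exceed the
    permutation null at ``slope_alpha``.
    """
    n = max(3, int(round(params.slope_window_s / frame_interval_s)))
    v = np.asarray(values, dtype=float)[:n]
    if len(v) < 3 or np.ptp(v) == 0:
        return False
    t = np.arange(len(v), dtype=float)

    def slope(y):
        return np.polyfit(t, y, 1)[0]

    obs = slope(v)
    if obs <= 0:
        return False
    hits = sum(slope(rng.permutation(v)) >= obs
               for _ in range(params.n_permutations))
    p = (1 + hits) / (params.n_permutations + 1)
    return bool(p < params.slope_alpha)


def biogenesis_rate(lc3b_tracks: list[Track], video_duration_s: float,
                    frame_interval_s: float,
                    params: ClassificationParams = ClassificationParams()
                    ) -> tuple[float, int]:
    """De-novo LC3B puncta per minute; returns (rate, count).

    Counts tracks of at least ``min_track_frames`` detections born after
    frame 0, plus frame-0 tracks whose intensity or area trend is
    significantly increasing.
    """
    if video_duration_s <= 0:
        raise ValueError("video_duration_s must be > 0")
    rng = np.random.default_rng(params.seed)
    count = 0
    for tr in lc3b_tracks:
        if tr.n_frames < params.min_track_frames:
            continue
        if tr.birth_frame > 0:
            count += 1
        else:
            intens = tr.intensities()
            areas = np.array([d.area_um2 for d in tr.detections])
            if (increasing_trend(intens, frame_interval_s, params, rng)
                    or increasing_trend(areas, frame_interval_s, params, rng)):
                count += 1
    return count / (video_duration_s / 60.0), count


def assemble_events(tracks_by_channel: dict[str, list[Track]],
                    marker_channel: str, video_duration_s: float,
                    frame_interval_s: float, pixel_size_um: float,
                    params: ClassificationParams = ClassificationParams(),
                    neuron_id: int = 0) -> NeuronSummary:
    """Pair channels, classify every marker track, and summarize the video."""
    candidates = pair_channels(tracks_by_channel, marker_channel,
                               pixel_size_um, params)
    events = [classify_event(c, video_duration_s, frame_interval_s,
                             pixel_size_um, params, event_id=i)
              for i, c in enumerate(candidates)]
    rate, n_denovo = biogenesis_rate(tracks_by_channel.get("LC3B", []),
                                     video_duration_s, frame_interval_s,
                                     params)
    counts = {"productive": 0, "stalled": 0, "ambiguous": 0}
    for ev in events:
        counts[ev.event_class] += 1
    return NeuronSummary(neuron_id=neuron_id, duration_s=video_duration_s,
                         n_denovo_lc3b=n_denovo,
                         biogenesis_rate_per_min=rate,
                         n_productive=counts["productive"],
                         n_stalled=counts["stalled"],
                         n_ambiguous=counts["ambiguous"],
                         events=events)
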