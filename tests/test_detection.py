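"""Detection: false positives, localization, photometry, area, invariances."""

import numpy as np
import pytest

import avpipe
from avpipe.detection import DetectionParams
from avpipe.simulate import PRODUCTIVE, STALLED

from conftest import forced_event


def _single_spot_video(noise=False, seed=0, xy=(128.0, 32.0),
                       channels=("ATG13",), amplitude=200.0):
    cfg = avpipe.SimConfig(noise=noise, seed=seed, event_rate_per_min=0.0,
                           channels=channels, spot_amplitude=amplitude)
    ev = forced_event(cfg, STALLED, {channels[0]: (-30.0, 700.0)}, xy=xy)
    video, _ = avpipe.generate_video(cfg, events=[ev])
    return cfg, video


class TestDetectSpots:
    def test_false_positive_rate_below_one_percent(self):
        """Pure-noise frames yield a detection in <1% of frames."""
        cfg = avpipe.SimConfig(event_rate_per_min=0.0, seed=42,
                               duration_s=600.0)
        video, _ = avpipe.generate_video(cfg)
        hits = sum(bool(avpipe.detect_spots(video, "ATG13", f))
                   for f in range(video.n_frames))
        # a second realization for 400 noise frames total
        video2, _ = avpipe.generate_video(
            avpipe.SimConfig(event_rate_per_min=0.0, seed=43))
        hits += sum(bool(avpipe.detect_spots(video2, "ATG13", f))
                    for f in range(video2.n_frames))
        assert hits / 400 < 0.01

    def test_single_bright_spot_localized_within_half_pixel(self):
        xy = (127.3, 31.6)
        cfg, video = _single_spot_video(noise=True, seed=5, xy=xy)
        dets = avpipe.detect_spots(video, "ATG13", 100)
        assert len(dets) == 1
        assert dets[0].x == pytest.approx(xy[0], abs=0.5)
        assert dets[0].y == pytest.approx(xy[1], abs=0.5)
        assert dets[0].peak_snr > 5

    def test_two_spots_five_pixels_apart_resolved(self):
        cfg = avpipe.SimConfig(noise=False, event_rate_per_min=0.0)
        e1 = forced_event(cfg, STALLED, {"ATG13": (-30.0, 700.0)},
                          xy=(100.0, 32.0))
        e2 = forced_event(cfg, STALLED, {"ATG13": (-30.0, 700.0)},
                          xy=(105.0, 32.0), event_id=1)
        video, _ = avpipe.generate_video(cfg, events=[e1, e2])
        dets = avpipe.detect_spots(video, "ATG13", 50)
        assert len(dets) == 2

    def test_nonfinite_pixels_rejected(self):
        cfg, video = _single_spot_video()
        video.pixels[0, 0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            avpipe.detect_spots(video, "ATG13", 0)

    def test_background_offset_invariance(self):
        """Adding a constant to every pixel changes no detection."""
        cfg, video = _single_spot_video(noise=True, seed=8)
        d0 = avpipe.detect_spots(video, "ATG13", 50)
        shifted = avpipe.Video(pixels=video.pixels + 500.0,
                               channels=video.channels,
                               pixel_size_um=video.pixel_size_um,
                               frame_interval_s=video.frame_interval_s)
        d1 = avpipe.detect_spots(shifted, "ATG13", 50)
        assert len(d0) == len(d1)
        for a, b in zip(d0, d1):
            assert a.x == pytest.approx(b.x, abs=1e-6)
            assert a.y == pytest.approx(b.y, abs=1e-6)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_threshold_monotonicity(self, seed):
        """Raising k never increases the number of detections."""
        cfg = avpipe.SimConfig(seed=seed, event_rate_per_min=1.0,
                               productive_fraction=0.0)
        video, _ = avpipe.generate_video(cfg)
        counts = [len(avpipe.detect_spots(video, "ATG13", 100,
                                          DetectionParams(k=k)))
                  for k in (3.0, 5.0, 8.0, 12.0)]
        assert counts == sorted(counts, reverse=True)

    def test_recall_and_precision_on_default_noise(self):
        """>=95% recall and precision vs ground truth at default noise,
        matching within 2 px, over several videos."""
        tp = fp = fn = 0
        for seed in range(6):
            cfg = avpipe.SimConfig(seed=seed, event_rate_per_min=1.0,
                                   productive_fraction=0.0,
                                   channels=("ATG13",))
            video, truth = avpipe.generate_video(cfg)
            times = cfg.frame_times_s
            for f in range(0, video.n_frames, 7):
                bright, visible = [], []
                for ev in truth:
                    amp = avpipe.event_kinetics(ev, times[f], "ATG13", cfg)
                    if amp >= 0.5:
                        bright.append(ev.trajectory[f])
                    if amp > 0.0:
                        visible.append(ev.trajectory[f])
                dets = avpipe.detect_spots(video, "ATG13", f)
                # recall over clearly visible spots (>= half amplitude)
                matched = set()
                for d in dets:
                    for i, pos in enumerate(bright):
                        if i in matched:
                            continue
                        if np.hypot(d.x - pos[0], d.y - pos[1]) <= 2.0:
                            matched.add(i)
                            break
                tp += len(matched)
                fn += len(bright) - len(matched)
                # precision: a detection is true if any rendered spot
                # (of whatever momentary amplitude) lies within 2 px
                for d in dets:
                    if not any(np.hypot(d.x - p[0], d.y - p[1]) <= 2.0
                               for p in visible):
                        fp += 1
        assert tp / (tp + fn) >= 0.95  # recall
        assert tp / (tp + fp) >= 0.95  # precision


class TestPhotometry:
    def test_background_measurement_centers_at_zero(self):
        """Mean background-subtracted intensity at blank positions is within
        2 SE of zero (the estimator is clipped at 0, so compare against the
        clipped-null expectation via a far-off channel-free video)."""
        cfg = avpipe.SimConfig(event_rate_per_min=0.0, seed=11)
        video, _ = avpipe.generate_video(cfg)
        rng = np.random.default_rng(0)
        vals = []
        for _ in range(500):
            f = int(rng.integers(0, video.n_frames))
            x = float(rng.uniform(20, 235))
            y = float(rng.uniform(20, 43))
            vals.append(avpipe.measure_trace_point(video, "ATG13", f, (x, y)))
        # clipping at zero folds the null; the folded mean stays small
        # relative to the spot scale (~2500 units for a bright punctum)
        assert np.mean(vals) < 60.0

    def test_known_spot_integral_within_five_percent(self):
        cfg, video = _single_spot_video(noise=False, xy=(128.0, 32.0))
        sigma_px = cfg.spot_sigma_um / cfg.pixel_size_um
        params = DetectionParams()
        r = params.disk_radius_px
        # analytic integral of A*exp(-r^2/2sigma^2) over a disk of radius r
        A = cfg.spot_amplitude
        expected = 2 * np.pi * sigma_px ** 2 * A * (
            1 - np.exp(-r ** 2 / (2 * sigma_px ** 2)))
        got = avpipe.measure_trace_point(video, "ATG13", 100, (128.0, 32.0),
                                         params)
        assert got == pytest.approx(expected, rel=0.05)

    def test_stalled_marker_intensity_plateaus(self):
        """A stalled punctum's measured intensity stays near its plateau
        for >= 5 min (noise off)."""
        cfg = avpipe.SimConfig(noise=False, event_rate_per_min=0.0)
        ev = forced_event(cfg, STALLED, {"ATG13": (0.0, 600.0)})
        video, _ = avpipe.generate_video(cfg, events=[ev])
        vals = [avpipe.measure_trace_point(video, "ATG13", f,
                                           tuple(ev.trajectory[f]))
                for f in range(20, 120)]  # 60 s .. 360 s
        assert np.std(vals) / np.mean(vals) < 0.02

    def test_centroid_out_of_bounds_rejected(self):
        cfg, video = _single_spot_video()
        with pytest.raises(ValueError):
            avpipe.measure_trace_point(video, "ATG13", 0, (-5.0, 10.0))


class TestArea:
    def test_mature_lc3b_area_near_analytic_half_max(self):
        cfg = avpipe.SimConfig(noise=False, event_rate_per_min=0.0,
                               channels=("ATG13", "LC3B"))
        ev = forced_event(cfg, PRODUCTIVE,
                          {"ATG13": (0.0, 125.0), "LC3B": (80.0, 600.0)})
        video, _ = avpipe.generate_video(cfg, events=[ev])
        area = avpipe.measure_area(video, "LC3B", video.n_frames - 1,
                                   tuple(ev.trajectory[-1]))
        assert area == pytest.approx(np.pi * 0.5 ** 2, rel=0.15)

    def test_area_zero_before_onset(self):
        cfg = avpipe.SimConfig(noise=False, event_rate_per_min=0.0,
                               channels=("ATG13", "LC3B"))
        ev = forced_event(cfg, PRODUCTIVE,
                          {"ATG13": (60.0, 185.0), "LC3B": (140.0, 600.0)})
        video, _ = avpipe.generate_video(cfg, events=[ev])
        assert avpipe.measure_area(video, "LC3B", 5,
                                   tuple(ev.trajectory[5])) == 0.0

    def test_growing_event_area_increases_over_three_minutes(self):
        cfg = avpipe.SimConfig(noise=False, event_rate_per_min=0.0,
                               channels=("ATG13", "LC3B"))
        ev = forced_event(cfg, PRODUCTIVE,
                          {"ATG13": (0.0, 125.0), "LC3B": (80.0, 600.0)})
        video, _ = avpipe.generate_video(cfg, events=[ev])
        frames = [40, 60, 80, 95]  # 120 s .. 285 s, during the rise
        areas = [avpipe.measure_area(video, "LC3B", f,
                                     tuple(ev.trajectory[f]))
                 for f in frames]
        assert all(b > a for a, b in zip(areas, areas[1:]))
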