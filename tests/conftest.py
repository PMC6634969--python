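import numpy as np
import pytest

import avpipe


@pytest.fixture(scope="session")
def noiseless_video():
    """One noiseless two-channel video with a few events, shared by tests."""
    cfg = avpipe.SimConfig(noise=False, seed=7, event_rate_per_min=0.4,
                           productive_fraction=0.5)
    video, truth = avpipe.generate_video(cfg)
    return cfg, video, truth


@pytest.fixture(scope="session")
def noisy_video():
    cfg = avpipe.SimConfig(seed=3, event_rate_per_min=0.4,
                           productive_fraction=0.5)
    video, truth = avpipe.generate_video(cfg)
    return cfg, video, truth


def forced_event(cfg, true_class, windows, xy=(128.0, 32.0),
                 event_id=0, atg9_persistent=False):
    """Ground-truth event with a stationary trajectory, for targeted tests."""
    traj = np.tile(np.asarray(xy, dtype=float), (cfg.n_frames, 1))
    return avpipe.GroundTruthEvent(
        event_id=event_id, true_class=true_class,
        onset_s=min(a for a, _ in windows.values()),
        windows=windows, trajectory=traj,
        peak_amplitude={ch: 1.0 for ch in windows},
        atg9_persistent=atg9_persistent)
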