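import numpy as np
import pytest

from fidgetlab import behavior, synthdata


@pytest.fixture(scope="session")
def small_video_session():
    """One short rendered session shared across video-level tests."""
    cfg = synthdata.SynthConfig(
        session_duration=60.0, n_fidgets=4, n_movement_bouts=2, n_neurons=1, seed=11
    )
    frames, track, events, amps = synthdata.generate_video_session(cfg)
    return cfg, frames, track, events, amps


@pytest.fixture(scope="session")
def trace_session():
    """One trace-only session with stimulus and running ground truth."""
    cfg = synthdata.SynthConfig(
        session_duration=400.0, n_fidgets=25, n_neurons=300, seed=21
    )
    return cfg, synthdata.generate_session(cfg, with_video=False)


@pytest.fixture(scope="session")
def textured_frame():
    from scipy import ndimage

    rng = np.random.default_rng(0)
    tex = ndimage.gaussian_filter(rng.random((120, 120)), 2)
    return (tex - tex.min()) / np.ptp(tex)


def make_track(labels, fps=30.0):
    return behavior.FrameLabelTrack(labels=np.asarray(labels), fps=fps)
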