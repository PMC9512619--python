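"""Motion-energy quantification of fidget events with dense optical flow.

The magnitude of a fidget is measured by integrating dense optical flow
over the frames of the event: for every consecutive frame pair inside the
event the per-pixel L2 norm of the Farnebäck displacement field is summed,
and those per-pair sums are accumulated over the event.  Because the flow
norm approximates instantaneous speed, the integral approximates the total
path length swept by the moving body — it depends on the excursion of the
movement, not on how long the animal takes to perform it, which is what
makes the statistic comparable across events of different durations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._farneback import farneback

__all__ = [
    "FlowConfig",
    "farneback_flow",
    "flow_magnitude",
    "event_magnitude",
    "magnitude_stereotypy",
]


@dataclass(frozen=True)
class FlowConfig:
    """Farnebäck parameters.  ``kernel_size`` is the integration window in
    pixels; the remaining parameters control the pyramid and the
    polynomial neighborhood and are fixed implementation choices."""

    kernel_size: int = 30
    levels: int = 3
    pyr_scale: float = 0.5
    iterations: int = 3
    poly_n: int = 7
    poly_sigma: float = 1.5


def farneback_flow(
    frame_a: np.ndarray, frame_b: np.ndarray, config: FlowConfig = FlowConfig()
) -> np.ndarray:
    """Dense two-frame optical flow.

    Returns an (H, W, 2) array where ``flow[..., 0]`` is the horizontal
    (x, columns, positive rightward) and ``flow[..., 1]`` the vertical
    (y, rows, positive downward) displacement in pixels/frame.
    """
    d = farneback(
        frame_a,
        frame_b,
        winsize=config.kernel_size,
        levels=config.levels,
        pyr_scale=config.pyr_scale,
        iterations=config.iterations,
        poly_n=config.poly_n,
        poly_sigma=config.poly_sigma,
    )
    return d[..., ::-1]  # internal (row, col) -> public (x, y)


def flow_magnitude(flow: np.ndarray) -> float:
    """Summed per-pixel L2 norm of one displacement field."""
    return float(np.sqrt((flow.astype(np.float64) ** 2).sum(axis=-1)).sum())


def event_magnitude(
    frames: np.ndarray,
    onset_frame: int,
    offset_frame: int,
    config: FlowConfig = FlowConfig(),
) -> float:
    """Integrated optical-flow magnitude of one event.

    ``frames`` is a (T, H, W) grayscale stack; the event covers the
    half-open frame range [onset_frame, offset_frame).  A single-frame
    event has no frame pair and yields 0.
    """
    if not 0 <= onset_frame < offset_frame <= len(frames):
        raise ValueError(
            f"event [{onset_frame}, {offset_frame}) outside stack of {len(frames)} frames"
        )
    if offset_frame - onset_frame < 2:
        import warnings

        warnings.warn("single-frame event has no flow; magnitude is 0", stacklevel=2)
        return 0.0
    total = 0.0
    for t in range(onset_frame, offset_frame - 1):
        total += flow_magnitude(farneback_flow(frames[t], frames[t + 1], config))
    return total


@dataclass
class StereotypyResult:
    fraction_within_30pct: float
    max_magnitude: float
    sorted_magnitudes: np.ndarray = field(repr=False)
    cumulative_fraction: np.ndarray = field(repr=False)


def magnitude_stereotypy(magnitudes, rel_window: float = 0.3) -> StereotypyResult:
    """Fraction of event magnitudes within ``rel_window`` of the maximum.

    An event counts as stereotyped if its magnitude is at least
    ``(1 - rel_window) * max``.  Also returns the empirical cumulative
    distribution of magnitudes for plotting.
    """
    m = np.asarray(list(magnitudes), dtype=np.float64)
    if m.size == 0:
        raise ValueError("magnitude_stereotypy requires at least one magnitude")
    mx = float(m.max())
    frac = float(np.mean(m >= (1.0 - rel_window) * mx)) if mx > 0 else 1.0
    order = np.sort(m)
    cum = np.arange(1, m.size + 1) / m.size
    return StereotypyResult(frac, mx, order, cum)
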