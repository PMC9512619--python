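"""Synthetic sessions with known ground truth.

Emulates the structure of a head-fixed passive-viewing two-photon
experiment: a 30-Hz side-view behavior video in which a textured
body-like blob briefly lifts and contracts during fidget events, ΔF/F
traces built from four event-locked response archetypes (neutral, phasic,
active, depressed), a drifting-grating stimulus table (8 directions x 5
temporal frequencies, 2 s on / 1 s gray, occasional blank sweeps), and a
running-speed trace that multiplicatively boosts visual responses of a
modulated subset of neurons.

Every generated quantity is recorded in a ``truth`` record that the
observable outputs never expose, so each downstream analysis stage can be
scored against ground truth it cannot see.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .behavior import FidgetEvent, FrameLabelTrack

__all__ = [
    "TYPE_LABELS",
    "DIRECTIONS_DEG",
    "TEMPORAL_FREQUENCIES_HZ",
    "SynthConfig",
    "ResponseTemplate",
    "SyntheticSession",
    "generate_response_templates",
    "generate_stimulus_table",
    "generate_video_session",
    "generate_running_speed",
    "generate_traces",
    "generate_session",
    "generate_cohort",
]

TYPE_LABELS = ("neutral", "phasic", "active", "depressed")
DIRECTIONS_DEG = tuple(range(0, 360, 45))
TEMPORAL_FREQUENCIES_HZ = (1.0, 2.0, 4.0, 8.0, 15.0)

# depth (um) -> cortical layer, following the imaging-depth convention of
# the dataset this generator emulates; 350 um sessions group with layer 4
LAYER_BY_DEPTH = {175: "L2/3", 275: "L4", 350: "L4", 375: "L5"}

#: peak ΔF/F response amplitude per archetype (fraction units)
TYPE_AMPLITUDE = {"neutral": 0.0, "phasic": 0.30, "active": 0.20, "depressed": 0.12}


@dataclass(frozen=True)
class SynthConfig:
    """Knobs of the generator; defaults define the standard study conditions."""

    fps: float = 30.0
    session_duration: float = 600.0  # seconds
    image_size: tuple[int, int] = (128, 128)  # (H, W) pixels
    n_fidgets: int = 20
    fidget_duration_range: tuple[int, int] = (15, 45)  # frames (0.5-1.5 s)
    fidget_amplitude_px: float = 7.0  # peak vertical lift of the body
    fidget_amplitude_cv: float = 0.10
    min_event_gap_frames: int = 300  # keep the 100+200 analysis windows clean
    n_movement_bouts: int = 8
    n_neurons: int = 200
    type_probs: tuple[float, float, float, float] = (0.528, 0.139, 0.120, 0.213)
    amp_cv: float = 0.05  # neuron-to-neuron response-amplitude variability
    noise_sd: float = 0.06  # ΔF/F units per frame
    running_fraction: float = 0.3
    running_gain: float = 0.5
    indicator_tau: float = 0.7  # s, GCaMP6f-like decay
    visual_amp: float = 0.15  # ΔF/F at the preferred grating condition
    grating_repeats: int | None = None  # None -> as many as fit the session
    blank_sweep_every: int = 20
    area_effect: float = 0.0
    seed: int = 0

    def __post_init__(self):
        p = np.asarray(self.type_probs, dtype=float)
        if p.shape != (4,) or abs(p.sum() - 1.0) > 1e-9 or (p < 0).any():
            raise ValueError("type_probs must be 4 non-negative values summing to 1")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        for name in ("n_fidgets", "n_movement_bouts", "n_neurons"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.fidget_duration_range
        if not 0 < lo <= hi:
            raise ValueError("invalid fidget_duration_range")
        if self.indicator_tau <= 0:
            raise ValueError("indicator_tau must be positive")

    @property
    def n_frames(self) -> int:
        return int(round(self.fps * self.session_duration))

    def replace(self, **kw) -> "SynthConfig":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class ResponseTemplate:
    """300-sample archetype; samples 0-99 pre-onset (all zero), 100-299 post."""

    waveform: np.ndarray
    type_label: str


@dataclass
class SyntheticSession:
    frames: np.ndarray | None  # (T, H, W) in [0, 1], or None for trace-only
    labels: FrameLabelTrack
    dff: np.ndarray  # (n_neurons, T) ΔF/F
    stim_table: pd.DataFrame
    running_speed: np.ndarray  # cm/s per frame
    truth: dict
    meta: dict

    def __post_init__(self):
        t = len(self.labels)
        if self.dff.shape[1] != t or len(self.running_speed) != t:
            raise ValueError("frames/labels/dff/running_speed lengths disagree")
        if self.frames is not None and len(self.frames) != t:
            raise ValueError("video frame count disagrees with labels")
        for e in self.truth["events"]:
            if not (0 <= e.onset_frame and e.offset_frame <= t):
                raise ValueError("true event outside session")


def _rng(config: SynthConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream]))


# ---------------------------------------------------------------------------
# response templates


def generate_response_templates(
    indicator_decay_tau: float = 0.7,
    fps: float = 30.0,
    pre: int = 100,
    post: int = 200,
) -> dict[str, ResponseTemplate]:
    """Peak-normalized archetype waveforms for the four response types.

    phasic: instantaneous rise at onset, exponential decay with the
    indicator time constant; active: rise to a plateau sustained over the
    full post window; depressed: sustained negative deflection; neutral:
    identically zero.  Pre-onset samples are zero for all (causality).
    """
    if indicator_decay_tau <= 0:
        raise ValueError("indicator_decay_tau must be positive")
    t = np.arange(post) / fps
    decay = np.exp(-t / indicator_decay_tau)
    rise = 1.0 - np.exp(-t / indicator_decay_tau)
    shapes = {
        "neutral": np.zeros(post),
        "phasic": decay,
        "active": rise / rise.max(),
        "depressed": -rise / rise.max(),
    }
    out = {}
    for label, s in shapes.items():
        w = np.zeros(pre + post)
        w[pre:] = s
        out[label] = ResponseTemplate(waveform=w, type_label=label)
    return out


# ---------------------------------------------------------------------------
# stimulus table


def generate_stimulus_table(config: SynthConfig) -> pd.DataFrame:
    """Drifting-grating protocol: 2-s gratings, 1-s gray gaps, blank sweeps.

    Conditions are the 8 x 5 direction/temporal-frequency grid in random
    (seeded) order; a blank sweep replaces a grating roughly once every
    ``blank_sweep_every`` gratings.  ``grating_repeats=None`` packs as
    many full trials as fit the session; an explicit repeat count that
    does not fit raises.
    """
    rng = _rng(config, 1)
    fps = config.fps
    on, gap = int(round(2 * fps)), int(round(1 * fps))
    trial = on + gap
    conditions = [(d, tf) for d in DIRECTIONS_DEG for tf in TEMPORAL_FREQUENCIES_HZ]

    max_trials = config.n_frames // trial

    def build_order(repeats: int) -> list:
        seq: list[tuple[float, float] | None] = []
        g = 0
        for _ in range(repeats):
            block = list(conditions)
            rng.shuffle(block)
            for c in block:
                seq.append(c)
                g += 1
                if g % config.blank_sweep_every == 0:
                    seq.append(None)
        return seq

    if config.grating_repeats is None:
        # fill the session, allowing a partial final repeat
        full = build_order(max_trials // len(conditions) + 1)
        order = full[:max_trials]
    else:
        order = build_order(config.grating_repeats)
        if len(order) * trial > config.n_frames:
            raise ValueError(
                f"{config.grating_repeats} repeats need {len(order) * trial} "
                f"frames; session has {config.n_frames}"
            )

    rows = []
    f = 0
    for cond in order:
        if cond is None:
            rows.append((f, f + on, "blank", np.nan, np.nan))
        else:
            rows.append((f, f + on, "drifting_grating", float(cond[0]), float(cond[1])))
        rows.append((f + on, f + trial, "gray", np.nan, np.nan))
        f += trial
    if f < config.n_frames:
        rows.append((f, config.n_frames, "gray", np.nan, np.nan))
    return pd.DataFrame(
        rows,
        columns=[
            "start_frame",
            "end_frame",
            "stimulus_type",
            "direction_deg",
            "temporal_frequency_hz",
        ],
    )


# ---------------------------------------------------------------------------
# behavior video


def _schedule_events(config: SynthConfig, rng: np.random.Generator):
    """Non-overlapping fidget events, one per equal time slot, away from edges."""
    t = config.n_frames
    pad_start, pad_end = 120, 260  # room for the 100-pre/200-post windows
    lo, hi = config.fidget_duration_range
    if config.n_fidgets == 0:
        return [], np.array([])
    usable = t - pad_start - pad_end
    slot = usable // config.n_fidgets
    if slot < hi + 30:
        raise ValueError(
            f"session too short for {config.n_fidgets} fidgets of up to {hi} frames"
        )
    events, amps = [], []
    base = config.fidget_amplitude_px
    prev_end = -config.min_event_gap_frames
    for i in range(config.n_fidgets):
        dur = int(rng.integers(lo, hi + 1))
        slot_start = pad_start + i * slot
        start = slot_start + int(rng.integers(0, slot - dur - 15))
        # keep neighboring events out of each other's analysis windows
        # when the slot geometry allows it (best effort, never overlap)
        start = min(
            max(start, prev_end + config.min_event_gap_frames),
            slot_start + slot - dur - 15,
        )
        start = max(start, prev_end + 15)
        amp = base * (1.0 + config.fidget_amplitude_cv * rng.standard_normal())
        amps.append(max(amp, 0.1 * base))
        events.append(FidgetEvent(start, start + dur))
        prev_end = start + dur
    return events, np.asarray(amps)


def _schedule_movement(config, rng, events) -> list[tuple[int, int]]:
    t = config.n_frames
    bouts: list[tuple[int, int]] = []
    taken = [(e.onset_frame - 15, e.offset_frame + 15) for e in events]
    for _ in range(config.n_movement_bouts):
        for _attempt in range(50):
            dur = int(rng.integers(60, 150))
            start = int(rng.integers(0, max(t - dur, 1)))
            span = (start, start + dur)
            if all(span[1] <= a or span[0] >= b for a, b in taken):
                bouts.append(span)
                taken.append(span)
                break
    return bouts


def _hann(n: int) -> np.ndarray:
    u = np.linspace(0.0, 1.0, n)
    return np.sin(np.pi * u) ** 2


def generate_video_session(
    config: SynthConfig,
) -> tuple[np.ndarray, FrameLabelTrack, list[FidgetEvent], np.ndarray]:
    """Render the behavior video and its ground-truth label track.

    The body is a textured elliptical blob on a static textured
    background.  During a fidget the body lifts vertically and contracts
    horizontally with a Hann-shaped time course whose peak displacement is
    drawn with coefficient of variation ``fidget_amplitude_cv``; movement
    bouts are a slow horizontal sway.  Returns (frames, labels,
    true_events, true_amplitudes).
    """
    rng = _rng(config, 2)
    t = config.n_frames
    h, w = config.image_size
    events, amps = _schedule_events(config, rng)
    bouts = _schedule_movement(config, rng, events)

    lift = np.zeros(t)
    contract = np.zeros(t)
    sway = np.zeros(t)
    labels = np.full(t, "resting", dtype="<U16")
    for (b0, b1) in bouts:
        n = b1 - b0
        tt = np.arange(n) / config.fps
        sway[b0:b1] = 3.0 * np.sin(2 * np.pi * 2.0 * tt) * _hann(n)
        labels[b0:b1] = "movement"
    for e, a in zip(events, amps):
        n = e.duration_frames
        env = _hann(n)
        lift[e.onset_frame : e.offset_frame] = a * env
        contract[e.onset_frame : e.offset_frame] = 0.25 * env
        labels[e.onset_frame : e.offset_frame] = "fidget"

    bg = 0.25 + 0.1 * _smooth_noise((h, w), rng, sigma=3.0)
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    cy0, cx0 = 0.60 * h, 0.50 * w
    ry0, rx0 = 0.20 * h, 0.30 * w

    frames = np.empty((t, h, w), dtype=np.float32)
    sensor_noise = 0.003
    for i in range(t):
        ry = ry0 * (1.0 + 0.6 * contract[i])
        rx = rx0 * (1.0 - contract[i])
        yb = (yy - (cy0 - lift[i])) / ry
        xb = (xx - (cx0 + sway[i])) / rx
        r2 = yb * yb + xb * xb
        mask = 1.0 / (1.0 + np.exp((r2 - 1.0) / 0.06))
        tex = np.sin(7.0 * xb + 0.5) * np.cos(5.0 * yb)
        body = 0.55 + 0.20 * tex
        frame = bg * (1.0 - mask) + body * mask
        frame += sensor_noise * rng.standard_normal((h, w))
        frames[i] = np.clip(frame, 0.0, 1.0)
    track = FrameLabelTrack(labels=labels, fps=config.fps)
    return frames, track, events, amps


def _smooth_noise(shape, rng, sigma=3.0):
    n = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    span = np.ptp(n)
    return (n - n.min()) / span if span > 0 else np.zeros(shape)


# ---------------------------------------------------------------------------
# running speed


def generate_running_speed(config: SynthConfig) -> np.ndarray:
    """Running-speed trace (cm/s): smooth bouts of 10-25 cm/s on a near-zero
    baseline, occupying roughly a third of the session."""
    rng = _rng(config, 3)
    t = config.n_frames
    speed = np.abs(0.1 * rng.standard_normal(t))
    n_bouts = max(1, int(config.session_duration / 60))
    for _ in range(n_bouts):
        dur = int(rng.integers(int(5 * config.fps), int(20 * config.fps)))
        start = int(rng.integers(0, max(t - dur, 1)))
        peak = rng.uniform(10, 25)
        speed[start : start + dur] += peak * _hann(dur)
    return ndimage.gaussian_filter1d(speed, 5)


# ---------------------------------------------------------------------------
# ΔF/F traces


def _direction_tuning(pref_deg: np.ndarray, kappa: float = 2.0) -> np.ndarray:
    """(n, 8) von Mises direction-tuning gains, peak-normalized."""
    d = np.asarray(DIRECTIONS_DEG, dtype=float)
    delta = np.deg2rad(d[None, :] - pref_deg[:, None])
    g = np.exp(kappa * (np.cos(delta) - 1.0))
    return g


def _tf_tuning(pref_hz: np.ndarray, sigma_oct: float = 1.0) -> np.ndarray:
    tf = np.asarray(TEMPORAL_FREQUENCIES_HZ)
    d = np.log2(tf[None, :]) - np.log2(pref_hz[:, None])
    return np.exp(-0.5 * (d / sigma_oct) ** 2)


def generate_traces(
    config: SynthConfig,
    events: list[FidgetEvent],
    stim_table: pd.DataFrame | None = None,
    running_speed: np.ndarray | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """ΔF/F traces for ``config.n_neurons`` neurons plus per-neuron truth.

    Each neuron draws a response type from ``type_probs`` and adds its
    amplitude-scaled archetype at every fidget onset; grating trials add a
    direction/TF-tuned visual response (convolved with the indicator
    kinetics); running-modulated neurons multiply their visual response by
    ``1 + running_gain`` during running frames; i.i.d. Gaussian noise of
    SD ``noise_sd`` is added throughout.
    """
    rng = _rng(config, 4)
    n, t = config.n_neurons, config.n_frames
    for e in events:
        if e.offset_frame > t:
            raise ValueError("event outside session")

    type_idx = rng.choice(4, size=n, p=np.asarray(config.type_probs))
    type_label = np.asarray(TYPE_LABELS)[type_idx]
    base_amp = np.asarray([TYPE_AMPLITUDE[l] for l in type_label])
    amp = base_amp * np.exp(config.amp_cv * rng.standard_normal(n))

    templates = generate_response_templates(config.indicator_tau, config.fps)
    post = {l: templates[l].waveform[100:] for l in TYPE_LABELS}
    post_len = 200

    dff = np.zeros((n, t), dtype=np.float64)
    for e in events:
        stop = min(e.onset_frame + post_len, t)
        seg = slice(e.onset_frame, stop)
        for li, label in enumerate(TYPE_LABELS):
            sel = type_idx == li
            if label == "neutral" or not sel.any():
                continue
            dff[sel, seg] += amp[sel, None] * post[label][: stop - e.onset_frame]

    pref_dir = rng.choice(DIRECTIONS_DEG, size=n).astype(float)
    pref_tf = rng.choice(TEMPORAL_FREQUENCIES_HZ, size=n)
    vamp = config.visual_amp * np.exp(0.3 * rng.standard_normal(n))
    modulated = rng.random(n) < config.running_fraction
    gain = np.where(modulated, config.running_gain, 0.0)

    if stim_table is not None and running_speed is not None:
        run_mask = np.asarray(running_speed) > 1.0
        dir_gain = _direction_tuning(pref_dir)
        tf_gain = _tf_tuning(pref_tf)
        dir_index = {d: i for i, d in enumerate(DIRECTIONS_DEG)}
        tf_index = {tf: i for i, tf in enumerate(TEMPORAL_FREQUENCIES_HZ)}
        tau_frames = config.indicator_tau * config.fps
        on = int(round(2 * config.fps))
        tail = int(round(1 * config.fps))
        tt = np.arange(on + tail, dtype=float)
        shape = np.where(
            tt < on,
            1.0 - np.exp(-tt / tau_frames),
            (1.0 - np.exp(-on / tau_frames)) * np.exp(-(tt - on) / tau_frames),
        )
        gratings = stim_table[stim_table.stimulus_type == "drifting_grating"]
        for _, row in gratings.iterrows():
            s = int(row.start_frame)
            stop = min(s + on + tail, t)
            g = (
                vamp
                * dir_gain[:, dir_index[row.direction_deg]]
                * tf_gain[:, tf_index[row.temporal_frequency_hz]]
            )
            seg_shape = shape[: stop - s]
            runfac = 1.0 + gain[:, None] * run_mask[None, s:stop]
            dff[:, s:stop] += g[:, None] * seg_shape[None, :] * runfac

    if config.noise_sd > 0:
        dff += config.noise_sd * rng.standard_normal((n, t))

    truth = pd.DataFrame(
        {
            "neuron_id": np.arange(n),
            "type_label": type_label,
            "amplitude_dff": amp,
            "pref_direction_deg": pref_dir,
            "pref_tf_hz": pref_tf,
            "visual_amp_dff": vamp,
            "running_modulated": modulated,
            "running_gain": gain,
        }
    )
    return dff, truth


# ---------------------------------------------------------------------------
# sessions and cohorts


def generate_session(
    config: SynthConfig, meta: dict | None = None, with_video: bool = True
) -> SyntheticSession:
    """One full synthetic session (video optional for trace-only analyses)."""
    meta = dict(meta or {"area": "VISp", "depth_um": 175, "cre_line": "Cux2"})
    if with_video:
        frames, labels, events, amps = generate_video_session(config)
    else:
        rng = _rng(config, 2)
        events, amps = _schedule_events(config, rng)
        lab = np.full(config.n_frames, "resting", dtype="<U16")
        for e in events:
            lab[e.onset_frame : e.offset_frame] = "fidget"
        frames, labels = None, FrameLabelTrack(labels=lab, fps=config.fps)
    stim = generate_stimulus_table(config)
    running = generate_running_speed(config)
    dff, truth_neurons = generate_traces(config, events, stim, running)
    truth = {"neurons": truth_neurons, "events": events, "event_amplitudes": amps}
    return SyntheticSession(
        frames=frames,
        labels=labels,
        dff=dff,
        stim_table=stim,
        running_speed=running,
        truth=truth,
        meta=meta,
    )


#: which type an area's prevalence shift boosts, in cohort order
_AREA_BOOST_TYPES = ("phasic", "active", "depressed")


def shifted_type_probs(
    base: tuple[float, float, float, float], area_rank: int, area_effect: float
) -> tuple[float, float, float, float]:
    """Per-area type probabilities under a cohort prevalence shift.

    The first three requested areas each boost one non-neutral type
    (phasic, active, depressed respectively) by ``area_effect``, taking
    the probability mass from neutral; later areas keep the base mix.
    With ``area_effect = 0`` every area is identical (null cohort).
    """
    if area_effect == 0 or area_rank >= len(_AREA_BOOST_TYPES):
        return tuple(base)
    p = list(base)
    boost = TYPE_LABELS.index(_AREA_BOOST_TYPES[area_rank])
    p[boost] += area_effect
    p[0] -= area_effect
    if p[0] < 0:
        raise ValueError("area_effect too large: neutral probability went negative")
    return tuple(p)


def generate_cohort(
    n_sessions: int,
    areas: tuple[str, ...] = ("VISp", "VISpm", "VISal", "VISl"),
    depths: tuple[int, ...] = (175, 275, 375),
    cre_lines: tuple[str, ...] = ("Cux2", "Rorb", "Rbp4"),
    config: SynthConfig = SynthConfig(),
    with_video: bool = False,
) -> list[SyntheticSession]:
    """Multi-session cohort with cycling area/depth/Cre-line metadata.

    ``config.area_effect`` controls whether the cohort is a null cohort
    (0: identical generating prevalences everywhere) or a positive
    control (> 0: per-area prevalence shifts; see
    :func:`shifted_type_probs`).
    """
    if n_sessions < 1:
        raise ValueError("n_sessions must be >= 1")
    if not areas:
        raise ValueError("areas must be non-empty")
    sessions = []
    for i in range(n_sessions):
        area = areas[i % len(areas)]
        probs = shifted_type_probs(
            config.type_probs, areas.index(area), config.area_effect
        )
        meta = {
            "area": area,
            "depth_um": depths[i % len(depths)],
            "cre_line": cre_lines[i % len(cre_lines)],
            "type_probs": probs,
        }
        cfg = config.replace(seed=config.seed + 1000 + i, type_probs=probs)
        sessions.append(generate_session(cfg, meta=meta, with_video=with_video))
    return sessions
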