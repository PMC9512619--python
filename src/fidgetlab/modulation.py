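"""Behavioral-state modulation of visually evoked responses.

For each neuron the preferred drifting-grating condition (direction x
temporal frequency eliciting the largest mean ΔF/F) is found, and the
mean response at that condition is compared between two behavioral states
(fidget vs non-fidget, or running vs stationary) with a Cohen's d whose
denominator is the Euclidean norm of the two state SDs:

    d = (x̄1 - x̄2) / sqrt(s1² + s2²)

Per-cell significance uses two-sided two-sample Kolmogorov-Smirnov tests
with Benjamini-Hochberg correction across cells, and the interaction
analysis asks whether fidget- and running-modulation co-occur in the same
cells (covariance/correlation of the two d vectors plus the fraction of
running-modulated cells that are also fidget-modulated).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .behavior import FidgetEvent

__all__ = [
    "cohens_d",
    "preferred_condition",
    "preferred_trial_samples",
    "state_modulation",
    "bh_reject",
    "per_cell_significance",
    "modulation_interaction",
    "tuning_metrics",
    "fidget_state_mask",
    "running_state_mask",
]


def cohens_d(
    mean1: float, mean2: float, sd1: float, sd2: float, norm: str = "euclidean"
) -> float:
    """Standardized mean difference between two states.

    ``norm='euclidean'`` uses s = sqrt(s1² + s2²) (the plain reading of
    "the norm of the two SDs"); ``'pooled'`` uses sqrt((s1² + s2²)/2).
    """
    if norm == "euclidean":
        s = float(np.hypot(sd1, sd2))
    elif norm == "pooled":
        s = float(np.sqrt((sd1**2 + sd2**2) / 2.0))
    else:
        raise ValueError(f"unknown norm {norm!r}")
    if s == 0:
        return np.nan
    return (mean1 - mean2) / s


# ---------------------------------------------------------------------------
# state masks


def fidget_state_mask(events: list[FidgetEvent], n_frames: int) -> np.ndarray:
    mask = np.zeros(n_frames, dtype=bool)
    for e in events:
        mask[e.onset_frame : e.offset_frame] = True
    return mask


def running_state_mask(
    speed: np.ndarray, threshold_cm_s: float = 1.0, min_duration_s: float = 1.0, fps: float = 30.0
) -> np.ndarray:
    """Frames where the mouse runs: speed above threshold sustained for at
    least ``min_duration_s``."""
    fast = np.asarray(speed) > threshold_cm_s
    min_len = int(round(min_duration_s * fps))
    out = np.zeros_like(fast)
    padded = np.concatenate([[False], fast, [False]]).astype(np.int8)
    d = np.diff(padded)
    for on, off in zip(np.flatnonzero(d == 1), np.flatnonzero(d == -1)):
        if off - on >= min_len:
            out[on:off] = True
    return out


# ---------------------------------------------------------------------------
# preferred condition


def _grating_on_frames(row, fps: float) -> slice:
    return slice(int(row.start_frame), int(row.end_frame))


def _grating_trials(
    stim_table: pd.DataFrame, exclude_mask: np.ndarray | None
) -> pd.DataFrame:
    """Drifting-grating rows, optionally dropping trials whose on-window
    overlaps an exclusion mask (e.g. fidget-response frames, so that
    movement-evoked activity does not contaminate tuning estimates)."""
    gratings = stim_table[stim_table.stimulus_type == "drifting_grating"]
    if exclude_mask is None or gratings.empty:
        return gratings
    mask = np.asarray(exclude_mask, dtype=bool)
    clean = [
        not mask[int(r.start_frame) : int(r.end_frame)].any()
        for r in gratings.itertuples()
    ]
    return gratings[np.asarray(clean)]


def preferred_condition(
    dff: np.ndarray,
    stim_table: pd.DataFrame,
    fps: float = 30.0,
    exclude_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Preferred (direction, temporal frequency) per neuron.

    The response to a grating trial is the mean ΔF/F over the stimulus-on
    frames; responses are averaged per condition and the argmax condition
    returned.  Exact ties resolve to the lowest direction, then the
    lowest temporal frequency.
    """
    gratings = _grating_trials(stim_table, exclude_mask)
    if gratings.empty:
        raise ValueError("stimulus table contains no drifting-grating trials")
    dff = np.asarray(dff)
    n = dff.shape[0]
    sums: dict[tuple[float, float], np.ndarray] = {}
    counts: dict[tuple[float, float], int] = {}
    for _, row in gratings.iterrows():
        resp = dff[:, _grating_on_frames(row, fps)].mean(axis=1)
        key = (float(row.direction_deg), float(row.temporal_frequency_hz))
        if key in sums:
            sums[key] += resp
            counts[key] += 1
        else:
            sums[key] = resp.copy()
            counts[key] = 1
    conds = sorted(sums)  # lexicographic: direction then TF — the tie-break
    mat = np.stack([sums[c] / counts[c] for c in conds], axis=1)  # (n, n_cond)
    best = mat.argmax(axis=1)  # argmax takes the first (lowest) on ties
    return pd.DataFrame(
        {
            "neuron_id": np.arange(n),
            "direction_deg": [conds[b][0] for b in best],
            "temporal_frequency_hz": [conds[b][1] for b in best],
            "mean_response_dff": mat[np.arange(n), best],
        }
    )


def preferred_trial_samples(
    dff: np.ndarray,
    stim_table: pd.DataFrame,
    preferred: pd.DataFrame,
    state_mask: np.ndarray,
    exclude_mask: np.ndarray | None = None,
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Per-neuron ΔF/F samples at the preferred condition, split by state.

    Returns (in_state, out_of_state) lists of per-neuron sample arrays.
    Frames in ``exclude_mask`` are removed from the out-of-state pool
    (e.g. fidget frames when contrasting running vs stationary).
    """
    gratings = stim_table[stim_table.stimulus_type == "drifting_grating"]
    state_mask = np.asarray(state_mask, dtype=bool)
    out_ok = ~state_mask if exclude_mask is None else ~state_mask & ~np.asarray(exclude_mask)
    n = dff.shape[0]
    in_s: list[list[np.ndarray]] = [[] for _ in range(n)]
    out_s: list[list[np.ndarray]] = [[] for _ in range(n)]
    pref = list(
        zip(preferred["direction_deg"].to_numpy(), preferred["temporal_frequency_hz"].to_numpy())
    )
    for _, row in gratings.iterrows():
        key = (float(row.direction_deg), float(row.temporal_frequency_hz))
        sl = slice(int(row.start_frame), int(row.end_frame))
        frames_in = state_mask[sl]
        frames_out = out_ok[sl]
        seg = dff[:, sl]
        for i in range(n):
            if pref[i] != key:
                continue
            if frames_in.any():
                in_s[i].append(seg[i, frames_in])
            if frames_out.any():
                out_s[i].append(seg[i, frames_out])
    cat = lambda parts: np.concatenate(parts) if parts else np.array([])
    return [cat(p) for p in in_s], [cat(p) for p in out_s]


def state_modulation(
    dff: np.ndarray,
    stim_table: pd.DataFrame,
    state_mask: np.ndarray,
    preferred: pd.DataFrame,
    state_pair: str = "state1/state2",
    exclude_mask: np.ndarray | None = None,
    norm: str = "euclidean",
) -> pd.DataFrame:
    """Per-neuron Cohen's d between states at the preferred condition.

    A neuron whose preferred-condition trials contain no frames in one of
    the states gets NaN statistics and ``defined=False``.
    """
    in_s, out_s = preferred_trial_samples(dff, stim_table, preferred, state_mask, exclude_mask)
    rows = []
    for i, (a, b) in enumerate(zip(in_s, out_s)):
        ok = a.size >= 2 and b.size >= 2
        if ok:
            d = cohens_d(a.mean(), b.mean(), a.std(ddof=0), b.std(ddof=0), norm=norm)
        else:
            d = np.nan
        rows.append(
            {
                "neuron_id": i,
                "mean_dff_state1": a.mean() if a.size else np.nan,
                "mean_dff_state2": b.mean() if b.size else np.nan,
                "sd_state1": a.std(ddof=0) if a.size else np.nan,
                "sd_state2": b.std(ddof=0) if b.size else np.nan,
                "cohens_d": d,
                "n_state1": a.size,
                "n_state2": b.size,
                "state_pair": state_pair,
                "defined": ok,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# significance


def bh_reject(p_values, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejections at FDR level q."""
    p = np.asarray(p_values, dtype=float)
    return multipletests(p, alpha=q, method="fdr_bh")[0]


def per_cell_significance(
    samples_state1: list[np.ndarray],
    samples_state2: list[np.ndarray],
    q: float = 0.05,
) -> pd.DataFrame:
    """Two-sided two-sample KS test per cell, BH-corrected across cells.

    Cells with fewer than 2 samples in either state are untestable: their
    p is NaN and they are excluded from the BH family.
    """
    p = np.full(len(samples_state1), np.nan)
    for i, (a, b) in enumerate(zip(samples_state1, samples_state2)):
        if len(a) >= 2 and len(b) >= 2:
            p[i] = stats.ks_2samp(a, b, alternative="two-sided").pvalue
    testable = ~np.isnan(p)
    sig = np.zeros(len(p), dtype=bool)
    if testable.any():
        sig[testable] = bh_reject(p[testable], q)
    return pd.DataFrame(
        {"neuron_id": np.arange(len(p)), "p_value": p, "q_significant": sig, "testable": testable}
    )


# ---------------------------------------------------------------------------
# interaction


@dataclass
class InteractionResult:
    covariance: float
    correlation: float
    joint_fraction: float  # |sig_running ∩ sig_fidget| / |sig_running|
    joint_fraction_defined: bool
    n_sig_fidget: int
    n_sig_running: int
    per_type: pd.DataFrame | None = None
    scatter: pd.DataFrame | None = None


def modulation_interaction(
    d_fidget: np.ndarray,
    d_running: np.ndarray,
    sig_fidget: np.ndarray,
    sig_running: np.ndarray,
    type_labels: np.ndarray | None = None,
) -> InteractionResult:
    """Do fidget- and running-modulation co-occur in the same cells?

    Reports the covariance and Pearson correlation of the two Cohen's d
    vectors (over cells where both are finite), the fraction of
    significantly running-modulated cells that are also fidget-modulated,
    and an optional per-response-type breakdown.
    """
    d_f = np.asarray(d_fidget, dtype=float)
    d_r = np.asarray(d_running, dtype=float)
    sig_f = np.asarray(sig_fidget, dtype=bool)
    sig_r = np.asarray(sig_running, dtype=bool)
    ok = np.isfinite(d_f) & np.isfinite(d_r)
    if ok.sum() >= 2:
        cov = float(np.cov(d_f[ok], d_r[ok])[0, 1])
        corr = float(np.corrcoef(d_f[ok], d_r[ok])[0, 1])
    else:
        cov = corr = np.nan
    n_r = int(sig_r.sum())
    frac = float((sig_r & sig_f).sum() / n_r) if n_r else np.nan

    per_type = None
    scatter = pd.DataFrame({"d_fidget": d_f, "d_running": d_r, "sig_fidget": sig_f, "sig_running": sig_r})
    if type_labels is not None:
        scatter["type_label"] = np.asarray(type_labels)
        grp = scatter.groupby("type_label")
        per_type = pd.DataFrame(
            {
                "pct_sig_fidget": grp["sig_fidget"].mean() * 100.0,
                "pct_sig_running": grp["sig_running"].mean() * 100.0,
                "median_d_fidget": grp["d_fidget"].median(),
                "median_d_running": grp["d_running"].median(),
                "n": grp.size(),
            }
        )
    return InteractionResult(
        covariance=cov,
        correlation=corr,
        joint_fraction=frac,
        joint_fraction_defined=bool(n_r),
        n_sig_fidget=int(sig_f.sum()),
        n_sig_running=n_r,
        per_type=per_type,
        scatter=scatter,
    )


# ---------------------------------------------------------------------------
# tuning metrics


def tuning_metrics(
    dff: np.ndarray,
    stim_table: pd.DataFrame,
    fps: float = 30.0,
    exclude_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Direction selectivity, preferred orientation and preferred TF.

    DSI = (R_pref - R_null) / (R_pref + R_null) with R_null the mean
    response 180° opposite the preferred direction, both at the preferred
    temporal frequency; undefined (NaN) when R_pref + R_null <= 0.
    Preferred orientation is the preferred direction mod 180.

    ``exclude_mask`` drops trials contaminated by the marked frames
    (typically the post-fidget response window) from the estimates.
    """
    gratings = _grating_trials(stim_table, exclude_mask)
    if gratings.empty:
        raise ValueError("stimulus table contains no drifting-grating trials")
    pref = preferred_condition(dff, stim_table, fps=fps, exclude_mask=exclude_mask)
    dff = np.asarray(dff)
    n = dff.shape[0]
    # condition-mean matrix
    sums, counts = {}, {}
    for _, row in gratings.iterrows():
        key = (float(row.direction_deg), float(row.temporal_frequency_hz))
        resp = dff[:, _grating_on_frames(row, fps)].mean(axis=1)
        if key in sums:
            sums[key] += resp
            counts[key] += 1
        else:
            sums[key], counts[key] = resp.copy(), 1
    mean_by_cond = {k: sums[k] / counts[k] for k in sums}

    dsi = np.full(n, np.nan)
    for i in range(n):
        d0 = pref.loc[i, "direction_deg"]
        tf = pref.loc[i, "temporal_frequency_hz"]
        r_pref = mean_by_cond[(d0, tf)][i]
        null_key = ((d0 + 180.0) % 360.0, tf)
        if null_key not in mean_by_cond:
            continue
        r_null = mean_by_cond[null_key][i]
        if r_pref + r_null > 0:
            dsi[i] = (r_pref - r_null) / (r_pref + r_null)
    return pd.DataFrame(
        {
            "neuron_id": np.arange(n),
            "dsi": dsi,
            "pref_direction_deg": pref["direction_deg"],
            "pref_orientation_deg": pref["direction_deg"] % 180.0,
            "pref_tf_hz": pref["temporal_frequency_hz"],
        }
    )
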