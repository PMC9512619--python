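"""Event-aligned neural response analysis.

ΔF/F traces are cut into trials of 100 pre-onset and 200 post-onset
samples around each fidget onset, z-scored trial-by-trial against the
pre-onset baseline, and trial-averaged per neuron.  Mean responses are
clustered with k-means++ and the number of clusters is selected with the
gap statistic; clusters are then mapped onto the four semantic response
types (neutral / phasic / active / depressed) from the shape of their
centroids.  Threshold criteria on raw ΔF/F re-label weakly modulated
neurons as "criteria neutral", and per-stratum type-distribution tables
summarize how the types spread over areas, layers and Cre-lines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .behavior import FidgetEvent
from .synthdata import LAYER_BY_DEPTH, generate_response_templates

__all__ = [
    "AlignedTrials",
    "MeanResponses",
    "ThresholdCriterion",
    "GapStatisticResult",
    "align_and_zscore",
    "mean_responses",
    "cluster_mean_responses",
    "label_clusters",
    "assign_response_types",
    "apply_threshold_criteria",
    "type_distribution",
]

PRE_SAMPLES = 100
POST_SAMPLES = 200


@dataclass
class AlignedTrials:
    """neurons x events x (pre+post) samples; NaN marks excluded trials."""

    data: np.ndarray
    onsets: np.ndarray  # event onset frames actually retained
    pre: int = PRE_SAMPLES
    post: int = POST_SAMPLES
    n_dropped_events: int = 0
    n_excluded_trials: int = 0  # zero-baseline-SD trials NaN'd out

    @property
    def n_neurons(self) -> int:
        return self.data.shape[0]

    @property
    def n_trials(self) -> int:
        return self.data.shape[1]


@dataclass
class MeanResponses:
    mean_z: np.ndarray  # neurons x 300, trial-averaged z-scores
    n_trials: np.ndarray  # valid trials per neuron
    mean_dff_post: np.ndarray  # trial-averaged mean raw ΔF/F over post window
    max_dff_post: np.ndarray  # max |ΔF/F| of the trial-averaged post trace


@dataclass(frozen=True)
class ThresholdCriterion:
    """Raw-ΔF/F modulation criterion: mean or max of the post window."""

    kind: str  # "mean_post" | "max_post"
    threshold: float  # ΔF/F fraction, e.g. 0.06

    def __post_init__(self):
        if self.kind not in ("mean_post", "max_post"):
            raise ValueError(f"unknown criterion kind {self.kind!r}")
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")

    def passes(self, resp: MeanResponses) -> np.ndarray:
        stat = resp.mean_dff_post if self.kind == "mean_post" else resp.max_dff_post
        return np.abs(stat) > self.threshold


def align_and_zscore(
    dff: np.ndarray,
    events: list[FidgetEvent],
    pre: int = PRE_SAMPLES,
    post: int = POST_SAMPLES,
) -> tuple[AlignedTrials, AlignedTrials]:
    """Cut event-aligned trials and z-score each against its own baseline.

    Events without a full pre/post window are dropped (and counted).  Each
    trial is normalized as (x - baseline_mean) / baseline_SD using only
    that trial's ``pre`` pre-onset samples; trials with zero baseline SD
    are excluded (set to NaN) and counted.  Returns (z-scored, raw).
    """
    dff = np.asarray(dff, dtype=np.float64)
    n, t = dff.shape
    kept = [e for e in events if e.onset_frame - pre >= 0 and e.onset_frame + post <= t]
    dropped = len(events) - len(kept)
    if not kept:
        empty = np.empty((n, 0, pre + post))
        a = AlignedTrials(empty, np.array([], int), pre, post, dropped)
        return a, AlignedTrials(empty.copy(), np.array([], int), pre, post, dropped)
    onsets = np.array([e.onset_frame for e in kept])
    idx = onsets[:, None] + np.arange(-pre, post)[None, :]
    raw = dff[:, idx]  # (n, trials, pre+post)
    base = raw[:, :, :pre]
    mu = base.mean(axis=2, keepdims=True)
    sd = base.std(axis=2, keepdims=True)
    bad = sd[..., 0] == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (raw - mu) / sd
    z[bad] = np.nan
    n_excluded = int(bad.sum())
    if n_excluded:
        warnings.warn(
            f"excluded {n_excluded} trial(s) with zero baseline SD", stacklevel=2
        )
    za = AlignedTrials(z, onsets, pre, post, dropped, n_excluded)
    ra = AlignedTrials(raw, onsets, pre, post, dropped, n_excluded)
    return za, ra


def mean_responses(
    z_trials: AlignedTrials, raw_trials: AlignedTrials, min_trials: int = 3
) -> tuple[MeanResponses, np.ndarray]:
    """Trial-average each neuron; returns (responses, retained-neuron mask).

    Neurons with fewer than ``min_trials`` valid trials are masked out —
    a one-trial "mean" is indistinguishable from noise.
    """
    z = z_trials.data
    valid = ~np.isnan(z[:, :, 0])
    n_valid = valid.sum(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_z = np.nanmean(z, axis=1)
        raw_mean = np.nanmean(raw_trials.data, axis=1)
    base = raw_mean[:, : raw_trials.pre].mean(axis=1)
    post = raw_mean[:, raw_trials.pre :] - base[:, None]
    resp = MeanResponses(
        mean_z=np.nan_to_num(mean_z),
        n_trials=n_valid,
        mean_dff_post=post.mean(axis=1),
        max_dff_post=post[np.arange(len(post)), np.abs(post).argmax(axis=1)],
    )
    return resp, n_valid >= min_trials


# ---------------------------------------------------------------------------
# clustering and the gap statistic


@dataclass
class GapStatisticResult:
    optimal_k: int
    k_values: np.ndarray
    gap: np.ndarray
    s_k: np.ndarray
    log_w: np.ndarray
    labels_by_k: dict[int, np.ndarray] = field(repr=False)
    centroids_by_k: dict[int, np.ndarray] = field(repr=False)

    @property
    def labels(self) -> np.ndarray:
        return self.labels_by_k[self.optimal_k]

    @property
    def centroids(self) -> np.ndarray:
        return self.centroids_by_k[self.optimal_k]


def _within_dispersion(x: np.ndarray, k: int, seed: int):
    if k == 1:
        c = x.mean(axis=0, keepdims=True)
        w = float(((x - c) ** 2).sum())
        return np.zeros(len(x), dtype=int), c, w
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=seed)
    labels = km.fit_predict(x)
    return labels, km.cluster_centers_, float(km.inertia_)


def cluster_mean_responses(
    mean_z: np.ndarray,
    k_range=range(1, 9),
    n_ref: int = 20,
    seed: int = 0,
    selection_rule: str = "global_se_max",
) -> GapStatisticResult:
    """k-means++ over ``k_range`` with gap-statistic model selection.

    The gap at k compares log within-cluster dispersion of the data with
    that of ``n_ref`` reference datasets drawn uniformly over the data's
    bounding box in its principal-component frame; s(k) includes the
    simulation-error correction sqrt(1 + 1/n_ref).

    ``selection_rule='global_se_max'`` (default) picks the smallest k
    whose gap is within one s of the global maximum; ``'tibshirani'``
    picks the smallest k with gap(k) >= gap(k+1) - s(k+1).  The
    first-crossing rule is unreliable when one dominant compact cluster
    coexists with small distant ones (the gap curve dips at k=2 before
    its true maximum), which is exactly the geometry of a mostly-neutral
    population, hence the default.
    """
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValueError("k_range is empty")
    x = np.asarray(mean_z, dtype=np.float64)
    if len(x) < max(ks):
        raise ValueError(f"need at least {max(ks)} neurons, got {len(x)}")

    labels_by_k, centroids_by_k, log_w = {}, {}, []
    for k in ks:
        labels, cents, w = _within_dispersion(x, k, seed)
        labels_by_k[k], centroids_by_k[k] = labels, cents
        log_w.append(np.log(w) if w > 0 else -np.inf)
    log_w = np.asarray(log_w)

    # uniform reference in the PCA-rotated bounding box (Tibshirani's
    # rotation-respecting variant)
    rng = np.random.default_rng(seed)
    mu = x.mean(axis=0)
    xc = x - mu
    _, _, vt = np.linalg.svd(xc, full_matrices=False)
    proj = xc @ vt.T
    lo, hi = proj.min(axis=0), proj.max(axis=0)
    ref_log_w = np.empty((n_ref, len(ks)))
    for b in range(n_ref):
        ref = rng.uniform(lo, hi, size=proj.shape) @ vt + mu
        for j, k in enumerate(ks):
            _, _, w = _within_dispersion(ref, k, seed + 7919 * (b + 1))
            ref_log_w[b, j] = np.log(w) if w > 0 else -np.inf

    gap = ref_log_w.mean(axis=0) - log_w
    s_k = ref_log_w.std(axis=0) * np.sqrt(1.0 + 1.0 / n_ref)

    if selection_rule == "tibshirani":
        optimal = ks[-1]
        for j in range(len(ks) - 1):
            if gap[j] >= gap[j + 1] - s_k[j + 1]:
                optimal = ks[j]
                break
    elif selection_rule == "global_se_max":
        jmax = int(np.argmax(gap))
        optimal = ks[
            next(j for j in range(len(ks)) if gap[j] >= gap[jmax] - s_k[jmax])
        ]
    else:
        raise ValueError(f"unknown selection_rule {selection_rule!r}")
    return GapStatisticResult(
        optimal_k=optimal,
        k_values=np.asarray(ks),
        gap=gap,
        s_k=s_k,
        log_w=log_w,
        labels_by_k=labels_by_k,
        centroids_by_k=centroids_by_k,
    )


# ---------------------------------------------------------------------------
# semantic labeling of clusters


def label_clusters(
    centroids: np.ndarray,
    pre: int = PRE_SAMPLES,
    theta: float = 0.25,
    peak_theta: float = 0.5,
    sustained_cutoff: float = 0.5,
) -> list[str]:
    """Map cluster centroids (mean-z traces) onto the four response types.

    Let M be the mean post-onset z, P the signed extremum, and L the
    fraction of the post window above half of P.  Small |M| and |P| is
    neutral; M < -theta is depressed; M > theta is phasic when the
    response is transient (L < sustained_cutoff) and active when
    sustained.  Anything else is ambiguous and falls back to the nearest
    archetype, with a warning.
    """
    templates = generate_response_templates()
    archetypes = {l: t.waveform for l, t in templates.items()}
    out = []
    for c in np.asarray(centroids, dtype=np.float64):
        post = c[pre:]
        m = post.mean()
        p = post[np.abs(post).argmax()]
        if abs(m) < theta and abs(p) < peak_theta:
            out.append("neutral")
        elif m < -theta:
            out.append("depressed")
        elif m > theta:
            frac_high = float(np.mean(post > 0.5 * p)) if p > 0 else 0.0
            out.append("phasic" if frac_high < sustained_cutoff else "active")
        else:
            label = _nearest_archetype(post, archetypes, pre)
            warnings.warn(
                f"ambiguous centroid (mean {m:.2f}, peak {p:.2f}); "
                f"labeled by nearest archetype as {label!r}",
                stacklevel=2,
            )
            out.append(label)
    return out


def _nearest_archetype(post: np.ndarray, archetypes: dict, pre: int) -> str:
    scale = np.abs(post).max()
    if scale == 0:
        return "neutral"
    unit = post / scale
    names = list(archetypes)
    mats = np.stack([archetypes[n][pre:] for n in names])
    d = ((mats - unit[None]) ** 2).sum(axis=1)
    return names[int(np.argmin(d))]


def assign_response_types(
    mean_z: np.ndarray,
    gap_result: GapStatisticResult | None = None,
    k: int | None = None,
    seed: int = 0,
    **label_kwargs,
) -> pd.DataFrame:
    """Cluster (or reuse a clustering) and attach semantic type labels.

    Returns a table with neuron_id, cluster_id, type_label and the
    distance to the assigned centroid.
    """
    if gap_result is not None:
        labels, centroids = gap_result.labels, gap_result.centroids
    else:
        if k is None:
            raise ValueError("provide either gap_result or k")
        labels, centroids, _ = _within_dispersion(
            np.asarray(mean_z, dtype=np.float64), k, seed
        )
    names = label_clusters(centroids, **label_kwargs)
    x = np.asarray(mean_z, dtype=np.float64)
    dist = np.linalg.norm(x - centroids[labels], axis=1)
    return pd.DataFrame(
        {
            "neuron_id": np.arange(len(x)),
            "cluster_id": labels,
            "type_label": [names[c] for c in labels],
            "distance_to_centroid": dist,
        }
    )


def apply_threshold_criteria(
    assignments: pd.DataFrame, responses: MeanResponses, criterion: ThresholdCriterion
) -> pd.DataFrame:
    """Re-label non-neutral neurons failing a raw-ΔF/F criterion.

    Only the non-neutral -> "criteria neutral" direction is allowed:
    neurons already neutral keep their label, and passing neurons are
    untouched, so a stricter threshold always yields a subset of a looser
    one's modulated set.
    """
    passes = criterion.passes(responses)
    out = assignments.copy()
    relabel = (~passes[out["neuron_id"].to_numpy()]) & (out["type_label"] != "neutral")
    out.loc[relabel, "type_label"] = "criteria neutral"
    return out


# ---------------------------------------------------------------------------
# distribution tables


def cohort_mean_responses(
    sessions, use_true_events: bool = True, events_by_session=None, min_trials: int = 3
) -> tuple[MeanResponses, pd.DataFrame]:
    """Align and trial-average every neuron of a multi-session cohort.

    Returns pooled mean responses (retained neurons only) and a metadata
    table (neuron_id, session, area, depth_um, cre_line, true type).
    Detected events can be supplied per session via ``events_by_session``;
    by default the sessions' ground-truth events are used.
    """
    mean_z_parts, meta_rows = [], []
    mean_post, max_post, n_trials = [], [], []
    nid = 0
    for si, sess in enumerate(sessions):
        events = (
            sess.truth["events"] if use_true_events else events_by_session[si]
        )
        z, raw = align_and_zscore(sess.dff, events)
        resp, keep = mean_responses(z, raw, min_trials=min_trials)
        idx = np.flatnonzero(keep)
        mean_z_parts.append(resp.mean_z[idx])
        mean_post.append(resp.mean_dff_post[idx])
        max_post.append(resp.max_dff_post[idx])
        n_trials.append(resp.n_trials[idx])
        truth_types = sess.truth["neurons"]["type_label"].to_numpy()
        for j in idx:
            meta_rows.append(
                {
                    "neuron_id": nid,
                    "session": si,
                    "area": sess.meta["area"],
                    "depth_um": sess.meta["depth_um"],
                    "cre_line": sess.meta["cre_line"],
                    "true_type": truth_types[j],
                }
            )
            nid += 1
    pooled = MeanResponses(
        mean_z=np.concatenate(mean_z_parts),
        n_trials=np.concatenate(n_trials),
        mean_dff_post=np.concatenate(mean_post),
        max_dff_post=np.concatenate(max_post),
    )
    return pooled, pd.DataFrame(meta_rows)


def layer_from_depth(depth_um: int) -> str:
    try:
        return LAYER_BY_DEPTH[int(depth_um)]
    except KeyError:
        raise ValueError(f"unknown imaging depth {depth_um} um") from None


def type_distribution(
    assignments: pd.DataFrame, metadata: pd.DataFrame, stratify_by: str = "area"
) -> pd.DataFrame:
    """Percentage of each response type per stratum (area, layer or cre).

    ``metadata`` must carry one row per neuron_id with area, depth_um and
    cre_line columns; the layer stratum is derived from depth.
    """
    df = assignments.merge(metadata, on="neuron_id", validate="one_to_one")
    if stratify_by == "layer":
        df["layer"] = df["depth_um"].map(lambda d: layer_from_depth(d))
        key = "layer"
    elif stratify_by in ("area", "cre", "cre_line"):
        key = "area" if stratify_by == "area" else "cre_line"
    else:
        raise ValueError(f"unknown stratification {stratify_by!r}")
    counts = df.groupby([key, "type_label"]).size().unstack(fill_value=0)
    pct = counts.div(counts.sum(axis=1), axis=0) * 100.0
    pct.columns = [f"pct_{c}" for c in pct.columns]
    counts.columns = [f"n_{c}" for c in counts.columns]
    return pd.concat([pct, counts], axis=1)
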