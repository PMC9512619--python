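"""Fidget detection from side-view behavioral video.

The detector follows a classical supervised computer-vision recipe:
grayscale frames are power-law normalized and cropped, per-frame histogram
of oriented gradients (HOG) descriptors are computed (8 orientation bins,
32-px square cells, one cell per block), reduced with PCA and concatenated
into 1-s blocks, and an RBF-kernel support vector machine classifies every
block as fidget / movement / resting.  Contiguous fidget frames are merged
into events, which are scored against annotations at the event or frame
level.

The PCA basis is part of the trained model: it is fit on training frames
only and re-used (never re-fit) at inference time.
"""

from __future__ import annotations

import io as _io
import warnings
import zipfile
from dataclasses import dataclass, field, asdict

import joblib
import numpy as np
import pandas as pd
from skimage.feature import hog as _skimage_hog
from sklearn.decomposition import PCA
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.svm import SVC

__all__ = [
    "CLASSES",
    "CropRectangle",
    "FrameLabelTrack",
    "FidgetEvent",
    "FeatureBlock",
    "FeatureConfig",
    "DetectorModel",
    "DetectionMetrics",
    "preprocess_frames",
    "compute_hog_features",
    "extract_block_features",
    "block_labels_from_frames",
    "train_detector",
    "session_hog_features",
    "fit_detector_on_features",
    "fit_detector_on_sessions",
    "detect_session",
    "predict_labels",
    "extract_events",
    "score_detection",
    "normalized_fidget_rate",
]

CLASSES = ("fidget", "movement", "resting")


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class CropRectangle:
    """Axis-aligned crop, origin top-left, half-open on the high edge."""

    x0: int
    y0: int
    x1: int
    y1: int

    def __post_init__(self):
        if not (self.x1 > self.x0 and self.y1 > self.y0):
            raise ValueError(f"degenerate crop rectangle {self}")

    def validate_against(self, height: int, width: int) -> None:
        if self.x0 < 0 or self.y0 < 0 or self.x1 > width or self.y1 > height:
            raise ValueError(
                f"crop {self} outside frame bounds ({height}x{width})"
            )

    def apply(self, frames: np.ndarray) -> np.ndarray:
        self.validate_against(frames.shape[-2], frames.shape[-1])
        return frames[..., self.y0 : self.y1, self.x0 : self.x1]


@dataclass
class FrameLabelTrack:
    """Per-frame behavior class at a fixed frame rate."""

    labels: np.ndarray  # array of str, one of CLASSES
    fps: float = 30.0

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype="<U16")
        unknown = set(np.unique(self.labels)) - set(CLASSES)
        if unknown:
            raise ValueError(f"unknown behavior classes: {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.labels)

    def n_fidget_frames(self) -> int:
        return int(np.sum(self.labels == "fidget"))


@dataclass(frozen=True)
class FidgetEvent:
    """One detected fidget; frame range is half-open [onset, offset)."""

    onset_frame: int
    offset_frame: int
    magnitude: float | None = None

    def __post_init__(self):
        if self.offset_frame <= self.onset_frame:
            raise ValueError(f"empty event [{self.onset_frame}, {self.offset_frame})")

    @property
    def duration_frames(self) -> int:
        return self.offset_frame - self.onset_frame

    def overlaps(self, other: "FidgetEvent") -> bool:
        return self.onset_frame < other.offset_frame and other.onset_frame < self.offset_frame


@dataclass
class FeatureBlock:
    vector: np.ndarray
    block_index: int
    frame_span: tuple[int, int]


@dataclass(frozen=True)
class FeatureConfig:
    fps: float = 30.0
    orientations: int = 8
    cell_size: int = 32
    n_components: int = 50
    gamma: float = 0.5

    @property
    def frames_per_block(self) -> int:
        return int(round(self.fps))


@dataclass
class DetectionMetrics:
    precision: float
    recall: float
    n_events_true: int
    n_events_pred: int
    level: str
    precision_defined: bool = True
    recall_defined: bool = True


# ---------------------------------------------------------------------------
# preprocessing and features


def preprocess_frames(
    frames: np.ndarray, crop: CropRectangle | None = None, gamma: float = 0.5
) -> np.ndarray:
    """Normalize to [0, 1], apply power-law compression I**gamma, crop."""
    frames = np.asarray(frames)
    if frames.ndim == 2:
        frames = frames[None]
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    if crop is not None:
        crop.validate_against(frames.shape[-2], frames.shape[-1])
        frames = crop.apply(frames)  # crop commutes with per-pixel ops
    out = frames.astype(np.float32)  # also makes the crop view contiguous
    if np.issubdtype(frames.dtype, np.integer):
        out /= np.iinfo(frames.dtype).max
    else:
        np.clip(out, 0.0, 1.0, out=out)
    if gamma == 0.5:
        np.sqrt(out, out=out)
    elif gamma != 1.0:
        np.power(out, np.float32(gamma), out=out)
    return out


def compute_hog_features(
    frames: np.ndarray, orientations: int = 8, cell_size: int = 32
) -> np.ndarray:
    """Per-frame HOG descriptors, (T, n_features).

    One cell per block, so each 32-px cell contributes its own
    ``orientations``-bin histogram with no cross-cell normalization.
    """
    frames = np.asarray(frames, dtype=np.float64)
    if frames.ndim == 2:
        frames = frames[None]
    h, w = frames.shape[-2:]
    if h < cell_size or w < cell_size:
        raise ValueError(f"frame {h}x{w} smaller than one {cell_size}-px cell")
    return np.stack(
        [
            _skimage_hog(
                f,
                orientations=orientations,
                pixels_per_cell=(cell_size, cell_size),
                cells_per_block=(1, 1),
                feature_vector=True,
            )
            for f in frames
        ]
    )


def extract_block_features(
    frames: np.ndarray,
    config: FeatureConfig = FeatureConfig(),
    pca: PCA | None = None,
) -> tuple[list[FeatureBlock], PCA]:
    """HOG -> PCA -> 1-s concatenated block vectors.

    If ``pca`` is None a new basis is fit on these frames (training mode);
    otherwise the provided basis is applied unchanged (inference mode).
    The trailing partial block is discarded.
    """
    feats = compute_hog_features(frames, config.orientations, config.cell_size)
    if pca is None:
        n_comp = min(config.n_components, feats.shape[1], feats.shape[0])
        pca = PCA(n_components=n_comp, random_state=0)
        reduced = pca.fit_transform(feats)
    else:
        reduced = pca.transform(feats)
    fpb = config.frames_per_block
    n_blocks = len(reduced) // fpb
    if n_blocks == 0:
        warnings.warn("fewer frames than one block; no features extracted", stacklevel=2)
        return [], pca
    blocks = [
        FeatureBlock(
            vector=reduced[i * fpb : (i + 1) * fpb].ravel(),
            block_index=i,
            frame_span=(i * fpb, (i + 1) * fpb),
        )
        for i in range(n_blocks)
    ]
    return blocks, pca


def block_labels_from_frames(
    track: FrameLabelTrack, frames_per_block: int | None = None, fidget_majority: float = 0.25
) -> list[str]:
    """Reduce per-frame annotations to per-block training labels.

    A block is labeled fidget when more than ``fidget_majority`` of its
    frames are fidget-annotated; otherwise it takes the modal non-fidget
    label.  The trailing partial block is dropped, mirroring feature
    extraction.

    The default threshold of 0.25 (rather than a strict majority) keeps
    sub-second fidgets trainable: a 0.5-s event split across two 1-s
    blocks can contribute at most half a block, so a majority rule would
    silently discard every short event.
    """
    fpb = frames_per_block or int(round(track.fps))
    labels = []
    for i in range(len(track) // fpb):
        chunk = track.labels[i * fpb : (i + 1) * fpb]
        if np.mean(chunk == "fidget") > fidget_majority:
            labels.append("fidget")
        else:
            rest = chunk[chunk != "fidget"]
            vals, counts = np.unique(rest if rest.size else chunk, return_counts=True)
            labels.append(str(vals[np.argmax(counts)]))
    return labels


# ---------------------------------------------------------------------------
# detector


@dataclass
class DetectorModel:
    pca: PCA
    svm: SVC
    classes: tuple[str, ...]
    feature_config: FeatureConfig
    cv_results: pd.DataFrame | None = field(default=None, repr=False)

    def save(self, path) -> None:
        """Single-archive serialization (feature config embedded)."""
        with zipfile.ZipFile(path, "w") as zf:
            buf = _io.BytesIO()
            joblib.dump({"pca": self.pca, "svm": self.svm}, buf)
            zf.writestr("model.joblib", buf.getvalue())
            zf.writestr(
                "meta.json",
                pd.Series(
                    {"classes": list(self.classes), **asdict(self.feature_config)}
                ).to_json(),
            )
            if self.cv_results is not None:
                zf.writestr("cv_results.csv", self.cv_results.to_csv(index=False))

    @classmethod
    def load(cls, path) -> "DetectorModel":
        with zipfile.ZipFile(path) as zf:
            payload = joblib.load(_io.BytesIO(zf.read("model.joblib")))
            meta = pd.read_json(_io.BytesIO(zf.read("meta.json")), typ="series")
            cv = None
            if "cv_results.csv" in zf.namelist():
                cv = pd.read_csv(_io.BytesIO(zf.read("cv_results.csv")))
        fc = FeatureConfig(
            fps=float(meta["fps"]),
            orientations=int(meta["orientations"]),
            cell_size=int(meta["cell_size"]),
            n_components=int(meta["n_components"]),
            gamma=float(meta["gamma"]),
        )
        return cls(payload["pca"], payload["svm"], tuple(meta["classes"]), fc, cv)


DEFAULT_C_GRID = (1.0, 10.0, 100.0)
DEFAULT_GAMMA_GRID = ("scale", 0.01, 0.001)


def train_detector(
    blocks: list[FeatureBlock],
    block_labels,
    pca: PCA,
    feature_config: FeatureConfig = FeatureConfig(),
    C_grid=DEFAULT_C_GRID,
    gamma_grid=DEFAULT_GAMMA_GRID,
    cv_folds: int = 5,
    seed: int = 0,
) -> DetectorModel:
    """Grid-searched RBF SVM over (C, gamma) with stratified cross-validation."""
    y = np.asarray(list(block_labels))
    X = np.stack([b.vector for b in blocks])
    if len(X) != len(y):
        raise ValueError("blocks and labels length mismatch")
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    if len(C_grid) == 0 or len(gamma_grid) == 0:
        raise ValueError("empty hyperparameter grid")
    cv_folds = min(cv_folds, int(np.min(np.unique(y, return_counts=True)[1])))
    if cv_folds < 2:
        raise ValueError("too few samples in the rarest class for cross-validation")
    search = GridSearchCV(
        SVC(kernel="rbf", class_weight="balanced"),
        {"C": list(C_grid), "gamma": list(gamma_grid)},
        cv=StratifiedKFold(cv_folds, shuffle=True, random_state=seed),
        n_jobs=1,
    )
    search.fit(X, y)
    table = pd.DataFrame(search.cv_results_)[
        ["param_C", "param_gamma", "mean_test_score", "rank_test_score"]
    ]
    return DetectorModel(
        pca=pca,
        svm=search.best_estimator_,
        classes=tuple(sorted(np.unique(y))),
        feature_config=feature_config,
        cv_results=table,
    )


def predict_labels(
    model: DetectorModel, blocks: list[FeatureBlock], n_frames: int | None = None
) -> FrameLabelTrack:
    """Classify blocks and broadcast each block label to its frames.

    Frames beyond the last full block default to resting.
    """
    fpb = model.feature_config.frames_per_block
    if n_frames is None:
        n_frames = (max(b.frame_span[1] for b in blocks)) if blocks else 0
    labels = np.full(n_frames, "resting", dtype="<U16")
    if blocks:
        X = np.stack([b.vector for b in blocks])
        if X.shape[1] != model.svm.n_features_in_:
            raise ValueError(
                f"feature length {X.shape[1]} does not match model "
                f"({model.svm.n_features_in_}); blocks must be built with the "
                "model's feature config and PCA basis"
            )
        pred = model.svm.predict(X)
        for b, p in zip(blocks, pred):
            lo, hi = b.frame_span
            labels[lo:min(hi, n_frames)] = p
    return FrameLabelTrack(labels=labels, fps=model.feature_config.fps)


# ---------------------------------------------------------------------------
# events and scoring


def extract_events(
    track: FrameLabelTrack, min_duration_frames: int = 10, merge_gap_frames: int = 5
) -> list[FidgetEvent]:
    """Maximal runs of fidget frames; nearby runs merged, short runs dropped."""
    mask = track.labels == "fidget"
    if not mask.any():
        return []
    padded = np.concatenate([[False], mask, [False]]).astype(np.int8)
    d = np.diff(padded)
    onsets = np.flatnonzero(d == 1)
    offsets = np.flatnonzero(d == -1)
    runs: list[list[int]] = []
    for on, off in zip(onsets, offsets):
        if runs and on - runs[-1][1] <= merge_gap_frames:
            runs[-1][1] = off
        else:
            runs.append([int(on), int(off)])
    return [
        FidgetEvent(on, off)
        for on, off in runs
        if off - on >= min_duration_frames
    ]


def score_detection(
    pred_events: list[FidgetEvent],
    true_events: list[FidgetEvent],
    level: str = "event",
    n_frames: int | None = None,
) -> DetectionMetrics:
    """Precision/recall of predicted fidget events against annotations.

    Event level uses any-overlap matching: a true event is recalled if any
    prediction overlaps it, and a prediction is a true positive if it
    overlaps any true event.  Frame level counts per-frame confusions and
    requires ``n_frames``.
    """
    if level == "event":
        n_pred, n_true = len(pred_events), len(true_events)
        tp_pred = sum(any(p.overlaps(t) for t in true_events) for p in pred_events)
        recalled = sum(any(t.overlaps(p) for p in pred_events) for t in true_events)
        precision = tp_pred / n_pred if n_pred else 0.0
        recall = recalled / n_true if n_true else 0.0
        return DetectionMetrics(
            precision=precision,
            recall=recall,
            n_events_true=n_true,
            n_events_pred=n_pred,
            level="event",
            precision_defined=n_pred > 0,
            recall_defined=n_true > 0,
        )
    if level == "frame":
        if n_frames is None:
            raise ValueError("frame-level scoring requires n_frames")
        pm = np.zeros(n_frames, dtype=bool)
        tm = np.zeros(n_frames, dtype=bool)
        for e in pred_events:
            pm[e.onset_frame : e.offset_frame] = True
        for e in true_events:
            tm[e.onset_frame : e.offset_frame] = True
        tp = int((pm & tm).sum())
        precision = tp / pm.sum() if pm.any() else 0.0
        recall = tp / tm.sum() if tm.any() else 0.0
        return DetectionMetrics(
            precision=precision,
            recall=recall,
            n_events_true=len(true_events),
            n_events_pred=len(pred_events),
            level="frame",
            precision_defined=bool(pm.any()),
            recall_defined=bool(tm.any()),
        )
    raise ValueError(f"unknown level {level!r}")


def session_hog_features(
    frames: np.ndarray,
    crop: CropRectangle | None = None,
    feature_config: FeatureConfig = FeatureConfig(),
) -> np.ndarray:
    """Preprocess one session's video and compute per-frame HOG features.

    Computing features session-by-session lets callers free each video
    before generating the next one.
    """
    return compute_hog_features(
        preprocess_frames(frames, crop=crop, gamma=feature_config.gamma),
        feature_config.orientations,
        feature_config.cell_size,
    )


def fit_detector_on_features(
    session_features: list[np.ndarray],
    session_tracks: list[FrameLabelTrack],
    feature_config: FeatureConfig = FeatureConfig(),
    fidget_majority: float = 0.25,
    seed: int = 0,
    **train_kwargs,
) -> DetectorModel:
    """Train from per-session HOG feature matrices: one shared PCA basis
    fit on all training frames, blocks tiled per session so no block
    straddles a session boundary."""
    feats = session_features
    allf = np.concatenate(feats)
    n_comp = min(feature_config.n_components, allf.shape[1], allf.shape[0])
    pca = PCA(n_components=n_comp, random_state=0).fit(allf)
    fpb = feature_config.frames_per_block
    blocks: list[FeatureBlock] = []
    labels: list[str] = []
    for f, tr in zip(feats, session_tracks):
        red = pca.transform(f)
        n_blocks = len(red) // fpb
        blocks += [
            FeatureBlock(red[i * fpb : (i + 1) * fpb].ravel(), i, (i * fpb, (i + 1) * fpb))
            for i in range(n_blocks)
        ]
        labels += block_labels_from_frames(tr, fpb, fidget_majority)
    return train_detector(
        blocks, labels, pca, feature_config, seed=seed, **train_kwargs
    )


def fit_detector_on_sessions(
    session_videos: list[np.ndarray],
    session_tracks: list[FrameLabelTrack],
    crop: CropRectangle | None = None,
    feature_config: FeatureConfig = FeatureConfig(),
    fidget_majority: float = 0.25,
    seed: int = 0,
    **train_kwargs,
) -> DetectorModel:
    """Train a detector from raw session videos (convenience wrapper)."""
    feats = [session_hog_features(v, crop, feature_config) for v in session_videos]
    return fit_detector_on_features(
        feats, session_tracks, feature_config, fidget_majority, seed, **train_kwargs
    )


def detect_session(
    model: DetectorModel,
    frames: np.ndarray,
    crop: CropRectangle | None = None,
    min_duration_frames: int = 10,
    merge_gap_frames: int = 5,
) -> tuple[FrameLabelTrack, list[FidgetEvent]]:
    """Run a trained detector on one session's raw video."""
    pre = preprocess_frames(frames, crop=crop, gamma=model.feature_config.gamma)
    blocks, _ = extract_block_features(pre, model.feature_config, pca=model.pca)
    track = predict_labels(model, blocks, n_frames=len(frames))
    return track, extract_events(track, min_duration_frames, merge_gap_frames)


def normalized_fidget_rate(
    events: list[FidgetEvent], stim_table: pd.DataFrame, fps: float = 30.0
) -> pd.DataFrame:
    """Per-stimulus-type fidget initiation rate, baseline-normalized.

    The rate in each stimulus epoch is the number of events whose onset
    falls inside the epoch divided by the epoch duration.  The session's
    gray-screen rate is subtracted and the result divided by the SD of the
    per-epoch rates, so positive values mean more fidgeting than during
    the interstimulus gray baseline.
    """
    if "stimulus_type" not in stim_table or not (stim_table["stimulus_type"] == "gray").any():
        raise ValueError("stimulus table must contain gray epochs for the baseline")
    onsets = np.array([e.onset_frame for e in events])
    rows = []
    for _, r in stim_table.iterrows():
        dur_min = (r.end_frame - r.start_frame) / fps / 60.0
        if dur_min <= 0:
            continue
        n = int(np.sum((onsets >= r.start_frame) & (onsets < r.end_frame)))
        rows.append({"stimulus_type": r.stimulus_type, "rate_per_min": n / dur_min})
    per_epoch = pd.DataFrame(rows)
    sd = float(per_epoch["rate_per_min"].std(ddof=0))
    gray_rate = float(
        per_epoch.loc[per_epoch.stimulus_type == "gray", "rate_per_min"].mean()
    )
    out = (
        per_epoch.groupby("stimulus_type")["rate_per_min"]
        .mean()
        .reset_index()
        .rename(columns={"rate_per_min": "rate_per_min"})
    )
    if sd == 0:
        out["normalized_rate"] = np.nan
        out.attrs["undefined"] = True
    else:
        out["normalized_rate"] = (out["rate_per_min"] - gray_rate) / sd
        out.attrs["undefined"] = False
    return out
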