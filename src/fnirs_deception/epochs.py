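"""Post-stimulus epoching and event-related averaging.

Each interview question is reduced to its per-voxel mean hemodynamic change
over the 5 s immediately following the stimulus (the end of the question) —
the hemodynamic response peaks within ~1.6 s, so a 5-s window brackets it:

    mean_dB[v, q] = (1/n) * sum_k dB[v, q](k)        (window-local k = 1..n)

and analogously for oxygenation.  Question means are then grouped by response
class m and averaged:

    mean_dB[v, m] = (1/Q_m) * sum_{q in m} mean_dB[v, q]

Windows are half-open ``[t_event, t_event + dt)`` on the sample grid
``t_k = k / fs`` so a boundary sample is never double-counted by consecutive
questions.  An optional window offset (to start at the expected response peak
rather than the stimulus) is exposed but defaults to 0.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fnirs_io import CLASS_LABELS, StimulusEvent
from .preprocess import HemoSeries

__all__ = [
    "QuestionFeatures",
    "ClassMeans",
    "window_indices",
    "extract_window",
    "question_mean",
    "compute_question_features",
    "class_means",
    "class_activity_level",
    "features_to_frame",
    "features_from_frame",
]

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_S = 5.0


@dataclass
class QuestionFeatures:
    """Per-question, per-voxel window means for one subject.

    ``mean_dB`` and ``mean_dO`` have shape ``[Q, V]`` (umol/L).
    ``n_samples_used[q]`` is the number of samples in question q's window;
    at non-integer sampling rates it can differ by one sample between
    questions because the window endpoints fall on a fractional grid.
    """

    subject_id: str
    question_ids: np.ndarray
    class_labels: np.ndarray
    mean_dB: np.ndarray
    mean_dO: np.ndarray
    window_len_s: float
    n_samples_used: np.ndarray
    window_offset_s: float = 0.0

    @property
    def n_questions(self) -> int:
        return self.mean_dB.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.mean_dB.shape[1]


@dataclass
class ClassMeans:
    """Per-class, per-voxel means; absent classes are absent, never zero.

    ``mean_dB[m]`` / ``mean_dO[m]`` are length-V vectors keyed by class label;
    ``counts[m]`` is Q_m.
    """

    subject_id: str
    mean_dB: dict[int, np.ndarray]
    mean_dO: dict[int, np.ndarray]
    counts: dict[int, int]

    @property
    def classes(self) -> list[int]:
        return sorted(self.mean_dB)


# ---------------------------------------------------------------------------
# windows
# ---------------------------------------------------------------------------

def window_indices(
    fs: float, n_samples: int, t_event: float, dt_s: float
) -> np.ndarray:
    """All sample indices k with ``t_event <= k/fs < t_event + dt_s``.

    Evaluates the defining predicate directly on a bracketed candidate range,
    so it agrees with an exhaustive scan of the whole sample grid even when
    ``t_event * fs`` lands on an awkward float.
    """
    if fs <= 0 or dt_s <= 0:
        raise ValueError(f"fs and dt_s must be positive, got fs={fs}, dt_s={dt_s}")
    if t_event + dt_s > n_samples / fs:
        raise ValueError(
            f"window [{t_event}, {t_event + dt_s}) extends past recording "
            f"end {n_samples / fs:.6g}"
        )
    lo = max(0, math.floor(t_event * fs) - 2)
    hi = min(n_samples - 1, math.ceil((t_event + dt_s) * fs) + 2)
    k = np.arange(lo, hi + 1)
    t_k = k / fs
    k = k[(t_k >= t_event) & (t_k < t_event + dt_s)]
    if k.size == 0:
        raise ValueError(
            f"empty window: no sample grid point in [{t_event}, {t_event + dt_s})"
        )
    return k


def extract_window(
    series: HemoSeries,
    event: StimulusEvent,
    dt_s: float = DEFAULT_WINDOW_S,
    offset_s: float = 0.0,
) -> np.ndarray:
    """Sample index range of the post-stimulus window for one event."""
    return window_indices(
        series.fs, series.n_samples, event.time_s + offset_s, dt_s
    )


def question_mean(
    series: HemoSeries,
    event: StimulusEvent,
    dt_s: float = DEFAULT_WINDOW_S,
    offset_s: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel arithmetic mean of (dB, dO) over the event's window."""
    idx = extract_window(series, event, dt_s, offset_s)
    return series.dB[idx].mean(axis=0), series.dO[idx].mean(axis=0)


def compute_question_features(
    series: HemoSeries,
    dt_s: float = DEFAULT_WINDOW_S,
    offset_s: float = 0.0,
) -> QuestionFeatures:
    """Window means for every event of a recording."""
    if not series.events:
        raise ValueError("recording has no events to epoch")
    times = [e.time_s for e in series.events]
    gaps = np.diff(times)
    if (gaps < dt_s).any():
        logger.warning(
            "subject %s: %d inter-question gaps shorter than the %g-s window; "
            "windows overlap",
            series.subject_id,
            int((gaps < dt_s).sum()),
            dt_s,
        )
    mB, mO, used = [], [], []
    for ev in series.events:
        idx = extract_window(series, ev, dt_s, offset_s)
        mB.append(series.dB[idx].mean(axis=0))
        mO.append(series.dO[idx].mean(axis=0))
        used.append(idx.size)
    return QuestionFeatures(
        subject_id=series.subject_id,
        question_ids=np.array([e.question_id for e in series.events]),
        class_labels=np.array([e.class_label for e in series.events]),
        mean_dB=np.vstack(mB),
        mean_dO=np.vstack(mO),
        window_len_s=dt_s,
        n_samples_used=np.array(used),
        window_offset_s=offset_s,
    )


# ---------------------------------------------------------------------------
# class-level aggregation
# ---------------------------------------------------------------------------

def class_means(features: QuestionFeatures) -> ClassMeans:
    """Per-class, per-voxel arithmetic means of the question means."""
    mB: dict[int, np.ndarray] = {}
    mO: dict[int, np.ndarray] = {}
    counts: dict[int, int] = {}
    for m in CLASS_LABELS:
        sel = features.class_labels == m
        if not sel.any():
            continue  # absent class stays absent
        mB[m] = features.mean_dB[sel].mean(axis=0)
        mO[m] = features.mean_dO[sel].mean(axis=0)
        counts[m] = int(sel.sum())
    return ClassMeans(
        subject_id=features.subject_id, mean_dB=mB, mean_dO=mO, counts=counts
    )


def class_activity_level(
    features: QuestionFeatures, relevant_flags: np.ndarray
) -> dict[int, float]:
    """Relative activity level per class: mean blood-volume change over the
    relevant voxels and the questions of that class (one scalar per class)."""
    flags = np.asarray(relevant_flags, dtype=bool)
    if flags.shape != (features.n_voxels,) or not flags.any():
        raise ValueError("relevant-voxel mask must be a non-empty length-V vector")
    out: dict[int, float] = {}
    for m in CLASS_LABELS:
        sel = features.class_labels == m
        if sel.any():
            out[m] = float(features.mean_dB[np.ix_(sel, flags)].mean())
    return out


# ---------------------------------------------------------------------------
# tidy serialization (subject, question, class, voxel, mean_dB, mean_dO)
# ---------------------------------------------------------------------------

def features_to_frame(features: QuestionFeatures) -> pd.DataFrame:
    Q, V = features.mean_dB.shape
    return pd.DataFrame(
        {
            "subject": np.repeat(features.subject_id, Q * V),
            "question": np.repeat(features.question_ids, V),
            "class": np.repeat(features.class_labels, V),
            "voxel": np.tile(np.arange(1, V + 1), Q),
            "mean_dB": features.mean_dB.ravel(),
            "mean_dO": features.mean_dO.ravel(),
            "n_samples": np.repeat(features.n_samples_used, V),
            "window_len_s": features.window_len_s,
        }
    )


def features_from_frame(frame: pd.DataFrame) -> dict[str, QuestionFeatures]:
    """Inverse of :func:`features_to_frame`; one entry per subject."""
    out: dict[str, QuestionFeatures] = {}
    for sid, sub in frame.groupby("subject", sort=True):
        piv_b = sub.pivot(index="question", columns="voxel", values="mean_dB")
        piv_o = sub.pivot(index="question", columns="voxel", values="mean_dO")
        qmeta = sub.drop_duplicates("question").set_index("question").sort_index()
        out[str(sid)] = QuestionFeatures(
            subject_id=str(sid),
            question_ids=piv_b.index.to_numpy(dtype=int),
            class_labels=qmeta["class"].to_numpy(dtype=int),
            mean_dB=piv_b.to_numpy(dtype=float),
            mean_dO=piv_o.to_numpy(dtype=float),
            window_len_s=float(qmeta["window_len_s"].iloc[0]),
            n_samples_used=qmeta["n_samples"].to_numpy(dtype=int),
        )
    return out
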