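"""Relevant-voxel selection and cross-subject aggregation.

Three per-subject criteria flag candidate voxels from the question-level
blood-volume means (1 = candidate, 0 = not):

* **heuristic** — the absolute difference of two class means exceeds a fixed
  threshold (default 1 umol/L).  Total fallback: if no voxel qualifies, take
  the two voxels with the greatest difference; if exactly one qualifies, take
  it plus the voxel with the second-greatest difference.  So the mask always
  has >= 2 voxels.
* **nonparametric** — the closed interquartile ranges of the two classes'
  question-mean samples are disjoint (boxplot IQRs do not overlap).
* **parametric** — a two-sample two-tailed t-test rejects at alpha = 0.1 for
  at least one of the contrasts (induced lie vs induced truth, non-induced
  lie vs non-induced truth, induced vs non-induced).  No multiple-testing
  correction is applied.

Per-subject masks are then aggregated into the smallest voxel set containing
at least one relevant voxel for every subject, by greedy set cover (most
not-yet-covered subjects first, ties to the lowest voxel index) followed by a
redundancy-elimination pass.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .epochs import ClassMeans, QuestionFeatures

__all__ = [
    "VoxelMask",
    "AggregateResult",
    "heuristic_select",
    "nonparametric_select",
    "parametric_select",
    "class_samples",
    "select_voxels",
    "aggregate_masks",
    "masks_to_frame",
    "DEFAULT_CONTRASTS",
]

logger = logging.getLogger(__name__)

CRITERIA = ("heuristic", "nonparametric", "parametric", "combined", "all")

#: t-test contrasts: IL vs IT, NL vs NT, induced vs non-induced.
DEFAULT_CONTRASTS: tuple[tuple[tuple[int, ...], tuple[int, ...]], ...] = (
    ((1,), (2,)),
    ((3,), (4,)),
    ((1, 2), (3, 4)),
)


@dataclass
class VoxelMask:
    """Boolean relevance flags for one subject under one criterion."""

    subject_id: str
    criterion: str
    flags: np.ndarray
    contrast: str | None = None
    measure: str = "dB"

    def __post_init__(self) -> None:
        self.flags = np.asarray(self.flags, dtype=bool)
        if self.criterion not in CRITERIA:
            raise ValueError(f"unknown criterion {self.criterion!r}")

    @property
    def n_voxels(self) -> int:
        return self.flags.size

    @property
    def voxels(self) -> np.ndarray:
        """1-based indices of flagged voxels."""
        return np.flatnonzero(self.flags) + 1


def _contrast_name(a: tuple[int, ...], b: tuple[int, ...]) -> str:
    return f"m{''.join(map(str, a))}-vs-m{''.join(map(str, b))}"


# ---------------------------------------------------------------------------
# criteria
# ---------------------------------------------------------------------------

def heuristic_select(
    cm: ClassMeans,
    pair: tuple[int, int] = (1, 2),
    threshold: float = 1.0,
    measure: str = "dB",
) -> VoxelMask:
    """Threshold on |class-mean difference|, with the two fallback rules."""
    if threshold <= 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    a, b = pair
    means = cm.mean_dB if measure == "dB" else cm.mean_dO
    if a not in means or b not in means:
        raise ValueError(f"classes {pair} not both present (have {cm.classes})")
    diffs = np.abs(means[a] - means[b])
    if diffs.size < 2:
        raise ValueError("need at least 2 voxels for heuristic selection")
    flags = diffs >= threshold
    order = np.argsort(-diffs, kind="stable")  # desc, ties to lowest index
    if flags.sum() == 0:
        flags = np.zeros_like(flags)
        flags[order[:2]] = True
    elif flags.sum() == 1:
        runner = next(i for i in order if not flags[i])
        flags = flags.copy()
        flags[runner] = True
    return VoxelMask(
        subject_id=cm.subject_id,
        criterion="heuristic",
        flags=flags,
        contrast=_contrast_name((a,), (b,)),
        measure=measure,
    )


def quartiles(x: np.ndarray, method: str = "linear") -> tuple[np.ndarray, np.ndarray]:
    """(Q1, Q3) along axis 0, linear interpolation between order statistics."""
    q1, q3 = np.percentile(np.asarray(x, dtype=float), [25, 75], axis=0,
                           method=method)
    return q1, q3


def nonparametric_select(
    samples_a: np.ndarray,
    samples_b: np.ndarray,
    subject_id: str = "",
    contrast: str | None = None,
    measure: str = "dB",
    quartile_method: str = "linear",
) -> VoxelMask:
    """Select voxels whose closed IQR intervals for the two classes are disjoint.

    ``samples_a``/``samples_b`` hold the question-level means, shape
    ``[Q_m, V]``.
    """
    sa = np.atleast_2d(np.asarray(samples_a, dtype=float))
    sb = np.atleast_2d(np.asarray(samples_b, dtype=float))
    if sa.shape[0] < 4 or sb.shape[0] < 4:
        raise ValueError(
            f"need >= 4 observations per class to form quartiles, got "
            f"{sa.shape[0]} and {sb.shape[0]}"
        )
    q1a, q3a = quartiles(sa, quartile_method)
    q1b, q3b = quartiles(sb, quartile_method)
    flags = (q3a < q1b) | (q3b < q1a)
    return VoxelMask(
        subject_id=subject_id,
        criterion="nonparametric",
        flags=flags,
        contrast=contrast,
        measure=measure,
    )


def _ttest_pvalues(ga: np.ndarray, gb: np.ndarray, equal_var: bool) -> np.ndarray:
    """Two-sample two-tailed p-values per voxel, with the zero-variance rule:
    if both groups are constant, p = 1 when the means agree, else 0."""
    import warnings as _warnings

    with np.errstate(divide="ignore", invalid="ignore"), _warnings.catch_warnings():
        # constant groups trigger a precision warning; handled explicitly below
        _warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(ga, gb, axis=0, equal_var=equal_var)
    p = np.atleast_1d(np.asarray(res.pvalue, dtype=float))
    degenerate = ~np.isfinite(p)
    if degenerate.any():
        logger.warning(
            "%d voxel(s) with zero variance in both groups; p set to 0/1 by "
            "mean equality",
            int(degenerate.sum()),
        )
        same = np.isclose(ga.mean(axis=0), gb.mean(axis=0))
        p[degenerate] = np.where(same[degenerate], 1.0, 0.0)
    return p


def class_samples(features: QuestionFeatures, measure: str = "dB") -> dict[int, np.ndarray]:
    """S_v^m: the question-level means of each present class, shape [Q_m, V]."""
    vals = features.mean_dB if measure == "dB" else features.mean_dO
    return {
        int(m): vals[features.class_labels == m]
        for m in np.unique(features.class_labels)
    }


def parametric_select(
    samples: dict[int, np.ndarray],
    contrasts: tuple[tuple[tuple[int, ...], tuple[int, ...]], ...] = DEFAULT_CONTRASTS,
    alpha: float = 0.1,
    equal_var: bool = True,
    subject_id: str = "",
    measure: str = "dB",
) -> tuple[VoxelMask, dict[str, VoxelMask]]:
    """t-test selection over the configured contrasts.

    Returns the union mask plus one mask per contrast.  ``equal_var=True``
    gives the classic pooled-variance Student test; ``False`` gives Welch.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    per_contrast: dict[str, VoxelMask] = {}
    union: np.ndarray | None = None
    for grp_a, grp_b in contrasts:
        missing = [m for m in (*grp_a, *grp_b) if m not in samples]
        if missing:
            raise ValueError(f"classes {missing} absent; cannot test contrast")
        ga = np.vstack([samples[m] for m in grp_a])
        gb = np.vstack([samples[m] for m in grp_b])
        if ga.shape[0] < 2 or gb.shape[0] < 2:
            raise ValueError("each t-test group needs >= 2 observations")
        p = _ttest_pvalues(ga, gb, equal_var)
        flags = p < alpha
        name = _contrast_name(grp_a, grp_b)
        per_contrast[name] = VoxelMask(
            subject_id=subject_id,
            criterion="parametric",
            flags=flags,
            contrast=name,
            measure=measure,
        )
        union = flags if union is None else (union | flags)
    assert union is not None
    return (
        VoxelMask(
            subject_id=subject_id, criterion="parametric", flags=union,
            measure=measure,
        ),
        per_contrast,
    )


# ---------------------------------------------------------------------------
# per-subject driver + aggregation
# ---------------------------------------------------------------------------

def select_voxels(
    features: QuestionFeatures,
    cm: ClassMeans | None = None,
    threshold: float = 1.0,
    alpha: float = 0.1,
    measure: str = "dB",
) -> dict[str, VoxelMask]:
    """All three criteria (plus their union, 'combined') for one subject.

    Heuristic and nonparametric criteria are applied to both within-condition
    contrasts (IL vs IT and NL vs NT) and unioned; the parametric criterion
    additionally tests induced vs non-induced.
    """
    from .epochs import class_means as _cmeans

    cm = cm or _cmeans(features)
    samples = class_samples(features, measure)

    heur = None
    for pair in ((1, 2), (3, 4)):
        msk = heuristic_select(cm, pair, threshold, measure)
        heur = msk.flags if heur is None else (heur | msk.flags)
    nonp = None
    for a, b in ((1, 2), (3, 4)):
        msk = nonparametric_select(
            samples[a], samples[b], features.subject_id,
            _contrast_name((a,), (b,)), measure,
        )
        nonp = msk.flags if nonp is None else (nonp | msk.flags)
    par, _ = parametric_select(
        samples, alpha=alpha, subject_id=features.subject_id, measure=measure
    )

    sid = features.subject_id
    out = {
        "heuristic": VoxelMask(sid, "heuristic", heur, measure=measure),
        "nonparametric": VoxelMask(sid, "nonparametric", nonp, measure=measure),
        "parametric": VoxelMask(sid, "parametric", par.flags, measure=measure),
    }
    out["combined"] = VoxelMask(
        sid, "combined",
        out["heuristic"].flags | out["nonparametric"].flags | out["parametric"].flags,
        measure=measure,
    )
    out["all"] = VoxelMask(
        sid, "all", np.ones(features.n_voxels, dtype=bool), measure=measure
    )
    return out


@dataclass
class AggregateResult:
    """Cross-subject cover: selected voxels + per-voxel subject frequencies."""

    flags: np.ndarray
    frequency: np.ndarray
    subjects_covered: list[str]
    subjects_excluded: list[str]

    @property
    def voxels(self) -> np.ndarray:
        return np.flatnonzero(self.flags) + 1


def _greedy_cover(flag_mat: np.ndarray) -> list[int]:
    """Greedy cover (most uncovered subjects first, ties to lowest voxel
    index) followed by redundancy elimination."""
    selected: list[int] = []
    uncovered = np.ones(flag_mat.shape[0], dtype=bool)
    while uncovered.any():
        gain = flag_mat[uncovered].sum(axis=0)
        v = int(np.argmax(gain))  # argmax ties -> lowest index
        if gain[v] == 0:  # unreachable: all-zero subjects were excluded
            break
        selected.append(v)
        uncovered &= ~flag_mat[:, v]
    for v in list(reversed(selected)):
        rest = [u for u in selected if u != v]
        if rest and flag_mat[:, rest].any(axis=1).all():
            selected = rest
    return selected


def _exact_cover(flag_mat: np.ndarray, frequency: np.ndarray) -> list[int]:
    """Minimum-cardinality cover by ascending-size exhaustive search.

    Among minimum covers, prefer the highest total subject frequency (the
    most-frequently-flagged voxels), then the lexicographically smallest
    index set.  Only voxels flagged by someone are candidates.
    """
    cand = np.flatnonzero(flag_mat.any(axis=0))
    for k in range(1, cand.size + 1):
        best: tuple[float, tuple[int, ...]] | None = None
        for comb in itertools.combinations(cand.tolist(), k):
            if flag_mat[:, comb].any(axis=1).all():
                key = (-float(frequency[list(comb)].sum()), comb)
                if best is None or key < best:
                    best = key
        if best is not None:
            return list(best[1])
    return []


def aggregate_masks(masks: list[VoxelMask]) -> AggregateResult:
    """Smallest voxel set with >= 1 relevant voxel per subject.

    Multiple masks per subject are unioned first.  For the usual voxel counts
    (V <= 16) the minimum-cardinality cover is found exactly by exhaustive
    ascending-size search, preferring the most frequently flagged voxels among
    ties; for larger V a greedy cover (most not-yet-covered subjects first,
    ties to the lowest voxel index) with redundancy elimination is used.
    Subjects whose union mask is all-zero cannot be covered and are excluded
    with a warning.
    """
    if not masks:
        raise ValueError("no masks to aggregate")
    V = masks[0].n_voxels
    by_subject: dict[str, np.ndarray] = {}
    for m in masks:
        if m.n_voxels != V:
            raise ValueError("masks disagree on voxel count")
        by_subject[m.subject_id] = by_subject.get(
            m.subject_id, np.zeros(V, dtype=bool)
        ) | m.flags

    excluded = sorted(s for s, f in by_subject.items() if not f.any())
    for s in excluded:
        logger.warning("subject %s has an all-zero mask; excluded from cover", s)
    subjects = sorted(s for s in by_subject if s not in excluded)
    flag_mat = np.array([by_subject[s] for s in subjects], dtype=bool)
    frequency = flag_mat.sum(axis=0) if subjects else np.zeros(V, dtype=int)

    if subjects:
        if V <= 16:
            selected = _exact_cover(flag_mat, frequency)
        else:
            selected = _greedy_cover(flag_mat)
    else:
        selected = []

    flags = np.zeros(V, dtype=bool)
    flags[selected] = True
    return AggregateResult(
        flags=flags,
        frequency=frequency,
        subjects_covered=subjects,
        subjects_excluded=excluded,
    )


def masks_to_frame(masks: list[VoxelMask]) -> pd.DataFrame:
    """Tidy table (subject, criterion, contrast, measure, voxel, flag)."""
    rows = []
    for m in masks:
        for v in range(m.n_voxels):
            rows.append(
                {
                    "subject": m.subject_id,
                    "criterion": m.criterion,
                    "contrast": m.contrast or "",
                    "measure": m.measure,
                    "voxel": v + 1,
                    "flag": int(m.flags[v]),
                }
            )
    return pd.DataFrame(rows)
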