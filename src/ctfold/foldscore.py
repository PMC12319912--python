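"""The CT Folding Score and topologically-compact state classification.

Per frame the score is P/<P> + S/<S> + X/<X>, where (P, S, X) are the
frame's relation counts and <.> are their means over all snapshots of the
normalization scope. By construction the ensemble-mean score equals the
number of retained terms — 3 whenever all three relation types occur — so
"score above its own mean" is the natural compactness criterion: a frame is
*topologically compact* (T-compact) iff its score strictly exceeds the
threshold, and *solvent-exposed* otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .circuit_topology import RelationCounts

COMPACT = "compact"
EXPOSED = "exposed"

__all__ = [
    "Normalizers",
    "FoldScoreSeries",
    "StateLabels",
    "ensemble_normalizers",
    "fold_score",
    "score_series",
    "classify_states",
    "histogram_threshold",
    "COMPACT",
    "EXPOSED",
]


@dataclass(frozen=True)
class Normalizers:
    """Ensemble means of the P/S/X relation counts over a frame scope."""

    mean_P: float
    mean_S: float
    mean_X: float
    scope: str = "ensemble"

    def __post_init__(self) -> None:
        if min(self.mean_P, self.mean_S, self.mean_X) < 0:
            raise ValueError("normalizer means must be >= 0")

    @property
    def n_terms(self) -> int:
        """Number of relation types with a nonzero ensemble mean; terms with
        zero mean are dropped from the score."""
        return sum(m > 0 for m in (self.mean_P, self.mean_S, self.mean_X))


@dataclass
class FoldScoreSeries:
    """Per-frame CT Folding Scores with their normalizers and threshold."""

    times: np.ndarray
    scores: np.ndarray
    normalizers: Normalizers
    threshold: float
    n_terms: int


@dataclass
class StateLabels:
    """Per-frame compact/exposed labels, aligned with a score series."""

    labels: np.ndarray  # array of "compact"/"exposed"

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def is_compact(self) -> np.ndarray:
        return np.asarray(self.labels) == COMPACT


def ensemble_normalizers(counts, scope: str = "ensemble") -> Normalizers:
    """Arithmetic means of (P, S, X) over all frames of the scope."""
    counts = list(counts)
    if not counts:
        raise ValueError("cannot normalize over an empty frame set")
    arr = np.array([[c.P, c.S, c.X] for c in counts], dtype=float)
    means = arr.mean(axis=0)
    return Normalizers(mean_P=means[0], mean_S=means[1], mean_X=means[2], scope=scope)


def fold_score(counts: RelationCounts, norm: Normalizers) -> float:
    """Score of one frame: sum of count/mean over relation types with a
    nonzero ensemble mean."""
    if norm.n_terms == 0:
        raise ValueError(
            "degenerate ensemble: all three relation-count means are zero"
        )
    score = 0.0
    for count, mean in (
        (counts.P, norm.mean_P),
        (counts.S, norm.mean_S),
        (counts.X, norm.mean_X),
    ):
        if mean > 0:
            score += count / mean
    return score


def score_series(
    counts,
    times=None,
    norm: Normalizers | None = None,
    scope: str = "ensemble",
) -> FoldScoreSeries:
    """Score a whole trajectory of relation counts.

    Normalizers default to the means over the supplied frames (the
    trajectory is its own normalization scope); pass ``norm`` explicitly to
    score against another scope, e.g. all replicates of a variant combined.
    """
    counts = list(counts)
    if norm is None:
        norm = ensemble_normalizers(counts, scope=scope)
    scores = np.array([fold_score(c, norm) for c in counts])
    if times is None:
        times = np.arange(len(counts), dtype=float)
    times = np.asarray(times, dtype=float)
    return FoldScoreSeries(
        times=times,
        scores=scores,
        normalizers=norm,
        threshold=float(norm.n_terms),
        n_terms=norm.n_terms,
    )


def classify_states(series: FoldScoreSeries, threshold: float | None = None) -> StateLabels:
    """Label frames compact iff score > threshold (strict).

    The default threshold is the ensemble-mean score, i.e. the number of
    retained score terms (3 when all relation types occur). A frame scoring
    exactly the threshold is exposed.
    """
    thr = series.threshold if threshold is None else threshold
    labels = np.where(series.scores > thr, COMPACT, EXPOSED)
    return StateLabels(labels=labels)


def histogram_threshold(series: FoldScoreSeries, n_bins: int = 50) -> float:
    """Alternative threshold at the lowest-probability point between the two
    dominant modes of the score histogram.

    Builds an ``n_bins`` histogram of the scores, locates its two largest
    local maxima, and returns the center of the minimum-count bin strictly
    between them (the mean center of the tied lowest bins when several tie).
    The histogram only counts as bimodal if the valley drops below half the
    smaller of the two modes; otherwise — and whenever fewer than two modes
    exist — the mean-score threshold is returned with a warning.
    """
    scores = np.asarray(series.scores)
    if scores.size < 3:
        raise ValueError("histogram threshold needs at least 3 frames")
    counts, edges = np.histogram(scores, bins=n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])

    # local maxima: occupied bins strictly above the left neighbour and at
    # least as high as the right one (leftmost bin of a plateau)
    padded = np.concatenate([[-1], counts.astype(int), [-1]])
    pruned = [
        k
        for k in range(len(counts))
        if counts[k] > 0 and padded[k] < counts[k] and counts[k] >= padded[k + 2]
    ]
    pruned.sort(key=lambda k: counts[k], reverse=True)
    if len(pruned) < 2:
        warnings.warn(
            "score histogram is unimodal; falling back to the mean-score threshold",
            stacklevel=2,
        )
        return float(series.n_terms)

    lo, hi = sorted(pruned[:2])
    between = counts[lo + 1 : hi]
    if between.size == 0 or between.min() >= 0.5 * min(counts[lo], counts[hi]):
        warnings.warn(
            "score histogram has no clear valley between its modes (unimodal); "
            "falling back to the mean-score threshold",
            stacklevel=2,
        )
        return float(series.n_terms)
    ties = np.flatnonzero(between == between.min())
    return float(centers[lo + 1 + ties].mean())
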