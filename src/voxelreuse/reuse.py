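"""Top-k voxel selection and the voxel re-use index.

For each task, the voxels contributing the most signal are the top
fraction (default 10 %) of the activation pattern by magnitude.  The
re-use index between two tasks is the proportion of those voxels the
two selections share: e.g. if 40 of an ROI's 200 top orientation-coding
voxels are also among the 200 top breadth-coding voxels, re-use is
40/200 = 0.2.  Under independent selections the expected proportion is
k/N (the hypergeometric mean over k).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .haufe import ActivationPattern, CovarianceEstimate, fit_full_data_pattern
from .simulate import BetaPatternSet, round_half_away

__all__ = ["TopKSet", "ReuseIndex", "select_top_k", "reuse_index", "observed_reuse"]

DEFAULT_FRACTION = 0.10


@dataclass
class TopKSet:
    """Indices of the top-fraction voxels of an activation pattern."""

    indices: np.ndarray  # sorted voxel indices, |indices| = k
    k: int
    fraction: float
    n_voxels: int
    ranking: str = "absolute"  # "absolute" | "signed"

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        if self.indices.size != self.k or self.k < 1:
            raise ValueError("selection size must equal k >= 1")


@dataclass
class ReuseIndex:
    overlap: int
    k: int
    proportion: float
    subject: str | None = None
    roi_name: str | None = None
    relevance: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.overlap <= self.k):
            raise ValueError("overlap must lie in [0, k]")
        if self.proportion != self.overlap / self.k:
            raise ValueError("proportion must equal overlap / k exactly")


def select_top_k(
    pattern: ActivationPattern | np.ndarray,
    fraction: float = DEFAULT_FRACTION,
    ranking: str = "absolute",
) -> TopKSet:
    """Select the k = round(fraction * N) voxels with the largest
    contribution (|a| by default; ``ranking="signed"`` uses a as-is).

    k is at least 1; ties are broken by ascending voxel index (stable
    sort on descending value).
    """
    a = pattern.values if isinstance(pattern, ActivationPattern) else np.asarray(pattern, float)
    if a.ndim != 1 or a.size < 1:
        raise ValueError("pattern must be a nonempty vector")
    if not np.all(np.isfinite(a)):
        raise ValueError("pattern contains non-finite values")
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must be in (0, 1]")
    if ranking == "absolute":
        score = np.abs(a)
    elif ranking == "signed":
        score = a
    else:
        raise ValueError(f"unknown ranking {ranking!r}")
    n = a.size
    k = max(1, round_half_away(fraction * n))
    order = np.argsort(-score, kind="stable")  # ties resolve to lower index
    return TopKSet(indices=np.sort(order[:k]), k=k, fraction=fraction, n_voxels=n,
                   ranking=ranking)


def reuse_index(
    set1: TopKSet,
    set2: TopKSet,
    subject: str | None = None,
    roi_name: str | None = None,
    relevance: str | None = None,
) -> ReuseIndex:
    """Proportion of shared voxels between two equal-size top-k sets."""
    if set1.k != set2.k:
        raise ValueError(f"mismatched k: {set1.k} vs {set2.k}")
    if set1.n_voxels != set2.n_voxels:
        raise ValueError("top-k sets come from different ROI voxel spaces")
    overlap = int(np.intersect1d(set1.indices, set2.indices, assume_unique=True).size)
    return ReuseIndex(overlap=overlap, k=set1.k, proportion=overlap / set1.k,
                      subject=subject, roi_name=roi_name, relevance=relevance)


def observed_reuse(
    patterns: BetaPatternSet,
    relevance: str = "relevant",
    fraction: float = DEFAULT_FRACTION,
    C: float = 1.0,
    ranking: str = "absolute",
    cov_kind: str = "auto",
    covs: dict[int, CovarianceEstimate] | None = None,
) -> ReuseIndex:
    """Per-subject voxel re-use between the two tasks' codes.

    Pipeline: full-data SVM + covariance transform per task, top-k
    selection per task, overlap proportion.  ``covs`` may carry
    precomputed per-task covariances (label-independent), e.g. when
    looping over label permutations.
    """
    sets = {}
    for t in (1, 2):
        cov = covs.get(t) if covs else None
        ap = fit_full_data_pattern(patterns, task=t, relevance=relevance, C=C,
                                   cov_kind=cov_kind, cov=cov)
        sets[t] = select_top_k(ap, fraction=fraction, ranking=ranking)
    return reuse_index(sets[1], sets[2], subject=patterns.subject,
                       roi_name=patterns.roi_name, relevance=relevance)
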