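"""Two-step permutation inference for the voxel re-use index.

Step 1 (within subject): relabel the condition of each task's samples
by a random permutation, rerun the full re-use computation (SVM +
covariance transform + top-k overlap), and repeat B times, giving a
per-subject null distribution of re-use proportions.  Because the
pooled, column-demeaned covariance does not depend on the condition
labels, it is estimated once per subject and task and reused across
permutations.

Step 2 (group): build M group-null values, each the mean of one value
drawn uniformly with replacement from every subject's null vector, and
compare the observed group-mean re-use against that distribution with
the add-one rule p = (1 + #{null >= observed}) / (1 + M), so p is never
zero.  The within-subject step absorbs subject-specific structure (e.g.
vasculature) that could make some voxels win multiple discriminations
for uninteresting reasons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .decoding import SingleClassError, train_lsvm
from .haufe import estimate_covariance
from .reuse import DEFAULT_FRACTION, observed_reuse
from .simulate import BetaPatternSet, round_half_away

__all__ = [
    "SubjectNull",
    "GroupNull",
    "PermutationResult",
    "permute_condition_labels",
    "subject_null",
    "group_null",
    "p_value",
    "two_step_test",
]

DEFAULT_B = 100
DEFAULT_M = 10_000


@dataclass
class SubjectNull:
    subject: str
    values: np.ndarray  # B null re-use proportions in [0, 1]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size < 1:
            raise ValueError("null vector must have at least one value")
        if self.values.min() < 0 or self.values.max() > 1:
            raise ValueError("re-use proportions must lie in [0, 1]")


@dataclass
class GroupNull:
    values: np.ndarray  # M group-mean null values
    B: int
    M: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size != self.M:
            raise ValueError("group null length must equal M")


@dataclass
class PermutationResult:
    observed: float
    p: float
    null: GroupNull
    alpha: float = 0.05
    details: dict = field(default_factory=dict)

    @property
    def rejected(self) -> bool:
        return self.p < self.alpha


def permute_condition_labels(
    patterns: BetaPatternSet,
    task: int,
    rng: np.random.Generator,
    relevance: str | None = None,
    unit: str = "sample",
) -> BetaPatternSet:
    """Permute condition labels among one task's samples.

    Permutation is stratified by relevance level (each stratum's labels
    are shuffled among that stratum's samples), so per-class counts in
    every stratum are preserved — a permutation of 16 labels over the
    16 (block, condition) samples in the default design.  Restricting
    ``relevance`` permutes only that stratum.

    ``unit="sample"`` (default) permutes freely within the stratum, the
    right null for full-data fits.  ``unit="block"`` permutes condition
    labels within each block (for two conditions, a random swap per
    block): this respects block exchangeability and keeps every
    leave-one-block-out training fold class-balanced, avoiding the
    below-chance bias unrestricted permutation induces in
    cross-validated accuracy.
    """
    if unit not in ("sample", "block"):
        raise ValueError(f"unknown permutation unit {unit!r}")
    labels = patterns.labels.copy()
    cond = labels["condition"].to_numpy().copy()
    task_mask = (labels["task"] == task).to_numpy()
    strata = [relevance] if relevance else list(labels.loc[task_mask, "relevance"].unique())
    for r in strata:
        m = task_mask & (labels["relevance"] == r).to_numpy()
        if unit == "sample":
            idx = np.flatnonzero(m)
            cond[idx] = cond[idx[rng.permutation(idx.size)]]
        else:
            blocks = labels["block"].to_numpy()
            for b in np.unique(blocks[m]):
                idx = np.flatnonzero(m & (blocks == b))
                cond[idx] = cond[idx[rng.permutation(idx.size)]]
    labels["condition"] = cond
    return BetaPatternSet(
        subject=patterns.subject,
        data=patterns.data,
        labels=labels,
        voxel_coords_mm=patterns.voxel_coords_mm,
        roi_name=patterns.roi_name,
        grid_dims=patterns.grid_dims,
    )


def subject_null(
    patterns: BetaPatternSet,
    relevance: str = "relevant",
    fraction: float = DEFAULT_FRACTION,
    B: int = DEFAULT_B,
    C: float = 1.0,
    rng: np.random.Generator | int | None = None,
    cov_kind: str = "auto",
) -> SubjectNull:
    """B label-permutation null re-use values for one subject.

    Each draw relabels both tasks independently and runs the observed
    re-use computation on the relabelled data.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    # pre-extract per-task data and covariance once; each permutation only
    # needs a relabelled SVM fit plus the (cached) Sigma @ w transform.
    # equivalent to permute_condition_labels + observed_reuse per draw,
    # with the same rng consumption order (task 1 stratum, then task 2).
    X, y, sigmas = {}, {}, {}
    for t in (1, 2):
        sel = patterns.select(task=t, relevance=relevance)
        X[t], y[t] = sel.data, sel.labels["condition"].to_numpy()
        kind = cov_kind
        if kind == "auto":
            kind = "shrinkage" if sel.n_voxels >= sel.n_samples else "empirical"
        sigmas[t] = estimate_covariance(sel.data, kind=kind).sigma
    n_vox = patterns.n_voxels
    k = max(1, round_half_away(fraction * n_vox))
    vals = np.empty(B)
    member = np.zeros((2, n_vox), dtype=bool)
    for b in range(B):
        member[:] = False
        for i, t in enumerate((1, 2)):
            y_perm = y[t][rng.permutation(y[t].size)]
            try:
                model = train_lsvm(X[t], y_perm, C=C)
            except SingleClassError:  # unreachable: permutation preserves counts
                raise
            a = sigmas[t] @ model.weights
            order = np.argsort(-np.abs(a), kind="stable")
            member[i, order[:k]] = True
        vals[b] = np.count_nonzero(member[0] & member[1]) / k
    return SubjectNull(subject=patterns.subject, values=vals)


def group_null(
    subject_nulls: list[SubjectNull],
    M: int = DEFAULT_M,
    rng: np.random.Generator | int | None = None,
) -> GroupNull:
    """M group-mean null values, each averaging one resampled value per
    subject (uniform, with replacement)."""
    if not subject_nulls:
        raise ValueError("empty subject collection")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    mat = [sn.values for sn in subject_nulls]
    draws = np.stack([v[rng.integers(0, v.size, size=M)] for v in mat])  # subjects x M
    return GroupNull(values=draws.mean(axis=0), B=int(min(v.size for v in mat)), M=M)


def p_value(observed: float, null: GroupNull, alpha: float = 0.05) -> PermutationResult:
    """One-sided add-one permutation p-value against the group null."""
    M = null.values.size
    if M == 0:
        raise ValueError("empty null distribution")
    p = (1 + int(np.sum(null.values >= observed))) / (1 + M)
    return PermutationResult(observed=float(observed), p=float(p), null=null, alpha=alpha)


def two_step_test(
    dataset: list[BetaPatternSet],
    relevance: str = "relevant",
    fraction: float = DEFAULT_FRACTION,
    B: int = DEFAULT_B,
    M: int = DEFAULT_M,
    C: float = 1.0,
    alpha: float = 0.05,
    rng: np.random.Generator | int | None = None,
) -> PermutationResult:
    """Observed group-mean re-use and its two-step permutation p-value."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    observed = [
        observed_reuse(ps, relevance=relevance, fraction=fraction, C=C).proportion
        for ps in dataset
    ]
    nulls = [
        subject_null(ps, relevance=relevance, fraction=fraction, B=B, C=C, rng=rng)
        for ps in dataset
    ]
    gnull = group_null(nulls, M=M, rng=rng)
    res = p_value(float(np.mean(observed)), gnull, alpha=alpha)
    res.details = {
        "per_subject_observed": {ps.subject: o for ps, o in zip(dataset, observed)},
        "B": B,
        "M": M,
    }
    return res
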