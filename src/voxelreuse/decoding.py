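"""Linear-SVM decoding: cross-validated accuracy, cross-task
generalization, group tests against chance, and searchlight mapping.

Conventions
-----------
* The classifier is a hard/soft-margin linear SVM (libsvm via
  scikit-learn), cost C = 1 by default, no per-fold tuning: downstream
  weight-to-pattern transformation consumes the fitted weight vector, so
  the model must be fixed, not tuned.
* Cross-validation defaults to leave-one-block-out within task; the
  block is the beta-estimation unit of the design.
* Accuracy is pooled over test samples (well defined for unequal folds)
  and reported in percent; chance for binary labels is 50 %.
* Group inference vs chance is a one-sided one-sample t-test (the
  hypotheses are directional: coding above chance).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from sklearn.svm import SVC

from .io import AccuracyMap, ROIMask
from .simulate import BetaPatternSet

__all__ = [
    "FoldScheme",
    "LinearModel",
    "DecodingResult",
    "SingleClassError",
    "train_lsvm",
    "leave_one_block_out",
    "cross_validate",
    "cross_generalize",
    "group_test_vs_chance",
    "sphere_neighbors",
    "searchlight_map",
    "cluster_extent_threshold",
]

CHANCE = 50.0


class SingleClassError(ValueError):
    """Raised when a training set contains a single class."""


@dataclass
class FoldScheme:
    """Ordered train/test index partitions over the selected samples."""

    folds: list[tuple[np.ndarray, np.ndarray]]

    def __post_init__(self) -> None:
        seen: list[np.ndarray] = []
        for train, test in self.folds:
            if np.intersect1d(train, test).size:
                raise ValueError("train and test sets overlap within a fold")
            seen.append(np.asarray(test))
        allt = np.concatenate(seen) if seen else np.array([], dtype=int)
        if len(np.unique(allt)) != len(allt):
            raise ValueError("a sample appears in more than one test set")

    @property
    def n_folds(self) -> int:
        return len(self.folds)


@dataclass
class LinearModel:
    weights: np.ndarray
    bias: float

    def decision(self, X: np.ndarray) -> np.ndarray:
        return X @ self.weights + self.bias

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.decision(X) >= 0).astype(int)


@dataclass
class DecodingResult:
    """Per-subject decoding accuracies (%) for one ROI x condition cell."""

    accuracies: dict[str, float]
    task: object = None
    relevance: str | None = None
    chance: float = CHANCE
    details: dict = field(default_factory=dict)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(list(self.accuracies.values())))


def train_lsvm(X: np.ndarray, y: np.ndarray, C: float = 1.0) -> LinearModel:
    """Fit a binary linear SVM and return its weight vector and bias.

    Labels may be any two distinct values; the positive class is the
    larger label after sorting, so the sign convention is deterministic.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size < 2:
        raise SingleClassError("training labels contain a single class")
    if classes.size > 2:
        raise ValueError("only binary problems are supported")
    clf = SVC(kernel="linear", C=C)
    clf.fit(X, y)
    return LinearModel(weights=clf.coef_.ravel().copy(), bias=float(clf.intercept_[0]))


def leave_one_block_out(blocks: np.ndarray) -> FoldScheme:
    """One fold per unique block label: that block tests, the rest train."""
    blocks = np.asarray(blocks)
    folds = []
    for b in np.unique(blocks):
        test = np.flatnonzero(blocks == b)
        train = np.flatnonzero(blocks != b)
        folds.append((train, test))
    return FoldScheme(folds=folds)


def _cv_accuracy(X: np.ndarray, y: np.ndarray, scheme: FoldScheme, C: float,
                 standardize: bool = False) -> float:
    correct = 0
    total = 0
    for train, test in scheme.folds:
        Xtr, Xte = X[train], X[test]
        if standardize:
            mu = Xtr.mean(axis=0)
            sd = Xtr.std(axis=0, ddof=0)
            sd[sd == 0] = 1.0
            Xtr, Xte = (Xtr - mu) / sd, (Xte - mu) / sd
        model = train_lsvm(Xtr, y[train], C=C)
        pred_pos = model.decision(Xte) >= 0
        pos_label = np.sort(np.unique(y[train]))[-1]
        correct += int(np.sum((y[test] == pos_label) == pred_pos))
        total += len(test)
    return 100.0 * correct / total


def cross_validate(
    patterns: BetaPatternSet,
    task: int,
    relevance: str = "relevant",
    scheme: FoldScheme | None = None,
    C: float = 1.0,
    standardize: bool = False,
) -> float:
    """Within-task cross-validated condition-decoding accuracy (%) for
    one subject; ``scheme`` defaults to leave-one-block-out.

    ``standardize`` z-scores each voxel on the training fold (betas are
    already on a common scale, so it is off by default — and it would
    change the inputs to the weight-to-pattern transform, so it must be
    an explicit choice).
    """
    sel = patterns.select(task=task, relevance=relevance)
    if sel.n_samples == 0:
        raise ValueError(f"no samples for task={task}, relevance={relevance}")
    y = sel.labels["condition"].to_numpy()
    if scheme is None:
        scheme = leave_one_block_out(sel.labels["block"].to_numpy())
    return _cv_accuracy(sel.data, y, scheme, C, standardize=standardize)


def cross_generalize(
    patterns: BetaPatternSet,
    train_task: int = 1,
    test_task: int = 2,
    relevance: str = "relevant",
    C: float = 1.0,
) -> dict:
    """Cross-task generalization of condition (category-number) decoding.

    Trains on all samples of one task and tests on all samples of the
    other, in both directions; the reported accuracy is the arithmetic
    mean of the two directional accuracies.
    """
    accs = {}
    for a, b in ((train_task, test_task), (test_task, train_task)):
        tr = patterns.select(task=a, relevance=relevance)
        te = patterns.select(task=b, relevance=relevance)
        if tr.n_samples == 0 or te.n_samples == 0:
            raise ValueError("both tasks must be present")
        model = train_lsvm(tr.data, tr.labels["condition"].to_numpy(), C=C)
        pos = np.sort(np.unique(tr.labels["condition"]))[-1]
        pred_pos = model.decision(te.data) >= 0
        truth = te.labels["condition"].to_numpy() == pos
        accs[f"{a}->{b}"] = 100.0 * float(np.mean(truth == pred_pos))
    accs["mean"] = float(np.mean([accs[k] for k in accs if "->" in k]))
    return accs


def group_test_vs_chance(result: DecodingResult | dict) -> dict:
    """One-sample, one-sided t-test of subject accuracies against 50 %.

    Returns mean accuracy, t, one-sided p, and a ``degenerate`` flag set
    when the between-subject variance is zero (t undefined).
    """
    accs = result.accuracies if isinstance(result, DecodingResult) else result
    vals = np.asarray(list(accs.values()), dtype=float)
    if vals.size < 2:
        raise ValueError("group test needs at least 2 subjects")
    mean = float(vals.mean())
    if np.allclose(vals.std(ddof=1), 0.0):
        return {"mean_accuracy": mean, "t": np.nan, "p": np.nan, "n": int(vals.size),
                "degenerate": True}
    t, p = stats.ttest_1samp(vals, CHANCE, alternative="greater")
    return {"mean_accuracy": mean, "t": float(t), "p": float(p), "n": int(vals.size),
            "degenerate": False}


def sphere_neighbors(
    grid_dims: tuple[int, int, int],
    affine: np.ndarray,
    center: tuple[int, int, int],
    radius_mm: float,
) -> np.ndarray:
    """In-grid voxel linear indices whose mm centre lies within
    ``radius_mm`` of the centre voxel's mm centre (inclusive)."""
    grid_dims = tuple(int(d) for d in grid_dims)
    center = np.asarray(center, dtype=int)
    if np.any(center < 0) or np.any(center >= grid_dims):
        raise ValueError("center voxel outside grid")
    lin = np.asarray(affine)[:3, :3]
    # conservative per-axis bound on the index offset reaching radius_mm
    inv_norms = np.linalg.norm(np.linalg.inv(lin), axis=1)
    max_off = np.ceil(radius_mm * inv_norms).astype(int)
    ranges = [
        np.arange(max(0, center[i] - max_off[i]), min(grid_dims[i], center[i] + max_off[i] + 1))
        for i in range(3)
    ]
    grid = np.stack(np.meshgrid(*ranges, indexing="ij"), axis=-1).reshape(-1, 3)
    d_mm = (grid - center) @ lin.T
    keep = np.linalg.norm(d_mm, axis=1) <= radius_mm + 1e-9
    kept = grid[keep]
    return np.ravel_multi_index((kept[:, 0], kept[:, 1], kept[:, 2]), grid_dims)


def searchlight_map(
    patterns: BetaPatternSet,
    mask: ROIMask,
    radius_mm: float,
    task: int,
    relevance: str = "relevant",
    C: float = 1.0,
) -> AccuracyMap:
    """Roaming-sphere decoding: assign each sphere's leave-one-block-out
    accuracy to its centre voxel.

    ``patterns`` must cover the full grid (column order = ascending
    linear index), as produced by the simulator or a full-grid mask.
    Spheres where decoding fails are left unevaluated (NaN).
    """
    if patterns.grid_dims is None or int(np.prod(patterns.grid_dims)) != patterns.n_voxels:
        raise ValueError("searchlight needs a full-grid pattern set")
    grid_dims = patterns.grid_dims
    sel = patterns.select(task=task, relevance=relevance)
    y = sel.labels["condition"].to_numpy()
    scheme = leave_one_block_out(sel.labels["block"].to_numpy())

    vol = np.full(grid_dims, np.nan)
    evaluated = np.zeros(grid_dims, dtype=bool)
    for lin_idx in mask.linear_indices:
        center = np.unravel_index(lin_idx, grid_dims)
        sphere = sphere_neighbors(grid_dims, mask.affine, center, radius_mm)
        try:
            acc = _cv_accuracy(sel.data[:, sphere], y, scheme, C)
        except SingleClassError:
            continue
        vol[center] = acc
        evaluated[center] = True
    return AccuracyMap(volume=vol, affine=np.asarray(mask.affine), mask=evaluated)


def cluster_extent_threshold(
    stat_volume: np.ndarray,
    voxel_threshold: float,
    extent: int = 20,
) -> list[dict]:
    """Suprathreshold clusters (6-connectivity) with size >= ``extent``.

    Returns a list of {size, peak_index, peak_value} sorted by
    descending size; NaNs are subthreshold.
    """
    vol = np.asarray(stat_volume, dtype=float)
    above = np.where(np.isfinite(vol), vol > voxel_threshold, False)
    structure = ndimage.generate_binary_structure(3, 1)  # faces only
    labelled, n = ndimage.label(above, structure=structure)
    clusters = []
    for lab in range(1, n + 1):
        members = np.argwhere(labelled == lab)
        if len(members) < extent:
            continue
        vals = vol[tuple(members.T)]
        peak = members[int(np.argmax(vals))]
        clusters.append(
            {"size": int(len(members)), "peak_index": tuple(int(i) for i in peak),
             "peak_value": float(vals.max())}
        )
    clusters.sort(key=lambda c: c["size"], reverse=True)
    return clusters
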