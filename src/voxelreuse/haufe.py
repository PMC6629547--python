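"""Backward-to-forward model transformation of classifier weights.

A linear classifier's raw weights are a backward model: a voxel may get
a large weight because it carries signal, or merely because it helps
cancel structured noise.  Multiplying the weight vector by the data
covariance, a = Sigma @ w, converts the weights into forward-model
activation patterns — per-voxel signal contributions that are
neurophysiologically interpretable.  For a single binary discriminant
the omitted inverse latent-variance factor is a positive scalar and
cannot change any ranking of |a|, so it is dropped.

Covariance estimation: with the study-like design there are only 16
training samples (8 blocks x 2 conditions) against hundreds of voxels,
so the empirical covariance is singular; the default in that regime is
an analytic shrinkage estimator toward the diagonal of the sample
covariance (Schafer–Strimmer-style intensity), which stabilises the
|a| ranking the downstream overlap statistic consumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .decoding import LinearModel, train_lsvm
from .simulate import BetaPatternSet

__all__ = [
    "CovarianceEstimate",
    "ActivationPattern",
    "estimate_covariance",
    "transform_weights",
    "fit_full_data_pattern",
]


@dataclass
class CovarianceEstimate:
    sigma: np.ndarray  # voxels x voxels, symmetric PSD
    kind: str  # "empirical" | "shrinkage"
    n_samples: int
    shrinkage: float | None = None  # intensity actually used (shrinkage kind)

    def __post_init__(self) -> None:
        if not np.allclose(self.sigma, self.sigma.T, atol=1e-10):
            raise ValueError("covariance must be symmetric")


@dataclass
class ActivationPattern:
    """Transformed weights a = Sigma @ w: per-voxel signal contributions."""

    values: np.ndarray
    task: object = None
    model: LinearModel | None = None
    covariance: CovarianceEstimate | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("activation pattern contains non-finite values")


def _diagonal_shrinkage_intensity(Xc: np.ndarray, S: np.ndarray) -> float:
    """Analytic shrinkage weight toward diag(S).

    lambda* = sum_{i!=j} Var^(s_ij) / sum_{i!=j} s_ij^2, clipped to
    [0, 1], with Var^(s_ij) = n / (n-1)^3 * sum_k (w_kij - mean_w)^2 and
    w_kij = x_ki x_kj on centred data.
    """
    n = Xc.shape[0]
    if n < 2:
        return 1.0
    # var of each covariance entry via E[w^2] - E[w]^2 without the n x p x p tensor
    w_bar = (Xc.T @ Xc) / n
    w2_bar = (Xc.T**2) @ (Xc**2) / n
    var_s = n / (n - 1) ** 3 * n * (w2_bar - w_bar**2)
    off = ~np.eye(S.shape[0], dtype=bool)
    denom = float(np.sum(S[off] ** 2))
    if denom <= 0:
        return 1.0
    lam = float(np.sum(var_s[off])) / denom
    return float(np.clip(lam, 0.0, 1.0))


def estimate_covariance(
    X: np.ndarray,
    kind: str = "empirical",
    shrinkage: float | None = None,
) -> CovarianceEstimate:
    """Column-demeaned sample covariance (denominator n-1), optionally
    shrunk toward its diagonal.

    Parameters
    ----------
    X
        samples x voxels data; demeaned per column before estimation
        (classes pooled).
    kind
        "empirical" or "shrinkage".
    shrinkage
        Explicit intensity in [0, 1] for kind="shrinkage"; if None the
        analytic intensity is used.  1.0 returns the diagonal target
        exactly.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("covariance estimation needs at least 2 samples")
    Xc = X - X.mean(axis=0, keepdims=True)
    S = (Xc.T @ Xc) / (n - 1)
    if kind == "empirical":
        return CovarianceEstimate(sigma=S, kind=kind, n_samples=n)
    if kind != "shrinkage":
        raise ValueError(f"unknown covariance kind {kind!r}")
    lam = _diagonal_shrinkage_intensity(Xc, S) if shrinkage is None else float(shrinkage)
    if not 0.0 <= lam <= 1.0:
        raise ValueError("shrinkage intensity must be in [0, 1]")
    target = np.diag(np.diag(S))
    sigma = (1.0 - lam) * S + lam * target
    return CovarianceEstimate(sigma=sigma, kind=kind, n_samples=n, shrinkage=lam)


def transform_weights(cov: CovarianceEstimate, model: LinearModel, task=None) -> ActivationPattern:
    """a = Sigma @ w."""
    w = np.asarray(model.weights, dtype=float)
    if cov.sigma.shape[1] != w.shape[0]:
        raise ValueError(
            f"dimension mismatch: covariance is {cov.sigma.shape}, weights {w.shape}"
        )
    return ActivationPattern(values=cov.sigma @ w, task=task, model=model, covariance=cov)


def fit_full_data_pattern(
    patterns: BetaPatternSet,
    task: int,
    relevance: str = "relevant",
    C: float = 1.0,
    cov_kind: str = "auto",
    cov: CovarianceEstimate | None = None,
) -> ActivationPattern:
    """Train on all of one task's samples and return the transformed weights.

    Uses every (block, condition) sample of the task (16 in the default
    8-block design), estimates the covariance on the same samples, and
    returns a = Sigma @ w.  ``cov_kind="auto"`` picks shrinkage when the
    voxel count is at least the sample count (singular empirical
    regime), empirical otherwise; a precomputed ``cov`` (the covariance
    is label-independent) may be supplied to avoid re-estimation, e.g.
    across label permutations.
    """
    sel = patterns.select(task=task, relevance=relevance)
    counts = sel.labels.groupby(["block", "condition"]).size()
    if sel.n_samples == 0 or (counts < 1).any():
        raise ValueError(f"missing design cells for task={task}, relevance={relevance}")
    model = train_lsvm(sel.data, sel.labels["condition"].to_numpy(), C=C)
    if cov is None:
        if cov_kind == "auto":
            cov_kind = "shrinkage" if sel.n_voxels >= sel.n_samples else "empirical"
        cov = estimate_covariance(sel.data, kind=cov_kind)
    return transform_weights(cov, model, task=task)
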