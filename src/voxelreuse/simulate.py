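"""Synthetic multi-subject beta-pattern datasets with planted multivoxel codes.

The generator emulates the output of a block-wise first-level GLM for a
two-task design: for each subject it emits one beta pattern (one sample)
per (task, block, condition, relevance) cell, i.e. 2 tasks x 8 blocks x
2 conditions x 2 relevance levels = 64 samples by default.

Each task carries a planted multivoxel code: a set of informative voxels
whose condition means are separated by ``effect_size`` noise standard
deviations.  A controllable fraction ``shared_fraction`` of each task's
informative voxels is shared between the two tasks, which is the quantity
the downstream voxel re-use statistic is designed to recover.  Shared
voxels carry the same signed effect in both tasks (a genuinely shared
code).  The never-attended (irrelevant) feature dimension gets its own,
independently drawn pattern with ``irrelevant_effect_size`` (default 0,
i.e. pure noise).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "TaskTruth",
    "GroundTruth",
    "BetaPatternSet",
    "DegenerateConfigError",
    "generate_dataset",
    "summarize_dataset",
    "round_half_away",
]

TASKS = (1, 2)
CONDITIONS = (1, 2)
RELEVANCES = ("relevant", "irrelevant")


class DegenerateConfigError(ValueError):
    """Raised when a configuration rounds to an empty planted voxel set."""


def round_half_away(x: float) -> int:
    """Round half away from zero (1.5 -> 2, 2.5 -> 3, -1.5 -> -2)."""
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters of the simulated world.

    Parameters
    ----------
    n_subjects
        Number of simulated participants.
    grid_dims
        Voxel grid shape (nx, ny, nz); the ROI is the full grid.
    voxel_size_mm
        Isotropic voxel size in millimetres.
    n_blocks_per_task
        Scanning blocks per task; each block yields one beta per
        (condition, relevance) cell.
    informative_fraction
        Fraction of grid voxels planted with signal in each task.
    shared_fraction
        rho: fraction of each task's informative voxels shared between
        the two tasks' codes (the ground-truth re-use level).
    effect_size
        d: condition-mean separation at informative voxels, in units of
        the noise standard deviation.
    noise_sd
        sigma: standard deviation of the additive Gaussian noise.
    irrelevant_effect_size
        Effect size planted on the irrelevant feature dimension
        (independent voxel sets per task); 0 means pure noise.
    smooth_fwhm_mm
        Optional isotropic Gaussian smoothing of the noise field
        (variance-renormalised); 0 disables it.  Only matters for
        searchlight-style spatial analyses.
    rng_seed
        Seed; identical config + seed gives a bit-identical dataset.
    """

    n_subjects: int = 12
    grid_dims: tuple[int, int, int] = (10, 5, 4)
    voxel_size_mm: float = 3.0
    n_blocks_per_task: int = 8
    informative_fraction: float = 0.1
    shared_fraction: float = 1.0
    effect_size: float = 1.5
    noise_sd: float = 1.0
    irrelevant_effect_size: float = 0.0
    baseline: float = 0.0
    smooth_fwhm_mm: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_blocks_per_task < 1:
            raise ValueError("counts must be >= 1")
        if len(self.grid_dims) != 3 or any(d < 1 for d in self.grid_dims):
            raise ValueError("grid_dims must be 3 positive integers")
        if not (0.0 < self.informative_fraction <= 1.0):
            raise ValueError("informative_fraction must be in (0, 1]")
        if not (0.0 <= self.shared_fraction <= 1.0):
            raise ValueError("shared_fraction must be in [0, 1]")
        if self.effect_size < 0 or self.irrelevant_effect_size < 0:
            raise ValueError("effect sizes must be nonnegative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative (0 is the noiseless limit)")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.grid_dims))

    @property
    def n_informative(self) -> int:
        k = round_half_away(self.informative_fraction * self.n_voxels)
        if k == 0:
            raise DegenerateConfigError(
                "informative_fraction rounds to zero informative voxels "
                f"({self.informative_fraction} of {self.n_voxels})"
            )
        return k

    @property
    def n_shared(self) -> int:
        return round_half_away(self.shared_fraction * self.n_informative)

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[0, 0] = aff[1, 1] = aff[2, 2] = self.voxel_size_mm
        return aff

    def to_dict(self) -> dict:
        d = asdict(self)
        d["grid_dims"] = list(self.grid_dims)
        return d


@dataclass
class TaskTruth:
    """Planted code of one task: informative voxel indices and signed pattern."""

    informative: np.ndarray  # sorted voxel indices
    pattern: np.ndarray  # signed effect per voxel, zero outside `informative`


@dataclass
class GroundTruth:
    """Planted codes per subject, keyed by subject id then task (1, 2)."""

    subjects: dict[str, dict[int, TaskTruth]] = field(default_factory=dict)
    irrelevant: dict[str, dict[int, TaskTruth]] = field(default_factory=dict)

    def to_json(self) -> str:
        def enc(d):
            return {
                sid: {
                    str(t): {
                        "informative": tt.informative.tolist(),
                        "pattern": tt.pattern.tolist(),
                    }
                    for t, tt in tasks.items()
                }
                for sid, tasks in d.items()
            }

        return json.dumps({"subjects": enc(self.subjects), "irrelevant": enc(self.irrelevant)})


@dataclass
class BetaPatternSet:
    """Per-subject samples x voxels matrix of block-wise beta estimates.

    ``labels`` has one row per sample with columns task, block, condition,
    relevance; columns of ``data`` follow ascending linear voxel index of
    the ROI (C order over the grid).
    """

    subject: str
    data: np.ndarray
    labels: pd.DataFrame
    voxel_coords_mm: np.ndarray
    roi_name: str = "all"
    grid_dims: tuple[int, int, int] | None = None

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]

    def select(self, task: int | None = None, relevance: str | None = None) -> "BetaPatternSet":
        """Row-subset by task and/or relevance, preserving label alignment."""
        m = np.ones(self.n_samples, dtype=bool)
        if task is not None:
            m &= (self.labels["task"] == task).to_numpy()
        if relevance is not None:
            m &= (self.labels["relevance"] == relevance).to_numpy()
        return BetaPatternSet(
            subject=self.subject,
            data=self.data[m],
            labels=self.labels.loc[m].reset_index(drop=True),
            voxel_coords_mm=self.voxel_coords_mm,
            roi_name=self.roi_name,
            grid_dims=self.grid_dims,
        )


def _design_table(n_blocks: int) -> pd.DataFrame:
    rows = [
        (t, b, c, r)
        for t in TASKS
        for b in range(1, n_blocks + 1)
        for c in CONDITIONS
        for r in RELEVANCES
    ]
    return pd.DataFrame(rows, columns=["task", "block", "condition", "relevance"])


def _voxel_coords_mm(grid_dims, affine) -> np.ndarray:
    idx = np.indices(grid_dims).reshape(3, -1).T  # ascending linear (C) order
    return idx @ affine[:3, :3].T + affine[:3, 3]


def _draw_supports(rng: np.random.Generator, n_voxels: int, k: int, n_shared: int):
    """Informative sets for the two tasks with exactly ``n_shared`` common voxels."""
    i1 = rng.choice(n_voxels, size=k, replace=False)
    shared = rng.choice(i1, size=n_shared, replace=False)
    rest = np.setdiff1d(np.arange(n_voxels), i1, assume_unique=False)
    extra = rng.choice(rest, size=k - n_shared, replace=False)
    i2 = np.concatenate([shared, extra])
    return np.sort(i1), np.sort(i2), np.sort(shared)


def _smooth_noise(noise: np.ndarray, grid_dims, sigma_vox: float) -> np.ndarray:
    """Gaussian-smooth each sample's noise field and restore unit variance."""
    from scipy.ndimage import gaussian_filter

    out = np.empty_like(noise)
    # variance shrink factor of the discrete kernel, estimated on a delta
    delta = np.zeros(grid_dims)
    delta[tuple(d // 2 for d in grid_dims)] = 1.0
    kern = gaussian_filter(delta, sigma_vox)
    scale = 1.0 / np.sqrt(np.sum(kern**2))
    for i in range(noise.shape[0]):
        vol = noise[i].reshape(grid_dims)
        out[i] = gaussian_filter(vol, sigma_vox).ravel() * scale
    return out


def generate_dataset(config: SimulationConfig) -> tuple[list[BetaPatternSet], GroundTruth]:
    """Generate the multi-subject dataset and its ground truth.

    Sample construction at voxel v for a (task t, block, condition c,
    relevance) cell::

        x_v = baseline + s_c * a_v + noise,   s_c = +1 (condition 1) / -1

    where ``a`` is the task's signed effect pattern (magnitude d/2 on
    informative voxels, zero elsewhere) for relevant samples, or the
    task's independent irrelevant-dimension pattern otherwise.  The
    condition means are therefore separated by d noise SDs.
    """
    n_vox = config.n_voxels
    k = config.n_informative
    n_shared = config.n_shared
    rng = np.random.default_rng(config.rng_seed)
    labels = _design_table(config.n_blocks_per_task)
    coords = _voxel_coords_mm(config.grid_dims, config.affine)
    sigma_vox = (
        config.smooth_fwhm_mm / config.voxel_size_mm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
        if config.smooth_fwhm_mm > 0
        else 0.0
    )

    subjects: list[BetaPatternSet] = []
    truth = GroundTruth()
    half = config.effect_size / 2.0
    irr_half = config.irrelevant_effect_size / 2.0

    for s in range(config.n_subjects):
        sid = f"sub-{s + 1:02d}"
        i1, i2, shared = _draw_supports(rng, n_vox, k, n_shared)

        patterns: dict[int, np.ndarray] = {}
        a1 = np.zeros(n_vox)
        a1[i1] = rng.choice([-half, half], size=k)
        a2 = np.zeros(n_vox)
        # shared voxels carry the same signed effect in both tasks
        a2[shared] = a1[shared]
        private2 = np.setdiff1d(i2, shared)
        a2[private2] = rng.choice([-half, half], size=private2.size)
        patterns[1], patterns[2] = a1, a2
        truth.subjects[sid] = {
            1: TaskTruth(informative=i1, pattern=a1),
            2: TaskTruth(informative=i2, pattern=a2),
        }

        irr_patterns: dict[int, np.ndarray] = {}
        truth.irrelevant[sid] = {}
        for t in TASKS:
            idx = np.sort(rng.choice(n_vox, size=k, replace=False))
            a = np.zeros(n_vox)
            a[idx] = rng.choice([-irr_half, irr_half], size=k) if irr_half > 0 else 0.0
            irr_patterns[t] = a
            truth.irrelevant[sid][t] = TaskTruth(informative=idx, pattern=a)

        noise = rng.normal(0.0, 1.0, size=(len(labels), n_vox))
        if sigma_vox > 0:
            noise = _smooth_noise(noise, config.grid_dims, sigma_vox)
        noise *= config.noise_sd

        data = np.full((len(labels), n_vox), config.baseline, dtype=float)
        for i, row in enumerate(labels.itertuples(index=False)):
            sign = 1.0 if row.condition == 1 else -1.0
            a = patterns[row.task] if row.relevance == "relevant" else irr_patterns[row.task]
            data[i] += sign * a
        data += noise

        subjects.append(
            BetaPatternSet(
                subject=sid,
                data=data,
                labels=labels.copy(),
                voxel_coords_mm=coords,
                roi_name="all",
                grid_dims=config.grid_dims,
            )
        )
    return subjects, truth


def summarize_dataset(dataset: list[BetaPatternSet]) -> pd.DataFrame:
    """Per-condition means/SDs and sample counts, one row per design cell."""
    rows = []
    for ps in dataset:
        for (t, c, r), grp in ps.labels.groupby(["task", "condition", "relevance"], sort=True):
            x = ps.data[grp.index.to_numpy()]
            rows.append(
                {
                    "subject": ps.subject,
                    "task": t,
                    "condition": c,
                    "relevance": r,
                    "n_samples": len(grp),
                    "mean": float(x.mean()),
                    # across-sample SD per voxel, averaged over voxels: 0 for
                    # a noiseless dataset even though the planted pattern
                    # varies over space
                    "sd": float(x.std(axis=0, ddof=0).mean()),
                }
            )
    cols = ["subject", "task", "condition", "relevance", "n_samples", "mean", "sd"]
    return pd.DataFrame(rows, columns=cols)
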