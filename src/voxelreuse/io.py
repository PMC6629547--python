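"""NIfTI / TSV / JSON input-output and ROI-masked pattern extraction.

Voxel ordering convention: within an ROI, pattern-matrix columns follow
ascending linear voxel index of the true mask voxels, with the linear
index computed in C order over (x, y, z).  Voxel indices are 0-based;
millimetre coordinates come from the NIfTI affine.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .simulate import BetaPatternSet, GroundTruth, SimulationConfig

__all__ = [
    "ROIMask",
    "AccuracyMap",
    "EmptyMaskError",
    "load_mask",
    "write_mask",
    "extract_patterns",
    "write_map",
    "load_map",
    "write_beta_set",
    "load_beta_set",
    "write_dataset",
    "load_label_table",
]


class EmptyMaskError(ValueError):
    """Raised when a mask volume contains no nonzero voxel."""


@dataclass
class ROIMask:
    name: str
    volume: np.ndarray  # boolean 3D
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.volume = np.asarray(self.volume, dtype=bool)
        if self.volume.ndim != 3:
            raise ValueError("mask volume must be 3D")
        if not self.volume.any():
            raise EmptyMaskError(f"mask {self.name!r} has no true voxel")
        if abs(np.linalg.det(np.asarray(self.affine)[:3, :3])) < 1e-12:
            raise ValueError("mask affine is not invertible")

    @property
    def n_voxels(self) -> int:
        return int(self.volume.sum())

    @property
    def linear_indices(self) -> np.ndarray:
        """Ascending linear (C-order) indices of the true voxels."""
        return np.flatnonzero(self.volume.ravel(order="C"))

    @property
    def voxel_coords_mm(self) -> np.ndarray:
        ijk = np.array(np.unravel_index(self.linear_indices, self.volume.shape)).T
        aff = np.asarray(self.affine)
        return ijk @ aff[:3, :3].T + aff[:3, 3]


@dataclass
class AccuracyMap:
    """3D map of decoding accuracy (%, chance 50) defined on evaluated voxels."""

    volume: np.ndarray  # float 3D, NaN where unevaluated
    affine: np.ndarray
    mask: np.ndarray  # boolean 3D, True where evaluated

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        vals = self.volume[self.mask]
        if vals.size and (np.nanmin(vals) < 0 or np.nanmax(vals) > 100):
            raise ValueError("accuracy values must lie in [0, 100] on the mask")


def load_mask(path: str | Path, name: str | None = None) -> ROIMask:
    img = nib.load(str(path))
    vol = np.asarray(img.dataobj) != 0
    return ROIMask(name=name or Path(path).name.split(".")[0], volume=vol, affine=img.affine)


def write_mask(mask: ROIMask, path: str | Path) -> Path:
    path = Path(path)
    nib.save(nib.Nifti1Image(mask.volume.astype(np.uint8), mask.affine), str(path))
    return path


def extract_patterns(
    beta_images: str | Path | nib.Nifti1Image,
    label_table: pd.DataFrame,
    mask: ROIMask,
    subject: str | None = None,
) -> BetaPatternSet:
    """Extract an ROI-masked samples x voxels matrix from a 4D beta image.

    The number of volumes must equal the number of label rows; matrix
    columns follow the mask's ascending linear voxel index.
    """
    img = beta_images if isinstance(beta_images, nib.Nifti1Image) else nib.load(str(beta_images))
    data = np.asarray(img.dataobj)
    if data.ndim == 3:
        data = data[..., np.newaxis]
    n_vols = data.shape[3]
    if n_vols != len(label_table):
        raise ValueError(f"{n_vols} volumes but {len(label_table)} label rows")
    flat = data.reshape(-1, n_vols, order="C")  # voxels x volumes
    matrix = flat[mask.linear_indices].T.astype(float)
    sid = subject
    if sid is None:
        sid = str(label_table["subject"].iloc[0]) if "subject" in label_table else "unknown"
    cols = [c for c in ("task", "block", "condition", "relevance") if c in label_table]
    return BetaPatternSet(
        subject=sid,
        data=matrix,
        labels=label_table[cols].reset_index(drop=True),
        voxel_coords_mm=mask.voxel_coords_mm,
        roi_name=mask.name,
        grid_dims=tuple(mask.volume.shape),
    )


def write_map(amap: AccuracyMap, path: str | Path) -> Path:
    path = Path(path)
    vol = np.where(amap.mask, amap.volume, np.nan).astype(np.float32)
    nib.save(nib.Nifti1Image(vol, amap.affine), str(path))
    return path


def load_map(path: str | Path) -> AccuracyMap:
    img = nib.load(str(path))
    vol = np.asarray(img.dataobj, dtype=float)
    return AccuracyMap(volume=vol, affine=img.affine, mask=np.isfinite(vol))


def write_beta_set(ps: BetaPatternSet, directory: str | Path, affine: np.ndarray) -> dict:
    """Write one subject's patterns as a 4D NIfTI plus a TSV label table.

    Requires ``ps.grid_dims`` covering all voxels (full-grid ROI); one
    volume per sample, volume order equals label-row order.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if ps.grid_dims is None or int(np.prod(ps.grid_dims)) != ps.n_voxels:
        raise ValueError("write_beta_set needs a full-grid pattern set")
    vols = ps.data.T.reshape(*ps.grid_dims, ps.n_samples, order="C")
    img_path = directory / f"{ps.subject}_beta.nii"
    nib.save(nib.Nifti1Image(vols.astype(np.float64), affine), str(img_path))
    table = ps.labels.copy()
    table.insert(0, "subject", ps.subject)
    table["volume_index"] = np.arange(ps.n_samples)
    tsv_path = directory / f"{ps.subject}_labels.tsv"
    table.to_csv(tsv_path, sep="\t", index=False)
    return {"beta": img_path, "labels": tsv_path}


def load_label_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def load_beta_set(beta_path: str | Path, labels_path: str | Path, mask: ROIMask) -> BetaPatternSet:
    return extract_patterns(beta_path, load_label_table(labels_path), mask)


def write_dataset(
    dataset: list[BetaPatternSet],
    truth: GroundTruth,
    config: SimulationConfig,
    directory: str | Path,
) -> dict:
    """Write all subjects' beta images + labels, ground truth JSON, config JSON."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {ps.subject: write_beta_set(ps, directory, config.affine) for ps in dataset}
    (directory / "ground_truth.json").write_text(truth.to_json())
    (directory / "config.json").write_text(json.dumps(config.to_dict(), indent=1))
    return {
        "subjects": paths,
        "ground_truth": directory / "ground_truth.json",
        "config": directory / "config.json",
    }
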