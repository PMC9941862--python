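"""In-memory containers and file I/O for volumes and sampled traces.

NIfTI-1 volumes go through nibabel; tabular traces are TSV with a JSON
sidecar recording sampling rate and units, in the spirit of BIDS physio
conventions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = ["FunctionalSeries", "LabelVolume", "write_tsv", "read_tsv"]


def _affine(voxel_size_mm) -> np.ndarray:
    aff = np.diag(list(voxel_size_mm) + [1.0])
    return aff


@dataclass
class FunctionalSeries:
    """A 4D functional acquisition: voxel grid x time, with TR metadata."""

    data: np.ndarray  # (x, y, z, t)
    tr: float
    voxel_size_mm: tuple = (1.0, 1.0, 1.0)

    def __post_init__(self):
        if self.data.ndim != 4:
            raise ValueError(f"expected 4D data, got shape {self.data.shape}")
        if self.tr <= 0:
            raise ValueError("tr must be positive")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[-1]

    @property
    def grid_shape(self) -> tuple:
        return self.data.shape[:3]

    def to_nifti(self) -> nib.Nifti1Image:
        img = nib.Nifti1Image(np.asarray(self.data, np.float32), _affine(self.voxel_size_mm))
        img.header.set_zooms((*self.voxel_size_mm, self.tr))
        return img

    def save(self, path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def load(cls, path) -> "FunctionalSeries":
        img = nib.load(str(path))
        zooms = img.header.get_zooms()
        return cls(
            data=np.asarray(img.dataobj, dtype=np.float32),
            tr=float(zooms[3]),
            voxel_size_mm=tuple(float(z) for z in zooms[:3]),
        )


@dataclass
class LabelVolume:
    """Per-voxel cortical depth layer (1-20, 0 outside), ROI id, and vein flag."""

    depth: np.ndarray  # int, 0 = outside cortex
    roi: np.ndarray  # int, 0 = none
    vein: np.ndarray  # bool
    voxel_size_mm: tuple = (1.0, 1.0, 1.0)
    depth_axis: int = 2
    roi_names: dict = field(default_factory=lambda: {1: "V1", 2: "V2", 3: "V3"})

    def __post_init__(self):
        if not (self.depth.shape == self.roi.shape == self.vein.shape):
            raise ValueError("depth, roi and vein grids must share a shape")
        in_cortex = self.depth >= 1
        if np.any((self.roi > 0) & ~in_cortex):
            raise ValueError("ROI labels must lie within the cortical ribbon")

    @property
    def grid_shape(self) -> tuple:
        return self.depth.shape

    @property
    def cortex_mask(self) -> np.ndarray:
        return self.depth >= 1

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        aff = _affine(self.voxel_size_mm)
        nib.save(nib.Nifti1Image(self.depth.astype(np.int16), aff), directory / "labels_depth.nii.gz")
        nib.save(nib.Nifti1Image(self.roi.astype(np.int16), aff), directory / "labels_roi.nii.gz")
        nib.save(nib.Nifti1Image(self.vein.astype(np.uint8), aff), directory / "labels_vein.nii.gz")
        (directory / "labels.json").write_text(json.dumps({
            "depth_axis": self.depth_axis,
            "voxel_size_mm": list(self.voxel_size_mm),
            "roi_names": {str(k): v for k, v in self.roi_names.items()},
        }, indent=2))

    @classmethod
    def load(cls, directory) -> "LabelVolume":
        directory = Path(directory)
        meta = json.loads((directory / "labels.json").read_text())
        load = lambda name: np.asarray(nib.load(str(directory / name)).dataobj)
        return cls(
            depth=load("labels_depth.nii.gz").astype(int),
            roi=load("labels_roi.nii.gz").astype(int),
            vein=load("labels_vein.nii.gz").astype(bool),
            voxel_size_mm=tuple(meta["voxel_size_mm"]),
            depth_axis=int(meta["depth_axis"]),
            roi_names={int(k): v for k, v in meta["roi_names"].items()},
        )


def write_tsv(df: pd.DataFrame, path, sidecar: dict | None = None) -> None:
    """Write a TSV table, with an optional JSON sidecar (units, sampling)."""
    path = Path(path)
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")
    if sidecar is not None:
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
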