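"""Volume I/O, spatial smoothing, and per-ROI intensity extraction.

The pipeline consumes already-segmented gray-matter volume maps together
with an integer-labeled parcellation on the same grid; tissue segmentation
and spatial normalization are upstream of this package.  Smoothing uses a
separable Gaussian kernel parameterized by full width at half maximum in
millimetres (6 mm by default in the pipeline), converted per axis to a sigma
in voxel units from the affine's voxel sizes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

from jssenet.cohort import ROIIntensitySamples

# FWHM = 2 sqrt(2 ln 2) sigma for a Gaussian
FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass(frozen=True)
class LabeledVolume:
    """A 3D scalar volume with its spatial affine and semantic kind."""

    data: np.ndarray
    affine: np.ndarray
    kind: str  # "gm_map" | "parcellation"

    def __post_init__(self) -> None:
        if self.kind not in ("gm_map", "parcellation"):
            raise ValueError(f"unknown volume kind {self.kind!r}")
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise ValueError("expected a 3D volume")
        if self.kind == "parcellation":
            if not np.issubdtype(data.dtype, np.integer):
                raise ValueError("parcellation volumes must be integer-typed")
            if data.min() < 0:
                raise ValueError("parcellation labels must be nonnegative")

    @property
    def voxel_sizes(self) -> np.ndarray:
        """Per-axis voxel edge length in mm, from the affine column norms."""
        return np.sqrt((np.asarray(self.affine)[:3, :3] ** 2).sum(axis=0))

    @classmethod
    def from_nifti(cls, path, kind: str) -> "LabeledVolume":
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        if kind == "parcellation":
            data = np.asarray(np.rint(data), dtype=np.int32)
        else:
            data = np.asarray(data, dtype=np.float64)
        return cls(data=data, affine=np.asarray(img.affine), kind=kind)

    def to_nifti(self, path) -> None:
        nib.save(nib.Nifti1Image(np.asarray(self.data), np.asarray(self.affine)), str(path))


def gaussian_smooth(volume: LabeledVolume, fwhm_mm: float) -> LabeledVolume:
    """Smooth a gray-matter map with a Gaussian of the given FWHM (mm).

    Sigma is computed per axis in voxel units (anisotropic voxels get
    per-axis sigmas).  Boundaries are zero-padded, so regions touching the
    volume edge lose a little mass; the synthetic fixtures keep a background
    margin for this reason.
    """
    if volume.kind != "gm_map":
        raise ValueError("smoothing is defined for gm_map volumes")
    if fwhm_mm <= 0:
        raise ValueError("fwhm_mm must be positive")
    data = np.asarray(volume.data, dtype=np.float64)
    if not np.all(np.isfinite(data)):
        raise ValueError("gm_map contains non-finite voxels")
    sigma_vox = fwhm_mm / volume.voxel_sizes / FWHM_TO_SIGMA
    smoothed = ndimage.gaussian_filter(data, sigma=sigma_vox, mode="constant", cval=0.0)
    return LabeledVolume(data=smoothed, affine=volume.affine, kind="gm_map")


def read_label_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    required = {"index", "name", "hemisphere"}
    if not required.issubset(table.columns):
        raise ValueError(f"label table must have columns {sorted(required)}")
    return table


def write_label_table(table: pd.DataFrame, path) -> None:
    table.to_csv(Path(path), sep="\t", index=False)


def extract_roi_samples(
    gm: LabeledVolume,
    parcels: LabeledVolume,
    label_table: pd.DataFrame,
    subject_id: str = "",
) -> ROIIntensitySamples:
    """Collect, per region, the GM intensities at voxels carrying its label.

    Voxel ordering within each region is deterministic row-major (C order).
    Regions are keyed 0..n_rois-1 in label-table row order.  A region with
    fewer than two voxels is an error because downstream density estimation
    is impossible for it.
    """
    if gm.kind != "gm_map" or parcels.kind != "parcellation":
        raise ValueError("expected a gm_map and a parcellation volume")
    gm_data = np.asarray(gm.data)
    parcel_data = np.asarray(parcels.data)
    if gm_data.shape != parcel_data.shape:
        raise ValueError(
            f"grid mismatch: gm {gm_data.shape} vs parcellation {parcel_data.shape}"
        )
    flat_gm = gm_data.ravel(order="C")
    flat_labels = parcel_data.ravel(order="C")
    samples: dict[int, np.ndarray] = {}
    for roi_idx, (_, row) in enumerate(label_table.iterrows()):
        label = int(row["index"])
        vec = flat_gm[flat_labels == label]
        if vec.size == 0:
            raise ValueError(f"label {label} ({row['name']}) absent from parcellation")
        if vec.size < 2:
            raise ValueError(
                f"ROI {row['name']} (label {label}) has {vec.size} voxel; "
                "density estimation needs at least 2"
            )
        samples[roi_idx] = vec.astype(np.float64)
    return ROIIntensitySamples(subject_id=subject_id, samples=samples)
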