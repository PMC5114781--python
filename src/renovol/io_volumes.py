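"""NIfTI input/output: MR volumes, binary ROI masks and label overlays.

The pipeline operates strictly in voxel space: an image and its ROI mask must
share one grid (no resampling or registration is attempted), and voxel geometry
is taken from the NIfTI header zooms. Intensities are read through the header's
scale slope/intercept (nibabel's ``get_fdata``) and never otherwise normalised.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING

import nibabel as nib
import numpy as np

from .errors import (
    AlignmentError,
    DimensionalityError,
    EmptyROIError,
    HeaderError,
)

if TYPE_CHECKING:  # pragma: no cover - import only for annotations
    from .volumetry import SegmentationResult

#: overlay label codes
LABEL_OUTSIDE = 0  #: voxel outside the ROI
LABEL_KEPT = 1  #: parenchyma kept between the thresholds
LABEL_BELOW = 2  #: removed, intensity below the lower threshold (vessels)
LABEL_ABOVE = 3  #: removed, intensity above the upper threshold (calyces/fluid)

#: hues used for rasterised feedback slices, matching the conventional
#: blue-for-subthreshold / orange-for-suprathreshold colouring
BELOW_COLOR = (0.20, 0.42, 0.85)
ABOVE_COLOR = (1.00, 0.55, 0.10)


@dataclass(frozen=True)
class ImageVolume:
    """A 3-D scalar MR volume with voxel spacing in mm.

    ``affine`` is carried opaquely from the source header so derived files
    (overlays, phantoms) land in the same world frame.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray
    source_path: str = ""

    def __post_init__(self):
        if self.data.ndim != 3:
            raise DimensionalityError(
                f"expected a 3-D volume, got shape {self.data.shape}"
            )
        sp = np.asarray(self.spacing, dtype=float)
        if sp.shape != (3,) or not np.all(np.isfinite(sp)) or np.any(sp <= 0):
            raise HeaderError(f"invalid voxel spacing {self.spacing!r}")
        if np.isnan(self.data).any():
            raise HeaderError("volume contains NaN values")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape


@dataclass(frozen=True)
class ROIMask:
    """Binary region-of-interest mask on the grid of an :class:`ImageVolume`."""

    data: np.ndarray
    reference_shape: tuple[int, ...]

    def __post_init__(self):
        if self.data.dtype != bool:
            object.__setattr__(self, "data", self.data.astype(bool))
        if tuple(self.data.shape) != tuple(self.reference_shape):
            raise AlignmentError(
                f"mask shape {self.data.shape} does not match reference "
                f"{tuple(self.reference_shape)}"
            )
        if not self.data.any():
            raise EmptyROIError("ROI mask contains no foreground voxel")

    @property
    def count(self) -> int:
        """Number of foreground voxels."""
        return int(self.data.sum())


def _load_3d(path: str | Path) -> tuple[np.ndarray, tuple[float, ...], np.ndarray]:
    """Load a NIfTI file, squeeze a trailing degenerate 4th axis, validate."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = img.get_fdata(dtype=np.float64)  # applies scl_slope / scl_inter
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise DimensionalityError(
            f"{path.name}: expected 3-D data (or a length-1 4th axis), "
            f"got shape {data.shape}"
        )
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, zooms, np.asarray(img.affine, dtype=float)


def read_volume(path: str | Path) -> ImageVolume:
    """Read an MR volume from a NIfTI-1 file (.nii or .nii.gz)."""
    data, zooms, affine = _load_3d(path)
    if any((not np.isfinite(z)) or z <= 0 for z in zooms):
        raise HeaderError(f"{Path(path).name}: non-positive voxel size {zooms}")
    return ImageVolume(
        data=data, spacing=zooms, affine=affine, source_path=str(path)
    )


def read_mask(path: str | Path, reference: ImageVolume) -> ROIMask:
    """Read a binary ROI mask aligned with ``reference``.

    Any stored value strictly greater than 0.5 is foreground, so float-stored
    and multi-label masks from external tracing tools load deterministically.
    """
    data, _zooms, _affine = _load_3d(path)
    if tuple(data.shape) != tuple(reference.data.shape):
        raise AlignmentError(
            f"mask shape {data.shape} does not match image "
            f"shape {reference.data.shape}"
        )
    return ROIMask(data=data > 0.5, reference_shape=reference.data.shape)


def write_volume(volume: ImageVolume, path: str | Path) -> None:
    """Write an :class:`ImageVolume` back to NIfTI, preserving affine/zooms."""
    img = nib.Nifti1Image(np.asarray(volume.data), volume.affine)
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def write_mask(mask: np.ndarray, volume: ImageVolume, path: str | Path) -> None:
    """Write a binary or label array on ``volume``'s grid as uint8 NIfTI."""
    img = nib.Nifti1Image(np.asarray(mask).astype(np.uint8), volume.affine)
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def voxel_volume_ml(volume: ImageVolume) -> float:
    """Volume of a single voxel in ml (spacing product in mm^3 / 1000)."""
    sx, sy, sz = volume.spacing
    return sx * sy * sz / 1000.0


def overlay_labels(roi: ROIMask, result: "SegmentationResult") -> np.ndarray:
    """Build the label volume: 0 outside ROI, 1 kept, 2 below, 3 above."""
    labels = np.zeros(roi.data.shape, dtype=np.uint8)
    labels[result.kept_mask] = LABEL_KEPT
    labels[result.below_mask] = LABEL_BELOW
    labels[result.above_mask] = LABEL_ABOVE
    return labels


def write_overlay(
    volume: ImageVolume,
    roi: ROIMask,
    result: "SegmentationResult",
    path: str | Path,
    slice_dir: str | Path | None = None,
) -> np.ndarray:
    """Write the visual-feedback label volume (and optional slice PNGs).

    The label codes partition the ROI; voxels outside the ROI are 0. When
    ``slice_dir`` is given, every axial slice intersecting the ROI is rendered
    with the ROI boundary as a contour, sub-threshold voxels in blue and
    supra-threshold voxels in orange.
    """
    labels = overlay_labels(roi, result)
    write_mask(labels, volume, path)
    if slice_dir is not None:
        render_overlay_slices(volume, roi, labels, slice_dir)
    return labels


def render_overlay_slices(
    volume: ImageVolume,
    roi: ROIMask,
    labels: np.ndarray,
    outdir: str | Path,
    prefix: str = "slice",
) -> list[Path]:
    """Rasterise axial feedback slices as PNG files; returns written paths."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    z_indices = np.where(roi.data.any(axis=(0, 1)))[0]
    vmin, vmax = np.percentile(volume.data, [1, 99])
    for k in z_indices:
        fig, ax = plt.subplots(figsize=(4, 4))
        ax.imshow(
            volume.data[:, :, k].T,
            cmap="gray",
            vmin=vmin,
            vmax=vmax,
            origin="lower",
            interpolation="nearest",
        )
        sl = labels[:, :, k].T
        for code, color in ((LABEL_BELOW, BELOW_COLOR), (LABEL_ABOVE, ABOVE_COLOR)):
            rgba = np.zeros(sl.shape + (4,))
            rgba[sl == code] = (*color, 0.85)
            ax.imshow(rgba, origin="lower", interpolation="nearest")
        ax.contour(roi.data[:, :, k].T, levels=[0.5], colors=["yellow"], linewidths=0.8)
        ax.set_axis_off()
        out = outdir / f"{prefix}_{k:03d}.png"
        fig.savefig(out, dpi=100, bbox_inches="tight")
        plt.close(fig)
        written.append(out)
    return written
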