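"""Intensity distribution of the ROI: Gaussian-kernel density and its maxima.

From all voxel intensities inside the coarse ROI a probability distribution
function (PDF) is estimated with a Gaussian kernel and Scott's bandwidth rule
h = s * n^(-1/5) (s the sample standard deviation, denominator n-1). The PDF
is evaluated exactly (no binning) on an even grid padded by a few bandwidths
beyond the sample range, and its local maxima are found by a prominence-gated
peak seeker. The global maximum is the default working peak; the user may
select another detected peak by its 1-based left-to-right ordinal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import find_peaks as _scipy_find_peaks

from .errors import (
    ConfigurationError,
    DegenerateSampleError,
    EmptyROIError,
    NoPeakError,
    PeakSelectionError,
)
from .io_volumes import ImageVolume, ROIMask

log = logging.getLogger("renovol.density")

_SQRT_2PI = float(np.sqrt(2.0 * np.pi))

#: default number of PDF grid points; at 12-bit MR intensity ranges the
#: sub-grid threshold error is then well below one intensity unit
DEFAULT_GRID_POINTS = 1024
#: default grid padding in bandwidths on each side of the sample range
DEFAULT_PAD = 3.0
#: default peak prominence floor, as a fraction of the global density maximum
DEFAULT_PROMINENCE_FRACTION = 0.01


@dataclass(frozen=True)
class IntensitySample:
    """The multiset of ROI voxel intensities with its basic statistics."""

    values: np.ndarray
    n: int
    mean: float
    sd: float  # sample SD, denominator n - 1

    @classmethod
    def from_values(cls, values: np.ndarray) -> "IntensitySample":
        values = np.asarray(values, dtype=float).ravel()
        n = values.size
        if n < 2:
            raise DegenerateSampleError(f"need at least 2 voxels, got {n}")
        sd = float(values.std(ddof=1))
        if sd <= 0:
            raise DegenerateSampleError("constant-intensity ROI (sd = 0)")
        return cls(values=values, n=n, mean=float(values.mean()), sd=sd)


@dataclass(frozen=True)
class IntensityPDF:
    """Gridded kernel-density estimate of the ROI intensity distribution."""

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float
    sample: IntensitySample

    @property
    def step(self) -> float:
        """Grid spacing in intensity units."""
        return float(self.grid[1] - self.grid[0])

    def integral(self) -> float:
        """Trapezoidal integral of the density over the grid."""
        return float(np.trapezoid(self.density, self.grid))


@dataclass(frozen=True)
class PeakSet:
    """Detected PDF maxima; ``selected_index`` drives the thresholding."""

    peak_indices: np.ndarray  # grid indices, ascending
    global_index: int  # grid index of the largest-density peak
    selected_index: int  # peak used downstream (defaults to global)

    @property
    def n_peaks(self) -> int:
        return int(self.peak_indices.size)

    def ordinal_of(self, grid_index: int) -> int:
        """1-based left-to-right ordinal of a peak grid index."""
        (where,) = np.where(self.peak_indices == grid_index)
        return int(where[0]) + 1


def extract_intensities(volume: ImageVolume, roi: ROIMask) -> IntensitySample:
    """Collect all voxel intensities within the ROI as an ordered sample."""
    if tuple(roi.data.shape) != tuple(volume.data.shape):
        from .errors import AlignmentError

        raise AlignmentError(
            f"ROI shape {roi.data.shape} does not match volume {volume.data.shape}"
        )
    values = volume.data[roi.data]
    if values.size == 0:
        raise EmptyROIError("ROI mask contains no foreground voxel")
    return IntensitySample.from_values(values)


def scott_bandwidth(sample: IntensitySample) -> float:
    """Scott's rule bandwidth h = sd * n^(-1/5) for 1-D data."""
    if sample.n < 2 or sample.sd <= 0:
        raise DegenerateSampleError(
            f"Scott bandwidth undefined for n={sample.n}, sd={sample.sd}"
        )
    return sample.sd * sample.n ** (-0.2)


def estimate_pdf(
    sample: IntensitySample,
    grid_points: int = DEFAULT_GRID_POINTS,
    pad: float = DEFAULT_PAD,
    bandwidth: float | None = None,
) -> IntensityPDF:
    """Evaluate the Gaussian-kernel density estimate on an even grid.

    density(x) = (1 / (n h)) * sum_i phi((x - v_i) / h), phi the standard
    normal density and h the Scott bandwidth unless ``bandwidth`` overrides it
    (an explicit bandwidth also permits degenerate, constant samples).

    The grid spans [min(v) - pad*h, max(v) + pad*h]; with the default pad of 3
    the trapezoidal integral of the density exceeds 0.99.
    """
    if grid_points < 16:
        raise ConfigurationError(f"grid_points must be >= 16, got {grid_points}")
    h = float(bandwidth) if bandwidth is not None else scott_bandwidth(sample)
    if h <= 0:
        raise ConfigurationError(f"bandwidth must be positive, got {h}")
    values = np.asarray(sample.values, dtype=float)
    lo = float(values.min()) - pad * h
    hi = float(values.max()) + pad * h
    grid = np.linspace(lo, hi, int(grid_points))
    density = np.zeros(grid.shape, dtype=float)
    # exact kernel sum, chunked over sample values to bound memory
    chunk = max(1, int(4_000_000 // grid.size))
    for start in range(0, values.size, chunk):
        z = (grid[None, :] - values[start : start + chunk, None]) / h
        density += np.exp(-0.5 * z * z).sum(axis=0)
    density /= sample.n * h * _SQRT_2PI
    return IntensityPDF(grid=grid, density=density, bandwidth=h, sample=sample)


def find_peaks(
    pdf: IntensityPDF,
    min_prominence_fraction: float = DEFAULT_PROMINENCE_FRACTION,
) -> PeakSet:
    """Locate interior local maxima of the PDF.

    Maxima with topographic prominence below ``min_prominence_fraction`` times
    the global density maximum are discarded as numerical jitter. The global
    (largest-density) peak becomes the initial selection; an exact height tie
    resolves to the lower-intensity peak.
    """
    if not 0 <= min_prominence_fraction < 1:
        raise ConfigurationError(
            f"min_prominence_fraction must be in [0, 1), got {min_prominence_fraction}"
        )
    floor = min_prominence_fraction * float(pdf.density.max())
    indices, _props = _scipy_find_peaks(pdf.density, prominence=floor)
    if indices.size == 0:
        raise NoPeakError("PDF has no interior local maximum")
    heights = pdf.density[indices]
    global_index = int(indices[int(np.argmax(heights))])  # first max = lower intensity
    log.debug(
        "peaks at grid indices %s (intensities %s), global at %d",
        indices.tolist(),
        np.round(pdf.grid[indices], 2).tolist(),
        global_index,
    )
    return PeakSet(
        peak_indices=indices.astype(int),
        global_index=global_index,
        selected_index=global_index,
    )


def select_peak(peaks: PeakSet, choice: int | None = None) -> PeakSet:
    """Override the working peak by its 1-based ordinal in grid order.

    Without ``choice`` the set is returned unchanged (global-maximum default,
    the method's standard behaviour); an out-of-range ordinal is an error.
    """
    if choice is None:
        return peaks
    if not 1 <= choice <= peaks.n_peaks:
        raise PeakSelectionError(
            f"peak ordinal {choice} out of range (1..{peaks.n_peaks})"
        )
    return replace(peaks, selected_index=int(peaks.peak_indices[choice - 1]))
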