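"""Two-sided unimodal (Rosin-style) thresholding of the ROI intensity PDF.

On each side of the working peak a straight line is drawn from the peak point
to the point on the PDF one sample standard deviation away (the sigma-point;
anchoring the line there instead of at the tail ends keeps high-intensity
outliers from inflating the upper threshold). The threshold is the "corner" of
the PDF under that line: the grid point maximising the perpendicular distance
between the PDF and the line, among points on that side lying strictly below
the line. Maximising the perpendicular distance is equivalent to maximising
the area of a right triangle whose hypotenuse lies on the line and whose right
vertex is on the PDF — and, for a fixed line, to maximising the vertical
deviation line(x) - density(x), since the perpendicular distance is the
vertical deviation times |cos(theta)| with theta the constant line
inclination. The implementation maximises the vertical deviation; tests check
the equivalence against an explicit point-to-line distance search.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .density import IntensityPDF, PeakSet
from .errors import CornerNotFoundError, DegenerateChordError

log = logging.getLogger("renovol.thresholding")

Side = Literal["lower", "upper"]

#: endpoint policies: "sigma" anchors the chord at peak +/- one sample SD
#: (the method's default); "tail" anchors it at the grid end, for comparison
#: experiments only.
ENDPOINT_POLICIES = ("sigma", "tail")


@dataclass(frozen=True)
class ChordSpec:
    """The line on one side of the peak: peak point, endpoint, and side."""

    peak_point: tuple[float, float]  # (grid value, density)
    endpoint: tuple[float, float]
    side: Side
    peak_index: int
    endpoint_index: int

    @property
    def slope(self) -> float:
        (xp, yp), (xe, ye) = self.peak_point, self.endpoint
        return (ye - yp) / (xe - xp)


@dataclass(frozen=True)
class CornerDiagnostics:
    """Where and how far the PDF sags below the chord line."""

    corner_index: int
    vertical_deviation: float
    perpendicular_distance: float
    chord: ChordSpec
    used_fallback: bool = False


@dataclass(frozen=True)
class ThresholdPair:
    """Lower and upper intensity thresholds with per-side diagnostics."""

    lower: float
    upper: float
    lower_diag: CornerDiagnostics
    upper_diag: CornerDiagnostics
    peak_value: float

    def __post_init__(self):
        if not (self.lower < self.peak_value < self.upper):
            raise CornerNotFoundError(
                "both",
                f"thresholds ({self.lower}, {self.upper}) do not bracket the "
                f"peak at {self.peak_value}",
            )


def build_chord(
    pdf: IntensityPDF,
    peaks: PeakSet,
    side: Side,
    endpoint_policy: str = "sigma",
) -> ChordSpec:
    """Anchor the side's line from the selected peak to its endpoint.

    Under the default "sigma" policy the endpoint abscissa is the peak value
    minus (lower) or plus (upper) one sample SD, snapped to the nearest grid
    point and clipped to the grid range. If sigma is smaller than one grid
    step the chord degenerates and an error is raised.
    """
    if endpoint_policy not in ENDPOINT_POLICIES:
        raise DegenerateChordError(f"unknown endpoint policy {endpoint_policy!r}")
    p_idx = int(peaks.selected_index)
    grid, density = pdf.grid, pdf.density
    m = grid.size
    if endpoint_policy == "tail":
        e_idx = 0 if side == "lower" else m - 1
    else:
        sd = pdf.sample.sd
        target = grid[p_idx] - sd if side == "lower" else grid[p_idx] + sd
        e_idx = int(np.clip(round((target - grid[0]) / pdf.step), 0, m - 1))
    if e_idx == p_idx:
        raise DegenerateChordError(
            f"{side} chord endpoint coincides with the peak grid point "
            f"(sigma = {pdf.sample.sd:.4g} below one grid step {pdf.step:.4g})"
        )
    if (side == "lower") != (e_idx < p_idx):
        raise DegenerateChordError(f"{side} chord endpoint on the wrong side")
    return ChordSpec(
        peak_point=(float(grid[p_idx]), float(density[p_idx])),
        endpoint=(float(grid[e_idx]), float(density[e_idx])),
        side=side,
        peak_index=p_idx,
        endpoint_index=e_idx,
    )


def corner_threshold(
    pdf: IntensityPDF, chord: ChordSpec
) -> tuple[float, CornerDiagnostics]:
    """Find the PDF corner under the chord line on the chord's side.

    Candidates are all grid points on the chord's side of the peak that lie
    strictly below the line through peak point and endpoint (the line is
    extended beyond the endpoint; since density >= 0, candidates vanish where
    the line drops below zero). The corner maximises the vertical deviation
    line(x) - density(x); an exact tie resolves to the candidate farthest from
    the peak (the more conservative removal boundary).
    """
    if abs(chord.endpoint_index - chord.peak_index) < 2:
        raise DegenerateChordError(
            f"{chord.side} chord spans fewer than 3 grid points"
        )
    grid, density = pdf.grid, pdf.density
    p_idx = chord.peak_index
    if chord.side == "lower":
        cand = np.arange(0, p_idx)
    else:
        cand = np.arange(p_idx + 1, grid.size)
    xp, yp = chord.peak_point
    slope = chord.slope
    line = yp + slope * (grid[cand] - xp)
    dev = line - density[cand]
    below = dev > 0
    if not below.any():
        raise CornerNotFoundError(chord.side)
    dev = np.where(below, dev, -np.inf)
    best = float(dev.max())
    # deterministic tie-break: farthest candidate from the peak
    ties = cand[dev == best]
    corner = int(ties[0]) if chord.side == "lower" else int(ties[-1])
    perp = best / float(np.hypot(1.0, slope))
    diag = CornerDiagnostics(
        corner_index=corner,
        vertical_deviation=best,
        perpendicular_distance=perp,
        chord=chord,
    )
    return float(grid[corner]), diag


def compute_thresholds(
    pdf: IntensityPDF,
    peaks: PeakSet,
    endpoint_policy: str = "sigma",
    fallback_on_missing_corner: bool = False,
) -> ThresholdPair:
    """Apply the corner criterion on both sides of the selected peak.

    A side with no point below its chord raises a side-labelled
    :class:`CornerNotFoundError` unless ``fallback_on_missing_corner`` is set,
    in which case the chord endpoint itself becomes the threshold (logged; a
    batch-robustness aid, not part of the default method).
    """
    results: dict[Side, tuple[float, CornerDiagnostics]] = {}
    for side in ("lower", "upper"):
        chord = build_chord(pdf, peaks, side, endpoint_policy=endpoint_policy)
        try:
            results[side] = corner_threshold(pdf, chord)
        except CornerNotFoundError:
            if not fallback_on_missing_corner:
                raise
            log.warning(
                "no corner on the %s side; falling back to the chord endpoint "
                "at %.4g",
                side,
                chord.endpoint[0],
            )
            diag = CornerDiagnostics(
                corner_index=chord.endpoint_index,
                vertical_deviation=0.0,
                perpendicular_distance=0.0,
                chord=chord,
                used_fallback=True,
            )
            results[side] = (chord.endpoint[0], diag)
    (lower, lower_diag), (upper, upper_diag) = results["lower"], results["upper"]
    pair = ThresholdPair(
        lower=lower,
        upper=upper,
        lower_diag=lower_diag,
        upper_diag=upper_diag,
        peak_value=float(pdf.grid[peaks.selected_index]),
    )
    log.debug(
        "thresholds: lower=%.4g upper=%.4g (peak at %.4g)",
        pair.lower,
        pair.upper,
        pair.peak_value,
    )
    return pair
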