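"""Apply thresholds within the ROI, compute volumes in ml, persist results.

Voxels whose intensity lies within the closed interval [lower, upper] are kept
as parenchyma; the rest of the ROI is split into the sub-threshold (vessel)
and supra-threshold (calyx/fluid) sets. No morphological clean-up is applied:
removed voxels may be scattered, exactly as the raw thresholding leaves them.
Volumes are voxel counts times the voxel volume, so kept + removed equals the
ROI volume as an integer identity on counts.

Result records are appended to a single-table SQLite database (or a CSV with
the same columns); re-exporting an identical record set is idempotent per the
(subject, kidney, observer, run_id) key.
"""

from __future__ import annotations

import hashlib
import json
import sqlite3
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .density import (
    IntensityPDF,
    PeakSet,
    estimate_pdf,
    extract_intensities,
    find_peaks,
    select_peak,
)
from .errors import AlignmentError, ExportError
from .io_volumes import ImageVolume, ROIMask, voxel_volume_ml
from .thresholding import ThresholdPair, compute_thresholds


@dataclass(frozen=True)
class SegmentationResult:
    """Kept/removed voxel partition of the ROI with volumes in ml."""

    kept_mask: np.ndarray
    below_mask: np.ndarray
    above_mask: np.ndarray
    thresholds: ThresholdPair
    kept_ml: float
    removed_ml: float
    roi_ml: float
    removed_fraction: float

    @property
    def counts(self) -> tuple[int, int, int]:
        """(kept, below, above) voxel counts."""
        return (
            int(self.kept_mask.sum()),
            int(self.below_mask.sum()),
            int(self.above_mask.sum()),
        )


def apply_thresholds(
    volume: ImageVolume, roi: ROIMask, thresholds: ThresholdPair
) -> SegmentationResult:
    """Partition the ROI by the threshold pair (closed kept interval).

    Voxels exactly at a threshold are kept — "within the thresholds" is read
    as a closed interval.
    """
    if tuple(roi.data.shape) != tuple(volume.data.shape):
        raise AlignmentError(
            f"ROI shape {roi.data.shape} does not match volume {volume.data.shape}"
        )
    data, inside = volume.data, roi.data
    below = inside & (data < thresholds.lower)
    above = inside & (data > thresholds.upper)
    kept = inside & ~below & ~above
    vml = voxel_volume_ml(volume)
    n_roi = int(inside.sum())
    n_kept = int(kept.sum())
    n_removed = n_roi - n_kept
    return SegmentationResult(
        kept_mask=kept,
        below_mask=below,
        above_mask=above,
        thresholds=thresholds,
        kept_ml=n_kept * vml,
        removed_ml=n_removed * vml,
        roi_ml=n_roi * vml,
        removed_fraction=n_removed / n_roi,
    )


def segment(
    volume: ImageVolume,
    roi: ROIMask,
    peak_choice: int | None = None,
    grid_points: int = 1024,
    pad: float = 3.0,
    min_prominence_fraction: float = 0.01,
    endpoint_policy: str = "sigma",
    fallback_on_missing_corner: bool = False,
) -> tuple[SegmentationResult, IntensityPDF, PeakSet]:
    """Run the whole per-kidney pipeline: sample, PDF, peaks, thresholds, masks.

    Defaults reproduce the standard method: Scott-bandwidth Gaussian KDE,
    global-maximum peak, sigma-anchored chords, no fallback.
    """
    sample = extract_intensities(volume, roi)
    pdf = estimate_pdf(sample, grid_points=grid_points, pad=pad)
    peaks = select_peak(find_peaks(pdf, min_prominence_fraction), peak_choice)
    thresholds = compute_thresholds(
        pdf,
        peaks,
        endpoint_policy=endpoint_policy,
        fallback_on_missing_corner=fallback_on_missing_corner,
    )
    return apply_thresholds(volume, roi, thresholds), pdf, peaks


#: results-table columns, in storage order
RESULT_COLUMNS = (
    "subject",
    "kidney",
    "observer",
    "run_id",
    "n_roi",
    "n_kept",
    "n_below",
    "n_above",
    "lower_threshold",
    "upper_threshold",
    "selected_peak",
    "n_peaks",
    "bandwidth",
    "kept_ml",
    "removed_ml",
    "roi_ml",
    "removed_fraction",
    "software_version",
    "created_utc",
)

_SQL_TYPES = {
    "subject": "TEXT",
    "kidney": "TEXT",
    "observer": "TEXT",
    "run_id": "TEXT",
    "n_roi": "INTEGER",
    "n_kept": "INTEGER",
    "n_below": "INTEGER",
    "n_above": "INTEGER",
    "selected_peak": "INTEGER",
    "n_peaks": "INTEGER",
    "software_version": "TEXT",
    "created_utc": "TEXT",
}


def summarize(
    result: SegmentationResult,
    subject: str = "",
    kidney: str = "",
    observer: str = "",
    peaks: PeakSet | None = None,
    bandwidth: float | None = None,
    run_id: str | None = None,
) -> dict:
    """Flatten a segmentation result into one provenance-complete record.

    ``run_id`` defaults to a content hash of labels, thresholds and counts, so
    identical runs produce identical records (except the timestamp) and
    re-exports deduplicate.
    """
    from . import __version__

    n_kept, n_below, n_above = result.counts
    selected = peaks.ordinal_of(peaks.selected_index) if peaks is not None else 1
    n_peaks = peaks.n_peaks if peaks is not None else 1
    if run_id is None:
        key = json.dumps(
            [
                subject,
                kidney,
                observer,
                result.thresholds.lower,
                result.thresholds.upper,
                n_kept,
                n_below,
                n_above,
                selected,
            ]
        )
        run_id = hashlib.sha1(key.encode()).hexdigest()[:12]
    return {
        "subject": subject,
        "kidney": kidney,
        "observer": observer,
        "run_id": run_id,
        "n_roi": n_kept + n_below + n_above,
        "n_kept": n_kept,
        "n_below": n_below,
        "n_above": n_above,
        "lower_threshold": float(result.thresholds.lower),
        "upper_threshold": float(result.thresholds.upper),
        "selected_peak": selected,
        "n_peaks": n_peaks,
        "bandwidth": float(bandwidth) if bandwidth is not None else float("nan"),
        "kept_ml": float(result.kept_ml),
        "removed_ml": float(result.removed_ml),
        "roi_ml": float(result.roi_ml),
        "removed_fraction": float(result.removed_fraction),
        "software_version": __version__,
        "created_utc": datetime.now(timezone.utc).isoformat(timespec="seconds"),
    }


def _create_sql() -> str:
    cols = ", ".join(
        f"{c} {_SQL_TYPES.get(c, 'REAL')}" for c in RESULT_COLUMNS
    )
    return (
        f"CREATE TABLE IF NOT EXISTS results ({cols}, "
        "UNIQUE(subject, kidney, observer, run_id))"
    )


def export_results(records: list[dict], destination: str | Path) -> int:
    """Append result records to a SQLite database or CSV table file.

    Returns the number of rows present for the exported keys afterwards.
    Destinations ending in ``.csv`` are handled as CSV; anything else is
    treated as a SQLite database file. An existing destination with different
    columns raises :class:`ExportError`.
    """
    destination = Path(destination)
    for rec in records:
        missing = set(RESULT_COLUMNS) - set(rec)
        if missing:
            raise ExportError(f"record missing fields {sorted(missing)}")
    if destination.suffix.lower() == ".csv":
        return _export_csv(records, destination)
    return _export_sqlite(records, destination)


def _export_sqlite(records: list[dict], path: Path) -> int:
    with sqlite3.connect(path) as con:
        existing = con.execute(
            "SELECT name FROM sqlite_master WHERE type='table' AND name='results'"
        ).fetchone()
        if existing:
            cols = [r[1] for r in con.execute("PRAGMA table_info(results)")]
            if tuple(cols) != RESULT_COLUMNS:
                raise ExportError(
                    f"existing results table has columns {cols}, "
                    f"expected {list(RESULT_COLUMNS)}"
                )
        else:
            con.execute(_create_sql())
        placeholders = ", ".join("?" for _ in RESULT_COLUMNS)
        con.executemany(
            f"INSERT OR IGNORE INTO results VALUES ({placeholders})",
            [tuple(rec[c] for c in RESULT_COLUMNS) for rec in records],
        )
        (count,) = con.execute("SELECT COUNT(*) FROM results").fetchone()
    return int(count)


_KEY = ["subject", "kidney", "observer", "run_id"]


def _export_csv(records: list[dict], path: Path) -> int:
    new = pd.DataFrame.from_records(records, columns=RESULT_COLUMNS)
    if path.exists():
        old = pd.read_csv(path, dtype={k: str for k in _KEY}).fillna({k: "" for k in _KEY})
        if tuple(old.columns) != RESULT_COLUMNS:
            raise ExportError(
                f"existing CSV has columns {list(old.columns)}, "
                f"expected {list(RESULT_COLUMNS)}"
            )
        merged = pd.concat([old, new], ignore_index=True)
    else:
        merged = new
    merged = merged.drop_duplicates(subset=_KEY, keep="first")
    merged.to_csv(path, index=False)
    return int(len(merged))


def read_results(path: str | Path) -> pd.DataFrame:
    """Load a results table previously written by :func:`export_results`."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        return pd.read_csv(path)
    with sqlite3.connect(path) as con:
        return pd.read_sql_query("SELECT * FROM results", con)
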