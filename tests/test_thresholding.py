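import numpy as np
import pytest

from renovol import (
    CornerNotFoundError,
    DegenerateChordError,
    IntensityPDF,
    IntensitySample,
    PeakSet,
    build_chord,
    compute_thresholds,
    corner_threshold,
    estimate_pdf,
    find_peaks,
    segment,
)
from renovol.volumetry import apply_thresholds
from renovol.io_volumes import ImageVolume, ROIMask

import oracles


def _manual_pdf(grid, density, sd, peak_index):
    sample = IntensitySample(
        values=np.array([grid[peak_index]]), n=1000,
        mean=float(grid[peak_index]), sd=sd,
    )
    pdf = IntensityPDF(grid=grid, density=density, bandwidth=1.0, sample=sample)
    peaks = PeakSet(
        peak_indices=np.array([peak_index]),
        global_index=peak_index,
        selected_index=peak_index,
    )
    return pdf, peaks


def test_build_chord_endpoint_arithmetic():
    """Peak at 300 with sd 40: endpoints snap to the grid points nearest
    260 and 340."""
    grid = np.linspace(0.0, 600.0, 601)
    density = np.exp(-0.5 * ((grid - 300.0) / 50.0) ** 2)
    pdf, peaks = _manual_pdf(grid, density, sd=40.0, peak_index=300)
    lower = build_chord(pdf, peaks, "lower")
    upper = build_chord(pdf, peaks, "upper")
    assert lower.endpoint[0] == pytest.approx(260.0)
    assert upper.endpoint[0] == pytest.approx(340.0)
    assert lower.endpoint_index == 260 and upper.endpoint_index == 340
    assert lower.peak_point == (300.0, pytest.approx(1.0))


def test_build_chord_clipping_and_degeneracy():
    grid = np.linspace(0.0, 600.0, 601)
    density = np.exp(-0.5 * ((grid - 300.0) / 50.0) ** 2)
    pdf, peaks = _manual_pdf(grid, density, sd=350.0, peak_index=300)
    assert build_chord(pdf, peaks, "lower").endpoint_index == 0  # clipped
    assert build_chord(pdf, peaks, "upper").endpoint_index == 600
    pdf2, peaks2 = _manual_pdf(grid, density, sd=0.4, peak_index=300)
    with pytest.raises(DegenerateChordError):
        build_chord(pdf2, peaks2, "lower")  # sigma below one grid step


def test_corner_unique_dip_is_found():
    """A density lying on the chord line except for one dipped point makes
    that point the corner."""
    grid = np.arange(101, dtype=float)
    density = np.full(101, 0.2)
    # linear flank from the peak at 60 (height 1.0) down to 0.2 at index 20
    flank = slice(20, 61)
    density[flank] = 0.2 + (np.arange(20, 61) - 20) * 0.02
    density[35] -= 0.05  # the single dip below the chord
    density[61:] = 0.0
    pdf, peaks = _manual_pdf(grid, density, sd=40.0, peak_index=60)
    chord = build_chord(pdf, peaks, "lower")
    threshold, diag = corner_threshold(pdf, chord)
    assert diag.corner_index == 35
    assert threshold == pytest.approx(grid[35])
    assert diag.vertical_deviation == pytest.approx(0.05)


def test_corner_matches_perpendicular_distance_oracle():
    """Production vertical-deviation corners equal an exhaustive
    point-to-line perpendicular-distance search on random mixtures."""
    rng = np.random.default_rng(42)
    for _ in range(10):
        pdf = oracles.random_mixture_pdf(rng)
        peaks = find_peaks(pdf)
        for side in ("lower", "upper"):
            chord = build_chord(pdf, peaks, side)
            _t, diag = corner_threshold(pdf, chord)
            assert diag.corner_index == oracles.corner_by_perpendicular_distance(
                pdf, chord
            )


def test_symmetric_density_gives_mirror_chords_and_thresholds():
    """For an exactly symmetric sample the two chords have equal |slope| and
    the thresholds sit symmetrically about the peak."""
    rng = np.random.default_rng(7)
    half = np.concatenate([rng.normal(0, 30, 4000), rng.normal(90, 15, 700)])
    values = np.concatenate([300.0 + half, 300.0 - half])
    s = IntensitySample.from_values(values)
    pdf = estimate_pdf(s, grid_points=1025)  # odd count centres the grid on 300
    peaks = find_peaks(pdf)
    lower_chord = build_chord(pdf, peaks, "lower")
    upper_chord = build_chord(pdf, peaks, "upper")
    assert abs(lower_chord.slope) == pytest.approx(abs(upper_chord.slope), rel=1e-9)
    pair = compute_thresholds(pdf, peaks)
    peak_x = pdf.grid[peaks.selected_index]
    assert (pair.upper - peak_x) == pytest.approx(peak_x - pair.lower, abs=pdf.step)


def test_left_shoulder_corner_brackets_between_modes():
    """Gaussian with a low-intensity shoulder: the lower corner falls between
    the two modes."""
    rng = np.random.default_rng(8)
    values = np.concatenate(
        [rng.normal(300, 30, 45_000), rng.normal(150, 20, 5_000)]
    )
    pdf = estimate_pdf(IntensitySample.from_values(values))
    peaks = find_peaks(pdf)
    pair = compute_thresholds(pdf, peaks)
    assert 150.0 < pair.lower < 300.0
    assert pair.lower < pdf.grid[peaks.selected_index] < pair.upper


def test_pure_gaussian_thresholds_remove_little():
    """On a single-Gaussian sample the corners land in the tails, so well
    under a quarter of the voxels are removed."""
    rng = np.random.default_rng(9)
    data = rng.normal(300.0, 30.0, (30, 30, 20))
    vol = ImageVolume(data=data, spacing=(1, 1, 1), affine=np.eye(4))
    roi = ROIMask(data=np.ones(data.shape, bool), reference_shape=data.shape)
    result, pdf, peaks = segment(vol, roi)
    assert result.removed_fraction < 0.25
    assert pair_brackets(result.thresholds, pdf, peaks)


def pair_brackets(pair, pdf, peaks) -> bool:
    peak_x = pdf.grid[peaks.selected_index]
    return pair.lower < peak_x < pair.upper


def test_corner_not_found_and_endpoint_fallback():
    """An exactly triangular density has no point below either chord: without
    the fallback this is a side-labelled error, with it the chord endpoint
    becomes the threshold."""
    grid = np.arange(201, dtype=float)
    density = np.maximum(0.0, 1.0 - np.abs(grid - 100.0) / 80.0)
    pdf, peaks = _manual_pdf(grid, density, sd=40.0, peak_index=100)
    with pytest.raises(CornerNotFoundError) as err:
        compute_thresholds(pdf, peaks)
    assert err.value.side == "lower"
    pair = compute_thresholds(pdf, peaks, fallback_on_missing_corner=True)
    assert pair.lower == pytest.approx(60.0)
    assert pair.upper == pytest.approx(140.0)
    assert pair.lower_diag.used_fallback and pair.upper_diag.used_fallback


def test_tail_endpoint_policy_widens_upper_threshold():
    """Anchoring chords at the PDF tails (the non-default policy) must not
    tighten the thresholds; outliers then drag the upper threshold up."""
    rng = np.random.default_rng(10)
    values = np.concatenate(
        [rng.normal(300, 30, 20_000), rng.uniform(800, 1600, 300)]  # hot outliers
    )
    pdf = estimate_pdf(IntensitySample.from_values(values))
    peaks = find_peaks(pdf)
    sigma_pair = compute_thresholds(pdf, peaks, endpoint_policy="sigma")
    tail_pair = compute_thresholds(pdf, peaks, endpoint_policy="tail")
    assert tail_pair.upper > sigma_pair.upper


def test_threshold_pipeline_affine_equivariance(small_phantom):
    """Intensity transform x -> a*x + b moves both thresholds to a*T + b
    within one grid step."""
    volume, roi, _ = small_phantom
    base, base_pdf, _ = segment(volume, roi)
    for a, b in ((2.0, 50.0), (0.75, -120.0)):
        transformed = ImageVolume(
            data=a * volume.data + b, spacing=volume.spacing, affine=volume.affine
        )
        res, pdf, _ = segment(transformed, roi)
        step = pdf.step
        assert res.thresholds.lower == pytest.approx(
            a * base.thresholds.lower + b, abs=step + 1e-9
        )
        assert res.thresholds.upper == pytest.approx(
            a * base.thresholds.upper + b, abs=step + 1e-9
        )
        assert np.array_equal(res.kept_mask, base.kept_mask) or (
            np.abs(res.counts[0] - base.counts[0]) <= 0.005 * roi.count
        )


def test_contaminant_separation_never_crosses_peak():
    """Pulling the vessel mode further from the parenchyma mode never moves
    the lower threshold across the parenchyma peak."""
    from renovol import PhantomSpec, generate_phantom

    for mean in (180.0, 140.0, 100.0, 60.0):
        spec = PhantomSpec(
            shape=(64, 64, 20),
            semi_axes=(20.0, 13.0, 7.5),
            vessels=(mean, 60.0, 0.08),
            seed=31,
        )
        volume, roi, _ = generate_phantom(spec)
        result, pdf, peaks = segment(volume, roi)
        peak_x = pdf.grid[peaks.selected_index]
        assert result.thresholds.lower < peak_x < result.thresholds.upper
        assert abs(peak_x - 300.0) < 30.0  # working peak stays the parenchyma mode
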