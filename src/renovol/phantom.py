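"""Synthetic kidney phantoms with voxel-level ground truth.

The generator emulates the data regime the thresholding method was designed
for: a T2-weighted abdominal MR volume with an ellipsoidal kidney whose
parenchyma is the predominant, characteristically-valued tissue inside a
generously drawn ROI, contaminated by dark intrarenal vessels (flow voids,
modelled as random-walk tubes) and bright central calyces/fluid (Gaussian
blobs). Contaminant intensity laws are deliberately broad — partial-volume
smearing spreads real vessel and calyx voxels over a wide range — so the ROI
intensity PDF is unimodal with shoulders, as observed in vivo, rather than
multi-modal.

The coarse manual ROI is the kidney body dilated in-plane by ``roi_margin``
voxels; the rim this adds is drawn from the parenchyma law (partial-volume
kidney margin), matching the method's documented behaviour that
parenchyma-like voxels included by a generous tracing are not removed.

All randomness flows from ``PhantomSpec.seed``; identical specs yield
bit-identical phantoms.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.stats import truncnorm

from .errors import PhantomSpecError
from .io_volumes import ImageVolume, ROIMask, voxel_volume_ml, write_mask, write_volume


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, intensity laws and contaminant load of one phantom.

    Intensity means/SDs are in arbitrary MR units on a 12-bit-like scale.
    ``vessels`` and ``calyces`` are (mean, sd, volume fraction of the ROI);
    the default fractions 0.08 + 0.05 target the ~13% removal regime observed
    for coarse kidney pre-segmentations. ``second_parenchyma`` optionally
    splits the parenchyma into two sub-modes (mean, sd, fraction of
    parenchyma voxels) to emulate the rare bimodal cortex/medulla histograms.
    """

    shape: tuple[int, int, int] = (96, 96, 28)
    spacing: tuple[float, float, float] = (1.0, 1.0, 4.4)
    parenchyma: tuple[float, float] = (300.0, 30.0)
    vessels: tuple[float, float, float] = (130.0, 95.0, 0.08)
    calyces: tuple[float, float, float] = (560.0, 150.0, 0.05)
    background: tuple[float, float] = (60.0, 20.0)
    second_parenchyma: tuple[float, float, float] | None = None
    roi_margin: int = 1
    semi_axes: tuple[float, float, float] = (32.0, 19.0, 12.6)
    seed: int = 0

    def validate(self) -> None:
        v_mean, _v_sd, v_frac = self.vessels
        c_mean, _c_sd, c_frac = self.calyces
        p_mean = self.parenchyma[0]
        if not (v_mean < p_mean < c_mean):
            raise PhantomSpecError(
                "T2 appearance requires vessel mean < parenchyma mean < calyx "
                f"mean, got {v_mean}, {p_mean}, {c_mean}"
            )
        if v_frac < 0 or c_frac < 0 or v_frac + c_frac >= 0.5:
            raise PhantomSpecError(
                f"contaminant fractions ({v_frac}, {c_frac}) must be >= 0 and "
                "sum to < 0.5 (parenchyma must dominate)"
            )
        if self.roi_margin < 0:
            raise PhantomSpecError("roi_margin must be >= 0")


@dataclass(frozen=True)
class PhantomTruth:
    """Ground-truth region masks and scalars for one phantom.

    ``true_contaminant_fraction`` is planted (vessel + calyx) voxels divided
    by ROI voxels — the same basis as the pipeline's removed fraction.
    """

    parenchyma_mask: np.ndarray
    vessel_mask: np.ndarray
    calyx_mask: np.ndarray
    true_parenchyma_ml: float
    true_contaminant_fraction: float


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, size: int
) -> np.ndarray:
    """Draw from N(mean, sd^2) truncated below at 0 (intensities stay >= 0)."""
    if size == 0:
        return np.empty(0)
    a = (0.0 - mean) / sd
    return truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size, random_state=rng)


def _ellipsoid(
    shape: tuple[int, int, int],
    center: np.ndarray,
    axes: np.ndarray,
) -> np.ndarray:
    x, y, z = np.ogrid[: shape[0], : shape[1], : shape[2]]
    return (
        ((x - center[0]) / axes[0]) ** 2
        + ((y - center[1]) / axes[1]) ** 2
        + ((z - center[2]) / axes[2]) ** 2
    ) <= 1.0


# in-plane cross, used so the coarse-ROI dilation mimics per-slice tracing
_XY_CROSS = np.zeros((3, 3, 3), dtype=bool)
_XY_CROSS[1, :, 1] = _XY_CROSS[:, 1, 1] = True


def _paint_ball(
    mask: np.ndarray, pos: np.ndarray, radius: float, allowed: np.ndarray
) -> None:
    """Set voxels within an in-plane-weighted ball of ``radius`` at ``pos``."""
    shape = mask.shape
    r = int(np.ceil(radius)) + 1
    lo = np.maximum(np.round(pos).astype(int) - r, 0)
    hi = np.minimum(np.round(pos).astype(int) + r + 1, shape)
    if np.any(lo >= hi):
        return
    x, y, z = np.ogrid[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    # z counts triple so tubes/blobs stay mostly in-plane (thick slices)
    d2 = (x - pos[0]) ** 2 + (y - pos[1]) ** 2 + (3.0 * (z - pos[2])) ** 2
    sub = (slice(lo[0], hi[0]), slice(lo[1], hi[1]), slice(lo[2], hi[2]))
    mask[sub] |= (d2 <= radius**2) & allowed[sub]


def _grow_calyces(
    rng: np.random.Generator,
    body: np.ndarray,
    center: np.ndarray,
    axes: np.ndarray,
    target: int,
) -> np.ndarray:
    """Central Gaussian-blob cluster occupying ``target`` voxels of the body."""
    mask = np.zeros(body.shape, dtype=bool)
    for _ in range(2000):
        if mask.sum() >= target:
            break
        offset = rng.normal(0.0, 0.18, 3) * axes
        radii = np.array(
            [rng.uniform(2.0, 4.5), rng.uniform(2.0, 4.5), rng.uniform(0.8, 1.8)]
        )
        blob = _ellipsoid(body.shape, center + offset, radii)
        mask |= blob & body
    else:
        raise PhantomSpecError("could not place the requested calyx volume")
    return mask


def _grow_vessels(
    rng: np.random.Generator,
    body: np.ndarray,
    center: np.ndarray,
    axes: np.ndarray,
    target: int,
    forbidden: np.ndarray,
) -> np.ndarray:
    """Random-walk tubes (radius 1-2 voxels) occupying ``target`` voxels."""
    mask = np.zeros(body.shape, dtype=bool)
    allowed = body & ~forbidden
    for _walk in range(4000):
        if mask.sum() >= target:
            break
        pos = center + rng.uniform(-0.5, 0.5, 3) * axes
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        radius = rng.uniform(1.0, 2.0)
        for _step in range(60):
            _paint_ball(mask, pos, radius, allowed)
            direction = direction + rng.normal(0.0, 0.35, 3)
            direction /= np.linalg.norm(direction)
            pos = pos + direction * 1.2 * np.array([1.0, 1.0, 0.35])
            rel = (pos - center) / axes
            if (rel**2).sum() > 1.0:
                break
            if mask.sum() >= target:
                break
    else:
        raise PhantomSpecError("could not place the requested vessel volume")
    return mask


def generate_phantom(spec: PhantomSpec) -> tuple[ImageVolume, ROIMask, PhantomTruth]:
    """Build one phantom: image volume, coarse ROI and ground truth."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    shape = tuple(int(s) for s in spec.shape)

    # kidney body: jittered ellipsoid, kept clear of the grid boundary
    center = np.array(shape, dtype=float) / 2.0 - 0.5
    center[:2] += rng.uniform(-2.0, 2.0, 2)
    axes = np.asarray(spec.semi_axes, dtype=float) * rng.uniform(0.92, 1.08, 3)
    limit = np.array(shape, dtype=float) / 2.0 - spec.roi_margin - 1.5
    axes = np.minimum(axes, limit)
    if np.any(axes < 3):
        raise PhantomSpecError(f"kidney semi-axes {axes} too small for grid {shape}")
    body = _ellipsoid(shape, center, axes)

    roi_arr = body.copy()
    if spec.roi_margin > 0:
        roi_arr = ndimage.binary_dilation(
            body, structure=_XY_CROSS, iterations=spec.roi_margin
        )
    n_roi = int(roi_arr.sum())
    n_body = int(body.sum())

    v_mean, v_sd, v_frac = spec.vessels
    c_mean, c_sd, c_frac = spec.calyces
    v_target = int(round(v_frac * n_roi))
    c_target = int(round(c_frac * n_roi))
    if v_target + c_target > 0.5 * n_body:
        raise PhantomSpecError(
            f"contaminant targets ({v_target} + {c_target} voxels) exceed half "
            f"the kidney interior ({n_body} voxels)"
        )

    calyx = (
        _grow_calyces(rng, body, center, axes, c_target)
        if c_target
        else np.zeros(shape, dtype=bool)
    )
    vessel = (
        _grow_vessels(rng, body, center, axes, v_target, forbidden=calyx)
        if v_target
        else np.zeros(shape, dtype=bool)
    )
    parenchyma = body & ~calyx & ~vessel
    rim = roi_arr & ~body

    img = np.empty(shape, dtype=float)
    outside = ~roi_arr
    img[outside] = _truncated_normal(rng, *spec.background, int(outside.sum()))
    p_mean, p_sd = spec.parenchyma
    for region in (parenchyma, rim):
        img[region] = _truncated_normal(rng, p_mean, p_sd, int(region.sum()))
    if spec.second_parenchyma is not None:
        m2, s2, f2 = spec.second_parenchyma
        par_idx = np.flatnonzero(parenchyma.ravel())
        pick = rng.choice(par_idx, size=int(round(f2 * par_idx.size)), replace=False)
        img.ravel()[pick] = _truncated_normal(rng, m2, s2, pick.size)
    img[vessel] = _truncated_normal(rng, v_mean, v_sd, int(vessel.sum()))
    img[calyx] = _truncated_normal(rng, c_mean, c_sd, int(calyx.sum()))

    affine = np.diag([*spec.spacing, 1.0])
    volume = ImageVolume(
        data=img, spacing=spec.spacing, affine=affine, source_path="<phantom>"
    )
    roi = ROIMask(data=roi_arr, reference_shape=shape)
    truth = PhantomTruth(
        parenchyma_mask=parenchyma,
        vessel_mask=vessel,
        calyx_mask=calyx,
        true_parenchyma_ml=int(parenchyma.sum()) * voxel_volume_ml(volume),
        true_contaminant_fraction=(int(vessel.sum()) + int(calyx.sum())) / n_roi,
    )
    return volume, roi, truth


def bimodal_spec(seed: int = 0, **overrides) -> PhantomSpec:
    """A phantom whose parenchyma splits into two close intensity sub-modes.

    The two modes (290 and 335, component SD 15, 50/50 split) sit 45 units
    apart — less than twice the combined parenchyma SD (~27) — producing the
    two-maxima PDFs occasionally seen in vivo. The contaminant load is lighter
    and smeared even wider than the default so that exactly the two
    parenchyma maxima register as peaks.
    """
    return PhantomSpec(
        parenchyma=(290.0, 15.0),
        second_parenchyma=(335.0, 15.0, 0.5),
        vessels=(150.0, 120.0, 0.05),
        calyces=(560.0, 170.0, 0.04),
        seed=seed,
        **overrides,
    )


def generate_batch(
    n: int, base_seed: int = 0, spec: PhantomSpec | None = None
) -> list[tuple[ImageVolume, ROIMask, PhantomTruth]]:
    """Generate ``n`` phantoms with consecutive seeds from ``base_seed``."""
    template = spec if spec is not None else PhantomSpec()
    return [
        generate_phantom(replace(template, seed=(base_seed + i) % 2**31))
        for i in range(n)
    ]


def write_phantom(
    volume: ImageVolume,
    roi: ROIMask,
    truth: PhantomTruth,
    spec: PhantomSpec,
    outdir: str | Path,
    stem: str = "phantom",
) -> dict:
    """Write phantom NIfTI files plus a JSON manifest; returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_volume(volume, outdir / f"{stem}_image.nii.gz")
    write_mask(roi.data, volume, outdir / f"{stem}_roi.nii.gz")
    write_mask(truth.parenchyma_mask, volume, outdir / f"{stem}_parenchyma.nii.gz")
    write_mask(truth.vessel_mask, volume, outdir / f"{stem}_vessels.nii.gz")
    write_mask(truth.calyx_mask, volume, outdir / f"{stem}_calyces.nii.gz")
    manifest = {
        "stem": stem,
        "spec": asdict(spec),
        "roi_voxels": roi.count,
        "parenchyma_voxels": int(truth.parenchyma_mask.sum()),
        "vessel_voxels": int(truth.vessel_mask.sum()),
        "calyx_voxels": int(truth.calyx_mask.sum()),
        "true_parenchyma_ml": truth.true_parenchyma_ml,
        "true_contaminant_fraction": truth.true_contaminant_fraction,
    }
    with open(outdir / f"{stem}_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
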