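import dataclasses

import nibabel as nib
import numpy as np
import pytest

from renovol import PhantomSpec, generate_phantom, segment


def write_nifti(path, data, spacing=(1.0, 1.0, 1.0), dtype=None):
    """Write a small NIfTI file for I/O tests."""
    arr = np.asarray(data, dtype=dtype) if dtype else np.asarray(data)
    affine = np.diag([*spacing[:3], 1.0])
    img = nib.Nifti1Image(arr, affine)
    zooms = (tuple(spacing) + (1.0,) * arr.ndim)[: arr.ndim]
    img.header.set_zooms(zooms)
    nib.save(img, str(path))
    return path


#: a reduced-grid phantom spec for fast unit tests (~9k-voxel kidney)
SMALL_SPEC = PhantomSpec(
    shape=(64, 64, 20), semi_axes=(20.0, 13.0, 7.5), seed=11
)


@pytest.fixture(scope="session")
def small_phantom():
    """One small seeded phantom: (volume, roi, truth)."""
    return generate_phantom(SMALL_SPEC)


@pytest.fixture(scope="session")
def small_segmentation(small_phantom):
    """Full pipeline output on the small phantom."""
    volume, roi, _truth = small_phantom
    return segment(volume, roi)


@pytest.fixture(scope="session")
def phantom_batch():
    """Twenty seeded full-size phantoms in the ~13% contaminant regime,
    each with its end-to-end segmentation."""
    out = []
    for i in range(20):
        spec = dataclasses.replace(PhantomSpec(), seed=100 + i)
        volume, roi, truth = generate_phantom(spec)
        result, pdf, peaks = segment(volume, roi)
        out.append((volume, roi, truth, result, pdf, peaks))
    return out
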