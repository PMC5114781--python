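"""Independent reference computations used by the test suite.

These routines deliberately avoid the package's own code paths: the KDE
oracle evaluates the kernel sum point by point through scipy.stats.norm, and
the corner oracle measures explicit point-to-line perpendicular distances
instead of the production vertical-deviation shortcut.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import norm

from renovol import IntensitySample, estimate_pdf


def kde_pointwise(values: np.ndarray, bandwidth: float, grid: np.ndarray) -> np.ndarray:
    """Direct kernel-sum density, one grid point at a time."""
    values = np.asarray(values, dtype=float)
    out = np.empty(grid.size)
    for j, x in enumerate(grid):
        out[j] = norm.pdf((x - values) / bandwidth).sum() / (values.size * bandwidth)
    return out


def corner_by_perpendicular_distance(pdf, chord) -> int:
    """Exhaustive point-to-line perpendicular-distance corner search.

    Candidates: grid points on the chord's side of the peak lying strictly
    below the (extended) chord line; ties resolve to the candidate farthest
    from the peak.
    """
    grid, density = pdf.grid, pdf.density
    (xp, yp), (xe, ye) = chord.peak_point, chord.endpoint
    p_idx = chord.peak_index
    if chord.side == "lower":
        cand = np.arange(0, p_idx)
    else:
        cand = np.arange(p_idx + 1, grid.size)
    x, d = grid[cand], density[cand]
    line_y = yp + (ye - yp) / (xe - xp) * (x - xp)
    below = d < line_y
    assert below.any(), "oracle found no candidate below the chord"
    # |cross product| / |chord direction|
    dist = np.abs((xe - xp) * (d - yp) - (x - xp) * (ye - yp)) / np.hypot(
        xe - xp, ye - yp
    )
    dist = np.where(below, dist, -np.inf)
    best = dist.max()
    ties = cand[dist == best]
    return int(ties[0]) if chord.side == "lower" else int(ties[-1])


def random_mixture_sample(rng: np.random.Generator, n: int = 3000) -> IntensitySample:
    """A 1-3 component Gaussian-mixture intensity sample on an MR-like scale."""
    k = rng.integers(1, 4)
    weights = rng.dirichlet(np.ones(k) * 2.0)
    weights = 0.5 * weights + 0.5 / k  # keep every component non-negligible
    weights /= weights.sum()
    means = rng.uniform(100.0, 900.0, k)
    sds = rng.uniform(15.0, 80.0, k)
    counts = rng.multinomial(n, weights)
    parts = [
        rng.normal(m, s, c) for m, s, c in zip(means, sds, counts) if c > 0
    ]
    return IntensitySample.from_values(np.concatenate(parts))


def random_mixture_pdf(rng: np.random.Generator, n: int = 3000):
    return estimate_pdf(random_mixture_sample(rng, n))
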