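"""Observer-agreement statistics for paired kidney-volume result sets.

Implements the classical toolkit used to validate semiautomatic volumetry
against repeated or reference measurements: the two-tailed paired t test with
its 95% CI, the mean absolute difference (MAD), Pearson's product-moment
correlation with a Fisher-z 95% CI, and Bland–Altman bias with 1.96-SD limits
of agreement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateSampleError

#: limits-of-agreement multiplier (the conventional 95% normal range)
LOA_MULTIPLIER = 1.96


@dataclass(frozen=True)
class PairedVolumes:
    """Per-kidney paired volumes (ml) from two observers/sessions/methods."""

    labels: tuple[str, ...]
    a: np.ndarray
    b: np.ndarray

    @classmethod
    def from_arrays(cls, a, b, labels=None) -> "PairedVolumes":
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        if a.ndim != 1 or a.shape != b.shape:
            raise DegenerateSampleError(
                f"paired arrays must be equal-length 1-D, got {a.shape} vs {b.shape}"
            )
        if a.size < 3:
            raise DegenerateSampleError(f"need n >= 3 pairs, got {a.size}")
        if not (np.isfinite(a).all() and np.isfinite(b).all()):
            raise DegenerateSampleError("paired volumes contain missing values")
        if labels is None:
            labels = tuple(str(i) for i in range(a.size))
        return cls(labels=tuple(labels), a=a, b=b)

    @property
    def n(self) -> int:
        return int(self.a.size)


@dataclass(frozen=True)
class PairedStats:
    mean_diff: float
    ci95: tuple[float, float]
    t_stat: float
    p_value: float
    mad: float


@dataclass(frozen=True)
class BlandAltman:
    bias: float
    loa_lo: float
    loa_hi: float
    means: np.ndarray
    diffs: np.ndarray


@dataclass(frozen=True)
class AgreementReport:
    """All agreement statistics for one pair of volume sets."""

    n: int
    mean_diff: float
    ci95: tuple[float, float]
    t_stat: float
    p_value: float
    mad: float
    pearson_r: float
    pearson_ci95: tuple[float, float]
    bland_altman: BlandAltman


def paired_stats(pairs: PairedVolumes) -> PairedStats:
    """Two-tailed paired t test on d = a - b, with 95% CI and MAD.

    t = mean(d) / (sd(d) / sqrt(n)), df = n - 1; the CI uses the t quantile.
    """
    d = pairs.a - pairs.b
    n = pairs.n
    sd = float(d.std(ddof=1))
    if sd == 0:
        raise DegenerateSampleError("zero-variance differences; t test undefined")
    md = float(d.mean())
    se = sd / np.sqrt(n)
    t_stat = md / se
    p = 2.0 * float(stats.t.sf(abs(t_stat), df=n - 1))
    q = float(stats.t.ppf(0.975, df=n - 1))
    return PairedStats(
        mean_diff=md,
        ci95=(md - q * se, md + q * se),
        t_stat=float(t_stat),
        p_value=p,
        mad=float(np.abs(d).mean()),
    )


def correlation(pairs: PairedVolumes) -> tuple[float, tuple[float, float]]:
    """Pearson r with a Fisher-z 95% confidence interval."""
    a, b = pairs.a, pairs.b
    if a.std() == 0 or b.std() == 0:
        raise DegenerateSampleError("constant array; correlation undefined")
    am, bm = a - a.mean(), b - b.mean()
    r = float((am * bm).sum() / np.sqrt((am**2).sum() * (bm**2).sum()))
    r = float(np.clip(r, -1.0, 1.0))
    if pairs.n <= 3 or abs(r) == 1.0:
        return r, (r, r)
    z = np.arctanh(r)
    zq = float(stats.norm.ppf(0.975))
    half = zq / np.sqrt(pairs.n - 3)
    return r, (float(np.tanh(z - half)), float(np.tanh(z + half)))


def bland_altman(pairs: PairedVolumes) -> BlandAltman:
    """Bland–Altman bias and limits of agreement bias +/- 1.96 * sd(d)."""
    d = pairs.a - pairs.b
    bias = float(d.mean())
    sd = float(d.std(ddof=1)) if pairs.n > 1 else 0.0
    half = LOA_MULTIPLIER * sd
    return BlandAltman(
        bias=bias,
        loa_lo=bias - half,
        loa_hi=bias + half,
        means=(pairs.a + pairs.b) / 2.0,
        diffs=d,
    )


def compile_report(pairs: PairedVolumes) -> AgreementReport:
    """Run all agreement statistics on one paired volume set."""
    ps = paired_stats(pairs)
    r, r_ci = correlation(pairs)
    ba = bland_altman(pairs)
    return AgreementReport(
        n=pairs.n,
        mean_diff=ps.mean_diff,
        ci95=ps.ci95,
        t_stat=ps.t_stat,
        p_value=ps.p_value,
        mad=ps.mad,
        pearson_r=r,
        pearson_ci95=r_ci,
        bland_altman=ba,
    )


def bland_altman_plot(pairs: PairedVolumes, path) -> None:
    """Save the Bland–Altman scatter (mean vs difference) with bias/LoA lines."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ba = bland_altman(pairs)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(ba.means, ba.diffs, s=18, alpha=0.8)
    for y, style in ((ba.bias, "-"), (ba.loa_lo, "--"), (ba.loa_hi, "--")):
        ax.axhline(y, linestyle=style, color="k", linewidth=1)
    ax.set_xlabel("mean of paired volumes (ml)")
    ax.set_ylabel("difference (ml)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
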