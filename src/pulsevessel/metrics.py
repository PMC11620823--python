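"""Segmentation performance and reproducibility statistics.

Covers the overlap metrics used against ground truth (Dice, percent
overlap, volumes) and the repeated-scan reproducibility battery:
intraclass correlation ICC(A,1) — two-way model, single rater, absolute
agreement — total-least-squares regression, Pearson correlation,
Bland–Altman limits of agreement and the paired t-test, computed for
every unordered pair of repeated scans.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import PulseVesselError
from .io import Mask3D

__all__ = [
    "AgreementReport",
    "dice",
    "percent_overlap",
    "volume_cm3",
    "icc_absolute_agreement",
    "tls_regression",
    "bland_altman",
    "pairwise_agreement",
]


@dataclass
class AgreementReport:
    """Agreement between two series of repeated segmentation volumes.

    The difference is computed as x - y (first argument minus second),
    matching a Bland-Altman plot whose difference axis is "x-axis minus
    y-axis".  Limits of agreement are mean_diff ± 1.96 s.d.
    """

    pearson_r: float
    tls_slope: float
    tls_intercept: float
    mean_diff: float
    diff_sd: float
    loa_low: float
    loa_high: float
    paired_t_p: float

    def to_dict(self) -> dict:
        return asdict(self)


def _as_bool(mask: "Mask3D | np.ndarray") -> np.ndarray:
    if isinstance(mask, Mask3D):
        return mask.data
    return np.asarray(mask).astype(bool)


def dice(x: "Mask3D | np.ndarray", y: "Mask3D | np.ndarray") -> float:
    """Dice similarity 2|X∩Y| / (|X| + |Y|) of two binary masks."""
    xa, ya = _as_bool(x), _as_bool(y)
    if xa.shape != ya.shape:
        raise PulseVesselError(f"mask grids differ: {xa.shape} vs {ya.shape}")
    nx, ny = int(xa.sum()), int(ya.sum())
    if nx + ny == 0:
        raise PulseVesselError("Dice undefined: both masks are empty")
    return 2.0 * int((xa & ya).sum()) / (nx + ny)


def percent_overlap(
    seg: "Mask3D | np.ndarray",
    ref: "Mask3D | np.ndarray",
    semantics: str = "intersection",
) -> float:
    """Percent overlap of a tested segmentation against a reference.

    ``semantics='intersection'`` (default) reports |X∩Y| / |Y| × 100 —
    how much of the reference the tested segmentation covers;
    ``semantics='size_ratio'`` reports |X| / |Y| × 100, the raw voxel
    count ratio.  Swapping the arguments gives the complementary reading,
    so both orderings are usually reported.
    """
    sa, ra = _as_bool(seg), _as_bool(ref)
    if sa.shape != ra.shape:
        raise PulseVesselError(f"mask grids differ: {sa.shape} vs {ra.shape}")
    n_ref = int(ra.sum())
    if n_ref == 0:
        raise PulseVesselError("percent overlap undefined: empty reference")
    if semantics == "intersection":
        return 100.0 * int((sa & ra).sum()) / n_ref
    if semantics == "size_ratio":
        return 100.0 * int(sa.sum()) / n_ref
    raise PulseVesselError(f"unknown overlap semantics {semantics!r}")


def volume_cm3(mask: "Mask3D | np.ndarray", voxel_dims) -> float:
    """Mask volume in cm³: voxel count × voxel volume (mm³) / 1000."""
    data = _as_bool(mask)
    return float(data.sum()) * float(np.prod(np.asarray(voxel_dims, float))) / 1000.0


def icc_absolute_agreement(
    table: "pd.DataFrame | np.ndarray", ci: float = 0.95
) -> tuple[float, float, float, float]:
    """ICC(A,1): two-way model, single rater, absolute agreement.

    ``table`` is subjects × repeated measurements (no missing cells).
    Returns ``(icc, ci_low, ci_high, p)``.  The estimate comes from the
    two-way ANOVA mean squares,

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE)),

    with the confidence interval from the McGraw & Wong F-based interval
    and the p-value from F = MSR/MSE against ICC = 0.  A table with no
    between-subject variance yields ICC ≤ 0, which is reported, not
    raised.
    """
    x = np.asarray(table, dtype=float)
    if x.ndim != 2:
        raise PulseVesselError("volume table must be 2D (subjects x scans)")
    if np.any(~np.isfinite(x)):
        raise PulseVesselError("volume table contains missing cells")
    n, k = x.shape
    if n < 2 or k < 2:
        raise PulseVesselError("need at least 2 subjects and 2 scans")

    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sse = np.sum((x - row_means[:, None] - col_means[None, :] + grand) ** 2)
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    icc = (msr - mse) / denom if denom != 0 else 0.0

    # p-value against ICC = 0
    if mse > 0:
        f_stat = msr / mse
        p = float(stats.f.sf(f_stat, n - 1, (n - 1) * (k - 1)))
    else:
        p = 0.0 if msr > 0 else 1.0

    # McGraw & Wong confidence interval for ICC(A,1)
    alpha = 1.0 - ci
    a = (k * icc) / (n * (1.0 - icc)) if icc < 1 else np.inf
    b = 1.0 + (k * icc * (n - 1)) / (n * (1.0 - icc)) if icc < 1 else np.inf
    if np.isfinite(a) and mse > 0:
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        )
        f_l = stats.f.ppf(1.0 - alpha / 2.0, n - 1, v)
        f_u = stats.f.ppf(1.0 - alpha / 2.0, v, n - 1)
        ci_low = n * (msr - f_l * mse) / (
            f_l * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        ci_high = n * (f_u * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f_u * msr
        )
    else:
        ci_low, ci_high = icc, icc
    return float(icc), float(ci_low), float(ci_high), p


def tls_regression(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Total-least-squares (orthogonal) regression line through (x, y).

    The slope is taken from the principal eigenvector of the centered
    covariance matrix (Deming regression with error-variance ratio 1),
    the intercept from the centroid.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise PulseVesselError("need at least 3 paired points")
    xc, yc = x - x.mean(), y - y.mean()
    cov = np.cov(np.vstack([xc, yc]), ddof=1)
    if np.allclose(cov, 0):
        raise PulseVesselError("all points identical; TLS line undefined")
    eigvals, eigvecs = np.linalg.eigh(cov)
    v = eigvecs[:, np.argmax(eigvals)]
    if v[0] == 0:
        raise PulseVesselError("TLS line is vertical; slope undefined")
    slope = v[1] / v[0]
    intercept = y.mean() - slope * x.mean()
    return float(slope), float(intercept)


def bland_altman(x: np.ndarray, y: np.ndarray) -> AgreementReport:
    """Agreement battery between two paired volume series.

    Differences are x - y.  With identical inputs the paired t-test is
    reported as p = 1 (perfect agreement) rather than NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise PulseVesselError("paired series must have equal length")
    if x.size < 2:
        raise PulseVesselError("need at least 2 pairs")
    d = x - y
    mean_diff = float(d.mean())
    diff_sd = float(d.std(ddof=1))
    if diff_sd == 0:
        p = 1.0 if mean_diff == 0 else 0.0
    else:
        p = float(stats.ttest_rel(x, y).pvalue)
    if np.std(x) == 0 or np.std(y) == 0:
        r = float("nan")
    else:
        r = float(stats.pearsonr(x, y).statistic)
    slope, intercept = tls_regression(x, y) if x.size >= 3 else (float("nan"),) * 2
    return AgreementReport(
        pearson_r=r,
        tls_slope=slope,
        tls_intercept=intercept,
        mean_diff=mean_diff,
        diff_sd=diff_sd,
        loa_low=mean_diff - 1.96 * diff_sd,
        loa_high=mean_diff + 1.96 * diff_sd,
        paired_t_p=p,
    )


def pairwise_agreement(table: pd.DataFrame) -> dict[tuple[str, str], AgreementReport]:
    """Agreement reports for every unordered pair of repeated scans.

    ``table`` is subjects × scans (e.g. four repeated scans give six
    comparisons).  The difference convention in each report is
    first-named scan minus second-named scan.
    """
    table = pd.DataFrame(table)
    out: dict[tuple[str, str], AgreementReport] = {}
    for a, b in combinations(table.columns, 2):
        out[(a, b)] = bland_altman(table[a].to_numpy(), table[b].to_numpy())
    return out
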