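"""Agreement statistics for segmentation and biometry evaluation.

Dice overlap, absolute/relative volume difference and the intraclass
correlation coefficient ICC(2,1) — two-way random effects, absolute
agreement, single measurement — the standard statistic for agreement
between raters or between a manual and an automated method.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import LabelVolume

__all__ = ["AgreementReport", "dice_score", "volume_difference", "icc"]


@dataclass
class AgreementReport:
    dice: dict[int, float]
    abs_volume_diff_mm3: dict[int, float]
    rel_volume_diff_pct: dict[int, float]


def _check_same_grid(a: LabelVolume, b: LabelVolume) -> None:
    if a.shape != b.shape or not np.allclose(a.affine, b.affine, atol=1e-5):
        raise ValueError("volumes are on different grids")


def dice_score(a: LabelVolume, b: LabelVolume, label: int) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); 1.0 when both masks are empty."""
    _check_same_grid(a, b)
    ma = a.voxels == label
    mb = b.voxels == label
    denom = int(ma.sum()) + int(mb.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((ma & mb).sum()) / denom


def volume_difference(
    a: LabelVolume, b: LabelVolume, label: int
) -> tuple[float, float]:
    """(absolute mm^3, relative %) volume difference, referenced to ``a``.

    The first argument is the reference (ground-truth / refined) volume.
    Both empty -> (0, 0); reference empty with prediction non-empty -> the
    relative difference is undefined and returned as ``nan`` with a warning.
    """
    _check_same_grid(a, b)
    va = float((a.voxels == label).sum()) * a.voxel_volume_mm3()
    vb = float((b.voxels == label).sum()) * b.voxel_volume_mm3()
    absolute = abs(va - vb)
    if va == 0.0:
        if vb == 0.0:
            return 0.0, 0.0
        warnings.warn("reference volume is 0: relative difference undefined")
        return absolute, float("nan")
    return absolute, 100.0 * absolute / va


def icc(measurements: np.ndarray) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    ``measurements`` is an (n cases x k raters) matrix with no missing
    cells.  Uses the classical mean-squares decomposition:

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    where MSR, MSC, MSE are the rows (cases), columns (raters) and residual
    mean squares.  Degenerate all-equal data has no variance to apportion;
    by convention it is returned as perfect agreement (1.0) with a warning.
    """
    x = np.asarray(measurements, dtype=float)
    if x.ndim != 2 or x.shape[0] < 3 or x.shape[1] < 2:
        raise ValueError("need >= 3 cases and >= 2 raters")
    if not np.all(np.isfinite(x)):
        raise ValueError("missing or non-finite cells")
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sst = np.sum((x - grand) ** 2)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if abs(denom) < 1e-30:
        warnings.warn("zero total variance: ICC defined as 1.0")
        return 1.0
    return float((msr - mse) / denom)
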