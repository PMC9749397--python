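"""Synthesis-accuracy metrics: PSNR, RD%, Abs%, regional scores, joint fit.

All three headline metrics are invariant to joint positive rescaling of the
true and synthetic volumes (and hence to the PET normalization scheme):

* PSNR = 10 log10(MAX^2 / MSE), MAX = max of the true image within the
  brain mask, MSE over mask voxels — higher is better;
* RD%  = 100 * mean((yhat - y) / y): signed bias, positive when the
  synthetic image overestimates true uptake;
* Abs% = 100 * mean(|yhat - y| / y): average deviation magnitude.

The relative metrics exclude voxels whose true uptake falls below a small
floor (default 1% of the within-mask mean) to avoid near-zero-denominator
blowups in CSF.  The joint fit is ordinary least squares of synthetic on
true uptake with R^2 the squared Pearson correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .volume import Volume

__all__ = [
    "MetricsReport",
    "psnr",
    "rd_percent",
    "abs_percent",
    "regional_metrics",
    "joint_fit",
    "denormalize",
    "evaluate_pair",
]

#: default relative-metric denominator floor, as a fraction of mask-mean(y)
FLOOR_FRACTION = 0.01


def _masked(y: Volume | np.ndarray, yhat, mask) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y.data if isinstance(y, Volume) else y, dtype=float)
    yhat = np.asarray(yhat.data if isinstance(yhat, Volume) else yhat, dtype=float)
    m = np.asarray(mask.data if isinstance(mask, Volume) else mask) > 0
    if not m.any():
        raise ValueError("empty mask")
    if y.shape != yhat.shape or y.shape != m.shape:
        raise ValueError("volumes and mask must share one shape")
    return y[m], yhat[m]


def psnr(y, yhat, mask) -> float:
    """Peak signal-to-noise ratio in dB within the mask.

    The peak is the maximum of the true image over the mask, which makes the
    metric covariant with scale in numerator and denominator and therefore
    invariant to joint rescaling.
    """
    yv, yh = _masked(y, yhat, mask)
    mse = float(np.mean((yv - yh) ** 2))
    if mse == 0:
        raise ValueError("identical volumes: PSNR is infinite")
    peak = float(yv.max())
    return float(10.0 * np.log10(peak**2 / mse))


def _eligible(yv, yh, floor):
    if floor is None:
        floor = FLOOR_FRACTION * float(yv.mean())
    keep = yv > floor
    if not keep.any():
        raise ValueError("no voxels above the relative-metric floor")
    return yv[keep], yh[keep]


def rd_percent(y, yhat, mask, floor: float | None = None) -> float:
    """Signed mean relative %-difference (bias); >0 = overestimation."""
    yv, yh = _eligible(*_masked(y, yhat, mask), floor)
    return float(100.0 * np.mean((yh - yv) / yv))


def abs_percent(y, yhat, mask, floor: float | None = None) -> float:
    """Mean absolute relative %-difference (deviation magnitude)."""
    yv, yh = _eligible(*_masked(y, yhat, mask), floor)
    return float(100.0 * np.mean(np.abs(yh - yv) / yv))


def regional_metrics(
    y: Volume, yhat: Volume, atlas: Volume, regions: list[int] | None = None,
    floor: float | None = None,
) -> pd.DataFrame:
    """RD% and Abs% restricted to each atlas label's voxels."""
    labels = np.asarray(atlas.data).astype(int)
    if labels.shape != y.shape:
        raise ValueError("atlas grid does not match the volumes")
    present = sorted(np.unique(labels[labels > 0]).tolist())
    if regions is None:
        regions = present
    rows = []
    for label in regions:
        if label not in present:
            raise ValueError(f"atlas label {label} not present")
        m = labels == label
        rows.append(
            {
                "region": int(label),
                "rd_pct": rd_percent(y, yhat, y.with_data(m), floor),
                "abs_pct": abs_percent(y, yhat, y.with_data(m), floor),
                "n_voxels": int(m.sum()),
            }
        )
    return pd.DataFrame(rows)


def joint_fit(y, yhat, mask) -> tuple[float, float, float]:
    """OLS fit of synthetic on true uptake: (slope, intercept, R^2)."""
    yv, yh = _masked(y, yhat, mask)
    if np.unique(yv).size < 2:
        raise ValueError("degenerate true-uptake variance")
    res = stats.linregress(yv, yh)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def denormalize(vol: Volume, constant: float) -> Volume:
    """Map a unit-normalized volume back to original uptake units (MBq/ml)."""
    if constant <= 0:
        raise ValueError("normalization constant must be > 0")
    return vol.with_data(vol.data * constant)


@dataclass
class MetricsReport:
    psnr: float
    rd_pct: float
    abs_pct: float
    fit_slope: float
    fit_intercept: float
    fit_r2: float
    n_voxels: int
    per_region: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        d = {
            "psnr": self.psnr,
            "rd_pct": self.rd_pct,
            "abs_pct": self.abs_pct,
            "fit_slope": self.fit_slope,
            "fit_intercept": self.fit_intercept,
            "fit_r2": self.fit_r2,
            "n_voxels": self.n_voxels,
        }
        if self.per_region is not None:
            d["per_region"] = self.per_region.to_dict(orient="records")
        return d


def evaluate_pair(
    y: Volume, yhat: Volume, mask: Volume, atlas: Volume | None = None,
    floor: float | None = None,
) -> MetricsReport:
    """Whole-brain + optional per-region accuracy of one synthetic volume."""
    m = np.asarray(mask.data) > 0
    return MetricsReport(
        psnr=psnr(y, yhat, mask),
        rd_pct=rd_percent(y, yhat, mask, floor),
        abs_pct=abs_percent(y, yhat, mask, floor),
        fit_slope=(fit := joint_fit(y, yhat, mask))[0],
        fit_intercept=fit[1],
        fit_r2=fit[2],
        n_voxels=int(m.sum()),
        per_region=regional_metrics(y, yhat, atlas, floor=floor) if atlas is not None else None,
    )
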