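"""Empirical-line reflectance calibration and validity masking.

Raw digital numbers (DN) from a pushbroom imager are converted to
surface reflectance with the empirical-line method: for each band, an
ordinary-least-squares line ``reflectance = gain * DN + offset`` is
fitted against ground targets of known reflectance, then applied to the
whole grid. Slightly out-of-range results (below 0 or above 1) are
clipped rather than rejected — routine for satellite DNs — and the clip
count is logged. Crop/non-crop masks are boolean grids derived from a
categorical classification layer.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import CalibrationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LineCalibration:
    """Per-band affine DN -> reflectance calibration.

    ``gain`` is reflectance per DN, ``offset`` reflectance;
    ``residual_rmse`` is the per-band RMSE of the fit at the targets.
    """

    gain: dict[str, float]
    offset: dict[str, float]
    n_targets: dict[str, int]
    residual_rmse: dict[str, float]

    @property
    def bands(self) -> list[str]:
        return list(self.gain)


def calibrate_empirical_line(pairs: pd.DataFrame) -> LineCalibration:
    """Fit the empirical line per band from (DN, reflectance) target pairs.

    Parameters
    ----------
    pairs : DataFrame
        Columns ``band, dn, reflectance``; at least two pairs with
        distinct DN per band.

    Raises
    ------
    CalibrationError
        Fewer than two pairs, identical DN values (singular fit), or a
        zero fitted gain (reflectance does not respond to DN).
    """
    required = {"band", "dn", "reflectance"}
    if not required.issubset(pairs.columns):
        raise CalibrationError(f"pairs must have columns {sorted(required)}")
    gain, offset, n_targets, rmse = {}, {}, {}, {}
    for band, grp in pairs.groupby("band", sort=False):
        dn = grp["dn"].to_numpy(dtype=float)
        refl = grp["reflectance"].to_numpy(dtype=float)
        if dn.size < 2:
            raise CalibrationError(f"band {band!r}: need >= 2 calibration pairs, got {dn.size}")
        if np.ptp(dn) == 0:
            raise CalibrationError(f"band {band!r}: all DN values identical, singular fit")
        design = np.column_stack([dn, np.ones_like(dn)])
        (g, b), *_ = np.linalg.lstsq(design, refl, rcond=None)
        # a gain whose reflectance change across the full DN range is
        # negligible means the band does not respond to DN at all
        if not np.isfinite(g) or abs(g) * np.ptp(dn) < 1e-10:
            raise CalibrationError(f"band {band!r}: zero or non-finite gain {g}")
        resid = refl - (g * dn + b)
        gain[band], offset[band] = float(g), float(b)
        n_targets[band] = int(dn.size)
        rmse[band] = float(np.sqrt(np.mean(resid**2)))
    if not gain:
        raise CalibrationError("no calibration pairs supplied")
    return LineCalibration(gain=gain, offset=offset, n_targets=n_targets, residual_rmse=rmse)


def apply_calibration(
    dn_grid: np.ndarray, cal: LineCalibration, band: str
) -> np.ndarray | np.ma.MaskedArray:
    """Map a DN grid to reflectance; clips to [0, 1] and propagates masks.

    Accepts a plain array or a masked array; returns the same kind.
    The number of clipped cells is logged at INFO level.
    """
    if band not in cal.gain:
        raise CalibrationError(f"no calibration for band {band!r}; have {cal.bands}")
    refl = cal.gain[band] * np.asanyarray(dn_grid, dtype=float) + cal.offset[band]
    if isinstance(refl, np.ma.MaskedArray):
        valid = ~np.ma.getmaskarray(refl)
        n_clip = int(np.sum((refl[valid] < 0) | (refl[valid] > 1)))
    else:
        n_clip = int(np.sum((refl < 0) | (refl > 1)))
    if n_clip:
        logger.info("apply_calibration: clipped %d out-of-range cells in band %s", n_clip, band)
    return np.clip(refl, 0.0, 1.0)


def binarize_mask(class_grid: np.ndarray, wheat_label) -> np.ndarray:
    """Boolean mask, true exactly where the classification equals ``wheat_label``.

    Warns (and returns an all-false mask) when the label is absent.
    """
    class_grid = np.asarray(class_grid)
    mask = class_grid == wheat_label
    if not mask.any():
        warnings.warn(
            f"wheat label {wheat_label!r} absent from classification grid; mask is all false",
            stacklevel=2,
        )
    return mask
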