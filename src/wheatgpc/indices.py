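"""The 14 candidate remote-sensing variables: four bands + ten vegetation indices.

Index algebra (R denotes band reflectance):

==========  =====================================================
NDVI        (R_nir - R_red) / (R_nir + R_red)
SAVI        (R_nir - R_red) / (R_nir + R_red + 0.5) * 1.5
OSAVI       (R_nir - R_red) / (R_nir + R_red + 0.16) * 1.16
NRI         (R_green - R_red) / (R_green + R_red)
GNDVI       (R_nir - R_green) / (R_nir + R_green)
SIPI        (R_nir - R_blue) / (R_nir + R_blue)
PSRI        (R_red - R_blue) / R_nir
EVI         2.5 (R_nir - R_red) / (R_nir + 6 R_red - 7.5 R_green + 1)
DVI         R_nir - R_red
RVI         R_nir / R_red
==========  =====================================================

The EVI form above keeps the green band in the 7.5 aerosol term, as
used throughout this pipeline's source study; the conventional blue-band
EVI is available via ``evi_variant="standard"``.

A vanishing denominator flags the sample rather than silently emitting
infinities; flagged samples are excluded (with a logged count) when a
variable table is assembled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import GridError, IndexComputationError

logger = logging.getLogger(__name__)

BAND_NAMES = ["R_blue", "R_green", "R_red", "R_nir"]
INDEX_NAMES = ["NDVI", "SAVI", "OSAVI", "NRI", "GNDVI", "SIPI", "PSRI", "EVI", "DVI", "RVI"]
#: canonical column order of the 14-variable table
VARIABLE_NAMES = BAND_NAMES + INDEX_NAMES

_SAMPLE_COLS = {"R_blue": "r_blue", "R_green": "r_green", "R_red": "r_red", "R_nir": "r_nir"}


def _ratio(num, den, name, flags):
    bad = den == 0
    if np.any(bad):
        flags |= bad
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(bad, np.nan, num / np.where(bad, 1.0, den))
    return out


def _compute_arrays(
    r_blue, r_green, r_red, r_nir, evi_variant: str = "paper"
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Vectorized index algebra; returns (values, zero-denominator flags)."""
    if evi_variant not in ("paper", "standard"):
        raise ValueError(f"evi_variant must be 'paper' or 'standard', got {evi_variant!r}")
    b, g, r, n = (np.asarray(x, dtype=float) for x in (r_blue, r_green, r_red, r_nir))
    flags = np.zeros(np.broadcast(b, g, r, n).shape, dtype=bool)
    evi_den = n + 6.0 * r - 7.5 * (g if evi_variant == "paper" else b) + 1.0
    out = {
        "R_blue": b + flags * 0.0,
        "R_green": g + flags * 0.0,
        "R_red": r + flags * 0.0,
        "R_nir": n + flags * 0.0,
        "NDVI": _ratio(n - r, n + r, "NDVI", flags),
        "SAVI": _ratio(n - r, n + r + 0.5, "SAVI", flags) * 1.5,
        "OSAVI": _ratio(n - r, n + r + 0.16, "OSAVI", flags) * 1.16,
        "NRI": _ratio(g - r, g + r, "NRI", flags),
        "GNDVI": _ratio(n - g, n + g, "GNDVI", flags),
        "SIPI": _ratio(n - b, n + b, "SIPI", flags),
        "PSRI": _ratio(r - b, n, "PSRI", flags),
        "EVI": 2.5 * _ratio(n - r, evi_den, "EVI", flags),
        "DVI": n - r,
        "RVI": _ratio(n, r, "RVI", flags),
    }
    return out, flags


def compute_indices(
    r_blue: float, r_green: float, r_red: float, r_nir: float, evi_variant: str = "paper"
) -> dict[str, float]:
    """Compute the 14-variable record for one sample.

    Raises :class:`IndexComputationError` if any index denominator is
    zero (e.g. RVI with ``r_red == 0``).
    """
    for name, v in zip(["r_blue", "r_green", "r_red", "r_nir"], [r_blue, r_green, r_red, r_nir]):
        if not (0.0 <= v <= 1.0):
            raise IndexComputationError(f"{name}={v} outside [0, 1]")
    vals, flag = _compute_arrays(r_blue, r_green, r_red, r_nir, evi_variant)
    if bool(flag):
        bad = [k for k, v in vals.items() if not np.isfinite(v)]
        raise IndexComputationError(f"zero denominator for {bad} at this sample")
    return {k: float(v) for k, v in vals.items()}


def compute_index_grids(
    band_grids: dict[str, np.ndarray],
    mask: np.ndarray | None = None,
    evi_variant: str = "paper",
) -> dict[str, np.ma.MaskedArray]:
    """Element-wise index computation over congruent band grids.

    ``band_grids`` maps ``r_blue/r_green/r_red/r_nir`` to 2-D arrays.
    Masked-out or zero-denominator cells come back masked in every
    output grid.
    """
    try:
        bands = [np.asarray(band_grids[c]) for c in ("r_blue", "r_green", "r_red", "r_nir")]
    except KeyError as e:
        raise GridError(f"missing band grid {e.args[0]!r}") from e
    shapes = {b.shape for b in bands}
    if len(shapes) != 1:
        raise GridError(f"band grids not congruent: shapes {sorted(shapes)}")
    shape = bands[0].shape
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != shape:
        raise GridError(f"mask shape {mask.shape} != band shape {shape}")
    vals, flags = _compute_arrays(*bands)
    invalid = ~mask | flags
    return {
        name: np.ma.masked_array(np.where(invalid, np.nan, arr), mask=invalid)
        for name, arr in vals.items()
    }


@dataclass
class VariableTable:
    """n x 14 matrix of remote-sensing variables with optional GPC response."""

    data: pd.DataFrame
    y: pd.Series | None = None
    n_excluded: int = 0

    def __post_init__(self):
        missing = [c for c in VARIABLE_NAMES if c not in self.data.columns]
        if missing:
            raise ValueError(f"variable table missing columns {missing}")
        self.data = self.data[VARIABLE_NAMES]

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def names(self) -> list[str]:
        return list(VARIABLE_NAMES)

    @property
    def X(self) -> np.ndarray:
        return self.data.to_numpy()

    def subset(self, columns: list[str]) -> pd.DataFrame:
        missing = [c for c in columns if c not in self.data.columns]
        if missing:
            raise ValueError(f"unknown variables {missing}")
        return self.data[columns]

    def to_csv(self, path: str | Path) -> None:
        frame = self.data.copy()
        if self.y is not None:
            frame["gpc"] = self.y.to_numpy()
        frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "VariableTable":
        frame = pd.read_csv(path, comment="#")
        y = frame.pop("gpc") if "gpc" in frame.columns else None
        return cls(data=frame, y=y)


def build_variable_table(samples: pd.DataFrame, evi_variant: str = "paper") -> VariableTable:
    """Assemble the canonical 14-variable table from band samples.

    ``samples`` needs columns ``r_blue, r_green, r_red, r_nir`` and
    optionally ``gpc``. Rows with any zero-denominator index are
    excluded and counted in ``n_excluded`` (also logged).
    """
    if len(samples) < 1:
        raise ValueError("need at least one sample")
    vals, flags = _compute_arrays(
        samples["r_blue"].to_numpy(),
        samples["r_green"].to_numpy(),
        samples["r_red"].to_numpy(),
        samples["r_nir"].to_numpy(),
        evi_variant,
    )
    keep = ~flags
    n_excluded = int(flags.sum())
    if n_excluded:
        logger.warning("build_variable_table: excluded %d samples with degenerate indices", n_excluded)
    if not keep.any():
        raise IndexComputationError("all samples flagged with degenerate indices")
    data = pd.DataFrame({k: np.asarray(v)[keep] for k, v in vals.items()})
    y = None
    if "gpc" in samples.columns:
        y = pd.Series(samples["gpc"].to_numpy()[keep], name="gpc")
    return VariableTable(data=data.reset_index(drop=True), y=y, n_excluded=n_excluded)
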