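"""Synthetic four-band wheat scenes with a controllable GPC signal.

Real winter-wheat canopies observed by a four-band (blue/green/red/NIR)
spaceborne imager show two dominant axes of variation: an overall
brightness axis that moves all bands together (soil background, canopy
closure, illumination), and a pigment/structure axis tied to crop
nitrogen status — and hence to grain protein content (GPC). The
generator reproduces that structure with a linear latent model

    band_b = base_b + loading_b * z + brightness_b * c + eps_b

where ``z`` is standardized GPC, ``c`` is a shared standard-normal
brightness factor and ``eps_b`` is small independent band noise. The
shared factor is what makes the raw bands strongly inter-correlated
while ratio indices such as NDVI (which largely cancel brightness)
correlate far more strongly with GPC than any single band — the
empirical signature this pipeline is designed around.

GPC itself is drawn from a truncated normal, emulating a field
population with mean near 12% of dry matter, SD near 1.4% and an
observed range of roughly 9.3-14.6%.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ParameterError

BANDS = ("r_blue", "r_green", "r_red", "r_nir")

# Reflectance clipped into the open unit interval: a physical surface
# reflects a positive, sub-unity fraction in every band.
_CLIP_LO, _CLIP_HI = 0.001, 0.999


@dataclass(frozen=True)
class SceneParams:
    """Generator parameters; defaults emulate the flowering-stage wheat study population.

    Parameters
    ----------
    n_samples : int
        Number of field sampling points to draw.
    gpc_mean, gpc_sd : float
        Mean and SD (% of dry matter) of the untruncated GPC normal.
    gpc_min, gpc_max : float
        Truncation bounds (%): no generated GPC falls outside them.
    band_base : tuple of 4 floats
        Mean reflectance per band (blue, green, red, NIR).
    band_loadings : tuple of 4 floats
        Slope of band reflectance on standardized GPC. Negative for the
        visible bands (greener, higher-N canopies absorb more) and
        positive for NIR (denser canopies scatter more).
    band_brightness : tuple of 4 floats
        Loading on a shared canopy-brightness factor; drives the strong
        positive inter-band correlations seen in real scenes.
    band_noise_sd : tuple of 4 floats
        Independent residual SD per band (reflectance units).
    seed : int
        RNG seed; identical params give byte-identical output.
    """

    n_samples: int = 255
    gpc_mean: float = 12.1
    gpc_sd: float = 1.4
    gpc_min: float = 9.3
    gpc_max: float = 14.6
    band_base: tuple[float, float, float, float] = (0.06, 0.09, 0.07, 0.45)
    band_loadings: tuple[float, float, float, float] = (-0.0023, -0.0009, -0.0063, 0.0214)
    band_brightness: tuple[float, float, float, float] = (0.010, 0.011, 0.012, 0.036)
    band_noise_sd: tuple[float, float, float, float] = (0.002, 0.002, 0.002, 0.002)
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 1:
            raise ParameterError(f"n_samples must be positive, got {self.n_samples}")
        if not (self.gpc_min < self.gpc_mean < self.gpc_max):
            raise ParameterError(
                "degenerate truncation interval: require "
                f"gpc_min < gpc_mean < gpc_max, got ({self.gpc_min}, "
                f"{self.gpc_mean}, {self.gpc_max})"
            )
        if self.gpc_sd < 0:
            raise ParameterError(f"gpc_sd must be >= 0, got {self.gpc_sd}")
        for name in ("band_base", "band_loadings", "band_brightness", "band_noise_sd"):
            vals = getattr(self, name)
            if len(vals) != 4:
                raise ParameterError(f"{name} must have 4 entries, got {len(vals)}")
        if not all(0.0 < b < 1.0 for b in self.band_base):
            raise ParameterError(f"band_base must lie in (0, 1), got {self.band_base}")
        if not all(s >= 0 for s in self.band_noise_sd):
            raise ParameterError(f"band_noise_sd must be >= 0, got {self.band_noise_sd}")

    def to_dict(self) -> dict:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SceneParams":
        kwargs = dict(d)
        for k in ("band_base", "band_loadings", "band_brightness", "band_noise_sd"):
            if k in kwargs:
                kwargs[k] = tuple(kwargs[k])
        return cls(**kwargs)


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, size: int
) -> np.ndarray:
    """Rejection sampler; exact for the mild truncations used here."""
    if sd == 0.0:
        if not (lo <= mean <= hi):
            raise ParameterError("gpc_mean outside truncation bounds with gpc_sd = 0")
        return np.full(size, mean)
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(mean, sd, size=2 * (size - filled) + 16)
        keep = draw[(draw >= lo) & (draw <= hi)][: size - filled]
        out[filled : filled + keep.size] = keep
        filled += keep.size
    return out


def _bands_from_gpc(
    gpc: np.ndarray, params: SceneParams, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Apply the latent linear band model to an array of GPC values."""
    z = (gpc - params.gpc_mean) / params.gpc_sd if params.gpc_sd > 0 else np.zeros_like(gpc)
    c = rng.standard_normal(gpc.shape)
    bands = {}
    for i, name in enumerate(BANDS):
        eps = rng.normal(0.0, params.band_noise_sd[i], size=gpc.shape) \
            if params.band_noise_sd[i] > 0 else 0.0
        vals = (
            params.band_base[i]
            + params.band_loadings[i] * z
            + params.band_brightness[i] * c
            + eps
        )
        bands[name] = np.clip(vals, _CLIP_LO, _CLIP_HI)
    return bands


def generate_samples(params: SceneParams) -> pd.DataFrame:
    """Draw a table of field sampling points.

    Returns a DataFrame with columns ``r_blue, r_green, r_red, r_nir,
    gpc`` (GPC in % of dry matter, reflectances unitless in [0, 1]).
    Deterministic given ``params`` (including the seed).
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    gpc = _truncated_normal(
        rng, params.gpc_mean, params.gpc_sd, params.gpc_min, params.gpc_max, params.n_samples
    )
    bands = _bands_from_gpc(gpc, params, rng)
    frame = pd.DataFrame({**bands, "gpc": gpc})
    return frame[list(BANDS) + ["gpc"]]


def generate_scene(
    rows: int,
    cols: int,
    wheat_fraction: float,
    params: SceneParams,
    smooth_sigma: float = 5.0,
) -> tuple[dict[str, np.ndarray], np.ndarray, np.ndarray]:
    """Generate gridded band reflectance over a spatially smooth GPC field.

    The GPC field is Gaussian-smoothed white noise (kernel width
    ``smooth_sigma`` cells) rescaled to the configured GPC distribution
    and clipped to its truncation bounds; bands follow the same latent
    model as :func:`generate_samples`, per cell. The wheat mask is a
    thresholded second smooth field, so wheat forms contiguous patches
    covering approximately ``wheat_fraction`` of the scene.

    Returns ``(band_grids, mask, gpc_field)`` where ``band_grids`` maps
    band name to a ``rows x cols`` array and ``mask`` is boolean.
    """
    params.validate()
    if rows < 1 or cols < 1:
        raise ParameterError(f"zero-area grid: rows={rows}, cols={cols}")
    if not (0.0 <= wheat_fraction <= 1.0):
        raise ParameterError(f"wheat_fraction must be in [0, 1], got {wheat_fraction}")
    rng = np.random.default_rng(params.seed)

    def smooth_unit_field() -> np.ndarray:
        f = ndimage.gaussian_filter(rng.standard_normal((rows, cols)), sigma=smooth_sigma)
        sd = f.std()
        return (f - f.mean()) / sd if sd > 0 else np.zeros_like(f)

    gpc_field = params.gpc_mean + params.gpc_sd * smooth_unit_field()
    gpc_field = np.clip(gpc_field, params.gpc_min, params.gpc_max)

    band_grids = _bands_from_gpc(gpc_field, params, rng)

    if wheat_fraction <= 0.0:
        mask = np.zeros((rows, cols), dtype=bool)
    elif wheat_fraction >= 1.0:
        mask = np.ones((rows, cols), dtype=bool)
    else:
        mask_field = smooth_unit_field()
        thresh = np.quantile(mask_field, 1.0 - wheat_fraction)
        mask = mask_field >= thresh
    return band_grids, mask, gpc_field


def generate_dn(
    samples: pd.DataFrame,
    gain: float | Sequence[float],
    offset: float | Sequence[float],
    noise_sd: float = 0.0,
    n_targets: int = 5,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Convert reflectance samples to raw digital numbers plus calibration targets.

    DN = gain * reflectance + offset + N(0, noise_sd), per band. Also
    emits ``n_targets`` (DN, known-reflectance) calibration pairs per
    band spanning reflectance 0.05-0.60, with the same DN noise — the
    input an empirical-line calibration needs.

    Returns ``(dn_table, targets)``; ``targets`` has columns
    ``band, dn, reflectance``.
    """
    gains = np.broadcast_to(np.asarray(gain, dtype=float), (4,))
    offsets = np.broadcast_to(np.asarray(offset, dtype=float), (4,))
    if np.any(gains == 0):
        raise ParameterError("gain must be nonzero for every band")
    if n_targets < 2:
        raise ParameterError(f"need >= 2 calibration targets per band, got {n_targets}")
    rng = np.random.default_rng(seed)

    dn = {}
    for i, name in enumerate(BANDS):
        refl = samples[name].to_numpy()
        noise = rng.normal(0.0, noise_sd, size=refl.shape) if noise_sd > 0 else 0.0
        dn[f"dn_{name[2:]}"] = gains[i] * refl + offsets[i] + noise
    dn_table = pd.DataFrame(dn)

    target_refl = np.linspace(0.05, 0.60, n_targets)
    rows = []
    for i, name in enumerate(BANDS):
        noise = rng.normal(0.0, noise_sd, size=n_targets) if noise_sd > 0 else np.zeros(n_targets)
        for r, e in zip(target_refl, noise):
            rows.append({"band": name, "dn": gains[i] * r + offsets[i] + e, "reflectance": r})
    targets = pd.DataFrame(rows, columns=["band", "dn", "reflectance"])
    return dn_table, targets
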