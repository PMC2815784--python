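"""Film-like 2-D dose images: rendering, profile extraction, falloff metrics.

Radiochromic film is the geometric verification medium for microbeam
irradiations: it records the array pattern and the interlaced plateau as an
optical-density image.  Here a dose map is box-averaged onto pixels, mapped
through a monotone dose->OD response (identity by default, since no absolute
film calibration is modelled) and optionally degraded with Gaussian noise;
profiles are recovered by row averaging and inverse response.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import tifffile

from .compose import LateralProfile, penumbra_90_10
from .errors import ConfigurationError, RangeError

__all__ = [
    "FilmResponse",
    "IdentityResponse",
    "SaturatingResponse",
    "FilmImage",
    "render_film",
    "profile_from_film",
    "falloff_comparison",
]


class FilmResponse:
    """Monotone dose -> optical density map with an inverse."""

    dose_max: float = np.inf

    def forward(self, dose):
        raise NotImplementedError

    def inverse(self, od):
        raise NotImplementedError


class IdentityResponse(FilmResponse):
    """Dose-proportional response (OD = dose); never saturates."""

    def forward(self, dose):
        return np.asarray(dose, dtype=float)

    def inverse(self, od):
        return np.asarray(od, dtype=float)


class SaturatingResponse(FilmResponse):
    """OD = od_max * d / (d + d_half): strictly increasing, saturating."""

    def __init__(self, od_max: float = 4.0, d_half: float = 200.0,
                 dose_max: float = 5000.0):
        if od_max <= 0 or d_half <= 0:
            raise ConfigurationError("response parameters must be positive")
        self.od_max = od_max
        self.d_half = d_half
        self.dose_max = dose_max

    def forward(self, dose):
        d = np.asarray(dose, dtype=float)
        return self.od_max * d / (d + self.d_half)

    def inverse(self, od):
        o = np.asarray(od, dtype=float)
        return self.d_half * o / np.maximum(self.od_max - o, 1e-300)


@dataclass
class FilmImage:
    pixels: np.ndarray          # optical density (or dose, identity response)
    pixel_pitch_um: float
    response: FilmResponse
    noise_sigma: float = 0.0
    seed: int = 0

    def save_tiff(self, path, scale: float | None = None) -> None:
        """16-bit TIFF export; ``scale`` maps OD to integer counts
        (default: full range)."""
        px = self.pixels
        if scale is None:
            scale = 65535.0 / max(px.max(), 1e-12)
        tifffile.imwrite(path, np.clip(px * scale, 0, 65535).astype(np.uint16))


def render_film(dose_map, map_pitch_um: float, pixel_pitch_um: float,
                response: FilmResponse | None = None,
                noise_sigma: float = 0.0, seed: int = 0) -> FilmImage:
    """Box-average a dose map onto film pixels, apply the response, add noise.

    ``dose_map`` is (rows, columns) with column pitch ``map_pitch_um``; the
    pixel pitch must be >= 1 um.  Noise is additive Gaussian on the OD
    signal, seeded.
    """
    if pixel_pitch_um < 1.0:
        raise ConfigurationError("pixel pitch must be >= 1 um")
    response = response or IdentityResponse()
    dm = np.asarray(dose_map, dtype=float)
    if dm.ndim != 2:
        raise ConfigurationError("dose map must be 2-D")
    block = pixel_pitch_um / map_pitch_um
    if abs(block - round(block)) > 1e-9:
        raise ConfigurationError(
            "pixel pitch must be an integer multiple of the map pitch"
        )
    block = int(round(block))
    nr = dm.shape[0] // block * block
    nc = dm.shape[1] // block * block
    binned = dm[:nr, :nc].reshape(nr // block, block,
                                  nc // block, block).mean(axis=(1, 3))
    od = np.asarray(response.forward(binned), dtype=float)
    if noise_sigma > 0:
        od = od + np.random.default_rng(seed).normal(0.0, noise_sigma,
                                                     od.shape)
    return FilmImage(od, float(pixel_pitch_um), response, noise_sigma, seed)


def profile_from_film(image: FilmImage, band_rows: slice) -> LateralProfile:
    """Row-averaged lateral profile of a film band, in dose units.

    Saturated pixels (beyond the response's stated dose range) are masked
    to NaN; the returned profile drops the mask into zero dose with the
    warning recorded on ``profile.uncertainty`` left as None.
    """
    n_rows = image.pixels.shape[0]
    rows = range(*band_rows.indices(n_rows))
    if len(rows) == 0:
        raise RangeError("band rows outside image")
    band = image.pixels[band_rows, :].mean(axis=0)
    dose = np.asarray(image.response.inverse(band), dtype=float)
    saturated = dose > image.response.dose_max
    if saturated.any():
        dose = np.where(saturated, np.nan, dose)
    n = dose.size
    x = (np.arange(n) - (n - 1) / 2.0) * image.pixel_pitch_um
    return LateralProfile(x, np.nan_to_num(np.maximum(dose, 0.0)),
                          depth_mm=0.0)


def falloff_comparison(profile_a: LateralProfile,
                       profile_b: LateralProfile,
                       offsets_mm=(10.0,)) -> dict:
    """Edge-falloff metrics for two centrally normalized profiles.

    Both profiles must be normalized to central dose 1 (checked to 5%).
    Reports each profile's 90-10% falloff distance beyond its outermost
    edge peak and the dose fraction remaining at the requested offsets from
    the field center.  Metrics are invariant to global dose rescaling by
    construction of the normalization check.
    """
    report: dict = {"offsets_mm": list(offsets_mm)}
    for name, prof in (("a", profile_a), ("b", profile_b)):
        central = prof.window_mean(0.0, 200.0)
        if not (0.95 <= central <= 1.05):
            raise ConfigurationError(
                f"profile {name} must be normalized to central dose 1 "
                f"(got {central:.3f})"
            )
        dist, warn = penumbra_90_10(prof, side="right")
        fractions = []
        for off in offsets_mm:
            x_um = off * 1000.0
            if x_um > prof.extent_um:
                raise RangeError(
                    f"offset {off} mm beyond profile extent "
                    f"({prof.extent_um / 1000.0:.1f} mm)"
                )
            fractions.append(prof.window_mean(x_um, 100.0) / central)
        report[name] = {"falloff_90_10_um": dist,
                        "nonmonotone_warning": warn,
                        "fraction_at_offsets": fractions}
    return report
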