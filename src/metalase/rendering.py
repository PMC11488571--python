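"""Composite rendering: the multichannel metabolic composite and the
pseudocolor virtual-H&E representation.

The metabolic composite assigns ORR, UV scattering and collagen
autofluorescence to the red, green and blue channels of an 8-bit RGB image,
then superimposes the intrinsically sparse nuclear (PARS) contrast as a
yellow-to-white overlay.  The virtual-H&E rendering assigns PARS and UV
reflectance to red and green, zeroes blue and takes the complement, so
nuclei come out blue-cyan on a white background — the colour convention of
hematoxylin/eosin bright-field histology (and the input representation for
learned stain-style transfer, which is out of scope here).

Per channel, outlier pixels above the 98th percentile are clipped to that
percentile before min-max normalization, so renderings are invariant to
per-channel positive rescaling of the inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import imageio.v3 as iio
import numpy as np

from .metabolic import ORRMap
from .reconstruction import GridSpec


@dataclass
class RGBComposite:
    """8-bit RGB rendering plus the mapping/normalization that produced it."""

    rgb: np.ndarray  # (rows, cols, 3) uint8
    mapping: dict[str, str]
    normalization: dict[str, dict] = field(default_factory=dict)
    grid: GridSpec | None = None

    def save_png(self, path) -> None:
        iio.imwrite(path, self.rgb, extension=".png")


def clip_outliers(img: np.ndarray, percentile: float = 98.0) -> np.ndarray:
    """Clip values above the given percentile of the valid pixels to that
    percentile value (linear-interpolation percentile definition).

    Idempotent and monotone (output <= input everywhere); NaN pixels pass
    through unchanged.
    """
    if not (0.0 < percentile < 100.0):
        raise ValueError(f"percentile must lie in (0, 100), got {percentile!r}")
    img = np.asarray(img, dtype=float)
    valid = np.isfinite(img)
    if not valid.any():
        raise ValueError("image has no valid pixels")
    thresh = np.percentile(img[valid], percentile)
    return np.where(valid & (img > thresh), thresh, img)


def _normalize(img: np.ndarray, percentile: float | None = 98.0) -> tuple[np.ndarray, dict]:
    """Clip then min-max normalize to [0, 1] over valid pixels."""
    if percentile is not None:
        img = clip_outliers(img, percentile)
    valid = np.isfinite(img)
    lo = float(img[valid].min())
    hi = float(img[valid].max())
    out = np.zeros_like(img, dtype=float)
    if hi > lo:
        out = np.where(valid, (img - lo) / (hi - lo), 0.0)
    elif hi > 0:  # constant positive image -> full scale
        out = np.where(valid, 1.0, 0.0)
    return out, {"min": lo, "max": hi, "percentile": percentile}


def compose_metalase(orr: ORRMap, scattering: np.ndarray, collagen: np.ndarray,
                     pars: np.ndarray, percentile: float = 98.0) -> RGBComposite:
    """Fuse ORR (red), UV scattering (green) and collagen autofluorescence
    (blue), with normalized PARS alpha-blended on top along a yellow-to-white
    ramp.  Invalid pixels render black."""
    shapes = {orr.values.shape, scattering.shape, collagen.shape, pars.shape}
    if len(shapes) != 1:
        raise ValueError(f"input grids do not match: {shapes}")
    norm = {}
    r, norm["orr"] = _normalize(orr.values, percentile)
    g, norm["uv_scattering"] = _normalize(scattering, percentile)
    b, norm["collagen_af"] = _normalize(collagen, percentile)
    p, norm["pars"] = _normalize(pars, percentile)

    base = np.stack([r, g, b], axis=-1)
    # yellow (1,1,0) -> white (1,1,1) ramp, alpha = normalized PARS
    overlay = np.stack([np.ones_like(p), np.ones_like(p), p], axis=-1)
    alpha = p[..., None]
    rgb = (1.0 - alpha) * base + alpha * overlay

    invalid = ~(orr.mask & np.isfinite(scattering) & np.isfinite(collagen)
                & np.isfinite(pars))
    rgb[invalid] = 0.0
    rgb8 = np.clip(np.round(rgb * 255.0), 0, 255).astype(np.uint8)
    mapping = {"R": "orr", "G": "uv_scattering", "B": "collagen_af",
               "overlay": "pars (yellow-white ramp)",
               "outliers": f"clipped to p{percentile:g}"}
    return RGBComposite(rgb=rgb8, mapping=mapping, normalization=norm, grid=orr.grid)


def pseudocolor_virtual_he(pars: np.ndarray, uv_refl: np.ndarray,
                           percentile: float = 98.0,
                           grid: GridSpec | None = None) -> RGBComposite:
    """Virtual-H&E pseudocolor: PARS -> red, reflectance -> green, blue
    zeroed, then per-channel complement.  Background (both channels zero)
    renders white; invalid pixels render white as well."""
    if pars.shape != uv_refl.shape:
        raise ValueError(f"input grids do not match: {pars.shape} vs {uv_refl.shape}")
    norm = {}
    r, norm["pars"] = _normalize(pars, percentile)
    g, norm["uv_refl"] = _normalize(uv_refl, percentile)
    rgb = np.stack([r, g, np.zeros_like(r)], axis=-1)
    rgb = 1.0 - rgb  # complement
    invalid = ~(np.isfinite(pars) & np.isfinite(uv_refl))
    rgb[invalid] = 1.0
    rgb8 = np.clip(np.round(rgb * 255.0), 0, 255).astype(np.uint8)
    mapping = {"R": "255 - pars", "G": "255 - uv_refl", "B": "255",
               "outliers": f"clipped to p{percentile:g}"}
    return RGBComposite(rgb=rgb8, mapping=mapping, normalization=norm, grid=grid)
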