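"""Optical redox ratio (ORR) mapping and patch-based statistics.

The ORR is the ratio of FAD autofluorescence intensity to the summed
NAD(P)H and FAD autofluorescence intensities, FAD / (NAD(P)H + FAD): a
unitless metabolic-state readout in [0, 1] that is invariant to common
intensity scaling of the two channels.  It is computed per pixel on the
reconstructed channel images, after gridding.

Region comparisons follow the patch workflow: the valid ORR map is tiled
into non-overlapping square patches, the mean ORR per patch is taken, and
patch-mean populations from two regions are compared with a two-sample,
two-tailed Welch unequal-variances t test (normality checked with an
Anderson-Darling test).  No multiple-comparison correction is applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .reconstruction import GridSpec, ImageStack

logger = logging.getLogger(__name__)


@dataclass
class ORRMap:
    """Pixel ORR values; ``mask`` flags valid pixels (sources valid and
    NAD(P)H + FAD > 0).  Values are NaN where invalid and in [0, 1]
    everywhere else."""

    values: np.ndarray
    mask: np.ndarray
    grid: GridSpec
    meta: dict = field(default_factory=dict)


@dataclass
class PatchStats:
    """Mean ORR of non-overlapping square patches."""

    patch_size_um: float
    table: pd.DataFrame  # columns: cx_um, cy_um, mean_orr, frac_valid, group
    n_dropped: int = 0

    def group_values(self, label: int) -> np.ndarray:
        return self.table.loc[self.table["group"] == label, "mean_orr"].to_numpy()


@dataclass
class WelchResult:
    t: float
    df: float
    p: float
    mean_a: float
    mean_b: float
    n_a: int
    n_b: int


@dataclass
class ADResult:
    a2: float
    critical_5pct: float
    normal_at_5pct: bool


def compute_orr(nadh: np.ndarray, fad: np.ndarray,
                grid: GridSpec | None = None) -> ORRMap:
    """Per-pixel ORR = fad / (nadh + fad).

    Pixels where either source is invalid (NaN) or the denominator is not
    positive are masked invalid.  Intensities are physical quantities, so
    small negative excursions from read-out noise are floored at zero
    before the ratio; the ORR is therefore always in [0, 1] where defined.
    """
    nadh = np.asarray(nadh, dtype=float)
    fad = np.asarray(fad, dtype=float)
    if nadh.shape != fad.shape:
        raise ValueError(
            f"channel grids do not match: {nadh.shape} vs {fad.shape}")
    nadh = np.maximum(nadh, 0.0)
    fad = np.maximum(fad, 0.0)
    total = nadh + fad
    valid = np.isfinite(total) & (total > 0)
    values = np.full(nadh.shape, np.nan)
    np.divide(fad, total, out=values, where=valid)
    if grid is None:
        grid = GridSpec(origin=(0.0, 0.0), spacing=(1.0, 1.0), shape=nadh.shape)
    return ORRMap(values=values, mask=valid, grid=grid)


def orr_from_stack(stack: ImageStack, gains: dict[str, float] | None = None) -> ORRMap:
    """ORR from the NAD(P)H / FAD channels of an image stack.

    ``gains`` optionally rescales channels before the ratio (identity by
    default); ORR is invariant to a *common* gain but not to differential
    ones, so any cross-calibration is applied here.
    """
    g = {"af_nadh": 1.0, "af_fad": 1.0, **(gains or {})}
    orr = compute_orr(stack.channel("af_nadh") * g["af_nadh"],
                      stack.channel("af_fad") * g["af_fad"], grid=stack.grid)
    orr.meta["gains"] = g
    return orr


def patch_means(orr: ORRMap, patch_size_um: float,
                region_mask: np.ndarray | None = None,
                min_valid_fraction: float = 0.5) -> PatchStats:
    """Tile the map into non-overlapping ``patch_size_um`` squares from the
    grid origin and average valid ORR pixels per patch.

    Patches with less than ``min_valid_fraction`` valid pixels are dropped
    (and counted).  With ``region_mask`` (integer labels per pixel) each
    patch is assigned the majority label over its pixels; otherwise all
    patches get group 0.
    """
    if patch_size_um <= 0:
        raise ValueError(f"patch size must be > 0, got {patch_size_um!r}")
    dx, dy = orr.grid.spacing
    px = int(round(patch_size_um / dx))
    py = int(round(patch_size_um / dy))
    if px < 2 or py < 2:
        raise ValueError(
            f"patch size {patch_size_um} um is under 2 pixels per side on this grid")
    ny, nx = orr.values.shape
    if py > ny or px > nx:
        raise ValueError(f"patch ({py}x{px} px) larger than image ({ny}x{nx} px)")

    rows = []
    n_dropped = 0
    for r0 in range(0, ny - py + 1, py):
        for c0 in range(0, nx - px + 1, px):
            block = orr.values[r0:r0 + py, c0:c0 + px]
            valid = orr.mask[r0:r0 + py, c0:c0 + px]
            frac = valid.mean()
            if frac < min_valid_fraction:
                n_dropped += 1
                continue
            if region_mask is not None:
                labels, counts = np.unique(
                    region_mask[r0:r0 + py, c0:c0 + px], return_counts=True)
                group = int(labels[np.argmax(counts)])
            else:
                group = 0
            rows.append({
                "cx_um": orr.grid.origin[0] + (c0 + (px - 1) / 2.0) * dx,
                "cy_um": orr.grid.origin[1] + (r0 + (py - 1) / 2.0) * dy,
                "mean_orr": float(np.nanmean(np.where(valid, block, np.nan))),
                "frac_valid": float(frac),
                "group": group,
            })
    if n_dropped:
        logger.info("dropped %d patches with < %.0f%% valid pixels",
                    n_dropped, 100 * min_valid_fraction)
    table = pd.DataFrame(rows, columns=["cx_um", "cy_um", "mean_orr", "frac_valid", "group"])
    return PatchStats(patch_size_um=patch_size_um, table=table, n_dropped=n_dropped)


def welch_test(a, b) -> WelchResult:
    """Two-sample, two-tailed Welch unequal-variances t test.

    t = (mean_a - mean_b) / sqrt(s2_a/n_a + s2_b/n_b), with the
    Welch-Satterthwaite degrees of freedom and a two-sided p value from the
    t distribution.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError(f"each group needs n >= 2, got {a.size} and {b.size}")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if np.mean(a) == np.mean(b):
            return WelchResult(t=0.0, df=float(a.size + b.size - 2), p=1.0,
                               mean_a=float(a.mean()), mean_b=float(b.mean()),
                               n_a=a.size, n_b=b.size)
        raise ValueError("both groups have zero variance with different means")
    res = stats.ttest_ind(a, b, equal_var=False)
    return WelchResult(t=float(res.statistic), df=float(res.df), p=float(res.pvalue),
                       mean_a=float(a.mean()), mean_b=float(b.mean()),
                       n_a=a.size, n_b=b.size)


def anderson_darling_normality(x) -> ADResult:
    """Anderson-Darling test of composite normality (estimated mean/sd),
    decided at the 5% level with sample-size-adjusted critical values."""
    x = np.asarray(x, dtype=float)
    if x.size < 8:
        raise ValueError(f"Anderson-Darling needs n >= 8, got {x.size}")
    if x.var(ddof=1) == 0:
        raise ValueError("constant input: normality test undefined")
    import warnings
    with warnings.catch_warnings():
        # scipy >= 1.17 warns about a future change to p-value reporting; the
        # decision here is against the 5% critical value, which is stable
        warnings.simplefilter("ignore", FutureWarning)
        res = stats.anderson(x, dist="norm")
    crit = float(res.critical_values[list(res.significance_level).index(5.0)])
    a2 = float(res.statistic)
    return ADResult(a2=a2, critical_5pct=crit, normal_at_5pct=a2 < crit)
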