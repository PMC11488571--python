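"""Resolution and response characterization.

Lateral resolution is measured from an edge target: an error-function edge
spread function (ESF) is fit to the intensity profile across the edge,

    I(x) = b + (a / 2) * (1 + erf((x - x0) / (sigma * sqrt(2)))),

whose derivative is a Gaussian point spread function (PSF); the resolution
is the PSF full width at half maximum, FWHM = 2 sqrt(2 ln 2) sigma, taken
in closed form from the fitted sigma (no numerical differentiation).

Detector response linearity is summarized with an ordinary least-squares
line and its coefficient of determination R².
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, special, stats

from .reconstruction import ImageStack

#: FWHM of a Gaussian with unit standard deviation
FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass
class ESFFit:
    amplitude: float
    baseline: float
    center_um: float
    sigma_um: float
    rmse: float


@dataclass
class ResolutionReport:
    channel: str
    fit: ESFFit
    fwhm_um: float
    n_averaged_lines: int = 1


@dataclass
class LinFit:
    slope: float
    intercept: float
    r2: float


def _erf_model(x, a, b, x0, sigma):
    return b + (a / 2.0) * (1.0 + special.erf((x - x0) / (sigma * np.sqrt(2.0))))


def fit_esf(positions_um, intensities) -> ESFFit:
    """Least-squares erf fit to an edge profile.

    Initialization: baseline = min, amplitude = range, centre = position of
    half rise, sigma = span / 10.
    """
    x = np.asarray(positions_um, dtype=float)
    y = np.asarray(intensities, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 8:
        raise ValueError(f"need >= 8 finite points spanning the edge, got {x.size}")
    y_rng = y.max() - y.min()
    if y_rng == 0:
        raise ValueError("flat intensity profile: no edge to fit")
    span = x.max() - x.min()
    half = y.min() + y_rng / 2.0
    x0_init = float(x[np.argmin(np.abs(y - half))])
    p0 = [y_rng, y.min(), x0_init, span / 10.0]
    # fit a rising edge; a falling profile is flipped first
    flipped = stats.pearsonr(x, y).statistic < 0 if y.size > 2 else False
    yy = y[::-1] if flipped else y
    xx = (x.max() + x.min()) - x[::-1] if flipped else x
    order = np.argsort(xx)
    xx, yy = xx[order], yy[order]
    try:
        popt, _ = optimize.curve_fit(
            _erf_model, xx, yy, p0=p0, maxfev=20000,
            bounds=([0.0, -np.inf, xx.min() - span, 1e-12],
                    [np.inf, np.inf, xx.max() + span, 10.0 * span]))
    except RuntimeError as exc:
        raise ValueError(f"ESF fit did not converge: {exc}") from exc
    a, b, x0, sigma = popt
    if flipped:
        x0 = (x.max() + x.min()) - x0
    resid = _erf_model(xx, *popt) - yy
    return ESFFit(amplitude=float(a), baseline=float(b), center_um=float(x0),
                  sigma_um=float(sigma), rmse=float(np.sqrt(np.mean(resid ** 2))))


def measure_resolution(stack: ImageStack, channel: str, axis: str = "fast",
                       line: int | None = None, n_average: int = 5) -> ResolutionReport:
    """Lateral resolution of one channel from an edge image.

    The profile is taken along ``axis`` ('fast' = along a row, 'slow' =
    along a column), averaging ``n_average`` adjacent parallel lines centred
    on ``line`` (defaults to the image centre).  FWHM is computed in closed
    form from the fitted ESF sigma.
    """
    img = stack.channel(channel)
    if axis not in ("fast", "slow"):
        raise ValueError(f"axis must be 'fast' or 'slow', got {axis!r}")
    if axis == "slow":
        img = img.T
        positions = stack.grid.y
    else:
        positions = stack.grid.x
    n_lines = img.shape[0]
    center = n_lines // 2 if line is None else int(line)
    half = max(0, (n_average - 1) // 2)
    lo = max(0, center - half)
    hi = min(n_lines, center + half + 1)
    with np.errstate(invalid="ignore"):
        profile = np.nanmean(img[lo:hi], axis=0)
    fit = fit_esf(positions, profile)
    return ResolutionReport(channel=channel, fit=fit,
                            fwhm_um=FWHM_FACTOR * fit.sigma_um,
                            n_averaged_lines=hi - lo)


def linear_fit_r2(x, y) -> LinFit:
    """Ordinary least squares line with R² = 1 - SS_res / SS_tot."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError(f"need n >= 3 points, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("constant x: line fit undefined")
    res = stats.linregress(x, y)
    yhat = res.intercept + res.slope * x
    ss_res = float(((y - yhat) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return LinFit(slope=float(res.slope), intercept=float(res.intercept), r2=r2)
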