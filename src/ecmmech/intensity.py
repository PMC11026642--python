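"""ECM immunofluorescence quantification by kernel density estimation.

A Gaussian KDE (Silverman bandwidth) of all pixel intensities is evaluated on
a fixed grid spanning the bit-depth range and renormalized to integrate to
one over that grid.  A user-supplied (lower, upper) intensity threshold pair
isolates the stained regions; the density's area below vs above its peak
within the thresholds gives the weak/intense split, each normalized by the
total thresholded area.  The per-image scalar used for group comparisons is
the *activated-pixel fraction*: the fraction of pixels with intensity inside
[lower, upper] — defined by direct counting, never by the KDE.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
from scipy.stats import gaussian_kde

from .stats import two_sample_t
from .types import IntensityProfile


def _auc(grid: np.ndarray, density: np.ndarray, lo: float, hi: float) -> float:
    """Trapezoidal area of the density over [lo, hi], interpolating endpoints."""
    if hi <= lo:
        return 0.0
    pts = grid[(grid > lo) & (grid < hi)]
    xs = np.concatenate(([lo], pts, [hi]))
    ys = np.interp(xs, grid, density)
    return float(np.trapezoid(ys, xs))


def compute_intensity_profile(channel: np.ndarray, lower: float, upper: float,
                              bit_depth: int | None = None,
                              grid_size: int = 256,
                              max_pixels: int = 100_000,
                              subsample_seed: int = 0) -> IntensityProfile:
    """KDE intensity profile of one single-channel image.

    Parameters
    ----------
    channel : 2-D pixel array in native intensity units.
    lower, upper : intensity thresholds isolating the stained regions.
    bit_depth : grid span (0 .. 2**bit_depth - 1); inferred from dtype if None.
    max_pixels : KDE sample cap; larger images are subsampled reproducibly.
    """
    channel = np.asarray(channel)
    if channel.ndim != 2:
        raise ValueError("expected a single-channel 2-D image")
    if bit_depth is None:
        bit_depth = 16 if channel.dtype == np.uint16 else 8
    vmax = 2**bit_depth - 1
    if not (0 <= lower < upper <= vmax):
        raise ValueError(f"need 0 <= lower < upper <= {vmax}, got ({lower}, {upper})")

    pixels = channel.ravel().astype(float)
    inside = (pixels >= lower) & (pixels <= upper)
    activated = float(inside.sum()) / pixels.size

    grid = np.linspace(0.0, vmax, grid_size)
    if pixels.std() == 0:
        return IntensityProfile(
            kde_grid=grid, density=np.zeros_like(grid), peak_intensity=float(pixels[0]),
            weak_area=math.nan, intense_area=math.nan, activated_fraction=activated,
            thresholds=(lower, upper), flagged=True,
            flag_reason="constant image: zero-variance KDE")

    sample = pixels
    if sample.size > max_pixels:
        rng = np.random.default_rng(subsample_seed)
        sample = rng.choice(sample, size=max_pixels, replace=False)
    kde = gaussian_kde(sample, bw_method="silverman")
    density = kde(grid)
    total = np.trapezoid(density, grid)
    density = density / total  # probability density on the intensity domain

    peak = float(grid[int(np.argmax(density))])
    peak_c = min(max(peak, lower), upper)
    auc_total = _auc(grid, density, lower, upper)
    if auc_total <= 0:
        return IntensityProfile(
            kde_grid=grid, density=density, peak_intensity=peak,
            weak_area=math.nan, intense_area=math.nan, activated_fraction=activated,
            thresholds=(lower, upper), flagged=True,
            flag_reason="no density mass inside thresholds")
    weak = _auc(grid, density, lower, peak_c) / auc_total
    intense = _auc(grid, density, peak_c, upper) / auc_total
    return IntensityProfile(kde_grid=grid, density=density, peak_intensity=peak,
                            weak_area=weak, intense_area=intense,
                            activated_fraction=activated, thresholds=(lower, upper))


def compare_protein_groups(young_profiles: list[IntensityProfile],
                           aged_profiles: list[IntensityProfile],
                           metric: str = "activated_fraction",
                           welch: bool = False) -> dict:
    """Percent change (aged vs young) of a per-image scalar plus a t-test.

    percent_change = 100 * (mean_aged - mean_young) / mean_young.  With fewer
    than two images in either group the change is still reported but the test
    is suppressed with a warning.
    """
    if metric not in ("activated_fraction", "intense_area", "weak_area"):
        raise ValueError(f"unknown comparison metric {metric!r}")
    y = np.array([getattr(p, metric) for p in young_profiles], float)
    a = np.array([getattr(p, metric) for p in aged_profiles], float)
    if y.size == 0 or a.size == 0:
        raise ValueError("both groups need at least one image")
    my, ma = float(y.mean()), float(a.mean())
    if my == 0:
        raise ValueError("young-group mean is zero; percent change undefined")
    row = {
        "metric": metric, "n_young": y.size, "n_aged": a.size,
        "mean_young": my, "mean_aged": ma,
        "percent_change": 100.0 * (ma - my) / my,
        "t": math.nan, "p": math.nan, "significant": None,
    }
    if y.size < 2 or a.size < 2:
        warnings.warn("fewer than 2 images in a group: t-test suppressed")
        return row
    res = two_sample_t(a, y, welch=welch)
    row.update(t=res.t, p=res.p, significant=res.significant)
    return row
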