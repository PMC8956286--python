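"""Patch statistics and constant-response contours for On/Off parasol models.

Each image patch is summarized by two statistics measured in the receptive
field center: the change in mean luminance relative to background
(RF-weighted, in contrast units) and the spatial contrast (unweighted
SD/mean of aperture pixels).  Simplified one-pathway models (linear or
rectified-subunit, On or Off polarity) are evaluated on many patches and
averaged on a 2-D grid over these statistics; iso-response contours of the
resulting surface reveal what stimulus combinations a model confounds.  A
spatially linear model's contours are horizontal (luminance-only); a
rectified model's contours tilt because spatial structure adds response,
and the tilt is stronger for Off models on dark-skewed (natural-like)
inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .stimuli import CenterRF, aperture_mask, center_weights
from .subunits import run_simple_model

logger = logging.getLogger(__name__)

__all__ = ["PatchStats", "ResponseSurface", "patch_stats", "response_surface",
           "constant_response_contours", "contour_slope"]


@dataclass
class PatchStats:
    delta_mean_luminance: float
    spatial_contrast: float
    flagged: bool = False


def patch_stats(patch: np.ndarray, rf: CenterRF, background: float,
                pixel_pitch: float = 3.0) -> PatchStats:
    """Luminance change and spatial contrast within the receptive field center.

    ``spatial_contrast`` = SD / mean of aperture pixels (unweighted);
    ``delta_mean_luminance`` = (RF-weighted mean - background) / background.
    A non-positive pixel mean flags the result (contrast undefined).
    """
    patch = np.asarray(patch, dtype=float)
    mask = aperture_mask(rf, pixel_pitch)
    if patch.shape != mask.shape:
        raise ValueError("patch must cover the aperture grid")
    px = patch[mask]
    w = center_weights(rf, pixel_pitch)
    wmean = float(np.sum(w * patch) / np.sum(w))
    dml = (wmean - background) / background
    m = px.mean()
    if m <= 0:
        return PatchStats(delta_mean_luminance=dml, spatial_contrast=np.nan, flagged=True)
    return PatchStats(delta_mean_luminance=dml, spatial_contrast=float(px.std() / m))


@dataclass
class ResponseSurface:
    """Mean model response binned over (spatial contrast, luminance change)."""

    contrast_edges: np.ndarray
    luminance_edges: np.ndarray
    mean_response: np.ndarray  # (n_lum_bins, n_con_bins), NaN where empty
    counts: np.ndarray

    @property
    def contrast_centers(self) -> np.ndarray:
        return 0.5 * (self.contrast_edges[:-1] + self.contrast_edges[1:])

    @property
    def luminance_centers(self) -> np.ndarray:
        return 0.5 * (self.luminance_edges[:-1] + self.luminance_edges[1:])


def response_surface(
    patches: list,
    rf: CenterRF,
    polarity: str,
    integration: str,
    background: float = 4000.0,
    pixel_pitch: float = 3.0,
    bins: int = 15,
    seed: int = 0,
) -> ResponseSurface:
    """Run the simplified model over patches and bin by patch statistics.

    Bin edges span the 1st-99th percentile range of each statistic; patches
    with flagged statistics are dropped.
    """
    stats, resp = [], []
    for p in patches:
        s = patch_stats(p, rf, background, pixel_pitch)
        if s.flagged:
            continue
        stats.append((s.spatial_contrast, s.delta_mean_luminance))
        resp.append(run_simple_model(p, polarity, integration, rf,
                                     background=background, pixel_pitch=pixel_pitch,
                                     seed=seed))
    stats = np.array(stats)
    resp = np.array(resp)
    if len(stats) < bins:
        raise ValueError("too few valid patches for the requested binning")
    ce = np.linspace(*np.percentile(stats[:, 0], [1, 99]), bins + 1)
    le = np.linspace(*np.percentile(stats[:, 1], [1, 99]), bins + 1)
    ci = np.clip(np.digitize(stats[:, 0], ce) - 1, 0, bins - 1)
    li = np.clip(np.digitize(stats[:, 1], le) - 1, 0, bins - 1)
    total = np.zeros((bins, bins))
    count = np.zeros((bins, bins), dtype=int)
    np.add.at(total, (li, ci), resp)
    np.add.at(count, (li, ci), 1)
    with np.errstate(invalid="ignore"):
        mean = np.where(count > 0, total / np.where(count == 0, 1, count), np.nan)
    return ResponseSurface(contrast_edges=ce, luminance_edges=le,
                           mean_response=mean, counts=count)


def constant_response_contours(surface: ResponseSurface, levels) -> dict:
    """Iso-response polylines in (spatial contrast, luminance) space.

    For each level and each contrast column, the luminance at which the
    (column-wise interpolated) response crosses the level is found by linear
    interpolation; columns without a crossing are skipped.  Levels outside
    the surface range give empty polylines.
    """
    out = {}
    lc = surface.luminance_centers
    cc = surface.contrast_centers
    for level in np.atleast_1d(levels):
        pts = []
        for j, c in enumerate(cc):
            col = surface.mean_response[:, j]
            ok = np.isfinite(col)
            if ok.sum() < 2:
                continue
            y = lc[ok]
            r = col[ok]
            for i in range(len(r) - 1):
                lo, hi = sorted((r[i], r[i + 1]))
                if lo <= level <= hi and hi > lo:
                    frac = (level - r[i]) / (r[i + 1] - r[i])
                    pts.append((c, y[i] + frac * (y[i + 1] - y[i])))
                    break
        out[float(level)] = np.array(pts) if pts else np.empty((0, 2))
    return out


def contour_slope(polyline: np.ndarray) -> float:
    """Mean d(luminance)/d(contrast) along a contour polyline (NaN if degenerate)."""
    if len(polyline) < 2:
        return float("nan")
    d = np.diff(polyline, axis=0)
    good = d[:, 0] != 0
    if not good.any():
        return float("nan")
    return float(np.mean(d[good, 1] / d[good, 0]))
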