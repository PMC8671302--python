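"""RMS topographical maps, region-of-activity segmentation and centroids.

A cleaned differential epoch yields one RMS value per channel, arranged by
grid position into a (n_rows-1) x n_cols image.  The image is upsampled
(bicubic, factor 15 by default, giving a pixel pitch of ied/15 mm) and the
Region of Activity (ROA) is segmented with a two-phase Chan-Vese active
contour whenever the map's spatial mean exceeds the noise level (5 uV_RMS
by default); otherwise the whole map is the ROA.  RMS_ROA is the spatial
mean of the map inside the ROA, and the ROA centroid is the
intensity-weighted centre of mass of the masked pixels.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.interpolate import RectBivariateSpline
from skimage.filters import threshold_otsu as _otsu
from skimage.measure import label as _cc_label
from skimage.segmentation import chan_vese as _chan_vese

from .core import DifferentialEpoch, RegionOfActivity, RmsMap
from .preprocess import channel_rms

__all__ = [
    "compute_rms_map",
    "interpolate_map",
    "segment_roa",
    "centroid",
    "centroid_displacement",
    "estimate_noise_level",
    "DEFAULT_NOISE_LEVEL_UV",
]

#: conservative baseline noise level of an RMS map (uV_RMS): about twice the
#: mean and 1.5 times the maximum of the resting-condition map means.
DEFAULT_NOISE_LEVEL_UV = 5.0


def compute_rms_map(
    diff: DifferentialEpoch,
    bad_rms_factor: float = 10.0,
    max_excluded_fraction: float = 0.25,
) -> RmsMap:
    """Per-channel RMS arranged by grid position.

    Channels that are non-finite or whose RMS exceeds ``bad_rms_factor``
    times the grid median are excluded and imputed as the mean of their
    valid 4-neighbours.  If more than ``max_excluded_fraction`` of channels
    are excluded the trial is rejected.
    """
    finite = np.isfinite(diff.samples).all(axis=-1)
    vals = np.full(diff.samples.shape[:2], np.nan)
    vals[finite] = channel_rms(diff.samples[finite], axis=-1)
    med = np.nanmedian(vals)
    bad = ~finite | (vals > bad_rms_factor * med)
    n_bad = int(bad.sum())
    if n_bad > max_excluded_fraction * bad.size:
        raise ValueError(
            f"{n_bad}/{bad.size} channels excluded; trial unusable "
            f"(limit {max_excluded_fraction:.0%})"
        )
    if n_bad:
        vals[bad] = np.nan
        ny, nx = vals.shape
        for r, c in zip(*np.nonzero(bad)):
            neigh = [
                vals[rr, cc]
                for rr, cc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1))
                if 0 <= rr < ny and 0 <= cc < nx and np.isfinite(vals[rr, cc])
            ]
            if not neigh:
                raise ValueError(f"channel ({r}, {c}) has no valid neighbours to impute from")
            vals[r, c] = float(np.mean(neigh))
    ied = diff.grid.ied_mm
    return RmsMap(values=vals, pixel_mm=(ied, ied), key=diff.key)


def interpolate_map(m: RmsMap, factor: int = 15) -> RmsMap:
    """Bicubic upsampling by ``factor`` per axis.

    The upsampled image samples a bicubic spline through the native pixel
    centres on a grid with pitch exactly ied/factor mm, covering the native
    map extent; values are clamped to >= 0 (RMS cannot be negative).
    """
    if factor < 1:
        raise ValueError("interpolation factor must be >= 1")
    if factor == 1:
        return m
    ny, nx = m.values.shape
    dx, dy = m.pixel_mm
    x = np.arange(nx) * dx
    y = np.arange(ny) * dy
    kx = min(3, nx - 1)
    ky = min(3, ny - 1)
    spline = RectBivariateSpline(y, x, m.values, kx=ky, ky=kx)
    xf = np.arange((nx - 1) * factor + 1) * (dx / factor)
    yf = np.arange((ny - 1) * factor + 1) * (dy / factor)
    vals = np.clip(spline(yf, xf), 0.0, None)
    return RmsMap(
        values=vals,
        pixel_mm=(dx / factor, dy / factor),
        key=m.key,
        orientation=m.orientation,
        interpolated=True,
    )


def _pick_component(mask: np.ndarray, img: np.ndarray) -> np.ndarray:
    """Keep the connected component with the highest mean intensity."""
    lab, n = _cc_label(mask, return_num=True, connectivity=1)
    if n <= 1:
        return mask
    means = [img[lab == i].mean() for i in range(1, n + 1)]
    return lab == (1 + int(np.argmax(means)))


def segment_roa(
    m: RmsMap,
    noise_level: float = DEFAULT_NOISE_LEVEL_UV,
    mu: float = 0.25,
    max_iter: int = 200,
    tol: float = 1e-3,
) -> RegionOfActivity:
    """Segment the Region of Activity of an RMS map.

    If the map's spatial mean exceeds ``noise_level`` the ROA is found by
    two-phase Chan-Vese active-contour segmentation (smoothing weight
    ``mu``, lambda1 = lambda2 = 1) run on the map normalized by its
    maximum, initialized from the Otsu threshold of the normalized map.
    Both the image and the initialization then depend only on relative
    contrast, so the segmentation commutes with amplitude scaling and the
    solver converges well within the iteration cap (an absolute-threshold
    initialization leaves the contour far from equilibrium at the cap,
    making the mask depend on overall map amplitude and biasing
    between-condition amplitude ratios).  The connected component with the
    highest mean is kept.  Degenerate segmentations (empty or
    all-foreground) fall back to the noise-threshold mask with a warning.
    Otherwise the whole map is used (``used_full_map``).
    """
    vals = m.values
    if vals.mean() > noise_level:
        vmax = vals.max()
        img = (vals / vmax).astype(np.float32)
        init = np.where(img > _otsu(img), 1.0, -1.0)
        mask = _chan_vese(
            img,
            mu=mu,
            lambda1=1.0,
            lambda2=1.0,
            tol=tol,
            max_num_iter=max_iter,
            init_level_set=init,
        )
        # Chan-Vese labels the two phases arbitrarily; take the brighter one.
        if mask.any() and not mask.all() and vals[mask].mean() < vals[~mask].mean():
            mask = ~mask
        if not mask.any() or mask.all():
            warnings.warn(
                "degenerate active-contour result; falling back to threshold mask",
                stacklevel=2,
            )
            mask = vals > noise_level
            if not mask.any() or mask.all():
                return _full_map_roa(m, noise_level)
        mask = _pick_component(mask, vals)
        rms_roa = float(vals[mask].mean())
        roa = RegionOfActivity(
            mask=mask,
            used_full_map=False,
            rms_roa=rms_roa,
            centroid_mm=(np.nan, np.nan),
            noise_level=noise_level,
        )
    else:
        roa = _full_map_roa(m, noise_level)
    if m.values[roa.mask].sum() > 0:
        roa.centroid_mm = centroid(m, roa)
    return roa


def _full_map_roa(m: RmsMap, noise_level: float) -> RegionOfActivity:
    return RegionOfActivity(
        mask=np.ones_like(m.values, dtype=bool),
        used_full_map=True,
        rms_roa=float(m.values.mean()),
        centroid_mm=(np.nan, np.nan),
        noise_level=noise_level,
    )


def centroid(m: RmsMap, roa: RegionOfActivity) -> tuple[float, float]:
    """Intensity-weighted centre of mass (X_CM, Y_CM) in mm.

    Coordinates are measured from the top-left pixel centre of the map,
    x along columns, y along rows; only pixels inside the ROA mask
    contribute.
    """
    mask = roa.mask
    w = m.values[mask]
    total = w.sum()
    if total <= 0:
        raise ValueError("total intensity inside the ROA is zero")
    x, y = m.coords_mm()
    yy, xx = np.nonzero(mask)
    return float((x[xx] * w).sum() / total), float((y[yy] * w).sum() / total)


def centroid_displacement(track: pd.DataFrame) -> pd.DataFrame:
    """Chair-related displacement of the ROA centroid over the session.

    ``track`` holds one row per (subject, chair, side, trial_index) with
    columns ``x_cm_mm`` and ``y_cm_mm``.  For each subject and side the
    displacement difference is

        D = (CM_A - CM_SS) at the last trial - (CM_A - CM_SS) at the first,

    per coordinate, in mm.  Subjects missing an endpoint trial for either
    chair are skipped.
    """
    required = {"subject", "chair", "side", "trial_index", "x_cm_mm", "y_cm_mm"}
    missing = required - set(track.columns)
    if missing:
        raise ValueError(f"track table lacks columns {sorted(missing)}")
    first = int(track["trial_index"].min())
    last = int(track["trial_index"].max())
    out = []
    for (subject, side), g in track.groupby(["subject", "side"]):
        piv = g.set_index(["chair", "trial_index"])
        try:
            d_end_x = piv.loc[("A", last), "x_cm_mm"] - piv.loc[("SS", last), "x_cm_mm"]
            d_start_x = piv.loc[("A", first), "x_cm_mm"] - piv.loc[("SS", first), "x_cm_mm"]
            d_end_y = piv.loc[("A", last), "y_cm_mm"] - piv.loc[("SS", last), "y_cm_mm"]
            d_start_y = piv.loc[("A", first), "y_cm_mm"] - piv.loc[("SS", first), "y_cm_mm"]
        except KeyError:
            continue
        out.append(
            {
                "subject": subject,
                "side": side,
                "delta_x_mm": float(d_end_x - d_start_x),
                "delta_y_mm": float(d_end_y - d_start_y),
            }
        )
    return pd.DataFrame(out, columns=["subject", "side", "delta_x_mm", "delta_y_mm"])


def estimate_noise_level(resting_map_means: np.ndarray) -> float:
    """Conservative noise level from resting-condition map spatial means:
    max(2 x mean, 1.5 x max)."""
    m = np.asarray(resting_map_means, dtype=float)
    if m.size == 0:
        raise ValueError("need at least one resting map mean")
    return float(max(2.0 * m.mean(), 1.5 * m.max()))
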