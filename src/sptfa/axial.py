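"""3D localization post-processing: lateral drift correction, mean-z maps
and per-region axial distributions with fitted occurrence peaks.

z coordinates are absolute heights above the coverslip/sample interface
(nm) and are taken as input; only lateral (xy) drift is corrected, the
axial coordinate being drift-free by construction of the detection scheme.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import curve_fit

from .io import INSIDE_FA, OUTSIDE_FA, LocalizationTable, RegionMaskSet

logger = logging.getLogger("sptfa")


# ---------------------------------------------------------------------------
# drift correction


def _block_histogram(x, y, extent, pixel):
    (x0, x1), (y0, y1) = extent
    nx = max(1, int(np.ceil((x1 - x0) / pixel)))
    ny = max(1, int(np.ceil((y1 - y0) / pixel)))
    h, _, _ = np.histogram2d(y, x, bins=(ny, nx),
                             range=((y0, y0 + ny * pixel), (x0, x0 + nx * pixel)))
    return h


def _quadratic_peak(c: np.ndarray, idx: int) -> float:
    """Subpixel peak position by quadratic interpolation around idx."""
    if idx <= 0 or idx >= len(c) - 1:
        return float(idx)
    denom = c[idx - 1] - 2 * c[idx] + c[idx + 1]
    if denom == 0:
        return float(idx)
    return idx + 0.5 * (c[idx - 1] - c[idx + 1]) / denom


def _xcorr_shift(ref: np.ndarray, img: np.ndarray) -> tuple[float, float]:
    """(dy, dx) shift of img relative to ref from the cross-correlation peak."""
    f = np.fft.rfft2(ref) * np.conj(np.fft.rfft2(img))
    c = np.fft.irfft2(f, s=ref.shape)
    c = np.fft.fftshift(c)
    iy, ix = np.unravel_index(np.argmax(c), c.shape)
    py = _quadratic_peak(c[:, ix], iy)
    px = _quadratic_peak(c[iy, :], ix)
    dy = py - ref.shape[0] // 2
    dx = px - ref.shape[1] // 2
    return -dy, -dx  # img appears shifted by (+dy, +dx) => drift is opposite


def drift_correct_xy(
    table: LocalizationTable,
    block_frames: int = 2000,
    corr_pixel: float = 0.05,
) -> tuple[LocalizationTable, pd.DataFrame]:
    """Correct lateral drift by block-wise image cross-correlation.

    Localizations are binned into temporal blocks of ``block_frames``; the
    2D histogram of each block is cross-correlated against block 1 and the
    correlation peak (subpixel, quadratic interpolation) gives the block
    shift.  Shifts are interpolated linearly per frame and subtracted from
    x/y; z is untouched.  Returns the corrected table and the per-frame
    drift trace.  A single block yields the identity transform.
    """
    df = table.df.copy()
    frames = df["frame"].to_numpy(dtype=np.int64)
    x = df["x_um"].to_numpy(dtype=float)
    y = df["y_um"].to_numpy(dtype=float)
    n_frames = int(frames.max()) + 1
    n_blocks = max(1, int(np.ceil(n_frames / block_frames)))

    all_frames = np.arange(n_frames)
    if n_blocks == 1:
        trace = pd.DataFrame({"frame": all_frames, "dx_um": 0.0, "dy_um": 0.0})
        return LocalizationTable(df=df, frame_interval=table.frame_interval,
                                 pixel_size=table.pixel_size), trace

    pad = 10 * corr_pixel
    extent = ((x.min() - pad, x.max() + pad), (y.min() - pad, y.max() + pad))
    block_of = frames // block_frames
    centers = (np.arange(n_blocks) + 0.5) * block_frames
    shifts = np.full((n_blocks, 2), np.nan)  # (dx, dy) in µm
    ref = None
    for b in range(n_blocks):
        sel = block_of == b
        if not np.any(sel):
            continue
        h = _block_histogram(x[sel], y[sel], extent, corr_pixel)
        if ref is None:
            ref = h
            shifts[b] = (0.0, 0.0)
            continue
        dy, dx = _xcorr_shift(ref, h)
        shifts[b] = (dx * corr_pixel, dy * corr_pixel)
    # interpolate missing blocks (no localizations) from neighbors
    for k in range(2):
        col = shifts[:, k]
        bad = np.isnan(col)
        if np.any(bad):
            good = ~bad
            col[bad] = np.interp(centers[bad], centers[good], col[good])

    def _interp_extrap(f, xp, yp):
        out = np.interp(f, xp, yp)
        # linear extrapolation beyond the first/last block centers
        if len(xp) >= 2:
            lo = f < xp[0]
            hi = f > xp[-1]
            out[lo] = yp[0] + (f[lo] - xp[0]) * (yp[1] - yp[0]) / (xp[1] - xp[0])
            out[hi] = yp[-1] + (f[hi] - xp[-1]) * (yp[-1] - yp[-2]) / (xp[-1] - xp[-2])
        return out

    dx_f = _interp_extrap(all_frames.astype(float), centers, shifts[:, 0])
    dy_f = _interp_extrap(all_frames.astype(float), centers, shifts[:, 1])
    df["x_um"] = x - dx_f[frames]
    df["y_um"] = y - dy_f[frames]
    trace = pd.DataFrame({"frame": all_frames, "dx_um": dx_f, "dy_um": dy_f})
    corrected = LocalizationTable(df=df, frame_interval=table.frame_interval,
                                 pixel_size=table.pixel_size)
    return corrected, trace


# ---------------------------------------------------------------------------
# mean-z rendering


@dataclass
class MeanZMap:
    mean_z: np.ndarray        # nm; NaN where no localization landed
    render_pixel: float       # µm
    origin: tuple[float, float]
    display_cut: float        # nm
    smoothing_kernel: int


def render_mean_z(
    table: LocalizationTable,
    render_pixel: float = 0.015,
    display_cut: float = 150.0,
    kernel: int = 5,
    extent: Optional[tuple[tuple[float, float], tuple[float, float]]] = None,
) -> MeanZMap:
    """Per-pixel mean axial position, smoothed with a mean filter.

    Localizations above ``display_cut`` (150 nm) are discarded before
    averaging.  The mean filter averages only *defined* pixels in each
    kernel window; pixels with zero localizations stay NaN.
    """
    if not table.has_z:
        raise ValueError("table has no z_nm column")
    df = table.df
    keep = df["z_nm"].to_numpy(dtype=float) <= display_cut
    x = df["x_um"].to_numpy(dtype=float)[keep]
    y = df["y_um"].to_numpy(dtype=float)[keep]
    z = df["z_nm"].to_numpy(dtype=float)[keep]
    if extent is None:
        if len(x) == 0:
            raise ValueError("no localizations below the display cut")
        x0, y0 = x.min(), y.min()
        nx = int(np.floor((x.max() - x0) / render_pixel)) + 1
        ny = int(np.floor((y.max() - y0) / render_pixel)) + 1
    else:
        (x0, x1), (y0, y1) = extent
        nx = max(1, int(np.ceil((x1 - x0) / render_pixel)))
        ny = max(1, int(np.ceil((y1 - y0) / render_pixel)))
    col = np.floor((x - x0) / render_pixel).astype(int)
    row = np.floor((y - y0) / render_pixel).astype(int)
    inb = (col >= 0) & (col < nx) & (row >= 0) & (row < ny)
    count = np.zeros((ny, nx))
    zsum = np.zeros((ny, nx))
    np.add.at(count, (row[inb], col[inb]), 1)
    np.add.at(zsum, (row[inb], col[inb]), z[inb])
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_z = zsum / count
    if kernel and kernel > 1:
        defined = count > 0
        num = ndimage.uniform_filter(np.where(defined, mean_z, 0.0), size=kernel)
        den = ndimage.uniform_filter(defined.astype(float), size=kernel)
        with np.errstate(invalid="ignore", divide="ignore"):
            smoothed = num / den
        mean_z = np.where(defined, smoothed, np.nan)
    return MeanZMap(mean_z=mean_z, render_pixel=render_pixel,
                    origin=(float(x0), float(y0)), display_cut=display_cut,
                    smoothing_kernel=kernel)


# ---------------------------------------------------------------------------
# z distributions


@dataclass
class AxialProfile:
    region: str
    bin_edges: np.ndarray    # nm
    counts: np.ndarray       # raw counts, sum == n
    z_peak: float            # nm, Gaussian-fitted occurrence maximum
    z_peak_err: float        # nm, 1-sigma fit uncertainty
    box_stats: dict          # median/mean/quartiles of z <= box_cut
    n: int
    low_confidence: bool


def _gauss(z, a, mu, sigma):
    return a * np.exp(-0.5 * ((z - mu) / sigma) ** 2)


def _fit_peak(edges: np.ndarray, counts: np.ndarray) -> tuple[float, float]:
    """Gaussian fit around the dominant histogram mode.

    The window starts at +-3 bins around the mode and grows until the
    fitted center moves by less than a tenth of a bin (or the window spans
    the whole histogram).  Falls back to the mode-bin center.
    """
    centers = 0.5 * (edges[:-1] + edges[1:])
    bw = edges[1] - edges[0]
    mode = int(np.argmax(counts))
    prev_mu = centers[mode]
    err = bw / 2.0
    for half in range(3, len(centers) + 1):
        lo = max(0, mode - half)
        hi = min(len(centers), mode + half + 1)
        zz, cc = centers[lo:hi], counts[lo:hi]
        if len(zz) < 4:
            continue
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, pcov = curve_fit(
                    _gauss, zz, cc,
                    p0=[counts[mode], centers[mode], max(bw, 2 * bw)],
                    maxfev=5000,
                )
            mu = float(popt[1])
            err = float(np.sqrt(pcov[1, 1])) if np.all(np.isfinite(pcov)) else bw / 2
        except (RuntimeError, ValueError):
            continue
        if abs(mu - prev_mu) < bw / 10.0 or hi - lo == len(centers):
            return mu, err
        prev_mu = mu
    return float(prev_mu), err


def z_profile(
    table: LocalizationTable,
    masks: Optional[RegionMaskSet] = None,
    bin_width: float = 10.0,
    box_cut: float = 200.0,
    min_n: int = 100,
) -> dict[str, AxialProfile]:
    """Per-region axial occurrence histograms with fitted z_peak.

    All detections enter the histogram (full range); the box statistics
    are computed only on the subset with z <= ``box_cut`` (200 nm).  When
    ``masks`` is None a single combined region ``"all"`` is profiled.
    """
    if not table.has_z:
        raise ValueError("table has no z_nm column")
    df = table.df
    x = df["x_um"].to_numpy(dtype=float)
    y = df["y_um"].to_numpy(dtype=float)
    z = df["z_nm"].to_numpy(dtype=float)
    if masks is None:
        regions = {"all": np.ones(len(z), dtype=bool)}
    else:
        on_fa = masks.fa_label_at(x, y) > 0
        in_cell = masks.in_cell(x, y)
        regions = {INSIDE_FA: on_fa, OUTSIDE_FA: in_cell & ~on_fa}

    out: dict[str, AxialProfile] = {}
    for name, sel in regions.items():
        zz = z[sel]
        if len(zz) == 0:
            logger.warning("region %s has no localizations; skipped", name)
            continue
        lo = min(0.0, np.floor(zz.min() / bin_width) * bin_width)
        hi = np.ceil(max(zz.max(), lo + bin_width) / bin_width) * bin_width
        edges = np.arange(lo, hi + bin_width / 2, bin_width)
        counts, _ = np.histogram(zz, bins=edges)
        z_peak, err = _fit_peak(edges, counts)
        z_peak = float(np.clip(z_peak, edges[0], edges[-1]))
        sub = zz[zz <= box_cut]
        box = {
            "median": float(np.median(sub)) if len(sub) else np.nan,
            "mean": float(np.mean(sub)) if len(sub) else np.nan,
            "q25": float(np.percentile(sub, 25)) if len(sub) else np.nan,
            "q75": float(np.percentile(sub, 75)) if len(sub) else np.nan,
            "n": int(len(sub)),
        }
        out[name] = AxialProfile(
            region=name,
            bin_edges=edges,
            counts=counts,
            z_peak=z_peak,
            z_peak_err=err,
            box_stats=box,
            n=int(len(zz)),
            low_confidence=len(zz) < min_n,
        )
    return out
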