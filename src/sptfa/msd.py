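"""MSD computation, diffusion-coefficient estimation and motion classification.

The decision tree per trajectory:

1. fewer than ``min_points`` localizations -> ``excluded``;
2. ``D`` (initial MSD slope / 4) below the immobility threshold
   ``fwhm^2 / (4 * slope_points * frame_interval)`` -> ``immobile``;
3. otherwise a weighted bounded-diffusion fit
   ``MSD(t) = (4 r_conf^2 / 3) (1 - exp(-t / tau))`` decides:
   ``tau < tau_threshold`` -> ``confined``, else ``free``.

All lags are frame-index differences, so blinking gaps contribute only the
pairs that actually exist at each lag.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .io import Trajectory

logger = logging.getLogger("sptfa")

EXCLUDED = "excluded"
IMMOBILE = "immobile"
CONFINED = "confined"
FREE = "free"
MODES = (IMMOBILE, CONFINED, FREE)


@dataclass
class MSDCurve:
    """Time-averaged MSD of one trajectory (gap-aware)."""

    lags: np.ndarray        # s, strictly increasing multiples of dt
    values: np.ndarray      # µm²
    pair_counts: np.ndarray  # number of displacement pairs per lag
    frame_interval: float

    def __len__(self) -> int:
        return len(self.lags)


@dataclass(frozen=True)
class ClassifierConfig:
    """Thresholds and windows of the motion classifier."""

    min_points: int = 13            # >= 13 points (260 ms at 50 Hz)
    slope_points: int = 4           # lags n = 1..4 for the initial slope
    resolution_fwhm: float = 0.059  # µm
    frame_interval: float = 0.02    # s
    fit_fraction: float = 0.8       # fraction of lags entering the bounded fit
    fit_min_points: int = 10        # floor of the fit window (200 ms)
    tau_threshold: Optional[float] = None  # s; derived when None
    tau_max: float = 100.0          # s, upper fit bound
    tau_min_factor: float = 0.1     # lower bound = factor * frame_interval

    def __post_init__(self):
        if self.fit_min_points < self.slope_points:
            raise ValueError("fit_min_points must be >= slope_points")
        for name in ("min_points", "slope_points", "resolution_fwhm",
                     "frame_interval", "fit_fraction", "fit_min_points"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def tau_split(self) -> float:
        """Confined/free split: half the minimum fit duration (100 ms default)."""
        if self.tau_threshold is not None:
            return self.tau_threshold
        return 0.5 * self.fit_min_points * self.frame_interval

    @property
    def min_duration(self) -> float:
        """Minimum track duration implied by the point filter, in s."""
        return self.min_points * self.frame_interval

    @property
    def fit_min_duration(self) -> float:
        """Minimum bounded-fit window duration, in s."""
        return self.fit_min_points * self.frame_interval


@dataclass
class MotionClassification:
    mode: str
    n_points: int
    D: float = np.nan            # µm²/s, initial slope / 4
    msd_slope: float = np.nan    # µm²/s, raw initial slope (= 4 D)
    r_conf: float = np.nan       # µm
    tau: float = np.nan          # s
    D_conf: float = np.nan       # µm²/s, r_conf² / (3 tau)
    fit_ok: bool = False


def compute_msd(traj: Trajectory) -> MSDCurve:
    """Time-averaged MSD over all pairs separated by n frames, n = 1..span.

    Only lags with at least one pair are reported, so gapped tracks yield
    a sparse lag grid.
    """
    frames = traj.frames
    x, y = traj.x, traj.y
    span = int(frames[-1] - frames[0])
    lags, values, counts = [], [], []
    for n in range(1, span + 1):
        j = np.searchsorted(frames, frames + n)
        valid = (j < len(frames))
        valid[valid] &= frames[j[valid]] == frames[valid] + n
        if not np.any(valid):
            continue
        i = np.nonzero(valid)[0]
        jj = j[i]
        sq = (x[jj] - x[i]) ** 2 + (y[jj] - y[i]) ** 2
        lags.append(n * traj.frame_interval)
        values.append(sq.mean())
        counts.append(len(i))
    return MSDCurve(
        lags=np.asarray(lags),
        values=np.asarray(values),
        pair_counts=np.asarray(counts, dtype=int),
        frame_interval=traj.frame_interval,
    )


def estimate_D(msd: MSDCurve, config: ClassifierConfig = ClassifierConfig()) -> float:
    """Diffusion coefficient from the initial MSD slope.

    Ordinary least squares with a free intercept through the first
    ``slope_points`` available lags; the intercept absorbs the constant
    localization-noise offset.  D = slope / 4 (2D convention); negative
    slopes pass through unclamped.
    """
    k = config.slope_points
    if len(msd) < k:
        raise ValueError(f"need at least {k} MSD lags, got {len(msd)}")
    t = msd.lags[:k]
    v = msd.values[:k]
    slope, _ = np.polyfit(t, v, 1)
    return float(slope) / 4.0


def initial_slope(msd: MSDCurve, config: ClassifierConfig = ClassifierConfig()) -> float:
    """Raw initial MSD slope (= 4 D), reported alongside D for transparency."""
    return 4.0 * estimate_D(msd, config)


def immobile_threshold(config: ClassifierConfig = ClassifierConfig()) -> float:
    """D below which a molecule explored less than one resolution cell.

    ``fwhm^2 / (4 * slope_points * frame_interval)``; with the defaults
    (0.059 µm, 4 points, 20 ms) this is ~0.011 µm²/s.
    """
    return config.resolution_fwhm ** 2 / (
        4.0 * config.slope_points * config.frame_interval
    )


def _confinement_model(t, r_conf, tau):
    return (4.0 * r_conf ** 2 / 3.0) * (1.0 - np.exp(-t / tau))


def fit_confinement(
    msd: MSDCurve,
    config: ClassifierConfig = ClassifierConfig(),
) -> tuple[float, float, float, bool]:
    """Weighted bounded-diffusion fit of the MSD.

    The window is the first ``max(fit_min_points, floor(fit_fraction *
    n_lags))`` lags (capped at what exists).  Weights are the per-lag pair
    counts, countering MSD down-sampling at large lags.  Returns
    ``(r_conf, tau, D_conf, fit_ok)``; on failure ``tau`` is pinned at the
    upper bound so the caller classifies the track as free.
    """
    n_lags = len(msd)
    n_fit = min(n_lags, max(config.fit_min_points, int(config.fit_fraction * n_lags)))
    t = msd.lags[:n_fit]
    v = msd.values[:n_fit]
    w = msd.pair_counts[:n_fit].astype(float)

    tau_lo = config.tau_min_factor * config.frame_interval
    tau_hi = config.tau_max
    vmax = float(np.max(v)) if np.max(v) > 0 else 1e-12
    r0 = np.sqrt(3.0 * vmax / 4.0)
    above = np.nonzero(v >= (1.0 - np.e ** -1) * vmax)[0]
    tau0 = float(t[above[0]]) if len(above) else float(t[-1])
    tau0 = min(max(tau0, tau_lo * 1.5), tau_hi * 0.5)

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                _confinement_model, t, v,
                p0=[max(r0, 1e-4), tau0],
                sigma=1.0 / np.sqrt(w),
                bounds=([1e-6, tau_lo], [np.inf, tau_hi]),
                maxfev=10000,
            )
        r_conf, tau = float(popt[0]), float(popt[1])
        fit_ok = tau_lo * 1.001 < tau < tau_hi * 0.999
    except (RuntimeError, ValueError):
        r_conf, tau, fit_ok = np.nan, tau_hi, False
    if not np.isfinite(tau) or tau <= 0:
        tau, fit_ok = tau_hi, False
    D_conf = r_conf ** 2 / (3.0 * tau) if np.isfinite(r_conf) else np.nan
    return r_conf, tau, D_conf, fit_ok


def classify(
    traj: Trajectory,
    config: ClassifierConfig = ClassifierConfig(),
) -> MotionClassification:
    """Three-way motion classification of one trajectory."""
    n = len(traj)
    if n < config.min_points:
        return MotionClassification(mode=EXCLUDED, n_points=n)
    msd = compute_msd(traj)
    if len(msd) < config.slope_points:
        # heavily gapped track without enough distinct lags
        return MotionClassification(mode=EXCLUDED, n_points=n)
    D = estimate_D(msd, config)
    result = MotionClassification(mode=IMMOBILE, n_points=n, D=D, msd_slope=4.0 * D)
    if D < immobile_threshold(config):
        return result
    r_conf, tau, D_conf, fit_ok = fit_confinement(msd, config)
    result.r_conf, result.tau, result.D_conf, result.fit_ok = r_conf, tau, D_conf, fit_ok
    result.mode = CONFINED if tau < config.tau_split else FREE
    return result


@dataclass
class CellSummary:
    cell_id: object
    region: str
    fractions: dict  # mode -> fraction over non-excluded tracks
    logD_histogram: np.ndarray  # normalized (sums to 1)
    logD_bin_edges: np.ndarray
    n_trajectories: int
    mean_D_free: float = np.nan


DEFAULT_LOGD_EDGES = np.linspace(-5.0, 1.0, 31)


def _logd_hist(D_values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    if len(D_values) == 0:
        return np.zeros(len(edges) - 1)
    logd = np.log10(np.clip(D_values, 10.0 ** edges[0], None))
    logd = np.clip(logd, edges[0], np.nextafter(edges[-1], -np.inf))
    counts, _ = np.histogram(logd, bins=edges)
    return counts / counts.sum()


def aggregate(
    records: Iterable[tuple[MotionClassification, str, object]],
    logd_edges: Sequence[float] = DEFAULT_LOGD_EDGES,
) -> tuple[list[CellSummary], dict]:
    """Per-cell mode fractions and log10(D) histograms, plus pooled mean ± SEM.

    ``records`` are ``(classification, region, cell_id)`` triples; excluded
    tracks are ignored.  Pooled statistics average *per-cell* values within
    each region (cells are the statistical unit), with SEM = sd / sqrt(n_cells)
    (sample sd, ddof=1; 0 for a single cell).
    """
    logd_edges = np.asarray(logd_edges, dtype=float)
    groups: dict[tuple, list[MotionClassification]] = {}
    for cls, region, cell_id in records:
        if cls.mode == EXCLUDED:
            continue
        groups.setdefault((cell_id, region), []).append(cls)

    summaries = []
    for (cell_id, region), items in sorted(groups.items(), key=lambda kv: str(kv[0])):
        n = len(items)
        fractions = {m: sum(c.mode == m for c in items) / n for m in MODES}
        D_all = np.array([c.D for c in items if np.isfinite(c.D)])
        free_D = [c.D for c in items if c.mode == FREE]
        summaries.append(CellSummary(
            cell_id=cell_id,
            region=region,
            fractions=fractions,
            logD_histogram=_logd_hist(D_all, logd_edges),
            logD_bin_edges=logd_edges,
            n_trajectories=n,
            mean_D_free=float(np.mean(free_D)) if free_D else np.nan,
        ))

    pooled: dict = {}
    for region in sorted({s.region for s in summaries}):
        cells = [s for s in summaries if s.region == region]
        frac = np.array([[s.fractions[m] for m in MODES] for s in cells])
        mean = frac.mean(axis=0)
        sem = (frac.std(axis=0, ddof=1) / np.sqrt(len(cells))
               if len(cells) > 1 else np.zeros(3))
        hist = np.mean([s.logD_histogram for s in cells], axis=0)
        pooled[region] = {
            "n_cells": len(cells),
            "fractions_mean": dict(zip(MODES, mean.tolist())),
            "fractions_sem": dict(zip(MODES, sem.tolist())),
            "logD_histogram_mean": hist.tolist(),
            "logD_bin_edges": logd_edges.tolist(),
        }
    if not summaries:
        logger.warning("aggregate called with no classified trajectories")
    return summaries, pooled


@dataclass
class ResolutionEstimate:
    s_xy: float   # µm, mean fitted sigma
    fwhm: float   # µm, 2.3 * s_xy
    n_clouds: int


def estimate_resolution(
    position_clouds: Iterable[Trajectory],
    min_points: int = 50,
) -> ResolutionEstimate:
    """Pointing accuracy from long immobile-molecule position clouds.

    Each cloud is fit with an isotropic 2D Gaussian: the maximum-likelihood
    sigma is the per-axis sample standard deviation, averaged over x and y
    (documented convention for anisotropic clouds).  The resolution FWHM is
    2.3 * s_xy.
    """
    sigmas = []
    for cloud in position_clouds:
        if len(cloud) < min_points:
            raise ValueError(
                f"cloud {cloud.id!r} has {len(cloud)} < {min_points} points"
            )
        sx = np.std(cloud.x, ddof=1)
        sy = np.std(cloud.y, ddof=1)
        sigmas.append(0.5 * (sx + sy))
    if not sigmas:
        raise ValueError("no position clouds supplied")
    s_xy = float(np.mean(sigmas))
    return ResolutionEstimate(s_xy=s_xy, fwhm=2.3 * s_xy, n_clouds=len(sigmas))
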