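"""Ground-truth-labeled synthetic inputs for every pipeline stage.

The generator emulates 50 Hz single-molecule acquisitions: mixed motion
modes (free Brownian, confined-in-disc, immobile), Gaussian localization
noise (~25 nm pointing accuracy per axis), geometric blinking gaps, FA-shaped
label masks, paired TIRF/epifluorescence frames and axial localization
clouds peaked a few tens of nm above the coverslip.

Determinism: one :class:`numpy.random.SeedSequence` per dataset; each
trajectory draws from a child stream spawned from ``(seed, trajectory_id)``
so identical seed + config reproduce tables bit-identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from enum import Enum
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import LocalizationTable, RegionMaskSet, Trajectory


class MotionMode(str, Enum):
    IMMOBILE = "immobile"
    CONFINED = "confined"
    FREE = "free"


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic acquisition."""

    frame_interval: float = 0.02  # s (50 Hz)
    n_frames: int = 50
    pointing_accuracy: float = 0.0255  # µm per axis (FWHM 2.3*s_xy ~ 59 nm)
    D_free: float = 0.2  # µm²/s
    disc_radius: float = 0.1  # µm
    D_conf: float = 0.1  # µm²/s
    mode_proportions: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    blink_off_prob: float = 0.0
    max_gap: int = 3
    rng_seed: int = 0
    field_size: tuple[float, float] = (20.0, 20.0)  # µm
    n_tracks: int = 300
    fa_fraction: float = 0.5  # fraction of tracks seeded on FA pixels

    def __post_init__(self):
        p = np.asarray(self.mode_proportions, dtype=float)
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("mode_proportions must be nonnegative and sum to 1")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if self.pointing_accuracy < 0:
            raise ValueError("pointing_accuracy must be >= 0")
        if self.D_free < 0 or self.D_conf < 0:
            raise ValueError("diffusion coefficients must be >= 0")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if not 0.0 <= self.blink_off_prob < 1.0:
            raise ValueError("blink_off_prob must be in [0, 1)")
        if not 0.0 <= self.fa_fraction <= 1.0:
            raise ValueError("fa_fraction must be in [0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruthLabel:
    trajectory_id: object
    true_mode: str
    true_D: float
    true_disc_radius: float
    inside_fa: bool

    def to_dict(self) -> dict:
        return asdict(self)


def _traj_rng(seed: int, trajectory_id: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(seed), int(trajectory_id))))


def _reflect_into_disc(p: np.ndarray, center: np.ndarray, radius: float) -> np.ndarray:
    """Radial mirror reflection at a circular boundary (iterated for big steps)."""
    for _ in range(64):
        d = p - center
        r = float(np.hypot(d[0], d[1]))
        if r <= radius:
            return p
        # fold the radial excess back inside; a negative factor (r > 2R)
        # reflects through the center and is folded again next iteration
        p = center + d * ((2.0 * radius - r) / r)
    d = p - center
    return center + d * (radius / np.linalg.norm(d))


def _blink_frames(n_frames: int, off_prob: float, max_gap: int,
                  rng: np.random.Generator) -> np.ndarray:
    """Frame indices retained after blinking; gaps clipped at max_gap."""
    if off_prob <= 0.0:
        return np.arange(n_frames)
    on = rng.random(n_frames) >= off_prob
    on[0] = True
    on[-1] = True
    # clip any off-run longer than max_gap (a real tracker would split there)
    gap = 0
    for i in range(n_frames):
        if on[i]:
            gap = 0
        else:
            gap += 1
            if gap > max_gap:
                on[i] = True
                gap = 0
    return np.nonzero(on)[0]


def simulate_trajectory(
    mode: MotionMode | str,
    config: SimulationConfig,
    origin: Sequence[float] = (0.0, 0.0),
    seed: Optional[int] = None,
    trajectory_id: object = 0,
    rng: Optional[np.random.Generator] = None,
) -> Trajectory:
    """Simulate one trajectory of the requested motion mode.

    free      -- per-axis Gaussian increments, variance ``2*D_free*dt``
    confined  -- same increments reflected at a disc of ``disc_radius``
                 centered on ``origin`` (using ``D_conf``)
    immobile  -- fixed true position

    Independent Gaussian localization noise (sigma = ``pointing_accuracy``
    per axis per frame) is added after the true path is drawn.
    """
    mode = MotionMode(mode)
    if rng is None:
        rng = np.random.default_rng(seed)
    n = config.n_frames
    if n < 2:
        raise ValueError("n_frames must be >= 2")
    origin = np.asarray(origin, dtype=float)
    dt = config.frame_interval

    if mode is MotionMode.IMMOBILE:
        pos = np.tile(origin, (n, 1))
    elif mode is MotionMode.FREE:
        steps = rng.normal(0.0, np.sqrt(2.0 * config.D_free * dt), size=(n - 1, 2))
        pos = origin + np.vstack([np.zeros(2), np.cumsum(steps, axis=0)])
    else:  # confined
        steps = rng.normal(0.0, np.sqrt(2.0 * config.D_conf * dt), size=(n - 1, 2))
        pos = np.empty((n, 2))
        pos[0] = origin
        for i in range(1, n):
            pos[i] = _reflect_into_disc(pos[i - 1] + steps[i - 1], origin,
                                        config.disc_radius)

    frames = _blink_frames(n, config.blink_off_prob, config.max_gap, rng)
    pos = pos[frames]
    if config.pointing_accuracy > 0:
        pos = pos + rng.normal(0.0, config.pointing_accuracy, size=pos.shape)
    return Trajectory(
        id=trajectory_id,
        frames=frames,
        x=pos[:, 0],
        y=pos[:, 1],
        frame_interval=dt,
    )


def _sample_origin(mask: RegionMaskSet, inside_fa: bool,
                   rng: np.random.Generator) -> np.ndarray:
    target = mask.fa_labels > 0 if inside_fa else (mask.cell_mask & (mask.fa_labels == 0))
    rows, cols = np.nonzero(target)
    if len(rows) == 0:
        raise ValueError("mask has no pixels for requested region")
    k = rng.integers(len(rows))
    jitter = rng.random(2)
    x = mask.origin[0] + (cols[k] + jitter[0]) * mask.pixel_size
    y = mask.origin[1] + (rows[k] + jitter[1]) * mask.pixel_size
    return np.array([x, y])


_MODE_ORDER = (MotionMode.IMMOBILE, MotionMode.CONFINED, MotionMode.FREE)


def simulate_dataset(
    config: SimulationConfig,
    mask: RegionMaskSet,
) -> tuple[LocalizationTable, list[GroundTruthLabel]]:
    """Simulate a labeled mixed-mode dataset placed on a region mask."""
    if not np.any(mask.cell_mask):
        raise ValueError("empty mask")
    master = np.random.default_rng(np.random.SeedSequence(int(config.rng_seed)))
    rows = []
    labels = []
    for tid in range(config.n_tracks):
        mode = _MODE_ORDER[master.choice(3, p=np.asarray(config.mode_proportions))]
        inside = bool(master.random() < config.fa_fraction)
        rng = _traj_rng(config.rng_seed, tid)
        origin = _sample_origin(mask, inside, rng)
        traj = simulate_trajectory(mode, config, origin, trajectory_id=tid, rng=rng)
        rows.append(pd.DataFrame({
            "track_id": tid,
            "frame": traj.frames,
            "x_um": traj.x,
            "y_um": traj.y,
        }))
        true_D = {MotionMode.IMMOBILE: 0.0, MotionMode.CONFINED: config.D_conf,
                  MotionMode.FREE: config.D_free}[mode]
        labels.append(GroundTruthLabel(
            trajectory_id=tid,
            true_mode=mode.value,
            true_D=true_D,
            true_disc_radius=config.disc_radius if mode is MotionMode.CONFINED else 0.0,
            inside_fa=inside,
        ))
    table = LocalizationTable(
        df=pd.concat(rows, ignore_index=True),
        frame_interval=config.frame_interval,
        pixel_size=mask.pixel_size,
    )
    return table, labels


def write_ground_truth(labels: list[GroundTruthLabel], path) -> None:
    with open(path, "w") as fh:
        json.dump([lab.to_dict() for lab in labels], fh, indent=1)


def make_fa_mask(
    shape: tuple[int, int] = (128, 128),
    pixel_size: float = 0.16,
    n_fa: int = 6,
    seed: int = 0,
    fa_half_axes: tuple[float, float] = (10.0, 3.0),  # pixels
) -> RegionMaskSet:
    """Synthetic cell outline (ellipse) with elongated FA-shaped labels."""
    ny, nx = shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    cy, cx = (ny - 1) / 2, (nx - 1) / 2
    cell = ((xx - cx) / (0.45 * nx)) ** 2 + ((yy - cy) / (0.45 * ny)) ** 2 <= 1.0
    rng = np.random.default_rng(seed)
    fa = np.zeros(shape, dtype=int)
    a, b = fa_half_axes
    placed = 0
    attempts = 0
    while placed < n_fa and attempts < 200:
        attempts += 1
        fy = rng.uniform(0.2 * ny, 0.8 * ny)
        fx = rng.uniform(0.2 * nx, 0.8 * nx)
        theta = rng.uniform(0, np.pi)
        u = (xx - fx) * np.cos(theta) + (yy - fy) * np.sin(theta)
        v = -(xx - fx) * np.sin(theta) + (yy - fy) * np.cos(theta)
        ell = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        if not np.all(cell[ell]):
            continue
        if np.any(fa[ell] > 0):
            continue
        placed += 1
        fa[ell] = placed
    return RegionMaskSet(fa_labels=fa, cell_mask=cell, pixel_size=pixel_size)


def simulate_intensity_pair(
    membrane_fraction_true: float,
    bg_level: float,
    gain: float,
    mask: RegionMaskSet,
    seed: Optional[int] = None,
    poisson: bool = False,
) -> tuple[np.ndarray, np.ndarray, list[np.ndarray]]:
    """Paired TIRF/epi images encoding a known membrane fraction.

    The cell foreground is encoded as *fold over background*: inside the
    cell TIRF = ``bg * gain * f`` (membrane subpopulation) and
    epi = ``bg * gain`` (all molecules), outside = ``bg``.  With this
    encoding the ratio-of-ratios estimator recovers ``f`` exactly in the
    noiseless case, which is what the exact tests rely on.
    """
    if not 0.0 <= membrane_fraction_true <= 1.0:
        raise ValueError("membrane_fraction_true must be in [0, 1]")
    if bg_level <= 0 or gain <= 0:
        raise ValueError("bg_level and gain must be > 0")
    cell = mask.cell_mask
    tirf = np.full(cell.shape, float(bg_level))
    epi = np.full(cell.shape, float(bg_level))
    tirf[cell] = bg_level * gain * membrane_fraction_true
    epi[cell] = bg_level * gain
    if poisson:
        rng = np.random.default_rng(seed)
        tirf = rng.poisson(tirf).astype(float)
        epi = rng.poisson(epi).astype(float)
    bg_rois = _corner_bg_rois(cell)
    return tirf, epi, bg_rois


def _corner_bg_rois(cell: np.ndarray, size: int = 8) -> list[np.ndarray]:
    """Three square background ROIs in cell-free corners."""
    ny, nx = cell.shape
    corners = [(0, 0), (0, nx - size), (ny - size, 0), (ny - size, nx - size)]
    rois = []
    for r0, c0 in corners:
        roi = np.zeros_like(cell, dtype=bool)
        roi[r0:r0 + size, c0:c0 + size] = True
        if not np.any(roi & cell):
            rois.append(roi)
        if len(rois) == 3:
            break
    if len(rois) < 3:
        raise ValueError("could not place 3 background ROIs outside the cell")
    return rois


def simulate_axial_cloud(
    z_center: float,
    z_sigma: float,
    n: int,
    region: RegionMaskSet,
    seed: Optional[int] = None,
    n_frames: int = 1000,
    inside_fa: bool = True,
) -> LocalizationTable:
    """Localization table with z ~ Gaussian(z_center, z_sigma) truncated at z >= 0.

    xy positions are uniform over the requested region (FA pixels when
    ``inside_fa`` else cell-not-FA pixels).
    """
    if n <= 0:
        raise ValueError("n must be > 0")
    rng = np.random.default_rng(seed)
    z = np.empty(0)
    while len(z) < n:
        draw = rng.normal(z_center, z_sigma, size=max(n, 16)) if z_sigma > 0 \
            else np.full(max(n, 16), float(z_center))
        z = np.concatenate([z, draw[draw >= 0]])
    z = z[:n]
    target = region.fa_labels > 0 if inside_fa else (region.cell_mask & (region.fa_labels == 0))
    rows, cols = np.nonzero(target)
    if len(rows) == 0:
        raise ValueError("region has no pixels")
    k = rng.integers(len(rows), size=n)
    jit = rng.random((n, 2))
    x = region.origin[0] + (cols[k] + jit[:, 0]) * region.pixel_size
    y = region.origin[1] + (rows[k] + jit[:, 1]) * region.pixel_size
    df = pd.DataFrame({
        "track_id": np.arange(n),
        "frame": rng.integers(0, n_frames, size=n),
        "x_um": x,
        "y_um": y,
        "z_nm": z,
    })
    return LocalizationTable(df=df, pixel_size=region.pixel_size)
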