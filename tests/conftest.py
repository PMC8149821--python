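import numpy as np
import pytest

from sptfa.io import RegionMaskSet, Trajectory
from sptfa.msd import ClassifierConfig
from sptfa.simulate import SimulationConfig, make_fa_mask


@pytest.fixture(scope="session")
def default_mask() -> RegionMaskSet:
    return make_fa_mask(seed=0)


@pytest.fixture
def clf_config() -> ClassifierConfig:
    return ClassifierConfig()


@pytest.fixture
def sim_config() -> SimulationConfig:
    return SimulationConfig()


@pytest.fixture
def straight_track() -> Trajectory:
    # x = 0,1,2,3 µm on a line; MSD = 1, 4, 9 µm²
    return Trajectory(
        id="line",
        frames=np.arange(4),
        x=np.array([0.0, 1.0, 2.0, 3.0]),
        y=np.zeros(4),
        frame_interval=0.02,
    )


def msd_brute_force(traj: Trajectory):
    """Independent O(N²) double-loop oracle for the MSD definition."""
    acc: dict[int, list[float]] = {}
    n_pts = len(traj.frames)
    for i in range(n_pts):
        for j in range(i + 1, n_pts):
            lag = int(traj.frames[j] - traj.frames[i])
            sq = (traj.x[j] - traj.x[i]) ** 2 + (traj.y[j] - traj.y[i]) ** 2
            acc.setdefault(lag, []).append(sq)
    lags = sorted(acc)
    values = np.array([np.mean(acc[n]) for n in lags])
    counts = np.array([len(acc[n]) for n in lags])
    return np.array(lags) * traj.frame_interval, values, counts


def random_gapped_track(rng: np.random.Generator, max_points: int = 30) -> Trajectory:
    n = int(rng.integers(2, max_points))
    frames = np.sort(rng.choice(200, size=n, replace=False))
    return Trajectory(
        id=int(rng.integers(1 << 30)),
        frames=frames,
        x=rng.normal(size=n),
        y=rng.normal(size=n),
        frame_interval=0.02,
    )
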