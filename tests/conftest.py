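import numpy as np
import pytest

from granmotion.trajsim import SimulationParams, Trajectory, simulate_trajectory


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_track(positions, dt=1.0, track_id="t0", condition=""):
    positions = np.asarray(positions, dtype=float)
    times = np.arange(len(positions), dtype=float) * dt
    return Trajectory(track_id=track_id, times=times, positions=positions,
                      condition=condition)


def brute_force_msd(positions, times, max_lag_fraction=1.0):
    """Independent double-loop MSD oracle (kept deliberately naive)."""
    positions = np.asarray(positions, dtype=float)
    times = np.asarray(times, dtype=float)
    base = min(times[i + 1] - times[i] for i in range(len(times) - 1))
    frames = [int(round((t - times[0]) / base)) for t in times]
    max_lag = int(np.floor(frames[-1] * max_lag_fraction))
    lags, msds, counts = [], [], []
    for lag in range(1, max_lag + 1):
        acc, cnt = 0.0, 0
        for i in range(len(frames)):
            for j in range(len(frames)):
                if frames[j] - frames[i] == lag:
                    d = positions[j] - positions[i]
                    acc += float(np.dot(d, d))
                    cnt += 1
        if cnt:
            lags.append(lag * base)
            msds.append(acc / cnt)
            counts.append(cnt)
    return np.array(lags), np.array(msds), np.array(counts)


@pytest.fixture
def brownian_track():
    params = SimulationParams(model="random", dim=3, D=0.02, sigma_loc=0.02,
                              n_steps=50, dt=1.0, seed=7)
    return simulate_trajectory(params, track_id="brownian")
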