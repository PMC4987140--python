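import numpy as np
import pytest

from circakit.cosinor import TimeSeries, damped_cosinor


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


def make_series(B=100.0, A=30.0, k=0.0, T=24.0, P=1.0, noise_sd=0.0,
                times=None, n_replicates=1, seed=0, series_id="s"):
    """Small helper used across test modules: model + optional noise."""
    if times is None:
        times = np.arange(2.0, 31.0, 4.0)
    times = np.asarray(times, dtype=float)
    rng = np.random.default_rng(seed)
    all_t, all_v, all_r = [], [], []
    clean = damped_cosinor(times, B, A, k, T, P)
    for r in range(n_replicates):
        noise = rng.normal(0, noise_sd, times.size) if noise_sd else 0.0
        all_t.append(times)
        all_v.append(clean + noise)
        all_r.append(np.repeat(f"r{r+1}", times.size))
    return TimeSeries(times=np.concatenate(all_t),
                      values=np.concatenate(all_v),
                      replicates=np.concatenate(all_r),
                      series_id=series_id)


def grid_search_ssres(times, values, period=24.0, n_phases=20000):
    """Independent cosinor oracle: exact (B, A) linear solve on a fine
    phase grid; returns the minimal residual sum of squares."""
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    omega = 2.0 * np.pi / period
    phases = np.linspace(0.0, 2.0 * np.pi, n_phases, endpoint=False)
    S = np.sin(omega * t[:, None] + phases[None, :])     # (n, J)
    n = t.size
    # per-phase normal equations for [1, sin(.)]
    s1 = S.sum(axis=0)
    s2 = (S * S).sum(axis=0)
    y1 = y.sum()
    y2 = y @ S
    det = n * s2 - s1 * s1
    B = (s2 * y1 - s1 * y2) / det
    A = (n * y2 - s1 * y1) / det
    resid = y[:, None] - (B[None, :] + A[None, :] * S)
    return float((resid ** 2).sum(axis=0).min())
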