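import numpy as np
import pytest

from dcepk.forward_model import TimeGrid, population_aif
from dcepk.simulator import SimConfig, generate_dataset, reference_plasma_curve


@pytest.fixture(scope="session")
def grid():
    return TimeGrid()


@pytest.fixture(scope="session")
def cb(grid):
    """Population arterial blood curve on the default 65-frame grid."""
    return population_aif(grid)


@pytest.fixture(scope="session")
def reference_cp():
    """Channel-1 reference plasma curve (SF = 1, no delay, no dispersion)."""
    return reference_plasma_curve(SimConfig(n_samples=1))


@pytest.fixture(scope="session")
def toy_dataset():
    """Small full-condition dataset shared across training-based tests."""
    return generate_dataset(SimConfig(n_samples=600, seed=42))


def brute_force_curves(tau_d, sf, hct, kep, ve, vp, tau_bat, grid,
                       fine_dt=0.01):
    """Independent quadrature oracle on a 0.01 s grid.

    Evaluates the population AIF closed form directly, convolves with the
    dispersion and residue kernels by trapezoidal convolution, and samples
    at the frame times.  Returns (cp_frames, ct_frames).
    """
    from dcepk.forward_model import PARKER_AIF_PARAMS, _parker_form

    t = np.arange(0.0, grid.duration + fine_dt / 2, fine_dt)
    cb_f = _parker_form(t, PARKER_AIF_PARAMS)
    cb_f[t <= 0] = 0.0

    def conv_trap(x, k):
        full = np.convolve(x, k)[: len(x)] * fine_dt
        full -= 0.5 * fine_dt * (x[0] * k + x * k[0])
        return full

    if tau_d > 0:
        kern = (1.0 / tau_d) * np.exp(-t / tau_d)
        cp_f = conv_trap(cb_f, kern)
    else:
        cp_f = cb_f.copy()
    cp_f *= sf / (1.0 - hct)
    cps = np.interp(t - tau_bat, t, cp_f, left=0.0)
    cps[t <= tau_bat] = 0.0
    ks = kep / 60.0
    conv = conv_trap(cps, np.exp(-ks * t))
    ct_f = ks * ve * conv + vp * cps
    step = int(round(grid.dt / fine_dt))
    return cp_f[::step], ct_f[::step]
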