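import numpy as np
import pytest

from dynpet import phantom as ph


@pytest.fixture(scope="session")
def noiseless_scene():
    return ph.default_scene(alpha=0.0)


@pytest.fixture(scope="session")
def noiseless_tacs(noiseless_scene):
    return ph.simulate_scene_tacs(noiseless_scene)


@pytest.fixture(scope="session")
def noiseless_voxels(noiseless_scene):
    return ph.voxelize_scene(noiseless_scene)


def brute_force_tissue(tp, aif, times, step=0.005):
    """Independent trapezoidal convolution oracle for the tissue model.

    Evaluates (1−vb)·[K1·∫Cp·e^{−k2(t−s)}ds + Ki·∫Cp ds] + vb·Cp(t) by
    direct quadrature at half the implementation's grid step.
    """
    out = np.empty(len(times))
    for j, t in enumerate(times):
        n = max(int(round(t / step)), 1)
        s = np.linspace(0.0, t, n + 1)
        cp = np.asarray(ph.aif_value(aif, s))
        conv = np.trapezoid(cp * np.exp(-tp.k2 * (t - s)), s)
        trap = np.trapezoid(cp, s)
        out[j] = ((1 - tp.vb) * (tp.K1 * conv + tp.Ki * trap)
                  + tp.vb * float(ph.aif_value(aif, t)))
    return out
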