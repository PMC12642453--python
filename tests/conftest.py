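import numpy as np
import pytest

from mlipal import (AxisPositionCV, Dataset, DoubleWell1D, MuellerBrown2D,
                    TriatomicExchange)


@pytest.fixture
def double_well():
    return DoubleWell1D()


@pytest.fixture
def dw_config(double_well):
    return double_well.make_configuration((-1.0,))


@pytest.fixture
def triatomic():
    return TriatomicExchange()


@pytest.fixture
def mueller_brown():
    return MuellerBrown2D()


@pytest.fixture
def dw_cv():
    return AxisPositionCV(0, 0, name="x")


@pytest.fixture
def dw_dataset(double_well):
    """30 labelled configurations spread over both wells of the double well."""
    rng = np.random.default_rng(0)
    ds = Dataset()
    for x in np.linspace(-1.4, 1.4, 30):
        c = double_well.make_configuration((x + 0.01 * rng.standard_normal(),))
        ds.append(double_well.label(c))
    return ds


def finite_difference_forces(potential, config, step=1e-5):
    """Central finite-difference forces for gradient contracts."""
    f = np.zeros_like(config.positions)
    work = config.copy()
    for i in range(config.n_atoms):
        for ax in range(3):
            if config.frozen_axes is not None and config.frozen_axes[i, ax]:
                continue
            work.positions[:] = config.positions
            work.positions[i, ax] += step
            ep = potential.energy_forces(work)[0]
            work.positions[i, ax] -= 2 * step
            em = potential.energy_forces(work)[0]
            f[i, ax] = -(ep - em) / (2 * step)
    return f
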