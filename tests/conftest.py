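import numpy as np
import pytest

from ergtherm.core import ERGTrace, Stimulus


def make_trace(
    voltage,
    fs_hz=10_000.0,
    flash_index=0,
    pre_stim_s=0.0,
    cls="dim",
    wavelength_nm=532,
    strength=1.0,
    temperature_C=37.0,
    clock_time_s=0.0,
    retina_id="r1",
):
    """Bare ERGTrace around a voltage array, for unit tests."""
    return ERGTrace(
        voltage_uV=np.asarray(voltage, dtype=float),
        fs_hz=fs_hz,
        flash_index=flash_index,
        pre_stim_s=pre_stim_s,
        stimulus=Stimulus(wavelength_nm=wavelength_nm, strength_rstar=strength, cls=cls),
        retina_id=retina_id,
        clock_time_s=clock_time_s,
        temperature_C=temperature_C,
    )


@pytest.fixture
def trace_factory():
    return make_trace


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
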