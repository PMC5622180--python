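"""Seeded synthetic-data generation with known ground truth.

Two levels are generated, matching the two halves of the pipeline:

Feature level
    Relative feature values are drawn directly from the calibrated
    linear model x_rel = 1 + slope·(T − 37) + eps, eps ~ N(0, rmsd),
    with the per-feature slope and residual scatter taken from the
    published training-data calibration (:data:`TABLE1`). This is the
    statistical ground truth for the regression/selection stage.

Waveform level
    Raw 10 kHz ERG traces are synthesized from analytic a-/b-wave
    templates whose kinetics compress uniformly with temperature and
    whose amplitudes scale linearly per stimulus wavelength, so the
    full extract→normalize→fit pipeline can be exercised end to end
    with analytic ground truth.

Both generators are deterministic given a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import DEFAULT_FS_HZ, ERGTrace, Session, Stimulus
from .exceptions import ParameterError
from .features import FEATURE_NAMES, META_COLUMNS

__all__ = [
    "TABLE1",
    "FeatureGenSpec",
    "table1_defaults",
    "simulate_feature_table",
    "WaveformGenSpec",
    "simulate_waveform",
    "simulate_session",
    "dim_template",
    "bright_template",
]

#: Per-feature calibration: (slope in relative units per °C, residual sd
#: in relative units, published RMSD/|slope| ratio in °C).
TABLE1: dict[str, tuple[float, float, float]] = {
    "a10": (-0.024, 0.019, 0.79),
    "a20": (-0.025, 0.019, 0.76),
    "a30": (-0.025, 0.021, 0.84),
    "a40": (-0.024, 0.024, 1.00),
    "a50": (-0.023, 0.028, 1.19),
    "a60": (-0.023, 0.030, 1.32),
    "a70": (-0.023, 0.032, 1.40),
    "a80": (-0.023, 0.031, 1.39),
    "a90": (-0.022, 0.033, 1.47),
    "a100": (-0.023, 0.034, 1.46),
    "aip": (-0.024, 0.029, 1.22),
    "aa": (-0.040, 0.056, 1.40),
    "b10L": (-0.024, 0.028, 1.16),
    "b20L": (-0.024, 0.029, 1.21),
    "b30L": (-0.024, 0.026, 1.09),
    "b40L": (-0.024, 0.024, 1.01),
    "b50L": (-0.024, 0.023, 0.95),
    "b60L": (-0.025, 0.022, 0.89),
    "b70L": (-0.025, 0.021, 0.85),
    "b80L": (-0.025, 0.020, 0.81),
    "b90L": (-0.026, 0.019, 0.74),
    "b100": (-0.035, 0.022, 0.64),
    "b90T": (-0.033, 0.017, 0.52),
    "b80T": (-0.034, 0.016, 0.47),
    "b70T": (-0.034, 0.016, 0.47),
    "b60T": (-0.034, 0.017, 0.49),
    "b50T": (-0.035, 0.018, 0.51),
    "b40T": (-0.035, 0.019, 0.54),
    "b30T": (-0.035, 0.021, 0.59),
    "b20T": (-0.036, 0.026, 0.73),
    "b10T": (-0.040, 0.050, 1.24),
    "bit": (-0.044, 0.038, 0.88),
    "ba": (-0.063, 0.085, 1.34),
    "LRS": (-0.032, 0.032, 0.99),
}

#: Feature families sharing a common noise factor when rho > 0.
_FAMILIES: dict[str, tuple[str, ...]] = {
    "a_kinetics": tuple(f"a{x}" for x in range(10, 101, 10)) + ("aip",),
    "a_amp": ("aa",),
    "b_leading": tuple(f"b{x}L" for x in range(10, 91, 10)) + ("b100",),
    "b_trailing": tuple(f"b{x}T" for x in range(10, 91, 10)) + ("bit",),
    "b_amp": ("ba",),
    "lrs": ("LRS",),
}
_FAMILY_OF = {f: fam for fam, members in _FAMILIES.items() for f in members}


@dataclass(frozen=True)
class FeatureGenSpec:
    """Conditions for feature-level simulation.

    Defaults reproduce the published study layout: 8 training and 5
    test retinas, each recorded at 15 temperatures drawn uniformly from
    35.0–44.0 °C, with 37.0 °C reference observations every 20 min;
    slopes and residual sds per feature come from :data:`TABLE1` and
    residuals are independent across features unless ``rho`` > 0 (then
    features of one family share a Gaussian factor with weight
    sqrt(rho)).
    """

    slopes: Mapping[str, float] = field(
        default_factory=lambda: {k: v[0] for k, v in TABLE1.items()}
    )
    rmsds: Mapping[str, float] = field(
        default_factory=lambda: {k: v[1] for k, v in TABLE1.items()}
    )
    features: tuple[str, ...] = FEATURE_NAMES
    temp_range_C: tuple[float, float] = (35.0, 44.0)
    temps_per_retina: int = 15
    n_train_retinas: int = 8
    n_test_retinas: int = 5
    reference_interval_s: float = 1200.0
    obs_interval_s: float = 180.0
    rho: float = 0.0
    drift_per_s: Mapping[str, float] | None = None
    ref_temperature_C: float = 37.0
    ref_tolerance_C: float = 0.05

    def __post_init__(self) -> None:
        lo, hi = self.temp_range_C
        if not (30.0 <= lo <= hi <= 45.0):
            raise ParameterError("temperature range must lie within [30, 45] °C")
        if not (0.0 <= self.rho < 1.0):
            raise ParameterError("rho must be in [0, 1)")
        for f in self.features:
            if f not in self.slopes or f not in self.rmsds:
                raise ParameterError(f"no slope/rmsd calibration for feature {f!r}")
            if self.rmsds[f] < 0:
                raise ParameterError(f"negative rmsd for feature {f!r}")
        if self.temps_per_retina < 1 or self.n_train_retinas < 0:
            raise ParameterError("counts must be positive")


def table1_defaults() -> FeatureGenSpec:
    """Feature-generation spec with the published per-feature calibration."""
    return FeatureGenSpec()


def _draw_noise(rng: np.random.Generator, spec: FeatureGenSpec) -> dict[str, float]:
    eps: dict[str, float] = {}
    if spec.rho > 0:
        shared = {fam: rng.standard_normal() for fam in _FAMILIES}
        for f in spec.features:
            z = math.sqrt(spec.rho) * shared[_FAMILY_OF[f]] + math.sqrt(
                1.0 - spec.rho
            ) * rng.standard_normal()
            eps[f] = spec.rmsds[f] * z
    else:
        for f in spec.features:
            eps[f] = spec.rmsds[f] * rng.standard_normal()
    return eps


def _feature_row(
    rng: np.random.Generator, spec: FeatureGenSpec, temperature_C: float, t_s: float
) -> dict[str, float]:
    eps = _draw_noise(rng, spec)
    row = {}
    for f in spec.features:
        x = 1.0 + spec.slopes[f] * (temperature_C - 37.0) + eps[f]
        if spec.drift_per_s:
            x *= 1.0 + spec.drift_per_s.get(f, 0.0) * t_s
        row[f] = x
    return row


def _draw_temperature(rng: np.random.Generator, spec: FeatureGenSpec) -> float:
    """Stimulus temperature; the 37.0 °C reference band is excluded so
    that reference blocks remain unambiguous."""
    lo, hi = spec.temp_range_C
    for _ in range(1000):
        T = float(rng.uniform(lo, hi))
        if abs(T - spec.ref_temperature_C) > spec.ref_tolerance_C:
            return T
    return lo  # degenerate range pinned at the reference; caller's choice


def simulate_feature_table(
    spec: FeatureGenSpec = FeatureGenSpec(), seed: int | None = 0
) -> pd.DataFrame:
    """Simulate a relative feature table with ground-truth temperatures.

    Returns one row per observation with the standard metadata columns
    plus a ``split`` column ('train' or 'test'). ``temperature_C`` is
    the ground truth. Output is bit-identical for identical seeds.
    """
    rng = np.random.default_rng(seed)
    rows = []
    names = [f"train{i + 1:02d}" for i in range(spec.n_train_retinas)] + [
        f"test{i + 1:02d}" for i in range(spec.n_test_retinas)
    ]
    for rid in names:
        split = "train" if rid.startswith("train") else "test"
        t = 0.0
        last_ref = -math.inf
        emitted = 0
        while emitted < spec.temps_per_retina:
            if t - last_ref >= spec.reference_interval_s:
                rows.append(
                    {
                        "retina_id": rid,
                        "clock_time_s": t,
                        "temperature_C": spec.ref_temperature_C,
                        "is_reference": True,
                        "split": split,
                        **_feature_row(rng, spec, spec.ref_temperature_C, t),
                    }
                )
                last_ref = t
            else:
                T = _draw_temperature(rng, spec)
                rows.append(
                    {
                        "retina_id": rid,
                        "clock_time_s": t,
                        "temperature_C": T,
                        "is_reference": False,
                        "split": split,
                        **_feature_row(rng, spec, T, t),
                    }
                )
                emitted += 1
            t += spec.obs_interval_s
        # closing reference so interpolation has a flanking value
        rows.append(
            {
                "retina_id": rid,
                "clock_time_s": t,
                "temperature_C": spec.ref_temperature_C,
                "is_reference": True,
                "split": split,
                **_feature_row(rng, spec, spec.ref_temperature_C, t),
            }
        )
    cols = list(META_COLUMNS) + ["split"] + list(spec.features)
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# Waveform level


@dataclass(frozen=True)
class WaveformGenSpec:
    """Analytic waveform templates and their temperature dependence.

    Kinetics: all event times scale by (1 + kinetics_coeff·(T − 37)),
    i.e. responses get uniformly faster by ~3% per °C of warming.
    Amplitudes: linear per-wavelength factors; the 780 nm coefficient is
    derived from the 532 nm one so the 532/780 amplitude ratio (the LRS
    feature) declines by ``lrs_coeff`` per °C. The dim b-wave is a gamma
    bump with a small slow undershoot (so the response crosses zero
    after the peak); the bright response is a fast saturating negative
    a-wave blended into a larger, slower positive b-wave.
    """

    fs_hz: float = DEFAULT_FS_HZ
    pre_stim_s: float = 0.5
    post_stim_s: float = 1.2
    # dim b-wave template (per wavelength amplitudes at 37 °C)
    b_amp_uV: float = 30.0
    b_tpeak_s: float = 0.120
    b_shape: float = 4.0
    undershoot_frac: float = 0.05
    undershoot_stretch: float = 3.0
    # bright-flash template
    a_amp_uV: float = 150.0
    a_tau_s: float = 0.030
    ab_amp_uV: float = 250.0
    ab_tpeak_s: float = 0.150
    # temperature coefficients (per °C)
    kinetics_coeff: float = -0.03
    amp_coeff_532: float = -0.019
    lrs_coeff: float = -0.032
    noise_sd_uV: float = 0.5
    temp_range_C: tuple[float, float] = (35.0, 44.0)

    def __post_init__(self) -> None:
        if self.b_amp_uV <= 0 or self.a_amp_uV <= 0 or self.ab_amp_uV <= 0:
            raise ParameterError("template amplitudes must be positive")
        if self.noise_sd_uV < 0:
            raise ParameterError("noise sd must be non-negative")
        for T in self.temp_range_C:
            if self.time_scale(T) <= 0:
                raise ParameterError("kinetics coefficient collapses the time axis")
            for coeff in (self.amp_coeff_532, self.amp_coeff_780):
                if 1.0 + coeff * (T - 37.0) <= 0:
                    raise ParameterError(
                        "amplitude coefficients produce non-positive amplitudes"
                    )

    @property
    def amp_coeff_780(self) -> float:
        # d/dT (A532/A780) ≈ amp532 − amp780 = lrs_coeff at 37 °C
        return self.amp_coeff_532 - self.lrs_coeff

    def time_scale(self, temperature_C: float) -> float:
        return 1.0 + self.kinetics_coeff * (temperature_C - 37.0)

    def amp_scale(self, wavelength_nm: int, temperature_C: float) -> float:
        coeff = self.amp_coeff_532 if wavelength_nm == 532 else self.amp_coeff_780
        return 1.0 + coeff * (temperature_C - 37.0)


def _gamma_bump(t: np.ndarray, tpeak: float, shape: float) -> np.ndarray:
    """Unit-peak gamma bump, maximum 1 at t = tpeak, 0 for t <= 0."""
    u = np.clip(t / tpeak, 0.0, None)
    with np.errstate(over="ignore"):
        out = u**shape * np.exp(shape * (1.0 - u))
    return np.where(t > 0, out, 0.0)


def dim_template(
    t: np.ndarray, spec: WaveformGenSpec, wavelength_nm: int, temperature_C: float
) -> np.ndarray:
    """Noiseless dim-flash response at temperature T (µV)."""
    c = spec.time_scale(temperature_C)
    amp = spec.b_amp_uV * spec.amp_scale(wavelength_nm, temperature_C)
    main = _gamma_bump(t / c, spec.b_tpeak_s, spec.b_shape)
    slow = _gamma_bump(t / c, spec.b_tpeak_s * spec.undershoot_stretch, spec.b_shape)
    return amp * (main - spec.undershoot_frac * slow)


def bright_template(
    t: np.ndarray, spec: WaveformGenSpec, temperature_C: float
) -> np.ndarray:
    """Noiseless bright-flash response (negative a-wave + b-wave, µV)."""
    c = spec.time_scale(temperature_C)
    amp = spec.amp_scale(532, temperature_C)
    u = np.clip(t / (c * spec.a_tau_s), 0.0, None)
    onset = np.where(t > 0, 1.0 - np.exp(-(u**2)), 0.0)
    bwave = _gamma_bump(t / c, spec.ab_tpeak_s, spec.b_shape)
    return amp * (-spec.a_amp_uV * onset + spec.ab_amp_uV * bwave)


def simulate_waveform(
    stimulus: Stimulus,
    temperature_C: float,
    spec: WaveformGenSpec = WaveformGenSpec(),
    rng: np.random.Generator | None = None,
    retina_id: str = "sim",
    clock_time_s: float = 0.0,
) -> ERGTrace:
    """One synthetic ERG trace for a stimulus at a given temperature."""
    lo, hi = spec.temp_range_C
    if not (lo <= temperature_C <= hi):
        raise ParameterError(
            f"temperature {temperature_C} outside the spec range [{lo}, {hi}]"
        )
    n_pre = int(round(spec.pre_stim_s * spec.fs_hz))
    n_post = int(round(spec.post_stim_s * spec.fs_hz))
    t = (np.arange(n_pre + n_post + 1) - n_pre) / spec.fs_hz
    if stimulus.cls == "bright":
        v = bright_template(t, spec, temperature_C)
    else:
        v = dim_template(t, spec, stimulus.wavelength_nm, temperature_C)
    if spec.noise_sd_uV > 0:
        if rng is None:
            rng = np.random.default_rng()
        v = v + rng.normal(0.0, spec.noise_sd_uV, size=v.size)
    return ERGTrace(
        voltage_uV=v,
        fs_hz=spec.fs_hz,
        flash_index=n_pre,
        pre_stim_s=spec.pre_stim_s,
        stimulus=stimulus,
        retina_id=retina_id,
        clock_time_s=clock_time_s,
        temperature_C=temperature_C,
    )


_DIM_STRENGTH = 1.0        # linear-range dim flash, ~10–15% of max b-wave
_BRIGHT_STRENGTH = 170.0   # photoisomerizations per rod, mid published range


def simulate_session(
    spec: WaveformGenSpec = WaveformGenSpec(),
    temperatures_C: Sequence[float] | None = None,
    n_temperatures: int = 15,
    n_dim_per_wavelength: int = 4,
    reference_interval_s: float = 1200.0,
    retina_id: str = "sim01",
    seed: int | None = 0,
) -> tuple[Session, pd.DataFrame]:
    """Simulate a full recording session for one retina.

    Each temperature block holds 4 dim 532 nm, 4 dim 780 nm and one
    bright trace (6.5 s apart); a 37.0 °C reference block is inserted
    whenever ~20 simulated minutes have elapsed since the last one, and
    the session is book-ended by reference blocks. Returns the Session
    and a ground-truth table (block clock time, temperature, role).
    """
    rng = np.random.default_rng(seed)
    if temperatures_C is None:
        lo, hi = spec.temp_range_C
        temperatures_C = []
        while len(temperatures_C) < n_temperatures:
            T = float(rng.uniform(lo, hi))
            if abs(T - 37.0) > 0.05:
                temperatures_C.append(T)
    traces: list[ERGTrace] = []
    truth_rows = []
    clock = 0.0
    last_ref = -math.inf

    def emit_block(T: float, is_ref: bool) -> None:
        nonlocal clock
        block_start = clock
        for wl in (532, 780):
            for _ in range(n_dim_per_wavelength):
                stim = Stimulus(wavelength_nm=wl, strength_rstar=_DIM_STRENGTH, cls="dim")
                traces.append(
                    simulate_waveform(stim, T, spec, rng, retina_id, clock)
                )
                clock += 6.5
        stim = Stimulus(wavelength_nm=532, strength_rstar=_BRIGHT_STRENGTH, cls="bright")
        traces.append(simulate_waveform(stim, T, spec, rng, retina_id, clock))
        clock += 6.5
        truth_rows.append(
            {
                "clock_time_s": block_start,
                "temperature_C": T,
                "is_reference": is_ref,
            }
        )
        clock += 120.0  # stabilization wait before the next block

    emit_block(37.0, True)
    last_ref = 0.0
    for T in temperatures_C:
        if clock - last_ref >= reference_interval_s:
            last_ref = clock
            emit_block(37.0, True)
        emit_block(float(T), False)
    emit_block(37.0, True)
    truth = pd.DataFrame(truth_rows)
    truth.insert(0, "retina_id", retina_id)
    return Session(retina_id=retina_id, traces=traces), truth
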