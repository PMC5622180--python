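"""Waveform feature extraction: 34 kinetics/amplitude features per observation.

Bright-flash (a-wave) features
    a10…a90   time to X% of the a-wave peak amplitude on the descent (s)
    a100      time to the a-wave peak (s)
    aip       time to the inflection point of the a-wave leading edge (s)
    aa        a-wave amplitude, V(t_a-peak) (µV, negative)

Dim-flash (b-wave) features
    b10L…b90L time to X% of the b-wave peak on the leading edge (s)
    b100      time to the b-wave peak (s)
    b90T…b10T time to X% of the peak on the trailing edge (s)
    bit       integration time: ∫|V| dt over [0, first zero after peak]
              divided by the peak amplitude (s)
    ba        b-wave amplitude of the 532 nm response (µV, positive)
    LRS       long-wavelength relative sensitivity, the 532/780 nm
              b-wave amplitude ratio (dimensionless)

All of these shrink (times) or change (amplitudes, LRS) roughly
linearly by 2–4% per °C near body temperature, which is what the
temperature regression exploits.

One *observation* is extracted from a block of one bright flash, four
532 nm dim flashes and four 780 nm dim flashes recorded at a single
temperature. Dim traces are averaged per wavelength before extraction;
dim kinetics features are then averaged across the two wavelengths,
while ``ba`` uses the 532 nm response only and ``LRS`` is the amplitude
ratio itself.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .core import ERGTrace, Session, average_traces, baseline_correct, fir_lowpass
from .exceptions import DetectionError, ParameterError, PreconditionError

__all__ = [
    "FeatureConfig",
    "Observation",
    "FEATURE_NAMES",
    "META_COLUMNS",
    "detect_a_peak",
    "a_time_to_pct",
    "a_inflection",
    "fit_b_peak",
    "b_time_to_pct",
    "integration_time",
    "lrs",
    "extract_observation",
    "extract_session",
    "group_blocks",
    "read_feature_table",
    "write_feature_table",
]

logger = logging.getLogger(__name__)

_PCTS = (10, 20, 30, 40, 50, 60, 70, 80, 90)

#: Canonical order of the 34 features.
FEATURE_NAMES: tuple[str, ...] = (
    tuple(f"a{x}" for x in _PCTS)
    + ("a100", "aip", "aa")
    + tuple(f"b{x}L" for x in _PCTS)
    + ("b100",)
    + tuple(f"b{x}T" for x in reversed(_PCTS))
    + ("bit", "ba", "LRS")
)

META_COLUMNS = ("retina_id", "clock_time_s", "temperature_C", "is_reference")


@dataclass(frozen=True)
class FeatureConfig:
    """Extraction settings.

    The three FIR filters follow the recording convention: order 50 /
    100 Hz for bright flashes, order 600 / 20 Hz for the b-wave leading
    edge and order 400 / 30 Hz for the trailing edge, peak fit and
    integration time. ``apply_filters=False`` runs all detections on the
    raw baseline-corrected traces (used for analytic self-tests).
    """

    apply_filters: bool = True
    bright_filter: tuple[int, float] = (50, 100.0)
    leading_filter: tuple[int, float] = (600, 20.0)
    trailing_filter: tuple[int, float] = (400, 30.0)
    a_search_window_s: tuple[float, float] = (0.0, 0.2)
    a_diff_half_width_s: float = 1e-3
    b_fit_half_width_s: float = 0.015
    ref_temperature_C: float = 37.0
    ref_tolerance_C: float = 0.05

    def _maybe_filter(self, trace: ERGTrace, which: str) -> ERGTrace:
        if not self.apply_filters:
            return trace
        order, fc = getattr(self, f"{which}_filter")
        return fir_lowpass(trace, order, fc)


@dataclass
class Observation:
    """Feature vector plus annotations for one temperature block."""

    retina_id: str
    clock_time_s: float
    temperature_C: float
    features: dict[str, float]
    is_reference: bool = False

    def as_row(self) -> dict:
        row = {
            "retina_id": self.retina_id,
            "clock_time_s": self.clock_time_s,
            "temperature_C": self.temperature_C,
            "is_reference": self.is_reference,
        }
        row.update({name: self.features.get(name, math.nan) for name in FEATURE_NAMES})
        return row


# ---------------------------------------------------------------------------
# a-wave (bright flash)


def detect_a_peak(
    trace: ERGTrace, config: FeatureConfig = FeatureConfig()
) -> tuple[float, float]:
    """Locate the a-wave trough on a filtered bright-flash trace.

    The peak is the first t > 0 where the central difference
    V(t + 1 ms) − V(t − 1 ms) changes sign from negative to positive,
    searched within ``config.a_search_window_s``.
    """
    v = trace.voltage_uV
    h = max(1, int(round(config.a_diff_half_width_s * trace.fs_hz)))
    lo_t, hi_t = config.a_search_window_s
    lo = max(trace.flash_index + 1, trace.sample_at(lo_t) + 1, h)
    hi = min(trace.sample_at(hi_t), v.size - h - 1)
    if hi <= lo:
        raise DetectionError("a-peak search window is empty")
    diff = v[lo + h : hi + h] - v[lo - h : hi - h]
    # first positive difference whose most recent nonzero difference was
    # negative (exact zeros at the trough are skipped)
    sign = np.sign(diff)
    nz = np.nonzero(sign)[0]
    flips = np.nonzero((sign[nz][1:] > 0) & (sign[nz][:-1] < 0))[0]
    if flips.size == 0:
        raise DetectionError("no negative-to-positive sign change of the "
                             "a-wave central difference in the search window")
    i = lo + int(nz[flips[0] + 1])
    t = (i - trace.flash_index) / trace.fs_hz
    return t, float(v[i])


def a_time_to_pct(
    trace: ERGTrace,
    x_pct: int,
    v_apeak: float,
    t_apeak: float | None = None,
) -> float:
    """Time to X% of the a-wave amplitude on the descent.

    First sample t > 0 where V(t) < (X/100)·V(t_a-peak); both are
    negative, so this is the descent crossing. No sub-sample
    interpolation is applied.
    """
    if not v_apeak < 0:
        raise PreconditionError("a-wave amplitude must be negative")
    v = trace.voltage_uV
    start = trace.flash_index + 1
    stop = trace.sample_at(t_apeak) + 1 if t_apeak is not None else v.size
    thresh = (x_pct / 100.0) * v_apeak
    idx = np.nonzero(v[start:stop] < thresh)[0]
    if idx.size == 0:
        raise DetectionError(f"a-wave never crossed {x_pct}% of its peak")
    return (start + int(idx[0]) - trace.flash_index) / trace.fs_hz


def a_inflection(trace: ERGTrace, t_apeak: float) -> float:
    """Inflection point of the a-wave leading edge.

    A cubic p(t) is least-squares fitted on [0, t_a-peak]; the feature
    is the argmin of p'(t): the interior stationary point −b/(3a) when
    the cubic opens upward and that point lies inside the window,
    otherwise the window endpoint with the smaller slope.
    """
    i0 = trace.flash_index
    i1 = trace.sample_at(t_apeak) + 1
    if i1 - i0 < 8:
        raise DetectionError("fewer than 8 samples on the a-wave leading edge")
    t = (np.arange(i0, i1) - trace.flash_index) / trace.fs_hz
    v = trace.voltage_uV[i0:i1]
    # polyfit warns instead of failing on degenerate designs
    with warnings.catch_warnings():
        warnings.simplefilter("error", np.exceptions.RankWarning)
        try:
            a3, a2, a1, _ = np.polyfit(t, v, 3)
        except np.exceptions.RankWarning as exc:
            raise DetectionError(f"degenerate cubic fit: {exc}") from exc
    lo, hi = float(t[0]), float(t[-1])
    if a3 > 0:
        t_star = -a2 / (3.0 * a3)
        if lo <= t_star <= hi:
            return float(t_star)
    dp = lambda x: 3 * a3 * x**2 + 2 * a2 * x + a1
    return lo if dp(lo) <= dp(hi) else hi


# ---------------------------------------------------------------------------
# b-wave (dim flash)


def fit_b_peak(
    trace: ERGTrace, config: FeatureConfig = FeatureConfig()
) -> tuple[float, float]:
    """b-wave peak time and amplitude from a quadratic fit.

    t_max is the argmax of the (trailing-edge-filtered) trace for t > 0;
    a quadratic is fitted over ±15 ms around it and its vertex is
    returned. If the vertex escapes the window the discrete maximum is
    used instead.
    """
    filt = config._maybe_filter(trace, "trailing")
    v = filt.voltage_uV
    start = trace.flash_index + 1
    i_max = start + int(np.argmax(v[start:]))
    if i_max >= v.size - 1 or i_max <= start:
        raise DetectionError("b-wave maximum at the record edge")
    if not v[i_max] > 0:
        raise DetectionError("no positive b-wave maximum after the flash")
    half = int(round(config.b_fit_half_width_s * trace.fs_hz))
    lo = max(start, i_max - half)
    hi = min(v.size, i_max + half + 1)
    t = (np.arange(lo, hi) - trace.flash_index) / trace.fs_hz
    c2, c1, c0 = np.polyfit(t, v[lo:hi], 2)
    t_max = (i_max - trace.flash_index) / trace.fs_hz
    if c2 < 0:
        t_vertex = -c1 / (2.0 * c2)
        if t[0] <= t_vertex <= t[-1]:
            return float(t_vertex), float(c0 + c1 * t_vertex + c2 * t_vertex**2)
    logger.warning("b-peak quadratic vertex outside the fit window; "
                   "falling back to the discrete maximum")
    return t_max, float(v[i_max])


def b_time_to_pct(
    trace: ERGTrace,
    x_pct: int,
    edge: str,
    t_bpeak: float,
    v_bpeak: float,
    config: FeatureConfig = FeatureConfig(),
) -> float:
    """Time to X% of the b-wave amplitude on the leading or trailing edge.

    Leading: first t > 0 with V(t) > X%·V(t_b-peak) on the 20 Hz-filtered
    trace. Trailing: first t > t_b-peak with V(t) < X%·V(t_b-peak) on the
    30 Hz-filtered trace.
    """
    if not v_bpeak > 0:
        raise PreconditionError("b-wave amplitude must be positive")
    if edge not in ("leading", "trailing"):
        raise ParameterError(f"edge must be 'leading' or 'trailing', got {edge!r}")
    thresh = (x_pct / 100.0) * v_bpeak
    if edge == "leading":
        v = config._maybe_filter(trace, "leading").voltage_uV
        start = trace.flash_index + 1
        idx = np.nonzero(v[start:] > thresh)[0]
    else:
        v = config._maybe_filter(trace, "trailing").voltage_uV
        start = trace.sample_at(t_bpeak) + 1
        idx = np.nonzero(v[start:] < thresh)[0]
    if idx.size == 0:
        raise DetectionError(
            f"b-wave {edge} edge never crossed {x_pct}% of its peak"
        )
    return (start + int(idx[0]) - trace.flash_index) / trace.fs_hz


def integration_time(
    trace: ERGTrace,
    t_bpeak: float,
    v_bpeak: float,
    config: FeatureConfig = FeatureConfig(),
) -> float:
    """Integration time of the dim-flash response.

    Trapezoidal integral of |V(t)| on the 30 Hz-filtered trace from
    t = 0 to the first sample after the peak with V ≤ 0, divided by the
    b-wave amplitude. Scale-invariant; has units of seconds.
    """
    if not v_bpeak > 0:
        raise PreconditionError("b-wave amplitude must be positive")
    v = config._maybe_filter(trace, "trailing").voltage_uV
    i_peak = trace.sample_at(t_bpeak)
    idx = np.nonzero(v[i_peak + 1 :] <= 0)[0]
    if idx.size == 0:
        raise DetectionError("response never returned to zero after the b-peak")
    i_zero = i_peak + 1 + int(idx[0])
    seg = np.abs(v[trace.flash_index : i_zero + 1])
    integral = float(np.trapezoid(seg, dx=1.0 / trace.fs_hz))
    return integral / v_bpeak


def lrs(v_bpeak_532: float, v_bpeak_780: float) -> float:
    """Long-wavelength relative sensitivity: 532/780 nm amplitude ratio.

    Declines with temperature because thermal energy increasingly
    supplements 780 nm photon absorption, boosting the 780 nm response.
    """
    if not (v_bpeak_532 > 0 and v_bpeak_780 > 0):
        raise PreconditionError("both b-wave amplitudes must be positive")
    return v_bpeak_532 / v_bpeak_780


# ---------------------------------------------------------------------------
# Observation assembly


def _extract_bright(trace: ERGTrace, config: FeatureConfig) -> dict[str, float]:
    filt = config._maybe_filter(baseline_correct(trace), "bright")
    out: dict[str, float] = {}
    try:
        t_apeak, v_apeak = detect_a_peak(filt, config)
    except DetectionError as exc:
        logger.warning("a-peak detection failed: %s", exc)
        return {}
    out["a100"] = t_apeak
    out["aa"] = v_apeak
    for x in _PCTS:
        try:
            out[f"a{x}"] = a_time_to_pct(filt, x, v_apeak, t_apeak)
        except DetectionError as exc:
            logger.warning("a%d failed: %s", x, exc)
    try:
        out["aip"] = a_inflection(filt, t_apeak)
    except DetectionError as exc:
        logger.warning("aip failed: %s", exc)
    return out


def _extract_dim(trace: ERGTrace, config: FeatureConfig) -> dict[str, float]:
    """Per-wavelength dim-flash features; 'ba' here is that wavelength's amplitude."""
    corrected = baseline_correct(trace)
    # filter once per edge; the detection ops then run on the prepared traces
    leading = config._maybe_filter(corrected, "leading")
    trailing = config._maybe_filter(corrected, "trailing")
    prepared = replace(config, apply_filters=False)
    out: dict[str, float] = {}
    try:
        t_bpeak, v_bpeak = fit_b_peak(trailing, prepared)
    except DetectionError as exc:
        logger.warning("b-peak detection failed: %s", exc)
        return {}
    out["b100"] = t_bpeak
    out["ba"] = v_bpeak
    for x in _PCTS:
        try:
            out[f"b{x}L"] = b_time_to_pct(
                leading, x, "leading", t_bpeak, v_bpeak, prepared
            )
        except DetectionError as exc:
            logger.warning("b%dL failed: %s", x, exc)
        try:
            out[f"b{x}T"] = b_time_to_pct(
                trailing, x, "trailing", t_bpeak, v_bpeak, prepared
            )
        except DetectionError as exc:
            logger.warning("b%dT failed: %s", x, exc)
    try:
        out["bit"] = integration_time(trailing, t_bpeak, v_bpeak, prepared)
    except DetectionError as exc:
        logger.warning("bit failed: %s", exc)
    return out


_DIM_KINETICS = tuple(
    [f"b{x}L" for x in _PCTS] + ["b100"] + [f"b{x}T" for x in _PCTS] + ["bit"]
)


def extract_observation(
    bright: ERGTrace | None,
    dim532: Sequence[ERGTrace],
    dim780: Sequence[ERGTrace],
    config: FeatureConfig = FeatureConfig(),
) -> Observation:
    """Extract the full feature vector for one temperature block.

    Dim traces are averaged per wavelength at the trace level; dim
    kinetics features are the mean of the 532- and 780-derived values;
    ``ba`` comes from the 532 nm response only and ``LRS`` from the two
    amplitudes. Bright features come from the single bright trace. A
    failed detection leaves only the affected features missing (NaN).
    """
    if not dim532 or not dim780:
        raise PreconditionError("need at least one dim trace per wavelength")
    for tr, wl in [(t, 532) for t in dim532] + [(t, 780) for t in dim780]:
        if tr.stimulus.wavelength_nm != wl:
            raise PreconditionError(f"trace wavelength != {wl} nm in dim{wl} group")

    avg532 = average_traces(dim532)
    avg780 = average_traces(dim780)
    f532 = _extract_dim(avg532, config)
    f780 = _extract_dim(avg780, config)

    features: dict[str, float] = {name: math.nan for name in FEATURE_NAMES}
    for name in _DIM_KINETICS:
        vals = [d[name] for d in (f532, f780) if name in d]
        if vals:
            features[name] = float(np.mean(vals))
    if "ba" in f532:
        features["ba"] = f532["ba"]
    if "ba" in f532 and "ba" in f780:
        features["LRS"] = lrs(f532["ba"], f780["ba"])

    if bright is not None:
        features.update(_extract_bright(bright, config))

    anchor = bright if bright is not None else avg532
    member_temps = [tr.temperature_C for tr in list(dim532) + list(dim780)]
    if bright is not None:
        member_temps.append(bright.temperature_C)
    temp = float(np.mean(member_temps))
    return Observation(
        retina_id=anchor.retina_id,
        clock_time_s=float(
            np.mean([tr.clock_time_s for tr in list(dim532) + list(dim780)])
        ),
        temperature_C=temp,
        features=features,
        is_reference=abs(temp - config.ref_temperature_C) <= config.ref_tolerance_C,
    )


def group_blocks(
    session: Session, max_gap_s: float = 60.0
) -> list[list[ERGTrace]]:
    """Split a session into temperature blocks.

    Consecutive traces belong to one block while they share a measured
    temperature and follow each other within ``max_gap_s``.
    """
    blocks: list[list[ERGTrace]] = []
    for tr in session:
        if (
            blocks
            and tr.temperature_C == blocks[-1][-1].temperature_C
            and tr.clock_time_s - blocks[-1][-1].clock_time_s <= max_gap_s
        ):
            blocks[-1].append(tr)
        else:
            blocks.append([tr])
    return blocks


def extract_session(
    session: Session, config: FeatureConfig = FeatureConfig()
) -> pd.DataFrame:
    """Extract one observation per temperature block of a session."""
    rows = []
    for block in group_blocks(session):
        bright = [tr for tr in block if tr.stimulus.cls == "bright"]
        dim532 = [
            tr
            for tr in block
            if tr.stimulus.cls == "dim" and tr.stimulus.wavelength_nm == 532
        ]
        dim780 = [
            tr
            for tr in block
            if tr.stimulus.cls == "dim" and tr.stimulus.wavelength_nm == 780
        ]
        if not dim532 or not dim780:
            logger.warning(
                "skipping block at t=%.0f s: missing dim traces", block[0].clock_time_s
            )
            continue
        obs = extract_observation(
            bright[0] if bright else None, dim532, dim780, config
        )
        rows.append(obs.as_row())
    return pd.DataFrame(rows, columns=list(META_COLUMNS) + list(FEATURE_NAMES))


# ---------------------------------------------------------------------------
# Feature table I/O (one row per observation; missing = empty cell)


def write_feature_table(
    table: pd.DataFrame, path, provenance: dict | None = None
) -> None:
    with open(path, "w") as fh:
        if provenance:
            for key, val in provenance.items():
                fh.write(f"# {key}: {val}\n")
        table.to_csv(fh, index=False)


def read_feature_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, comment="#")
    missing = [c for c in META_COLUMNS if c not in table.columns]
    if missing:
        from .exceptions import FormatError

        raise FormatError(f"feature table missing columns: {missing}")
    return table
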