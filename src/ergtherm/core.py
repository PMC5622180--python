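"""Trace data model, session I/O, baseline correction, FIR filtering, averaging.

An ex vivo ERG session is a set of transretinal flash responses recorded
from one isolated retina at 10 kHz while its temperature is stepped
around the 35–44 °C range. Each response is stored with its stimulus
(wavelength, strength, dim/bright class), the retina identifier, the
wall-clock time of the recording and the measured bath temperature.

Sessions are serialized as a directory with one ``session.json``
metadata file and one two-column CSV (``time_s,voltage_uV``) per trace;
time zero is the midpoint of the light flash.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.signal import firwin

from .exceptions import FormatError, ParameterError, PreconditionError

__all__ = [
    "Stimulus",
    "ERGTrace",
    "Session",
    "read_session",
    "write_session",
    "baseline_correct",
    "fir_lowpass",
    "average_traces",
]

DEFAULT_FS_HZ = 10_000.0

#: Relative tolerance on the sampling interval of trace files.
_UNIFORMITY_PPM = 1.0


@dataclass(frozen=True)
class Stimulus:
    """A single light flash.

    Dim flashes (either 532 or 780 nm) evoke a linear-range b-wave of
    10–15% of the maximal amplitude; bright flashes are 532 nm only, in
    the 130–210 photoisomerizations-per-rod range, and evoke a clear
    a-wave followed by the b-wave.
    """

    wavelength_nm: int
    strength_rstar: float
    cls: str  # "dim" or "bright"
    flash_duration_ms: float = 2.0

    def __post_init__(self) -> None:
        if self.wavelength_nm not in (532, 780):
            raise ParameterError(
                f"wavelength_nm must be 532 or 780, got {self.wavelength_nm}"
            )
        if self.cls not in ("dim", "bright"):
            raise ParameterError(f"cls must be 'dim' or 'bright', got {self.cls!r}")
        if self.cls == "bright" and self.wavelength_nm != 532:
            raise ParameterError("bright stimuli use the 532 nm source")
        if not (self.strength_rstar > 0):
            raise ParameterError("strength_rstar must be positive")


@dataclass(frozen=True)
class ERGTrace:
    """One sampled flash response.

    ``flash_index`` is the sample index of the flash midpoint and
    defines t = 0; ``pre_stim_s`` is the pre-stimulus window used for
    baseline correction. ``temperature_C`` is the measured bath
    temperature (ground truth for training/validation only).
    """

    voltage_uV: np.ndarray
    fs_hz: float
    flash_index: int
    pre_stim_s: float
    stimulus: Stimulus
    retina_id: str
    clock_time_s: float
    temperature_C: float

    def __post_init__(self) -> None:
        v = np.asarray(self.voltage_uV, dtype=float)
        object.__setattr__(self, "voltage_uV", v)
        if not self.fs_hz > 0:
            raise ParameterError("fs_hz must be positive")
        if not np.all(np.isfinite(v)):
            raise FormatError("trace contains non-finite samples")
        if self.flash_index < int(round(self.pre_stim_s * self.fs_hz)):
            raise PreconditionError(
                "pre-stimulus window extends before the start of the record"
            )

    @property
    def n_samples(self) -> int:
        return self.voltage_uV.size

    @property
    def time_s(self) -> np.ndarray:
        """Time axis in seconds, t = 0 at the flash midpoint."""
        return (np.arange(self.n_samples) - self.flash_index) / self.fs_hz

    def sample_at(self, t_s: float) -> int:
        """Nearest sample index for a time relative to the flash."""
        return int(round(t_s * self.fs_hz)) + self.flash_index

    def with_voltage(self, voltage_uV: np.ndarray) -> "ERGTrace":
        return replace(self, voltage_uV=np.asarray(voltage_uV, dtype=float))


@dataclass
class Session:
    """All traces recorded from one retina, ordered by clock time."""

    retina_id: str
    traces: list[ERGTrace] = field(default_factory=list)

    def __post_init__(self) -> None:
        for tr in self.traces:
            if tr.retina_id != self.retina_id:
                raise FormatError(
                    f"trace retina_id {tr.retina_id!r} != session {self.retina_id!r}"
                )
        times = [tr.clock_time_s for tr in self.traces]
        if any(b < a for a, b in zip(times, times[1:])):
            self.traces = sorted(self.traces, key=lambda tr: tr.clock_time_s)

    def __len__(self) -> int:
        return len(self.traces)

    def __iter__(self):
        return iter(self.traces)


# ---------------------------------------------------------------------------
# Session directory I/O


def _require(meta: dict, key: str, typ, where: str):
    if key not in meta:
        raise FormatError(f"{where}: missing field {key!r}")
    val = meta[key]
    if typ is float and isinstance(val, int):
        val = float(val)
    if not isinstance(val, typ):
        raise FormatError(f"{where}: field {key!r} has wrong type {type(val).__name__}")
    return val


def read_session(path: str | Path) -> Session:
    """Read a session directory (``session.json`` plus per-trace CSVs)."""
    path = Path(path)
    meta_path = path / "session.json"
    if not meta_path.is_file():
        raise FormatError(f"no session.json in {path}")
    meta = json.loads(meta_path.read_text())
    retina_id = _require(meta, "retina_id", str, "session.json")
    entries = _require(meta, "traces", list, "session.json")
    if not entries:
        raise FormatError("session.json: empty trace list")

    traces = []
    for i, entry in enumerate(entries):
        where = f"session.json traces[{i}]"
        fname = _require(entry, "file", str, where)
        stim = Stimulus(
            wavelength_nm=_require(entry, "wavelength_nm", int, where),
            strength_rstar=_require(entry, "strength_rstar", float, where),
            cls=_require(entry, "cls", str, where),
        )
        t, v = _read_trace_csv(path / fname)
        fs, flash_index = _axis_from_times(t, path / fname)
        traces.append(
            ERGTrace(
                voltage_uV=v,
                fs_hz=fs,
                flash_index=flash_index,
                pre_stim_s=_require(entry, "pre_stim_s", float, where),
                stimulus=stim,
                retina_id=retina_id,
                clock_time_s=_require(entry, "clock_time_s", float, where),
                temperature_C=_require(entry, "temperature_C", float, where),
            )
        )
    traces.sort(key=lambda tr: tr.clock_time_s)
    return Session(retina_id=retina_id, traces=traces)


def _read_trace_csv(fpath: Path) -> tuple[np.ndarray, np.ndarray]:
    if not fpath.is_file():
        raise FormatError(f"missing trace file {fpath}")
    with open(fpath) as fh:
        header = fh.readline().strip()
        if header.replace(" ", "") != "time_s,voltage_uV":
            raise FormatError(f"{fpath}: expected header 'time_s,voltage_uV'")
        data = np.loadtxt(fh, delimiter=",", ndmin=2)
    if data.shape[1] != 2 or data.shape[0] < 2:
        raise FormatError(f"{fpath}: expected two columns of samples")
    return data[:, 0], data[:, 1]


def _axis_from_times(t: np.ndarray, fpath: Path) -> tuple[float, int]:
    """Sampling rate and flash index from a trace's time column."""
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise FormatError(f"{fpath}: time column not strictly increasing")
    mean_dt = (t[-1] - t[0]) / (t.size - 1)
    if np.max(np.abs(dt - mean_dt)) > _UNIFORMITY_PPM * 1e-6 * mean_dt:
        raise FormatError(f"{fpath}: non-uniform sampling interval")
    flash_index = int(np.argmin(np.abs(t)))
    return 1.0 / mean_dt, flash_index


def write_session(session: Session, path: str | Path) -> None:
    """Write a session directory readable by :func:`read_session`.

    Voltages are written with 17 significant digits so that a
    write→read round trip is bit-exact.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, tr in enumerate(session.traces):
        fname = f"trace_{i:04d}.csv"
        t = tr.time_s
        with open(path / fname, "w") as fh:
            fh.write("time_s,voltage_uV\n")
            for ti, vi in zip(t, tr.voltage_uV):
                fh.write(f"{ti:.17g},{vi:.17g}\n")
        entries.append(
            {
                "file": fname,
                "wavelength_nm": tr.stimulus.wavelength_nm,
                "strength_rstar": tr.stimulus.strength_rstar,
                "cls": tr.stimulus.cls,
                "clock_time_s": tr.clock_time_s,
                "temperature_C": tr.temperature_C,
                "pre_stim_s": tr.pre_stim_s,
            }
        )
    meta = {"retina_id": session.retina_id, "traces": entries}
    (path / "session.json").write_text(json.dumps(meta, indent=1))


# ---------------------------------------------------------------------------
# Preprocessing


def baseline_correct(trace: ERGTrace) -> ERGTrace:
    """Subtract the mean of the pre-stimulus window.

    The offset is the arithmetic mean of the ``pre_stim_s`` seconds
    immediately preceding the flash midpoint. Idempotent.
    """
    n_pre = int(round(trace.pre_stim_s * trace.fs_hz))
    start = trace.flash_index - n_pre
    if start < 0:
        raise PreconditionError("pre-stimulus window extends before record start")
    offset = float(np.mean(trace.voltage_uV[start : trace.flash_index]))
    return trace.with_voltage(trace.voltage_uV - offset)


def fir_lowpass(trace: ERGTrace, n_taps_order: int, fc_hz: float) -> ERGTrace:
    """Zero-delay linear-phase FIR low-pass filter.

    A Hamming-window FIR of order ``n_taps_order`` (``n+1`` taps) with
    cutoff ``fc_hz`` is applied by convolution; the constant group delay
    of n/2 samples is compensated so event times are not shifted, and
    edges are reflection-padded so the output has the input's length.
    """
    v = filter_kernel_apply(
        trace.voltage_uV, design_fir(n_taps_order, fc_hz, trace.fs_hz), n_taps_order
    )
    return trace.with_voltage(v)


def design_fir(n_taps_order: int, fc_hz: float, fs_hz: float) -> np.ndarray:
    if n_taps_order < 2:
        raise ParameterError("filter order must be >= 2")
    if not (0 < fc_hz < fs_hz / 2):
        raise ParameterError(
            f"cutoff {fc_hz} Hz must lie in (0, Nyquist={fs_hz / 2} Hz)"
        )
    return firwin(n_taps_order + 1, fc_hz, fs=fs_hz, window="hamming")


def filter_kernel_apply(v: np.ndarray, taps: np.ndarray, order: int) -> np.ndarray:
    """Convolve with reflection padding and group-delay compensation."""
    ext = np.pad(v, order, mode="reflect")
    full = np.convolve(ext, taps, mode="valid")  # length len(v) + order
    lo = order // 2
    return full[lo : lo + v.size]


def average_traces(traces: Sequence[ERGTrace] | Iterable[ERGTrace]) -> ERGTrace:
    """Pointwise mean of aligned traces of one stimulus wavelength.

    Metadata is copied from the first trace; the temperature is the mean
    of the member temperatures.
    """
    traces = list(traces)
    if not traces:
        raise PreconditionError("cannot average an empty set of traces")
    first = traces[0]
    for tr in traces[1:]:
        if tr.stimulus.wavelength_nm != first.stimulus.wavelength_nm:
            raise PreconditionError("cannot average traces of mixed wavelengths")
        if tr.fs_hz != first.fs_hz or tr.flash_index != first.flash_index:
            raise PreconditionError("traces are not aligned (fs or flash index differ)")
        if tr.n_samples != first.n_samples:
            raise PreconditionError("traces have different lengths")
    mean_v = np.mean([tr.voltage_uV for tr in traces], axis=0)
    mean_T = float(np.mean([tr.temperature_C for tr in traces]))
    return replace(first, voltage_uV=mean_v, temperature_C=mean_T)
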