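"""Normalization of raw features to per-retina 37.0 °C reference values.

Absolute response kinetics and sensitivity differ between retinas, and
they drift over hours of ex vivo recording. Every feature x is
therefore expressed relative to its own retina's reference value x37
recorded at 37.0 °C. Two modes mirror the two use cases:

``interpolate``
    x37(t) is the linear interpolant in clock time between the flanking
    reference recordings — the retrospective analysis of a completed
    experiment.
``recent``
    x37(t) is the most recent reference at or before t — the causal
    variant available in real time during a heating session.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DataError, ParameterError
from .features import FEATURE_NAMES

__all__ = ["ReferenceSeries", "build_reference_series", "normalize"]

logger = logging.getLogger(__name__)


@dataclass
class ReferenceSeries:
    """Ordered 37.0 °C reference feature values of one retina."""

    retina_id: str
    times_s: np.ndarray          # strictly increasing
    values: pd.DataFrame         # one row per reference, feature columns

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        if self.times_s.size == 0:
            raise DataError(f"retina {self.retina_id!r} has no reference entries")
        if np.any(np.diff(self.times_s) <= 0):
            raise DataError(
                f"retina {self.retina_id!r}: reference times not strictly increasing"
            )

    def __len__(self) -> int:
        return self.times_s.size

    def at(self, t_s: float, mode: str, feature: str) -> float:
        """Reference value x37(t) for one feature."""
        col = self.values[feature].to_numpy(dtype=float)
        ok = np.isfinite(col)
        if not ok.any():
            return np.nan
        times, col = self.times_s[ok], col[ok]
        if mode == "interpolate":
            # np.interp clamps outside the reference span (logged by caller)
            return float(np.interp(t_s, times, col))
        if mode == "recent":
            i = int(np.searchsorted(times, t_s, side="right")) - 1
            if i < 0:
                raise DataError(
                    f"retina {self.retina_id!r}: no reference at or before "
                    f"t={t_s:.0f} s (mode='recent')"
                )
            return float(col[i])
        raise ParameterError(f"mode must be 'interpolate' or 'recent', got {mode!r}")


def build_reference_series(table: pd.DataFrame) -> dict[str, ReferenceSeries]:
    """One ReferenceSeries per retina from the is_reference rows."""
    out: dict[str, ReferenceSeries] = {}
    for retina_id, grp in table.groupby("retina_id", sort=False):
        refs = grp[grp["is_reference"].astype(bool)].sort_values("clock_time_s")
        if refs.empty:
            raise DataError(f"retina {retina_id!r} has no 37.0 °C reference rows")
        out[str(retina_id)] = ReferenceSeries(
            retina_id=str(retina_id),
            times_s=refs["clock_time_s"].to_numpy(dtype=float),
            values=refs[list(FEATURE_NAMES)].reset_index(drop=True),
        )
    return out


def normalize(
    table: pd.DataFrame,
    refs: dict[str, ReferenceSeries] | None = None,
    mode: str = "interpolate",
) -> pd.DataFrame:
    """Replace each feature value x with the relative value x / x37(t).

    ``refs`` defaults to the reference series built from the table
    itself. A zero or missing x37 makes the relative value missing.
    Observations outside the reference span are clamped to the nearest
    reference in interpolate mode (with a log message); in recent mode
    an observation before the first reference is an error.
    """
    if mode not in ("interpolate", "recent"):
        raise ParameterError(f"mode must be 'interpolate' or 'recent', got {mode!r}")
    if refs is None:
        refs = build_reference_series(table)
    out = table.copy()
    for retina_id, grp in table.groupby("retina_id", sort=False):
        if str(retina_id) not in refs:
            raise DataError(f"no reference series for retina {retina_id!r}")
        series = refs[str(retina_id)]
        times = grp["clock_time_s"].to_numpy(dtype=float)
        if mode == "interpolate" and (
            times.min() < series.times_s[0] or times.max() > series.times_s[-1]
        ):
            logger.warning(
                "retina %s: observations outside the reference span are "
                "clamped to the nearest reference",
                retina_id,
            )
        for feature in FEATURE_NAMES:
            x = grp[feature].to_numpy(dtype=float)
            x37 = np.array([series.at(t, mode, feature) for t in times])
            with np.errstate(divide="ignore", invalid="ignore"):
                rel = np.where(x37 != 0, x / x37, np.nan)
            out.loc[grp.index, feature] = rel
    return out
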