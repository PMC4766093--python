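"""Sampled time-course containers shared across the kinetic pipeline.

Two conventions are enforced at module boundaries: tracer-kinetic
quantities (tissue and plasma concentration) live on a time axis in
*minutes*, while raw scanner signal lives on a time axis in *seconds*.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ConcentrationCurve", "SignalCurve"]

SECONDS_PER_MINUTE = 60.0


def _validate_axes(
    times: np.ndarray, values: np.ndarray, allow_nan_values: bool = False
) -> None:
    if times.ndim != 1 or values.ndim != 1:
        raise ValueError("times and values must be one-dimensional")
    if len(times) != len(values):
        raise ValueError(
            f"times ({len(times)}) and values ({len(values)}) differ in length"
        )
    if len(times) < 2:
        raise ValueError("a curve needs at least 2 samples")
    if not np.all(np.isfinite(times)):
        raise ValueError("times must be finite")
    ok = np.isfinite(values) | (allow_nan_values & np.isnan(values))
    if not np.all(ok):
        raise ValueError("values must be finite")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")


@dataclass(frozen=True)
class ConcentrationCurve:
    """Contrast-agent concentration vs. time.

    Parameters
    ----------
    times
        Sample times in minutes, strictly increasing.
    values
        Concentration in mM, one per time point.
    """

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        # NaN values are tolerated as per-frame "not invertible" flags
        # from the signal conversion; infinities are never valid
        _validate_axes(t, v, allow_nan_values=True)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return len(self.times)

    def same_grid(self, other: "ConcentrationCurve", atol: float = 1e-9) -> bool:
        return len(self) == len(other) and bool(
            np.allclose(self.times, other.times, atol=atol)
        )


@dataclass(frozen=True)
class SignalCurve:
    """MR signal intensity vs. time (arbitrary scanner units, seconds)."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        _validate_axes(t, v)
        if np.any(v < 0):
            raise ValueError("signal values must be non-negative")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return len(self.times)

    @property
    def times_minutes(self) -> np.ndarray:
        return self.times / SECONDS_PER_MINUTE
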