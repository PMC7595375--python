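"""Sway outcome metrics.

Spontaneous-sway trials yield a mean sway velocity (sway path per unit
time after an initial discard).  Pseudo-random tilt trials are cut into
stimulus cycles and decomposed into a periodic component (across-cycle
mean) and a random component (across-cycle SD); each component's power is
the sum of its squared trace.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy import signal

__all__ = [
    "SpontaneousSwayResult",
    "TiltResponseResult",
    "lowpass",
    "sway_velocity",
    "cycle_decompose",
    "sway_power",
]


@dataclass(frozen=True)
class SpontaneousSwayResult:
    """Mean sway velocity over the analysis window."""

    sway_velocity_s: float  # deg/s
    window_start: float  # s discarded before the window
    window_length: float  # s
    filter_spec: Optional[Tuple[int, float]] = None  # (order, cutoff Hz)


@dataclass(frozen=True)
class TiltResponseResult:
    """Periodic/random decomposition of a cyclic tilt response."""

    periodic: np.ndarray  # deg, one cycle
    random_sd: np.ndarray  # deg, one cycle, >= 0
    periodic_power: float  # deg^2 * samples
    random_power: float  # deg^2 * samples
    n_cycles_used: int
    extras: dict = field(default_factory=dict)


def lowpass(
    trace: np.ndarray, order: int, cutoff: float, sample_rate: float
) -> np.ndarray:
    """Zero-phase Butterworth low-pass (forward-backward; effective order 2x)."""
    if not 0 < cutoff < sample_rate / 2:
        raise ValueError(
            f"cutoff must lie in (0, Nyquist={sample_rate / 2} Hz), got {cutoff}"
        )
    sos = signal.butter(order, cutoff, btype="low", fs=sample_rate, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(trace, dtype=float))


def sway_velocity(
    trace: np.ndarray,
    sample_rate: float,
    discard: float = 15.0,
    window: float = 30.0,
    filter_spec: Optional[Tuple[int, float]] = None,
) -> SpontaneousSwayResult:
    """Sway path over a half-open window divided by the window duration.

    The first ``discard`` seconds are dropped; the sway path is the sum of
    absolute sample-to-sample differences over the following ``window``
    seconds.  ``filter_spec`` is carried through for provenance only.
    """
    trace = np.asarray(trace, dtype=float)
    i0 = int(round(discard * sample_rate))
    i1 = i0 + int(round(window * sample_rate))
    if len(trace) < i1:
        raise ValueError(
            f"trace of {len(trace)} samples is shorter than discard + window "
            f"= {i1} samples at {sample_rate} Hz"
        )
    path = float(np.sum(np.abs(np.diff(trace[i0:i1]))))
    return SpontaneousSwayResult(
        sway_velocity_s=path / window,
        window_start=discard,
        window_length=window,
        filter_spec=filter_spec,
    )


def cycle_decompose(
    trace: np.ndarray,
    cycle_duration: float,
    n_cycles: int,
    sample_rate: float,
    discard_first: int = 1,
    ddof: int = 1,
) -> TiltResponseResult:
    """Periodic/random decomposition of a concatenated cyclic response.

    The trace is reshaped into ``n_cycles`` rows, the first ``discard_first``
    cycles are dropped, every retained cycle is centered on its own mean, and
    the pointwise mean (periodic) and sample SD (random, ``ddof`` denominator)
    across cycles are returned together with each component's power.
    """
    trace = np.asarray(trace, dtype=float)
    samples_per_cycle = int(round(cycle_duration * sample_rate))
    expected = n_cycles * samples_per_cycle
    if len(trace) != expected:
        raise ValueError(
            f"trace length {len(trace)} != n_cycles * cycle_duration * "
            f"sample_rate = {expected}"
        )
    n_used = n_cycles - discard_first
    if n_used < 2:
        raise ValueError(
            f"need at least 2 retained cycles, got {n_cycles} - "
            f"{discard_first} = {n_used}"
        )
    cycles = trace.reshape(n_cycles, samples_per_cycle)[discard_first:]
    centered = cycles - cycles.mean(axis=1, keepdims=True)
    periodic = centered.mean(axis=0)
    random_sd = centered.std(axis=0, ddof=ddof)
    return TiltResponseResult(
        periodic=periodic,
        random_sd=random_sd,
        periodic_power=sway_power(periodic),
        random_power=sway_power(random_sd),
        n_cycles_used=n_used,
        extras={"centered_cycles": centered},
    )


def sway_power(component: np.ndarray) -> float:
    """Sum of the squared trace (no length normalization)."""
    component = np.asarray(component, dtype=float)
    if component.size == 0:
        raise ValueError("cannot compute sway power of an empty trace")
    return float(np.sum(component**2))
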