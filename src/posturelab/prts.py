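"""Pseudo-random ternary sequence (PRTS) tilt-stimulus generation.

A maximal-length sequence over GF(3) is produced by a linear feedback shift
register.  Its symbols are mapped to platform tilt velocities {+v, 0, -v},
integrated to a piecewise-linear tilt trace, and concatenated into a trial
stimulus.  The shipped default reproduces the classic posturography geometry:
80 states of 0.25 s at +/-1.78 deg/s, a 20-s cycle with 4 deg peak-to-peak
tilt, 13 cycles per trial (260 s).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Dict, Sequence, Tuple

import numpy as np

__all__ = [
    "TernarySequence",
    "TiltStimulus",
    "NonPrimitiveTapsError",
    "generate_ternary_mls",
    "sequence_to_velocity",
    "integrate_tilt",
    "concatenate_cycles",
    "find_default_config",
    "default_stimulus",
    "make_stimulus",
    "DEFAULT_V_PEAK",
    "DEFAULT_STATE_DURATION",
    "DEFAULT_N_CYCLES",
]

#: published stimulus geometry: +/-1.78 deg/s states of 0.25 s, 13 cycles
DEFAULT_V_PEAK = 1.78
DEFAULT_STATE_DURATION = 0.25
DEFAULT_N_CYCLES = 13

#: canonical enumeration order of the six bijections {0,1,2} -> {+1,0,-1};
#: entry i of a mapping tuple is the signed unit velocity assigned to symbol i
MAPPINGS: Tuple[Tuple[int, int, int], ...] = tuple(
    itertools.permutations((1, 0, -1))
)


class NonPrimitiveTapsError(ValueError):
    """Feedback taps do not generate a maximal-length sequence."""

    def __init__(self, message: str, period: int | None = None):
        super().__init__(message)
        self.period = period


@dataclass(frozen=True)
class TernarySequence:
    """One period of a ternary m-sequence with its generator configuration."""

    symbols: np.ndarray  # values in {0, 1, 2}
    stages: int
    feedback_taps: Tuple[int, ...]
    initial_state: Tuple[int, ...]

    def __len__(self) -> int:
        return len(self.symbols)

    def symbol_counts(self) -> Dict[int, int]:
        return {s: int(np.sum(self.symbols == s)) for s in (0, 1, 2)}


@dataclass(frozen=True)
class TiltStimulus:
    """Velocity states and the integrated tilt trace (single cycle and trial)."""

    velocity_states: np.ndarray  # deg/s, one entry per state
    state_duration: float  # s
    v_peak: float  # deg/s
    tilt_cycle: np.ndarray  # deg, sampled at sample_rate, covers [0, cycle_duration)
    n_cycles: int
    tilt_full: np.ndarray  # deg, n_cycles concatenated copies
    sample_rate: float  # Hz
    metadata: dict = field(default_factory=dict)

    @property
    def cycle_duration(self) -> float:
        return len(self.velocity_states) * self.state_duration

    @property
    def duration(self) -> float:
        return len(self.tilt_full) / self.sample_rate

    @property
    def peak_to_peak(self) -> float:
        return float(np.max(self.tilt_cycle) - np.min(self.tilt_cycle))


def generate_ternary_mls(
    stages: int,
    feedback_taps: Sequence[int],
    initial_state: Sequence[int],
) -> TernarySequence:
    """Run a GF(3) Fibonacci shift register for one full period.

    The register state is ``(s_0, ..., s_{m-1})``; each step outputs
    ``s_{m-1}`` and feeds back ``sum(taps[i] * s_i) mod 3`` at the front.
    Raises :class:`NonPrimitiveTapsError` unless the state orbit has the
    maximal period ``3**stages - 1``.
    """
    if stages < 1:
        raise ValueError(f"stages must be >= 1, got {stages}")
    taps = tuple(int(t) % 3 for t in feedback_taps)
    state0 = tuple(int(s) % 3 for s in initial_state)
    if len(taps) != stages or len(state0) != stages:
        raise ValueError(
            f"feedback_taps and initial_state must have length {stages}"
        )
    if all(s == 0 for s in state0):
        raise ValueError("initial_state must not be all-zero")

    max_period = 3**stages - 1
    symbols = []
    seen = {state0: 0}
    state = state0
    for step in range(1, max_period + 1):
        symbols.append(state[-1])
        fb = sum(t * s for t, s in zip(taps, state)) % 3
        state = (fb,) + state[:-1]
        if state == state0:
            if step < max_period:
                raise NonPrimitiveTapsError(
                    f"taps {taps} are not primitive: state sequence repeats "
                    f"with period {step} < {max_period}",
                    period=step,
                )
            return TernarySequence(
                symbols=np.array(symbols, dtype=np.int64),
                stages=stages,
                feedback_taps=taps,
                initial_state=state0,
            )
        if state in seen:
            raise NonPrimitiveTapsError(
                f"taps {taps} are not primitive: register enters a cycle of "
                f"period {step - seen[state]} not containing the initial "
                f"state (after {step} steps)",
                period=step - seen[state],
            )
        seen[state] = step
    raise NonPrimitiveTapsError(  # pragma: no cover - unreachable
        f"taps {taps} did not return to the initial state within "
        f"{max_period} steps",
        period=None,
    )


def sequence_to_velocity(
    seq: TernarySequence | np.ndarray,
    v_peak: float,
    mapping: Tuple[int, int, int] = MAPPINGS[0],
) -> np.ndarray:
    """Map ternary symbols to velocity states ``{+v_peak, 0, -v_peak}``.

    ``mapping[i]`` is the signed unit (+1, 0 or -1) assigned to symbol ``i``;
    it must be a bijection of {0,1,2} onto {+1,0,-1}.
    """
    if sorted(mapping) != [-1, 0, 1]:
        raise ValueError(
            f"mapping must be a bijection of symbols onto (+1, 0, -1), got {mapping}"
        )
    symbols = seq.symbols if isinstance(seq, TernarySequence) else np.asarray(seq)
    lut = np.array(mapping, dtype=float) * float(v_peak)
    return lut[symbols]


def integrate_tilt(
    velocity_states: np.ndarray,
    state_duration: float,
    sample_rate: float,
) -> np.ndarray:
    """Integrate piecewise-constant velocity states to a tilt trace in deg.

    The trace is the exact piecewise-linear integral sampled at
    ``sample_rate`` over ``[0, n_states * state_duration)``, starting at 0.
    ``state_duration * sample_rate`` must be an integer number of samples.
    """
    v = np.asarray(velocity_states, dtype=float)
    spst_f = state_duration * sample_rate
    spst = int(round(spst_f))
    if spst < 1 or abs(spst_f - spst) > 1e-9:
        raise ValueError(
            f"state_duration * sample_rate = {spst_f} is not a positive integer "
            "number of samples per state"
        )
    dt = 1.0 / sample_rate
    # velocity at each sample (zero-order hold), integrated exactly: the
    # integral of a staircase is piecewise-linear and the cumulative sum of
    # v*dt lands on the exact line at every sample time.
    v_samples = np.repeat(v, spst)
    tilt = np.concatenate(([0.0], np.cumsum(v_samples[:-1] * dt)))
    return tilt


def concatenate_cycles(tilt_cycle: np.ndarray, n_cycles: int) -> np.ndarray:
    """Tile one tilt cycle into a full-trial stimulus trace."""
    if n_cycles < 1:
        raise ValueError(f"n_cycles must be >= 1, got {n_cycles}")
    return np.tile(np.asarray(tilt_cycle, dtype=float), n_cycles)


def _cumulative_range(units: np.ndarray) -> int:
    """Range (max - min) of the running sum of signed unit states, incl. 0."""
    c = np.concatenate(([0], np.cumsum(units)))
    return int(c.max() - c.min())


@lru_cache(maxsize=None)
def find_default_config(
    stages: int = 4, target_range: int = 9
) -> Tuple[Tuple[int, ...], Tuple[int, ...], Tuple[int, int, int]]:
    """Search for the default (taps, initial_state, mapping) configuration.

    Iterates tap vectors, then initial states, then sign mappings, each in
    lexicographic/canonical order, and returns the first primitive
    configuration whose signed-unit cumulative sum has range ``target_range``
    (in state units).  At the published geometry (0.25-s states, 1.78 deg/s)
    a range of 9 gives the 4 deg peak-to-peak tilt amplitude.
    """
    for taps in itertools.product(range(3), repeat=stages):
        base_state = (1,) + (0,) * (stages - 1)
        try:
            generate_ternary_mls(stages, taps, base_state)
        except NonPrimitiveTapsError:
            continue
        for state in itertools.product(range(3), repeat=stages):
            if all(s == 0 for s in state):
                continue
            seq = generate_ternary_mls(stages, taps, state)
            for mapping in MAPPINGS:
                lut = np.array(mapping)
                units = lut[seq.symbols]
                if _cumulative_range(units) == target_range:
                    return taps, state, mapping
    raise RuntimeError(
        f"no {stages}-stage configuration with cumulative range {target_range}"
    )


def make_stimulus(
    stages: int = 4,
    feedback_taps: Sequence[int] | None = None,
    initial_state: Sequence[int] | None = None,
    mapping: Tuple[int, int, int] | None = None,
    v_peak: float = DEFAULT_V_PEAK,
    state_duration: float = DEFAULT_STATE_DURATION,
    n_cycles: int = DEFAULT_N_CYCLES,
    sample_rate: float = 1000.0,
) -> TiltStimulus:
    """Build a :class:`TiltStimulus`; unspecified generator parameters fall
    back to the searched default configuration (see :func:`find_default_config`)."""
    if feedback_taps is None or initial_state is None or mapping is None:
        d_taps, d_state, d_map = find_default_config(stages=stages)
        feedback_taps = feedback_taps if feedback_taps is not None else d_taps
        initial_state = initial_state if initial_state is not None else d_state
        mapping = mapping if mapping is not None else d_map
    seq = generate_ternary_mls(stages, feedback_taps, initial_state)
    velocities = sequence_to_velocity(seq, v_peak, mapping)
    cycle = integrate_tilt(velocities, state_duration, sample_rate)
    full = concatenate_cycles(cycle, n_cycles)
    stim = TiltStimulus(
        velocity_states=velocities,
        state_duration=state_duration,
        v_peak=v_peak,
        tilt_cycle=cycle,
        n_cycles=n_cycles,
        tilt_full=full,
        sample_rate=sample_rate,
        metadata={
            "stages": stages,
            "feedback_taps": tuple(seq.feedback_taps),
            "initial_state": tuple(seq.initial_state),
            "mapping": tuple(mapping),
            "n_states": len(seq),
            "cumulative_range_units": _cumulative_range(
                np.array(mapping)[seq.symbols]
            ),
            "amplitude_source": "sequence_choice",
        },
    )
    stim.metadata["peak_to_peak_deg"] = stim.peak_to_peak
    return stim


def default_stimulus(sample_rate: float = 1000.0) -> TiltStimulus:
    """The package's default PRTS stimulus (published geometry)."""
    return make_stimulus(sample_rate=sample_rate)
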