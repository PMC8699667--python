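"""Forward simulation of the multilevel atrioventricular block (MAVB).

A perfectly regular atrial impulse train (cycle length ``delta_a``) is
cascaded through up to three blocking levels; the conducted times at the
last level are the simulated ventricular activations, and their successive
differences are the simulated RR intervals.  The deviation of a simulated
RR series from an observed one, measured in the Euclidean norm, is the
objective the inverse solver minimises.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np

from .blocks import BlockLevel, decision_cycle


@lru_cache(maxsize=256)
def _cycle_arrays(pattern) -> tuple[np.ndarray, np.ndarray]:
    cycle = decision_cycle(pattern)
    flags = np.array([c for c, _ in cycle], dtype=bool)
    mults = np.array([m for _, m in cycle], dtype=float)
    return flags, mults


@lru_cache(maxsize=8192)
def _decisions_for(pattern, offset: int, size: int) -> tuple[np.ndarray, np.ndarray]:
    """Conducted mask over ``size`` incoming signals plus the Wenckebach
    delay multipliers of the conducted ones, for a pattern/offset pair."""
    flags, mults = _cycle_arrays(pattern)
    pos = (offset + np.arange(size)) % flags.size
    conducted = flags[pos]
    conducted.setflags(write=False)
    sel = mults[pos][conducted]
    sel.setflags(write=False)
    return conducted, sel

__all__ = [
    "RRSeries",
    "MAVBParams",
    "SimulationTrace",
    "InfeasibleParametersError",
    "DegenerateModelError",
    "CLIP_THRESHOLD_MS",
    "atrial_train",
    "conduct_level",
    "forward_simulate",
    "objective",
]

#: Per-interval deviation (ms) beyond which a candidate simulation is
#: considered infeasible ("clipped") rather than merely penalised.
CLIP_THRESHOLD_MS = 150.0

AFIB = "AFib"
AFLU = "AFlu"


class InfeasibleParametersError(ValueError):
    """Parameters produce non-monotone conduction times."""


class DegenerateModelError(ValueError):
    """The block cascade conducts too few signals to form RR intervals."""


@dataclass
class RRSeries:
    """One sample: an ordered series of RR-interval durations in ms.

    Intervals are measured at 1 ms precision; the label (AFib/AFlu) and the
    patient's age are optional annotations carried through the pipeline.
    """

    intervals: np.ndarray
    label: Optional[str] = None
    age: Optional[float] = None
    sample_id: Optional[str] = None
    patient_id: Optional[str] = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.intervals, dtype=float)
        if arr.ndim != 1 or arr.size < 2:
            raise ValueError("an RR series needs at least 2 intervals")
        if np.any(arr <= 0):
            raise ValueError("all RR intervals must be positive")
        self.intervals = arr
        if self.label is not None and self.label not in (AFIB, AFLU):
            raise ValueError(f"label must be {AFIB!r} or {AFLU!r}")

    def __len__(self) -> int:
        return int(self.intervals.size)

    def window(self, start: int, stop: int) -> "RRSeries":
        """Contiguous sub-series over the half-open index range [start, stop)."""
        if not (0 <= start < stop <= len(self)):
            raise ValueError("invalid window bounds")
        return RRSeries(
            self.intervals[start:stop],
            label=self.label,
            age=self.age,
            sample_id=self.sample_id,
            patient_id=self.patient_id,
        )


@dataclass(frozen=True)
class MAVBParams:
    """A point in the inverse-simulation search space.

    ``delta_a`` is the atrial cycle length (ms, on the search grid within
    [175, 400] by default); ``blocktype_id`` selects a registry preset and
    ``levels`` carries the concrete per-level assignments (ratio pattern,
    phase offset, base delay, delay increment).  ``t_start`` is fixed to 0:
    the objective compares RR differences, so the global offset cancels.
    """

    delta_a: float
    blocktype_id: int
    levels: tuple[BlockLevel, ...]
    t_start: float = 0.0

    def __post_init__(self) -> None:
        if self.delta_a <= 0:
            raise ValueError("delta_a must be positive")
        if not self.levels:
            raise ValueError("at least one level required")

    def oc_vector(self) -> list[float]:
        """Canonical flat encoding of the per-level assignments.

        Per level: ratio ``n`` of the first pattern pair, phase offset and
        delay increment.  Used for deterministic tie-breaking and for the
        numeric solution features.
        """
        out: list[float] = []
        for lv in self.levels:
            out.extend(
                [
                    float(lv.ratio_pattern[0][1]),
                    float(lv.phase_offset_o),
                    float(lv.increment_delta),
                ]
            )
        return out


@dataclass
class SimulationTrace:
    """Activation times per cascade level plus the resulting RR intervals.

    ``times_per_level[0]`` is the atrial train itself; each further entry
    holds the conducted times leaving that level.  ``conducted_flags[i]``
    marks which of level ``i+1``'s incoming signals were conducted.
    """

    times_per_level: list[np.ndarray]
    conducted_flags: list[np.ndarray]
    ventricular_rr: np.ndarray


def atrial_train(delta_a: float, t_start: float, count: int) -> np.ndarray:
    """Regular atrial activation times ``t_start + j * delta_a``, j=0..count-1."""
    if delta_a <= 0:
        raise ValueError("delta_a must be positive")
    if count < 1:
        raise ValueError("count must be >= 1")
    return t_start + delta_a * np.arange(count, dtype=float)


def conduct_level(
    incoming: Sequence[float], level: BlockLevel
) -> tuple[np.ndarray, np.ndarray]:
    """Pass an ordered signal train through one blocking level.

    Signals walk the level's decision cycle starting at its phase offset:
    the ``k``-th conducted signal of an ``n+1 : n`` pair leaves at
    ``incoming + c + (k - 1) * delta``; the ``(n+1)``-th signal of the pair
    is blocked.  Returns the outgoing times and a per-incoming-signal
    conducted flag.

    Raises
    ------
    InfeasibleParametersError
        If the delay increment makes outgoing times non-monotone.
    """
    inc = np.asarray(incoming, dtype=float)
    if inc.ndim != 1:
        raise ValueError("incoming must be one-dimensional")
    if inc.size > 1 and (inc[1:] <= inc[:-1]).any():
        raise ValueError("incoming times must be strictly increasing")
    flags, mults_sel = _decisions_for(
        level.ratio_pattern, level.phase_offset_o, inc.size
    )
    out_arr = inc[flags] + level.base_delay_c + mults_sel * level.increment_delta
    if out_arr.size > 1 and (out_arr[1:] <= out_arr[:-1]).any():
        raise InfeasibleParametersError(
            "delay increment too large: outgoing times not increasing"
        )
    return out_arr, flags.copy()


def _mean_conducted_fraction(levels: Sequence[BlockLevel]) -> float:
    frac = 1.0
    for lv in levels:
        frac *= float(lv.conducted_fraction())
    return frac


def forward_simulate(params: MAVBParams, n_intervals: int) -> SimulationTrace:
    """Simulate the cascade until ``n_intervals`` ventricular RR intervals exist.

    Enough atrial beats are generated for the final level to conduct at
    least ``n_intervals + 1`` signals; the RR intervals are the successive
    differences of the last level's conducted times, truncated to exactly
    ``n_intervals`` entries.
    """
    if n_intervals < 1:
        raise ValueError("n_intervals must be >= 1")
    rho = _mean_conducted_fraction(params.levels)
    if rho <= 0:  # pragma: no cover - patterns always conduct >= 1 per cycle
        raise DegenerateModelError("blocktype conducts nothing")
    margin = sum(len(lv.decision_cycle()) for lv in params.levels) + 4
    count = math.ceil((n_intervals + 1) / rho) + margin
    for _ in range(8):
        times = [atrial_train(params.delta_a, params.t_start, count)]
        flags: list[np.ndarray] = []
        current = times[0]
        for lv in params.levels:
            current, fl = conduct_level(current, lv)
            times.append(current)
            flags.append(fl)
        if current.size >= n_intervals + 1:
            rr = current[1: n_intervals + 1] - current[:n_intervals]
            return SimulationTrace(times, flags, rr)
        count *= 2
    raise DegenerateModelError(
        "cascade failed to conduct enough signals"
    )  # pragma: no cover - margin makes this unreachable


def objective(
    params: MAVBParams,
    observed: RRSeries | Sequence[float],
    clip_threshold: float = CLIP_THRESHOLD_MS,
) -> tuple[float, np.ndarray, bool]:
    """Euclidean deviation of the forward simulation from observed RR data.

    Returns ``(F, residuals, feasible)`` with ``residuals = simulated -
    observed`` (ms) and ``F = sqrt(sum(residuals**2))``.  A candidate whose
    simulation deviates by more than ``clip_threshold`` ms on any single
    interval is clipped: ``feasible`` is False and ``F`` is reported as
    ``inf`` so the candidate never wins the minimisation.
    """
    obs = observed.intervals if isinstance(observed, RRSeries) else np.asarray(
        observed, dtype=float
    )
    trace = forward_simulate(params, obs.size)
    residuals = trace.ventricular_rr - obs
    feasible = bool(np.all(np.abs(residuals) <= clip_threshold))
    f = float(np.sqrt(np.sum(residuals**2))) if feasible else math.inf
    return f, residuals, feasible
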