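"""Inverse simulation: fit the multilevel AV block model to observed RR data.

The search space is a finite grid: five blocktype presets, the atrial
cycle length ``delta_a`` on a 1 ms grid within physiological bounds
(175–400 ms, further restricted per blocktype by the observed mean RR),
and per-level phase offsets and delay increments on the same grid.  The
solver enumerates this space exactly — no randomness, no local search —
and returns the feasible grid point with the smallest Euclidean deviation
from the observed intervals.  Ties are broken deterministically: lowest
``delta_a``, then lowest blocktype id, then lexicographically smallest
per-level parameter vector (see :func:`_candidate_key` for why ``delta_a``
leads).

Two equivalent implementations are provided.  :func:`solve` exploits the
fact that, with the discrete structure (blocktype, ratio choices, phase
offsets) fixed, every simulated RR interval is a *linear* function of
``(delta_a, delta_1, .., delta_L)``; the whole grid of a structure is then
evaluated as a vectorised matrix product, with candidates discarded as
soon as a single interval deviates beyond the clipping threshold or (when
pruning is enabled) the prefix residual norm exceeds the incumbent.
:func:`brute_force_solve` walks the identical grid one scalar forward
simulation at a time and exists as the testing oracle.  On integer-valued
inputs and grids both paths are bit-exact.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np

from .blocks import (
    DEFAULT_REGISTRY,
    TYPE_I,
    BlockLevel,
    Blocktype,
    BlocktypeRegistry,
    LevelSpec,
    conducted_fraction,
    decision_cycle,
)
from .mavb import (
    CLIP_THRESHOLD_MS,
    InfeasibleParametersError,
    MAVBParams,
    RRSeries,
    objective,
)

__all__ = [
    "SolverConfig",
    "MAVBSolution",
    "delta_a_bounds_for",
    "solve",
    "brute_force_solve",
    "sensitivity_scan",
    "ScanPoint",
]


@dataclass(frozen=True)
class SolverConfig:
    """Definition of the feasible set X and of the enumeration strategy.

    ``delta_a_bounds`` are the physiological limits on the atrial cycle
    length; per structure they are intersected with the data-consistency
    range ``rho * mean(RR) * (1 -/+ delta_a_slack)`` where ``rho`` is the
    structure's mean conducted fraction.  ``grid_step`` (ms, >= 1) is the
    lattice for ``delta_a`` and the delay increments.  ``prune`` toggles
    the monotone prefix-norm bound; it never changes the result.
    """

    delta_a_bounds: tuple[float, float] = (175.0, 400.0)
    grid_step: float = 1.0
    blocktype_ids: Optional[tuple[int, ...]] = None
    clip_threshold: float = CLIP_THRESHOLD_MS
    prune: bool = True
    delta_a_slack: float = 0.25
    registry: BlocktypeRegistry = field(default=DEFAULT_REGISTRY)

    def __post_init__(self) -> None:
        lo, hi = self.delta_a_bounds
        if lo < 0 or lo >= hi:
            raise ValueError("need 0 <= lo < hi for delta_a_bounds")
        if self.grid_step < 1:
            raise ValueError("grid_step must be >= 1 ms")

    def resolved_blocktype_ids(self) -> list[int]:
        if self.blocktype_ids is None:
            return self.registry.ids
        return sorted(self.blocktype_ids)


@dataclass
class MAVBSolution:
    """Result of the grid minimisation on one RR (sub-)series."""

    params: Optional[MAVBParams]
    objective_value: float
    residuals: Optional[np.ndarray]
    feasible: bool
    n_candidates_evaluated: int
    window: tuple[int, int]

    def oc_vector(self) -> list[float]:
        return [] if self.params is None else self.params.oc_vector()


@dataclass(frozen=True)
class ScanPoint:
    offset: float
    objective: float
    params: Optional[MAVBParams]


# ---------------------------------------------------------------------------
# feasible-set geometry
# ---------------------------------------------------------------------------

def _lattice(lo: float, hi: float, step: float) -> np.ndarray:
    """Multiples of ``step`` within [lo, hi] (absolute lattice, ascending)."""
    start = math.ceil(lo / step - 1e-9)
    stop = math.floor(hi / step + 1e-9)
    if stop < start:
        return np.empty(0, dtype=float)
    return np.arange(start, stop + 1, dtype=float) * step


def _delta_a_range_for_rho(
    rho: float, mean_rr: float, config: SolverConfig
) -> Optional[tuple[float, float]]:
    centre = rho * mean_rr
    lo = max(config.delta_a_bounds[0], centre * (1.0 - config.delta_a_slack))
    hi = min(config.delta_a_bounds[1], centre * (1.0 + config.delta_a_slack))
    if lo > hi:
        return None
    return (lo, hi)


def delta_a_bounds_for(
    blocktype: Blocktype,
    observed: "RRSeries | Sequence[float]",
    config: SolverConfig = SolverConfig(),
) -> Optional[tuple[float, float]]:
    """Data-dependent atrial cycle length bounds for one blocktype.

    The blocktype's mean conducted fraction ``rho`` implies
    ``delta_a ~= rho * mean(RR)``; the physiological bounds are intersected
    with that estimate widened by the configured slack.  For presets with
    free ratios the union over all ratio choices is returned.  ``None``
    means the blocktype cannot plausibly explain the sample.
    """
    obs = observed.intervals if isinstance(observed, RRSeries) else np.asarray(
        observed, dtype=float
    )
    if obs.size == 0:
        raise ValueError("observed series is empty")
    mean_rr = float(obs.mean())
    ranges = []
    for combo in _iter_structures(blocktype):
        rho = _structure_rho(combo)
        r = _delta_a_range_for_rho(rho, mean_rr, config)
        if r is not None:
            ranges.append(r)
    if not ranges:
        return None
    return (min(r[0] for r in ranges), max(r[1] for r in ranges))


# ---------------------------------------------------------------------------
# structure enumeration (shared by both solver paths)
# ---------------------------------------------------------------------------

#: one concrete discrete choice per level: (LevelSpec, ratio_pattern, offset)
Structure = tuple[tuple[LevelSpec, tuple, int], ...]


def _iter_structures(blocktype: Blocktype) -> Iterator[Structure]:
    per_level = []
    for spec in blocktype.levels:
        opts = []
        for pat in spec.ratio_options:
            n_positions = len(decision_cycle(pat))
            offsets = range(n_positions) if spec.free_offset else (0,)
            for o in offsets:
                opts.append((spec, pat, o))
        per_level.append(opts)
    return itertools.product(*per_level)


def _structure_rho(structure: Structure) -> float:
    rho = 1.0
    for _, pat, _ in structure:
        rho *= float(conducted_fraction(pat))
    return rho


def _structure_levels(structure: Structure, deltas: Sequence[float]) -> tuple:
    return tuple(
        BlockLevel(
            block_type=spec.block_type,
            ratio_pattern=pat,
            base_delay_c=0.0,
            increment_delta=float(d),
            phase_offset_o=o,
        )
        for (spec, pat, o), d in zip(structure, deltas)
    )


def _delta_grids(structure: Structure, config: SolverConfig) -> list[np.ndarray]:
    grids = []
    for spec, _, _ in structure:
        lo, hi = spec.delta_bounds
        if spec.block_type == TYPE_I and hi > lo:
            grids.append(_lattice(lo, hi, config.grid_step))
        else:
            grids.append(np.zeros(1))
    return grids


def _atrial_count(structure: Structure, n_intervals: int) -> int:
    # mirror of mavb.forward_simulate so both solver paths see the same
    # number of generated beats (monotonicity is checked on all of them)
    rho = _structure_rho(structure)
    margin = sum(len(decision_cycle(pat)) for _, pat, _ in structure) + 4
    return math.ceil((n_intervals + 1) / rho) + margin


_ARRAY_CACHE: dict = {}


def _structure_arrays(
    structure: Structure, n_intervals: int
) -> tuple[np.ndarray, np.ndarray, list]:
    """Linear coefficients of the structure's simulated RR intervals.

    Returns ``(A, C, D)`` over the parameter basis
    ``theta = (delta_a, delta_1, .., delta_L)``:

    * ``A`` (n_intervals x (1+L)): simulated RR interval ``j`` equals
      ``A[j] @ theta`` (base delays shift all conducted times equally and
      cancel in the differences),
    * ``C`` (m x (1+L)): monotonicity constraints — a parameter point is
      admissible iff ``C @ theta > 0`` componentwise (final-level RR
      positivity included),
    * ``D``: per non-final Type I level, ``(column, rows)`` where
      ``rows @ theta == 0`` for every row means the level's conducted
      output is a perfectly regular train.  Such a level with a positive
      increment is observationally redundant (equivalent to dropping the
      level at a rescaled atrial cycle) and is excluded from the
      canonical feasible set.
    """
    key = (
        tuple((spec.block_type, pat, o) for spec, pat, o in structure),
        n_intervals,
    )
    hit = _ARRAY_CACHE.get(key)
    if hit is not None:
        return hit
    n_params = 1 + len(structure)
    count = _atrial_count(structure, n_intervals)
    for _ in range(8):
        coeffs = np.zeros((count, n_params))
        coeffs[:, 0] = np.arange(count)
        per_level_out = []
        cur = coeffs
        ok = True
        for li, (_, pat, off) in enumerate(structure):
            cycle = decision_cycle(pat)
            flags = np.array([c for c, _ in cycle], dtype=bool)
            mults = np.array([m for _, m in cycle], dtype=float)
            pos = (off + np.arange(len(cur))) % len(cycle)
            conducted = flags[pos]
            nxt = cur[conducted].copy()
            nxt[:, 1 + li] += mults[pos][conducted]
            per_level_out.append(nxt)
            cur = nxt
        if len(cur) >= n_intervals + 1:
            break
        count *= 2
    else:  # pragma: no cover - margin makes this unreachable
        raise RuntimeError("structure conducts too few signals")
    a = np.diff(cur[: n_intervals + 1], axis=0)
    constraints = [np.diff(out, axis=0) for out in per_level_out if len(out) > 1]
    c = np.vstack(constraints) if constraints else np.empty((0, n_params))
    # constraints with no negative entry hold automatically (theta >= 0 with
    # a strictly positive delta_a coefficient); dedupe the rest
    if c.size:
        keep = np.any(c < 0, axis=1) | (c[:, 0] <= 0)
        c = np.unique(c[keep], axis=0)
    degeneracy = []
    for li, (spec, _, _) in enumerate(structure[:-1]):
        if spec.block_type != TYPE_I:
            continue
        gaps = np.diff(per_level_out[li], axis=0)
        rows = np.unique(np.diff(gaps, axis=0), axis=0)
        rows = rows[np.any(rows != 0, axis=1)]
        degeneracy.append((1 + li, rows))
    result = (a, c, degeneracy)
    if len(_ARRAY_CACHE) > 4096:
        _ARRAY_CACHE.clear()
    _ARRAY_CACHE[key] = result
    return result


# ---------------------------------------------------------------------------
# vectorised enumeration
# ---------------------------------------------------------------------------

def _evaluate_structure(
    a: np.ndarray,
    c: np.ndarray,
    degen: list,
    obs: np.ndarray,
    grids: list[np.ndarray],
    clip: float,
    incumbent: float,
    prune: bool,
) -> tuple[Optional[tuple[float, np.ndarray]], int]:
    """Best feasible grid point of one structure, in flat-grid tie order.

    Returns ``((F, theta), n_grid_points)`` or ``(None, n_grid_points)``.
    The grid is laid out delta_a-major, then the per-level increments in
    level order, so the first minimum matches the canonical tie-break.
    """
    # interval arithmetic on the clipping rule: every interval j requires
    # |a[j] @ theta - obs[j]| <= clip, which (with the increment grids
    # bounded) confines delta_a to an intersection of intervals; candidates
    # outside are clipped with certainty and need not be enumerated
    d_lo, d_hi = grids[0][0], grids[0][-1]
    for j in range(obs.size):
        alpha = a[j, 0]
        extra_lo = extra_hi = 0.0
        for d in range(1, a.shape[1]):
            beta = a[j, d]
            vals = (beta * grids[d][0], beta * grids[d][-1])
            extra_lo += min(vals)
            extra_hi += max(vals)
        d_lo = max(d_lo, (obs[j] - clip - extra_hi) / alpha)
        d_hi = min(d_hi, (obs[j] + clip - extra_lo) / alpha)
    if d_lo > grids[0][0] or d_hi < grids[0][-1]:
        grids = [grids[0][(grids[0] >= d_lo) & (grids[0] <= d_hi)]] + grids[1:]
        if grids[0].size == 0:
            return None, 0
    shape = tuple(g.size for g in grids)
    n_grid = int(np.prod(shape))
    bound_sq = incumbent * incumbent if (prune and math.isfinite(incumbent)) else None
    # first interval via broadcasting: no need to materialise the full mesh
    ndim = len(grids)
    r0 = -obs[0]
    for d, g in enumerate(grids):
        contrib = a[0][d] * g
        r0 = r0 + contrib.reshape((1,) * d + (-1,) + (1,) * (ndim - d - 1))
    r0 = np.broadcast_to(r0, shape).ravel()
    keep = np.abs(r0) <= clip
    idx = np.flatnonzero(keep)  # flat C-order indices: delta_a-major
    if idx.size == 0:
        return None, n_grid
    acc = r0[idx] ** 2
    if bound_sq is not None:
        sub = acc <= bound_sq
        idx, acc = idx[sub], acc[sub]
        if idx.size == 0:
            return None, n_grid
    multi = np.unravel_index(idx, shape)
    theta = np.stack([g[m] for g, m in zip(grids, multi)], axis=1)
    for j in range(1, obs.size):
        r = theta @ a[j] - obs[j]
        keep = np.abs(r) <= clip
        acc = acc[keep] + r[keep] ** 2
        theta = theta[keep]
        if bound_sq is not None:
            sub = acc <= bound_sq
            if not sub.all():
                acc, theta = acc[sub], theta[sub]
        if theta.shape[0] == 0:
            return None, n_grid
    # admissibility: strictly increasing conduction times at every level
    # (checked on the few survivors; independent of the residual columns)
    if c.size:
        alive = np.ones(theta.shape[0], dtype=bool)
        for row in c:
            alive &= theta @ row > 0
        acc, theta = acc[alive], theta[alive]
        if theta.shape[0] == 0:
            return None, n_grid
    # canonicality: drop redundant candidates whose non-final Type I level
    # (with a positive increment) emits a perfectly regular train
    for col, rows in degen:
        regular = np.ones(theta.shape[0], dtype=bool)
        for row in rows:
            regular &= theta @ row == 0
        keep = ~(regular & (theta[:, col] > 0))
        if not keep.all():
            acc, theta = acc[keep], theta[keep]
            if theta.shape[0] == 0:
                return None, n_grid
    # boolean masking preserves the flat (delta_a-major) order, so the first
    # minimum realises the canonical tie-break within the structure
    best = int(np.argmin(acc))
    return (float(math.sqrt(acc[best])), theta[best]), n_grid


def _candidate_key(
    f: float, bt_id: int, delta_a: float, structure: Structure,
    deltas: Sequence[float]
) -> tuple:
    oc: list[float] = []
    for (spec, pat, o), d in zip(structure, deltas):
        oc.extend([float(pat[0][1]), float(o), float(d)])
    # tie order: smallest delta_a, then lowest blocktype id, then lex oc.
    # Preferring the smallest consistent atrial cycle resolves the common
    # aliasing where dropping a leading 2:1 level and doubling delta_a
    # yields the identical RR sequence: the generating delta_a is the
    # smaller one, so exact noiseless recovery stays well defined.
    return (f, float(delta_a), bt_id, tuple(oc))


def solve(
    observed: "RRSeries | Sequence[float]",
    config: SolverConfig = SolverConfig(),
    window: Optional[tuple[int, int]] = None,
) -> MAVBSolution:
    """Globally minimise the deviation objective over the feasible grid.

    Exact enumeration with vectorised per-structure evaluation; optional
    pruning (clipping always applies, prefix-norm bounding against the
    incumbent when ``config.prune``).  Never raises on an unexplainable
    sample: if every candidate is clipped the sentinel solution with
    ``feasible=False`` and an infinite objective is returned.
    """
    series = observed if isinstance(observed, RRSeries) else RRSeries(
        np.asarray(observed, dtype=float)
    )
    obs = series.intervals
    if window is not None:
        obs = obs[window[0]: window[1]]
    else:
        window = (0, obs.size)
    if obs.size < 2:
        raise ValueError("need at least 2 observed intervals")
    mean_rr = float(obs.mean())
    best_key: Optional[tuple] = None
    best_params: Optional[MAVBParams] = None
    n_eval = 0
    for bt_id in config.resolved_blocktype_ids():
        blocktype = config.registry[bt_id]
        for structure in _iter_structures(blocktype):
            rho = _structure_rho(structure)
            rng = _delta_a_range_for_rho(rho, mean_rr, config)
            if rng is None:
                continue
            d_vals = _lattice(rng[0], rng[1], config.grid_step)
            if d_vals.size == 0:
                continue
            a, c, degen = _structure_arrays(structure, obs.size)
            grids = [d_vals] + _delta_grids(structure, config)
            # an increment that influences neither the intervals nor the
            # admissibility constraints is not identifiable: collapse its
            # grid to {0} (the tie-break would select 0 anyway)
            for li in range(len(structure)):
                col = 1 + li
                if grids[col].size > 1 and not (
                    np.any(a[:, col]) or (c.size and np.any(c[:, col]))
                ):
                    grids[col] = np.zeros(1)
            incumbent = best_key[0] if best_key is not None else math.inf
            result, n_grid = _evaluate_structure(
                a, c, degen, obs, grids, config.clip_threshold, incumbent,
                config.prune,
            )
            n_eval += n_grid
            if result is None:
                continue
            f, theta = result
            key = _candidate_key(f, bt_id, theta[0], structure, theta[1:])
            if best_key is None or key < best_key:
                best_key = key
                best_params = MAVBParams(
                    delta_a=float(theta[0]),
                    blocktype_id=bt_id,
                    levels=_structure_levels(structure, theta[1:]),
                )
    if best_key is None:
        return MAVBSolution(None, math.inf, None, False, n_eval, window)
    f, residuals, feasible = objective(
        best_params, obs, clip_threshold=config.clip_threshold
    )
    return MAVBSolution(best_params, f, residuals, feasible, n_eval, window)


def _is_canonical(params: MAVBParams, n_intervals: int) -> bool:
    """Scalar counterpart of the canonicality rule in the vectorised path:
    a non-final Type I level with a positive increment must not emit a
    perfectly regular conducted train."""
    from .mavb import forward_simulate

    if len(params.levels) < 2:
        return True
    if not any(
        lv.block_type == TYPE_I and lv.increment_delta > 0
        for lv in params.levels[:-1]
    ):
        return True
    trace = forward_simulate(params, n_intervals)
    for lv, out in zip(params.levels[:-1], trace.times_per_level[1:-1]):
        if lv.block_type == TYPE_I and lv.increment_delta > 0:
            gaps = np.diff(out)
            if gaps.size > 1 and np.all(gaps == gaps[0]):
                return False
    return True


def brute_force_solve(
    observed: "RRSeries | Sequence[float]",
    config: SolverConfig = SolverConfig(),
    window: Optional[tuple[int, int]] = None,
) -> MAVBSolution:
    """Exhaustive scalar enumeration of the identical grid (testing oracle).

    One forward simulation per candidate, no vectorisation, no pruning.
    Intended for coarse grids and short series only.
    """
    series = observed if isinstance(observed, RRSeries) else RRSeries(
        np.asarray(observed, dtype=float)
    )
    obs = series.intervals
    if window is not None:
        obs = obs[window[0]: window[1]]
    else:
        window = (0, obs.size)
    if obs.size < 2:
        raise ValueError("need at least 2 observed intervals")
    mean_rr = float(obs.mean())
    best_key: Optional[tuple] = None
    best_params: Optional[MAVBParams] = None
    n_eval = 0
    for bt_id in config.resolved_blocktype_ids():
        blocktype = config.registry[bt_id]
        for structure in _iter_structures(blocktype):
            rho = _structure_rho(structure)
            rng = _delta_a_range_for_rho(rho, mean_rr, config)
            if rng is None:
                continue
            d_vals = _lattice(rng[0], rng[1], config.grid_step)
            if d_vals.size == 0:
                continue
            grids = _delta_grids(structure, config)
            for deltas in itertools.product(*grids):
                levels = _structure_levels(structure, deltas)
                for delta_a in d_vals:
                    n_eval += 1
                    params = MAVBParams(
                        delta_a=float(delta_a),
                        blocktype_id=bt_id,
                        levels=levels,
                    )
                    try:
                        f, _, feasible = objective(
                            params, obs, clip_threshold=config.clip_threshold
                        )
                    except InfeasibleParametersError:
                        continue
                    if not feasible:
                        continue
                    if not _is_canonical(params, obs.size):
                        continue
                    key = _candidate_key(f, bt_id, delta_a, structure, deltas)
                    if best_key is None or key < best_key:
                        best_key, best_params = key, params
    if best_key is None:
        return MAVBSolution(None, math.inf, None, False, n_eval, window)
    f, residuals, feasible = objective(
        best_params, obs, clip_threshold=config.clip_threshold
    )
    return MAVBSolution(best_params, f, residuals, feasible, n_eval, window)


def sensitivity_scan(
    observed: "RRSeries | Sequence[float]",
    index: int,
    lo: float,
    hi: float,
    step: float = 1.0,
    config: SolverConfig = SolverConfig(),
) -> list[ScanPoint]:
    """Objective landscape under perturbation of a single interval.

    For every offset in ``lo..hi`` (inclusive, spacing ``step``) the
    interval at ``index`` is shifted by the offset and the full inverse
    problem re-solved.  Offsets driving the interval non-positive are
    recorded as infeasible.  The scan exposes the piecewise structure of
    the objective: locally quadratic in the offset while the argmin stays
    put, with jumps where clipping switches the optimal candidate.
    """
    series = observed if isinstance(observed, RRSeries) else RRSeries(
        np.asarray(observed, dtype=float)
    )
    obs = series.intervals
    if not 0 <= index < obs.size:
        raise ValueError("index out of range")
    if lo > 0 or hi < 0:
        raise ValueError("scan range must contain offset 0")
    n_points = int(round((hi - lo) / step)) + 1
    points: list[ScanPoint] = []
    for i in range(n_points):
        offset = lo + i * step
        perturbed = obs.copy()
        perturbed[index] += offset
        if perturbed[index] <= 0:
            points.append(ScanPoint(offset, math.inf, None))
            continue
        sol = solve(perturbed, config)
        points.append(ScanPoint(offset, sol.objective_value, sol.params))
    return points
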