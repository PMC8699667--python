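"""Feature generation from RR series and inverse-simulation fits.

Feature sets follow the study design:

========================  ====================================================
``rawRR``                 N-gram subsequence statistics of the raw intervals
``heatObjective``         the optimal deviation F(x*) alone
``heatSolution``          F(x*), the solution encoding, RRvar and RRmean
``heatSerAvg``            mean/sd of each moving-horizon component series
``heatSerAvgAge``         heatSerAvg plus patient age
``heatSeries``            N-gram statistics of the moving-horizon series
========================  ====================================================

The solution encoding is ``[delta_a*, blocktype id, oc*]`` with the
per-level parameter vector zero-padded (or truncated) to a fixed length
of 4, giving the 9-dimensional ``heatSolution`` vector.  When a window
admits no feasible candidate the objective feature saturates at
``sqrt(n) * 150`` — the largest value a feasible candidate could attain
under the clipping rule — and the solution fields are zero.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.preprocessing import StandardScaler

from .mavb import RRSeries, objective
from .solver import MAVBSolution, SolverConfig, solve

__all__ = [
    "OC_ENCODING_LENGTH",
    "WindowConfig",
    "FeatureVector",
    "StandardizationParams",
    "HeatSeries",
    "basic_features",
    "heat_features",
    "moving_windows",
    "heat_series",
    "series_avg",
    "ngram_features",
    "fit_standardizer",
    "apply_standardizer",
    "inverse_standardizer",
    "saturated_objective",
]

#: Fixed length of the flattened per-level parameter vector in features.
OC_ENCODING_LENGTH = 4

MIN_WINDOW = 10


@dataclass(frozen=True)
class WindowConfig:
    """Moving-horizon windows: stride-1 contiguous spans of length n_sub."""

    n_rr: int
    n_sub: int

    def __post_init__(self) -> None:
        if not MIN_WINDOW <= self.n_sub <= self.n_rr:
            raise ValueError(
                f"n_sub must lie in [{MIN_WINDOW}, n_rr={self.n_rr}]"
            )

    @property
    def windows(self) -> list[tuple[int, int]]:
        """Half-open (start, end) index pairs, count ``n_rr - n_sub + 1``."""
        return [
            (s, s + self.n_sub) for s in range(self.n_rr - self.n_sub + 1)
        ]

    def __len__(self) -> int:
        return self.n_rr - self.n_sub + 1


@dataclass
class FeatureVector:
    """Named numeric features with provenance."""

    names: list[str]
    values: np.ndarray
    feature_set: str
    sample_id: Optional[str] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.names) != self.values.size:
            raise ValueError("names and values must have equal length")

    def __len__(self) -> int:
        return self.values.size


def saturated_objective(n_intervals: int, clip_threshold: float = 150.0) -> float:
    """Largest objective a feasible candidate can attain on n intervals."""
    return math.sqrt(n_intervals) * clip_threshold


def basic_features(rr: RRSeries) -> tuple[float, float]:
    """Mean RR (ms) and sample variance of RR (ms^2), ddof 1."""
    if len(rr) < 2:
        raise ValueError("need at least 2 intervals")
    return float(rr.intervals.mean()), float(rr.intervals.var(ddof=1))


def _encode_solution(sol: MAVBSolution, n_intervals: int,
                     clip_threshold: float) -> tuple[float, list[float]]:
    """(objective feature, solution encoding of length 2 + OC_ENCODING_LENGTH)."""
    if sol.params is None or not math.isfinite(sol.objective_value):
        return (
            saturated_objective(n_intervals, clip_threshold),
            [0.0] * (2 + OC_ENCODING_LENGTH),
        )
    oc = sol.params.oc_vector()
    oc = (oc + [0.0] * OC_ENCODING_LENGTH)[:OC_ENCODING_LENGTH]
    return (
        sol.objective_value,
        [float(sol.params.delta_a), float(sol.params.blocktype_id)] + oc,
    )


def heat_features(
    rr: RRSeries, config: SolverConfig = SolverConfig()
) -> FeatureVector:
    """The 9-feature ``heatSolution`` vector for one full sample.

    Layout: ``[HEATobj, delta_a*, bt*, oc*_1..oc*_4, RRvar, RRmean]``.
    """
    sol = solve(rr, config)
    obj, enc = _encode_solution(sol, len(rr), config.clip_threshold)
    mean, var = basic_features(rr)
    names = (
        ["heat_obj", "delta_a", "blocktype"]
        + [f"oc_{i}" for i in range(1, OC_ENCODING_LENGTH + 1)]
        + ["rr_var", "rr_mean"]
    )
    values = [obj] + enc + [var, mean]
    return FeatureVector(names, np.array(values), "heatSolution", rr.sample_id)


def moving_windows(rr: RRSeries, n_sub: int) -> WindowConfig:
    """Stride-1 moving-horizon windows of length ``n_sub`` over the series."""
    return WindowConfig(n_rr=len(rr), n_sub=n_sub)


@dataclass
class HeatSeries:
    """Per-window fit series: objective, solution encoding, cross-window fit.

    ``heatfit[k]`` measures how well window ``k``'s optimal parameters
    explain the *next* window (the last window is evaluated on its
    predecessor) — a robustness/generalisation series.  Component series
    are rows of :meth:`components`.
    """

    window_config: WindowConfig
    heatobj: np.ndarray
    heatsol: np.ndarray  # (n_windows, 6)
    heatfit: np.ndarray
    solutions: list[MAVBSolution] = field(repr=False, default_factory=list)

    def components(self) -> dict[str, np.ndarray]:
        comp = {"heat_obj": self.heatobj}
        sol_names = ["delta_a", "blocktype"] + [
            f"oc_{i}" for i in range(1, OC_ENCODING_LENGTH + 1)
        ]
        for i, nm in enumerate(sol_names):
            comp[nm] = self.heatsol[:, i]
        comp["heat_fit"] = self.heatfit
        return comp


def heat_series(
    rr: RRSeries, n_sub: int, config: SolverConfig = SolverConfig()
) -> HeatSeries:
    """Moving-horizon fit series over all windows of length ``n_sub``."""
    wc = moving_windows(rr, n_sub)
    sols = [solve(rr.intervals[s:e], config) for s, e in wc.windows]
    n_win = len(wc)
    heatobj = np.empty(n_win)
    heatsol = np.empty((n_win, 2 + OC_ENCODING_LENGTH))
    heatfit = np.empty(n_win)
    for k, sol in enumerate(sols):
        heatobj[k], enc = _encode_solution(sol, n_sub, config.clip_threshold)
        heatsol[k] = enc
        # cross-window evaluation: params of window k on the adjacent window
        other = k + 1 if k + 1 < n_win else k - 1
        if other < 0:
            heatfit[k] = heatobj[k]  # single window: self-evaluation
            continue
        s, e = wc.windows[other]
        if sol.params is None:
            heatfit[k] = saturated_objective(n_sub, config.clip_threshold)
        else:
            f, _, feasible = objective(
                sol.params, rr.intervals[s:e],
                clip_threshold=config.clip_threshold,
            )
            heatfit[k] = f if feasible else saturated_objective(
                n_sub, config.clip_threshold
            )
    return HeatSeries(wc, heatobj, heatsol, heatfit, sols)


def series_avg(
    series: HeatSeries,
    age: Optional[float] = None,
    sample_id: Optional[str] = None,
) -> FeatureVector:
    """Mean and sample sd of every moving-horizon component series.

    With ``age`` given the feature set becomes ``heatSerAvgAge`` with age
    appended as the final feature.  A single-window series has no sample
    sd; 0 is reported with a warning.
    """
    comps = series.components()
    names: list[str] = []
    values: list[float] = []
    for nm, arr in comps.items():
        if arr.size == 0:
            raise ValueError("empty component series")
        names.append(f"{nm}_mean")
        values.append(float(arr.mean()))
        names.append(f"{nm}_sd")
        if arr.size < 2:
            warnings.warn(
                "single-window series: sample sd undefined, reporting 0",
                stacklevel=2,
            )
            values.append(0.0)
        else:
            values.append(float(arr.std(ddof=1)))
    feature_set = "heatSerAvg"
    if age is not None:
        names.append("age")
        values.append(float(age))
        feature_set = "heatSerAvgAge"
    return FeatureVector(names, np.array(values), feature_set, sample_id)


def ngram_features(
    seq: Sequence[float],
    feature_set: str = "rawRR",
    sample_id: Optional[str] = None,
    prefix: str = "",
) -> FeatureVector:
    """Means and sample sds of all contiguous subsequences (N-grams).

    For a series of length ``n``: the ``n (n + 1) / 2`` subsequence means
    (length >= 1) followed by the ``n (n - 1) / 2`` sample sds
    (length >= 2), each group ordered by start index then length —
    ``n ** 2`` features in total.
    """
    x = np.asarray(seq, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("need a series of length >= 2")
    names: list[str] = []
    values: list[float] = []
    for start in range(n):
        for length in range(1, n - start + 1):
            names.append(f"{prefix}mean_s{start}_l{length}")
            values.append(float(x[start: start + length].mean()))
    for start in range(n):
        for length in range(2, n - start + 1):
            names.append(f"{prefix}sd_s{start}_l{length}")
            values.append(float(x[start: start + length].std(ddof=1)))
    return FeatureVector(names, np.array(values), feature_set, sample_id)


@dataclass
class StandardizationParams:
    """Per-feature location/scale learned on training data only."""

    mean: np.ndarray
    scale: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.scale <= 0):
            raise ValueError("scales must be positive")


def fit_standardizer(train: np.ndarray) -> StandardizationParams:
    """Learn zero-mean/unit-sd transforms per column from training rows.

    Constant columns get scale 1 (with a warning) so the transform stays
    invertible.
    """
    x = np.asarray(train, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a 2-d array with >= 2 training samples")
    scaler = StandardScaler().fit(x)
    if np.any(x.var(axis=0) == 0):
        warnings.warn("constant feature column: scale set to 1", stacklevel=2)
    return StandardizationParams(
        mean=scaler.mean_.copy(), scale=scaler.scale_.copy()
    )


def apply_standardizer(
    params: StandardizationParams, features: np.ndarray
) -> np.ndarray:
    """Apply training-set location/scale to (train or held-out) rows."""
    return (np.asarray(features, dtype=float) - params.mean) / params.scale


def inverse_standardizer(
    params: StandardizationParams, standardized: np.ndarray
) -> np.ndarray:
    return np.asarray(standardized, dtype=float) * params.scale + params.mean


FEATURE_SETS = (
    "rawRR",
    "heatObjective",
    "heatSolution",
    "heatSerAvg",
    "heatSerAvgAge",
    "heatSeries",
)


def _sample_features(
    rr: RRSeries, feature_set: str, config: SolverConfig, n_sub: Optional[int]
) -> FeatureVector:
    if feature_set == "rawRR":
        cut = rr.intervals[: n_sub] if n_sub else rr.intervals
        return ngram_features(cut, "rawRR", rr.sample_id)
    if feature_set in ("heatObjective", "heatSolution"):
        fv = heat_features(rr, config)
        if feature_set == "heatObjective":
            return FeatureVector(
                ["heat_obj"], fv.values[:1], "heatObjective", rr.sample_id
            )
        return fv
    if feature_set in ("heatSerAvg", "heatSerAvgAge", "heatSeries"):
        ns = n_sub or max(MIN_WINDOW, len(rr) - 5)
        hs = heat_series(rr, ns, config)
        if feature_set == "heatSeries":
            parts = [
                ngram_features(arr, "heatSeries", rr.sample_id, prefix=f"{nm}_")
                for nm, arr in hs.components().items()
            ]
            return FeatureVector(
                [n for p in parts for n in p.names],
                np.concatenate([p.values for p in parts]),
                "heatSeries",
                rr.sample_id,
            )
        age = rr.age if feature_set == "heatSerAvgAge" else None
        fv = series_avg(hs, age=age, sample_id=rr.sample_id)
        return fv
    raise ValueError(f"unknown feature set {feature_set!r}")


def feature_table(
    samples: Sequence[RRSeries],
    feature_set: str,
    config: SolverConfig = SolverConfig(),
    n_sub: Optional[int] = None,
):
    """Feature matrix for a list of samples as a pandas DataFrame.

    Columns: ``sample_id``, ``label``, ``age`` followed by the feature
    set's canonical feature names in canonical order.
    """
    import pandas as pd

    rows = []
    for rr in samples:
        fv = _sample_features(rr, feature_set, config, n_sub)
        row = {"sample_id": rr.sample_id, "label": rr.label, "age": rr.age}
        row.update(dict(zip(fv.names, fv.values)))
        rows.append(row)
    return pd.DataFrame(rows)
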