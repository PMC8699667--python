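"""Synthetic labelled RR datasets emulating the clinical study population.

AFlu samples are generated by the forward multilevel-block model itself:
a regular atrial cycle around 240 ms (constant within a sample, i.e.
well inside the sub-5 ms regularity seen in flutter recordings) driving
a randomly drawn blocktype, plus independent Gaussian measurement jitter
on each RR interval.  AFib samples come from an irregular atrial renewal
process (gamma inter-arrival times, mean cycle 182 ms) filtered by a
concealed-conduction rule: an impulse conducts only when the time since
the last conducted beat exceeds a refractory period redrawn per beat.
A pseudo-regularisation variant uses a narrow refractory distribution at
high rate (about 160 beats/min), producing the near-regular ventricular
response that is the model's known failure mode — still labelled AFib.

All randomness flows from a single seed; the ground-truth parameters of
every sample are kept in a sidecar for parameter-recovery scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .blocks import DEFAULT_REGISTRY, TYPE_I, BlocktypeRegistry
from .mavb import (
    AFIB,
    AFLU,
    InfeasibleParametersError,
    MAVBParams,
    RRSeries,
    forward_simulate,
)
from .solver import _iter_structures, _structure_levels

__all__ = [
    "GeneratorConfig",
    "Dataset",
    "gen_aflu",
    "gen_afib",
    "gen_pseudo_regular",
    "make_benchmark",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition parameters of the synthetic benchmark."""

    n_per_class: int = 190
    n_rr: int = 22

    # AFlu: forward-model generation
    aflu_delta_a_mean: float = 240.0
    aflu_delta_a_sd: float = 20.0  # between samples; within a sample it is 0
    aflu_delta_a_range: tuple[float, float] = (180.0, 340.0)
    aflu_blocktype_ids: Optional[tuple[int, ...]] = None
    aflu_increment_max: float = 40.0
    jitter_sd: float = 5.0

    # AFib: irregular atrial renewal + concealed conduction
    afib_atrial_mean: float = 182.0
    afib_atrial_cv: float = 0.25
    afib_refractory: tuple[float, float] = (250.0, 550.0)

    # pseudo-regular AFib: narrow refractory at high ventricular rate
    pseudo_refractory: tuple[float, float] = (265.0, 290.0)
    pseudo_regular_fraction: float = 0.05

    age_mean: float = 68.0
    age_sd: float = 10.0

    registry: BlocktypeRegistry = field(default=DEFAULT_REGISTRY)

    def __post_init__(self) -> None:
        if self.n_per_class < 1 or self.n_rr < 2:
            raise ValueError("need n_per_class >= 1 and n_rr >= 2")
        for lo, hi in (self.afib_refractory, self.pseudo_refractory):
            if not 0 < lo < hi:
                raise ValueError("refractory bounds must satisfy 0 < lo < hi")
        if not 0 <= self.pseudo_regular_fraction <= 1:
            raise ValueError("pseudo_regular_fraction must lie in [0, 1]")


@dataclass
class Dataset:
    """Labelled samples plus the generating ground truth."""

    samples: list[RRSeries]
    truth: dict[str, dict]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for s in self.samples:
            row = {"sample_id": s.sample_id, "label": s.label, "age": s.age}
            for i, v in enumerate(s.intervals, start=1):
                row[f"rr_{i:02d}"] = int(v)
            rows.append(row)
        return pd.DataFrame(rows)

    def labels01(self) -> np.ndarray:
        """Binary labels with AFib = 1 (the positive/detected class)."""
        return np.array([1 if s.label == AFIB else 0 for s in self.samples])

    def rr_matrix(self) -> np.ndarray:
        return np.stack([s.intervals for s in self.samples])


def _draw_age(rng: np.random.Generator, config: GeneratorConfig) -> float:
    return float(np.clip(round(rng.normal(config.age_mean, config.age_sd)),
                         30, 90))


def _random_aflu_params(
    rng: np.random.Generator, config: GeneratorConfig
) -> MAVBParams:
    ids = (
        config.registry.ids
        if config.aflu_blocktype_ids is None
        else sorted(config.aflu_blocktype_ids)
    )
    bt_id = int(rng.choice(ids))
    structures = list(_iter_structures(config.registry[bt_id]))
    structure = structures[int(rng.integers(len(structures)))]
    deltas = []
    for spec, _, _ in structure:
        lo, hi = spec.delta_bounds
        if spec.block_type == TYPE_I and hi > lo:
            top = min(hi, config.aflu_increment_max)
            deltas.append(float(rng.integers(int(lo), int(top) + 1)))
        else:
            deltas.append(0.0)
    lo, hi = config.aflu_delta_a_range
    delta_a = float(
        np.clip(round(rng.normal(config.aflu_delta_a_mean,
                                 config.aflu_delta_a_sd)), lo, hi)
    )
    return MAVBParams(delta_a, bt_id, _structure_levels(structure, deltas))


def gen_aflu(
    config: GeneratorConfig,
    seed: int,
    n: Optional[int] = None,
    id_prefix: str = "aflu",
) -> Dataset:
    """AFlu samples: forward simulation plus measurement jitter.

    Each sample draws an atrial cycle length (1 ms grid), a blocktype
    preset with random on-grid parameters, simulates ``n_rr`` intervals
    and adds independent zero-mean Gaussian jitter before rounding back
    to the 1 ms measurement grid.
    """
    rng = np.random.default_rng(seed)
    n = config.n_per_class if n is None else n
    samples, truth = [], {}
    for i in range(n):
        for _ in range(100):
            params = _random_aflu_params(rng, config)
            try:
                rr = forward_simulate(params, config.n_rr).ventricular_rr
            except InfeasibleParametersError:
                continue
            jittered = np.round(
                rr + rng.normal(0.0, config.jitter_sd, rr.size)
            )
            if np.all(jittered > 0):
                break
        else:  # pragma: no cover - resampling always succeeds in practice
            raise RuntimeError("could not draw a feasible AFlu sample")
        sid = f"{id_prefix}_{i:04d}"
        samples.append(
            RRSeries(jittered, label=AFLU, age=_draw_age(rng, config),
                     sample_id=sid, patient_id=sid)
        )
        truth[sid] = {
            "generator": "aflu",
            "delta_a": params.delta_a,
            "blocktype_id": params.blocktype_id,
            "oc": params.oc_vector(),
            "clean_rr": [float(v) for v in rr],
        }
    return Dataset(samples, truth)


def _conducted_rr(
    rng: np.random.Generator,
    config: GeneratorConfig,
    refractory: tuple[float, float],
    n_rr: int,
) -> np.ndarray:
    """RR intervals from the renewal-process/concealed-conduction mechanism."""
    cv = config.afib_atrial_cv
    shape = 1.0 / (cv * cv)
    scale = config.afib_atrial_mean / shape
    ref_lo, ref_hi = refractory
    for horizon in (40 * (n_rr + 1), 400 * (n_rr + 1)):
        arrivals = np.cumsum(rng.gamma(shape, scale, size=horizon))
        conducted = [arrivals[0]]
        refractory_now = rng.uniform(ref_lo, ref_hi)
        for t in arrivals[1:]:
            if t - conducted[-1] > refractory_now:
                conducted.append(t)
                refractory_now = rng.uniform(ref_lo, ref_hi)
                if len(conducted) == n_rr + 1:
                    break
        if len(conducted) == n_rr + 1:
            rr = np.diff(np.asarray(conducted))
            return np.maximum(np.round(rr), 1.0)
    raise RuntimeError(
        "refractory filter conducted too few beats within the horizon"
    )


def gen_afib(
    config: GeneratorConfig,
    seed: int,
    n: Optional[int] = None,
    id_prefix: str = "afib",
    refractory: Optional[tuple[float, float]] = None,
    generator_name: str = "afib",
) -> Dataset:
    """AFib samples: chaotic atrial input with concealed AV conduction."""
    rng = np.random.default_rng(seed)
    n = config.n_per_class if n is None else n
    refr = config.afib_refractory if refractory is None else refractory
    samples, truth = [], {}
    for i in range(n):
        rr = _conducted_rr(rng, config, refr, config.n_rr)
        sid = f"{id_prefix}_{i:04d}"
        samples.append(
            RRSeries(rr, label=AFIB, age=_draw_age(rng, config),
                     sample_id=sid, patient_id=sid)
        )
        truth[sid] = {
            "generator": generator_name,
            "atrial_mean": config.afib_atrial_mean,
            "atrial_cv": config.afib_atrial_cv,
            "refractory": list(refr),
        }
    return Dataset(samples, truth)


def gen_pseudo_regular(
    config: GeneratorConfig,
    seed: int,
    n: Optional[int] = None,
    id_prefix: str = "pseudo",
) -> Dataset:
    """High-rate pseudo-regular AFib (mean ventricular rate ~ 160 bpm).

    Same chaotic atrial mechanism as :func:`gen_afib` but with a narrow
    refractory distribution, so the RR variability collapses despite the
    irregular atrial input.  These samples are labelled AFib and exist to
    stress the classifier (the mechanistic model fits them too well).
    """
    return gen_afib(
        config,
        seed,
        n=n,
        id_prefix=id_prefix,
        refractory=config.pseudo_refractory,
        generator_name="pseudo_regular",
    )


def make_benchmark(config: GeneratorConfig, seed: int) -> Dataset:
    """Balanced, shuffled benchmark: AFlu vs AFib (incl. pseudo-regular).

    ``n_per_class`` samples per class; within the AFib class a fraction
    ``pseudo_regular_fraction`` comes from the pseudo-regularisation
    generator.  The shuffle and all draws are deterministic in ``seed``.
    """
    root = np.random.default_rng(seed)
    seeds = root.integers(0, 2**31 - 1, size=4)
    n_pseudo = int(round(config.pseudo_regular_fraction * config.n_per_class))
    n_afib = config.n_per_class - n_pseudo
    aflu = gen_aflu(config, int(seeds[0]))
    afib = gen_afib(config, int(seeds[1]), n=n_afib)
    parts = [aflu, afib]
    if n_pseudo:
        parts.append(gen_pseudo_regular(config, int(seeds[2]), n=n_pseudo))
    samples = [s for p in parts for s in p.samples]
    truth = {k: v for p in parts for k, v in p.truth.items()}
    order = np.random.default_rng(int(seeds[3])).permutation(len(samples))
    return Dataset([samples[i] for i in order], truth)
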