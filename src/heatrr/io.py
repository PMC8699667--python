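"""Readers, writers and run configuration.

File formats: samples as CSV (``sample_id, label, age, rr_01..rr_NN``,
ms integers), solutions and cross-validation results as JSON with a
schema version field, feature tables as CSV with a JSON sidecar carrying
provenance (feature set, window length, solver-config hash), and the run
configuration as YAML.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .blocks import BlocktypeRegistry, DEFAULT_REGISTRY
from .mavb import MAVBParams, RRSeries
from .ml import CVResult, HyperParamGrid
from .simulate import Dataset, GeneratorConfig
from .solver import MAVBSolution, SolverConfig

SCHEMA_VERSION = 1

__all__ = [
    "RunConfig",
    "read_rr_csv",
    "write_samples_csv",
    "write_truth_json",
    "write_solution",
    "read_solution",
    "write_features",
    "write_cvresult",
    "load_config",
    "save_config",
    "config_hash",
]


# ---------------------------------------------------------------------------
# samples
# ---------------------------------------------------------------------------

def _rr_columns(df: pd.DataFrame) -> list[str]:
    cols = [c for c in df.columns if c.startswith("rr_")]
    if not cols:
        raise ValueError("missing rr_* interval columns")
    return sorted(cols, key=lambda c: int(c.split("_")[1]))


def read_rr_csv(path: "str | Path") -> list[RRSeries]:
    """Read a samples table into validated RR series.

    Interval values are snapped to the 1 ms measurement grid (with a
    warning when any value was not integral); non-positive intervals are
    a parse error naming the offending row.
    """
    df = pd.read_csv(path)
    if "sample_id" not in df.columns:
        raise ValueError("missing required column 'sample_id'")
    rr_cols = _rr_columns(df)
    out: list[RRSeries] = []
    rounding = 0.0
    for i, rec in df.iterrows():
        vals = rec[rr_cols].to_numpy(dtype=float)
        rounded = np.round(vals)
        rounding = max(rounding, float(np.max(np.abs(vals - rounded))))
        if np.any(rounded <= 0):
            raise ValueError(
                f"non-positive RR interval in row {i} "
                f"(sample_id={rec['sample_id']!r})"
            )
        label = rec.get("label")
        if isinstance(label, float) and math.isnan(label):
            label = None
        age = rec.get("age")
        if age is not None and (isinstance(age, float) and math.isnan(age)):
            age = None
        out.append(
            RRSeries(
                rounded,
                label=label,
                age=None if age is None else float(age),
                sample_id=str(rec["sample_id"]),
                patient_id=str(rec["patient_id"]) if "patient_id" in df.columns
                else None,
            )
        )
    if rounding > 1e-9:
        warnings.warn(
            f"RR values rounded to the 1 ms grid (max adjustment "
            f"{rounding:.3f} ms)",
            stacklevel=2,
        )
    return out


def write_samples_csv(
    samples: "Dataset | Sequence[RRSeries]", path: "str | Path"
) -> None:
    if isinstance(samples, Dataset):
        df = samples.to_dataframe()
    else:
        rows = []
        for s in samples:
            row = {"sample_id": s.sample_id, "label": s.label, "age": s.age}
            for i, v in enumerate(s.intervals, start=1):
                row[f"rr_{i:02d}"] = int(v)
            rows.append(row)
        df = pd.DataFrame(rows)
    df.to_csv(path, index=False)


def write_truth_json(dataset: Dataset, path: "str | Path") -> None:
    payload = {"schema_version": SCHEMA_VERSION, "truth": dataset.truth}
    Path(path).write_text(json.dumps(payload, indent=1))


# ---------------------------------------------------------------------------
# solutions
# ---------------------------------------------------------------------------

def _params_to_dict(params: Optional[MAVBParams]) -> Optional[dict]:
    if params is None:
        return None
    return {
        "delta_a": params.delta_a,
        "blocktype_id": params.blocktype_id,
        "t_start": params.t_start,
        "levels": [
            {
                "block_type": lv.block_type,
                "ratio_pattern": [list(p) for p in lv.ratio_pattern],
                "base_delay_c": lv.base_delay_c,
                "increment_delta": lv.increment_delta,
                "phase_offset_o": lv.phase_offset_o,
            }
            for lv in params.levels
        ],
    }


def _params_from_dict(d: Optional[dict]) -> Optional[MAVBParams]:
    if d is None:
        return None
    from .blocks import BlockLevel

    return MAVBParams(
        delta_a=d["delta_a"],
        blocktype_id=d["blocktype_id"],
        t_start=d.get("t_start", 0.0),
        levels=tuple(
            BlockLevel(
                block_type=lv["block_type"],
                ratio_pattern=tuple(tuple(p) for p in lv["ratio_pattern"]),
                base_delay_c=lv["base_delay_c"],
                increment_delta=lv["increment_delta"],
                phase_offset_o=lv["phase_offset_o"],
            )
            for lv in d["levels"]
        ),
    )


def solution_to_dict(sol: MAVBSolution) -> dict:
    return {
        "params": _params_to_dict(sol.params),
        "objective_value": sol.objective_value
        if math.isfinite(sol.objective_value)
        else None,
        "residuals": None if sol.residuals is None else [
            float(r) for r in sol.residuals
        ],
        "feasible": sol.feasible,
        "n_candidates_evaluated": sol.n_candidates_evaluated,
        "window": list(sol.window),
    }


def solution_from_dict(d: dict) -> MAVBSolution:
    return MAVBSolution(
        params=_params_from_dict(d["params"]),
        objective_value=math.inf
        if d["objective_value"] is None
        else d["objective_value"],
        residuals=None if d["residuals"] is None else np.asarray(d["residuals"]),
        feasible=d["feasible"],
        n_candidates_evaluated=d["n_candidates_evaluated"],
        window=tuple(d["window"]),
    )


def write_solution(
    solutions: "MAVBSolution | dict[str, MAVBSolution]", path: "str | Path"
) -> None:
    if isinstance(solutions, MAVBSolution):
        body = solution_to_dict(solutions)
    else:
        body = {k: solution_to_dict(v) for k, v in solutions.items()}
    Path(path).write_text(
        json.dumps({"schema_version": SCHEMA_VERSION, "solution": body},
                   indent=1)
    )


def read_solution(path: "str | Path"):
    payload = json.loads(Path(path).read_text())
    body = payload["solution"]
    if "params" in body:
        return solution_from_dict(body)
    return {k: solution_from_dict(v) for k, v in body.items()}


# ---------------------------------------------------------------------------
# features / CV results
# ---------------------------------------------------------------------------

def write_features(
    table: pd.DataFrame,
    path: "str | Path",
    feature_set: str,
    n_sub: Optional[int] = None,
    solver_config: Optional[SolverConfig] = None,
) -> None:
    """Feature CSV plus a JSON sidecar with provenance."""
    path = Path(path)
    table.to_csv(path, index=False)
    sidecar = {
        "schema_version": SCHEMA_VERSION,
        "feature_set": feature_set,
        "n_sub": n_sub,
        "n_features": int(
            sum(c not in ("sample_id", "label", "age") for c in table.columns)
        ),
        "solver_config_hash": None
        if solver_config is None
        else config_hash(solver_config),
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=1)
    )


def write_cvresult(cv: CVResult, path: "str | Path") -> None:
    payload = {
        "schema_version": SCHEMA_VERSION,
        "mean_accuracy": cv.mean_accuracy,
        "sd_accuracy": cv.sd_accuracy,
        "mean_roc": cv.mean_roc,
        "sd_roc": cv.sd_roc,
        "sensitivity": cv.sensitivity,
        "specificity": cv.specificity,
        "chosen_hyperparameters": {
            str(k): v for k, v in cv.chosen_hyperparameters.items()
        },
        "per_fold": cv.per_fold.to_dict(orient="records"),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RunConfig:
    """Everything a pipeline run depends on, serialisable round-trip."""

    solver: SolverConfig = field(default_factory=SolverConfig)
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    ml: HyperParamGrid = field(default_factory=HyperParamGrid)
    seed: int = 0
    log_level: str = "INFO"


def _to_plain(obj):
    if isinstance(obj, BlocktypeRegistry):
        return obj.to_dict()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {
            f.name: _to_plain(getattr(obj, f.name))
            for f in dataclasses.fields(obj)
        }
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _tupled(v):
    return tuple(v) if isinstance(v, list) else v


def save_config(config: RunConfig, path: "str | Path") -> None:
    Path(path).write_text(yaml.safe_dump(_to_plain(config), sort_keys=True))


def load_config(path: "str | Path") -> RunConfig:
    d = yaml.safe_load(Path(path).read_text())
    solver = d.get("solver", {})
    registry = solver.get("registry")
    solver_cfg = SolverConfig(
        delta_a_bounds=tuple(solver.get("delta_a_bounds", (175.0, 400.0))),
        grid_step=solver.get("grid_step", 1.0),
        blocktype_ids=_tupled(solver.get("blocktype_ids")),
        clip_threshold=solver.get("clip_threshold", 150.0),
        prune=solver.get("prune", True),
        delta_a_slack=solver.get("delta_a_slack", 0.25),
        registry=DEFAULT_REGISTRY
        if registry is None
        else BlocktypeRegistry.from_dict(registry),
    )
    gen = d.get("generator", {})
    gen_registry = gen.get("registry")
    gen_cfg = GeneratorConfig(
        **{
            k: (tuple(v) if isinstance(v, list) else v)
            for k, v in gen.items()
            if k != "registry"
        },
        registry=DEFAULT_REGISTRY
        if gen_registry is None
        else BlocktypeRegistry.from_dict(gen_registry),
    )
    ml = d.get("ml", {})
    ml_cfg = HyperParamGrid(
        kernels=tuple(ml.get("kernels", ("rbf", "poly"))),
        C=tuple(ml.get("C", (0.1, 1.0, 10.0))),
        gamma=tuple(ml.get("gamma", (0.01, 0.1, 1.0))),
        n_sub=_tupled(ml.get("n_sub")),
        dropout=tuple(ml.get("dropout", (0.1, 0.2, 0.3))),
    )
    return RunConfig(
        solver=solver_cfg,
        generator=gen_cfg,
        ml=ml_cfg,
        seed=int(d.get("seed", 0)),
        log_level=str(d.get("log_level", "INFO")),
    )


def config_hash(config) -> str:
    """Stable short hash of any config dataclass (logged with every run)."""
    plain = _to_plain(config)
    blob = json.dumps(plain, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
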