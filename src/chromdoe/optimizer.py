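"""Constraint-based selection of operating conditions from fitted surfaces.

The screening models predict the retention factors and the two critical
resolutions anywhere in the design region; the optimizer scans a coded grid,
keeps the conditions satisfying the resolution and run-time constraints, and
ranks the feasible set by the chosen objective (fastest run by default —
separation quality is a constraint, speed is the prize).

The default grid spans the factorial cube [−1, 1] per factor, where all
three factors were jointly varied and the quadratic surface interpolates;
any grid must stay inside the rotatable sphere (coded norm ≤ alpha).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .doe import FactorDef, rotatable_alpha, to_actual
from .pls import PLSModel, expand_terms


@dataclass(frozen=True)
class OptimizationCriteria:
    """Feasibility thresholds and ranking objective."""

    min_resolution: float = 2.0
    max_last_peak_time: float = 12.0  # min
    objective: str = "minimize_run_time"  # or "maximize_min_resolution"

    def __post_init__(self) -> None:
        if self.min_resolution <= 0:
            raise ValueError("min_resolution must be > 0")
        if self.objective not in ("minimize_run_time", "maximize_min_resolution"):
            raise ValueError(f"unknown objective {self.objective!r}")


@dataclass
class OptimizationResult:
    """Ranked feasible conditions (may be empty — that is a result, not an error)."""

    table: pd.DataFrame      # feasible rows, sorted by objective
    criteria: OptimizationCriteria
    n_evaluated: int

    @property
    def feasible(self) -> bool:
        return len(self.table) > 0

    @property
    def best(self) -> pd.Series | None:
        return self.table.iloc[0] if self.feasible else None


def predicted_runtime(k_values, t0: float, flow: float = 1.0) -> float:
    """Predicted last-peak elution time: t0 (1 + max k) / flow."""
    k = np.asarray(k_values, dtype=float)
    if np.any(k < 0):
        raise ValueError("retention factors must be >= 0")
    return t0 * (1.0 + float(k.max())) / flow


def grid_search(
    models: dict[str, PLSModel],
    factors: tuple[FactorDef, ...],
    criteria: OptimizationCriteria | None = None,
    t0: float = 2.05,
    flow: float = 1.0,
    n_points: int = 21,
    grid_limits: tuple[float, float] = (-1.0, 1.0),
    alpha: float | None = None,
) -> OptimizationResult:
    """Scan a coded grid of conditions against the fitted response models.

    ``models`` must contain the five retention-factor models (k_M, k_A, k_B,
    k_C, k_D) and the two resolution models (Rs_AB, Rs_CD).  Points outside
    the sphere of radius ``alpha`` (rotatable alpha by default) are dropped.
    Deterministic: ties in the objective break toward the design centre and
    then lexicographically.
    """
    criteria = criteria or OptimizationCriteria()
    k = len(factors)
    if alpha is None:
        alpha = rotatable_alpha(k)
    axes = [np.linspace(grid_limits[0], grid_limits[1], n_points)] * k
    mesh = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, k)
    mesh = mesh[np.linalg.norm(mesh, axis=1) <= alpha + 1e-12]

    X = expand_terms(mesh).to_numpy()
    pred: dict[str, np.ndarray] = {}
    for name, model in models.items():
        pred[name] = X @ model.coef + model.intercept

    k_cols = ["k_M", "k_A", "k_B", "k_C", "k_D"]
    missing = [c for c in k_cols + ["Rs_AB", "Rs_CD"] if c not in pred]
    if missing:
        raise KeyError(f"missing response models: {missing}")

    k_pred = np.clip(np.column_stack([pred[c] for c in k_cols]), 0.0, None)
    runtime = t0 * (1.0 + k_pred.max(axis=1)) / flow
    min_rs = np.minimum(pred["Rs_AB"], pred["Rs_CD"])
    feasible = (
        (pred["Rs_AB"] >= criteria.min_resolution)
        & (pred["Rs_CD"] >= criteria.min_resolution)
        & (runtime <= criteria.max_last_peak_time)
    )

    table = pd.DataFrame(mesh[feasible], columns=[f"coded_{f.name}" for f in factors])
    actual = to_actual(mesh[feasible], factors) if feasible.any() else np.empty((0, k))
    for j, f in enumerate(factors):
        table[f"actual_{f.name}"] = actual[:, j] if len(actual) else []
    for c in k_cols + ["Rs_AB", "Rs_CD"]:
        table[c] = pred[c][feasible]
    table["min_resolution"] = min_rs[feasible]
    table["runtime_min"] = runtime[feasible]
    table["coded_norm"] = np.linalg.norm(mesh[feasible], axis=1)

    if criteria.objective == "minimize_run_time":
        sort_cols = ["runtime_min", "coded_norm"] + [f"coded_{f.name}" for f in factors]
        ascending = [True] * len(sort_cols)
    else:
        sort_cols = ["min_resolution", "coded_norm"] + [f"coded_{f.name}" for f in factors]
        ascending = [False, True] + [True] * k
    table = table.sort_values(sort_cols, ascending=ascending, kind="mergesort")
    table = table.reset_index(drop=True)
    return OptimizationResult(table=table, criteria=criteria, n_evaluated=len(mesh))
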