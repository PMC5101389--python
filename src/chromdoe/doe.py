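"""Central composite designs (CCD) for chromatographic method screening.

A rotatable CCD in K factors consists of a 2^K full factorial block at coded
levels ±1, 2K axial (star) runs at coded distance ±alpha on one factor at a
time, and n_center replicated centre runs.  Rotatability (constant prediction
variance on spheres around the centre) requires alpha = (2^K)^(1/4).

Factors are handled in *coded* units; ``FactorDef`` carries the affine map
between coded and actual units (actual = center + coded * step).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd


class DesignError(ValueError):
    """Invalid factor definition or unsupported design request."""


@dataclass(frozen=True)
class FactorDef:
    """One design factor: an affine map between coded and actual levels.

    Parameters
    ----------
    name:
        Short identifier used in column names (e.g. ``"acn"``).
    center:
        Actual value at coded level 0.
    step:
        Actual distance corresponding to one coded unit; must be > 0.
    unit:
        Unit string for reporting (e.g. ``"% v/v"``).
    """

    name: str
    center: float
    step: float
    unit: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite(self.step) or self.step <= 0:
            raise DesignError(f"factor {self.name!r}: step must be > 0, got {self.step}")


#: The three HILIC mobile-phase factors of the case study: acetonitrile
#: content (70/75/80 % v/v), aqueous-phase pH (2.8/3.5/4.2) and ammonium
#: formate concentration (20/40/60 mM).
HILIC_FACTORS: tuple[FactorDef, ...] = (
    FactorDef("acn", center=75.0, step=5.0, unit="% v/v"),
    FactorDef("ph", center=3.5, step=0.7, unit="pH"),
    FactorDef("buffer", center=40.0, step=20.0, unit="mM"),
)

BLOCKS = ("center", "factorial", "axial")


def rotatable_alpha(k: int) -> float:
    """Axial distance giving a rotatable CCD: alpha = (2^k)^(1/4)."""
    return float((2.0**k) ** 0.25)


def to_actual(coded: Sequence[float], factors: Sequence[FactorDef]) -> np.ndarray:
    """Decode coded levels to actual units (actual_i = center_i + coded_i * step_i)."""
    coded = np.asarray(coded, dtype=float)
    if coded.shape[-1] != len(factors):
        raise DesignError(
            f"length mismatch: {coded.shape[-1]} coded levels for {len(factors)} factors"
        )
    centers = np.array([f.center for f in factors])
    steps = np.array([f.step for f in factors])
    return centers + coded * steps


def to_coded(actual: Sequence[float], factors: Sequence[FactorDef]) -> np.ndarray:
    """Encode actual levels to coded units (coded_i = (actual_i - center_i) / step_i)."""
    actual = np.asarray(actual, dtype=float)
    if actual.shape[-1] != len(factors):
        raise DesignError(
            f"length mismatch: {actual.shape[-1]} actual levels for {len(factors)} factors"
        )
    centers = np.array([f.center for f in factors])
    steps = np.array([f.step for f in factors])
    return (actual - centers) / steps


@dataclass
class DesignTable:
    """An ordered CCD plan with coded and actual levels per run.

    The canonical run order is centre runs first, then the factorial block
    (first factor varying fastest), then axial runs in factor order
    (low star level before high).
    """

    factors: tuple[FactorDef, ...]
    frame: pd.DataFrame
    alpha: float

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def k(self) -> int:
        return len(self.factors)

    @property
    def coded(self) -> np.ndarray:
        cols = [f"coded_{f.name}" for f in self.factors]
        return self.frame[cols].to_numpy(dtype=float)

    @property
    def actual(self) -> np.ndarray:
        return to_actual(self.coded, self.factors)

    @property
    def blocks(self) -> pd.Series:
        return self.frame["block"]

    @property
    def run_ids(self) -> pd.Series:
        return self.frame["run_id"]

    def to_frame(self, display: bool = True) -> pd.DataFrame:
        """Tabulate the plan; ``display=True`` rounds actual levels to 2 dp.

        Full precision is always retained internally (and in the coded
        columns); the 2-decimal rounding only affects the actual-level
        columns of the returned copy, matching how such plans are printed.
        """
        out = self.frame.copy()
        actual = self.actual
        for j, f in enumerate(self.factors):
            col = actual[:, j]
            out[f"actual_{f.name}"] = np.round(col, 2) if display else col
        return out

    def to_csv(self, path) -> None:
        self.to_frame(display=True).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, factors: Sequence[FactorDef], alpha: float | None = None) -> "DesignTable":
        raw = pd.read_csv(path, skipinitialspace=True)
        needed = ["run_id", "block"] + [f"coded_{f.name}" for f in factors]
        missing = [c for c in needed if c not in raw.columns]
        if missing:
            raise DesignError(f"design CSV missing columns: {missing}")
        frame = raw[needed].copy()
        if alpha is None:
            axial = frame.loc[frame["block"] == "axial", [f"coded_{f.name}" for f in factors]]
            alpha = float(np.abs(axial.to_numpy()).max()) if len(axial) else 1.0
        return cls(factors=tuple(factors), frame=frame, alpha=alpha)


def _factorial_rows(k: int) -> np.ndarray:
    # first factor varies fastest (the customary printed order of these plans)
    rows = [tuple(reversed(combo)) for combo in itertools.product((-1.0, 1.0), repeat=k)]
    return np.array(rows)


def build_ccd(
    factors: Sequence[FactorDef],
    n_center: int = 6,
    alpha_mode: str | float = "rotatable",
    randomize: int | None = None,
) -> DesignTable:
    """Construct a central composite design.

    Parameters
    ----------
    factors:
        Between 2 and 6 factor definitions.
    n_center:
        Number of replicated centre runs (>= 1).
    alpha_mode:
        ``"rotatable"`` for alpha = (2^K)^(1/4), ``"face_centered"`` for
        alpha = 1, or an explicit positive float.
    randomize:
        If given, a seed used to shuffle the run order; by default the
        canonical order (centre, factorial, axial) is kept.

    Returns
    -------
    DesignTable with 2^K + 2K + n_center runs.
    """
    factors = tuple(factors)
    k = len(factors)
    if not 2 <= k <= 6:
        raise DesignError(f"unsupported dimension: K={k} (need 2 <= K <= 6)")
    if n_center < 1:
        raise DesignError("n_center must be >= 1")

    if alpha_mode == "rotatable":
        alpha = rotatable_alpha(k)
    elif alpha_mode == "face_centered":
        alpha = 1.0
    else:
        alpha = float(alpha_mode)
        if alpha <= 0:
            raise DesignError(f"explicit alpha must be > 0, got {alpha}")

    center = np.zeros((n_center, k))
    factorial = _factorial_rows(k)
    axial = np.zeros((2 * k, k))
    for j in range(k):
        axial[2 * j, j] = -alpha
        axial[2 * j + 1, j] = alpha

    coded = np.vstack([center, factorial, axial])
    block = (
        ["center"] * n_center
        + ["factorial"] * len(factorial)
        + ["axial"] * len(axial)
    )

    order = np.arange(len(coded))
    if randomize is not None:
        rng = np.random.default_rng(randomize)
        order = rng.permutation(order)
    coded = coded[order]
    block = [block[i] for i in order]

    frame = pd.DataFrame({"run_id": np.arange(1, len(coded) + 1), "block": block})
    for j, f in enumerate(factors):
        frame[f"coded_{f.name}"] = coded[:, j]
    return DesignTable(factors=factors, frame=frame, alpha=alpha)
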