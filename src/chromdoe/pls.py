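"""PLS response-surface models on the quadratic factor block.

Each chromatographic response (retention factors, critical resolutions) is
modelled separately (PLS1) on the 9-term block built from coded factor
levels: linear terms, squares and pairwise interactions, in the fixed order

    x1, x2, x3, x1x1, x2x2, x3x3, x1x2, x1x3, x2x3   (for K = 3).

The latent-variable fit is scikit-learn's NIPALS ``PLSRegression`` on
centred (and, by default, unit-variance) data; with all components on
full-rank data it coincides with ordinary least squares.  Model quality is
reported as R² (training) and leave-one-out Q² = 1 − PRESS/TSS; coefficient
uncertainty as jackknife confidence intervals over the LOO refits, with a
term flagged significant when its interval excludes zero.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cross_decomposition import PLSRegression
from sklearn.exceptions import ConvergenceWarning

from .doe import DesignTable


class DegenerateResponseError(ValueError):
    """Response has no variance (or zero total sum of squares)."""


class ExtrapolationWarning(UserWarning):
    """Prediction requested outside the design region."""


class UnstableCIWarning(UserWarning):
    """Too few runs for a stable jackknife interval."""


def term_names(k: int) -> list[str]:
    """Fixed term order: linear, squares, pairwise interactions (i < j)."""
    lin = [f"x{i + 1}" for i in range(k)]
    sq = [f"x{i + 1}x{i + 1}" for i in range(k)]
    inter = [f"x{i + 1}x{j + 1}" for i in range(k) for j in range(i + 1, k) ]
    return lin + sq + inter


def n_terms(k: int) -> int:
    return 2 * k + k * (k - 1) // 2


def expand_terms(design) -> pd.DataFrame:
    """Expand coded levels into the quadratic model matrix.

    Accepts a :class:`~chromdoe.doe.DesignTable` or a (n, K) array of coded
    levels; returns a DataFrame with the fixed column order of
    :func:`term_names`.
    """
    if isinstance(design, DesignTable):
        coded = design.coded
        index = design.run_ids.to_numpy()
    else:
        coded = np.atleast_2d(np.asarray(design, dtype=float))
        index = None
    if coded.size == 0:
        raise ValueError("empty design: nothing to expand")
    n, k = coded.shape
    cols: dict[str, np.ndarray] = {}
    for i in range(k):
        cols[f"x{i + 1}"] = coded[:, i]
    for i in range(k):
        cols[f"x{i + 1}x{i + 1}"] = coded[:, i] ** 2
    for i in range(k):
        for j in range(i + 1, k):
            cols[f"x{i + 1}x{j + 1}"] = coded[:, i] * coded[:, j]
    out = pd.DataFrame(cols, columns=term_names(k))
    if index is not None:
        out.index = pd.Index(index, name="run_id")
    return out


@dataclass
class PLSModel:
    """A fitted PLS1 model of one response on the quadratic factor block."""

    terms: list[str]
    n_factors: int
    n_components: int
    scale: bool
    coef: np.ndarray            # original (response-unit per coded-term) scale
    intercept: float
    coef_scaled: np.ndarray     # autoscaled (dimensionless) coefficients
    x_mean: np.ndarray
    x_std: np.ndarray
    y_mean: float
    y_std: float
    r2: float
    q2: float
    press: float
    x_weights: np.ndarray | None = None
    x_loadings: np.ndarray | None = None
    y_loadings: np.ndarray | None = None
    x_scores: np.ndarray | None = None
    ci: pd.DataFrame | None = None  # columns: coefficient, ci_low, ci_high, significant
    response: str = ""
    extrapolation_limit: float | None = None

    def predict(self, conditions) -> np.ndarray:
        """Predict the response at coded conditions.

        ``conditions`` may be a coded vector of length ``n_factors`` (or an
        (n, K) array), or a pre-expanded term matrix of width
        ``len(self.terms)``.  Points outside the guard radius raise an
        :class:`ExtrapolationWarning` (prediction is still returned).
        """
        arr = np.atleast_2d(np.asarray(conditions, dtype=float))
        if arr.shape[1] == self.n_factors:
            if self.extrapolation_limit is not None:
                norms = np.linalg.norm(arr, axis=1)
                if np.any(norms > self.extrapolation_limit):
                    warnings.warn(
                        f"prediction at coded norm {norms.max():.3f} exceeds the "
                        f"extrapolation guard {self.extrapolation_limit:.3f}",
                        ExtrapolationWarning,
                        stacklevel=2,
                    )
            X = expand_terms(arr).to_numpy()
        elif arr.shape[1] == len(self.terms):
            X = arr
        else:
            raise ValueError(
                f"conditions must have {self.n_factors} coded levels or "
                f"{len(self.terms)} terms, got width {arr.shape[1]}"
            )
        return X @ self.coef + self.intercept

    def coefficient_table(self) -> pd.DataFrame:
        """Terms, coefficients and (if computed) CIs in fixed term order."""
        tab = pd.DataFrame({"term": self.terms, "coefficient": self.coef})
        if self.ci is not None:
            tab["ci_low"] = self.ci["ci_low"].to_numpy()
            tab["ci_high"] = self.ci["ci_high"].to_numpy()
            tab["significant"] = self.ci["significant"].to_numpy()
        return tab

    def to_json(self, path=None) -> str:
        payload = {
            "response": self.response,
            "terms": self.terms,
            "n_factors": self.n_factors,
            "n_components": self.n_components,
            "scale": self.scale,
            "coef": self.coef.tolist(),
            "intercept": self.intercept,
            "coef_scaled": self.coef_scaled.tolist(),
            "x_mean": self.x_mean.tolist(),
            "x_std": self.x_std.tolist(),
            "y_mean": self.y_mean,
            "y_std": self.y_std,
            "r2": self.r2,
            "q2": self.q2,
            "press": self.press,
            "extrapolation_limit": self.extrapolation_limit,
            "ci": None if self.ci is None else self.ci.to_dict(orient="list"),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "PLSModel":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        ci = payload.get("ci")
        return cls(
            terms=list(payload["terms"]),
            n_factors=int(payload["n_factors"]),
            n_components=int(payload["n_components"]),
            scale=bool(payload["scale"]),
            coef=np.asarray(payload["coef"], dtype=float),
            intercept=float(payload["intercept"]),
            coef_scaled=np.asarray(payload["coef_scaled"], dtype=float),
            x_mean=np.asarray(payload["x_mean"], dtype=float),
            x_std=np.asarray(payload["x_std"], dtype=float),
            y_mean=float(payload["y_mean"]),
            y_std=float(payload["y_std"]),
            r2=float(payload["r2"]),
            q2=float(payload["q2"]),
            press=float(payload["press"]),
            ci=None if ci is None else pd.DataFrame(ci),
            response=payload.get("response", ""),
            extrapolation_limit=payload.get("extrapolation_limit"),
        )


def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    arr = np.asarray(X, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr, [f"t{i}" for i in range(arr.shape[1])]


def _infer_n_factors(names: list[str], width: int) -> int:
    # quadratic block widths: K -> 2K + K(K-1)/2
    for k in range(1, 10):
        if n_terms(k) == width and names[:k] == [f"x{i + 1}" for i in range(k)]:
            return k
    return width  # generic matrix: treat every column as a "factor"


def _pls_fit(X: np.ndarray, y: np.ndarray, nc: int, scale: bool) -> PLSRegression:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)  # exhausted y-deflation
        warnings.filterwarnings("ignore", message="y residual is constant")
        return PLSRegression(n_components=nc, scale=scale).fit(X, y)


def _affine_coef(est: PLSRegression) -> tuple[np.ndarray, float]:
    """Original-scale (coef, intercept) such that y ≈ X @ coef + intercept.

    ``PLSRegression.predict`` centres X before applying ``coef_``, so the
    plain-X intercept is intercept_ − x_mean @ coef_.
    """
    coef = np.asarray(est.coef_).reshape(-1)
    b0 = float(np.asarray(est.intercept_).ravel()[0] - est._x_mean @ coef)
    return coef, b0


def fit_pls(X, y, n_components: int | None = None, scale: bool = True) -> PLSModel:
    """Fit a PLS1 model of ``y`` on the term matrix ``X``.

    ``n_components=None`` selects the component count maximising the
    leave-one-out Q² over 1..rank(X), ties broken toward fewer components.
    The fit is deterministic for fixed inputs.
    """
    Xm, names = _as_matrix(X)
    yv = np.asarray(y, dtype=float).ravel()
    n, p = Xm.shape
    if len(yv) != n:
        raise ValueError(f"X has {n} rows but y has {len(yv)} entries")
    if np.ptp(yv) == 0:
        raise DegenerateResponseError("constant response: nothing to model")

    rank = int(np.linalg.matrix_rank(Xm - Xm.mean(axis=0)))
    max_nc = max(1, min(rank, n - 1))

    if n_components is None:
        best_nc, best_q2 = 1, -np.inf
        for nc in range(1, max_nc + 1):
            q2_nc, _ = q2_loo(Xm, yv, nc, scale=scale)
            if q2_nc > best_q2 + 1e-12:
                best_nc, best_q2 = nc, q2_nc
        n_components = best_nc
    elif n_components > max_nc:
        warnings.warn(
            f"n_components={n_components} exceeds usable rank {max_nc}; truncating",
            UserWarning,
            stacklevel=2,
        )
        n_components = max_nc
    if n < n_components + 2:
        raise ValueError(f"need at least n_components + 2 = {n_components + 2} runs, got {n}")

    est = _pls_fit(Xm, yv, n_components, scale)
    coef, intercept = _affine_coef(est)

    y_hat = Xm @ coef + intercept
    tss = float(np.sum((yv - yv.mean()) ** 2))
    rss = float(np.sum((yv - y_hat) ** 2))
    r2 = 1.0 - rss / tss

    q2, press = q2_loo(Xm, yv, n_components, scale=scale)

    x_std = Xm.std(axis=0, ddof=1)
    y_std = float(yv.std(ddof=1))
    safe_x_std = np.where(x_std > 0, x_std, 1.0)
    coef_scaled = coef * safe_x_std / (y_std if y_std > 0 else 1.0)

    return PLSModel(
        terms=names,
        n_factors=_infer_n_factors(names, p),
        n_components=n_components,
        scale=scale,
        coef=coef,
        intercept=intercept,
        coef_scaled=coef_scaled,
        x_mean=Xm.mean(axis=0),
        x_std=x_std,
        y_mean=float(yv.mean()),
        y_std=y_std,
        r2=r2,
        q2=q2,
        press=press,
        x_weights=np.asarray(est.x_weights_),
        x_loadings=np.asarray(est.x_loadings_),
        y_loadings=np.asarray(est.y_loadings_),
        x_scores=np.asarray(est.x_scores_),
    )


def _loo_coefs(Xm: np.ndarray, yv: np.ndarray, nc: int, scale: bool) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Leave-one-out refits: per-fold predictions, coefficients, intercepts."""
    n, p = Xm.shape
    preds = np.empty(n)
    coefs = np.empty((n, p))
    intercepts = np.empty(n)
    idx = np.arange(n)
    for i in range(n):
        keep = idx != i
        est = _pls_fit(Xm[keep], yv[keep], nc, scale)
        c, b0 = _affine_coef(est)
        coefs[i] = c
        intercepts[i] = b0
        preds[i] = Xm[i] @ c + b0
    return preds, coefs, intercepts


def q2_loo(X, y, n_components: int, scale: bool = True) -> tuple[float, float]:
    """Leave-one-out cross-validation: Q² = 1 − PRESS/TSS and PRESS.

    Each run is predicted from a model refit without it;
    PRESS = Σ (y_i − ŷ_(−i))².
    """
    Xm, _ = _as_matrix(X)
    yv = np.asarray(y, dtype=float).ravel()
    n = len(yv)
    if n < 3:
        raise ValueError("leave-one-out Q2 needs at least 3 runs")
    tss = float(np.sum((yv - yv.mean()) ** 2))
    if tss == 0:
        raise DegenerateResponseError("zero total sum of squares")
    preds, _, _ = _loo_coefs(Xm, yv, n_components, scale)
    press = float(np.sum((yv - preds) ** 2))
    return 1.0 - press / tss, press


def coefficient_ci(X, y, model: PLSModel, level: float = 0.95) -> pd.DataFrame:
    """Jackknife confidence intervals for the model coefficients.

    The coefficient vector is re-estimated on every leave-one-out fold; the
    jackknife standard error SE_j = sqrt((n−1)/n · Σ_i (θ_(i) − θ̄)²) is
    combined with the two-sided Student critical value at ``level`` on n−1
    degrees of freedom.  A term is flagged significant when its interval
    excludes zero (the "error bar does not cross the axis" rule of the
    coefficient plots).  The table is also attached to ``model.ci``.
    """
    Xm, _ = _as_matrix(X)
    yv = np.asarray(y, dtype=float).ravel()
    n = len(yv)
    if n < 5:
        warnings.warn("fewer than 5 runs: jackknife CI is unstable", UnstableCIWarning, stacklevel=2)
    _, coefs, _ = _loo_coefs(Xm, yv, model.n_components, model.scale)
    theta_bar = coefs.mean(axis=0)
    se = np.sqrt((n - 1) / n * np.sum((coefs - theta_bar) ** 2, axis=0))
    tcrit = stats.t.ppf(0.5 + level / 2.0, df=n - 1)
    low = model.coef - tcrit * se
    high = model.coef + tcrit * se
    significant = (low > 0) | (high < 0)
    tab = pd.DataFrame(
        {
            "term": model.terms,
            "coefficient": model.coef,
            "se": se,
            "ci_low": low,
            "ci_high": high,
            "significant": significant,
        }
    )
    model.ci = tab[["term", "coefficient", "ci_low", "ci_high", "significant"]].copy()
    return tab


def predict(model: PLSModel, conditions) -> np.ndarray:
    """Functional alias for :meth:`PLSModel.predict`."""
    return model.predict(conditions)


def coefficient_plot_table(model: PLSModel) -> pd.DataFrame:
    """Export table for a bar-with-error coefficient plot.

    Rows follow the fixed term order; columns are term, coefficient, ci_low,
    ci_high, significant.  CIs require a prior :func:`coefficient_ci` call
    (NaN otherwise).
    """
    tab = model.coefficient_table()
    for col in ("ci_low", "ci_high"):
        if col not in tab:
            tab[col] = np.nan
    if "significant" not in tab:
        tab["significant"] = pd.NA
    return tab[["term", "coefficient", "ci_low", "ci_high", "significant"]]


def fit_response_models(
    design: DesignTable,
    responses: pd.DataFrame,
    n_components: int | None = None,
    scale: bool = True,
    with_ci: bool = True,
    level: float = 0.95,
    extrapolation_factor: float = 1.1,
) -> dict[str, PLSModel]:
    """Fit one PLS model per response column of a study table.

    ``responses`` must contain one column per response (e.g. k_M ... Rs_CD),
    row-aligned with the design.  Each model gets an extrapolation guard of
    ``alpha * extrapolation_factor`` in coded units.
    """
    X = expand_terms(design)
    models: dict[str, PLSModel] = {}
    for col in responses.columns:
        if col == "run_id":
            continue
        model = fit_pls(X, responses[col].to_numpy(), n_components=n_components, scale=scale)
        model.response = col
        model.extrapolation_limit = design.alpha * extrapolation_factor
        if with_ci:
            coefficient_ci(X, responses[col].to_numpy(), model, level=level)
        models[col] = model
    return models
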