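"""Second-order response-surface modelling for central composite designs.

Fits the full quadratic polynomial in coded variables

    y = b0 + sum_i bi x_i + sum_{i<j} bij x_i x_j + sum_i bii x_i^2

by ordinary least squares, and partitions the variation into an ANOVA
table with per-term sums of squares, a lack-of-fit / pure-error split
based on replicated runs, and the usual fit diagnostics (R^2, coefficient
of variation, adequate precision).

Per-term sums of squares are computed by single-term deletion
(SS(full model) - SS(model without the term)).  On an orthogonal CCD this
equals the sequential sum of squares and also ``beta^2 * sum(x^2)``; for
non-orthogonal user designs the deletion SS is a partial SS and the three
quantities need not agree.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .designs import DesignMatrix, ResponseVector

__all__ = ["QuadraticModel", "AnovaTable", "FitStats", "fit_quadratic", "anova", "fit_stats"]


def quadratic_terms(factor_names: list[str]) -> list[str]:
    """Model-matrix column names after the intercept: linear terms,
    pairwise interactions, then pure quadratics."""
    names = list(factor_names)
    inter = [f"{a}:{b}" for a, b in combinations(names, 2)]
    quad = [f"{n}^2" for n in names]
    return names + inter + quad


def expand_quadratic(points: np.ndarray, factor_names: list[str]) -> pd.DataFrame:
    """Expand coded points (m, k) into the full quadratic model matrix
    (with intercept column first)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    k = len(factor_names)
    if pts.shape[1] != k:
        raise ValueError(f"points have {pts.shape[1]} columns, expected {k}")
    cols: dict[str, np.ndarray] = {"Intercept": np.ones(len(pts))}
    for i, n in enumerate(factor_names):
        cols[n] = pts[:, i]
    for (i, a), (j, b) in combinations(enumerate(factor_names), 2):
        cols[f"{a}:{b}"] = pts[:, i] * pts[:, j]
    for i, n in enumerate(factor_names):
        cols[f"{n}^2"] = pts[:, i] ** 2
    return pd.DataFrame(cols)


@dataclass
class QuadraticModel:
    """A fitted second-order polynomial in coded variables.

    Coefficients are split by term type: ``intercept``, ``linear`` (per
    factor), ``interaction`` (per ordered factor pair), ``quadratic``
    (per factor).  ``predict`` evaluates the surface at arbitrary coded
    points.
    """

    factor_names: list[str]
    intercept: float
    linear: dict[str, float]
    interaction: dict[tuple[str, str], float]
    quadratic: dict[str, float]
    n: int
    fitted: np.ndarray
    residuals: np.ndarray

    @property
    def k(self) -> int:
        return len(self.factor_names)

    @property
    def p(self) -> int:
        """Number of model parameters: 1 + k + k(k-1)/2 + k."""
        k = self.k
        return 1 + 2 * k + k * (k - 1) // 2

    @property
    def residual_df(self) -> int:
        return self.n - self.p

    @property
    def coefficients(self) -> pd.Series:
        """All coefficients as a Series in canonical term order.
        Terms absent from the coefficient dicts count as zero."""
        vals = {"Intercept": self.intercept}
        for nm in self.factor_names:
            vals[nm] = self.linear.get(nm, 0.0)
        for a, b in combinations(self.factor_names, 2):
            vals[f"{a}:{b}"] = self.interaction.get((a, b), self.interaction.get((b, a), 0.0))
        for nm in self.factor_names:
            vals[f"{nm}^2"] = self.quadratic.get(nm, 0.0)
        return pd.Series(vals)

    def predict(self, points) -> np.ndarray:
        """Predicted response at coded points of shape (m, k) or (k,)."""
        X = expand_quadratic(points, self.factor_names)
        return X.to_numpy() @ self.coefficients.to_numpy()

    def quadratic_form(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (b, B): the linear-coefficient vector and the symmetric
        quadratic-form matrix (diagonal = pure quadratics, off-diagonal =
        half the interaction coefficients), so that
        ``y = b0 + b.x + x'Bx``."""
        k = self.k
        b = np.array([self.linear.get(n, 0.0) for n in self.factor_names])
        B = np.zeros((k, k))
        for i, n in enumerate(self.factor_names):
            B[i, i] = self.quadratic.get(n, 0.0)
        for (a, bb), v in self.interaction.items():
            i, j = self.factor_names.index(a), self.factor_names.index(bb)
            B[i, j] = B[j, i] = v / 2.0
        return b, B


@dataclass
class AnovaTable:
    """ANOVA of a quadratic response-surface fit.

    ``table`` rows: model, each model term, residual, lack-of-fit and
    pure-error (when replicate runs exist), and the corrected total.
    """

    table: pd.DataFrame
    has_lack_of_fit: bool

    def row(self, source: str) -> pd.Series:
        hit = self.table[self.table["source"] == source]
        if hit.empty:
            raise KeyError(f"no ANOVA row {source!r}")
        return hit.iloc[0]

    @property
    def ss_model(self) -> float:
        return float(self.row("model")["ss"])

    @property
    def ss_residual(self) -> float:
        return float(self.row("residual")["ss"])

    @property
    def ss_total(self) -> float:
        return float(self.row("corrected total")["ss"])

    @property
    def ms_residual(self) -> float:
        return float(self.row("residual")["ms"])

    @property
    def model_f(self) -> float:
        return float(self.row("model")["F"])

    @property
    def lack_of_fit_f(self) -> float:
        return float(self.row("lack of fit")["F"])


@dataclass
class FitStats:
    """Whole-model diagnostics: R^2, CV% and adequate precision.

    CV is ``100 * sqrt(MS_residual) / mean(y)`` — residual noise relative
    to the mean response.  Adequate precision is the range of fitted
    values over the design points divided by the average prediction
    standard error ``sqrt(p * MS_residual / n)``; values above 4 indicate
    the model discriminates signal from noise well enough to navigate the
    design space.
    """

    r_squared: float
    r_squared_adj: float
    cv_pct: float
    adequate_precision: float
    cv_undefined: bool = False


def _model_frame(design: DesignMatrix, response: ResponseVector) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    names = design.process_columns
    y = response.aligned_to(design)
    X = expand_quadratic(design.coded[names].to_numpy(), names)
    return X, y, names


def fit_quadratic(design: DesignMatrix, response: ResponseVector) -> QuadraticModel:
    """Fit the full second-order model by ordinary least squares.

    Raises an error when the expanded model matrix is rank deficient
    (naming the collinear columns) or when there are not more runs than
    parameters.
    """
    X, y, names = _model_frame(design, response)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"insufficient runs for inference: n={n} <= p={p}")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < p:
        # identify columns whose removal restores full column rank
        collinear = []
        for c in X.columns:
            sub = X.drop(columns=[c]).to_numpy()
            if np.linalg.matrix_rank(sub) == rank:
                collinear.append(c)
        raise ValueError(f"singular design: collinear model columns {collinear}")
    res = sm.OLS(y, X).fit()
    beta = res.params

    linear = {nm: float(beta[nm]) for nm in names}
    interaction = {(a, b): float(beta[f"{a}:{b}"]) for a, b in combinations(names, 2)}
    quadratic = {nm: float(beta[f"{nm}^2"]) for nm in names}
    return QuadraticModel(
        factor_names=names,
        intercept=float(beta["Intercept"]),
        linear=linear,
        interaction=interaction,
        quadratic=quadratic,
        n=n,
        fitted=np.asarray(res.fittedvalues),
        residuals=np.asarray(res.resid),
    )


def replicate_groups(design: DesignMatrix, tol: float = 1e-9) -> list[np.ndarray]:
    """Indices of runs identical in all coded columns (within ``tol``),
    keeping only groups of two or more runs."""
    coded = design.coded[design.process_columns].to_numpy()
    keys = np.round(coded / tol) * tol
    df = pd.DataFrame(keys)
    out = []
    for _, g in df.groupby(list(df.columns), sort=False):
        if len(g) >= 2:
            out.append(g.index.to_numpy())
    return out


def anova(
    model: QuadraticModel,
    design: DesignMatrix,
    response: ResponseVector,
) -> AnovaTable:
    """ANOVA table with per-term SS and lack-of-fit decomposition.

    * SS(model) = sum((yhat - ybar)^2), SS(residual) = sum((y - yhat)^2).
    * Per-term SS by single-term deletion refits.
    * Pure error pooled within groups of replicated (identical-coded)
      runs; lack of fit is the remainder of the residual SS.  Without
      replicates the lack-of-fit rows are omitted.
    * F(model) and per-term F are against MS(residual); F(lack of fit)
      is against MS(pure error).
    """
    X, y, names = _model_frame(design, response)
    yhat = model.predict(design.coded[names].to_numpy())
    ybar = y.mean()
    ss_model = float(((yhat - ybar) ** 2).sum())
    ss_res = float(((y - yhat) ** 2).sum())
    ss_tot = float(((y - ybar) ** 2).sum())
    df_model = model.p - 1
    df_res = model.residual_df
    ms_model = ss_model / df_model
    ms_res = ss_res / df_res if df_res > 0 else np.nan
    f_model = ms_model / ms_res if df_res > 0 else np.nan
    p_model = stats.f.sf(f_model, df_model, df_res) if df_res > 0 else np.nan

    rows = [
        {"source": "model", "ss": ss_model, "df": df_model, "ms": ms_model,
         "F": f_model, "p": p_model},
    ]

    # single-term deletion SS
    full_cols = list(X.columns)
    for term in full_cols[1:]:
        Xr = X.drop(columns=[term])
        beta_r, *_ = np.linalg.lstsq(Xr.to_numpy(), y, rcond=None)
        ss_res_r = float(((y - Xr.to_numpy() @ beta_r) ** 2).sum())
        ss_term = ss_res_r - ss_res
        f_term = ss_term / ms_res if df_res > 0 else np.nan
        p_term = stats.f.sf(f_term, 1, df_res) if df_res > 0 else np.nan
        rows.append({"source": term, "ss": ss_term, "df": 1, "ms": ss_term,
                     "F": f_term, "p": p_term})

    rows.append({"source": "residual", "ss": ss_res, "df": df_res, "ms": ms_res,
                 "F": np.nan, "p": np.nan})

    groups = replicate_groups(design)
    has_lof = bool(groups)
    if has_lof:
        ss_pe = 0.0
        df_pe = 0
        for idx in groups:
            vals = y[idx]
            ss_pe += float(((vals - vals.mean()) ** 2).sum())
            df_pe += len(vals) - 1
        ss_lof = ss_res - ss_pe
        df_lof = df_res - df_pe
        ms_pe = ss_pe / df_pe if df_pe > 0 else np.nan
        ms_lof = ss_lof / df_lof if df_lof > 0 else np.nan
        f_lof = ms_lof / ms_pe if (df_pe > 0 and ms_pe > 0) else np.nan
        p_lof = stats.f.sf(f_lof, df_lof, df_pe) if np.isfinite(f_lof) else np.nan
        rows.append({"source": "lack of fit", "ss": ss_lof, "df": df_lof,
                     "ms": ms_lof, "F": f_lof, "p": p_lof})
        rows.append({"source": "pure error", "ss": ss_pe, "df": df_pe,
                     "ms": ms_pe, "F": np.nan, "p": np.nan})

    rows.append({"source": "corrected total", "ss": ss_tot, "df": len(y) - 1,
                 "ms": np.nan, "F": np.nan, "p": np.nan})
    return AnovaTable(table=pd.DataFrame(rows), has_lack_of_fit=has_lof)


def fit_stats(model: QuadraticModel, anova_table: AnovaTable, response: ResponseVector) -> FitStats:
    """R^2, adjusted R^2, CV% and adequate precision for a fitted model."""
    ss_model = anova_table.ss_model
    ss_tot = anova_table.ss_total
    ms_res = anova_table.ms_residual
    r2 = ss_model / ss_tot if ss_tot > 0 else np.nan
    n, p = model.n, model.p
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p) if n > p else np.nan
    ymean = float(np.mean(response.values))
    cv_undef = ymean == 0.0
    cv = np.nan if cv_undef else 100.0 * np.sqrt(ms_res) / ymean
    # signal-to-noise: spread of fitted values over the design points
    # relative to the average prediction SE sqrt(p * MS_res / n)
    denom = np.sqrt(p * ms_res / n)
    adeq = (model.fitted.max() - model.fitted.min()) / denom if denom > 0 else np.inf
    return FitStats(
        r_squared=float(r2),
        r_squared_adj=float(r2_adj),
        cv_pct=float(cv),
        adequate_precision=float(adeq),
        cv_undefined=cv_undef,
    )
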