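"""Plackett-Burman main-effect screening with dummy-column error estimation.

The main effect of a two-level factor is the difference between the mean
response at its high (+1) level and at its low (-1) level:

    E(X_i) = 2 * (sum(M+) - sum(M-)) / N

where M+/M- are the responses of the runs at the two levels and N is the
total run count.  The apparent "effects" of the unassigned dummy columns
estimate pure experimental error:

    Veff = sum(Ed^2) / n_dummy,      Es = sqrt(Veff)

and each factor is screened with a Student t statistic
``t = E / Es`` on ``n_dummy`` degrees of freedom.  A factor is retained
when its confidence ``100 * (1 - p)`` reaches the screening threshold
(95 % by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .designs import DesignMatrix, ResponseVector

__all__ = ["PBAnalysis", "main_effect", "dummy_error", "pb_analyze"]


@dataclass
class PBAnalysis:
    """Per-factor screening results of a Plackett-Burman experiment.

    ``table`` has one row per process factor, in design column order,
    with columns ``factor, effect, magnitude, std_error, t, p,
    confidence_pct, significant``.  Effects are stored *signed*;
    ``magnitude`` is the absolute value, which is what screening tables
    conventionally print.
    """

    table: pd.DataFrame
    dummy_effects: np.ndarray
    veff: float
    std_error: float
    n_dummy: int
    n_runs: int
    confidence_threshold: float
    degenerate_error: bool = False

    @property
    def significant_factors(self) -> list[str]:
        return self.table.loc[self.table["significant"], "factor"].tolist()

    def __repr__(self) -> str:
        sig = ", ".join(self.significant_factors) or "none"
        return (
            f"<PBAnalysis of {len(self.table)} factors, Es={self.std_error:.4g}, "
            f"significant at {self.confidence_threshold:g}%: {sig}>"
        )


def _column_values(design: DesignMatrix, column: str) -> np.ndarray:
    if column not in design.coded.columns:
        raise KeyError(f"no column {column!r} in design")
    if design.design_kind != "plackett-burman":
        raise ValueError("main effects are defined for Plackett-Burman designs")
    return design.coded[column].to_numpy(dtype=float)


def main_effect(design: DesignMatrix, response: ResponseVector, column: str) -> float:
    """Signed main effect of one design column.

    Requires the column to be balanced (equal counts of +1 and -1); the
    formula 2*(sum(M+) - sum(M-))/N equals mean(M+) - mean(M-) only then.
    """
    x = _column_values(design, column)
    y = response.aligned_to(design)
    if int(x.sum()) != 0:
        raise ValueError(f"column {column!r} is unbalanced; effect formula assumes balance")
    n = len(y)
    return float(2.0 * (y[x > 0].sum() - y[x < 0].sum()) / n)


def dummy_error(design: DesignMatrix, response: ResponseVector) -> tuple[float, float]:
    """Experimental-error variance and standard error from dummy columns.

    Returns ``(Veff, Es)`` where ``Veff = sum(Ed^2)/n`` over the dummy
    effects Ed and ``Es = sqrt(Veff)``.  Es applies uniformly to every
    factor effect because all columns of an orthogonal two-level design
    share the same estimation variance.
    """
    dummies = design.dummy_columns
    if not dummies:
        raise ValueError("design has no dummy columns; no error estimate possible")
    ed = np.array([main_effect(design, response, c) for c in dummies])
    veff = float((ed**2).sum() / len(ed))
    return veff, float(np.sqrt(veff))


def pb_analyze(
    design: DesignMatrix,
    response: ResponseVector,
    confidence_threshold: float = 95.0,
) -> PBAnalysis:
    """Screen all process factors of a Plackett-Burman experiment.

    Two-tailed p-values come from a Student t distribution with degrees
    of freedom equal to the number of dummy columns.  If the dummy
    effects are all exactly zero (Es = 0) each nonzero effect is reported
    as infinitely significant and the result carries a
    ``degenerate_error`` flag.
    """
    if not 0 < confidence_threshold < 100:
        raise ValueError("confidence_threshold must be in (0, 100)")
    dummies = design.dummy_columns
    veff, es = dummy_error(design, response)
    df = len(dummies)
    degenerate = es == 0.0

    rows = []
    for col in design.process_columns:
        eff = main_effect(design, response, col)
        if degenerate:
            t = np.inf if eff != 0 else 0.0
            p = 0.0 if eff != 0 else 1.0
        else:
            t = eff / es
            p = 2.0 * stats.t.sf(abs(t), df)
        conf = 100.0 * (1.0 - p)
        rows.append(
            {
                "factor": col,
                "effect": eff,
                "magnitude": abs(eff),
                "std_error": es,
                "t": t,
                "p": p,
                "confidence_pct": conf,
                "significant": conf >= confidence_threshold,
            }
        )
    ed = np.array([main_effect(design, response, c) for c in dummies])
    return PBAnalysis(
        table=pd.DataFrame(rows),
        dummy_effects=ed,
        veff=veff,
        std_error=es,
        n_dummy=df,
        n_runs=design.n_runs,
        confidence_threshold=confidence_threshold,
        degenerate_error=degenerate,
    )
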