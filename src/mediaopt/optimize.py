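"""Optima of a fitted quadratic response surface.

Three views of "where is the best medium":

* the analytic **stationary point** (gradient zero), classified as
  maximum / minimum / saddle by the eigenvalues of the quadratic-form
  matrix — the textbook canonical analysis;
* the **constrained maximum** over the explored design region (coded box
  ``[-alpha, +alpha]^k`` by default, or the sphere of radius alpha),
  found by combining the analytic interior candidate with deterministic
  multi-start bounded optimization — this is the number to act on when
  the stationary point lies outside the region or is a saddle;
* rectangular **surface grids** for any factor pair, for contour /
  response-surface plots.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .designs import DesignMatrix, Factor, coded_to_actual
from .rsm import QuadraticModel

__all__ = [
    "StationaryPoint",
    "RegionOptimum",
    "SurfaceGrid",
    "stationary_point",
    "optimize_in_region",
    "surface_grid",
]

#: eigenvalue magnitude below which the surface is treated as flat in
#: that direction when classifying the stationary point
_EIG_TOL = 1e-10


@dataclass
class StationaryPoint:
    coded: np.ndarray
    predicted: float
    nature: str  # "maximum" | "minimum" | "saddle"
    eigenvalues: np.ndarray
    actual: dict[str, float] | None = None


@dataclass
class RegionOptimum:
    coded: np.ndarray
    predicted: float
    region: str
    bound: float
    actual: dict[str, float] | None = None


@dataclass
class SurfaceGrid:
    """Predictions of the fitted surface over a 2-D coded grid, the
    remaining factors held at fixed levels."""

    factor_pair: tuple[str, str]
    fixed_levels: dict[str, float]
    x: np.ndarray  # coded levels of factor_pair[0]
    y: np.ndarray  # coded levels of factor_pair[1]
    z: np.ndarray  # predictions, shape (len(y), len(x))

    def to_frame(self) -> pd.DataFrame:
        xx, yy = np.meshgrid(self.x, self.y)
        return pd.DataFrame(
            {
                self.factor_pair[0]: xx.ravel(),
                self.factor_pair[1]: yy.ravel(),
                "predicted": self.z.ravel(),
            }
        )


def _actual_coords(model: QuadraticModel, coded: np.ndarray,
                   factors: list[Factor] | None) -> dict[str, float] | None:
    if factors is None:
        return None
    import warnings

    from .designs import InfeasibleLevelWarning

    by_name = {f.name: f for f in factors}
    out = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", InfeasibleLevelWarning)
        for name, c in zip(model.factor_names, coded):
            f = by_name.get(name)
            if f is None or f.center is None:
                return None
            out[name] = coded_to_actual(f, float(c))
    return out


def stationary_point(
    model: QuadraticModel, factors: list[Factor] | None = None
) -> StationaryPoint:
    """Solve for the gradient-zero point of the fitted surface.

    Writing the surface as ``y = b0 + b'x + x'Bx``, the stationary point
    is the solution of ``2 B x = -b``; its nature follows from the
    eigenvalues of B (all negative: maximum; all positive: minimum;
    mixed signs: saddle).
    """
    b, B = model.quadratic_form()
    if abs(np.linalg.det(B)) < 1e-12:
        raise np.linalg.LinAlgError(
            "quadratic-form matrix is singular (ridge system); "
            "use optimize_in_region for a constrained optimum"
        )
    x = np.linalg.solve(2.0 * B, -b)
    eig = np.linalg.eigvalsh(B)
    if (eig < -_EIG_TOL).all():
        nature = "maximum"
    elif (eig > _EIG_TOL).all():
        nature = "minimum"
    else:
        nature = "saddle"
    return StationaryPoint(
        coded=x,
        predicted=float(model.predict(x)[0]),
        nature=nature,
        eigenvalues=eig,
        actual=_actual_coords(model, x, factors),
    )


def optimize_in_region(
    model: QuadraticModel,
    region: str = "box",
    bound: float = 1.681793,
    factors: list[Factor] | None = None,
) -> RegionOptimum:
    """Global maximum of the quadratic over the explored design region.

    ``region`` is ``"box"`` (the coded cube ``[-bound, +bound]^k``) or
    ``"sphere"`` (radius ``bound``).  Candidates: the analytic stationary
    point when it lies inside the region, plus bounded local ascents from
    a fixed 3^k lattice of starts.  Everything is deterministic — no
    random restarts.
    """
    if region not in ("box", "sphere"):
        raise ValueError(f"unknown region {region!r}")
    if bound <= 0:
        raise ValueError("bound must be > 0")
    k = model.k

    def neg(x: np.ndarray) -> float:
        return -float(model.predict(x)[0])

    candidates: list[np.ndarray] = []
    try:
        sp = stationary_point(model)
        inside = (
            np.abs(sp.coded).max() <= bound
            if region == "box"
            else np.linalg.norm(sp.coded) <= bound
        )
        if inside:
            candidates.append(sp.coded)
    except np.linalg.LinAlgError:
        pass

    starts = [np.array(s, dtype=float) for s in itertools.product((-bound, 0.0, bound), repeat=k)]
    if region == "box":
        bounds = [(-bound, bound)] * k
        for s in starts:
            res = minimize(neg, s, method="L-BFGS-B", bounds=bounds)
            candidates.append(np.clip(res.x, -bound, bound))
    else:
        cons = {"type": "ineq", "fun": lambda x: bound**2 - float(x @ x)}
        for s in starts:
            nrm = np.linalg.norm(s)
            s0 = s if nrm <= bound else s * (bound / nrm)
            res = minimize(neg, s0, method="SLSQP", constraints=[cons])
            x = res.x
            nrm = np.linalg.norm(x)
            if nrm > bound:
                x = x * (bound / nrm)
            candidates.append(x)

    best = max(candidates, key=lambda x: float(model.predict(x)[0]))
    return RegionOptimum(
        coded=best,
        predicted=float(model.predict(best)[0]),
        region=region,
        bound=bound,
        actual=_actual_coords(model, best, factors),
    )


def surface_grid(
    model: QuadraticModel,
    factor_pair: tuple[str, str],
    fixed_levels: dict[str, float] | None = None,
    resolution: int = 50,
    span: float = 1.681793,
) -> SurfaceGrid:
    """Predictions over a coded 2-D grid for one factor pair.

    The remaining factors sit at ``fixed_levels`` (default 0, the design
    centre).  ``resolution`` points per axis spanning ``[-span, +span]``.
    """
    a, bname = factor_pair
    if a == bname:
        raise ValueError("factor_pair must name two distinct factors")
    for nm in factor_pair:
        if nm not in model.factor_names:
            raise KeyError(f"model has no factor {nm!r}")
    if resolution < 2:
        raise ValueError("resolution must be >= 2")
    fixed_levels = dict(fixed_levels or {})
    others = [n for n in model.factor_names if n not in factor_pair]
    missing = [n for n in others if n not in fixed_levels]
    for n in missing:
        fixed_levels.setdefault(n, 0.0)

    axis = np.linspace(-span, span, resolution)
    xx, yy = np.meshgrid(axis, axis)
    pts = np.zeros((xx.size, model.k))
    ia = model.factor_names.index(a)
    ib = model.factor_names.index(bname)
    pts[:, ia] = xx.ravel()
    pts[:, ib] = yy.ravel()
    for n in others:
        pts[:, model.factor_names.index(n)] = fixed_levels[n]
    z = model.predict(pts).reshape(xx.shape)
    return SurfaceGrid(
        factor_pair=(a, bname),
        fixed_levels={n: fixed_levels[n] for n in others},
        x=axis,
        y=axis,
        z=z,
    )
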