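"""Two-level screening designs and rotatable central composite designs.

This module constructs the two experimental designs used in sequential
media optimization:

* **Plackett-Burman (PB) designs** — orthogonal two-level fractional
  factorials with ``N`` runs for up to ``N - 1`` factors, built by cyclic
  rotation of a stored generator row.  Columns left unassigned to real
  process factors ("dummy" columns) later provide an estimate of
  experimental error.
* **Central composite designs (CCD)** — a ``2^k`` factorial core at coded
  levels ±1, ``2k`` axial (star) points at ±alpha, and replicated centre
  points, supporting a full second-order polynomial model.

All designs are expressed in *coded* units.  A :class:`Factor` carries the
mapping between coded and actual units: for a CCD factor,
``actual = center + step * coded``.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Factor",
    "DesignMatrix",
    "ResponseVector",
    "CCDSpec",
    "PB_GENERATORS",
    "generate_pb_design",
    "rotatable_alpha",
    "build_ccd",
    "coded_to_actual",
    "actual_to_coded",
    "InfeasibleLevelWarning",
]

#: Generator rows for cyclic Plackett-Burman construction.  Run 1 is the
#: generator itself, each following run is a one-position right rotation,
#: and the final run is all -1.  Every stored row yields a balanced,
#: mutually orthogonal design (verified by the test suite).
PB_GENERATORS: dict[int, tuple[int, ...]] = {
    8: (1, 1, 1, -1, 1, -1, -1),
    12: (1, 1, -1, 1, 1, 1, -1, -1, -1, 1, -1),
    16: (1, 1, 1, 1, -1, 1, -1, 1, 1, -1, -1, 1, -1, -1, -1),
    20: (1, 1, -1, -1, 1, 1, 1, 1, -1, 1, -1, 1, -1, -1, -1, -1, 1, 1, -1),
}


class InfeasibleLevelWarning(UserWarning):
    """An actual factor level implied by the coded design is physically
    impossible (e.g. a negative concentration).  The level is reported
    as computed, never clipped."""


@dataclass
class Factor:
    """A named process variable with its actual-unit levels.

    For a two-level screening factor, ``low``/``high`` are the actual
    values attached to coded -1/+1.  For a CCD factor, ``center`` and
    ``step`` define the coded-to-actual affine map.  Dummy factors carry
    no actual levels at all.
    """

    name: str
    low: float | None = None
    high: float | None = None
    center: float | None = None
    step: float | None = None
    role: str = "process"  # "process" | "dummy"

    def __post_init__(self) -> None:
        if self.role not in ("process", "dummy"):
            raise ValueError(f"unknown factor role {self.role!r}")
        if self.role == "dummy":
            if any(v is not None for v in (self.low, self.high, self.center, self.step)):
                raise ValueError(f"dummy factor {self.name!r} must not carry actual levels")
            return
        if self.step is not None and self.step <= 0:
            raise ValueError(f"factor {self.name!r}: step must be > 0")

    @property
    def is_dummy(self) -> bool:
        return self.role == "dummy"


@dataclass
class DesignMatrix:
    """Runs-by-columns matrix of coded factor levels.

    Attributes
    ----------
    coded : pandas.DataFrame
        One row per run (index = run id, 1-based), one column per factor,
        entries in coded units.
    roles : dict
        Column name -> ``"process"`` or ``"dummy"``.
    design_kind : str
        ``"plackett-burman"`` or ``"central-composite"``.
    actual : pandas.DataFrame, optional
        Parallel matrix of actual-unit levels (CCD only).
    factors : list of Factor, optional
        Factor metadata used to produce ``actual``.
    """

    coded: pd.DataFrame
    roles: dict[str, str]
    design_kind: str
    actual: pd.DataFrame | None = None
    factors: list[Factor] | None = None
    infeasible_levels: list[tuple[int, str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = [c for c in self.coded.columns if c not in self.roles]
        if missing:
            raise ValueError(f"columns without a role: {missing}")
        if self.design_kind == "plackett-burman":
            vals = self.coded.to_numpy()
            if not np.isin(vals, (-1, 1)).all():
                raise ValueError("Plackett-Burman designs contain only +1/-1 entries")
        if self.coded.isna().any().any():
            raise ValueError("every run must have a value for every column")

    @property
    def n_runs(self) -> int:
        return len(self.coded)

    @property
    def columns(self) -> list[str]:
        return list(self.coded.columns)

    @property
    def process_columns(self) -> list[str]:
        return [c for c in self.coded.columns if self.roles[c] == "process"]

    @property
    def dummy_columns(self) -> list[str]:
        return [c for c in self.coded.columns if self.roles[c] == "dummy"]

    @property
    def run_ids(self) -> np.ndarray:
        return self.coded.index.to_numpy()

    def factor(self, name: str) -> Factor:
        if self.factors is None:
            raise KeyError("design carries no factor metadata")
        for f in self.factors:
            if f.name == name:
                return f
        raise KeyError(f"no factor named {name!r}")


@dataclass
class ResponseVector:
    """Measured response per run, aligned to a :class:`DesignMatrix`."""

    values: np.ndarray
    run_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.run_ids = np.asarray(self.run_ids)
        if self.values.ndim != 1:
            raise ValueError("response must be one-dimensional")
        if len(self.values) != len(self.run_ids):
            raise ValueError("values and run_ids differ in length")
        if not np.isfinite(self.values).all():
            raise ValueError("all response values must be finite")

    def __len__(self) -> int:
        return len(self.values)

    def aligned_to(self, design: DesignMatrix) -> np.ndarray:
        """Return values reordered to the design's run order."""
        if len(self) != design.n_runs:
            raise ValueError(
                f"response has {len(self)} runs, design has {design.n_runs}"
            )
        order = pd.Series(self.values, index=self.run_ids)
        try:
            return order.loc[design.run_ids].to_numpy()
        except KeyError as exc:
            raise ValueError(f"response run ids do not match design: {exc}") from exc


@dataclass
class CCDSpec:
    """Specification of a rotatable central composite design.

    ``alpha`` may be the string ``"rotatable"`` (the default), in which
    case the axial distance is ``(2**k) ** 0.25`` — the value that makes
    prediction variance a function of distance from the centre only.
    ``n_center`` is the number of replicated all-zero centre runs; total
    runs = ``2**k + 2*k + n_center``.
    """

    factors: list[Factor]
    alpha: float | str = "rotatable"
    n_center: int = 6

    def __post_init__(self) -> None:
        if not self.factors:
            raise ValueError("CCDSpec needs at least one factor")
        for f in self.factors:
            if f.center is None or f.step is None:
                raise ValueError(f"CCD factor {f.name!r} needs center and step")
        if self.n_center < 0:
            raise ValueError("n_center must be >= 0")
        if isinstance(self.alpha, str):
            if self.alpha != "rotatable":
                raise ValueError(f"unknown alpha policy {self.alpha!r}")
        elif self.alpha <= 0:
            raise ValueError("alpha must be > 0")

    @property
    def k(self) -> int:
        return len(self.factors)

    @property
    def alpha_value(self) -> float:
        if self.alpha == "rotatable":
            return rotatable_alpha(self.k)
        return float(self.alpha)

    @property
    def n_runs(self) -> int:
        return 2**self.k + 2 * self.k + self.n_center


def generate_pb_design(
    n_runs: int,
    n_process: int,
    n_dummy: int,
    factor_names: list[str] | None = None,
) -> DesignMatrix:
    """Construct a Plackett-Burman design by cyclic rotation.

    Parameters
    ----------
    n_runs : int
        Number of runs; must have a stored generator row
        (currently 8, 12, 16 or 20).
    n_process, n_dummy : int
        Number of real process columns and unassigned dummy columns;
        must sum to ``n_runs - 1``.
    factor_names : list of str, optional
        Names for the process columns, in design order.  Dummy columns
        are always named ``D1, D2, ...``.

    Returns
    -------
    DesignMatrix
        Run 1 is the generator row; each subsequent run is a one-position
        right rotation; the final run is all -1.  Columns beyond
        ``n_process`` are flagged as dummies.
    """
    if n_runs not in PB_GENERATORS:
        raise ValueError(
            f"no Plackett-Burman generator for {n_runs} runs; "
            f"supported sizes: {sorted(PB_GENERATORS)}"
        )
    if n_process < 1 or n_dummy < 0:
        raise ValueError("need n_process >= 1 and n_dummy >= 0")
    if n_process + n_dummy != n_runs - 1:
        raise ValueError(
            f"n_process + n_dummy must equal n_runs - 1 "
            f"({n_process} + {n_dummy} != {n_runs - 1})"
        )
    gen = list(PB_GENERATORS[n_runs])
    rows = [gen]
    for _ in range(n_runs - 2):
        prev = rows[-1]
        rows.append([prev[-1]] + prev[:-1])
    rows.append([-1] * (n_runs - 1))

    if factor_names is None:
        factor_names = [f"X{i + 1}" for i in range(n_process)]
    if len(factor_names) != n_process:
        raise ValueError("factor_names length must equal n_process")
    dummy_names = [f"D{i + 1}" for i in range(n_dummy)]
    columns = list(factor_names) + dummy_names
    coded = pd.DataFrame(
        np.array(rows, dtype=int),
        index=pd.RangeIndex(1, n_runs + 1, name="run"),
        columns=columns,
    )
    roles = {c: "process" for c in factor_names}
    roles.update({c: "dummy" for c in dummy_names})
    return DesignMatrix(coded=coded, roles=roles, design_kind="plackett-burman")


def rotatable_alpha(k: int) -> float:
    """Axial distance making a CCD rotatable: ``(2**k) ** (1/4)``.

    Rotatability means the variance of a model prediction depends only on
    the distance from the design centre, not on direction.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    return float((2.0**k) ** 0.25)


def coded_to_actual(factor: Factor, coded: float) -> float:
    """Map a coded level to actual units: ``center + step * coded``.

    Negative actual concentrations are possible for large axial
    distances; they are returned as computed (with
    :class:`InfeasibleLevelWarning`), never clipped, because the design
    itself — not this function — is what would need to change.
    """
    if factor.center is None or factor.step is None:
        raise ValueError(f"factor {factor.name!r} has no center/step coding")
    actual = factor.center + factor.step * coded
    if actual < 0 and factor.center > 0:
        warnings.warn(
            f"coded level {coded:g} of {factor.name!r} maps to a negative "
            f"actual level {actual:.4g}",
            InfeasibleLevelWarning,
            stacklevel=2,
        )
    return actual


def actual_to_coded(factor: Factor, actual: float) -> float:
    """Inverse of :func:`coded_to_actual`: ``(actual - center) / step``."""
    if factor.center is None or factor.step is None:
        raise ValueError(f"factor {factor.name!r} has no center/step coding")
    return (actual - factor.center) / factor.step


def build_ccd(spec: CCDSpec) -> DesignMatrix:
    """Build a central composite design from a :class:`CCDSpec`.

    Run order is deterministic: the ``2^k`` factorial block in standard
    order (first factor varying fastest), then axial pairs (-alpha then
    +alpha) in factor order, then the centre replicates.  Actual levels
    are attached via :func:`coded_to_actual`; any physically impossible
    actual level (negative concentration) triggers an
    :class:`InfeasibleLevelWarning` and is recorded in
    ``infeasible_levels``.
    """
    k = spec.k
    alpha = spec.alpha_value
    names = [f.name for f in spec.factors]

    factorial = np.array(list(itertools.product((-1.0, 1.0), repeat=k)))[:, ::-1]
    axial = np.zeros((2 * k, k))
    for i in range(k):
        axial[2 * i, i] = -alpha
        axial[2 * i + 1, i] = alpha
    center = np.zeros((spec.n_center, k))
    coded_arr = np.vstack([factorial, axial, center])

    coded = pd.DataFrame(
        coded_arr,
        index=pd.RangeIndex(1, len(coded_arr) + 1, name="run"),
        columns=names,
    )
    actual = coded.copy()
    infeasible: list[tuple[int, str, float]] = []
    for f in spec.factors:
        actual[f.name] = f.center + f.step * coded[f.name]
        # negative level is impossible for a concentration-like factor
        # whose natural scale is positive
        if f.center > 0:
            for run, val in actual[f.name].items():
                if val < 0:
                    infeasible.append((int(run), f.name, float(val)))
    if infeasible:
        desc = ", ".join(f"{n}={v:.4g} (run {r})" for r, n, v in infeasible)
        warnings.warn(
            f"design contains physically infeasible actual levels: {desc}",
            InfeasibleLevelWarning,
            stacklevel=2,
        )
    return DesignMatrix(
        coded=coded,
        roles={n: "process" for n in names},
        design_kind="central-composite",
        actual=actual,
        factors=list(spec.factors),
        infeasible_levels=infeasible,
    )
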