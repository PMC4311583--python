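"""Tabular I/O, study configuration and the two-stage pipeline.

CSV dialect is fixed: comma-separated, UTF-8, mandatory header row,
``.`` decimal.  A design CSV carries the coded matrix (``run`` column
first); column roles and the design kind live in a JSON sidecar
``<stem>.roles.json`` so user-supplied designs can mark dummy columns.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .designs import DesignMatrix, Factor, ResponseVector
from .optimize import optimize_in_region, stationary_point
from .rsm import anova, fit_quadratic, fit_stats
from .screening import pb_analyze

log = logging.getLogger("mediaopt")

__all__ = [
    "save_design_csv",
    "load_design_csv",
    "save_response_csv",
    "load_response_csv",
    "StudyConfig",
    "CONFIG_SCHEMA",
    "run_pipeline",
]

# ---------------------------------------------------------------------------
# design / response CSV

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix("").with_suffix(".roles.json")


def save_design_csv(design: DesignMatrix, path: str | Path) -> None:
    """Write coded design CSV, a ``_actual`` CSV when actual levels
    exist, and a JSON sidecar with column roles and design kind."""
    path = Path(path)
    design.coded.to_csv(path, index=True)
    if design.actual is not None:
        actual_path = path.with_name(path.stem + "_actual" + path.suffix)
        design.actual.to_csv(actual_path, index=True)
    sidecar = {
        "design_kind": design.design_kind,
        "roles": design.roles,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1) + "\n")


def _strict_read(path: Path) -> pd.DataFrame:
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: empty file, no header row") from exc
    if df.empty and len(df.columns) == 0:
        raise ValueError(f"{path}: no data rows")
    return df


def _checked_numeric(df: pd.DataFrame, path: Path) -> pd.DataFrame:
    out = {}
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise ValueError(
                f"{path}: malformed numeric cell at row {row + 2}, column {col!r}: "
                f"{df[col][bad].iloc[0]!r}"
            )
        if converted.isna().any():
            row = int(converted.isna().idxmax())
            raise ValueError(f"{path}: missing value at row {row + 2}, column {col!r}")
        out[col] = converted
    return pd.DataFrame(out)


def load_design_csv(path: str | Path, roles: dict[str, str] | None = None) -> DesignMatrix:
    """Load a coded design CSV (strict parsing).

    Roles come from, in order of precedence: the ``roles`` argument, the
    JSON sidecar written by :func:`save_design_csv`, or the fallback of
    treating every column as a process factor.  The design kind is taken
    from the sidecar or inferred: all-±1 entries mean Plackett-Burman,
    anything else central-composite; the coded-value domain is then
    validated against that kind.
    """
    path = Path(path)
    df = _strict_read(path)
    if "run" not in df.columns:
        raise ValueError(f"{path}: first column must be 'run'")
    df = _checked_numeric(df, path)
    if df["run"].duplicated().any():
        dupes = df.loc[df["run"].duplicated(), "run"].tolist()
        raise ValueError(f"{path}: duplicate run ids {dupes}")
    df = df.set_index(df["run"].astype(int)).drop(columns=["run"])
    df.index.name = "run"

    kind = None
    if roles is None and _sidecar_path(path).exists():
        side = json.loads(_sidecar_path(path).read_text())
        roles = side.get("roles")
        kind = side.get("design_kind")
    if roles is None:
        roles = {c: "process" for c in df.columns}
    unknown = [c for c in df.columns if c not in roles]
    if unknown:
        raise ValueError(f"{path}: columns {unknown} not declared in roles")
    if kind is None:
        kind = (
            "plackett-burman"
            if np.isin(df.to_numpy(), (-1, 1)).all()
            else "central-composite"
        )
    if kind == "plackett-burman":
        df = df.astype(int)
    return DesignMatrix(coded=df, roles=dict(roles), design_kind=kind)


def save_response_csv(response: ResponseVector, path: str | Path) -> None:
    pd.DataFrame({"run": response.run_ids, "response": response.values}).to_csv(
        path, index=False
    )


def load_response_csv(path: str | Path) -> ResponseVector:
    path = Path(path)
    df = _strict_read(path)
    expected = {"run", "response"}
    if set(df.columns) != expected:
        raise ValueError(f"{path}: expected columns {sorted(expected)}, got {list(df.columns)}")
    df = _checked_numeric(df, path)
    if df["run"].duplicated().any():
        raise ValueError(f"{path}: duplicate run ids")
    return ResponseVector(
        values=df["response"].to_numpy(), run_ids=df["run"].astype(int).to_numpy()
    )


# ---------------------------------------------------------------------------
# study configuration

CONFIG_SCHEMA: dict = {
    "type": "object",
    "required": ["screening_threshold_pct"],
    "properties": {
        "screening_threshold_pct": {"type": "number", "exclusiveMinimum": 0, "exclusiveMaximum": 100},
        "alpha_policy": {"enum": ["rotatable", "numeric"]},
        "alpha_value": {"type": "number", "exclusiveMinimum": 0},
        "region": {"enum": ["box", "sphere"]},
        "region_bound": {"type": "number", "exclusiveMinimum": 0},
        "display_decimals": {"type": "integer", "minimum": 0},
        "ccd_factors": {
            "type": "array",
            "items": {
                "type": "object",
                "required": ["name", "center", "step"],
                "properties": {
                    "name": {"type": "string"},
                    "center": {"type": "number"},
                    "step": {"type": "number", "exclusiveMinimum": 0},
                },
            },
        },
    },
}


class StudyConfig:
    """Validated configuration for the two-stage pipeline."""

    def __init__(
        self,
        screening_threshold_pct: float = 95.0,
        alpha_policy: str = "rotatable",
        alpha_value: float | None = None,
        region: str = "box",
        region_bound: float | None = None,
        display_decimals: int = 6,
        ccd_factors: list[dict] | None = None,
    ) -> None:
        if not 0 < screening_threshold_pct < 100:
            raise ValueError("screening_threshold_pct must be in (0, 100)")
        if alpha_policy not in ("rotatable", "numeric"):
            raise ValueError(f"unknown alpha policy {alpha_policy!r}")
        if alpha_policy == "numeric" and (alpha_value is None or alpha_value <= 0):
            raise ValueError("numeric alpha policy needs alpha_value > 0")
        if region not in ("box", "sphere"):
            raise ValueError(f"unknown region {region!r}")
        if region_bound is not None and region_bound <= 0:
            raise ValueError("region_bound must be > 0")
        if display_decimals < 0:
            raise ValueError("display_decimals must be >= 0")
        self.screening_threshold_pct = float(screening_threshold_pct)
        self.alpha_policy = alpha_policy
        self.alpha_value = alpha_value
        self.region = region
        self.region_bound = region_bound
        self.display_decimals = int(display_decimals)
        self.factors = None
        if ccd_factors is not None:
            self.factors = [
                Factor(name=f["name"], center=float(f["center"]), step=float(f["step"]))
                for f in ccd_factors
            ]

    @classmethod
    def from_json(cls, path: str | Path) -> "StudyConfig":
        data = json.loads(Path(path).read_text())
        if not isinstance(data, dict):
            raise ValueError("config must be a JSON object")
        allowed = set(CONFIG_SCHEMA["properties"])
        unknown = set(data) - allowed
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        return cls(**data)


# ---------------------------------------------------------------------------
# pipeline

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _round_floats(obj, nd: int):
    if isinstance(obj, float):
        return round(obj, nd)
    if isinstance(obj, dict):
        return {k: _round_floats(v, nd) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, nd) for v in obj]
    return obj


def run_pipeline(
    config: StudyConfig,
    pb_design: DesignMatrix,
    pb_response: ResponseVector,
    ccd_design: DesignMatrix,
    ccd_response: ResponseVector,
    out_dir: str | Path | None = None,
    input_paths: list[Path] | None = None,
) -> dict:
    """Run screening -> quadratic fit -> ANOVA -> optimization and
    return (and optionally write) a single report bundle.

    The CCD stage uses the supplied design; factor selection from the
    screen is reported and cross-checked against the CCD's factors, but
    a user-provided CCD is accepted as-is.  Float values in the report
    are rounded to ``config.display_decimals`` so identical inputs give
    byte-identical reports.
    """
    for p in input_paths or []:
        log.info("input %s sha256=%s", p, _sha256(Path(p)))

    stage = "pb-screen"
    try:
        screen = pb_analyze(pb_design, pb_response, config.screening_threshold_pct)
        log.info("screening kept %s", screen.significant_factors)

        stage = "rsm-fit"
        model = fit_quadratic(ccd_design, ccd_response)
        aov = anova(model, ccd_design, ccd_response)
        stats_ = fit_stats(model, aov, ccd_response)

        stage = "rsm-optimize"
        bound = config.region_bound
        if bound is None:
            bound = float(np.abs(ccd_design.coded.to_numpy()).max())
        factors = ccd_design.factors
        try:
            sp = stationary_point(model, factors)
            sp_dict = {
                "coded": sp.coded.tolist(),
                "actual": sp.actual,
                "predicted": sp.predicted,
                "nature": sp.nature,
                "eigenvalues": sp.eigenvalues.tolist(),
            }
        except np.linalg.LinAlgError as exc:
            sp_dict = {"error": str(exc)}
        opt = optimize_in_region(model, region=config.region, bound=bound, factors=factors)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    report = {
        "screening": {
            "threshold_pct": config.screening_threshold_pct,
            "std_error": screen.std_error,
            "veff": screen.veff,
            "dummy_effects": screen.dummy_effects.tolist(),
            "table": screen.table.to_dict(orient="records"),
            "significant_factors": screen.significant_factors,
        },
        "model": {
            "factors": model.factor_names,
            "coefficients": screen_safe(model.coefficients.to_dict()),
            "n": model.n,
            "p": model.p,
        },
        "anova": aov.table.replace({np.nan: None}).to_dict(orient="records"),
        "fit_stats": {
            "r_squared": stats_.r_squared,
            "r_squared_adj": stats_.r_squared_adj,
            "cv_pct": stats_.cv_pct,
            "adequate_precision": stats_.adequate_precision,
        },
        "stationary_point": sp_dict,
        "region_optimum": {
            "region": opt.region,
            "bound": opt.bound,
            "coded": opt.coded.tolist(),
            "actual": opt.actual,
            "predicted": opt.predicted,
        },
        "predictions": {
            "run": ccd_design.run_ids.tolist(),
            "observed": ccd_response.aligned_to(ccd_design).tolist(),
            "predicted": model.fitted.tolist(),
        },
    }
    report = _round_floats(report, config.display_decimals)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(
            json.dumps(report, indent=1, sort_keys=True) + "\n"
        )
        screen.table.round(config.display_decimals).to_csv(out / "screening.csv", index=False)
        aov.table.round(config.display_decimals).to_csv(out / "anova.csv", index=False)
        pd.DataFrame(report["predictions"]).to_csv(out / "predictions.csv", index=False)
    return report


def screen_safe(d: dict) -> dict:
    """Replace non-JSON-serializable keys/values in a coefficient dict."""
    return {str(k): float(v) for k, v in d.items()}
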