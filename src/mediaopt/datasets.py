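"""Bundled cellulase media-optimization study data.

A published two-stage optimization of cellulase production by a soil
isolate of *Bacillus amyloliquefaciens*: a 12-run Plackett-Burman screen
of eight medium/process factors (CMC, sucrose, yeast extract, peptone,
K2HPO4, MgSO4, temperature, pH) with three dummy columns, followed by a
20-run rotatable central composite design over the three factors the
screen retained (CMC, MgSO4, pH).  Responses are cellulase activity in
U/mL.  The tables ship as plain CSV inside the package so the whole
pipeline is reproducible offline.

Notes on the source tables, kept verbatim rather than "fixed":

* The screening-stage factor table lists pH with the *high* (+1) level
  at 5 and the *low* (-1) level at 9 — inverted relative to every other
  row.  The sign matrix is authoritative; the level table is stored as
  printed.
* The CCD axial level of MgSO4 at -alpha is a negative concentration
  (-0.1034 g%), physically impossible but printed in the source design;
  it is preserved as-is.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .designs import DesignMatrix, Factor, ResponseVector

__all__ = [
    "load_pb_study",
    "load_ccd_study",
    "pb_factor_table",
    "ccd_factors",
    "VALIDATION_METADATA",
]

#: Reported wet-lab outcomes of the study's validation experiment.
#: These are experimental fixtures, not quantities this package computes:
#: the validated activity is a triplicate flask measurement, and the
#: fold-increase is relative to an unoptimized baseline that was never
#: printed.
VALIDATION_METADATA = {
    "validated_activity_U_per_mL": 30.62,
    "reported_predicted_activity_U_per_mL": 29.95,
    "reported_fold_increase": 6.81,
    "reported_optimum_actual": {"CMC": 1.84, "MgSO4": 0.275, "pH": 8.5},
}


def _read(name: str) -> pd.DataFrame:
    with resources.files("mediaopt.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def pb_factor_table() -> pd.DataFrame:
    """Screening-stage factor levels (variable, component, +/- values),
    exactly as printed in the source study."""
    return _read("pb_factors_cellulase.csv")


def load_pb_study() -> tuple[DesignMatrix, ResponseVector]:
    """The 12-run Plackett-Burman screen: 8 process factors, 3 dummies,
    cellulase activity response (U/mL)."""
    df = _read("pb_design_cellulase.csv").set_index("run")
    roles = {c: ("dummy" if c.startswith("D") else "process") for c in df.columns}
    design = DesignMatrix(
        coded=df.astype(int), roles=roles, design_kind="plackett-burman"
    )
    resp = _read("pb_response_cellulase.csv")
    response = ResponseVector(
        values=resp["response"].to_numpy(), run_ids=resp["run"].to_numpy()
    )
    return design, response


def ccd_factors() -> list[Factor]:
    """CCD factor definitions (center and per-coded-unit step, actual units)."""
    df = _read("ccd_factors_cellulase.csv")
    return [
        Factor(name=r["name"], center=float(r["center"]), step=float(r["step"]))
        for _, r in df.iterrows()
    ]


def load_ccd_study() -> tuple[DesignMatrix, ResponseVector]:
    """The 20-run rotatable CCD over CMC, MgSO4 and pH with cellulase
    activity response (U/mL); coded and actual levels as printed."""
    coded = _read("ccd_design_cellulase.csv").set_index("run")
    actual = _read("ccd_design_actual_cellulase.csv").set_index("run")
    design = DesignMatrix(
        coded=coded,
        roles={c: "process" for c in coded.columns},
        design_kind="central-composite",
        actual=actual,
        factors=ccd_factors(),
    )
    resp = _read("ccd_response_cellulase.csv")
    response = ResponseVector(
        values=resp["response"].to_numpy(), run_ids=resp["run"].to_numpy()
    )
    return design, response
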