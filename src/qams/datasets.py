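"""Packaged reference datasets for the *Fructus Corni* QAMS method.

These are the published method-development results shipped as plain-text
fixtures: calibration curves, mixed-standard stock concentrations, relative
correction factors (per mixed solution and per instrument/column/
temperature/flow-rate condition), relative retention times, spike-recovery
results, and the 31-sample ESM-vs-QAMS content comparison.

Everything is returned either as small domain objects or as tidy
:class:`pandas.DataFrame` objects indexed the way the aggregation functions
in :mod:`qams.rcf` and :mod:`qams.quantify` expect.
"""

from __future__ import annotations

import json
from importlib import resources

import pandas as pd

from .calibration import CalibrationCurve
from .chromdata import StandardLevel, default_registry  # noqa: F401  (re-export)

__all__ = [
    "calibration_curves",
    "stock_concentrations",
    "stock_level",
    "recovery_results",
    "rcf_solutions",
    "rcf_condition_table",
    "rrt_conditions",
    "rrt_reference_data",
    "content_comparison",
]


def _path(name: str):
    return resources.files("qams.data").joinpath(name)


def calibration_curves() -> dict[str, CalibrationCurve]:
    """Published linear calibration curves (area vs µg/mL) per compound."""
    raw = json.loads(_path("calibration_curves.json").read_text())
    return {
        cid: CalibrationCurve(
            compound_id=cid,
            slope=v["slope"],
            intercept=v["intercept"],
            r=v["r"],
            range=(v["range"][0], v["range"][1]),
        )
        for cid, v in raw.items()
    }


def stock_concentrations() -> dict[str, float]:
    """Mixed standard stock solution, µg/mL per compound."""
    return json.loads(_path("stock_concentrations.json").read_text())


def stock_level(level_id: str = "stock") -> StandardLevel:
    """The stock mixed-standard solution as a :class:`StandardLevel`."""
    return StandardLevel(level_id=level_id, concentrations=stock_concentrations())


def recovery_results() -> pd.DataFrame:
    """Published spike-recovery results (mg amounts, printed recovery %)."""
    return pd.read_csv(_path("recovery.csv"), index_col="compound_id")


def rcf_solutions() -> pd.DataFrame:
    """Relative correction factors of six mixed standard solutions.

    Rows: solution 1..6; columns: the ten non-reference compounds.
    """
    return pd.read_csv(_path("rcf_solutions.csv"), index_col="solution")


def rcf_condition_table(kind: str) -> pd.DataFrame:
    """A condition-by-compound RCF matrix from the ruggedness study.

    Parameters
    ----------
    kind :
        ``"instrument_column"`` (8 instrument/column combinations),
        ``"temperature"`` (25/30/35 °C; the co-eluting cornin and sweroside
        cells at 35 °C are missing), or ``"flow_rate"`` (0.9/1.0/1.1 mL/min).
    """
    if kind == "instrument_column":
        df = pd.read_csv(_path("rcf_instrument_column.csv"))
        df.index = df["instrument"] + " / " + df["column"]
        return df.drop(columns=["instrument", "column"])
    if kind == "temperature":
        return pd.read_csv(_path("rcf_temperature.csv"), index_col="temperature_c")
    if kind == "flow_rate":
        return pd.read_csv(_path("rcf_flow_rate.csv"), index_col="flow_rate_ml_min")
    raise ValueError(f"unknown ruggedness table kind {kind!r}")


def rrt_conditions() -> pd.DataFrame:
    """Relative retention times on 8 instrument/column combinations."""
    df = pd.read_csv(_path("rrt_instrument_column.csv"))
    df.index = df["instrument"] + " / " + df["column"]
    return df.drop(columns=["instrument", "column"])


def rrt_reference_data() -> dict:
    """Raw dict behind the default RRT reference (mean RRT per compound)."""
    return json.loads(_path("rrt_reference.json").read_text())


def content_comparison(tidy: bool = True) -> pd.DataFrame:
    """The 31-sample ESM-vs-QAMS content comparison (mg per g of herb).

    With ``tidy=True`` (default) returns one row per
    (sample, compound) with columns ``sample_id``, ``sample_type``,
    ``compound_id``, ``esm``, ``qams``; compounds absent from a sample are
    omitted.  Loganin, quantified from its own curve in both methods, carries
    its single published value in both columns.  With ``tidy=False`` the
    wide paired-column layout is returned as shipped.
    """
    wide = pd.read_csv(_path("contents_esm_qams.csv"))
    if not tidy:
        return wide
    records = []
    compounds = [c.id for c in default_registry()]
    for _, row in wide.iterrows():
        for cid in compounds:
            if cid == "loganin":
                esm = qams = row["loganin_esm"]
            else:
                esm = row[f"{cid}_esm"]
                qams = row[f"{cid}_qams"]
            if pd.isna(esm) and pd.isna(qams):
                continue
            records.append(
                {
                    "sample_id": str(row["sample_id"]),
                    "sample_type": row["sample_type"],
                    "compound_id": cid,
                    "esm": esm,
                    "qams": qams,
                }
            )
    return pd.DataFrame.from_records(records)
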