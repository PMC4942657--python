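"""Domain types and reader/writer layer for chromatographic peak tables.

The in-memory model is deliberately small: a :class:`Compound` registry in
which exactly one compound is flagged as the internal reference substance
(loganin in the shipped registry), :class:`InjectionRun` objects holding
retention-time-sorted :class:`PeakRecord` lists, and the standard-mixture /
sample-preparation bookkeeping needed by the calibration and quantification
stages.

All tabular exchange goes through plain CSV (comma separated, UTF-8, header
row mandatory, decimal point).  Retention times are minutes; peak areas are
an opaque detector unit — every downstream formula only ever uses area
ratios, so no unit conversion is attempted.  Cells that are genuinely absent
(a component not detected in a run) are represented by an explicit
not-detected state, never by zero.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .errors import PeakTableParseError, RegistryError, SchemaError

__all__ = [
    "Compound",
    "PeakRecord",
    "RunCondition",
    "InjectionRun",
    "SamplePrep",
    "StandardLevel",
    "DEFAULT_ANALYSIS_WINDOW_MIN",
    "default_registry",
    "validate_registry",
    "internal_reference",
    "read_peak_table",
    "write_peak_table",
    "read_concentration_table",
    "write_concentration_table",
    "read_run_metadata",
    "write_run_metadata",
    "check_analysis_window",
    "strip_labels",
]

#: Length of the gradient program, minutes. Peaks beyond this are suspicious
#: but not fatal; see :func:`check_analysis_window`.
DEFAULT_ANALYSIS_WINDOW_MIN = 50.0


@dataclass(frozen=True)
class Compound:
    """One analyte of the 11-component panel.

    Parameters
    ----------
    id :
        Short stable token used as a key everywhere (``"loganin"``).
    name :
        Display name (``"7α-O-methylmorroniside"``).
    is_internal_reference :
        True for the single compound used as the QAMS internal reference.
    """

    id: str
    name: str
    is_internal_reference: bool = False


@dataclass
class PeakRecord:
    """A single integrated peak: retention time (min) and area.

    ``compound_id`` stays ``None`` until peak location assigns the peak to a
    compound.
    """

    retention_time: float
    area: float
    compound_id: str | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.retention_time) or self.retention_time <= 0:
            raise ValueError(
                f"retention_time must be a positive finite number of minutes, "
                f"got {self.retention_time!r}"
            )
        if not math.isfinite(self.area) or self.area < 0:
            raise ValueError(f"area must be finite and >= 0, got {self.area!r}")


@dataclass(frozen=True)
class RunCondition:
    """Chromatographic condition metadata for a run."""

    instrument: str = "default"
    column: str = "default"
    temperature_c: float = 30.0
    flow_rate_ml_min: float = 1.0

    def __post_init__(self) -> None:
        if self.temperature_c <= 0:
            raise ValueError("temperature_c must be positive (degrees Celsius)")
        if self.flow_rate_ml_min <= 0:
            raise ValueError("flow_rate_ml_min must be positive")

    @property
    def label(self) -> str:
        return (
            f"{self.instrument}|{self.column}|"
            f"{self.temperature_c:g}C|{self.flow_rate_ml_min:g}mL"
        )


@dataclass
class InjectionRun:
    """One chromatographic injection: condition metadata plus a peak list.

    Peaks are kept sorted by retention time; two peaks may not share an
    identical retention time within one run.
    """

    run_id: str
    condition: RunCondition = field(default_factory=RunCondition)
    peaks: list[PeakRecord] = field(default_factory=list)
    #: standard-mixture level id or sample id this injection came from
    source: str | None = None

    def __post_init__(self) -> None:
        self.peaks = sorted(self.peaks, key=lambda p: p.retention_time)
        times = [p.retention_time for p in self.peaks]
        if len(set(times)) != len(times):
            raise ValueError(
                f"run {self.run_id!r}: two peaks share an identical retention time"
            )

    def peak_for(self, compound_id: str) -> PeakRecord | None:
        """Return the located peak for ``compound_id``, or None."""
        for p in self.peaks:
            if p.compound_id == compound_id:
                return p
        return None


@dataclass(frozen=True)
class SamplePrep:
    """Sample solution bookkeeping: herb mass (g) extracted into a methanol
    volume (mL), optionally diluted before injection."""

    mass_g: float = 2.0
    extraction_volume_ml: float = 50.0
    dilution_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.mass_g <= 0:
            raise ValueError("mass_g must be > 0")
        if self.extraction_volume_ml <= 0:
            raise ValueError("extraction_volume_ml must be > 0")
        if self.dilution_factor < 1:
            raise ValueError("dilution_factor must be >= 1")


@dataclass(frozen=True)
class StandardLevel:
    """One dilution level of the mixed standard solution: a concentration
    (µg/mL) per compound id."""

    level_id: str
    concentrations: Mapping[str, float]

    def __post_init__(self) -> None:
        for cid, c in self.concentrations.items():
            if not (c > 0 and math.isfinite(c)):
                raise ValueError(
                    f"level {self.level_id!r}: concentration for {cid!r} must be > 0"
                )


# ---------------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------------

#: The 11-compound panel in elution order; loganin is the internal reference.
_PANEL: tuple[tuple[str, str, bool], ...] = (
    ("gallic_acid", "gallic acid", False),
    ("hmf", "5-hydroxymethyl-2-furfural", False),
    ("morroniside", "morroniside", False),
    ("cornin", "cornin", False),
    ("sweroside", "sweroside", False),
    ("loganin", "loganin", True),
    ("methylmorroniside_7a", "7α-O-methylmorroniside", False),
    ("methylmorroniside_7b", "7β-O-methylmorroniside", False),
    ("ethylmorroniside_7a", "7α-O-ethylmorroniside", False),
    ("ethylmorroniside_7b", "7β-O-ethylmorroniside", False),
    ("cornuside", "cornuside", False),
)


def default_registry() -> list[Compound]:
    """The packaged 11-compound *Fructus Corni* panel, in elution order."""
    return [Compound(i, n, ref) for i, n, ref in _PANEL]


def validate_registry(registry: Sequence[Compound]) -> list[Compound]:
    """Check registry invariants and return the registry as a list.

    Raises
    ------
    RegistryError
        If the registry is empty, contains duplicate ids, or does not have
        exactly one internal reference compound.
    """
    if not registry:
        raise RegistryError("compound registry is empty")
    ids = [c.id for c in registry]
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        raise RegistryError(f"duplicate compound ids: {sorted(dupes)}")
    refs = [c.id for c in registry if c.is_internal_reference]
    if len(refs) != 1:
        raise RegistryError(
            f"exactly one internal reference compound required, found {len(refs)}"
            f"{' (' + ', '.join(refs) + ')' if refs else ''}"
        )
    return list(registry)


def internal_reference(registry: Sequence[Compound]) -> Compound:
    """Return the single internal-reference compound of a valid registry."""
    return next(c for c in validate_registry(registry) if c.is_internal_reference)


# ---------------------------------------------------------------------------
# peak-table CSV I/O
# ---------------------------------------------------------------------------

_PEAK_REQUIRED = ("run_id", "rt_min", "area")
_PEAK_OPTIONAL = (
    "compound_id",
    "source",
    "instrument",
    "column",
    "temperature_c",
    "flow_rate_ml_min",
)


def _parse_float(raw: str | None, column: str, line: int) -> float:
    if raw is None or raw == "" or raw.lower() == "nan":
        raise PeakTableParseError(
            f"line {line}: missing value in column {column!r}", line=line
        )
    try:
        return float(raw)
    except ValueError:
        raise PeakTableParseError(
            f"line {line}: non-numeric value {raw!r} in column {column!r}",
            line=line,
        ) from None


def read_peak_table(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
) -> list[InjectionRun]:
    """Read a peak-table CSV into a list of injection runs.

    Parameters
    ----------
    path :
        CSV file with at least the columns ``run_id``, ``rt_min``, ``area``.
        Optional columns: ``compound_id``, ``source``, ``instrument``,
        ``column``, ``temperature_c``, ``flow_rate_ml_min``.
    schema :
        Optional mapping from the canonical column names above to the names
        actually used in the file, e.g. ``{"rt_min": "RT"}``.

    Returns
    -------
    list of InjectionRun
        One run per distinct ``run_id``, in order of first appearance, with
        peaks sorted by retention time.

    Raises
    ------
    SchemaError
        If a required column is absent.
    PeakTableParseError
        If a retention time or area cell is not numeric; the error names the
        1-based line of the offending row.
    """
    schema = dict(schema or {})
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    colmap = {canon: schema.get(canon, canon) for canon in _PEAK_REQUIRED + _PEAK_OPTIONAL}
    missing = [colmap[c] for c in _PEAK_REQUIRED if colmap[c] not in raw.columns]
    if missing:
        raise SchemaError(f"peak table {path}: missing required column(s) {missing}")

    def cell(row: pd.Series, canon: str) -> str | None:
        col = colmap[canon]
        if col not in raw.columns:
            return None
        v = str(row[col]).strip()
        return v or None

    grouped: dict[str, dict] = {}
    for idx, row in raw.iterrows():
        line = int(idx) + 2  # header is line 1
        run_id = cell(row, "run_id")
        if not run_id:
            raise PeakTableParseError(f"line {line}: empty run_id", line=line)
        rt = _parse_float(cell(row, "rt_min"), colmap["rt_min"], line)
        area = _parse_float(cell(row, "area"), colmap["area"], line)
        entry = grouped.setdefault(
            run_id, {"peaks": [], "source": None, "condition": {}}
        )
        try:
            entry["peaks"].append(
                PeakRecord(rt, area, compound_id=cell(row, "compound_id"))
            )
        except ValueError as exc:
            raise PeakTableParseError(f"line {line}: {exc}", line=line) from None
        if cell(row, "source"):
            entry["source"] = cell(row, "source")
        for key in ("instrument", "column"):
            if cell(row, key):
                entry["condition"][key] = cell(row, key)
        for key in ("temperature_c", "flow_rate_ml_min"):
            if cell(row, key):
                entry["condition"][key] = _parse_float(cell(row, key), colmap[key], line)

    runs = []
    for run_id, entry in grouped.items():
        condition = RunCondition(**entry["condition"]) if entry["condition"] else RunCondition()
        runs.append(
            InjectionRun(run_id, condition=condition, peaks=entry["peaks"],
                         source=entry["source"])
        )
    return runs


def write_peak_table(runs: Iterable[InjectionRun], path: str | Path) -> None:
    """Write runs to a peak-table CSV readable by :func:`read_peak_table`."""
    rows = []
    for run in runs:
        for p in run.peaks:
            rows.append(
                {
                    "run_id": run.run_id,
                    "rt_min": repr(p.retention_time),
                    "area": repr(p.area),
                    "compound_id": p.compound_id or "",
                    "source": run.source or "",
                    "instrument": run.condition.instrument,
                    "column": run.condition.column,
                    "temperature_c": repr(run.condition.temperature_c),
                    "flow_rate_ml_min": repr(run.condition.flow_rate_ml_min),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# concentration-table CSV I/O
# ---------------------------------------------------------------------------


def read_concentration_table(path: str | Path) -> list[StandardLevel]:
    """Read a standard-mixture concentration CSV.

    Layout: a ``level_id`` column plus one column per compound id, values in
    µg/mL.  Empty cells mean the compound is absent from that level.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "level_id" not in raw.columns:
        raise SchemaError(f"concentration table {path}: missing 'level_id' column")
    levels = []
    for idx, row in raw.iterrows():
        line = int(idx) + 2
        conc = {}
        for col in raw.columns:
            if col == "level_id":
                continue
            v = str(row[col]).strip()
            if v:
                conc[col] = _parse_float(v, col, line)
        levels.append(StandardLevel(level_id=str(row["level_id"]).strip(), concentrations=conc))
    return levels


def write_concentration_table(levels: Iterable[StandardLevel], path: str | Path) -> None:
    levels = list(levels)
    compounds: list[str] = []
    for lv in levels:
        for cid in lv.concentrations:
            if cid not in compounds:
                compounds.append(cid)
    rows = []
    for lv in levels:
        row = {"level_id": lv.level_id}
        for cid in compounds:
            c = lv.concentrations.get(cid)
            row[cid] = repr(c) if c is not None else ""
        rows.append(row)
    pd.DataFrame(rows, columns=["level_id", *compounds]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# run metadata (JSON / YAML)
# ---------------------------------------------------------------------------


def read_run_metadata(path: str | Path) -> tuple[RunCondition, SamplePrep]:
    """Read run-condition and sample-prep metadata from a JSON or YAML file.

    Expected keys: ``instrument``, ``column``, ``temperature_c``,
    ``flow_rate_ml_min`` and a ``sample`` block with ``mass_g``,
    ``volume_ml`` and ``dilution``.  All keys are optional; defaults are the
    reference conditions (30 °C, 1.0 mL/min, 2 g / 50 mL, no dilution).
    """
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    data = data or {}
    cond = RunCondition(
        instrument=data.get("instrument", "default"),
        column=data.get("column", "default"),
        temperature_c=float(data.get("temperature_c", 30.0)),
        flow_rate_ml_min=float(data.get("flow_rate_ml_min", 1.0)),
    )
    sample = data.get("sample", {}) or {}
    prep = SamplePrep(
        mass_g=float(sample.get("mass_g", 2.0)),
        extraction_volume_ml=float(sample.get("volume_ml", 50.0)),
        dilution_factor=float(sample.get("dilution", 1.0)),
    )
    return cond, prep


def write_run_metadata(
    condition: RunCondition, prep: SamplePrep, path: str | Path
) -> None:
    path = Path(path)
    data = {
        "instrument": condition.instrument,
        "column": condition.column,
        "temperature_c": condition.temperature_c,
        "flow_rate_ml_min": condition.flow_rate_ml_min,
        "sample": {
            "mass_g": prep.mass_g,
            "volume_ml": prep.extraction_volume_ml,
            "dilution": prep.dilution_factor,
        },
    }
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def check_analysis_window(
    run: InjectionRun, t_max: float = DEFAULT_ANALYSIS_WINDOW_MIN
) -> list[PeakRecord]:
    """Return the peaks of ``run`` eluting after the analysis window ends."""
    return [p for p in run.peaks if p.retention_time > t_max]


def strip_labels(run: InjectionRun) -> InjectionRun:
    """Return a copy of ``run`` with all compound assignments removed.

    Useful for exercising peak location on synthetic runs whose peaks are
    emitted pre-labelled with the generating compound.
    """
    return InjectionRun(
        run.run_id,
        condition=run.condition,
        peaks=[replace(p, compound_id=None) for p in run.peaks],
        source=run.source,
    )
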