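"""Relative correction factors (RCFs) and their ruggedness statistics.

The single-marker method rests on the relative correction factor of a
compound *i* against the internal reference substance *s* (loganin):

    f_is = (C_i * A_s) / (C_s * A_i)

i.e. the ratio of response factors concentration/area.  Because only area
ratios enter, f_is is invariant under any common rescaling of all areas in a
run (detector gain), and f for the reference against itself is exactly 1.

This module computes per-injection RCF observations from located standard
runs, aggregates them into per-compound mean / SD / RSD% tables, and
summarizes RCF stability across chromatographic conditions (instruments,
columns, temperature, flow rate) against an RSD threshold.

All dispersion statistics use the sample standard deviation (n-1
denominator); RSD% is 100 * SD / mean.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .chromdata import Compound, InjectionRun, StandardLevel, internal_reference
from .errors import ConfigurationError, DomainError

__all__ = [
    "RcfObservation",
    "RcfStats",
    "RcfTable",
    "RuggednessReport",
    "compute_rcf",
    "aggregate_observations",
    "rcf_from_dilution_series",
    "summarize_condition_table",
    "ruggedness_panel",
]

logger = logging.getLogger(__name__)

#: Default acceptance threshold on the RSD% of an RCF across conditions.
DEFAULT_RSD_THRESHOLD_PCT = 5.0


def compute_rcf(c_i: float, a_i: float, c_s: float, a_s: float) -> float:
    """Relative correction factor f_is = (C_i * A_s) / (C_s * A_i).

    Parameters are the target compound's concentration and area and the
    internal reference's concentration and area from the same injection.
    All four must be positive.
    """
    for name, v in (("c_i", c_i), ("a_i", a_i), ("c_s", c_s), ("a_s", a_s)):
        if not (math.isfinite(v) and v > 0):
            raise DomainError(f"{name} must be finite and > 0, got {v!r}")
    return (c_i * a_s) / (c_s * a_i)


@dataclass(frozen=True)
class RcfObservation:
    """One RCF value for one compound from one injection run."""

    compound_id: str
    f_is: float
    source: str

    def __post_init__(self) -> None:
        if not (math.isfinite(self.f_is) and self.f_is > 0):
            raise ValueError(f"f_is must be finite and > 0, got {self.f_is!r}")


@dataclass(frozen=True)
class RcfStats:
    """Aggregated RCF of one compound: mean, sample SD and RSD%."""

    compound_id: str
    n: int
    mean: float
    sd: float
    rsd_percent: float
    observations: tuple[RcfObservation, ...] = ()


@dataclass
class RcfTable:
    """Per-compound RCF statistics keyed by compound id."""

    stats: dict[str, RcfStats] = field(default_factory=dict)

    def __getitem__(self, compound_id: str) -> RcfStats:
        return self.stats[compound_id]

    def __contains__(self, compound_id: str) -> bool:
        return compound_id in self.stats

    def compounds(self) -> list[str]:
        return list(self.stats)

    def mean(self, compound_id: str) -> float:
        """The mean RCF used for quantification ("a constant of
        proportionality")."""
        return self.stats[compound_id].mean

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "compound_id": s.compound_id,
                "n": s.n,
                "mean": s.mean,
                "sd": s.sd,
                "rsd_percent": s.rsd_percent,
            }
            for s in self.stats.values()
        ]
        return pd.DataFrame(rows).set_index("compound_id")

    def to_solution_frame(self) -> pd.DataFrame:
        """Observations as a solutions-by-compounds matrix with trailing
        Mean / RSD% rows (the layout of the published RCF table)."""
        cols = {}
        for cid, s in self.stats.items():
            cols[cid] = pd.Series(
                {o.source: o.f_is for o in s.observations}, name=cid
            )
        df = pd.DataFrame(cols)
        df.loc["Mean"] = [self.stats[c].mean for c in df.columns]
        df.loc["RSD %"] = [self.stats[c].rsd_percent for c in df.columns]
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_solution_frame().to_csv(path, index_label="solution")

    def to_json(self, path: str | Path | None = None) -> str:
        data = {
            cid: {
                "n": s.n,
                "mean": s.mean,
                "sd": s.sd,
                "rsd_percent": s.rsd_percent,
                "observations": [
                    {"f_is": o.f_is, "source": o.source} for o in s.observations
                ],
            }
            for cid, s in self.stats.items()
        }
        text = json.dumps(data, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "RcfTable":
        if isinstance(source, Path) or not str(source).lstrip().startswith("{"):
            text = Path(source).read_text()
        else:
            text = str(source)
        raw = json.loads(text)
        stats = {}
        for cid, v in raw.items():
            obs = tuple(
                RcfObservation(cid, o["f_is"], o["source"])
                for o in v.get("observations", [])
            )
            stats[cid] = RcfStats(
                cid, v["n"], v["mean"], v["sd"], v["rsd_percent"], obs
            )
        return cls(stats)

    @classmethod
    def from_means(cls, means: Mapping[str, float]) -> "RcfTable":
        """Build a table carrying only mean RCFs (e.g. published values)."""
        stats = {
            cid: RcfStats(cid, n=1, mean=float(m), sd=0.0, rsd_percent=0.0)
            for cid, m in means.items()
        }
        return cls(stats)


def _sample_sd(values: np.ndarray) -> float:
    return float(np.std(values, ddof=1)) if len(values) > 1 else 0.0


def aggregate_observations(
    observations: Iterable[RcfObservation],
) -> RcfTable:
    """Aggregate raw RCF observations into per-compound statistics."""
    by_compound: dict[str, list[RcfObservation]] = {}
    for o in observations:
        by_compound.setdefault(o.compound_id, []).append(o)
    stats = {}
    for cid, obs in by_compound.items():
        values = np.array([o.f_is for o in obs])
        mean = float(values.mean())
        sd = _sample_sd(values)
        stats[cid] = RcfStats(
            compound_id=cid,
            n=len(obs),
            mean=mean,
            sd=sd,
            rsd_percent=100.0 * sd / mean,
            observations=tuple(obs),
        )
    return RcfTable(stats)


def rcf_from_dilution_series(
    levels: Sequence[StandardLevel],
    runs: Sequence[InjectionRun],
    registry: Sequence[Compound],
) -> RcfTable:
    """Compute an RCF table from located standard-mixture injections.

    Each run's ``source`` must name a concentration level in ``levels``;
    each run contributes one :class:`RcfObservation` per compound whose peak
    is located in that run (never averaged before aggregation).  Runs whose
    internal-reference peak is missing are excluded with a logged warning.
    """
    ref = internal_reference(registry)
    level_by_id = {lv.level_id: lv for lv in levels}
    observations: list[RcfObservation] = []
    n_used = 0
    for run in runs:
        if run.source not in level_by_id:
            raise ConfigurationError(
                f"run {run.run_id!r}: source {run.source!r} matches no "
                f"standard level"
            )
        level = level_by_id[run.source]
        ref_peak = run.peak_for(ref.id)
        if ref_peak is None or ref_peak.area <= 0:
            logger.warning(
                "run %s: internal-reference (%s) peak missing; run excluded",
                run.run_id,
                ref.id,
            )
            continue
        c_s = level.concentrations[ref.id]
        n_used += 1
        for compound in registry:
            peak = run.peak_for(compound.id)
            if peak is None or compound.id not in level.concentrations:
                continue
            f = compute_rcf(
                level.concentrations[compound.id], peak.area, c_s, ref_peak.area
            )
            observations.append(RcfObservation(compound.id, f, source=run.run_id))
    if n_used == 0:
        raise ConfigurationError("no usable runs: internal-reference peak never found")
    return aggregate_observations(observations)


# ---------------------------------------------------------------------------
# ruggedness
# ---------------------------------------------------------------------------


@dataclass
class RuggednessReport:
    """RCF stability across chromatographic conditions.

    Attributes
    ----------
    per_condition :
        Conditions-by-compounds matrix of per-condition mean RCFs; NaN marks
        a compound not detected under that condition (e.g. a co-eluting peak
        pair), which is excluded from the overall statistics.
    mean, rsd_percent :
        Overall mean and RSD% per compound across the available conditions.
    passed :
        Per-compound flag: RSD% at or below the threshold.
    threshold_percent :
        The acceptance threshold applied.
    """

    per_condition: pd.DataFrame
    mean: pd.Series
    rsd_percent: pd.Series
    passed: pd.Series
    n_conditions: pd.Series
    threshold_percent: float

    @property
    def all_passed(self) -> bool:
        return bool(self.passed.all())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mean": self.mean,
                "rsd_percent": self.rsd_percent,
                "n_conditions": self.n_conditions,
                "passed": self.passed,
            }
        )


def summarize_condition_table(
    table: pd.DataFrame,
    threshold_percent: float = DEFAULT_RSD_THRESHOLD_PCT,
) -> RuggednessReport:
    """Summarize a conditions-by-compounds RCF matrix.

    Missing cells (NaN) are excluded from mean and SD, not imputed: a
    compound that could not be separated under some condition simply
    contributes fewer observations.
    """
    if table.empty:
        raise ConfigurationError("condition table is empty")
    mean = table.mean(axis=0, skipna=True)
    sd = table.std(axis=0, ddof=1, skipna=True).fillna(0.0)
    rsd = 100.0 * sd / mean
    return RuggednessReport(
        per_condition=table,
        mean=mean,
        rsd_percent=rsd,
        passed=rsd <= threshold_percent,
        n_conditions=table.notna().sum(axis=0),
        threshold_percent=threshold_percent,
    )


def ruggedness_panel(
    groups: Mapping[str, Sequence[InjectionRun]],
    levels: Sequence[StandardLevel],
    registry: Sequence[Compound],
    threshold_percent: float = DEFAULT_RSD_THRESHOLD_PCT,
) -> RuggednessReport:
    """Aggregate RCFs within each condition group and across groups.

    Parameters
    ----------
    groups :
        Mapping of condition label to the located standard injections
        acquired under that condition; at least two non-empty groups are
        required.
    levels :
        The standard-mixture concentration levels referenced by the runs.
    threshold_percent :
        Pass/fail threshold on the across-condition RSD% per compound.
    """
    if len(groups) < 2:
        raise ConfigurationError("ruggedness needs at least two condition groups")
    rows = {}
    for label, runs in groups.items():
        if not runs:
            raise ConfigurationError(f"condition group {label!r} is empty")
        table = rcf_from_dilution_series(levels, runs, registry)
        rows[label] = {cid: s.mean for cid, s in table.stats.items()}
    ref_id = internal_reference(registry).id
    df = pd.DataFrame.from_dict(rows, orient="index")
    df = df.drop(columns=[ref_id], errors="ignore")
    # keep compound order of the registry
    order = [c.id for c in registry if c.id in df.columns]
    return summarize_condition_table(df[order], threshold_percent)
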