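"""External-standard and single-marker quantification of located runs.

Two routes from a located injection to solution concentrations (µg/mL):

* **ESM** (external standard method): each compound is inverted through its
  own calibration curve.
* **QAMS** (single marker): only the internal reference substance *s* is
  inverted through a curve; every target compound *i* is obtained from its
  mean relative correction factor,

      C_i = f_is * A_i * C_s / A_s.

Solution concentrations convert to herb contents (mg per g of dried herb)
through the sample preparation: content = C * V * dilution / (m * 1000).

`compare_methods` quantifies the agreement of paired ESM/QAMS results per
compound (mean and max relative difference, paired t-test or Wilcoxon
signed-rank) and flags "no significant difference" when every per-compound
p-value exceeds the significance level.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .calibration import CalibrationCurve, InversionResult, invert_calibration
from .chromdata import PeakRecord, SamplePrep
from .errors import ConfigurationError
from .peak_location import LocationResult
from .rcf import RcfTable

__all__ = [
    "ConcentrationResult",
    "ContentRecord",
    "MethodComparison",
    "esm_concentration",
    "qams_concentration",
    "content_from_concentration",
    "contents_for_run",
    "compare_methods",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConcentrationResult:
    """A per-compound solution concentration, or an explicit not-detected.

    ``value`` is µg/mL and is None iff ``flags`` contains ``"not_detected"``.
    Range flags from calibration inversion propagate unchanged.
    """

    compound_id: str
    value: float | None
    flags: tuple[str, ...] = ()

    @property
    def detected(self) -> bool:
        return self.value is not None

    @classmethod
    def not_detected(cls, compound_id: str) -> "ConcentrationResult":
        return cls(compound_id, None, ("not_detected",))

    @classmethod
    def from_inversion(
        cls, compound_id: str, inv: InversionResult
    ) -> "ConcentrationResult":
        flags = () if inv.flag == "ok" else (inv.flag,)
        return cls(compound_id, inv.concentration, flags)


@dataclass(frozen=True)
class ContentRecord:
    """Per-sample, per-compound herb content with its producing method.

    ``method`` is ``"ESM"`` or ``"QAMS"``; ``content`` is mg per g of herb,
    None iff the compound was not detected.
    """

    sample_id: str
    compound_id: str
    method: str
    content: float | None
    flags: tuple[str, ...] = ()

    @property
    def detected(self) -> bool:
        return self.content is not None


def _located_compounds(
    location: LocationResult | Mapping[str, PeakRecord | None],
) -> tuple[dict[str, PeakRecord], tuple[str, ...]]:
    """Normalize a location result or plain mapping into (detected, nd)."""
    if isinstance(location, LocationResult):
        return dict(location.assignment), tuple(location.not_detected)
    detected = {c: p for c, p in location.items() if p is not None}
    nd = tuple(c for c, p in location.items() if p is None)
    return detected, nd


def esm_concentration(
    curves: Mapping[str, CalibrationCurve],
    location: LocationResult | Mapping[str, PeakRecord | None],
) -> dict[str, ConcentrationResult]:
    """External-standard concentrations for every compound of a located run.

    Raises
    ------
    ConfigurationError
        If a located compound has no calibration curve.
    """
    detected, nd = _located_compounds(location)
    missing = sorted(set(detected) - set(curves))
    if missing:
        raise ConfigurationError(f"no calibration curve for located compound(s) {missing}")
    out: dict[str, ConcentrationResult] = {}
    for cid, peak in detected.items():
        inv = invert_calibration(curves[cid], peak.area)
        out[cid] = ConcentrationResult.from_inversion(cid, inv)
    for cid in nd:
        out[cid] = ConcentrationResult.not_detected(cid)
    return out


def qams_concentration(
    rcf_table: RcfTable,
    reference_curve: CalibrationCurve,
    location: LocationResult | Mapping[str, PeakRecord | None],
) -> dict[str, ConcentrationResult]:
    """Single-marker concentrations from the internal reference alone.

    The reference concentration C_s comes from ``reference_curve``; each
    target compound uses its mean RCF: C_i = f_is * A_i * C_s / A_s.  The
    reference's own result is the curve inversion.

    Raises
    ------
    ConfigurationError
        If the internal-reference peak is not located, or a detected target
        compound has no RCF entry.
    """
    ref_id = reference_curve.compound_id
    detected, nd = _located_compounds(location)
    ref_peak = detected.get(ref_id)
    if ref_peak is None:
        raise ConfigurationError(
            f"internal-reference peak ({ref_id!r}) not located; "
            f"QAMS impossible for this run"
        )
    inv_s = invert_calibration(reference_curve, ref_peak.area)
    c_s, a_s = inv_s.concentration, ref_peak.area
    out: dict[str, ConcentrationResult] = {
        ref_id: ConcentrationResult.from_inversion(ref_id, inv_s)
    }
    for cid, peak in detected.items():
        if cid == ref_id:
            continue
        if cid not in rcf_table:
            raise ConfigurationError(f"no RCF for located compound {cid!r}")
        c_i = rcf_table.mean(cid) * peak.area * c_s / a_s
        flags = ("negative",) if c_i < 0 else ()
        out[cid] = ConcentrationResult(cid, c_i, flags)
    for cid in nd:
        out[cid] = ConcentrationResult.not_detected(cid)
    return out


def content_from_concentration(c_ug_ml: float, prep: SamplePrep) -> float:
    """Convert a solution concentration (µg/mL) to herb content (mg/g).

    content = C * V_extract * dilution / (m * 1000); the factor 1000 turns
    µg into mg.
    """
    return (
        c_ug_ml
        * prep.extraction_volume_ml
        * prep.dilution_factor
        / (prep.mass_g * 1000.0)
    )


def contents_for_run(
    concentrations: Mapping[str, ConcentrationResult],
    prep: SamplePrep,
    sample_id: str,
    method: str,
) -> list[ContentRecord]:
    """Convert a run's concentration map into content records."""
    records = []
    for cid, res in concentrations.items():
        content = (
            content_from_concentration(res.value, prep) if res.detected else None
        )
        records.append(
            ContentRecord(sample_id, cid, method, content, flags=res.flags)
        )
    return records


# ---------------------------------------------------------------------------
# method comparison
# ---------------------------------------------------------------------------


@dataclass
class MethodComparison:
    """Agreement report between paired ESM and QAMS contents.

    ``per_compound`` has one row per compound with columns ``n_pairs``,
    ``mean_rel_diff_pct`` (mean of (QAMS-ESM)/ESM in percent),
    ``max_abs_rel_diff_pct``, ``statistic``, ``p_value`` and
    ``significant``.  ``no_significant_difference`` is True when every
    per-compound p-value exceeds ``alpha``.
    """

    per_compound: pd.DataFrame
    n_samples: int
    alpha: float
    test: str
    skipped: tuple[str, ...] = ()

    @property
    def no_significant_difference(self) -> bool:
        return bool((self.per_compound["p_value"] > self.alpha).all())


def _paired_frame(
    esm: Iterable[ContentRecord], qams: Iterable[ContentRecord]
) -> pd.DataFrame:
    e = {(r.sample_id, r.compound_id): r.content for r in esm if r.detected}
    q = {(r.sample_id, r.compound_id): r.content for r in qams if r.detected}
    keys = sorted(set(e) & set(q))
    return pd.DataFrame(
        {
            "sample_id": [k[0] for k in keys],
            "compound_id": [k[1] for k in keys],
            "esm": [e[k] for k in keys],
            "qams": [q[k] for k in keys],
        }
    )


def compare_methods(
    esm: Iterable[ContentRecord] | pd.DataFrame,
    qams: Iterable[ContentRecord] | None = None,
    test: str = "ttest",
    alpha: float = 0.05,
) -> MethodComparison:
    """Compare paired ESM and QAMS contents per compound.

    Parameters
    ----------
    esm, qams :
        Either two lists of :class:`ContentRecord` (paired on sample and
        compound; not-detected values are dropped), or — passing ``esm``
        alone — a tidy DataFrame with columns ``sample_id``,
        ``compound_id``, ``esm``, ``qams``.
    test :
        ``"ttest"`` (paired two-sided t-test, default) or ``"wilcoxon"``
        (signed-rank).
    alpha :
        Significance level for the per-compound "significant" flag.

    Compounds with fewer than two pairs are skipped with a warning.
    """
    if isinstance(esm, pd.DataFrame):
        pairs = esm[["sample_id", "compound_id", "esm", "qams"]].dropna()
    else:
        if qams is None:
            raise ConfigurationError("qams records required when passing record lists")
        pairs = _paired_frame(esm, qams)
    if test not in ("ttest", "wilcoxon"):
        raise ConfigurationError(f"unknown test {test!r}")

    rows = []
    skipped = []
    for cid, grp in pairs.groupby("compound_id", sort=False):
        if len(grp) < 2:
            logger.warning("compound %s: <2 ESM/QAMS pairs, skipped", cid)
            skipped.append(cid)
            continue
        e = grp["esm"].to_numpy(dtype=float)
        q = grp["qams"].to_numpy(dtype=float)
        rel = (q - e) / e
        diffs = q - e
        if np.allclose(diffs, 0.0):
            stat, p = 0.0, 1.0
        elif test == "ttest":
            stat, p = stats.ttest_rel(q, e)
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                stat, p = stats.wilcoxon(q, e)
        rows.append(
            {
                "compound_id": cid,
                "n_pairs": len(grp),
                "mean_rel_diff_pct": 100.0 * float(rel.mean()),
                "max_abs_rel_diff_pct": 100.0 * float(np.abs(rel).max()),
                "statistic": float(stat),
                "p_value": float(p),
                "significant": bool(p <= alpha),
            }
        )
    per_compound = pd.DataFrame(
        rows,
        columns=[
            "compound_id",
            "n_pairs",
            "mean_rel_diff_pct",
            "max_abs_rel_diff_pct",
            "statistic",
            "p_value",
            "significant",
        ],
    ).set_index("compound_id")
    return MethodComparison(
        per_compound=per_compound,
        n_samples=int(pairs["sample_id"].nunique()),
        alpha=alpha,
        test=test,
        skipped=tuple(skipped),
    )
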