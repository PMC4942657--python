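"""Method-validation statistics: RSD reports and spike recovery.

Covers the classical HPLC validation battery: injection precision
(replicate injections of one solution), repeatability (independently
prepared samples), solution stability over a time grid, and spike recovery.
The universal dispersion metric is the relative standard deviation,
RSD% = 100 * sample SD / mean, judged against an acceptance threshold
(5 % by default).

Recovery uses the marginal form 100 * (detected - original) / added: the
fraction of the *added* analyte mass that is actually recovered on
re-analysis.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError

__all__ = ["RecoveryRow", "rsd", "recovery", "recovery_report", "validation_report",
           "ValidationReport"]

logger = logging.getLogger(__name__)

DEFAULT_RSD_THRESHOLD_PCT = 5.0
_KINDS = ("precision", "repeatability", "stability")


def rsd(values: Sequence[float]) -> float:
    """Relative standard deviation in percent: 100 * SD(n-1) / mean.

    Requires at least two values and a positive mean.
    """
    v = np.asarray(list(values), dtype=float)
    if len(v) < 2:
        raise DomainError(f"rsd needs >= 2 values, got {len(v)}")
    if not np.all(np.isfinite(v)):
        raise DomainError("rsd values must all be finite")
    mean = v.mean()
    if mean <= 0:
        raise DomainError(f"rsd needs a positive mean, got {mean!r}")
    return float(100.0 * v.std(ddof=1) / mean)


def recovery(original: float, added: float, detected: float) -> float:
    """Spike recovery in percent: 100 * (detected - original) / added.

    ``original`` is the analyte mass already present in the sample,
    ``added`` the spiked reference mass, ``detected`` the total mass found
    on re-analysis (all in the same unit).
    """
    if not (math.isfinite(added) and added > 0):
        raise DomainError(f"added must be finite and > 0, got {added!r}")
    if not (math.isfinite(original) and original >= 0):
        raise DomainError(f"original must be finite and >= 0, got {original!r}")
    if not (math.isfinite(detected) and detected >= 0):
        raise DomainError(f"detected must be finite and >= 0, got {detected!r}")
    return 100.0 * (detected - original) / added


@dataclass(frozen=True)
class RecoveryRow:
    """One compound's spike-recovery result (masses in mg)."""

    compound_id: str
    original: float
    added: float
    detected: float
    rsd_percent: float = float("nan")

    @property
    def recovery_percent(self) -> float:
        return recovery(self.original, self.added, self.detected)


def recovery_report(rows: Sequence[RecoveryRow]) -> pd.DataFrame:
    """Tabulate recovery rows: one line per compound with recovery %."""
    return pd.DataFrame(
        [
            {
                "compound_id": r.compound_id,
                "original_mg": r.original,
                "added_mg": r.added,
                "detected_mg": r.detected,
                "recovery_pct": r.recovery_percent,
                "rsd_pct": r.rsd_percent,
            }
            for r in rows
        ]
    ).set_index("compound_id")


@dataclass
class ValidationReport:
    """Per-compound RSD report for one validation experiment.

    ``table`` has columns ``n``, ``mean``, ``sd``, ``rsd_percent``,
    ``passed``; ``skipped`` lists compounds with fewer than two values.
    For stability studies ``time_grid_h`` records the analysis times.
    """

    kind: str
    table: pd.DataFrame
    threshold_percent: float
    skipped: tuple[str, ...] = ()
    time_grid_h: tuple[float, ...] | None = None

    @property
    def all_passed(self) -> bool:
        return bool(self.table["passed"].all())

    def to_text(self) -> str:
        lines = [f"{self.kind} report (RSD threshold {self.threshold_percent:g} %)"]
        for cid, row in self.table.iterrows():
            lines.append(
                f"  {cid}: n={int(row['n'])} mean={row['mean']:.4g} "
                f"RSD={row['rsd_percent']:.2f}% "
                f"{'pass' if row['passed'] else 'FAIL'}"
            )
        if self.skipped:
            lines.append(f"  skipped (single value): {', '.join(self.skipped)}")
        if self.time_grid_h is not None:
            lines.append(f"  time grid (h): {list(self.time_grid_h)}")
        return "\n".join(lines)


def validation_report(
    kind: str,
    groups: Mapping[str, Sequence[float]],
    threshold_percent: float = DEFAULT_RSD_THRESHOLD_PCT,
    time_grid_h: Sequence[float] | None = None,
) -> ValidationReport:
    """Per-compound RSD with pass/fail at a threshold.

    Parameters
    ----------
    kind :
        ``"precision"``, ``"repeatability"`` or ``"stability"``.  A
        stability report should also carry the ``time_grid_h`` the
        measurements were taken on.
    groups :
        Mapping compound id -> measured values (peak areas or contents —
        RSD is scale-invariant, so either works; label accordingly).
    """
    if kind not in _KINDS:
        raise DomainError(f"kind must be one of {_KINDS}, got {kind!r}")
    rows = []
    skipped = []
    for cid, values in groups.items():
        values = list(values)
        if len(values) < 2:
            logger.warning("%s: %s has <2 values, skipped", kind, cid)
            skipped.append(cid)
            continue
        v = np.asarray(values, dtype=float)
        r = rsd(v)
        rows.append(
            {
                "compound_id": cid,
                "n": len(v),
                "mean": float(v.mean()),
                "sd": float(v.std(ddof=1)),
                "rsd_percent": r,
                "passed": r <= threshold_percent,
            }
        )
    table = pd.DataFrame(
        rows, columns=["compound_id", "n", "mean", "sd", "rsd_percent", "passed"]
    ).set_index("compound_id")
    return ValidationReport(
        kind=kind,
        table=table,
        threshold_percent=threshold_percent,
        skipped=tuple(skipped),
        time_grid_h=tuple(time_grid_h) if time_grid_h is not None else None,
    )
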