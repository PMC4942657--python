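"""Peak identification by relative retention time (RRT).

In a single-marker assay only the internal reference substance is injected
as a pure standard, so target peaks cannot be confirmed compound by
compound.  Instead each compound carries an expected retention time
*relative to the reference peak* (t_i / t_s), which is far more stable
across instruments and columns than the absolute time.  Location proceeds
in two steps:

1. anchor: find the internal-reference peak near its expected absolute
   retention time (largest area inside a +/- window);
2. assign: for every compound, candidate peaks are those whose observed RRT
   deviates from the expected RRT by at most a relative tolerance; peaks are
   handed out greedily in order of increasing relative deviation, each peak
   to at most one compound.

The greedy smallest-deviation-first order makes the assignment independent
of compound enumeration order and resolves a merged (co-eluting) peak in
favour of the compound it sits closest to; the displaced compound is
reported as contested rather than silently mis-assigned, and an exact
deviation tie raises instead of guessing.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import pandas as pd

from .chromdata import InjectionRun, PeakRecord
from .errors import AmbiguousAssignmentError, AnchorNotFoundError, DomainError

__all__ = [
    "RrtEntry",
    "RrtReference",
    "LocationResult",
    "relative_retention",
    "locate_internal_reference",
    "locate_peaks",
    "locate_run",
]

DEFAULT_TOLERANCE_PCT = 5.0
_TIE_EPS = 1e-12


def relative_retention(t_i: float, t_s: float) -> float:
    """Relative retention time t_i / t_s (both in minutes, > 0)."""
    if not (math.isfinite(t_i) and t_i > 0):
        raise DomainError(f"t_i must be finite and > 0, got {t_i!r}")
    if not (math.isfinite(t_s) and t_s > 0):
        raise DomainError(f"t_s must be finite and > 0, got {t_s!r}")
    return t_i / t_s


@dataclass(frozen=True)
class RrtEntry:
    expected_rrt: float
    tolerance_percent: float = DEFAULT_TOLERANCE_PCT

    def __post_init__(self) -> None:
        if self.expected_rrt <= 0:
            raise ValueError("expected_rrt must be > 0")
        if self.tolerance_percent <= 0:
            raise ValueError("tolerance_percent must be > 0")


@dataclass
class RrtReference:
    """Expected RRT (and per-compound tolerance) for each compound.

    The internal reference compound itself must carry an expected RRT of
    exactly 1.
    """

    entries: dict[str, RrtEntry]
    reference_id: str = "loganin"

    def __post_init__(self) -> None:
        entry = self.entries.get(self.reference_id)
        if entry is not None and entry.expected_rrt != 1.0:
            raise ValueError(
                f"internal reference {self.reference_id!r} must have "
                f"expected_rrt exactly 1"
            )

    @classmethod
    def from_mapping(
        cls,
        expected: Mapping[str, float],
        reference_id: str = "loganin",
        tolerance_percent: float = DEFAULT_TOLERANCE_PCT,
        overrides: Mapping[str, float] | None = None,
    ) -> "RrtReference":
        overrides = overrides or {}
        entries = {
            cid: RrtEntry(rrt, overrides.get(cid, tolerance_percent))
            for cid, rrt in expected.items()
        }
        return cls(entries=entries, reference_id=reference_id)

    @classmethod
    def default(cls) -> "RrtReference":
        """The packaged reference: published mean RRTs, 5 % tolerance."""
        from .datasets import rrt_reference_data

        raw = rrt_reference_data()
        return cls.from_mapping(
            raw["expected_rrt"],
            reference_id=raw["reference_id"],
            tolerance_percent=raw["default_tolerance_percent"],
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "RrtReference":
        raw = json.loads(Path(path).read_text())
        return cls.from_mapping(
            raw["expected_rrt"],
            reference_id=raw.get("reference_id", "loganin"),
            tolerance_percent=raw.get("default_tolerance_percent", DEFAULT_TOLERANCE_PCT),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "expected_rrt": {c: e.expected_rrt for c, e in self.entries.items()},
                "tolerance_percent": {
                    c: e.tolerance_percent for c, e in self.entries.items()
                },
            }
        )


def locate_internal_reference(
    run: InjectionRun,
    expected_rt: float,
    window_percent: float = 5.0,
) -> PeakRecord:
    """Find the internal-reference (anchor) peak of a run.

    Returns the largest-area peak whose retention time lies within
    ``+/- window_percent`` of ``expected_rt``.  The reference compound is by
    far the dominant, well-characterised peak of the assay, so area is the
    tie-break inside the window.

    Raises
    ------
    AnchorNotFoundError
        If the run is empty or no peak falls inside the window; without an
        anchor, single-marker quantification is impossible for the run.
    """
    if expected_rt <= 0:
        raise DomainError("expected_rt must be > 0")
    if not run.peaks:
        raise AnchorNotFoundError(f"run {run.run_id!r} has no peaks")
    half = abs(window_percent) / 100.0 * expected_rt
    in_window = [
        p for p in run.peaks if abs(p.retention_time - expected_rt) <= half
    ]
    if not in_window:
        raise AnchorNotFoundError(
            f"run {run.run_id!r}: no peak within +/-{window_percent:g}% of "
            f"{expected_rt:g} min"
        )
    # largest area wins; exact area ties fall back to proximity
    return max(
        in_window,
        key=lambda p: (p.area, -abs(p.retention_time - expected_rt)),
    )


@dataclass
class LocationResult:
    """Outcome of assigning a run's peaks to compounds.

    ``assignment`` maps compound id -> peak for every detected compound
    (including the internal reference, mapped to the anchor).
    ``not_detected`` lists compounds with no acceptable peak;
    ``contested`` is the subset whose only candidate peak(s) were claimed by
    a closer compound — the signature of a merged, unseparated peak pair.
    """

    assignment: dict[str, PeakRecord]
    not_detected: tuple[str, ...]
    contested: tuple[str, ...]
    anchor: PeakRecord
    run_id: str = ""

    def peak(self, compound_id: str) -> PeakRecord | None:
        return self.assignment.get(compound_id)

    def detected(self) -> list[str]:
        return list(self.assignment)


def locate_peaks(
    run: InjectionRun,
    anchor: PeakRecord,
    reference: RrtReference,
) -> LocationResult:
    """Assign the peaks of ``run`` to compounds via relative retention time.

    For each compound, candidate peaks satisfy
    ``|observed_rrt - expected_rrt| / expected_rrt <= tolerance``.
    Candidates across all compounds are sorted by that relative deviation
    and granted greedily, each peak to at most one compound.  Compounds left
    without a peak are reported not-detected; those whose candidates were
    all claimed by other compounds are additionally flagged contested.

    Raises
    ------
    AmbiguousAssignmentError
        If two compounds claim the same peak with exactly equal deviation.
    ValueError
        If ``anchor`` is not a peak of ``run``.
    """
    if anchor not in run.peaks:
        raise ValueError(f"anchor peak does not belong to run {run.run_id!r}")
    t_s = anchor.retention_time

    # (deviation, compound, peak index) for every in-tolerance pair
    candidates: list[tuple[float, str, int]] = []
    for cid, entry in reference.entries.items():
        if cid == reference.reference_id:
            continue
        for idx, peak in enumerate(run.peaks):
            if peak is anchor:
                continue
            rrt = relative_retention(peak.retention_time, t_s)
            dev = abs(rrt - entry.expected_rrt) / entry.expected_rrt
            if dev <= entry.tolerance_percent / 100.0:
                candidates.append((dev, cid, idx))
    candidates.sort(key=lambda t: (t[0], t[1], t[2]))

    assignment: dict[str, PeakRecord] = {}
    claimed: dict[int, tuple[str, float]] = {}  # peak idx -> (compound, dev)
    had_candidates: set[str] = set()
    for dev, cid, idx in candidates:
        had_candidates.add(cid)
        if cid in assignment:
            continue
        if idx in claimed:
            owner, owner_dev = claimed[idx]
            if abs(dev - owner_dev) <= _TIE_EPS and owner != cid:
                raise AmbiguousAssignmentError(
                    f"run {run.run_id!r}: compounds {owner!r} and {cid!r} claim "
                    f"the same peak at {run.peaks[idx].retention_time:g} min "
                    f"with equal deviation",
                    compounds=(owner, cid),
                )
            continue
        assignment[cid] = run.peaks[idx]
        claimed[idx] = (cid, dev)

    if reference.reference_id in reference.entries:
        assignment[reference.reference_id] = anchor

    not_detected = tuple(
        cid for cid in reference.entries if cid not in assignment
    )
    contested = tuple(cid for cid in not_detected if cid in had_candidates)
    return LocationResult(
        assignment=assignment,
        not_detected=not_detected,
        contested=contested,
        anchor=anchor,
        run_id=run.run_id,
    )


def locate_run(
    run: InjectionRun,
    expected_anchor_rt: float,
    reference: RrtReference | None = None,
    window_percent: float = 5.0,
) -> tuple[InjectionRun, LocationResult]:
    """Anchor and assign a run in one step.

    Returns a copy of the run whose peaks carry their assigned compound ids,
    together with the :class:`LocationResult`.
    """
    reference = reference or RrtReference.default()
    anchor = locate_internal_reference(run, expected_anchor_rt, window_percent)
    result = locate_peaks(run, anchor, reference)
    peak_to_cid = {id(p): cid for cid, p in result.assignment.items()}
    located = InjectionRun(
        run.run_id,
        condition=run.condition,
        peaks=[
            replace(p, compound_id=peak_to_cid.get(id(p), p.compound_id))
            for p in run.peaks
        ],
        source=run.source,
    )
    return located, result
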