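"""Linear calibration curves: fitting, inversion, and (de)serialization.

The detector response of every compound is modelled as an unweighted
straight line ``area = slope * concentration + intercept`` over a validated
concentration range, fitted by ordinary least squares.  The correlation
coefficient ``r`` is the Pearson correlation of (concentration, area).

Inversion (area -> concentration) never raises for out-of-range or negative
results: quantification of real samples must proceed near range edges, so
such results are returned flagged instead.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import FitError

__all__ = [
    "CalibrationCurve",
    "InversionResult",
    "fit_calibration",
    "invert_calibration",
    "curves_to_json",
    "curves_from_json",
]

#: Fewer calibration levels than this triggers a warning (fits are still
#: produced down to the mathematical floor of 3 distinct concentrations).
RECOMMENDED_MIN_LEVELS = 6


@dataclass(frozen=True)
class CalibrationCurve:
    """A fitted linear response curve for one compound.

    Attributes
    ----------
    slope :
        Area units per µg/mL; must be positive for a usable curve.
    intercept :
        Area units at zero concentration.
    r :
        Pearson correlation coefficient of the calibration points.
    range :
        ``(low, high)`` validated concentration range in µg/mL.
    """

    compound_id: str
    slope: float
    intercept: float
    r: float
    range: tuple[float, float]

    def __post_init__(self) -> None:
        if not math.isfinite(self.slope) or self.slope <= 0:
            raise ValueError(f"{self.compound_id}: slope must be finite and > 0")
        low, high = self.range
        if not low < high:
            raise ValueError(f"{self.compound_id}: range low must be < high")
        if not -1.0 <= self.r <= 1.0:
            raise ValueError(f"{self.compound_id}: r must lie in [-1, 1]")

    def predict(self, concentration: float) -> float:
        """Expected area at ``concentration`` (µg/mL)."""
        return self.slope * concentration + self.intercept


@dataclass(frozen=True)
class InversionResult:
    """Concentration recovered from an area, with range bookkeeping.

    ``flag`` is one of ``"ok"``, ``"below_range"``, ``"above_range"`` or
    ``"negative"``; ``in_range`` is True only for ``"ok"``.
    """

    concentration: float
    in_range: bool
    flag: str


def fit_calibration(
    points: Sequence[tuple[float, float]] | Iterable[tuple[float, float]],
    compound_id: str,
) -> CalibrationCurve:
    """Fit a calibration line to (concentration, area) points by OLS.

    Parameters
    ----------
    points :
        Pairs of (concentration µg/mL, integrated area).  At least three
        distinct concentrations are required; fewer than
        :data:`RECOMMENDED_MIN_LEVELS` distinct levels emits a warning.

    Raises
    ------
    FitError
        For fewer than 3 points or a degenerate design (all concentrations
        equal).
    """
    pts = [(float(c), float(a)) for c, a in points]
    if len(pts) < 3:
        raise FitError(
            f"{compound_id}: need at least 3 calibration points, got {len(pts)}"
        )
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    n_levels = len(np.unique(x))
    if n_levels < 3:
        raise FitError(
            f"{compound_id}: need at least 3 distinct concentrations, "
            f"got {n_levels}"
        )
    if n_levels < RECOMMENDED_MIN_LEVELS:
        warnings.warn(
            f"{compound_id}: only {n_levels} distinct calibration levels "
            f"(>= {RECOMMENDED_MIN_LEVELS} recommended)",
            stacklevel=2,
        )
    res = stats.linregress(x, y)
    return CalibrationCurve(
        compound_id=compound_id,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(np.clip(res.rvalue, -1.0, 1.0)),
        range=(float(x.min()), float(x.max())),
    )


def invert_calibration(curve: CalibrationCurve, area: float) -> InversionResult:
    """Recover the concentration producing ``area`` on ``curve``.

    Returns the algebraic inverse ``(area - intercept) / slope`` together
    with a range flag; out-of-range and negative concentrations are flagged,
    never rejected.
    """
    c = (float(area) - curve.intercept) / curve.slope
    low, high = curve.range
    if c < 0:
        flag = "negative"
    elif c < low:
        flag = "below_range"
    elif c > high:
        flag = "above_range"
    else:
        flag = "ok"
    return InversionResult(concentration=c, in_range=flag == "ok", flag=flag)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def curves_to_json(
    curves: Mapping[str, CalibrationCurve], path: str | Path | None = None
) -> str:
    """Serialize curves to the JSON layout used by the packaged fixture."""
    data = {
        cid: {
            "slope": c.slope,
            "intercept": c.intercept,
            "r": c.r,
            "range": list(c.range),
        }
        for cid, c in curves.items()
    }
    text = json.dumps(data, indent=2)
    if path is not None:
        Path(path).write_text(text)
    return text


def curves_from_json(source: str | Path) -> dict[str, CalibrationCurve]:
    """Load curves from a JSON file path or JSON string."""
    if isinstance(source, Path) or (
        isinstance(source, str) and not source.lstrip().startswith("{")
    ):
        text = Path(source).read_text()
    else:
        text = source
    raw = json.loads(text)
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
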