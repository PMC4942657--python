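"""Ground-truthed synthetic chromatographic runs.

Every pipeline stage in this package is testable offline against simulated
injections whose generating parameters are known exactly.  The emulation is
phenomenological, not physical:

* detector response per compound is a straight line ``area = slope*C +
  intercept`` on the scale of the published calibration curves (intercepts
  default to zero, i.e. response through the origin);
* area noise is multiplicative lognormal with a small CV (areas stay
  positive and the CV maps directly onto the RSDs reported by replicate
  injections);
* retention times are ``base_rt`` scaled by a *common* per-run drift (the
  whole chromatogram shifts together, which is why relative retention time
  is a useful locator) plus a much smaller independent per-peak selectivity
  jitter;
* condition panels add per-condition response and retention multipliers,
  and above a temperature threshold the cornin/sweroside pair co-elutes
  into a single merged peak (sum of areas, area-weighted retention time);
* crude samples lack 5-HMF and both O-ethylmorronisides; processed samples
  contain them.

An optional per-compound RCF perturbation decouples the response of sample
runs from the calibration response: with ``rcf_perturbation_pct = p`` the
factor governing sample runs becomes ``slope_s/slope_i * (1 + delta_i)``,
``delta_i ~ U(-p%, p%)``, emulating the small systematic ESM-vs-QAMS
offsets seen when correction factors are carried across systems.  The
default is 0 (sample and standard response identical).

All randomness flows from a single integer seed; identical seeds reproduce
identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .chromdata import (
    Compound,
    InjectionRun,
    PeakRecord,
    RunCondition,
    SamplePrep,
    StandardLevel,
    default_registry,
    internal_reference,
)
from .errors import ConfigurationError

__all__ = [
    "GeneratorConfig",
    "StandardSeriesTruth",
    "SampleBatchTruth",
    "ConditionPanelTruth",
    "generate_standard_series",
    "generate_sample_batch",
    "generate_condition_panel",
]

#: Per-compound true content ranges (mg per g of herb) used for sample
#: batches, spanning the published 31-sample survey.
DEFAULT_CONTENT_RANGES: dict[str, tuple[float, float]] = {
    "gallic_acid": (0.39, 2.40),
    "hmf": (1.42, 2.43),
    "morroniside": (3.50, 14.02),
    "cornin": (0.18, 0.34),
    "sweroside": (0.66, 1.10),
    "loganin": (6.22, 8.70),
    "methylmorroniside_7a": (0.01, 0.03),
    "methylmorroniside_7b": (0.04, 0.09),
    "ethylmorroniside_7a": (0.14, 0.35),
    "ethylmorroniside_7b": (0.23, 0.38),
    "cornuside": (0.81, 1.78),
}

#: Components introduced by wine processing, absent from crude samples.
PROCESSED_ONLY: tuple[str, ...] = ("hmf", "ethylmorroniside_7a", "ethylmorroniside_7b")

# RNG sub-streams
_STREAM_RCF, _STREAM_STANDARD, _STREAM_BATCH, _STREAM_PANEL = 101, 102, 103, 104


def _default_response() -> dict[str, tuple[float, float]]:
    from .datasets import calibration_curves

    return {cid: (c.slope, 0.0) for cid, c in calibration_curves().items()}


def _default_base_rt(anchor_rt: float) -> dict[str, float]:
    from .datasets import rrt_reference_data

    expected = rrt_reference_data()["expected_rrt"]
    return {cid: rrt * anchor_rt for cid, rrt in expected.items()}


def _default_stock() -> dict[str, float]:
    from .datasets import stock_concentrations

    return stock_concentrations()


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic chromatographic system.

    Defaults emulate the published method: response slopes of the
    calibration table (intercepts zero), loganin anchored at 31.0 min with
    the other compounds at their published mean relative retention times
    inside the 50-min gradient window, 2 % area CV and 1 % common
    retention-time drift per run.
    """

    registry: list[Compound] = field(default_factory=default_registry)
    #: per-compound (slope, intercept) of the calibration-run response
    true_response: dict[str, tuple[float, float]] = field(
        default_factory=_default_response
    )
    anchor_rt: float = 31.0
    base_rt: dict[str, float] | None = None
    area_cv: float = 0.02
    #: common multiplicative retention drift per run (whole chromatogram)
    rt_jitter_cv: float = 0.01
    #: independent per-peak selectivity jitter.  Within-run apex
    #: reproducibility is much tighter than across-condition selectivity
    #: shifts (modelled by ``condition_selectivity_cv``); the default keeps
    #: 3 sigma of the relative-retention noise below half the smallest
    #: relative retention gap of the panel (~0.8 %), the regime in which
    #: location by relative retention is error-free.
    rt_selectivity_cv: float = 0.0005
    #: per-(condition, compound) response spread in condition panels
    condition_response_cv: float = 0.015
    #: per-condition common retention shift and per-compound selectivity
    condition_rt_cv: float = 0.01
    condition_selectivity_cv: float = 0.002
    #: sample-run RCF offset amplitude in percent (0 = none)
    rcf_perturbation_pct: float = 0.0
    merge_temperature_c: float = 35.0
    merge_pair: tuple[str, str] = ("cornin", "sweroside")
    stock: dict[str, float] = field(default_factory=_default_stock)
    content_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CONTENT_RANGES)
    )
    processed_only: tuple[str, ...] = PROCESSED_ONLY
    prep: SamplePrep = field(default_factory=SamplePrep)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base_rt is None:
            self.base_rt = _default_base_rt(self.anchor_rt)
        if self.area_cv < 0 or self.rt_jitter_cv < 0:
            raise ConfigurationError("noise CVs must be >= 0")
        for cid, (slope, _) in self.true_response.items():
            if slope <= 0:
                raise ConfigurationError(f"{cid}: response slope must be > 0")
        rts = [self.base_rt[c.id] for c in self.registry if c.id in self.base_rt]
        if any(later <= earlier for later, earlier in zip(rts[1:], rts[:-1])):
            raise ConfigurationError(
                "base_rt must be strictly increasing in elution order"
            )

    @property
    def reference_id(self) -> str:
        return internal_reference(self.registry).id

    def rcf_deltas(self) -> dict[str, float]:
        """Per-compound sample-run RCF offsets, drawn once per seed."""
        p = self.rcf_perturbation_pct / 100.0
        cids = [c.id for c in self.registry]
        if p == 0:
            return {cid: 0.0 for cid in cids}
        rng = np.random.default_rng([self.seed, _STREAM_RCF])
        deltas = rng.uniform(-p, p, size=len(cids))
        out = dict(zip(cids, deltas))
        out[self.reference_id] = 0.0
        return out

    def true_rcf(self) -> dict[str, float]:
        """The RCF governing sample runs: slope_s/slope_i * (1 + delta_i)."""
        s_ref = self.true_response[self.reference_id][0]
        deltas = self.rcf_deltas()
        return {
            c.id: s_ref / self.true_response[c.id][0] * (1.0 + deltas[c.id])
            for c in self.registry
        }

    def sample_response(self) -> dict[str, tuple[float, float]]:
        """(slope, intercept) governing sample runs, RCF offsets applied."""
        deltas = self.rcf_deltas()
        return {
            cid: (slope / (1.0 + deltas[cid]), intercept)
            for cid, (slope, intercept) in self.true_response.items()
        }


def _area_sigma(cv: float) -> float:
    return float(np.sqrt(np.log1p(cv**2)))


def _noisy_area(line_value: float, cv: float, rng: np.random.Generator) -> float:
    if cv == 0:
        return line_value
    return line_value * float(np.exp(rng.normal(0.0, _area_sigma(cv))))


def _emit_peaks(
    config: GeneratorConfig,
    concentrations: Mapping[str, float],
    response: Mapping[str, tuple[float, float]],
    rng: np.random.Generator,
    rt_scale: float = 1.0,
    rt_selectivity: Mapping[str, float] | None = None,
    response_scale: Mapping[str, float] | None = None,
    label: bool = True,
) -> list[PeakRecord]:
    """One injection's peaks for the given solution concentrations."""
    drift = 1.0 + (
        rng.normal(0.0, config.rt_jitter_cv) if config.rt_jitter_cv > 0 else 0.0
    )
    peaks = []
    for compound in config.registry:
        cid = compound.id
        c = concentrations.get(cid)
        if c is None:
            continue
        slope, intercept = response[cid]
        line = slope * c + intercept
        scale = response_scale.get(cid, 1.0) if response_scale else 1.0
        area = _noisy_area(max(line, 0.0) * scale, config.area_cv, rng)
        sel = 1.0 + (
            rng.normal(0.0, config.rt_selectivity_cv)
            if config.rt_selectivity_cv > 0
            else 0.0
        )
        extra = rt_selectivity.get(cid, 1.0) if rt_selectivity else 1.0
        rt = config.base_rt[cid] * drift * sel * rt_scale * extra
        peaks.append(PeakRecord(rt, area, compound_id=cid if label else None))
    return peaks


def _merge_pair(peaks: list[PeakRecord], pair: tuple[str, str]) -> list[PeakRecord]:
    """Replace the peaks of a co-eluting pair by one merged, unlabelled peak."""
    merged_members = [p for p in peaks if p.compound_id in pair]
    if len(merged_members) < 2:
        return peaks
    total = sum(p.area for p in merged_members)
    rt = sum(p.retention_time * p.area for p in merged_members) / total
    rest = [p for p in peaks if p.compound_id not in pair]
    return rest + [PeakRecord(rt, total, compound_id=None)]


# ---------------------------------------------------------------------------
# standard series
# ---------------------------------------------------------------------------


@dataclass
class StandardSeriesTruth:
    """Every generating parameter of a standard dilution series."""

    response: dict[str, tuple[float, float]]
    base_rt: dict[str, float]
    concentrations: dict[str, dict[str, float]]  # level -> compound -> µg/mL
    true_rcf: dict[str, float]
    area_cv: float
    seed: int

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(
            {
                "response": {k: list(v) for k, v in self.response.items()},
                "base_rt": self.base_rt,
                "concentrations": self.concentrations,
                "true_rcf": self.true_rcf,
                "area_cv": self.area_cv,
                "seed": self.seed,
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(text)
        return text


def generate_standard_series(
    config: GeneratorConfig,
    dilutions: Sequence[float] = (1, 2, 4, 8, 16, 32),
    replicates: int = 1,
    seed: int | None = None,
) -> tuple[list[StandardLevel], list[InjectionRun], StandardSeriesTruth]:
    """Simulate injections of the mixed standard solution at dilutions.

    The default six-level twofold series spans stock down to stock/32, the
    published calibration design (the printed linearity ranges are exactly
    stock/32 .. stock); quantifying herb samples against a shallower series
    leaves the minor components below the calibrated range, where the
    external-standard route suffers intercept-extrapolation error.

    Each dilution factor (>= 1) yields one :class:`StandardLevel` with
    concentrations ``stock / factor`` and ``replicates`` injection runs.
    Peaks come pre-labelled with their generating compound (standards are
    known mixtures); use :func:`qams.chromdata.strip_labels` to exercise
    peak location.
    """
    if any(d < 1 for d in dilutions):
        raise ConfigurationError("dilution factors must be >= 1")
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng([seed, _STREAM_STANDARD])
    levels, runs = [], []
    truth_conc: dict[str, dict[str, float]] = {}
    for d in dilutions:
        level_id = f"std_d{d:g}"
        conc = {cid: c / d for cid, c in config.stock.items()}
        levels.append(StandardLevel(level_id=level_id, concentrations=conc))
        truth_conc[level_id] = conc
        for rep in range(1, replicates + 1):
            run_id = f"{level_id}_r{rep}" if replicates > 1 else level_id
            peaks = _emit_peaks(config, conc, config.true_response, rng)
            runs.append(
                InjectionRun(run_id, peaks=peaks, source=level_id)
            )
    truth = StandardSeriesTruth(
        response=dict(config.true_response),
        base_rt=dict(config.base_rt),
        concentrations=truth_conc,
        true_rcf=config.true_rcf(),
        area_cv=config.area_cv,
        seed=seed,
    )
    return levels, runs, truth


# ---------------------------------------------------------------------------
# sample batch
# ---------------------------------------------------------------------------


@dataclass
class SampleBatchTruth:
    """True contents and concentrations behind a simulated sample batch."""

    contents: dict[str, dict[str, float]]  # sample -> compound -> mg/g
    concentrations: dict[str, dict[str, float]]  # sample -> compound -> µg/mL
    sample_type: dict[str, str]
    true_rcf: dict[str, float]
    prep: SamplePrep
    area_cv: float
    seed: int

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(
            {
                "contents": self.contents,
                "concentrations": self.concentrations,
                "sample_type": self.sample_type,
                "true_rcf": self.true_rcf,
                "prep": {
                    "mass_g": self.prep.mass_g,
                    "volume_ml": self.prep.extraction_volume_ml,
                    "dilution": self.prep.dilution_factor,
                },
                "area_cv": self.area_cv,
                "seed": self.seed,
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(text)
        return text


def generate_sample_batch(
    config: GeneratorConfig,
    n_crude: int = 21,
    n_processed: int = 10,
    seed: int | None = None,
) -> tuple[list[InjectionRun], dict[str, SamplePrep], SampleBatchTruth]:
    """Simulate a batch of herb sample injections with known true contents.

    True contents are drawn uniformly within per-compound ranges spanning
    the published sample survey; crude samples omit the processing-derived
    components (5-HMF and the two O-ethylmorronisides).  Solution
    concentrations follow from the fixed 2 g / 50 mL preparation; areas use
    the sample-run response (RCF offsets applied if configured).
    """
    if n_crude < 0 or n_processed < 0:
        raise ConfigurationError("sample counts must be >= 0")
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng([seed, _STREAM_BATCH])
    response = config.sample_response()
    prep = config.prep
    to_conc = prep.mass_g * 1000.0 / (prep.extraction_volume_ml * prep.dilution_factor)

    runs: list[InjectionRun] = []
    preps: dict[str, SamplePrep] = {}
    contents: dict[str, dict[str, float]] = {}
    concentrations: dict[str, dict[str, float]] = {}
    sample_type: dict[str, str] = {}
    kinds = [("crude", i + 1) for i in range(n_crude)] + [
        ("processed", i + 1) for i in range(n_processed)
    ]
    for kind, idx in kinds:
        sample_id = f"{kind}_{idx:02d}"
        true_content = {}
        for compound in config.registry:
            cid = compound.id
            if kind == "crude" and cid in config.processed_only:
                continue
            low, high = config.content_ranges[cid]
            true_content[cid] = float(rng.uniform(low, high))
        conc = {cid: v * to_conc for cid, v in true_content.items()}
        peaks = _emit_peaks(config, conc, response, rng)
        runs.append(InjectionRun(sample_id, peaks=peaks, source=sample_id))
        preps[sample_id] = prep
        contents[sample_id] = true_content
        concentrations[sample_id] = conc
        sample_type[sample_id] = kind
    truth = SampleBatchTruth(
        contents=contents,
        concentrations=concentrations,
        sample_type=sample_type,
        true_rcf=config.true_rcf(),
        prep=prep,
        area_cv=config.area_cv,
        seed=seed,
    )
    return runs, preps, truth


# ---------------------------------------------------------------------------
# condition panel
# ---------------------------------------------------------------------------


@dataclass
class ConditionPanelTruth:
    """Per-condition perturbations behind a ruggedness panel."""

    response_scale: dict[str, dict[str, float]]  # condition -> compound -> x
    rt_scale: dict[str, float]
    merged_conditions: tuple[str, ...]
    seed: int


def generate_condition_panel(
    config: GeneratorConfig,
    instruments: Sequence[str] = ("inst_A",),
    columns: Sequence[str] = ("col_1",),
    temperatures: Sequence[float] = (30.0,),
    flow_rates: Sequence[float] = (1.0,),
    seed: int | None = None,
    dilutions: Sequence[float] = (2, 4, 8),
) -> tuple[dict[str, list[InjectionRun]], list[StandardLevel], ConditionPanelTruth]:
    """Simulate standard injections across a grid of conditions.

    The full cross product of the four factor lists is generated; each
    condition gets one injection per dilution with its own small
    multiplicative response perturbation per compound (sized so that
    recomputed RCF RSDs stay below the 5 % acceptance threshold) and a
    common retention shift (flow rate scales retention as 1/flow).  At or
    above ``config.merge_temperature_c`` the cornin/sweroside pair is
    emitted as a single merged peak, reproducing the co-elution failure
    seen at 35 °C.
    """
    if not (instruments and columns and temperatures and flow_rates):
        raise ConfigurationError("each condition factor needs >= 1 level")
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng([seed, _STREAM_PANEL])

    levels = [
        StandardLevel(
            level_id=f"std_d{d:g}",
            concentrations={cid: c / d for cid, c in config.stock.items()},
        )
        for d in dilutions
    ]

    groups: dict[str, list[InjectionRun]] = {}
    response_scale: dict[str, dict[str, float]] = {}
    rt_scale_truth: dict[str, float] = {}
    merged: list[str] = []
    for instrument in instruments:
        for column in columns:
            for temperature in temperatures:
                for flow in flow_rates:
                    condition = RunCondition(
                        instrument=instrument,
                        column=column,
                        temperature_c=temperature,
                        flow_rate_ml_min=flow,
                    )
                    label = condition.label
                    scale = {
                        c.id: float(
                            np.exp(rng.normal(0.0, config.condition_response_cv))
                        )
                        for c in config.registry
                    }
                    rt_common = (1.0 / flow) * (
                        1.0 + rng.normal(0.0, config.condition_rt_cv)
                    )
                    rt_sel = {
                        c.id: 1.0
                        + rng.normal(0.0, config.condition_selectivity_cv)
                        for c in config.registry
                    }
                    merge = temperature >= config.merge_temperature_c
                    if merge:
                        merged.append(label)
                    cond_runs = []
                    for level in levels:
                        peaks = _emit_peaks(
                            config,
                            level.concentrations,
                            config.true_response,
                            rng,
                            rt_scale=rt_common,
                            rt_selectivity=rt_sel,
                            response_scale=scale,
                        )
                        if merge:
                            peaks = _merge_pair(peaks, config.merge_pair)
                        cond_runs.append(
                            InjectionRun(
                                f"{label}_{level.level_id}",
                                condition=condition,
                                peaks=peaks,
                                source=level.level_id,
                            )
                        )
                    groups[label] = cond_runs
                    response_scale[label] = scale
                    rt_scale_truth[label] = float(rt_common)
    truth = ConditionPanelTruth(
        response_scale=response_scale,
        rt_scale=rt_scale_truth,
        merged_conditions=tuple(merged),
        seed=seed,
    )
    return groups, levels, truth
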