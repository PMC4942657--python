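"""The synthetic run generator: determinism, truth recovery, structure."""

import numpy as np
import pytest

from qams import (
    ConfigurationError,
    GeneratorConfig,
    RcfTable,
    datasets,
    generate_condition_panel,
    generate_sample_batch,
    generate_standard_series,
    locate_run,
    qams_concentration,
    strip_labels,
)
from qams.synthetic_data import DEFAULT_CONTENT_RANGES, PROCESSED_ONLY

from conftest import fit_curves_from_series


def peaks_tuple(run):
    return tuple((p.retention_time, p.area, p.compound_id) for p in run.peaks)


class TestDeterminism:
    def test_identical_seeds_reproduce_identical_series(self):
        a = generate_standard_series(GeneratorConfig(seed=8))
        b = generate_standard_series(GeneratorConfig(seed=8))
        assert [peaks_tuple(r) for r in a[1]] == [peaks_tuple(r) for r in b[1]]
        assert a[2].to_json() == b[2].to_json()

    def test_different_seeds_differ(self):
        a = generate_standard_series(GeneratorConfig(seed=8))
        b = generate_standard_series(GeneratorConfig(seed=9))
        assert [peaks_tuple(r) for r in a[1]] != [peaks_tuple(r) for r in b[1]]

    def test_batch_and_panel_determinism(self):
        cfg = GeneratorConfig(seed=8)
        r1, _, t1 = generate_sample_batch(cfg, 3, 2)
        r2, _, t2 = generate_sample_batch(cfg, 3, 2)
        assert [peaks_tuple(r) for r in r1] == [peaks_tuple(r) for r in r2]
        assert t1.to_json() == t2.to_json()
        g1, _, _ = generate_condition_panel(cfg, instruments=("i1", "i2"))
        g2, _, _ = generate_condition_panel(cfg, instruments=("i1", "i2"))
        assert {k: [peaks_tuple(r) for r in v] for k, v in g1.items()} == {
            k: [peaks_tuple(r) for r in v] for k, v in g2.items()
        }


class TestStandardSeries:
    def test_noise_free_areas_sit_exactly_on_response_lines(self):
        cfg = GeneratorConfig(
            seed=1, area_cv=0.0, rt_jitter_cv=0.0, rt_selectivity_cv=0.0
        )
        levels, runs, truth = generate_standard_series(cfg, dilutions=(1, 2))
        lv = {l.level_id: l for l in levels}
        for run in runs:
            conc = lv[run.source].concentrations
            for p in run.peaks:
                slope, intercept = truth.response[p.compound_id]
                assert p.area == slope * conc[p.compound_id] + intercept
                assert p.retention_time == truth.base_rt[p.compound_id]

    def test_dilutions_scale_concentrations_exactly(self, stock):
        levels, _, _ = generate_standard_series(
            GeneratorConfig(seed=1), dilutions=(1, 2, 4, 8)
        )
        for level, d in zip(levels, (1, 2, 4, 8)):
            for cid, c in level.concentrations.items():
                assert c == pytest.approx(stock[cid] / d, rel=1e-15)

    def test_calibration_recovers_true_slope_within_three_se(self):
        """Slope recovery within 3 standard errors, where the SE is the
        exact sampling SE of the OLS slope under the generator's own
        multiplicative noise model (residual-based SEs underestimate under
        the heteroscedasticity + leverage of a dilution design)."""
        cfg = GeneratorConfig(seed=1)
        levels, runs, truth = generate_standard_series(cfg, replicates=3)

        lv = {l.level_id: l for l in levels}
        curves = fit_curves_from_series(levels, runs)
        for cid, curve in curves.items():
            slope_true, intercept_true = truth.response[cid]
            x = np.array([lv[r.source].concentrations[cid] for r in runs])
            dx = x - x.mean()
            sigma_i = cfg.area_cv * (slope_true * x + intercept_true)
            se = np.sqrt((dx**2 * sigma_i**2).sum()) / (dx**2).sum()
            assert abs(curve.slope - slope_true) <= 3 * se + 1e-9, cid

    def test_dilution_below_one_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_standard_series(GeneratorConfig(seed=1), dilutions=(0.5,))

    def test_mean_generated_rrt_matches_published_reference_within_1pct(self):
        cfg = GeneratorConfig(seed=6)
        _, runs, _ = generate_standard_series(cfg, dilutions=(1,), replicates=25)
        expected = datasets.rrt_reference_data()["expected_rrt"]
        observed = {cid: [] for cid in expected}
        for run in runs:
            t_s = run.peak_for("loganin").retention_time
            for p in run.peaks:
                observed[p.compound_id].append(p.retention_time / t_s)
        for cid, rrts in observed.items():
            assert np.mean(rrts) == pytest.approx(expected[cid], rel=0.01)


class TestSampleBatch:
    def test_crude_processed_split_and_presence_pattern(self):
        runs, preps, truth = generate_sample_batch(GeneratorConfig(seed=2), 21, 10)
        assert len(runs) == 31
        lacking_hmf = [r for r in runs if r.peak_for("hmf") is None]
        assert len(lacking_hmf) == 21
        for run in runs:
            kind = truth.sample_type[run.run_id]
            for cid in PROCESSED_ONLY:
                assert (run.peak_for(cid) is None) == (kind == "crude")
        assert all(p.mass_g == 2.0 and p.extraction_volume_ml == 50.0
                   for p in preps.values())

    def test_empty_batch(self):
        runs, preps, truth = generate_sample_batch(GeneratorConfig(seed=2), 0, 0)
        assert runs == [] and preps == {} and truth.contents == {}

    def test_negative_counts_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_sample_batch(GeneratorConfig(seed=2), -1, 0)

    def test_true_contents_inside_configured_ranges(self):
        _, _, truth = generate_sample_batch(GeneratorConfig(seed=3), 4, 4)
        for sample, contents in truth.contents.items():
            for cid, v in contents.items():
                low, high = DEFAULT_CONTENT_RANGES[cid]
                assert low <= v <= high

    def test_noise_free_pipeline_returns_truth_exactly(self, registry):
        """With all noise off, locate + QAMS reproduce the generating
        concentrations to floating tolerance."""
        cfg = GeneratorConfig(
            seed=4, area_cv=0.0, rt_jitter_cv=0.0, rt_selectivity_cv=0.0
        )
        levels, std_runs, truth = generate_standard_series(cfg)
        curves = fit_curves_from_series(levels, std_runs)
        from qams import rcf_from_dilution_series

        rcf_table = rcf_from_dilution_series(levels, std_runs, registry)
        runs, _, batch_truth = generate_sample_batch(cfg, 2, 2)
        for run in runs:
            located, result = locate_run(strip_labels(run), cfg.anchor_rt)
            assert not result.not_detected or all(
                cid in PROCESSED_ONLY for cid in result.not_detected
            )
            loc = {p.compound_id: p for p in located.peaks if p.compound_id}
            out = qams_concentration(rcf_table, curves["loganin"], loc)
            for cid, res in out.items():
                if not res.detected:
                    continue
                assert res.value == pytest.approx(
                    batch_truth.concentrations[run.run_id][cid], rel=1e-9
                )


class TestConditionPanel:
    def test_single_condition_is_a_standard_series(self):
        groups, levels, truth = generate_condition_panel(GeneratorConfig(seed=2))
        assert len(groups) == 1
        (runs,) = groups.values()
        assert len(runs) == len(levels) == 3
        assert truth.merged_conditions == ()

    def test_grid_shape_and_condition_metadata(self):
        groups, _, _ = generate_condition_panel(
            GeneratorConfig(seed=21),
            instruments=("i1", "i2", "i3"),
            columns=("c1", "c2", "c3"),
        )
        assert len(groups) == 9
        for label, runs in groups.items():
            assert all(r.condition.label == label for r in runs)

    def test_35C_merges_cornin_sweroside_into_one_unlabelled_peak(self):
        groups, _, truth = generate_condition_panel(
            GeneratorConfig(seed=7), temperatures=(25.0, 30.0, 35.0)
        )
        merged = [lab for lab in groups if "35C" in lab]
        assert list(truth.merged_conditions) == merged
        for lab, runs in groups.items():
            for run in runs:
                labelled = {p.compound_id for p in run.peaks if p.compound_id}
                if lab in merged:
                    assert len(run.peaks) == 10
                    assert "cornin" not in labelled and "sweroside" not in labelled
                else:
                    assert len(run.peaks) == 11

    def test_cornin_not_detected_after_location_at_35C(self):
        """Peak location on a merged-pair run: the merged apex sits by the
        larger sweroside peak, so cornin comes back not-detected."""
        cfg = GeneratorConfig(seed=7)
        groups, _, _ = generate_condition_panel(cfg, temperatures=(35.0,))
        (runs,) = groups.values()
        for run in runs:
            _, result = locate_run(strip_labels(run), cfg.anchor_rt)
            assert "cornin" in result.not_detected
            assert "cornin" in result.contested
            assert result.peak("sweroside") is not None

    def test_empty_factor_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_condition_panel(GeneratorConfig(seed=1), instruments=())


class TestRcfPerturbation:
    def test_default_true_rcf_is_slope_ratio(self):
        cfg = GeneratorConfig(seed=5)
        s = cfg.true_response["loganin"][0]
        for cid, f in cfg.true_rcf().items():
            assert f == pytest.approx(s / cfg.true_response[cid][0], rel=1e-15)

    def test_perturbation_bounded_and_seed_stable(self):
        cfg = GeneratorConfig(seed=5, rcf_perturbation_pct=5.0)
        d1, d2 = cfg.rcf_deltas(), cfg.rcf_deltas()
        assert d1 == d2
        assert d1["loganin"] == 0.0
        assert all(abs(v) <= 0.05 for v in d1.values())
        assert any(v != 0.0 for v in d1.values())
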