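import itertools
import json
import math

import numpy as np
import pytest
from sklearn.metrics import auc as sk_auc

from betaprobe.count_model import Cohort, District, Patient, Sample
from betaprobe.discrimination import AlgorithmConfig, classify_sample, \
    estimate_district_background
from betaprobe.optimization import (
    ConfusionCounts,
    GridSpec,
    RocCurve,
    UndefinedMetricError,
    auc,
    build_roc_family,
    district_split,
    enumerate_grid,
    evaluate_config,
    evaluate_fixed_sbr,
    run_full_pipeline,
    select_best,
    sensitivity_specificity,
)
from betaprobe.synthetic import CohortParams, generate_cohort

from conftest import background, measurement


class TestMetrics:
    def test_sensitivity_closed_form(self):
        sens, _ = sensitivity_specificity(ConfusionCounts(3, 5, 1, 1))
        assert sens == pytest.approx(75.0)

    def test_specificity_closed_form(self):
        _, spec = sensitivity_specificity(ConfusionCounts(3, 13, 1, 1))
        assert spec == pytest.approx(100 * 13 / 14)

    def test_empty_stratum_raises(self):
        with pytest.raises(UndefinedMetricError):
            sensitivity_specificity(ConfusionCounts(0, 5, 1, 0))
        with pytest.raises(UndefinedMetricError):
            sensitivity_specificity(ConfusionCounts(2, 0, 0, 1))


class TestGrid:
    def test_default_grid_has_504_configs(self):
        grid = GridSpec()
        assert grid.size == 504
        assert len(enumerate_grid(grid)) == 504

    def test_default_axis_sizes(self):
        grid = GridSpec()
        assert (len(grid.n_sigma_values), len(grid.eps_frac_values),
                len(grid.eps_num_values)) == (18, 4, 7)

    def test_deterministic_ordering_n_sigma_outer(self):
        configs = enumerate_grid(GridSpec())
        assert configs[0] == AlgorithmConfig(0.5, 0.05, 2)
        assert configs[1] == AlgorithmConfig(0.5, 0.05, 3)
        assert configs[7] == AlgorithmConfig(0.5, 0.10, 2)
        assert configs[28] == AlgorithmConfig(1.0, 0.05, 2)

    def test_singleton_axes(self):
        grid = GridSpec((3.0,), (0.1,), (4,))
        assert len(enumerate_grid(grid)) == 1

    def test_product_of_axis_sizes(self):
        grid = GridSpec((1, 2), (0.1, 0.2, 0.3), (2, 3, 4, 5))
        assert len(enumerate_grid(grid)) == 24

    def test_empty_or_unsorted_axes_rejected(self):
        with pytest.raises(ValueError):
            GridSpec(n_sigma_values=())
        with pytest.raises(ValueError):
            GridSpec(eps_frac_values=(0.2, 0.1))


class TestEvaluateConfig:
    def test_hand_tallied_toy_district(self, toy_district):
        # cutoff = 100 + 3 * 20/sqrt(12) = 117.32 CPS; by hand:
        # T1, T2, T3, T5 fire (TP), T4 stays at background (FN),
        # H5 at 130 fires (FP), H1-H4 stay below (TN).
        counts = evaluate_config(
            [toy_district], AlgorithmConfig(n_sigma=3, eps_frac=0.30, eps_num=4)
        )
        assert (counts.tp, counts.tn, counts.fp, counts.fn) == (4, 4, 1, 1)

    def test_extreme_cutoff_silences_everything(self, toy_district):
        counts = evaluate_config(
            [toy_district], AlgorithmConfig(n_sigma=30, eps_frac=0.05, eps_num=2)
        )
        assert (counts.tp, counts.fp) == (0, 0)
        assert counts.fn == 5 and counts.tn == 5

    def test_background_only_data_never_fires_at_30_sigma(self):
        cohort, _ = generate_cohort(CohortParams(
            seed=21, lesion_uplift=(1.0, 1.0), healthy_jitter_log_sigma=0.0,
            decay=False,
        ))
        # sanity: no count stream exceeds its district cutoff at 30 sigma
        for d in cohort.districts():
            est = estimate_district_background(d)
            cutoff = est.mean_flat + 30 * est.sigma_flat
            for s in d.samples:
                for m in s.measurements:
                    assert m.counts.max() <= cutoff
        counts = evaluate_config(
            list(cohort.districts()),
            AlgorithmConfig(n_sigma=30, eps_frac=0.05, eps_num=2),
        )
        assert counts.tp == 0 and counts.fp == 0

    def test_matches_per_sample_reclassification_oracle(self, toy_district):
        config = AlgorithmConfig(n_sigma=2, eps_frac=0.10, eps_num=3)
        est = estimate_district_background(toy_district)
        tp = tn = fp = fn = 0
        for sample in toy_district.samples:
            pred = classify_sample(sample, est, config).probe_label == "positive"
            truth = sample.pathology_label == "positive"
            tp += pred and truth
            fn += (not pred) and truth
            fp += pred and not truth
            tn += (not pred) and (not truth)
        counts = evaluate_config([toy_district], config)
        assert (counts.tp, counts.tn, counts.fp, counts.fn) == (tp, tn, fp, fn)

    def test_unknown_labels_excluded_and_counted(self, toy_district):
        from dataclasses import replace
        samples = tuple(
            s.with_label("unknown") if s.sample_id == "T1" else s
            for s in toy_district.samples
        )
        district = replace(toy_district, samples=samples)
        counts = evaluate_config(
            [district], AlgorithmConfig(n_sigma=3, eps_frac=0.30, eps_num=4)
        )
        assert counts.n_unknown == 1
        assert counts.total == 9

    def test_separable_cohort_is_perfect(self, separable_cohort):
        counts = evaluate_config(
            list(separable_cohort.districts()),
            AlgorithmConfig(n_sigma=3, eps_frac=0.05, eps_num=2),
        )
        assert counts.fp == 0 and counts.fn == 0


class TestRocFamily:
    def test_default_family_shape(self, default_cohort):
        family = build_roc_family(default_cohort)
        assert len(family) == 28
        assert all(len(c.points) == 18 for c in family)

    def test_single_pair_grid_gives_one_curve(self, default_cohort):
        grid = GridSpec(eps_frac_values=(0.05,), eps_num_values=(10,))
        family = build_roc_family(default_cohort, grid)
        assert len(family) == 1

    def test_separable_cohort_reaches_perfect_corner(self, separable_cohort):
        family = build_roc_family(separable_cohort)
        for curve in family:
            assert any(s == 100.0 and p == 100.0 for _, s, p in curve.points)
            assert curve.auc == pytest.approx(1.0)

    def test_monotonicity_enforced_on_construction(self):
        with pytest.raises(ValueError, match="monotonicity"):
            RocCurve(eps_frac=0.05, eps_num=2,
                     points=((1.0, 50.0, 50.0), (2.0, 60.0, 60.0)))

    def test_lowering_eps_thresholds_never_lowers_sensitivity(
        self, default_cohort
    ):
        districts = list(default_cohort.districts())
        for en in (2, 10):
            sens = []
            for ef in (0.05, 0.10, 0.20, 0.50):
                c = evaluate_config(
                    districts, AlgorithmConfig(n_sigma=2, eps_frac=ef, eps_num=en)
                )
                sens.append(sensitivity_specificity(c)[0])
            assert all(a >= b for a, b in zip(sens, sens[1:]))
        for ef in (0.05, 0.50):
            sens = []
            for en in (2, 3, 4, 6, 8, 10, 20):
                c = evaluate_config(
                    districts, AlgorithmConfig(n_sigma=2, eps_frac=ef, eps_num=en)
                )
                sens.append(sensitivity_specificity(c)[0])
            assert all(a >= b for a, b in zip(sens, sens[1:]))


class TestAuc:
    def test_perfect_single_point(self):
        curve = RocCurve(0.05, 2, ((3.0, 100.0, 100.0),))
        assert auc(curve) == pytest.approx(1.0)

    def test_diagonal_curve(self):
        curve = RocCurve(0.05, 2,
                         ((1.0, 80.0, 20.0), (2.0, 50.0, 50.0),
                          (3.0, 20.0, 80.0)))
        assert auc(curve) == pytest.approx(0.5)

    def test_matches_trapezoid_oracle(self):
        rng = np.random.default_rng(8)
        sens = np.sort(rng.uniform(0, 100, 5))[::-1]
        spec = np.sort(rng.uniform(0, 100, 5))
        points = tuple((float(i), float(s), float(p))
                       for i, (s, p) in enumerate(zip(sens, spec)))
        curve = RocCurve(0.05, 2, points)
        x = np.concatenate(([0.0], (100 - spec) / 100, [1.0]))
        y = np.concatenate(([0.0], sens / 100, [1.0]))
        order = np.argsort(x, kind="stable")
        assert auc(curve) == pytest.approx(sk_auc(x[order], y[order]))

    def test_bounded_in_unit_interval(self, default_cohort):
        for curve in build_roc_family(default_cohort):
            assert 0.0 <= curve.auc <= 1.0


def _point_curve(eps_frac, eps_num, sens, spec):
    return RocCurve(eps_frac, eps_num, ((1.0, sens, spec),))


class TestSelectBest:
    def test_nearest_to_ideal_corner(self):
        family = [
            _point_curve(0.05, 2, 86.0, 90.0),
            _point_curve(0.10, 3, 60.0, 95.0),
            _point_curve(0.20, 4, 100.0, 50.0),
        ]
        # distances: sqrt(296) < sqrt(1625) < 50
        best = select_best(family)
        assert (best.sensitivity, best.specificity) == (86.0, 90.0)
        assert best.distance == pytest.approx(math.sqrt(296))

    def test_single_point_family(self):
        best = select_best([_point_curve(0.05, 2, 70.0, 80.0)])
        assert (best.sensitivity, best.specificity) == (70.0, 80.0)

    def test_tie_prefers_higher_specificity(self):
        family = [
            _point_curve(0.05, 2, 95.0, 90.0),
            _point_curve(0.10, 3, 90.0, 95.0),
        ]
        best = select_best(family)
        assert (best.sensitivity, best.specificity) == (90.0, 95.0)

    def test_full_tie_lands_mid_plateau(self):
        # identical perfect points across n_sigma: the centre one is chosen
        points = tuple((ns, 100.0, 100.0) for ns in (1.0, 2.0, 3.0, 4.0, 5.0))
        best = select_best([RocCurve(0.05, 2, points)])
        assert best.config.n_sigma == 3.0

    def test_empty_family_rejected(self):
        with pytest.raises(ValueError):
            select_best([])


def _labelled_district(did, n_pos, n_neg):
    samples = []
    for i in range(n_pos):
        samples.append(Sample(f"{did}-p{i}", (measurement([200] * 5),),
                              "positive"))
    for i in range(n_neg):
        samples.append(Sample(f"{did}-n{i}", (measurement([100] * 5),),
                              "negative"))
    return District(did, (background([95, 100, 105, 98, 102]),),
                    tuple(samples))


class TestDistrictSplit:
    def test_balanced_four_district_case(self):
        # (pos, neg) per district; exhaustive enumeration shows imbalance 0
        # is attainable by pairing one of each type per side.
        specs = [(2, 1), (1, 2), (2, 1), (1, 2)]
        districts = [_labelled_district(f"D{i}", p, n)
                     for i, (p, n) in enumerate(specs)]
        cohort = Cohort((Patient("P1", 100.0, tuple(districts)),))
        best_exhaustive = min(
            abs(sum(specs[i][0] for i in range(4) if m & (1 << i))
                - sum(specs[i][0] for i in range(4) if not m & (1 << i)))
            + abs(sum(specs[i][1] for i in range(4) if m & (1 << i))
                  - sum(specs[i][1] for i in range(4) if not m & (1 << i)))
            for m in range(1, 15)
        )
        assert best_exhaustive == 0
        split = district_split(cohort, seed=0, n_candidates=200)
        assert split.imbalance == 0

    def test_two_identical_districts(self):
        districts = [_labelled_district("D0", 1, 1),
                     _labelled_district("D1", 1, 1)]
        cohort = Cohort((Patient("P1", 100.0, tuple(districts)),))
        split = district_split(cohort, seed=3, n_candidates=50)
        assert split.imbalance == 0

    def test_sample_conservation_on_synthetic_cohort(self, default_cohort):
        split = district_split(default_cohort, seed=1)
        n_total = default_cohort.n_samples()
        assert (split.train_pos + split.train_neg
                + split.test_pos + split.test_neg) == n_total
        assert set(split.train_district_ids) | set(split.test_district_ids) \
            == {d.district_id for d in default_cohort.districts()}
        assert not set(split.train_district_ids) & set(split.test_district_ids)

    def test_deterministic_given_seed(self, default_cohort):
        assert district_split(default_cohort, seed=9) == \
            district_split(default_cohort, seed=9)

    def test_single_district_cannot_split(self):
        cohort = Cohort((Patient("P1", 100.0,
                                 (_labelled_district("D0", 1, 1),)),))
        with pytest.raises(ValueError):
            district_split(cohort, seed=0)


class TestFullPipeline:
    def test_report_is_byte_identical_for_fixed_seed(self, default_cohort):
        a = run_full_pipeline(default_cohort, seed=4)
        b = run_full_pipeline(default_cohort, seed=4)
        assert json.dumps(a.to_dict(), sort_keys=True) == \
            json.dumps(b.to_dict(), sort_keys=True)

    def test_separable_cohort_perfect_on_test(self, separable_cohort):
        report = run_full_pipeline(separable_cohort, seed=2)
        conf = report.to_dict()["confusion"]["test"]
        assert conf["sensitivity_pct"] == 100.0
        assert conf["specificity_pct"] == 100.0

    def test_fixed_sbr_comparators_present(self, separable_cohort):
        report = run_full_pipeline(separable_cohort, seed=2)
        conf = report.to_dict()["confusion"]
        assert "sbr1.5" in conf and "sbr2" in conf
        # separable cohort: tumors at 2x background, healthy below 1x
        assert conf["sbr1.5"]["sensitivity_pct"] == 100.0
        assert conf["sbr1.5"]["specificity_pct"] == 100.0

    def test_auc_summary_within_unit_interval(self, default_cohort):
        report = run_full_pipeline(default_cohort, seed=4)
        d = report.to_dict()["train_auc"]
        assert 0.0 <= d["iqr"][0] <= d["median"] <= d["iqr"][1] <= 1.0
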