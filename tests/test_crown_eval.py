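"""Crown matching, commission/omission rates, area RMSE, plot sampling."""

import itertools
import math

import numpy as np
import pytest
from shapely.geometry import Point

from sahelcarbon import synthetic
from sahelcarbon.crown_eval import (
    area_class,
    area_rmse,
    error_rates,
    match_crowns,
    sample_eval_plots,
)


def circle(x, y, area):
    return Point(x, y).buffer(math.sqrt(area / math.pi), quad_segs=16)


def brute_force_best_assignment(labelled, predicted):
    """Exhaustive maximum-total-overlap one-to-one assignment (tiny instances)."""
    lab_ids, pred_ids = list(labelled), list(predicted)
    best, best_score = [], -1.0
    k = min(len(lab_ids), len(pred_ids))
    for lab_sub in itertools.permutations(lab_ids, k):
        for pred_sub in itertools.permutations(pred_ids, k):
            pairs = [
                (li, pi, labelled[li].intersection(predicted[pi]).area)
                for li, pi in zip(lab_sub, pred_sub)
            ]
            pairs = [p for p in pairs if p[2] > 0]
            score = sum(p[2] for p in pairs)
            if score > best_score:
                best, best_score = pairs, score
    return best, best_score


class TestMatching:
    def test_identical_sets_self_match(self):
        crowns = {i: circle(20.0 * i, 0.0, 10.0 + i) for i in range(5)}
        m = match_crowns(crowns, dict(crowns))
        assert len(m.pairs) == 5
        assert m.omissions == [] and m.commissions == []

    def test_unmatched_labelled_is_omission(self):
        m = match_crowns({1: circle(0, 0, 10.0)}, {})
        assert m.omissions == [1] and m.pairs == []

    def test_unmatched_predicted_is_commission(self):
        m = match_crowns({}, {7: circle(0, 0, 10.0)})
        assert m.commissions == [7]

    def test_greedy_equals_exhaustive_on_crossing_instance(self):
        rng = np.random.default_rng(5)
        labelled = {i: circle(rng.uniform(0, 12), rng.uniform(0, 12), 30.0)
                    for i in range(3)}
        predicted = {i: circle(rng.uniform(0, 12), rng.uniform(0, 12), 30.0)
                     for i in range(3)}
        m = match_crowns(labelled, predicted)
        _, best_score = brute_force_best_assignment(labelled, predicted)
        greedy_score = sum(p[2] for p in m.pairs)
        assert greedy_score == pytest.approx(best_score, rel=1e-9)

    def test_clumped_prediction_counts_extra_labels_as_omissions(self):
        labelled = {0: circle(0, 0, 20.0), 1: circle(6, 0, 20.0)}
        predicted = {0: circle(3, 0, 120.0)}  # one blob over both labels
        m = match_crowns(labelled, predicted)
        assert len(m.pairs) == 1
        assert len(m.omissions) == 1
        assert m.commissions == []

    def test_count_conservation(self):
        rng = np.random.default_rng(0)
        labelled = {i: circle(rng.uniform(0, 100), rng.uniform(0, 100), 15.0)
                    for i in range(20)}
        predicted = {i: circle(rng.uniform(0, 100), rng.uniform(0, 100), 15.0)
                     for i in range(25)}
        m = match_crowns(labelled, predicted)
        assert len(m.pairs) + len(m.omissions) == 20
        assert len(m.pairs) + len(m.commissions) == 25

    def test_swap_symmetry(self):
        rng = np.random.default_rng(3)
        a = {i: circle(rng.uniform(0, 50), rng.uniform(0, 50), 12.0) for i in range(10)}
        b = {i: circle(rng.uniform(0, 50), rng.uniform(0, 50), 12.0) for i in range(14)}
        fwd, rev = match_crowns(a, b), match_crowns(b, a)
        assert len(fwd.omissions) == len(rev.commissions)
        assert len(fwd.commissions) == len(rev.omissions)
        assert len(fwd.pairs) == len(rev.pairs)

    def test_invalid_geometry_rejected(self):
        from shapely.geometry import Polygon
        bowtie = Polygon([(0, 0), (2, 2), (2, 0), (0, 2)])
        with pytest.raises(ValueError):
            match_crowns({0: bowtie}, {})


class TestRates:
    def test_planted_rates(self):
        plots = synthetic.gen_eval_fixture(1000, 0.049, 0.027, seed=1)
        r = error_rates([match_crowns(p.labelled, p.predicted) for p in plots])
        assert r.commission_rate == pytest.approx(0.049, abs=1e-15)
        assert r.omission_rate == pytest.approx(0.027, abs=1e-15)
        assert r.net_rate == pytest.approx(0.022, abs=1e-15)

    def test_perfect_fixture(self):
        plots = synthetic.gen_eval_fixture(100, 0.0, 0.0, seed=2)
        r = error_rates([match_crowns(p.labelled, p.predicted) for p in plots])
        assert (r.commission_rate, r.omission_rate, r.net_rate) == (0.0, 0.0, 0.0)

    def test_single_plot_direct_counts(self):
        labelled = {i: circle(30.0 * i, 0, 10.0) for i in range(9)}
        predicted = dict(labelled)
        predicted[99] = circle(1000.0, 0, 10.0)  # spurious
        r = error_rates([match_crowns(labelled, predicted)])
        assert r.n_labelled == 9 and r.n_predicted == 10
        assert r.commission_rate == pytest.approx(1 / 9)
        assert r.omission_rate == 0.0
        assert r.commission_rate_predicted == pytest.approx(0.1)

    def test_pooling_is_plot_order_invariant(self):
        plots = synthetic.gen_eval_fixture(200, 0.2, 0.1, seed=3)
        plots += synthetic.gen_eval_fixture(300, 0.0, 0.2, seed=4)
        ms = [match_crowns(p.labelled, p.predicted) for p in plots]
        assert error_rates(ms) == error_rates(ms[::-1])

    def test_per_class_counts_cover_all_classes(self):
        plots = synthetic.gen_eval_fixture(500, 0.049, 0.027, seed=5)
        r = error_rates([match_crowns(p.labelled, p.predicted) for p in plots])
        assert sum(c["n_labelled"] for c in r.per_class.values()) == 500
        assert area_class(10.0) == "0-15"
        assert area_class(250.0) == ">200"

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            error_rates([])


class TestAreaRmse:
    def test_perfect_areas(self):
        crowns = {i: circle(30.0 * i, 0, 10.0) for i in range(4)}
        assert area_rmse(match_crowns(crowns, dict(crowns))) == pytest.approx(0.0)

    def test_single_missed_tree(self):
        m = match_crowns({0: circle(0, 0, 10.0)}, {})
        assert area_rmse(m) == pytest.approx(circle(0, 0, 10.0).area, rel=1e-9)

    def test_two_trees_hand_arithmetic(self):
        # matched areas differ by 2 and 0 -> RMSE = sqrt((4+0)/2) = sqrt(2)
        labelled = {0: circle(0, 0, 10.0), 1: circle(50, 0, 20.0)}
        a0, a1 = labelled[0].area, labelled[1].area
        predicted = {0: circle(0, 0, 10.0).buffer(0), 1: circle(50, 0, 20.0)}
        m = match_crowns(labelled, predicted)
        m.predicted_areas[0] = a0 + 2.0  # perturb the recorded area directly
        assert area_rmse(m) == pytest.approx(math.sqrt(2.0), rel=1e-12)

    def test_undefined_without_labels(self):
        with pytest.raises(ValueError):
            area_rmse(match_crowns({}, {0: circle(0, 0, 5.0)}))


class TestPlotSampling:
    def test_full_wet_bias(self, small_landscape):
        _, rainfall, crowns = small_landscape
        plots = sample_eval_plots(rainfall, crowns, 20, wet_bias=1.0, seed=0)
        assert plots and all(p.rainfall >= 200.0 for p in plots)

    def test_wet_fraction_within_binomial_interval(self, small_landscape):
        _, rainfall, crowns = small_landscape
        plots = sample_eval_plots(
            rainfall, crowns, 300, wet_bias=0.8, seed=1, drop_empty=False
        )
        wet = np.mean([p.rainfall >= 200.0 for p in plots])
        # 99% binomial interval around 0.8 at n=300
        half = 2.576 * math.sqrt(0.8 * 0.2 / 300)
        assert abs(wet - 0.8) < half

    def test_all_dry_landscape_degrades_gracefully(self):
        config = synthetic.LandscapeConfig(
            extent=(0.0, 0.0, 1000.0, 500.0), rainfall_west=50.0, rainfall_east=120.0,
            seed=9,
        )
        rainfall, crowns = synthetic.gen_landscape(config)
        plots = sample_eval_plots(rainfall, crowns, 10, wet_bias=0.8, seed=2,
                                  drop_empty=False)
        assert all(p.rainfall < 200.0 for p in plots)

    def test_rejects_nonpositive_count(self, small_landscape):
        _, rainfall, crowns = small_landscape
        with pytest.raises(ValueError):
            sample_eval_plots(rainfall, crowns, 0)
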