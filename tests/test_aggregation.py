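"""Unit and property tests for the discrepancy-weighted aggregation rule."""

import math

import numpy as np
import pytest
from hypothesis import assume, given, settings, strategies as st

from fedhetero.aggregation import (
    AggregationWeights,
    DiscoConfig,
    LabelDistribution,
    aggregate_params,
    disco_weights,
    fedavg_weights,
    label_discrepancy,
    representation_discrepancy,
)
from fedhetero.params import ParamVector

from conftest import make_report


def simplex(n):
    """Hypothesis strategy for an n-class probability vector."""
    return st.lists(
        st.floats(0.01, 1.0, allow_nan=False), min_size=n, max_size=n
    ).map(lambda xs: np.array(xs) / np.sum(xs))


class TestLabelDiscrepancy:
    @pytest.mark.parametrize(
        "dist, target, expected, tol",
        [
            ([0.5, 0.5], [0.5, 0.5], 0.0, 1e-12),
            ([1.0, 0.0], [0.5, 0.5], math.log(2), 1e-12),
            # 71% positive prevalence against the uniform target
            ([0.71, 0.29], [0.5, 0.5], 0.0910, 5e-5),
        ],
    )
    def test_known_values(self, dist, target, expected, tol):
        d = label_discrepancy(LabelDistribution(dist), LabelDistribution(target))
        assert d == pytest.approx(expected, abs=tol)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="lengths differ"):
            label_discrepancy(
                LabelDistribution([0.5, 0.5]), LabelDistribution([1 / 3] * 3)
            )

    def test_zero_target_mass_rejected(self):
        with pytest.raises(ValueError, match="zero mass"):
            label_discrepancy(
                LabelDistribution([0.5, 0.5]), LabelDistribution([1.0, 0.0])
            )

    def test_zero_target_ok_where_dist_is_zero(self):
        assert label_discrepancy(
            LabelDistribution([0.0, 1.0]), LabelDistribution([0.0, 1.0])
        ) == 0.0

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(p=simplex(3), q=simplex(3))
    def test_nonnegative_zero_iff_equal(self, p, q):
        d = label_discrepancy(LabelDistribution(p), LabelDistribution(q))
        assert d >= 0.0
        if np.allclose(p, q, atol=1e-15):
            assert d <= 1e-12
        d_self = label_discrepancy(LabelDistribution(p), LabelDistribution(p))
        assert abs(d_self) <= 1e-12


class TestRepresentationDiscrepancy:
    def test_identical_is_zero(self):
        v = np.array([1.0, -2.0, 3.0])
        assert representation_discrepancy(v, v) == pytest.approx(0.0, abs=1e-15)

    def test_antiparallel_is_two(self):
        v = np.array([1.0, -2.0, 3.0])
        assert representation_discrepancy(v, -v) == pytest.approx(2.0)

    def test_orthogonal_is_one(self):
        assert representation_discrepancy([1.0, 0.0], [0.0, 1.0]) == pytest.approx(1.0)

    def test_zero_norm_gives_zero(self):
        assert representation_discrepancy([0.0, 0.0], [1.0, 2.0]) == 0.0
        assert representation_discrepancy([1.0, 2.0], [0.0, 0.0]) == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            representation_discrepancy([1.0], [1.0, 2.0])

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(
        v=st.lists(st.floats(-5, 5), min_size=3, max_size=3),
        c=st.floats(1e-3, 1e3),
    )
    def test_scale_invariance(self, v, c):
        v = np.array(v)
        assume(np.linalg.norm(v) > 1e-6)
        ref = np.array([1.0, 2.0, -1.0])
        assert representation_discrepancy(c * v, ref) == pytest.approx(
            representation_discrepancy(v, ref), abs=1e-9
        )

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(
        v=st.lists(st.floats(-5, 5), min_size=4, max_size=4),
        w=st.lists(st.floats(-5, 5), min_size=4, max_size=4),
    )
    def test_bounded_in_0_2(self, v, w):
        d = representation_discrepancy(np.array(v), np.array(w))
        assert 0.0 <= d <= 2.0


def _cohort_reports(head=(1.0, 0.0)):
    return [
        make_report("ukb", 180, [0.29, 0.71], head),
        make_report("berlin", 163, [0.31, 0.69], head),
        make_report("goettingen", 203, [0.36, 0.64], head),
    ]


class TestDiscoWeights:
    def test_zero_config_gives_size_fractions(self):
        reports = _cohort_reports()
        w = disco_weights(reports, np.array([1.0, 0.0]), DiscoConfig.fedavg())
        assert w.weights["ukb"] == pytest.approx(0.32967, abs=1e-5)
        assert w.weights["berlin"] == pytest.approx(0.29853, abs=1e-5)
        assert w.weights["goettingen"] == pytest.approx(0.37179, abs=1e-5)

    def test_symmetric_clients_share_weight(self):
        reports = [
            make_report(f"c{i}", 50, [0.4, 0.6], (1.0, 2.0)) for i in range(4)
        ]
        w = disco_weights(
            reports, np.array([0.5, 0.5]), DiscoConfig(a=1.0, b=0.3, gamma=2.0)
        )
        for v in w.weights.values():
            assert v == pytest.approx(0.25, abs=1e-12)

    def test_relu_clips_negative_scores(self):
        # two clients n~ = 0.5 each, d = (0.6, 0.1), a=1, b=0, gamma=0:
        # scores ReLU(0.5-0.6)=0 and ReLU(0.5-0.1)=0.4 -> weights (0, 1)
        target = LabelDistribution([0.5, 0.5])
        d_hi = [0.9815, 0.0185]  # KL approx 0.6 nats
        d_lo = [0.72, 0.28]  # KL approx 0.1 nats
        assert label_discrepancy(LabelDistribution(d_hi), target) == pytest.approx(0.6, abs=5e-3)
        assert label_discrepancy(LabelDistribution(d_lo), target) == pytest.approx(0.1, abs=5e-3)
        reports = [
            make_report("hi", 100, d_hi, (1.0, 0.0)),
            make_report("lo", 100, d_lo, (1.0, 0.0)),
        ]
        w = disco_weights(
            reports, np.array([1.0, 0.0]), DiscoConfig(a=1.0, b=0.0, gamma=0.0)
        )
        assert w.weights["hi"] == 0.0
        assert w.weights["lo"] == pytest.approx(1.0)
        assert not w.fallback_used

    def test_all_zero_scores_fall_back_to_sample_size(self):
        reports = _cohort_reports()
        cfg = DiscoConfig(a=100.0, b=-10.0, gamma=0.0)
        w = disco_weights(reports, np.array([1.0, 0.0]), cfg)
        assert w.fallback_used
        assert w.weights["ukb"] == pytest.approx(180 / 546)

    def test_fallback_policies(self):
        reports = _cohort_reports()
        cfg = DiscoConfig(a=100.0, b=-10.0, gamma=0.0, fallback="uniform")
        w = disco_weights(reports, np.array([1.0, 0.0]), cfg)
        assert all(v == pytest.approx(1 / 3) for v in w.weights.values())
        cfg = DiscoConfig(a=100.0, b=-10.0, gamma=0.0, fallback="error")
        with pytest.raises(ArithmeticError):
            disco_weights(reports, np.array([1.0, 0.0]), cfg)

    def test_empty_reports_rejected(self):
        with pytest.raises(ValueError):
            disco_weights([], np.array([1.0]), DiscoConfig.fedavg())
        with pytest.raises(ValueError):
            fedavg_weights([])

    def test_raw_count_mode(self):
        reports = _cohort_reports()
        cfg = DiscoConfig(a=0.0, b=0.0, gamma=0.0, normalize_sizes=False)
        w = disco_weights(reports, np.array([1.0, 0.0]), cfg)
        # raw counts normalize to the same fractions when a=b=gamma=0
        assert w.weights["goettingen"] == pytest.approx(203 / 546, abs=1e-12)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        sizes=st.lists(st.integers(1, 500), min_size=1, max_size=5),
        a=st.floats(0, 5),
        b=st.floats(-0.5, 2),
        gamma=st.floats(0, 5),
        seed=st.integers(0, 1000),
    )
    def test_weights_always_on_simplex(self, sizes, a, b, gamma, seed):
        rng = np.random.default_rng(seed)
        reports = []
        for i, n in enumerate(sizes):
            p = rng.dirichlet([1.0, 1.0])
            head = rng.normal(size=3)
            reports.append(make_report(f"c{i}", n, p, head))
        w = disco_weights(reports, rng.normal(size=3), DiscoConfig(a=a, b=b, gamma=gamma))
        vals = np.array(list(w.weights.values()))
        assert np.all(vals >= 0)
        assert vals.sum() == pytest.approx(1.0, abs=1e-9)

    def test_matches_brute_force_oracle(self):
        """Independently recompute scores for small federations to 1e-12."""
        rng = np.random.default_rng(7)
        target = LabelDistribution([0.5, 0.5])
        for _ in range(25):
            k = rng.integers(2, 5)
            ns = rng.integers(1, 30, size=k)
            dists = rng.dirichlet([2.0, 2.0], size=k)
            heads = rng.normal(size=(k, 4))
            theta_ref = rng.normal(size=4)
            a, b, g = rng.uniform(0, 2, size=3)
            reports = [
                make_report(f"c{i}", int(ns[i]), dists[i], heads[i]) for i in range(k)
            ]
            w = disco_weights(reports, theta_ref, DiscoConfig(a=a, b=b, gamma=g))
            # oracle: literal transcription of the scoring rule
            scores = []
            for i in range(k):
                p = dists[i]
                kl = sum(pc * math.log(pc / 0.5) for pc in p if pc > 0)
                cos = float(heads[i] @ theta_ref) / (
                    np.linalg.norm(heads[i]) * np.linalg.norm(theta_ref)
                )
                s = ns[i] / ns.sum() - a * kl - g * (1 - cos) + b
                scores.append(max(0.0, s))
            total = sum(scores)
            if total == 0:
                continue
            for i in range(k):
                assert w.weights[f"c{i}"] == pytest.approx(scores[i] / total, abs=1e-12)

    def test_monotone_in_label_discrepancy(self):
        """Raising one client's label skew never raises its weight."""
        target_head = np.array([1.0, 0.0])
        prev_weight = None
        for p_pos in (0.5, 0.6, 0.7, 0.8, 0.9):
            reports = [
                make_report("skewed", 100, [1 - p_pos, p_pos], (1.0, 0.0)),
                make_report("other", 100, [0.5, 0.5], (1.0, 0.0)),
            ]
            w = disco_weights(reports, target_head, DiscoConfig(a=1.0, b=0.2, gamma=0.0))
            if prev_weight is not None:
                assert w.weights["skewed"] <= prev_weight + 1e-12
            prev_weight = w.weights["skewed"]

    def test_monotone_in_representation_drift(self):
        theta_ref = np.array([1.0, 0.0])
        prev_weight = None
        for angle in np.linspace(0, np.pi, 7):
            head = (math.cos(angle), math.sin(angle))
            reports = [
                make_report("drifting", 100, [0.5, 0.5], head),
                make_report("other", 100, [0.5, 0.5], (1.0, 0.0)),
            ]
            w = disco_weights(reports, theta_ref, DiscoConfig(a=0.0, b=0.5, gamma=0.5))
            if prev_weight is not None:
                assert w.weights["drifting"] <= prev_weight + 1e-12
            prev_weight = w.weights["drifting"]


class TestFedavgWeights:
    @pytest.mark.parametrize(
        "sizes, expected",
        [
            ((1, 1, 1), (1 / 3, 1 / 3, 1 / 3)),
            ((180, 163, 203), (0.32967, 0.29853, 0.37179)),
            ((42,), (1.0,)),
        ],
    )
    def test_size_proportional(self, sizes, expected):
        reports = [
            make_report(f"c{i}", n, [0.5, 0.5], (1.0, 0.0)) for i, n in enumerate(sizes)
        ]
        w = fedavg_weights(reports)
        for i, e in enumerate(expected):
            assert w.weights[f"c{i}"] == pytest.approx(e, abs=1e-5)


class TestAggregateParams:
    def test_single_client_identity(self):
        r = make_report("only", 10, [0.5, 0.5], (1.0, 2.0, 3.0))
        w = fedavg_weights([r])
        out = aggregate_params([r], w)
        np.testing.assert_array_equal(out.values, r.params.values)

    def test_convex_combination(self):
        r0 = make_report("a", 1, [0.5, 0.5], (0.0,), backbone=())
        r4 = make_report("b", 3, [0.5, 0.5], (4.0,), backbone=())
        w = AggregationWeights(weights={"a": 0.25, "b": 0.75})
        out = aggregate_params([r0, r4], w)
        assert out.values[0] == pytest.approx(3.0)

    def test_identical_inputs_are_fixed_point(self):
        reports = [make_report(f"c{i}", i + 1, [0.5, 0.5], (1.0, -2.0)) for i in range(3)]
        w = AggregationWeights(weights={"c0": 0.2, "c1": 0.5, "c2": 0.3})
        out = aggregate_params(reports, w)
        np.testing.assert_allclose(out.values, reports[0].params.values, atol=1e-15)

    def test_excluded_segment_keeps_reference_values(self):
        segments = {"backbone": (0, 2), "norm": (2, 4), "head": (4, 6)}
        ref = ParamVector(np.arange(6, dtype=float), segments)
        reports = []
        from fedhetero.aggregation import ClientReport

        for i in range(2):
            reports.append(
                ClientReport(
                    client_id=f"c{i}",
                    params=ParamVector(np.full(6, float(i + 10)), segments),
                    n_train=5,
                    label_dist=LabelDistribution([0.5, 0.5]),
                )
            )
        w = AggregationWeights(weights={"c0": 0.5, "c1": 0.5})
        out = aggregate_params(reports, w, exclude_segments=("norm",), reference=ref)
        np.testing.assert_array_equal(out.values[2:4], ref.values[2:4])
        np.testing.assert_allclose(out.values[0:2], 10.5)

    def test_weight_report_mismatch_rejected(self):
        r = make_report("a", 1, [0.5, 0.5], (0.0,))
        w = AggregationWeights(weights={"b": 1.0})
        with pytest.raises(ValueError):
            aggregate_params([r], w)


class TestWeightValidation:
    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            AggregationWeights(weights={"a": -0.1, "b": 1.1})

    def test_non_simplex_rejected(self):
        with pytest.raises(ValueError):
            AggregationWeights(weights={"a": 0.5, "b": 0.6})
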