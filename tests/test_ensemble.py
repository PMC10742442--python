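"""Ensemble metrics: pooling, pairwise Jensen-Shannon divergences,
incoherence and cohesion, checked against hand evaluations, an
independent brute-force summation oracle and scipy's JSD."""

import json
import math
import warnings
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import jensenshannon

from cohesion.ensemble import (
    Ensemble,
    EnsembleReport,
    KindMismatchError,
    Sample,
    analyse_ensemble,
    cohesion,
    divergence_set,
    incoherence,
    pairwise_jsd,
    pooled_distribution,
)

LN2 = math.log(2)


def categorical(id_, *counts):
    return Sample(id=id_, counts={chr(97 + i): c for i, c in enumerate(counts)})


# ---------------------------------------------------------------- oracles

def oracle_entropy(p):
    return -sum(x * math.log(x) for x in p if x > 0)


def oracle_jsd(pa, pb, wa, wb):
    mix = [wa * a + wb * b for a, b in zip(pa, pb)]
    return oracle_entropy(mix) - wa * oracle_entropy(pa) - wb * oracle_entropy(pb)


def oracle_incoherence(vectors, weights):
    pool = [sum(w * v[j] for w, v in zip(weights, vectors)) for j in range(len(vectors[0]))]
    h_pool = oracle_entropy(pool)
    s = sum(w * (h_pool - oracle_entropy(v)) ** 2 for w, v in zip(weights, vectors))
    return math.sqrt(s / h_pool)


# ------------------------------------------------------------------ tests

class TestSampleAndEnsemble:
    def test_sample_needs_exactly_one_payload(self):
        with pytest.raises(ValueError):
            Sample(id="x")
        with pytest.raises(ValueError):
            Sample(id="x", observations=(1.0,), counts={"a": 1})
        with pytest.raises(ValueError):
            Sample(id="x", counts={"a": 0.0})

    def test_mixed_kinds_rejected(self):
        with pytest.raises(KindMismatchError):
            Ensemble((Sample(id="a", observations=(1.0,)), categorical("b", 1)))

    def test_weights_sum_to_one(self):
        e = Ensemble(
            (categorical("a", 3, 0), categorical("b", 0, 1)), weighting="proportional"
        )
        assert e.weights().sum() == pytest.approx(1.0, abs=1e-12)
        assert e.weights() == pytest.approx([0.75, 0.25])


class TestPooledDistribution:
    def test_symmetric_mixture(self):
        assert pooled_distribution([[1, 0], [0, 1]]) == pytest.approx([0.5, 0.5])

    def test_identical_samples_unchanged(self):
        p = [0.3, 0.7]
        assert pooled_distribution([p, p, p], [0.2, 0.5, 0.3]) == pytest.approx(p)

    def test_proportional_weighting_by_hand(self):
        e = Ensemble(
            (categorical("a", 3, 0), categorical("b", 0, 1)), weighting="proportional"
        )
        pool = pooled_distribution(e.probability_vectors(), e.weights())
        assert pool == pytest.approx([0.75, 0.25])


class TestIncoherence:
    def test_identical_samples_give_zero(self):
        e = Ensemble(tuple(categorical(str(i), 2, 5) for i in range(4)))
        assert incoherence(e) == 0.0

    def test_disjoint_pair_base2_is_one(self):
        e = Ensemble((categorical("a", 1, 0), categorical("b", 0, 1)))
        assert incoherence(e, base=2) == pytest.approx(1.0, abs=1e-12)

    def test_unrooted_is_square_of_rooted(self):
        e = Ensemble((categorical("a", 3, 1), categorical("b", 1, 4), categorical("c", 2, 2)))
        r = incoherence(e, rooted=True)
        assert incoherence(e, rooted=False) == pytest.approx(r**2, rel=1e-12)

    def test_degenerate_pool_warns_and_returns_zero(self):
        e = Ensemble((categorical("a", 5), categorical("b", 3)))
        with pytest.warns(UserWarning):
            assert incoherence(e) == 0.0


class TestPairwiseJSD:
    def test_self_divergence_is_zero(self):
        a = categorical("a", 2, 3)
        assert pairwise_jsd(a, categorical("b", 2, 3)) == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_supports_reach_ln2(self):
        d = pairwise_jsd(categorical("a", 1, 0), categorical("b", 0, 1))
        assert d == pytest.approx(LN2, abs=1e-12)

    def test_hand_evaluated_pair(self):
        # [1,0] vs [.5,.5] at w=1/2: pooled [.75,.25], 0.311278 bits
        d = pairwise_jsd(categorical("a", 2, 0), categorical("b", 1, 1))
        assert d / LN2 == pytest.approx(0.3112781244591328, abs=1e-12)

    @given(
        st.lists(st.integers(min_value=0, max_value=50), min_size=2, max_size=6),
        st.lists(st.integers(min_value=0, max_value=50), min_size=2, max_size=6),
    )
    @settings(derandomize=True, max_examples=150, deadline=None)
    def test_symmetry_nonnegativity_and_ln2_bound(self, ca, cb):
        n = max(len(ca), len(cb))
        ca = ca + [0] * (n - len(ca))
        cb = cb + [0] * (n - len(cb))
        if sum(ca) == 0 or sum(cb) == 0:
            return
        a, b = categorical("a", *ca), categorical("b", *cb)
        d_ab = pairwise_jsd(a, b)
        d_ba = pairwise_jsd(b, a)
        assert d_ab == pytest.approx(d_ba, abs=1e-12)
        assert 0.0 <= d_ab <= LN2 + 1e-12

    def test_matches_scipy_jensenshannon(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            pa = rng.dirichlet(np.ones(4))
            pb = rng.dirichlet(np.ones(4))
            a = Sample(id="a", counts={str(i): v for i, v in enumerate(pa)})
            b = Sample(id="b", counts={str(i): v for i, v in enumerate(pb)})
            ours = pairwise_jsd(a, b)
            reference = jensenshannon(pa, pb) ** 2  # scipy returns the sqrt, in nats
            assert ours == pytest.approx(reference, abs=1e-10)


class TestDivergenceSet:
    def test_identical_samples_normalise_to_zero(self):
        e = Ensemble(tuple(categorical(str(i), 1, 1) for i in range(3)))
        d = divergence_set(e)
        assert list(d.normalised) == [0.0, 0.0, 0.0]

    def test_disjoint_pair_normalises_to_one(self):
        e = Ensemble((categorical("a", 1, 0), categorical("b", 0, 1)))
        assert divergence_set(e).normalised == (1.0,)

    def test_pair_count_is_k_choose_2(self):
        e = Ensemble(tuple(categorical(str(i), i + 1, 1) for i in range(30)))
        assert len(divergence_set(e).pairs) == 435


class TestCohesion:
    def test_identical_samples_are_maximally_cohesive(self, dv_params):
        e = Ensemble(tuple(categorical(str(i), 4, 1) for i in range(5)))
        assert cohesion(e, dv_params) == 1.0

    def test_even_divergence_spread_destroys_cohesion(self, dv_params):
        from cohesion.entropy import density_variance_entropy

        h = density_variance_entropy(np.linspace(0, 1, 100_000), dv_params)
        assert (1 - h) ** 2 == pytest.approx(0.0, abs=1e-9)

    def test_two_scenario_gaussians(self, dv_params, two_scenario_samples):
        values = [
            cohesion(Ensemble(two_scenario_samples(seed)), dv_params)
            for seed in range(10)
        ]
        assert 0.7 < np.median(values) < 0.9

    def test_incoherent_implies_incohesive_coupling(self, dv_params):
        # a coherent ensemble (I == 0 via identical samples) must be
        # maximally cohesive
        e = Ensemble(tuple(categorical(str(i), 3, 3, 1) for i in range(4)))
        assert incoherence(e) == 0.0
        assert cohesion(e, dv_params) == 1.0


class TestBruteForceOracle:
    """Incoherence and divergence recomputed by independent direct
    summation on small categorical ensembles."""

    def test_agreement_to_1e12(self):
        rng = np.random.default_rng(99)
        for _ in range(25):
            k = int(rng.integers(2, 5))
            counts = rng.integers(0, 8, size=(k, 3))
            counts[counts.sum(axis=1) == 0, 0] = 1
            samples = tuple(categorical(str(i), *row) for i, row in enumerate(counts))
            e = Ensemble(samples)
            vectors = [row / row.sum() for row in counts.astype(float)]
            weights = [1.0 / k] * k

            for (i, j) in combinations(range(k), 2):
                expected = oracle_jsd(vectors[i], vectors[j], 0.5, 0.5)
                got = pairwise_jsd(samples[i], samples[j])
                assert got == pytest.approx(expected, abs=1e-12)

            pool = pooled_distribution(np.array(vectors), weights)
            if oracle_entropy(pool) > 0:
                assert incoherence(e) == pytest.approx(
                    oracle_incoherence(vectors, weights), abs=1e-12
                )


class TestAnalyseEnsemble:
    def test_report_is_internally_consistent(self, dv_params):
        e = Ensemble(
            (categorical("a", 5, 1), categorical("b", 1, 5), categorical("c", 3, 3))
        )
        rep = analyse_ensemble(e, dv_params)
        assert rep.cohesion == pytest.approx((1 - rep.h_g) ** 2, abs=1e-12)
        assert rep.incoherence == pytest.approx(incoherence(e), abs=1e-12)
        assert rep.incoherence_unrooted == pytest.approx(rep.incoherence**2, rel=1e-12)
        assert len(rep.divergences_raw) == 3

    def test_json_round_trip(self, dv_params):
        e = Ensemble((categorical("a", 2, 1), categorical("b", 1, 2)))
        rep = analyse_ensemble(e, dv_params)
        back = EnsembleReport.from_dict(json.loads(rep.to_json()))
        assert back.to_dict() == rep.to_dict()

    def test_identical_ensemble_anchor(self, dv_params):
        e = Ensemble(tuple(categorical(str(i), 2, 7) for i in range(6)))
        rep = analyse_ensemble(e, dv_params)
        assert rep.incoherence == 0.0
        assert rep.cohesion == 1.0
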