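import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pocketfish.gsea import (
    DegenerateSetError,
    nes_and_p,
    permutation_null,
    rank_genes,
    run_gsea,
    running_enrichment_score,
)
from pocketfish.io import GeneSetCollection, PocketfishError

from .oracles import running_es_bruteforce


def _ranked(n, seed=0):
    rng = np.random.default_rng(seed)
    weights = np.sort(rng.exponential(1.0, size=n))[::-1]
    return [(f"g{i}", float(w)) for i, w in enumerate(weights)]


class TestRunningEnrichmentScore:
    RANKED = [("g1", 3.0), ("g2", 2.0), ("g3", 1.0), ("g4", 1.0)]

    def test_top_singleton_peaks_at_one(self):
        es, peak, leading = running_enrichment_score(self.RANKED, {"g1"})
        assert es == pytest.approx(1.0, abs=1e-12)
        assert peak == 0
        assert leading == ["g1"]

    def test_bottom_singleton_is_minus_one(self):
        # misses walk the sum to -1 before the final hit returns it to 0
        es, peak, leading = running_enrichment_score(self.RANKED, {"g4"})
        assert es == pytest.approx(-1.0, abs=1e-12)
        assert leading == ["g4"]

    def test_singleton_set_indifferent_to_exponent(self):
        es1, _, _ = running_enrichment_score(self.RANKED, {"g1"}, exponent=1)
        es0, _, _ = running_enrichment_score(self.RANKED, {"g1"}, exponent=0)
        assert es1 == es0

    def test_set_covering_whole_list_rejected(self):
        with pytest.raises(DegenerateSetError):
            running_enrichment_score(self.RANKED, {"g1", "g2", "g3", "g4"})

    def test_no_overlap_rejected(self):
        with pytest.raises(PocketfishError):
            running_enrichment_score(self.RANKED, {"zzz"})

    def test_matches_bruteforce_scan_on_random_instances(self):
        """Exact agreement with an explicit position-by-position oracle."""
        rng = np.random.default_rng(11)
        for _ in range(200):
            n = int(rng.integers(3, 51))
            ranked = [
                (f"g{i}", float(rng.normal())) for i in range(n)
            ]
            k = int(rng.integers(1, n))
            members = set(
                f"g{i}" for i in rng.choice(n, size=k, replace=False)
            )
            es, peak, _ = running_enrichment_score(ranked, members)
            es_o, peak_o = running_es_bruteforce(ranked, members)
            assert es == es_o
            assert peak == peak_o

    def test_running_sum_conserves_to_zero(self):
        rng = np.random.default_rng(5)
        ranked = [(f"g{i}", float(rng.normal())) for i in range(40)]
        members = {f"g{i}" for i in range(0, 40, 7)}
        genes = [g for g, _ in ranked]
        w = {g: abs(x) for g, x in ranked}
        hit_total = sum(w[g] for g in genes if g in members)
        n_miss = len(genes) - len(members & set(genes))
        total = sum(
            w[g] / hit_total if g in members else -1.0 / n_miss for g in genes
        )
        assert abs(total) < 1e-12

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        st.lists(st.floats(0.1, 10, allow_nan=False), min_size=4, max_size=20),
        st.data(),
        st.floats(0.5, 5),
    )
    def test_scale_invariance_and_reversal_antisymmetry(self, ws, data, c):
        ranked = [(f"g{i}", w) for i, w in enumerate(ws)]
        k = data.draw(st.integers(1, len(ws) - 1))
        members = {f"g{i}" for i in range(k)}
        es, _, _ = running_enrichment_score(ranked, members)
        scaled = [(g, c * w) for g, w in ranked]
        es_scaled, _, _ = running_enrichment_score(scaled, members)
        assert es_scaled == pytest.approx(es, rel=1e-9)
        es_rev, _, _ = running_enrichment_score(list(reversed(ranked)), members)
        assert es_rev == pytest.approx(-es, rel=1e-9, abs=1e-12)


class TestPermutationNull:
    def test_deterministic_for_fixed_seed(self):
        ranked = _ranked(30)
        a = permutation_null(ranked, 5, 100, seed=9)
        b = permutation_null(ranked, 5, 100, seed=9)
        assert np.array_equal(a, b)

    def test_bounds_at_maximal_set_size(self):
        ranked = _ranked(15)
        null = permutation_null(ranked, 14, 200, seed=1)
        assert np.all(np.isfinite(null))
        assert np.all((null >= -1) & (null <= 1))

    def test_symmetric_weights_give_symmetric_null(self):
        ranked = [(f"g{i}", 2.0) for i in range(50)]
        null = permutation_null(ranked, 10, 10_000, seed=3)
        assert abs(null.mean()) < 3 * null.std() / math.sqrt(null.size)

    def test_vectorized_null_distribution_matches_scalar_path(self):
        """The fast vectorized null and a scalar loop over random sets
        sample the same ES distribution (two-sample KS check)."""
        from scipy import stats

        ranked = _ranked(25, seed=4)
        null_vec = permutation_null(ranked, 6, 2000, seed=5)
        rng = np.random.default_rng(99)
        null_scalar = []
        for _ in range(500):
            members = {
                f"g{i}" for i in rng.choice(25, size=6, replace=False)
            }
            es, _, _ = running_enrichment_score(ranked, members)
            null_scalar.append(es)
        assert stats.ks_2samp(null_vec, null_scalar).pvalue > 1e-3

    def test_invalid_sizes_rejected(self):
        ranked = _ranked(10)
        with pytest.raises(PocketfishError):
            permutation_null(ranked, 10, 10, seed=0)
        with pytest.raises(PocketfishError):
            permutation_null(ranked, 3, 0, seed=0)


class TestNesAndP:
    def test_positive_nes_arithmetic(self):
        nes, _ = nes_and_p(0.5, [0.25, 0.25, -0.3])
        assert nes == pytest.approx(2.0)

    def test_zero_es(self):
        assert nes_and_p(0.0, [0.1, -0.1]) == (0.0, 1.0)

    def test_null_all_more_extreme_gives_p_one(self):
        _, p = nes_and_p(0.1, [0.5, 0.6, 0.7])
        assert p == 1.0

    def test_negative_es_keeps_negative_sign(self):
        nes, p = nes_and_p(-0.5, [-0.25, -0.25, 0.9])
        assert nes == pytest.approx(-2.0)
        assert 0 < p <= 1

    def test_no_same_sign_null_flags_undefined(self):
        nes, p = nes_and_p(0.5, [-0.2, -0.3])
        assert math.isnan(nes) and p == 1.0

    def test_addone_estimator_never_zero(self):
        _, p = nes_and_p(0.99, [0.01] * 50)
        assert p == pytest.approx(1 / 51)


class TestRunGsea:
    def _collection(self, sets):
        return GeneSetCollection(
            {sid: (sid, frozenset(m)) for sid, m in sets.items()}
        )

    def test_top_decile_set_significant(self):
        ranked = [(f"g{i}", float(200 - i)) for i in range(200)]
        coll = self._collection({"TOP": {f"g{i}" for i in range(20)}})
        res = run_gsea(ranked, coll, n_perm=10_000, seed=2, alpha=0.05)
        r = res[0]
        assert r.nes > 0
        assert r.adjusted_p < 0.05
        assert r.significant
        assert set(r.leading_edge) <= {f"g{i}" for i in range(20)}

    def test_opposite_plantings_have_opposite_signs(self):
        ranked = [(f"g{i}", float(100 - i)) for i in range(100)]
        coll = self._collection(
            {
                "TOP": {f"g{i}" for i in range(10)},
                "BOTTOM": {f"g{i}" for i in range(90, 100)},
            }
        )
        res = {r.set_id: r for r in run_gsea(ranked, coll, n_perm=500, seed=4)}
        assert res["TOP"].es > 0 > res["BOTTOM"].es
        assert res["TOP"].nes > 0 > res["BOTTOM"].nes

    def test_fixed_seed_reproducible_bitwise(self):
        ranked = _ranked(60, seed=8)
        coll = self._collection({"S1": {f"g{i}" for i in range(5)},
                                 "S2": {f"g{i}" for i in range(30, 45)}})
        r1 = run_gsea(ranked, coll, n_perm=300, seed=77)
        r2 = run_gsea(ranked, coll, n_perm=300, seed=77)
        assert r1 == r2

    def test_ties_in_score_broken_by_gene_symbol(self):
        ranked = rank_genes([("B", 1.0), ("A", 1.0), ("C", 2.0)])
        assert [g for g, _ in ranked] == ["C", "A", "B"]

    def test_no_overlap_set_reported_flagged(self):
        ranked = _ranked(20)
        coll = self._collection({"MISS": {"absent1", "absent2"}})
        res = run_gsea(ranked, coll, n_perm=100, seed=1)
        assert math.isnan(res[0].es) and res[0].n_overlap == 0
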