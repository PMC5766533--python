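"""Empirical tail-area, conditional, and conjunction FDR estimators."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import conjfdr.fdr as fdr
from conjfdr.ld import PruneEnsemble
from conjfdr.utils import neglog10


# --- independent brute-force counting oracles -------------------------------

def oracle_marginal(p):
    p = np.asarray(p, float)
    out = np.empty_like(p)
    for i, pi in enumerate(p):
        out[i] = pi * len(p) / np.sum(p <= pi)
    return np.minimum(out, 1.0)


def oracle_cond(p1, p2):
    p1, p2 = np.asarray(p1, float), np.asarray(p2, float)
    out = np.empty_like(p1)
    for i in range(len(p1)):
        stratum = p2 <= p2[i]
        out[i] = p1[i] * stratum.sum() / np.sum((p1 <= p1[i]) & stratum)
    return np.minimum(out, 1.0)


class TestMarginalFdr:
    def test_worked_example(self):
        p = [0.01, 0.2, 0.3, 0.05, 0.5]
        got = fdr.marginal_fdr(p)
        assert got[0] == pytest.approx(0.05)  # smallest p: 0.01 / (1/5)
        np.testing.assert_allclose(got, oracle_marginal(p), rtol=0, atol=0)

    def test_all_ties_give_fdr_equal_p(self):
        q = 0.37
        np.testing.assert_array_equal(fdr.marginal_fdr(np.full(9, q)), np.full(9, q))

    def test_uniform_null_mean_near_one(self):
        p = np.random.default_rng(0).uniform(size=100_000)
        assert fdr.marginal_fdr(p).mean() == pytest.approx(1.0, abs=0.02)

    def test_empty_and_out_of_range_rejected(self):
        with pytest.raises(fdr.FdrError):
            fdr.marginal_fdr([])
        with pytest.raises(fdr.FdrError):
            fdr.marginal_fdr([0.0, 0.5])


class TestCondFdr:
    def test_worked_example(self, micro_pair):
        p1, p2 = micro_pair
        got = fdr.cond_fdr(p1, p2)
        assert got[0] == pytest.approx(0.03)  # 0.01 * 3 / 1
        np.testing.assert_allclose(got, oracle_cond(p1, p2), atol=1e-15)

    def test_full_stratum_reduces_to_marginal(self):
        p1 = np.random.default_rng(1).uniform(size=200)
        p2 = np.ones(200)
        np.testing.assert_allclose(fdr.cond_fdr(p1, p2), fdr.marginal_fdr(p1), atol=1e-15)

    def test_independent_conditioning_converges_to_marginal(self):
        rng = np.random.default_rng(2)
        diffs = []
        for n in (500, 50_000):
            p1, p2 = rng.uniform(size=n), rng.uniform(size=n)
            diffs.append(np.mean(np.abs(fdr.cond_fdr(p1, p2) - fdr.marginal_fdr(p1))))
        assert diffs[1] < diffs[0] / 3

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        st.lists(
            st.tuples(
                st.floats(1e-6, 1.0, exclude_min=False),
                st.floats(1e-6, 1.0),
            ),
            min_size=1,
            max_size=60,
        )
    )
    def test_matches_oracle_on_arbitrary_tables(self, pairs):
        p1 = np.array([a for a, _ in pairs])
        p2 = np.array([b for _, b in pairs])
        np.testing.assert_allclose(fdr.cond_fdr(p1, p2), oracle_cond(p1, p2), atol=1e-13)
        np.testing.assert_allclose(fdr.marginal_fdr(p1), oracle_marginal(p1), atol=1e-13)


class TestSurface:
    def _grid_at_data(self, p1, p2):
        return np.unique(np.concatenate([neglog10(p1), neglog10(p2), [0.0]]))

    def test_node_lookup_matches_direct_estimator(self):
        rng = np.random.default_rng(3)
        p1, p2 = rng.uniform(0.001, 1, 300), rng.uniform(0.001, 1, 300)
        cfg = fdr.FdrConfig(grid=self._grid_at_data(p1, p2))
        surf = fdr.build_fdr_surface(p1, p2, cfg, monotonize=False)
        got = surf.lookup(neglog10(p1), neglog10(p2), raw=True)
        np.testing.assert_allclose(got, fdr.cond_fdr(p1, p2), atol=1e-12)

    def test_averaging_identical_masks_is_idempotent(self):
        rng = np.random.default_rng(4)
        p1, p2 = rng.uniform(size=400), rng.uniform(size=400)
        one = np.ones((1, 400), dtype=bool)
        two = np.ones((2, 400), dtype=bool)
        s1 = fdr.build_fdr_surface(p1, p2, ensemble=PruneEnsemble(one, np.array([0]), 0.8))
        s2 = fdr.build_fdr_surface(p1, p2, ensemble=PruneEnsemble(two, np.array([0, 1]), 0.8))
        np.testing.assert_allclose(s1.values, s2.values)

    def test_monotone_nonincreasing_along_primary_axis(self):
        from conjfdr.utils import p_from_z

        rng = np.random.default_rng(5)
        p1 = p_from_z(rng.normal(0, 1.3, size=5000))
        p2 = rng.uniform(size=5000)
        surf = fdr.build_fdr_surface(p1, p2)
        assert (np.diff(surf.values, axis=0) <= 1e-12).all()

    def test_mismatched_ensemble_rejected(self):
        ens = PruneEnsemble(np.ones((1, 5), dtype=bool), np.array([0]), 0.8)
        with pytest.raises(fdr.FdrError):
            fdr.build_fdr_surface(np.full(6, 0.5), np.full(6, 0.5), ensemble=ens)


class TestConjunction:
    def test_worked_example_exact(self, micro_pair):
        p1, p2 = micro_pair
        res = fdr.conj_fdr_exact(p1, p2)
        assert res.cond_fdr_1_given_2[0] == pytest.approx(0.03)
        assert res.cond_fdr_2_given_1[0] == pytest.approx(0.04)  # 0.04 * 1 / 1
        assert res.conj_fdr[0] == pytest.approx(0.04)

    def test_identical_traits_components_equal(self):
        p = np.random.default_rng(6).uniform(size=300)
        res = fdr.conj_fdr_exact(p, p.copy())
        np.testing.assert_allclose(res.cond_fdr_1_given_2, res.cond_fdr_2_given_1)
        np.testing.assert_allclose(res.conj_fdr, res.cond_fdr_1_given_2)

    def test_symmetric_under_trait_swap(self):
        rng = np.random.default_rng(7)
        p1, p2 = rng.uniform(size=500), rng.uniform(size=500)
        a = fdr.conj_fdr(p1, p2)
        b = fdr.conj_fdr(p2, p1)
        np.testing.assert_allclose(a.conj_fdr, b.conj_fdr, atol=1e-14)

    def test_conj_at_least_each_component(self):
        rng = np.random.default_rng(8)
        p1, p2 = rng.uniform(size=800), rng.uniform(size=800)
        for res in (fdr.conj_fdr_exact(p1, p2), fdr.conj_fdr(p1, p2)):
            assert (res.conj_fdr >= res.cond_fdr_1_given_2 - 1e-15).all()
            assert (res.conj_fdr >= res.cond_fdr_2_given_1 - 1e-15).all()


class TestDiscoveries:
    def _tables(self, p1, p2):
        import pandas as pd

        n = len(p1)
        base = pd.DataFrame(
            {"SNP": [f"s{i}" for i in range(n)], "CHR": 1, "BP": np.arange(n) + 1,
             "A1": "A", "A2": "G"}
        )
        t1 = base.assign(P=p1, Z=1.0)
        t2 = base.assign(P=p2, Z=-1.0)
        return t1, t2

    def test_no_discoveries_gives_empty_table(self):
        p = np.full(20, 0.5)
        t1, t2 = self._tables(p, p)
        res = fdr.conj_fdr_exact(p, p)
        out = fdr.call_discoveries(res, t1, t2)
        assert out.empty

    def test_sorted_ascending_with_both_traits_stats(self):
        rng = np.random.default_rng(9)
        p1 = np.concatenate([[1e-9, 1e-7], rng.uniform(size=500)])
        p2 = np.concatenate([[1e-8, 1e-9], rng.uniform(size=500)])
        t1, t2 = self._tables(p1, p2)
        res = fdr.conj_fdr_exact(p1, p2)
        out = fdr.call_discoveries(res, t1, t2)
        assert not out.empty
        assert (np.diff(out["CONJFDR"]) >= 0).all()
        assert {"P_TRAIT1", "P_TRAIT2", "Z_TRAIT1", "Z_TRAIT2", "CONJFDR"} <= set(out.columns)
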