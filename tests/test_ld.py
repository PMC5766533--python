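"""LD panel I/O, random pruning, LD scores, and clumping."""

import io
import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import conjfdr.ld as ld
from conftest import make_panel


class TestLoadLd:
    def test_empty_pair_file_gives_unit_ld_scores(self):
        panel = ld.load_ld(io.StringIO("SNP_A SNP_B R2\n"), ["a", "b", "c"])
        np.testing.assert_array_equal(panel.ld_scores(), [1.0, 1.0, 1.0])

    def test_single_pair_ld_score(self):
        panel = ld.load_ld(io.StringIO("SNP_A SNP_B R2\ns1 s2 0.9\n"), ["s1", "s2", "s3"])
        np.testing.assert_allclose(panel.ld_scores(), [1.9, 1.9, 1.0])

    def test_conflicting_duplicate_pair_errors_naming_pair(self):
        text = "SNP_A SNP_B R2\ns1 s2 0.9\ns2 s1 0.5\n"
        with pytest.raises(ld.LDError, match="s1.*s2|s2.*s1"):
            ld.load_ld(io.StringIO(text), ["s1", "s2"])

    def test_consistent_duplicates_and_unknown_snps_tolerated(self):
        text = "CHR_A BP_A SNP_A CHR_B BP_B SNP_B R2\n1 1 s1 1 2 s2 0.9\n1 2 s2 1 1 s1 0.9\n1 9 zz 1 1 s1 0.5\n"
        panel = ld.load_ld(io.StringIO(text), ["s1", "s2"])
        np.testing.assert_allclose(panel.ld_scores(), [1.9, 1.9])

    def test_r2_out_of_range_errors(self):
        with pytest.raises(ld.LDError):
            ld.load_ld(io.StringIO("SNP_A SNP_B R2\ns1 s2 1.5\n"), ["s1", "s2"])

    def test_round_trip(self, tmp_path):
        panel = make_panel([(0, 1, 0.9), (2, 3, 0.25)], n=5)
        path = tmp_path / "panel.ld"
        ld.write_ld(panel, path)
        back = ld.load_ld(path, list(panel.snps))
        np.testing.assert_allclose(back.r2.toarray(), panel.r2.toarray())


class TestRandomPrune:
    def test_independent_panel_keeps_everything(self):
        panel = make_panel([], n=20)
        for seed in (0, 1, 99):
            assert ld.random_prune(panel, 0.8, seed).all()

    def test_full_block_keeps_exactly_one_uniformly(self):
        panel = make_panel([(i, j, 1.0) for i in range(5) for j in range(i + 1, 5)])
        counts = np.zeros(5)
        for seed in range(2000):
            mask = ld.random_prune(panel, 0.8, seed)
            assert mask.sum() == 1
            counts[mask] += 1
        # uniform selection over the block members
        chi2 = ((counts - 400.0) ** 2 / 400.0).sum()
        assert chi2 < stats.chi2.ppf(0.99, df=4)

    def test_chain_outcomes_over_all_visit_orders(self, chain_panel):
        outcomes = set()
        for seed in range(100):
            mask = ld.random_prune(chain_panel, 0.8, seed)
            outcomes.add(tuple(np.flatnonzero(mask)))
        assert outcomes == {(1,), (0, 2)}

    def test_masks_satisfy_invariants_on_random_panels(self):
        rng = np.random.default_rng(7)
        for trial in range(50):
            n = int(rng.integers(5, 40))
            pairs = [
                (i, j, float(rng.uniform()))
                for i, j in itertools.combinations(range(n), 2)
                if rng.uniform() < 0.3
            ]
            panel = make_panel(pairs, n=n)
            mask = ld.random_prune(panel, 0.8, seed=trial)
            dense = panel.r2.toarray()
            kept = np.flatnonzero(mask)
            assert (dense[np.ix_(kept, kept)] <= 0.8).all()
            for i in np.flatnonzero(~mask):  # maximality
                assert (dense[i, kept] > 0.8).any()

    def test_deterministic_given_seed(self, chain_panel):
        m1 = ld.random_prune(chain_panel, 0.8, 123)
        m2 = ld.random_prune(chain_panel, 0.8, 123)
        np.testing.assert_array_equal(m1, m2)


class TestPruneEnsemble:
    def test_single_iteration_matches_derived_seed(self, chain_panel):
        ens = ld.build_prune_ensemble(chain_panel, n_iter=1, base_seed=5)
        expected = ld.random_prune(chain_panel, 0.8, int(ens.seeds[0]))
        np.testing.assert_array_equal(ens.masks[0], expected)

    def test_bit_identical_across_runs(self, chain_panel):
        a = ld.build_prune_ensemble(chain_panel, n_iter=10, base_seed=3)
        b = ld.build_prune_ensemble(chain_panel, n_iter=10, base_seed=3)
        np.testing.assert_array_equal(a.masks, b.masks)

    def test_independence_panel_all_masks_true(self):
        panel = make_panel([], n=12)
        ens = ld.build_prune_ensemble(panel, n_iter=5, base_seed=0)
        assert ens.masks.all()


class TestClump:
    def _hits(self, rows):
        return pd.DataFrame(rows, columns=["SNP", "CONJFDR", "P_TRAIT1"])

    def test_singleton(self):
        panel = make_panel([], ids=["a"])
        (locus,) = ld.clump_loci(self._hits([("a", 0.001, 1e-5)]), panel)
        assert locus.lead == "a" and locus.members == ["a"]

    def test_absorption_lead_is_best(self):
        panel = make_panel([(0, 1, 0.5)], ids=["a", "b"])
        (locus,) = ld.clump_loci(self._hits([("a", 0.005, 1e-4), ("b", 0.002, 1e-5)]), panel)
        assert locus.lead == "b" and set(locus.members) == {"a", "b"}

    def test_hand_executed_four_hit_case(self):
        # r2: a-b 0.3, c-d 0.25, a-c 0.05; ranking a < c < b < d
        panel = make_panel([(0, 1, 0.3), (2, 3, 0.25), (0, 2, 0.05)], ids=["a", "b", "c", "d"])
        hits = self._hits([("a", 0.001, 1e-6), ("c", 0.002, 1e-5), ("b", 0.003, 1e-4), ("d", 0.004, 1e-3)])
        loci = ld.clump_loci(hits, panel, r2_threshold=0.2)
        assert [(l.lead, sorted(l.members)) for l in loci] == [("a", ["a", "b"]), ("c", ["c", "d"])]

    def test_invariant_to_input_order_and_leads_independent(self):
        rng = np.random.default_rng(11)
        n = 30
        pairs = [
            (i, j, float(rng.uniform()))
            for i, j in itertools.combinations(range(n), 2)
            if rng.uniform() < 0.2
        ]
        panel = make_panel(pairs, n=n)
        hits = self._hits(
            [(f"s{i}", float(rng.uniform(0, 0.01)), float(rng.uniform(0, 1e-4))) for i in range(n)]
        )
        loci_a = ld.clump_loci(hits, panel, 0.2)
        loci_b = ld.clump_loci(hits.sample(frac=1, random_state=4), panel, 0.2)
        assert [(l.lead, l.members) for l in loci_a] == [(l.lead, l.members) for l in loci_b]
        dense = panel.r2.toarray()
        leads = panel.index_of([l.lead for l in loci_a])
        off = dense[np.ix_(leads, leads)]
        assert (off[~np.eye(len(leads), dtype=bool)] <= 0.2).all()


class TestLdScores:
    def test_additive_over_disjoint_pair_sets(self):
        p1 = make_panel([(0, 1, 0.4)], n=4)
        p2 = make_panel([(2, 3, 0.3)], n=4)
        both = make_panel([(0, 1, 0.4), (2, 3, 0.3)], n=4)
        np.testing.assert_allclose(
            both.ld_scores(), p1.ld_scores() + p2.ld_scores() - 1.0
        )
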