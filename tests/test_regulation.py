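"""Targets, differential expression, enrichment, qPCR arithmetic."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mirnaforge import regulation as rg
from mirnaforge import synthetic_data as sd
from mirnaforge.seqcore import reverse_complement

MIRNA = "UGAGGUAGUAGGUUGUAUAGUU"  # let-7 archetype


class TestSeedMatch:
    def test_exact_complement_found(self):
        site = reverse_complement(MIRNA[1:8])
        utr = "A" * 30 + site + "A" * 30
        assert rg.seed_match(MIRNA, utr) == [30]

    def test_gu_wobble_site_rejected(self):
        # replace one A of the site (pairing a seed U) with G: G:U wobble
        site = list(reverse_complement(MIRNA[1:8]))
        idx = site.index("A")
        site[idx] = "G"
        utr = "C" * 30 + "".join(site) + "C" * 30
        assert rg.seed_match(MIRNA, utr) == []

    def test_triple_site_matches_naive_scan(self):
        site = reverse_complement(MIRNA[1:8])
        utr = ("GG" + site + "CC") * 3
        naive = [i for i in range(len(utr) - 6) if utr[i:i + 7] == site]
        assert rg.seed_match(MIRNA, utr) == naive
        assert len(naive) == 3

    def test_short_utr_empty(self):
        assert rg.seed_match(MIRNA, "ACGU") == []

    def test_seed_len_8(self):
        site = reverse_complement(MIRNA[1:9])
        utr = "A" * 10 + site + "A" * 10
        assert rg.seed_match(MIRNA, utr, seed_len=8) == [10]


class TestDuplexEnergy:
    def test_perfect_gc_duplex_below_threshold(self):
        m = "GCGCGCGCGCGCGCGCGCGCGC"
        assert rg.duplex_energy(m, reverse_complement(m)) < -20

    def test_au_only_short_duplex_above_threshold(self):
        m = "AUAUAUAU"
        dg = rg.duplex_energy(m, reverse_complement(m))
        assert -20 < dg < 0

    def test_unpairable_zero(self):
        assert rg.duplex_energy("AAAA", "CCCC") == 0.0

    def test_hand_computed_stack_sum(self):
        # GGG:CCC duplex = two GG stacks (-3.26 each) + initiation
        dg = rg.duplex_energy("GGG", "CCC")
        assert dg == pytest.approx(2 * -3.26 + rg.HELIX_INIT)

    @given(st.text(alphabet="ACGU", min_size=4, max_size=16))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_under_pair_addition(self, core):
        """Extending the complementary region never raises ΔG."""
        full = rg.duplex_energy(core, reverse_complement(core))
        sub = rg.duplex_energy(core[1:], reverse_complement(core[1:]))
        assert full <= sub + 1e-9


class TestConsensusTargets:
    def test_seed_and_energy_consensus(self):
        mirnas = {"m": "GCGCGCGCGCGCGCGCGCGCGC"}
        utr = "A" * 20 + reverse_complement(mirnas["m"]) + "A" * 20
        pairs, summary = rg.consensus_targets(mirnas, {"g": utr})
        assert any(p.consensus for p in pairs)
        assert summary.loc[0, "n_target_genes"] == 1

    def test_seed_only_is_not_consensus(self):
        mirnas = {"m": "UAUAUAUAUAUAUAUAUAUAUA"}  # AU-only: weak duplex
        utr = "C" * 20 + reverse_complement(mirnas["m"][1:8]) + "C" * 20
        pairs, _ = rg.consensus_targets(mirnas, {"g": utr})
        assert pairs and not any(p.consensus for p in pairs)
        assert all(p.criteria_passed == ("seed",) for p in pairs)

    def test_consensus_count_bounded_by_each_criterion(self):
        mirnas = {"m": MIRNA}
        utrs, _ = sd.simulate_transcriptome(mirnas, n_genes=20, seed=2)
        pairs, _ = rg.consensus_targets(mirnas, utrs)
        n_seed = sum(1 for p in pairs if "seed" in p.criteria_passed)
        n_energy = sum(1 for p in pairs if "energy" in p.criteria_passed)
        n_cons = sum(1 for p in pairs if p.consensus)
        assert n_cons <= min(n_seed, n_energy)

    def test_planted_site_recall(self):
        rng = np.random.default_rng(0)
        mirnas = {f"m{i}": sd.random_mature(rng, 22, 0.7) for i in range(5)}
        utrs, truth = sd.simulate_transcriptome(mirnas, n_genes=40,
                                                site_prob=0.4, seed=3)
        pairs, _ = rg.consensus_targets(mirnas, utrs)
        predicted = {(p.mirna_id, p.gene_id) for p in pairs if p.consensus}
        planted = {(r.mirna, r.gene) for _, r in truth.iterrows()}
        recall = len(planted & predicted) / len(planted)
        assert recall >= 0.9

    def test_order_invariance(self):
        rng = np.random.default_rng(1)
        mirnas = {f"m{i}": sd.random_mature(rng, 22, 0.7) for i in range(3)}
        utrs, _ = sd.simulate_transcriptome(mirnas, n_genes=10, seed=4)
        pairs_a, _ = rg.consensus_targets(mirnas, utrs)
        pairs_b, _ = rg.consensus_targets(dict(reversed(mirnas.items())),
                                          dict(reversed(utrs.items())))
        key = lambda p: (p.mirna_id, p.gene_id, p.position)
        assert sorted(map(key, pairs_a)) == sorted(map(key, pairs_b))


class TestBhFdr:
    def test_step_up_by_hand(self):
        assert rg.bh_fdr([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_and_degenerate(self):
        assert rg.bh_fdr([0.2]) == pytest.approx([0.2])
        assert rg.bh_fdr([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])
        assert rg.bh_fdr([]).size == 0

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=60))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_reference_implementation(self, p):
        import statsmodels.stats.multitest as smm
        ours = rg.bh_fdr(p)
        ref = smm.multipletests(p, method="fdr_bh")[1]
        assert np.allclose(ours, ref)
        assert np.all(ours >= np.asarray(p) - 1e-12)


def hypergeom_tail(a, b, c, d):
    """P(X >= a) for the 2x2 table by exhaustive tail summation."""
    n_set, n_term, total = a + b, a + c, a + b + c + d
    num = 0.0
    den = 0.0
    for x in range(max(0, n_set + n_term - total), min(n_set, n_term) + 1):
        w = math.comb(n_term, x) * math.comb(total - n_term, n_set - x)
        den += w
        if x >= a:
            num += w
    return num / den


class TestFisherEnrichment:
    def test_balanced_table_p_one(self):
        p = hypergeom_tail(5, 5, 5, 5)
        universe = {f"g{i}" for i in range(20)}
        term_map = {g: {"T"} if i < 10 else {"U"}
                    for i, g in enumerate(sorted(universe))}
        gene_set = set(sorted(universe)[5:15])  # 5 with T, 5 with U
        table = rg.fisher_enrichment(gene_set, universe, term_map)
        row = table[table["term"] == "T"].iloc[0]
        assert row["p_value"] == pytest.approx(p)

    def test_matches_brute_force_tail(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            a, b, c, d = rng.integers(0, 15, size=4)
            if (a + b) == 0 or (a + c) == 0:
                continue
            from scipy.stats import fisher_exact
            p_impl = fisher_exact([[a, b], [c, d]], alternative="greater")[1]
            assert p_impl == pytest.approx(hypergeom_tail(a, b, c, d))

    def test_fully_enriched_term_is_top_hit(self):
        universe = {f"g{i}" for i in range(30)}
        term_map = {g: {"HIT"} if i < 8 else {"BG"}
                    for i, g in enumerate(sorted(universe))}
        gene_set = set(sorted(universe)[:8])
        table = rg.fisher_enrichment(gene_set, universe, term_map)
        assert table.iloc[0]["term"] == "HIT"
        assert table.iloc[0]["p_value"] < 1e-4

    def test_gene_set_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            rg.fisher_enrichment({"x"}, {"a"}, {"a": {"T"}})


class TestDeTest:
    @staticmethod
    def matrix(counts_by_lib):
        return pd.DataFrame(counts_by_lib)

    def test_identical_counts_not_biased(self):
        m = self.matrix({"m1": [100, 50], "f1": [100, 50]})
        m.index = ["a", "b"]
        res = rg.de_test(m, {"m1": "male", "f1": "female"})
        assert (res["biased"] == "none").all()
        assert (res["p_value"] > 0.9).all()

    def test_null_calibration(self):
        counts, cond, _ = sd.simulate_count_matrix(500, depth=100_000,
                                                   lfc=0.0, n_biased=0, seed=3)
        res = rg.de_test(counts, cond)
        frac = float((res["p_value"] < 0.05).mean())
        assert 0.03 <= frac <= 0.07
        # loose uniformity sanity check on the p-value distribution
        grid = np.linspace(0, 1, 101)
        ecdf = np.array([(res["p_value"] <= g).mean() for g in grid])
        assert np.max(np.abs(ecdf - grid)) < 0.08

    def test_power_and_direction(self):
        counts, cond, lfcs = sd.simulate_count_matrix(
            200, depth=100_000, lfc=2.0, n_biased=100, seed=4)
        res = rg.de_test(counts, cond)
        biased = lfcs[lfcs != 0]
        correct = sum(
            res.loc[m, "biased"] == ("female" if v > 0 else "male")
            for m, v in biased.items())
        assert correct / len(biased) >= 0.9
        wrong = sum(
            res.loc[m, "biased"] not in
            ("none", "female" if v > 0 else "male")
            for m, v in biased.items())
        assert wrong == 0

    def test_zero_count_mirnas_excluded_with_warning(self):
        m = self.matrix({"m1": [10, 0], "f1": [12, 0]})
        m.index = ["a", "b"]
        with pytest.warns(UserWarning, match="zero"):
            res = rg.de_test(m, {"m1": "male", "f1": "female"})
        assert list(res.index) == ["a"]

    def test_fdr_at_least_p(self):
        counts, cond, _ = sd.simulate_count_matrix(100, seed=9)
        res = rg.de_test(counts, cond)
        assert (res["fdr"] >= res["p_value"] - 1e-12).all()


class TestDdct:
    @pytest.mark.parametrize("cts,fold", [
        ((20, 15, 20, 15), 1.0),     # ΔΔCt = 0
        ((19, 15, 20, 15), 2.0),     # ΔΔCt = -1
        ((22, 15, 20, 15), 0.25),    # ΔΔCt = +2
        ((20, 15, 22, 15), 4.0),
    ])
    def test_closed_form(self, cts, fold):
        assert rg.ddct_fold_change(*cts) == pytest.approx(fold)
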