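"""Diversity/differentiation estimators against hand and brute-force oracles."""

import itertools

import numpy as np
import pytest
from scipy.special import gammaln

from streamscape import popgen
from streamscape.datasets import GenotypeDataset, MISSING

from conftest import make_dataset


class TestLocusSummaries:
    def test_monomorphic_locus(self):
        data = make_dataset(["P"] * 3, np.full((3, 1, 2), 100))
        row = popgen.locus_summaries(data).iloc[0]
        assert (row.Na, row.Ho, row.He) == (1, 0.0, 0.0)

    def test_hand_unbiased_he(self):
        # two individuals both 100/102: Ho=1, He=(4/3)*0.5
        calls = np.array([[[100, 102]], [[100, 102]]])
        data = make_dataset(["P", "P"], calls)
        row = popgen.locus_summaries(data).iloc[0]
        assert row.Ho == 1.0
        assert row.He == pytest.approx(4 / 3 * 0.5)

    def test_missing_genotype_excluded_from_denominator(self):
        calls = np.array([[[100, 102]], [[100, 102]], [[MISSING, MISSING]]])
        data = make_dataset(["P"] * 3, calls)
        row = popgen.locus_summaries(data).iloc[0]
        assert row.n == 2
        assert row.He == pytest.approx(4 / 3 * 0.5)


class TestHWE:
    def test_monomorphic_p_is_one(self):
        data = make_dataset(["P"] * 6, np.full((6, 1, 2), 100))
        assert popgen.hwe_test(data, "P", "L1", n_reps=99, seed=0) == 1.0

    def test_all_homozygotes_rejects_and_matches_enumeration(self):
        # 5 of 100/100 and 5 of 102/102: exact p by complete enumeration
        # over heterozygote counts under Levene's conditional distribution
        calls = np.zeros((10, 1, 2), dtype=int)
        calls[:5] = 100
        calls[5:] = 102
        data = make_dataset(["P"] * 10, calls)
        p_mc = popgen.hwe_test(data, "P", "L1", n_reps=20000, seed=3)

        def log_prob(h):  # h heterozygotes, allele counts 10/10, n=10
            n, nA = 10, 10
            nAA = (nA - h) // 2
            nBB = n - h - nAA
            return (
                gammaln(n + 1) - gammaln(nAA + 1) - gammaln(h + 1)
                - gammaln(nBB + 1) + h * np.log(2)
                + gammaln(nA + 1) + gammaln(2 * n - nA + 1)
                - gammaln(2 * n + 1)
            )

        hs = np.arange(0, 11, 2)  # parity fixed by allele counts
        logs = np.array([log_prob(h) for h in hs])
        probs = np.exp(logs - logs.max())
        probs /= probs.sum()
        exact = probs[logs <= logs[0] + 1e-9].sum()  # observed h = 0
        assert p_mc < 0.05
        se = np.sqrt(exact * (1 - exact) / 20000)
        assert abs(p_mc - exact) < 4 * se + 1e-4

    def test_random_mating_calibration(self):
        rng = np.random.default_rng(12)
        rejections = 0
        n_rep = 300
        for _ in range(n_rep):
            genes = rng.choice([100, 102, 104], size=(20, 2),
                               p=[0.5, 0.3, 0.2])
            data = make_dataset(["P"] * 20, genes[:, None, :])
            p = popgen.hwe_test(data, "P", "L1", n_reps=200,
                                seed=int(rng.integers(2**31)))
            rejections += p < 0.05
        rate = rejections / n_rep
        ci = 1.96 * np.sqrt(0.05 * 0.95 / n_rep)
        assert abs(rate - 0.05) < ci + 0.02


class TestFst:
    def test_identical_frequencies_near_zero(self):
        rng = np.random.default_rng(7)
        genes = rng.choice([100, 102], size=(200, 3, 2))
        data = make_dataset(["A"] * 100 + ["B"] * 100, genes)
        assert abs(popgen.fst_wc(data, "A", "B")) < 0.02

    def test_fixed_differences_give_one(self, fixed_difference_pair):
        assert popgen.fst_wc(fixed_difference_pair, "A", "B") == \
            pytest.approx(1.0)

    def test_matches_independent_variance_component_oracle(self):
        rng = np.random.default_rng(3)
        calls = rng.integers(98, 104, size=(20, 3, 2))
        data = make_dataset(["A"] * 10 + ["B"] * 10, calls)
        theta = popgen.fst_wc(data, "A", "B")

        # independent re-derivation, structured as explicit loops
        num = den = 0.0
        for li, locus in enumerate(data.loci):
            ga = calls[:10, li, :]
            gb = calls[10:, li, :]
            n_i = np.array([10.0, 10.0])
            r = 2
            nbar = n_i.mean()
            nc = (r * nbar - (n_i**2).sum() / (r * nbar)) / (r - 1)
            for allele in np.unique(calls[:, li, :]):
                p_i, h_i = [], []
                for g in (ga, gb):
                    p_i.append((g == allele).sum() / (2 * len(g)))
                    h_i.append(
                        np.mean([(allele in row) and row[0] != row[1]
                                 for row in g])
                    )
                p_i, h_i = np.array(p_i), np.array(h_i)
                pbar = (n_i * p_i).sum() / (r * nbar)
                s2 = (n_i * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
                hbar = (n_i * h_i).sum() / (r * nbar)
                a = (nbar / nc) * (
                    s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
                    / (nbar - 1)
                )
                b = (nbar / (nbar - 1)) * (
                    pbar * (1 - pbar) - (r - 1) / r * s2
                    - (2 * nbar - 1) / (4 * nbar) * hbar
                )
                c = hbar / 2
                num += a
                den += a + b + c
        assert theta == pytest.approx(num / den, abs=1e-10)


class TestGstAndDps:
    def test_fixed_differences_maximal(self, fixed_difference_pair):
        comp, gprime = popgen.gst_hedrick(fixed_difference_pair, "A", "B")
        assert comp.HS == 0.0
        assert gprime == pytest.approx(1.0)
        assert popgen.dps(fixed_difference_pair, "A", "B") == 1.0

    def test_identical_pops_zero(self):
        calls = np.tile(np.array([[100, 102]]), (8, 2, 1))
        data = make_dataset(["A"] * 4 + ["B"] * 4, calls)
        comp, gprime = popgen.gst_hedrick(data, "A", "B")
        assert gprime == pytest.approx(0.0, abs=1e-12)
        assert popgen.dps(data, "A", "B") == pytest.approx(0.0, abs=1e-12)

    def test_gprime_closed_form(self):
        # HS=0.8, GST=0.05, k=2 -> G' = 0.05*1.8/0.2 = 0.45
        gst, hs, k = 0.05, 0.8, 2
        gprime = gst * (k - 1 + hs) / ((k - 1) * (1 - hs))
        assert gprime == pytest.approx(0.45)

    def test_dps_hand_min_sum(self):
        # A: p=(0.7,0.3), B: p=(0.4,0.6) -> ps=0.7? no: 0.4+0.3=0.7, D=0.3
        a_genes = [100] * 7 + [102] * 3
        b_genes = [100] * 4 + [102] * 6
        calls = np.array(a_genes + b_genes).reshape(10, 1, 2)
        data = make_dataset(["A"] * 5 + ["B"] * 5, calls)
        assert popgen.dps(data, "A", "B") == pytest.approx(0.3)

    def test_gprime_at_least_gst(self):
        rng = np.random.default_rng(5)
        calls = rng.choice([100, 102, 104], size=(30, 4, 2),
                           p=[0.5, 0.3, 0.2])
        calls[15:] = rng.choice([100, 102, 104], size=(15, 4, 2),
                                p=[0.2, 0.3, 0.5])
        data = make_dataset(["A"] * 15 + ["B"] * 15, calls)
        comp, gprime = popgen.gst_hedrick(data, "A", "B")
        if comp.GST > 0 and comp.HS > 0:
            assert gprime >= comp.GST


class TestAllelicRichness:
    def test_full_sample_recovers_observed_count(self):
        calls = np.array([[[100, 102]], [[100, 104]], [[100, 100]]])
        data = make_dataset(["P"] * 3, calls)
        table, _ = popgen.allelic_richness(data, g=6)
        assert table.A_g.iloc[0] == pytest.approx(3.0)

    def test_g_one_is_identity(self):
        calls = np.array([[[100, 102]], [[104, 104]]])
        data = make_dataset(["P"] * 2, calls)
        table, _ = popgen.allelic_richness(data, g=1)
        assert table.A_g.iloc[0] == pytest.approx(1.0)

    def test_combinatorial_oracle_by_exhaustive_subsampling(self):
        # N=6 gene copies, counts (4, 2), g=4
        calls = np.array([[[100, 100]], [[100, 100]], [[102, 102]]])
        data = make_dataset(["P"] * 3, calls)
        table, _ = popgen.allelic_richness(data, g=4)
        genes = [100, 100, 100, 100, 102, 102]
        expected = np.mean([
            len(set(sub)) for sub in itertools.combinations(genes, 4)
        ])
        assert table.A_g.iloc[0] == pytest.approx(expected, abs=1e-10)
        assert expected == pytest.approx(1 + (1 - 1 / 15))

    def test_rejects_bad_g(self):
        data = make_dataset(["P"] * 2, np.full((2, 1, 2), 100))
        with pytest.raises(ValueError):
            popgen.allelic_richness(data, g=0)


class TestAmova:
    def test_identical_pops_all_within(self):
        calls = np.tile(np.array([[100, 102]]), (12, 2, 1))
        data = make_dataset(
            ["p1"] * 4 + ["p2"] * 4 + ["p3"] * 4, calls,
            regions=["r1"] * 8 + ["r2"] * 4,
        )
        res = popgen.amova(data)
        assert res.percentages["within_pops"] == pytest.approx(100.0)

    def test_percentages_sum_to_100(self, toy_three_pop):
        res = popgen.amova(toy_three_pop)
        assert sum(res.percentages.values()) == pytest.approx(100.0,
                                                              abs=1e-6)
        assert all(v >= 0 for v in res.truncated.values())

    def test_sums_of_squares_match_pairwise_oracle(self, toy_three_pop):
        res = popgen.amova(toy_three_pop)
        data = toy_three_pop
        tot = {"within_pops": 0.0, "among_pops": 0.0, "among_regions": 0.0}
        for li in range(data.n_loci):
            genes = []
            for i in range(data.n_individuals):
                pop = data.individuals.population[i]
                reg = data.individuals.region[i]
                for a in data.calls[i, li]:
                    genes.append((a, pop, reg))

            def ssd(group_of):
                groups = {}
                for g in genes:
                    groups.setdefault(group_of(g), []).append(g[0])
                s = 0.0
                for vals in groups.values():
                    diff = sum(
                        1 for x, y in itertools.combinations(vals, 2)
                        if x != y
                    )
                    s += diff / len(vals)
                return s

            ss_wp = ssd(lambda g: g[1])
            ss_wr = ssd(lambda g: g[2])
            ss_t = ssd(lambda g: 0)
            tot["within_pops"] += ss_wp
            tot["among_pops"] += ss_wr - ss_wp
            tot["among_regions"] += ss_t - ss_wr
        for key, val in tot.items():
            assert res.ss[key] == pytest.approx(val, abs=1e-10)


class TestMultipleTestCorrection:
    def test_single_p_unchanged(self):
        out = popgen.multiple_test_correction([0.03])
        assert out.p_adjusted.iloc[0] == pytest.approx(0.03)

    def test_bonferroni_arithmetic(self):
        out = popgen.multiple_test_correction([0.004] + [0.5] * 9,
                                              "bonferroni", alpha=0.05)
        assert out.p_adjusted.iloc[0] == pytest.approx(0.04)
        assert bool(out.reject.iloc[0])

    def test_hochberg_matches_stepup_definition(self):
        p = [0.01, 0.04, 0.03]
        out = popgen.multiple_test_correction(p, "hochberg", alpha=0.05)
        # brute-force step-up: largest k with p_(k) <= alpha/(m-k+1)
        srt = sorted(p)
        m = len(p)
        reject_upto = 0
        for k in range(m, 0, -1):
            if srt[k - 1] <= 0.05 / (m - k + 1):
                reject_upto = k
                break
        expected = {pv: (rank < reject_upto)
                    for rank, pv in enumerate(srt)}
        for pv, rej in zip(out.p, out.reject):
            assert bool(rej) == expected[pv]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            popgen.multiple_test_correction([])
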