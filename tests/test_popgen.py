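import math
from itertools import combinations, permutations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from ampligen.models import GenotypeTable
from ampligen.popgen import (allelic_richness, compare_populations,
                             heterozygosities, hurlbert_richness,
                             individual_metrics, locus_heterozygosities,
                             multilocus_heterozygosity, nucleotide_diversity,
                             population_summary, private_alleles,
                             randomization_test, rarefied_richness,
                             rarefied_richness_sets, spearman, summary_frame,
                             tajimas_d)
from ampligen.simulate import (SimulationConfig, simulate_allele_pool,
                               simulate_genotypes, simulate_microsats)

# ---------------------------------------------------------------------------
# oracles


def oracle_tajima(seqs):
    """Straight-from-the-formulas Tajima (1989) D."""
    n = len(seqs)
    L = len(seqs[0])
    S = sum(1 for i in range(L) if len({s[i] for s in seqs}) > 1)
    diffs = [sum(1 for x, y in zip(a, b) if x != y)
             for a, b in combinations(seqs, 2)]
    khat = sum(diffs) / len(diffs)
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (khat - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


def random_sequences(rng, n, length, n_variable):
    base = "".join(rng.choice(list("ACGT"), size=length))
    out = []
    for _ in range(n):
        s = list(base)
        for pos in rng.choice(length, size=n_variable, replace=False):
            if rng.random() < 0.5:
                s[pos] = rng.choice([b for b in "ACGT" if b != s[pos]])
        out.append("".join(s))
    return out


# ---------------------------------------------------------------------------


class TestNucleotideDiversity:
    def test_identical(self):
        assert nucleotide_diversity(["ACGT", "ACGT", "ACGT"]) == 0.0

    def test_two_seq_fixture(self):
        # 2 differences over 10 sites
        assert nucleotide_diversity(["AAAAAAAAAA", "AAAAAAAATT"]) == 0.2

    def test_single_sequence_undefined(self):
        with pytest.raises(ValueError):
            nucleotide_diversity(["ACGT"])

    def test_matches_mean_pairwise_matrix(self):
        rng = np.random.default_rng(1)
        seqs = random_sequences(rng, 6, 50, 10)
        direct = np.mean([
            sum(1 for x, y in zip(a, b) if x != y) / 50
            for a, b in combinations(seqs, 2)])
        assert nucleotide_diversity(seqs) == pytest.approx(direct, abs=1e-12)

    def test_weighted_equals_expansion(self):
        seqs = ["AAAA", "AATT", "TTTT"]
        weights = [3, 1, 2]
        expanded = [s for s, w in zip(seqs, weights) for _ in range(w)]
        assert nucleotide_diversity(seqs, weights=weights) == pytest.approx(
            nucleotide_diversity(expanded), abs=1e-12)

    def test_pairwise_deletion(self):
        assert nucleotide_diversity(["AANA", "AATA"]) == 0.0


class TestTajimasD:
    def test_no_segregating_sites(self):
        res = tajimas_d(["ACGT"] * 5)
        assert res.D is None and res.S == 0

    def test_matches_oracle_on_fixtures(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            seqs = random_sequences(rng, 10, 80, 12)
            if tajimas_d(seqs).S == 0:
                continue
            assert tajimas_d(seqs).D == pytest.approx(
                oracle_tajima(seqs), abs=1e-10)

    def test_needs_four_sequences(self):
        with pytest.raises(ValueError):
            tajimas_d(["ACGT"] * 3)

    def test_p_values_in_range(self):
        rng = np.random.default_rng(3)
        seqs = random_sequences(rng, 8, 60, 10)
        res = tajimas_d(seqs)
        assert 0 <= res.p_beta <= 1 and 0 <= res.p_normal <= 1

    def test_iid_null_centered_near_zero(self):
        # i.i.d. draws from a fixed pool: D has no systematic extreme values
        rng = np.random.default_rng(11)
        ds = []
        for _ in range(20):
            pool = random_sequences(rng, 4, 60, 10)
            sample = [pool[i] for i in rng.integers(0, 4, size=10)]
            res = tajimas_d(sample)
            if res.D is not None:
                ds.append(res.D)
        assert abs(np.mean(ds)) < 1.5  # sanity band, not exact


class TestRichness:
    def test_identical_homozygotes(self):
        assert allelic_richness([("a", "a")] * 5) == 1

    def test_union_at_least_per_population(self):
        pops = {"p1": {"a", "b", "c"}, "p2": {"b", "d"}}
        union = set().union(*pops.values())
        assert all(len(s) <= len(union) for s in pops.values())
        assert private_alleles(pops) == {"p1": {"a", "c"}, "p2": {"d"}}

    def test_empty_error(self):
        with pytest.raises(ValueError):
            allelic_richness([])


class TestRarefaction:
    def test_worked_value(self):
        # copies {3,1}, g=2: 1 + (1 - C(3,2)/C(4,2)) = 1.5
        assert hurlbert_richness([3, 1], 2) == pytest.approx(1.5)

    def test_g_equals_n(self):
        assert hurlbert_richness([3, 1], 4) == 2.0
        value, se = rarefied_richness_sets([{"a"}, {"a", "b"}], 2)
        assert value == 2.0 and se == 0.0

    def test_g_too_large(self):
        with pytest.raises(ValueError):
            hurlbert_richness([3, 1], 5)
        with pytest.raises(ValueError):
            rarefied_richness_sets([{"a"}], 2)

    def test_monotone_in_g(self):
        counts = [5, 3, 2, 1, 1]
        values = [hurlbert_richness(counts, g) for g in range(1, 13)]
        assert values == sorted(values)

    def test_analytic_equals_resampling_oracle(self):
        # Hurlbert closed form vs Monte-Carlo subsampling of gene copies
        counts = {"a": 6, "b": 3, "c": 1}
        g = 4
        analytic = hurlbert_richness(list(counts.values()), g)
        rng = np.random.default_rng(0)
        copies = [al for al, c in counts.items() for _ in range(c)]
        reps = 4000
        vals = [len(set(rng.choice(copies, size=g, replace=False)))
                for _ in range(reps)]
        mc_mean = np.mean(vals)
        mc_se = np.std(vals, ddof=1) / math.sqrt(reps)
        assert abs(analytic - mc_mean) <= 3 * mc_se

    def test_dispatcher(self):
        assert rarefied_richness([3, 1], 2, mode="analytic") == (1.5, 0.0)
        val, se = rarefied_richness([{"a"}, {"b"}], 1, mode="resampling",
                                    n_resamples=50, seed=0)
        assert val == 1.0 and se == 0.0


class TestHeterozygosity:
    def test_monomorphic(self):
        ho, he = locus_heterozygosities([("a", "a"), ("a", "a")])
        assert ho == 0.0 and he == 0.0

    def test_worked_example(self):
        # {A/A, A/B}: Ho = 0.5; He = (4/3)(1 - 0.5625 - 0.0625) = 0.5
        ho, he = locus_heterozygosities([("A", "A"), ("A", "B")])
        assert ho == 0.5
        assert he == pytest.approx(0.5)

    def test_relabel_invariance(self):
        g1 = [("A", "B"), ("B", "B"), ("A", "A")]
        g2 = [("x", "y"), ("y", "y"), ("x", "x")]
        assert locus_heterozygosities(g1) == locus_heterozygosities(g2)

    def test_hardy_weinberg_ho_close_to_he(self):
        config = SimulationConfig(seed=13, n_populations=1,
                                  individuals_per_population=(400,))
        df = simulate_microsats(config, n_loci=4,
                                allele_freqs=[{"a": 0.5, "b": 0.5}] * 4)
        het = heterozygosities(df)
        assert het["Ho"] == pytest.approx(het["He"], abs=0.05)

    def test_across_locus_means(self, tmp_path):
        df = pd.DataFrame([
            {"individual": "i1", "population": "p", "locus": "L1",
             "allele1": "A", "allele2": "A"},
            {"individual": "i2", "population": "p", "locus": "L1",
             "allele1": "A", "allele2": "B"},
            {"individual": "i1", "population": "p", "locus": "L2",
             "allele1": "C", "allele2": "C"},
            {"individual": "i2", "population": "p", "locus": "L2",
             "allele1": "C", "allele2": "C"},
        ])
        het = heterozygosities(df)
        assert het["Ho"] == pytest.approx(0.25)
        assert set(het["per_locus"]) == {"L1", "L2"}


class TestMLH:
    def test_half(self):
        geno = {f"L{i}": ("a", "b") if i < 3 else ("a", "a") for i in range(6)}
        assert multilocus_heterozygosity(geno) == 0.5

    def test_all_homozygous(self):
        assert multilocus_heterozygosity({"L1": ("a", "a")}) == 0.0

    def test_missing_excluded_from_denominator(self):
        geno = {"L1": ("a", "b"), "L2": ("a", "b"), "L3": ("a", "a"),
                "L4": ("b", "b"), "L5": None, "L6": None}
        assert multilocus_heterozygosity(geno) == 0.5

    def test_nothing_typed(self):
        assert multilocus_heterozygosity({"L1": None}) is None


class TestRandomization:
    def test_matches_exhaustive_enumeration(self):
        a, b = [1.0, 2.0], [5.0, 6.0]
        stat = lambda xs: sum(xs) / len(xs)
        observed = abs(stat(a) - stat(b))
        pooled = a + b
        count = total = 0
        for idx in combinations(range(4), 2):
            ga = [pooled[i] for i in idx]
            gb = [pooled[i] for i in range(4) if i not in idx]
            total += 1
            if abs(stat(ga) - stat(gb)) >= observed - 1e-12:
                count += 1
        expected = count / total
        assert randomization_test(a, b, stat, n_perm=10000, seed=0) == expected

    def test_identical_groups_large_p(self):
        a = [1.0, 2.0, 3.0, 4.0]
        stat = lambda xs: sum(xs) / len(xs)
        p = randomization_test(a, list(a), stat, n_perm=2000, seed=1)
        assert p > 0.5

    def test_nperm_validated(self):
        with pytest.raises(ValueError):
            randomization_test([1], [2], lambda x: 0.0, n_perm=0)

    def test_shifted_groups_significant(self):
        rng = np.random.default_rng(2)
        a = list(rng.normal(0, 1, size=12))
        b = list(rng.normal(4, 1, size=12))
        stat = lambda xs: float(np.mean(xs))
        assert randomization_test(a, b, stat, n_perm=999, seed=3) < 0.05


class TestSpearman:
    def test_perfect_monotone(self):
        rho, _ = spearman([1, 2, 3, 5], [2, 4, 9, 11])
        assert rho == pytest.approx(1.0)

    def test_reversed(self):
        rho, _ = spearman([1, 2, 3, 5], [11, 9, 4, 2])
        assert rho == pytest.approx(-1.0)

    def test_constant_vector(self):
        with pytest.raises(ValueError, match="undefined"):
            spearman([1, 1, 1], [1, 2, 3])

    def test_exact_enumeration_small_n(self):
        x = [3.0, 1.0, 4.0, 1.5, 9.0]
        y = [2.0, 7.0, 1.0, 8.0, 2.5]
        rho, p = spearman(x, y)
        # oracle: enumerate all y permutations, Pearson on midranks
        rx = sps.rankdata(x)
        ry = sps.rankdata(y)
        obs = np.corrcoef(rx, ry)[0, 1]
        count = total = 0
        for perm in permutations(ry):
            total += 1
            if abs(np.corrcoef(rx, perm)[0, 1]) >= abs(obs) - 1e-12:
                count += 1
        assert rho == pytest.approx(obs, abs=1e-12)
        assert p == pytest.approx(count / total, abs=1e-12)

    def test_t_approximation_matches_scipy(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=20)
        y = x + rng.normal(size=20)
        rho, p = spearman(x, y)
        ref = sps.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    @given(st.lists(st.floats(min_value=-100, max_value=100), min_size=10,
                    max_size=15, unique=True))
    @settings(max_examples=25, deadline=None)
    def test_rho_bounds(self, x):
        y = list(reversed(x))
        rho, p = spearman(x, y)
        assert -1.0 <= rho <= 1.0 and 0.0 <= p <= 1.0


class TestPopulationSummary:
    def _truth_table(self, seed=21, sizes=(20, 10, 5)):
        config = SimulationConfig(
            seed=seed, n_populations=len(sizes),
            individuals_per_population=sizes, n_alleles_pool=15, n_loci=4)
        pool = simulate_allele_pool(config)
        truth = simulate_genotypes(pool, config)
        genotypes = GenotypeTable(mhc=dict(truth.genotype_of),
                                  population=dict(truth.population_of))
        return config, pool, genotypes

    def test_descending_richness_recovered(self):
        config, pool, genotypes = self._truth_table()
        summaries = population_summary(genotypes, pool, seed=0)
        rich = [summaries[p].richness_mhc for p in ("pop1", "pop2", "pop3")]
        assert rich == sorted(rich, reverse=True)
        mean_alleles = [summaries[p].mean_alleles for p in ("pop1", "pop2", "pop3")]
        assert all(m is not None for m in mean_alleles)

    def test_single_population_n(self):
        config, pool, genotypes = self._truth_table(sizes=(12,))
        summaries = population_summary(genotypes, pool, seed=0)
        assert summaries["pop1"].n_mhc == 12

    def test_excluded_individuals_dropped(self):
        config, pool, genotypes = self._truth_table(sizes=(10,))
        first = sorted(genotypes.mhc)[0]
        genotypes.excluded[first] = "known_offspring"
        summaries = population_summary(genotypes, pool, seed=0)
        assert summaries["pop1"].n_mhc == 9

    def test_rarefied_not_above_observed(self):
        config, pool, genotypes = self._truth_table()
        summaries = population_summary(genotypes, pool, seed=0)
        for s in summaries.values():
            if s.rarefied_mhc is not None:
                assert s.rarefied_mhc <= s.richness_mhc + 1e-9

    def test_summary_frame_shape(self):
        config, pool, genotypes = self._truth_table()
        summaries = population_summary(genotypes, pool, seed=0)
        frame = summary_frame(summaries)
        assert list(frame.columns) == ["pop1", "pop2", "pop3"]
        assert "Mean alleles per individual" in frame.index

    def test_pi_modes_both_valid(self):
        config, pool, genotypes = self._truth_table()
        s1 = population_summary(genotypes, pool, seed=0, pi_mode="distinct")
        s2 = population_summary(genotypes, pool, seed=0, pi_mode="weighted")
        assert s1["pop1"].pi is not None and s2["pop1"].pi is not None


class TestComparisons:
    def test_same_distribution_usually_nonsignificant(self):
        config = SimulationConfig(seed=31, n_populations=2,
                                  individuals_per_population=(12, 12))
        freqs = [{"a": 0.4, "b": 0.3, "c": 0.3}] * 3
        df = simulate_microsats(config, n_loci=3,
                                allele_freqs={"pop1": freqs, "pop2": freqs})
        res = compare_populations(df, "pop1", "pop2", n_perm=300, seed=0)
        assert res["expected_heterozygosity"] > 0.05

    def test_very_different_pools_significant(self):
        config = SimulationConfig(seed=32, n_populations=2,
                                  individuals_per_population=(15, 15))
        rich = [{f"a{i}": 1 / 8 for i in range(8)}] * 3
        poor = [{"a0": 1.0}] * 3
        df = simulate_microsats(config, n_loci=3,
                                allele_freqs={"pop1": rich, "pop2": poor})
        res = compare_populations(df, "pop1", "pop2", n_perm=500, seed=0)
        assert res["expected_heterozygosity"] < 0.05
        assert res["rarefied_richness"] < 0.05


class TestIndividualMetrics:
    def test_table_contents(self):
        config = SimulationConfig(seed=41, n_populations=1,
                                  individuals_per_population=(6,),
                                  n_alleles_pool=8, n_loci=3)
        pool = simulate_allele_pool(config)
        truth = simulate_genotypes(pool, config)
        genotypes = GenotypeTable(mhc=dict(truth.genotype_of),
                                  population=dict(truth.population_of))
        df = simulate_microsats(config, n_loci=3,
                                allele_freqs=[{"a": 0.5, "b": 0.5}] * 3)
        for r in df.itertuples():
            genotypes.microsat[(r.individual, r.locus)] = (r.allele1, r.allele2)
        metrics = individual_metrics(genotypes, pool,
                                     read_totals={i: 100 for i in genotypes.mhc})
        assert len(metrics) == 6
        assert metrics["mlh"].between(0, 1).all()
        assert (metrics["n_mhc_alleles"] >= 1).all()
        single = metrics[metrics["n_mhc_alleles"] == 1]
        assert single["mhc_pi"].isna().all()
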