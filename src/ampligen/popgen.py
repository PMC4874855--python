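"""Population- and individual-level diversity statistics.

Nucleotide diversity, Tajima's D (beta and normal p-values), allelic
richness with Hurlbert analytic and individual-resampling rarefaction,
observed/expected heterozygosity, multilocus heterozygosity, permutation
tests for between-population comparisons, and Spearman rank correlations.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations, permutations

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# sequence diversity


def _pairwise_p(a: str, b: str) -> float | None:
    compared = diff = 0
    for x, y in zip(a.upper(), b.upper()):
        if x not in "ACGT" or y not in "ACGT":
            continue
        compared += 1
        if x != y:
            diff += 1
    return diff / compared if compared else None


def nucleotide_diversity(seqs, weights=None) -> float:
    """Mean pairwise proportion of differing sites (pi), with pairwise
    deletion of gaps/ambiguous bases.

    ``weights`` (optional, parallel to ``seqs``) gives per-sequence
    multiplicities for the occurrence-weighted mode; identical copies
    contribute zero-distance pairs.
    """
    seqs = list(seqs)
    if weights is None:
        if len(seqs) < 2:
            raise ValueError("need >= 2 sequences")
        num = den = 0.0
        for a, b in combinations(seqs, 2):
            d = _pairwise_p(a, b)
            if d is None:
                continue
            num += d
            den += 1
    else:
        weights = list(weights)
        if len(weights) != len(seqs):
            raise ValueError("weights length != sequence count")
        if sum(weights) < 2:
            raise ValueError("need >= 2 sequence occurrences")
        num = den = 0.0
        for (i, a), (j, b) in combinations(enumerate(seqs), 2):
            d = _pairwise_p(a, b)
            if d is None:
                continue
            w = weights[i] * weights[j]
            num += w * d
            den += w
        for w in weights:
            den += w * (w - 1) / 2.0  # identical-copy pairs, distance 0
    if den == 0:
        raise ValueError("no comparable sequence pairs")
    return num / den


def pi_standard_error(seqs) -> float:
    """SE of pi as the standard deviation of the pairwise distances divided
    by sqrt(number of pairs)."""
    dists = [d for a, b in combinations(list(seqs), 2)
             if (d := _pairwise_p(a, b)) is not None]
    if len(dists) < 2:
        return 0.0
    return float(np.std(dists, ddof=1) / math.sqrt(len(dists)))


@dataclass
class TajimaResult:
    D: float | None
    p_beta: float | None
    p_normal: float | None
    n: int
    S: int
    khat: float


def tajimas_d(seqs) -> TajimaResult:
    """Tajima (1989) D with both the beta-distribution and the normal
    approximation p-values (two-tailed).

    Sites with any gap/ambiguous base across the sample are excluded
    (complete deletion); D is undefined when there are no segregating sites.
    """
    seqs = [s.upper() for s in seqs]
    n = len(seqs)
    if n < 4:
        raise ValueError("need >= 4 sequences")
    L = min(len(s) for s in seqs)
    columns = [[s[i] for s in seqs] for i in range(L)
               if all(s[i] in "ACGT" for s in seqs)]
    S = sum(1 for col in columns if len(set(col)) > 1)
    # mean pairwise differences
    total = 0
    npairs = n * (n - 1) // 2
    for col in columns:
        counts = {}
        for b in col:
            counts[b] = counts.get(b, 0) + 1
        same = sum(c * (c - 1) // 2 for c in counts.values())
        total += npairs - same
    khat = total / npairs
    if S == 0:
        return TajimaResult(D=None, p_beta=None, p_normal=None, n=n, S=0, khat=khat)
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    D = (khat - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))
    # beta approximation on [Dmin, Dmax]
    Dmin = (2.0 / n - 1.0 / a1) / math.sqrt(e2)
    Dmax = ((n + 1) / (2.0 * n) - 1.0 / a1) / math.sqrt(e2)
    tmp1 = 1 + Dmin * Dmax
    tmp2 = Dmax - Dmin
    alpha = -tmp1 * Dmax / tmp2
    beta = tmp1 * Dmin / tmp2
    x = (D - Dmin) / tmp2
    cdf = float(stats.beta.cdf(x, beta, alpha))
    p_beta = 2 * cdf if cdf < 0.5 else 2 * (1 - cdf)
    p_normal = 2 * float(stats.norm.sf(abs(D)))
    return TajimaResult(D=float(D), p_beta=p_beta, p_normal=p_normal,
                        n=n, S=S, khat=khat)


# ---------------------------------------------------------------------------
# allelic richness and rarefaction


def allelic_richness(genotypes) -> int:
    """Distinct alleles observed in a population.

    ``genotypes`` is an iterable of per-individual allele collections
    (MHC presence sets, or diploid pairs for one microsatellite locus).
    """
    observed: set = set()
    count = 0
    for alleles in genotypes:
        count += 1
        observed |= set(alleles)
    if count == 0:
        raise ValueError("no genotyped individuals")
    return len(observed)


def private_alleles(pop_allele_sets: dict[str, set]) -> dict[str, set]:
    """Alleles observed in exactly one population, keyed by population."""
    out = {}
    for pop, alleles in pop_allele_sets.items():
        others = set().union(*(s for p, s in pop_allele_sets.items() if p != pop)) \
            if len(pop_allele_sets) > 1 else set()
        out[pop] = set(alleles) - others
    return out


def hurlbert_richness(copy_counts, g: int) -> float:
    """Analytic rarefied richness for allele copy counts: the Hurlbert
    expectation sum_i [1 - C(N - N_i, g)/C(N, g)]."""
    counts = [int(c) for c in copy_counts if c > 0]
    N = sum(counts)
    if g > N:
        raise ValueError(f"rarefaction size g={g} exceeds N={N}")
    if g < 1:
        raise ValueError("g must be >= 1")
    denom = math.comb(N, g)
    return float(sum(1.0 - math.comb(N - ni, g) / denom for ni in counts))


def rarefied_richness_sets(allele_sets, g: int, n_resamples: int = 1000,
                           seed=None) -> tuple[float, float]:
    """Rarefied richness for presence/absence data by resampling ``g``
    individuals without replacement; returns (mean, SD). With g equal to
    the sample size this is the observed richness with SE 0."""
    sets = [frozenset(s) for s in allele_sets]
    N = len(sets)
    if g > N:
        raise ValueError(f"rarefaction size g={g} exceeds sample size {N}")
    if g < 1:
        raise ValueError("g must be >= 1")
    if g == N:
        return float(len(set().union(*sets))), 0.0
    rng = np.random.default_rng(seed)
    values = np.empty(n_resamples)
    for r in range(n_resamples):
        idx = rng.choice(N, size=g, replace=False)
        values[r] = len(set().union(*(sets[i] for i in idx)))
    return float(values.mean()), float(values.std(ddof=1))


def rarefied_richness(data, g: int, mode: str = "analytic",
                      n_resamples: int = 1000, seed=None) -> tuple[float, float]:
    """Dispatch: ``mode='analytic'`` treats ``data`` as allele copy counts
    (gene-copy rarefaction, SE 0); ``mode='resampling'`` treats ``data`` as
    per-individual allele sets."""
    if mode == "analytic":
        return hurlbert_richness(data, g), 0.0
    if mode == "resampling":
        return rarefied_richness_sets(data, g, n_resamples=n_resamples, seed=seed)
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# heterozygosity


def locus_heterozygosities(genotype_pairs) -> tuple[float, float]:
    """(Ho, He) for one locus from diploid allele pairs (missing excluded
    by the caller). He is Nei's unbiased estimator (2n/(2n-1))(1 - sum p_i^2)."""
    pairs = [tuple(p) for p in genotype_pairs]
    n = len(pairs)
    if n == 0:
        raise ValueError("no genotypes at locus")
    ho = sum(1 for a, b in pairs if a != b) / n
    counts: dict = {}
    for a, b in pairs:
        counts[a] = counts.get(a, 0) + 1
        counts[b] = counts.get(b, 0) + 1
    total = 2 * n
    he = 1.0 - sum((c / total) ** 2 for c in counts.values())
    he *= total / (total - 1) if total > 1 else 1.0
    return ho, he


def heterozygosities(microsat: pd.DataFrame) -> dict:
    """Across-locus (Ho, He) means with SEs over loci for one population's
    long-format microsatellite table (blank alleles = missing)."""
    per_locus = {}
    for locus, sub in microsat.groupby("locus"):
        pairs = [(r.allele1, r.allele2) for r in sub.itertuples()
                 if _present(r.allele1) and _present(r.allele2)]
        if not pairs:
            logger.warning("locus %s fully missing: dropped", locus)
            continue
        per_locus[locus] = locus_heterozygosities(pairs)
    if not per_locus:
        raise ValueError("no genotyped loci")
    ho = np.array([v[0] for v in per_locus.values()])
    he = np.array([v[1] for v in per_locus.values()])
    L = len(per_locus)
    sem = lambda x: float(np.std(x, ddof=1) / math.sqrt(L)) if L > 1 else 0.0
    return {
        "per_locus": per_locus,
        "Ho": float(ho.mean()), "Ho_se": sem(ho),
        "He": float(he.mean()), "He_se": sem(he),
    }


def _present(v) -> bool:
    return isinstance(v, str) and v != "" and v.lower() != "nan" or (
        not isinstance(v, str) and pd.notna(v))


def multilocus_heterozygosity(locus_genotypes: dict) -> float | None:
    """Heterozygous loci / genotyped loci for one individual; missing loci
    (None) excluded from the denominator; None when nothing is genotyped."""
    typed = [(a, b) for pair in locus_genotypes.values()
             if pair is not None for a, b in [tuple(pair)]]
    if not typed:
        return None
    het = sum(1 for a, b in typed if a != b)
    return het / len(typed)


# ---------------------------------------------------------------------------
# tests


def randomization_test(pop_a: list, pop_b: list, statistic,
                       n_perm: int = 10000, seed=None) -> float:
    """Two-tailed permutation test of ``|statistic(A) - statistic(B)|``.

    Individuals are permuted between the two groups preserving group sizes.
    When the number of distinct splits is small (<= n_perm) the exact
    enumeration is used; otherwise Monte Carlo with the add-one correction
    p = (count + 1)/(n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    pooled = list(pop_a) + list(pop_b)
    na = len(pop_a)
    observed = abs(statistic(list(pop_a)) - statistic(list(pop_b)))
    n_splits = math.comb(len(pooled), na)
    eps = 1e-12
    if n_splits <= n_perm:
        count = 0
        for idx_a in combinations(range(len(pooled)), na):
            set_a = set(idx_a)
            a = [pooled[i] for i in idx_a]
            b = [pooled[i] for i in range(len(pooled)) if i not in set_a]
            if abs(statistic(a) - statistic(b)) >= observed - eps:
                count += 1
        return count / n_splits
    rng = np.random.default_rng(seed)
    count = 0
    idx = np.arange(len(pooled))
    for _ in range(n_perm):
        rng.shuffle(idx)
        a = [pooled[i] for i in idx[:na]]
        b = [pooled[i] for i in idx[na:]]
        if abs(statistic(a) - statistic(b)) >= observed - eps:
            count += 1
    return (count + 1) / (n_perm + 1)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with midrank ties.

    p-value from exact enumeration of rank permutations for n <= 9, else
    the t-approximation (two-tailed).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("vectors must have equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need n >= 3")
    if len(set(x.tolist())) == 1 or len(set(y.tolist())) == 1:
        raise ValueError("correlation undefined for a constant vector")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)

    def _rho(a, b):
        a = a - a.mean()
        b = b - b.mean()
        return float(a @ b / math.sqrt((a @ a) * (b @ b)))

    rho = _rho(rx, ry)
    if n <= 9:
        count = total = 0
        for perm in permutations(ry):
            total += 1
            if abs(_rho(rx, np.array(perm))) >= abs(rho) - 1e-12:
                count += 1
        return rho, count / total
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    p = 2 * float(stats.t.sf(abs(t), df=n - 2))
    return rho, p


# ---------------------------------------------------------------------------
# population and individual summaries


@dataclass
class PopulationSummary:
    population: str
    # microsatellites
    n_microsat: int | None = None
    richness_microsat: float | None = None
    richness_microsat_se: float | None = None
    rarefied_microsat: float | None = None
    rarefied_microsat_se: float | None = None
    ho: float | None = None
    ho_se: float | None = None
    he: float | None = None
    he_se: float | None = None
    # MHC
    n_mhc: int | None = None
    tajima_d: float | None = None
    tajima_p: float | None = None
    richness_mhc: int | None = None
    private_mhc: int | None = None
    rarefied_mhc: float | None = None
    rarefied_mhc_se: float | None = None
    pi: float | None = None
    pi_se: float | None = None
    mean_alleles: float | None = None
    mean_alleles_se: float | None = None


def _microsat_pairs_by_locus(df: pd.DataFrame) -> dict[str, list[tuple[str, str]]]:
    out: dict[str, list[tuple[str, str]]] = {}
    for r in df.itertuples():
        if _present(r.allele1) and _present(r.allele2):
            out.setdefault(r.locus, []).append((str(r.allele1), str(r.allele2)))
    return out


def population_summary(genotypes, catalog, microsat: pd.DataFrame | None = None,
                       rarefy_to: int | str = "auto", n_resamples: int = 1000,
                       seed=None, pi_mode: str = "distinct") -> dict[str, PopulationSummary]:
    """Assemble per-population summaries of microsatellite and MHC variation.

    ``genotypes`` is a :class:`ampligen.models.GenotypeTable`; individuals in
    its ``excluded`` map (QC failures, known offspring) are dropped from all
    population-level values. MHC sequence statistics (pi, Tajima's D) use
    functional alleles only; allele counts and richness include every called
    allele. ``pi_mode`` is 'distinct' (each allele once, default) or
    'weighted' (each allele once per carrier).
    """
    if pi_mode not in ("distinct", "weighted"):
        raise ValueError("pi_mode must be distinct|weighted")
    functional_seq = {a.name: a.nt for a in catalog if a.functional}
    mhc_pops: dict[str, dict[str, set]] = {}
    for pop in sorted(set(genotypes.population.values())):
        members = genotypes.mhc_by_population(pop)
        if members:
            mhc_pops[pop] = members
    pops = sorted(mhc_pops)
    if microsat is not None and len(microsat):
        pops = sorted(set(pops) | set(microsat["population"].unique()))
    if not pops:
        raise ValueError("no populations with data")

    priv = private_alleles({p: set().union(*m.values())
                            for p, m in mhc_pops.items()}) if mhc_pops else {}
    g_mhc = min((len(m) for m in mhc_pops.values()), default=0) \
        if rarefy_to == "auto" else int(rarefy_to)

    # per-locus minimum gene-copy count across populations (microsat rarefaction size)
    locus_g: dict[str, int] = {}
    if microsat is not None and len(microsat):
        for pop, sub in microsat.groupby("population"):
            for locus, pairs in _microsat_pairs_by_locus(sub).items():
                copies = 2 * len(pairs)
                locus_g[locus] = min(locus_g.get(locus, copies), copies)

    out: dict[str, PopulationSummary] = {}
    for pop in pops:
        s = PopulationSummary(population=pop)
        if microsat is not None and len(microsat):
            sub = microsat[microsat["population"] == pop]
            if len(sub):
                pairs_by_locus = _microsat_pairs_by_locus(sub)
                s.n_microsat = sub["individual"].nunique()
                rich, rare = [], []
                for locus, pairs in sorted(pairs_by_locus.items()):
                    counts: dict[str, int] = {}
                    for a, b in pairs:
                        counts[a] = counts.get(a, 0) + 1
                        counts[b] = counts.get(b, 0) + 1
                    rich.append(len(counts))
                    rare.append(hurlbert_richness(list(counts.values()),
                                                  locus_g[locus]))
                L = len(rich)
                sem = (lambda x: float(np.std(x, ddof=1) / math.sqrt(L))
                       if L > 1 else 0.0)
                s.richness_microsat = float(np.mean(rich))
                s.richness_microsat_se = sem(np.array(rich, dtype=float))
                s.rarefied_microsat = float(np.mean(rare))
                s.rarefied_microsat_se = sem(np.array(rare, dtype=float))
                het = heterozygosities(sub)
                s.ho, s.ho_se = het["Ho"], het["Ho_se"]
                s.he, s.he_se = het["He"], het["He_se"]
        members = mhc_pops.get(pop)
        if members:
            s.n_mhc = len(members)
            union = set().union(*members.values())
            s.richness_mhc = len(union)
            s.private_mhc = len(priv.get(pop, set()))
            counts = [len(v) for v in members.values()]
            s.mean_alleles = float(np.mean(counts))
            s.mean_alleles_se = (float(np.std(counts, ddof=1) / math.sqrt(len(counts)))
                                 if len(counts) > 1 else 0.0)
            if 0 < g_mhc <= len(members):
                val, sd = rarefied_richness_sets(list(members.values()), g_mhc,
                                                 n_resamples=n_resamples, seed=seed)
                s.rarefied_mhc, s.rarefied_mhc_se = val, sd
            func_union = sorted(a for a in union if a in functional_seq)
            if pi_mode == "distinct":
                seqs = [functional_seq[a] for a in func_union]
                weights = None
            else:
                seqs = [functional_seq[a] for a in func_union]
                weights = [sum(1 for v in members.values() if a in v)
                           for a in func_union]
            if len(seqs) >= 2:
                s.pi = nucleotide_diversity(seqs, weights=weights)
                s.pi_se = pi_standard_error(seqs)
            if len(seqs) >= 4:
                taj = tajimas_d(seqs)
                s.tajima_d, s.tajima_p = taj.D, taj.p_beta
        out[pop] = s
    return out


def summary_frame(summaries: dict[str, PopulationSummary]) -> pd.DataFrame:
    """Population summaries as a rows=measure, columns=population table."""
    pops = sorted(summaries)
    fmt = lambda v, se: ("" if v is None else
                         f"{v:.2f}" + (f" ({se:.2f})" if se is not None else ""))
    rows = {
        "Microsatellites: n": [summaries[p].n_microsat for p in pops],
        "Allelic richness": [fmt(summaries[p].richness_microsat,
                                 summaries[p].richness_microsat_se) for p in pops],
        "Rarefied allelic richness": [fmt(summaries[p].rarefied_microsat,
                                          summaries[p].rarefied_microsat_se) for p in pops],
        "Observed heterozygosity": [fmt(summaries[p].ho, summaries[p].ho_se) for p in pops],
        "Expected heterozygosity": [fmt(summaries[p].he, summaries[p].he_se) for p in pops],
        "MHC: n": [summaries[p].n_mhc for p in pops],
        "Tajima's D (P)": ["" if summaries[p].tajima_d is None else
                           f"{summaries[p].tajima_d:.3f} ({summaries[p].tajima_p:.3f})"
                           for p in pops],
        "MHC allelic richness": [summaries[p].richness_mhc for p in pops],
        "MHC rarefied richness": [fmt(summaries[p].rarefied_mhc,
                                      summaries[p].rarefied_mhc_se) for p in pops],
        "Nucleotide diversity": ["" if summaries[p].pi is None else
                                 f"{summaries[p].pi:.3f} ({summaries[p].pi_se:.3f})"
                                 for p in pops],
        "Mean alleles per individual": [fmt(summaries[p].mean_alleles,
                                            summaries[p].mean_alleles_se) for p in pops],
    }
    return pd.DataFrame(rows, index=pops).T.rename_axis("measure")


def compare_populations(microsat: pd.DataFrame, pop_a: str, pop_b: str,
                        n_perm: int = 10000, seed=None) -> dict[str, float]:
    """Randomization p-values for rarefied allelic richness and expected
    heterozygosity between two populations (individuals permuted between
    groups; richness rarefied to the smaller group's gene-copy count)."""
    def individuals(pop):
        sub = microsat[microsat["population"] == pop]
        by_ind: dict[str, dict] = {}
        for r in sub.itertuples():
            if _present(r.allele1) and _present(r.allele2):
                by_ind.setdefault(r.individual, {})[r.locus] = (
                    str(r.allele1), str(r.allele2))
        return list(by_ind.values())

    a, b = individuals(pop_a), individuals(pop_b)
    if not a or not b:
        raise ValueError("both populations need genotyped individuals")
    g = 2 * min(len(a), len(b))

    def mean_he(group):
        by_locus: dict[str, list] = {}
        for ind in group:
            for locus, pair in ind.items():
                by_locus.setdefault(locus, []).append(pair)
        return float(np.mean([locus_heterozygosities(p)[1]
                              for p in by_locus.values()]))

    def mean_rarefied(group):
        by_locus: dict[str, list] = {}
        for ind in group:
            for locus, pair in ind.items():
                by_locus.setdefault(locus, []).append(pair)
        vals = []
        for pairs in by_locus.values():
            counts: dict[str, int] = {}
            for x, y in pairs:
                counts[x] = counts.get(x, 0) + 1
                counts[y] = counts.get(y, 0) + 1
            vals.append(hurlbert_richness(list(counts.values()),
                                          min(g, 2 * len(pairs))))
        return float(np.mean(vals))

    rng = np.random.default_rng(seed)
    return {
        "expected_heterozygosity": randomization_test(
            a, b, mean_he, n_perm=n_perm, seed=rng.integers(2**31)),
        "rarefied_richness": randomization_test(
            a, b, mean_rarefied, n_perm=n_perm, seed=rng.integers(2**31)),
    }


def individual_metrics(genotypes, catalog, read_totals: dict | None = None) -> pd.DataFrame:
    """Per-individual table: multilocus heterozygosity, MHC allele count,
    MHC nucleotide diversity over carried functional alleles, usable reads."""
    functional_seq = {a.name: a.nt for a in catalog if a.functional}
    loci = genotypes.microsat_loci()
    rows = []
    individuals = sorted(set(genotypes.mhc) |
                         {i for i, _ in genotypes.microsat})
    for ind in individuals:
        if ind in genotypes.excluded:
            continue
        locus_geno = {loc: genotypes.microsat.get((ind, loc)) for loc in loci}
        mlh = multilocus_heterozygosity(locus_geno) if loci else None
        alleles = genotypes.mhc.get(ind)
        n_alleles = len(alleles) if alleles else None
        pi = None
        if alleles:
            seqs = [functional_seq[a] for a in sorted(alleles)
                    if a in functional_seq]
            if len(seqs) >= 2:
                pi = nucleotide_diversity(seqs)
        rows.append({
            "individual": ind,
            "population": genotypes.population.get(ind),
            "mlh": mlh,
            "n_mhc_alleles": n_alleles,
            "mhc_pi": pi,
            "usable_reads": (read_totals or {}).get(ind),
        })
    return pd.DataFrame(rows)
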