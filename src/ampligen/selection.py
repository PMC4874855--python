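"""Molecular-evolution statistics on the functional allele set.

Implements pairwise amino-acid p-distances, Tamura–Nei (1993) nucleotide
distances, and synonymous/nonsynonymous substitution rates by the modified
Nei–Gojobori method (transition/transversion-weighted site counts, equal
pathway weighting) with Jukes–Cantor correction, codon-bootstrap standard
errors, and a one-tailed Z-test for positive selection, on three codon
partitions (total / antigen-binding sites / non-ABS).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import combinations, permutations

import numpy as np
from scipy import stats

from .models import AlleleCatalog
from .seqs import CODON_TABLE, STOP_CODONS, is_transition

logger = logging.getLogger(__name__)

DEFAULT_TS_TV_RATIO = 2.0

_GAPLIKE = set("-.NX*")


@dataclass
class CodonAlignment:
    """Equal-length in-frame nucleotide sequences with an optional per-codon
    antigen-binding-site mask."""

    sequences: list[str]
    labels: list[str] | None = None
    abs_mask: list[bool] | None = None

    def __post_init__(self) -> None:
        if len(self.sequences) < 2:
            raise ValueError("need >= 2 sequences")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise ValueError(f"unequal sequence lengths: {sorted(lengths)}")
        (length,) = lengths
        if length % 3 != 0:
            raise ValueError(f"alignment length {length} not a codon multiple")
        self.sequences = [s.upper() for s in self.sequences]
        if self.labels is None:
            self.labels = [f"seq{i + 1}" for i in range(len(self.sequences))]
        if self.abs_mask is not None and len(self.abs_mask) != self.n_codons:
            raise ValueError("abs_mask length != codon count")

    @property
    def n_codons(self) -> int:
        return len(self.sequences[0]) // 3

    def codons(self, i: int) -> list[str]:
        s = self.sequences[i]
        return [s[3 * j:3 * j + 3] for j in range(self.n_codons)]

    def partition_indices(self, partition: str) -> list[int]:
        """Codon indices for 'total', 'abs', or 'non_abs'."""
        if partition == "total":
            return list(range(self.n_codons))
        if self.abs_mask is None:
            raise ValueError(f"partition {partition!r} requires an abs_mask")
        if partition == "abs":
            return [i for i, m in enumerate(self.abs_mask) if m]
        if partition == "non_abs":
            return [i for i, m in enumerate(self.abs_mask) if not m]
        raise ValueError(f"unknown partition {partition!r}")


def alignment_from_catalog(catalog: AlleleCatalog,
                           abs_sites: list[int] | None = None) -> CodonAlignment:
    """Build a codon alignment from the functional alleles of a catalog.

    ``abs_sites`` is a 1-based list of ABS codon positions.
    """
    functional = catalog.functional()
    if len(functional) < 2:
        raise ValueError("need >= 2 functional alleles")
    seqs, labels = [], []
    for a in functional:
        nt = a.nt[a.frame - 1:]
        nt = nt[:len(nt) - len(nt) % 3]
        seqs.append(nt)
        labels.append(a.name)
    mask = None
    if abs_sites is not None:
        n_codons = len(seqs[0]) // 3
        mask = [False] * n_codons
        for pos in abs_sites:
            if not 1 <= pos <= n_codons:
                raise ValueError(f"ABS codon position {pos} outside 1..{n_codons}")
            mask[pos - 1] = True
    return CodonAlignment(sequences=seqs, labels=labels, abs_mask=mask)


# ---------------------------------------------------------------------------
# pairwise distances


def aa_p_distance(a: str, b: str) -> float | None:
    """Uncorrected amino-acid p-distance with pairwise deletion of
    gapped/ambiguous sites; None when no sites are comparable."""
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    compared = diff = 0
    for x, y in zip(a.upper(), b.upper()):
        if x in _GAPLIKE or y in _GAPLIKE:
            continue
        compared += 1
        if x != y:
            diff += 1
    if compared == 0:
        return None
    return diff / compared


def tamura_nei_distance(a: str, b: str) -> float | None:
    """Tamura–Nei (1993) distance, equal rates across sites, pairwise
    deletion of gaps/ambiguity. None on saturation (log of a non-positive
    argument) or degenerate base composition."""
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    pairs = [(x, y) for x, y in zip(a.upper(), b.upper())
             if x in "ACGT" and y in "ACGT"]
    n = len(pairs)
    if n == 0:
        return None
    counts = {base: 0 for base in "ACGT"}
    p1 = p2 = q = 0
    for x, y in pairs:
        counts[x] += 1
        counts[y] += 1
        if x != y:
            if {x, y} == {"A", "G"}:
                p1 += 1
            elif {x, y} == {"C", "T"}:
                p2 += 1
            else:
                q += 1
    g = {base: counts[base] / (2 * n) for base in "ACGT"}
    gr, gy = g["A"] + g["G"], g["C"] + g["T"]
    P1, P2, Q = p1 / n, p2 / n, q / n
    if P1 == P2 == Q == 0:
        return 0.0
    if gr == 0 or gy == 0:
        return None
    k1 = 2 * g["A"] * g["G"] / gr
    k2 = 2 * g["T"] * g["C"] / gy
    k3 = 2 * (gr * gy - g["A"] * g["G"] * gy / gr - g["T"] * g["C"] * gr / gy)
    d = 0.0
    if P1 > 0 or k1 > 0:
        if k1 == 0:
            if P1 > 0:
                return None
        else:
            w1 = 1 - P1 / k1 - Q / (2 * gr)
            if w1 <= 0:
                return None
            d += -k1 * np.log(w1)
    if P2 > 0 or k2 > 0:
        if k2 == 0:
            if P2 > 0:
                return None
        else:
            w2 = 1 - P2 / k2 - Q / (2 * gy)
            if w2 <= 0:
                return None
            d += -k2 * np.log(w2)
    w3 = 1 - Q / (2 * gr * gy)
    if w3 <= 0:
        return None
    d += -k3 * np.log(w3)
    return float(d)


def pairwise_distance_matrix(seqs: dict[str, str], metric) -> "np.ndarray":
    """Square symmetric matrix of ``metric`` over a name->sequence mapping
    (NaN where the metric is undefined)."""
    names = list(seqs)
    n = len(names)
    mat = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        d = metric(seqs[names[i]], seqs[names[j]])
        mat[i, j] = mat[j, i] = np.nan if d is None else d
    return mat


# ---------------------------------------------------------------------------
# modified Nei-Gojobori


def jukes_cantor(p: float) -> float:
    """JC correction d = -(3/4) ln(1 - 4p/3); requires p < 0.75."""
    if p < 0:
        raise ValueError("p must be >= 0")
    if p >= 0.75:
        raise ValueError(f"p = {p} >= 0.75: correction undefined")
    return float(-0.75 * np.log1p(-4.0 * p / 3.0))


@lru_cache(maxsize=None)
def _codon_syn_sites(codon: str, R: float) -> float:
    """Weighted synonymous-site count for a codon (0..3).

    At each position the transitional change carries weight R and each of
    the two transversional changes weight 0.5, so R = 0.5 reduces to the
    unmodified equal-weight Nei-Gojobori counts. Changes producing stop
    codons count as nonsynonymous.
    """
    total = 0.0
    aa = CODON_TABLE[codon]
    for i in range(3):
        wsum = wsyn = 0.0
        for b in "ACGT":
            if b == codon[i]:
                continue
            w = R if is_transition(codon[i], b) else 0.5
            wsum += w
            alt = codon[:i] + b + codon[i + 1:]
            if alt not in STOP_CODONS and CODON_TABLE[alt] == aa:
                wsyn += w
        total += wsyn / wsum
    return total


@lru_cache(maxsize=None)
def _codon_pair_differences(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) difference counts between two codons,
    averaged with equal weight over minimal substitution pathways.

    Pathways passing through stop codons are excluded; if every pathway is
    blocked, all pathways are used (standard fallback).
    """
    diffs = [i for i in range(3) if c1[i] != c2[i]]
    if not diffs:
        return 0.0, 0.0

    def walk(exclude_stops: bool):
        results = []
        for order in permutations(diffs):
            cur, sd, nd = c1, 0, 0
            blocked = False
            for pos in order:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
                if exclude_stops and nxt in STOP_CODONS:
                    blocked = True
                    break
                if CODON_TABLE[cur] == CODON_TABLE[nxt]:
                    sd += 1
                else:
                    nd += 1
                cur = nxt
            if not blocked:
                results.append((sd, nd))
        return results

    paths = walk(exclude_stops=True) or walk(exclude_stops=False)
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


def _codon_ok(codon: str) -> bool:
    return (len(codon) == 3 and all(b in "ACGT" for b in codon)
            and codon not in STOP_CODONS)


def _pair_codon_arrays(aln: CodonAlignment, R: float):
    """Per sequence pair and codon column: synonymous sites S, synonymous
    differences Sd, nonsynonymous differences Nd (NaN where the codon pair
    is pairwise-deleted). Shapes (n_pairs, n_codons)."""
    n_seqs = len(aln.sequences)
    n_codons = aln.n_codons
    codons = [aln.codons(i) for i in range(n_seqs)]
    pairs = list(combinations(range(n_seqs), 2))
    S = np.full((len(pairs), n_codons), np.nan)
    Sd = np.full((len(pairs), n_codons), np.nan)
    Nd = np.full((len(pairs), n_codons), np.nan)
    for pi, (i, j) in enumerate(pairs):
        for k in range(n_codons):
            c1, c2 = codons[i][k], codons[j][k]
            if not (_codon_ok(c1) and _codon_ok(c2)):
                continue
            S[pi, k] = 0.5 * (_codon_syn_sites(c1, R) + _codon_syn_sites(c2, R))
            sd, nd = _codon_pair_differences(c1, c2)
            Sd[pi, k] = sd
            Nd[pi, k] = nd
    return pairs, S, Sd, Nd


def _rates_from_arrays(S, Sd, Nd, idx, warn: bool = True) -> tuple[float, float]:
    """Mean pairwise (dN, dS) over the codon columns in ``idx``; pairs whose
    JC correction is undefined (p >= 0.75) or that have no comparable
    codons are dropped."""
    Ssub, Sdsub, Ndsub = S[:, idx], Sd[:, idx], Nd[:, idx]
    n_cod = np.sum(~np.isnan(Ssub), axis=1)
    with np.errstate(invalid="ignore"):
        Ssum = np.nansum(Ssub, axis=1)
        total_sites = 3.0 * n_cod
        Nsum = total_sites - Ssum
        Sd_sum = np.nansum(Sdsub, axis=1)
        Nd_sum = np.nansum(Ndsub, axis=1)
    dn_list, ds_list = [], []
    dropped = 0
    for k in range(len(Ssum)):
        if n_cod[k] == 0 or Ssum[k] <= 0 or Nsum[k] <= 0:
            dropped += 1
            continue
        pS = Sd_sum[k] / Ssum[k]
        pN = Nd_sum[k] / Nsum[k]
        if pS >= 0.75 or pN >= 0.75:
            dropped += 1
            continue
        ds_list.append(jukes_cantor(pS))
        dn_list.append(jukes_cantor(pN))
    if dropped and warn:
        logger.warning("dropped %d sequence pair(s) (saturation or no data)", dropped)
    if not dn_list:
        return float("nan"), float("nan")
    return float(np.mean(dn_list)), float(np.mean(ds_list))


def nei_gojobori_modified(aln: CodonAlignment, partition="total",
                          R: float = DEFAULT_TS_TV_RATIO) -> tuple[float, float]:
    """Mean pairwise (dN, dS) over the selected codon partition.

    ``partition`` is 'total'/'abs'/'non_abs' or an explicit list of 0-based
    codon indices.
    """
    idx = (aln.partition_indices(partition) if isinstance(partition, str)
           else list(partition))
    if not idx:
        raise ValueError("empty codon partition")
    _, S, Sd, Nd = _pair_codon_arrays(aln, R)
    return _rates_from_arrays(S, Sd, Nd, idx)


def bootstrap_se(aln: CodonAlignment, partition="total",
                 R: float = DEFAULT_TS_TV_RATIO, statistic: str = "dN",
                 n_reps: int = 1000, seed: int | None = None) -> float:
    """Codon-resampling bootstrap SE of 'dN', 'dS', or 'diff' (= dN - dS)."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    idx = (aln.partition_indices(partition) if isinstance(partition, str)
           else list(partition))
    if len(idx) == 1:
        logger.warning("single-codon partition: bootstrap SE degenerate (0)")
        return 0.0
    _, S, Sd, Nd = _pair_codon_arrays(aln, R)
    rng = np.random.default_rng(seed)
    values = []
    for _ in range(n_reps):
        resampled = rng.choice(idx, size=len(idx), replace=True)
        dn, ds = _rates_from_arrays(S, Sd, Nd, resampled, warn=False)
        if np.isnan(dn):
            continue
        values.append({"dN": dn, "dS": ds, "diff": dn - ds}[statistic])
    if len(values) < 2:
        return float("nan")
    return float(np.std(values, ddof=1))


def z_test_positive_selection(dN: float, dS: float, se_diff: float) -> tuple[float, float]:
    """One-tailed Z-test of dN > dS: Z = (dN - dS)/se_diff, p = upper normal
    tail."""
    if se_diff <= 0:
        raise ValueError("se_diff must be > 0")
    Z = (dN - dS) / se_diff
    return float(Z), float(stats.norm.sf(Z))


@dataclass
class SelectionResult:
    partition: str
    dN: float
    dS: float
    se_dN: float
    se_dS: float
    se_diff: float
    Z: float | None
    p: float | None
    R: float
    n_bootstrap: int

    @property
    def dn_ds_ratio(self) -> float:
        return self.dN / self.dS if self.dS > 0 else float("nan")


def run_selection_table(catalog: AlleleCatalog, abs_sites: list[int] | None,
                        R: float = DEFAULT_TS_TV_RATIO, n_reps: int = 1000,
                        seed: int | None = None,
                        se_mode: str = "joint") -> list[SelectionResult]:
    """Partitioned dN/dS table (Total / ABS / non-ABS) on the functional
    alleles of a catalog; pseudogene-flagged alleles are excluded.

    ``se_mode='joint'`` bootstraps (dN - dS) directly for the Z denominator;
    ``'independent'`` combines se_dN and se_dS in quadrature.
    """
    if se_mode not in ("joint", "independent"):
        raise ValueError("se_mode must be joint|independent")
    aln = alignment_from_catalog(catalog, abs_sites=abs_sites)
    partitions = ["total"]
    if aln.abs_mask is not None:
        partitions += ["abs", "non_abs"]
    else:
        logger.warning("no ABS mask supplied: emitting Total partition only")
    _, S, Sd, Nd = _pair_codon_arrays(aln, R)
    results = []
    rng = np.random.default_rng(seed)
    for part in partitions:
        idx = aln.partition_indices(part)
        dn, ds = _rates_from_arrays(S, Sd, Nd, idx)
        boots = {"dN": [], "dS": [], "diff": []}
        if len(idx) > 1:
            for _ in range(n_reps):
                resampled = rng.choice(idx, size=len(idx), replace=True)
                bdn, bds = _rates_from_arrays(S, Sd, Nd, resampled, warn=False)
                if np.isnan(bdn):
                    continue
                boots["dN"].append(bdn)
                boots["dS"].append(bds)
                boots["diff"].append(bdn - bds)
        def _sd(xs):
            return float(np.std(xs, ddof=1)) if len(xs) > 1 else 0.0
        se_dn, se_ds, se_joint = _sd(boots["dN"]), _sd(boots["dS"]), _sd(boots["diff"])
        se_diff = se_joint if se_mode == "joint" else float(np.hypot(se_dn, se_ds))
        if se_diff > 0 and not np.isnan(dn):
            Z, p = z_test_positive_selection(dn, ds, se_diff)
        else:
            Z = p = None
        results.append(SelectionResult(
            partition={"total": "Total", "abs": "ABS", "non_abs": "non-ABS"}[part],
            dN=dn, dS=ds, se_dN=se_dn, se_dS=se_ds, se_diff=se_diff,
            Z=Z, p=p, R=R, n_bootstrap=n_reps))
    return results


def selection_table_frame(results: list[SelectionResult]):
    """Selection results as a table-shaped DataFrame."""
    import pandas as pd
    rows = []
    for r in results:
        rows.append({
            "partition": r.partition,
            "dN": round(r.dN, 3),
            "se_dN": round(r.se_dN, 3),
            "dS": round(r.dS, 3),
            "se_dS": round(r.se_dS, 3),
            "dN_dS": round(r.dn_ds_ratio, 2) if not np.isnan(r.dn_ds_ratio) else "",
            "Z": round(r.Z, 2) if r.Z is not None else "",
            "P": round(r.p, 3) if r.p is not None else "",
        })
    return pd.DataFrame(rows)
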