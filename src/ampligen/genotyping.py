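"""MID-tagged amplicon reads -> per-individual MHC genotypes.

Stepwise filtering:

1. :func:`demultiplex` — perfect-match MID + primer assignment (both
   orientations; degenerate primer bases match their IUPAC sets), trimming.
2. :func:`tally_variants` — exact-sequence variant counts per sample.
3. :func:`reference_filter` — local-alignment identity against a supplied
   reference set (stand-in for a remote BLASTn screen).
4. :func:`compute_mpaf` / :func:`global_allele_filter` — the maximum
   per-amplicon frequency (MPAF) artifact filter: a variant is a putative
   allele only if, in at least one amplicon, it reaches the threshold
   fraction of that amplicon's usable reads.
5. :func:`call_genotype` — within-amplicon rule: an observed catalog allele
   is called iff its count is >= the threshold fraction of the most frequent
   catalog allele in that amplicon.
6. :func:`depth_qc`, :func:`flag_pseudogenes`, :func:`depth_bias_check`,
   :func:`infer_min_loci` — QC and characterization.
"""

from __future__ import annotations

import logging
import math
import re
from collections import Counter
from dataclasses import dataclass

from Bio import Align

from .models import (Allele, AlleleCatalog, AmpliconReadSet, ConfigurationError,
                     GenotypeTable, ReadRecord, VariantTable)
from .seqs import iupac_match, reverse_complement

logger = logging.getLogger(__name__)

DEFAULT_MPAF_THRESHOLD = 0.10
DEFAULT_WITHIN_THRESHOLD = 0.10
DEFAULT_MIN_READS = 100
DEFAULT_MIN_IDENTITY = 0.70
DEFAULT_MIN_OVERLAP = 120


# ---------------------------------------------------------------------------
# demultiplexing


def demultiplex(reads, mid_map, forward_primer: str, reverse_primer: str) -> AmpliconReadSet:
    """Assign each read to a sample by exact MID match plus IUPAC-aware
    primer match in either orientation; trim MID and primers.

    ``reads`` is an iterable of ``(read_id, sequence)``; ``mid_map`` maps
    MID sequence -> sample name (or is a DataFrame with mid/sample columns).
    Discard reasons: ``no_mid``, ``no_primer``, ``multiple_mid``.
    """
    if hasattr(mid_map, "columns"):  # DataFrame
        mid_map = dict(zip(mid_map["mid"], mid_map["sample"]))
    mids = {m.upper(): s for m, s in mid_map.items()}
    if len(mids) != len(mid_map):
        raise ConfigurationError("duplicate MIDs in MID map")
    lengths = {len(m) for m in mids}
    if len(lengths) > 1:
        raise ConfigurationError("MIDs must all have the same length")
    fwd = forward_primer.upper()
    rev_rc = reverse_complement(reverse_primer)
    n_rev = len(reverse_primer)

    records = []
    for read_id, raw in reads:
        seq = raw.upper()
        hits = []
        mid_seen = False
        for oriented, orientation in ((seq, "forward"),
                                      (reverse_complement(seq), "reverse")):
            for mid, sample in mids.items():
                if not oriented.startswith(mid):
                    continue
                mid_seen = True
                if len(oriented) <= len(mid) + len(fwd) + n_rev:
                    continue
                head = oriented[len(mid):len(mid) + len(fwd)]
                tail = oriented[len(oriented) - n_rev:] if n_rev else ""
                if iupac_match(fwd, head) and (not n_rev or iupac_match(rev_rc, tail)):
                    trimmed = oriented[len(mid) + len(fwd):len(oriented) - n_rev]
                    hits.append((sample, orientation, trimmed))
        if not mid_seen:
            records.append(ReadRecord(read_id, raw, discard_reason="no_mid"))
        elif not hits:
            records.append(ReadRecord(read_id, raw, discard_reason="no_primer"))
        elif len({h[0] for h in hits}) > 1:
            records.append(ReadRecord(read_id, raw, discard_reason="multiple_mid"))
        else:
            sample, orientation, trimmed = hits[0]
            records.append(ReadRecord(read_id, raw, sample=sample,
                                      orientation=orientation, trimmed=trimmed))
    return AmpliconReadSet(records)


# ---------------------------------------------------------------------------
# tallying and MPAF


def tally_variants(readset: AmpliconReadSet) -> VariantTable:
    """Exact-sequence grouping of trimmed variants per sample."""
    counts: dict[str, Counter] = {}
    for rec in readset.assigned():
        counts.setdefault(rec.sample, Counter())[rec.trimmed] += 1
    return VariantTable(counts=counts)


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 2.0
    aligner.mismatch_score = -3.0
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -2.0
    return aligner


def best_reference_hit(variant: str, references: dict[str, str],
                       aligner: Align.PairwiseAligner | None = None):
    """Best gap-tolerant local alignment of ``variant`` against the
    reference set; returns ``(ref_name, identity, overlap_columns)``."""
    if aligner is None:
        aligner = _make_aligner()
    best = (None, 0.0, 0)
    for name, ref in references.items():
        try:
            alignment = aligner.align(variant, ref)[0]
        except (IndexError, ValueError):
            continue
        counts = alignment.counts()
        columns = counts.identities + counts.mismatches + counts.internal_gaps
        identity = counts.identities / columns if columns else 0.0
        key = (identity, columns)
        if key > (best[1], best[2]):
            best = (name, identity, columns)
    return best


def _gapfree_passes(variant: str, ref: str, min_identity: float,
                    min_overlap: int) -> bool:
    """Quick accept: an end-anchored gap-free overlap is itself a local
    alignment, so meeting the thresholds here implies the best local
    alignment does too. Checked left- and right-anchored."""
    for a, b in ((variant, ref), (variant[::-1], ref[::-1])):
        n = min(len(a), len(b))
        if n < min_overlap:
            return False
        matches = sum(1 for x, y in zip(a[:n], b[:n]) if x == y)
        if matches / n >= min_identity:
            return True
    return False


def reference_filter(table: VariantTable, references: dict[str, str],
                     min_identity: float = DEFAULT_MIN_IDENTITY,
                     min_overlap: int = DEFAULT_MIN_OVERLAP) -> VariantTable:
    """Retain variants whose best local alignment to any reference meets the
    identity and overlap thresholds; removed variants are logged with their
    best-hit identity."""
    if not references:
        raise ConfigurationError("reference set is empty")
    aligner = _make_aligner()
    keep: set[str] = set()
    removed: dict[str, float] = {}
    for variant in table.pooled_counts():
        if any(_gapfree_passes(variant, ref, min_identity, min_overlap)
               for ref in references.values()):
            keep.add(variant)
            continue
        _, identity, overlap = best_reference_hit(variant, references, aligner)
        if identity >= min_identity and overlap >= min_overlap:
            keep.add(variant)
        else:
            removed[variant] = identity
    counts = {
        sample: Counter({v: c for v, c in ctr.items() if v in keep})
        for sample, ctr in table.counts.items()
    }
    if removed:
        logger.info("reference filter removed %d variant(s)", len(removed))
    return VariantTable(counts=counts, removed=removed)


def compute_mpaf(table: VariantTable) -> VariantTable:
    """Annotate each variant with its maximum per-amplicon frequency: the
    highest within-sample read fraction it attains in any single sample.

    Samples with zero usable reads are excluded from the maximum (and
    logged)."""
    totals = table.sample_totals()
    zero = [s for s, t in totals.items() if t == 0]
    if zero:
        logger.warning("excluding %d zero-read sample(s) from MPAF: %s",
                       len(zero), zero)
    mpaf: dict[str, float] = {}
    for sample, ctr in table.counts.items():
        total = totals[sample]
        if total == 0:
            continue
        for variant, count in ctr.items():
            freq = count / total
            if freq > mpaf.get(variant, 0.0):
                mpaf[variant] = freq
    return VariantTable(counts=table.counts, mpaf=mpaf, removed=table.removed)


def global_allele_filter(table: VariantTable,
                         mpaf_threshold: float = DEFAULT_MPAF_THRESHOLD,
                         known_alleles: dict[str, str] | None = None,
                         name_prefix: str = "DAB") -> AlleleCatalog:
    """Catalog of variants with MPAF >= threshold (inclusive).

    Names: variants sequence-identical to a supplied known allele keep its
    name; new alleles are numbered by descending pooled read count (ties
    broken by sequence) continuing after the highest known number.
    """
    if not 0.0 < mpaf_threshold <= 1.0:
        raise ConfigurationError(f"mpaf_threshold {mpaf_threshold} outside (0, 1]")
    if table.mpaf is None:
        raise ConfigurationError("MPAF not annotated; run compute_mpaf first")
    pooled = table.pooled_counts()
    passing = [v for v, f in table.mpaf.items() if f >= mpaf_threshold]
    passing.sort(key=lambda v: (-pooled[v], v))
    known_by_seq = {seq.upper(): name for name, seq in (known_alleles or {}).items()}
    next_num = 1
    for name in known_by_seq.values():
        m = re.search(r"(\d+)$", name)
        if m:
            next_num = max(next_num, int(m.group(1)) + 1)
    width = max(2, len(str(next_num + len(passing))))
    alleles = []
    for variant in passing:
        if variant in known_by_seq:
            name = known_by_seq[variant]
        else:
            name = f"{name_prefix}*{next_num:0{width}d}"
            next_num += 1
        alleles.append(Allele(name=name, nt=variant,
                              mpaf=table.mpaf[variant],
                              pooled_count=pooled[variant]))
    return AlleleCatalog(alleles)


# ---------------------------------------------------------------------------
# genotype calling


def call_genotype(sample_counts: Counter, catalog: AlleleCatalog,
                  within_threshold: float = DEFAULT_WITHIN_THRESHOLD,
                  within_ref: str = "catalog") -> set[str]:
    """Within-amplicon rule: keep catalog allele ``a`` iff
    ``count(a) >= within_threshold * count(reference variant)``.

    The reference variant is the most frequent catalog allele in the sample
    (``within_ref='catalog'``, default) or the most frequent raw variant
    (``within_ref='raw'``). Ties broken by lexicographic sequence. Returns
    the called allele-name set; empty set means no catalog allele observed
    (individual is ungenotypeable).
    """
    if not 0.0 < within_threshold <= 1.0:
        raise ConfigurationError(f"within_threshold {within_threshold} outside (0, 1]")
    if within_ref not in ("raw", "catalog"):
        raise ConfigurationError(f"within_ref must be raw|catalog, got {within_ref!r}")
    if len(catalog) == 0:
        raise ConfigurationError("catalog is empty")
    by_seq = {a.nt: a.name for a in catalog}
    observed = {seq: c for seq, c in sample_counts.items() if seq in by_seq and c > 0}
    if not observed:
        return set()
    if within_ref == "catalog":
        ref_count = max(observed.values())
    else:
        ref_count = max(c for c in sample_counts.values())
    cutoff = within_threshold * ref_count
    return {by_seq[seq] for seq, c in observed.items() if c >= cutoff}


def depth_qc(table: VariantTable, min_reads: int = DEFAULT_MIN_READS) -> list[str]:
    """Samples whose usable-read totals fall below ``min_reads``; these are
    excluded from genotyping and downstream per-individual statistics."""
    if min_reads < 1:
        raise ConfigurationError("min_reads must be >= 1")
    excluded = sorted(s for s, t in table.sample_totals().items() if t < min_reads)
    if excluded:
        logger.info("depth QC excluded %d sample(s): %s", len(excluded), excluded)
    return excluded


def flag_pseudogenes(catalog: AlleleCatalog, expected_length: int,
                     frame: int = 1) -> AlleleCatalog:
    """Flag alleles as nonfunctional when their length is incongruent with
    the expected length modulo 3 (frameshifting indel) or their in-frame
    translation contains a stop codon."""
    flagged = []
    for a in catalog:
        reason = None
        if len(a.nt) % 3 != expected_length % 3:
            delta = expected_length - len(a.nt)
            reason = f"{abs(delta)}-nt {'deletion' if delta > 0 else 'insertion'} (frameshift)"
        elif a.has_stop():
            reason = "internal stop codon"
        flagged.append(Allele(
            name=a.name, nt=a.nt, frame=frame,
            functional=reason is None,
            flag_reason=reason,
            mpaf=a.mpaf, pooled_count=a.pooled_count,
        ))
    n_flagged = sum(not a.functional for a in flagged)
    if n_flagged:
        logger.info("flagged %d pseudogene-like allele(s)", n_flagged)
    return AlleleCatalog(flagged)


@dataclass
class DepthBiasReport:
    n: int
    rho: float | None
    p: float | None
    note: str = ""


def depth_bias_check(genotypes: dict[str, set[str]],
                     table: VariantTable) -> DepthBiasReport:
    """Spearman correlation between per-individual usable reads and called
    allele count — a systematic-bias check on genotyping depth."""
    from .popgen import spearman
    totals = table.sample_totals()
    individuals = sorted(i for i in genotypes if i in totals and genotypes[i])
    if len(individuals) < 3:
        raise ConfigurationError("need >= 3 genotyped individuals")
    x = [totals[i] for i in individuals]
    y = [len(genotypes[i]) for i in individuals]
    if len(set(x)) == 1 or len(set(y)) == 1:
        return DepthBiasReport(n=len(individuals), rho=None, p=None,
                               note="correlation undefined (constant vector)")
    rho, p = spearman(x, y)
    return DepthBiasReport(n=len(individuals), rho=rho, p=p)


def infer_min_loci(genotypes: dict[str, set[str]]) -> int:
    """Minimum locus count implied by the largest per-individual allele set
    (ceil(max/2); a diploid locus contributes at most two alleles)."""
    if not genotypes:
        raise ConfigurationError("no genotypes")
    return math.ceil(max(len(s) for s in genotypes.values()) / 2)


# ---------------------------------------------------------------------------
# orchestration


@dataclass
class GenotypingResult:
    readset: AmpliconReadSet
    raw_table: VariantTable
    filtered_table: VariantTable
    catalog: AlleleCatalog
    genotypes: GenotypeTable
    excluded_samples: list[str]


def genotype_pipeline(reads, mid_map, forward_primer: str, reverse_primer: str,
                      references: dict[str, str],
                      mpaf_threshold: float = DEFAULT_MPAF_THRESHOLD,
                      within_threshold: float = DEFAULT_WITHIN_THRESHOLD,
                      within_ref: str = "catalog",
                      min_reads: int = DEFAULT_MIN_READS,
                      min_identity: float = DEFAULT_MIN_IDENTITY,
                      min_overlap: int = DEFAULT_MIN_OVERLAP,
                      expected_length: int | None = None,
                      known_alleles: dict[str, str] | None = None,
                      name_prefix: str = "DAB") -> GenotypingResult:
    """Run the full filtering cascade and call per-individual genotypes."""
    readset = demultiplex(reads, mid_map, forward_primer, reverse_primer)
    raw_table = tally_variants(readset)
    table = reference_filter(raw_table, references,
                             min_identity=min_identity, min_overlap=min_overlap)
    table = compute_mpaf(table)
    catalog = global_allele_filter(table, mpaf_threshold=mpaf_threshold,
                                   known_alleles=known_alleles,
                                   name_prefix=name_prefix)
    if expected_length is None:
        lengths = Counter(len(a.nt) for a in catalog)
        expected_length = lengths.most_common(1)[0][0] if lengths else 0
    catalog = flag_pseudogenes(catalog, expected_length=expected_length)
    excluded = depth_qc(table, min_reads=min_reads)

    populations = {}
    if hasattr(mid_map, "columns") and "population" in getattr(mid_map, "columns", []):
        populations = dict(zip(mid_map["sample"], mid_map["population"]))

    genotypes = GenotypeTable(population=populations)
    for sample, ctr in sorted(table.counts.items()):
        if sample in excluded:
            genotypes.excluded[sample] = "low_depth"
            continue
        called = call_genotype(ctr, catalog, within_threshold=within_threshold,
                               within_ref=within_ref)
        if not called:
            genotypes.excluded[sample] = "ungenotypeable"
            continue
        genotypes.mhc[sample] = called
    return GenotypingResult(readset=readset, raw_table=raw_table,
                            filtered_table=table, catalog=catalog,
                            genotypes=genotypes, excluded_samples=excluded)
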