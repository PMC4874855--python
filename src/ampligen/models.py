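"""Core data structures shared by the simulation, genotyping, and statistics
modules."""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterator, Mapping

from .seqs import has_internal_stop, translate


class ConfigurationError(ValueError):
    """Invalid run or simulation configuration."""


@dataclass
class Allele:
    """A named putative allele with its nucleotide sequence and annotations."""

    name: str
    nt: str
    frame: int = 1
    functional: bool = True
    flag_reason: str | None = None
    mpaf: float | None = None
    pooled_count: int | None = None

    @property
    def aa(self) -> str:
        return translate(self.nt, frame=self.frame)

    def has_stop(self) -> bool:
        return has_internal_stop(self.nt, frame=self.frame)


@dataclass
class AlleleCatalog:
    """Ordered collection of named alleles; names are unique."""

    alleles: list[Allele] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [a.name for a in self.alleles]
        if len(names) != len(set(names)):
            dup = next(n for n in names if names.count(n) > 1)
            raise ValueError(f"duplicate allele name {dup!r}")

    def __len__(self) -> int:
        return len(self.alleles)

    def __iter__(self) -> Iterator[Allele]:
        return iter(self.alleles)

    def __contains__(self, name: str) -> bool:
        return any(a.name == name for a in self.alleles)

    def get(self, name: str) -> Allele:
        for a in self.alleles:
            if a.name == name:
                return a
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [a.name for a in self.alleles]

    def sequences(self, functional_only: bool = False) -> dict[str, str]:
        return {a.name: a.nt for a in self.alleles
                if a.functional or not functional_only}

    def functional(self) -> "AlleleCatalog":
        return AlleleCatalog([a for a in self.alleles if a.functional])

    def by_sequence(self) -> dict[str, Allele]:
        return {a.nt: a for a in self.alleles}


@dataclass
class ReadRecord:
    """One read with its demultiplexing outcome."""

    read_id: str
    sequence: str
    sample: str | None = None
    orientation: str | None = None  # "forward" | "reverse"
    trimmed: str | None = None
    discard_reason: str | None = None  # no_mid | no_primer | multiple_mid

    @property
    def assigned(self) -> bool:
        return self.sample is not None


@dataclass
class AmpliconReadSet:
    """Reads plus per-read demultiplexing outcome."""

    records: list[ReadRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def assigned(self) -> list[ReadRecord]:
        return [r for r in self.records if r.assigned]

    def discarded(self) -> list[ReadRecord]:
        return [r for r in self.records if not r.assigned]

    def discard_tally(self) -> Counter:
        return Counter(r.discard_reason for r in self.discarded())


@dataclass
class VariantTable:
    """Per-sample counts of unique trimmed variant sequences.

    ``counts`` maps sample -> Counter(variant sequence -> read count).
    ``mpaf`` is filled by :func:`ampligen.genotyping.compute_mpaf`.
    """

    counts: dict[str, Counter] = field(default_factory=dict)
    mpaf: dict[str, float] | None = None
    removed: dict[str, float] = field(default_factory=dict)  # variant -> best identity

    def sample_totals(self) -> dict[str, int]:
        return {s: sum(c.values()) for s, c in self.counts.items()}

    def pooled_counts(self) -> Counter:
        pooled: Counter = Counter()
        for c in self.counts.values():
            pooled.update(c)
        return pooled

    @property
    def variants(self) -> list[str]:
        return sorted(self.pooled_counts())

    def total_reads(self) -> int:
        return sum(self.sample_totals().values())


@dataclass
class GenotypeTable:
    """Per-individual MHC allele sets, microsatellite genotypes, and
    population labels."""

    mhc: dict[str, set[str]] = field(default_factory=dict)
    microsat: dict[tuple[str, str], tuple[str, str] | None] = field(default_factory=dict)
    population: dict[str, str] = field(default_factory=dict)
    excluded: dict[str, str] = field(default_factory=dict)  # individual -> QC reason

    def individuals(self) -> list[str]:
        return sorted(set(self.mhc) | {i for i, _ in self.microsat})

    def populations(self) -> list[str]:
        return sorted(set(self.population.values()))

    def mhc_by_population(self, population: str) -> dict[str, set[str]]:
        return {i: s for i, s in self.mhc.items()
                if self.population.get(i) == population and i not in self.excluded}

    def microsat_loci(self) -> list[str]:
        return sorted({locus for _, locus in self.microsat})

    def validate_against(self, catalog: AlleleCatalog) -> None:
        known = set(catalog.names)
        for ind, alleles in self.mhc.items():
            unknown = alleles - known
            if unknown:
                raise ValueError(
                    f"individual {ind!r} carries unknown allele(s) {sorted(unknown)}")


def genotype_table_from_mappings(
    mhc: Mapping[str, set],
    population: Mapping[str, str],
    microsat: Mapping | None = None,
    excluded: Mapping[str, str] | None = None,
) -> GenotypeTable:
    return GenotypeTable(
        mhc={k: set(v) for k, v in mhc.items()},
        microsat=dict(microsat or {}),
        population=dict(population),
        excluded=dict(excluded or {}),
    )
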