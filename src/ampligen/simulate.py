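"""Synthetic data generation with known truth.

Produces a diverse allele pool, per-individual multilocus genotypes,
artifact-laden MID-tagged amplicon reads (PCR point errors and chimeras), and
diploid microsatellite genotypes. Every read carries a provenance record so
downstream filtering can be scored against truth.

All randomness flows from a single seed through named substreams, so each
stage is individually reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import Allele, AlleleCatalog, ConfigurationError
from .seqs import CODON_TABLE, STOP_CODONS, reverse_complement

_BASES = np.array(list("ACGT"))

# substream ids keyed by stage name (mixed with the seed for independence)
_STREAMS = {"pool": 11, "genotypes": 23, "reads": 37, "microsats": 53,
            "mids": 71, "msfreqs": 97}

DEFAULT_FORWARD_PRIMER = "ACWGGTCAYGCTTACGACGG"
DEFAULT_REVERSE_PRIMER = "GTCATSGCAGTRCCTTCAC"


@dataclass
class SimulationConfig:
    seed: int = 0
    n_populations: int = 3
    individuals_per_population: tuple[int, ...] = (79, 17, 6)
    n_alleles_pool: int = 24
    allele_length_nt: int = 165
    n_loci: int = 6
    depth_mean: float = 200.0
    depth_sd: float = 60.0
    point_error_rate: float = 0.005
    chimera_rate: float = 0.05
    include_pseudogene: bool = True
    pseudogene_deletion_span: tuple[int, int] = (111, 123)
    # pool diversity knob: max fraction of ancestor sites mutated per allele;
    # higher values widen pairwise divergence but push alleles away from the
    # reference set used by the identity filter
    pool_divergence: float = 0.20
    # fraction of the pool accessible to each population (None = descending)
    population_pool_fractions: tuple[float, ...] | None = None
    mid_length: int = 10
    forward_primer: str = DEFAULT_FORWARD_PRIMER
    reverse_primer: str = DEFAULT_REVERSE_PRIMER
    allele_name_prefix: str = "DAB"

    def __post_init__(self) -> None:
        for name in ("point_error_rate", "chimera_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise ConfigurationError(f"{name}={rate} outside [0, 1]")
        if self.n_populations < 1:
            raise ConfigurationError("n_populations must be >= 1")
        self.individuals_per_population = tuple(self.individuals_per_population)
        if len(self.individuals_per_population) != self.n_populations:
            raise ConfigurationError(
                "individuals_per_population length != n_populations")
        if any(n < 1 for n in self.individuals_per_population):
            raise ConfigurationError("individuals_per_population must all be >= 1")
        if self.depth_mean <= 0:
            raise ConfigurationError("depth_mean must be > 0")
        if self.n_loci < 1:
            raise ConfigurationError("n_loci must be >= 1")
        if self.n_alleles_pool < 1:
            raise ConfigurationError("n_alleles_pool must be >= 1")
        if self.allele_length_nt % 3 != 0:
            raise ConfigurationError("allele_length_nt must be a multiple of 3")
        if self.include_pseudogene:
            start, end = self.pseudogene_deletion_span
            if end - start + 1 != 13:
                raise ConfigurationError("pseudogene deletion span must be 13 nt")
            if not (1 <= start <= end <= self.allele_length_nt):
                raise ConfigurationError("pseudogene deletion span out of range")

    def rng(self, stage: str) -> np.random.Generator:
        return np.random.default_rng([self.seed, _STREAMS[stage]])

    def to_flat_dict(self) -> dict[str, str]:
        out = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, tuple):
                v = ",".join(str(x) for x in v)
            out[f.name] = str(v)
        return out


@dataclass
class SimulationTruth:
    """Ground truth emitted alongside the simulated data."""

    allele_pool: AlleleCatalog
    genotype_of: dict[str, set[str]] = field(default_factory=dict)
    population_of: dict[str, str] = field(default_factory=dict)
    read_provenance: dict[str, dict] = field(default_factory=dict)

    def validate(self) -> None:
        pool = set(self.allele_pool.names)
        for ind, alleles in self.genotype_of.items():
            if not alleles <= pool:
                raise ValueError(f"{ind}: genotype allele(s) not in pool")


@dataclass
class SimulatedReads:
    reads: list[tuple[str, str]]  # (read_id, sequence)
    mid_map: pd.DataFrame         # columns mid, sample, population
    depths: dict[str, int]


# ---------------------------------------------------------------------------
# allele pool


def _random_coding_sequence(rng: np.random.Generator, length_nt: int) -> str:
    codons = [c for c in CODON_TABLE if c not in STOP_CODONS]
    idx = rng.integers(0, len(codons), size=length_nt // 3)
    return "".join(codons[i] for i in idx)


def _mutate(rng: np.random.Generator, seq: str, n_subs: int) -> str:
    """Apply ``n_subs`` random substitutions, then repair any in-frame stop
    codons by remutating their third position."""
    arr = np.array(list(seq))
    pos = rng.choice(len(arr), size=min(n_subs, len(arr)), replace=False)
    for p in pos:
        arr[p] = rng.choice([b for b in "ACGT" if b != arr[p]])
    for i in range(0, len(arr) - 2, 3):
        while "".join(arr[i:i + 3]) in STOP_CODONS:
            arr[i + 2] = rng.choice(list("ACGT"))
    return "".join(arr)


def simulate_allele_pool(config: SimulationConfig) -> AlleleCatalog:
    """Generate ``n_alleles_pool`` distinct in-frame alleles (no internal
    stops) plus, optionally, one frameshifted pseudogene carrying the
    configured internal deletion."""
    if config.n_alleles_pool < 2:
        raise ConfigurationError("need n_alleles_pool >= 2")
    rng = config.rng("pool")
    L = config.allele_length_nt
    ancestor = _random_coding_sequence(rng, L)
    max_subs = max(1, int(round(config.pool_divergence * L)))
    seqs: list[str] = []
    seen = set()
    attempts = 0
    while len(seqs) < config.n_alleles_pool:
        n_subs = int(rng.integers(1, max_subs + 1))
        cand = _mutate(rng, ancestor, n_subs)
        attempts += 1
        if attempts > 1000 * config.n_alleles_pool:
            raise ConfigurationError(
                "could not generate enough distinct alleles; "
                "increase pool_divergence or allele_length_nt")
        if cand in seen:
            continue
        seen.add(cand)
        seqs.append(cand)
    width = max(2, len(str(config.n_alleles_pool + 1)))
    alleles = [
        Allele(name=f"{config.allele_name_prefix}*{i + 1:0{width}d}", nt=s)
        for i, s in enumerate(seqs)
    ]
    if config.include_pseudogene:
        start, end = config.pseudogene_deletion_span
        donor = seqs[int(rng.integers(0, len(seqs)))]
        pseudo_nt = donor[:start - 1] + donor[end:]
        alleles.append(Allele(
            name=f"{config.allele_name_prefix}*{config.n_alleles_pool + 1:0{width}d}ps",
            nt=pseudo_nt,
            functional=False,
            flag_reason=f"{end - start + 1}-nt deletion at {start}-{end} (frameshift)",
        ))
    return AlleleCatalog(alleles)


# ---------------------------------------------------------------------------
# genotypes


def simulate_genotypes(pool: AlleleCatalog, config: SimulationConfig) -> SimulationTruth:
    """Assign each individual an allele set of uniform size in
    [1, 2*n_loci], drawn from its population's accessible slice of the pool.

    Population slices are nested and descending in size by default, so later
    (smaller) populations have lower allelic richness.
    """
    if len(pool) == 0:
        raise ConfigurationError("allele pool is empty")
    rng = config.rng("genotypes")
    fractions = config.population_pool_fractions
    if fractions is None:
        if config.n_populations == 1:
            fractions = (1.0,)
        else:
            step = 0.5 / (config.n_populations - 1)
            fractions = tuple(1.0 - step * i for i in range(config.n_populations))
    names = pool.names
    truth = SimulationTruth(allele_pool=pool)
    for p, (n_ind, frac) in enumerate(
            zip(config.individuals_per_population, fractions), start=1):
        accessible = names[:max(1, int(round(frac * len(names))))]
        popname = f"pop{p}"
        for j in range(n_ind):
            ind = f"{popname}_{j + 1:03d}"
            k = int(rng.integers(1, 2 * config.n_loci + 1))
            k = min(k, len(accessible))
            chosen = rng.choice(len(accessible), size=k, replace=False)
            truth.genotype_of[ind] = {accessible[i] for i in chosen}
            truth.population_of[ind] = popname
    truth.validate()
    return truth


# ---------------------------------------------------------------------------
# reads


def _make_mids(rng: np.random.Generator, n: int, length: int) -> list[str]:
    mids: list[str] = []
    seen = set()
    while len(mids) < n:
        mid = "".join(rng.choice(_BASES, size=length))
        # no MID may be a prefix of another (prefix matching must be unique)
        if mid in seen or any(m.startswith(mid) or mid.startswith(m) for m in mids):
            continue
        seen.add(mid)
        mids.append(mid)
    return mids


def _concretize(rng: np.random.Generator, primer: str) -> str:
    from .seqs import IUPAC
    return "".join(
        b if b in "ACGT" else rng.choice(sorted(IUPAC[b])) for b in primer)


def _point_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    n_err = rng.binomial(len(seq), rate)
    if n_err == 0:
        return seq
    arr = np.array(list(seq))
    pos = rng.choice(len(arr), size=n_err, replace=False)
    for p in pos:
        arr[p] = rng.choice([b for b in "ACGT" if b != arr[p]])
    return "".join(arr)


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


def simulate_reads(truth: SimulationTruth, config: SimulationConfig) -> SimulatedReads:
    """Emit MID-tagged amplicon reads per individual.

    Depth is log-normal (heavy-tailed, emulating highly variable amplicon
    yields). Each read is a true allele copy, a point-error derivative, or a
    chimera of two genotype alleles at a uniform breakpoint; chimeras form
    only within an individual. Point errors hit the template region only.
    Reads are emitted in either orientation. Provenance is recorded per read.
    """
    truth.validate()
    rng = config.rng("reads")
    mid_rng = config.rng("mids")
    individuals = sorted(truth.genotype_of)
    mids = _make_mids(mid_rng, len(individuals), config.mid_length)
    mid_map = pd.DataFrame({
        "mid": mids,
        "sample": individuals,
        "population": [truth.population_of[i] for i in individuals],
    })
    mu, sigma = _lognormal_params(config.depth_mean, config.depth_sd)
    seqs = {a.name: a.nt for a in truth.allele_pool}
    reads: list[tuple[str, str]] = []
    depths: dict[str, int] = {}
    counter = 0
    for mid, ind in zip(mids, individuals):
        genotype = sorted(truth.genotype_of[ind])
        depth = 0
        while depth <= 0:
            depth = int(round(rng.lognormal(mu, sigma)))
        depths[ind] = depth
        for _ in range(depth):
            counter += 1
            read_id = f"read{counter:07d}"
            if len(genotype) >= 2 and rng.random() < config.chimera_rate:
                i, j = rng.choice(len(genotype), size=2, replace=False)
                a, b = genotype[i], genotype[j]
                bp = int(rng.integers(1, min(len(seqs[a]), len(seqs[b]))))
                template = seqs[a][:bp] + seqs[b][bp:]
                provenance = {"kind": "chimera", "parents": (a, b), "breakpoint": bp}
            else:
                a = genotype[int(rng.integers(0, len(genotype)))]
                template = seqs[a]
                provenance = {"kind": "true", "source": a}
            mutated = _point_errors(rng, template, config.point_error_rate)
            if mutated != template:
                provenance = {"kind": "point_error", "parent": provenance}
            full = (mid
                    + _concretize(rng, config.forward_primer)
                    + mutated
                    + reverse_complement(_concretize(rng, config.reverse_primer)))
            if rng.random() < 0.5:
                full = reverse_complement(full)
                provenance["orientation"] = "reverse"
            else:
                provenance["orientation"] = "forward"
            provenance["sample"] = ind
            truth.read_provenance[read_id] = provenance
            reads.append((read_id, full))
    return SimulatedReads(reads=reads, mid_map=mid_map, depths=depths)


# ---------------------------------------------------------------------------
# microsatellites


def simulate_microsats(
    config: SimulationConfig,
    n_loci: int,
    allele_freqs,
    individuals_by_population: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """Draw diploid genotypes by random union of gametes.

    ``allele_freqs`` maps population -> list (per locus) of
    ``{allele_name: frequency}``; a bare list applies to every population.
    Returns the long-format microsatellite table.
    """
    rng = config.rng("microsats")
    if individuals_by_population is None:
        individuals_by_population = {
            f"pop{p + 1}": [f"pop{p + 1}_{j + 1:03d}" for j in range(n_ind)]
            for p, n_ind in enumerate(config.individuals_per_population)
        }
    if not isinstance(allele_freqs, dict):
        allele_freqs = {pop: allele_freqs for pop in individuals_by_population}
    rows = []
    for pop, individuals in sorted(individuals_by_population.items()):
        freqs = allele_freqs[pop]
        if len(freqs) != n_loci:
            raise ConfigurationError(
                f"{pop}: {len(freqs)} frequency vectors for {n_loci} loci")
        for locus_i, fvec in enumerate(freqs):
            names = sorted(fvec)
            p = np.array([fvec[a] for a in names], dtype=float)
            if abs(p.sum() - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"{pop} locus {locus_i + 1}: frequencies sum to {p.sum()}")
            for ind in individuals:
                a1, a2 = rng.choice(names, size=2, p=p)
                rows.append({
                    "individual": ind,
                    "population": pop,
                    "locus": f"locus{locus_i + 1}",
                    "allele1": str(a1),
                    "allele2": str(a2),
                })
    return pd.DataFrame(rows)


def default_microsat_freqs(
    config: SimulationConfig, n_loci: int, n_alleles: int = 6,
) -> dict[str, list[dict[str, float]]]:
    """Dirichlet-drawn per-population, per-locus allele frequencies with
    population-specific perturbations (so populations differ)."""
    rng = config.rng("msfreqs")
    out: dict[str, list[dict[str, float]]] = {}
    for p in range(config.n_populations):
        pop = f"pop{p + 1}"
        # smaller populations get more skewed (lower-diversity) frequencies
        alpha = np.full(n_alleles, max(0.2, 1.0 / (p + 1)))
        out[pop] = []
        for _ in range(n_loci):
            f = rng.dirichlet(alpha)
            out[pop].append({f"a{k + 1}": float(f[k]) for k in range(n_alleles)})
    return out
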