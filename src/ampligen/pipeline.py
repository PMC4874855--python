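"""Stage orchestration: simulation -> genotyping -> statistics.

Each stage reads/writes plain-text artifacts (FASTQ/FASTA/TSV/JSON) inside a
run directory and a manifest recording the seed, thresholds, and input
checksums, so a run is fully reproducible from its directory alone.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__, io
from .genotyping import (DEFAULT_MIN_IDENTITY, DEFAULT_MIN_OVERLAP,
                         DEFAULT_MIN_READS, DEFAULT_MPAF_THRESHOLD,
                         DEFAULT_WITHIN_THRESHOLD, GenotypingResult,
                         depth_bias_check, genotype_pipeline, infer_min_loci)
from .models import AlleleCatalog, GenotypeTable
from .popgen import (compare_populations, individual_metrics,
                     population_summary, summary_frame)
from .selection import (DEFAULT_TS_TV_RATIO, run_selection_table,
                        selection_table_frame)
from .simulate import (SimulationConfig, default_microsat_freqs,
                       simulate_allele_pool, simulate_genotypes,
                       simulate_microsats, simulate_reads)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    seed: int = 42
    out_dir: str = "run"
    # genotyping thresholds
    mpaf_threshold: float = DEFAULT_MPAF_THRESHOLD
    within_threshold: float = DEFAULT_WITHIN_THRESHOLD
    within_ref: str = "catalog"
    min_reads: int = DEFAULT_MIN_READS
    min_identity: float = DEFAULT_MIN_IDENTITY
    min_overlap: int = DEFAULT_MIN_OVERLAP
    # selection
    ts_tv_ratio: float = DEFAULT_TS_TV_RATIO
    n_bootstrap: int = 1000
    abs_sites: tuple[int, ...] = ()
    # popgen
    n_perm: int = 10000
    n_resamples: int = 1000
    pi_mode: str = "distinct"
    # simulation
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    n_reference_alleles: int = 5

    def flat(self) -> dict[str, str]:
        # out_dir is a location, not a parameter: excluded so the config
        # hash identifies the analysis, wherever it is written
        d = {k: v for k, v in asdict(self).items() if k not in ("sim", "out_dir")}
        d["abs_sites"] = ",".join(map(str, self.abs_sites))
        d.update({f"sim.{k}": v for k, v in self.sim.to_flat_dict().items()})
        return {k: str(v) for k, v in d.items()}

    @property
    def config_hash(self) -> str:
        return io.config_hash(self.flat())


def _write_manifest(out: Path, config: RunConfig, inputs: dict[str, Path],
                    outputs: list[str]) -> None:
    manifest = {
        "tool": "ampligen",
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash,
        "config": config.flat(),
        "input_checksums": {name: io.file_sha256(p)
                           for name, p in inputs.items() if Path(p).exists()},
        "outputs": sorted(outputs),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# stages


def run_simulate(config: RunConfig, out_dir: Path):
    """Simulate pool, genotypes, reads, and microsatellites; write all
    artifacts plus truth tables."""
    out_dir.mkdir(parents=True, exist_ok=True)
    sim = config.sim
    pool = simulate_allele_pool(sim)
    truth = simulate_genotypes(pool, sim)
    simulated = simulate_reads(truth, sim)
    freqs = default_microsat_freqs(sim, n_loci=sim.n_loci)
    microsats = simulate_microsats(sim, n_loci=sim.n_loci, allele_freqs=freqs)

    seed, chash = config.seed, config.config_hash
    io.write_fastq(out_dir / "reads.fastq", simulated.reads)
    io.write_tsv(out_dir / "mids.tsv", simulated.mid_map, seed=seed, config_hash=chash)
    io.write_fasta(out_dir / "pool.fasta", {a.name: a.nt for a in pool})
    # the first n_reference_alleles functional alleles play the role of
    # previously known sequences for the reference-identity filter
    refs = {a.name: a.nt for a in pool if a.functional}
    refs = dict(list(refs.items())[:config.n_reference_alleles])
    io.write_fasta(out_dir / "refs.fasta", refs)
    truth_df = pd.DataFrame(
        [{"individual": ind, "population": truth.population_of[ind],
          "alleles": ";".join(sorted(truth.genotype_of[ind]))}
         for ind in sorted(truth.genotype_of)])
    io.write_tsv(out_dir / "truth_genotypes.tsv", truth_df, seed=seed, config_hash=chash)
    prov_df = pd.DataFrame(
        [{"read_id": rid, "kind": rec.get("kind"), "sample": rec.get("sample")}
         for rid, rec in sorted(truth.read_provenance.items())])
    io.write_tsv(out_dir / "truth_provenance.tsv", prov_df, seed=seed, config_hash=chash)
    io.write_tsv(out_dir / "microsats.tsv", microsats, seed=seed, config_hash=chash)
    with open(out_dir / "sim_config.txt", "w") as fh:
        for k, v in sim.to_flat_dict().items():
            fh.write(f"{k}={v}\n")
    return truth, simulated, microsats


def run_genotype(config: RunConfig, reads_path, mids_path, refs_path,
                 out_dir: Path) -> GenotypingResult:
    """Demultiplex, filter, and call genotypes; write catalog, genotype
    matrix, MPAF table, and discard log."""
    out_dir.mkdir(parents=True, exist_ok=True)
    reads = io.read_reads(reads_path)
    mid_map = io.read_mid_map(mids_path)
    refs = io.read_fasta(refs_path)
    result = genotype_pipeline(
        reads, mid_map,
        forward_primer=config.sim.forward_primer,
        reverse_primer=config.sim.reverse_primer,
        references=refs,
        mpaf_threshold=config.mpaf_threshold,
        within_threshold=config.within_threshold,
        within_ref=config.within_ref,
        min_reads=config.min_reads,
        min_identity=config.min_identity,
        min_overlap=config.min_overlap,
        known_alleles=refs,
        name_prefix=config.sim.allele_name_prefix,
    )
    seed, chash = config.seed, config.config_hash
    io.write_fasta(out_dir / "catalog.fasta",
                   {a.name: a.nt for a in result.catalog})
    cat_df = pd.DataFrame([{
        "name": a.name, "length": len(a.nt), "functional": int(a.functional),
        "flag_reason": a.flag_reason or "", "mpaf": a.mpaf,
        "pooled_count": a.pooled_count} for a in result.catalog])
    io.write_tsv(out_dir / "catalog.tsv", cat_df, seed=seed, config_hash=chash)
    names = result.catalog.names
    rows = []
    for ind in sorted(result.genotypes.mhc):
        row = {"individual": ind}
        row.update({n: int(n in result.genotypes.mhc[ind]) for n in names})
        rows.append(row)
    io.write_tsv(out_dir / "genotypes.tsv", pd.DataFrame(rows), seed=seed, config_hash=chash)
    pooled = result.filtered_table.pooled_counts()
    mpaf_df = pd.DataFrame(
        [{"variant": v, "mpaf": f, "pooled_count": pooled[v]}
         for v, f in sorted(result.filtered_table.mpaf.items(),
                            key=lambda kv: -kv[1])])
    io.write_tsv(out_dir / "mpaf.tsv", mpaf_df, seed=seed, config_hash=chash)
    discards = pd.DataFrame(
        [{"read_id": r.read_id, "reason": r.discard_reason}
         for r in result.readset.discarded()])
    io.write_tsv(out_dir / "discards.tsv", discards, seed=seed, config_hash=chash)
    excl = pd.DataFrame(
        [{"individual": i, "reason": r}
         for i, r in sorted(result.genotypes.excluded.items())])
    io.write_tsv(out_dir / "excluded.tsv", excl, seed=seed, config_hash=chash)
    if len(result.genotypes.mhc) >= 3:
        try:
            bias = depth_bias_check(result.genotypes.mhc, result.filtered_table)
            report = {"n": bias.n, "rho": bias.rho, "p": bias.p, "note": bias.note,
                      "min_loci": infer_min_loci(result.genotypes.mhc)}
        except Exception as exc:  # degenerate vectors
            report = {"error": str(exc)}
        (out_dir / "depth_bias.json").write_text(json.dumps(report, indent=2) + "\n")
    return result


def run_selection(config: RunConfig, catalog: AlleleCatalog, out_dir: Path):
    out_dir.mkdir(parents=True, exist_ok=True)
    abs_sites = list(config.abs_sites) or None
    results = run_selection_table(catalog, abs_sites=abs_sites,
                                  R=config.ts_tv_ratio,
                                  n_reps=config.n_bootstrap, seed=config.seed)
    df = selection_table_frame(results)
    io.write_tsv(out_dir / "selection.tsv", df, seed=config.seed,
                 config_hash=config.config_hash)
    return results


def run_summarize(config: RunConfig, genotypes: GenotypeTable,
                  catalog: AlleleCatalog, microsats: pd.DataFrame | None,
                  out_dir: Path, read_totals: dict | None = None):
    out_dir.mkdir(parents=True, exist_ok=True)
    summaries = population_summary(
        genotypes, catalog, microsat=microsats,
        n_resamples=config.n_resamples, seed=config.seed,
        pi_mode=config.pi_mode)
    frame = summary_frame(summaries)
    io.write_tsv(out_dir / "population_summary.tsv", frame.reset_index(),
                 seed=config.seed, config_hash=config.config_hash)
    metrics = individual_metrics(genotypes, catalog, read_totals=read_totals)
    io.write_tsv(out_dir / "individual_metrics.tsv", metrics,
                 seed=config.seed, config_hash=config.config_hash)
    comparisons = {}
    if microsats is not None and len(microsats):
        pops = sorted(microsats["population"].unique())
        for i in range(len(pops)):
            for j in range(i + 1, len(pops)):
                key = f"{pops[i]}_vs_{pops[j]}"
                try:
                    comparisons[key] = compare_populations(
                        microsats, pops[i], pops[j],
                        n_perm=config.n_perm, seed=config.seed)
                except ValueError as exc:
                    comparisons[key] = {"error": str(exc)}
        (out_dir / "comparisons.json").write_text(
            json.dumps(comparisons, indent=2) + "\n")
    return summaries, metrics, comparisons


def run_pipeline(config: RunConfig) -> Path:
    """``all`` mode: simulate, genotype, selection, summarize, manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth, simulated, microsats = run_simulate(config, out)
    result = run_genotype(config, out / "reads.fastq", out / "mids.tsv",
                          out / "refs.fasta", out)
    if len(result.catalog.functional()) >= 2:
        run_selection(config, result.catalog, out)
    else:
        logger.warning("fewer than 2 functional alleles: skipping selection stage")
    read_totals = result.filtered_table.sample_totals()
    genotypes = result.genotypes
    for r in microsats.itertuples():
        a1 = r.allele1 if r.allele1 != "" else None
        genotypes.microsat[(r.individual, r.locus)] = (
            (str(r.allele1), str(r.allele2)) if a1 is not None else None)
        genotypes.population.setdefault(r.individual, r.population)
    run_summarize(config, genotypes, result.catalog, microsats, out,
                  read_totals=read_totals)
    outputs = [p.name for p in out.iterdir() if p.is_file() and p.name != "manifest.json"]
    _write_manifest(out, config, inputs={}, outputs=outputs)
    return out
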