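"""Format plumbing: FASTA/FASTQ, TSV tables, GenePop import.

All TSV writers prepend ``#``-comment header lines carrying the run seed and
config hash so that any table can be traced back to the run that produced it;
readers skip those lines transparently.
"""

from __future__ import annotations

import hashlib
import io as _io
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class ParseError(ValueError):
    """Malformed input file; message carries file and line context."""


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def read_fasta(path) -> dict[str, str]:
    """Read FASTA into an ordered ``{id: uppercase sequence}`` mapping."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ParseError(f"{path}: duplicate FASTA id {rec.id!r}")
        out[rec.id] = str(rec.seq).upper()
    return out


def write_fasta(path, seqs: Mapping[str, str], wrap: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            if wrap:
                for i in range(0, len(seq), wrap):
                    fh.write(seq[i:i + wrap] + "\n")
            else:
                fh.write(seq + "\n")


def read_reads(path) -> list[tuple[str, str]]:
    """Read FASTA or FASTQ (sniffed from the first character) as
    ``[(read_id, sequence), ...]``."""
    path = Path(path)
    with open(path) as fh:
        first = fh.read(1)
    fmt = "fastq" if first == "@" else "fasta"
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), fmt)]


def write_fastq(path, reads: Iterable[tuple[str, str]], quality: int = 40) -> None:
    """Write reads as FASTQ with a constant per-base quality."""
    records = (
        SeqRecord(
            Seq(seq),
            id=read_id,
            description="",
            letter_annotations={"phred_quality": [quality] * len(seq)},
        )
        for read_id, seq in reads
    )
    SeqIO.write(records, str(path), "fastq")


# ---------------------------------------------------------------------------
# TSV tables


def write_tsv(path, df: pd.DataFrame, *, seed=None, config_hash=None,
              index: bool = False) -> None:
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        if config_hash is not None:
            fh.write(f"# config={config_hash}\n")
        df.to_csv(fh, sep="\t", index=index)


def read_tsv(path, required: Iterable[str] = ()) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = set(required) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing required column(s) {sorted(missing)}")
    return df


def read_mid_map(path) -> pd.DataFrame:
    """MID map TSV with columns mid, sample, population."""
    df = read_tsv(path, required=("mid", "sample", "population"))
    dup = df["mid"][df["mid"].duplicated()]
    if not dup.empty:
        raise ParseError(f"{path}: duplicate MID {dup.iloc[0]!r}")
    dup = df["sample"][df["sample"].duplicated()]
    if not dup.empty:
        raise ParseError(f"{path}: duplicate sample {dup.iloc[0]!r}")
    return df


def read_microsat_table(path) -> pd.DataFrame:
    """Long-format microsatellite TSV: individual, population, locus,
    allele1, allele2 (blank alleles = missing genotype)."""
    df = read_tsv(path, required=("individual", "population", "locus",
                                  "allele1", "allele2"))
    dup = df[df.duplicated(subset=["individual", "locus"])]
    if not dup.empty:
        row = dup.iloc[0]
        raise ParseError(
            f"{path}: duplicate genotype for individual {row['individual']!r} "
            f"at locus {row['locus']!r}")
    return df


def read_genotype_matrix(path) -> dict[str, set[str]]:
    """0/1 individuals x alleles matrix -> {individual: set of allele names}."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ParseError(f"{path}: duplicated individual id {dup!r}")
    return {ind: {a for a in df.columns if df.at[ind, a] == 1}
            for ind in df.index}


# ---------------------------------------------------------------------------
# GenePop


def read_genepop(path) -> pd.DataFrame:
    """Import a GenePop file as the long-format microsatellite table.

    Supports 2- and 3-digit diploid codes; populations are labeled pop1,
    pop2, ... in file order. Allele code 0 means missing.
    """
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty GenePop file")
    # line 1 is a title; locus names follow (one per line, or comma-separated)
    loci: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().lower() != "pop":
        part = lines[i].strip()
        if part:
            loci.extend(x.strip() for x in part.split(",") if x.strip())
        i += 1
    if not loci:
        raise ParseError(f"{path}: no locus names before first 'pop'")
    rows = []
    pop_idx = 0
    while i < len(lines):
        if lines[i].strip().lower() == "pop":
            pop_idx += 1
            i += 1
            continue
        line = lines[i].strip()
        i += 1
        if not line:
            continue
        if "," not in line:
            raise ParseError(f"{path} line {i}: expected 'name , genotypes'")
        name, geno_part = line.split(",", 1)
        codes = geno_part.split()
        if len(codes) != len(loci):
            raise ParseError(
                f"{path} line {i}: {len(codes)} genotypes for {len(loci)} loci")
        for locus, code in zip(loci, codes):
            width = len(code) // 2
            if len(code) not in (4, 6):
                raise ParseError(f"{path} line {i}: bad genotype code {code!r}")
            a1, a2 = code[:width], code[width:]
            rows.append({
                "individual": name.strip(),
                "population": f"pop{pop_idx}",
                "locus": locus,
                "allele1": "" if int(a1) == 0 else str(int(a1)),
                "allele2": "" if int(a2) == 0 else str(int(a2)),
            })
    df = pd.DataFrame(rows)
    df[["allele1", "allele2"]] = df[["allele1", "allele2"]].astype(str)
    return df


# ---------------------------------------------------------------------------
# config files and hashing


def read_config_file(path) -> dict[str, str]:
    """Flat ``key=value`` config file; '#' starts a comment."""
    out: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ParseError(f"{path} line {lineno}: expected key=value")
        key, value = line.split("=", 1)
        out[key.strip()] = value.strip()
    return out


def config_hash(config: Mapping) -> str:
    payload = "\n".join(f"{k}={config[k]}" for k in sorted(map(str, config)))
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
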