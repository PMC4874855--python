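"""Low-level nucleotide/protein sequence helpers shared across modules."""

from __future__ import annotations

IUPAC = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

# standard genetic code
CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

STOP_CODONS = frozenset(c for c, aa in CODON_TABLE.items() if aa == "*")

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")


def reverse_complement(seq: str) -> str:
    """Reverse complement; degenerate IUPAC codes are complemented too."""
    return seq.upper().translate(_COMPLEMENT)[::-1]


def iupac_match(primer: str, target: str) -> bool:
    """True if ``target`` (ACGT) matches ``primer`` position by position,
    with degenerate primer bases matching any base of their IUPAC set."""
    if len(primer) != len(target):
        return False
    for p, t in zip(primer.upper(), target.upper()):
        allowed = IUPAC.get(p)
        if allowed is None or t not in allowed:
            return False
    return True


def translate(nt: str, frame: int = 1, to_stop: bool = False) -> str:
    """Translate ``nt`` starting at 1-based ``frame`` offset.

    Trailing partial codons are dropped. ``X`` is emitted for codons with
    non-ACGT characters.
    """
    s = nt.upper()[frame - 1:]
    aa = []
    for i in range(0, len(s) - len(s) % 3, 3):
        codon = s[i:i + 3]
        residue = CODON_TABLE.get(codon, "X")
        if to_stop and residue == "*":
            break
        aa.append(residue)
    return "".join(aa)


def has_internal_stop(nt: str, frame: int = 1) -> bool:
    """True if the in-frame translation contains a stop codon.

    The amplified fragment is exon-internal, so any in-frame stop marks a
    nonfunctional sequence.
    """
    return "*" in translate(nt, frame=frame)


def is_transition(a: str, b: str) -> bool:
    """A<->G or C<->T."""
    if a == b:
        return False
    pair = {a, b}
    return pair <= PURINES or pair <= PYRIMIDINES
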