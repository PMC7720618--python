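"""In-silico double restriction digestion for ddRAD enzyme-pair evaluation.

Only fragments with one end cut by each of the two enzymes ("different-end"
fragments) ligate both sequencing adapters and end up in a ddRAD library,
so the figure of merit for an enzyme pair is the count and total length of
different-end fragments inside the size-selection window (100-600 bp by
default) and the genome fraction they cover.

Motifs use IUPAC degeneracy codes and are scanned on the top strand;
palindromic-family motifs such as GANTC (HinfI) and ACGT (HpyCH4IV) give
strand-symmetric site sets, so this suffices for them. Overlapping matches
are allowed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass(frozen=True)
class Enzyme:
    name: str
    motif: str  # IUPAC codes, e.g. GANTC
    cut_offset: int  # bases after motif start, top strand

    def __post_init__(self) -> None:
        if len(self.motif) < 4:
            raise ValueError("recognition motif must be at least 4 bases")
        if not 0 <= self.cut_offset <= len(self.motif):
            raise ValueError("cut offset outside motif")
        bad = set(self.motif.upper()) - set(IUPAC)
        if bad:
            raise ValueError(f"non-IUPAC symbols in motif: {sorted(bad)}")


HINFI = Enzyme("HinfI", "GANTC", 1)
HPYCH4IV = Enzyme("HpyCH4IV", "ACGT", 1)


@dataclass
class Fragment:
    start: int  # 0-based, inclusive
    end: int  # exclusive
    left_end: str  # enzyme name or "terminal"
    right_end: str

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def different_ends(self) -> bool:
        ends = {self.left_end, self.right_end}
        return "terminal" not in ends and len(ends) == 2


@dataclass
class DigestReport:
    """Digest statistics: Frag (all fragments), FragDe (different-end),
    LengthDeFrag (their total bases), DeFrag100_600 and
    LengthDeFrag100_600 (restricted to the size window), and coverage_pct
    (window different-end bases as % of genome length)."""

    frag: int
    frag_de: int
    length_de_frag: int
    de_frag_in_range: int
    length_de_frag_in_range: int
    coverage_pct: float
    size_range: tuple[int, int]


def _motif_regex(motif: str) -> re.Pattern:
    # lookahead so overlapping matches are all found
    body = "".join(f"[{IUPAC[c]}]" for c in motif.upper())
    return re.compile(f"(?=({body}))")


def find_sites(sequence: str, enzyme: Enzyme) -> list[int]:
    """Sorted 0-based cut positions (a cut at position p separates p-1 | p):
    every top-strand match of the IUPAC motif, overlapping matches included,
    cut at match start + offset."""
    seq = sequence.upper()
    return [m.start() + enzyme.cut_offset for m in _motif_regex(enzyme.motif).finditer(seq)]


def digest_pair(sequence: str, enzyme_a: Enzyme, enzyme_b: Enzyme) -> list[Fragment]:
    """Fragments from a double digest, each end labelled with the enzyme that
    produced it; chromosome-terminal ends are labelled "terminal" and never
    count toward different-end fragments."""
    cuts: list[tuple[int, str]] = [(p, enzyme_a.name) for p in find_sites(sequence, enzyme_a)]
    cuts += [(p, enzyme_b.name) for p in find_sites(sequence, enzyme_b)]
    # drop degenerate cuts at the very ends of the sequence
    cuts = sorted((p, name) for p, name in cuts if 0 < p < len(sequence))
    frags: list[Fragment] = []
    prev_pos, prev_name = 0, "terminal"
    for pos, name in cuts:
        if pos == prev_pos:  # both enzymes cutting at the same point
            prev_name = name
            continue
        frags.append(Fragment(prev_pos, pos, prev_name, name))
        prev_pos, prev_name = pos, name
    if len(sequence) > 0:
        frags.append(Fragment(prev_pos, len(sequence), prev_name, "terminal"))
    return frags


def summarize_digest(
    fragments: list[Fragment],
    genome_length: int,
    size_range: tuple[int, int] = (100, 600),
) -> DigestReport:
    """Tabulate a fragment list into the standard enzyme-pair report."""
    lo, hi = size_range
    de = [f for f in fragments if f.different_ends]
    de_in = [f for f in de if lo <= f.length <= hi]
    length_in = sum(f.length for f in de_in)
    return DigestReport(
        frag=len(fragments),
        frag_de=len(de),
        length_de_frag=sum(f.length for f in de),
        de_frag_in_range=len(de_in),
        length_de_frag_in_range=length_in,
        coverage_pct=100.0 * length_in / genome_length if genome_length else 0.0,
        size_range=size_range,
    )


def digest_fasta(
    path: str,
    enzyme_a: Enzyme,
    enzyme_b: Enzyme,
    size_range: tuple[int, int] = (100, 600),
) -> DigestReport:
    """Digest every sequence of a FASTA file and pool the fragments."""
    from Bio import SeqIO

    frags: list[Fragment] = []
    total = 0
    for rec in SeqIO.parse(path, "fasta"):
        seq = str(rec.seq)
        total += len(seq)
        frags.extend(digest_pair(seq, enzyme_a, enzyme_b))
    return summarize_digest(frags, total, size_range)
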