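"""In-silico tryptic digestion with protein-coordinate tracking.

Trypsin cleaves C-terminal to K or R, except before proline (the
FindMod/MASCOT convention).  Peptides carry 1-based inclusive
coordinates in the parent protein so that localized modification sites
can be reported in protein coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio import SeqIO


@dataclass(frozen=True)
class TheoreticalPeptide:
    sequence: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    missed_cleavages: int
    parent_id: str

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError("peptide coordinates inconsistent with sequence length")


def cleavage_sites(sequence: str) -> list[int]:
    """0-based indices after which trypsin cuts (K/R not followed by P)."""
    return [
        i
        for i in range(len(sequence) - 1)
        if sequence[i] in "KR" and sequence[i + 1] != "P"
    ]


def digest(sequence: str, accession: str, max_missed: int = 1) -> list[TheoreticalPeptide]:
    """Tryptic peptides of a protein with 0..max_missed missed cleavages.

    Returns all fragments ordered by (start, end).  Peptides identical
    in sequence but at distinct coordinates are both retained.  No
    length or mass windowing is applied here; that is the prediction
    stage's concern.
    """
    if not sequence:
        raise ValueError("protein sequence is empty")
    cuts = cleavage_sites(sequence)
    # boundaries[i]..boundaries[i+1]-1 is the i-th fully cleaved peptide
    boundaries = [0] + [c + 1 for c in cuts] + [len(sequence)]
    n_frag = len(boundaries) - 1
    peptides = []
    for i in range(n_frag):
        for m in range(min(max_missed, n_frag - 1 - i) + 1):
            start, end = boundaries[i], boundaries[i + m + 1]
            peptides.append(
                TheoreticalPeptide(
                    sequence=sequence[start:end],
                    start=start + 1,
                    end=end,
                    missed_cleavages=m,
                    parent_id=accession,
                )
            )
    peptides.sort(key=lambda p: (p.start, p.end))
    return peptides


def read_fasta(path: str | Path) -> dict[str, str]:
    """Multi-record FASTA → {accession: sequence}; the accession is the
    first whitespace-delimited token of the header."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        records[rec.id] = str(rec.seq).upper()
    return records


def digest_proteins(
    proteins: dict[str, str], max_missed: int = 1
) -> dict[str, list[TheoreticalPeptide]]:
    return {acc: digest(seq, acc, max_missed) for acc, seq in proteins.items()}


def peptides_covering(
    peptides: Iterable[TheoreticalPeptide], position: int
) -> list[TheoreticalPeptide]:
    """Peptides whose coordinate span contains a 1-based protein position."""
    return [p for p in peptides if p.start <= position <= p.end]
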