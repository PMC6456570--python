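"""Genome sequences, regions, and basic DNA string utilities.

Coordinates are 0-based, half-open (BED convention) throughout the
package; 1-based inputs are converted at the boundary by the readers
that accept them.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID = re.compile(r"^[ACGTN]+$")

__all__ = [
    "GenomeSequence",
    "Region",
    "revcomp",
    "gc_fraction",
    "max_homopolymer_run",
    "parse_region",
]


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    """Fraction of G+C bases; N counts toward the denominator."""
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)


def max_homopolymer_run(seq: str) -> int:
    """Length of the longest single-base run."""
    best = 0
    for m in re.finditer(r"(.)\1*", seq):
        best = max(best, m.end() - m.start())
    return best


@dataclass(frozen=True)
class Region:
    """A genomic interval ``chrom:[start, end)``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty region {self.chrom}:{self.start}-{self.end}")
        if self.start < 0:
            raise ValueError("region start must be >= 0")

    @property
    def size(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


def parse_region(text: str) -> Region:
    """Parse ``chrom:start-end`` (0-based half-open) into a Region."""
    m = re.fullmatch(r"([\w.]+):(\d+)-(\d+)", text.replace(",", ""))
    if m is None:
        raise ValueError(f"cannot parse region {text!r}; expected chrom:start-end")
    return Region(m.group(1), int(m.group(2)), int(m.group(3)))


class GenomeSequence:
    """An in-memory genome: uppercase DNA strings keyed by chromosome name.

    The alphabet is restricted to {A, C, G, T, N}; sequences are
    case-folded on construction. Intended for the desk-scale synthetic
    genomes this package operates on, not chromosome-scale assemblies.
    """

    def __init__(self, records: Mapping[str, str], genome_id: str = "genome") -> None:
        if not records:
            raise ValueError("genome must contain at least one sequence")
        clean: dict[str, str] = {}
        for name, seq in records.items():
            s = str(seq).upper()
            if not s:
                raise ValueError(f"chromosome {name!r} is empty")
            if not _VALID.match(s):
                bad = sorted(set(s) - set("ACGTN"))
                raise ValueError(f"chromosome {name!r} contains invalid characters {bad}")
            clean[name] = s
        self.records: dict[str, str] = clean
        self.genome_id = genome_id

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.records.items()}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.records

    def __iter__(self) -> Iterator[str]:
        return iter(self.records)

    def slice(self, chrom: str, start: int, end: int) -> str:
        """Forward-strand sequence of ``chrom:[start, end)`` with bounds checks."""
        seq = self.records[chrom]
        if start < 0 or end > len(seq) or end <= start:
            raise IndexError(f"{chrom}:{start}-{end} outside chromosome of length {len(seq)}")
        return seq[start:end]

    @classmethod
    def from_fasta(cls, path: str | Path, genome_id: str | None = None) -> "GenomeSequence":
        path = Path(path)
        records = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
        return cls(records, genome_id=genome_id or path.stem)

    def to_fasta(self, path: str | Path) -> None:
        recs = [
            SeqRecord(Seq(seq), id=name, description="")
            for name, seq in self.records.items()
        ]
        SeqIO.write(recs, str(path), "fasta")
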