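"""Probe oligo assembly and primer derivation.

Each synthesized oligo is the 5'->3' concatenation of four segments:
a color/detection adapter C (20 nt), a forward PCR adapter F (20 nt),
the genome-targeting sequence T (40 nt), and a reverse PCR adapter R
(20 nt). All oligos of one probe share (C, F, R) and differ in T; each
probe gets a unique (F, R) combination so it can be amplified
selectively out of a pooled synthesis.

Derived primers: forward PCR primer = C + F; reverse PCR primer = T7
promoter + reverse complement of R (appending the promoter for in vitro
transcription); reverse-transcription primer = C. Per-oligo qPCR
forward primers are the reverse complement of the first 20 nt of T.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .genome import revcomp

T7_PROMOTER = "TAATACGACTCACTATAG"

__all__ = [
    "AdapterSet",
    "ProbeOligo",
    "PrimerSet",
    "assign_adapters",
    "build_oligo",
    "primers_for_probe",
    "qpcr_oligo_primers",
    "pool_capacity",
    "dropout_rate",
    "T7_PROMOTER",
]

_DNA = re.compile(r"^[ACGT]+$")


def _check_dna(seq: str, what: str) -> str:
    seq = seq.upper()
    if not _DNA.match(seq):
        raise ValueError(f"{what} must be non-empty ACGT, got {seq!r}")
    return seq


@dataclass(frozen=True)
class AdapterSet:
    """Color adapters, the (F, R) combination pool, and the promoter."""

    c_adapters: dict  # color name -> 20-mer
    fr_pool: tuple  # ordered (F, R) pairs
    t7_promoter: str = T7_PROMOTER

    def __post_init__(self) -> None:
        if len(set(self.c_adapters.values())) != len(self.c_adapters):
            raise ValueError("color adapters must be distinct")
        if len(set(self.fr_pool)) != len(self.fr_pool):
            raise ValueError("(F, R) combinations must be distinct")


@dataclass(frozen=True)
class ProbeOligo:
    c: str
    f: str
    t: str
    r: str

    @property
    def full_sequence(self) -> str:
        return self.c + self.f + self.t + self.r

    def segments(self) -> tuple[str, str, str, str]:
        return (self.c, self.f, self.t, self.r)


@dataclass(frozen=True)
class PrimerSet:
    forward: str  # C + F
    reverse: str  # T7 + revcomp(R)
    rt_primer: str  # C


def assign_adapters(probes: list[tuple[str, str]], adapter_set: AdapterSet) -> dict:
    """Map (probe id, color) pairs to (C, F, R) triples.

    Deterministic: (F, R) combinations are consumed in pool order, so
    the assignment is injective over (F, R) and reproducible.
    """
    if len(probes) > len(adapter_set.fr_pool):
        raise ValueError(
            f"adapter pool exhausted: {len(probes)} probes need {len(probes)} "
            f"(F,R) combinations, pool has {len(adapter_set.fr_pool)}"
        )
    out: dict = {}
    for (probe_id, color), (f_ad, r_ad) in zip(probes, adapter_set.fr_pool):
        if color not in adapter_set.c_adapters:
            raise KeyError(f"no C adapter for color {color!r}")
        out[probe_id] = (adapter_set.c_adapters[color], f_ad, r_ad)
    return out


def build_oligo(
    c: str, f: str, t: str, r: str,
    segment_lengths: tuple[int, int, int, int] | None = (20, 20, 40, 20),
) -> ProbeOligo:
    """Concatenate C, F, T, R (5'->3'); lengths enforced unless None."""
    c, f, t, r = (_check_dna(x, n) for x, n in ((c, "C"), (f, "F"), (t, "T"), (r, "R")))
    if segment_lengths is not None:
        actual = (len(c), len(f), len(t), len(r))
        if actual != tuple(segment_lengths):
            raise ValueError(f"segment lengths {actual} != required {tuple(segment_lengths)}")
    return ProbeOligo(c=c, f=f, t=t, r=r)


def primers_for_probe(assignment: tuple[str, str, str], t7_promoter: str = T7_PROMOTER) -> PrimerSet:
    """(C, F, R) -> amplification and reverse-transcription primers."""
    c, f, r = assignment
    return PrimerSet(forward=c + f, reverse=t7_promoter + revcomp(r), rt_primer=c)


def qpcr_oligo_primers(probe_oligos: list[ProbeOligo]) -> list[str]:
    """Per-oligo qPCR forward primers: revcomp of the first 20 nt of T.

    The shared reverse primer is the probe's RT primer (its C adapter).
    Duplicate T prefixes within a probe yield non-unique primers and a
    warning.
    """
    import warnings

    primers = [revcomp(o.t[:20]) for o in probe_oligos]
    if len(set(primers)) != len(primers):
        warnings.warn("duplicate T prefixes produce non-unique qPCR primers", stacklevel=2)
    return primers


def pool_capacity(pool_size: int, oligos_per_probe: int) -> int:
    """Number of whole probes a synthesis pool can hold."""
    if oligos_per_probe < 1:
        raise ValueError("oligos_per_probe must be >= 1")
    return pool_size // oligos_per_probe


def dropout_rate(failed: int, probes: int, oligos_per_probe: int) -> float:
    """Percentage of oligo species that failed to amplify."""
    total = probes * oligos_per_probe
    if failed < 0 or failed > total:
        raise ValueError("failed count out of range")
    return 100.0 * failed / total
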