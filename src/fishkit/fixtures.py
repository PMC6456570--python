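"""Deterministic synthetic-data generators.

Everything the other modules consume — genomes, oligo databases, 3D dot
tables, adapter pools — can be generated here from an explicit seed, so
the whole package is testable without downloading any reference data.
Each generator is a pure function of its arguments; a single
numpy Generator is created per call and no global state is touched.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from .genome import GenomeSequence, revcomp
from .seqdb import CAND_COLUMNS, OligoDatabase
from .spatial import DOT_COLUMNS
from . import thermo

__all__ = [
    "random_dna",
    "mutate_sequence",
    "synth_genome",
    "synth_database",
    "synth_dot_clouds",
    "synth_adapter_pool",
]

_BASES = np.array(list("ACGT"))


def random_dna(length: int, rng: np.random.Generator, gc: float = 0.5) -> str:
    """Random DNA of the given length and expected GC fraction."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=length, p=p))


def mutate_sequence(seq: str, n_mutations: int, rng: np.random.Generator) -> str:
    """Substitute exactly n_mutations distinct positions to different bases."""
    if n_mutations > len(seq):
        raise ValueError("more mutations than positions")
    positions = rng.choice(len(seq), size=n_mutations, replace=False)
    out = list(seq)
    for pos in positions:
        choices = [b for b in "ACGT" if b != out[pos]]
        out[pos] = choices[rng.integers(len(choices))]
    return "".join(out)


def synth_genome(
    lengths: dict | None = None,
    gc: float = 0.5,
    seed: int = 0,
    genome_id: str = "synthetic",
) -> GenomeSequence:
    """Random genome at the requested GC content; seed-deterministic."""
    lengths = lengths or {"chr1": 20_000}
    rng = np.random.default_rng(seed)
    records = {name: random_dna(n, rng, gc) for name, n in sorted(lengths.items())}
    return GenomeSequence(records, genome_id=genome_id)


def synth_database(
    genome: GenomeSequence,
    k: int = 40,
    gap: float | tuple = 20,
    seed: int = 0,
    start_offset: int = 0,
) -> OligoDatabase:
    """Non-overlapping oligos at controlled spacing, read from the genome.

    ``gap`` is either a constant inter-oligo gap in bp or
    ``("gamma", mean, shape)`` for gamma-jittered gaps (rounded down,
    floor 0). Oligos are laid left to right until the chromosome ends.
    """
    rng = np.random.default_rng(seed)

    def next_gap() -> int:
        if isinstance(gap, tuple):
            kind, mean, shape = gap
            if kind != "gamma":
                raise ValueError(f"unknown spacing model {kind!r}")
            return max(0, int(rng.gamma(shape, mean / shape)))
        return int(gap)

    rows = []
    for chrom in sorted(genome.records):
        clen = genome.lengths[chrom]
        pos = start_offset
        if pos + k > clen:
            raise ValueError(f"chromosome {chrom} too short for one {k}-mer at offset {start_offset}")
        while pos + k <= clen:
            rows.append((chrom, pos, pos + k, genome.slice(chrom, pos, pos + k)))
            pos += k + next_gap()
    frame = pd.DataFrame(rows, columns=CAND_COLUMNS)
    return OligoDatabase(
        k=k, genome_id=genome.genome_id, frame=frame,
        params={"synthetic": True, "gap": str(gap), "seed": seed},
    )


def synth_dot_clouds(
    specs: list[dict],
    seed: int = 0,
    nucleus_id: object = 1,
) -> pd.DataFrame:
    """Gaussian dot clouds: one spec per cloud.

    Each spec is ``{"label": str, "n": int, "center": (x, y, z),
    "sd": float}``; several specs may share a label (two-territory
    chromosomes are two clouds with the same label).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for spec in specs:
        center = np.asarray(spec["center"], dtype=float)
        pts = rng.normal(loc=center, scale=spec["sd"], size=(spec["n"], 3))
        for p in pts:
            rows.append((nucleus_id, spec["label"], p[0], p[1], p[2]))
    return pd.DataFrame(rows, columns=DOT_COLUMNS)


def _pairwise_ok(
    seqs: list[str], pair_threshold: float, temperature: float
) -> bool:
    for a, b in itertools.combinations(seqs, 2):
        if thermo.duplex_dg(a, b, temperature) < pair_threshold:
            return False
    return True


def synth_adapter_pool(
    n: int,
    k: int = 20,
    clique_size: int = 4,
    seed: int = 0,
    self_threshold: float = -5.0,
    pair_threshold: float = -9.0,
    temperature: float = 37.0,
    gc: float = 0.4,
) -> tuple[list[str], list[int]]:
    """Random k-mer pool with a planted mutually compatible subset.

    Returns (sequences, planted_indices). The planted subset is
    rejection-sampled until it passes the self-dimer filter and is
    pairwise compatible (hetero-dimer dG above ``pair_threshold``), so a
    clique of at least ``clique_size`` exists in the compatibility graph
    of the filtered pool. The remaining sequences carry planted
    cross-complementarities (a reverse-complement block of a planted
    member) making them incompatible with the planted subset.
    """
    if clique_size > n:
        raise ValueError("clique size cannot exceed pool size")
    rng = np.random.default_rng(seed)

    planted: list[str] = []
    attempts = 0
    while len(planted) < clique_size:
        cand = random_dna(k, rng, gc)
        attempts += 1
        if attempts > 20_000:
            raise RuntimeError("could not plant a compatible subset; relax the spec")
        if thermo.self_dg(cand, temperature) <= self_threshold:
            continue
        if not _pairwise_ok(planted + [cand], pair_threshold, temperature):
            continue
        planted.append(cand)

    others: list[str] = []
    block = max(10, k // 2)
    while len(others) < n - clique_size:
        base = random_dna(k, rng, gc)
        target = planted[len(others) % clique_size]
        # embed the reverse complement of a chunk of a planted member:
        # a long complementary run makes this sequence cross-dimerize
        chunk = revcomp(target[:block])
        pos = int(rng.integers(0, k - block + 1))
        seq = base[:pos] + chunk + base[pos + block :]
        others.append(seq)

    seqs = planted + others
    order = rng.permutation(n)
    shuffled = [seqs[i] for i in order]
    planted_idx = sorted(int(np.nonzero(order == i)[0][0]) for i in range(clique_size))
    return shuffled, planted_idx
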