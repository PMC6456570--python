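"""Single-probe design: enumerate windows of consecutive database
oligos inside a region of interest and rank them by size, centrality,
and homogeneity.

A probe candidate is N consecutive non-overlapping oligos. Its features:

* size  — covered span, end of last oligo minus start of first
  (half-open, so a single k-mer probe has size k); smaller is better.
* centrality — ``1 - |M - N| / (S/2)`` where M is the probe midpoint, N
  the region midpoint, and S the region size; 1 for a perfectly central
  probe, 0 at the region borders; larger is better.
* homogeneity — reciprocal of the spread of the gaps between
  consecutive oligos, ``H = 1 / sigma_d`` with
  ``sigma_d = (1/(N-1)) * sqrt(sum_i (d_i - mu_d)^2)`` and
  ``mu_d = (1/(N-1)) * sum_i d_i`` over the N-1 gaps; equal gaps give an
  infinite sentinel that outranks every finite value. The ``N-1``
  normalizer sits *outside* the square root by design (see the methods
  note); ``sd_convention="sample"`` switches to the conventional
  sample standard deviation.

Ranking is lexicographic with a tolerance band: the best value of the
first feature defines a relative band (times ``1+r`` when minimizing,
``1-r`` when maximizing), survivors are ordered by the second feature,
ties broken by the third, then by genomic start.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .genome import Region
from .seqdb import OligoDatabase

FEATURES = ("size", "centrality", "homogeneity")
_MINIMIZE = {"size": True, "centrality": False, "homogeneity": False}

__all__ = [
    "ProbeCandidate",
    "RankingSpec",
    "SingleDesignResult",
    "enumerate_candidates",
    "probe_size",
    "centrality",
    "homogeneity",
    "rank_candidates",
    "design_single_probe",
]


@dataclass(frozen=True)
class ProbeCandidate:
    """A window of consecutive oligos with its design features."""

    chrom: str
    starts: tuple
    ends: tuple
    sequences: tuple = ()
    centrality: float = float("nan")

    @property
    def n_oligos(self) -> int:
        return len(self.starts)

    @property
    def start(self) -> int:
        return self.starts[0]

    @property
    def end(self) -> int:
        return self.ends[-1]

    @property
    def size(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0

    @property
    def gaps(self) -> tuple:
        return tuple(s - e for s, e in zip(self.starts[1:], self.ends[:-1]))

    @property
    def homogeneity(self) -> float:
        return homogeneity(self)

    def feature(self, name: str) -> float:
        if name == "size":
            return float(self.size)
        if name == "centrality":
            return self.centrality
        if name == "homogeneity":
            return self.homogeneity
        raise KeyError(name)


@dataclass(frozen=True)
class RankingSpec:
    """Feature precedence, tolerance band, and report length."""

    feature_order: tuple = FEATURES
    tolerance: float = 0.1
    top_m: int = 1

    def __post_init__(self) -> None:
        if sorted(self.feature_order) != sorted(FEATURES):
            raise ValueError(f"feature_order must permute {FEATURES}")
        if self.tolerance < 0:
            raise ValueError("tolerance must be >= 0")
        if self.top_m < 1:
            raise ValueError("top_m must be >= 1")


def probe_size(candidate: ProbeCandidate) -> int:
    """Covered span in bp (half-open end minus start)."""
    return candidate.size


def centrality(candidate: ProbeCandidate, region: Region) -> float:
    """1 - |probe midpoint - region midpoint| / (region size / 2)."""
    return 1.0 - abs(candidate.midpoint - region.midpoint) / (region.size / 2.0)


def homogeneity(candidate: ProbeCandidate, sd_convention: str = "printed") -> float:
    """Reciprocal gap spread; inf sentinel for perfectly even spacing."""
    n = candidate.n_oligos
    if n < 2:
        raise ValueError("homogeneity needs at least 2 oligos")
    d = np.asarray(candidate.gaps, dtype=float)
    mu = d.mean()
    ss = float(((d - mu) ** 2).sum())
    if sd_convention == "printed":
        sigma = math.sqrt(ss) / (n - 1)
    elif sd_convention == "sample":
        sigma = math.sqrt(ss / (n - 2)) if n > 2 else 0.0
    else:
        raise ValueError("sd_convention must be 'printed' or 'sample'")
    return math.inf if sigma == 0.0 else 1.0 / sigma


def enumerate_candidates(
    db: OligoDatabase, region: Region, n_oligos: int
) -> list[ProbeCandidate]:
    """All windows of ``n_oligos`` consecutive oligos fully inside the region."""
    if n_oligos < 2:
        raise ValueError("a probe needs at least 2 oligos")
    f = db.frame
    sel = f[(f["chrom"] == region.chrom) & (f["start"] >= region.start) & (f["end"] <= region.end)]
    starts = sel["start"].to_numpy()
    ends = sel["end"].to_numpy()
    seqs = tuple(sel["sequence"])
    k_avail = len(sel)
    out: list[ProbeCandidate] = []
    for i in range(k_avail - n_oligos + 1):
        cand = ProbeCandidate(
            chrom=region.chrom,
            starts=tuple(int(x) for x in starts[i : i + n_oligos]),
            ends=tuple(int(x) for x in ends[i : i + n_oligos]),
            sequences=seqs[i : i + n_oligos],
        )
        out.append(
            ProbeCandidate(
                chrom=cand.chrom, starts=cand.starts, ends=cand.ends,
                sequences=cand.sequences, centrality=centrality(cand, region),
            )
        )
    return out


def _band(values: list[float], minimize: bool, r: float) -> list[int]:
    """Indices inside the relative tolerance band around the best value."""
    if minimize:
        best = min(values)
        return [i for i, v in enumerate(values) if v <= best * (1.0 + r)]
    best = max(values)
    if math.isinf(best):
        return [i for i, v in enumerate(values) if math.isinf(v)]
    return [i for i, v in enumerate(values) if v >= best * (1.0 - r)]


def _sort_key(c: ProbeCandidate, feat: str) -> float:
    v = c.feature(feat)
    return v if _MINIMIZE[feat] else -v


def rank_candidates(
    candidates: list[ProbeCandidate], ranking: RankingSpec
) -> list[ProbeCandidate]:
    """Tolerance band on feature 1, then sort by features 2, 3 and start."""
    if not candidates:
        return []
    f1, f2, f3 = ranking.feature_order
    values = [c.feature(f1) for c in candidates]
    kept = [candidates[i] for i in _band(values, _MINIMIZE[f1], ranking.tolerance)]
    kept.sort(key=lambda c: (_sort_key(c, f2), _sort_key(c, f3), c.start))
    return kept[: ranking.top_m]


@dataclass
class SingleDesignResult:
    feasible: bool
    best: ProbeCandidate | None
    ranked: list = field(default_factory=list)
    n_candidates: int = 0
    k_available: int = 0
    n_requested: int = 0
    diagnostics: str = ""


def design_single_probe(
    db: OligoDatabase, region: Region, n_oligos: int, ranking: RankingSpec | None = None
) -> SingleDesignResult:
    """Enumerate, score, and rank; deterministic for identical inputs."""
    ranking = ranking or RankingSpec()
    f = db.frame
    sel = f[(f["chrom"] == region.chrom) & (f["start"] >= region.start) & (f["end"] <= region.end)]
    k_avail = len(sel)
    if k_avail < n_oligos:
        return SingleDesignResult(
            feasible=False, best=None, k_available=k_avail, n_requested=n_oligos,
            diagnostics=f"region {region} holds {k_avail} oligos; {n_oligos} requested",
        )
    cands = enumerate_candidates(db, region, n_oligos)
    ranked = rank_candidates(cands, ranking)
    return SingleDesignResult(
        feasible=True, best=ranked[0], ranked=ranked, n_candidates=len(cands),
        k_available=k_avail, n_requested=n_oligos,
    )
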