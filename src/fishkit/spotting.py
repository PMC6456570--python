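"""Spotting (multi-probe) design: spread M probes evenly over a region.

The region is divided into M+1 equal windows; the single-probe designer
runs on the first M windows, the window frame is then shifted by a
fraction of the window size and the search repeats until the cumulative
shift reaches one full window. Each complete probe set is scored by its
set homogeneity

    H_s = 2 / (sigma_D + sigma_S)

where sigma_D is the spread of the M-1 inter-probe distances and
sigma_S the spread of the M probe sizes, both with the 1/(M-1)
normalizer outside the square root (matching the single-probe
convention). A set that is perfectly even in both respects gets an
infinite sentinel. A shift in which any window is infeasible is
discarded whole: a probe set must contain exactly M probes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .design import ProbeCandidate, RankingSpec, SingleDesignResult, design_single_probe
from .genome import Region
from .seqdb import OligoDatabase

__all__ = [
    "ProbeSetCandidate",
    "SpottingResult",
    "window_partition",
    "set_homogeneity",
    "design_probe_set",
]


@dataclass(frozen=True)
class ProbeSetCandidate:
    """An ordered set of probes produced by one window shift."""

    probes: tuple
    window_size: float
    shift_index: int

    @property
    def n_probes(self) -> int:
        return len(self.probes)

    @property
    def inter_probe_distances(self) -> tuple:
        return tuple(
            b.start - a.end for a, b in zip(self.probes[:-1], self.probes[1:])
        )

    @property
    def sizes(self) -> tuple:
        return tuple(p.size for p in self.probes)

    @property
    def h_s(self) -> float:
        return set_homogeneity(self)


def _printed_sd(values, n_minus_1: int) -> float:
    v = np.asarray(values, dtype=float)
    mu = v.mean()
    return math.sqrt(float(((v - mu) ** 2).sum())) / n_minus_1


def set_homogeneity(probe_set: ProbeSetCandidate) -> float:
    """2 / (sigma_D + sigma_S); inf sentinel when both spreads are zero."""
    m = probe_set.n_probes
    if m < 2:
        raise ValueError("set homogeneity needs at least 2 probes")
    sigma_d = _printed_sd(probe_set.inter_probe_distances, m - 1)
    sigma_s = _printed_sd(probe_set.sizes, m - 1)
    total = sigma_d + sigma_s
    return math.inf if total == 0.0 else 2.0 / total


def window_partition(
    region: Region,
    n_probes: int,
    shift_fraction: float = 0.1,
    shift_index: int = 0,
) -> list[Region]:
    """First ``n_probes`` of the M+1 equal windows, shifted.

    Window width w = S/(M+1); window i spans
    [start + i*w + shift_index*shift_fraction*w, ... + w), truncated at
    the region end, with floor rounding to integer coordinates.
    """
    if n_probes < 1:
        raise ValueError("n_probes must be >= 1")
    w = region.size / (n_probes + 1)
    shift = shift_index * shift_fraction * w
    windows = []
    for i in range(n_probes):
        ws = math.floor(region.start + i * w + shift)
        we = math.floor(region.start + (i + 1) * w + shift)
        we = min(we, region.end)
        ws = min(ws, we - 1)
        windows.append(Region(region.chrom, ws, we))
    return windows


@dataclass
class SpottingResult:
    feasible: bool
    best: ProbeSetCandidate | None
    per_shift: list = field(default_factory=list)  # (shift_index, h_s or None, note)
    diagnostics: str = ""


def design_probe_set(
    db: OligoDatabase,
    region: Region,
    n_probes: int,
    n_oligos: int,
    ranking: RankingSpec | None = None,
    shift_fraction: float = 0.1,
) -> SpottingResult:
    """Search all window shifts and return the set with the best
    set homogeneity (ties go to the smaller shift index)."""
    ranking = ranking or RankingSpec()
    if not 0 < shift_fraction <= 1:
        raise ValueError("shift_fraction must be in (0, 1]")
    w = region.size / (n_probes + 1)
    n_shifts = math.ceil(1.0 / shift_fraction)

    if n_probes == 1:
        window = window_partition(region, 1, shift_fraction, 0)[0]
        res = design_single_probe(db, window, n_oligos, ranking)
        if not res.feasible:
            return SpottingResult(False, None, [], res.diagnostics)
        pset = ProbeSetCandidate(probes=(res.best,), window_size=w, shift_index=0)
        return SpottingResult(True, pset, [(0, math.inf, "single-probe degenerate")])

    per_shift: list = []
    best: ProbeSetCandidate | None = None
    best_score = -math.inf
    for shift_index in range(n_shifts):
        if shift_index * shift_fraction * w >= w:
            break
        windows = window_partition(region, n_probes, shift_fraction, shift_index)
        probes: list[ProbeCandidate] = []
        note = ""
        for wi, window in enumerate(windows):
            res: SingleDesignResult = design_single_probe(db, window, n_oligos, ranking)
            if not res.feasible:
                note = f"window {wi} ({window}): {res.diagnostics}"
                break
            probes.append(res.best)
        if note:
            per_shift.append((shift_index, None, note))
            continue
        for a, b in zip(probes[:-1], probes[1:]):
            if b.start < a.end:
                raise AssertionError("probes from consecutive windows overlap")
        pset = ProbeSetCandidate(probes=tuple(probes), window_size=w, shift_index=shift_index)
        score = pset.h_s
        per_shift.append((shift_index, score, ""))
        if score > best_score:
            best, best_score = pset, score
    if best is None:
        return SpottingResult(
            False, None, per_shift, "no shift produced a complete probe set"
        )
    return SpottingResult(True, best, per_shift)
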