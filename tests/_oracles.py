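"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately re-derive results from first principles (plain loops,
exhaustive enumeration, direct table sums) instead of calling the
library code paths they are checking.
"""

from __future__ import annotations

import itertools
import math

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


# ---------------------------------------------------------------- thermo

def run_dg_from_table(run_seq: str, temperature_c: float, params) -> float:
    """Direct stack/initiation/salt sum for a fully paired run."""
    t_k = temperature_c + 273.15
    dh = ds = 0.0
    for i in range(len(run_seq) - 1):
        st = run_seq[i : i + 2]
        h, s = params.nn_table.get(st) or params.nn_table[revcomp(st)]
        dh += h
        ds += s
    for base in (run_seq[0], run_seq[-1]):
        h, s = params.nn_table["init_GC" if base in "GC" else "init_AT"]
        dh += h
        ds += s
    ds += 0.368 * (len(run_seq) - 1) * math.log(params.na_conc)
    return dh - t_k * ds / 1000.0


def brute_duplex_dg(a: str, b: str, temperature_c: float, params,
                    include_revcomp: bool = True) -> float:
    """Min dG over every contiguous complementary run at every offset
    and orientation (not just the longest run per offset)."""
    best = 0.0
    orientations = [b, revcomp(b)] if include_revcomp else [b]
    for s in orientations:
        t = s[::-1]
        for offset in range(-(len(t) - 1), len(a)):
            i = max(0, offset)
            while i < min(len(a), len(t) + offset):
                if _COMP[a[i]] == t[i - offset]:
                    j = i
                    while j + 1 < min(len(a), len(t) + offset) and _COMP[a[j + 1]] == t[j + 1 - offset]:
                        j += 1
                    # every sub-run of [i, j]
                    for p in range(i, j + 1):
                        for q in range(p + 1, j + 1):
                            best = min(best, run_dg_from_table(a[p : q + 1], temperature_c, params))
                    i = j + 1
                else:
                    i += 1
    return min(best, 0.0)


# ---------------------------------------------------------------- design

def single_probe_oracle(oligos, region, n, order, tolerance, top_m):
    """Exhaustive single-probe scoring.

    ``oligos``: list of (start, end) inside the database chromosome;
    ``region``: (start, end). Returns the ranked list of candidate
    index tuples with their features, best first.
    """
    rs, re_ = region
    inside = [(s, e) for s, e in oligos if s >= rs and e <= re_]
    cands = []
    for i in range(len(inside) - n + 1):
        win = inside[i : i + n]
        starts = [s for s, _ in win]
        ends = [e for _, e in win]
        size = ends[-1] - starts[0]
        mid = (starts[0] + ends[-1]) / 2
        cent = 1 - abs(mid - (rs + re_) / 2) / ((re_ - rs) / 2)
        gaps = [starts[j + 1] - ends[j] for j in range(n - 1)]
        mu = sum(gaps) / len(gaps)
        sigma = math.sqrt(sum((g - mu) ** 2 for g in gaps)) / (n - 1)
        hom = math.inf if sigma == 0 else 1 / sigma
        cands.append({"start": starts[0], "size": size, "centrality": cent,
                      "homogeneity": hom})
    if not cands:
        return []
    f1, f2, f3 = order
    minimize = {"size": True, "centrality": False, "homogeneity": False}
    vals = [c[f1] for c in cands]
    if minimize[f1]:
        best = min(vals)
        kept = [c for c in cands if c[f1] <= best * (1 + tolerance)]
    else:
        best = max(vals)
        if math.isinf(best):
            kept = [c for c in cands if math.isinf(c[f1])]
        else:
            kept = [c for c in cands if c[f1] >= best * (1 - tolerance)]

    def key(c):
        k2 = c[f2] if minimize[f2] else -c[f2]
        k3 = c[f3] if minimize[f3] else -c[f3]
        return (k2, k3, c["start"])

    kept.sort(key=key)
    return kept[:top_m]


def spotting_oracle(oligos, region, n_probes, n_oligos, order, tolerance,
                    shift_fraction):
    """Exhaustive shift search; returns (best_shift, best_hs, per_shift)."""
    rs, re_ = region
    size = re_ - rs
    w = size / (n_probes + 1)
    n_shifts = math.ceil(1.0 / shift_fraction)
    per_shift = {}
    best_shift, best_hs = None, -math.inf
    for si in range(n_shifts):
        shift = si * shift_fraction * w
        if shift >= w:
            break
        probes = []
        ok = True
        for i in range(n_probes):
            ws = math.floor(rs + i * w + shift)
            we = min(math.floor(rs + (i + 1) * w + shift), re_)
            ws = min(ws, we - 1)
            ranked = single_probe_oracle(oligos, (ws, we), n_oligos, order,
                                         tolerance, 1)
            if not ranked:
                ok = False
                break
            probes.append(ranked[0])
        if not ok:
            per_shift[si] = None
            continue
        sizes = [p["size"] for p in probes]
        # recompute probe spans: start + size
        spans = [(p["start"], p["start"] + p["size"]) for p in probes]
        dists = [spans[i + 1][0] - spans[i][1] for i in range(n_probes - 1)]
        m = n_probes

        def printed_sd(vals):
            mu = sum(vals) / len(vals)
            return math.sqrt(sum((v - mu) ** 2 for v in vals)) / (m - 1)

        tot = printed_sd(dists) + printed_sd(sizes)
        hs = math.inf if tot == 0 else 2.0 / tot
        per_shift[si] = hs
        if hs > best_hs:
            best_shift, best_hs = si, hs
    return best_shift, best_hs, per_shift


# ---------------------------------------------------------------- clique

def brute_force_max_clique(n: int, edges: set) -> int:
    """Maximum clique size by subset enumeration over bitmasks."""
    adj = [0] * n
    for u, v in edges:
        adj[u] |= 1 << v
        adj[v] |= 1 << u
    best = 0
    for mask in range(1, 1 << n):
        if mask.bit_count() <= best:
            continue
        m = mask
        ok = True
        while m:
            v = (m & -m).bit_length() - 1
            m &= m - 1
            if (mask & ~adj[v]) != (1 << v):  # v must see every other member
                ok = False
                break
        if ok:
            best = mask.bit_count()
    return best


def brute_count_sites(candidate: str, genome: dict, min_matches: int,
                      max_matches: int | None = None) -> int:
    """Plain-loop both-strand ungapped site count."""
    k = len(candidate)
    hi = max_matches if max_matches is not None else k
    n = 0
    for seq in genome.values():
        for strand in (seq, revcomp(seq)):
            for i in range(len(strand) - k + 1):
                m = sum(1 for x, y in zip(candidate, strand[i : i + k]) if x == y)
                if min_matches <= m <= hi:
                    n += 1
    return n
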