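"""Orthogonal adapter selection.

From a pool of genome-orthogonal source sequences, extract all 20-mer
substrings, discard those with appreciable genome homology (>= 80%
identity anywhere, either strand) or stable self-dimers (dG <= -5
kcal/mol), build a compatibility graph whose edges join pairs with
hetero-dimerization dG >= -9 kcal/mol (minimum over the pair and the
partner's reverse complement), and return the largest mutually
compatible set as a maximum clique.

The exact clique solver is a deterministic branch-and-bound with greedy
coloring bounds; above ``exact_limit`` nodes a degeneracy-ordered greedy
heuristic is used instead and the result is flagged as such.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import networkx as nx

from .genome import GenomeSequence, revcomp
from .seqdb import count_sites_batch
from . import thermo

__all__ = [
    "AdapterCandidate",
    "extract_substrings",
    "filter_genome_homology",
    "filter_self_dimer",
    "build_compat_graph",
    "max_compatible_set",
]


@dataclass(frozen=True)
class AdapterCandidate:
    sequence: str
    self_dg: float = 0.0
    max_genome_identity: float = 0.0


def extract_substrings(seqs: list[str], k: int = 20, dedupe: bool = False) -> list[str]:
    """All length-k substrings of each input, in (input order, offset) order."""
    out: list[str] = []
    seen: set[str] = set()
    for seq in seqs:
        seq = seq.upper()
        if len(seq) < k:
            warnings.warn(f"input of length {len(seq)} shorter than k={k}; skipped",
                          stacklevel=2)
            continue
        for i in range(len(seq) - k + 1):
            sub = seq[i : i + k]
            if dedupe:
                if sub in seen:
                    continue
                seen.add(sub)
            out.append(sub)
    return out


def filter_genome_homology(
    candidates: list[str], genome: GenomeSequence | None, max_identity: float = 0.80
) -> list[str]:
    """Discard candidates with any genome site at >= max_identity
    (ungapped, both strands). ``genome=None`` retains everything."""
    if genome is None or not candidates:
        return list(candidates)
    k = len(candidates[0])
    need = math.ceil(max_identity * k)
    counts = count_sites_batch([c.upper() for c in candidates], genome, need)
    return [c for c, n in zip(candidates, counts) if n == 0]


def filter_self_dimer(
    candidates: list[str],
    threshold: float = -5.0,
    temperature: float = 37.0,
    params: thermo.ThermoParams | None = None,
) -> list[AdapterCandidate]:
    """Discard candidates whose self-dimerization dG <= threshold."""
    out = []
    for seq in candidates:
        dg = thermo.self_dg(seq, temperature, params)
        if dg > threshold:
            out.append(AdapterCandidate(sequence=seq, self_dg=dg))
    return out


def build_compat_graph(
    candidates: list,
    threshold: float = -9.0,
    temperature: float = 37.0,
    params: thermo.ThermoParams | None = None,
) -> nx.Graph:
    """Compatibility graph: nodes are candidate indices (with ``sequence``
    attributes); an edge joins pairs whose hetero-dimer dG (min over the
    partner and its reverse complement) stays above the threshold."""
    seqs = [c.sequence if isinstance(c, AdapterCandidate) else str(c) for c in candidates]
    g = nx.Graph()
    for i, s in enumerate(seqs):
        g.add_node(i, sequence=s)
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            dg = thermo.duplex_dg(seqs[i], seqs[j], temperature, params, include_revcomp=True)
            if dg >= threshold:
                g.add_edge(i, j, pair_dg=dg)
    return g


def _adjacency_masks(graph: nx.Graph) -> tuple[list, list[int]]:
    nodes = sorted(graph.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    adj = [0] * len(nodes)
    for u, v in graph.edges:
        adj[index[u]] |= 1 << index[v]
        adj[index[v]] |= 1 << index[u]
    return nodes, adj


def _greedy_color_bound(cand: int, adj: list[int]) -> list[tuple[int, int]]:
    """Greedy coloring of candidate set; returns (vertex, color#) in
    non-decreasing color order for branch ordering/bounding."""
    order: list[tuple[int, int]] = []
    color = 0
    remaining = cand
    while remaining:
        color += 1
        avail = remaining
        while avail:
            v = (avail & -avail).bit_length() - 1
            order.append((v, color))
            avail &= ~adj[v]
            avail &= ~(1 << v)
            remaining &= ~(1 << v)
    return order


def _bb_max_clique(adj: list[int], n: int) -> int:
    """Maximum clique as a bitmask (Tomita-style branch and bound)."""
    best_mask = 0
    best_size = 0

    def expand(r_mask: int, r_size: int, cand: int) -> None:
        nonlocal best_mask, best_size
        order = _greedy_color_bound(cand, adj)
        for v, color in reversed(order):
            if r_size + color <= best_size:
                return
            new_r = r_mask | (1 << v)
            new_cand = cand & adj[v]
            if new_cand:
                expand(new_r, r_size + 1, new_cand)
            elif r_size + 1 > best_size:
                best_mask, best_size = new_r, r_size + 1
            cand &= ~(1 << v)

    if n:
        expand(0, 0, (1 << n) - 1)
    return best_mask


def _clique_exists(adj: list[int], cand: int, need: int) -> bool:
    """Is there a clique of size >= need within the candidate mask?"""
    if need <= 0:
        return True
    if cand.bit_count() < need:
        return False
    order = _greedy_color_bound(cand, adj)
    if order and order[-1][1] < need:
        return False
    for v, color in reversed(order):
        if color < need:
            return False
        if _clique_exists(adj, cand & adj[v], need - 1):
            return True
        cand &= ~(1 << v)
    return False


def _lex_smallest_clique(adj: list[int], n: int, size: int) -> list[int]:
    """Lexicographically smallest vertex set forming a clique of ``size``."""
    chosen: list[int] = []
    cand = (1 << n) - 1
    need = size
    v = 0
    while need:
        while v < n:
            if cand & (1 << v) and _clique_exists(adj, cand & adj[v], need - 1):
                chosen.append(v)
                cand &= adj[v]
                need -= 1
                v += 1
                break
            v += 1
        else:  # pragma: no cover - guarded by construction
            raise RuntimeError("clique reconstruction failed")
    return chosen


def _degeneracy_greedy(adj: list[int], n: int) -> list[int]:
    """Deterministic greedy clique via degeneracy ordering."""
    degree = [adj[v].bit_count() for v in range(n)]
    removed = [False] * n
    order: list[int] = []
    for _ in range(n):
        v = min((x for x in range(n) if not removed[x]), key=lambda x: (degree[x], x))
        order.append(v)
        removed[v] = True
        mask = adj[v]
        while mask:
            u = (mask & -mask).bit_length() - 1
            mask &= mask - 1
            if not removed[u]:
                degree[u] -= 1
    best: list[int] = []
    for start in reversed(order):
        clique = [start]
        cand = adj[start]
        while cand:
            u = (cand & -cand).bit_length() - 1
            clique.append(u)
            cand &= adj[u]
        if len(clique) > len(best):
            best = sorted(clique)
    return best


def max_compatible_set(graph: nx.Graph, exact_limit: int = 64) -> tuple[list, bool]:
    """Largest mutually compatible node set.

    Returns (nodes, exact). Exact branch-and-bound when the graph has at
    most ``exact_limit`` nodes (ties resolved to the lexicographically
    smallest node-index set); a deterministic degeneracy-ordered greedy
    heuristic beyond that, flagged by ``exact=False``.
    """
    if graph.number_of_nodes() == 0:
        return [], True
    nodes, adj = _adjacency_masks(graph)
    n = len(nodes)
    if n <= exact_limit:
        best_mask = _bb_max_clique(adj, n)
        size = best_mask.bit_count()
        idxs = _lex_smallest_clique(adj, n, size)
        return [nodes[i] for i in sorted(idxs)], True
    idxs = _degeneracy_greedy(adj, n)
    return [nodes[i] for i in idxs], False
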