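"""Spatial statistics on per-nucleus 3D FISH dot tables.

A dot table is a pandas DataFrame with columns
(nucleus_id, label, x, y, z); the label names a chromosome/channel and
coordinates are in a consistent length unit per table (pixels or nm).

Implemented statistics:

* count-based nucleus filtering — a nucleus enters a pairwise analysis
  only when each chromosome's dot count is within a tolerance of the
  expected count (number of probes times the ploidy factor, 2 for G1
  diploid cells);
* mixing index — the pair's joint bounding box is divided into cubes of
  a given side; the index is the fraction of dot-occupied cubes holding
  dots of both chromosomes;
* nearest-neighbor index — per direction, the fraction of one
  chromosome's dots whose nearest neighbor (among all dots of the pair)
  belongs to the other chromosome; distance ties break toward the
  homologous neighbor, which deflates apparent intermingling;
* 2-means territory clustering with a GAP-statistic guard for the
  single-territory case, silhouette quality, and convex-hull volumes of
  channel-subset sub-clusters.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError, cKDTree
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_samples

DOT_COLUMNS = ["nucleus_id", "label", "x", "y", "z"]

__all__ = [
    "ExpectedCounts",
    "MixingResult",
    "NeighborResult",
    "read_dot_table",
    "write_dot_table",
    "filter_nuclei_by_counts",
    "mixing_index",
    "neighbor_index",
    "cluster_territories",
    "silhouette_mean",
    "territory_volume",
]


@dataclass(frozen=True)
class ExpectedCounts:
    """Expected dots per label: probes x ploidy (2 for G1 diploid)."""

    probes_per_label: dict
    ploidy_factor: int = 2

    def expected(self, label: str) -> float:
        try:
            return self.probes_per_label[label] * self.ploidy_factor
        except KeyError:
            raise KeyError(f"label {label!r} missing from expected counts") from None


@dataclass(frozen=True)
class MixingResult:
    nucleus_id: object
    label_pair: tuple
    cube_side: float
    n_cubes_with_dots: int
    n_cubes_both: int
    mixing_index: float


@dataclass(frozen=True)
class NeighborResult:
    nucleus_id: object
    direction: tuple  # (from_label, to_label)
    fraction_heterologous: float


def read_dot_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in DOT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"dot table missing columns {missing}")
    if not np.isfinite(df[["x", "y", "z"]].to_numpy()).all():
        raise ValueError("dot coordinates must be finite")
    return df[DOT_COLUMNS].copy()


def write_dot_table(df: pd.DataFrame, path: str | Path) -> None:
    df[DOT_COLUMNS].to_csv(path, sep="\t", index=False)


def _coords(dots: pd.DataFrame | np.ndarray) -> np.ndarray:
    if isinstance(dots, pd.DataFrame):
        return dots[["x", "y", "z"]].to_numpy(dtype=float)
    a = np.asarray(dots, dtype=float)
    if a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("expected an (n, 3) coordinate array")
    return a


def filter_nuclei_by_counts(
    dots: pd.DataFrame,
    expected: ExpectedCounts,
    tolerance: float,
) -> dict:
    """Retained nucleus ids per label pair.

    A nucleus is kept for pair (a, b) iff each label's dot count lies in
    [(1-tol)*E, (1+tol)*E] inclusive, with E the expected count.
    """
    if not 0 <= tolerance < 1:
        raise ValueError("tolerance must be in [0, 1)")
    labels = sorted(expected.probes_per_label)
    counts = dots.groupby(["nucleus_id", "label"]).size()
    ok: dict = {}
    for lab in labels:
        e = expected.expected(lab)
        lo, hi = (1 - tolerance) * e, (1 + tolerance) * e
        per_nucleus = counts.xs(lab, level="label") if lab in counts.index.get_level_values(1) else pd.Series(dtype=int)
        ok[lab] = {nid for nid, c in per_nucleus.items() if lo <= c <= hi}
    out: dict = {}
    for a, b in itertools.combinations(labels, 2):
        out[(a, b)] = sorted(ok[a] & ok[b], key=str)
    return out


def mixing_index(
    dots_a: pd.DataFrame | np.ndarray,
    dots_b: pd.DataFrame | np.ndarray,
    cube_side: float,
    nucleus_id: object = None,
    label_pair: tuple = ("A", "B"),
) -> MixingResult:
    """Fraction of occupied grid cubes containing dots of both labels.

    The grid is anchored at the minimum corner of the joint bounding box
    of the two dot sets; dots exactly on the maximum boundary fall into
    the last cube.
    """
    if cube_side <= 0:
        raise ValueError("cube_side must be positive")
    a, b = _coords(dots_a), _coords(dots_b)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("mixing index undefined when a dot set is empty")
    allpts = np.vstack([a, b])
    lo = allpts.min(axis=0)
    hi = allpts.max(axis=0)
    n_cubes = np.maximum(np.ceil((hi - lo) / cube_side), 1).astype(int)

    def cube_ids(pts: np.ndarray) -> set:
        idx = np.floor((pts - lo) / cube_side).astype(int)
        idx = np.minimum(idx, n_cubes - 1)  # max-boundary dots -> last cube
        return set(map(tuple, idx))

    ca, cb = cube_ids(a), cube_ids(b)
    occupied = ca | cb
    both = ca & cb
    return MixingResult(
        nucleus_id=nucleus_id,
        label_pair=tuple(label_pair),
        cube_side=cube_side,
        n_cubes_with_dots=len(occupied),
        n_cubes_both=len(both),
        mixing_index=len(both) / len(occupied),
    )


def _fraction_hetero(own: np.ndarray, other: np.ndarray) -> float:
    """Fraction of ``own`` dots whose nearest neighbor (self excluded)
    is in ``other``; exact ties count as homologous."""
    if len(other) == 0:
        return 0.0
    tree_other = cKDTree(other)
    d_het, _ = tree_other.query(own, k=1)
    if len(own) >= 2:
        tree_own = cKDTree(own)
        d_hom, _ = tree_own.query(own, k=2)
        d_hom = d_hom[:, 1]
    else:
        d_hom = np.full(len(own), np.inf)
    return float(np.mean(d_het < d_hom))


def neighbor_index(
    dots_a: pd.DataFrame | np.ndarray,
    dots_b: pd.DataFrame | np.ndarray,
    nucleus_id: object = None,
    labels: tuple = ("A", "B"),
) -> tuple[NeighborResult, NeighborResult]:
    """Heterologous nearest-neighbor fractions, both directions."""
    a, b = _coords(dots_a), _coords(dots_b)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("neighbor index undefined when a dot set is empty")
    if len(a) + len(b) < 2:
        raise ValueError("need at least two dots overall")
    return (
        NeighborResult(nucleus_id, (labels[0], labels[1]), _fraction_hetero(a, b)),
        NeighborResult(nucleus_id, (labels[1], labels[0]), _fraction_hetero(b, a)),
    )


def _log_wk(points: np.ndarray, k: int, seed: int) -> float:
    if k == 1:
        centroid = points.mean(axis=0)
        w = float(((points - centroid) ** 2).sum())
    else:
        km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(points)
        w = float(km.inertia_)
    return math.log(max(w, 1e-300))


def cluster_territories(
    dots: pd.DataFrame | np.ndarray, seed: int = 0, gap_refs: int = 100
) -> np.ndarray:
    """2-means labels, or all zeros when the GAP statistic prefers k=1.

    GAP uses uniform references over the axis-aligned bounding box and
    the one-standard-error rule: keep k=1 when
    Gap(1) >= Gap(2) - s(2). Deterministic for a fixed seed.
    """
    pts = _coords(dots)
    if len(pts) < 2:
        raise ValueError("need at least 2 dots to cluster")
    if np.allclose(pts, pts[0]):
        return np.zeros(len(pts), dtype=int)
    rng = np.random.default_rng(seed)
    lo, hi = pts.min(axis=0), pts.max(axis=0)
    log_w = {k: _log_wk(pts, k, seed) for k in (1, 2)}
    ref_log_w = {1: [], 2: []}
    for _ in range(gap_refs):
        ref = rng.uniform(lo, hi, size=pts.shape)
        for k in (1, 2):
            ref_log_w[k].append(_log_wk(ref, k, seed))
    gap = {k: float(np.mean(ref_log_w[k])) - log_w[k] for k in (1, 2)}
    s2 = float(np.std(ref_log_w[2])) * math.sqrt(1 + 1 / gap_refs)
    if gap[1] >= gap[2] - s2:
        return np.zeros(len(pts), dtype=int)
    km = KMeans(n_clusters=2, n_init=10, random_state=seed).fit(pts)
    return km.labels_.astype(int)


def silhouette_mean(dots: pd.DataFrame | np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette over all dots; singleton clusters score 0.

    Returns NaN (explicit sentinel) when fewer than two clusters exist.
    """
    pts = _coords(dots)
    labels = np.asarray(labels)
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        return float("nan")
    if (counts == 1).all():
        return 0.0
    if (counts >= 1).all() and len(uniq) <= len(pts) - 1:
        vals = silhouette_samples(pts, labels)
        # sklearn assigns 0 to singleton clusters already
        return float(vals.mean())
    return 0.0


def _prune_isolated(pts: np.ndarray, prune_dist: float) -> np.ndarray:
    """Mask of dots whose nearest other dot is within prune_dist."""
    if len(pts) < 2:
        return np.zeros(len(pts), dtype=bool)
    tree = cKDTree(pts)
    d, _ = tree.query(pts, k=2)
    return d[:, 1] <= prune_dist


def _hull_volume(pts: np.ndarray) -> float:
    if len(pts) < 4:
        return 0.0
    try:
        return float(ConvexHull(pts).volume)
    except QhullError:  # coplanar / degenerate
        return 0.0


def territory_volume(
    dots: pd.DataFrame,
    expected: ExpectedCounts,
    tolerance: float = 0.3,
    prune_dist: float = 1300.0,
    seed: int = 0,
    gap_refs: int = 100,
) -> list[dict]:
    """Convex-hull volumes of channel-subset sub-clusters in one nucleus.

    Dots farther than ``prune_dist`` from every other dot are removed;
    the remainder (all channels together) is split into territories by
    2-means unless the GAP statistic prefers one cluster. Within each
    territory, every non-empty channel subset whose per-channel dot
    count is within ``tolerance`` of the expected count yields one
    record with its convex-hull volume. ``expected`` should carry the
    per-territory expectation (ploidy_factor=1 for one territory of a
    diploid G1 cell).
    """
    pts = _coords(dots)
    labels = dots["label"].to_numpy()
    keep = _prune_isolated(pts, prune_dist)
    pts, labels = pts[keep], labels[keep]
    if len(pts) < 2:
        return []
    cluster_labels = cluster_territories(pts, seed=seed, gap_refs=gap_refs)
    channels = sorted(expected.probes_per_label)
    out: list[dict] = []
    for cl in sorted(set(cluster_labels)):
        in_cluster = cluster_labels == cl
        for r in range(1, len(channels) + 1):
            for subset in itertools.combinations(channels, r):
                ok = True
                sel = np.zeros(len(pts), dtype=bool)
                for ch in subset:
                    ch_mask = in_cluster & (labels == ch)
                    e = expected.expected(ch)
                    if not (1 - tolerance) * e <= ch_mask.sum() <= (1 + tolerance) * e:
                        ok = False
                        break
                    sel |= ch_mask
                if not ok:
                    continue
                out.append(
                    {
                        "cluster": int(cl),
                        "channels": subset,
                        "n_dots": int(sel.sum()),
                        "volume": _hull_volume(pts[sel]),
                    }
                )
    return out
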