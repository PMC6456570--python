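"""Genome-wide oligo database construction, conversion, and validation.

The pipeline mirrors a genome-wide unique k-mer mining workflow:
uniqueness -> base composition (homopolymer + GC) -> multi-locus
homology -> secondary structure at the hybridization temperature ->
melting-temperature window around the post-composition mean -> greedy
non-overlap selection -> off-target flagging. Candidates travel through
the stages as a pandas DataFrame with columns
(chrom, start, end, sequence [, tm, dg_struct, offtarget_flag]).

Homology and off-target scans are brute-force ungapped comparisons of
the candidate against every genome window on both strands, vectorised
with a one-hot match-count matmul so that 10-100 kb synthetic genomes
run in seconds. External k-mer counters and aligners are intentionally
not used: the filtering semantics themselves are the contract.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import GenomeSequence, gc_fraction, max_homopolymer_run, revcomp
from . import thermo

CAND_COLUMNS = ["chrom", "start", "end", "sequence"]
DB_COLUMNS = CAND_COLUMNS + ["tm", "dg_struct", "offtarget_flag"]

_BASE_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i

__all__ = [
    "DbParams",
    "OligoDatabase",
    "DatabaseStats",
    "ValidationReport",
    "extract_unique_kmers",
    "filter_composition",
    "filter_tm_window",
    "count_homologous_sites",
    "filter_homology",
    "filter_secondary_structure",
    "flag_offtargets",
    "annotate_offtargets",
    "select_nonoverlapping",
    "build_database",
    "convert_database",
    "validate_database",
    "database_stats",
]


@dataclass(frozen=True)
class DbParams:
    """Filter parameter set for database construction.

    Defaults follow the 40-mer mining recipe: homopolymer runs of 7+
    rejected (max_run 6), GC in [0.35, 0.80] inclusive, homology
    threshold 70% to more than one locus, structure filter dG < 0 at
    65 C, Tm within +-10 C of the post-composition mean, off-target
    flag when more than 10 sites carry 1-5 mismatches.
    """

    max_run: int = 6
    gc_min: float = 0.35
    gc_max: float = 0.80
    homology_identity: float = 0.70
    structure_temperature: float = 65.0
    tm_half_width: float = 10.0
    mm_min: int = 1
    mm_max: int = 5
    flag_threshold: int = 10
    canonical: bool = True
    homology_filter: bool = True
    structure_filter: bool = True
    tm_filter: bool = True


def _encode(seq: str) -> np.ndarray:
    return _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _empty_candidates() -> pd.DataFrame:
    return pd.DataFrame(columns=CAND_COLUMNS)


def extract_unique_kmers(
    genome: GenomeSequence, k: int, canonical: bool = True
) -> pd.DataFrame:
    """All positions whose k-mer occurs exactly once genome-wide.

    ``canonical=True`` merges forward and reverse-complement occurrences
    before counting (hybridization is strand-agnostic); k-mers containing
    N are excluded. Output sorted by (chrom, start).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    counts: dict[str, int] = {}
    positions: list[tuple[str, int, str]] = []
    for chrom in sorted(genome.records):
        seq = genome.records[chrom]
        for start in range(len(seq) - k + 1):
            kmer = seq[start : start + k]
            if "N" in kmer:
                continue
            key = min(kmer, revcomp(kmer)) if canonical else kmer
            counts[key] = counts.get(key, 0) + 1
            positions.append((chrom, start, kmer))
    rows = []
    for chrom, start, kmer in positions:
        key = min(kmer, revcomp(kmer)) if canonical else kmer
        if counts[key] == 1:
            rows.append((chrom, start, start + k, kmer))
    df = pd.DataFrame(rows, columns=CAND_COLUMNS)
    return df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def filter_composition(
    candidates: pd.DataFrame,
    max_run: int = 6,
    gc_min: float = 0.35,
    gc_max: float = 0.80,
) -> pd.DataFrame:
    """Retain sequences with longest run <= max_run and GC in [gc_min, gc_max]."""
    if candidates.empty:
        return candidates.copy()
    keep = candidates["sequence"].map(
        lambda s: max_homopolymer_run(s) <= max_run and gc_min <= gc_fraction(s) <= gc_max
    )
    return candidates[keep].reset_index(drop=True)


def filter_tm_window(
    candidates: pd.DataFrame,
    half_width: float = 10.0,
    params: thermo.ThermoParams | None = None,
    reference_tm: float | None = None,
) -> pd.DataFrame:
    """Retain candidates with |Tm - reference| <= half_width.

    ``reference_tm`` defaults to the mean Tm of the input set; the
    database pipeline passes the mean computed right after the
    composition stage. Retained rows carry a ``tm`` column.
    """
    if candidates.empty:
        return candidates.copy()
    out = candidates.copy()
    if "tm" not in out.columns:
        out["tm"] = [thermo.melting_temperature(s, params) for s in out["sequence"]]
    ref = float(out["tm"].mean()) if reference_tm is None else reference_tm
    out = out[(out["tm"] - ref).abs() <= half_width]
    return out.reset_index(drop=True)


def _genome_window_onehot(seq: str, k: int) -> np.ndarray | None:
    """(n_windows x 4k) float32 one-hot of all k-windows of a string."""
    enc = _encode(seq)
    if len(enc) < k:
        return None
    win = np.lib.stride_tricks.sliding_window_view(enc, k)  # (n, k)
    onehot = np.zeros((win.shape[0], k, 4), dtype=np.float32)
    mask = win < 4
    idx0, idx1 = np.nonzero(mask)
    onehot[idx0, idx1, win[mask]] = 1.0
    return onehot.reshape(win.shape[0], 4 * k)


def _candidate_onehot(seqs: list[str], k: int) -> np.ndarray:
    enc = np.stack([_encode(s) for s in seqs])
    onehot = np.zeros((enc.shape[0], k, 4), dtype=np.float32)
    mask = enc < 4
    idx0, idx1 = np.nonzero(mask)
    onehot[idx0, idx1, enc[mask]] = 1.0
    return onehot.reshape(enc.shape[0], 4 * k)


def count_sites_batch(
    seqs: list[str],
    genome: GenomeSequence,
    min_matches: int,
    max_matches: int | None = None,
    chunk: int = 512,
) -> np.ndarray:
    """Per-candidate count of genome windows (both strands) whose
    ungapped full-length match count lies in [min_matches, max_matches]."""
    if not seqs:
        return np.zeros(0, dtype=np.int64)
    k = len(seqs[0])
    if any(len(s) != k for s in seqs):
        raise ValueError("candidates must have uniform length")
    hi = k if max_matches is None else max_matches
    cand = _candidate_onehot(seqs, k)
    totals = np.zeros(len(seqs), dtype=np.int64)
    for chrom in sorted(genome.records):
        for strand_seq in (genome.records[chrom], revcomp(genome.records[chrom])):
            w = _genome_window_onehot(strand_seq, k)
            if w is None:
                continue
            for lo_i in range(0, len(seqs), chunk):
                block = cand[lo_i : lo_i + chunk]
                m = block @ w.T  # match counts
                sel = (m >= min_matches - 0.5) & (m <= hi + 0.5)
                totals[lo_i : lo_i + chunk] += sel.sum(axis=1)
    return totals


def count_homologous_sites(
    candidate: str, genome: GenomeSequence, min_identity: float = 0.70
) -> int:
    """Number of genome sites (both strands, ungapped) with identity
    >= min_identity to the candidate; its own locus counts as one."""
    k = len(candidate)
    need = math.ceil(min_identity * k)
    return int(count_sites_batch([candidate.upper()], genome, need)[0])


def filter_homology(
    candidates: pd.DataFrame, genome: GenomeSequence, min_identity: float = 0.70
) -> pd.DataFrame:
    """Discard candidates homologous to more than one genomic location."""
    if candidates.empty:
        return candidates.copy()
    seqs = list(candidates["sequence"])
    need = math.ceil(min_identity * len(seqs[0]))
    counts = count_sites_batch(seqs, genome, need)
    return candidates[counts <= 1].reset_index(drop=True)


def filter_secondary_structure(
    candidates: pd.DataFrame,
    temperature: float = 65.0,
    params: thermo.ThermoParams | None = None,
) -> pd.DataFrame:
    """Discard candidates whose most stable hairpin has dG < 0 at the
    given temperature; retained rows carry ``dg_struct``."""
    if candidates.empty:
        return candidates.copy()
    out = candidates.copy()
    out["dg_struct"] = [thermo.hairpin_dg(s, temperature, params) for s in out["sequence"]]
    out = out[out["dg_struct"] >= 0.0]
    return out.reset_index(drop=True)


def flag_offtargets(
    candidate: str,
    genome: GenomeSequence,
    mm_min: int = 1,
    mm_max: int = 5,
    flag_threshold: int = 10,
) -> bool:
    """True iff the candidate has more than ``flag_threshold`` genome
    sites at Hamming distance mm_min..mm_max (its exact locus, distance
    0, never counts)."""
    k = len(candidate)
    n = int(count_sites_batch([candidate.upper()], genome, k - mm_max, k - mm_min)[0])
    return n > flag_threshold


def annotate_offtargets(
    candidates: pd.DataFrame,
    genome: GenomeSequence,
    mm_min: int = 1,
    mm_max: int = 5,
    flag_threshold: int = 10,
) -> pd.DataFrame:
    """Add a boolean ``offtarget_flag`` column (flagged rows are kept)."""
    out = candidates.copy()
    if out.empty:
        out["offtarget_flag"] = pd.Series(dtype=bool)
        return out
    seqs = list(out["sequence"])
    k = len(seqs[0])
    counts = count_sites_batch(seqs, genome, k - mm_max, k - mm_min)
    out["offtarget_flag"] = counts > flag_threshold
    return out.reset_index(drop=True)


def select_nonoverlapping(candidates: pd.DataFrame) -> pd.DataFrame:
    """Greedy left-to-right non-overlap selection per chromosome.

    Keeps the first candidate, then each candidate whose start is at or
    beyond the end of the last kept one. Input must already be sorted by
    (chrom, start); unsorted input is a contract violation.
    """
    if candidates.empty:
        return candidates.copy()
    key = candidates[["chrom", "start"]]
    if not key.equals(key.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)):
        raise ValueError("select_nonoverlapping requires input sorted by (chrom, start)")
    keep = []
    last_end: dict[str, int] = {}
    for idx, row in candidates.iterrows():
        if row["start"] >= last_end.get(row["chrom"], -1):
            keep.append(idx)
            last_end[row["chrom"]] = row["end"]
    return candidates.loc[keep].reset_index(drop=True)


@dataclass
class OligoDatabase:
    """A sorted, per-chromosome non-overlapping oligo set plus metadata."""

    k: int
    genome_id: str
    frame: pd.DataFrame
    params: dict = field(default_factory=dict)
    stage_counts: dict = field(default_factory=dict)
    warnings_: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.frame)

    @staticmethod
    def _normalize(frame: pd.DataFrame) -> pd.DataFrame:
        out = frame.copy()
        for col in DB_COLUMNS:
            if col not in out.columns:
                out[col] = np.nan if col in ("tm", "dg_struct") else False
        out = out[DB_COLUMNS]
        out["start"] = out["start"].astype(int)
        out["end"] = out["end"].astype(int)
        out["offtarget_flag"] = out["offtarget_flag"].astype(bool)
        return out.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)

    def __post_init__(self) -> None:
        self.frame = self._normalize(self.frame)

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.frame.to_csv(directory / "oligos.tsv", sep="\t", index=False)
        meta = {
            "k": self.k,
            "genome_id": self.genome_id,
            "params": self.params,
            "stage_counts": self.stage_counts,
            "warnings": self.warnings_,
            "n_records": len(self.frame),
        }
        (directory / "meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")

    @classmethod
    def load(cls, directory: str | Path) -> "OligoDatabase":
        directory = Path(directory)
        frame = pd.read_csv(directory / "oligos.tsv", sep="\t")
        meta = json.loads((directory / "meta.json").read_text())
        return cls(
            k=meta["k"],
            genome_id=meta["genome_id"],
            frame=frame,
            params=meta.get("params", {}),
            stage_counts=meta.get("stage_counts", {}),
            warnings_=meta.get("warnings", []),
        )

    def to_bed(self, path: str | Path) -> None:
        bed = self.frame[["chrom", "start", "end"]].copy()
        bed["name"] = [f"oligo_{i}" for i in range(len(bed))]
        bed.to_csv(path, sep="\t", header=False, index=False)


def build_database(
    genome: GenomeSequence, k: int = 40, params: DbParams | None = None
) -> OligoDatabase:
    """Run the full mining pipeline and return the resulting database.

    Stage order: unique k-mers -> composition -> (mean Tm recorded) ->
    homology -> secondary structure -> Tm window around the recorded
    mean -> greedy non-overlap -> off-target flagging. Per-stage
    survivor counts land in ``stage_counts``.
    """
    params = params or DbParams()
    counts: dict[str, int] = {}
    notes: list[str] = []

    cands = extract_unique_kmers(genome, k, canonical=params.canonical)
    counts["unique_kmers"] = len(cands)

    cands = filter_composition(cands, params.max_run, params.gc_min, params.gc_max)
    counts["composition"] = len(cands)

    reference_tm = None
    if params.tm_filter and not cands.empty:
        cands = cands.copy()
        cands["tm"] = [thermo.melting_temperature(s) for s in cands["sequence"]]
        reference_tm = float(cands["tm"].mean())

    if params.homology_filter:
        cands = filter_homology(cands, genome, params.homology_identity)
    counts["homology"] = len(cands)

    if params.structure_filter:
        cands = filter_secondary_structure(cands, params.structure_temperature)
    counts["structure"] = len(cands)

    if params.tm_filter:
        cands = filter_tm_window(cands, params.tm_half_width, reference_tm=reference_tm)
    counts["tm_window"] = len(cands)

    cands = select_nonoverlapping(cands)
    counts["nonoverlap"] = len(cands)

    cands = annotate_offtargets(
        cands, genome, params.mm_min, params.mm_max, params.flag_threshold
    )
    counts["offtarget_flagged"] = int(cands["offtarget_flag"].sum()) if len(cands) else 0

    if cands.empty:
        notes.append("no oligos survived the filter pipeline; database is empty")
        warnings.warn(notes[-1], stacklevel=2)

    return OligoDatabase(
        k=k,
        genome_id=genome.genome_id,
        frame=cands,
        params=asdict(params),
        stage_counts=counts,
        warnings_=notes,
    )


def convert_database(
    bed_like: str | Path | pd.DataFrame,
    genome: GenomeSequence,
    k: int | None = None,
    one_based: bool = False,
    resolve_overlaps: bool = False,
) -> tuple[OligoDatabase, dict]:
    """Convert an external chrom/start/end table into an OligoDatabase.

    Sequences are filled from the supplied genome (no remote fetch).
    Returns (database, report); the report lists per-record coordinate
    errors and any overlap violations (resolved greedily when asked).
    """
    if isinstance(bed_like, pd.DataFrame):
        raw = bed_like.copy()
    else:
        raw = pd.read_csv(
            bed_like, sep="\t", comment="#", header=None, usecols=[0, 1, 2],
            names=["chrom", "start", "end"],
        )
    report: dict = {"errors": [], "overlaps": [], "n_input": len(raw)}
    rows = []
    for line_no, row in enumerate(raw.itertuples(index=False), start=1):
        try:
            chrom = str(row.chrom)
            start = int(row.start) - (1 if one_based else 0)
            end = int(row.end)
        except (TypeError, ValueError):
            report["errors"].append((line_no, "malformed row"))
            continue
        if chrom not in genome:
            report["errors"].append((line_no, f"unknown chromosome {chrom!r}"))
            continue
        if start < 0 or end > genome.lengths[chrom] or end <= start:
            report["errors"].append((line_no, f"coordinates {start}-{end} outside {chrom}"))
            continue
        rows.append((chrom, start, end, genome.slice(chrom, start, end)))
    frame = pd.DataFrame(rows, columns=CAND_COLUMNS)
    frame = frame.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    # overlap check per chromosome
    for chrom, grp in frame.groupby("chrom"):
        ends = grp["end"].to_numpy()
        starts = grp["start"].to_numpy()
        bad = np.nonzero(starts[1:] < ends[:-1])[0]
        for i in bad:
            report["overlaps"].append((chrom, int(starts[i + 1]), int(ends[i])))
    if report["overlaps"] and resolve_overlaps:
        frame = select_nonoverlapping(frame)
        report["resolved"] = True
    lengths = frame["end"] - frame["start"] if len(frame) else pd.Series(dtype=int)
    k_out = k if k is not None else (int(lengths.iloc[0]) if len(frame) else 0)
    db = OligoDatabase(k=k_out, genome_id=genome.genome_id, frame=frame,
                       params={"converted": True, "one_based_input": one_based})
    return db, report


@dataclass
class ValidationReport:
    checks: dict
    details: dict

    @property
    def passed(self) -> bool:
        return all(self.checks.values())


def validate_database(db: OligoDatabase, genome: GenomeSequence | None = None) -> ValidationReport:
    """Check sortedness, non-overlap, length uniformity, bounds, and
    (when a genome is supplied) sequence/genome agreement."""
    f = db.frame
    checks: dict[str, bool] = {}
    details: dict[str, list] = {}

    key = f[["chrom", "start"]].reset_index(drop=True)
    checks["sorted"] = key.equals(
        key.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    )

    offending = []
    for chrom, grp in f.groupby("chrom"):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        for i in np.nonzero(starts[1:] < ends[:-1])[0]:
            offending.append((chrom, int(starts[i + 1]), int(ends[i])))
    checks["non_overlapping"] = not offending
    details["overlaps"] = offending

    lengths = (f["end"] - f["start"]).to_numpy() if len(f) else np.array([], dtype=int)
    seq_ok = all(len(s) == e - st for s, st, e in zip(f["sequence"], f["start"], f["end"]))
    checks["uniform_length"] = bool(len(set(lengths)) <= 1) and seq_ok
    checks["length_matches_k"] = bool(len(f) == 0 or (lengths == db.k).all())

    if genome is not None:
        in_bounds = []
        agree = []
        for row in f.itertuples(index=False):
            ok = row.chrom in genome and 0 <= row.start < row.end <= genome.lengths[row.chrom]
            in_bounds.append(ok)
            agree.append(ok and genome.slice(row.chrom, row.start, row.end) == row.sequence)
        checks["coordinates_in_bounds"] = all(in_bounds)
        checks["sequence_agreement"] = all(agree)
        details["disagreements"] = [i for i, ok in enumerate(agree) if not ok]
    return ValidationReport(checks=checks, details=details)


@dataclass(frozen=True)
class DatabaseStats:
    window_size: int
    frac_windows_ge_n: float
    median_window_gap_sd: float
    genome_coverage: float


def database_stats(
    db: OligoDatabase,
    genome: GenomeSequence,
    window_size: int,
    min_count: int = 96,
) -> DatabaseStats:
    """Windowed database statistics.

    The genome is tiled in non-overlapping windows; an oligo counts for
    every window it overlaps, even partially. Per window the standard
    deviation (population) of the gaps between consecutive overlapping
    oligos is computed; windows with fewer than two oligos contribute no
    gap s.d. Coverage is oligo bases over genome bases.
    """
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    n_windows = 0
    n_ge = 0
    gap_sds: list[float] = []
    covered = 0
    total = sum(genome.lengths.values())
    for chrom in sorted(genome.records):
        clen = genome.lengths[chrom]
        grp = db.frame[db.frame["chrom"] == chrom]
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        covered += int((ends - starts).sum())
        for wstart in range(0, clen, window_size):
            wend = min(wstart + window_size, clen)
            n_windows += 1
            sel = (starts < wend) & (ends > wstart)
            s, e = starts[sel], ends[sel]
            if len(s) >= min_count:
                n_ge += 1
            if len(s) >= 2:
                gaps = s[1:] - e[:-1]
                gap_sds.append(float(np.std(gaps)))
    return DatabaseStats(
        window_size=window_size,
        frac_windows_ge_n=(n_ge / n_windows) if n_windows else 0.0,
        median_window_gap_sd=float(np.median(gap_sds)) if gap_sds else 0.0,
        genome_coverage=(covered / total) if total else 0.0,
    )
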