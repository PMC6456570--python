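"""Nearest-neighbor DNA thermodynamics.

Melting temperatures and duplex/hairpin free energies from summed
nearest-neighbor stack enthalpies and entropies (unified parameter set,
shipped as a TSV data file and fully overridable). Dimer energies follow
a deliberately simple model: over all ungapped antiparallel offsets of
the two strands, the single longest contiguous Watson-Crick run is
scored (stacks + duplex initiation + monovalent-salt entropy
correction). Mismatch and bulge energetics, dangling ends, and full
secondary-structure folding are out of scope; only signs and thresholds
are contractual for the filters built on top of this module.

Temperatures are degrees Celsius at every interface and Kelvin
internally. Free energies are kcal/mol; stabilizing values are negative
and a 0.0 sentinel means "no structure".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

from .genome import revcomp

R_GAS = 1.987204  # cal / (mol K)
_T37 = 310.15  # K
_SALT_DS = 0.368  # cal/(mol K) per phosphate pair, entropy salt term

__all__ = [
    "ThermoParams",
    "default_params",
    "melting_temperature",
    "duplex_dg",
    "self_dg",
    "hairpin_dg",
]


def _load_nn_table(path: Path | None = None) -> dict[str, tuple[float, float]]:
    if path is None:
        text = resources.files("fishkit.data").joinpath("nn_params.tsv").read_text()
    else:
        text = Path(path).read_text()
    table: dict[str, tuple[float, float]] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("stack"):
            continue
        key, dh, ds = line.split("\t")
        table[key] = (float(dh), float(ds))
    return table


def _load_loop_table(path: Path | None = None) -> dict[int, float]:
    if path is None:
        text = resources.files("fishkit.data").joinpath("loop_penalties.tsv").read_text()
    else:
        text = Path(path).read_text()
    table: dict[int, float] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("loop_len"):
            continue
        n, dg = line.split("\t")
        table[int(n)] = float(dg)
    return table


@dataclass(frozen=True)
class ThermoParams:
    """Nearest-neighbor parameter set plus solution conditions.

    nn_table maps a top-strand 5'->3' dinucleotide to (dH kcal/mol,
    dS cal/mol/K); only the 10 unique stacks need be present, the
    reverse-complement stack is looked up automatically. ``init_GC`` /
    ``init_AT`` are duplex initiation terms per helix end. ``na_conc``
    is the monovalent cation molarity and ``oligo_conc`` the total
    strand molarity entering the Tm concentration term.
    """

    nn_table: dict = field(default_factory=_load_nn_table)
    loop_table: dict = field(default_factory=_load_loop_table)
    na_conc: float = 0.05
    oligo_conc: float = 0.25

    def __post_init__(self) -> None:
        if self.na_conc <= 0 or self.oligo_conc <= 0:
            raise ValueError("concentrations must be positive")

    def with_(self, **kw) -> "ThermoParams":
        return replace(self, **kw)

    def stack(self, dinuc: str) -> tuple[float, float]:
        """(dH, dS) for a stack, folding to the canonical orientation."""
        try:
            return self.nn_table[dinuc]
        except KeyError:
            return self.nn_table[revcomp(dinuc)]

    def init_term(self, base: str) -> tuple[float, float]:
        return self.nn_table["init_GC" if base in "GC" else "init_AT"]

    def loop_penalty(self, loop_len: int, temperature_c: float) -> float:
        """Hairpin loop penalty at the given temperature (kcal/mol).

        Tabulated dG37 values, Jacobson-Stockmayer extrapolation beyond
        the table, scaled entropically with absolute temperature.
        """
        if loop_len < 3:
            raise ValueError("hairpin loops are at least 3 nt")
        t_k = temperature_c + 273.15
        keys = sorted(self.loop_table)
        if loop_len in self.loop_table:
            dg37 = self.loop_table[loop_len]
        else:
            x = max(k for k in keys if k <= loop_len) if loop_len > keys[0] else keys[0]
            dg37 = self.loop_table[x] + 1.75 * R_GAS / 1000.0 * _T37 * math.log(loop_len / x)
        return dg37 * t_k / _T37


_DEFAULT: ThermoParams | None = None


def default_params() -> ThermoParams:
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = ThermoParams()
    return _DEFAULT


def _check_acgt(seq: str) -> None:
    if not seq or set(seq) - set("ACGT"):
        raise ValueError(f"sequence must be non-empty ACGT, got {seq!r}")


def _stack_sums(seq: str, params: ThermoParams) -> tuple[float, float]:
    dh = ds = 0.0
    for i in range(len(seq) - 1):
        h, s = params.stack(seq[i : i + 2])
        dh += h
        ds += s
    return dh, ds


def melting_temperature(seq: str, params: ThermoParams | None = None) -> float:
    """Nearest-neighbor melting temperature in deg C.

    Summed stack dH/dS with per-end initiation terms, an entropic
    monovalent-salt correction, and the standard strand-concentration
    term (CT/4, non-self-complementary assumption).
    """
    params = params or default_params()
    seq = seq.upper()
    _check_acgt(seq)
    if len(seq) < 2:
        raise ValueError("need at least 2 nt for a nearest-neighbor Tm")
    dh, ds = _stack_sums(seq, params)
    for base in (seq[0], seq[-1]):
        h, s = params.init_term(base)
        dh += h
        ds += s
    ds += _SALT_DS * (len(seq) - 1) * math.log(params.na_conc)
    tm_k = dh * 1000.0 / (ds + R_GAS * math.log(params.oligo_conc / 4.0))
    return tm_k - 273.15


def _run_dg(run_seq: str, temperature_c: float, params: ThermoParams) -> float:
    """dG(T) of a fully paired contiguous run: stacks + initiation + salt."""
    t_k = temperature_c + 273.15
    dh, ds = _stack_sums(run_seq, params)
    for base in (run_seq[0], run_seq[-1]):
        h, s = params.init_term(base)
        dh += h
        ds += s
    ds += _SALT_DS * (len(run_seq) - 1) * math.log(params.na_conc)
    return dh - t_k * ds / 1000.0


def _best_offset_dg(a: str, b: str, temperature_c: float, params: ThermoParams) -> float:
    """Minimum dG over ungapped antiparallel offsets of strands a and b.

    At each offset the longest contiguous WC-complementary run is
    scored. Strand b is reversed so index i of a faces index i-offset of
    the reversed b (antiparallel geometry).
    """
    t = b[::-1]
    comp_a = revcomp(a)[::-1]  # position-wise complement of a
    best = 0.0
    na, nt = len(a), len(t)
    for offset in range(-(nt - 1), na):
        run_start = None
        run_len = 0
        best_start, best_len = 0, 0
        lo = max(0, offset)
        hi = min(na, nt + offset)
        for i in range(lo, hi):
            if comp_a[i] == t[i - offset]:
                if run_start is None:
                    run_start, run_len = i, 1
                else:
                    run_len += 1
                if run_len > best_len:
                    best_start, best_len = run_start, run_len
            else:
                run_start, run_len = None, 0
        if best_len >= 2:
            dg = _run_dg(a[best_start : best_start + best_len], temperature_c, params)
            best = min(best, dg)
    return best


def duplex_dg(
    seq_a: str,
    seq_b: str,
    temperature: float = 37.0,
    params: ThermoParams | None = None,
    include_revcomp: bool = True,
) -> float:
    """Dimerization dG (kcal/mol) of the longest complementary stretch.

    Considers every ungapped antiparallel offset of ``seq_a`` against
    ``seq_b`` and, when ``include_revcomp`` (the PCR situation, where
    both strands of the partner species exist), also against
    ``revcomp(seq_b)``; returns the minimum. 0.0 sentinel when no
    complementary run of length >= 2 exists; never positive.
    """
    params = params or default_params()
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    _check_acgt(seq_a)
    _check_acgt(seq_b)
    if len(seq_a) < 2 or len(seq_b) < 2:
        raise ValueError("duplex partners must each be >= 2 nt")
    best = _best_offset_dg(seq_a, seq_b, temperature, params)
    if include_revcomp:
        best = min(best, _best_offset_dg(seq_a, revcomp(seq_b), temperature, params))
    return min(best, 0.0)


def self_dg(seq: str, temperature: float = 37.0, params: ThermoParams | None = None) -> float:
    """Self-dimerization dG: the oligo paired against another copy of itself.

    The reverse complement is *not* a partner here (an oligo and its
    perfect complement form the intended product duplex, not a
    self-dimer), so only seq-vs-seq pairings are scored.
    """
    return duplex_dg(seq, seq, temperature, params, include_revcomp=False)


def hairpin_dg(seq: str, temperature: float = 37.0, params: ThermoParams | None = None) -> float:
    """Minimum hairpin dG over all contiguous-stem decompositions.

    A hairpin is a stem of >= 2 contiguous WC pairs closing a loop of
    >= 3 nt; dG = stem stack sum (with salt correction) + loop penalty.
    Returns 0.0 when no decomposition is stabilizing.
    """
    params = params or default_params()
    seq = seq.upper()
    _check_acgt(seq)
    n = len(seq)
    if n < 7:
        return 0.0
    t_k = temperature + 273.15
    comp = revcomp(seq)[::-1]  # comp[i] pairs seq[i]
    best = 0.0
    # stem 5' arm starts at i, 3' arm ends at j (pairing seq[i+t] with seq[j-t])
    for i in range(n - 6):
        for j in range(i + 6, n):
            max_l = (j - i - 2) // 2  # loop >= 3 => 2L <= j - i - 2 ... enforced below
            length = 0
            dh = ds = 0.0
            while True:
                t = length
                if seq[j - t] != comp[i + t]:
                    break
                length += 1
                if t > 0:
                    h, s = params.stack(seq[i + t - 1 : i + t + 1])
                    dh += h
                    ds += s
                loop = j - i - 2 * length + 1
                if loop < 3:
                    break
                if length >= 2:
                    ds_salt = ds + _SALT_DS * (length - 1) * math.log(params.na_conc)
                    dg = dh - t_k * ds_salt / 1000.0 + params.loop_penalty(loop, temperature)
                    best = min(best, dg)
                if length > max_l:
                    break
    return min(best, 0.0)
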