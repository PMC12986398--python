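"""Sequence model, CpG-island detection and in silico bisulfite conversion.

Everything downstream (primer design, CoBRA, pyrosequencing) operates on the
objects defined here.  Coordinates are 0-based half-open throughout; strand
``+`` refers to the sequence as given.

Bisulfite chemistry, in brief: treatment deaminates unmethylated cytosine to
uracil (read as T after PCR) while 5-methylcytosine is protected.  Only
CpG-context methylation is modelled.  Note that after conversion the two
strands of a locus are no longer complementary, so an assay on the minus
strand must be designed against the converted reverse complement explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "GenomicLocus",
    "CpGIsland",
    "MethylationPattern",
    "BisulfiteSequence",
    "find_cpg_islands",
    "bisulfite_convert",
    "reverse_complement",
    "cpg_positions_of",
]

_DNA = set("ACGT")

_IUPAC_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN"
)
_IUPAC = set("ACGTRYSWKMBDHVN")


def _clean(sequence: str, *, strict: bool = True) -> str:
    """Upper-case and validate a DNA string (ACGT only when strict)."""
    if not isinstance(sequence, str):
        raise TypeError("sequence must be a string")
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    alphabet = _DNA if strict else _IUPAC
    bad = set(seq) - alphabet
    if bad:
        raise ValueError(f"invalid characters in sequence: {sorted(bad)}")
    return seq


def cpg_positions_of(sequence: str) -> list[int]:
    """0-based offsets of the C of every CpG dinucleotide in ``sequence``."""
    seq = sequence.upper()
    return [i for i in range(len(seq) - 1) if seq[i] == "C" and seq[i + 1] == "G"]


def reverse_complement(sequence: str) -> str:
    """Reverse complement of an IUPAC DNA string (involution: rc(rc(s)) == s)."""
    seq = _clean(sequence, strict=False)
    return seq.translate(_IUPAC_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class CpGIsland:
    """A CpG-dense, GC-rich interval detected by the sliding-window scan."""

    start: int
    end: int
    gc_fraction: float
    obs_exp_cpg: float
    n_cpg: int

    @property
    def length(self) -> int:
        return self.end - self.start

    def __contains__(self, position: int) -> bool:
        return self.start <= position < self.end


@dataclass
class GenomicLocus:
    """A genomic sequence with TSS/isoform annotation and CpG positions.

    ``tss`` is a 0-based offset into ``sequence``; ``isoforms`` maps
    additional named transcription starts onto the same sequence.
    """

    name: str
    sequence: str
    tss: int
    strand: str = "+"
    isoforms: list[tuple[str, int]] = field(default_factory=list)
    cpg_positions: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = _clean(self.sequence)
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")
        if not (0 <= self.tss < len(self.sequence)):
            raise ValueError("tss must fall inside the sequence")
        if not self.cpg_positions:
            self.cpg_positions = cpg_positions_of(self.sequence)
        for p in self.cpg_positions:
            if self.sequence[p : p + 2] != "CG":
                raise ValueError(f"position {p} is not the C of a CpG")
        if any(b >= a for a, b in zip(self.cpg_positions[1:], self.cpg_positions)):
            raise ValueError("cpg_positions must be strictly increasing")

    def __len__(self) -> int:
        return len(self.sequence)

    def cpgs_in(self, start: int, end: int) -> list[int]:
        """CpG C offsets whose dinucleotide lies fully inside [start, end)."""
        return [p for p in self.cpg_positions if start <= p and p + 1 < end]


@dataclass
class MethylationPattern:
    """Per-CpG methylation state.

    ``levels`` maps a CpG C offset either to a binary state (for conversion:
    True/"methylated" or False/"unmethylated") or to a fraction in [0, 1]
    (for simulation).
    """

    levels: Mapping[int, object]

    def binary_state(self, offset: int) -> bool:
        v = self.levels[offset]
        if isinstance(v, bool):
            return v
        if v in ("methylated", 1):
            return True
        if v in ("unmethylated", 0):
            return False
        raise ValueError(
            f"pattern value {v!r} at offset {offset} is not a binary "
            "methylation state; conversion needs methylated/unmethylated"
        )

    def fraction(self, offset: int) -> float:
        v = self.levels[offset]
        if isinstance(v, bool):
            return 1.0 if v else 0.0
        if v == "methylated":
            return 1.0
        if v == "unmethylated":
            return 0.0
        f = float(v)  # type: ignore[arg-type]
        if not (0.0 <= f <= 1.0):
            raise ValueError(f"methylation fraction {f} outside [0, 1]")
        return f


@dataclass
class BisulfiteSequence:
    """A bisulfite-converted strand with a map back to the original region.

    The original (pre-conversion) region is retained because CpG and
    conversion-control positions are only defined on it.  ``coord_map[i]``
    gives the original offset of converted position ``i`` (identity here;
    kept explicit so sub-regions can carry their provenance).
    """

    converted: str
    original: str
    source: str
    mode: str
    coord_map: np.ndarray

    def __post_init__(self) -> None:
        if len(self.converted) != len(self.original):
            raise ValueError("conversion must preserve length")

    def __len__(self) -> int:
        return len(self.converted)

    @property
    def cpg_positions(self) -> list[int]:
        return cpg_positions_of(self.original)


def bisulfite_convert(
    region: str,
    pattern: MethylationPattern | None = None,
    mode: str = "all_unmethylated",
    *,
    source: str = "region/+",
) -> BisulfiteSequence:
    """In silico bisulfite conversion of ``region`` (the strand as given).

    Every cytosine deaminates to T except a CpG-context C that is marked
    methylated.  ``mode`` is one of ``all_unmethylated`` (every C -> T),
    ``all_methylated`` (every CpG C retained) or ``pattern`` (per-CpG states
    from ``pattern``; unlisted CpGs are treated as unmethylated).
    """
    seq = _clean(region)
    cpgs = set(cpg_positions_of(seq))
    if mode not in ("all_unmethylated", "all_methylated", "pattern"):
        raise ValueError(f"unknown conversion mode {mode!r}")
    if mode == "pattern":
        if pattern is None:
            raise ValueError("mode='pattern' requires a MethylationPattern")
        bad = set(pattern.levels) - cpgs
        if bad:
            raise ValueError(f"pattern keys are not CpG C offsets: {sorted(bad)}")
        methylated = {p for p in pattern.levels if pattern.binary_state(p)}
    elif mode == "all_methylated":
        methylated = cpgs
    else:
        methylated = set()

    out = []
    for i, base in enumerate(seq):
        if base == "C" and i not in methylated:
            out.append("T")
        else:
            out.append(base)
    return BisulfiteSequence(
        converted="".join(out),
        original=seq,
        source=source,
        mode=mode,
        coord_map=np.arange(len(seq)),
    )


def _window_arrays(seq: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cumulative counts of C, G and CG-dinucleotide starts (prefix sums)."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    is_c = (arr == ord("C")).astype(np.int64)
    is_g = (arr == ord("G")).astype(np.int64)
    is_cg = np.zeros(len(seq), dtype=np.int64)
    if len(seq) > 1:
        is_cg[:-1] = (arr[:-1] == ord("C")) & (arr[1:] == ord("G"))
    zero = np.zeros(1, dtype=np.int64)
    return (
        np.concatenate([zero, np.cumsum(is_c)]),
        np.concatenate([zero, np.cumsum(is_g)]),
        np.concatenate([zero, np.cumsum(is_cg)]),
    )


def _interval_stats(
    cum: tuple[np.ndarray, np.ndarray, np.ndarray], start: int, end: int
) -> tuple[float, float, int]:
    """(gc_fraction, obs/exp CpG, CpG count) of [start, end)."""
    cum_c, cum_g, cum_cg = cum
    length = end - start
    c = int(cum_c[end] - cum_c[start])
    g = int(cum_g[end] - cum_g[start])
    # CG starts fully inside the interval: start offsets in [start, end-1)
    cg = int(cum_cg[end - 1] - cum_cg[start]) if length > 1 else 0
    gc = (c + g) / length
    obs_exp = (cg * length) / (c * g) if c > 0 and g > 0 else 0.0
    return gc, obs_exp, cg


def find_cpg_islands(
    sequence: str,
    *,
    min_length: int = 200,
    min_gc: float = 0.50,
    min_obs_exp: float = 0.60,
    window: int = 200,
    step: int = 1,
) -> list[CpGIsland]:
    """Sliding-window CpG-island scan (Gardiner-Garden/Frommer-style criteria).

    A window passes when GC fraction >= ``min_gc`` and observed/expected CpG
    (count(CG) * length / (count(C) * count(G))) >= ``min_obs_exp``.
    Overlapping passing windows are merged; within each merged region the
    longest sub-interval of length >= ``min_length`` that itself passes both
    thresholds is reported (leftmost on ties).  Islands are non-overlapping
    and sorted by start.
    """
    seq = _clean(sequence)
    if min(min_length, window, step) <= 0 or min_gc <= 0 or min_obs_exp <= 0:
        raise ValueError("detection parameters must be positive")
    if len(seq) < window:
        raise ValueError("sequence shorter than the scan window")

    cum = _window_arrays(seq)
    n = len(seq)

    # vectorized per-window stats at starts 0, step, 2*step, ...
    starts = np.arange(0, n - window + 1, step)
    cum_c, cum_g, cum_cg = cum
    c = cum_c[starts + window] - cum_c[starts]
    g = cum_g[starts + window] - cum_g[starts]
    cg = cum_cg[starts + window - 1] - cum_cg[starts]
    gc = (c + g) / window
    with np.errstate(divide="ignore", invalid="ignore"):
        obs_exp = np.where((c > 0) & (g > 0), cg * window / (c * g), 0.0)
    passing = starts[(gc >= min_gc) & (obs_exp >= min_obs_exp)]

    # merge overlapping/adjacent passing windows into candidate regions
    regions: list[list[int]] = []
    for s in passing:
        s = int(s)
        if regions and s <= regions[-1][1]:
            regions[-1][1] = max(regions[-1][1], s + window)
        else:
            regions.append([s, s + window])

    islands: list[CpGIsland] = []
    for rs, re_ in regions:
        hit = _best_subinterval(cum, rs, re_, min_length, min_gc, min_obs_exp)
        if hit is not None:
            s, e = hit
            gc_f, oe, ncg = _interval_stats(cum, s, e)
            islands.append(CpGIsland(s, e, gc_f, oe, ncg))
    return islands


def _best_subinterval(
    cum: tuple[np.ndarray, np.ndarray, np.ndarray],
    start: int,
    end: int,
    min_length: int,
    min_gc: float,
    min_obs_exp: float,
) -> tuple[int, int] | None:
    """Longest (leftmost on ties) sub-interval of [start, end) passing both
    thresholds with length >= min_length; None if no sub-interval passes."""
    region_len = end - start
    cum_c, cum_g, cum_cg = cum
    for length in range(region_len, min_length - 1, -1):
        ss = np.arange(start, end - length + 1)
        c = cum_c[ss + length] - cum_c[ss]
        g = cum_g[ss + length] - cum_g[ss]
        cg = cum_cg[ss + length - 1] - cum_cg[ss]
        gc = (c + g) / length
        with np.errstate(divide="ignore", invalid="ignore"):
            oe = np.where((c > 0) & (g > 0), cg * length / (c * g), 0.0)
        ok = np.flatnonzero((gc >= min_gc) & (oe >= min_obs_exp))
        if ok.size:
            s = int(ss[ok[0]])
            return s, s + length
    return None
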