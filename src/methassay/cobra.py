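"""Combined bisulfite restriction analysis (CoBRA).

A restriction site is *methylation-informative* when it exists in the
bisulfite-converted amplicon only if specific CpGs were methylated: the
enzyme then cuts methylated molecules but not unmethylated ones, and the
fragment ladder on a gel reports methylation qualitatively.  On a fully
converted unmethylated template no TaqI (TCGA) or Bsh1236I (CGCG) site can
survive, because the converted strand contains no cytosine at all.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .seqcore import bisulfite_convert, cpg_positions_of

__all__ = [
    "Enzyme",
    "TAQI",
    "BSH1236I",
    "DEFAULT_ENZYMES",
    "CobraAssay",
    "CobraCall",
    "find_informative_sites",
    "predict_fragments",
    "build_cobra_assay",
    "make_calls",
    "call_and_summarize",
]


@dataclass(frozen=True)
class Enzyme:
    """A restriction enzyme: recognition sequence and cut offset within it."""

    name: str
    recognition: str
    cut_offset: int

    def __post_init__(self) -> None:
        if not self.recognition or set(self.recognition) - set("ACGT"):
            raise ValueError("recognition sequence must be non-empty A/C/G/T")
        if not (0 <= self.cut_offset <= len(self.recognition)):
            raise ValueError("cut_offset outside recognition site")


# TaqI cuts T^CGA; Bsh1236I cuts CG^CG.
TAQI = Enzyme("TaqI", "TCGA", 1)
BSH1236I = Enzyme("Bsh1236I", "CGCG", 2)
DEFAULT_ENZYMES: tuple[Enzyme, ...] = (TAQI, BSH1236I)


def _occurrences(haystack: str, needle: str) -> list[int]:
    """All (overlapping) occurrence offsets of needle in haystack."""
    out, i = [], haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def find_informative_sites(
    amplicon: str, enzyme: Enzyme
) -> list[tuple[int, list[int]]]:
    """Offsets where ``enzyme``'s site appears in the fully methylated
    conversion of ``amplicon`` but not in the unmethylated conversion.

    ``amplicon`` is the original (pre-conversion) top-strand sequence; the
    converted top strand defines both strands of the PCR product.  Each site
    is annotated with the CpG C offsets it covers — the CpGs whose
    methylation its cutting reports.  Overlapping sites are all returned.
    """
    if not amplicon:
        raise ValueError("empty amplicon")
    meth = bisulfite_convert(amplicon, mode="all_methylated").converted
    unmeth = bisulfite_convert(amplicon, mode="all_unmethylated").converted
    in_unmeth = set(_occurrences(unmeth, enzyme.recognition))
    cpgs = cpg_positions_of(amplicon)
    sites = []
    k = len(enzyme.recognition)
    for off in _occurrences(meth, enzyme.recognition):
        if off in in_unmeth:
            continue
        covered = [p for p in cpgs if off <= p < off + k]
        sites.append((off, covered))
    return sites


def predict_fragments(
    amplicon_length: int, cut_positions: Sequence[int]
) -> list[int]:
    """Fragment lengths (5' to 3') from cutting at ``cut_positions``.

    Positions are strictly increasing bp offsets in (0, amplicon_length);
    the returned lengths always sum to the amplicon length.
    """
    if amplicon_length <= 0:
        raise ValueError("amplicon length must be positive")
    cuts = list(cut_positions)
    if any(b <= a for a, b in zip(cuts, cuts[1:])):
        raise ValueError("cut positions must be strictly increasing")
    if any(not (0 < c < amplicon_length) for c in cuts):
        raise ValueError("cut position outside (0, amplicon length)")
    bounds = [0, *cuts, amplicon_length]
    return [b - a for a, b in zip(bounds, bounds[1:])]


@dataclass
class CobraAssay:
    """A CoBRA assay over one amplicon: informative sites and the fragment
    ladders expected for fully methylated vs unmethylated input."""

    amplicon_start: int
    amplicon_end: int
    amplicon: str
    enzyme: Enzyme
    informative_sites: list[tuple[int, list[int]]]
    fragments_methylated: list[int]
    fragments_unmethylated: list[int]

    @property
    def n_covered_cpgs(self) -> int:
        return len({p for _, covered in self.informative_sites for p in covered})


def build_cobra_assay(
    amplicon: str,
    enzyme: Enzyme,
    *,
    amplicon_start: int = 0,
) -> CobraAssay:
    """Construct the assay for one amplicon: find informative sites, predict
    the methylated fragment ladder (complete digestion assumed) and the
    unmethylated ladder (no informative cut)."""
    sites = find_informative_sites(amplicon, enzyme)
    length = len(amplicon)
    cuts = sorted({off + enzyme.cut_offset for off, _ in sites})
    cuts = [c for c in cuts if 0 < c < length]
    return CobraAssay(
        amplicon_start=amplicon_start,
        amplicon_end=amplicon_start + length,
        amplicon=amplicon,
        enzyme=enzyme,
        informative_sites=sites,
        fragments_methylated=predict_fragments(length, cuts),
        fragments_unmethylated=[length],
    )


@dataclass(frozen=True)
class CobraCall:
    """Per-sample digestion readout and the binary hypermethylation call."""

    sample: str
    digested_fraction: float
    group: str
    hypermethylated: bool

    def __post_init__(self) -> None:
        if not (0.0 <= self.digested_fraction <= 1.0):
            raise ValueError("digested_fraction outside [0, 1]")


#: Default digested-fraction threshold for calling a sample hypermethylated.
#: Gel-based calls are visual; 25% digestion is a conservative, configurable
#: stand-in for a clearly visible cut band.
DEFAULT_CALL_THRESHOLD = 0.25


def make_calls(
    samples: Iterable[tuple[str, float, str]],
    threshold: float = DEFAULT_CALL_THRESHOLD,
) -> list[CobraCall]:
    """Turn (sample, digested_fraction, group) triples into CobraCalls using
    ``digested_fraction >= threshold`` as the hypermethylation rule."""
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must be in (0, 1]")
    return [
        CobraCall(s, f, g, hypermethylated=f >= threshold) for s, f, g in samples
    ]


def call_and_summarize(
    calls: Sequence[CobraCall],
) -> dict[str, dict[str, float]]:
    """Per-group hypermethylation frequency.

    Returns {group: {"n": samples, "n_hypermethylated": count,
    "frequency_pct": 100 * count / n}}, preserving first-seen group order.
    """
    if not calls:
        raise ValueError("no calls to summarize")
    groups: dict[str, list[CobraCall]] = {}
    for c in calls:
        groups.setdefault(c.group, []).append(c)
    out = {}
    for g, cs in groups.items():
        if not cs:
            raise ValueError(f"empty group {g!r}")
        k = sum(c.hypermethylated for c in cs)
        out[g] = {
            "n": len(cs),
            "n_hypermethylated": k,
            "frequency_pct": 100.0 * k / len(cs),
        }
    return out


def virtual_gel(ladders: Mapping[str, Sequence[int]], width: int = 50) -> str:
    """ASCII rendering of fragment ladders, one lane per named digest.

    Band position is proportional to log fragment length (large fragments
    near the top, as on an agarose gel)."""
    import math as _math

    all_lengths = [l for lane in ladders.values() for l in lane]
    if not all_lengths:
        raise ValueError("no fragments to render")
    lo, hi = min(all_lengths), max(all_lengths)
    span = _math.log(hi) - _math.log(lo) if hi > lo else 1.0
    n_rows = 12
    lanes = list(ladders)
    grid = {lane: [" "] * n_rows for lane in lanes}
    for lane, lengths in ladders.items():
        for l in lengths:
            row = int(round((_math.log(hi) - _math.log(l)) / span * (n_rows - 1)))
            grid[lane][row] = "="
    col_w = max(max(len(l) for l in lanes), 8) + 2
    out = ["".join(lane.ljust(col_w) for lane in lanes)]
    for r in range(n_rows):
        out.append("".join(grid[lane][r].center(col_w - 2) + "  " for lane in lanes))
    out.append(f"(top = {hi} bp, bottom = {lo} bp, log scale)")
    return "\n".join(out)
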