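"""Bisulfite-PCR assay design against a promoter CpG island.

Primers are designed on the fully converted (all-unmethylated) top strand so
the PCR is methylation-independent: windows overlapping CpGs are capped and
penalised because their converted sequence depends on methylation state.
Assays are nested or semi-nested two-round PCRs whose inner amplicon must
satisfy the design guidelines: product length 120-350 bp, per-primer melting
temperature 53-62 degC with similar pair temperatures, the amplicon within
+/- 400 bp of the TSS and overlapping the CpG island, at least one
methylation-informative restriction site for CoBRA, and a CpG-rich
pyrosequencing window.
"""

from __future__ import annotations

import bisect
import math
from collections import Counter
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Sequence

import numpy as np
from Bio.SeqUtils import MeltingTemp as _mt

from . import cobra as _cobra
from .seqcore import (
    BisulfiteSequence,
    CpGIsland,
    GenomicLocus,
    bisulfite_convert,
    reverse_complement,
)

__all__ = [
    "ReactionConditions",
    "ScoreWeights",
    "DesignConstraints",
    "Primer",
    "AssayDesign",
    "DesignResult",
    "melting_temperature",
    "enumerate_candidates",
    "design_assay",
    "NoIslandError",
]


class NoIslandError(ValueError):
    """Raised when assay design is requested without a CpG island ("no CGI")."""


@dataclass(frozen=True)
class ReactionConditions:
    """PCR salt/primer conditions for the nearest-neighbor Tm model.

    Mg2+ enters through a monovalent-equivalent correction
    (Na_eq = monovalent + 120 * sqrt([Mg2+])); defaults mirror a standard
    Taq buffer with 1.5 mM MgCl2 and 250 nM of each primer.
    """

    monovalent_mM: float = 50.0
    mg_mM: float = 1.5
    primer_nM: float = 250.0

    @property
    def monovalent_equivalent_mM(self) -> float:
        return self.monovalent_mM + (120.0 * math.sqrt(self.mg_mM) if self.mg_mM > 0 else 0.0)


DEFAULT_CONDITIONS = ReactionConditions()


@lru_cache(maxsize=200_000)
def _tm_nn(seq: str, na_eq: float, primer_nM: float) -> float:
    return _mt.Tm_NN(
        seq,
        nn_table=_mt.DNA_NN3,
        Na=na_eq,
        K=0,
        Tris=0,
        Mg=0,
        dNTPs=0,
        dnac1=primer_nM,
        dnac2=0,
        saltcorr=5,
    )


def melting_temperature(
    primer_sequence: str, conditions: ReactionConditions = DEFAULT_CONDITIONS
) -> float:
    """Nearest-neighbor duplex melting temperature (degC).

    Unified nearest-neighbor enthalpy/entropy parameters with a
    monovalent-equivalent salt correction; deterministic for a given
    sequence and conditions.  Requires >= 8 unambiguous bases.
    """
    seq = primer_sequence.upper()
    if len(seq) < 8:
        raise ValueError("primer too short for a meaningful Tm (need >= 8 nt)")
    if set(seq) - set("ACGT"):
        raise ValueError("ambiguous bases not allowed in Tm calculation")
    return float(_tm_nn(seq, conditions.monovalent_equivalent_mM, conditions.primer_nM))


@dataclass(frozen=True)
class ScoreWeights:
    """Soft-scoring weights; the hard constraints are never traded away."""

    cpg_covered: float = 1.0
    informative_site: float = 2.0
    pyro_cpg: float = 0.5
    gc_clamp: float = 0.5
    tm_diff: float = 1.0
    internal_cpg: float = 1.0


@dataclass(frozen=True)
class DesignConstraints:
    """Hard design bounds.  Defaults are the published assay guidelines."""

    product_len_min: int = 120
    product_len_max: int = 350
    tm_min: float = 53.0
    tm_max: float = 62.0
    tm_pair_max_diff: float = 5.0
    tss_window: int = 400
    primer_len_min: int = 18
    primer_len_max: int = 27
    max_internal_cpg: int = 1
    max_homopolymer: int = 4
    min_informative_sites: int = 1
    min_island_overlap: float = 0.5
    nesting: str = "semi_nested"
    outer_product_max: int = 600
    pyro_window_len: int = 120
    weights: ScoreWeights = field(default_factory=ScoreWeights)

    def __post_init__(self) -> None:
        if self.product_len_min > self.product_len_max:
            raise ValueError("product_len_min > product_len_max")
        if self.primer_len_min > self.primer_len_max:
            raise ValueError("primer_len_min > primer_len_max")
        if self.tm_min > self.tm_max:
            raise ValueError("tm_min > tm_max")
        if self.nesting not in ("nested", "semi_nested"):
            raise ValueError("nesting must be 'nested' or 'semi_nested'")
        for name in (
            "product_len_min", "tss_window", "primer_len_min",
            "outer_product_max", "pyro_window_len",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class Primer:
    """One oligo on the converted template.

    ``start``/``end`` are half-open template coordinates of the annealing
    window; ``sequence`` is written 5'->3' (for '-' primers it is the
    reverse complement of the template window).
    """

    sequence: str
    start: int
    end: int
    strand: str
    tm: float
    gc_fraction: float
    n_internal_cpg: int
    gc_clamp: bool

    def __len__(self) -> int:
        return self.end - self.start

    def shifted(self, offset: int) -> "Primer":
        return Primer(
            sequence=self.sequence,
            start=self.start + offset,
            end=self.end + offset,
            strand=self.strand,
            tm=self.tm,
            gc_fraction=self.gc_fraction,
            n_internal_cpg=self.n_internal_cpg,
            gc_clamp=self.gc_clamp,
        )


def _has_long_run(seq: str, max_run: int) -> bool:
    run, prev = 1, ""
    for b in seq:
        run = run + 1 if b == prev else 1
        if run > max_run:
            return True
        prev = b
    return False


def _gc_fraction(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq)


def _gc_clamp(seq: str) -> bool:
    return any(b in "GC" for b in seq[-2:])


def enumerate_candidates(
    template: BisulfiteSequence,
    strand: str,
    constraints: DesignConstraints = DesignConstraints(),
    conditions: ReactionConditions = DEFAULT_CONDITIONS,
) -> list[Primer]:
    """All primer windows on the converted template passing the per-primer
    filters, sorted by position.

    Filters: length within bounds, Tm within [tm_min, tm_max], at most
    ``max_internal_cpg`` template CpGs overlapped, no mononucleotide run
    longer than ``max_homopolymer``, and the 3'-terminal base must not sit on
    a methylation-variable template position (the CpG C on '+', the same
    variable position approached from the right on '-').
    """
    if strand not in ("+", "-"):
        raise ValueError("strand must be '+' or '-'")
    conv = template.converted
    cpgs = template.cpg_positions
    cpg_set = set(cpgs)
    n = len(conv)
    out: list[Primer] = []
    for start in range(n):
        for length in range(constraints.primer_len_min, constraints.primer_len_max + 1):
            end = start + length
            if end > n:
                break
            n_cpg = bisect.bisect_left(cpgs, end) - bisect.bisect_left(cpgs, start)
            if n_cpg > constraints.max_internal_cpg:
                continue
            if strand == "+":
                if end - 1 in cpg_set:
                    continue
                seq = conv[start:end]
            else:
                if start in cpg_set:
                    continue
                seq = reverse_complement(conv[start:end])
            if _has_long_run(seq, constraints.max_homopolymer):
                continue
            tm = melting_temperature(seq, conditions)
            if not (constraints.tm_min <= tm <= constraints.tm_max):
                continue
            out.append(
                Primer(
                    sequence=seq,
                    start=start,
                    end=end,
                    strand=strand,
                    tm=tm,
                    gc_fraction=_gc_fraction(seq),
                    n_internal_cpg=n_cpg,
                    gc_clamp=_gc_clamp(seq),
                )
            )
    out.sort(key=lambda p: (p.start, p.end))
    return out


@dataclass(frozen=True)
class AssayDesign:
    """A complete nested/semi-nested bisulfite-PCR assay (locus coordinates)."""

    outer_pair: tuple[Primer, Primer]
    inner_pair: tuple[Primer, Primer]
    nesting: str
    amplicon_start: int
    amplicon_end: int
    outer_start: int
    outer_end: int
    cpgs_covered: tuple[int, ...]
    informative_sites: dict
    pyro_window: tuple[int, int]
    pyro_cpg_count: int
    score: float
    score_breakdown: dict

    @property
    def amplicon_length(self) -> int:
        return self.amplicon_end - self.amplicon_start

    @property
    def n_informative_sites(self) -> int:
        return sum(len(v) for v in self.informative_sites.values())


@dataclass
class DesignResult:
    """Ranked feasible designs plus per-constraint rejection counts."""

    designs: list[AssayDesign]
    rejections: Counter
    island: CpGIsland

    def __iter__(self):
        return iter(self.designs)

    def __len__(self) -> int:
        return len(self.designs)


def _pick_outer(
    inner_f: Primer,
    inner_r: Primer,
    fwd_desc_start: Sequence[Primer],
    rev_asc_end: Sequence[Primer],
    constraints: DesignConstraints,
    fwd_neg_starts: Sequence[int] | None = None,
    rev_end_keys: Sequence[int] | None = None,
) -> tuple[Primer, Primer] | None:
    """Deterministically choose an outer pair for one inner pair.

    The search prefers the tightest outer primers: forward candidates are
    scanned from the one closest upstream of the inner forward primer,
    reverse candidates from the smallest amplicon end, so the first feasible
    combination (outer product <= outer_product_max, pair Tm difference
    within bounds) wins.  In semi-nested mode exactly one inner primer is
    reused and the branch with the shorter outer product is taken.  Returns
    None when no feasible outer pair exists.
    """
    A, B = inner_f.start, inner_r.end
    max_prod = constraints.outer_product_max
    max_diff = constraints.tm_pair_max_diff
    # entry points: a forward outer with start >= A always ends past A, and a
    # reverse outer ending before B + min primer length cannot start at B
    if fwd_neg_starts is None:
        fwd_neg_starts = [-p.start for p in fwd_desc_start]
    if rev_end_keys is None:
        rev_end_keys = [p.end for p in rev_asc_end]
    fwd_from = bisect.bisect_left(fwd_neg_starts, -(A - 1))
    rev_from = bisect.bisect_left(rev_end_keys, B + constraints.primer_len_min)

    if constraints.nesting == "nested":
        for fo in fwd_desc_start[fwd_from:]:
            if fo.end > A:
                continue
            if fo.start < B - max_prod:
                break  # starts only decrease: every later fo is too far left
            for ro in rev_asc_end[rev_from:]:
                if ro.end > fo.start + max_prod:
                    break
                if ro.start < B:
                    continue
                if abs(fo.tm - ro.tm) <= max_diff:
                    return fo, ro
        return None

    # semi-nested: share the inner forward (extend right) or the inner
    # reverse (extend left); take the branch with the smaller outer product
    shared_f: tuple[Primer, Primer] | None = None
    for ro in rev_asc_end[rev_from:]:
        if ro.end > inner_f.start + max_prod:
            break
        if ro.start < B:
            continue
        if abs(inner_f.tm - ro.tm) <= max_diff:
            shared_f = (inner_f, ro)
            break
    shared_r: tuple[Primer, Primer] | None = None
    for fo in fwd_desc_start[fwd_from:]:
        if fo.end > A:
            continue
        if fo.start < B - max_prod:
            break
        if abs(inner_r.tm - fo.tm) <= max_diff:
            shared_r = (fo, inner_r)
            break
    if shared_f and shared_r:
        pf = shared_f[1].end - shared_f[0].start
        pr = shared_r[1].end - shared_r[0].start
        return shared_f if pf <= pr else shared_r
    return shared_f or shared_r


def design_assay(
    locus: GenomicLocus,
    islands: Sequence[CpGIsland],
    constraints: DesignConstraints = DesignConstraints(),
    *,
    enzymes: Sequence[_cobra.Enzyme] = _cobra.DEFAULT_ENZYMES,
    conditions: ReactionConditions = DEFAULT_CONDITIONS,
    max_designs: int | None = None,
) -> DesignResult:
    """Enumerate, check and rank bisulfite-PCR assays for a promoter island.

    The island containing (or nearest to) the TSS anchors the design.  Every
    emitted design satisfies all hard constraints; designs are sorted by
    descending score with a stable tie-break (more CpGs covered, shorter
    product, leftmost start).  When nothing is feasible an empty result is
    returned whose ``rejections`` counter says which constraint removed how
    many candidate pairs.
    """
    if not islands:
        raise NoIslandError("no CGI")
    tss = locus.tss
    island = min(
        islands,
        key=lambda isl: (0 if tss in isl else min(abs(tss - isl.start), abs(tss - isl.end))),
    )

    margin = constraints.outer_product_max
    lo = max(0, tss - constraints.tss_window - margin)
    hi = min(len(locus), tss + constraints.tss_window + margin)
    region = locus.sequence[lo:hi]
    template = bisulfite_convert(region, mode="all_unmethylated", source=f"{locus.name}:{lo}-{hi}/+")

    fwd = enumerate_candidates(template, "+", constraints, conditions)
    rev = enumerate_candidates(template, "-", constraints, conditions)

    cpgs = template.cpg_positions  # region coordinates, sorted
    # prefix[i] = number of CpG C offsets < i, for O(1) interval counts
    cpg_prefix = np.zeros(len(region) + 1, dtype=np.int64)
    cpg_prefix[[p + 1 for p in cpgs]] = 1
    cpg_prefix = np.cumsum(cpg_prefix)
    site_offsets: dict[str, list[tuple[int, list[int]]]] = {
        enz.name: _cobra.find_informative_sites(region, enz) for enz in enzymes
    }
    enz_offs = {name: [off for off, _ in sites] for name, sites in site_offsets.items()}
    enz_len = {enz.name: len(enz.recognition) for enz in enzymes}

    win_lo = tss - constraints.tss_window - lo  # TSS window in region coords
    win_hi = tss + constraints.tss_window - lo

    rejections: Counter = Counter()
    scored: list[AssayDesign] = []
    w = constraints.weights

    # nested outer choice depends only on the inner amplicon boundaries;
    # semi-nested also on the shared primer's Tm — cache per inner pair key
    outer_cache: dict = {}
    shared_f_cache: dict = {}
    shared_r_cache: dict = {}
    fwd_desc_start = sorted(fwd, key=lambda p: (-p.start, p.end))
    fwd_neg_starts = [-p.start for p in fwd_desc_start]

    def pick_outer(f: Primer, r: Primer):
        if constraints.nesting == "nested":
            key = (f.start, r.end)
            if key not in outer_cache:
                outer_cache[key] = _pick_outer(
                    f, r, fwd_desc_start, rev_by_end, constraints,
                    fwd_neg_starts, rev_ends,
                )
            return outer_cache[key]
        # semi-nested: the two sharing branches have independent, reusable
        # keys (forward-sharing depends on the forward primer and the inner
        # end; reverse-sharing on the reverse primer and the inner start)
        max_prod = constraints.outer_product_max
        max_diff = constraints.tm_pair_max_diff
        kf = (id(f), r.end)
        if kf not in shared_f_cache:
            hit = None
            start_i = bisect.bisect_left(rev_ends, r.end + constraints.primer_len_min)
            for ro in rev_by_end[start_i:]:
                if ro.end > f.start + max_prod:
                    break
                if ro.start < r.end:
                    continue
                if abs(f.tm - ro.tm) <= max_diff:
                    hit = (f, ro)
                    break
            shared_f_cache[kf] = hit
        kr = (f.start, id(r))
        if kr not in shared_r_cache:
            hit = None
            start_i = bisect.bisect_left(fwd_neg_starts, -(f.start - 1))
            for fo in fwd_desc_start[start_i:]:
                if fo.end > f.start:
                    continue
                if fo.start < r.end - max_prod:
                    break
                if abs(r.tm - fo.tm) <= max_diff:
                    hit = (fo, r)
                    break
            shared_r_cache[kr] = hit
        sf, sr = shared_f_cache[kf], shared_r_cache[kr]
        if sf and sr:
            return sf if sf[1].end - sf[0].start <= sr[1].end - sr[0].start else sr
        return sf or sr

    # reverse candidates ordered by amplicon end so each forward primer only
    # sees the slice with a product length inside the allowed range
    rev_by_end = sorted(rev, key=lambda p: (p.end, p.start))
    rev_ends = [p.end for p in rev_by_end]
    n_rev = len(rev_by_end)

    for f in fwd:
        lo_i = bisect.bisect_left(rev_ends, f.start + constraints.product_len_min)
        hi_i = bisect.bisect_right(rev_ends, f.start + constraints.product_len_max)
        rejections["product_length"] += n_rev - (hi_i - lo_i)
        if f.start < win_lo:  # amplicon would start upstream of the TSS window
            rejections["tss_window"] += hi_i - lo_i
            continue
        for r in rev_by_end[lo_i:hi_i]:
            a, b = f.start, r.end
            product = b - a
            if f.end > r.start:
                rejections["primer_overlap"] += 1
                continue
            if abs(f.tm - r.tm) > constraints.tm_pair_max_diff:
                rejections["tm_pair_diff"] += 1
                continue
            if a < win_lo or b > win_hi:
                rejections["tss_window"] += 1
                continue
            overlap = min(b + lo, island.end) - max(a + lo, island.start)
            if overlap < constraints.min_island_overlap * product:
                rejections["island_overlap"] += 1
                continue
            inf_sites = {}
            n_inf = 0
            for name, sites in site_offsets.items():
                offs = enz_offs[name]
                sel = sites[
                    bisect.bisect_left(offs, a) : bisect.bisect_right(offs, b - enz_len[name])
                ]
                inf_sites[name] = sel
                n_inf += len(sel)
            if n_inf < constraints.min_informative_sites:
                rejections["informative_sites"] += 1
                continue

            outer = pick_outer(f, r)
            if outer is None:
                rejections["no_outer_pair"] += 1
                continue

            covered = cpgs[bisect.bisect_left(cpgs, a) : bisect.bisect_left(cpgs, b - 1)]
            pyro = _best_pyro_window(cpg_prefix, f.end, r.start, constraints.pyro_window_len)
            breakdown = {
                "cpg_covered": w.cpg_covered * len(covered),
                "informative_site": w.informative_site * n_inf,
                "pyro_cpg": w.pyro_cpg * pyro[2],
                "gc_clamp": w.gc_clamp * (int(f.gc_clamp) + int(r.gc_clamp)),
                "tm_diff": -w.tm_diff * abs(f.tm - r.tm),
                "internal_cpg": -w.internal_cpg * (f.n_internal_cpg + r.n_internal_cpg),
            }
            score = sum(breakdown.values())
            fo, ro = outer
            scored.append(
                AssayDesign(
                    outer_pair=(fo.shifted(lo), ro.shifted(lo)),
                    inner_pair=(f.shifted(lo), r.shifted(lo)),
                    nesting=constraints.nesting,
                    amplicon_start=a + lo,
                    amplicon_end=b + lo,
                    outer_start=fo.start + lo,
                    outer_end=ro.end + lo,
                    cpgs_covered=tuple(p + lo for p in covered),
                    informative_sites={
                        name: [(off + lo, [p + lo for p in cov]) for off, cov in sites]
                        for name, sites in inf_sites.items()
                    },
                    pyro_window=(pyro[0] + lo, pyro[1] + lo),
                    pyro_cpg_count=pyro[2],
                    score=score,
                    score_breakdown=breakdown,
                )
            )

    scored.sort(
        key=lambda d: (
            -d.score,
            -len(d.cpgs_covered),
            d.amplicon_length,
            d.amplicon_start,
        )
    )
    if max_designs is not None:
        scored = scored[:max_designs]
    return DesignResult(designs=scored, rejections=rejections, island=island)


def _best_pyro_window(
    cpg_prefix: np.ndarray, start: int, end: int, window_len: int
) -> tuple[int, int, int]:
    """Sub-window of [start, end) (the region between the inner primers) of
    length <= window_len with the most fully contained CpGs; leftmost on
    ties.  ``cpg_prefix[i]`` counts CpG C offsets below i."""
    if end <= start:
        return (start, start, 0)
    length = min(window_len, end - start)
    counts = cpg_prefix[start + length - 1 : end] - cpg_prefix[start : end - length + 1]
    i = int(counts.argmax())
    return (start + i, start + i + length, int(counts[i]))
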