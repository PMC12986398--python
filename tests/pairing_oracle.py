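"""Independent exhaustive pairing oracle for assay design.

Re-derives the best feasible design by looping over every candidate primer
pair and re-stating each hard constraint and score term from the design
rules, without reusing the library's pairing, filtering or scoring code.
Candidate enumeration itself is oracled separately.
"""

from __future__ import annotations

from methassay.cobra import DEFAULT_ENZYMES
from methassay.primer_design import enumerate_candidates
from methassay.seqcore import bisulfite_convert

from .oracles import naive_informative_sites


def exhaustive_best_design(locus, island, constraints):
    """(amplicon_start, amplicon_end, score) of the maximum-score feasible
    design, with the stable tie-break (more CpGs covered, shorter product,
    leftmost); None when nothing is feasible."""
    tss = locus.tss
    lo = max(0, tss - constraints.tss_window - constraints.outer_product_max)
    hi = min(len(locus.sequence), tss + constraints.tss_window + constraints.outer_product_max)
    region = locus.sequence[lo:hi]
    template = bisulfite_convert(region)
    fwd = enumerate_candidates(template, "+", constraints)
    rev = enumerate_candidates(template, "-", constraints)
    cpgs = template.cpg_positions
    w = constraints.weights

    def has_outer(f, r):
        if constraints.nesting == "semi_nested":
            for ro in rev:
                if (
                    ro.start >= r.end
                    and ro.end - f.start <= constraints.outer_product_max
                    and abs(f.tm - ro.tm) <= constraints.tm_pair_max_diff
                ):
                    return True
            for fo in fwd:
                if (
                    fo.end <= f.start
                    and r.end - fo.start <= constraints.outer_product_max
                    and abs(r.tm - fo.tm) <= constraints.tm_pair_max_diff
                ):
                    return True
            return False
        for fo in fwd:
            if fo.end > f.start:
                continue
            for ro in rev:
                if (
                    ro.start >= r.end
                    and ro.end - fo.start <= constraints.outer_product_max
                    and abs(fo.tm - ro.tm) <= constraints.tm_pair_max_diff
                ):
                    return True
        return False

    best = None
    for f in fwd:
        for r in rev:
            a, b = f.start, r.end
            product = b - a
            if not (constraints.product_len_min <= product <= constraints.product_len_max):
                continue
            if f.end > r.start:
                continue
            if abs(f.tm - r.tm) > constraints.tm_pair_max_diff:
                continue
            if a + lo < tss - constraints.tss_window or b + lo > tss + constraints.tss_window:
                continue
            overlap = min(b + lo, island.end) - max(a + lo, island.start)
            if overlap < constraints.min_island_overlap * product:
                continue
            amp = region[a:b]
            n_inf = sum(
                len(naive_informative_sites(amp, e.recognition)) for e in DEFAULT_ENZYMES
            )
            if n_inf < constraints.min_informative_sites:
                continue
            if not has_outer(f, r):
                continue
            covered = [p for p in cpgs if a <= p and p + 1 < b]
            length = min(constraints.pyro_window_len, r.start - f.end)
            pyro_best = 0
            for s in range(f.end, r.start - length + 1):
                pyro_best = max(
                    pyro_best, sum(1 for p in cpgs if s <= p < s + length - 1)
                )
            score = (
                w.cpg_covered * len(covered)
                + w.informative_site * n_inf
                + w.pyro_cpg * pyro_best
                + w.gc_clamp * (int(f.gc_clamp) + int(r.gc_clamp))
                - w.tm_diff * abs(f.tm - r.tm)
                - w.internal_cpg * (f.n_internal_cpg + r.n_internal_cpg)
            )
            key = (score, len(covered), -product, -a)
            if best is None or key > best[0]:
                best = (key, (a + lo, b + lo, score))
    return None if best is None else best[1]
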