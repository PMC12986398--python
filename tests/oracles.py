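"""Independent brute-force oracles used by the test suite.

Every function here recomputes a result from first principles — naive
per-window recounting, exhaustive double loops, explicit enumeration —
without reusing the library's incremental implementations, so agreement is
meaningful.
"""

from __future__ import annotations

import itertools
import math

from methassay.primer_design import melting_temperature


# ---------------------------------------------------------------- CpG islands
def _interval_stats_naive(s: str) -> tuple[float, float]:
    c, g = s.count("C"), s.count("G")
    cg = sum(1 for i in range(len(s) - 1) if s[i : i + 2] == "CG")
    gc = (c + g) / len(s)
    obs_exp = cg * len(s) / (c * g) if c and g else 0.0
    return gc, obs_exp


def brute_force_islands(
    seq: str,
    min_length: int = 200,
    min_gc: float = 0.50,
    min_obs_exp: float = 0.60,
    window: int = 200,
    step: int = 1,
) -> list[tuple[int, int]]:
    """All-windows scan with naive per-window recounting: mark every passing
    window, merge overlapping ones, then report the longest (leftmost)
    sub-interval of each merged region that still passes both thresholds."""
    passing = []
    for s in range(0, len(seq) - window + 1, step):
        gc, oe = _interval_stats_naive(seq[s : s + window])
        if gc >= min_gc and oe >= min_obs_exp:
            passing.append(s)
    regions: list[list[int]] = []
    for s in passing:
        if regions and s <= regions[-1][1]:
            regions[-1][1] = max(regions[-1][1], s + window)
        else:
            regions.append([s, s + window])
    out = []
    for rs, re_ in regions:
        found = None
        for length in range(re_ - rs, min_length - 1, -1):
            for s in range(rs, re_ - length + 1):
                gc, oe = _interval_stats_naive(seq[s : s + length])
                if gc >= min_gc and oe >= min_obs_exp:
                    found = (s, s + length)
                    break
            if found:
                break
        if found:
            out.append(found)
    return out


# ------------------------------------------------------------------- primers
def brute_force_candidates(converted: str, cpg_positions, strand, constraints):
    """Exhaustive double loop re-applying every per-primer predicate."""
    comp = str.maketrans("ACGT", "TGCA")
    cpgs = set(cpg_positions)
    hits = []
    n = len(converted)
    for start in range(n):
        for end in range(start + constraints.primer_len_min,
                         min(n, start + constraints.primer_len_max) + 1):
            if sum(1 for p in cpgs if start <= p < end) > constraints.max_internal_cpg:
                continue
            if strand == "+":
                if end - 1 in cpgs:
                    continue
                seq = converted[start:end]
            else:
                if start in cpgs:
                    continue
                seq = converted[start:end].translate(comp)[::-1]
            run = max(
                len(list(grp)) for _, grp in itertools.groupby(seq)
            )
            if run > constraints.max_homopolymer:
                continue
            tm = melting_temperature(seq)
            if not (constraints.tm_min <= tm <= constraints.tm_max):
                continue
            hits.append((start, end, strand, seq))
    return sorted(hits)


# --------------------------------------------------------------------- CoBRA
def naive_informative_sites(amplicon: str, recognition: str):
    """Convert both ways by per-character string building and string-search."""
    cpg = [i for i in range(len(amplicon) - 1) if amplicon[i : i + 2] == "CG"]
    cpg_set = set(cpg)
    meth = "".join(
        b if b != "C" or i in cpg_set else "T" for i, b in enumerate(amplicon)
    )
    unmeth = amplicon.replace("C", "T")

    def occurrences(hay):
        return {
            i for i in range(len(hay) - len(recognition) + 1)
            if hay[i : i + len(recognition)] == recognition
        }

    sites = sorted(occurrences(meth) - occurrences(unmeth))
    return [
        (off, [p for p in cpg if off <= p < off + len(recognition)]) for off in sites
    ]


# ---------------------------------------------------------------- statistics
def exact_mwu_two_sided(a, b) -> float:
    """Two-sided exact Mann-Whitney p by enumeration of all C(n1+n2, n1)
    assignments of the pooled observations to the first group."""
    pooled = list(a) + list(b)
    n1 = len(a)

    def u_of(group_a, group_b):
        return sum(
            (1.0 if x > y else 0.5 if x == y else 0.0)
            for x in group_a for y in group_b
        )

    u_obs = u_of(a, b)
    us = []
    idx = range(len(pooled))
    for comb in itertools.combinations(idx, n1):
        ga = [pooled[i] for i in comb]
        gb = [pooled[i] for i in idx if i not in set(comb)]
        us.append(u_of(ga, gb))
    n = len(us)
    p_le = sum(1 for u in us if u <= u_obs) / n
    p_ge = sum(1 for u in us if u >= u_obs) / n
    return min(1.0, 2.0 * min(p_le, p_ge))


def welch_by_hand(a, b):
    """Welch t statistic and Welch-Satterthwaite df from the textbook
    formulas (no scipy)."""
    ma = sum(a) / len(a)
    mb = sum(b) / len(b)
    va = sum((x - ma) ** 2 for x in a) / (len(a) - 1)
    vb = sum((x - mb) ** 2 for x in b) / (len(b) - 1)
    se2 = va / len(a) + vb / len(b)
    t = (ma - mb) / math.sqrt(se2)
    df = se2**2 / (
        (va / len(a)) ** 2 / (len(a) - 1) + (vb / len(b)) ** 2 / (len(b) - 1)
    )
    return t, df


# -------------------------------------------------------- melting temperature
#: Unified nearest-neighbor enthalpy (kcal/mol) and entropy (cal/mol/K).
NN_TABLE = {
    "AA": (-7.9, -22.2), "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4), "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2), "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}


def hand_summed_tm(seq: str, mono_mM=50.0, mg_mM=1.5, primer_nM=250.0) -> float:
    """Hand summation over the unified nearest-neighbor table with terminal
    initiation penalties, the entropic monovalent salt correction
    (0.368 (N-1) ln[Na+], Mg as monovalent equivalent) and excess-primer
    melting at the given oligo concentration."""
    dh, ds = 0.0, 0.0
    for term in (seq[0], seq[-1]):
        if term in "AT":
            dh += 2.3
            ds += 4.1
        else:
            dh += 0.1
            ds += -2.8
    for i in range(len(seq) - 1):
        h, s = NN_TABLE[seq[i : i + 2]]
        dh += h
        ds += s
    na_molar = (mono_mM + 120.0 * math.sqrt(mg_mM)) / 1000.0
    ds += 0.368 * (len(seq) - 1) * math.log(na_molar)
    return 1000.0 * dh / (ds + 1.987 * math.log(primer_nM * 1e-9)) - 273.15
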