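"""Seeded generators for every input class the toolkit consumes.

These emulate the study conditions — a promoter locus with an embedded CpG
island around a TSS, stage-labelled beta-value cohorts whose group means
follow the published tumor-progression pattern, CoBRA digestion cohorts, and
noisy pyrograms with known per-CpG methylation — so the full pipeline runs
and is tested without any download.  All generators are pure functions of
(spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cobra import DEFAULT_CALL_THRESHOLD, CobraCall, make_calls
from .methstats import MethylationMatrix
from .pyro import Dispensation, Pyrogram, simulate_pyrogram
from .seqcore import GenomicLocus, find_cpg_islands

__all__ = [
    "LocusSpec",
    "GroupSpec",
    "CohortSpec",
    "CobraGroupSpec",
    "DEFAULT_COHORT_GROUPS",
    "DEFAULT_COBRA_GROUPS",
    "make_locus",
    "make_cohort",
    "make_pyro_set",
    "make_cobra_calls",
]


@dataclass(frozen=True)
class LocusSpec:
    """Blueprint for a synthetic promoter locus with an embedded CpG island.

    ``island_cpg_density`` is planted CG dinucleotides per bp (real promoter
    islands run around one CpG per 10-12 bp); ``background_gc`` is kept below
    the island-detection GC threshold and background CpGs are depleted, as in
    bulk genomic sequence.
    """

    total_length: int = 3000
    island_length: int = 600
    island_gc: float = 0.65
    island_cpg_density: float = 0.08
    background_gc: float = 0.40
    island_start: int | None = None
    tss_offset: int | None = None  # relative to island start; default: centre
    seed: int = 0

    def __post_init__(self) -> None:
        if self.island_length >= self.total_length:
            raise ValueError("island_length must be smaller than total_length")
        for name in ("island_gc", "island_cpg_density", "background_gc"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.island_gc < 0.5:
            raise ValueError(
                "island_gc below 0.5 cannot satisfy the CpG-island GC threshold"
            )
        if 2 * self.island_cpg_density * self.island_length > self.island_length:
            raise ValueError("island CpG density infeasible (> 0.5 per bp)")
        if self.island_gc * self.island_length < 2 * round(
            self.island_cpg_density * self.island_length
        ):
            raise ValueError("island_gc too low for the requested CpG density")


def _random_dna(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=n, p=p)


def _deplete_cpg(seq: np.ndarray) -> None:
    """Replace the G of every CG dinucleotide with A, in place (one pass
    suffices: an introduced A can never create a new CG)."""
    for i in range(len(seq) - 1):
        if seq[i] == b"C" and seq[i + 1] == b"G":
            seq[i + 1] = b"A"


def _build_island(rng: np.random.Generator, spec: LocusSpec) -> str:
    """Interleave CG dinucleotides into a GC-rich filler until the target
    density is reached; filler GC is solved so the whole island hits
    ``island_gc`` on average."""
    L = spec.island_length
    k = int(round(spec.island_cpg_density * L))
    filler_len = L - 2 * k
    filler_gc = (spec.island_gc * L - 2 * k) / filler_len if filler_len else 0.0
    filler_gc = min(max(filler_gc, 0.0), 1.0)
    filler = _random_dna(rng, filler_len, filler_gc)
    # split the filler into k+1 chunks and join with CG between chunks
    cuts = np.sort(rng.choice(filler_len + 1, size=k, replace=True))
    parts = []
    prev = 0
    for c in cuts:
        parts.append(filler[prev:c].tobytes().decode())
        parts.append("CG")
        prev = int(c)
    parts.append(filler[prev:].tobytes().decode())
    return "".join(parts)


def make_locus(spec: LocusSpec = LocusSpec(), *, max_attempts: int = 20) -> GenomicLocus:
    """Generate a locus whose planted island passes ``find_cpg_islands`` at
    the default thresholds, with the TSS inside the island.  Deterministic
    per spec/seed; raises after ``max_attempts`` rejected draws."""
    master = np.random.default_rng(spec.seed)
    island_start = (
        spec.island_start
        if spec.island_start is not None
        else (spec.total_length - spec.island_length) // 2
    )
    if not (0 <= island_start <= spec.total_length - spec.island_length):
        raise ValueError("island does not fit inside the locus")
    tss_offset = (
        spec.tss_offset if spec.tss_offset is not None else spec.island_length // 2
    )
    if not (0 <= tss_offset < spec.island_length):
        raise ValueError("tss_offset must fall inside the island")

    for _ in range(max_attempts):
        rng = np.random.default_rng(master.integers(0, 2**31 - 1))
        background = _random_dna(
            rng, spec.total_length - spec.island_length, spec.background_gc
        )
        _deplete_cpg(background)
        island = _build_island(rng, spec)
        seq = (
            background[:island_start].tobytes().decode()
            + island
            + background[island_start:].tobytes().decode()
        )
        planted = (island_start, island_start + spec.island_length)
        detected = find_cpg_islands(seq)
        ok = any(
            min(isl.end, planted[1]) - max(isl.start, planted[0])
            >= 0.9 * spec.island_length
            for isl in detected
        )
        if ok:
            tss = island_start + tss_offset
            return GenomicLocus(
                name=f"synthetic_locus_seed{spec.seed}",
                sequence=seq,
                tss=tss,
                strand="+",
                isoforms=[("isoformA", tss)],
            )
    raise RuntimeError(
        "could not generate a locus whose planted island passes detection; "
        "island_gc/island_cpg_density too close to the thresholds"
    )


@dataclass(frozen=True)
class GroupSpec:
    """One cohort group: size, target mean beta, beta concentration."""

    n: int
    mean_beta: float
    concentration: float = 20.0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("group size must be >= 1")
        if not (0.0 < self.mean_beta < 1.0):
            raise ValueError("target mean beta must lie in (0, 1)")
        if self.concentration <= 0:
            raise ValueError("concentration must be positive")


#: Stage-wise mean CGI methylation used as simulation defaults, following the
#: published tumor-progression pattern (nevi 15%, primary melanomas 44%, skin
#: metastases 45%, lymph-node metastases 62%, brain metastases 49%) with the
#: published per-stage sample sizes.
DEFAULT_COHORT_GROUPS: dict[str, GroupSpec] = {
    "nevi": GroupSpec(7, 0.15),
    "primary": GroupSpec(21, 0.44),
    "metastasis_skin": GroupSpec(6, 0.45),
    "metastasis_lymph_node": GroupSpec(2, 0.62),
    "metastasis_brain": GroupSpec(6, 0.49),
}


@dataclass(frozen=True)
class CohortSpec:
    """Blueprint for a stage-labelled beta-value cohort."""

    groups: Mapping[str, GroupSpec] = field(
        default_factory=lambda: dict(DEFAULT_COHORT_GROUPS)
    )
    probes_per_island: int = 10
    n_flank_probes: int = 3
    flank_mean_beta: float = 0.05
    probe_concentration: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("cohort needs at least one group")
        if self.probes_per_island < 1:
            raise ValueError("need at least one island probe")


def make_cohort(spec: CohortSpec = CohortSpec()) -> MethylationMatrix:
    """Draw a samples x probes beta matrix: per sample a latent CGI
    methylation level from Beta(mean, concentration), then per-probe values
    around that level; flank probes stay near ``flank_mean_beta`` for every
    group.  Deterministic per spec/seed."""
    rng = np.random.default_rng(spec.seed)
    island_ids = [f"cg{i:05d}" for i in range(spec.probes_per_island)]
    flank_ids = [f"flank{i:02d}" for i in range(spec.n_flank_probes)]
    probe_ids = island_ids + flank_ids
    positions = pd.Series(
        list(range(0, 30 * spec.probes_per_island, 30))
        + list(range(-30 * spec.n_flank_probes, 0, 30)),
        index=probe_ids,
    )
    eps = 1e-6

    def beta_draw(mean: float, conc: float, size) -> np.ndarray:
        return rng.beta(mean * conc, (1 - mean) * conc, size=size)

    rows, sample_ids, labels = [], [], []
    for gname, g in spec.groups.items():
        latent = np.clip(beta_draw(g.mean_beta, g.concentration, g.n), eps, 1 - eps)
        for i, mu in enumerate(latent):
            island_vals = beta_draw(float(mu), spec.probe_concentration, spec.probes_per_island)
            flank_vals = beta_draw(
                spec.flank_mean_beta, spec.probe_concentration, spec.n_flank_probes
            )
            rows.append(np.concatenate([island_vals, flank_vals]))
            sample_ids.append(f"{gname}_{i + 1:03d}")
            labels.append(gname)
    beta = pd.DataFrame(rows, index=sample_ids, columns=probe_ids)
    return MethylationMatrix(
        beta=beta,
        groups=pd.Series(labels, index=sample_ids),
        island_probes=pd.Series(
            [True] * len(island_ids) + [False] * len(flank_ids), index=probe_ids
        ),
        probe_positions=positions,
    )


def make_pyro_set(
    dispensation: Dispensation,
    n_samples: int,
    m_profile: Mapping[int, float],
    noise_cv: float = 0.05,
    seed: int = 0,
    *,
    incomplete_conversion_rate: float = 0.0,
) -> tuple[list[Pyrogram], pd.DataFrame]:
    """A batch of simulated pyrograms plus their truth table.

    Every sample shares the per-CpG truth ``m_profile``; noise differs per
    sample through per-sample sub-seeds.  The truth table has one row per
    (sample, CpG offset) pair.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(0, 2**31 - 1, size=n_samples)
    pyrograms, rows = [], []
    for i in range(n_samples):
        name = f"pyro_{i + 1:03d}"
        pg = simulate_pyrogram(
            dispensation,
            m_profile,
            noise_cv=noise_cv,
            incomplete_conversion_rate=incomplete_conversion_rate,
            seed=int(sub_seeds[i]),
            sample=name,
        )
        pyrograms.append(pg)
        for off, m in m_profile.items():
            rows.append({"sample": name, "cpg_offset": off, "m_true": float(m)})
    truth = pd.DataFrame(rows, columns=["sample", "cpg_offset", "m_true"])
    return pyrograms, truth


@dataclass(frozen=True)
class CobraGroupSpec:
    """One CoBRA cohort group: size and target hypermethylation frequency."""

    n: int
    target_frequency: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("group size must be >= 1")
        if not (0.0 <= self.target_frequency <= 1.0):
            raise ValueError("target frequency must lie in [0, 1]")


#: CoBRA hypermethylation frequencies by stage used as simulation defaults
#: (23% of nevi, 68% of primary melanomas, 82% of metastases, 100% of
#: melanoma cell lines).
DEFAULT_COBRA_GROUPS: dict[str, CobraGroupSpec] = {
    "nevi": CobraGroupSpec(13, 0.23),
    "primary": CobraGroupSpec(22, 0.68),
    "metastasis": CobraGroupSpec(11, 0.82),
    "cell_line": CobraGroupSpec(5, 1.00),
}


def make_cobra_calls(
    groups: Mapping[str, CobraGroupSpec] | None = None,
    threshold: float = DEFAULT_CALL_THRESHOLD,
    seed: int = 0,
) -> list[CobraCall]:
    """Stage-labelled digestion cohort: per group, round(n * frequency)
    samples get a digested fraction above the call threshold and the rest
    below it, in shuffled order.  Deterministic per seed."""
    groups = dict(DEFAULT_COBRA_GROUPS) if groups is None else dict(groups)
    rng = np.random.default_rng(seed)
    triples = []
    for gname, g in groups.items():
        k = int(round(g.n * g.target_frequency))
        hyper = threshold + (0.95 - threshold) * rng.random(k)
        hypo = 0.8 * threshold * rng.random(g.n - k)
        fractions = np.concatenate([hyper, hypo])
        rng.shuffle(fractions)
        for i, f in enumerate(fractions):
            triples.append((f"{gname}_{i + 1:03d}", float(f), gname))
    return make_calls(triples, threshold)
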