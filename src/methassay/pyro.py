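"""Pyrosequencing assay construction, pyrogram simulation and quantification.

At a bisulfite-converted CpG the incorporated base is C when the cytosine
was methylated and T otherwise; dispensing C then T at each CpG lets the
peak-height ratio h_C / (h_C + h_T) estimate percent methylation per CpG.
Non-CpG cytosines must read as T after complete conversion, so a C
dispensation at such a position is a conversion control: any signal there is
unconverted background.

The peak model is linear and single-template: each template position is
assigned to exactly one dispensation at build time, homopolymer runs give
peaks proportional to run length, and there is no de-phasing or dark
nucleotide modelling.  A consequence of the static assignment is that a
template T run immediately after a CpG gets its own T dispensation rather
than merging into the CpG's T peak, which keeps per-CpG quantification
exact in the noise-free limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .seqcore import BisulfiteSequence, cpg_positions_of

__all__ = [
    "Dispensation",
    "Pyrogram",
    "CpGQuantification",
    "build_dispensation",
    "simulate_pyrogram",
    "quantify",
    "conversion_qc",
    "pyrogram_to_frame",
    "frame_to_pyrogram",
    "DEFAULT_QC_THRESHOLD_PCT",
]

DEFAULT_QC_THRESHOLD_PCT = 5.0


@dataclass(frozen=True)
class Dispensation:
    """A dispensation order with CpG quantification pairs and controls.

    ``bases[i]`` is the nucleotide dispensed at step i and ``weights[i]`` the
    expected full-signal incorporation (run length for plain runs, 1.0 for
    the variable positions).  ``cpg_pairs`` lists (C step, T step, CpG offset)
    per quantified CpG; ``control_pairs`` the same for conversion controls at
    non-CpG cytosines.
    """

    bases: tuple[str, ...]
    weights: tuple[float, ...]
    cpg_pairs: tuple[tuple[int, int, int], ...]
    control_pairs: tuple[tuple[int, int, int], ...]

    def __post_init__(self) -> None:
        quant = {i for c, t, _ in self.cpg_pairs for i in (c, t)}
        ctrl = {i for c, t, _ in self.control_pairs for i in (c, t)}
        if quant & ctrl:
            raise ValueError("control dispensations overlap CpG quantification pairs")
        for c, t, _ in self.cpg_pairs:
            if c >= t:
                raise ValueError("C dispensation must precede T at each CpG")

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class Pyrogram:
    """Peak heights over a dispensation order, plus sample metadata."""

    dispensation: Dispensation
    peak_heights: np.ndarray
    sample: str = "sample"
    seed: int | None = None

    def __post_init__(self) -> None:
        self.peak_heights = np.asarray(self.peak_heights, dtype=float)
        if len(self.peak_heights) != len(self.dispensation):
            raise ValueError("one peak height per dispensation required")
        if (self.peak_heights < 0).any():
            raise ValueError("peak heights must be non-negative")


@dataclass
class CpGQuantification:
    """Per-CpG methylation estimates (%) with conversion QC."""

    per_cpg: dict[int, float]
    no_signal: list[int]
    region_mean: float
    qc_pass: bool
    background_pct: float


def build_dispensation(
    target: BisulfiteSequence | str, *, max_controls: int = 2
) -> Dispensation:
    """Dispensation order for the converted sequence downstream of a
    sequencing primer.

    ``target`` carries the original region (a BisulfiteSequence, or the raw
    pre-conversion string); the dispensation follows the converted base
    order, emits a C-then-T pair at every CpG, compresses homopolymer runs
    into single dispensations, and inserts a C control at up to
    ``max_controls`` non-CpG cytosines (evenly spread).  Deterministic.
    """
    region = target.original if isinstance(target, BisulfiteSequence) else str(target).upper()
    if set(region) - set("ACGT"):
        raise ValueError("target region must be A/C/G/T")
    cpg_set = set(cpg_positions_of(region))
    if not cpg_set:
        raise ValueError("nothing to quantify: target region contains no CpG")
    non_cpg_c = [i for i, b in enumerate(region) if b == "C" and i not in cpg_set]
    if non_cpg_c and max_controls > 0:
        idx = np.unique(
            np.linspace(0, len(non_cpg_c) - 1, min(max_controls, len(non_cpg_c))).round().astype(int)
        )
        controls = {non_cpg_c[i] for i in idx}
    else:
        controls = set()

    bases: list[str] = []
    weights: list[float] = []
    cpg_pairs: list[tuple[int, int, int]] = []
    control_pairs: list[tuple[int, int, int]] = []

    i, n = 0, len(region)
    while i < n:
        if i in cpg_set:
            bases.append("C"); weights.append(1.0)
            bases.append("T"); weights.append(1.0)
            cpg_pairs.append((len(bases) - 2, len(bases) - 1, i))
            i += 1
        elif i in controls:
            bases.append("C"); weights.append(1.0)
            bases.append("T"); weights.append(1.0)
            control_pairs.append((len(bases) - 2, len(bases) - 1, i))
            i += 1
        else:
            b = "T" if region[i] == "C" else region[i]
            run = 1
            j = i + 1
            while (
                j < n
                and j not in cpg_set
                and j not in controls
                and ("T" if region[j] == "C" else region[j]) == b
            ):
                run += 1
                j += 1
            bases.append(b)
            weights.append(float(run))
            i = j
    return Dispensation(
        bases=tuple(bases),
        weights=tuple(weights),
        cpg_pairs=tuple(cpg_pairs),
        control_pairs=tuple(control_pairs),
    )


def simulate_pyrogram(
    dispensation: Dispensation,
    m_levels: Mapping[int, float],
    noise_cv: float = 0.0,
    incomplete_conversion_rate: float = 0.0,
    seed: int | None = None,
    *,
    sample: str = "sim",
) -> Pyrogram:
    """Simulate peak heights for known per-CpG methylation fractions.

    C peaks at CpG pairs are proportional to the methylation fraction m and
    T peaks to 1 - m; plain runs give their run length; control pairs carry
    ``incomplete_conversion_rate`` on C and its complement on T.
    Multiplicative Gaussian noise with coefficient of variation ``noise_cv``
    is applied to every peak (clipped at zero); fully reproducible per seed.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    if not (0.0 <= incomplete_conversion_rate <= 1.0):
        raise ValueError("incomplete_conversion_rate outside [0, 1]")
    for off, m in m_levels.items():
        if not (0.0 <= float(m) <= 1.0):
            raise ValueError(f"methylation fraction {m} at offset {off} outside [0, 1]")
    missing = {off for _, _, off in dispensation.cpg_pairs} - set(m_levels)
    if missing:
        raise ValueError(f"m_levels missing CpG offsets {sorted(missing)}")

    heights = np.array(dispensation.weights, dtype=float)
    for c_i, t_i, off in dispensation.cpg_pairs:
        m = float(m_levels[off])
        heights[c_i] = m
        heights[t_i] = 1.0 - m
    r = incomplete_conversion_rate
    for c_i, t_i, _ in dispensation.control_pairs:
        heights[c_i] = r
        heights[t_i] = 1.0 - r
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        heights = heights * (1.0 + rng.normal(0.0, noise_cv, size=heights.shape))
        heights = np.clip(heights, 0.0, None)
    return Pyrogram(dispensation=dispensation, peak_heights=heights, sample=sample, seed=seed)


def conversion_qc(
    pyrogram: Pyrogram, threshold_pct: float = DEFAULT_QC_THRESHOLD_PCT
) -> tuple[bool, float]:
    """(qc_pass, background %) from the conversion-control dispensations.

    Background is the mean C/(C+T) signal ratio at control positions, in
    percent; QC fails when it exceeds ``threshold_pct``.
    """
    pairs = pyrogram.dispensation.control_pairs
    if not pairs:
        raise ValueError("dispensation has no conversion controls")
    h = pyrogram.peak_heights
    ratios = []
    for c_i, t_i, _ in pairs:
        tot = h[c_i] + h[t_i]
        if tot > 0:
            ratios.append(100.0 * h[c_i] / tot)
    background = float(np.mean(ratios)) if ratios else 0.0
    return background <= threshold_pct, background


def quantify(
    pyrogram: Pyrogram, qc_threshold_pct: float = DEFAULT_QC_THRESHOLD_PCT
) -> CpGQuantification:
    """Per-CpG methylation estimates: 100 * h_C / (h_C + h_T) at each CpG
    pair; zero-signal CpGs are flagged and excluded from the region mean."""
    pairs = pyrogram.dispensation.cpg_pairs
    if not pairs:
        raise ValueError("dispensation has no CpG quantification pairs")
    h = pyrogram.peak_heights
    per_cpg: dict[int, float] = {}
    no_signal: list[int] = []
    for c_i, t_i, off in pairs:
        tot = h[c_i] + h[t_i]
        if tot <= 0:
            no_signal.append(off)
        else:
            per_cpg[off] = 100.0 * float(h[c_i]) / float(tot)
    region_mean = float(np.mean(list(per_cpg.values()))) if per_cpg else float("nan")
    if pyrogram.dispensation.control_pairs:
        qc_pass, background = conversion_qc(pyrogram, qc_threshold_pct)
    else:
        qc_pass, background = True, 0.0
    return CpGQuantification(
        per_cpg=per_cpg,
        no_signal=no_signal,
        region_mean=region_mean,
        qc_pass=qc_pass,
        background_pct=background,
    )


def pyrogram_to_frame(pyrogram: Pyrogram) -> pd.DataFrame:
    """Flatten a pyrogram to a TSV-friendly frame: one row per dispensation
    with its base, expected weight, measured height, role and CpG offset."""
    d = pyrogram.dispensation
    role = ["plain"] * len(d)
    offset = [-1] * len(d)
    for c_i, t_i, off in d.cpg_pairs:
        role[c_i], role[t_i] = "cpg_c", "cpg_t"
        offset[c_i] = offset[t_i] = off
    for c_i, t_i, off in d.control_pairs:
        role[c_i], role[t_i] = "ctrl_c", "ctrl_t"
        offset[c_i] = offset[t_i] = off
    return pd.DataFrame(
        {
            "step": range(len(d)),
            "base": d.bases,
            "weight": d.weights,
            "height": pyrogram.peak_heights,
            "role": role,
            "offset": offset,
        }
    )


def frame_to_pyrogram(frame: pd.DataFrame, sample: str = "sample") -> Pyrogram:
    """Rebuild a Pyrogram from the frame written by `pyrogram_to_frame`."""
    frame = frame.sort_values("step").reset_index(drop=True)

    def pairs(c_role: str, t_role: str) -> tuple[tuple[int, int, int], ...]:
        cs = frame[frame["role"] == c_role]
        ts = frame[frame["role"] == t_role].set_index("offset")
        out = []
        for _, row in cs.iterrows():
            off = int(row["offset"])
            out.append((int(row["step"]), int(ts.loc[off, "step"]), off))
        return tuple(out)

    disp = Dispensation(
        bases=tuple(frame["base"]),
        weights=tuple(float(w) for w in frame["weight"]),
        cpg_pairs=pairs("cpg_c", "cpg_t"),
        control_pairs=pairs("ctrl_c", "ctrl_t"),
    )
    return Pyrogram(
        dispensation=disp,
        peak_heights=frame["height"].to_numpy(dtype=float),
        sample=sample,
    )
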