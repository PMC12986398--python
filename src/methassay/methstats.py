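"""Methylation and expression statistics for screening and validation.

Group contrasts of array-style beta values use the two-sided Mann-Whitney U
rank test with Bonferroni adjustment over the pairwise comparisons actually
performed; pyrosequencing and RT-PCR contrasts use the one-tailed Welch
t-test.  Relative expression follows the 2^-ddCt convention against a
reference gene and calibrator sample.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _st

__all__ = [
    "MethylationMatrix",
    "GroupComparison",
    "cgi_mean_per_sample",
    "mann_whitney_u",
    "bonferroni",
    "welch_t_one_tailed",
    "relative_expression",
    "stage_summary",
    "significance_stars",
]


def significance_stars(p: float) -> str:
    """Render a p-value as the conventional stars (* <0.05, ** <0.01, *** <0.001)."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass
class MethylationMatrix:
    """Samples x probes beta values with group labels and probe annotation.

    ``beta`` has samples as rows and probes as columns; values in [0, 1]
    with NaN allowed for missing.  ``groups`` maps each sample to its stage
    label; ``island_probes`` flags probes inside the promoter CpG island;
    ``probe_positions`` holds 0-based probe coordinates.
    """

    beta: pd.DataFrame
    groups: pd.Series
    island_probes: pd.Series
    probe_positions: pd.Series | None = None

    def __post_init__(self) -> None:
        vals = self.beta.to_numpy(dtype=float)
        finite = vals[~np.isnan(vals)]
        if ((finite < 0) | (finite > 1)).any():
            raise ValueError("beta values must lie in [0, 1]")
        missing = set(self.beta.index) - set(self.groups.index)
        if missing:
            raise ValueError(f"samples without a group label: {sorted(missing)}")
        self.groups = self.groups.loc[self.beta.index]

    @property
    def samples(self) -> list[str]:
        return list(self.beta.index)

    @property
    def probes(self) -> list[str]:
        return list(self.beta.columns)

    def island_probe_ids(self) -> list[str]:
        return list(self.island_probes[self.island_probes].index)

    def to_tsv(self, beta_path, sample_path, probe_path) -> None:
        self.beta.rename_axis("sample").to_csv(beta_path, sep="\t")
        self.groups.rename("group").rename_axis("sample").to_csv(sample_path, sep="\t")
        probe_df = pd.DataFrame({"island": self.island_probes.astype(int)})
        if self.probe_positions is not None:
            probe_df["position"] = self.probe_positions
        probe_df.rename_axis("probe").to_csv(probe_path, sep="\t")

    @classmethod
    def from_tsv(cls, beta_path, sample_path, probe_path) -> "MethylationMatrix":
        beta = pd.read_csv(beta_path, sep="\t", index_col=0)
        beta.index.name = None
        samples = pd.read_csv(sample_path, sep="\t", index_col=0)
        samples.index.name = None
        probes = pd.read_csv(probe_path, sep="\t", index_col=0)
        probes.index.name = None
        return cls(
            beta=beta,
            groups=samples["group"],
            island_probes=probes["island"].astype(bool),
            probe_positions=probes["position"] if "position" in probes else None,
        )


@dataclass(frozen=True)
class GroupComparison:
    """One two-group test: statistic, raw and adjusted p, group means."""

    group_a: str
    group_b: str
    test: str
    tail: str
    statistic: float
    p_raw: float
    p_adjusted: float
    mean_a: float
    mean_b: float
    n_a: int
    n_b: int

    @property
    def stars(self) -> str:
        return significance_stars(self.p_adjusted)


def cgi_mean_per_sample(
    matrix: MethylationMatrix, island_probes: Sequence[str] | None = None
) -> pd.Series:
    """Mean beta over the island probes, per sample (missing probes excluded;
    samples with no non-missing island probe come back as NaN)."""
    probes = list(island_probes) if island_probes is not None else matrix.island_probe_ids()
    if not probes:
        raise ValueError("empty island probe set")
    absent = set(probes) - set(matrix.beta.columns)
    if absent:
        raise ValueError(f"probes not in matrix: {sorted(absent)}")
    return matrix.beta[probes].mean(axis=1, skipna=True)


def mann_whitney_u(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U rank test.

    Exact p by enumeration of rank assignments when the smaller group has
    <= 8 observations and there are no ties; otherwise the normal
    approximation with tie and continuity corrections.  Returns (U, p) with
    U the statistic of the first sample.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    method = "exact" if (min(a.size, b.size) <= 8 and not ties) else "asymptotic"
    res = _st.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def bonferroni(p_values: Sequence[float], m_comparisons: int | None = None) -> list[float]:
    """Bonferroni adjustment: min(1, p * m); m defaults to len(p_values) and
    may be larger when the family of tests extends beyond those given."""
    p = list(p_values)
    if m_comparisons is None:
        m_comparisons = len(p)
    if p and m_comparisons < 1:
        raise ValueError("m_comparisons must be >= 1")
    if m_comparisons < len(p):
        raise ValueError("m_comparisons smaller than the number of tests")
    for x in p:
        if not (0.0 <= x <= 1.0):
            raise ValueError("p-values must lie in [0, 1]")
    return [min(1.0, x * m_comparisons) for x in p]


def welch_t_one_tailed(
    a: Sequence[float], b: Sequence[float], direction: str = "a<b"
) -> tuple[float, float, float]:
    """One-tailed Welch's t-test (unequal variances).

    ``direction`` states the alternative: "a<b" or "a>b".  Returns
    (t, Welch-Satterthwaite df, one-tailed p).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("Welch's t-test needs >= 2 observations per group")
    if direction not in ("a<b", "a>b"):
        raise ValueError("direction must be 'a<b' or 'a>b'")
    alternative = "less" if direction == "a<b" else "greater"
    res = _st.ttest_ind(a, b, equal_var=False, alternative=alternative)
    return float(res.statistic), float(res.df), float(res.pvalue)


def relative_expression(
    ct_target_reps: Sequence[float],
    ct_ref_reps: Sequence[float],
    calibrator_delta_ct: float,
) -> float:
    """Fold change by the 2^-ddCt method.

    dCt = mean(target Ct) - mean(reference Ct); the fold change relative to
    the calibrator sample is 2^-(dCt - calibrator dCt).
    """
    if len(ct_target_reps) == 0 or len(ct_ref_reps) == 0:
        raise ValueError("need at least one Ct replicate per gene")
    delta_ct = float(np.mean(ct_target_reps)) - float(np.mean(ct_ref_reps))
    return float(2.0 ** -(delta_ct - calibrator_delta_ct))


def stage_summary(
    values_by_group: Mapping[str, Sequence[float]],
) -> tuple[pd.DataFrame, list[GroupComparison]]:
    """Per-group mean and n plus all pairwise Mann-Whitney comparisons,
    Bonferroni-adjusted over the number of pairs actually tested.

    Group order is preserved as given (e.g. nevi -> primary -> metastasis).
    """
    groups = list(values_by_group)
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = {}
    for g in groups:
        v = np.asarray(values_by_group[g], dtype=float)
        v = v[~np.isnan(v)]
        if v.size == 0:
            raise ValueError(f"group {g!r} has no observations")
        arrays[g] = v
    summary = pd.DataFrame(
        {
            "group": groups,
            "n": [arrays[g].size for g in groups],
            "mean": [float(arrays[g].mean()) for g in groups],
        }
    ).set_index("group")

    pairs = list(itertools.combinations(groups, 2))
    raw = []
    stats = []
    for ga, gb in pairs:
        u, p = mann_whitney_u(arrays[ga], arrays[gb])
        raw.append(p)
        stats.append(u)
    adjusted = bonferroni(raw, len(pairs))
    comparisons = [
        GroupComparison(
            group_a=ga,
            group_b=gb,
            test="mann-whitney-u",
            tail="two-sided",
            statistic=stats[i],
            p_raw=raw[i],
            p_adjusted=adjusted[i],
            mean_a=float(arrays[ga].mean()),
            mean_b=float(arrays[gb].mean()),
            n_a=arrays[ga].size,
            n_b=arrays[gb].size,
        )
        for i, (ga, gb) in enumerate(pairs)
    ]
    return summary, comparisons
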