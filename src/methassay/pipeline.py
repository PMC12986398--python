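"""End-to-end orchestration: screen -> design -> interpret -> report.

`run_pipeline` runs the statistics screening on a beta-value cohort, detects
the promoter CpG island, designs bisulfite-PCR assays, derives the CoBRA and
pyrosequencing layers for the top design, and writes one machine-readable
JSON report (schema-validated, byte-identical across runs with the same
seed) plus a human-readable summary.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as _io
from . import report as _report
from .cobra import DEFAULT_CALL_THRESHOLD, DEFAULT_ENZYMES, build_cobra_assay, call_and_summarize
from .methstats import MethylationMatrix, cgi_mean_per_sample, stage_summary
from .primer_design import DesignConstraints, design_assay
from .pyro import DEFAULT_QC_THRESHOLD_PCT, build_dispensation, quantify, simulate_pyrogram
from .seqcore import GenomicLocus, bisulfite_convert, find_cpg_islands
from .synthfix import CohortSpec, LocusSpec, make_cobra_calls, make_cohort, make_locus

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; `stage` names it."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Inputs and knobs for one pipeline run.

    File paths are optional: anything missing is generated by the seeded
    synthetic-fixture layer, so the bundled configuration runs end to end
    with zero downloads.
    """

    locus_fasta: str | None = None
    locus_bed: str | None = None
    beta_tsv: str | None = None
    sample_tsv: str | None = None
    probe_tsv: str | None = None
    constraints: DesignConstraints = field(default_factory=DesignConstraints)
    cobra_threshold: float = DEFAULT_CALL_THRESHOLD
    qc_threshold_pct: float = DEFAULT_QC_THRESHOLD_PCT
    seed: int = 0
    outdir: str = "methassay_out"
    max_designs_reported: int = 5

    def validate(self) -> None:
        for name in ("locus_fasta", "locus_bed", "beta_tsv", "sample_tsv", "probe_tsv"):
            p = getattr(self, name)
            if p is not None and not os.path.exists(p):
                raise FileNotFoundError(f"{name}: no such file: {p}")


def _primer_dict(p) -> dict:
    return {
        "sequence": p.sequence,
        "start": p.start,
        "end": p.end,
        "strand": p.strand,
        "tm": round(p.tm, 3),
        "gc_fraction": round(p.gc_fraction, 4),
        "n_internal_cpg": p.n_internal_cpg,
        "gc_clamp": p.gc_clamp,
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full workflow and write ``report.json`` / ``report.txt`` into
    ``config.outdir``.  Returns the report dict."""
    try:
        config.validate()
    except FileNotFoundError as e:
        raise PipelineError("config", str(e)) from e
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config.seed

    # --- inputs (load or simulate) -------------------------------------
    try:
        if config.locus_fasta is not None:
            locus = _io.read_locus(config.locus_fasta, config.locus_bed)
        else:
            locus = make_locus(LocusSpec(seed=seed))
        if config.beta_tsv is not None:
            matrix = MethylationMatrix.from_tsv(
                config.beta_tsv, config.sample_tsv, config.probe_tsv
            )
        else:
            matrix = make_cohort(CohortSpec(seed=seed))
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError("inputs", str(e)) from e

    # --- screening statistics ------------------------------------------
    try:
        means = cgi_mean_per_sample(matrix)
        by_group = {
            g: means[matrix.groups == g].to_numpy()
            for g in matrix.groups.unique()
        }
        summary, comparisons = stage_summary(by_group)
    except Exception as e:
        raise PipelineError("screening", str(e)) from e

    # --- island detection + assay design -------------------------------
    try:
        islands = find_cpg_islands(locus.sequence)
        result = design_assay(locus, islands, config.constraints)
        if not result.designs:
            raise ValueError(
                f"no feasible assay design; rejections: {dict(result.rejections)}"
            )
    except Exception as e:
        raise PipelineError("design", str(e)) from e
    top = result.designs[0]

    # --- CoBRA layer ----------------------------------------------------
    try:
        amplicon = locus.sequence[top.amplicon_start : top.amplicon_end]
        best_enzyme = max(
            DEFAULT_ENZYMES,
            key=lambda e: len(top.informative_sites.get(e.name, [])),
        )
        assay = build_cobra_assay(
            amplicon, best_enzyme, amplicon_start=top.amplicon_start
        )
        cobra_calls = make_cobra_calls(threshold=config.cobra_threshold, seed=seed)
        cobra_freq = call_and_summarize(cobra_calls)
    except Exception as e:
        raise PipelineError("cobra", str(e)) from e

    # --- pyrosequencing layer -------------------------------------------
    try:
        pw_start, pw_end = top.pyro_window
        pyro_region = locus.sequence[pw_start:pw_end]
        target = bisulfite_convert(pyro_region, source=f"{locus.name}:{pw_start}-{pw_end}/+")
        disp = build_dispensation(target)
        rng = np.random.default_rng(seed)
        m_truth = {off: float(m) for off, m in zip(
            (off for _, _, off in disp.cpg_pairs),
            rng.uniform(0, 1, size=len(disp.cpg_pairs)),
        )}
        pyrogram = simulate_pyrogram(disp, m_truth, noise_cv=0.05, seed=seed)
        quant = quantify(pyrogram, config.qc_threshold_pct)
    except Exception as e:
        raise PipelineError("pyro", str(e)) from e

    # --- report ---------------------------------------------------------
    report = {
        "schema_version": _report.SCHEMA_VERSION,
        "seed": seed,
        "locus": {
            "name": locus.name,
            "length": len(locus),
            "tss": locus.tss,
            "n_cpg": len(locus.cpg_positions),
        },
        "islands": [
            {
                "start": isl.start,
                "end": isl.end,
                "gc_fraction": round(isl.gc_fraction, 4),
                "obs_exp_cpg": round(isl.obs_exp_cpg, 4),
                "n_cpg": isl.n_cpg,
            }
            for isl in islands
        ],
        "screening": {
            "group_means": {
                g: round(float(summary.loc[g, "mean"]), 6) for g in summary.index
            },
            "comparisons": [
                {
                    "groups": [c.group_a, c.group_b],
                    "U": c.statistic,
                    "p_raw": c.p_raw,
                    "p_adjusted": c.p_adjusted,
                    "stars": c.stars,
                }
                for c in comparisons
            ],
        },
        "designs": [
            {
                "rank": i + 1,
                "score": round(d.score, 4),
                "nesting": d.nesting,
                "amplicon_start": d.amplicon_start,
                "amplicon_end": d.amplicon_end,
                "amplicon_length": d.amplicon_length,
                "outer_start": d.outer_start,
                "outer_end": d.outer_end,
                "inner_forward": _primer_dict(d.inner_pair[0]),
                "inner_reverse": _primer_dict(d.inner_pair[1]),
                "outer_forward": _primer_dict(d.outer_pair[0]),
                "outer_reverse": _primer_dict(d.outer_pair[1]),
                "n_cpgs_covered": len(d.cpgs_covered),
                "n_informative_sites": d.n_informative_sites,
                "pyro_window": list(d.pyro_window),
                "pyro_cpg_count": d.pyro_cpg_count,
            }
            for i, d in enumerate(result.designs[: config.max_designs_reported])
        ],
        "cobra": {
            "enzyme": assay.enzyme.name,
            "informative_sites": [
                {"offset": off, "covered_cpgs": cov}
                for off, cov in assay.informative_sites
            ],
            "fragments_methylated": assay.fragments_methylated,
            "fragments_unmethylated": assay.fragments_unmethylated,
            "group_frequencies_pct": {
                g: round(v["frequency_pct"], 2) for g, v in cobra_freq.items()
            },
        },
        "pyro": {
            "n_cpg_pairs": len(disp.cpg_pairs),
            "region_mean_pct": round(quant.region_mean, 3),
            "per_cpg_pct": {str(k): round(v, 3) for k, v in quant.per_cpg.items()},
            "qc_pass": bool(quant.qc_pass),
            "background_pct": round(quant.background_pct, 3),
        },
    }
    _report.dump_report(report, outdir / "report.json")
    _write_text_report(report, outdir / "report.txt")
    return report


def _write_text_report(report: dict, path) -> None:
    lines = [
        "methassay pipeline report",
        "=" * 60,
        f"locus {report['locus']['name']}: {report['locus']['length']} bp, "
        f"TSS at {report['locus']['tss']}, {report['locus']['n_cpg']} CpGs",
        "",
        "CpG islands (0-based half-open; report coordinates 1-based inclusive):",
    ]
    for isl in report["islands"]:
        lines.append(
            f"  {isl['start'] + 1}-{isl['end']}  GC={isl['gc_fraction']:.2f}  "
            f"obs/exp={isl['obs_exp_cpg']:.2f}  CpGs={isl['n_cpg']}"
        )
    lines += ["", "Screening (mean CGI methylation per group):"]
    for g, m in report["screening"]["group_means"].items():
        lines.append(f"  {g:<24s} {100 * m:5.1f}%")
    for c in report["screening"]["comparisons"]:
        lines.append(
            f"  {c['groups'][0]} vs {c['groups'][1]}: U={c['U']:.1f} "
            f"p_adj={c['p_adjusted']:.3g} {c['stars']}"
        )
    lines += ["", f"Assay designs (top {len(report['designs'])}):"]
    for d in report["designs"]:
        f, r = d["inner_forward"], d["inner_reverse"]
        lines.append(
            f"  #{d['rank']} score={d['score']:.2f} {d['nesting']} "
            f"product={d['amplicon_length']} bp "
            f"[{d['amplicon_start'] + 1}-{d['amplicon_end']}] "
            f"Tm {f['tm']:.1f}/{r['tm']:.1f} degC, "
            f"{d['n_cpgs_covered']} CpGs, {d['n_informative_sites']} CoBRA sites"
        )
    cb = report["cobra"]
    lines += [
        "",
        f"CoBRA ({cb['enzyme']}): {len(cb['informative_sites'])} informative sites",
        f"  methylated fragments:   {cb['fragments_methylated']}",
        f"  unmethylated fragments: {cb['fragments_unmethylated']}",
        "  hypermethylation frequency by stage:",
    ]
    for g, f_ in cb["group_frequencies_pct"].items():
        lines.append(f"    {g:<16s} {f_:5.1f}%")
    py = report["pyro"]
    lines += [
        "",
        f"Pyrosequencing: {py['n_cpg_pairs']} CpGs quantified, "
        f"region mean {py['region_mean_pct']:.1f}%, "
        f"QC {'pass' if py['qc_pass'] else 'FAIL'} "
        f"(background {py['background_pct']:.2f}%)",
        "",
    ]
    Path(path).write_text("\n".join(lines))
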