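# methassay

Design and interpretation of bisulfite-based promoter methylation assays,
with the cohort statistics used to call a gene hypermethylated and silenced.

## The problem

Tumor suppressor genes are frequently inactivated in cancer not by mutation
but by DNA hypermethylation of the CpG island (CGI) at their promoter.
Validating a candidate — showing that its promoter CGI gains methylation
with tumor progression while expression falls — requires bisulfite-based
wet-lab assays: bisulfite PCR of the converted promoter region, combined
bisulfite restriction analysis (CoBRA) for a fast qualitative readout, and
pyrosequencing for per-CpG quantification, followed by group statistics on
array beta values and RT-PCR expression data.

Designing those assays by hand is fiddly: bisulfite conversion (unmethylated
C → T, 5-methyl-C retained) makes the two strands non-complementary and
drains the sequence of cytosines, primers must avoid CpGs so amplification
is methylation-independent, and the amplicon must simultaneously sit near
the transcription start site (TSS), inside the CGI, contain
methylation-informative restriction sites, and offer a CpG-rich
pyrosequencing window.  `methassay` automates the whole workflow for
wet-lab groups, with seeded synthetic fixtures so every stage can be
exercised and tested without downloading any data.

## What it computes

* **CpG islands** — sliding-window detection with the classical criteria
  (length ≥ 200 bp, GC ≥ 0.50, observed/expected CpG ≥ 0.6, where
  obs/exp = N·n(CG) / (n(C)·n(G))).
* **Bisulfite-PCR assays** — nested or semi-nested primer pairs on the
  converted strand satisfying the standard guidelines: product 120–350 bp,
  per-primer nearest-neighbor Tm 53–62 °C with similar pair temperatures,
  amplicon within ±400 bp of the TSS and overlapping the CGI, minimal
  internal CpGs, ranked by CpG coverage, CoBRA sites and the best
  pyrosequencing window.
* **CoBRA** — restriction sites (TaqI 5′-TCGA-3′, Bsh1236I 5′-CGCG-3′)
  present only in the methylated-converted amplicon, the expected fragment
  ladders, and per-stage hypermethylation frequencies.
* **Pyrosequencing** — dispensation orders with C/T pairs at each CpG and
  conversion-control dispensations; per-CpG methylation as
  100·h_C/(h_C+h_T); conversion QC.
* **Statistics** — mean CGI methylation (beta values) per sample,
  two-sided Mann–Whitney U with Bonferroni adjustment for group contrasts,
  one-tailed Welch t for pyro/RT-PCR contrasts, and 2^−ΔΔCt relative
  expression.

## Worked example

```python
from methassay import DesignConstraints, design_assay, find_cpg_islands
from methassay.synthfix import LocusSpec, make_locus

locus = make_locus(LocusSpec(seed=42))          # 3 kb promoter, CGI + TSS
islands = find_cpg_islands(locus.sequence)
result = design_assay(locus, islands, DesignConstraints(nesting="semi_nested"))
d = result.designs[0]
print(d.amplicon_length, round(d.inner_pair[0].tm, 1), len(d.cpgs_covered))
```

Running `python examples/01_design_bisulfite_assay.py` prints:

```
locus: 3000 bp, TSS at 1500, 94 CpGs
island: [1094, 1952)  GC=0.59 obs/exp=1.28  94 CpGs

7253 feasible designs; top 3:
#1 score=82.0 product=318 bp [1299-1617] Tm=55.1/54.6 degC 50 CpGs covered, 11 informative sites
   fwd 5'-GTGTTGTTGTATAGGAGAG-3'
   rev 5'-ATCCAATCACAAACCTAC-3'
...
```

i.e. the top-ranked semi-nested assay amplifies a 318-bp product inside the
island around the TSS, both primers melt near 55 °C, 50 CpGs fall in the
amplicon and 11 restriction sites report methylation after digestion.  The
other examples continue the workflow: `02_cobra_digest.py` (fragment
ladders and stage frequencies), `03_pyrosequencing.py` (simulated pyrogram,
per-CpG recovery, conversion QC) and `04_cohort_statistics.py` (stage
means such as nevi 12.2 % → primary 41.4 %, with nevi-vs-primary
significant at p_adj ≈ 1.2 × 10⁻⁴ after Bonferroni).

A thin CLI mirrors the workflow
(`methassay simulate | islands | convert | design | cobra | pyro-sim |
pyro-quant | stats | run`); `methassay run --seed 1 --outdir out` executes
the whole screen → design → interpret → report pipeline and writes a
schema-validated, byte-reproducible `report.json`.

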