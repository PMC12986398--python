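"""CoBRA: methylation-informative restriction sites and fragment ladders.

After bisulfite conversion, a TaqI (TCGA) or Bsh1236I (CGCG) site survives
only where its CpGs were methylated, so digestion of the PCR product reports
methylation on a gel.  This example finds the informative sites in the
top-ranked assay's amplicon, predicts both fragment ladders, and summarizes
a simulated stage-labelled digestion cohort.
"""

from methassay import design_assay, find_cpg_islands
from methassay.cobra import DEFAULT_ENZYMES, build_cobra_assay, call_and_summarize, virtual_gel
from methassay.synthfix import LocusSpec, make_cobra_calls, make_locus

locus = make_locus(LocusSpec(seed=42))
design = design_assay(locus, find_cpg_islands(locus.sequence)).designs[0]
amplicon = locus.sequence[design.amplicon_start : design.amplicon_end]

enzyme = max(DEFAULT_ENZYMES, key=lambda e: len(design.informative_sites[e.name]))
assay = build_cobra_assay(amplicon, enzyme)
print(f"amplicon {len(amplicon)} bp, enzyme {enzyme.name} ({enzyme.recognition})")
for off, covered in assay.informative_sites:
    print(f"  informative site at {off}, reports CpGs {covered}")
print(f"methylated ladder:   {assay.fragments_methylated}")
print(f"unmethylated ladder: {assay.fragments_unmethylated}")
print(virtual_gel({"methylated": assay.fragments_methylated,
                   "unmethylated": assay.fragments_unmethylated}))

# A digestion cohort: per-stage fraction of samples called hypermethylated
# (digested fraction >= 0.25).  Frequencies rise with tumor progression.
summary = call_and_summarize(make_cobra_calls(seed=0))
for group, row in summary.items():
    print(f"{group:<12s} {row['n_hypermethylated']:>2d}/{row['n']:<2d} "
          f"hypermethylated = {row['frequency_pct']:.0f}%")
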