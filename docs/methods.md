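# Methods

This note documents the models, algorithms, defaults and design choices
behind `methassay`, and what the synthetic fixtures do and do not emulate.

## Coordinates, alphabet, strand

All coordinates are 0-based half-open internally; rendered reports use
1-based inclusive coordinates (genome-browser convention).  Input sequence
is upper-cased; ambiguity codes are accepted by `reverse_complement` but
rejected on every design path.  Only CpG-context methylation is modelled
(no CHG/CHH).  Bisulfite conversion operates on the strand given; because
converted strands are not complementary, an assay against the minus strand
must be designed on the converted reverse complement explicitly.

## CpG-island detection

A window of 200 bp slides in 1-bp steps; a window passes when GC ≥ 0.50 and
observed/expected CpG ≥ 0.6, with obs/exp = n(CG)·N / (n(C)·n(G)) and 0
when either base count is 0.  Overlapping passing windows are merged, and
within each merged region the longest sub-interval of length ≥ 200 that
itself passes both thresholds is reported (leftmost on ties) — a
deterministic refinement of the classical merge-and-trim step.  These are
the classical criteria for promoter islands; array annotations follow
various definitions, so all four parameters are configurable.  Counting is
incremental (prefix sums); the test suite checks equality with a naive
all-windows rescan on every sequence it uses.  Genome-scale scanning and
repeat masking are out of scope.

## Bisulfite conversion

`bisulfite_convert` maps every C to T except a CpG C marked methylated, in
one of three modes (`all_unmethylated`, `all_methylated`, per-CpG
`pattern`).  The returned object keeps the original region and an explicit
(identity) coordinate map so downstream assays can recover CpG and
conversion-control positions.  Invariants enforced by tests: conversion
preserves length, the all-unmethylated strand is C-free, and converted C
positions equal exactly the methylated CpG set.

## Melting temperature

Unified nearest-neighbor enthalpies/entropies (the standard unified
parameter set, as implemented in Biopython's `Tm_NN` with table `DNA_NN3`)
with terminal initiation penalties.  Salt enters through a
monovalent-equivalent correction, Na_eq = monovalent + 120·√[Mg²⁺] (mM),
applied as the entropic correction 0.368·(N−1)·ln[Na_eq]; melting is
computed at the excess-primer limit with 250 nM oligo.  Defaults
(50 mM monovalent, 1.5 mM Mg²⁺, 250 nM primer) mirror a standard Taq
buffer.  The suite pins the implementation to an independent hand-summed
table in the tests.

## Assay design

Primers are enumerated on the fully converted (all-unmethylated) top strand
so the PCR is methylation-independent.  Per-primer hard filters: length
18–27 nt, Tm 53–62 °C, at most 1 template CpG overlapped (degenerate bases
are never emitted), no mononucleotide run > 4, and the 3′-terminal base may
not sit on a methylation-variable template position.  Pair/assay hard
constraints: inner product 120–350 bp, pair ΔTm ≤ 5 °C, the inner amplicon
entirely within TSS ± 400 bp *and* overlapping the CGI by ≥ 50 % of its
length (the chosen reading of "within the CGI ± 400 bp of the TSS", which
could also be read as bounding the primers or the analyzed CpG stretch),
and ≥ 1 methylation-informative restriction site.  The outer round of the
nested/semi-nested PCR reuses the same candidate set with an outer product
cap of 600 bp — chosen for compatibility with degraded clinical templates,
on which bisulfite PCR tolerates moderate fragmentation; the outer pair is
picked deterministically, preferring the tightest primers around the inner
amplicon, and in semi-nested mode exactly one inner primer is reused.

Soft score = 1.0·(CpGs in amplicon) + 2.0·(informative sites) +
0.5·(CpGs in the best ≤ 120-nt pyrosequencing window between the primers) +
0.5·(GC-clamp flags: ≥ 1 G/C among the two 3′ bases, a preference rather
than a filter) − 1.0·|ΔTm| − 1.0·(primer-internal CpGs).  Weights live in
`ScoreWeights`; informative sites are weighted highest because CoBRA
usability is binary in practice.  Ties break toward more CpGs covered,
shorter product, leftmost start, making the ranking fully deterministic;
tightening any constraint can only shrink the design set.  Primer-dimer and
secondary-structure thermodynamics, multiplexing and methylation-specific
(MSP) primers are out of scope — the designs are methylation-independent
bisulfite-PCR primers.

## CoBRA

A site is methylation-informative when it occurs in the all-methylated
conversion but not in the all-unmethylated conversion (which is C-free, so
TaqI TCGA and Bsh1236I CGCG can never survive there).  Sites are searched
on the converted top strand only — the converted sequence defines both
strands of the PCR product; overlapping sites are all reported and
digestion is assumed complete.  Cut offsets follow the standard enzyme
definitions (T^CGA, CG^CG).  Fragment ladders are consecutive differences
of the cut positions and always sum to the amplicon length.  Per-sample
gel calls use a digested-fraction threshold, default 0.25: published gel
calls are visual and no numeric criterion exists, so the threshold is an
explicit, configurable stand-in.  Densitometry and partial-digestion
kinetics are not modelled.

## Pyrosequencing

The dispensation order follows the converted target downstream of the
sequencing primer: homopolymer runs are compressed into single
dispensations (peak ∝ run length), each CpG gets a C-then-T pair, and up to
2 evenly spaced non-CpG cytosines receive a C control dispensation followed
by their T.  The peak model is linear and single-template: every template
position is statically assigned to one dispensation; there is no
de-phasing, no dark nucleotides, and a template T run immediately after a
CpG keeps its own dispensation rather than merging into the CpG's T peak.
This keeps the estimator 100·h_C/(h_C+h_T) exact in the noise-free limit,
at the cost of not reproducing instrument-level artifacts.  Simulated
noise is multiplicative Gaussian per peak (coefficient of variation
`noise_cv`, clipped at 0); incomplete conversion puts a fraction r of
signal on the control C and 1−r on its T, so the background estimate
100·c/(c+t) recovers 100·r.  QC fails above 5 % background by default.
Estimates are scale-invariant; zero-signal CpGs are flagged and excluded
from the region mean, which is the arithmetic mean of the remaining CpGs.

## Statistics

Group contrasts of beta values use the two-sided Mann–Whitney U test —
exact by enumeration when the smaller group has ≤ 8 observations and the
data are tie-free, otherwise the normal approximation with tie and
continuity corrections — with Bonferroni adjustment min(1, p·m) over the m
pairwise comparisons actually performed.  Pyrosequencing and RT-PCR
contrasts use the one-tailed Welch t-test with Welch–Satterthwaite degrees
of freedom.  This split (rank test + Bonferroni for array data, one-tailed
Welch for the wet-lab readouts) mirrors common practice for these two data
types.  Relative expression is 2^−ΔΔCt with ΔCt = mean Ct(target) − mean
Ct(reference) against a calibrator ΔCt.  Missing beta values are excluded
pairwise, never imputed.  Significance renders as * < 0.05, ** < 0.01,
*** < 0.001.  Survival analysis and array preprocessing/normalization are
out of scope.  When one beta matrix pools several datasets, the group
contrasts treat it as a single pooled cohort.

## Synthetic fixtures (what they emulate, and what not)

`make_locus` plants a CpG island in a CpG-depleted 40 %-GC background:
CG dinucleotides are interleaved into a GC-rich filler until the target
density (default 0.08/bp, about one CpG per 12 bp as in real promoter
islands) is reached, the filler GC solved so the island averages 65 % GC,
and the draw is rejected and retried (bounded) unless the planted island
passes detection at the default thresholds with the TSS inside it.  Specs
that cannot satisfy the thresholds (island GC < 0.5, infeasible density)
are refused up front.

`make_cohort` draws per-sample latent CGI methylation from a
mean/concentration-parameterized Beta distribution (concentration 20 —
only group means are published, so the spread is a modelling choice giving
realistic overlap between stages) and per-probe values around the latent
level (concentration 50), plus low-methylation flank probes.  Default
group means follow the published tumor-progression pattern (nevi 0.15,
primary 0.44, skin metastases 0.45, lymph-node metastases 0.62, brain
metastases 0.49) with the published per-stage sample sizes (7/21/6/2/6);
these are simulation parameters, not reproduced data.  `make_cobra_calls`
assigns round(n·f) samples per stage a digested fraction above the call
threshold (stage frequencies 0.23/0.68/0.82/1.00 by default, group sizes
13/22/11/5 chosen to make the rounded frequencies match the published
percentages).  `make_pyro_set` batches seeded pyrograms with a recorded
truth table.

All generators are pure functions of (spec, seed).  None of them emulate
450k probe chemistry, batch effects, inter-dataset heterogeneity or real
TCGA distributions — so passing tests demonstrate correctness of the
algorithms and estimators under the stated generative model, not
performance on real arrays or instruments.

## Problem sizes and determinism

The default synthetic locus is 3 kb with a 600-bp island; designs are
enumerated over the TSS ± (400 + 600) bp region, which typically yields
10³–10⁵ feasible pairs ranked in one to a few seconds.  Oracle-equivalence
tests run 100 seeded instances per operation on 150–900-bp sequences;
recovery simulations use 100 seeded pyrograms and cohorts of 200 samples
per group.  Every stochastic component takes an explicit seed
(numpy `default_rng`); the pipeline report is byte-identical across runs
with the same seed, and sub-seeds are derived from the master seed so a
single integer reproduces an entire run.

## Known limitations

No primer thermodynamic interactions (dimers, hairpins); single-template
linear pyrogram model; complete-digestion assumption in CoBRA; pooled-only
handling of multi-dataset beta matrices; the CoBRA call threshold is a
proxy for a visual gel criterion; CGI detection parameters are a declared
default rather than a reproduction of any array vendor's annotation.
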