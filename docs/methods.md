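# Methods

## The question the pipeline answers

Inversions in bacterial chromosomes frequently flip the transcriptional
orientation of genes. An orientation change can put a gene "head-on" to the
replication fork — a configuration associated with elevated mutation rate —
but it can also disrupt operons and regulation, so the genes that retain a
changed orientation may simply be those under relaxed selection. The
pipeline separates these explanations by comparing substitution rates
between changed-orientation genes (COGs) and same-orientation genes (SOGs)
while holding confounders fixed. The diagnostic logic: if the rate increase
in COGs is mutation-driven, dS (and dN) rise together and dN/dS is
unchanged; if it is selection-driven, dN/dS differs between the groups.

## Data model and conventions

* Coordinates are 1-based closed intervals (the GenBank convention);
  chromosomes are circular and genes may wrap the coordinate origin, in
  which case spans and midpoints are computed modulo the length.
* A gene's position for all geometry is its circular midpoint. The choice
  is symmetric in the gene's ends and stable under inversion.
* Coding sequences in the data model exclude the terminal stop codon; the
  GenBank parser strips it. Every retained gene satisfies the invariant
  that its CDS translates exactly to its protein under the bacterial code
  (table 11) with no internal stops; violating CDSs are skipped and
  counted, never silently repaired.
* Ori and Ter are required configuration inputs per genome. A cumulative
  GC-skew locator is provided as a convenience (minimum of the cumulative
  (G−C)/(G+C) curve ≈ Ori, maximum ≈ Ter, resolution one window) but is
  never substituted silently; it flags flat curves as unreliable.
* Replichore 1 is the arc from Ori in increasing coordinates to Ter, with
  positions exactly at Ori or Ter assigned to replichore 1 (a documented
  tie-break affecting at most a couple of genes). On replichore 1 the fork
  moves with increasing coordinates, so a `+`-strand gene is co-oriented
  and a `-`-strand gene is head-on; replichore 2 mirrors this.
* Orientation conservation is called on raw annotated strands in each
  genome's deposited frame. For largely collinear genomes this matches a
  dot-plot-based call; a per-genome `flip` switch is exposed for genomes
  deposited in the reverse frame, but the pipeline never guesses.

## Orthology

One-to-one orthologs are reciprocal best BLASTP hits. "Best" means maximal
bit score, with ties broken by minimal E-value and then lexicographic
subject id, making runs reproducible; multiple HSPs per pair collapse to
the best row by the same ordering. Both directions must pass strict
thresholds: E-value < 1e-5 and amino-acid identity > 50%. Three-genome
groups are closed triangles of the pairwise graph. Groups with any member
CDS shorter than 420 bp (140 codons) are dropped as a whole — the
terminal/middle analysis needs 50+20 terminal codons plus a 70-codon
middle in every member, and dropping per-group keeps the gene sets of all
comparisons aligned. The pipeline consumes hit tables (outfmt 6) rather
than invoking an aligner, so it is testable offline; for real genomes any
BLASTP run producing 12-column tabular output works.

## Rate estimation

Protein pairs are aligned globally (BLOSUM62, affine gaps: open 10,
extend 0.5) with Biopython's PairwiseAligner; among co-optimal alignments
the aligner's canonical first traceback is used, which is deterministic.
Alignments are back-translated to codon alignments (protein gaps become
`---` codons) with per-position translation checks.

dN and dS are estimated by Nei–Gojobori (1986) counting:

* synonymous sites per codon = one third of the single-nucleotide
  neighbours that preserve the amino acid; changes to stop codons count as
  nonsynonymous, so each codon contributes exactly 3 sites;
* for codons differing at k positions, all k! single-step paths are
  enumerated, paths through stop codons are excluded (all paths are used
  in the rare case every ordering hits a stop), and synonymous /
  nonsynonymous step counts are averaged over paths;
* site counts are averaged over the two sequences; columns with a gap,
  ambiguity code or stop in either sequence are excluded entirely;
* pN = Nd/N and pS = Sd/S are Jukes–Cantor corrected,
  d = −(3/4)·ln(1 − (4/3)p), undefined (reported as saturated) at
  p ≥ 3/4; ω = dN/dS only when dS is defined and positive.

All 61×61 codon-pair counts are certified in the test suite against an
independent exact-fraction enumeration oracle. NG86 is a counting
estimator, not a maximum-likelihood codon model: on deeply diverged pairs
it underestimates rates relative to ML, but the pipeline's conclusions
rest on rank-based group comparisons, for which monotone agreement
suffices. An external ML estimate (e.g. a CODEML run) can be substituted
by feeding its per-gene dN/dS table into the comparison stage.

Gene pairs with undefined dS or dS ≥ 3 are removed before comparisons
(counted separately, since an excess of saturated COGs is itself a
finding). The terminal region of a gene is its first 50 plus last 20
codons, indexed on the ungapped codons of the first-named genome's
sequence; columns where that sequence has a gap fall to the middle region
(they are excluded from counting regardless). The Δ analysis compares the
terminal region against 70 codon columns sampled uniformly without
replacement from the middle, one seeded draw per gene; the per-gene seed
is the global seed XOR a CRC-32 of the gene id, so results are
independent of processing order. Genes whose middle region is shorter
than the sample are excluded and logged.

## Statistics

Group contrasts use the two-sided Wilcoxon rank-sum test (exact
enumeration when n+m ≤ 12 without ties, otherwise the normal
approximation with tie and continuity correction; two identical constant
samples give p = 1 by convention) and report medians. Partial Spearman
correlations rank-transform all three variables (the binary COG/SOG type
becomes mid-ranks) and apply the first-order partial-correlation formula
with a t test on n−3 degrees of freedom. Expression tables are
quantile-normalized (columns replaced by rank-wise means of the sorted
columns, ties sharing the mean of their reference slots — the classic
limma behaviour, verified against it in the tests) and standardized to
median 0, variance 1 (n−1 denominator). The "highly expressed" stratum is
the top 20% per growth phase, boundary ties included; phases are never
pooled. Raw p-values are reported with stars at 0.05 / 0.01 / 0.0001; an
optional Benjamini–Hochberg flag exists but is off by default, matching
the reporting convention of the analysis the pipeline reproduces.

## The simulator

The generator emulates the study conditions so that every stage can be
scored against ground truth:

* a circular chromosome (default 500 kb) with non-overlapping genes
  (default 200, uniform 140–300 codons — at the 420-bp analysis floor and
  around the typical enterobacterial mean), codons uniform over the 61
  sense codons, random strands, Ori at 1 and Ter opposite;
* inversions (default 3 per lineage) symmetric about Ori or Ter with
  probability 0.8 — the dominant geometry of rearrangements between
  closely related bacteria — otherwise uniform arcs avoiding both
  landmarks; arcs never split genes; inverted genes have coordinates
  reflected and strand flipped (the strand-relative CDS is invariant);
  under these defaults roughly 5–30% of genes end up as COGs, bracketing
  the ~8% seen between real enterobacterial pairs;
* sequence divergence by a per-site proposal/acceptance scheme: proposals
  arrive at the gene's synonymous intensity
  μ × gradient(distance to Ter) × δ_headon^[head-on] × δ_CTO^[inverted];
  synonymous proposals are always accepted, nonsynonymous ones with
  probability ω_true (default 0.05, the empirical enterobacterial
  median), stop-creating ones never. μ defaults to 0.15 per branch
  (pairwise dS ≈ 0.30), a moderate divergence where counting estimators
  are well conditioned. The scheme is not a continuous-time codon model:
  it has no transition/transversion bias, no codon-usage bias and no
  indels, so passing tests demonstrate correctness of the estimators and
  statistics, not robustness to those real-data features;
* the Ter gradient is linear: multiplier `g` at Ter decaying to 1 at Ori;
* expression values are Gaussian on the log2 scale, two phases, optionally
  coupled to the realized rate multiplier through a Gaussian copula so a
  target Spearman correlation is matched;
* three-lineage mode evolves ancestor → outgroup (branch μ) and ancestor
  → ingroup stem → two terminals (stem inversions separate; stem sequence
  divergence folded into terminal branches of μ/2), giving the lineage
  classes conserved / stem-or-outgroup change / species-specific change.

Scenario constructors pin the three study conditions used for
verification: `null_config` (δ_CTO = 1: orientation change has no rate
effect), `cto_effect_config` (δ_CTO = 2, selection unchanged) and
`location_only_config` (Ter gradient 3, all other multipliers 1,
inversions Ter-symmetric so COGs cluster near Ter).

Everything is deterministic under the seed; replicate harnesses derive
per-replicate seeds from a NumPy seed sequence. Because the simulator
introduces no indels, the replicate harnesses feed the codon sequences
directly to the NG86 estimator (the alignment step would be an identity);
the full align → back-translate → estimate path is exercised separately.

## Verification scales

The test suite certifies: NG86 against the enumeration oracle (all 3 721
sense-codon pairs, exact); Wilcoxon against rank enumeration (all 2 026
tie-free splits with n+m ≤ 10, exact); type-I error of the COG-vs-SOG dS
test in null mode (200 genes × 200 replicates, 99% binomial band around
0.05); power and the mutation-driven signature with δ_CTO = 2 (100
replicates: dS significant in >90%, ω non-significant in ≥90%);
confounder attribution in location-only mode (500 genes: marginal type–dS
correlation positive, distance-controlled partial within 3 SE of zero);
orientation-call agreement with truth (100%) and conservation of
confrontation status under Ter-symmetric inversions (100% of inverted
genes); and the normalization identities to 1e-12. Problem sizes were
chosen so the full suite completes in a few minutes on one core.

## Known limitations

* NG86 with Jukes–Cantor correction saturates near p = 3/4; real
  enterobacterial pairs at median dS ≈ 1.5 lose a fraction of genes to
  saturation that an ML estimator would retain. Saturated genes are
  counted and reported, never silently dropped.
* Raw-strand orientation calls assume the deposited genome frames are
  consistent; the `flip` switch is manual.
* The simulator's rate gradient is linear in distance to Ter; real
  gradients need not be.
* Partial rank correlation is only approximately zero under conditional
  independence when both variables depend nonlinearly on the covariate
  and the binary type marks an extreme of it; in the location-only
  scenario this leaves a small negative residual (about -0.04 at n = 500),
  well inside the statistic's interpretive slack.
* Multi-replicon genomes: only the first replicon is analyzed (plasmids
  ignored with a warning).
* Whether the original analysis defined terminal regions on the first or
  second genome's sequence is unknowable from its description; the
  first-named genome is used and documented.
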