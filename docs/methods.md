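# Methods

This note documents the models behind `mirdiv`, the parameters that
matter, the numerical choices made where the design was genuinely open,
and what the synthetic-data tests do and do not demonstrate about real
data.

## Study design emulated

The pipeline is built around a three-species brain comparison: human and
chimpanzee as the ingroup pair whose expression divergence is measured,
rhesus macaque as the outgroup that polarises differences onto a lineage.
Small-RNA sequencing uses pooled RNA per species with two technical
replicates; mRNA expression comes from five individuals per species,
protein expression from four; target verification uses miRNA-mimic
transfection in two neuroblastoma cell lines against two independent
mock replicates.

## Synthetic-data generator

**Count model.** Read counts are negative binomial via a gamma–Poisson
mixture: per-miRNA relative abundances are log-normal (sd
`abundance_sigma`, default 1.0), the expected count is `depth · p_i`,
multiplied by `de_fold` in the up-species for implanted DE miRNA, and the
Poisson rate is gamma-perturbed with dispersion `nb_dispersion`.

The default dispersion is 1e-4 — nearly Poisson — because the generator
emulates *technical* replicates of pooled libraries, which are close to
Poisson; this is also the regime in which an exact conditional test on
the counts is calibrated.  Biological replication would need dispersion
two to three orders of magnitude larger, and Fisher's exact test would
then be anti-conservative; users studying that regime should raise
`nb_dispersion` and switch to a count model that estimates dispersion
(the `edger_filter` hook accepts such externally computed tables).

**Read placement.** Reads sit at 5′ offsets −3..+3 of the mature 5′
position, 84% at offset 0 (10% of those as a 21-mer sharing the 5′ end,
exercising the same-5′ summation rule), plus 5% decoy reads at offsets
±5, outside the quantification window.  The per-sample ground truth
records the implanted copies at the mature 5′ position, which the
quantifier must recover exactly.

**Lineage-weighted DE implants.** Each implanted DE miRNA is assigned an
up-species with probabilities proportional to species-tree branch
lengths, 1:1:4 for human:chimpanzee:macaque (roughly 6–7 Myr terminal
branches versus the ~25–30 Myr macaque lineage).  This is what gives the
synthetic data a phylogenetic signal: macaque-lineage changes outnumber
ingroup changes, so correlation-distance clustering recovers
((human, chimpanzee), macaque).  A uniform assignment would produce a
star phylogeny.

**Expression matrices.** Gene baselines are N(8, 2²) on the log2 scale;
true targets of a miRNA up in species A are shifted by −`target_effect`
in species A; Gaussian noise sd `noise_sd` (default 0.2; protein noise is
doubled to mimic the larger intra-species variance of proteomics).

**Transfection matrices.** Per cell line, the mimic-vs-mock log-ratio of
a true target is centred at −`target_effect`; the two mock-referenced
columns share the gene- and line-level signal and differ only by
mock-specific noise (sd 0.05), reproducing the high mock-to-mock
concordance of real negative-control replicates.

**SNP track.** SNP positions are uniform at density `snp_density`
(default 0.005/bp, giving ~250 SNPs per 50 kb window); a SNP classifies
as human-derived with probability `background_derived_fraction` (default
0.15) outside sweep windows and background + excess inside.  The
simulated region stands in for the genome: the track's own totals are the
"genome average" the scan compares against.

**Determinism.** One root seed; each stage draws from a child RNG derived
from `(seed, fixed stage offset)` via `numpy.random.SeedSequence`, so
outputs are byte-identical across runs and stages are independent.

**What the generator does not emulate.** Sequencing error, adapter
artefacts, hairpin thermodynamics, mapping ambiguity, batch effects,
biological replicate dispersion, and correlated miRNA families.  Passing
recovery tests therefore demonstrates the statistics are implemented
correctly and calibrated under their own assumptions — not that those
assumptions hold in any particular real data set.

## Statistical procedures and numerical choices

**Quantification.** "Within three nucleotides" is inclusive
(|offset| ≤ 3).  A copy-number tie for the reference sequence is broken
by the lexicographically smallest sequence.  Star-candidate separation is
the linear gap between the two intervals on the precursor (hairpin
geometry is out of scope).  On the minus strand a read's 5′ position is
the highest genomic coordinate it covers; all coordinates are 0-based
half-open.

**Quantile normalization** forces each column onto the per-rank mean of
the sorted columns; tied values receive the mean of the reference values
across their tied ranks.  With ties the column multisets are therefore
only approximately equal — the exact-equality property holds for
tie-free columns.

**Fisher DE test.** The published criteria name the test but not the
table; the only 2×2 consistent with testing one miRNA between two count
libraries contrasts the miRNA's normalized count against the remainder of
each library's normalized total (rounded to integers).  Fold changes add
a pseudocount of 0.5 to both sides.  The two-sided p follows the
"probability at most observed" convention.  Because the counts are
discrete, null p-values are conservative-to-uniform, never
anti-conservative — the calibration test checks exactly that
(ECDF ≤ diagonal + 0.03; one-sided KS against anti-conservatism).

**Lineage assignment.** A human–chimpanzee difference is assigned to the
human lineage when the human level is further from the macaque level than
the chimpanzee level is *and* the chimpanzee level lies on the macaque
side of the human level (the change then parsimoniously maps to the human
branch); mirrored for chimpanzee; otherwise unassigned.  This is the
minimal operational reading of outgroup polarisation, not a claim about
any particular published rule.

**UPGMA** is implemented directly so the tie-break is explicit (among
tied minimal distances, the pair containing the smallest original sample
index merges first); node heights are half the merge distance and
cluster distances are unweighted leaf averages.  Agreement with standard
average-linkage is asserted in the tests.

**Shift test.** The comparison of target-divergence distributions is the
unpaired two-sample rank-sum (Mann–Whitney) test, exact for small groups.
The procedure it implements is unambiguously an unpaired two-group
comparison of targets of human-high versus chimp-high miRNA, with genes
targeted by both groups excluded and an absolute-divergence filter of
0.5 (protein level: |pooled-SD effect size| > 1, strict).

**Association counting.** Opposite-direction evidence is decisive: a gene
with at least one opposite-direction miRNA pair counts as negatively
associated even if same-direction pairs exist.  A consequence worth
knowing: for genes targeted by several DE miRNA with random directions,
"at least one opposite" is more probable than "none opposite", so the
null expectation of percent-explained is slightly positive when
multi-targeting is common; at the default target density multi-targeted
genes are rare and the null averages near zero.  Printed percentages are
rounded half away from zero.

**Transfection FDR.** FDR at an inhibition cutoff is the fraction of
non-targets passing (inhibited beyond the cutoff in *both* cell lines)
divided by the fraction of predicted targets passing.  The published
wording is ambiguous about the denominator; the passing-fraction reading
makes the FDR a proper enrichment ratio and is the default, with the
expressed-fraction reading available by flag.  The cutoff scan runs from
0 to −2 in steps of 0.05, loosest cutoff first; an FDR threshold ≥ 1
short-circuits to a no-filter mode returning all expressed predictions.

**Selection scan.** Window tests are one-sided (the hypothesis is
derived-SNP *excess*); the genome totals include the window's own SNPs by
default (window versus genome average; with genome-scale totals the
difference is negligible, and exclusion is available by flag).  The
Bonferroni family is all windows tested across the scanned candidate set
(5 × 11 = 55 at the defaults); an empty window has p = 1.  The
permutation null draws candidate subsets without replacement and reports
`exceedances / n_permutations`, so 44 of 1000 is exactly 0.044 (the
(k+1)/(n+1) convention would bias small p-values upward and is not
used).

**Ortholog consensus.** Hits group into one locus at ≥ 50% reciprocal
overlap (locus identity across mapping methods is otherwise undefined);
a call needs ≥ 2 distinct supporting methods, and two qualifying loci
make the query ambiguous (no call).  Precursor–precursor alignment uses
match +1 / mismatch −1 / gap open −5 / gap extend −1; for the closely
related sequences this module sees, reasonable scoring schemes agree on
the projected mature to well under 0.1%, so the fixed scheme is a
reproducibility choice, not a tuning knob.

## Problem sizes used in the test suite

The suite exercises the pipeline at desk scale: 40–200 miRNA, 400–2000
genes, depths of 1e5–1e6 reads per sample, 150 kb SNP regions, and
permutation counts of 20–200 — large enough for the stated calibration
and recovery bounds to be meaningful, small enough to run the whole suite
in well under a minute.  Dataset-scale quantities (hundreds of expressed
miRNA from millions of reads) change none of the statistics, only their
run time.

## Known limitations

- The Fisher DE test's calibration is tied to near-Poisson replicates;
  biological-replicate designs need the NB hook.
- The lineage-assignment and human-specific classification rules are
  deliberately non-conservative (they classify every gene/miRNA with an
  outgroup measurement); they enrich for, rather than prove,
  lineage-specific change.
- Target predictions are consumed as given; no sequence-based target
  prediction is performed.
- The ortholog module consumes mapping hit tables; it does not run the
  mappers, so its calls are only as good as the supplied hits.
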