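# Methods

`editevol` studies how adenosine-to-inosine (A-to-I) RNA editing is
established, tuned, and selected across a group of related species.
Inosine is read as guanosine, so editing appears as A-to-G mismatches
between RNA reads and genomic DNA; the editing level of a site is the
fraction of reads carrying G, `G/(A+G)`.  This note records the models
and procedures each module implements, the defaults and why, what the
synthetic-data generator does and does not emulate, and the numerical
choices made where the design was genuinely open.

## Coordinate and sequence conventions

All coordinates are 0-based half-open internally; fixedStep wiggle
input (1-based) is converted at the I/O boundary.  Sequence-dependent
operations work on the transcribed (sense) strand in the RNA alphabet
(ACGU); minus-strand loci are reverse-complemented at read time and
editing is represented as an A→G substitution in sequence space.

## Site discovery and quantification

Variant calls require ≥ 2 supporting reads (base and mapping quality
filtering is assumed upstream of the pileup counts); sites in
bidirectionally transcribed regions are discarded because the mismatch
cannot be assigned to a strand.  Cross-species shared variants are
thresholded at the smallest editing-level cutoff at which the shared
set is at least 80% A-to-G — the signature that the set is dominated by
genuine A-to-I editing rather than SNPs or errors.  The default cutoff
grid is {1, 1.5, 2, 3, 5, 10, 15, 20}%.

The false-positive rate of a candidate set is estimated with an
ADAR-null sample: candidates (wild-type sites with more than two
altered reads and level ≥ 1.5%) that retain no A-to-G reads without the
enzyme are genuine outright; the rest are tested site-by-site with a
two-sided Fisher's exact test on the A/G counts, Benjamini–Hochberg
corrected at 0.05.  Two distinct alt-read thresholds (≥ 2 for calling,
> 2 for FDR candidacy) are deliberately kept as separate constants.

Editing levels are defined for sites with ≥ 20 reads (RNA-seq) or ≥ 50
reads (targeted mmPCR-seq).  mmPCR-seq measurements are kept only when
both biological replicates have ≥ 50 reads and agree within 10 points,
and then win over RNA-seq for the same site.  A site whose DNA base is
not A has editing level 0 by definition.  The representative level of a
site is its maximum across all samples — editing is often
tissue-restricted, so the maximum, not the mean, reflects a site's
capacity.

## cis-regulation: motif and dsRNA structure

ADAR's sequence preference is captured by the triplet around the edited
A.  The position weight matrix is built from triplets of highly edited
(≥ 50%) sites with an additive pseudocount (default 0.5); per-species
matrices are essentially identical, so the arithmetic mean matrix
(renormalised) is used for cross-species scoring.  Triplets are scored
by log-odds against a uniform background and affinely rescaled so the
16 possible N·A·N triplets span 0–10; a degenerate (zero-range) matrix
scores all triplets 0 with an explicit flag.  Only the ordering of
triplet scores matters downstream.

A cross-species site pair is Presence/Absence when the anchor species
is edited ≥ 10% in at least one dataset and the other species is
≤ 1.5% in every dataset with a measurement; Presence/Presence when both
reach 10%.  Among Presence/Absence pairs whose triplet scores differ,
an exact two-sided binomial test against 0.5 asks whether the species
with editing carries the better motif.

### Stem finding

ADAR requires a double-stranded substrate: the edited region pairs with
an editing-complementary sequence (ECS).  Proximal ECSs are sought
within 200 bp of the site; distal ECSs within 2,500 bp, restricted to
regions ≥ 20 bases long whose 51-bp-smoothed conservation is ≥ 0.90
(conserved structure betrays a distal duplex partner).

The stem finder is a complementarity alignment rather than a
thermodynamic folder: the site-containing segment (± 35 nt) is locally
aligned against the reverse complement of the window with Watson–Crick
matches (+3), GU wobble (+1.5), mismatches −10, and affine bulges
(open −12, extend −2).  Affine gaps matter: with cheap linear gaps,
chains of short accidental complementary runs outscore genuine
contiguous stems.  The search runs twice, once with the partner
restricted strictly downstream and once strictly upstream of each base,
which prevents an alignment path from crossing the hairpin centre and
pairing a stem with its own mirror image.  Up to four candidates are
returned per orientation by masking the ECS region of each accepted
alignment and realigning.  Hairpin loops shorter than 5 nt are
disallowed (`min_loop = 4`).

Candidates are split wherever either strand has an unpaired run longer
than the bulge limit, then filtered: ≥ 20 paired bases, maximum bulge
≤ 8, editing side covering the site (± 2 nt), and — when the sequence
is available — free energy ≤ −15 kcal/mol.  The energy gate stands in
for the selectivity of ensemble folding: random sequence produces
20-pair chains of short helices far more often than it produces stable
duplexes, and without the gate the false-positive rate on random 400-nt
windows roughly triples.

The interface is pluggable: any component producing a base-pair list
can replace the aligner, and any energy function over a pair list can
replace the evaluator.

### Free energy

Duplex energy is a nearest-neighbour model: an embedded Watson–Crick
stacking table (Turner-style values), GU-containing stacks assigned a
fixed modest stabilisation (−0.5 − 0.25·min partner strength), loop
interruptions penalised `3.0 + 1.1 ln(l)` kcal/mol for `l` unpaired
bases, and terminal AU/GU pairs penalised +0.5.  Every stack term is
≤ −0.1 by construction, so closing a stem with one more Watson–Crick
pair never raises the energy — a monotonicity the tests rely on.
Two-segment (distal) duplexes are treated as joined by a linker that
contributes no pairs, so only the stem itself is scored.  Absolute
energies are model-specific; only orderings and filter outcomes are
meaningful.

### The 8 structural features

free energy; stem length (editing-side span of the outermost pairs);
max bulge (longest unpaired run strictly inside the stem, per-side
maximum); percent of the stem paired; distance from the site to the
closest stem edge (nucleotides along the editing side); and the
number of paired bases in the whole stem and, separately, downstream
and upstream of the site.  Stem length and edge distance are measured
on the editing side; both conventions are recorded here because
alternatives exist.

## Random-forest models

Editing presence/absence (classification) and editing level
(regression) in a second species are modelled from the anchor-species
level, the motif-score change, and the 8 structural-feature changes
(other − anchor).  Forests are bagged decision trees with per-split
feature subsampling (`mtry = 3`; the reduced anchor-level-only model
uses `mtry = 1`), accuracy estimated out-of-bag.  Feature importance is
OOB permutation importance in the classic form: per tree, the
accuracy drop (or MSE increase) after permuting the feature on that
tree's out-of-bag samples, averaged over trees and divided by its
standard deviation.  Explained variance is `R² = 1 − MSE_oob /
Var(outcome)`.  The default forest size is 1,000 trees — OOB estimates
are stable well below 10,000 at these sample sizes — and is
configurable up to 10,000.  The full-vs-reduced ΔR² is reported with a
seed-resampling interval over 20 refits.

Presence/absence rows comprise anchor-present sites whose other-species
status is defined either way, requiring a filter-passing ECS in the
anchor species; level-regression rows are Presence/Presence sites with
a passing ECS in at least one species.  A species without a passing ECS
contributes the features of its best folded-but-failing candidate; if
no candidate covers the site at all, paired counts, stem length and
free energy default to 0 (a strict-exclusion mode is available).
Deltas plus the anchor level are the default predictors; raw per-species
values are an option.

## Evolutionary analyses

Editing-level divergence between species is `1 − ρ` where ρ is
Spearman's correlation over shared measured sites, computed as the
Pearson correlation of mid-ranks (many sites tie at level 0, so the tie
convention matters).  Divergence matrices feed Saitou–Nei neighbour
joining (negative branch lengths clamped to 0 with the deficit moved to
the adjacent branch) and an OLS regression of divergence against
species divergence time; under neutral level evolution the NJ tree
recapitulates the species phylogeny and divergence grows with time.

Dating uses parsimony: a site is edited in a species when its level is
≥ 2% in at least one dataset, unedited when every dataset has ≥ 20
reads and ≤ 1.5% (or the DNA base is not A), undefined otherwise —
absence cannot be asserted from thin coverage.  The age class of an
anchor site is the most distantly related species in which it is also
edited; sites with defined status in fewer than 5 species are not
dated.  Age classes are ordered categories derived from the supplied
species order; no species names are hard-coded.

A site is clustered when its nearest neighbouring site lies within 30
(or 40/50) bp; per-group clustered fractions carry a bootstrap
(1,000-resample) standard deviation.  Pairwise level differences use
`normalized_diff = |e1−e2| / mean(e1,e2)` and
`conservation = 1 − |e1−e2|/(e1+e2)`; the two are affinely related.

## Constraint classification

The S_region of a site spans 15 bp upstream to 30 bp downstream on the
transcribed strand (46 bases including the site; the asymmetry follows
the editing-stem geometry); the F_region is the 46 bases on each side,
pooled.  Sites with mean conservation > 0.9 in both regions are highly
constrained.  Remaining sites are moderately constrained when a
two-sample Kolmogorov–Smirnov test (asymptotic p; sample sizes of
46–92 make the asymptotic form adequate) finds the S_region
significantly more conserved after BH correction across the batch at
0.05.  Genic masks drop disallowed flanking bases (non-CDS flanks for
coding sites, CDS-overlapping flanks for 3'UTR sites).  The
window-profile operation slides 30-bp windows across ± 60 bp and the
normalised profile reports −D relative to the most conserved window.

Treating lowly edited (< 1.5%) sites as a neutral baseline, the excess
of the constrained fraction among edited over lowly edited sites
estimates the fraction of editing events that are likely functional,
with a two-sided Fisher's exact test on the 2×2 counts.

## 3'UTR function

Expression changes (catalytically dead ADAR mutant vs wild type) are
compared between 3'UTR-edited gene groups and control genes (edited
only in CDS/5'UTR) by two-sided Mann–Whitney U; grouping uses sites
with wild-type level > 5% and ≥ 20 reads.  Nascent-vs-polyA level
differences (≥ 20 reads in both, nascent level > 5%) contrast 3'UTR
with CDS sites: co-transcriptional editing predicts lower nascent
levels, so 3'UTR sites that fail to rise in polyA RNA point to
degradation of edited transcripts.

Seed scanning reimplements the canonical miRNA site types only: with
the miRNA written 5'→3', a 7mer-m8 is the reverse complement of seed
positions 2–8 in the UTR, an 8mer adds the A opposite position 1, and
a 7mer-A1 is positions 2–7 plus the A anchor.  Context scores and
6mers are out of scope — the question asked is only whether an A→G
edit creates or destroys a putative site.  Each edit is evaluated
independently (no combinatorial multi-edit variants); a lost match
must overlap the edited position.  miRNAs below 0.1% of total miRNA
reads and genes with |log2FC| ≤ 0.2 are excluded by default.

## The synthetic-data generator

The generator replaces inaccessible sequencing data with fully
specified truth; every stochastic draw flows from named substreams of
one seed (stream = CRC32 of the substream name mixed with the seed), so
identical seed + configuration give byte-identical outputs.

* **Levels on a phylogeny.**  Sites are born on branches chosen with
  probability proportional to branch length, plus a root pseudo-branch
  weighted by the mean branch length so pan-edited (oldest) sites
  exist.  The level starts uniform in [0.2, 0.8] at birth and evolves
  down descendant branches as a Gaussian walk with sd
  `0.01·√(branch length in Myr)`, reflected into [0, 1] (reflection
  preserves variance near the boundaries where truncation would not).
  Species outside the birth clade have level exactly 0.  The default
  tree is an ultrametric six-species topology with divergence times of
  5/10/30/45/60 Myr from the anchor.  The gentle walk keeps most edited
  sites clear of the 1.5%/2% call boundaries, which is what real
  persistent editing looks like; it underrepresents sites hovering at
  the detection limit.
* **Reads.**  Coverage is negative binomial (default mean 100,
  dispersion 5); G counts are binomial at `level + 0.01·(1−level)`
  (the 1% A-to-G error floor); non-G reads are A except C/T errors at
  0.5% each; an ADAR-null sample is the same machinery with level 0.
  Deep-coverage analyses (dating) use mean 2,000, the scale of
  targeted mmPCR-seq.
* **Sequences.**  Each site sits at offset 200 of its own 401-nt
  window (one contig per site, so planted windows cannot collide).
  With probability 0.7 a perfect hairpin is planted (21–32 pairs, 10-nt
  loop, editing arm covering the site) and the motif triplet is written
  at −1/+1.  Accidental complementary runs that would extend a planted
  stem past its ends are mutated away (mutated bases set equal to their
  would-be partner and frozen); a window that cannot be cleaned is
  regenerated, with an error after bounded retries.  Non-anchor species
  accumulate neutral background substitutions (0.5%/base) outside
  planted features.
* **Two regimes.**  In the neutral regime (default) levels come from
  the tree walk and planted features are independent of them; absent
  (Presence/Absence) species still lose at least one planted property
  so sequence and calls stay consistent.  In the cis-coupled regime
  (`structure_effect`/`motif_effect` > 0) every species' level is a
  logistic function of its own feature state
  (`z = −1 + structure_effect·(n_p−26)/6 + motif_effect·(q−1)` plus
  N(0, 0.25) noise, with q the motif quality in {0,1,2}); disrupted
  species lose the stem and, with probability 0.3, the motif as well,
  while non-disrupted species drift quietly (Poisson(3) outermost
  pairs unpaired, 1% quiet motif changes).  The two regimes are
  mutually exclusive by construction: a level cannot simultaneously
  follow the neutral walk and the logistic link.
* **Conservation.**  Background scores are Beta(2,2); "high" sites get
  Beta(57,3) (mean 0.95) over S and F regions, "moderate" over the
  S_region only, "none" background everywhere.
* **Expression and miRNAs.**  Control genes draw log2FC ~ N(0, 0.3);
  one edited 3'UTR site adds +0.5, several add +1.0 (expression rises
  when editing is lost).  Five bundled synthetic miRNAs carry fixed
  seeds; a configurable number of edited 3'UTRs contain an A whose
  editing completes an 8mer match to the most abundant miRNA; one
  bundled miRNA sits below the 0.1% expression threshold to exercise
  the filter.
* **Feature-level rows.**  For the forest analyses the generator can
  also emit model-matrix rows directly, planting an effect of a chosen
  feature delta on the other species' presence or level.

What passing tests show, and do not show: the generator's windows are
i.i.d. random sequence with exactly one planted duplex, its
conservation tracks have sharp planted boundaries, and its error model
is a uniform 1% binomial.  Real introns have repeats and compositional
structure (more accidental complementarity), real phastCons tracks are
autocorrelated, and real error rates vary by position and context.
Passing therefore demonstrates correctness of the statistical machinery
and recoverability under the stated generative assumptions, not
performance on any particular genome.

## Problem sizes and numerical choices

The validation suite runs at: 50 replicate phylogenies × 1,000 sites
(tree recovery), 1,000 sites at coverage 2,000 (dating), 500 planted
stems and 500 random windows (stem finder), 300 sites (constraint),
20 seeded forest runs at 1,000 trees and 20-refit ΔR² intervals, 600
two-species sites (discovery), and a full 1,000-site end-to-end run —
sizes at which every Monte-Carlo margin in the tests has comfortable
slack.  Ties in rank tests use mid-ranks; the exact Mann–Whitney path
is taken for tie-free groups up to n = 25; KS p-values are asymptotic
(an exact permutation option exists behind the test functions' inputs
simply by resampling).  Degenerate inputs are errors, not silent
defaults: zero coverage in a binomial test, a site outside its stem,
zero outcome variance, an unedited anchor in dating.

## Known limitations

The stem finder reports a single best duplex per site, not an ensemble;
pseudoknots and multibranch structures are out of scope.  Energy values
are not comparable to laboratory thermodynamic scales.  The
neutral-regime generator draws site categories independently of
position, so positional clustering of real editing sites is not
emulated (the clustering statistic is tested on constructed inputs).
Orthology, annotation, ω values and expression fold changes are
consumed as inputs; errors in them propagate. Genome-scale headline
counts from real fly data (thousands of exonic sites, hundreds of
constrained sites) depend on such inputs and are not reproduced at
desk scale; the pipeline's behaviors are validated on synthetic truth
instead.
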