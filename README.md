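# editevol

Comparative analysis of adenosine-to-inosine (A-to-I) RNA editing
evolution across a species group, as a tested, reusable Python
library.

A-to-I editing, catalysed by ADAR on double-stranded RNA, appears in
sequencing data as A-to-G mismatches between RNA reads and genomic
DNA; the editing level of a site is `G/(A+G)`.  `editevol` implements
the full analysis arc for studying how editing sites are born, tuned
and selected over evolutionary time:

* **Site discovery and quantification** from per-site pileup counts:
  variant calling, cross-species intersection at the frequency cutoff
  where shared variants are ≥ 80% A-to-G, false-positive estimation
  against an ADAR-null sample (Fisher's exact test, BH-corrected), and
  level quantification combining RNA-seq with replicated targeted
  (mmPCR-seq) measurements.
* **cis-regulatory modelling**: the ADAR triplet motif matrix with
  0–10 scaled scores; editing-complementary-sequence (ECS) prediction
  by complementarity alignment (≥ 20 paired bases, max bulge 8, within
  200 bp proximally or 2,500 bp of conserved intron distally); the 8
  structural features with a nearest-neighbour free-energy model; and
  random forests predicting editing presence/absence and level changes
  between species, with out-of-bag permutation importance and
  `R² = 1 − MSE/Var` model comparison.
* **Evolutionary analyses**: editing-level divergence `1 − ρ`
  (Spearman), neighbour-joining trees, divergence–time regression, and
  parsimony dating of sites (age = most distantly related species also
  edited; ≥ 5 species with defined status required).
* **Constraint classification** from per-base conservation tracks:
  S_region (site − 15 bp .. + 30 bp) vs pooled 46-bp flanks, "high"
  when both means exceed 0.9, "moderate" by a BH-corrected two-sample
  Kolmogorov–Smirnov test, plus the functional-fraction estimate
  (excess constraint among edited vs lowly edited sites).
* **3'UTR function**: expression-shift comparisons between 3'UTR-edited
  and control genes (Mann–Whitney U), nascent-vs-polyA editing
  contrasts, and a TargetScan-style scan for 8mer / 7mer-m8 / 7mer-A1
  miRNA seed matches created or destroyed by editing.
* **A synthetic-data generator** (`editevol.simulate`) producing truth
  plus observables with the statistical structure every stage assumes:
  levels evolving along a phylogeny with site birth on branches,
  binomial reads with a 1% A-to-G error floor and an ADAR-null sample,
  sequences with planted hairpins and motif triplets (optionally
  logistic-coupled to levels), conservation tracks with planted
  constraint classes, and expression tables with planted 3'UTR shifts
  and miRNA seed gains.

The library is used from Python; `examples/` contains one short
narrative script per capability, and `editevol.pipeline.run_pipeline`
chains every stage over one synthetic dataset and writes all result
tables (each stamped with the tool version, config hash and seed).
See `docs/methods.md` for models, defaults and limitations.

## Worked example

```bash
python examples/04_divergence_and_dating.py
```

prints, for an 800-site six-species simulation:

```
editing divergence (1 - Spearman's rho), mel row:
mel    0.000
sim    0.339
yak    0.427
ana    0.704
pse    0.907
vir    1.144
...
divergence vs time: slope 0.0116/Myr, Spearman rho 0.80
parsimony age classes of anchor-edited sites:
sim     14
yak     64
ana     54
pse     54
vir    104
```

Divergence grows monotonically with species age (`rho 0.80`), the
neighbour-joining tree printed above these lines reproduces the
generating topology, and the parsimony age classes show the expected
spread from recently born (`sim`) to pan-edited (`vir`) sites.
`examples/06_random_forest_models.py` shows the cis-modelling side: a
planted free-energy effect ranks first in permutation importance and
the full model beats the anchor-level-only model by ΔR² ≈ 0.5.

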