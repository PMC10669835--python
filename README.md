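# crocdiag

Species-diagnostic SNP/PA panels and hybrid classification for
conservation genetics.

## The problem

Captive populations of an endangered species can be silently introgressed
by a congener: first-generation (F1) hybrids, F2s and repeated backcrosses
(BC1, BC2, …) look increasingly like the parental species while carrying
foreign genomic ancestry.  Releasing such animals in reintroduction
programs erodes the genetic integrity of wild populations.  `crocdiag`
implements a screening workflow built around genome-wide reduced-
representation genotyping (DArT-style codominant SNP loci coded 0/1/2/−
and dominant presence/absence tags coded 1/0/−) for a two-species system —
a focal endangered species A and a comparison species B — and classifies
candidate individuals before release.

## What it computes

* **Quality filtering** of loci on reproducibility, recomputed call rate
  and sequencing depth, with the three nested depth tiers (>5X, >10X,
  >15X).
* **Species-diagnostic loci** by the 100:0 criterion — a locus whose
  called individuals of one species all share a single homozygous (or
  presence) state with zero heterozygotes, while the other species
  differs.  Two readings of "differs" are provided: `strict_absent` (the
  diagnostic allele is absent from the other species) and
  `fixed_nonfixed` (the other species is simply not fixed for the same
  state, the default).
* **Per-locus marker statistics**: Cochran–Armitage trend-test
  association between genotype and species (χ² on the genotype or allele
  scale; χ² = N at complete separation of N individuals, 2N on the allele
  scale), informativeness PIC = 1 − Σp² (0 at fixation, 0.5 at equal
  biallelic frequencies), proportional Hamming distances between
  individuals, and between/within-group consensus identity percentages.
* **Population statistics** in the GenAlEx idiom: Na, Ne = 1/Σp²,
  Shannon's I, Ho, He = 2p(1−p), F = (He − Ho)/He, FIS, overall and
  pairwise FST = (HT − H̄S)/HT with permutation p-values, pairwise
  Queller–Goodnight relatedness referenced to exclude-dyad allele
  frequencies, Hardy–Weinberg χ² tests, Welch's unequal-variance t, and
  distance-based two-level AMOVA (ΦPT with permutation significance).
* **Clustering views**: principal coordinate analysis (Gower
  double-centering, negative eigenvalues reported) and an ultrametric
  UPGMA dendrogram in newick.
* **Hybrid classification**: each candidate is scored by diagnostic
  allele-copy fractions propA/propB over called panel loci (an F1 reads
  50/50 with fully heterozygous panel loci; each backcross generation
  halves the minor-parent share), then passed through a combined decision
  scheme that integrates an external admixture q value, the mtDNA D-loop
  haplotype (maternal lineage annotation only) and PCR marker band
  patterns, demoting conflicting evidence to `unresolved` with a full
  evidence trail.
* **Primer-candidate screening** of panel loci against a reference
  sequence: repeat-free, SNP-free flanks of ≥ 50 bp and an allele
  matching the reference base.

A Mendelian simulator (`crocdiag.simulate`) generates two diverged
parental gene pools — reciprocally fixed, focal-fixed/other-polymorphic,
shared-polymorphic and monomorphic loci — plus F1/F2/BC1/BC2 pedigrees
with exact ground truth, so every stage is testable without study data.

## Worked example

`examples/05_hybrid_classification.py` simulates a 1000-locus reciprocally
fixed panel (10 + 10 parental individuals, no missing calls), a pedigree of
known hybrids, and classifies them:

```
panel: 1000 reciprocally fixed loci

individual   truth     propA  propB   het  assigned
F1_01        F1        0.500  0.500  1.00  F1
F1_02        F1        0.500  0.500  1.00  F1
F2_01        F2        0.479  0.521  0.49  F2
F2_02        F2        0.526  0.473  0.53  F2
BC1_toB_01   BC1_toB   0.256  0.745  0.51  BC1_toB
BC1_toB_02   BC1_toB   0.255  0.746  0.51  BC1_toB
BC2_toB_01   BC2_toB   0.128  0.873  0.26  BC2_toB
BC2_toB_02   BC2_toB   0.119  0.880  0.24  BC2_toB
```

propA/propB are the fractions of diagnostic allele copies attributable to
each species (they always sum to 1 over called panel loci); `het` is the
heterozygote fraction at reciprocally fixed panel loci, which separates F1
(≈1) from F2 (≈0.5); the assigned class follows the decision scheme with
backcross generation estimated from the expected halving of the minor
fraction (0.25 → BC1, 0.125 → BC2).

The other scripts in `examples/` each demonstrate one capability
(filtering and depth tiers, panel discovery, population statistics,
clustering, primer screening, the full pipeline).  A thin CLI mirrors the
stages: `crocdiag simulate | filter | diagnose-loci | stats | cluster |
hybrid-classify | primer-screen | run`.

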