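# Methods

This note documents the models, conventions and numerical choices behind
`crocdiag`, the assumptions of its synthetic-data generator, and the
limits of what its tests demonstrate.

## Data model

Genotypes live in a loci × samples matrix of small integer codes: SNP loci
are codominant alt-allele dosages (0 reference homozygote, 1 heterozygote,
2 alternate homozygote), presence/absence (PA) loci are dominant
restriction-site tags (1 presence, 0 absence).  Missing calls are `-` on
disk (`−`, `NA` and the empty string are accepted aliases on read) and −1
internally.  PA "putative heterozygosity" is treated as missing
throughout: a dominant marker cannot distinguish a heterozygote from a
presence homozygote, so an ambiguous call carries no usable state.
Positions are 1-based inclusive everywhere user-facing.

Quality filtering retains loci whose reproducibility, call rate and mean
depth are *strictly above* their thresholds.  Call rate is always
recomputed from the calls ((non-missing)/(samples)), never trusted from
metadata.  A threshold of exactly 0 is documented as a no-op (the
"−infinity equivalent"), so depth-tier construction does not silently
drop zero-scored loci on unrelated criteria.  The three depth tiers (>5X,
>10X, >15X) are nested by construction.

## Synthetic data

The generator emulates the structure of a two-species reduced-
representation genotyping study, not its sequences.  Loci fall into five
categories: reciprocally fixed between the species, fixed in one species
and polymorphic in the other (split by a skew parameter, default 0.86,
matching the strong asymmetry seen in real focal-vs-comparison panels),
polymorphic in both, and monomorphic.  Genotypes at polymorphic loci are
binomial Hardy–Weinberg draws with allele frequency uniform on [0.1, 0.9];
depth follows a lognormal law (median 12, σ = 0.5) so the three tiers are
non-trivially nested; missing calls are masked independently at a
configurable rate (default 0.02).  Default sample sizes are 29 focal (A)
and 30 comparison (B) individuals, the B population split 12/18 between
two geographic labels.

**Realized categories.**  A locus's category refers to the *sample that
was generated*, not merely to the law it was drawn from: polymorphic-
category loci are rejection-resampled until both states are actually
observed in the relevant species (both alleles for SNP loci; both dominant
presence states for PA loci).  Without this, a nominally polymorphic locus
can be sample-fixed by chance and the simulated truth would disagree with
any correct panel-discovery implementation — the category labels would be
wrong, not the method.  The conditioning displaces realized allele
frequencies from the drawing law by a negligible amount at the default
sample sizes (the all-fixed probability at n = 20, p = 0.1 is already
< 2 × 10⁻³).

Pedigrees are Mendelian with free recombination: one allele sampled
independently per locus per gamete; F1 = A×B, F2 = F1×F1 (two independent
F1s), BC1 = F1×parent, BC2 = BC1×parent.  A hidden diploid genotype is
retained for every individual so dominant coding and call masking never
lose the ground truth.  Linkage, mutation and demographic realism are
out of scope: the scoring model assumes independent loci, which matches
genome-dispersed restriction-site tags.

What passing tests on this generator do **not** show about real data:
genotyping error and allelic dropout are absent (missingness is
independent of genotype), loci are exactly unlinked, parental populations
are exactly at Hardy–Weinberg, and reference-genome artefacts (paralogy,
null alleles) do not occur.  Panel recovery and classification accuracy on
real data will degrade with these factors; the purity threshold
(`purity_epsilon`) exists precisely to absorb genotyping noise and is 0 by
default only because the simulator is noise-free at the locus level.

## Diagnostic panels

The fixation test requires every called individual of the diagnostic
species to share one homozygous/presence state with zero heterozygotes,
with at least max(2, ⌈0.8 · n_species⌉) called individuals (aligned with
the 0.8 call-rate filter; configurable).  Two criteria for the other
species are offered because the verbal "100:0" rule is ambiguous for
biallelic loci:

* `strict_absent`: the diagnostic allele is absent from all called
  individuals of the other species.  For biallelic SNPs this forces the
  other species to be fixed for the opposite homozygote, so only
  reciprocally fixed loci qualify — the most literal reading.
* `fixed_nonfixed` (default): the other species is not fixed for the same
  state.  This admits focal-fixed/other-polymorphic loci and is the only
  reading that can produce strongly asymmetric panel sizes between two
  biallelic gene pools, which is what published two-species panels show.

Reciprocally fixed loci satisfy both species' criteria and are assigned
exclusively by a priority (default species A, the focal species), so
|panel A| + |panel B| equals the panel total with no double counting.

The trend test is the score statistic T²/Var(T) with
T = Σⱼ sⱼ(n₁ⱼR₂ − n₂ⱼR₁) and the N-denominator variance (no N−1
correction); with 0/1 scores and complete separation it equals exactly N
(individual scale) or 2N (allele scale), which is why both scales are
exposed.  PIC is the expected-heterozygosity form 1 − Σp² with range
[0, 0.5] for biallelic loci; the three-term form (max 0.375) is available
by flag.  Hamming distances are proportional over co-called loci with the
co-called count reported per pair; pairs sharing no called locus are
flagged undefined rather than zeroed.

On diagnostic panels built from fixed loci, within-species distances are
0 by construction whenever calls are complete; nonzero published
within-species values on such panels can only arise from a particular
treatment of missing calls, which this package does not attempt to
emulate — it reports the definitional value.

## Population statistics

He uses 1 − Σp² with no small-sample correction (the unbiased 2n/(2n−1)
variant is a flag), matching the conventions of the spreadsheet-era tools
this module mirrors.  F = (He − Ho)/He is undefined at monomorphic loci
and excluded from means with the exclusion count reported — averaging
would otherwise silently depend on an arbitrary 0/0 convention.  For loci
with no calls in a population, two inclusion conventions are implemented:
`called` (drop the locus from that population's averages) and `all` (keep
it as a zero-allele row, which deflates mean Na/Ne below 1 — the only way
published per-population tables can print Na < 1).

FST is the ratio-of-sums (HT − H̄S)/HT with HT from the unweighted mean of
population allele frequencies; permutation significance shuffles
individuals across populations (default 999 permutations; any count can be
configured).  FIS = 1 − ΣHo/ΣHe within populations.  Relatedness is the
Queller–Goodnight estimator with reference allele frequencies computed
excluding the dyad, directional values formed as ratios of locus sums and
then averaged.  Two properties of the biallelic estimator are worth
stating: a heterozygous reference individual contributes 0/0 at every
locus (the denominator 1 + δ − p − q vanishes), and loci monomorphic in
the reference frequencies are skipped; a dyad with no informative locus is
reported NaN.  Identical homozygous dyads score exactly 1.

AMOVA is distance-based (Excoffier-style): squared distances enter the
sums of squares, ΦPT = σ²_among/(σ²_among + σ²_within) with a negative
among-component truncated to 0 and flagged, and significance from
permuting population labels.  The same Hamming matrix used everywhere else
is the input, keeping one distance model across the package.

## Clustering

PCoA is the classical Gower double-centering followed by a symmetric
eigendecomposition.  Negative eigenvalues (non-Euclidean input) are
reported verbatim; coordinates are returned only for positive axes and %
variance is computed over the positive spectrum.  This is implemented
directly rather than delegated because common library implementations
post-process the negative part of the spectrum; the library
implementation serves as the cross-check in the test suite.  UPGMA is
scipy average-linkage re-expressed as an ultrametric newick: a node merged
at height h sits at depth h/2.  Output is byte-stable for a fixed input
ordering.

## Hybrid classification

Scoring is allele-copy counting, not locus counting: a called SNP panel
locus contributes 2 copies split by dosage of the diagnostic allele, a PA
locus contributes 1 copy by state.  This makes propA + propB = 1 exactly
and gives heterozygotes their half-weight in both species, which is what
lets paired percentages sum to 100 and the minor-parent share halve per
backcross generation.

The decision sequence: (1) minor fraction ≤ `purity_epsilon` (default 0)
→ pure; (2) minor fraction in the F1 band (default [0.40, 0.60]) →
F1 if panel heterozygosity ≥ 0.85 else F2 (Mendelian expectation: F1 = 1,
F2 = 0.5 at reciprocally fixed loci); (3) below the band → backcross
toward the major species with generation g = round(−log₂ f) − 1, a point
estimate from the expected halving that is reported with a low-confidence
note beyond g = 2 (sampling noise at realistic panel sizes cannot resolve
deeper generations).  External evidence then corroborates or conflicts:
an admixture q (read as major-cluster membership) conflicts with a pure
call when min(q, 1−q) exceeds the 0.05 noise threshold and with an F1/F2
call when it does not; q never conflicts with a backcross call, whose
expected q ranges from intermediate to the upper tail.  PCR band patterns
conflict when they imply the opposite purity or hybrid banding against a
pure call; an all-absent pattern is inconclusive and triggers a
recommendation for genome-wide confirmation rather than a verdict, since
primer-site variation cannot be excluded.  Any conflict demotes the call
to `unresolved` with the conflict recorded in the evidence trail.  The
mtDNA haplotype annotates the maternal lineage only and never overrides
the nuclear verdict.

## Primer screening

"No repeated sequences" is operationalised as a motif rule — a
homopolymer run of ≥ 6 bases or a di-/trinucleotide tandem of ≥ 4 units in
either flank — as a reproducible proxy for primer-design repeat screens;
thresholds are configurable.  Flanks exclude the SNP base, truncate at
contig edges, and must both reach 50 bp; the SNP-free criterion checks a
variant catalogue on the same 1-based coordinates (the screened position
itself does not count); the allele criterion requires ref or alt to match
the reference base.  `synthesize_reference` builds a random reference with
each locus's reference allele planted at its position so the screen can be
exercised (and its planted-truth recovery tested) on simulated data.

## Problem sizes and determinism

All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; the pipeline records every stage's outputs
with SHA-256 digests and reruns byte-identically under a fixed config.
The test suite runs its stochastic checks at deliberately modest sizes —
panel recovery at 10,000 loci, classifier calibration at 40 individuals
per class over 1000 loci, permutation-uniformity at 299 permutations × 60
replicates, relatedness calibration at 150 individuals × 400 loci — sizes
chosen so the binomial/KS tolerances stated in each test are meaningful
while the whole suite stays interactive.  Statistical assertions use 3–4
standard-error bands or lenient KS thresholds and fixed seeds, so they are
deterministic in practice.

## Known limitations

* The simulator's idealisations listed above; in particular, PA loci are
  derived from a hidden biallelic state with the presence allele dominant,
  which is one of several plausible dominant-marker models.
* The backcross generation estimate is a coarse point estimate; adjacent
  generations overlap substantially beyond BC2 at 1000 panel loci.
* External admixture proportions are consumed, never computed; model-based
  clustering, species delimitation and tree-graph methods are out of
  scope by design and enter only as evidence labels.
* Between-group consensus identity uses majority calls with a
  lowest-code tie-break; other tie conventions will shift identity
  percentages on small groups.
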