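# Methods

This note documents the models, estimators and numerical choices behind
the package, and what the synthetic-data generator does and does not
emulate.

## Synthetic data generator

The generator (`hybridzone.synthetic`) defines the study conditions under
which everything is tested.

**Nuclear loci.** A `SpeciesPairModel` draws `n_loci` biallelic sites. A
fraction `prop_fixed_diff` (default 0.1 over 1,000 sites) is fixed for
alternative alleles between the two species — the truly diagnostic sites,
with the direction of fixation randomised per locus. The remaining loci
draw each species' allele-1 frequency independently from uniform(0.05,
0.95); the upper and lower edges deliberately produce "nearly fixed"
non-diagnostic loci that stress the strict fixation filter.

**Genealogical classes.** Each of the six classes fixes the expected
proportions of per-locus ancestry pairs (A,A)/(A,B)/(B,B): pure A (1,0,0),
pure B (0,0,1), F1 (0,1,0), F2 (¼,½,¼), backcross to A (½,½,0), backcross
to B (0,½,½). A simulated individual draws an ancestry pair per locus
from its class's mixture and then one allele from each ancestral species'
frequency. Loci are unlinked; later-generation crosses (F3, double
backcrosses) are outside the class space, matching the classifier's
hypothesis space.

**Pooled read counts.** Per site and pool, depth is negative-binomial
(mean 80, dispersion 10 — overdispersed as transcriptome coverage is)
clipped to [20, 200]; the allele-1 read count is binomial(depth, f′) with
f′ = f(1−e) + (1−f)e for a symmetric per-base error e (default 0).
Unequal individual contributions to a pool are not modelled; the binomial
is the simplest model matching a pooled-pileup substrate, and the error
knob is the only noise source beyond read sampling.

**Study design.** The default fixture mirrors the sampling of the
original field design: 94 individuals in 8 ponds (parental ponds of 10
and 14, six putative hybrid ponds of 21/12/8/7/12/10) genotyped at a
106-locus all-diagnostic panel, with hybrid ponds holding fixed mixtures
of the six classes. The mitochondrial alignment is 795 bp with the two
clade centroids 51 substitutions apart and Poisson(1.5) private
substitutions per sequence (substitutions only, no indels, so all
network/K2P stages see gap-free columns).

**What passing tests do not show.** The generator produces unlinked loci,
Hardy–Weinberg parental pools, panmictic classes and error-free or
symmetric-error reads. Real data add linkage, null alleles, assay
dropout, unequal pool contributions and reference bias; exact truth
recovery on fixtures therefore validates the *implementation*, not
robustness to those artefacts.

## Diagnostic SNP discovery

A site passes when (i) each pool's depth lies in
[`min_coverage`=10, `max_coverage`=8000]; (ii) each parental pool shows a
single base at frequency ≥ 1 − `fixation_tolerance` (default 0, i.e.
strict 100%), the two bases differing; (iii) both parental bases occur in
the hybrid pool and the rarer one has frequency ≥ `hybrid_min_maf`=0.10
*among reads carrying either parental allele* — third-allele reads count
toward depth but are excluded from the ratio, since the rule concerns
both species' alleles being present, not sequencing noise. A parental
pool with three observed bases above tolerance fails `multi_allelic`
(the panel is strictly biallelic). Coordinates are 1-based inclusive;
assay eligibility requires `pos − 1 ≥ 100` and `length − pos ≥ 100`, with
an optional `clean_flank` mode that also rejects sites with another
variant inside the flank. Every input site is returned with a status and
fail reasons so the panel is auditable. The exported VCF writes the
species-A allele as REF — a reference surrogate, as the transcriptome has
no published genome.

## Diversity and equilibrium statistics

Per locus and population: allele frequency p, observed heterozygosity Ho,
unbiased He = (2n/(2n−1))(1 − p² − q²), and Weir & Cockerham's (1984)
single-population f computed from the b (between-individual) and c
(within-individual) variance components, f = b/(b+c) — negative under
heterozygote excess. The naive 1 − Ho/He is also emitted for comparison.
The multilocus per-population F_IS sums components over loci; its
across-locus standard deviation is reported because no other estimator
for the summary spread is standard.

The exact HWE test uses Levene's distribution of the heterozygote count
conditional on allele counts; the p-value sums probabilities of all
same-parity heterozygote counts no more probable than the observed one
(ties within 1e-9 in log space included). The Markov-chain option is the
Guo–Thompson switch chain specialised to two alleles (merge two
heterozygotes / split a homozygote pair, Metropolis-accepted), with a
batch-means standard error floored by the add-one binomial error at a
conservative effective sample size of iterations/10 — the floor matters
when the chain never visits the rejection region. For biallelic data the
enumeration path is exact and cheap, so the chain exists as a
cross-check; its default length is 10⁵ steps. Per-population multi-locus
HWE combines per-locus exact p-values by Fisher's method (the convention
of the GENEPOP family, not a statement of the field protocol).

Genotypic LD uses the log-likelihood-ratio G on the 3×3 genotype table
with p from random re-pairings of single-locus genotypes; permutation
p-values throughout use the add-one estimator (never exactly zero), and a
monomorphic locus makes the test undefined (flagged), not p = 1.

## AMOVA and Fst

All designs run through one nested decomposition of squared inter-unit
distances. Sums of squares use the standard identity
SSD(partition) = Σ_clusters (1/2n_c) ΣΣ d²; expected mean squares for
unequal cluster sizes are assembled from the general nested-random-effects
coefficients (for component k at level r: Σ_d n_d²(1/n_anc_r(d) −
1/n_anc_{r−1}(d)), units contributing their degrees of freedom), and the
triangular system is solved for the variance components. Negative
components are reported as computed, never truncated, so percentages can
be negative. A level with zero degrees of freedom is dropped from the
moment system and its component and dependent Φ reported as undefined.

Units are allele copies for the genotypic 4-level design (group /
population / individual / copy). Copies use an arbitrary fixed phase;
every AMOVA sum of squares is phase-invariant because per-locus pairwise
allele differences depend only on allele counts within any cluster. Loci
with missing genotypes are dropped from the copy matrix to keep the
design balanced within individuals.

Permutation schemes follow the standard nested conventions (stated here
because they are rarely written out): units among populations for Φ_ST,
individuals among populations within groups for Φ_SC, whole populations
among groups for Φ_CT, allele copies among individuals within populations
for Φ_IS.

Pairwise Fst is the two-population AMOVA Φ_ST over numbers of allele
differences between individual multilocus genotypes (the Arlequin-style
distance approach), with 1,000 permutations of individuals between the
two populations by default; Weir–Cockerham θ is computed alongside from
the a/b/c components summed over loci. Two populations with zero total
variance have undefined Fst (NaN, no p-value).

## DAPC

Allele dosages (0/1/2; missing imputed to the locus mean) are centred and
scaled; PCA retains a fixed number of components or the smallest number
reaching a cumulative-variance target (the study convention: 20 PCs ≈
80%). Discriminant axes solve the generalised eigenproblem S_b w = λ
(S_w + εI) w in the retained space with ε = 1e-8 · tr(S_w)/k, a ridge
that only matters when the within-group scatter is singular. Group labels
are the sampled ponds (supervised).

## Admixture model

The Gibbs sampler assigns a latent cluster origin to every allele copy;
individual membership vectors Q get a symmetric Dirichlet(α = 1) prior
(α fixed, not sampled — a deliberate simplification of the cited program
adequate for diagnostic-marker recovery) and cluster allele frequencies a
uniform Beta prior. The per-sweep log-likelihood ln P(X | Q, P) trace is
recorded; its post-burn-in mean is the model-choice score. Evanno's ΔK =
|mean L(K+1) − 2 mean L(K) + mean L(K−1)| / sd(L(K)) across replicate
runs, undefined at the endpoints and when the replicate s.d. is zero.
Replicate runs at one K are label-aligned by maximising summed Q-column
agreement with the first run — exhaustively over permutations for K ≤ 6,
or by optimal column assignment (Hungarian), which attains the same score
at any K; the consensus Q is the element-wise mean of aligned runs.
Default chains are a scaled-down preset (hundreds of sweeps over ~100
diagnostic loci mix within tens of sweeps; the field-standard 100k/200k
chains are configurable).

## Six-class genealogical classifier

Per individual, class z; per locus, ancestry pair w ∈ {AA, AB, BB} with
P(w | z) from the class table; genotype likelihoods are Hardy–Weinberg
products in the corresponding species frequencies (for AB: one allele
from each species). Species frequencies get Dirichlet priors — uniform
Dir(1,1) or Jeffreys Dir(½,½). The sampler uses a blocked update: z is
drawn with w marginalised out (P(z | g, f) ∝ prior · Π_l Σ_w T[z,w]
P(g_l | w, f)), then w | z, then the frequencies from allele copies
attributed to each species, sampling the orientation of heterozygous
AB-ancestry copies from its conditional. Updating z from a sampled w
instead would freeze the chain: the deterministic classes (pure, F1)
force their ancestry states and become absorbing. Missing genotypes
contribute no likelihood. The class prior is uniform over the six
classes; mixing proportions are not modelled hierarchically.

Label switching between species A and B is resolved either by
`known_parentals` (clamping reference individuals to the pure classes) or,
absent that, by the convention that the first population's majority
assignment is pure A. Assignment requires the maximum posterior to
*strictly* exceed the 0.5 threshold; otherwise the individual is reported
unassigned. The scaled-down test preset is 2,000 burn-in / 8,000 sweeps.

## Mitochondrial statistics

Columns containing a gap or N anywhere are excluded before analysis
(complete deletion, the DnaSP convention); K2P additionally offers
pairwise deletion. K2P: d = −½ ln(1 − 2P − Q) − ¼ ln(1 − 2Q) with P/Q the
transition/transversion proportions; non-positive logarithm arguments
raise a defined saturation error, and such pairs appear as missing in
distance matrices. Haplotype diversity h = n(1 − Σx²)/(n−1) with Nei's
sampling variance; nucleotide diversity π is the mean pairwise difference
per analyzed site with Nei's (1987) variance. Tajima's D uses the
standard constants; n = 2 leaves both numerator and variance zero, so D
is undefined there. Significance classes come from Tajima's scaled-beta
approximation (mean 0, variance 1 on [D_min, D_max]), reported as
p < 0.05 / 0.05–0.10 / p > 0.10 (NS).

## Median-joining network

The network is built as a deterministic spanning tree (Kruskal over
Hamming distances, ties broken by lexicographic haplotype id) iterated
with quasi-median addition: a triplet generates its per-column majority
vector when every pair is adjacent or its direct link is within ε
(default 0) of the largest step on the connecting path — so tied
alternative connections count as feasible — and the median is kept only
when it strictly shortens the rebuilt tree. Dangling median vectors
(degree < 2, hence off every shortest observed-to-observed connection)
are removed. This variant resolves tied alternative links
deterministically instead of keeping them as reticulation loops; the
total network length therefore never exceeds the minimum-spanning-tree
length of the observed haplotypes, at the cost of not displaying
ambiguous cycles. ε is exposed for relaxed feasibility.

## Pipeline, determinism and problem sizes

The pipeline derives one sub-seed per stage from the global seed via
`numpy.random.SeedSequence` spawn keys, so stages are individually
rerunnable and full runs are byte-reproducible from (config, seed). All
tables are tab-separated UTF-8 with one header line and `NA` for missing
values.

Tests and the acceptance script run on deliberately scaled problem sizes
chosen once as representative: discovery on 1,000 sites, HWE tables with
n ≤ 25 against 50k-step chains, classifier fixtures of 120 individuals ×
100 loci at 2k/8k chains, admixture sweeps over K ∈ 1..5 with 5
replicates at a few hundred sweeps, and 795-bp two-clade alignments. At
these sizes the complete suite and the acceptance script each finish in a
few minutes on one CPU.

## Known limitations

- Multi-allelic loci are out of scope end to end; the panel is biallelic
  by construction.
- The admixture model omits α-updating, correlated frequencies and
  location priors; it is a recovery tool for strongly informative
  diagnostic panels, not a replacement for the full cited programs.
- The AMOVA moment solver supports up to four nested levels.
- The median-joining variant omits reticulation loops (see above) and the
  maximum-parsimony post-processing of the original algorithm.
- Pool-seq frequencies assume equal individual contributions; an
  overdispersion knob beyond the binomial is limited to the depth law.
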