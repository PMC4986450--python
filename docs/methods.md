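# Methods

## Coordinate and format conventions

Segment TSVs on disk are 1-based inclusive (the convention of array-CNV
callers); everything in memory and all BED output is 0-based half-open;
human-readable reports are 1-based. "Any base overlap" therefore means a
shared base under half-open arithmetic: segments [100, 200) and [200, 300)
abut and do not merge. Gene annotation is refFlat-like with 0-based
half-open transcript coordinates; when a gene has several transcripts the
longest is kept, ties broken to the smaller start and then lexicographic
transcript id (the tie-break is a package convention; any deterministic
rule would do). The segment `confidence` column is optional (default 0.0)
because segment callers and genotype callers carry different quality
fields.

## Segment filters

Five rules, tested in a fixed order so each rejected segment carries the
first rule it violates: autosomes only; probe count ≥ 5; maximum
inter-probe gap < 10 kb; LOD ≥ 10 (inclusive); span < 1 Mb (exclusive).
Two aggregation choices were genuinely open and are resolved
conservatively: "probes less than 10 kb apart" is enforced on the *maximum*
gap within the segment (the strictest reading), and segment size is the
genomic span end − start. Filtering is idempotent and monotone in every
threshold; both properties are tested.

## CNVR construction

Per chromosome, connected components of the any-base-overlap graph
(single-linkage, transitive) become candidate regions spanning the union of
their members. When one sample contributes several members with conflicting
states, the region state for that sample is taken from the member with the
largest overlap with the region; ties prefer the state most deviant from 2,
then the loss. The sample-frequency threshold (default 5%) is computed over
all cohort samples, after merging — a cohort-wide rule matching its purpose
of removing singletons and rare calls. Deletion/duplication frequencies are
per population, with all of that population's samples (including state-2
non-carriers) in the denominator. Region classes: `del` if every call is a
loss, `dup` if every call is a gain, `gain_loss` otherwise.

## Genotype recoding

Diploid copy-number states map to unordered pairs of haploid copy-number
alleles {0, 1, 2}: 0 → 0/0, 1 → 0/1, 2 → 1/1, 3 → 1/2, 4 → 2/2. The map is
total and invertible on {0..4}, and allele dosage is conserved (the pair
always sums to the state). A diploid CN of 2 could in principle be the
phase-ambiguous 0/2; the conventional 1/1 reading is adopted, as the true
allelic configuration is unknowable from diploid copy number alone.
Genotype confidence > 0.1 masks a cell as missing; exactly 0.1 is retained
(the boundary belongs to neither the keep nor the drop clause of the rule;
retention keeps data).

## Population structure

A supervised random forest (CART, Gini impurity, trees grown to purity on
bootstrap resamples, ⌊√n_features⌋ candidates per node — 23 for a
567-region map) is trained to predict the population label from CNVR
states. Proximity between two samples is the fraction of trees whose
terminal node holds both; by default all trees and all samples count, with
an out-of-bag-only variant available. Missing cells are imputed to the
locus modal state before fitting (trees need complete features). Accuracy
and the confusion matrix come from out-of-bag votes, the standard unbiased
choice. The production default of 50,000 trees follows the motivating
study design; tests and the demo use 300–1,500 trees, a scaled-down
setting at which the proximity matrix is already stable (entrywise
correlation > 0.9 across seeds is a tested property).

Distances 1 − proximity are embedded by classical (Torgerson) MDS: double
centering of squared distances, eigendecomposition, coordinates scaled by
the square roots of positive eigenvalues. Negative eigenvalues (the input
need not be Euclidean) are truncated and reported through the eigenvalue
spectrum and the captured positive-mass fraction. On Euclidean-embeddable
input the embedding reproduces all pairwise distances to 1e-9 (tested).
The hand-rolled implementation exists because the common SMACOF-style MDS
is an iterative stress minimiser, not this spectral construction.

## Admixture model and EM

Each of an individual's two allele copies at locus l is drawn by choosing
ancestral component k with probability q_ik, then allele a with probability
p_lka. EM alternates copy-level responsibilities with closed-form updates
of Q and P; the log-likelihood is non-decreasing (asserted on every fit)
and missing copies contribute nothing. This is a deliberate methodological
substitution: point estimation by EM on the same likelihood that Bayesian
admixture clustering samples by MCMC, without priors; burn-in/iteration
settings of an MCMC run have no EM counterpart and are recorded only as
run metadata. Initialisation draws Q rows from Dirichlet(1,…,1) and P from
observed allele frequencies with seeded multiplicative noise; 10 restarts
by default (2–5 in tests), best likelihood kept; convergence when the gain
drops below `tol`. Ancestral-role samples are *not* constrained to pure
ancestry by default (the unsupervised admixture model); a supervised
option pins chosen samples to unit ancestry vectors. Component labels are
arbitrary at convergence; `align_components` resolves label switching
afterwards by optimal assignment of components to reference populations
(verified against exhaustive permutation search).

Parameter recovery at the tested scale (1,000 loci, 30+30 ancestral + 40
admixed, Balding–Nichols θ = 0.2): mean admixed ancestry within ±0.05 of
truth and RMSE of admixed Q below 0.08.

## Weir–Cockerham F_ST

The two-population θ uses the Weir–Cockerham (1984) variance components
a (among populations), b (among individuals within populations) and c
(within individuals), computed per locus and per allele by treating each
allele of the {0, 1, 2} haploid alphabet as a presence/absence indicator
(an individual is heterozygous for allele A when it carries exactly one
copy). θ is the ratio of sums over loci and alleles. Individuals missing a
genotype are excluded at that locus; loci with fewer than two genotyped
individuals in either population are skipped. Fixed opposite differences
give θ = 1 exactly; two independent samples from one panmictic population
give θ near 0 — small *negative* estimates are expected finite-sample
behaviour of the estimator, and literally duplicating one sample table
into both populations yields a deterministic negative value of order
−1/(n−1), not 0, because the among-population sampling variance the
estimator corrects for is absent by construction.

## Ancestry-informative CNVRs

Only deletion- and duplication-class regions are classified (mixed
gain–loss regions are ambiguous). With f_OG the admixed population's
frequency of the region's own class, f_IND the assigned Indian ancestor's
and f_AFR the mean over African ancestors (max available as an option):
`unique` if f_OG ≥ rare while both ancestors are below rare;
`indian_close` if |f_OG − f_IND| < δ ≤ |f_OG − f_AFR|; `african_close`
symmetrically; `unassigned` otherwise. δ = 0.2 and rare = 0.05 by default —
rare deliberately equals the CNVR sample-frequency floor — and both are
exposed as parameters because the exact binning rule of the original
analysis is not published in recoverable form; this reconstruction is a
documented package rule, not a claim about the original. Separately,
"specific" regions have calls in the admixed target but none in the
designated ancestral populations, and "strictly private" regions have
calls in no other population at all (always a subset; tested).

## Enrichment

Genes are mapped to CNVRs by any-base overlap of half-open intervals, each
gene counted once. Over-representation of a set with K background members
in a query of n genes with k hits is the hypergeometric upper tail
P(X ≥ k) with X ~ Hypergeom(N, K, n), N the annotation universe. The
background is the full gene annotation table — multi-resource backgrounds
of web enrichment services are not reproducible, so externally reported
p-values are not comparable. Bonferroni correction is applied within each
gene-set category by default (matching per-category result tables), with a
global option; significance at corrected P ≤ 0.05. The implementation is
verified against exhaustive combinatorial enumeration for every instance
with N ≤ 12 (to 1e-12) and holds the null type-I rate at ≈ 0.05 (≤ 0.07,
discreteness making the test conservative).

## Synthetic-data generator

The generator emulates the design of an admixture CNV study: ancestral
populations with Balding–Nichols-differentiated variant-allele frequencies
(ancestral base frequency Uniform(0.05, 0.95); component frequency
Beta(p(1−θ)/θ, (1−p)(1−θ)/θ)), an admixed population with per-individual
Dirichlet ancestry (or an exact fixed Q for recovery tests), and haploid
alleles restricted to {0, 1, 2} copies so diploid states span 0–4. Default
conditions mirror the motivating study at desk scale: two ancestral panels
plus one admixed population whose mean African ancestry is 58.7%
(Dirichlet mean of `admix_alpha`), θ = 0.2, and a deletion-dominated
landscape with 12.6% duplication loci (the study's observed
duplication/call ratio). Loci are placed non-overlapping with at least one
probe spacing between them so CNVR ground truth is unambiguous.

Every non-normal state cell becomes a segment spanning its locus with
probe count, gap, LOD and confidence drawn to pass all five filters — LOD
is clipped up to 10 and gaps down below 10 kb so that a noise-free
simulation is filter-clean *by construction* (an unclipped Gaussian LOD
would occasionally leak below threshold and break exact bookkeeping).
Decoy segments, each violating exactly one rule, are appended at
configured rates and recorded only in the truth object, enabling exact
precision/recall accounting. All randomness flows from one seeded
generator in a documented draw order, so identical configs give
byte-identical output files.

What the generator does **not** emulate: linkage disequilibrium between
loci, overlapping CNV loci with distinct boundaries, batch effects, probe
intensity noise, or calling error correlated with copy number. Passing
recovery tests therefore demonstrates correctness of the estimators under
the stated generative model, not robustness to the artefacts of real
array data.

## Pipeline

Stages run in dependency order from one YAML config; each stage records
SHA-256 checksums of its inputs and outputs, enabling skip-on-rerun and
detection of hand-edited intermediates (the error names the stage). The
global seed fans out to per-stage seeds via a CRC-32 hash of
`"<seed>:<stage>"` (kept below 2^31), so any stage can be reproduced in
isolation. All intermediates are plain text (TSV/BED/GMT/JSON); optional
static MDS and ancestry bar plots are the only binary outputs.

## Problem sizes

Tests and the demo run at deliberately small scale — hundreds of loci,
tens of samples per population, hundreds to a few thousand trees, 1–5 EM
restarts — sizes at which every recovery property above is already stable
and the full suite completes in about a minute.

## Known limitations

* The AIC binning rule is a reconstruction (thresholds exposed; see above).
* Unsupervised EM shrinks extreme ancestry proportions slightly when
  ancestral panels are small; the supervised option removes this at the
  cost of assuming panel purity.
* The forest proximity of the out-of-bag-only variant uses many fewer tree
  pairs and is noisier at small tree counts.
* Multi-allelic θ treats alleles as independent indicators (the standard
  multi-allelic extension); no haplotype-distance AMOVA is attempted.
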