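# Methods

This note documents the models, conventions and design choices behind
the package, and what the synthetic-cohort tests do and do not
establish about real data.

## Rarefaction and alpha diversity

Sequencing effort is equalized by subsampling each sample's counts
without replacement (multivariate hypergeometric draws) to a common
depth `rarefaction_depth` (default D = 26,185 reads), repeated
`n_rarefactions` times (default R = 10) with sub-seeds spawned
deterministically from the master seed. Samples below D are dropped,
not rescaled — rarefaction semantics, not library-size normalization.
Every metric downstream of rarefaction is the mean over the R draws;
the number of draws is a variance knob, and the suite checks that
doubling R moves the averaged metrics by less than the across-draw
standard error.

Shannon diversity is computed in bits (log base 2, the historical
QIIME-1 convention); Pielou evenness J = H / log₂S is base-invariant.
Faith PD is root-inclusive: the branch length of the minimal subtree
connecting the present tips *and the root*, so a single-tip community
has PD equal to its root-to-tip path length. Root handling changes
values, so the convention is fixed and tested. J is undefined (NaN)
for single-taxon samples.

## Phylogenetic beta diversity

Both UniFrac variants are computed on a dense edge-incidence matrix
built in one postorder pass (edges × taxa indicator plus branch-length
vector), which turns all per-pair sums over edges into matrix products.
Unweighted UniFrac is unique-over-covered branch length on
presence/absence; weighted UniFrac is the *normalized* variant, with
the abundance-weighted edge differences divided by
Σⱼ dⱼ (p_Aj + p_Bj) over tip-to-root depths dⱼ, so values live in
[0, 1]. Distances are averaged over the rarefaction ensemble and the
ordination is computed once on the averaged matrix.

PCoA is classical metric scaling: double-center −½D², eigendecompose,
scale eigenvectors by √λ. Axes with negative eigenvalues (non-Euclidean
input) are reported but dropped from the coordinates; each retained
axis is sign-fixed so its largest-magnitude coordinate is positive,
making ordinations reproducible across runs.

The sample-type effect on community composition is tested on PC1 with
a linear mixed model (fixed site effect, random subject intercept)
fitted by maximum likelihood and compared against the
intercept-plus-random-intercept null by a likelihood-ratio chi-square
with (number of sites − 1) degrees of freedom. The LRT was chosen as
self-contained and asymptotically equivalent to the Satterthwaite-type
approximations common in mixed-model software for this balanced
design; a singular fit (zero between-subject variance) falls back to
an OLS likelihood ratio with a warning. The null calibration of this
test (uniform p under no site effect) is part of the suite.

The Mantel test uses the Pearson correlation of off-diagonal entries,
permutes subject identities (rows and columns jointly), and reports
p = (1 + #{|r_perm| ≥ |r_obs|}) / (1 + n_perm), two-sided. For the
nasal-vs-oral contribution comparison, matrix A is the inter-subject
unweighted UniFrac computed on each subject's BB taxa also present in
NB, matrix B the same on BB taxa also present in OW, restricted to
subjects with nonempty sets in both constructions. The published
description of this construction is ambiguous; this reading is one of
several defensible ones and is isolated in a single function.

## Shared-taxon partitioning

Presence is defined on a single canonical rarefaction (the first
ensemble member) so that detection effort is equal across samples; a
raw-count alternative is exposed. "Exclusively shared between IS and
BB" means present in exactly {IS, BB} among the sites that subject
has. Region sizes partition each subject's detected taxa exactly
(conservation is asserted). Shared-genus frequency distributions
retain a genus when ≥ `shared_subject_frequency_threshold` (default
20%) of a group's subjects carry ≥ 1 OTU of that genus in the region.
Genus-profile correlations are Pearson on untransformed relative
abundances over the union of detected genera (a log-ratio alternative
was considered and left out: the reference analyses name plain
Pearson).

## Dominance and clinical associations

"Dominated by genus g" means g is the argmax of genus relative
abundance, with no minimum-share threshold; exact ties break
lexicographically and are flagged. This depends only on relative
abundance, so calls are invariant to count rescaling.

Cytokines below the limit of detection are imputed as half the
minimum detected value of that analyte; analytes detected in fewer
than `detection_subject_fraction` (default 20%) of subjects are
dropped before any scan.

The association scan computes Spearman correlations between prevalent
(≥3% relative abundance in at least one sample of a site) genera and
clinical covariates within one subject group. Benjamini–Hochberg
correction is applied within each specimen type's scan by default:
each sample type forms its own family of hypotheses, matching how
per-site association panels are interpreted and keeping the family
size commensurate with the reference analyses; a pooled-scan option
(`fdr_scope="all"`) exists. Flags use q ≤ `fdr_q_assoc` (default 0.2).

## Three-model differential abundance

Per taxon, three count regressions with log link, binary group
covariate and log-depth offset are fitted by maximum likelihood
(L-BFGS-B on the exact likelihoods, with a warm restart of the
zero-inflated fit from the negative-binomial solution): Poisson,
NB2 (Var = μ + αμ²), and ZINB with a constant logit-linked
zero-inflation probability π. The fits are fixed-effects: each subject
contributes one sample to a site-stratified scan, leaving no
replication for a random intercept to absorb. The lowest-AIC converged
fit is selected (ties to the simpler family), β₁ is tested by Wald z
from the numerical Hessian, and BH correction runs across taxa with
flagging at q < `fdr_q_da` (default 0.10). Taxa present in fewer than
10% of samples are excluded before fitting — sparse taxa destabilize
the zero-inflation parameter. The in-house likelihoods are
cross-checked against statsmodels' GLM, NegativeBinomial and
ZeroInflatedNegativeBinomialP on fixed datasets in the test suite.

Degenerate inputs: all-zero taxa are skipped; complete separation
(a taxon absent from one group) drifts β₁ to the ±25 box bound with a
large Wald SE, which correctly yields a non-significant but recorded
result. Parameter boxes (intercept [−40, 15], |β₁| ≤ 25, log α and
logit π in ±12) keep the optimizer finite without binding in
well-posed problems.

## The synthetic cohort generator

The generator emulates the study design it stands in for: 22 + 12 + 11
subjects (AA/ANA/HC), BB + IS + OW for all, NB for an 18 + 3 + 6
subset; sequencing depths log-normal above the rarefaction floor so no
sample is lost at rarefaction.

Communities come from a three-pool source/mixture model. A base
composition is laid down per pool (oral, nasal, lung-specific) over a
genus-structured taxon roster; each subject draws personal pool
realizations from Dirichlets around those bases (concentrations 40 /
25 / 15 — lower concentration, more inter-subject variability). True
site compositions are OW = oral; NB = nasal with an imposed dominance
state (Corynebacterium-dominated with probability 0.5 in AA and 1.0
in ANA/HC; Moraxella-dominated only in AA, probability 1/6; imposed
dominant-genus mass uniform in [0.5, 0.8]); BB = a mixture of the
three pools (AA weights 0.835 / 0.045 / 0.12) after a per-subject
bronchial retention step that keeps each oral taxon with probability
0.4 (niche filtering — this is what places BB richness between NB and
OW/IS) and a Prevotella enrichment factor of 1.8 (bronchial niche
selection); IS = 0.45·OW + 0.55·BB (salivary admixture during sputum
induction). Observed counts are Dirichlet-multinomial around the true
composition (concentration 150) at the sampled depth.

The phylogeny is a two-level random coalescent: within-genus clades
(scale 0.3; 0.12 for the nasal genera, whose communities are kept
branch-length-sparse so that nasal-vs-bronchial UniFrac contrasts are
stable across tree realizations) joined by a cross-genus coalescent
(scale 0.4). Genus identity is by clade, so genus-level collapse is
meaningful on synthetic data, and a few OTUs carry family-only
taxonomy to exercise the collapse fallback labels.

Clinical covariates carry planted links on a standardized
logit-abundance scale: BAL (and sputum/blood) eosinophil measures rise
with nasal Moraxella (slope 1.8, Gaussian noise SD 1.0 — observed
Spearman rho ≈ 0.85 at n = 18, on the strong side of the plausible
range so that an 18-subject scan recovers the link reliably), and
pro-inflammatory BAL cytokines IL-6/IL-7/IL-21 fall with nasal
Corynebacterium (slope 1.4). A 21-analyte cytokine panel includes ten
analytes generated below their detection limits in most subjects, so
the half-LOD imputation and the 20%-detection filter are exercised
(11 analytes survive, as in the emulated assay). Five
Staphylococcus-analog OTUs are 4-fold enriched in AA nasal
communities, and Haemophilus-analog lung-pool OTUs are boosted in AA
bronchi, planting differential-abundance and exclusive-sharing
signals. Everything planted is recorded in a GroundTruth sidecar the
pipeline never reads.

All randomness flows from one master seed through named SeedSequence
child streams (tree, pools, subjects, counts, clinical), so cohorts
are bit-reproducible and schema-stable across seeds.

**What the generator does not model:** PCR/chimera artifacts,
contamination, compositional read-level noise beyond
Dirichlet-multinomial, longitudinal structure, covariate confounding
(age/sex are independent noise), or realistic phylogenetic signal in
pool membership beyond the genus-clade construction. Passing recovery
tests therefore show that the pipeline detects the planted structure
under idealized sampling — not that real airway data contain such
structure, nor that effect sizes estimated on real data would be
unbiased.

## Test and acceptance problem sizes

The replicate-based checks run 20 default-parameter cohorts (300 taxa,
162 samples each) through rarefaction, UniFrac, partitioning and the
association scan; the differential-abundance calibration uses 3
replicates of 1000 null taxa plus one 950-null/50-planted power scan
at the cohort's group sizes (11 vs 22) and depth distribution; the
mixed-model and Mantel null calibrations use 120–150 small synthetic
replicates. These sizes give stable Monte-Carlo assertions (3-standard-
error bands plus discreteness allowances for permutation p values)
while keeping the default suite fast.
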