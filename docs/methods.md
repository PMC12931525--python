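# Methods

`rhizodyn` re-implements, as a tested pipeline, the statistical machinery of
a rhizosphere study design: five ordered floral stages (TB, TIB, TFB, TS,
TF; three replicates each), grouped into a flowering phase FS = {TB, TIB,
TFB} and a senescing phase SS = {TFB, TS, TF}. TFB belongs to both phases,
so each phase-level analysis sees 9 of the 15 samples. This note records
the models, the defaults that matter, and the design decisions taken where
the procedure was genuinely open.

## Differential metabolites (DAMs)

A metabolite is differentially accumulated between two stage groups when
its PLS-DA variable importance in projection (VIP) is strictly greater
than 1 and |log2 fold change| >= 1. Fold change is the ratio of group
means of raw peak areas, B over A in the stated comparison direction; a
zero group mean is replaced by half the smallest positive value in the
table (logged per occurrence). The discriminant fit is a two-component
PLS-DA on autoscaled variables (sklearn's NIPALS engine), with

VIP_j = sqrt( p * sum_a[ s_a (w_ja/||w_a||)^2 ] / sum_a s_a ),
s_a = q_a^2 t_a' t_a,

which guarantees mean(VIP^2) = 1. This is an approximation of the
orthogonal variant (OPLS-DA): the VIP>1 screen is insensitive to the
orthogonal signal filtering and no orthogonal hyperparameters are
standard. The default comparisons are the consecutive stage pairs within
each phase plus the within-phase skips (TB-TIB, TIB-TFB, TB-TFB; TFB-TS,
TS-TF, TFB-TF). The fold-change direction (B over A) and the
pseudo-value policy are configuration, not science; both are recorded in
the output metadata.

## Temporal profiles

Short time-series clustering follows the classic model-profile recipe:
enumerate all (2c+1)^(T-1) unit-change candidate profiles (defaults T=5,
c=1, so 81 candidates), select m=20 mutually dissimilar model profiles by
greedy max-min distance (distance 1 - Pearson of profile values; a
constant vector correlates 0 with everything; selection starts from the
profile with the largest summed |unit change| and breaks all ties by
lowest profile id, so it is fully deterministic), assign each series - as
log2 ratios against its first time point - to the most correlated
profile, and test per-profile over-representation against within-series
time-order permutations with a Binomial(n_series, expected/n) upper tail
and Bonferroni correction over the m profiles. Stages are treated as
equally spaced ordinal time points; the real inter-stage durations in
days are deliberately not used, matching standard usage of the method.

## Diversity

Chao1 is the bias-corrected estimator S_obs + f1(f1-1)/(2(f2+1)) (defined
even when doubletons are absent) and requires integer counts; "Simpson"
is the Gini-Simpson complement 1 - sum p_i^2 - the common
ecology-package default; the convention is stated because sources often
leave it implicit. Both are computed on raw counts (no rarefaction).
Bray-Curtis and weighted UniFrac are computed on per-sample relative
abundances; UniFrac is the normalized variant
sum_b l_b |p_Ab - p_Bb| / sum_b l_b (p_Ab + p_Bb), so both distances live
in [0, 1] (verified against scikit-bio to machine precision). PCoA uses
Gower double-centering of -D^2/2; negative eigenvalues are dropped from
the variance shares. PERMANOVA computes the usual pseudo-F from the
distance matrix, with seeded label permutations and
p = (1 + #{F_perm >= F_obs}) / (1 + n_perm), or an exhaustive mode that
enumerates every distinct label arrangement (for tiny designs such as
3 + 3, where the permutation p has the exact value k/20).

## Co-occurrence networks

Taxa are filtered in two steps on relative abundances: mean relative
abundance >= 0.01% and prevalence >= ceil(n_samples/6). All remaining
taxon pairs are tested with Spearman correlation (average ranks for
ties); edges require |rho| > 0.7 and Benjamini-Hochberg q < 0.05 across
all tested pairs. Topology reports nodes (taxa with >= 1 edge), links,
average degree 2L/N, diameter of the largest component, average local
clustering (degree<2 nodes contribute 0), and relative modularity

RM = (M_obs - <M_rand>) / <M_rand>,

where M_obs is greedy modularity (deterministic; Louvain available with a
fixed seed) and <M_rand> the mean modularity of 100 Erdos-Renyi G(N, L)
graphs (a degree-preserving rewiring ensemble is available as an option).
This normalization is the only one consistent with published RM values
well above 1, which raw modularity (<= 1) cannot produce; the choice is
recorded in the topology output.

## Stability and keystones

Random-removal robustness is the fraction of original nodes that keep at
least one link after deleting round(fN) random nodes, averaged over
replicates and summarized by the OLS slope of robustness on f (the
giant-component fraction is an alternative statistic, available by
config). Natural connectivity is ln(mean exp(lambda_i)) over adjacency
eigenvalues, computed exactly - the networks here have at most a few
thousand nodes. Targeted attacks remove nodes one at a time (identified
keystones first, then remaining nodes by degree; plain degree order as
fallback when no keystones exist) and track natural connectivity, the
default y-axis statistic for the attack regression since the published
convention does not name one. Keystone classification uses the
within-module degree z-score Zi (z over the node's module members; Zi = 0
for a zero-spread module) and the among-module participation coefficient
Pi = 1 - sum_s (k_is/k_i)^2 with the classic cutoffs Zi > 2.5 and
Pi > 0.62; isolated nodes get Pi = 0. Non-peripheral nodes are
"keystones".

## Assembly null models

For every sample pair the pipeline computes the abundance-weighted beta
mean nearest taxon distance (betaMNTD; a presence/absence variant is
available by flag), its z-score betaNTI against n_null = 1000 (default)
taxon-label shuffles of the patristic matrix (rows and columns permuted
jointly; verified against picante's comdistnt to 1e-9), and RCbray - the
rescaled rank of the observed Bray-Curtis within a null that preserves
each sample's richness and total count, drawing species without
replacement by metacommunity occurrence frequency, seeding one individual
per drawn species and allocating the remainder multinomially by
metacommunity relative abundance. Processes follow the standard
thresholds: heterogeneous selection (betaNTI > +2), homogeneous selection
(betaNTI < -2), then dispersal limitation (RCbray > +0.95), homogenizing
dispersal (RCbray < -0.95), else undominated. Pairs whose null has zero
spread raise an explicit error rather than returning 0: a zero-spread
null arises exactly when the two samples have identical taxon membership
(shared taxa keep distance zero to themselves under any relabeling), and
a silent 0 would masquerade as "no signal". Of the two published
retention criteria for this analysis, only "abundance >= 1 in at least
two samples of a group" is enforced; the other ("present in at least one
sample and abundant in another") is implied by it and adds nothing.
Metabolite-betaNTI regressions use OLS of betaNTI on a per-pair
predictor, |a_i - a_j| by default (pair mean available), with two-sided
slope p-values; the per-pair difference construction is symmetric in pair
order by design.

Null-model tests and scenario-recovery runs use n_null = 200 (and the
type-I-error calibrations 99 permutations over 500 replicates); these
problem sizes keep the null-distribution estimates stable at the tested
effect sizes while keeping the default runs small.

## Integration

The Mantel test correlates the upper triangles of the community
Bray-Curtis matrix and the metabolite Euclidean matrix (computed on
per-metabolite z-scores, so unit changes cancel), with a joint
row/column permutation null and a one-sided (greater) p. The
metabolite-OTU network keeps pairs at |rho| > 0.7 with raw p < 0.05 -
without FDR, unlike the microbial network; the asymmetry follows the two
analyses' differing conventions and is intentional.

## Synthetic data

The generators emulate the statistical structure the analyses assume, not
the chemistry or sequencing behind the real data:

- **Tree.** A two-rate pure-birth tree, height 1: a base Yule tree plus
  one recent 12-tip radiation of relative height 0.08 replacing a random
  tip. Plain Yule trees at n = 100 are too "tippy" (within-clade vs
  tree-wide patristic contrast only ~2x) for any phylogenetically
  clustered community to stand out against the taxon-shuffling null; real
  16S phylogenies always carry dense genus-level radiations, which is
  what conserved habitat filtering acts on. The birth process is run
  slightly past the last speciation so every branch length is strictly
  positive.
- **Communities.** 5 stages x 3 replicates, multinomial counts at an
  expected depth of 20,000 per sample. Habitat filtering weights taxon i
  in sample s by exp(-(trait_i - E_s)^2 / (2 sigma^2)). Heterogeneous
  selection evolves the trait by Brownian motion on the tree (variance 1,
  tip-standardized) and separates the two stage-group environments at
  +/-1 with sigma = 0.3 - a ~6.7 sigma separation. Homogeneous selection
  filters on a perfectly conserved niche trait - patristic proximity to
  the focal lineage anchoring the tree's tightest 14-neighborhood - with
  50% per-sample pool dropout: high turnover among close relatives is
  what gives betaNTI < -2 its leverage, whereas a shared Brownian-trait
  optimum selects a phylogenetically incoherent set (every clade crosses
  any E) and produces no signal. Dispersal limitation gives every sample
  an independent random 40% species pool with lognormal abundances and no
  trait filter; drift samples one shared lognormal metacommunity at low
  depth (1,000 in the tests). All selection regimes add a small relative
  abundance floor (1e-5), lognormal jitter (sd 0.5; 0.3 for the
  homogeneous regime) and a random 5% per-sample pool dropout so that no
  two samples ever share identical membership - identical membership
  makes the betaMNTD null degenerate, in this implementation and in the
  reference one alike.
- **Metabolome.** Per-stage log2 means follow five unit-step archetypes
  (full-bloom peak with rebound, dip-recover, rise-plateau-fall, linear
  increase, W shape) with multiplicative lognormal noise at CV 0.2 and
  lognormal base peak areas around 1e6; planted differential metabolites
  ride on a flat archetype and multiply one stage's samples by
  2^(log2 effect), with +/-2 the default planted effect.
- **Fixture bundle.** One coherent four-file dataset combining
  heterogeneous-selection-structured taxa, three planted 8-taxon
  co-occurrence modules (Gaussian copula of log expected abundance,
  within-module latent rho = 0.8, between-module 0; the module factor is
  standardized to exact unit sample variance and taxon noise is
  orthogonalized against it, so the realized correlation sits at the
  planted value instead of fluctuating with the factor draw), and six
  OTUs whose expected abundance is proportional to a designated
  metabolite's per-sample abundance. Only the selection block is
  normalized per sample; the modular and coupled blocks get global
  scales (average per-sample mass 0.15 and 0.10). Normalizing the module
  block per sample would put the planted common factor into the
  compositional denominator and cancel the very correlations the fixture
  plants.

What the generators do **not** emulate: sequencing error and chimeras,
compositional biases of amplification, batch effects, platform-specific
peak drift, and realistic taxon-abundance distributions fitted to any
particular soil. Passing recovery tests therefore show that the
statistics detect the structures they target at realistic sizes and
noise levels - not that the pipeline's thresholds are optimal for any
particular real dataset.

## Known limitations

- At the planted module correlation (latent rho = 0.8) and n = 15
  samples, the sampling distribution of Spearman's r_s (true
  rho_s = (6/pi) asin(0.4) ~= 0.786) puts only ~76% of within-module
  pairs above the |rho| > 0.7 edge threshold; within-module edge recall
  in the mid-to-high 70s is the mathematical ceiling of that design, not
  an implementation defect.
- betaNTI at a 100-taxon pool has an intrinsic magnitude ceiling (the
  joint relabeling correlates all nearest-taxon minima within a null
  draw), so per-pair |betaNTI| rarely exceeds ~4; conclusions about
  selection strength should rest on the classified shares, not the raw
  z-values.
- The exhaustive PERMANOVA mode enumerates all label arrangements and is
  only intended for tiny designs (<= ~10 samples).
- The pipeline treats the stage factor as the only design variable;
  block/covariate adjustment (e.g., for batch) is out of scope.
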