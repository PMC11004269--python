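# Methods

`asvnet` analyses cross-domain (bacteria + fungi) microbial co-occurrence
from ASV count tables: abundance/prevalence screening, Spearman edge
inference, a topology panel, spectral stability under random node removal,
Zi–Pi keystone cartography, and the treatment-effect statistics that usually
accompany such a study (alpha/beta diversity, ANOVA with LSD letters,
Pearson panels, LMG relative importance). Because the motivating study type
deposits no raw data, the package ships a synthetic-data generator that
emulates its design and provides ground truth for every downstream stage.

## The emulated study design

The default `StudyDesign` mirrors a four-level phosphorus-addition gradient
(P0–P3, control first) with three field replicates, i.e. 12 samples. The
retained community is 505 bacterial and 87 fungal taxa — the scale of a
published cross-domain network under these conditions — on top of 2 000
rare background taxa destined to be removed by the screen. Sequencing depth
defaults to 80 000 reads per sample (≈10⁶ reads per domain over 12 samples,
matching the read budget such studies report).

Per-treatment effects on soil covariates and plant traits are multiplicative
shifts of control-level baselines. The non-unit defaults reproduce the mean
ratios of the emulated experiment — e.g. available P at 1.58×, 1.63×, 2.38×
control (percent increases 58.02–137.61 %), stem number up to 1.55×. TP, TN
and TC baselines are plausible arid calcic-soil values chosen here (0.60,
0.80, 15 g kg⁻¹); TN and TC carry no treatment effect, consistent with the
"no significant effect" finding they emulate. Replicate noise is
multiplicative Gaussian with CV 5 % (soil) and 3 % (traits), matching the
order of the reported standard errors. By default no taxon receives a
treatment effect, so community composition is null with respect to
treatment — mirroring the emulated finding that the P gradient left alpha
and beta diversity unchanged.

## Count model

Counts follow a lognormal–multinomial model: taxon *i* in sample *s* has
latent log abundance `log w_i + σ g_is` (σ = `dispersion`, default 0.6) and
each sample's reads are a single multinomial draw of the configured depth
over the softmax of latent abundances. The data are therefore compositional
and overdispersed. Retained-taxon base weights are drawn narrowly
(Uniform 1.6–2.0 in relative units) so that every retained taxon holds
> 0.1 % of total reads with margin, while background weights are 30–400×
smaller; this makes the abundance screen's ground truth deterministic.

**Planted modules.** Each `ModuleSpec` couples its members to a shared
latent factor with loading chosen via the Gaussian-copula relation
`r = 2 sin(π ρ_s / 6)`, so the members' latent rank correlation matches
`latent_correlation` (default 0.99). Half the non-hub members are
anti-coupled by default (`negative_fraction = 0.5`), producing negative
co-occurrence edges of equal strength. The factor itself is not an iid
normal draw: it is the set of evenly spaced standard-normal quantiles
assigned to samples in random order — an environmental/biotic *gradient*.
With only 12 samples, an iid factor occasionally clumps into near-ties,
which carries no rank information and produces "dead" modules that no
analysis could recover; the spread-quantile gradient removes this artefact
while keeping the factor marginally standard normal. Two caveats follow:
(1) compositional closure still perturbs ranks (the per-sample normaliser
has sd ≈ 0.2 log-units under the default design), so realized count-level
rank correlations sit slightly below the latent target; (2) if a single
module holds most of the community mass, closure cancels its own factor —
module mass fractions should stay modest (the defaults use 8 modules of
~74 taxa each, ≈12 % of mass apiece).

**Planted hubs.** A hub must end up the most-connected member of its
module. Pinning a hub to the latent factor is *not* sufficient: closure
displaces the whole cloud of member rank-profiles away from the factor, and
a factor-pinned taxon loses edges to members that drift with the closure.
Hubs are therefore planted as followers of the module's *realized*
share-level consensus — the mean sign-corrected standardized log-share of
the non-hub members — plus 2 % idiosyncratic noise, at 8× the abundance of
an ordinary member (dominant taxa; the higher depth also suppresses their
count-level rank noise). Because planting more-abundant hubs itself shifts
the closure, the consensus is recomputed once under the updated closure
(two fixed-point passes). Under the defaults, planted hubs reach the top
decile of within-module Zi in ≈97 % of cases; the residue reflects genuine
sampling noise at n = 12.

All randomness flows from `StudyDesign.seed` through named
`numpy.random.SeedSequence` children, so identical designs give
bit-identical tables.

**What the generator does not emulate:** sequencing error, chimeras and
primer artefacts (the tables model the post-denoising feature table);
taxon–environment feedbacks; phylogenetic correlation of abundances;
zero-inflation beyond what the multinomial induces. Passing tests therefore
certify the *analysis machinery* and its statistical calibration, not the
fidelity of any particular real soil community.

## Screening and edge inference

The screen keeps taxa whose grand-total relative abundance strictly exceeds
0.1 % **and** which are present (count > 0) in strictly more than 60 % of
samples. The 0.1 % rule is interpreted as a relative-abundance floor
(`total-proportion` mode): applied to a realistic table it yields
retained-community sizes of a few hundred taxa, the scale cross-domain
network studies report, whereas taking the top 0.1 % of the taxon *list*
would leave a handful of taxa. The literal list-fraction reading remains
available as `top-fraction` mode. The screen is idempotent: removing
below-threshold taxa only increases the survivors' relative abundances.

Edges are Spearman rank correlations over all retained taxon pairs, with
average ranks for ties and two-sided p-values from the t-approximation on
n − 2 df. An edge is kept iff ρ² > 0.9 (i.e. |ρ| > 0.9487) and p < 0.05.
With 12 samples the p-threshold is redundant given the ρ² threshold — any
|ρ| > 0.9487 at n = 12 has p ≪ 0.05 — but both are applied as configured.
No multiple-testing correction is applied by default;
Benjamini–Hochberg is available (`correction="BH"`). Taxa constant across
samples are excluded with a warning (ρ undefined). Correlations may be
computed across all samples or within one treatment's samples
(`samples="all" | "treatment"`); with 3 replicates per treatment the
within-treatment option is below the 5-sample floor and is refused, which
is itself informative about what a 4 × 3 design can support.

## Topology panel

For a network with N nodes and E edges the panel reports edge/node counts
split by sign and domain plus: edge density 2E/(N(N−1)), average degree
2E/N, average shortest-path length over connected pairs (components
weighted by their pair counts; infinite distances never enter), and
Freeman centralizations

* degree: Σ(d_max − d_i) / ((N−1)(N−2));
* betweenness (unnormalized b): Σ(b_max − b_i) / ((N−1)²(N−2)/2);
* closeness: Σ(c_max − c_i) / ((N−1)(N−2)/(2N−3)), with closeness computed
  within each node's component as (c−1)/Σd and 0 for isolated nodes.

On disconnected graphs the closeness centralization can exceed 1; the
convention (per-component closeness, centralized over all nodes) is chosen
to avoid infinite distances and is stated with the output. Published
centralization values are not comparison targets, since platforms differ in
exactly these normalizations.

## Stability

Natural connectivity is λ̄ = ln((1/N) Σ e^{λ_i}) over eigenvalues of the
unsigned, unweighted adjacency matrix (edge signs are a property of the
correlation, not of walk redundancy), computed via `eigvalsh` +
`logsumexp`; it is 0 for an edgeless graph and non-decreasing under edge
addition. Robustness removes ⌊fraction·N⌋ uniformly chosen nodes (default
fraction 0.5), takes the ratio of the induced subgraph's natural
connectivity to the intact value, and reports mean ± SE over replicates
(default 100; isolated survivors stay in the subgraph). The decay curve
reports mean natural connectivity after removing 0, s, 2s, … nodes in
random order.

## Modules, Zi–Pi and keystones

Module detection defaults to deterministic greedy modularity maximization
(nodes pre-sorted for a stable tie-break); seeded Louvain is the
alternative. Module ids are renumbered by each module's smallest member so
partitions are comparable across runs. Zi is the within-module degree
z-score (population sd; Zi = 0 where a module has < 2 members or zero
spread) and Pi = 1 − Σ_m (k_im/k_i)², with Pi = 0 for isolated nodes. Edge
signs are ignored throughout, following common practice in network
cartography. Roles use strict thresholds: module hub Zi > 2.5, connector
Pi > 0.62, network hub both, peripheral otherwise — boundary values fall to
peripheral. The "network hub requires both thresholds" reading follows the
standard functional-cartography definition. Keystone summaries aggregate
non-peripheral taxa by default (a hubs-only selection is exposed), as
relative abundance per treatment at a chosen rank; rows sum to the
treatment's total keystone read share.

## Supporting statistics

* **ACE** (rare cutoff 10): standard coverage-based estimator; when every
  rare taxon is a singleton the coverage is zero and the Chao1 estimator is
  returned instead, mirroring common ecology-software behaviour.
* **Simpson** is reported as Gini–Simpson 1 − Σp²; values near 0.99 for
  diverse communities are only consistent with this orientation.
* **Rarefaction** uses the exact hypergeometric expectation
  E[S_m] = Σ_i (1 − C(N−N_i, m)/C(N, m)) in log space.
* **ANOSIM**: R = (r̄_between − r̄_within)/(n(n−1)/4) on average-tied ranks
  of the dissimilarities; p is the add-one permutation estimate
  (1 + #{R_perm ≥ R_obs})/(1 + n_perm), which is valid (conservative) by
  construction.
* **ANOVA + LSD**: one-way ANOVA, pairwise LSD t-tests on the pooled MSE,
  and a compact letter display built from the maximal cliques of the
  "not-significantly-different" graph — this guarantees exactly that two
  groups share a letter iff their pairwise p ≥ α. Percent changes are
  rounded half-up to 2 d.p.
* **LMG** relative importance averages incremental R² over all predictor
  orderings, computed over subsets with the standard combinatorial weights;
  exact enumeration is limited to 8 predictors. Shares are non-negative,
  order-invariant and sum to the full-model R².

## Problem sizes and numerical choices

The default end-to-end run (2 592 simulated taxa × 12 samples, ~175 000
correlation tests, ~590-node network) completes in a few seconds; test and
acceptance runs use 20–100 stability replicates and 99–999 permutations,
sizes at which every reported quantity is stable to well within its
statistical error. Natural-connectivity agreement with closed forms is
asserted at 1e−9; Zi/Pi and LMG against brute-force oracles at 1e−12 and
1e−10. Calibration suites (ANOSIM rejection rate, Pearson star rate) use
200–500 null datasets and 3σ binomial bands around the nominal 5 %.

## Known limitations

* With 12 samples and |ρ| > 0.9487, edge retention is a knife-edge
  decision; network-level quantities are reproducible under a seed but
  sensitive to sampling noise, and hub identification is partially
  luck-limited — as it would be in the real study design.
* The positive-edge share of simulated networks (~58–70 %) runs above the
  planted 50/50 coupling split because negative associations attenuate more
  under compositional count noise (mutually exclusive taxa take turns being
  rare, and rare counts carry noisier ranks). Real networks show the same
  detection asymmetry.
* The letter display is exact for the LSD criterion but, like all compact
  letter displays, is not unique; ties in means are broken by input order.
* NMDS ordination, RDA and compositionality-aware correlation methods
  (SparCC/SpiecEasi) are deliberately out of scope.
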