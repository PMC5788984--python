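# Methods

This note documents the models, conventions and numerical choices behind
`mitogeo`, in the order the pipeline runs.

## Data model and missing data

The unit of analysis is an alignment of equal-length mtDNA sequences (the
classic marker is ND4 plus adjacent tRNAs, 866 bp, and 866 is the default
sequence length throughout) with a sample table mapping individuals to a
lineage and to geographic group/subgroup labels. Only `A C G T` count as
observed; gaps, `N` and IUPAC ambiguity codes are missing, because mutation
steps must be countable without ambiguity. The default policy is complete
deletion: a column with missing data anywhere is excluded everywhere, which
pins one fixed site mask for every statistic (haplotype identity, S, π,
mismatch distributions) so that totals, subgroups and rarefied subsamples are
commensurable. Pairwise deletion is available where per-pair masks are
wanted. Internally coordinates are 0-based half-open; all reported site
positions are 1-based.

A consequence worth knowing: group-level indices are computed on the
*alignment-wide* mask by default (option `global_mask=False` re-masks per
subset). With dirty data the two conventions differ; the default keeps a
rarefied northern sample comparable with its total.

## Haplotype networks

The network is the minimum-spanning network: the union of all minimum
spanning trees of the complete inter-haplotype distance graph. An edge
(u, v, w) belongs to some MST iff u and v are in different components of the
subgraph of strictly lighter edges; processing weight classes in increasing
order with a union–find, collecting each whole tie class before merging,
yields exactly this set. Tie classes produce the reticulations seen in real
networks. Each retained link of w steps is expanded into w − 1 anonymous
latent nodes ("missing haplotypes") so that every drawn edge is one mutation
step; latent nodes carry no sequence reconstruction — they are display
placeholders. An optional integer step limit (in the spirit of the
statistical-parsimony connection limit) drops longer links and may
disconnect clusters; the full TCS 95%-probability machinery is deliberately
not implemented.

Star-likeness is summarized as (central node, fraction of degree-1 haplotype
tips at one step from the centre), the centre being the max-degree haplotype
node with ties broken by frequency then label.

## Diversity and rarefaction

S counts polymorphic usable columns; π is mean pairwise differences per
usable site; Hd is Nei's estimator with the n/(n−1) correction; h_P counts
haplotypes confined to a single group of the partition. Rarefaction draws
`target_n` individuals without replacement (default: the smallest group of
the partition), recomputes all indices, repeats `reps = 5` times (the
classic protocol) and averages. One master seed spawns independent
per-repetition streams (`numpy.random.SeedSequence`), so results are
reproducible and repetitions are independent. Report rounding mirrors the
conventional table layout (Hd to 3 d.p., π × 10³ to 2 d.p.); full precision
is kept in the objects.

## Sudden-expansion mismatch model

For a pair of genes in a haploid population whose scaled mutation parameter
jumped from θ₀ to θ₁ at τ mutational units before present (θ = 2Nᵤe·u·L,
τ = 2·u·L·t), conditioning the pair's coalescence time on the epoch gives the
exact closed form

    F_i = Fhat_i(θ₁)·P[Gamma(i+1) ≤ x] + e^{−x} Σ_{j≤i} Fhat_j(θ₀)·τ^{i−j}/(i−j)!

with Fhat_i(θ) = θ^i/(1+θ)^{i+1} and x = τ(1+θ₁)/θ₁. Both pieces are finite
sums — no infinite-series truncation is involved; the only truncation is the
reporting cut at `i_max`, whose missing tail mass is exposed (and optionally
renormalized). The convolution term is evaluated in plain arithmetic because
`exp(m·log τ − log m! − x)` is bounded by the Poisson pmf (x ≥ τ), so no
overflow is possible. The equilibrium limit θ₀ = θ₁ and the τ = 0 limit are
exact identities of this form and are tested to 1e-10.

Fitting minimizes the SSD between observed relative mismatch frequencies and
F_i over (τ, θ₀, θ₁ − θ₀) with L-BFGS-B from a small multistart grid
(moment-based τ starts × θ grid) followed by a Nelder–Mead polish; bounds are
τ ∈ [0, 2·i_max], θ ∈ [0, 10⁴] with θ₀ ≤ θ₁ by parametrization. A histogram
with all mass at zero returns a flagged degenerate fit. Goodness of fit is a
parametric bootstrap: `n_boot = 100` coalescent samples of the same n and L
under the fitted demography, each refitted with the same multistart grid
(bias symmetry between observed and replicate SSDs), p = fraction of
replicates with statistic ≥ observed.

Raggedness is the sum of squared successive differences of the relative
frequencies padded with zeros at *both* ends (the uniform 5-class histogram
scores 0.2² + 0 + 0 + 0 + 0 + 0.2² = 0.08). This symmetric-padding
convention differs from the original formulation, which omits the leading
boundary term; observed and bootstrap values use the same convention, so
p-values are internally consistent.

The modality diagnostic counts local maxima after a 3-point moving average.
A 3-point smoother provably cannot separate two modes one dip class apart
(a smoothed mode at class 0 adjacent to one at class 2 would require a
negative count), which matters exactly for the two-subcluster structure
whose centres are two steps apart: its pooled histogram is bimodal in the
raw counts but unimodal after smoothing. `MismatchHistogram.n_modes(smooth=False)`
exposes the raw count; the smoothed count is the default because simulated
expansion histograms are jagged and would otherwise be called multimodal.

## Neutrality tests

Tajima's D uses the 1989 constants; it is undefined (flagged) at S = 0. Fu's
F_S computes S′ = Pr(K ≥ k_obs) under the Ewens sampling distribution at
θ = k̄, with unsigned Stirling numbers of the first kind built by the
log-space recurrence (exact to ~1e-12 against rational arithmetic for
n ≤ 12); F_S = ln(S′/(1−S′)), +∞-flagged when k_obs = 1 or k̄ = 0.

P-values for both come from one simulation mechanism: a vectorized
infinite-sites constant-size coalescent that tracks, per replicate, the
number of mutations (S), the pairwise-difference mean (each mutation on a
branch subtending i of n leaves contributes i(n−i) discordant pairs), and
the haplotype count K (mutation-free leaf clusters sealed at their first
mutation). D's p-value is two-tailed at θ̂ = S/a₁ (replicates with S = 0
dropped); F_S's is Pr(F_S,sim ≤ F_S,obs) at θ = k̄. Default 10,000
replicates. Tajima's beta approximation is available via `method="beta"`.
Significance conventions follow the tools of the field: α = 0.05 for D,
α = 0.02 for F_S. Under neutral simulations (n = 30, θ = 5) the test's
type-I error measured over 1,000 replicates is ≈ 5%.

## Coalescent simulator

msprime drives all sequence-level simulation: haploid samples, one
non-recombining locus of L discrete sites, Jukes–Cantor mutations
(invariant sites written as `A`; real base composition is deliberately not
imitated). Time is in generations, Ne is haploid. The three-population
scenarios are pure splits with no post-split migration: two gradual
directions (the most recently founded population merges into its neighbour
at t1, the remaining pair into the ancestral population at t2) and a sudden
trifurcation at t1. Each population and the ancestral population has its own
Ne. t1 = t2 is accepted for the gradual scenarios and encoded as the exact
trifurcation it degenerates to. The sudden-expansion demography maps
(θ₀, θ₁, τ) onto sizes and a change time through an arbitrary internal
mutation rate; only the scaled parameters matter. Everything is
byte-deterministic given a seed.

## ABC scenario choice

Priors are uniform: Ne ∈ [10, 10⁴] (each of the four sizes independent),
split times ∈ [10, 10⁴] generations with (t1, t2) drawn as the exact
conditional t1 < t2 (two uniforms sorted), and the per-site mutation rate
uniform on [10⁻⁸, 10⁻⁶] (log-uniform optional). The summary vector holds,
per group: haplotype count, segregating sites, mean pairwise differences,
private segregating sites (segregating in the group, invariant in every
other); per group pair: pooled within-pair mean W, between mean B, and
F_ST = 1 − W/B clipped to [0, 1] (0 when B = 0).

Model choice standardizes the statistics by the reference-table mean/SD
(affine-invariance), takes the n_closest rows by Euclidean distance,
weights them with the Epanechnikov kernel, and fits a weighted multinomial
logistic regression (Newton iterations on the reference-class
parametrization, small ridge for separation robustness). Probabilities are
evaluated at the observed point; 95% CIs come from the delta method on the
regression's observed information. n_closest defaults to 1% of the table —
the acceptance fraction used with 3,000 of 300,000 rows at full scale —
floored at 300 rows so the local regression keeps more points than
parameters at desk scale; much smaller explicit values trigger an
instability warning. A scenario absent from the accepted rows is floored at
probability 0 with a warning.

Parameter posteriors use Beaumont-style local-linear adjustment: log
parameters regressed on the standardized statistic offsets with the same
kernel weights, residuals re-centred at the observed point, weighted
2.5/50/97.5 percentiles back-transformed. The adjustment can push draws
slightly outside the prior box (a known artifact of the method); values are
reported unclipped. Split times are additionally reported in years with a
generation time of 10 years (configurable).

At full scale the reference table would hold 300,000 rows per lineage
(100,000 per scenario under the even-split reading); the shipped experiments
use 5,000 rows per scenario with the 1%-fraction acceptance rule, which the
recovery tests show is already sufficient to identify the generating
scenario in ≥ 70% of pseudo-observed replicates for well-separated truths.

## Synthetic fixtures

The generators plant every variant at a previously unused alignment column,
which makes all step counts exact by construction: a star (one dominant
centre, singleton tips one step away), a two-refuge structure (exclusive
cluster cores exactly `inter_cluster_steps` apart, `n_shared` haplotypes
present in both groups, a dominant-core north versus an equifrequent south so
Hd(South) > Hd(North)), and a bimodal pair (two frequent centres exactly
`centre_distance` = 2 steps apart with singleton tips, members interleaved
across groups). Defaults (L = 866, star with 12 tips, 4–5-step core
separation, one shared haplotype, 2-step centre distance) mirror the
qualitative structure of the empirical lineages. What the fixtures do *not*
emulate: realistic base composition, recurrent mutation, within-cluster
frequency spectra from a real coalescent — so passing fixture tests
demonstrates correctness of the statistics and constructions, not power on
real data; the coalescent-simulation tests cover the stochastic side.

## Problem sizes used by the shipped experiments

Test-suite and acceptance-script runs use: 200 random toy alignments
(n ≤ 10, L ≤ 50) for oracle equivalence; C(6,3) enumeration against 1,000
rarefaction draws; 100 coalescent replicates (n = 50) for τ recovery; 1,000
neutral replicates (n = 30, θ = 5, 2,000-replicate null per test) for
calibration; 5,000 reference rows per scenario and 20 pseudo-observed
datasets (three groups of 25) for ABC recovery. These sizes were chosen so
each stochastic check has comfortable Monte-Carlo margins while the whole
suite stays desk-scale.

## Known limitations

- Single non-recombining haploid locus only; no diploid/autosomal mode, no
  recombination, no migration after splits, no median-joining networks, no
  Bayesian skyline.
- The mismatch model is the demographic (not spatial) expansion model.
- Scenario probabilities from local logistic regression are overconfident
  when the accepted set is small relative to the statistic dimension; the
  floor on n_closest mitigates but does not remove this.
- K (haplotype count) in the neutrality null engine assumes infinite sites;
  at very high θ·L finite-site recurrent mutation would lower real K
  slightly.
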