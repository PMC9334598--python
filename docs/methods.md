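# Methods

## The collapse model

`speciesdelim` performs Bayesian species delimitation under the
multispecies coalescent (MSC) using a threshold ("collapse") tree prior.
Let *T* be a binary rooted ultrametric time tree over *n* tentative
species, with leaf heights 0 and internal node heights
*h*<sub>*i*</sub>.  Given a threshold ε (tree-height units) and a
collapse weight ω ∈ [0, 1], each internal node contributes a
spike-and-slab mixture factor to the prior: a uniform spike density 1/ε
on [0, ε) with weight ω, or a branching-process slab factor above ε with
weight 1 − ω.  With *k* nodes below ε the joint density is

    f(T | θ, ε, ω) = (1 − ω)^(n−k−1) · slab(T | θ, ε) · (ω / ε)^k .

Taxa whose connecting path runs entirely through nodes below ε belong to
one species, so a posterior sample of trees induces a posterior over set
partitions of the taxa — all B<sub>n</sub> assignment hypotheses are
scored by a single MCMC run.  A node at exactly ε counts as slab-side
(not collapsed); this follows the piecewise definition of the mixture
rather than the spike's support description, whose boundary conventions
disagree — the choice only matters on a measure-zero set.

Three slabs are implemented (`speciesdelim.priors`):

* **Exponential** — per-node iid density λe^{−λ(h−ε)} on [ε, ∞).  This
  is the generative reading of the mixture and the only slab with an
  exact direct simulator, which makes it the reference model for
  detailed-balance testing.
* **Birth–death conditioned on an origin** — per-node factors
  λp₁(h)/Z with p₁(t) = r²e^{−rt}/(λ − μe^{−rt})², r = λ − μ, truncated
  and renormalised on [ε, origin].  Setting μ = 0 gives the Yule case;
  as the origin → ∞ the Yule case reduces *exactly* to the exponential
  slab, which the tests exploit.
* **Yule-skyline** — a pure-birth process whose birth rate varies over
  *E* equal-width epochs spanning [ε, root height] (the grid is
  recomputed at every evaluation so it tracks the moving root).  The
  epoch rates carry Gamma(α, β<sub>j</sub>) priors that are integrated
  out analytically: epoch *j* with *b*<sub>j</sub> births over
  *L*<sub>j</sub> lineage-time contributes
  β<sub>j</sub>^α Γ(α + b<sub>j</sub>) / (Γ(α)(β<sub>j</sub> + L<sub>j</sub>)^{α+b<sub>j</sub>}).
  Smoothing across epochs keeps the shape α fixed and sets
  β<sub>j+1</sub> = α(β<sub>j</sub> + L<sub>j</sub>)/(α + b<sub>j</sub>),
  i.e. the prior mean of epoch *j*+1 equals the posterior mean of epoch
  *j*.  Published accounts of the skyline marginal leave the smoothing
  normalisation open; this convention is stated here as the package's
  definition and is validated by sampler-vs-density consistency tests
  rather than by authority.  Lineage-time above ε counts each collapsed
  clade as a single lineage.

### Normalisation caveat of the mixture

The spike is a normalised density but the Yule-skyline slab is an
unnormalised product over the above-threshold subtree; its tree-space
normaliser depends on ω and on the tree size (for n = 2 it is exactly
1/2).  Consequently, under the *joint* density Beta-prior(ω) × f(T | ω),
the marginal of ω is tilted away from its Beta hyperprior, and the
marginal collapse probability of a node is not exactly ω.  This is a
property of the model as defined, not of the implementation.  Every
sampler in the package (MCMC and the importance resampler used for
truth draws) targets the same coded joint, which is what makes the
calibration studies consistent; this was verified empirically after an
earlier version drew ω from the hyperprior directly and showed a
systematic calibration offset in the singleton-cluster bins.

## MCMC

The sampler (`speciesdelim.mcmc`) is a Metropolis–Hastings chain over
(species tree heights and ranked topology, ω, and in likelihood modes
per-branch Ne and substitution scalars).  Operators:

* **ThresholdUniform** — the delimitation-specific kernel.  A fair coin
  picks a direction.  Lump: choose uniformly among nodes at or above ε
  whose children are both below, and redraw the height uniformly on
  (max child height, ε).  Split: choose among nodes below ε whose
  parent is at or above, redraw on (ε, parent height).  If the chosen
  direction has no eligible node the proposal is rejected.  The log
  Hastings ratio is log|E_fwd| + log len_fwd − log|E_rev| − log len_rev,
  with the reverse eligible set counted in the proposed state.  Lumping
  the root produces a state with an empty reverse set, so the ratio is
  −∞ and the move self-rejects; all-collapsed states remain reachable
  through the generic height operators.
* **Node-height shift** — uniform redraw within (max child, parent); an
  optional side-preserving mode confines the window to the node's side
  of ε (used to isolate ThresholdUniform in tests).
* **Root-gap and whole-tree scalers** — multiplicative moves with the
  standard log-Jacobian Hastings terms.
* **ω updates** — a logit-space random walk, plus a conjugate Gibbs
  draw from Beta(a + k, b + n − k − 1), ω's full conditional given the
  tree.
* **Height-multiset resample** — an independence-style move drawing all
  n − 1 heights iid from the tractable collapse proposal (spike w.p. ω,
  otherwise the Gamma-marginalised shifted exponential) and mapping them
  onto the fixed topology rank-for-rank; the Hastings ratio is the
  proposal-density ratio of the two multisets.  Acceptance is high
  because the proposal closely tracks the Yule-skyline target, and the
  move decorrelates *k* and the tree height in a handful of steps.
* **Ranked-topology resample** — the collapse priors depend on the
  height multiset only, so redrawing the ranked topology uniformly at
  fixed heights (coalescent-style pairing) is symmetric; it is an exact
  Gibbs move in prior-only mode and accepts on the likelihood ratio
  otherwise.  Without it, cluster supports would be conditional on the
  initial topology instead of marginal.
* In likelihood modes: per-branch Ne scalers, per-locus κ/ν scalers, a
  Dirichlet walk on base frequencies, and gene-tree node-height moves.

Likelihood modes: `none` (prior-only), `msc` (fixed gene trees;
Rannala–Yang MSC density), `msc_hky` (gene-tree heights sampled; MSC +
pruning likelihood).  In data modes the chain starts from a
single-linkage tree built on the minimum cross-species gene coalescence
times; single-linkage cophenetic distances never exceed the input
distances, so the start state satisfies every MSC constraint and sits at
the scale of the data (a prior-drawn start squashed below the smallest
coalescence can be separated from the posterior mode by a spike barrier
of order (ω/ε)^k that local moves cannot cross).

The chain is deterministic given a seed (one PCG64 stream, draws
consumed in schedule order), logs every `log_every` steps in a
BEAST-style scalar table plus a Newick tree log, audits cached against
recomputed posteriors every 1000 steps (tolerance 1e−8), and can extend
itself (doubling, up to 3 times) until the effective sample size of the
posterior column after a 50% burn-in exceeds a target (default 200).

## Synthetic data

`speciesdelim.experiment` generates complete replicates under the
model.  Defaults are the study conditions used throughout validation:
ε = 10⁻⁴ (substitutions-per-site scale), ω ~ Beta(1, 2), a 4-epoch
skyline with α = 2 and first-epoch rate b ~ Lognormal(−1.63, 0.2),
pairwise coalescent rates ~ Gamma(shape 100, rate 0.01) converted to
Ne = 2/rate (so typical Ne ≈ 2 × 10⁻⁴ in tree-height units),
relaxed-clock stdev S ~ Gamma(shape 5, scale 0.05) with mean-one
lognormal branch rates (a gene branch inherits the time-weighted
average of the species branches it traverses), and HKY parameters
κ ~ LN(1, 1.25), f ~ Dirichlet(10,10,10,10), ν ~ LN(−0.18, 0.6); 6
species, 2 samples each, 2 loci of 200 sites.  Two Gamma
parameterisations in this list are ambiguous in their published form:
the coalescent-rate β is read as a *rate* (the scale reading gives
Ne ≈ 2, absurd on a per-site scale) and the clock-stdev β as a *scale*
(the rate reading gives a mean stdev of 100).  Both are surfaced in the
config rather than hidden.

Species trees have no closed-form direct simulator under the
Yule-skyline collapse prior (the epoch grid depends on the root
height), so truths are drawn by sampling-importance-resampling: 2048
particles from the exponential-slab collapse proposal with the birth
rate marginalised under its Gamma prior (closed form), weighted by the
coded joint density, resampled as (ω, tree) pairs.  The particle count
quadruples once if the weight effective sample size falls below 50.
This sampler shares no kernels with the MCMC it is used to validate.

What the generator does *not* emulate: SNP ascertainment and biallelic
likelihood approximations, site-rate heterogeneity, non-extant samples,
migration/hybridisation, and linkage between loci.  Passing validation
therefore says the *inference machinery* is self-consistent under the
model, not that the model fits any particular real dataset.

## Validation harnesses

* **Coverage** (`well_calibrated_study`): R = 100 truths from the prior,
  each recovered by prior-only MCMC; the count of replicates whose true
  tree height, tree length and ω fall in the 95% HPD interval must lie
  in the central 95% band of Binomial(100, 0.95) = [90, 99].  HPD
  intervals are smallest-width contiguous windows over sorted samples
  (leftmost tie); ESS uses Geyer initial-positive-sequence truncation
  (the leading autocorrelation pair is always included, so strongly
  antithetic series can legitimately report ESS > N).
* **Cluster calibration**: pooled over the same replicates, every
  cluster appearing in any posterior sample is binned (20 bins) by its
  marginal support; a cluster is "true" if it appears exactly in the
  generating tree's partition at the generating ε.  Each non-empty bin
  gets a 95% Clopper–Pearson CI of the empirical truth frequency, which
  should cover the bin's nominal support (the mean support of its
  members); empty bins are reported as empty.  Pooling ignores the
  within-replicate correlation of cluster hypotheses, so the CIs are
  mildly anticonservative; per-replicate averaging is a noted
  alternative.  In prior-only mode supports concentrate below ~0.5 for
  6 taxa, so the upper bins are legitimately empty.
* **Negative control**: the same study with every Hastings ratio forced
  to zero (a deliberately broken sampler) collapses coverage far below
  the acceptance band, demonstrating the study's power.
* **Threshold sensitivity** (`epsilon_sensitivity`): one full inference
  per ε (the threshold enters the prior, not just the summary), with
  the MAP clustering tabulated per threshold.

Problem sizes were chosen at desk scale as the package's own study
conditions: 6-taxon trees, prior-only chains of 40k steps (thinned by
40, auto-extended to ESS > 200), R = 100.  Tree size is the one study
condition not fixed by the published description of the validation
design.

## Numerical choices and edge cases

* All densities are log-space; −∞ is a legal zero-density return (e.g.
  an MSC-incompatible gene tree), never an exception.
* 0·log 0 := 0 at ω ∈ {0, 1}; ω = 1 with any slab node (or ω = 0 with
  any collapsed node) gives −∞.
* Leaves are clamped to height 0 when branch-length arithmetic leaves
  |h| < 10⁻⁸·max(1, root); larger deviations are rejected as
  non-extant tips.
* Bell numbers use exact integer arithmetic (Bell triangle).
* Bayes factors use the 2·ΔlnML convention, which is the only factor
  consistent with the published SNP-delimitation table this package's
  arithmetic is checked against.
* HKY: the generator is normalised to one expected substitution per
  unit time before scaling by ν; gaps/N/? are missing data; pattern
  compression and per-node rescaling keep the pruning stable.
* The critical birth–death case λ = μ uses the 1/(1+λt)² kernel.

## Known limitations

* Gene-tree topology is never resampled (heights only, in `msc_hky`
  mode); joint gene-tree/species-tree inference at scale is out of
  scope.
* The birth–death collapse slab is evaluation-only (no direct
  simulator), and the skyline variant with death rates or incomplete
  sampling is not implemented.
* Marginal-likelihood estimation (path sampling) is not provided; the
  Bayes-factor helper only reproduces the arithmetic from given
  marginal likelihoods.
* The importance resampler is exact only in the particle limit; with
  2048+ particles on ≤ 8 taxa its weight ESS is large, and the
  calibration study — which would expose resampler bias — passes.
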