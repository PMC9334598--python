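# speciesdelim

Threshold-based Bayesian species delimitation under the multispecies
coalescent.

Given multilocus sequence data where every sample is (tentatively) its
own species, which samples actually belong together?  Enumerating
assignment hypotheses explicitly is hopeless — 46 samples already admit
B₄₆ ≈ 2.2 × 10⁴² set partitions — and testing them one at a time by
marginal-likelihood comparison costs one expensive run per hypothesis.
`speciesdelim` instead scores *all* partitions in a single MCMC run: a
spike-and-slab "collapse" prior over species-tree node heights lumps
samples whose divergence falls below a threshold ε into one species, so
the posterior sample of trees *is* a posterior over species
assignments.

The package is aimed at researchers studying species boundaries with
multilocus data (and at methods developers who want a transparent,
test-covered reference implementation of the machinery): it provides
the collapse tree priors, the MCMC sampler with the
threshold-crossing proposal kernel, a full synthetic-data generator,
posterior clustering summaries, and the well-calibrated validation
harnesses used to certify the sampler.

## The model

For a binary rooted time tree *T* over *n* taxa with internal node
heights *h*ᵢ (leaves extant at height 0), threshold ε > 0 and collapse
weight ω ∈ [0, 1], the collapse prior is the per-node mixture

```
f(T | θ, ε, ω) = (1 − ω)^(n−k−1) · f_slab(T | θ, ε) · (ω / ε)^k
```

where *k* is the number of nodes below ε, ω/ε is the uniform spike
density on [0, ε), and the slab is a branching-process density defined
above the threshold.  Three slabs are provided: a per-node exponential,
a birth–death process conditioned on an origin height (death rate 0
gives the Yule model), and the **Yule-skyline collapse** — a pure-birth
process whose epoch-wise Gamma-distributed birth rates are integrated
out analytically and smoothed across epochs, letting the speciation
rate vary through time with no extra sampled parameters.  Cutting every
sampled tree at ε yields a partition of the taxa; tallying partitions
across the posterior gives partition supports, per-cluster marginal
supports, and a pairwise co-species probability matrix.

The dedicated MCMC kernel, *ThresholdUniform*, slides one node height
across ε — lumping two clusters or splitting one without changing the
topology — with a Hastings ratio that accounts for the
direction-dependent eligible sets and window lengths.  See
`docs/methods.md` for the full model, operator and validation details.

## Worked example

Simulate a 4-species, 2-locus replicate from the generative model, then
re-infer the species boundaries from the gene trees under the
Yule-skyline collapse prior:

```python
import numpy as np
from speciesdelim import (
    ExperimentConfig, sample_experiment_from_priors, CollapseModel,
    run_mcmc, map_clustering, parse_newick,
)
from speciesdelim.priors import SkylineConfig

cfg = ExperimentConfig(n_species=4, n_loci=2, sites=200)
rep = sample_experiment_from_priors(cfg, np.random.default_rng(1))
print("true partition:", rep.true_partition.clusters)

model = CollapseModel(
    epsilon=cfg.epsilon,                      # 1e-4 substitutions/site
    slab="yule_skyline",
    sky=SkylineConfig(4, 2.0, rep.skyline_beta),
    likelihood="msc",
    genes=rep.genes,
    init_pops=rep.pops,
)
trace = run_mcmc(model, chain_length=20000, log_every=20, seed=1)
summary = map_clustering([parse_newick(t) for t in trace.trees], cfg.epsilon)
print("MAP clustering:", summary.partition.clusters)
print("support: %.3f" % summary.support)
```

Output:

```
true partition: (('sp1', 'sp4'), ('sp2',), ('sp3',))
MAP clustering: (('sp1', 'sp4'), ('sp2',), ('sp3',))
support: 1.000
```

The generating tree placed the sp1–sp4 divergence below ε = 10⁻⁴, so
those two tentative species are one; the posterior recovers exactly
that partition (here with support 1.000, i.e. every post-burn-in sample
agrees), while sp2 and sp3 remain distinct species.

The same workflow is available from the shell:

```bash
speciesdelim write-config run.yaml
speciesdelim simulate --config run.yaml --out sim/
speciesdelim infer    --config run.yaml --out out/     # trace.tsv, trees.nexus
speciesdelim delimit  --config run.yaml --out out/     # clusters.tsv, report.json
```

plus `validate-coverage`, `validate-calibration` and `sensitivity`
subcommands for the validation studies.  Every run writes a
`manifest.json` (config, seed, version) from which it can be
reproduced.

## Choosing the threshold

ε lives in the same units as the tree height, so its meaning changes
with the calibration: `convert_epsilon_units` translates between years,
millennia, millions of years and substitutions per site (given a clock
rate), and `epsilon_guidance` converts a known between-species pairwise
divergence into an upper bound — ε should be much less than half the
divergence, because both lineages contribute to the pairwise distance.
`epsilon_sensitivity` re-runs inference over a grid of thresholds and
tabulates how the MAP clustering responds.

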