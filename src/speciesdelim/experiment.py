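"""Full synthetic replicates drawn from the generative model.

A replicate is one draw of the study conditions: collapse weight omega
and first-epoch birth-rate hyperparameter from their hyperpriors, a
species tree from the Yule-skyline collapse (YSC) prior, per-branch
effective population sizes, optional relaxed-clock branch rates, MSC
gene trees and HKY alignments, plus the true partition at the
generating threshold.

Default hyperparameters are the generative model used throughout the
validation studies: epsilon = 1e-4, omega ~ Beta(1, 2), a 4-epoch
skyline with Gamma(shape 2, rate b) first-epoch birth prior and
b ~ Lognormal(-1.63, 0.2), pairwise coalescent rates ~ Gamma(shape 100,
rate 0.01) (so Ne = 2/rate), relaxed-clock stdev S ~ Gamma(shape 5,
scale 0.05), kappa ~ Lognormal(1, 1.25), f ~ Dirichlet(10,10,10,10),
nu ~ Lognormal(-0.18, 0.6).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .clock import gene_branch_rates, simulate_branch_rates
from .coalescent import PopSizeMap, simulate_gene_tree
from .hky import HKYParams, simulate_alignment
from .priors import SkylineConfig, sample_ysc_joint
from .tree import Partition, TimeTree, extract_clusters

__all__ = [
    "ExperimentConfig",
    "GeneReplicate",
    "Replicate",
    "sample_experiment_from_priors",
    "write_replicate",
    "read_replicate",
]


@dataclass(frozen=True)
class ExperimentConfig:
    """Hyperparameters of the generative model (defaults: validation-study values)."""

    n_species: int = 6
    epsilon: float = 1e-4
    omega_prior: tuple[float, float] = (1.0, 2.0)  # Beta(alpha, beta)
    skyline_epochs: int = 4
    skyline_alpha: float = 2.0
    #: lognormal (mu, sigma) hyperprior of the first-epoch gamma RATE b
    skyline_beta_lognormal: tuple[float, float] = (-1.63, 0.2)
    #: pairwise coalescent rate ~ Gamma(shape, rate); Ne = 2 / rate
    coalescent_rate_gamma: tuple[float, float] = (100.0, 0.01)
    relaxed_clock: bool = True
    #: stdev S ~ Gamma(shape, scale) of the mean-one lognormal branch rates
    clock_stdev_gamma: tuple[float, float] = (5.0, 0.05)
    kappa_lognormal: tuple[float, float] = (1.0, 1.25)
    freq_dirichlet: float = 10.0
    nu_lognormal: tuple[float, float] = (-0.18, 0.6)
    n_loci: int = 2
    sites: int = 200
    samples_per_species: int = 2
    #: particle count of the importance resampler used for YSC tree draws
    sir_particles: int = 2048

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ValueError("need >= 2 species")
        if not self.epsilon > 0:
            raise ValueError("epsilon must be > 0")


@dataclass
class GeneReplicate:
    """One locus: gene tree, sample map, alignment and substitution/clock params."""

    gene_tree: TimeTree
    mapping: dict[str, str]
    alignment: dict[str, str]
    hky: HKYParams
    branch_rates: dict[int, float] | None = None


@dataclass
class Replicate:
    """One full draw from the generative model, with the truth recorded."""

    config: ExperimentConfig
    omega: float
    skyline_beta: float
    species_tree: TimeTree
    pops: PopSizeMap
    clock_stdev: float | None
    species_rates: dict[int, float] | None
    genes: list[GeneReplicate] = field(default_factory=list)
    true_partition: Partition | None = None

    @property
    def epsilon(self) -> float:
        return self.config.epsilon


def sample_truth(
    config: ExperimentConfig, rng: np.random.Generator
) -> tuple[float, float, TimeTree, SkylineConfig]:
    """Draw (omega, skyline beta, species tree) and the skyline used.

    This is the tree-level part of :func:`sample_experiment_from_priors`,
    exposed separately for prior-only validation studies.
    """
    mu, sigma = config.skyline_beta_lognormal
    beta1 = float(rng.lognormal(mu, sigma))
    sky = SkylineConfig(config.skyline_epochs, config.skyline_alpha, beta1)
    labels = [f"sp{i + 1}" for i in range(config.n_species)]
    omega, tree = sample_ysc_joint(
        config.n_species, config.epsilon, config.omega_prior, sky, rng,
        labels=labels, n_particles=config.sir_particles,
    )
    return omega, beta1, tree, sky


def sample_experiment_from_priors(
    config: ExperimentConfig, rng: np.random.Generator
) -> Replicate:
    """Draw a complete synthetic replicate from the generative model."""
    omega, beta1, species_tree, _ = sample_truth(config, rng)

    shape, rate = config.coalescent_rate_gamma
    rates = {i: float(rng.gamma(shape, 1.0 / rate)) for i in range(species_tree.n_nodes)}
    pops = PopSizeMap.from_coalescent_rates(rates)

    clock_stdev = None
    species_rates = None
    if config.relaxed_clock:
        s_shape, s_scale = config.clock_stdev_gamma
        clock_stdev = float(rng.gamma(s_shape, s_scale))
        species_rates = simulate_branch_rates(species_tree, clock_stdev, rng)

    rep = Replicate(
        config=config,
        omega=omega,
        skyline_beta=beta1,
        species_tree=species_tree,
        pops=pops,
        clock_stdev=clock_stdev,
        species_rates=species_rates,
        true_partition=extract_clusters(species_tree, config.epsilon),
    )

    mu_k, s_k = config.kappa_lognormal
    mu_n, s_n = config.nu_lognormal
    for _ in range(config.n_loci):
        gene_tree, mapping = simulate_gene_tree(
            species_tree, pops, config.samples_per_species, rng
        )
        hky = HKYParams(
            kappa=float(rng.lognormal(mu_k, s_k)),
            freqs=rng.dirichlet([config.freq_dirichlet] * 4),
            nu=float(rng.lognormal(mu_n, s_n)),
        )
        branch_rates = None
        if species_rates is not None:
            branch_rates = gene_branch_rates(
                gene_tree, species_tree, mapping, species_rates
            )
        aln = simulate_alignment(gene_tree, hky, config.sites, rng, branch_rates)
        rep.genes.append(GeneReplicate(gene_tree, mapping, aln, hky, branch_rates))
    return rep


# ----------------------------------------------------------------------
# Disk I/O: FASTA per locus, TSV sample map, Newick truth, JSON manifest
# ----------------------------------------------------------------------

def write_replicate(rep: Replicate, outdir) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    mapping: dict[str, str] = {}
    for g, gene in enumerate(rep.genes):
        records = [
            SeqRecord(Seq(seq), id=lab, description="")
            for lab, seq in sorted(gene.alignment.items())
        ]
        SeqIO.write(records, out / f"locus{g + 1}.fasta", "fasta")
        (out / f"locus{g + 1}.genetree.nwk").write_text(
            gene.gene_tree.to_newick() + "\n"
        )
        mapping.update(gene.mapping)
    pd.DataFrame(
        sorted(mapping.items()), columns=["sample_id", "species_id"]
    ).to_csv(out / "samples.tsv", sep="\t", index=False)
    (out / "species_tree.nwk").write_text(rep.species_tree.to_newick() + "\n")
    manifest = {
        "omega": rep.omega,
        "skyline_beta": rep.skyline_beta,
        "epsilon": rep.epsilon,
        "clock_stdev": rep.clock_stdev,
        "n_loci": len(rep.genes),
        "true_partition": [list(c) for c in rep.true_partition],
        "pops": {str(i): ne for i, ne in rep.pops.sizes.items()},
        "hky": [
            {"kappa": g.hky.kappa, "freqs": g.hky.freqs.tolist(), "nu": g.hky.nu}
            for g in rep.genes
        ],
    }
    (out / "replicate.json").write_text(json.dumps(manifest, indent=1))


def read_replicate(indir) -> Replicate:
    """Re-load a written replicate (species tree, gene trees, alignments, truth)."""
    from .tree import parse_newick

    ind = Path(indir)
    manifest = json.loads((ind / "replicate.json").read_text())
    species_tree = parse_newick((ind / "species_tree.nwk").read_text())
    mapping_df = pd.read_csv(ind / "samples.tsv", sep="\t")
    mapping = dict(zip(mapping_df["sample_id"], mapping_df["species_id"]))
    pops = PopSizeMap({int(i): ne for i, ne in manifest["pops"].items()})
    genes = []
    for g in range(manifest["n_loci"]):
        aln = {
            r.id: str(r.seq)
            for r in SeqIO.parse(ind / f"locus{g + 1}.fasta", "fasta")
        }
        gt = parse_newick((ind / f"locus{g + 1}.genetree.nwk").read_text())
        h = manifest["hky"][g]
        hky = HKYParams(h["kappa"], np.asarray(h["freqs"]), h["nu"])
        genes.append(GeneReplicate(gt, {k: mapping[k] for k in aln}, aln, hky))
    rep = Replicate(
        config=ExperimentConfig(
            n_species=species_tree.n_leaves,
            epsilon=manifest["epsilon"],
            n_loci=manifest["n_loci"],
        ),
        omega=manifest["omega"],
        skyline_beta=manifest["skyline_beta"],
        species_tree=species_tree,
        pops=pops,
        clock_stdev=manifest.get("clock_stdev"),
        species_rates=None,
        genes=genes,
        true_partition=Partition.from_clusters(manifest["true_partition"]),
    )
    return rep
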