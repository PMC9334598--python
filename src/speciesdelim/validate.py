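"""Well-calibrated validation harnesses: HPD/ESS utilities, prior-recovery
coverage, cluster-probability calibration, and threshold sensitivity.

The coverage study draws truths (species tree, collapse weight) from the
Yule-skyline collapse prior, re-infers them with the MCMC sampler in
prior-only mode, and counts how often each true parameter lands in its
95% highest-posterior-density interval.  For a correct sampler the
count follows Binomial(R, 0.95); with R = 100 the central 95% acceptance
interval is [90, 99].

The calibration study pools, over the same replicates, every cluster
hypothesis appearing in any posterior sample, bins it by its marginal
posterior support, and checks that the empirical frequency with which
binned hypotheses are true (exactly present in the generating tree's
partition) is consistent with the support: a cluster with 52% support
should be a true cluster roughly half the time.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .delimit import ClusteringSummary, map_clustering
from .experiment import ExperimentConfig, Replicate, sample_truth
from .mcmc import CollapseModel, Trace, run_mcmc
from .priors import SkylineConfig
from .tree import extract_clusters, parse_newick, tree_statistics

__all__ = [
    "hpd_interval",
    "effective_sample_size",
    "CoverageReport",
    "CalibrationReport",
    "binomial_acceptance_interval",
    "well_calibrated_study",
    "coverage_study",
    "cluster_calibration",
    "calibration_report_from_pairs",
    "epsilon_sensitivity",
]


# ----------------------------------------------------------------------
# HPD and ESS
# ----------------------------------------------------------------------

def hpd_interval(samples, level: float = 0.95) -> tuple[float, float]:
    """Smallest-width contiguous interval containing ceil(level * N) sorted samples.

    Ties in width are broken leftmost.
    """
    x = np.sort(np.asarray(samples, dtype=float))
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 samples")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    w = min(n, math.ceil(level * n))
    widths = x[w - 1:] - x[: n - w + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + w - 1])


def effective_sample_size(samples) -> float:
    """ESS = N / (1 + 2 sum rho_t) with initial-positive-sequence truncation.

    Autocorrelations are summed in Geyer pairs while the pair sums stay
    positive.  A constant series is reported as ESS = N with a warning;
    negative autocorrelation can legitimately push ESS above N.
    """
    x = np.asarray(samples, dtype=float)
    n = x.size
    if n < 10:
        raise ValueError("need at least 10 samples")
    v = x.var()
    if v == 0:
        warnings.warn("constant series; ESS defined as N", stacklevel=2)
        return float(n)
    xc = x - x.mean()
    m = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(xc, m)
    acov = np.fft.irfft(f * np.conj(f), m)[:n].real / n
    rho = acov / acov[0]
    tau = 1.0
    t = 1
    first = True
    while t + 1 < n:
        pair = rho[t] + rho[t + 1]
        if pair <= 0 and not first:
            break
        tau += 2.0 * pair
        first = False
        if pair <= 0:
            break
        t += 2
    # a leading negative pair (antithetic series) can push tau below 1,
    # legitimately yielding ESS > N; guard against tau <= 0
    tau = max(tau, 1.0 / n)
    return float(n / tau)


def binomial_acceptance_interval(
    total: int, p: float = 0.95, mass: float = 0.95
) -> tuple[int, int]:
    """Central acceptance interval of Binomial(total, p); [90, 99] for (100, .95)."""
    lo = int(sps.binom.ppf((1 - mass) / 2, total, p))
    hi = int(sps.binom.ppf(1 - (1 - mass) / 2, total, p))
    return lo, hi


# ----------------------------------------------------------------------
# Reports
# ----------------------------------------------------------------------

@dataclass
class CoverageReport:
    """Truth-in-95%-HPD counts per monitored parameter over R replicates."""

    counts: dict[str, int]
    total: int
    level: float = 0.95
    details: pd.DataFrame | None = None

    @property
    def acceptance_interval(self) -> tuple[int, int]:
        return binomial_acceptance_interval(self.total, self.level)

    def all_within(self) -> bool:
        lo, hi = self.acceptance_interval
        return all(lo <= c <= hi for c in self.counts.values())


@dataclass
class CalibrationReport:
    """Binned cluster-support calibration table (20 bins over [0, 1] by default)."""

    bins: pd.DataFrame  # columns: lo, hi, n, n_true, freq, ci_lo, ci_hi, nominal

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    @property
    def n_consistent(self) -> int:
        """Bins that are empty, or whose 95% CI covers the bin's nominal support."""
        ok = 0
        for _, r in self.bins.iterrows():
            if r["n"] == 0 or (r["ci_lo"] <= r["nominal"] <= r["ci_hi"]):
                ok += 1
        return ok


def calibration_report_from_pairs(
    pairs: list[tuple[float, bool]], n_bins: int = 20
) -> CalibrationReport:
    """Build the binned report from (posterior support, is-true) pairs.

    ``nominal`` per bin is the mean support of the hypotheses in it; the
    CI is the 95% Clopper-Pearson interval of the empirical truth
    frequency.  Empty bins are reported with NaN frequency, not dropped.
    """
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    rows = []
    supports = np.asarray([p for p, _ in pairs], dtype=float)
    truths = np.asarray([t for _, t in pairs], dtype=bool)
    which = np.clip(np.searchsorted(edges, supports, side="right") - 1, 0, n_bins - 1)
    for b in range(n_bins):
        sel = which == b
        n = int(sel.sum())
        if n == 0:
            rows.append(
                dict(lo=edges[b], hi=edges[b + 1], n=0, n_true=0, freq=np.nan,
                     ci_lo=np.nan, ci_hi=np.nan, nominal=np.nan)
            )
            continue
        nt = int(truths[sel].sum())
        ci_lo = 0.0 if nt == 0 else float(sps.beta.ppf(0.025, nt, n - nt + 1))
        ci_hi = 1.0 if nt == n else float(sps.beta.ppf(0.975, nt + 1, n - nt))
        rows.append(
            dict(lo=edges[b], hi=edges[b + 1], n=n, n_true=nt, freq=nt / n,
                 ci_lo=ci_lo, ci_hi=ci_hi,
                 nominal=float(supports[sel].mean()))
        )
    return CalibrationReport(bins=pd.DataFrame(rows))


# ----------------------------------------------------------------------
# The well-calibrated study
# ----------------------------------------------------------------------

MONITORED = ("TreeHeight", "TreeLength", "omega")


def well_calibrated_study(
    R: int,
    config: ExperimentConfig,
    seed: int,
    chain_length: int = 40000,
    log_every: int = 40,
    ess_target: float | None = 200.0,
    broken: bool = False,
) -> tuple[CoverageReport, CalibrationReport]:
    """Draw R truths from the YSC prior, recover each with prior-only MCMC.

    Returns the HPD coverage report for the monitored parameters (tree
    height, tree length, omega) and the pooled cluster-support
    calibration report.  ``broken`` runs the deliberately miscalibrated
    negative-control sampler (all Hastings ratios zeroed).
    """
    if R < 10:
        raise ValueError("need at least 10 replicates")
    counts = {p: 0 for p in MONITORED}
    detail_rows = []
    pairs: list[tuple[float, bool]] = []
    for r in range(R):
        rng = np.random.default_rng([seed, r])
        omega, beta1, tree, sky = sample_truth(config, rng)
        truth = dict(zip(MONITORED, (*tree_statistics(tree), omega)))
        true_part = extract_clusters(tree, config.epsilon)
        model = CollapseModel(
            epsilon=config.epsilon,
            omega_prior=config.omega_prior,
            slab="yule_skyline",
            sky=sky,
            taxa=tree.labels,
        )
        trace = run_mcmc(
            model,
            chain_length=chain_length,
            log_every=log_every,
            rng=rng,
            ess_target=None if broken else ess_target,
            break_hastings=broken,
        )
        post = trace.post_burnin()
        row = {"replicate": r}
        for p in MONITORED:
            lo, hi = hpd_interval(post[p].to_numpy())
            inside = lo <= truth[p] <= hi
            counts[p] += inside
            row[f"{p}_truth"] = truth[p]
            row[f"{p}_lo"], row[f"{p}_hi"] = lo, hi
            row[f"{p}_in"] = inside
        detail_rows.append(row)
        # pooled cluster-support calibration
        sampled = [
            extract_clusters(parse_newick(t), config.epsilon)
            for t in trace.post_burnin_trees()
        ]
        cluster_counts: Counter = Counter()
        for part in sampled:
            cluster_counts.update(part.clusters)
        for cluster, c in cluster_counts.items():
            support = c / len(sampled)
            pairs.append((support, cluster in true_part))
    coverage = CoverageReport(
        counts=counts, total=R, details=pd.DataFrame(detail_rows)
    )
    calibration = calibration_report_from_pairs(pairs)
    return coverage, calibration


def coverage_study(
    R: int, config: ExperimentConfig, seed: int, **kwargs
) -> CoverageReport:
    """HPD coverage of prior-drawn truths recovered by the prior-only sampler."""
    cov, _ = well_calibrated_study(R, config, seed, **kwargs)
    return cov


def cluster_calibration(
    R: int, config: ExperimentConfig, seed: int, bins: int = 20, **kwargs
) -> CalibrationReport:
    """Pooled 20-bin cluster-support calibration over R prior-recovery replicates."""
    _, cal = well_calibrated_study(R, config, seed, **kwargs)
    if bins != cal.n_bins:
        raise ValueError("bin count is fixed by the study; rebuild from pairs")
    return cal


# ----------------------------------------------------------------------
# Threshold sensitivity
# ----------------------------------------------------------------------

def epsilon_sensitivity(
    data: Replicate,
    epsilons: list[float],
    seed: int,
    chain_length: int = 4000,
    log_every: int = 10,
) -> pd.DataFrame:
    """Re-run inference once per threshold and tabulate the MAP clusterings.

    The threshold enters both the prior and the summarisation, so each
    epsilon gets its own MCMC run (MSC likelihood over the replicate's
    fixed gene trees).  Returns one row per epsilon with the MAP
    partition, its support and the cluster count.
    """
    if len(epsilons) < 2:
        raise ValueError("need at least 2 thresholds")
    rows = []
    for e_i, eps in enumerate(epsilons):
        rng = np.random.default_rng([seed, e_i])
        model = CollapseModel(
            epsilon=eps,
            omega_prior=data.config.omega_prior,
            slab="yule_skyline",
            sky=SkylineConfig(
                data.config.skyline_epochs, data.config.skyline_alpha,
                data.skyline_beta,
            ),
            likelihood="msc",
            genes=data.genes,
            init_pops=data.pops,
        )
        trace = run_mcmc(model, chain_length=chain_length, log_every=log_every, rng=rng)
        summary: ClusteringSummary = map_clustering(
            [parse_newick(t) for t in trace.trees], eps
        )
        rows.append(
            dict(
                epsilon=eps,
                map_partition=";".join(",".join(c) for c in summary.partition),
                support=summary.support,
                n_clusters=summary.partition.n_clusters,
            )
        )
    return pd.DataFrame(rows)
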