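"""Structured run configuration: YAML in, validated models out.

Unknown keys are rejected (naming the offender); defaults are the
generative-model values used throughout the validation studies
(epsilon = 1e-4, 4 skyline epochs, omega ~ Beta(1, 2)).
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError

from .experiment import ExperimentConfig

__all__ = ["RunConfig", "ConfigError", "load_config", "save_config"]


class ConfigError(ValueError):
    """Schema violation in a run configuration file."""


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class OmegaPrior(_Strict):
    alpha: float = 1.0
    beta: float = 2.0


class SkylineSection(_Strict):
    epochs: int = 4
    alpha: float = 2.0
    #: fixed gamma rate of the first epoch; if absent, drawn from the lognormal
    beta: Optional[float] = None
    beta_lognormal: tuple[float, float] = (-1.63, 0.2)


class BirthDeathSection(_Strict):
    lam: float = 10.0
    mu: float = 0.0
    origin: Optional[float] = None


class ExponentialSection(_Strict):
    lam: float = 10.0


class SimulateSection(_Strict):
    n_species: int = 6
    samples_per_species: int = 2
    n_loci: int = 2
    sites: int = 200
    coalescent_rate_gamma: tuple[float, float] = (100.0, 0.01)
    relaxed_clock: bool = True
    clock_stdev_gamma: tuple[float, float] = (5.0, 0.05)
    kappa_lognormal: tuple[float, float] = (1.0, 1.25)
    freq_dirichlet: float = 10.0
    nu_lognormal: tuple[float, float] = (-0.18, 0.6)


class McmcSection(_Strict):
    chain_length: int = 20000
    log_every: int = 20
    ess_target: Optional[float] = 200.0
    operators: Optional[dict[str, float]] = None


class ValidationSection(_Strict):
    replicates: int = 100
    bins: int = 20
    epsilons: list[float] = [1e-2, 1e-3, 1e-4, 1e-5]


class PathsSection(_Strict):
    replicate_dir: Optional[str] = None
    tree_log: Optional[str] = None
    taxon_map: Optional[str] = None


class RunConfig(_Strict):
    seed: int = 1
    epsilon: float = 1e-4
    burnin_fraction: float = 0.5
    slab: Literal["exponential", "birth_death", "yule_skyline"] = "yule_skyline"
    omega_prior: OmegaPrior = OmegaPrior()
    exponential: ExponentialSection = ExponentialSection()
    birth_death: BirthDeathSection = BirthDeathSection()
    skyline: SkylineSection = SkylineSection()
    simulate: SimulateSection = SimulateSection()
    mcmc: McmcSection = McmcSection()
    validation: ValidationSection = ValidationSection()
    paths: PathsSection = PathsSection()

    def experiment_config(self) -> ExperimentConfig:
        s = self.simulate
        return ExperimentConfig(
            n_species=s.n_species,
            epsilon=self.epsilon,
            omega_prior=(self.omega_prior.alpha, self.omega_prior.beta),
            skyline_epochs=self.skyline.epochs,
            skyline_alpha=self.skyline.alpha,
            skyline_beta_lognormal=tuple(self.skyline.beta_lognormal),
            coalescent_rate_gamma=tuple(s.coalescent_rate_gamma),
            relaxed_clock=s.relaxed_clock,
            clock_stdev_gamma=tuple(s.clock_stdev_gamma),
            kappa_lognormal=tuple(s.kappa_lognormal),
            freq_dirichlet=s.freq_dirichlet,
            nu_lognormal=tuple(s.nu_lognormal),
            n_loci=s.n_loci,
            sites=s.sites,
            samples_per_species=s.samples_per_species,
        )


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        offenders = []
        for err in exc.errors():
            loc = ".".join(str(p) for p in err["loc"])
            offenders.append(f"{loc}: {err['msg']}")
        raise ConfigError("invalid configuration: " + "; ".join(offenders)) from exc


def save_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.model_dump(), sort_keys=False))
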