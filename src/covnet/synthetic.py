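"""Synthetic cohort generator with planted covariance structure.

Emulates the statistical structure the analysis assumes, so every pipeline
stage is testable without clinical data: group-structured thickness
covariance in the form of a planted star (one hub region correlated with a
set of member regions through shared latent factors), linear covariate
effects on thickness, and Gaussian measurement noise.

Generative model, for subject ``s`` in group ``g`` and region ``j``::

    t[s, j] = mu[j] + sum_k beta[k, j] * c[s, k] + star[s, j] + eps
    eps ~ Normal(0, sigma^2)

Star structure: for each member ``m`` of group ``g``'s planted set an
independent factor ``f[s, m] ~ Normal(0, 1)`` is drawn; the hub receives
``lambda * sum_m f[s, m] / sqrt(|M|)`` and member ``m`` receives
``lambda * f[s, m]``.  Asymptotically the hub's variance is
``sigma^2 + lambda^2`` and each hub–member covariance is
``lambda^2 / sqrt(|M|)``, while member–member covariances vanish — making
exactly one node a degree/betweenness hub in the group's network.

Covariates named ``age`` are drawn Normal(40, 10) (years); covariates listed
in ``binary_rates`` are Bernoulli 0/1; all others are standard normal.

Defaults mirror the cohort the pipeline was designed around: three groups of
181/35/101 subjects, 148 cortical regions, eight covariates, a 2.5 mm mean
thickness and 0.25 mm between-subject noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from covnet.cohort import CohortError, RegionSet, ThicknessCohort

_DEFAULT_COVARIATES = (
    "age", "sex", "iq", "bdi", "tleq", "ces", "child_trauma", "med_5ht",
)
_DEFAULT_BINARY_RATES = {"sex": 0.18, "med_5ht": 0.19}
_DEFAULT_GROUPS = ("CONTROL", "REMIT-PTSD", "CURR-PTSD")


@dataclass(frozen=True)
class PlantedStar:
    """A planted hub: ``hub`` correlates with every region in ``members``."""

    hub: int
    members: tuple[int, ...]
    loading: float  # lambda, same units as thickness (mm)

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", tuple(self.members))
        if self.hub in self.members:
            raise ValueError("hub must not be one of its members")
        if len(set(self.members)) != len(self.members):
            raise ValueError("duplicate member index")
        if self.loading < 0:
            raise ValueError("loading must be >= 0")


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic cohort generator."""

    n_per_group: tuple[int, ...] = (181, 35, 101)
    p_regions: int = 148
    covariate_names: tuple[str, ...] = _DEFAULT_COVARIATES
    binary_rates: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_BINARY_RATES)
    )
    planted: tuple[PlantedStar | None, ...] | None = None
    covariate_betas: np.ndarray | None = None  # k x p, mm per covariate unit
    baseline_mu: float | np.ndarray = 2.5  # mm
    noise_sd: float = 0.25  # mm
    group_labels: tuple[str, ...] = _DEFAULT_GROUPS
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "n_per_group", tuple(self.n_per_group))
        object.__setattr__(self, "covariate_names", tuple(self.covariate_names))
        object.__setattr__(self, "group_labels", tuple(self.group_labels))
        if len(self.group_labels) != len(self.n_per_group):
            raise ValueError("group_labels and n_per_group length mismatch")
        planted = self.planted
        if planted is None:
            planted = (None,) * len(self.n_per_group)
        planted = tuple(planted)
        if len(planted) != len(self.n_per_group):
            raise ValueError("planted must give one entry per group")
        for star in planted:
            if star is None:
                continue
            idx = (star.hub, *star.members)
            if max(idx) >= self.p_regions or min(idx) < 0:
                raise ValueError("planted index out of range")
        object.__setattr__(self, "planted", planted)
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        k = len(self.covariate_names)
        for n in self.n_per_group:
            if n < k + 3:
                raise CohortError(
                    f"group size {n} too small for k={k} covariates (need n >= {k + 3})"
                )
        if self.covariate_betas is not None:
            betas = np.asarray(self.covariate_betas, dtype=float)
            if betas.shape != (k, self.p_regions):
                raise ValueError(
                    f"covariate_betas must be {k} x {self.p_regions}, got {betas.shape}"
                )
            object.__setattr__(self, "covariate_betas", betas)

    @property
    def k_covariates(self) -> int:
        return len(self.covariate_names)


@dataclass(frozen=True)
class PlantedTruth:
    """Which structure was planted in which group."""

    per_group: Mapping[str, PlantedStar | None]
    is_null: bool = False

    def hub_of(self, group: str) -> int | None:
        star = self.per_group[group]
        return None if star is None else star.hub


def _default_betas(config: SyntheticConfig) -> np.ndarray:
    # Mild age-related thinning only; other covariates carry no effect unless
    # the caller supplies betas.
    betas = np.zeros((config.k_covariates, config.p_regions))
    if "age" in config.covariate_names:
        betas[config.covariate_names.index("age"), :] = -0.005  # mm / year
    return betas


def _draw_covariates(rng: np.random.Generator, config: SyntheticConfig, n: int) -> np.ndarray:
    cov = np.empty((n, config.k_covariates))
    for k, name in enumerate(config.covariate_names):
        if name == "age":
            cov[:, k] = rng.normal(40.0, 10.0, size=n)
        elif name in config.binary_rates:
            cov[:, k] = rng.binomial(1, config.binary_rates[name], size=n)
        else:
            cov[:, k] = rng.normal(0.0, 1.0, size=n)
    return cov


def _region_set(p: int) -> RegionSet:
    half = p // 2
    labels = [f"L_region_{i + 1:03d}" for i in range(half)]
    labels += [f"R_region_{i + 1 - half:03d}" for i in range(half, p)]
    return RegionSet(tuple(labels))


def _generate(config: SyntheticConfig, planted: tuple[PlantedStar | None, ...],
              is_null: bool) -> tuple[ThicknessCohort, PlantedTruth]:
    rng = np.random.default_rng(config.seed)
    p = config.p_regions
    mu = np.broadcast_to(np.asarray(config.baseline_mu, dtype=float), (p,))
    betas = (config.covariate_betas if config.covariate_betas is not None
             else _default_betas(config))

    blocks_t, blocks_c, group_col = [], [], []
    for label, n, star in zip(config.group_labels, config.n_per_group, planted):
        cov = _draw_covariates(rng, config, n)
        thick = mu + cov @ betas + rng.normal(0.0, config.noise_sd, size=(n, p))
        if star is not None and star.loading > 0 and star.members:
            m = len(star.members)
            factors = rng.normal(0.0, 1.0, size=(n, m))
            thick[:, list(star.members)] += star.loading * factors
            thick[:, star.hub] += star.loading * factors.sum(axis=1) / np.sqrt(m)
        blocks_t.append(thick)
        blocks_c.append(cov)
        group_col.extend([label] * n)

    thickness = np.vstack(blocks_t)
    covariates = np.vstack(blocks_c)
    subject_ids = tuple(f"S{i + 1:04d}" for i in range(len(group_col)))
    cohort = ThicknessCohort(
        subject_ids, thickness, covariates, config.covariate_names,
        tuple(group_col), _region_set(p),
    )
    truth = PlantedTruth(
        dict(zip(config.group_labels, planted)), is_null=is_null
    )
    return cohort, truth


def generate_cohort(config: SyntheticConfig) -> tuple[ThicknessCohort, PlantedTruth]:
    """Generate a cohort with each group's own planted structure.

    Deterministic given ``config.seed``; the returned truth records the
    planted star (or ``None``) per group.
    """
    return _generate(config, config.planted, is_null=False)


def generate_null_cohort(config: SyntheticConfig) -> tuple[ThicknessCohort, PlantedTruth]:
    """Generate a cohort in which every group shares one planted structure.

    The first non-``None`` entry of ``config.planted`` (or no structure at
    all) is applied identically to every group, so all between-group
    topology differences are null by construction.
    """
    shared = next((s for s in config.planted if s is not None), None)
    planted = (shared,) * len(config.n_per_group)
    return _generate(config, planted, is_null=True)
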