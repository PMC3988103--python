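"""Synthetic data with the statistical structure the analysis assumes.

Two layers:

* **Species level** — :func:`simulate_traits` draws replicate response vectors
  from the pGLS generative model y = X beta + eps, eps ~ MVN(0, sigma2 *
  V(lambda)), via a Cholesky factor of the lambda-transformed phylogenetic
  covariance. This is Brownian-motion trait evolution on the tree (lambda = 1)
  shading into phylogenetic independence (lambda = 0).

* **Individual level** — :func:`simulate_study` emulates the field sampling
  design: a handful of males per species (6-19 in the study), per-male body
  and testes masses drawn lognormally around species targets, ten
  sperm-package lengths per male whose per-male means are averaged up to a
  species mean, and one to three spermatophores per species measured as
  (trunk area, trunk width) pairs whose product is the trunk volume. The
  derived species table is produced by the same averaging chain, and the
  per-individual gonadosomatic index (GSI) is averaged within species — which
  is why it differs from the ratio of species means whenever individual
  variation is present.

Within-species distributions are lognormal (traits are positive and SDs are
comparable to means, so Gaussian draws would go negative), moment-matched to
the target arithmetic mean and SD. Randomness uses a single root seed with
per-species streams derived by hashing the species name, so adding a species
leaves the other species' draws untouched.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import ConfigError
from .phylo import PhyloCovariance, Phylogeny, lambda_transform, vcv_from_tree
from .trait_data import TraitTable, gsi, log10_columns

#: Sperm packages measured per male in the sampling design.
PACKAGES_PER_MALE = 10

#: Spermatophores measured per species (one to three, by material availability).
SPERMATOPHORES_RANGE = (1, 3)

#: Within-male coefficient of variation of sperm-package length. The study
#: reports only between-male dispersion; this models measurement-level
#: scatter around each male's mean.
WITHIN_MALE_CV = 0.05


@dataclass(frozen=True)
class SimulationConfig:
    """Species-level simulation settings.

    ``X`` is the design matrix (intercept first) aligned with the tree's tip
    order; ``beta`` its coefficients. ``lam`` scales the off-diagonal of the
    tree covariance.
    """

    tree: Phylogeny
    X: np.ndarray
    beta: np.ndarray
    sigma2: float
    lam: float
    seed: int
    replicates: int = 1
    tip_order: Optional[tuple[str, ...]] = None

    def __post_init__(self):
        if self.sigma2 < 0:
            raise ConfigError("sigma2 must be >= 0")
        if not 0.0 <= self.lam <= 1.0:
            raise ConfigError("lambda must lie in [0, 1]")
        if self.replicates < 0:
            raise ConfigError("replicates must be >= 0")
        object.__setattr__(self, "X", np.atleast_2d(np.asarray(self.X, dtype=float)))
        object.__setattr__(self, "beta", np.asarray(self.beta, dtype=float))
        if self.X.shape[1] != self.beta.size:
            raise ConfigError("beta length must match design columns")


def simulate_traits(config: SimulationConfig) -> np.ndarray:
    """Replicate response vectors, shape (replicates, n_tips).

    Each replicate is ``X beta + L z`` with ``L`` the Cholesky factor of
    ``sigma2 * V(lam)`` and ``z`` standard normal. Bit-reproducible for a
    fixed seed.
    """
    order = config.tip_order or tuple(config.tree.tip_labels)
    V = lambda_transform(vcv_from_tree(config.tree, tip_order=order), config.lam)
    n = len(order)
    if config.X.shape[0] != n:
        raise ConfigError(f"design has {config.X.shape[0]} rows for {n} tips")
    mean = config.X @ config.beta
    rng = np.random.default_rng(config.seed)
    if config.sigma2 == 0:
        return np.tile(mean, (config.replicates, 1))
    try:
        L = np.linalg.cholesky(config.sigma2 * V.matrix)
    except np.linalg.LinAlgError as exc:
        raise ConfigError("lambda-transformed covariance is not PSD") from exc
    z = rng.standard_normal((config.replicates, n))
    return mean + z @ L.T


@dataclass(frozen=True)
class SyntheticStudy:
    """Individual-level records plus the species table derived from them."""

    individuals: pd.DataFrame  # one row per male
    packages: pd.DataFrame  # one row per sperm package
    spermatophores: pd.DataFrame  # one row per spermatophore
    table: TraitTable  # derived species-level table
    gsi_individual: pd.Series  # per-species mean of per-male GSI
    seed: int


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal with the given arithmetic mean and SD."""
    if mean <= 0:
        raise ConfigError("lognormal target mean must be positive")
    if sd < 0:
        raise ConfigError("target SD must be >= 0")
    if sd == 0:
        return np.log(mean), 0.0
    s2 = np.log1p((sd / mean) ** 2)
    return np.log(mean) - 0.5 * s2, np.sqrt(s2)


def _species_rng(seed: int, species: str) -> np.random.Generator:
    """Independent, name-stable stream for one species under a root seed."""
    digest = hashlib.sha256(species.encode("utf-8")).digest()
    key = int.from_bytes(digest[:8], "little")
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))


def _draw_lognormal(rng, mean, sd, size):
    mu, s = _lognormal_params(mean, sd)
    if s == 0:
        return np.full(size, mean, dtype=float)
    return rng.lognormal(mu, s, size=size)


def simulate_study(
    targets: TraitTable,
    seed: int = 0,
    n_males: Union[None, int, Mapping[str, int]] = None,
    packages_per_male: int = PACKAGES_PER_MALE,
    within_male_cv: float = WITHIN_MALE_CV,
    spermatophore_cv: float = 0.0,
) -> SyntheticStudy:
    """Simulate the individual-level sampling design around species targets.

    ``targets`` supplies per-species means and SDs (missing SD columns are
    treated as 0, i.e. no individual variation). ``n_males`` defaults to the
    table's ``n_males`` column (falling back to 10). The derived species
    table applies the study's averaging chain: package -> male mean ->
    species mean for sperm length, spermatophore (area x width) products
    averaged per species, and per-male GSI averaged per species.
    """
    if within_male_cv < 0 or spermatophore_cv < 0:
        raise ConfigError("coefficients of variation must be >= 0")
    df = targets.df
    males_rows, pkg_rows, sper_rows = [], [], []
    for _, row in df.iterrows():
        sp = row["species"]
        rng = _species_rng(seed, sp)
        if isinstance(n_males, Mapping):
            nm = int(n_males.get(sp, 10))
        elif n_males is not None:
            nm = int(n_males)
        else:
            nm = int(row["n_males"]) if "n_males" in df.columns and row.notna().get("n_males", False) else 10
        if nm < 1:
            raise ConfigError(f"n_males must be >= 1 for {sp}")
        bm_sd = float(row.get("body_mass_sd", 0.0) or 0.0)
        tm_sd = float(row.get("testes_mass_sd", 0.0) or 0.0)
        sl_sd = float(row.get("sperm_length_sd", 0.0) or 0.0)
        bm = _draw_lognormal(rng, float(row["body_mass_g"]), bm_sd, nm)
        tm = _draw_lognormal(rng, float(row["testes_mass_mg"]), tm_sd, nm)
        male_sl_mean = _draw_lognormal(rng, float(row["sperm_length_um"]), sl_sd, nm)
        for m in range(nm):
            lengths = _draw_lognormal(
                rng, male_sl_mean[m], within_male_cv * male_sl_mean[m], packages_per_male
            )
            for p, ln in enumerate(lengths):
                pkg_rows.append({"species": sp, "male": m, "package": p, "length_um": ln})
            males_rows.append(
                {
                    "species": sp,
                    "male": m,
                    "body_mass_g": bm[m],
                    "testes_mass_mg": tm[m],
                    "sperm_length_um": float(lengths.mean()),
                    "gsi": gsi(bm[m], tm[m]),
                }
            )
        n_sper = int(rng.integers(SPERMATOPHORES_RANGE[0], SPERMATOPHORES_RANGE[1] + 1))
        sv_target = float(row["spermatophore_volume_mm3"])
        vols = _draw_lognormal(rng, sv_target, spermatophore_cv * sv_target, n_sper)
        for s, v in enumerate(vols):
            # split the volume into an (area, width) pair with area*width = v
            width = v ** (1.0 / 3.0)
            sper_rows.append(
                {
                    "species": sp,
                    "spermatophore": s,
                    "trunk_area_mm2": v / width,
                    "trunk_width_mm": width,
                    "volume_mm3": v,
                }
            )
    individuals = pd.DataFrame(males_rows)
    packages = pd.DataFrame(pkg_rows)
    spermatophores = pd.DataFrame(sper_rows)

    by = individuals.groupby("species", sort=False)
    derived = pd.DataFrame(
        {
            "species": list(by.groups),
            "body_mass_g": by["body_mass_g"].mean().to_numpy(),
            "body_mass_sd": by["body_mass_g"].std(ddof=1).fillna(0.0).to_numpy(),
            "n_males": by.size().to_numpy(),
            "testes_mass_mg": by["testes_mass_mg"].mean().to_numpy(),
            "testes_mass_sd": by["testes_mass_mg"].std(ddof=1).fillna(0.0).to_numpy(),
            "sperm_length_um": by["sperm_length_um"].mean().to_numpy(),
            "sperm_length_sd": by["sperm_length_um"].std(ddof=1).fillna(0.0).to_numpy(),
        }
    )
    sv = spermatophores.groupby("species", sort=False)["volume_mm3"].mean()
    derived["spermatophore_volume_mm3"] = derived["species"].map(sv).to_numpy()
    derived["polyandry"] = derived["species"].map(
        df.set_index("species")["polyandry"]
    ).to_numpy()
    table = log10_columns(TraitTable(derived), strict=False)
    gsi_individual = by["gsi"].mean()
    return SyntheticStudy(
        individuals=individuals,
        packages=packages,
        spermatophores=spermatophores,
        table=table,
        gsi_individual=gsi_individual,
        seed=seed,
    )
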