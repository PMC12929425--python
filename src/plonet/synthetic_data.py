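"""Synthetic plant-pollinator studies with known ground truth.

The generator emulates the statistical structure the community analysis
assumes, so every downstream stage can be exercised end to end:

* **Networks** arise from a Gaussian niche-overlap kernel: pollinators sit at
  positions uniform on [0, 1]; each plant has a niche centre uniform on
  [0, 1] and a breadth sigma (diploid base ``sigma0``, polyploid
  ``sigma0 * kappa``); visit counts are Poisson with mean
  ``lambda * exp(-(u - c)^2 / (2 sigma^2))``.  ``kappa > 1`` gives polyploids
  a broadened pollination niche (more, more even partners -> more nested,
  less modular networks as polyploid frequency rises); ``kappa < 1`` narrows
  it; ``kappa = 1`` is the null.
* **Polyploid frequency** per network follows a logit model on standardized
  log precipitation seasonality, so climate covaries with the plant
  variables.
* **Traits** covary with ploidy through per-plant logits with negative
  defaults (polyploids are less often self-compatible and less often
  restrictive-flowered).
* **Missingness** masks trait values to ``unknown`` at per-trait rates
  mirroring the sparse coverage of real compilations (mating system is the
  sparsest by far).
* Climate also nudges niche breadth and community size, so the indices and
  network size respond to the environment.

Networks that would fail the retention filters (too few pollinators, too few
or too sparse ploidy classifications) are redrawn with a capped retry count,
so every generated study passes the filters by construction.  A single study
seed drives a per-network seed sequence: any one network can be regenerated
in isolation.

``simulate_path_model`` generates records directly from the five structural
equations (standardized linear-Gaussian), for calibrating and validating the
piecewise SEM machinery independently of the network generator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .network_io import (InteractionNetwork, NetworkCovariates, PlantTraitTable)
from .traits_and_filters import (MIN_PLOIDY_CLASSIFIED, MIN_POLLINATORS,
                                 MIN_PLOIDY_COVERAGE)

MAX_NETWORK_RETRIES = 200


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; the defaults emulate the assembled-cohort
    conditions (community sizes, trait covariation signs, trait coverage)."""

    n_networks: int = 325
    plants_range: tuple[int, int] = (6, 26)        # mean ~16 plants
    pollinators_range: tuple[int, int] = (6, 83)   # mean ~44 pollinators
    # polyploid frequency: logit(%PP) = intercept + slope * z(log BIO15)
    pp_logit_intercept: float = -0.6               # baseline %PP ~ 0.35
    pp_logit_b15: float = 0.8                      # seasonal regions richer in polyploids
    # pollination-niche kernel
    niche_ratio: float = 3.0                       # kappa; >1 broadens polyploid niches
    sigma0: float = 0.10                           # diploid niche breadth
    visit_intensity: float = 6.0                   # Poisson mean at zero niche distance
    env_to_log_sigma: float = -0.15                # seasonality narrows niches
    env_to_log_size: float = -0.10                 # seasonality shrinks communities
    # per-plant trait logits (negative: polyploids less SC / less restrictive)
    sc_logit_intercept: float = 0.0
    trait_logit_pp_to_sc: float = -0.8
    restrictive_logit_intercept: float = 0.0
    trait_logit_pp_to_restrictive: float = -1.5
    # per-trait missingness rates (share of species masked to unknown)
    missing_ploidy: float = 0.30
    missing_mating: float = 0.79
    missing_restrictive: float = 0.34
    seed: int = 0

    def __post_init__(self) -> None:
        if self.niche_ratio <= 0:
            raise ValueError("niche_ratio (kappa) must be positive")
        for name in ("missing_ploidy", "missing_mating", "missing_restrictive"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("plants_range", "pollinators_range"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 1:
                raise ValueError(f"{name} interval is empty or invalid")


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually did, per network and globally."""

    per_network: pd.DataFrame  # network_id, true_pct_pp, kappa, sigma_*, z_b15
    config: SyntheticConfig


def _sigmoid(x: float | np.ndarray) -> float | np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def generate_network(
    config: SyntheticConfig,
    seed: int | np.random.SeedSequence,
    network_id: str = "synth",
    pp_prob: float | None = None,
    sigma0: float | None = None,
    n_plants: int | None = None,
    n_pollinators: int | None = None,
) -> tuple[InteractionNetwork, dict[str, str]]:
    """One niche-kernel network plus its per-plant true ploidy labels.

    Redraws (up to ``MAX_NETWORK_RETRIES``) until the validated network keeps
    all plants and at least ``MIN_POLLINATORS`` visited pollinators.
    """
    rng = np.random.default_rng(seed)
    p_poly = _sigmoid(config.pp_logit_intercept) if pp_prob is None else pp_prob
    s0 = config.sigma0 if sigma0 is None else sigma0
    for _ in range(MAX_NETWORK_RETRIES):
        n_pl = n_plants or int(rng.integers(config.plants_range[0],
                                            config.plants_range[1] + 1))
        n_po = n_pollinators or int(rng.integers(config.pollinators_range[0],
                                                 config.pollinators_range[1] + 1))
        u = rng.uniform(0.0, 1.0, size=n_po)
        centers = rng.uniform(0.0, 1.0, size=n_pl)
        is_poly = rng.random(n_pl) < p_poly
        sigma = np.where(is_poly, s0 * config.niche_ratio, s0)
        mean = config.visit_intensity * np.exp(
            -((u[None, :] - centers[:, None]) ** 2) / (2.0 * sigma[:, None] ** 2))
        w = rng.poisson(mean).astype(float)
        # every plant must interact and enough pollinators must be visited
        if not (w.sum(axis=1) > 0).all():
            continue
        if int(((w.sum(axis=0)) > 0).sum()) < MIN_POLLINATORS:
            continue
        plants = tuple(f"{network_id}_p{i:03d}" for i in range(n_pl))
        polls = tuple(f"{network_id}_a{j:03d}" for j in range(n_po))
        net = InteractionNetwork(network_id, plants, polls, w).validate()
        ploidy = {p: ("polyploid" if q else "diploid")
                  for p, q in zip(plants, is_poly)}
        return net, ploidy
    raise RuntimeError(
        f"{network_id}: no admissible network in {MAX_NETWORK_RETRIES} draws "
        f"under config {config}"
    )


def _mask(values: Sequence[str], rate: float, rng: np.random.Generator) -> list[str]:
    return ["unknown" if rng.random() < rate else v for v in values]


def generate_study(
    config: SyntheticConfig,
) -> tuple[list[InteractionNetwork], PlantTraitTable, NetworkCovariates, GroundTruth]:
    """A complete synthetic study: networks, trait table, covariates, truth.

    Every network passes the retention filters by construction (ploidy
    coverage and classified counts are re-checked after missingness masking;
    failing draws are replaced).
    """
    ss = np.random.SeedSequence(config.seed)
    master = np.random.default_rng(ss)
    net_seeds = ss.spawn(config.n_networks)

    networks: list[InteractionNetwork] = []
    trait_rows: list[dict] = []
    cov_rows: list[dict] = []
    truth_rows: list[dict] = []

    for k in range(config.n_networks):
        rng = np.random.default_rng(net_seeds[k])
        net_id = f"synthnet{k:04d}"
        # climate context
        bio15 = float(rng.gamma(shape=4.0, scale=15.0))        # mean 60, CV 0.5
        z_b15 = (math.log(bio15 + 1.0) - 4.0) / 0.5            # approx standardized
        bio4 = float(max(rng.normal(600.0, 250.0), 1.0))
        bio10 = float(rng.normal(18.0, 6.0))
        bio18 = float(rng.gamma(shape=2.0, scale=100.0))
        lat = float(rng.uniform(-60.0, 70.0))
        lon = float(rng.uniform(-180.0, 180.0))

        p_poly = float(_sigmoid(config.pp_logit_intercept
                                + config.pp_logit_b15 * z_b15))
        sigma0 = config.sigma0 * math.exp(config.env_to_log_sigma * z_b15)
        size_scale = math.exp(config.env_to_log_size * z_b15)
        n_pl = int(np.clip(round(rng.integers(config.plants_range[0],
                                              config.plants_range[1] + 1)
                                 * size_scale),
                           config.plants_range[0], None))
        n_po = int(np.clip(round(rng.integers(config.pollinators_range[0],
                                              config.pollinators_range[1] + 1)
                                 * size_scale),
                           config.pollinators_range[0], None))

        for attempt in range(MAX_NETWORK_RETRIES):
            sub_seed = np.random.SeedSequence(
                entropy=net_seeds[k].entropy,
                spawn_key=(*net_seeds[k].spawn_key, attempt))
            net, ploidy = generate_network(
                config, sub_seed, network_id=net_id, pp_prob=p_poly,
                sigma0=sigma0, n_plants=n_pl, n_pollinators=n_po)
            arng = np.random.default_rng(sub_seed.spawn(1)[0])
            plants = list(net.plant_ids)
            is_poly = np.array([ploidy[p] == "polyploid" for p in plants])
            # ploidy-linked traits
            sc = arng.random(len(plants)) < _sigmoid(
                config.sc_logit_intercept
                + config.trait_logit_pp_to_sc * is_poly)
            restrictive = arng.random(len(plants)) < _sigmoid(
                config.restrictive_logit_intercept
                + config.trait_logit_pp_to_restrictive * is_poly)
            mating = np.where(sc, "self_compatible", "self_incompatible")
            restr = np.where(restrictive,
                             arng.choice(["moderate", "high"], size=len(plants)),
                             arng.choice(["unrestrictive", "low"], size=len(plants)))
            masked_ploidy = _mask([ploidy[p] for p in plants],
                                  config.missing_ploidy, arng)
            masked_mating = _mask(list(mating), config.missing_mating, arng)
            masked_restr = _mask(list(restr), config.missing_restrictive, arng)
            n_known = sum(v != "unknown" for v in masked_ploidy)
            if (n_known >= MIN_PLOIDY_CLASSIFIED
                    and n_known >= MIN_PLOIDY_COVERAGE * len(plants)):
                break
        else:
            raise RuntimeError(f"{net_id}: no filter-passing draw")

        networks.append(net)
        for p, pl, ma, rs in zip(plants, masked_ploidy, masked_mating, masked_restr):
            trait_rows.append({"species": p, "ploidy": pl, "mating": ma,
                               "restrictiveness": rs})
        cov_rows.append({"network_id": net_id, "latitude": lat, "longitude": lon,
                         "bio4": bio4, "bio10": bio10, "bio15": bio15,
                         "bio18": bio18})
        truth_rows.append({
            "network_id": net_id,
            "true_pct_pp": float(is_poly.mean()),
            "kappa": config.niche_ratio,
            "sigma_diploid": sigma0,
            "sigma_polyploid": sigma0 * config.niche_ratio,
            "z_b15": z_b15,
            "n_plants": net.n_plants,
            "n_pollinators": net.n_pollinators,
        })

    traits = PlantTraitTable(pd.DataFrame(trait_rows))
    covariates = NetworkCovariates(pd.DataFrame(cov_rows))
    truth = GroundTruth(per_network=pd.DataFrame(truth_rows), config=config)
    return networks, traits, covariates, truth


# ---------------------------------------------------------------------------
# Direct simulation from the structural equations (SEM validation)

#: standardized edge coefficients observed in the assembled cohort, used as
#: default generator settings for SEM validation
DEFAULT_SEM_COEFS: dict[tuple[str, str], float] = {
    ("log_bio15", "pct_pp"): 0.15,
    ("pct_pp", "pct_sc"): -0.20,
    ("pct_pp", "pct_restrictive"): -0.375,
    ("log_bio15", "pct_sc"): 0.10,
    ("log_bio15", "pct_restrictive"): 0.10,
    ("log_bio15", "log_network_size"): -0.10,
    ("pct_pp", "Y"): 0.206,
    ("pct_sc", "Y"): -0.14,
    ("pct_restrictive", "Y"): 0.12,
    ("log_bio15", "Y"): -0.15,
    ("log_network_size", "Y"): 0.15,
}


def simulate_path_model(
    n: int,
    coefs: Mapping[tuple[str, str], float] | None = None,
    seed: int = 0,
    index_name: str = "nestedness",
    missing_sc: float = 0.0,
    missing_rs: float = 0.0,
) -> pd.DataFrame:
    """Records drawn directly from the five structural equations.

    All variables are (approximately) standardized linear-Gaussian, so the
    generating coefficients are the true standardized path coefficients.
    Optional missingness masks %SC / %Restrictive per record, mimicking
    unequal trait coverage.
    """
    coefs = dict(DEFAULT_SEM_COEFS if coefs is None else coefs)
    rng = np.random.default_rng(seed)
    y_col = f"delta_{index_name}"

    def lincomb(parents: dict[str, np.ndarray], child: str) -> np.ndarray:
        lin = np.zeros(n)
        for name, vals in parents.items():
            lin = lin + coefs.get((name, child), 0.0) * vals
        var = float(np.var(lin))
        resid_sd = math.sqrt(max(1.0 - var, 0.05))
        return lin + rng.normal(0.0, resid_sd, size=n)

    b15 = rng.normal(0.0, 1.0, size=n)
    pp = lincomb({"log_bio15": b15}, "pct_pp")
    sc = lincomb({"log_bio15": b15, "pct_pp": pp}, "pct_sc")
    rs = lincomb({"log_bio15": b15, "pct_pp": pp}, "pct_restrictive")
    ns = lincomb({"log_bio15": b15}, "log_network_size")
    y = lincomb({"log_bio15": b15, "pct_pp": pp, "pct_sc": sc,
                 "pct_restrictive": rs, "log_network_size": ns}, "Y")

    df = pd.DataFrame({
        "network_id": [f"sim{i:05d}" for i in range(n)],
        "log_bio15": b15, "pct_pp": pp, "pct_sc": sc,
        "pct_restrictive": rs, "log_network_size": ns, y_col: y,
    })
    if missing_sc > 0:
        df.loc[rng.random(n) < missing_sc, "pct_sc"] = np.nan
    if missing_rs > 0:
        df.loc[rng.random(n) < missing_rs, "pct_restrictive"] = np.nan
    return df
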