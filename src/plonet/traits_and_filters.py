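"""Network-level trait frequencies and cohort retention filters.

Trait frequencies are computed over the species with a *known* state for the
focal trait: %PP is the share of polyploids among ploidy-classified plants,
%SC the share of self-compatible plants among those with known mating system,
and %Restrictive the share of restrictive-flowered plants among those with a
known restrictiveness level after binning the four morphological levels to a
binary (unrestrictive/low -> not restrictive, moderate/high -> restrictive).

Retention filters for the analysis cohort: at least six pollinator taxa, at
least six ploidy-classified plants, ploidy coverage of at least one third of
the plants (exact rational comparison, so a 6-of-18 network passes), and an
available climate record.  The path-analysis subset additionally drops
networks where both %SC and %Restrictive are undefined.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Literal, Mapping

import pandas as pd

from .network_io import InteractionNetwork, NetworkCovariates, PlantTraitTable

logger = logging.getLogger("plonet")

MIN_POLLINATORS = 6
MIN_PLOIDY_CLASSIFIED = 6
MIN_PLOIDY_COVERAGE = Fraction(1, 3)

TraitName = Literal["ploidy", "mating", "restrictiveness"]

#: focal state counted in each trait's numerator
_FOCAL_STATE = {
    "ploidy": "polyploid",
    "mating": "self_compatible",
    "restrictiveness": "restrictive",
}


@dataclass(frozen=True)
class TraitFrequencies:
    """Per-network trait frequencies with their known-state denominators."""

    pct_pp: float | None
    pct_sc: float | None
    pct_restrictive: float | None
    n_known_ploidy: int
    n_known_mating: int
    n_known_restrictive: int
    n_plants: int


def bin_restrictiveness(level: str) -> str:
    """Collapse the four morphological levels to a binary trait."""
    if level in ("unrestrictive", "low"):
        return "not_restrictive"
    if level in ("moderate", "high"):
        return "restrictive"
    if level == "unknown":
        return "unknown"
    raise ValueError(f"unrecognized restrictiveness level {level!r}")


def trait_frequency(network: InteractionNetwork, traits: PlantTraitTable,
                    trait: TraitName) -> tuple[float | None, int]:
    """(frequency of the focal state, number of plants with known state).

    The frequency is undefined (None) when no plant in the network has a
    known state for the trait; unmatched species count as unknown.
    """
    rows = traits.lookup(network.plant_ids)
    states = rows[trait]
    if trait == "restrictiveness":
        states = states.map(bin_restrictiveness)
    known = states[states != "unknown"]
    if len(known) == 0:
        return None, 0
    focal = int((known == _FOCAL_STATE[trait]).sum())
    return focal / len(known), len(known)


def trait_frequencies(network: InteractionNetwork,
                      traits: PlantTraitTable) -> TraitFrequencies:
    pp, n_pl = trait_frequency(network, traits, "ploidy")
    sc, n_sc = trait_frequency(network, traits, "mating")
    rs, n_rs = trait_frequency(network, traits, "restrictiveness")
    return TraitFrequencies(pct_pp=pp, pct_sc=sc, pct_restrictive=rs,
                            n_known_ploidy=n_pl, n_known_mating=n_sc,
                            n_known_restrictive=n_rs,
                            n_plants=network.n_plants)


def _climate_available(cov: NetworkCovariates, network_id: str) -> bool:
    row = cov.get(network_id)
    if row is None:
        return False
    return not row[["bio4", "bio10", "bio15", "bio18"]].isna().any()


def filter_reasons(network: InteractionNetwork, traits: PlantTraitTable,
                   covariates: NetworkCovariates) -> list[str]:
    """All retention criteria the network fails (empty list = retained)."""
    reasons: list[str] = []
    if network.n_pollinators < MIN_POLLINATORS:
        reasons.append("min_pollinators")
    _, n_ploidy = trait_frequency(network, traits, "ploidy")
    if n_ploidy < MIN_PLOIDY_CLASSIFIED:
        reasons.append("min_ploidy_classified")
    if Fraction(n_ploidy, max(network.n_plants, 1)) < MIN_PLOIDY_COVERAGE:
        reasons.append("ploidy_coverage")
    if not _climate_available(covariates, network.network_id):
        reasons.append("no_climate")
    return reasons


def apply_filters(
    networks: Iterable[InteractionNetwork],
    traits: PlantTraitTable,
    covariates: NetworkCovariates,
) -> tuple[list[InteractionNetwork], pd.DataFrame]:
    """Retain networks passing all four criteria; report why the rest fail.

    Returns the retained networks (input order preserved) and a reasons table
    with one row per rejected network listing every failed criterion.
    Idempotent: re-filtering a retained set changes nothing.
    """
    retained: list[InteractionNetwork] = []
    rows: list[dict] = []
    for net in networks:
        reasons = filter_reasons(net, traits, covariates)
        if reasons:
            rows.append({"network_id": net.network_id,
                         "reasons": ";".join(reasons)})
            logger.info("%s rejected: %s", net.network_id, ";".join(reasons))
        else:
            retained.append(net)
    report = pd.DataFrame(rows, columns=["network_id", "reasons"])
    return retained, report


def path_filter(networks: Iterable[InteractionNetwork],
                traits: PlantTraitTable) -> list[InteractionNetwork]:
    """Path-analysis subset: keep networks with at least some data for either
    %SC or %Restrictive (drop those where both are undefined)."""
    out = []
    for net in networks:
        _, n_sc = trait_frequency(net, traits, "mating")
        _, n_rs = trait_frequency(net, traits, "restrictiveness")
        if n_sc > 0 or n_rs > 0:
            out.append(net)
    return out
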