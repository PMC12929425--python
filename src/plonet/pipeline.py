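"""End-to-end orchestration: filter -> indices + nulls -> records ->
regressions -> SEM -> effect decomposition.

Every stochastic stage draws its seed deterministically from the single run
seed, and all intermediates are written as plain delimited tables so any
stage can be audited or re-entered.  Warnings (dropped empty rows/columns,
unmatched species) never abort a run; schema violations always do.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import metrics as _metrics
from .extinction import RemovalPolicy, mean_robustness
from .network_io import (InteractionNetwork, NetworkCovariates, PlantTraitTable,
                         binarize, read_covariates, read_networks_dir,
                         read_trait_table)
from .null_models import DEFAULT_N_NULL, NullVariant, delta_index
from .path_sem import SEMFit, decompose_effects, fit_sem
from .stats_regression import make_record, records_frame, regression_table
from .traits_and_filters import apply_filters, path_filter, trait_frequencies

logger = logging.getLogger("plonet")

INDEX_NAMES = ("connectance", "nestedness", "modularity", "robustness")


@dataclass(frozen=True)
class IndexSet:
    """Raw, null-mean and delta values of the four indices for one network."""

    network_id: str
    raw: dict[str, float]
    null_mean: dict[str, float]
    delta: dict[str, float]
    n_null: int

    def as_row(self) -> dict:
        row: dict = {"network_id": self.network_id, "n_null": self.n_null}
        for name in INDEX_NAMES:
            row[f"raw_{name}"] = self.raw[name]
            row[f"null_mean_{name}"] = self.null_mean[name]
            row[f"delta_{name}"] = self.delta[name]
        return row


@dataclass(frozen=True)
class RunConfig:
    """Settings for a full pipeline run."""

    networks_dir: str | None = None
    traits_path: str | None = None
    covariates_path: str | None = None
    out_dir: str | None = None
    n_null: int = DEFAULT_N_NULL
    n_extinction_orders: int = 100
    n_orders_per_null: int = 20
    null_variant: NullVariant = "fixed_marginals"
    modularity_restarts: int = _metrics.DEFAULT_RESTARTS
    modularity_weighted: bool = True
    sem_variant: str = "base"
    seed: int = 0


@dataclass
class ResultBundle:
    filter_report: pd.DataFrame
    index_sets: pd.DataFrame
    records: pd.DataFrame
    regressions: pd.DataFrame
    sem_fits: dict[str, SEMFit]
    effects: pd.DataFrame
    config: RunConfig = field(default_factory=RunConfig)


def _stage_seed(base: int, *tags: str) -> int:
    """A reproducible 31-bit seed derived from the run seed and stage tags."""
    ss = np.random.SeedSequence(
        [base, *(zlib.crc32(t.encode("utf-8")) for t in tags)])
    return int(ss.generate_state(1)[0] % 2**31)


def _index_fns(config: RunConfig, seed: int):
    """Per-index callables taking a validated network to a raw index value."""
    def modularity(net: InteractionNetwork) -> float:
        target = net if config.modularity_weighted else binarize(net)
        _, q = _metrics.optimize_modularity(
            target, seed=seed, n_restarts=config.modularity_restarts)
        return q

    def robustness_fn(net: InteractionNetwork) -> float:
        return mean_robustness(net, RemovalPolicy("random", seed),
                               n_orders=config.n_orders_per_null)

    return {
        "connectance": _metrics.connectance,
        "nestedness": _metrics.weighted_nodf,
        "modularity": modularity,
        "robustness": robustness_fn,
    }


def compute_index_set(network: InteractionNetwork, config: RunConfig) -> IndexSet:
    """All four indices of one network with their null standardization."""
    seed = _stage_seed(config.seed, "indices", network.network_id)
    fns = _index_fns(config, seed)
    raw: dict[str, float] = {}
    null_mean: dict[str, float] = {}
    delta: dict[str, float] = {}
    for name, fn in fns.items():
        if name == "robustness":
            # headline raw robustness averages more orders than the null loop
            raw_v = mean_robustness(network, RemovalPolicy("random", seed),
                                    n_orders=config.n_extinction_orders)
            _, nm, _ = delta_index(network, fn, name, n_null=config.n_null,
                                   seed=seed, variant=config.null_variant)
            raw[name], null_mean[name] = raw_v, nm
            delta[name] = raw_v - nm
        else:
            r, nm, d = delta_index(network, fn, name, n_null=config.n_null,
                                   seed=seed, variant=config.null_variant)
            raw[name], null_mean[name], delta[name] = r, nm, d
    return IndexSet(network_id=network.network_id, raw=raw,
                    null_mean=null_mean, delta=delta, n_null=config.n_null)


def analyze_study(
    networks: Sequence[InteractionNetwork],
    traits: PlantTraitTable,
    covariates: NetworkCovariates,
    config: RunConfig = RunConfig(),
) -> ResultBundle:
    """Run the full analysis on in-memory inputs and return every table."""
    retained, report = apply_filters(networks, traits, covariates)
    if not retained:
        raise ValueError("no network passed the retention filters")
    logger.info("retained %d of %d networks", len(retained), len(list(networks)))

    index_rows = []
    records = []
    for net in retained:
        iset = compute_index_set(net, config)
        index_rows.append(iset.as_row())
        freqs = trait_frequencies(net, traits)
        records.append(make_record(net, freqs, covariates, iset.delta))
    index_sets = pd.DataFrame(index_rows)
    rec = records_frame(records)

    regressions = regression_table(rec)

    sem_records = rec[rec["network_id"].isin(
        {n.network_id for n in path_filter(retained, traits)})]
    sem_fits: dict[str, SEMFit] = {}
    effect_rows = []
    for name in INDEX_NAMES:
        fit = fit_sem(sem_records, name, variant=config.sem_variant)
        sem_fits[name] = fit
        eff = decompose_effects(fit)
        effect_rows.append({
            "index": name,
            "direct": eff.direct,
            **{f"indirect[{k}]": v for k, v in eff.indirect_components.items()},
            "total": eff.total,
            "fisher_c": fit.fisher_c,
            "df": fit.df,
            "adequacy_p": fit.adequacy_p,
            "n": fit.n,
        })
    effects = pd.DataFrame(effect_rows)
    return ResultBundle(filter_report=report, index_sets=index_sets,
                        records=rec, regressions=regressions,
                        sem_fits=sem_fits, effects=effects, config=config)


def _sem_table(fit: SEMFit) -> pd.DataFrame:
    rows = []
    for resp, eq in fit.equations.items():
        for pred in eq.predictors:
            rows.append({"response": resp, "predictor": pred,
                         "coef": eq.coefs[pred],
                         "std_coef": eq.std_coefs[pred],
                         "p": eq.p_values[pred],
                         "r_squared": eq.r_squared, "n": eq.n})
    return pd.DataFrame(rows)


def write_bundle(bundle: ResultBundle, out_dir: str | Path) -> None:
    """Write every result table (tab-separated) plus the resolved config."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.filter_report.to_csv(out / "filter_report.tsv", sep="\t", index=False)
    bundle.index_sets.to_csv(out / "index_sets.tsv", sep="\t", index=False)
    bundle.records.to_csv(out / "records.tsv", sep="\t", index=False)
    bundle.regressions.to_csv(out / "regression_table.tsv", sep="\t", index=False)
    bundle.effects.to_csv(out / "effects.tsv", sep="\t", index=False)
    for name, fit in bundle.sem_fits.items():
        _sem_table(fit).to_csv(out / f"sem_{name}.tsv", sep="\t", index=False)
    (out / "run_config.json").write_text(
        json.dumps(dataclasses.asdict(bundle.config), indent=2, default=str))


def run_all(config: RunConfig) -> ResultBundle:
    """File-based entry point: read the inputs named in the config, analyze,
    and (if an output directory is set) write the result bundle."""
    if not (config.networks_dir and config.traits_path and config.covariates_path):
        raise ValueError("run_all needs networks_dir, traits_path and covariates_path")
    networks = read_networks_dir(config.networks_dir)
    traits = read_trait_table(config.traits_path)
    covariates = read_covariates(config.covariates_path)
    bundle = analyze_study(networks, traits, covariates, config)
    if config.out_dir:
        write_bundle(bundle, config.out_dir)
    return bundle
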