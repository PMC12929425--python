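"""Fixed-marginal null matrices and delta standardization of indices.

Observed indices are compared against randomized networks that preserve the
network's dimensions and its row and column marginal totals, via Patefield's
classic fixed-marginal contingency-table sampler (``scipy.stats.random_table``).
The delta transformation subtracts the null mean from the raw index:

    delta = raw - mean(index over n_null null matrices)

so positive deltas mean "more structured than expected under fixed marginals".
Weights are visit counts; non-integer weights are rounded half-up before the
marginals are computed.

A second null, ``fill``, is available behind a flag: it keeps the multiset of
positive cell values and shuffles their positions, preserving connectance
instead of the marginals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Literal, Sequence

import numpy as np
from scipy import stats

from .network_io import InteractionNetwork

#: default number of null replicates
DEFAULT_N_NULL = 100

#: how many times a degenerate null replicate may be redrawn
MAX_REDRAWS = 100

NullVariant = Literal["fixed_marginals", "fill"]


@dataclass(frozen=True)
class NullEnsemble:
    """Index values over null replicates of one network."""

    index_name: str
    values: tuple[float, ...]
    n_null: int
    seed: int

    def __post_init__(self) -> None:
        if len(self.values) != self.n_null:
            raise ValueError("ensemble length differs from n_null")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite null index value")

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))


def _round_half_up(w: np.ndarray) -> np.ndarray:
    return np.floor(w + 0.5).astype(int)


def null_matrix(row_totals: Sequence[int], col_totals: Sequence[int],
                seed: int | np.random.Generator) -> np.ndarray:
    """One random non-negative integer matrix with the given marginals.

    Sampling follows Patefield's algorithm, the classic fixed-marginal
    contingency-table sampler (each table drawn with its hypergeometric
    probability conditional on the marginals).  Dimensions and both marginal
    vectors are preserved exactly on every draw.
    """
    r = np.asarray(row_totals, dtype=int)
    c = np.asarray(col_totals, dtype=int)
    if np.any(r < 0) or np.any(c < 0):
        raise ValueError("marginal totals must be non-negative")
    if r.sum() != c.sum() or r.sum() == 0:
        raise ValueError(
            f"marginal totals disagree (rows {r.sum()}, columns {c.sum()}) or are zero"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return stats.random_table(r, c).rvs(random_state=rng).astype(int)


def _fill_null(w: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Connectance-preserving null: shuffle the positions of the positive
    cells, keeping their values."""
    flat = np.zeros(w.size)
    vals = w[w > 0]
    pos = rng.choice(w.size, size=vals.size, replace=False)
    flat[pos] = rng.permutation(vals)
    return flat.reshape(w.shape)


def null_network(network: InteractionNetwork, rng: np.random.Generator,
                 variant: NullVariant = "fixed_marginals") -> InteractionNetwork:
    """A null replicate of ``network`` with the same labels."""
    w = network.weights
    if variant == "fixed_marginals":
        wi = _round_half_up(w)
        nw = null_matrix(wi.sum(axis=1), wi.sum(axis=0), rng).astype(float)
    elif variant == "fill":
        nw = _fill_null(w, rng)
    else:
        raise ValueError(f"unknown null variant {variant!r}")
    return InteractionNetwork(
        network_id=f"{network.network_id}:null",
        plant_ids=network.plant_ids,
        pollinator_ids=network.pollinator_ids,
        weights=nw,
    )


def null_ensemble(network: InteractionNetwork,
                  index_fn: Callable[[InteractionNetwork], float],
                  index_name: str,
                  n_null: int = DEFAULT_N_NULL,
                  seed: int = 0,
                  variant: NullVariant = "fixed_marginals") -> NullEnsemble:
    """Index values over ``n_null`` null replicates.

    A replicate on which the index is undefined (e.g. a null draw with an
    empty row, where an index requires validated structure) is redrawn, up to
    ``MAX_REDRAWS`` attempts per replicate.
    """
    rng = np.random.default_rng(seed)
    values: list[float] = []
    for _ in range(n_null):
        for attempt in range(MAX_REDRAWS):
            cand = null_network(network, rng, variant)
            try:
                v = float(index_fn(cand.validate()))
            except (ValueError, ZeroDivisionError):
                continue
            if np.isfinite(v):
                values.append(v)
                break
        else:
            raise RuntimeError(
                f"{network.network_id}: index {index_name!r} undefined on "
                f"{MAX_REDRAWS} successive null draws"
            )
    return NullEnsemble(index_name=index_name, values=tuple(values),
                        n_null=n_null, seed=seed)


def delta_index(network: InteractionNetwork,
                index_fn: Callable[[InteractionNetwork], float],
                index_name: str = "index",
                n_null: int = DEFAULT_N_NULL,
                seed: int = 0,
                variant: NullVariant = "fixed_marginals") -> tuple[float, float, float]:
    """(raw, null_mean, delta) of an index, with delta = raw - null_mean."""
    if n_null < 2:
        raise ValueError("n_null must be >= 2")
    raw = float(index_fn(network))
    ens = null_ensemble(network, index_fn, index_name, n_null=n_null,
                        seed=seed, variant=variant)
    return raw, ens.mean, raw - ens.mean
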