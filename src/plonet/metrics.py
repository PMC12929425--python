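"""Static structural indices of weighted bipartite networks.

Three indices are provided:

* **connectance** -- fraction of realized links out of all possible
  plant x pollinator links, computed on the presence/absence matrix;
* **weighted NODF** -- nestedness by overlap and decreasing fill on the
  weighted matrix: a poorer row (or column) scores by how many of its
  positive cells are strictly exceeded by the richer partner, with ties in
  marginal totals contributing nothing;
* **Barber bipartite modularity Q** -- observed within-module weight minus
  the marginal-product expectation, maximized either by a seeded weighted
  label-propagation heuristic with agglomerative merging, or exactly by
  exhaustive search on small networks.

Nestedness and modularity operate on the weighted matrix; connectance on the
binarized one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Literal, Mapping

import numpy as np

from .network_io import InteractionNetwork, binarize

#: vertex-count bound above which exhaustive modularity search is refused
EXHAUSTIVE_LIMIT = 12

#: default number of seeded label-propagation restarts
DEFAULT_RESTARTS = 10


@dataclass(frozen=True)
class ModulePartition:
    """Assignment of every plant and pollinator to a module label."""

    plant_modules: Mapping[str, int]
    pollinator_modules: Mapping[str, int]

    @property
    def assignment(self) -> dict[str, int]:
        return {**dict(self.plant_modules), **dict(self.pollinator_modules)}

    @property
    def n_modules(self) -> int:
        return len(set(self.plant_modules.values())
                   | set(self.pollinator_modules.values()))

    def labels_for(self, network: InteractionNetwork) -> tuple[np.ndarray, np.ndarray]:
        try:
            row = np.array([self.plant_modules[p] for p in network.plant_ids])
            col = np.array([self.pollinator_modules[a] for a in network.pollinator_ids])
        except KeyError as exc:
            raise KeyError(f"vertex {exc.args[0]!r} missing from partition") from exc
        return row, col


def connectance(network: InteractionNetwork) -> float:
    """Proportion of realized interactions out of all possible ones."""
    if network.n_plants == 0 or network.n_pollinators == 0:
        raise ValueError(f"{network.network_id}: zero-dimension network")
    b = binarize(network).weights
    return float(b.sum() / b.size)


# ---------------------------------------------------------------------------
# Weighted NODF


def weighted_nodf(network: InteractionNetwork) -> float:
    """Weighted NODF nestedness in [0, 100].

    For each ordered pair of rows (i, j) whose marginal totals strictly
    decrease (t_i > t_j), the pair contributes
    ``100 * #{k : 0 < w_jk < w_ik} / #{k : w_jk > 0}``; ties contribute 0.
    Column pairs are scored the same way on the transpose, and the index is
    the mean over all unordered row pairs and column pairs.
    """
    if network.n_plants < 2 or network.n_pollinators < 2:
        raise ValueError(
            f"{network.network_id}: weighted NODF needs >=2 plants and >=2 pollinators"
        )
    w = network.weights
    total = _wnodf_pair_sum(w) + _wnodf_pair_sum(w.T)
    m, n = w.shape
    n_pairs = m * (m - 1) / 2 + n * (n - 1) / 2
    return float(total / n_pairs)


def _wnodf_pair_sum(w: np.ndarray) -> float:
    """Sum of contributions over unordered row pairs of ``w`` (vectorized)."""
    totals = w.sum(axis=1)
    # decreasing[i, j] True when row i strictly richer than row j
    decreasing = totals[:, None] > totals[None, :]
    # overlap[i, j] = #{k : 0 < w_jk < w_ik}
    less = (w[None, :, :] < w[:, None, :]) & (w[None, :, :] > 0)
    overlap = less.sum(axis=2)
    fill = np.maximum((w > 0).sum(axis=1), 1)  # poorer row is never empty post-validation
    contrib = 100.0 * overlap / fill[None, :]
    return float(contrib[decreasing].sum())


# ---------------------------------------------------------------------------
# Barber bipartite modularity


def barber_modularity(network: InteractionNetwork,
                      partition: ModulePartition) -> float:
    """Barber's bipartite Q for a given module partition.

    ``Q = (1/m) * sum_ij (w_ij - r_i c_j / m) [plant i, pollinator j share a
    module]`` with ``m`` the total weight, ``r_i`` row totals and ``c_j``
    column totals.  The single-module partition gives exactly 0.
    """
    row_lab, col_lab = partition.labels_for(network)
    return _q_from_labels(network.weights, row_lab, col_lab)


def _q_from_labels(w: np.ndarray, row_lab: np.ndarray, col_lab: np.ndarray) -> float:
    m = w.sum()
    if m <= 0:
        raise ValueError("network has no weight")
    r = w.sum(axis=1)
    c = w.sum(axis=0)
    same = row_lab[:, None] == col_lab[None, :]
    return float(((w - np.outer(r, c) / m) * same).sum() / m)


def optimize_modularity(
    network: InteractionNetwork,
    seed: int = 0,
    method: Literal["label_propagation", "exhaustive"] = "label_propagation",
    n_restarts: int = DEFAULT_RESTARTS,
) -> tuple[ModulePartition, float]:
    """Find a high-Q module partition.

    ``label_propagation`` runs ``n_restarts`` seeded rounds of two-phase
    optimization (side-wise relabelling to the best-gain neighbouring label,
    then greedy module merges accepted when Q increases) and keeps the best;
    it falls back to the single-module partition (Q = 0) if the heuristic
    lands below zero.  ``exhaustive`` returns the true maximum over all set
    partitions and is refused above ``EXHAUSTIVE_LIMIT`` vertices.
    """
    w = network.weights
    if method == "exhaustive":
        if network.size > EXHAUSTIVE_LIMIT:
            raise ValueError(
                f"{network.network_id}: exhaustive search limited to "
                f"{EXHAUSTIVE_LIMIT} vertices (network has {network.size})"
            )
        row_lab, col_lab, q = _exhaustive_partition(w)
    elif method == "label_propagation":
        rng = np.random.default_rng(seed)
        best = (-np.inf, None, None)
        for _ in range(max(1, n_restarts)):
            rl, cl, q = _label_propagation_once(w, rng)
            if q > best[0]:
                best = (q, rl, cl)
        q, row_lab, col_lab = best
        if q < 0:  # single-module fallback is always admissible at Q = 0
            row_lab = np.zeros(w.shape[0], dtype=int)
            col_lab = np.zeros(w.shape[1], dtype=int)
            q = 0.0
    else:
        raise ValueError(f"unknown method {method!r}")

    partition = ModulePartition(
        plant_modules=dict(zip(network.plant_ids, (int(x) for x in row_lab))),
        pollinator_modules=dict(zip(network.pollinator_ids, (int(x) for x in col_lab))),
    )
    return partition, float(q)


def _label_propagation_once(w: np.ndarray,
                            rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, float]:
    m = w.sum()
    r = w.sum(axis=1)
    c = w.sum(axis=0)
    n_rows, n_cols = w.shape
    # seeded random initial labels on the plant side; pollinators then adopt
    # their best-gain counterpart label
    row_lab = rng.permutation(n_rows)
    col_lab = _best_side_labels(w.T, c, r, row_lab, m)
    q = _q_from_labels(w, row_lab, col_lab)
    while True:
        row_lab = _best_side_labels(w, r, c, col_lab, m)
        col_lab = _best_side_labels(w.T, c, r, row_lab, m)
        row_lab, col_lab = _merge_modules(w, row_lab, col_lab, m)
        q_new = _q_from_labels(w, row_lab, col_lab)
        if q_new <= q + 1e-12:
            break
        q = q_new
    return row_lab, col_lab, q


def _best_side_labels(w: np.ndarray, own_tot: np.ndarray, other_tot: np.ndarray,
                      other_lab: np.ndarray, m: float) -> np.ndarray:
    """Best-gain label per vertex of one side, given the other side's labels.

    A vertex's Q contribution depends only on the opposite side, so the whole
    side is updated at once (exact coordinate ascent).  Ties break to the
    smallest label index; a vertex whose best gain is negative takes a fresh
    singleton label (contribution 0).
    """
    labels = np.unique(other_lab)
    ind = (other_lab[None, :] == labels[:, None]).astype(float)  # (L, n_other)
    s = w @ ind.T                                # (n_side, L) weight to each label
    cap = ind @ other_tot                        # (L,) opposite-side total per label
    gain = s - np.outer(own_tot, cap) / m
    best_idx = np.argmax(gain, axis=1)           # argmax takes first (smallest) on ties
    best_gain = gain[np.arange(len(own_tot)), best_idx]
    out = labels[best_idx]
    fresh = best_gain < 0
    if fresh.any():
        start = labels.max() + 1
        out = out.copy()
        out[fresh] = np.arange(start, start + fresh.sum())
    return out


def _merge_modules(w: np.ndarray, row_lab: np.ndarray, col_lab: np.ndarray,
                   m: float) -> tuple[np.ndarray, np.ndarray]:
    """Greedily merge module pairs while any merge increases Q."""
    while True:
        labels2 = np.unique(np.concatenate([np.unique(row_lab), np.unique(col_lab)]))
        lut = {lab: i for i, lab in enumerate(labels2)}
        ri = np.array([lut[x] for x in row_lab])
        ci = np.array([lut[x] for x in col_lab])
        L = len(labels2)
        if L < 2:
            return row_lab, col_lab
        rows_ind = (ri[None, :] == np.arange(L)[:, None]).astype(float)
        cols_ind = (ci[None, :] == np.arange(L)[:, None]).astype(float)
        wmod = rows_ind @ w @ cols_ind.T          # (L, L) weight plant-k x poll-l
        rk = rows_ind @ w.sum(axis=1)
        cl = cols_ind @ w.sum(axis=0)
        # delta-Q of merging modules k and l
        expct = np.outer(rk, cl)                  # R_k * C_l
        delta = (wmod + wmod.T - (expct + expct.T) / m) / m
        np.fill_diagonal(delta, -np.inf)
        k, l = np.unravel_index(np.argmax(delta), delta.shape)
        if delta[k, l] <= 1e-12:
            return row_lab, col_lab
        keep, drop = labels2[min(k, l)], labels2[max(k, l)]
        row_lab = np.where(row_lab == drop, keep, row_lab)
        col_lab = np.where(col_lab == drop, keep, col_lab)


def _set_partitions(items: list[int]) -> Iterator[list[list[int]]]:
    """All set partitions of ``items`` (restricted-growth enumeration)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def _exhaustive_partition(w: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Exact maximum-Q partition.

    Q decomposes over modules as ``(W_kk - R_k C_k / m) / m``, and a vertex of
    the unpartitioned side interacts only with the partitioned side's groups,
    so it suffices to enumerate set partitions of the smaller side and assign
    each opposite vertex to its best group (or a singleton at gain 0).  This
    is equivalent to the maximum over all vertex set partitions.
    """
    transposed = w.shape[1] < w.shape[0]
    a = w.T if transposed else w                  # partition rows of `a`
    m = a.sum()
    r = a.sum(axis=1)
    c = a.sum(axis=0)
    best_q, best = -np.inf, None
    for part in _set_partitions(list(range(a.shape[0]))):
        gains = np.stack([
            a[group].sum(axis=0) - c * (r[group].sum() / m) for group in part
        ])                                        # (G, n_cols)
        best_g = np.argmax(gains, axis=0)
        best_gain = gains[best_g, np.arange(a.shape[1])]
        col_lab = np.where(best_gain > 0, best_g, -1)
        q = best_gain[best_gain > 0].sum() / m
        if q > best_q:
            best_q = q
            row_lab = np.empty(a.shape[0], dtype=int)
            for g, group in enumerate(part):
                row_lab[group] = g
            # unassigned opposite vertices become singletons
            free = col_lab < 0
            cl = col_lab.copy()
            cl[free] = len(part) + np.arange(free.sum())
            best = (row_lab, cl)
    row_lab, col_lab = best
    if transposed:
        row_lab, col_lab = col_lab, row_lab
    return row_lab, col_lab, float(best_q)
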