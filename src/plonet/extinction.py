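"""Plant extinction simulations and robustness to species loss.

Plants are removed one at a time in a prescribed order; a pollinator goes
secondarily extinct once it has no remaining positive interaction.  The
extinction curve records the surviving pollinator fraction after each
removal, starting at (0, 1) and reaching (1, 0) when the last plant goes
(validated networks have no unattached pollinator).  Robustness is the
trapezoidal area under that curve, so the identity network declines linearly
and scores exactly 0.5 under every order.

Removal policies: uniform random orders, or ploidy-targeted orders in which
all plants of the targeted cytotype are removed first (in random order among
themselves) followed by the remaining plants; plants of unknown ploidy are
grouped with the non-targeted block, so targeting touches only what is
classified.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np

from .network_io import InteractionNetwork

PolicyKind = Literal["random", "diploids_first", "polyploids_first"]

#: default number of random removal orders averaged per network
DEFAULT_N_ORDERS = 100


@dataclass(frozen=True)
class ExtinctionCurve:
    """Surviving pollinator fraction as plants are sequentially removed."""

    points: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        xs = [p[0] for p in self.points]
        ys = [p[1] for p in self.points]
        if xs != sorted(set(xs)):
            raise ValueError("curve x values must be strictly increasing")
        if any(b > a + 1e-12 for a, b in zip(ys, ys[1:])):
            raise ValueError("surviving fraction must be non-increasing")

    @property
    def x(self) -> np.ndarray:
        return np.array([p[0] for p in self.points])

    @property
    def y(self) -> np.ndarray:
        return np.array([p[1] for p in self.points])


@dataclass(frozen=True)
class RemovalPolicy:
    """How plant extinction orders are drawn."""

    kind: PolicyKind = "random"
    seed: int = 0


def extinction_curve(network: InteractionNetwork,
                     removal_order: Sequence[str]) -> ExtinctionCurve:
    """Simulate secondary pollinator extinctions along one removal order."""
    if sorted(removal_order) != sorted(network.plant_ids):
        raise ValueError(
            f"{network.network_id}: removal order is not a permutation of the plants"
        )
    idx = {p: i for i, p in enumerate(network.plant_ids)}
    b = network.weights > 0
    n_plants, n_poll = b.shape
    alive_links = b.sum(axis=0).astype(int)   # positive partners per pollinator
    surviving = int((alive_links > 0).sum())  # == n_poll after validation
    points = [(0.0, surviving / n_poll)]
    for k, plant in enumerate(removal_order, start=1):
        alive_links -= b[idx[plant]]
        surviving = int((alive_links > 0).sum())
        points.append((k / n_plants, surviving / n_poll))
    return ExtinctionCurve(tuple(points))


def robustness(curve: ExtinctionCurve) -> float:
    """Area under the extinction curve (trapezoid rule), in [0, 1]."""
    return float(np.trapezoid(curve.y, curve.x))


def draw_removal_order(network: InteractionNetwork,
                       policy: RemovalPolicy,
                       rng: np.random.Generator,
                       ploidy: Mapping[str, str] | None = None) -> list[str]:
    """One plant removal order under the given policy."""
    plants = list(network.plant_ids)
    if policy.kind == "random":
        return list(rng.permutation(plants))
    if ploidy is None:
        raise ValueError("ploidy-targeted policy requires a ploidy map")
    target = {"diploids_first": "diploid",
              "polyploids_first": "polyploid"}[policy.kind]
    first = [p for p in plants if ploidy.get(p, "unknown") == target]
    rest = [p for p in plants if ploidy.get(p, "unknown") != target]
    if not any(ploidy.get(p, "unknown") in ("diploid", "polyploid") for p in plants):
        raise ValueError(
            f"{network.network_id}: targeted policy with no ploidy-classified plants"
        )
    return list(rng.permutation(first)) + list(rng.permutation(rest))


def mean_robustness(network: InteractionNetwork,
                    policy: RemovalPolicy = RemovalPolicy(),
                    n_orders: int = DEFAULT_N_ORDERS,
                    ploidy: Mapping[str, str] | None = None) -> float:
    """Mean robustness over ``n_orders`` seeded removal orders."""
    if n_orders < 1:
        raise ValueError("n_orders must be >= 1")
    rng = np.random.default_rng(policy.seed)
    vals = [robustness(extinction_curve(network,
                                        draw_removal_order(network, policy, rng, ploidy)))
            for _ in range(n_orders)]
    return float(np.mean(vals))
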