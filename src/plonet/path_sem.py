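"""Piecewise structural-equation model of ploidy, traits, climate and
network structure.

The path diagram relates precipitation seasonality (B15), polyploid
frequency (PP), self-compatible frequency (SC), restrictive-flower frequency
(RS), log network size (NS) and one focal delta-standardized network index
(Y) through five structural equations::

    PP ~ B15
    SC ~ PP + B15
    RS ~ PP + B15
    NS ~ B15
    Y  ~ PP + SC + RS + B15 + NS

Estimation is local ("piecewise"): each equation is an ordinary least
squares fit on its own complete cases, which keeps networks with partial
trait coverage informative.  Coefficients are reported raw and standardized
(``coef * sd(x) / sd(y)`` over the equation's complete cases).

Model adequacy is tested by d-separation: every unordered pair of
non-adjacent variables yields an independence claim conditioned on the union
of the pair's parents, tested as the p-value of the added term in the
corresponding regression (response = the later variable in topological
order).  Fisher's C = -2 * sum(ln p) over the claims is chi-square with
2 * (#claims) degrees of freedom under the model.  None of the claims of the
base diagram involves Y, so C is identical across the four index models
fitted to the same records.

Effects of PP on Y decompose over directed paths: the direct effect is the
PP -> Y coefficient, each mediated path contributes the product of its
standardized coefficients, and the total effect is the sum of all of them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

#: canonical record-column names of the model variables
VAR_COLUMNS = {
    "B15": "log_bio15",
    "B10": "bio10",
    "PP": "pct_pp",
    "SC": "pct_sc",
    "RS": "pct_restrictive",
    "NS": "log_network_size",
}

#: robustness-check variants of the base diagram
SEM_VARIANTS = ("base", "bio10", "both", "no-rs", "no-sc")


@dataclass(frozen=True)
class SEMModel:
    """A directed acyclic path model given as response -> predictors."""

    equations: Mapping[str, tuple[str, ...]]
    exogenous: tuple[str, ...]

    @property
    def variables(self) -> tuple[str, ...]:
        seen = list(self.exogenous)
        for resp, preds in self.equations.items():
            for v in (*preds, resp):
                if v not in seen:
                    seen.append(v)
        return tuple(seen)

    @property
    def edges(self) -> tuple[tuple[str, str], ...]:
        return tuple((p, r) for r, preds in self.equations.items() for p in preds)

    def parents(self, v: str) -> tuple[str, ...]:
        return tuple(self.equations.get(v, ()))

    def topological_order(self) -> list[str]:
        order: list[str] = []
        pending = dict(self.equations)
        placed = set(self.exogenous)
        order.extend(self.exogenous)
        while pending:
            progress = False
            for resp in list(pending):
                if set(pending[resp]) <= placed:
                    order.append(resp)
                    placed.add(resp)
                    del pending[resp]
                    progress = True
            if not progress:
                raise ValueError("model graph is cyclic")
        return order


@dataclass(frozen=True)
class DSepClaim:
    """Independence of (a, b) conditional on the union of their parents."""

    a: str           # earlier in topological order
    b: str           # later; used as the regression response
    conditioning: tuple[str, ...]


@dataclass(frozen=True)
class EquationFit:
    response: str
    predictors: tuple[str, ...]
    coefs: dict[str, float]
    std_coefs: dict[str, float]
    p_values: dict[str, float]
    r_squared: float
    n: int


@dataclass(frozen=True)
class SEMFit:
    model: SEMModel
    index_name: str
    equations: dict[str, EquationFit]
    fisher_c: float
    df: int
    adequacy_p: float
    n: int
    claims: tuple[DSepClaim, ...] = field(default=())
    claim_p_values: tuple[float, ...] = field(default=())

    def std_coef(self, source: str, target: str) -> float:
        return self.equations[target].std_coefs[source]


@dataclass(frozen=True)
class PathEffects:
    """Direct/indirect/total decomposition of one source->target effect."""

    direct: float
    indirect_components: dict[str, float]
    total: float


def build_model(index_col: str, variant: str = "base") -> SEMModel:
    """The path diagram for one focal index column, or a robustness variant."""
    if variant not in SEM_VARIANTS:
        raise ValueError(f"unknown SEM variant {variant!r}; pick from {SEM_VARIANTS}")
    env: tuple[str, ...]
    if variant == "bio10":
        env = (VAR_COLUMNS["B10"],)
    elif variant == "both":
        env = (VAR_COLUMNS["B10"], VAR_COLUMNS["B15"])
    else:
        env = (VAR_COLUMNS["B15"],)
    pp, sc, rs, ns = (VAR_COLUMNS[k] for k in ("PP", "SC", "RS", "NS"))
    mediators = [m for m in (sc, rs)
                 if not (variant == "no-sc" and m == sc)
                 and not (variant == "no-rs" and m == rs)]
    eqs: dict[str, tuple[str, ...]] = {pp: env}
    for m in mediators:
        eqs[m] = (pp, *env)
    eqs[ns] = env
    eqs[index_col] = (pp, *mediators, *env, ns)
    return SEMModel(equations=eqs, exogenous=env)


def dsep_basis(model: SEMModel) -> list[DSepClaim]:
    """The d-separation basis set: one claim per non-adjacent variable pair,
    conditioned on the union of the pair's parents."""
    order = model.topological_order()
    adjacent = {frozenset(e) for e in model.edges}
    claims = []
    for i, a in enumerate(order):
        for b in order[i + 1:]:
            if frozenset((a, b)) in adjacent:
                continue
            cond = tuple(dict.fromkeys((*model.parents(a), *model.parents(b))))
            cond = tuple(c for c in cond if c not in (a, b))
            claims.append(DSepClaim(a=a, b=b, conditioning=cond))
    return claims


def _fit_equation(records: pd.DataFrame, response: str,
                  predictors: Sequence[str]) -> EquationFit:
    cols = [response, *predictors]
    sub = records[cols].dropna()
    n = len(sub)
    if n < 3:
        raise ValueError(f"equation {response}: fewer than 3 complete cases")
    y = sub[response].to_numpy(float)
    if np.ptp(y) == 0:
        raise ValueError(f"equation {response}: zero-variance response")
    x = sm.add_constant(sub[list(predictors)].to_numpy(float))
    fit = sm.OLS(y, x).fit()
    sd_y = float(np.std(y, ddof=1))
    coefs, std_coefs, pvals = {}, {}, {}
    for k, pred in enumerate(predictors, start=1):
        sd_x = float(np.std(sub[pred].to_numpy(float), ddof=1))
        coefs[pred] = float(fit.params[k])
        std_coefs[pred] = float(fit.params[k]) * sd_x / sd_y
        pvals[pred] = float(fit.pvalues[k])
    return EquationFit(response=response, predictors=tuple(predictors),
                       coefs=coefs, std_coefs=std_coefs, p_values=pvals,
                       r_squared=float(fit.rsquared), n=n)


def _claim_p(records: pd.DataFrame, claim: DSepClaim) -> float:
    """p-value of the added term: regress the later variable on the earlier
    one plus the conditioning set, on complete cases."""
    cols = [claim.b, claim.a, *claim.conditioning]
    sub = records[cols].dropna()
    if len(sub) < len(cols) + 1:
        raise ValueError(f"claim ({claim.a},{claim.b}): too few complete cases")
    y = sub[claim.b].to_numpy(float)
    x = sm.add_constant(sub[[claim.a, *claim.conditioning]].to_numpy(float))
    fit = sm.OLS(y, x).fit()
    return float(fit.pvalues[1])


def fisher_c(p_values: Sequence[float]) -> tuple[float, int, float]:
    """Fisher's C statistic, its df = 2 * #claims, and the chi-square p."""
    ps = np.clip(np.asarray(p_values, dtype=float), 1e-300, 1.0)
    c = float(-2.0 * np.log(ps).sum())
    df = 2 * len(ps)
    p = float(stats.chi2.sf(c, df)) if df > 0 else 1.0
    return c, df, p


def fit_sem(records: pd.DataFrame, index_name: str,
            variant: str = "base",
            complete_cases_only: bool = False) -> SEMFit:
    """Fit the piecewise path model for one delta index.

    ``index_name`` is one of connectance/nestedness/modularity/robustness (or
    directly a record column).  ``complete_cases_only`` restricts every
    equation to rows complete for *all* model variables (the small strict
    cohort), instead of per-equation complete cases.
    """
    index_col = (index_name if index_name in records.columns
                 else f"delta_{index_name}")
    if index_col not in records.columns:
        raise KeyError(f"no record column for index {index_name!r}")
    model = build_model(index_col, variant)
    data = records
    if complete_cases_only:
        data = records[list(model.variables)].dropna()
    fits = {resp: _fit_equation(data, resp, preds)
            for resp, preds in model.equations.items()}
    claims = tuple(dsep_basis(model))
    ps = tuple(_claim_p(data, c) for c in claims)
    c, df, p = fisher_c(ps)
    n = int(data[list(model.variables)].dropna(how="all").shape[0])
    return SEMFit(model=model, index_name=index_name, equations=fits,
                  fisher_c=c, df=df, adequacy_p=p, n=n,
                  claims=claims, claim_p_values=ps)


def _all_paths(edges: Sequence[tuple[str, str]], source: str,
               target: str) -> list[tuple[str, ...]]:
    out: dict[str, list[str]] = {}
    for a, b in edges:
        out.setdefault(a, []).append(b)
    paths: list[tuple[str, ...]] = []

    def walk(node: str, trail: tuple[str, ...]) -> None:
        if node == target:
            paths.append(trail)
            return
        for nxt in out.get(node, ()):
            if nxt not in trail:
                walk(nxt, trail + (nxt,))

    walk(source, (source,))
    return paths


def decompose_effects(fit: SEMFit, source: str = "pct_pp",
                      target: str | None = None) -> PathEffects:
    """Direct, indirect and total standardized effects of source on target.

    Every directed path contributes the product of its standardized edge
    coefficients; the single-edge path is the direct effect and the total is
    the sum over all paths.  With no path, all effects are zero.
    """
    model = fit.model
    if target is None:
        target = (fit.index_name if fit.index_name in model.variables
                  else f"delta_{fit.index_name}")
    if source not in model.variables or target not in model.variables:
        raise KeyError(f"{source!r} or {target!r} not in the fitted model")
    direct = 0.0
    indirect: dict[str, float] = {}
    for path in _all_paths(model.edges, source, target):
        coef = math.prod(fit.std_coef(a, b) for a, b in zip(path, path[1:]))
        if len(path) == 2:
            direct = coef
        else:
            indirect["->".join(path)] = coef
    total = direct + sum(indirect.values())
    return PathEffects(direct=direct, indirect_components=indirect, total=total)
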