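"""Piecewise SEM: basis set, Fisher's C, estimation and path decomposition."""

import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from plonet import (build_model, decompose_effects, dsep_basis, fisher_c,
                    fit_sem, simulate_path_model)
from plonet.path_sem import EquationFit, SEMFit, SEMModel


class TestBasisSet:
    def test_base_model_has_four_claims_df_eight(self):
        model = build_model("delta_nestedness")
        claims = dsep_basis(model)
        assert len(claims) == 4
        pairs = {frozenset((c.a, c.b)) for c in claims}
        assert pairs == {
            frozenset(("pct_sc", "pct_restrictive")),
            frozenset(("pct_pp", "log_network_size")),
            frozenset(("pct_sc", "log_network_size")),
            frozenset(("pct_restrictive", "log_network_size")),
        }
        for c in claims:
            if "log_network_size" in (c.a, c.b) and "pct_pp" not in (c.a, c.b):
                assert set(c.conditioning) == {"pct_pp", "log_bio15"}

    def test_no_claim_involves_the_index(self):
        # the index equation contains every other variable, so adequacy is
        # shared across the four index models fitted to the same records
        model = build_model("delta_modularity")
        for c in dsep_basis(model):
            assert "delta_modularity" not in (c.a, c.b, *c.conditioning)

    def test_fisher_c_identical_across_indices(self):
        df = simulate_path_model(300, seed=5)
        for extra in ("connectance", "modularity"):
            df[f"delta_{extra}"] = df["delta_nestedness"]
        fits = [fit_sem(df, name) for name in
                ("nestedness", "connectance", "modularity")]
        assert len({f.fisher_c for f in fits}) == 1
        assert all(f.df == 8 for f in fits)

    def test_added_edge_removes_a_claim(self):
        base = build_model("delta_nestedness")
        eqs = {r: tuple(p) for r, p in base.equations.items()}
        eqs["pct_restrictive"] = (*eqs["pct_restrictive"], "pct_sc")
        model = SEMModel(equations=eqs, exogenous=base.exogenous)
        assert len(dsep_basis(model)) == 3

    def test_saturated_model_has_empty_basis(self):
        model = SEMModel(equations={"b": ("a",), "c": ("a", "b")},
                         exogenous=("a",))
        assert dsep_basis(model) == []
        c, df, p = fisher_c([])
        assert (c, df, p) == (0.0, 0, 1.0)


class TestFitSem:
    def test_univariate_std_coef_equals_pearson_r(self):
        df = simulate_path_model(500, seed=2)
        fit = fit_sem(df, "nestedness")
        r = np.corrcoef(df["log_bio15"], df["pct_pp"])[0, 1]
        assert fit.std_coef("log_bio15", "pct_pp") == pytest.approx(r, abs=1e-9)

    def test_equations_use_their_own_complete_cases(self):
        df = simulate_path_model(400, seed=3, missing_sc=0.5)
        fit = fit_sem(df, "nestedness")
        assert fit.equations["pct_sc"].n < 400
        assert fit.equations["pct_restrictive"].n == 400

    def test_complete_cases_only_flag(self):
        df = simulate_path_model(400, seed=4, missing_sc=0.5, missing_rs=0.3)
        strict = fit_sem(df, "nestedness", complete_cases_only=True)
        ns = {eq.n for eq in strict.equations.values()}
        assert len(ns) == 1  # every equation on the same strict cohort

    def test_zero_variance_response_named(self):
        df = simulate_path_model(100, seed=1)
        df["pct_sc"] = 0.5
        with pytest.raises(ValueError, match="pct_sc"):
            fit_sem(df, "nestedness")

    def test_recovery_at_moderate_n(self):
        df = simulate_path_model(4000, seed=10)
        fit = fit_sem(df, "nestedness")
        assert fit.std_coef("pct_pp", "pct_sc") == pytest.approx(-0.20, abs=0.05)
        assert fit.std_coef("pct_pp", "pct_restrictive") == pytest.approx(-0.375, abs=0.05)
        assert fit.std_coef("pct_pp", "delta_nestedness") == pytest.approx(0.206, abs=0.05)

    def test_median_recovery_error_at_cohort_size(self):
        errs = []
        for s in range(200):
            df = simulate_path_model(313, seed=1000 + s)
            fit = fit_sem(df, "nestedness")
            errs.append(abs(fit.std_coef("pct_pp", "delta_nestedness") - 0.206))
        assert float(np.median(errs)) <= 0.05


class TestDecomposeEffects:
    def _manual_fit(self, model, coefs):
        eqs = {}
        for resp, preds in model.equations.items():
            eqs[resp] = EquationFit(
                response=resp, predictors=tuple(preds),
                coefs={p: coefs.get((p, resp), 0.0) for p in preds},
                std_coefs={p: coefs.get((p, resp), 0.0) for p in preds},
                p_values={p: 1.0 for p in preds}, r_squared=0.0, n=0)
        return SEMFit(model=model, index_name="y", equations=eqs,
                      fisher_c=0.0, df=0, adequacy_p=1.0, n=0)

    def test_matches_networkx_path_enumeration_on_random_dags(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            n_vars = int(rng.integers(3, 9))
            names = [f"v{i}" for i in range(n_vars)]
            coefs, eqs = {}, {}
            for j in range(1, n_vars):
                parents = [names[i] for i in range(j) if rng.random() < 0.5]
                if parents:
                    eqs[names[j]] = tuple(parents)
                    for p in parents:
                        coefs[(p, names[j])] = float(rng.normal())
            model = SEMModel(equations=eqs,
                             exogenous=tuple(n for n in names if n not in eqs))
            fit = self._manual_fit(model, coefs)
            eff = decompose_effects(fit, source=names[0], target=names[-1])
            g = nx.DiGraph(list(model.edges))
            expected = 0.0
            if names[0] in g and names[-1] in g:
                for path in nx.all_simple_paths(g, names[0], names[-1]):
                    expected += math.prod(coefs[(a, b)]
                                          for a, b in zip(path, path[1:]))
            assert eff.total == pytest.approx(expected, abs=1e-12)

    def test_no_mediators_makes_total_equal_direct(self):
        model = SEMModel(equations={"y": ("x",)}, exogenous=("x",))
        fit = self._manual_fit(model, {("x", "y"): 0.3})
        eff = decompose_effects(fit, source="x", target="y")
        assert eff.indirect_components == {}
        assert eff.total == eff.direct == pytest.approx(0.3)

    def test_no_path_gives_zero_effects(self):
        model = SEMModel(equations={"y": ("x",)}, exogenous=("x", "z"))
        fit = self._manual_fit(model, {("x", "y"): 0.3})
        eff = decompose_effects(fit, source="z", target="y")
        assert (eff.direct, eff.indirect_components, eff.total) == (0.0, {}, 0.0)

    def test_variant_without_sc_lacks_sc_mediation(self):
        df = simulate_path_model(300, seed=6)
        fit = fit_sem(df, "nestedness", variant="no-sc")
        eff = decompose_effects(fit)
        assert all("pct_sc" not in k for k in eff.indirect_components)
        assert len(eff.indirect_components) == 1
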