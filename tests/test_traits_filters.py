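"""Trait frequencies, restrictiveness binning and cohort filters."""

import numpy as np
import pandas as pd
import pytest

from plonet import (NetworkCovariates, PlantTraitTable, apply_filters,
                    bin_restrictiveness, path_filter, trait_frequencies,
                    trait_frequency)
from conftest import make_net


def _traits(rows):
    return PlantTraitTable(pd.DataFrame(
        rows, columns=["species", "ploidy", "mating", "restrictiveness"]))


def _cov(ids, **overrides):
    base = {"latitude": 0.0, "longitude": 0.0, "bio4": 500.0,
            "bio10": 15.0, "bio15": 50.0, "bio18": 100.0}
    base.update(overrides)
    return NetworkCovariates(pd.DataFrame(
        [{"network_id": i, **base} for i in ids]))


class TestBinRestrictiveness:
    @pytest.mark.parametrize("level, binned", [
        ("unrestrictive", "not_restrictive"),
        ("low", "not_restrictive"),
        ("moderate", "restrictive"),
        ("high", "restrictive"),
        ("unknown", "unknown"),
    ])
    def test_binning(self, level, binned):
        assert bin_restrictiveness(level) == binned


class TestTraitFrequency:
    def test_denominator_excludes_unknowns(self):
        net = make_net(np.ones((7, 6)))
        traits = _traits([(f"p{i}", p, "unknown", "unknown") for i, p in
                          enumerate(["polyploid", "polyploid", "diploid",
                                     "diploid", "unknown", "unknown", "unknown"])])
        freq, n_known = trait_frequency(net, traits, "ploidy")
        assert (freq, n_known) == (0.5, 4)

    def test_all_unknown_is_undefined(self):
        net = make_net(np.ones((3, 6)))
        traits = _traits([(f"p{i}", "unknown", "unknown", "unknown")
                          for i in range(3)])
        assert trait_frequency(net, traits, "ploidy") == (None, 0)

    def test_all_polyploid_is_one(self):
        net = make_net(np.ones((4, 6)))
        traits = _traits([(f"p{i}", "polyploid", "unknown", "unknown")
                          for i in range(4)])
        assert trait_frequency(net, traits, "ploidy") == (1.0, 4)

    def test_restrictive_counts_binned_levels(self):
        net = make_net(np.ones((4, 6)))
        traits = _traits([("p0", "unknown", "unknown", "high"),
                          ("p1", "unknown", "unknown", "moderate"),
                          ("p2", "unknown", "unknown", "low"),
                          ("p3", "unknown", "unknown", "unknown")])
        freq, n_known = trait_frequency(net, traits, "restrictiveness")
        assert (freq, n_known) == (2 / 3, 3)

    def test_unknown_species_only_shrink_denominator(self):
        net = make_net(np.ones((5, 6)))
        traits = _traits([("p0", "polyploid", "unknown", "unknown"),
                          ("p1", "diploid", "unknown", "unknown")])
        freq, n_known = trait_frequency(net, traits, "ploidy")
        assert (freq, n_known) == (0.5, 2)


class TestApplyFilters:
    def _net(self, n_plants, n_poll, nid="n1"):
        return make_net(np.ones((n_plants, n_poll)), network_id=nid)

    def test_boundary_one_third_coverage_retained(self):
        # 6 classified of 18 plants is exactly one third -> passes ">= 33%"
        net = self._net(18, 6)
        traits = _traits(
            [(f"p{i}", "polyploid" if i < 6 else "unknown", "unknown", "unknown")
             for i in range(18)])
        retained, report = apply_filters([net], traits, _cov(["n1"]))
        assert [n.network_id for n in retained] == ["n1"]
        assert report.empty

    def test_too_few_pollinators_rejected_with_reason(self):
        net = self._net(8, 5)
        traits = _traits([(f"p{i}", "diploid", "unknown", "unknown")
                          for i in range(8)])
        retained, report = apply_filters([net], traits, _cov(["n1"]))
        assert not retained
        assert report.iloc[0]["reasons"] == "min_pollinators"

    def test_missing_climate_rejected(self):
        net = self._net(8, 8)
        traits = _traits([(f"p{i}", "diploid", "unknown", "unknown")
                          for i in range(8)])
        retained, report = apply_filters([net], traits, _cov(["other"]))
        assert report.iloc[0]["reasons"] == "no_climate"
        # a covariate row with a missing bioclim value also fails
        retained2, report2 = apply_filters([net], traits,
                                           _cov(["n1"], bio15=np.nan))
        assert report2.iloc[0]["reasons"] == "no_climate"

    def test_idempotent(self):
        nets = [self._net(8, 8, "a"), self._net(4, 8, "b")]
        traits = _traits([(f"p{i}", "diploid", "unknown", "unknown")
                          for i in range(8)])
        cov = _cov(["a", "b"])
        once, _ = apply_filters(nets, traits, cov)
        twice, report = apply_filters(once, traits, cov)
        assert [n.network_id for n in twice] == [n.network_id for n in once]
        assert report.empty


class TestPathFilter:
    def _make(self, mating, restrictiveness):
        net = make_net(np.ones((2, 6)), network_id="n")
        traits = _traits([("p0", "diploid", mating, restrictiveness),
                          ("p1", "diploid", "unknown", "unknown")])
        return net, traits

    def test_either_trait_known_retained(self):
        net, traits = self._make("unknown", "low")
        assert path_filter([net], traits) == [net]

    def test_both_unknown_dropped(self):
        net, traits = self._make("unknown", "unknown")
        assert path_filter([net], traits) == []

    def test_both_known_retained(self):
        net, traits = self._make("self_compatible", "high")
        assert path_filter([net], traits) == [net]
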