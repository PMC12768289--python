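"""Sediment geochemical indices: Igeo, EF, CF, PLI, PER, USEPA screening."""

import math

import numpy as np
import pandas as pd
import pytest

from metalrisk.core_data import ConfigurationError
from metalrisk.sediment_indices import (
    classify_cf,
    classify_ef,
    classify_igeo,
    classify_per,
    contamination_factor,
    enrichment_factor,
    igeo,
    pollution_load_index,
    potential_ecological_risk,
    sediment_index_table,
    sediment_long_table,
    usepa_sediment_class,
)


class TestIgeo:
    def test_one_and_a_half_background_is_zero(self):
        assert igeo(4.5, 3.0) == pytest.approx(0.0)

    def test_three_backgrounds_is_one(self):
        assert igeo(9.0, 3.0) == pytest.approx(1.0)

    def test_cadmium_at_a2(self):
        v = igeo(1.36, 0.3)
        assert v == pytest.approx(math.log2(1.36 / 0.45), rel=1e-12)
        assert v == pytest.approx(1.60, abs=5e-3)
        assert classify_igeo(v) == "moderate"

    def test_zero_concentration_sentinel(self):
        assert igeo(0.0, 3.0) == -math.inf
        assert classify_igeo(-math.inf) == "uncontaminated"

    def test_invalid_background(self):
        with pytest.raises(ValueError):
            igeo(1.0, 0.0)


class TestEnrichmentFactor:
    @pytest.mark.parametrize(
        "element,site,expected",
        [
            ("Pb", "A2", 27.67),
            ("Cd", "A2", 32.02),
            ("Se", "A1", 6.08),
            ("Ni", "A2", 7.86),
            ("Cd", "C", 37.02),
            ("Cd", "A3", 30.48),
            ("Cd", "B3", 30.61),
            ("Cd", "A1", 8.46),
            ("Hg", "B4", 7.03),
        ],
    )
    def test_survey_values(self, sediment, refs, element, site, expected):
        got = enrichment_factor(
            sediment.value(site, element),
            sediment.value(site, "Mn"),
            refs.background(element),
            refs.background("Mn"),
        )
        assert round(got, 2) == expected

    def test_reference_element_is_unity(self, sediment, refs):
        for site in sediment.sites:
            c = sediment.value(site, "Mn")
            assert enrichment_factor(c, c, 850, 850) == 1.0

    def test_vectorized_matches_raw_ratio_oracle(self, sediment, refs):
        results = sediment_index_table(sediment, refs)
        for r in results:
            for el in sediment.elements:
                raw = (
                    sediment.value(r.site, el) / sediment.value(r.site, "Mn")
                ) / (refs.background(el) / refs.background("Mn"))
                assert abs(r.ef[el] - raw) < 1e-12

    def test_zero_reference_concentration(self):
        with pytest.raises(ValueError):
            enrichment_factor(1.0, 0.0, 1.0, 1.0)


class TestContaminationAndLoad:
    def test_cf_at_background_is_one(self):
        assert contamination_factor(3.0, 3.0) == 1.0

    def test_cadmium_cf_at_a2(self, sediment, refs):
        cf = contamination_factor(sediment.value("A2", "Cd"), refs.background("Cd"))
        assert cf == pytest.approx(4.53, abs=5e-3)
        assert classify_cf(cf) == "considerable"

    def test_pli_geometric_mean(self):
        assert pollution_load_index([1.0, 4.0]) == pytest.approx(2.0)

    def test_pli_bounded_by_cf_range_and_order_invariant(self, sediment, refs):
        rng = np.random.default_rng(0)
        for r in sediment_index_table(sediment, refs):
            assert r.cf.min() <= r.pli <= r.cf.max()
            shuffled = r.cf.sample(frac=1, random_state=rng.integers(1 << 30))
            assert pollution_load_index(shuffled) == pytest.approx(r.pli, rel=1e-12)

    def test_pli_rejects_zero_cf(self):
        with pytest.raises(ValueError, match="exclude"):
            pollution_load_index([0.0, 2.0])


class TestPotentialEcologicalRisk:
    def test_zero_cf_gives_zero(self):
        v, label, _ = potential_ecological_risk(
            pd.Series({"Hg": 0.0}), pd.Series({"Hg": 40.0})
        )
        assert v == 0.0 and label == "low"

    def test_single_element(self):
        v, label, _ = potential_ecological_risk(
            pd.Series({"Ni": 2.0}), pd.Series({"Ni": 30.0})
        )
        assert v == 60.0 and label == "low"

    def test_additive_and_linear_in_cf(self, sediment, refs):
        tr = refs.toxic_response()
        results = sediment_index_table(sediment, refs)
        for r in results:
            loop = sum(tr[e] * r.cf[e] for e in r.cf.index if e in tr.index)
            assert r.per == pytest.approx(loop, rel=1e-12)
            doubled, _, _ = potential_ecological_risk(2 * r.cf, tr)
            assert doubled == pytest.approx(2 * r.per, rel=1e-12)

    def test_selenium_and_beryllium_excluded(self, sediment, refs):
        _, _, excluded = potential_ecological_risk(
            sediment_index_table(sediment, refs)[0].cf, refs.toxic_response()
        )
        assert set(excluded) == {"Se", "Be"}

    def test_site_ordering_and_classes(self, sediment, refs):
        results = sediment_index_table(sediment, refs)
        per = {r.site: r.per for r in results}
        order = sorted(per, key=per.get, reverse=True)
        assert order == ["A2", "B3", "B2", "C", "A3", "A4", "B4", "A1", "B1"]
        classes = {r.site: r.per_class for r in results}
        assert classes["A2"] == "considerable"
        assert classes["B3"] == "considerable"
        assert classes["A3"] == classes["B2"] == classes["C"] == "moderate"
        assert classes["A1"] == classes["B1"] == "low"

    def test_no_factor_at_all_is_error(self):
        with pytest.raises(ConfigurationError):
            potential_ecological_risk(pd.Series({"Se": 1.0}), pd.Series(dtype=float))


class TestUsepaClassification:
    @pytest.mark.parametrize(
        "element,site,expected",
        [
            ("Pb", "A2", "heavily_polluted"),
            ("Ni", "A2", "heavily_polluted"),
            ("Cu", "A4", "moderately_polluted"),
            ("Cu", "B1", "moderately_polluted"),
            ("Cu", "B2", "moderately_polluted"),
            ("As", "A1", "moderately_polluted"),
            ("As", "B1", "moderately_polluted"),
        ],
    )
    def test_survey_classes(self, sediment, element, site, expected):
        assert usepa_sediment_class(element, sediment.value(site, element)) == expected

    def test_all_sites_clean_for_mn_and_cd(self, sediment):
        for site in sediment.sites:
            assert usepa_sediment_class("Mn", sediment.value(site, "Mn")) == "non_polluted"
            assert usepa_sediment_class("Cd", sediment.value(site, "Cd")) == "non_polluted"

    def test_unsupported_element(self):
        with pytest.raises(ConfigurationError, match="Hg"):
            usepa_sediment_class("Hg", 1.0)


class TestClassificationBands:
    def test_every_finite_value_maps_to_exactly_one_class(self):
        """Bands are total and non-overlapping across each classifier."""
        probe = [-10, -1, 0, 0.5, 1, 2, 3, 4.999, 5, 6, 9.99, 10, 24, 25,
                 49, 50, 109, 110, 199, 200, 399, 400, 1000]
        for classifier in (classify_igeo, classify_ef, classify_cf, classify_per):
            for v in probe:
                label = classifier(float(v))
                assert isinstance(label, str) and label


def test_long_format_output(sediment, refs):
    long = sediment_long_table(sediment_index_table(sediment, refs))
    assert len(long) == 9 * 12
    assert {"igeo", "ef", "cf", "pli", "per", "per_class"} <= set(long.columns)
    assert long.loc[(long.site == "A2") & (long.element == "Pb"), "ef"].iloc[
        0
    ] == pytest.approx(27.67, abs=5e-3)
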