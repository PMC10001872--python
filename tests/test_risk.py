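"""Risk characterization: HQ/HI, CR/TCR, classification and shares."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dietrisk as dr
from dietrisk.exposure import ExposureResult, percentile_map
from dietrisk.risk import assess

# Reported mean daily intakes (μg/kg bw/day) used as fixed inputs for the
# arithmetic reproduction checks below.
MEAN_EDI = {"Cd": 0.108, "As": 0.250, "Pb": 0.100, "Cu": 6.35}

positive = st.floats(min_value=1e-6, max_value=1e6,
                     allow_nan=False, allow_infinity=False)


class TestHazardQuotient:
    def test_copper_mean_matches_reported_value(self, tox):
        assert dr.hazard_quotient(MEAN_EDI["Cu"], tox["Cu"].rfd) == \
            pytest.approx(0.159, rel=2e-3)

    def test_arsenic_mean_matches_reported_value(self, tox):
        hq = dr.hazard_quotient(MEAN_EDI["As"], tox["As"].rfd)
        assert hq == pytest.approx(0.834, rel=2e-3)

    def test_zero_intake_gives_zero_quotient(self):
        assert dr.hazard_quotient(0.0, 0.3) == 0.0

    def test_nonpositive_rfd_rejected(self):
        with pytest.raises(ValueError):
            dr.hazard_quotient(1.0, 0.0)


class TestHazardIndex:
    def test_reported_component_sum(self):
        assert dr.hazard_index([0.108, 0.834, 0.0282, 0.159]) == \
            pytest.approx(1.13, rel=5e-3)

    def test_single_and_zero_components(self):
        assert dr.hazard_index([0.7]) == pytest.approx(0.7)
        assert dr.hazard_index([0.0, 0.0]) == 0.0
        with pytest.raises(ValueError):
            dr.hazard_index([])

    def test_drawwise_sum_preserves_vector_shape(self, rng):
        hqs = {el: rng.lognormal(0, 1, 500) for el in ("A", "B")}
        hi = dr.hazard_index(hqs)
        assert np.allclose(hi, hqs["A"] + hqs["B"])


class TestCarcinogenicRisk:
    def test_arsenic_mean_reproduced_exactly(self, tox):
        assert dr.carcinogenic_risk(MEAN_EDI["As"], tox["As"].sf) == \
            pytest.approx(3.75e-4, rel=1e-12)

    def test_lead_mean_matches_to_rounding(self, tox):
        cr = dr.carcinogenic_risk(MEAN_EDI["Pb"], tox["Pb"].sf)
        assert cr == pytest.approx(8.54e-7, rel=0.01)

    def test_zero_intake_and_negative_sf(self):
        assert dr.carcinogenic_risk(0.0, 1.5) == 0.0
        with pytest.raises(ValueError):
            dr.carcinogenic_risk(1.0, -0.1)


class TestTotalCarcinogenicRisk:
    def test_reported_component_sum(self):
        tcr = dr.total_carcinogenic_risk([3.75e-4, 6.62e-4, 8.54e-7])
        assert tcr == pytest.approx(1.04e-3, rel=5e-3)

    def test_single_component_identity(self):
        assert dr.total_carcinogenic_risk([4.2e-5]) == pytest.approx(4.2e-5)
        assert dr.total_carcinogenic_risk([0.0, 0.0]) == 0.0


class TestClassification:
    def test_reported_total_risk_is_unacceptable(self):
        assert dr.classify_cancer_risk(1.04e-3) == "unacceptable"

    def test_reported_lead_risk_is_negligible(self):
        assert dr.classify_cancer_risk(8.54e-7) == "negligible"

    @pytest.mark.parametrize("value,label", [
        (1.0e-6, "acceptable"), (1.0e-4, "acceptable"), (5e-5, "acceptable"),
    ])
    def test_band_boundaries_are_compliant(self, value, label):
        assert dr.classify_cancer_risk(value) == label

    def test_hazard_threshold_is_strict(self):
        assert not dr.classify_hazard(1.0)
        assert dr.classify_hazard(1.0 + 1e-12)


class TestContributionShares:
    def test_reported_cancer_risk_shares(self):
        shares = dr.contribution_shares(
            {"As": 3.75e-4, "Cd": 6.62e-4, "Pb": 8.54e-7})
        assert shares["As"] == pytest.approx(0.361, abs=0.002)
        assert shares["Cd"] == pytest.approx(0.637, abs=0.002)

    def test_equal_components_share_equally(self):
        shares = dr.contribution_shares({"a": 2.0, "b": 2.0})
        assert shares == {"a": 0.5, "b": 0.5}

    def test_single_nonzero_component_takes_all(self):
        assert dr.contribution_shares({"a": 0.0, "b": 3.0})["b"] == 1.0

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            dr.contribution_shares({"a": 0.0})

    @given(st.dictionaries(st.sampled_from(["Cd", "As", "Pb", "Cu"]),
                           positive, min_size=1, max_size=4))
    @settings(max_examples=60, deadline=None)
    def test_shares_sum_to_one(self, components):
        assert sum(dr.contribution_shares(components).values()) == \
            pytest.approx(1.0, abs=1e-12)


class TestDrawwiseInvariants:
    def test_index_dominates_every_component(self, rng):
        hqs = {el: rng.lognormal(0, 1, 2000) for el in ("Cd", "As", "Pb")}
        hi = dr.hazard_index(hqs)
        for v in hqs.values():
            assert np.all(hi >= v)
            for p in (0.5, 0.95, 0.999):
                assert dr.quantile(hi, p) >= dr.quantile(v, p)

    def test_linearity_under_intake_doubling(self, tox, rng):
        edi = {el: rng.lognormal(-1, 0.5, 1000) for el in ("Cd", "As", "Pb")}
        hq1 = {el: dr.hazard_quotient(v, tox[el].rfd) for el, v in edi.items()}
        hq2 = {el: dr.hazard_quotient(2 * v, tox[el].rfd)
               for el, v in edi.items()}
        assert np.allclose(dr.hazard_index(hq2), 2 * dr.hazard_index(hq1))
        cr1 = {el: dr.carcinogenic_risk(v, tox[el].sf) for el, v in edi.items()}
        cr2 = {el: dr.carcinogenic_risk(2 * v, tox[el].sf)
               for el, v in edi.items()}
        assert np.allclose(dr.total_carcinogenic_risk(cr2),
                           2 * dr.total_carcinogenic_risk(cr1))
        s1 = dr.contribution_shares({el: float(v.mean())
                                     for el, v in cr1.items()})
        s2 = dr.contribution_shares({el: float(v.mean())
                                     for el, v in cr2.items()})
        for el in s1:
            assert s1[el] == pytest.approx(s2[el], rel=1e-12)


def _exposure(element, draws, group="g"):
    draws = np.asarray(draws, dtype=float)
    return ExposureResult(element=element, group=group, draws=draws,
                          mean=float(draws.mean()),
                          percentiles=percentile_map(draws),
                          seed=0, iterations=draws.size)


class TestAssess:
    def test_non_carcinogen_excluded_from_cancer_family(self, tox, rng, caplog):
        exposures = {el: _exposure(el, rng.lognormal(-2, 0.5, 500))
                     for el in ("Cd", "As", "Pb", "Cu")}
        with caplog.at_level("INFO", logger="dietrisk.risk"):
            result = assess(exposures, tox)
        assert set(result.cr) == {"Cd", "As", "Pb"}
        assert "Cu" in caplog.text
        assert sum(result.hi_shares.values()) == pytest.approx(1.0)
        assert sum(result.tcr_shares.values()) == pytest.approx(1.0)
        assert np.allclose(result.hi,
                           sum(result.hq[el] for el in result.hq))

    def test_unknown_element_is_hard_error(self, tox, rng):
        with pytest.raises(KeyError, match="Hg"):
            assess({"Hg": _exposure("Hg", rng.lognormal(0, 1, 10))}, tox)

    def test_mixed_groups_rejected(self, tox, rng):
        exposures = {"Cd": _exposure("Cd", rng.lognormal(0, 1, 10), group="a"),
                     "As": _exposure("As", rng.lognormal(0, 1, 10), group="b")}
        with pytest.raises(ValueError, match="groups"):
            assess(exposures, tox)

    def test_flags_follow_mean_values(self, tox):
        exposures = {"As": _exposure("As", np.full(100, 0.4))}
        result = assess(exposures, tox)
        assert result.flags["HQ>1 [As]"] is True          # 0.4/0.3 > 1
        assert result.flags["CR [As]"] == "unacceptable"  # 6e-4 > 1e-4
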