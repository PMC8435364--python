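"""Demographic chain, the five denominator methods, and their inverses."""
import pytest
from hypothesis import given, settings, strategies as st

from rhiscov.denominators import (
    census_cbr_denominator,
    census_livebirth_denominator,
    chain_from_live_births,
    denominator_for_indicator,
    live_births_from_pregnancies,
    live_births_from_surviving_infants,
    methods_for_indicator,
    service_based_denominator,
)
from rhiscov.model import (
    DenominatorMethod,
    Indicator,
    InputError,
    MissingDataError,
)

from conftest import make_assumptions

rate_st = st.floats(min_value=0.0, max_value=0.3, allow_nan=False)
births_st = st.floats(min_value=10.0, max_value=1e6, allow_nan=False)


class TestChainFromLiveBirths:
    def test_zero_rates_make_every_link_equal(self):
        chain = chain_from_live_births(1000.0, make_assumptions())
        assert chain.pregnancies == chain.deliveries == chain.total_births == 1000.0
        assert chain.live_births == chain.surviving_infants == 1000.0

    def test_worked_example_step_by_step(self, worked_assumptions):
        chain = chain_from_live_births(1000.0, worked_assumptions)
        assert chain.total_births == pytest.approx(1020.4081632653, abs=1e-6)
        assert chain.deliveries == pytest.approx(1005.3282397688, abs=1e-6)
        assert chain.pregnancies == pytest.approx(1117.0313775209, abs=1e-6)
        assert chain.surviving_infants == pytest.approx(970.0)

    def test_raising_stillbirths_raises_pregnancies_not_infants(self):
        low = chain_from_live_births(1000.0, make_assumptions(stillbirth_rate=0.01))
        high = chain_from_live_births(1000.0, make_assumptions(stillbirth_rate=0.05))
        assert high.pregnancies > low.pregnancies
        assert high.surviving_infants == low.surviving_infants

    def test_nonpositive_live_births_rejected(self):
        with pytest.raises(InputError):
            chain_from_live_births(0.0, make_assumptions())

    @settings(deadline=None, derandomize=True, max_examples=300)
    @given(lb=births_st, sb=rate_st, mb=rate_st, efl=rate_st, nmr=rate_st)
    def test_chain_ordering_invariant(self, lb, sb, mb, efl, nmr):
        chain = chain_from_live_births(
            lb,
            make_assumptions(
                stillbirth_rate=sb,
                multiple_birth_proportion=mb,
                early_fetal_loss_proportion=efl,
                nmr=nmr,
            ),
        )
        assert chain.pregnancies >= chain.deliveries > 0
        assert chain.total_births >= chain.live_births >= chain.surviving_infants

    @settings(deadline=None, derandomize=True, max_examples=300)
    @given(lb=births_st, sb=rate_st, mb=rate_st, efl=rate_st, nmr=rate_st)
    def test_pregnancy_inversion_recovers_live_births(self, lb, sb, mb, efl, nmr):
        a = make_assumptions(
            stillbirth_rate=sb,
            multiple_birth_proportion=mb,
            early_fetal_loss_proportion=efl,
            nmr=nmr,
        )
        chain = chain_from_live_births(lb, a)
        assert live_births_from_pregnancies(chain.pregnancies, a) == pytest.approx(
            lb, rel=1e-9
        )
        assert live_births_from_surviving_infants(
            chain.surviving_infants, a
        ) == pytest.approx(lb, rel=1e-9)


class TestCensusMethods:
    def test_cbr_method_derives_live_births_from_population(self):
        chain = census_cbr_denominator(make_assumptions(cbr=32.0))
        assert chain.live_births == pytest.approx(3200.0)

    def test_cbr_method_is_the_composition_with_the_chain(self, worked_assumptions):
        direct = census_cbr_denominator(worked_assumptions)
        lb = worked_assumptions.projected_population * worked_assumptions.cbr / 1000
        via_chain = chain_from_live_births(lb, worked_assumptions)
        assert direct.pregnancies == pytest.approx(via_chain.pregnancies)

    def test_methods_agree_when_projection_matches_cbr_product(self):
        a = make_assumptions(projected_population=100_000, cbr=32, projected_live_births=3200)
        assert census_livebirth_denominator(a).pregnancies == pytest.approx(
            census_cbr_denominator(a).pregnancies
        )

    def test_zero_cbr_rejected_at_construction(self):
        with pytest.raises(ValueError):
            make_assumptions(cbr=0.0)


class TestServiceBasedMethods:
    def test_anc1_anchor_inflates_for_nonuse_to_pregnancies(self):
        a = make_assumptions(nonuse={Indicator.ANC1: 0.10})
        chain = service_based_denominator(900.0, a, Indicator.ANC1)
        assert chain.pregnancies == pytest.approx(1000.0)
        # zero demographic rates: the whole chain collapses to 1000
        assert chain.surviving_infants == pytest.approx(1000.0)

    def test_bcg_anchor_is_live_births(self):
        a = make_assumptions(
            nonuse={Indicator.BCG: 0.03}, stillbirth_rate=0.02, nmr=0.03
        )
        chain = service_based_denominator(970.0, a, Indicator.BCG)
        assert chain.live_births == pytest.approx(1000.0)
        assert chain.total_births == pytest.approx(1000.0 / 0.98)

    def test_dpt1_anchor_inverts_neonatal_survival(self):
        a = make_assumptions(nonuse={Indicator.DPT1: 0.0}, nmr=0.03)
        chain = service_based_denominator(970.0, a, Indicator.DPT1)
        assert chain.live_births == pytest.approx(1000.0)
        assert chain.surviving_infants == pytest.approx(970.0)

    def test_missing_nonuse_is_an_error(self):
        with pytest.raises(MissingDataError, match="BCG"):
            service_based_denominator(970.0, make_assumptions(), Indicator.BCG)

    def test_non_anchor_indicator_rejected(self):
        with pytest.raises(InputError):
            service_based_denominator(970.0, make_assumptions(), Indicator.DPT3)


class TestDenominatorSelection:
    def test_indicator_to_target_population_mapping(self, worked_assumptions):
        chain = chain_from_live_births(1000.0, worked_assumptions)
        assert denominator_for_indicator(chain, Indicator.ANC1) == pytest.approx(
            1117.0313775209, abs=1e-6
        )
        assert denominator_for_indicator(chain, Indicator.DELIVERY) == pytest.approx(
            1005.3282397688, abs=1e-6
        )
        assert denominator_for_indicator(chain, Indicator.DPT3) == pytest.approx(970.0)

    def test_unmapped_indicator_rejected(self, worked_assumptions):
        chain = chain_from_live_births(1000.0, worked_assumptions)
        with pytest.raises(InputError):
            denominator_for_indicator(chain, Indicator.BCG)

    def test_self_anchored_method_excluded(self):
        anc1 = methods_for_indicator(Indicator.ANC1)
        assert DenominatorMethod.SERVICE_ANC1 not in anc1
        assert len(anc1) == 4
        assert len(methods_for_indicator(Indicator.DELIVERY)) == 5
        assert len(methods_for_indicator(Indicator.DPT3)) == 5
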