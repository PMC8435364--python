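import pytest

from rhiscov.model import DemographicAssumptions, Indicator
from rhiscov.simulate import scenario_presets, simulate


@pytest.fixture(scope="session")
def clean_bundle():
    """Zero-noise, complete-reporting bundle: the pipeline's exact inverse."""
    return simulate(scenario_presets("clean", seed=7))


@pytest.fixture(scope="session")
def sl_bundle():
    """Realistic noisy bundle emulating the Sierra Leone 2016 setting."""
    return simulate(scenario_presets("sierra_leone_like", seed=11))


def make_assumptions(
    geography="D1",
    projected_population=100_000.0,
    projected_live_births=3_200.0,
    cbr=32.0,
    stillbirth_rate=0.0,
    multiple_birth_proportion=0.0,
    early_fetal_loss_proportion=0.0,
    nmr=0.0,
    nonuse=None,
    year=None,
):
    return DemographicAssumptions(
        geography=geography,
        year=year,
        projected_population=projected_population,
        projected_live_births=projected_live_births,
        cbr=cbr,
        stillbirth_rate=stillbirth_rate,
        multiple_birth_proportion=multiple_birth_proportion,
        early_fetal_loss_proportion=early_fetal_loss_proportion,
        nmr=nmr,
        nonuse=nonuse or {},
    )


@pytest.fixture
def assumptions_factory():
    return make_assumptions


WORKED = dict(
    stillbirth_rate=0.02,
    multiple_birth_proportion=0.015,
    early_fetal_loss_proportion=0.10,
    nmr=0.03,
)


@pytest.fixture
def worked_assumptions():
    """Assumption set of the worked denominator-chain example."""
    return make_assumptions(
        nonuse={Indicator.ANC1: 0.10, Indicator.BCG: 0.03, Indicator.DPT1: 0.0},
        **WORKED,
    )
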