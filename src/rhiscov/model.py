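"""Domain model and configuration for RHIS coverage analysis.

Routine health information systems (RHIS, e.g. DHIS2 aggregate exports)
report monthly counts of services delivered — here first antenatal care
contact (ANC1), institutional delivery, and BCG / DPT1 / DPT3 vaccine doses —
by district. This module defines the typed records exchanged between the
pipeline stages: raw monthly counts, reporting-completeness fractions,
demographic assumptions used to derive target populations, household-survey
benchmark estimates, and the pipeline configuration (k-factor policy,
outlier threshold, score-bin options).

Conventions
-----------
* Coverage and quality scores are on the percent scale (0–100, coverage may
  exceed 100).
* Completeness, k-factors, and all demographic proportions are fractions.
* The reserved geography label ``NATIONAL`` denotes the country-level
  aggregate; every other label is a district matched case-sensitively
  across input files.
"""
from __future__ import annotations

from enum import Enum
from typing import Dict, Optional, Tuple

from pydantic import BaseModel, Field, field_validator, model_validator

NATIONAL = "NATIONAL"


class RhiscovError(Exception):
    """Base class for all errors raised by this package."""


class InputError(RhiscovError):
    """Malformed or invalid input data (parse/validation failures)."""


class MissingDataError(RhiscovError):
    """A required record (completeness match, form, district, benchmark) is absent."""


class ConfigError(RhiscovError):
    """Invalid pipeline configuration."""


class Indicator(str, Enum):
    """The five service indicators carried through the pipeline."""

    ANC1 = "ANC1"
    DELIVERY = "DELIVERY"
    BCG = "BCG"
    DPT1 = "DPT1"
    DPT3 = "DPT3"


class ServiceForm(str, Enum):
    """DHIS2 reporting forms; completeness of reporting is tracked per form."""

    ANC = "ANC"
    DELIVERY = "DELIVERY"
    IMMUNIZATION = "IMMUNIZATION"


#: Reporting form through which each indicator is reported.
FORM_FOR_INDICATOR: Dict[Indicator, ServiceForm] = {
    Indicator.ANC1: ServiceForm.ANC,
    Indicator.DELIVERY: ServiceForm.DELIVERY,
    Indicator.BCG: ServiceForm.IMMUNIZATION,
    Indicator.DPT1: ServiceForm.IMMUNIZATION,
    Indicator.DPT3: ServiceForm.IMMUNIZATION,
}

#: Indicators for which coverage is estimated (numerator indicators).
COVERAGE_INDICATORS: Tuple[Indicator, ...] = (
    Indicator.ANC1,
    Indicator.DELIVERY,
    Indicator.DPT3,
)


class DenominatorMethod(str, Enum):
    """How the target population (denominator) is derived.

    Two census-based methods (projected population × crude birth rate, or
    projected live births directly) and three health-service-based methods
    (an adjusted service count inflated for non-use of that service).
    """

    CENSUS_CBR = "CENSUS_CBR"
    CENSUS_LIVEBIRTHS = "CENSUS_LIVEBIRTHS"
    SERVICE_ANC1 = "SERVICE_ANC1"
    SERVICE_BCG = "SERVICE_BCG"
    SERVICE_DPT1 = "SERVICE_DPT1"


#: Anchor indicator of each service-based method.
ANCHOR_FOR_METHOD: Dict[DenominatorMethod, Indicator] = {
    DenominatorMethod.SERVICE_ANC1: Indicator.ANC1,
    DenominatorMethod.SERVICE_BCG: Indicator.BCG,
    DenominatorMethod.SERVICE_DPT1: Indicator.DPT1,
}


class Agreement(str, Enum):
    """Verdict of an RHIS coverage estimate against the survey 95% CI."""

    CONSISTENT = "CONSISTENT"
    OVER = "OVER"
    UNDER = "UNDER"


# ---------------------------------------------------------------------------
# Input records
# ---------------------------------------------------------------------------


class MonthlyServiceCount(BaseModel):
    """One reported service count for (district, year, month, indicator)."""

    district: str = Field(min_length=1)
    year: int
    month: int = Field(ge=1, le=12)
    indicator: Indicator
    count: float = Field(ge=0, allow_inf_nan=False)

    def key(self) -> Tuple[str, int, int, str]:
        return (self.district, self.year, self.month, self.indicator.value)


class CompletenessRecord(BaseModel):
    """Fraction of expected facility reports received for a reporting form."""

    district: str = Field(min_length=1)
    year: int
    service_form: ServiceForm
    completeness: float = Field(gt=0, le=1)


class DemographicAssumptions(BaseModel):
    """Projection and rate parameters used to derive target populations.

    ``stillbirth_rate`` is the proportion of total births that are
    stillbirths; ``multiple_birth_proportion`` the proportion by which total
    births exceed deliveries (twins, triplets); ``early_fetal_loss_proportion``
    the proportion of pregnancies ending in early fetal death; ``nmr`` the
    neonatal mortality rate as a proportion of live births. ``nonuse`` maps
    an anchor indicator to the proportion of its target population *not*
    using the service, estimated from the most recent household survey.
    """

    geography: str = Field(min_length=1)
    year: Optional[int] = None
    projected_population: float = Field(gt=0)
    projected_live_births: float = Field(gt=0)
    cbr: float = Field(gt=0, description="live births per 1,000 population")
    stillbirth_rate: float = Field(ge=0, lt=1)
    multiple_birth_proportion: float = Field(ge=0, lt=1)
    early_fetal_loss_proportion: float = Field(ge=0, lt=1)
    nmr: float = Field(ge=0, lt=1)
    nonuse: Dict[Indicator, float] = Field(default_factory=dict)

    @field_validator("nonuse")
    @classmethod
    def _nonuse_in_range(cls, v: Dict[Indicator, float]) -> Dict[Indicator, float]:
        for ind, p in v.items():
            if not (0 <= p < 1):
                raise ValueError(f"nonuse[{ind}] = {p} outside [0, 1)")
        return v


class SurveyBenchmark(BaseModel):
    """Household-survey coverage estimate with its 95% confidence interval.

    National rows may additionally carry the expected service ratios
    (ANC1:DPT1 and DPT1:DPT3) used by the pair-consistency quality check.
    """

    geography: str = Field(min_length=1)
    indicator: Indicator
    point: float = Field(ge=0, le=150)
    ci_low: float = Field(ge=0, le=150)
    ci_high: float = Field(ge=0, le=150)
    expected_ratio_anc1_dpt1: Optional[float] = Field(default=None, gt=0)
    expected_ratio_dpt1_dpt3: Optional[float] = Field(default=None, gt=0)

    @model_validator(mode="after")
    def _ci_ordered(self) -> "SurveyBenchmark":
        if not (self.ci_low <= self.point <= self.ci_high):
            raise ValueError(
                f"CI must satisfy ci_low <= point <= ci_high, got "
                f"({self.ci_low}, {self.point}, {self.ci_high})"
            )
        return self


class KFactorPolicy(BaseModel):
    """Assumed service level of non-reporting facilities, per form.

    k = 0 means non-reporting facilities provided no services; k = 1 means
    they provided the same level as reporting facilities.
    """

    k: Dict[ServiceForm, float]

    @field_validator("k")
    @classmethod
    def _k_in_unit_interval(cls, v: Dict[ServiceForm, float]) -> Dict[ServiceForm, float]:
        for form, kv in v.items():
            if not (0 <= kv <= 1):
                raise ValueError(f"k[{form}] = {kv} outside [0, 1]")
        return v

    @classmethod
    def uniform(cls, value: float = 0.25) -> "KFactorPolicy":
        return cls(k={form: value for form in ServiceForm})

    def k_for(self, form: ServiceForm) -> float:
        try:
            return self.k[form]
        except KeyError:
            raise ConfigError(f"no k-factor configured for form {form.value}") from None


# ---------------------------------------------------------------------------
# Derived records
# ---------------------------------------------------------------------------


class AdjustedCount(BaseModel):
    """An annual reported count adjusted for incomplete reporting."""

    district: str
    year: int
    indicator: Indicator
    n_rep: float = Field(ge=0)
    c: float = Field(gt=0, le=1)
    k: float = Field(ge=0, le=1)
    n_adj: float = Field(ge=0)


_CHAIN_SLACK = 1e-9  # relative slack for float round-off in ordering checks


class PopulationChain(BaseModel):
    """Expected pregnancies → deliveries → births → live births → infants.

    One internally consistent set of target populations for a geography and
    year, from which the denominator for any coverage indicator is read off.
    """

    geography: str
    year: Optional[int] = None
    pregnancies: float = Field(gt=0)
    deliveries: float = Field(gt=0)
    total_births: float = Field(gt=0)
    live_births: float = Field(gt=0)
    surviving_infants: float = Field(gt=0)

    @model_validator(mode="after")
    def _ordered(self) -> "PopulationChain":
        slack = 1 + _CHAIN_SLACK
        if self.pregnancies * slack < self.deliveries:
            raise ValueError("pregnancies must be >= deliveries")
        if self.total_births * slack < self.live_births:
            raise ValueError("total_births must be >= live_births")
        if self.live_births * slack < self.surviving_infants:
            raise ValueError("live_births must be >= surviving_infants")
        return self


class CoverageEstimate(BaseModel):
    """Coverage for one (geography, indicator, denominator method)."""

    geography: str
    indicator: Indicator
    method: DenominatorMethod
    numerator: float = Field(ge=0)
    denominator: float = Field(gt=0)
    coverage: float
    over_100: bool = False
    agreement: Optional[Agreement] = None
    gap: Optional[float] = None


class ModifiedZResult(BaseModel):
    """Modified Z-score of one value within its comparison series."""

    geography: Optional[str] = None
    indicator: Optional[Indicator] = None
    period: str
    value: float
    z: float
    is_outlier: bool


class QualityScorecardRow(BaseModel):
    """One scorecard row: the four quality scores and their mean."""

    geography: str
    score_completeness: float = Field(ge=0, le=100)
    pct_outliers: float = Field(ge=0, le=100)
    score_outliers: float = Field(ge=0, le=100)
    score_time: float = Field(ge=0, le=100)
    score_pair: float = Field(ge=0, le=100)
    score_total: float = Field(ge=0, le=100)


class AgreementSummary(BaseModel):
    """District agreement tally for one indicator × denominator method."""

    indicator: Indicator
    method: DenominatorMethod
    n_districts_consistent: int = Field(ge=0)
    n_districts_total: int = Field(ge=0)
    national_coverage: float
    national_agreement: Agreement

    @model_validator(mode="after")
    def _counts_ordered(self) -> "AgreementSummary":
        if self.n_districts_consistent > self.n_districts_total:
            raise ValueError("n_districts_consistent cannot exceed n_districts_total")
        return self


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


class ChainConventions(BaseModel):
    """Direction of each demographic-chain relation.

    Defaults follow the usual denominator-guidance conventions: stillbirths
    as a share of total births, multiple births as excess births per
    delivery, early fetal loss as a share of pregnancies. Setting a flag to
    False interprets the corresponding rate as a multiplicative increment
    instead (e.g. total births = live births × (1 + stillbirth_rate)).
    """

    stillbirth_of_total_births: bool = True
    multiple_births_per_delivery: bool = True
    fetal_loss_of_pregnancies: bool = True


class PipelineConfig(BaseModel):
    """All tunable pipeline settings, with the recommended defaults."""

    k_factors: KFactorPolicy = Field(default_factory=lambda: KFactorPolicy.uniform(0.25))
    outlier_z_threshold: float = Field(default=3.5, gt=0)
    completeness_threshold_pct: float = Field(default=80.0, ge=0, le=100)
    #: multiply modified Z by 0.6745 (textbook normal-consistency constant);
    #: off by default — the plain (x − median)/MAD ratio is used.
    mad_scaling_constant: bool = False
    outlier_indicators: Tuple[Indicator, Indicator] = (Indicator.ANC1, Indicator.DPT3)
    time_consistency_indicators: Tuple[Indicator, Indicator] = (
        Indicator.ANC1,
        Indicator.DPT1,
    )
    #: include the target year itself in the median/MAD comparison set
    time_consistency_include_target: bool = True
    pair_indicators: Tuple[Tuple[Indicator, Indicator], ...] = (
        (Indicator.ANC1, Indicator.DPT1),
        (Indicator.DPT1, Indicator.DPT3),
    )
    #: compare agreement on coverage rounded to 1 decimal (as printed) rather
    #: than on the unrounded value
    compare_rounded: bool = False
    chain: ChainConventions = Field(default_factory=ChainConventions)
    analysis_year: int = 2016

    @classmethod
    def from_dict(cls, raw: Optional[dict]) -> "PipelineConfig":
        """Build a config from a parsed YAML/JSON mapping, applying defaults.

        Accepts either ``k_factors: {ANC: .., DELIVERY: .., IMMUNIZATION: ..}``
        or the shorthand ``k: 0.25`` for a uniform policy.
        """
        raw = dict(raw or {})
        try:
            if "k" in raw and "k_factors" not in raw:
                raw["k_factors"] = KFactorPolicy.uniform(float(raw.pop("k")))
            elif isinstance(raw.get("k_factors"), dict) and "k" not in raw["k_factors"]:
                raw["k_factors"] = {"k": raw["k_factors"]}
            return cls.model_validate(raw)
        except ValueError as exc:
            raise ConfigError(str(exc)) from exc
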