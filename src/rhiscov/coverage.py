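"""Coverage estimation and agreement classification against survey benchmarks.

Coverage is 100 × numerator / denominator, where the numerator is the
adjusted annual service count and the denominator comes from one of the
five derivation methods. Values above 100% are permitted and flagged — they
are themselves a diagnostic of numerator over-reporting or denominator
under-estimation. National coverage pools numerator and denominator sums
across districts (not a mean of district coverages), so over- and
under-estimating districts can offset each other, as they do in practice.

An RHIS estimate *agrees* with the household-survey benchmark when it falls
inside the survey's 95% confidence interval (closed at both ends);
otherwise it is classified OVER or UNDER by the sign of its gap
(coverage − survey point, in percentage points).
"""
from __future__ import annotations

import logging
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import pandas as pd

from .adjust import adjust_all, national_adjusted
from .denominators import (
    _DENOMINATOR_FIELD,
    build_denominators,
    methods_for_indicator,
)
from .io import to_frame
from .model import (
    Agreement,
    AgreementSummary,
    CompletenessRecord,
    CoverageEstimate,
    COVERAGE_INDICATORS,
    DemographicAssumptions,
    DenominatorMethod,
    Indicator,
    InputError,
    KFactorPolicy,
    MissingDataError,
    MonthlyServiceCount,
    NATIONAL,
    PipelineConfig,
    SurveyBenchmark,
)

log = logging.getLogger("rhiscov")


def compute_coverage(numerator: float, denominator: float) -> float:
    """Coverage in percent; may exceed 100."""
    if denominator <= 0:
        raise InputError(f"denominator must be > 0, got {denominator}")
    if numerator < 0:
        raise InputError(f"numerator must be >= 0, got {numerator}")
    return 100.0 * numerator / denominator


def classify_agreement(
    coverage: float,
    benchmark: SurveyBenchmark,
    rounded: bool = False,
) -> Tuple[Agreement, float]:
    """Agreement verdict and gap (coverage − survey point, pp).

    CONSISTENT iff ci_low ≤ coverage ≤ ci_high (closed interval). With
    ``rounded`` the comparison uses coverage rounded to one decimal, as the
    values are printed; by default it uses the unrounded value.
    """
    value = round(coverage, 1) if rounded else coverage
    gap = coverage - benchmark.point
    if benchmark.ci_low <= value <= benchmark.ci_high:
        return Agreement.CONSISTENT, gap
    if value > benchmark.ci_high:
        return Agreement.OVER, gap
    return Agreement.UNDER, gap


def national_rollup(
    estimates: Sequence[CoverageEstimate],
    districts: Sequence[str],
) -> CoverageEstimate:
    """Pool district estimates of one indicator × method into a national one.

    National numerator and denominator are the sums over districts; national
    coverage is computed from the pooled sums, not averaged over districts.
    Every expected district must be present.
    """
    if not estimates:
        raise InputError("cannot roll up an empty estimate collection")
    indicators = {e.indicator for e in estimates}
    methods = {e.method for e in estimates}
    if len(indicators) > 1 or len(methods) > 1:
        raise InputError("rollup requires a single indicator x method slice")
    present = {e.geography for e in estimates}
    missing = sorted(set(districts) - present)
    if missing:
        raise MissingDataError(
            f"national rollup missing district(s): {', '.join(missing)}"
        )
    numerator = sum(e.numerator for e in estimates)
    denominator = sum(e.denominator for e in estimates)
    coverage = compute_coverage(numerator, denominator)
    return CoverageEstimate(
        geography=NATIONAL,
        indicator=next(iter(indicators)),
        method=next(iter(methods)),
        numerator=numerator,
        denominator=denominator,
        coverage=coverage,
        over_100=coverage > 100,
    )


def _benchmark_lookup(
    survey: Union[pd.DataFrame, Iterable[SurveyBenchmark]],
) -> Dict[Tuple[str, str], SurveyBenchmark]:
    if isinstance(survey, pd.DataFrame):
        records = [
            SurveyBenchmark(
                geography=r.geography,
                indicator=r.indicator,
                point=r.point,
                ci_low=r.ci_low,
                ci_high=r.ci_high,
            )
            for r in survey.itertuples(index=False)
        ]
    else:
        records = list(survey)
    return {(b.geography, b.indicator.value): b for b in records}


def build_coverage(
    adjusted: pd.DataFrame,
    denominators: pd.DataFrame,
    survey: Union[pd.DataFrame, Iterable[SurveyBenchmark]],
    year: int,
    config: Optional[PipelineConfig] = None,
    indicators: Sequence[Indicator] = COVERAGE_INDICATORS,
) -> pd.DataFrame:
    """Coverage per district and nationally, for every applicable method.

    Numerators come from ``adjusted`` (see :func:`rhiscov.adjust.adjust_all`),
    denominators from :func:`rhiscov.denominators.build_denominators`; each
    estimate is classified against its survey benchmark. Missing benchmarks
    are an error, never a silent skip.
    """
    config = config or PipelineConfig()
    benchmarks = _benchmark_lookup(survey)
    sub = adjusted[adjusted["year"] == year]
    districts = sorted(sub["district"].unique())
    numerators = sub.set_index(["district", "indicator"])["n_adj"]
    den_lookup = denominators[denominators["year"] == year].set_index(
        ["geography", "method"]
    )
    estimates: List[CoverageEstimate] = []
    for indicator in indicators:
        field = _DENOMINATOR_FIELD[indicator]
        for method in methods_for_indicator(indicator):
            district_estimates = []
            for district in districts:
                try:
                    numerator = float(numerators.loc[(district, indicator.value)])
                except KeyError:
                    raise MissingDataError(
                        f"no adjusted count for {district!r}, {indicator.value}, {year}"
                    ) from None
                try:
                    denominator = float(den_lookup.loc[(district, method.value), field])
                except KeyError:
                    raise MissingDataError(
                        f"no denominator for {district!r}, method {method.value}, {year}"
                    ) from None
                coverage = compute_coverage(numerator, denominator)
                est = CoverageEstimate(
                    geography=district,
                    indicator=indicator,
                    method=method,
                    numerator=numerator,
                    denominator=denominator,
                    coverage=coverage,
                    over_100=coverage > 100,
                )
                district_estimates.append(est)
            national = national_rollup(district_estimates, districts)
            for est in district_estimates + [national]:
                key = (est.geography, est.indicator.value)
                if key not in benchmarks:
                    raise MissingDataError(
                        f"no survey benchmark for {est.geography!r}, "
                        f"{est.indicator.value}"
                    )
                verdict, gap = classify_agreement(
                    est.coverage, benchmarks[key], rounded=config.compare_rounded
                )
                est.agreement = verdict
                est.gap = gap
            estimates.extend(district_estimates)
            estimates.append(national)
    frame = to_frame(estimates)
    order = [
        "geography",
        "indicator",
        "method",
        "numerator",
        "denominator",
        "coverage",
        "agreement",
        "gap",
        "over_100",
    ]
    log.info("coverage computed: %d estimates (year %d)", len(frame), year)
    return frame[order]


def summarize_agreement(coverage: pd.DataFrame) -> pd.DataFrame:
    """District agreement tallies per indicator × method, with the national
    verdict attached."""
    rows: List[AgreementSummary] = []
    for (indicator, method), grp in coverage.groupby(["indicator", "method"], sort=False):
        district_rows = grp[grp["geography"] != NATIONAL]
        national_rows = grp[grp["geography"] == NATIONAL]
        if national_rows.empty:
            raise MissingDataError(
                f"no national estimate for {indicator} x {method}"
            )
        nat = national_rows.iloc[0]
        rows.append(
            AgreementSummary(
                indicator=indicator,
                method=method,
                n_districts_consistent=int(
                    (district_rows["agreement"] == Agreement.CONSISTENT.value).sum()
                ),
                n_districts_total=len(district_rows),
                national_coverage=float(nat["coverage"]),
                national_agreement=nat["agreement"],
            )
        )
    return to_frame(rows)


def coverage_trend(
    adjusted: pd.DataFrame,
    demography: Iterable[DemographicAssumptions],
    config: Optional[PipelineConfig] = None,
    indicators: Sequence[Indicator] = COVERAGE_INDICATORS,
) -> pd.DataFrame:
    """National coverage per year × indicator × method, for every year with
    both adjusted counts and demographic assumptions.

    A plain descriptive table (no trend statistics): useful to compare the
    methods' trajectories against a survey point over the study period.
    """
    config = config or PipelineConfig()
    demography = list(demography)
    demo_years = {d.year for d in demography if d.year is not None}
    years = sorted(set(adjusted["year"].unique()) & demo_years) or sorted(
        adjusted["year"].unique()
    )
    rows = []
    for year in years:
        denominators = build_denominators(adjusted, demography, year, config.chain)
        nat_den = denominators[denominators["geography"] == NATIONAL].set_index("method")
        nat_num = (
            adjusted[adjusted["year"] == year]
            .groupby("indicator")["n_adj"]
            .sum()
        )
        for indicator in indicators:
            field = _DENOMINATOR_FIELD[indicator]
            for method in methods_for_indicator(indicator):
                rows.append(
                    {
                        "year": year,
                        "indicator": indicator.value,
                        "method": method.value,
                        "coverage": compute_coverage(
                            float(nat_num.loc[indicator.value]),
                            float(nat_den.loc[method.value, field]),
                        ),
                    }
                )
    return pd.DataFrame(rows)


def run_pipeline(
    counts: Union[pd.DataFrame, Iterable[MonthlyServiceCount]],
    completeness: Union[pd.DataFrame, Iterable[CompletenessRecord]],
    demography: Iterable[DemographicAssumptions],
    survey: Union[pd.DataFrame, Iterable[SurveyBenchmark]],
    config: Optional[PipelineConfig] = None,
    with_quality: bool = True,
    with_trend: bool = False,
) -> Dict[str, pd.DataFrame]:
    """Run the full analysis for the configured year.

    Returns a dict of frames: ``adjusted``, ``denominators``, ``coverage``,
    ``agreement_summary``, plus ``scorecard`` (unless ``with_quality`` is
    off) and ``trend`` on request.
    """
    from .quality import build_scorecard  # local import avoids cycle

    config = config or PipelineConfig()
    demography = list(demography)
    adjusted = adjust_all(counts, completeness, config.k_factors)
    denominators = build_denominators(
        adjusted, demography, config.analysis_year, config.chain
    )
    coverage = build_coverage(
        adjusted, denominators, survey, config.analysis_year, config
    )
    out: Dict[str, pd.DataFrame] = {
        "adjusted": adjusted,
        "denominators": denominators,
        "coverage": coverage,
        "agreement_summary": summarize_agreement(coverage),
    }
    if with_quality:
        out["scorecard"] = build_scorecard(
            counts, completeness, survey, config, config.analysis_year
        )
    if with_trend:
        out["trend"] = coverage_trend(adjusted, demography, config)
    return out
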