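"""WHO-style data-quality metrics and the composite district scorecard.

Four checks are computed per district and for the pooled national series:

* **Completeness of reporting** — mean of the ANC, delivery and
  immunization form completeness percentages.
* **Outliers** — share of monthly values whose modified Z-score (deviation
  from the annual median in units of the median absolute deviation) exceeds
  a threshold (default 3.5); stored on a good-is-high scale as
  ``100 − outlier%`` alongside the raw percentage.
* **Consistency over time** — modified Z of the target year's annual total
  against the surrounding years, mapped to a score through fixed bins.
* **Consistency between indicators** — relative difference between the
  reported and the survey-expected ratio of an indicator pair (ANC1:DPT1
  and DPT1:DPT3), mapped to a score through fixed bins.

The composite score is the unweighted mean of the four.
"""
from __future__ import annotations

import logging
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .io import to_frame
from .model import (
    CompletenessRecord,
    Indicator,
    InputError,
    MissingDataError,
    ModifiedZResult,
    MonthlyServiceCount,
    NATIONAL,
    PipelineConfig,
    QualityScorecardRow,
    ServiceForm,
    SurveyBenchmark,
)

log = logging.getLogger("rhiscov")

#: 0.6745 rescales MAD to the SD of a normal sample (optional, off by default)
MAD_NORMAL_CONSTANT = 0.6745


def _frame(data: Union[pd.DataFrame, Iterable]) -> pd.DataFrame:
    if isinstance(data, pd.DataFrame):
        return data
    return to_frame(list(data))


# ---------------------------------------------------------------------------
# Modified Z-score
# ---------------------------------------------------------------------------


def modified_z(
    values: Sequence[float],
    center: Optional[float] = None,
    scale_constant: bool = False,
) -> np.ndarray:
    """Modified Z-scores: (x − median) / MAD.

    MAD is the median absolute deviation from the (possibly overridden)
    center. A constant series has MAD = 0 and carries no internal evidence
    of anomaly, so every score is defined as 0 there. With
    ``scale_constant`` the textbook 0.6745 factor is applied.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise InputError(f"modified Z needs at least 2 values, got {x.size}")
    med = float(np.median(x)) if center is None else float(center)
    mad = float(np.median(np.abs(x - med)))
    if mad == 0:
        return np.zeros_like(x)
    z = (x - med) / mad
    if scale_constant:
        z = z * MAD_NORMAL_CONSTANT
    return z


def modified_z_scores(
    values: Sequence[float],
    periods: Optional[Sequence[str]] = None,
    geography: Optional[str] = None,
    indicator: Optional[Indicator] = None,
    center: Optional[float] = None,
    threshold: float = 3.5,
    scale_constant: bool = False,
) -> List[ModifiedZResult]:
    """Score a series and flag values with \\|z\\| above ``threshold``."""
    z = modified_z(values, center=center, scale_constant=scale_constant)
    if periods is None:
        periods = [str(i + 1) for i in range(len(z))]
    return [
        ModifiedZResult(
            geography=geography,
            indicator=indicator,
            period=str(p),
            value=float(v),
            z=float(zi),
            is_outlier=bool(abs(zi) > threshold),
        )
        for p, v, zi in zip(periods, np.asarray(values, dtype=float), z)
    ]


# ---------------------------------------------------------------------------
# Score-bin mappings (total, monotone non-increasing step functions)
# ---------------------------------------------------------------------------

#: (upper bound, score): |z| in [prev, bound) maps to score; |z| >= 2 -> 0
_TIME_Z_BINS: Tuple[Tuple[float, float], ...] = (
    (0.25, 100.0),
    (0.50, 80.0),
    (0.75, 60.0),
    (1.00, 50.0),
    (1.25, 40.0),
    (1.50, 30.0),
    (1.75, 20.0),
    (2.00, 10.0),
)


def score_from_time_z(abs_z: float) -> float:
    """Map \\|modified z\\| of an annual total to a consistency score (%)."""
    if abs_z < 0:
        raise InputError(f"|z| must be non-negative, got {abs_z}")
    for bound, score in _TIME_Z_BINS:
        if abs_z < bound:
            return score
    return 0.0


def score_from_ratio_diff(diff_pct: float) -> float:
    """Map the % difference between reported and expected indicator ratios
    to a pair-consistency score: ≤5 → 100, <15 → 75, <20 → 50, <25 → 25,
    ≥25 → 0."""
    if diff_pct < 0:
        raise InputError(f"ratio difference must be non-negative, got {diff_pct}")
    if diff_pct <= 5:
        return 100.0
    if diff_pct < 15:
        return 75.0
    if diff_pct < 20:
        return 50.0
    if diff_pct < 25:
        return 25.0
    return 0.0


# ---------------------------------------------------------------------------
# Series helpers
# ---------------------------------------------------------------------------


def _geo_counts(counts: pd.DataFrame, geography: str) -> pd.DataFrame:
    """Counts restricted to a geography; NATIONAL pools across districts."""
    if geography == NATIONAL:
        return (
            counts.groupby(["year", "month", "indicator"], as_index=False)["count"].sum()
        )
    sub = counts[counts["district"] == geography]
    if sub.empty:
        raise MissingDataError(f"no service counts for geography {geography!r}")
    return sub


def monthly_series(
    counts: Union[pd.DataFrame, Iterable[MonthlyServiceCount]],
    geography: str,
    year: int,
    indicator: Indicator,
) -> pd.Series:
    """Monthly values for one geography-year-indicator, indexed by month.

    Missing months are simply absent (not imputed as zero)."""
    df = _geo_counts(_frame(counts), geography)
    sub = df[(df["year"] == year) & (df["indicator"] == indicator.value)]
    if sub.empty:
        raise MissingDataError(
            f"no monthly data for {geography!r}, year {year}, indicator {indicator.value}"
        )
    return sub.sort_values("month").set_index("month")["count"].astype(float)


def annual_totals(
    counts: Union[pd.DataFrame, Iterable[MonthlyServiceCount]],
    geography: str,
    indicator: Indicator,
) -> pd.Series:
    """Annual totals (sum over reported months) indexed by year."""
    df = _geo_counts(_frame(counts), geography)
    sub = df[df["indicator"] == indicator.value]
    if sub.empty:
        raise MissingDataError(f"no data for {geography!r}, indicator {indicator.value}")
    return sub.groupby("year")["count"].sum().sort_index().astype(float)


# ---------------------------------------------------------------------------
# The four component metrics
# ---------------------------------------------------------------------------


def completeness_score(
    completeness: Union[pd.DataFrame, Iterable[CompletenessRecord]],
    geography: str,
    year: int,
) -> float:
    """Unweighted mean of the three service-form completeness percentages.

    For ``NATIONAL`` each form's completeness is first averaged across
    districts (unweighted), then the three form values are averaged.
    """
    df = _frame(completeness)
    df = df[df["year"] == year]
    if geography != NATIONAL:
        df = df[df["district"] == geography]
    per_form = df.groupby("service_form")["completeness"].mean()
    missing = [f.value for f in ServiceForm if f.value not in per_form.index]
    if missing:
        raise MissingDataError(
            f"completeness for {geography!r}, year {year}: missing form(s) "
            + ", ".join(missing)
        )
    return float(per_form.loc[[f.value for f in ServiceForm]].mean() * 100.0)


def outlier_results(
    counts: Union[pd.DataFrame, Iterable[MonthlyServiceCount]],
    geography: str,
    year: int,
    indicator: Indicator,
    threshold: float = 3.5,
    scale_constant: bool = False,
) -> List[ModifiedZResult]:
    """Modified-Z results for one geography-year-indicator monthly series."""
    series = monthly_series(counts, geography, year, indicator)
    periods = [f"{year}-{m:02d}" for m in series.index]
    return modified_z_scores(
        series.to_numpy(),
        periods=periods,
        geography=geography,
        indicator=indicator,
        threshold=threshold,
        scale_constant=scale_constant,
    )


def outlier_score(
    counts: Union[pd.DataFrame, Iterable[MonthlyServiceCount]],
    geography: str,
    year: int,
    indicators: Tuple[Indicator, Indicator] = (Indicator.ANC1, Indicator.DPT3),
    threshold: float = 3.5,
    scale_constant: bool = False,
) -> Tuple[float, float]:
    """(score, pct_outliers) for the outlier check.

    ``pct_outliers`` is the mean over the indicators of the percentage of
    monthly values flagged; the score is ``100 − pct_outliers`` so that
    higher is better, as for the other scorecard components.
    """
    pcts = []
    for ind in indicators:
        results = outlier_results(
            counts, geography, year, ind, threshold=threshold, scale_constant=scale_constant
        )
        n_flagged = sum(r.is_outlier for r in results)
        pcts.append(100.0 * n_flagged / len(results))
    pct = float(np.mean(pcts))
    return 100.0 - pct, pct


def time_consistency_score(
    counts: Union[pd.DataFrame, Iterable[MonthlyServiceCount]],
    geography: str,
    target_year: int,
    indicators: Tuple[Indicator, Indicator] = (Indicator.ANC1, Indicator.DPT1),
    include_target: bool = True,
    scale_constant: bool = False,
) -> float:
    """Consistency of the target year's annual totals with adjacent years.

    Per indicator, the modified Z of the target-year total is computed
    against the annual totals of all available years (including the target
    year itself by default, which keeps the MAD non-degenerate with short
    series) and mapped through the z-score bins; the two indicator scores
    are averaged. Requires at least 3 comparison years besides the target.
    """
    scores = []
    for ind in indicators:
        totals = annual_totals(counts, geography, ind)
        if target_year not in totals.index:
            raise MissingDataError(
                f"no annual total for target year {target_year} "
                f"({geography!r}, {ind.value})"
            )
        n_comparison = len(totals) - 1
        if n_comparison < 3:
            raise MissingDataError(
                f"time consistency needs >= 3 comparison years besides "
                f"{target_year}, got {n_comparison} ({geography!r}, {ind.value})"
            )
        comparison = totals if include_target else totals.drop(index=target_year)
        med = float(np.median(comparison.to_numpy()))
        mad = float(np.median(np.abs(comparison.to_numpy() - med)))
        if mad == 0:
            z = 0.0
        else:
            z = (float(totals.loc[target_year]) - med) / mad
            if scale_constant:
                z *= MAD_NORMAL_CONSTANT
        scores.append(score_from_time_z(abs(z)))
    return float(np.mean(scores))


_PAIR_RATIO_COLUMNS = {
    (Indicator.ANC1, Indicator.DPT1): "expected_ratio_anc1_dpt1",
    (Indicator.DPT1, Indicator.DPT3): "expected_ratio_dpt1_dpt3",
}


def expected_ratio(
    survey: Union[pd.DataFrame, Iterable[SurveyBenchmark]],
    pair: Tuple[Indicator, Indicator],
) -> float:
    """Survey-expected ratio for an indicator pair (from the national rows)."""
    col = _PAIR_RATIO_COLUMNS.get(pair)
    if col is None:
        raise InputError(
            f"no expected-ratio column defined for pair "
            f"({pair[0].value}, {pair[1].value})"
        )
    df = _frame(survey)
    national = df[df["geography"] == NATIONAL]
    if col not in df.columns or national.empty:
        raise MissingDataError(f"survey benchmarks carry no national {col}")
    vals = pd.to_numeric(national[col], errors="coerce").dropna()
    if vals.empty:
        raise MissingDataError(f"survey benchmarks carry no national {col}")
    ratio = float(vals.iloc[0])
    if ratio <= 0:
        raise InputError(f"expected ratio {col} must be > 0, got {ratio}")
    return ratio


def pair_consistency_score(
    counts: Union[pd.DataFrame, Iterable[MonthlyServiceCount]],
    survey: Union[pd.DataFrame, Iterable[SurveyBenchmark]],
    geography: str,
    year: int,
    pairs: Tuple[Tuple[Indicator, Indicator], ...] = (
        (Indicator.ANC1, Indicator.DPT1),
        (Indicator.DPT1, Indicator.DPT3),
    ),
) -> float:
    """Mean pair-consistency score over the indicator pairs.

    Per pair, the reported ratio (annual total of the first over the second)
    is compared with the survey-expected ratio; the absolute difference as a
    percentage of the expected ratio is mapped through the score bins.
    """
    scores = []
    for pair in pairs:
        exp = expected_ratio(survey, pair)
        num = annual_totals(counts, geography, pair[0])
        den = annual_totals(counts, geography, pair[1])
        for totals, ind in ((num, pair[0]), (den, pair[1])):
            if year not in totals.index:
                raise MissingDataError(
                    f"no annual total for {geography!r}, {ind.value}, year {year}"
                )
        den_total = float(den.loc[year])
        if den_total <= 0:
            raise InputError(
                f"pair ({pair[0].value}, {pair[1].value}) for {geography!r}: "
                f"zero annual total for {pair[1].value} in {year}"
            )
        reported = float(num.loc[year]) / den_total
        diff_pct = 100.0 * abs(reported - exp) / exp
        scores.append(score_from_ratio_diff(diff_pct))
    return float(np.mean(scores))


# ---------------------------------------------------------------------------
# Composite scorecard
# ---------------------------------------------------------------------------


def build_scorecard(
    counts: Union[pd.DataFrame, Iterable[MonthlyServiceCount]],
    completeness: Union[pd.DataFrame, Iterable[CompletenessRecord]],
    survey: Union[pd.DataFrame, Iterable[SurveyBenchmark]],
    config: Optional[PipelineConfig] = None,
    year: Optional[int] = None,
) -> pd.DataFrame:
    """One scorecard row per district plus a pooled NATIONAL row.

    The national row pools monthly counts across districts before scoring
    (completeness is averaged across districts per form); the composite
    ``score_total`` is the unweighted mean of the four component scores.
    """
    config = config or PipelineConfig()
    year = config.analysis_year if year is None else year
    counts_df = _frame(counts)
    completeness_df = _frame(completeness)
    survey_df = _frame(survey)
    districts = sorted(counts_df["district"].unique())
    rows: List[QualityScorecardRow] = []
    for geo in districts + [NATIONAL]:
        try:
            s_comp = completeness_score(completeness_df, geo, year)
            s_out, pct_out = outlier_score(
                counts_df,
                geo,
                year,
                indicators=config.outlier_indicators,
                threshold=config.outlier_z_threshold,
                scale_constant=config.mad_scaling_constant,
            )
            s_time = time_consistency_score(
                counts_df,
                geo,
                year,
                indicators=config.time_consistency_indicators,
                include_target=config.time_consistency_include_target,
                scale_constant=config.mad_scaling_constant,
            )
            s_pair = pair_consistency_score(
                counts_df, survey_df, geo, year, pairs=config.pair_indicators
            )
        except (MissingDataError, InputError) as exc:
            raise type(exc)(f"scorecard for {geo!r}: {exc}") from exc
        rows.append(
            QualityScorecardRow(
                geography=geo,
                score_completeness=s_comp,
                pct_outliers=pct_out,
                score_outliers=s_out,
                score_time=s_time,
                score_pair=s_pair,
                score_total=float(np.mean([s_comp, s_out, s_time, s_pair])),
            )
        )
    log.info("scorecard built for %d districts + national (year %d)", len(districts), year)
    return to_frame(rows)


def national_score_as_district_mean(scorecard: pd.DataFrame) -> pd.Series:
    """Alternative national summary: unweighted mean of the district rows.

    The scorecard's NATIONAL row is computed from pooled national counts;
    this helper provides the other defensible aggregation for comparison.
    """
    numeric = scorecard[scorecard["geography"] != NATIONAL].drop(columns=["geography"])
    return numeric.mean()
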