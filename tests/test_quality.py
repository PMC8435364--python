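"""Modified Z-scores, score-bin mappings, the four metrics, the scorecard."""
import statistics

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from rhiscov.model import (
    CompletenessRecord,
    Indicator,
    InputError,
    MissingDataError,
    NATIONAL,
    ServiceForm,
)
from rhiscov.quality import (
    build_scorecard,
    completeness_score,
    modified_z,
    modified_z_scores,
    national_score_as_district_mean,
    outlier_results,
    outlier_score,
    pair_consistency_score,
    score_from_ratio_diff,
    score_from_time_z,
    time_consistency_score,
)


def brute_force_modified_z(values):
    """Independent oracle: plain (x − median)/MAD via statistics.median."""
    med = statistics.median(values)
    mad = statistics.median(sorted(abs(v - med) for v in values))
    if mad == 0:
        return [0.0] * len(values)
    return [(v - med) / mad for v in values]


class TestModifiedZ:
    def test_hand_worked_series_flags_the_spike(self):
        series = [1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 100]
        results = modified_z_scores(series, threshold=3.5)
        # median 6.5, MAD 3.0, so the spike scores 93.5/3
        assert results[-1].z == pytest.approx(93.5 / 3.0)
        assert results[-1].is_outlier
        assert sum(r.is_outlier for r in results) == 1

    def test_constant_series_has_all_zero_scores(self):
        assert modified_z([5, 5, 5, 5]).tolist() == [0.0, 0.0, 0.0, 0.0]

    def test_value_at_the_median_scores_zero(self):
        z = modified_z([3, 7, 11, 21, 40])
        assert z[2] == 0.0

    def test_short_series_rejected(self):
        with pytest.raises(InputError):
            modified_z([4.0])

    def test_scaling_constant_multiplies_by_06745(self):
        series = [1, 2, 3, 4, 100]
        plain = modified_z(series)
        scaled = modified_z(series, scale_constant=True)
        assert scaled == pytest.approx(plain * 0.6745)

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(
        st.lists(
            st.floats(min_value=0, max_value=1e6, allow_nan=False),
            min_size=4,
            max_size=24,
        )
    )
    def test_matches_brute_force_oracle(self, values):
        assert modified_z(values) == pytest.approx(
            brute_force_modified_z(values), abs=1e-9
        )


class TestScoreBins:
    @pytest.mark.parametrize(
        "abs_z, expected",
        [
            (0.0, 100), (0.24, 100), (0.25, 80), (0.30, 80), (0.49, 80),
            (0.5, 60), (0.74, 60), (0.75, 50), (0.99, 50), (1.0, 40),
            (1.24, 40), (1.25, 30), (1.5, 20), (1.75, 10), (1.99, 10),
            (2.0, 0), (2.4, 0), (31.2, 0),
        ],
    )
    def test_time_bins_exact_at_printed_boundaries(self, abs_z, expected):
        assert score_from_time_z(abs_z) == expected

    @pytest.mark.parametrize(
        "diff, expected",
        [
            (0.0, 100), (5.0, 100), (5.01, 75), (10.0, 75), (14.99, 75),
            (15.0, 50), (19.99, 50), (20.0, 25), (24.99, 25), (25.0, 0),
            (30.0, 0),
        ],
    )
    def test_ratio_bins_exact_at_printed_boundaries(self, diff, expected):
        assert score_from_ratio_diff(diff) == expected

    @pytest.mark.parametrize("fn, hi", [(score_from_time_z, 4.0), (score_from_ratio_diff, 60.0)])
    def test_bins_are_total_and_monotone_non_increasing(self, fn, hi):
        grid = np.linspace(0, hi, 1201)
        scores = [fn(x) for x in grid]
        assert all(0 <= s <= 100 for s in scores)
        assert all(a >= b for a, b in zip(scores, scores[1:]))

    def test_negative_input_rejected(self):
        with pytest.raises(InputError):
            score_from_time_z(-0.1)
        with pytest.raises(InputError):
            score_from_ratio_diff(-1)


def _completeness(values_by_form, district="A", year=2016):
    return [
        CompletenessRecord(
            district=district, year=year, service_form=form, completeness=v
        )
        for form, v in values_by_form.items()
    ]


class TestCompletenessScore:
    def test_reported_service_values_give_the_overall_rate(self):
        recs = _completeness(
            {ServiceForm.ANC: 0.94, ServiceForm.IMMUNIZATION: 0.89, ServiceForm.DELIVERY: 0.94}
        )
        score = completeness_score(recs, "A", 2016)
        assert score == pytest.approx(92.3333, abs=1e-3)
        assert round(score) == 92

    def test_full_reporting_scores_100(self):
        recs = _completeness({f: 1.0 for f in ServiceForm})
        assert completeness_score(recs, "A", 2016) == 100.0

    def test_exactly_at_who_threshold(self):
        recs = _completeness({f: 0.8 for f in ServiceForm})
        assert completeness_score(recs, "A", 2016) == pytest.approx(80.0)

    def test_missing_form_error_names_the_form(self):
        recs = _completeness({ServiceForm.ANC: 0.9, ServiceForm.DELIVERY: 0.9})
        with pytest.raises(MissingDataError, match="IMMUNIZATION"):
            completeness_score(recs, "A", 2016)


def _monthly_frame(per_indicator, district="A", year=2016):
    rows = []
    for ind, values in per_indicator.items():
        for m, v in enumerate(values, start=1):
            rows.append(
                {"district": district, "year": year, "month": m, "indicator": ind.value, "count": v}
            )
    return pd.DataFrame(rows)


class TestOutlierScore:
    def test_no_outliers_scores_100(self):
        counts = _monthly_frame(
            {
                Indicator.ANC1: [100, 102, 98, 101, 99, 103, 97, 100, 102, 98, 101, 99],
                Indicator.DPT3: [50, 52, 48, 51, 49, 53, 47, 50, 52, 48, 51, 49],
            }
        )
        score, pct = outlier_score(counts, "A", 2016)
        assert (score, pct) == (100.0, 0.0)

    def test_one_outlier_month_of_twelve_in_one_indicator(self):
        counts = _monthly_frame(
            {
                Indicator.ANC1: [95, 98, 100, 102, 104, 96, 99, 101, 103, 97, 105, 1000],
                Indicator.DPT3: [50, 52, 48, 51, 49, 53, 47, 50, 52, 48, 51, 49],
            }
        )
        score, pct = outlier_score(counts, "A", 2016)
        # outlier percentages (8.33, 0) -> score 100 - 4.17
        assert pct == pytest.approx(100 / 24, abs=1e-6)
        assert score == pytest.approx(100 - 100 / 24, abs=1e-6)

    def test_missing_months_excluded_not_imputed(self):
        counts = _monthly_frame(
            {
                Indicator.ANC1: [95, 98, 100, 102, 104, 96],  # six months only
                Indicator.DPT3: [50, 52, 48, 51, 49, 53],
            }
        )
        results = outlier_results(counts, "A", 2016, Indicator.ANC1)
        assert len(results) == 6

    def test_no_monthly_data_is_an_error(self):
        counts = _monthly_frame({Indicator.ANC1: [1] * 12})
        with pytest.raises(MissingDataError):
            outlier_score(counts, "A", 2016)  # DPT3 absent


def _multi_year_frame(totals_by_year, indicator, district="A"):
    rows = []
    for year, total in totals_by_year.items():
        for m in range(1, 13):
            rows.append(
                {
                    "district": district,
                    "year": year,
                    "month": m,
                    "indicator": indicator.value,
                    "count": total / 12.0,
                }
            )
    return pd.DataFrame(rows)


class TestTimeConsistency:
    def test_target_year_at_the_median_scores_100(self):
        frames = [
            _multi_year_frame({2014: 900, 2015: 950, 2016: 1000, 2017: 1050, 2018: 1100}, ind)
            for ind in (Indicator.ANC1, Indicator.DPT1)
        ]
        counts = pd.concat(frames, ignore_index=True)
        assert time_consistency_score(counts, "A", 2016) == 100.0

    def test_fewer_than_three_comparison_years_rejected(self):
        frames = [
            _multi_year_frame({2015: 950, 2016: 1000, 2017: 1050}, ind)
            for ind in (Indicator.ANC1, Indicator.DPT1)
        ]
        counts = pd.concat(frames, ignore_index=True)
        with pytest.raises(MissingDataError, match="comparison years"):
            time_consistency_score(counts, "A", 2016)

    def test_discrepant_target_year_scores_low(self):
        frames = [
            _multi_year_frame({2014: 1000, 2015: 1010, 2016: 5000, 2017: 990, 2018: 1005}, ind)
            for ind in (Indicator.ANC1, Indicator.DPT1)
        ]
        counts = pd.concat(frames, ignore_index=True)
        assert time_consistency_score(counts, "A", 2016) == 0.0


def _survey_with_ratios(anc1_dpt1=1.1, dpt1_dpt3=1.05):
    return pd.DataFrame(
        [
            {
                "geography": NATIONAL,
                "indicator": "ANC1",
                "point": 97.1,
                "ci_low": 96.4,
                "ci_high": 97.7,
                "expected_ratio_anc1_dpt1": anc1_dpt1,
                "expected_ratio_dpt1_dpt3": dpt1_dpt3,
            }
        ]
    )


class TestPairConsistency:
    def _counts(self, anc1, dpt1, dpt3):
        return pd.concat(
            [
                _multi_year_frame({2016: anc1}, Indicator.ANC1),
                _multi_year_frame({2016: dpt1}, Indicator.DPT1),
                _multi_year_frame({2016: dpt3}, Indicator.DPT3),
            ],
            ignore_index=True,
        )

    def test_reported_equal_to_expected_scores_100(self):
        counts = self._counts(1100, 1000, 1000 / 1.05)
        survey = _survey_with_ratios(1.1, 1.05)
        assert pair_consistency_score(counts, survey, "A", 2016) == 100.0

    def test_ten_percent_difference_scores_75(self):
        # first pair off by 10%, second exact -> mean of (75, 100)
        counts = self._counts(1100 * 1.1, 1000, 1000 / 1.05)
        survey = _survey_with_ratios(1.1, 1.05)
        assert pair_consistency_score(counts, survey, "A", 2016) == pytest.approx(87.5)

    def test_zero_denominator_total_is_an_error(self):
        counts = self._counts(1100, 0.0, 1000)
        survey = _survey_with_ratios()
        with pytest.raises(InputError, match="zero annual total"):
            pair_consistency_score(counts, survey, "A", 2016)

    def test_missing_expected_ratio_is_an_error(self):
        counts = self._counts(1100, 1000, 950)
        survey = _survey_with_ratios().drop(columns=["expected_ratio_dpt1_dpt3"])
        with pytest.raises(MissingDataError):
            pair_consistency_score(counts, survey, "A", 2016)


@pytest.fixture(scope="module")
def scorecard(sl_bundle):
    return build_scorecard(
        sl_bundle.counts, sl_bundle.completeness, sl_bundle.survey, year=2016
    )


class TestScorecard:

    def test_one_row_per_district_plus_national(self, scorecard):
        assert len(scorecard) == 15
        assert (scorecard["geography"] == NATIONAL).sum() == 1

    def test_total_is_the_component_mean_to_machine_precision(self, scorecard):
        components = scorecard[
            ["score_completeness", "score_outliers", "score_time", "score_pair"]
        ].to_numpy()
        assert scorecard["score_total"].to_numpy() == pytest.approx(
            components.mean(axis=1)
        )

    def test_all_scores_within_bounds(self, scorecard):
        cols = [c for c in scorecard.columns if c != "geography"]
        values = scorecard[cols].to_numpy()
        assert (values >= 0).all() and (values <= 100).all()

    def test_national_completeness_matches_reported_rates(self, scorecard):
        nat = scorecard[scorecard["geography"] == NATIONAL].iloc[0]
        assert nat["score_completeness"] == pytest.approx(92.3333, abs=1e-3)

    def test_district_mean_alternative_summary(self, scorecard):
        means = national_score_as_district_mean(scorecard)
        assert 0 <= means["score_total"] <= 100
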