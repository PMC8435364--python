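"""Adjustment of reported counts for incomplete facility reporting.

Facility reporting is rarely complete; the reported count ``n_rep`` together
with the reporting completeness ``c`` (fraction of expected facility reports
received) and a k-factor (assumed service level of non-reporting facilities
relative to reporting ones) gives the adjusted count

    n_adj = n_rep + n_rep * (1/c - 1) * k

With k = 0 non-reporting facilities are assumed to provide no services
(adjustment is the identity); with k = 1 they provide the same level as
reporting facilities and the adjustment is a full inflation to n_rep / c.

Adjustment is applied to annual district aggregates with the annual form
completeness. Because the formula is linear in the count and completeness is
recorded annually per (district, form), adjusting each month and summing is
algebraically identical, so no separate monthly mode exists.
"""
from __future__ import annotations

import logging
from typing import Iterable, Union

import pandas as pd

from .io import to_frame
from .model import (
    AdjustedCount,
    CompletenessRecord,
    FORM_FOR_INDICATOR,
    Indicator,
    InputError,
    KFactorPolicy,
    MissingDataError,
    MonthlyServiceCount,
    NATIONAL,
)

log = logging.getLogger("rhiscov")


def adjust(n_rep: float, c: float, k: float) -> float:
    """Adjusted count for incomplete reporting.

    Continuous, monotone decreasing in ``c`` and increasing in ``k``;
    bounded by ``n_rep <= n_adj <= n_rep / c`` for k in [0, 1].
    """
    if n_rep < 0:
        raise InputError(f"reported count must be >= 0, got {n_rep}")
    if not (0 < c <= 1):
        raise InputError(f"completeness must be in (0, 1], got {c}")
    if not (0 <= k <= 1):
        raise InputError(f"k-factor must be in [0, 1], got {k}")
    return n_rep + n_rep * (1.0 / c - 1.0) * k


def _frame(data: Union[pd.DataFrame, Iterable]) -> pd.DataFrame:
    return data if isinstance(data, pd.DataFrame) else to_frame(list(data))


def adjust_all(
    counts: Union[pd.DataFrame, Iterable[MonthlyServiceCount]],
    completeness: Union[pd.DataFrame, Iterable[CompletenessRecord]],
    policy: KFactorPolicy,
) -> pd.DataFrame:
    """Adjust annual district totals for every (district, year, indicator).

    Annual totals are the sums of the reported monthly counts; each is
    matched to the completeness record of its reporting form for that
    district-year. A missing completeness match is an error naming the key.
    Adjusted counts are kept as real numbers (no rounding).

    Returns a frame with columns
    ``district, year, indicator, service_form, n_rep, c, k, n_adj``.
    """
    counts_df = _frame(counts)
    comp_df = _frame(completeness)
    annual = (
        counts_df.groupby(["district", "year", "indicator"], as_index=False)["count"].sum()
    )
    comp_lookup = comp_df.set_index(["district", "year", "service_form"])["completeness"]
    records = []
    for row in annual.itertuples(index=False):
        indicator = Indicator(row.indicator)
        form = FORM_FOR_INDICATOR[indicator]
        try:
            c = float(comp_lookup.loc[(row.district, row.year, form.value)])
        except KeyError:
            raise MissingDataError(
                f"no completeness record for district={row.district!r}, "
                f"year={row.year}, form={form.value} "
                f"(needed by indicator {indicator.value})"
            ) from None
        k = policy.k_for(form)
        records.append(
            AdjustedCount(
                district=row.district,
                year=int(row.year),
                indicator=indicator,
                n_rep=float(row.count),
                c=c,
                k=k,
                n_adj=adjust(float(row.count), c, k),
            )
        )
    out = to_frame(records)
    out.insert(3, "service_form", [FORM_FOR_INDICATOR[Indicator(i)].value for i in out["indicator"]])
    log.info("adjusted %d annual district aggregates", len(out))
    return out


def national_adjusted(adjusted: pd.DataFrame) -> pd.DataFrame:
    """National adjusted counts as sums of district adjusted counts.

    Summing district adjustments (rather than re-adjusting national sums
    with a national completeness) preserves district additivity.
    """
    nat = (
        adjusted.groupby(["year", "indicator"], as_index=False)[["n_rep", "n_adj"]].sum()
    )
    nat.insert(0, "district", NATIONAL)
    return nat
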