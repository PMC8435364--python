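"""Target-population (denominator) derivation.

Five methods estimate the population in need of each service:

* ``CENSUS_CBR`` — projected total population × crude birth rate / 1000
  gives expected live births, then the demographic chain.
* ``CENSUS_LIVEBIRTHS`` — projected live births from the census directly.
* ``SERVICE_ANC1`` / ``SERVICE_BCG`` / ``SERVICE_DPT1`` — the adjusted
  count of an anchor service, inflated for survey-estimated non-use of that
  service, anchors the chain at pregnancies (ANC1), live births (BCG) or
  surviving infants (DPT1).

The demographic chain links pregnancies, deliveries, total births, live
births and surviving infants through the stillbirth rate, the multiple-birth
proportion, the early-fetal-loss proportion and the neonatal mortality rate;
it can be entered at any anchor and completed in both directions, and the
relations invert exactly.
"""
from __future__ import annotations

import logging
from typing import Dict, Iterable, List, Optional, Tuple, Union

import pandas as pd

from .io import to_frame
from .model import (
    ANCHOR_FOR_METHOD,
    ChainConventions,
    DemographicAssumptions,
    DenominatorMethod,
    Indicator,
    InputError,
    MissingDataError,
    NATIONAL,
    PopulationChain,
)

log = logging.getLogger("rhiscov")

_DEFAULT_CONV = ChainConventions()


def _check_proportion(name: str, p: float) -> None:
    if not (0 <= p < 1):
        raise InputError(f"{name} must be in [0, 1), got {p}")


def chain_from_live_births(
    live_births: float,
    assumptions: DemographicAssumptions,
    conventions: ChainConventions = _DEFAULT_CONV,
    geography: Optional[str] = None,
    year: Optional[int] = None,
) -> PopulationChain:
    """Complete the demographic chain upward and downward from live births.

    total_births = live_births / (1 − stillbirth_rate);
    deliveries = total_births / (1 + multiple_birth_proportion);
    pregnancies = deliveries / (1 − early_fetal_loss_proportion);
    surviving_infants = live_births × (1 − nmr).
    """
    if live_births <= 0:
        raise InputError(f"live births must be > 0, got {live_births}")
    a = assumptions
    for name in ("stillbirth_rate", "multiple_birth_proportion", "early_fetal_loss_proportion", "nmr"):
        _check_proportion(name, getattr(a, name))
    if conventions.stillbirth_of_total_births:
        total_births = live_births / (1.0 - a.stillbirth_rate)
    else:
        total_births = live_births * (1.0 + a.stillbirth_rate)
    if conventions.multiple_births_per_delivery:
        deliveries = total_births / (1.0 + a.multiple_birth_proportion)
    else:
        deliveries = total_births * (1.0 - a.multiple_birth_proportion)
    if conventions.fetal_loss_of_pregnancies:
        pregnancies = deliveries / (1.0 - a.early_fetal_loss_proportion)
    else:
        pregnancies = deliveries * (1.0 + a.early_fetal_loss_proportion)
    surviving_infants = live_births * (1.0 - a.nmr)
    return PopulationChain(
        geography=geography or a.geography,
        year=year if year is not None else a.year,
        pregnancies=pregnancies,
        deliveries=deliveries,
        total_births=total_births,
        live_births=live_births,
        surviving_infants=surviving_infants,
    )


def live_births_from_pregnancies(
    pregnancies: float,
    assumptions: DemographicAssumptions,
    conventions: ChainConventions = _DEFAULT_CONV,
) -> float:
    """Invert the chain: expected live births implied by pregnancies."""
    if pregnancies <= 0:
        raise InputError(f"pregnancies must be > 0, got {pregnancies}")
    a = assumptions
    if conventions.fetal_loss_of_pregnancies:
        deliveries = pregnancies * (1.0 - a.early_fetal_loss_proportion)
    else:
        deliveries = pregnancies / (1.0 + a.early_fetal_loss_proportion)
    if conventions.multiple_births_per_delivery:
        total_births = deliveries * (1.0 + a.multiple_birth_proportion)
    else:
        total_births = deliveries / (1.0 - a.multiple_birth_proportion)
    if conventions.stillbirth_of_total_births:
        return total_births * (1.0 - a.stillbirth_rate)
    return total_births / (1.0 + a.stillbirth_rate)


def live_births_from_surviving_infants(
    surviving_infants: float,
    assumptions: DemographicAssumptions,
) -> float:
    """Invert the neonatal-survival step."""
    if surviving_infants <= 0:
        raise InputError(f"surviving infants must be > 0, got {surviving_infants}")
    return surviving_infants / (1.0 - assumptions.nmr)


def census_cbr_denominator(
    assumptions: DemographicAssumptions,
    conventions: ChainConventions = _DEFAULT_CONV,
) -> PopulationChain:
    """Census method 1: projected population × CBR / 1000 → live births."""
    live_births = assumptions.projected_population * assumptions.cbr / 1000.0
    return chain_from_live_births(live_births, assumptions, conventions)


def census_livebirth_denominator(
    assumptions: DemographicAssumptions,
    conventions: ChainConventions = _DEFAULT_CONV,
) -> PopulationChain:
    """Census method 2: projected live births used directly."""
    return chain_from_live_births(
        assumptions.projected_live_births, assumptions, conventions
    )


def service_based_denominator(
    n_adj: float,
    assumptions: DemographicAssumptions,
    anchor: Indicator,
    conventions: ChainConventions = _DEFAULT_CONV,
) -> PopulationChain:
    """Service-based method: adjusted anchor count inflated for non-use.

    The anchor population is ``n_adj / (1 − nonuse[anchor])``; ANC1 anchors
    the chain at pregnancies, BCG at live births, DPT1 at surviving infants,
    and the chain is completed from there.
    """
    if anchor not in ANCHOR_FOR_METHOD.values():
        raise InputError(f"{anchor.value} is not a service-denominator anchor")
    if anchor not in assumptions.nonuse:
        raise MissingDataError(
            f"no non-use proportion for anchor {anchor.value} "
            f"({assumptions.geography!r})"
        )
    nonuse = assumptions.nonuse[anchor]
    if not (0 <= nonuse < 1):
        raise InputError(f"nonuse[{anchor.value}] must be in [0, 1), got {nonuse}")
    if n_adj <= 0:
        raise InputError(f"adjusted anchor count must be > 0, got {n_adj}")
    anchor_population = n_adj / (1.0 - nonuse)
    if anchor == Indicator.ANC1:
        live_births = live_births_from_pregnancies(
            anchor_population, assumptions, conventions
        )
    elif anchor == Indicator.BCG:
        live_births = anchor_population
    else:  # DPT1
        live_births = live_births_from_surviving_infants(anchor_population, assumptions)
    return chain_from_live_births(live_births, assumptions, conventions)


_DENOMINATOR_FIELD: Dict[Indicator, str] = {
    Indicator.ANC1: "pregnancies",
    Indicator.DELIVERY: "deliveries",
    Indicator.DPT3: "surviving_infants",
}


def denominator_for_indicator(chain: PopulationChain, indicator: Indicator) -> float:
    """Target population for a coverage indicator: pregnancies for ANC1,
    deliveries for institutional delivery, surviving infants for DPT3."""
    try:
        field = _DENOMINATOR_FIELD[indicator]
    except KeyError:
        raise InputError(
            f"no target population defined for indicator {indicator.value}"
        ) from None
    return float(getattr(chain, field))


def methods_for_indicator(indicator: Indicator) -> List[DenominatorMethod]:
    """Denominator methods applicable to a coverage indicator.

    The method anchored on the indicator being measured is excluded (its
    coverage would be the tautological 1 − non-use), leaving four methods
    for ANC1 and five for delivery and DPT3.
    """
    return [
        m
        for m in DenominatorMethod
        if ANCHOR_FOR_METHOD.get(m) != indicator
    ]


def build_denominators(
    adjusted: pd.DataFrame,
    demography: Iterable[DemographicAssumptions],
    year: int,
    conventions: ChainConventions = _DEFAULT_CONV,
) -> pd.DataFrame:
    """Population chains per district × method for one year, plus NATIONAL.

    ``adjusted`` is the frame from :func:`rhiscov.adjust.adjust_all`.
    National chains are component-wise sums of the district chains (every
    chain relation is linear in its anchor, so summing is exact).

    Returns columns ``geography, year, method, pregnancies, deliveries,
    total_births, live_births, surviving_infants``.
    """
    demo_by_geo: Dict[str, DemographicAssumptions] = {}
    for d in demography:
        if d.geography == NATIONAL:
            continue
        if d.year is None or d.year == year:
            # exact-year records take precedence over year-agnostic ones
            if d.geography not in demo_by_geo or d.year == year:
                demo_by_geo[d.geography] = d
    sub = adjusted[adjusted["year"] == year]
    if sub.empty:
        raise MissingDataError(f"no adjusted counts for year {year}")
    districts = sorted(sub["district"].unique())
    anchor_counts = sub.set_index(["district", "indicator"])["n_adj"]
    rows = []
    for district in districts:
        try:
            a = demo_by_geo[district]
        except KeyError:
            raise MissingDataError(
                f"no demographic assumptions for district {district!r}, year {year}"
            ) from None
        for method in DenominatorMethod:
            if method == DenominatorMethod.CENSUS_CBR:
                chain = census_cbr_denominator(a, conventions)
            elif method == DenominatorMethod.CENSUS_LIVEBIRTHS:
                chain = census_livebirth_denominator(a, conventions)
            else:
                anchor = ANCHOR_FOR_METHOD[method]
                try:
                    n_adj = float(anchor_counts.loc[(district, anchor.value)])
                except KeyError:
                    raise MissingDataError(
                        f"no adjusted count for anchor {anchor.value} "
                        f"in district {district!r}, year {year}"
                    ) from None
                chain = service_based_denominator(n_adj, a, anchor, conventions)
            rows.append(
                {
                    "geography": district,
                    "year": year,
                    "method": method.value,
                    "pregnancies": chain.pregnancies,
                    "deliveries": chain.deliveries,
                    "total_births": chain.total_births,
                    "live_births": chain.live_births,
                    "surviving_infants": chain.surviving_infants,
                }
            )
    df = pd.DataFrame(rows)
    chain_cols = ["pregnancies", "deliveries", "total_births", "live_births", "surviving_infants"]
    national = df.groupby("method", as_index=False)[chain_cols].sum()
    national.insert(0, "geography", NATIONAL)
    national.insert(1, "year", year)
    out = pd.concat([df, national], ignore_index=True)
    log.info(
        "denominators built for %d districts x %d methods (year %d)",
        len(districts),
        len(DenominatorMethod),
        year,
    )
    return out
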