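"""Readers, writers and cross-file validation for the pipeline's CSV inputs.

All inputs are long-format (tidy) CSV: one record per row with explicit
keys, matching the shape of a DHIS2 aggregate export after unpivoting.
Readers validate every row against the typed records in :mod:`rhiscov.model`
and report parse/validation failures with 1-based file row numbers.
"""
from __future__ import annotations

import csv
import json
import logging
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Tuple, Union

import pandas as pd
import yaml
from pydantic import BaseModel, ValidationError

from .model import (
    CompletenessRecord,
    ConfigError,
    DemographicAssumptions,
    Indicator,
    InputError,
    MonthlyServiceCount,
    NATIONAL,
    PipelineConfig,
    SurveyBenchmark,
)

log = logging.getLogger("rhiscov")

#: output columns rounded to 1 decimal place (display precision only;
#: internal values stay unrounded)
_ONE_DP_COLUMNS = frozenset(
    {
        "coverage",
        "gap",
        "national_coverage",
        "point",
        "ci_low",
        "ci_high",
        "score_completeness",
        "pct_outliers",
        "score_outliers",
        "score_time",
        "score_pair",
        "score_total",
    }
)


def _open_rows(path: Union[str, Path], required: Sequence[str]) -> Tuple[List[dict], List[str]]:
    """Read a CSV into dict rows, checking the header. Returns (rows, header)."""
    path = Path(path)
    try:
        with path.open(newline="") as fh:
            reader = csv.DictReader(fh)
            header = reader.fieldnames or []
            missing = [c for c in required if c not in header]
            if missing:
                raise InputError(
                    f"{path}: missing required column(s) {', '.join(missing)}; "
                    f"found header {header}"
                )
            rows = list(reader)
    except OSError as exc:
        raise InputError(f"cannot read {path}: {exc}") from exc
    return rows, list(header)


def _row_errors(row: dict, rownum: int, path: Path) -> str:
    return f"{path.name} row {rownum}"


def read_service_counts(
    path: Union[str, Path], on_error: str = "raise"
) -> Union[List[MonthlyServiceCount], Tuple[List[MonthlyServiceCount], List[str]]]:
    """Read monthly service counts from CSV.

    Expected header: ``district,year,month,indicator,count``. Row numbers in
    error messages are 1-based file lines (header = line 1). Duplicate
    (district, year, month, indicator) keys are rejected.

    With ``on_error="collect"`` returns ``(accepted, errors)`` instead of
    raising, so that accepted + rejected rows always account for the input.
    """
    path = Path(path)
    rows, _ = _open_rows(path, ["district", "year", "month", "indicator", "count"])
    records: List[MonthlyServiceCount] = []
    errors: List[str] = []
    seen: dict = {}
    for i, row in enumerate(rows):
        rownum = i + 2  # line 1 is the header
        try:
            rec = MonthlyServiceCount(
                district=(row.get("district") or ""),
                year=row.get("year"),
                month=row.get("month"),
                indicator=row.get("indicator"),
                count=row.get("count"),
            )
        except ValidationError as exc:
            details = "; ".join(
                f"{'.'.join(str(p) for p in e['loc'])}: {e['msg']}" for e in exc.errors()
            )
            errors.append(f"{_row_errors(row, rownum, path)}: {details}")
            continue
        key = rec.key()
        if key in seen:
            errors.append(
                f"{_row_errors(row, rownum, path)}: duplicate key "
                f"(district={key[0]}, year={key[1]}, month={key[2]}, "
                f"indicator={key[3]}) first seen at row {seen[key]}"
            )
            continue
        seen[key] = rownum
        records.append(rec)
    if on_error == "collect":
        return records, errors
    if errors:
        raise InputError("\n".join(errors))
    log.info("read %d service-count records from %s", len(records), path)
    return records


def read_completeness(path: Union[str, Path]) -> List[CompletenessRecord]:
    """Read reporting-completeness records from CSV.

    Expected header: ``district,year,service_form,completeness`` with an
    optional ``unit`` column taking ``fraction`` or ``percent`` per row.
    Without a unit column every value must already be a fraction in (0, 1];
    values above 1 are rejected with a hint to add the unit column, so a
    percent file can never be silently misread 100× too large.
    """
    path = Path(path)
    rows, header = _open_rows(path, ["district", "year", "service_form", "completeness"])
    has_unit = "unit" in header
    records: List[CompletenessRecord] = []
    errors: List[str] = []
    for i, row in enumerate(rows):
        rownum = i + 2
        raw = row.get("completeness")
        try:
            value = float(raw)
        except (TypeError, ValueError):
            errors.append(f"{_row_errors(row, rownum, path)}: completeness {raw!r} is not a number")
            continue
        if has_unit:
            unit = (row.get("unit") or "").strip().lower()
            if unit == "percent":
                value /= 100.0
            elif unit != "fraction":
                errors.append(
                    f"{_row_errors(row, rownum, path)}: unit must be "
                    f"'fraction' or 'percent', got {row.get('unit')!r}"
                )
                continue
        elif value > 1:
            errors.append(
                f"{_row_errors(row, rownum, path)}: completeness {value} > 1; "
                "add a 'unit' column with value 'percent' if values are percentages"
            )
            continue
        try:
            records.append(
                CompletenessRecord(
                    district=row.get("district") or "",
                    year=row.get("year"),
                    service_form=row.get("service_form"),
                    completeness=value,
                )
            )
        except ValidationError as exc:
            errors.append(f"{_row_errors(row, rownum, path)}: {exc.errors()[0]['msg']}")
    if errors:
        raise InputError("\n".join(errors))
    log.info("read %d completeness records from %s", len(records), path)
    return records


_NONUSE_COLUMNS = {
    "nonuse_anc1": Indicator.ANC1,
    "nonuse_bcg": Indicator.BCG,
    "nonuse_dpt1": Indicator.DPT1,
}


def read_demography(path: Union[str, Path]) -> List[DemographicAssumptions]:
    """Read demographic assumptions from CSV.

    Expected header: ``district, [year,] projected_population,
    projected_live_births, cbr, stillbirth_rate, multiple_birth_proportion,
    early_fetal_loss_proportion, nmr, nonuse_anc1, nonuse_bcg, nonuse_dpt1``.
    """
    path = Path(path)
    required = [
        "district",
        "projected_population",
        "projected_live_births",
        "cbr",
        "stillbirth_rate",
        "multiple_birth_proportion",
        "early_fetal_loss_proportion",
        "nmr",
    ]
    rows, header = _open_rows(path, required)
    records: List[DemographicAssumptions] = []
    errors: List[str] = []
    for i, row in enumerate(rows):
        rownum = i + 2
        nonuse = {}
        for col, ind in _NONUSE_COLUMNS.items():
            if col in header and (row.get(col) or "").strip() != "":
                nonuse[ind] = row[col]
        try:
            records.append(
                DemographicAssumptions(
                    geography=row.get("district") or "",
                    year=(row.get("year") or None) if "year" in header else None,
                    projected_population=row.get("projected_population"),
                    projected_live_births=row.get("projected_live_births"),
                    cbr=row.get("cbr"),
                    stillbirth_rate=row.get("stillbirth_rate"),
                    multiple_birth_proportion=row.get("multiple_birth_proportion"),
                    early_fetal_loss_proportion=row.get("early_fetal_loss_proportion"),
                    nmr=row.get("nmr"),
                    nonuse=nonuse,
                )
            )
        except (ValidationError, ValueError) as exc:
            errors.append(f"{_row_errors(row, rownum, path)}: {exc}")
    if errors:
        raise InputError("\n".join(errors))
    log.info("read %d demography records from %s", len(records), path)
    return records


def read_survey(path: Union[str, Path]) -> List[SurveyBenchmark]:
    """Read household-survey benchmark estimates from CSV.

    Expected header: ``geography,indicator,point,ci_low,ci_high`` with
    optional ``expected_ratio_anc1_dpt1`` and ``expected_ratio_dpt1_dpt3``
    columns (national rows only; leave blank elsewhere).
    """
    path = Path(path)
    rows, header = _open_rows(path, ["geography", "indicator", "point", "ci_low", "ci_high"])
    records: List[SurveyBenchmark] = []
    errors: List[str] = []
    for i, row in enumerate(rows):
        rownum = i + 2
        kwargs = {
            "geography": row.get("geography") or "",
            "indicator": row.get("indicator"),
            "point": row.get("point"),
            "ci_low": row.get("ci_low"),
            "ci_high": row.get("ci_high"),
        }
        for opt in ("expected_ratio_anc1_dpt1", "expected_ratio_dpt1_dpt3"):
            if opt in header and (row.get(opt) or "").strip() != "":
                kwargs[opt] = row[opt]
        try:
            records.append(SurveyBenchmark(**kwargs))
        except ValidationError as exc:
            errors.append(f"{_row_errors(row, rownum, path)}: {exc.errors()[0]['msg']}")
    if errors:
        raise InputError("\n".join(errors))
    log.info("read %d survey benchmarks from %s", len(records), path)
    return records


def read_config(path: Optional[Union[str, Path]] = None) -> PipelineConfig:
    """Load the pipeline configuration from YAML or JSON.

    A missing path or empty file yields the defaults (k = 0.25 for every
    form, outlier |z| threshold 3.5, completeness threshold 80%).
    """
    if path is None:
        return PipelineConfig.from_dict(None)
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise ConfigError(f"cannot read config {path}: {exc}") from exc
    if path.suffix.lower() == ".json":
        raw = json.loads(text) if text.strip() else None
    else:
        raw = yaml.safe_load(text)
    if raw is not None and not isinstance(raw, dict):
        raise ConfigError(f"config {path} must contain a mapping, got {type(raw).__name__}")
    return PipelineConfig.from_dict(raw)


def to_frame(records: Iterable[BaseModel]) -> pd.DataFrame:
    """Convert typed records to a tidy DataFrame (enum values as strings)."""
    rows = [r.model_dump(mode="json") for r in records]
    if not rows:
        raise InputError("cannot build a frame from an empty record collection")
    return pd.DataFrame(rows)


def write_results(
    data: Union[pd.DataFrame, Sequence[BaseModel]], path: Union[str, Path]
) -> Path:
    """Write results to CSV with deterministic column order.

    Percent-scale columns (coverage, gap, scores, CI bounds) are rounded to
    one decimal on output only; internal values are never rounded. Refuses
    to write an empty collection.
    """
    if not isinstance(data, pd.DataFrame):
        data = to_frame(list(data))
    if data.empty:
        raise InputError(f"refusing to write empty results to {path}")
    out = data.copy()
    for col in out.columns:
        if col in _ONE_DP_COLUMNS:
            out[col] = pd.to_numeric(out[col]).round(1)
    path = Path(path)
    out.to_csv(path, index=False)
    log.info("wrote %d rows to %s", len(out), path)
    return path


def check_district_consistency(
    counts: Iterable[MonthlyServiceCount],
    completeness: Iterable[CompletenessRecord],
    demography: Iterable[DemographicAssumptions],
    survey: Iterable[SurveyBenchmark],
) -> List[str]:
    """Check that all input files agree on the district labels (exact match).

    Returns the sorted district list; raises :class:`InputError` naming any
    file whose districts differ from the service-count file's. The reserved
    ``NATIONAL`` label is ignored.
    """
    base = {c.district for c in counts}
    others = {
        "completeness": {c.district for c in completeness},
        "demography": {d.geography for d in demography} - {NATIONAL},
        "survey": {s.geography for s in survey} - {NATIONAL},
    }
    problems = []
    for name, labels in others.items():
        extra = sorted(labels - base)
        missing = sorted(base - labels)
        if extra or missing:
            problems.append(
                f"{name}: districts not in service counts {extra or '[]'}; "
                f"service-count districts missing here {missing or '[]'}"
            )
    if problems:
        raise InputError("district labels inconsistent across inputs:\n" + "\n".join(problems))
    return sorted(base)
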