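"""Bundled datasets: published Sydney reference tables and the demo city.

The Sydney tables are the published coverage and per-hub caseload summaries
for the five ECR-capable hospitals in metropolitan Sydney — Royal Prince
Alfred (RPA), Liverpool (LPH), Westmead (WH), Prince of Wales (POW) and
Royal North Shore (RNS) — across all printed hub combinations of a
226-suburb analysis at a 30-minute threshold. The underlying travel times
and census populations are not distributed, so these tables support
aggregation-arithmetic validation (row reconstruction, ranking), not
re-derivation of the percentages themselves.

Caseload columns come in pairs based on two age-specific incidence sources
(labelled melbourne/adelaide after the cities of the source studies; the
melbourne rates are the higher of the two).

The demo city is a synthetic bundle produced by
:func:`ecrplan.synthetic_data.generate_city` (seed 42) and shipped as CSVs
so examples and smoke tests need no generation step.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

#: Candidate hub ids of the Sydney reference analysis, in table column order.
SYDNEY_HOSPITALS = ("RPA", "LPH", "WH", "POW", "RNS")

#: Known internal inconsistencies in the printed reference tables, excluded
#: from reconstruction checks: rows whose printed total disagrees with their
#: own per-hub columns.
SYDNEY_INCONSISTENT_COVERAGE_ROWS = ("3 hospitals-8", "4 hospitals-5")
#: The 5-hospital coverage row prints a patients total inconsistent with the
#: caseload table's row sum (the caseload table's 9445/5503 is the
#: self-consistent pair).
SYDNEY_INCONSISTENT_PATIENT_ROWS = ("5 hospitals-1",)


def _data_path(*parts: str) -> Path:
    return Path(resources.files("ecrplan").joinpath("data", *parts))  # type: ignore[arg-type]


def load_sydney_coverage_table() -> pd.DataFrame:
    """Published per-hub coverage table (percent + catchment size per hub)."""
    return pd.read_csv(_data_path("sydney", "coverage_table.csv"))


def load_sydney_caseload_table() -> pd.DataFrame:
    """Published per-hub projected-stroke table under two incidence sources."""
    return pd.read_csv(_data_path("sydney", "caseload_table.csv"))


def coverage_row_pairs(row: pd.Series) -> list[tuple[float, int]]:
    """Extract the (covered_pct, catchment_count) pairs present in a row."""
    pairs = []
    for h in SYDNEY_HOSPITALS:
        pct, count = row[f"{h}_pct"], row[f"{h}_suburbs"]
        if pd.notna(pct) and pd.notna(count):
            pairs.append((float(pct), int(count)))
    return pairs


def caseload_row_counts(row: pd.Series, source: str = "melbourne") -> list[float]:
    """Per-hub projected stroke counts for one model row (zeros dropped)."""
    counts = [float(row[f"{h}_{source}"]) for h in SYDNEY_HOSPITALS]
    return [c for c in counts if c > 0]


def demo_city_dir() -> Path:
    """Directory holding the shipped demo-city CSVs."""
    return _data_path("demo")
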