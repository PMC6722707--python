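"""Bibliographic ingestion and bibliometric summaries.

Reads field-tagged plain-text exports (Web of Science style: two-letter
field tags at line start, continuation lines indented, records terminated
by ``ER``) or a tab-delimited table, applies inclusion filters
(subject categories, year window, abstract present), and computes the
standard summaries: yearly output with its OLS trend, journal activity
ratios, and the country/region distribution. The country of a publication
is taken from the first affiliation address (trailing-country convention),
the usual surrogate for study origin in bibliometrics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BibRecord",
    "JournalAggregate",
    "YearlySeries",
    "YearlyOutput",
    "ParseError",
    "read_bib_export",
    "filter_records",
    "yearly_output_summary",
    "journal_activity_table",
    "country_distribution",
    "round_half_up",
]


class ParseError(ValueError):
    """Malformed bibliographic record, with the offending record index."""


# WoS address strings end in the country; a few names need normalizing.
COUNTRY_NORMALIZATION = {
    "peoples r china": "China",
    "england": "United Kingdom",
    "scotland": "United Kingdom",
    "wales": "United Kingdom",
    "north ireland": "United Kingdom",
    "usa": "USA",
    "u arab emirates": "United Arab Emirates",
}


@dataclass
class BibRecord:
    """One publication's metadata."""

    title: str = ""
    abstract: str = ""
    year: int = 1900
    journal: str = ""
    doc_type: str = ""
    first_country: str = ""
    times_cited: int = 0
    categories: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 1900 <= self.year <= 2100:
            raise ValueError(f"year {self.year} outside [1900, 2100]")
        if self.times_cited < 0:
            raise ValueError("times_cited must be non-negative")


@dataclass
class JournalAggregate:
    """Per-journal publication and citation totals."""

    journal: str
    tpd: int  # publications on the focal subject in the journal
    tp: int  # all publications in the journal
    tc: int  # citations of the focal-subject publications

    def __post_init__(self) -> None:
        if not 0 <= self.tpd <= self.tp:
            raise ValueError(f"{self.journal}: require 0 <= tpd <= tp")
        if self.tc < 0:
            raise ValueError(f"{self.journal}: tc must be non-negative")


@dataclass
class YearlySeries:
    years: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.counts = np.asarray(self.counts, dtype=int)
        if self.years.shape != self.counts.shape:
            raise ValueError("years and counts must have equal length")
        if np.any(np.diff(self.years) <= 0):
            raise ValueError("years must be strictly increasing")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")


@dataclass
class YearlyOutput:
    """Per-year publication counts with an OLS linear trend (if defined)."""

    series: YearlySeries
    slope: float
    intercept: float
    p_value: float
    trend_available: bool


def extract_country(address: str) -> str:
    """Country from a single affiliation address (last comma-separated part)."""
    part = address.rstrip(". ").split(",")[-1].strip()
    norm = COUNTRY_NORMALIZATION.get(part.lower())
    if norm:
        return norm
    # "NC 27695 USA"-style zip-state suffixes
    if part.upper().endswith("USA"):
        return "USA"
    return part


def _parse_field_tagged(text: str) -> list[BibRecord]:
    records: list[BibRecord] = []
    fields: dict[str, list[str]] = {}
    tag = None
    idx = 0
    for raw in text.splitlines():
        if not raw.strip():
            continue
        head = raw[:2]
        if head in ("FN", "VR"):
            continue
        if head == "EF":
            break
        if head == "ER":
            if fields:
                records.append(_record_from_fields(fields, idx))
                idx += 1
            fields = {}
            tag = None
            continue
        if head.strip() and not raw.startswith("  "):
            tag = head
            fields.setdefault(tag, []).append(raw[3:].strip())
        elif tag is not None:
            fields.setdefault(tag, []).append(raw.strip())
        else:
            raise ParseError(f"record {idx}: continuation line before any field tag: {raw!r}")
    if fields:
        raise ParseError(f"record {idx}: file ends without ER terminator")
    return records


def _record_from_fields(fields: dict[str, list[str]], idx: int) -> BibRecord:
    def joined(tag: str, sep: str = " ") -> str:
        return sep.join(fields.get(tag, [])).strip()

    py = joined("PY")
    if not py:
        raise ParseError(f"record {idx}: missing publication year (PY)")
    try:
        year = int(py)
    except ValueError as exc:
        raise ParseError(f"record {idx}: unparseable year {py!r}") from exc
    tc_raw = joined("TC") or "0"
    try:
        tc = int(tc_raw)
    except ValueError as exc:
        raise ParseError(f"record {idx}: unparseable citation count {tc_raw!r}") from exc
    cats_raw = joined("WC", "; ") or joined("SC", "; ")
    categories = [c.strip() for c in cats_raw.split(";") if c.strip()]
    addresses = fields.get("C1", [])
    first_country = extract_country(addresses[0]) if addresses else ""
    try:
        return BibRecord(
            title=joined("TI"),
            abstract=joined("AB"),
            year=year,
            journal=joined("SO"),
            doc_type=joined("DT") or "Article",
            first_country=first_country,
            times_cited=tc,
            categories=categories,
        )
    except ValueError as exc:
        raise ParseError(f"record {idx}: {exc}") from exc


def _parse_delimited(path) -> list[BibRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"title", "year"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"delimited file missing columns: {sorted(missing)}")
    records = []
    for idx, row in df.iterrows():
        try:
            records.append(
                BibRecord(
                    title=row.get("title", ""),
                    abstract=row.get("abstract", ""),
                    year=int(row["year"]),
                    journal=row.get("journal", ""),
                    doc_type=row.get("doc_type", "Article"),
                    first_country=row.get("first_country", ""),
                    times_cited=int(row.get("times_cited", "0") or 0),
                    categories=[
                        c.strip() for c in row.get("categories", "").split(";") if c.strip()
                    ],
                )
            )
        except (ValueError, KeyError) as exc:
            raise ParseError(f"record {idx}: {exc}") from exc
    return records


def read_bib_export(path, dialect: str = "field_tagged") -> list[BibRecord]:
    """Parse a bibliographic export file into records.

    ``dialect`` is ``"field_tagged"`` (WoS plain text) or ``"delimited"``
    (tab-separated with a header row). A record with no abstract field gets
    an empty abstract, never a dropped record.
    """
    if dialect == "field_tagged":
        with open(path, encoding="utf-8-sig") as fh:
            return _parse_field_tagged(fh.read())
    if dialect == "delimited":
        return _parse_delimited(path)
    raise ValueError(f"unknown dialect {dialect!r}; use 'field_tagged' or 'delimited'")


def filter_records(
    records: list[BibRecord],
    allowed_categories=None,
    require_abstract: bool = False,
    year_range: tuple[int, int] | None = None,
) -> list[BibRecord]:
    """Apply the inclusion filters; order is preserved, result may be empty."""
    if year_range is not None and year_range[0] > year_range[1]:
        raise ValueError("year_range min must be <= max")
    allowed = (
        {c.strip().lower() for c in allowed_categories}
        if allowed_categories is not None
        else None
    )
    out = []
    for r in records:
        if year_range is not None and not year_range[0] <= r.year <= year_range[1]:
            continue
        if require_abstract and not r.abstract.strip():
            continue
        if allowed is not None and not allowed.intersection(
            c.strip().lower() for c in r.categories
        ):
            continue
        out.append(r)
    return out


def yearly_output_summary(records: list[BibRecord]) -> YearlyOutput:
    """Publications per calendar year and the OLS trend of count on year.

    Interior years with zero publications are included (omitting them would
    bias the slope). With fewer than 3 distinct years the counts are still
    returned but the trend is marked unavailable.
    """
    if not records:
        return YearlyOutput(
            YearlySeries(np.array([], dtype=int), np.array([], dtype=int)),
            np.nan, np.nan, np.nan, False,
        )
    years = np.array([r.year for r in records])
    full = np.arange(years.min(), years.max() + 1)
    counts = np.array([int(np.sum(years == y)) for y in full])
    series = YearlySeries(full, counts)
    if len(np.unique(years)) < 3:
        return YearlyOutput(series, np.nan, np.nan, np.nan, False)
    res = stats.linregress(full.astype(float), counts.astype(float))
    return YearlyOutput(series, float(res.slope), float(res.intercept), float(res.pvalue), True)


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round half away from zero (what printed tables use), not banker's."""
    factor = 10.0**decimals
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


def journal_activity_table(aggregates: list[JournalAggregate]) -> pd.DataFrame:
    """Activity ratios per journal, sorted by share of subject publications.

    ``tpd_tp_pct`` is 100*tpd/tp and ``tc_per_tpd`` is tc/tpd, both rounded
    half-up to one decimal. A journal with tpd = 0 gets an undefined (NaN)
    citation average, not zero. tp = 0 is a domain error.
    """
    rows = []
    for agg in aggregates:
        if agg.tp == 0:
            raise ValueError(f"{agg.journal}: tp = 0, activity ratio undefined")
        pct = round_half_up(100.0 * agg.tpd / agg.tp, 1)
        tc_per = round_half_up(agg.tc / agg.tpd, 1) if agg.tpd > 0 else np.nan
        rows.append(
            {
                "journal": agg.journal,
                "tpd": agg.tpd,
                "tp": agg.tp,
                "tc": agg.tc,
                "tpd_tp_pct": pct,
                "tc_per_tpd": tc_per,
            }
        )
    return (
        pd.DataFrame(rows)
        .sort_values("tpd_tp_pct", ascending=False, kind="stable")
        .reset_index(drop=True)
    )


def country_distribution(
    records: list[BibRecord],
    region_map: dict[str, str] | None = None,
    unknown_bucket: bool = True,
):
    """Per-country counts/percentages and per-region percentage shares.

    Records whose country cannot be resolved (empty string) are dropped from
    the denominator. With a region map, an unmapped country goes to the
    "Unknown" region when ``unknown_bucket`` is on, otherwise raises.
    Percentages are over resolvable-country records and sum to 100.
    """
    countries = [r.first_country for r in records if r.first_country]
    if not countries:
        empty = pd.DataFrame(columns=["country", "count", "pct"])
        return empty, pd.Series(dtype=float)
    counts = pd.Series(countries).value_counts()
    total = int(counts.sum())
    table = pd.DataFrame(
        {"country": counts.index, "count": counts.values, "pct": 100.0 * counts.values / total}
    )
    if region_map is None:
        return table, pd.Series(dtype=float)
    regions = []
    for c in table["country"]:
        region = region_map.get(c)
        if region is None:
            if not unknown_bucket:
                raise KeyError(f"country {c!r} missing from region map")
            region = "Unknown"
        regions.append(region)
    table = table.assign(region=regions)
    region_pct = table.groupby("region")["pct"].sum().sort_values(ascending=False)
    return table, region_pct
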