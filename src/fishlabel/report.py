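"""Aggregation of verdicts into audit summary statistics.

Categories are the normalized base commercial names, so "Tuna
(Albacore)", "Tuna (Spicy)" and plain "Tuna" all aggregate under
``tuna``. Rates are percentages rounded half-up to one decimal place.
Unidentifiable samples are reported separately and excluded from both
numerator and denominator.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

from .adjudicate import Rationale, Verdict, reporting_taxon
from .identify import CandidateSet, Resolution
from .taxa import IUCNStatus


def round_rate(n_mislabelled: int, n: int) -> float:
    """Percentage to one decimal, round half up (12/115 -> 10.4)."""
    if n == 0:
        return 0.0
    pct = Decimal(100 * n_mislabelled) / Decimal(n)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CategoryStats:
    n: int
    n_mislabelled: int

    @property
    def rate(self) -> float:
        return round_rate(self.n_mislabelled, self.n)


@dataclass(frozen=True)
class AuditReport:
    """Per-category and per-city counts with the overall rate."""

    per_category: dict[str, CategoryStats]
    per_city: dict[str, CategoryStats]
    overall: CategoryStats
    conservation_tally: dict[IUCNStatus, int]
    n_unidentifiable: int = 0
    empty: bool = False

    def __post_init__(self) -> None:
        # conservation of counts: marginals must sum to the totals
        for marginal in (self.per_category, self.per_city):
            assert sum(s.n for s in marginal.values()) == self.overall.n
            assert (
                sum(s.n_mislabelled for s in marginal.values())
                == self.overall.n_mislabelled
            )


def _identified(verdicts: list[Verdict]) -> list[Verdict]:
    return [v for v in verdicts if v.rationale is not Rationale.unidentifiable]


def summarize(verdicts: list[Verdict]) -> AuditReport:
    """Aggregate verdicts into an :class:`AuditReport`.

    Output ordering is deterministic: categories by frequency
    descending then name; cities by count descending then name.
    """
    if not verdicts:
        warnings.warn("no verdicts to summarize; report has zero counts")
        return AuditReport({}, {}, CategoryStats(0, 0), {}, 0, empty=True)
    usable = _identified(verdicts)
    cats: dict[str, list[Verdict]] = {}
    cities: dict[str, list[Verdict]] = {}
    for v in usable:
        cats.setdefault(v.category, []).append(v)
        cities.setdefault(v.city, []).append(v)

    def stats(group: list[Verdict]) -> CategoryStats:
        return CategoryStats(len(group), sum(v.mislabelled for v in group))

    per_category = {
        k: stats(g)
        for k, g in sorted(cats.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    }
    per_city = {
        k: stats(g)
        for k, g in sorted(cities.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    }
    return AuditReport(
        per_category=per_category,
        per_city=per_city,
        overall=stats(usable),
        conservation_tally=conservation_tally(verdicts),
        n_unidentifiable=len(verdicts) - len(usable),
    )


def species_diversity(verdicts: list[Verdict], category: str) -> int:
    """Number of distinct species-level reporting names among a
    category's molecular identifications."""
    group = [v for v in _identified(verdicts) if v.category == category]
    if not group and category not in {v.category for v in verdicts}:
        raise KeyError(f"unknown category: {category!r}")
    names = set()
    for v in group:
        taxon = reporting_taxon(_as_candidates(v))
        if taxon is not None:
            names.add(taxon.scientific_name)
    return len(names)


def _as_candidates(v: Verdict) -> CandidateSet:
    tier = 100.0 if v.candidate_taxa else None
    return CandidateSet(v.candidate_taxa, tier, v.resolution)


def conservation_tally(verdicts: list[Verdict]) -> dict[IUCNStatus, int]:
    """Sample counts per Red List status of the reported molecular
    identification."""
    tally: dict[IUCNStatus, int] = {}
    for v in _identified(verdicts):
        taxon = reporting_taxon(_as_candidates(v))
        if taxon is None:
            continue
        status = taxon.iucn_status
        tally[status] = tally.get(status, 0) + 1
    return tally


# --------------------------------------------------------------------------
# rendering

_FORMATS = ("tsv", "json", "markdown")


def render_report(report: AuditReport, format: str = "tsv") -> str:
    if format not in _FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {_FORMATS}")
    if format == "json":
        return _render_json(report)
    if format == "markdown":
        return _render_markdown(report)
    return _render_tsv(report)


def _render_json(report: AuditReport) -> str:
    doc = {
        "overall": {
            "n": report.overall.n,
            "n_mislabelled": report.overall.n_mislabelled,
            "rate_percent": report.overall.rate,
        },
        "per_category": {
            k: {"n": s.n, "n_mislabelled": s.n_mislabelled, "rate_percent": s.rate}
            for k, s in report.per_category.items()
        },
        "per_city": {
            k: {"n": s.n, "n_mislabelled": s.n_mislabelled}
            for k, s in report.per_city.items()
        },
        "conservation_tally": {
            k.value: v for k, v in report.conservation_tally.items()
        },
        "n_unidentifiable": report.n_unidentifiable,
        "empty": report.empty,
    }
    return json.dumps(doc, indent=2, sort_keys=True)


def _render_tsv(report: AuditReport) -> str:
    lines = ["section\tkey\tn\tn_mislabelled\trate_percent"]
    for k, s in report.per_category.items():
        lines.append(f"category\t{k}\t{s.n}\t{s.n_mislabelled}\t{s.rate}")
    for k, s in report.per_city.items():
        lines.append(f"city\t{k}\t{s.n}\t{s.n_mislabelled}\t{s.rate}")
    for k, v in sorted(report.conservation_tally.items(), key=lambda kv: kv[0].value):
        lines.append(f"conservation\t{k.value}\t{v}\t\t")
    o = report.overall
    lines.append(f"overall\tTOTAL\t{o.n}\t{o.n_mislabelled}\t{o.rate}")
    lines.append(f"overall\tunidentifiable\t{report.n_unidentifiable}\t\t")
    return "\n".join(lines) + "\n"


def parse_report_tsv(text: str) -> AuditReport:
    """Inverse of the TSV rendering (serialization round-trip)."""
    per_category: dict[str, CategoryStats] = {}
    per_city: dict[str, CategoryStats] = {}
    tally: dict[IUCNStatus, int] = {}
    overall = CategoryStats(0, 0)
    n_unid = 0
    lines = text.strip().split("\n")
    if lines[0] != "section\tkey\tn\tn_mislabelled\trate_percent":
        raise ValueError("unrecognized report header")
    for line in lines[1:]:
        fields = line.split("\t")
        fields += [""] * (5 - len(fields))  # trailing tabs may be stripped
        section, key, n, nm, _rate = fields
        if section == "category":
            per_category[key] = CategoryStats(int(n), int(nm))
        elif section == "city":
            per_city[key] = CategoryStats(int(n), int(nm))
        elif section == "conservation":
            tally[IUCNStatus(key)] = int(n)
        elif section == "overall" and key == "TOTAL":
            overall = CategoryStats(int(n), int(nm))
        elif section == "overall" and key == "unidentifiable":
            n_unid = int(n)
    return AuditReport(
        per_category, per_city, overall, tally, n_unid, empty=overall.n == 0
    )


def _render_markdown(report: AuditReport) -> str:
    """Summary grid: one row per city, one column per category, with
    mislabelled and total rows at the bottom."""
    cats = list(report.per_category)
    lines = ["| City | " + " | ".join(cats) + " | TOTAL |"]
    lines.append("|" + "---|" * (len(cats) + 2))
    # per-city-per-category counts are not retained in the report;
    # the grid shows city totals in the TOTAL column only
    for city, s in report.per_city.items():
        cells = [""] * len(cats)
        lines.append(f"| {city} | " + " | ".join(cells) + f" | {s.n} |")
    lines.append(
        "| TOTAL mislabelled | "
        + " | ".join(str(report.per_category[c].n_mislabelled) for c in cats)
        + f" | {report.overall.n_mislabelled} |"
    )
    lines.append(
        "| TOTAL | "
        + " | ".join(str(report.per_category[c].n) for c in cats)
        + f" | {report.overall.n} |"
    )
    lines.append("")
    lines.append(
        f"Overall mislabelling: {report.overall.n_mislabelled}/{report.overall.n} "
        f"= {report.overall.rate}%"
    )
    return "\n".join(lines) + "\n"
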