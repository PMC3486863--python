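"""Discovery curves: cumulative family counts over time.

Each family's discovery date is the oldest date associated with it —
either a literature reference date from its curated metadata or the
earliest sequence-record date among its annotations, whichever is older.
Curves are stratified by domain-distribution class (1-domain, 2-domain,
3-domain; viruses do not contribute to the domain count), binned by year.
"""

from __future__ import annotations

import logging
from datetime import date
from typing import Iterable, Mapping

import pandas as pd

from .census import PresenceMatrix
from .taxonomy import DOMAINS_OF_LIFE
from .vetting import FamilyMeta

logger = logging.getLogger(__name__)


def oldest_date(family: FamilyMeta, record_dates: Iterable[date]) -> date | None:
    """Minimum over the family's literature dates and its record dates.

    Returns None (caller excludes the family) when no date exists anywhere.
    """
    pool = [d for d in list(family.date_refs) + list(record_dates) if d is not None]
    if not pool:
        logger.warning("family %s has no dates; excluded", family.family_accession)
        return None
    return min(pool)


def domain_class_label(presence_set: Iterable[str]) -> str | None:
    """"1-domain" / "2-domain" / "3-domain" by domains of life only;
    virus-only units have no class (None)."""
    n = len(set(presence_set) & set(DOMAINS_OF_LIFE))
    return f"{n}-domain" if n >= 1 else None


def family_dates(
    families: Mapping[str, FamilyMeta], annotations: pd.DataFrame
) -> dict[str, date]:
    """Oldest date per family from metadata plus the annotation table."""
    rec_dates: dict[str, list[date]] = {}
    if "date" in annotations.columns:
        sub = annotations.dropna(subset=["date"])
        sub = sub[sub["date"] != ""]
        for fam, group in sub.groupby("family_accession"):
            rec_dates[str(fam)] = [date.fromisoformat(str(d)) for d in group["date"]]
    out = {}
    for acc, meta in families.items():
        d = oldest_date(meta, rec_dates.get(acc, []))
        if d is not None:
            out[acc] = d
    return out


def discovery_curve(
    dates: Mapping[str, date], classes: Mapping[str, str]
) -> dict[str, pd.Series]:
    """Per-class cumulative counts by year of discovery.

    ``classes`` maps family accession -> class label; families missing a
    class or a date are skipped. Each series is indexed by the years in
    which that class gained at least one family, is monotone
    non-decreasing, and ends at the class size.
    """
    events: dict[str, list[int]] = {}
    for acc, d in dates.items():
        label = classes.get(acc)
        if label is None:
            continue
        events.setdefault(label, []).append(d.year)
    curves: dict[str, pd.Series] = {}
    for label in sorted(events):
        years = pd.Series(events[label]).value_counts().sort_index()
        curves[label] = years.cumsum().rename(label).rename_axis("year")
    return curves


def classes_from_matrix(matrix: PresenceMatrix) -> dict[str, str]:
    """Domain-distribution class per unit from a domain-level matrix."""
    out = {}
    for unit in matrix.unit_ids:
        label = domain_class_label(matrix.presence_set(unit))
        if label is not None:
            out[unit] = label
    return out


def curves_frame(curves: Mapping[str, pd.Series]) -> pd.DataFrame:
    rows = []
    for label in sorted(curves):
        for year, cum in curves[label].items():
            rows.append((label, int(year), int(cum)))
    return pd.DataFrame(rows, columns=["class", "year", "cumulative"])
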