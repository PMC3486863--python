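"""Presence/absence census of RNA families across taxonomic units.

The census condenses a vetted annotation table into a boolean
family (or clan) × taxonomic-unit occupancy matrix, then derives the
headline quantities of a tree-of-life survey:

* the four-set Venn partition over {Archaea, Bacteria, Eukaryota, Viruses}
  and the fraction of domain-specific units;
* the list of interdomain units (present in >=2 domains of life — the
  candidates for either vertical descent from LUCA or horizontal transfer);
* per-domain broad-distribution calls: a unit is "broadly distributed" when
  present in at least 50% of the domain's major taxonomic divisions;
* normalized taxonomic abundance: the fraction of a group's sampled taxa
  carrying at least one annotation of the unit.

Clans group families believed to share ancestry; at clan level a clan is
present wherever any member family is, and clans replace their member
families so a clan is counted once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .taxonomy import DOMAIN_LABELS, DOMAINS_OF_LIFE, UNASSIGNED

logger = logging.getLogger(__name__)

#: Single-letter codes used in Venn region labels ("A+B+E" etc.).
DOMAIN_CODES = {"Archaea": "A", "Bacteria": "B", "Eukaryota": "E", "Viruses": "V"}


@dataclass
class PresenceMatrix:
    """Boolean occupancy with provenance counts.

    ``present`` and ``support`` are aligned DataFrames (rows: family or
    clan accessions; columns: taxonomic units — the four domains, or the
    divisions of one domain); ``present == (support > 0)`` always.
    """

    present: pd.DataFrame
    support: pd.DataFrame
    level: str = "FAMILY"
    domain: str | None = None  # set when columns are divisions of one domain

    def __post_init__(self) -> None:
        if self.level not in ("FAMILY", "CLAN"):
            raise ValueError(f"level must be FAMILY or CLAN, got {self.level}")
        if not self.present.index.equals(self.support.index) or not self.present.columns.equals(
            self.support.columns
        ):
            raise ValueError("present/support dimensions differ")
        if not (self.present.values == (self.support.values > 0)).all():
            raise ValueError("present must equal support > 0")

    @property
    def unit_ids(self) -> list[str]:
        return list(self.present.index)

    @property
    def column_ids(self) -> list[str]:
        return list(self.present.columns)

    def presence_set(self, unit_id: str) -> frozenset[str]:
        row = self.present.loc[unit_id]
        return frozenset(row.index[row])

    @classmethod
    def from_support(
        cls, support: pd.DataFrame, level: str = "FAMILY", domain: str | None = None
    ) -> "PresenceMatrix":
        support = support.astype(int)
        return cls(support > 0, support, level=level, domain=domain)

    def drop_units(self, units: Iterable[str]) -> "PresenceMatrix":
        keep = [u for u in self.unit_ids if u not in set(units)]
        return PresenceMatrix(
            self.present.loc[keep], self.support.loc[keep], self.level, self.domain
        )

    def to_tsv(self, path: str | Path) -> None:
        self.support.rename_axis("unit").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(
        cls, path: str | Path, level: str = "FAMILY", domain: str | None = None
    ) -> "PresenceMatrix":
        support = pd.read_csv(path, sep="\t", index_col="unit")
        return cls.from_support(support, level=level, domain=domain)


def build_presence(
    records: pd.DataFrame,
    assignments: pd.DataFrame,
    level: str = "FAMILY",
    columns: Sequence[str] | None = None,
    domain: str | None = None,
    clan_map: Mapping[str, str] | None = None,
) -> PresenceMatrix:
    """Aggregate annotations into an occupancy matrix.

    Parameters
    ----------
    records
        Vetted annotation table (``family_accession``, ``taxon_id``, ...).
    assignments
        Table with ``taxon_id``, ``domain``, ``division``.
    columns
        Explicit column universe. Default: the four domain labels when
        ``domain`` is None, else the divisions observed for that domain.
        Passing the full division roster from the taxonomy keeps
        unoccupied divisions in the denominator.
    domain
        When given, columns are the divisions of this domain and records
        from other domains are ignored.
    clan_map
        family accession -> clan accession; required for ``level="CLAN"``.
        Families without a clan entry stay as their own unit.
    """
    amap = assignments.set_index("taxon_id")
    merged = records.merge(
        amap[["domain", "division"]], left_on="taxon_id", right_index=True, how="left"
    )
    merged[["domain", "division"]] = merged[["domain", "division"]].fillna(UNASSIGNED)
    if domain is None:
        merged["column"] = merged["domain"]
        default_cols = list(DOMAIN_LABELS)
    else:
        merged = merged[merged["domain"] == domain]
        merged = merged.assign(column=merged["division"])
        default_cols = sorted(set(merged["column"]) - {UNASSIGNED})
    merged = merged[merged["column"] != UNASSIGNED]

    if level == "CLAN":
        if clan_map is None:
            raise ValueError("clan level requested but no clan map given")
        merged = merged.assign(
            unit=merged["family_accession"].map(lambda f: clan_map.get(f, f))
        )
    elif level == "FAMILY":
        merged = merged.assign(unit=merged["family_accession"])
    else:
        raise ValueError(f"unknown level {level!r}")

    cols = list(columns) if columns is not None else default_cols
    support = (
        merged.groupby(["unit", "column"], sort=True)
        .size()
        .unstack(fill_value=0)
        .reindex(columns=cols, fill_value=0)
    )
    support = support.loc[sorted(support.index)]
    support.index.name = "unit"
    return PresenceMatrix.from_support(support, level=level, domain=domain)


# -- Venn partition -------------------------------------------------------


@dataclass
class VennPartition:
    """Counts of units per non-empty presence subset of the four sets.

    ``region_counts`` is keyed by frozensets of domain labels; units with
    no presence at all are tallied separately (the empty set is not a Venn
    region).
    """

    region_counts: dict[frozenset[str], int]
    no_presence: int = 0

    def total_present(self) -> int:
        return sum(self.region_counts.values())

    def count(self, *labels: str) -> int:
        return self.region_counts.get(frozenset(labels), 0)

    def single_domain_count(self) -> int:
        """Units confined to a single set (including Viruses-only)."""
        return sum(n for s, n in self.region_counts.items() if len(s) == 1)

    def domain_specific_fraction(self) -> float:
        tot = self.total_present()
        return self.single_domain_count() / tot if tot else float("nan")

    def universal_count(self) -> int:
        """Units present in all three domains of life (viruses optional)."""
        return sum(
            n
            for s, n in self.region_counts.items()
            if set(DOMAINS_OF_LIFE) <= set(s)
        )

    def to_json_dict(self) -> dict[str, int]:
        out = {}
        for subset, n in sorted(
            self.region_counts.items(), key=lambda kv: (len(kv[0]), sorted(kv[0]))
        ):
            key = "+".join(sorted(DOMAIN_CODES[d] for d in subset))
            out[key] = n
        out["no_presence"] = self.no_presence
        return out


def venn_partition(matrix: PresenceMatrix) -> VennPartition:
    """Partition units by their exact presence-set over the four sets."""
    if set(matrix.column_ids) != set(DOMAIN_LABELS):
        raise ValueError(
            f"venn partition needs columns {set(DOMAIN_LABELS)}, got {set(matrix.column_ids)}"
        )
    counts: dict[frozenset[str], int] = {}
    empty = 0
    for unit in matrix.unit_ids:
        s = matrix.presence_set(unit)
        if not s:
            empty += 1
            continue
        counts[s] = counts.get(s, 0) + 1
    return VennPartition(counts, no_presence=empty)


# -- interdomain units ----------------------------------------------------


@dataclass
class InterdomainResult:
    """interdomain: present in >=2 domains of life. virus_shared: present
    in exactly one domain of life plus Viruses (not interdomain)."""

    interdomain: list[str]
    virus_shared: list[str]


def interdomain_units(matrix: PresenceMatrix) -> InterdomainResult:
    inter, shared = [], []
    for unit in matrix.unit_ids:
        s = matrix.presence_set(unit)
        n_life = len(s & set(DOMAINS_OF_LIFE))
        if n_life >= 2:
            inter.append(unit)
        elif n_life == 1 and "Viruses" in s:
            shared.append(unit)
    return InterdomainResult(sorted(set(inter)), sorted(set(shared)))


# -- broad distribution ---------------------------------------------------


@dataclass(frozen=True)
class BroadDistributionCall:
    unit_id: str
    domain: str
    divisions_present: int
    divisions_total: int
    broad: bool

    def __post_init__(self) -> None:
        if not 0 <= self.divisions_present <= self.divisions_total:
            raise ValueError("divisions_present out of range")


def broad_distribution(
    matrix: PresenceMatrix,
    threshold: float = 0.5,
    domain: str | None = None,
) -> list[BroadDistributionCall]:
    """Call each unit broadly distributed or not within one domain.

    A unit is broad when present in at least ``threshold`` (default 50%)
    of the domain's major divisions — inclusive at the boundary. The
    denominator is the number of division columns in the matrix, which
    should carry the domain's full division roster, occupied or not.
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    total = len(matrix.column_ids)
    if total < 1:
        raise ValueError("matrix has no division columns")
    dom = domain or matrix.domain or UNASSIGNED
    calls = []
    for unit in matrix.unit_ids:
        npresent = int(matrix.present.loc[unit].sum())
        calls.append(
            BroadDistributionCall(
                unit_id=unit,
                domain=dom,
                divisions_present=npresent,
                divisions_total=total,
                broad=npresent / total >= threshold,
            )
        )
    return calls


def percent_half_up(numerator: float, denominator: float, places: int = 1) -> float:
    """Percentage rounded half-up (17.25% -> 17.3%) — bankers' rounding
    would silently disagree with hand-computed tables."""
    q = Decimal(1).scaleb(-places)
    pct = Decimal(numerator) * 100 / Decimal(denominator)
    return float(pct.quantize(q, ROUND_HALF_UP))


def broad_distribution_rate(
    calls: Sequence[BroadDistributionCall],
) -> tuple[float, float]:
    """(fraction, percentage to 1 decimal) of broad units among units with
    at least one division presence in the domain."""
    eligible = [c for c in calls if c.divisions_present >= 1]
    if not eligible:
        raise ValueError("no units with presence; rate undefined")
    domains = {c.domain for c in eligible}
    if len(domains) > 1:
        raise ValueError(f"calls span multiple domains: {domains}")
    nbroad = sum(c.broad for c in eligible)
    return nbroad / len(eligible), percent_half_up(nbroad, len(eligible))


def broad_calls_frame(calls: Sequence[BroadDistributionCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (c.unit_id, c.domain, c.divisions_present, c.divisions_total, c.broad)
            for c in calls
        ],
        columns=["unit", "domain", "divisions_present", "divisions_total", "broad"],
    )


# -- normalized taxonomic abundance ---------------------------------------


def normalized_abundance(
    records: pd.DataFrame,
    assignments: pd.DataFrame,
    roster: Mapping[str, set[int]],
    clan_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Fraction of each group's sampled taxa annotated with each unit.

    ``roster`` maps a group label (a division, or any grouping matching
    the assignment table's ``division`` column) to the set of taxon ids
    sampled for it — making the normalisation denominator explicit rather
    than inferred from annotation density. Annotated taxa outside the
    roster are ignored with a warning; empty roster groups are skipped.
    Values are in [0, 1]: 1 iff the unit covers the whole group roster.
    """
    amap = assignments.set_index("taxon_id")["division"]
    merged = records.assign(group=records["taxon_id"].map(amap))
    if clan_map is not None:
        merged = merged.assign(
            unit=merged["family_accession"].map(lambda f: clan_map.get(f, f))
        )
    else:
        merged = merged.assign(unit=merged["family_accession"])
    groups = []
    for group, taxa in sorted(roster.items()):
        if not taxa:
            logger.warning("empty roster group %s skipped", group)
            continue
        sub = merged[merged["group"] == group]
        outside = set(sub["taxon_id"]) - set(taxa)
        if outside:
            logger.warning(
                "%d annotated taxa in group %s are outside the roster; ignored",
                len(outside),
                group,
            )
            sub = sub[sub["taxon_id"].isin(taxa)]
        frac = sub.groupby("unit")["taxon_id"].nunique() / len(taxa)
        frac.name = group
        groups.append(frac)
    units = sorted(merged["unit"].unique())
    out = pd.DataFrame(index=units)
    out.index.name = "unit"
    for s in groups:
        out[s.name] = s.reindex(out.index).fillna(0.0)
    return out
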