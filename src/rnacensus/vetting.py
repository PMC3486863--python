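"""False-positive vetting of RNA family annotations.

Families whose annotations span more than one domain (including viruses)
are suspicious: a single mis-taxonomised sequence, or a marginal
covariance-model hit, is enough to fake an interdomain family. Vetting
applies two filters to such families only:

1. taxonomic re-confirmation — records flagged ``MISANNOTATED`` by an
   upstream check (e.g. reciprocal BLAST identifying a cloning-vector
   contaminant) are dropped;
2. the bitscore-margin rule — records scoring within +``margin`` bits
   (default 10) of the family's curated seed cutoff are marginal and are
   dropped unless a curator marked them ``CONFIRMED``.

Single-domain families pass through untouched (set ``vet_all=True`` to
extend the filters globally).
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass
from datetime import date
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .taxonomy import UNASSIGNED


class Evidence(str, enum.Enum):
    CONFIRMED = "CONFIRMED"
    MISANNOTATED = "MISANNOTATED"
    UNTESTED = "UNTESTED"


@dataclass(frozen=True)
class AnnotationRecord:
    """One RNA sequence annotation."""

    seq_accession: str
    family_accession: str
    taxon_id: int
    bitscore: float
    evidence: Evidence = Evidence.UNTESTED
    discovery_date: date | None = None

    def __post_init__(self) -> None:
        if self.bitscore < 0:
            raise ValueError(f"negative bitscore {self.bitscore}")
        if not self.family_accession:
            raise ValueError("empty family accession")


@dataclass(frozen=True)
class FamilyMeta:
    """Rfam-style family metadata: seed bitscore cutoff, optional clan,
    functional-class path (e.g. Gene/sRNA/snoRNA/CD-box), literature dates."""

    family_accession: str
    name: str = ""
    clan_accession: str | None = None
    seed_cutoff: float = 0.0
    functional_path: tuple[str, ...] = ("Gene",)
    date_refs: tuple[date, ...] = ()

    def __post_init__(self) -> None:
        if self.seed_cutoff < 0:
            raise ValueError(f"negative seed cutoff {self.seed_cutoff}")
        if not self.functional_path:
            raise ValueError("empty functional path")


@dataclass(frozen=True)
class VetConfig:
    """margin: width in bits of the marginal zone above the seed cutoff."""

    margin: float = 10.0
    drop_misannotated: bool = True
    drop_flagged_untested: bool = True

    def __post_init__(self) -> None:
        if self.margin < 0:
            raise ValueError("margin must be >= 0")


@dataclass
class VetReport:
    kept: int = 0
    dropped_misannotation: int = 0
    dropped_margin: int = 0
    flagged_only: int = 0

    def __add__(self, other: "VetReport") -> "VetReport":
        return VetReport(
            self.kept + other.kept,
            self.dropped_misannotation + other.dropped_misannotation,
            self.dropped_margin + other.dropped_margin,
            self.flagged_only + other.flagged_only,
        )

    def to_dict(self) -> dict:
        return {
            "kept": self.kept,
            "dropped_misannotation": self.dropped_misannotation,
            "dropped_margin": self.dropped_margin,
            "flagged_only": self.flagged_only,
        }


def margin_flag(
    record: AnnotationRecord, meta: FamilyMeta, config: VetConfig = VetConfig()
) -> bool:
    """True iff the record is marginal: bitscore strictly below
    ``seed_cutoff + margin``. A score exactly at the boundary is confident
    ("within +10 bits" bounds the marginal zone half-open). Scores below the
    cutoff itself are marginal by the same predicate, not special-cased.
    """
    if record.family_accession != meta.family_accession:
        raise ValueError(
            f"record family {record.family_accession} != meta {meta.family_accession}"
        )
    return record.bitscore < meta.seed_cutoff + config.margin


def vet_family(
    records: Sequence[AnnotationRecord],
    meta: FamilyMeta,
    domains_spanned: Iterable[str],
    config: VetConfig = VetConfig(),
) -> tuple[list[AnnotationRecord], VetReport]:
    """Apply the two-step filter to one family's records.

    Vetting only applies when the family spans >1 domain (viruses count);
    otherwise all records are kept, with marginal ones tallied in
    ``flagged_only`` for the audit trail.
    """
    spanned = {d for d in domains_spanned if d != UNASSIGNED}
    report = VetReport()
    kept: list[AnnotationRecord] = []
    if len(spanned) <= 1:
        for r in records:
            kept.append(r)
            if margin_flag(r, meta, config):
                report.flagged_only += 1
        report.kept = len(kept)
        return kept, report
    for r in records:
        marginal = margin_flag(r, meta, config)
        if r.evidence is Evidence.MISANNOTATED and config.drop_misannotated:
            report.dropped_misannotation += 1
        elif (
            marginal
            and r.evidence is not Evidence.CONFIRMED
            and config.drop_flagged_untested
        ):
            report.dropped_margin += 1
        else:
            kept.append(r)
            if marginal:
                report.flagged_only += 1
    report.kept = len(kept)
    return kept, report


# -- table-level API ------------------------------------------------------

ANNOTATION_COLUMNS = [
    "seq_accession",
    "family_accession",
    "taxon_id",
    "bitscore",
    "evidence",
    "date",
]
FAMILY_COLUMNS = ["accession", "name", "clan", "seed_cutoff", "functional_path", "dates"]


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Annotation TSV with fixed header; ``date`` may be empty."""
    df = pd.read_csv(path, sep="\t", dtype={"seq_accession": str, "family_accession": str})
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"annotation table missing columns {missing}")
    return df


def _parse_dates(cell) -> tuple[date, ...]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)) or cell == "":
        return ()
    return tuple(date.fromisoformat(s) for s in str(cell).split(";") if s)


def read_families(path: str | Path) -> dict[str, FamilyMeta]:
    """Family TSV -> accession-keyed :class:`FamilyMeta` map. The
    functional path is slash-separated, dates semicolon-separated ISO."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in FAMILY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"family table missing columns {missing}")
    metas: dict[str, FamilyMeta] = {}
    for row in df.itertuples(index=False):
        clan = None if pd.isna(row.clan) or row.clan == "" else str(row.clan)
        metas[str(row.accession)] = FamilyMeta(
            family_accession=str(row.accession),
            name="" if pd.isna(row.name) else str(row.name),
            clan_accession=clan,
            seed_cutoff=float(row.seed_cutoff),
            functional_path=tuple(str(row.functional_path).split("/")),
            date_refs=_parse_dates(row.dates),
        )
    return metas


def records_from_frame(df: pd.DataFrame) -> list[AnnotationRecord]:
    out = []
    for row in df.itertuples(index=False):
        d = getattr(row, "date", None)
        if d == "":
            d = None
        out.append(
            AnnotationRecord(
                seq_accession=str(row.seq_accession),
                family_accession=str(row.family_accession),
                taxon_id=int(row.taxon_id),
                bitscore=float(row.bitscore),
                evidence=Evidence(str(row.evidence)),
                discovery_date=None if d is None or pd.isna(d) else date.fromisoformat(str(d)),
            )
        )
    return out


def frame_from_records(records: Sequence[AnnotationRecord]) -> pd.DataFrame:
    rows = [
        (
            r.seq_accession,
            r.family_accession,
            r.taxon_id,
            r.bitscore,
            r.evidence.value,
            "" if r.discovery_date is None else r.discovery_date.isoformat(),
        )
        for r in records
    ]
    return pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)


def vet_table(
    annotations: pd.DataFrame,
    families: Mapping[str, FamilyMeta],
    domain_of_taxon: Mapping[int, str],
    config: VetConfig = VetConfig(),
    vet_all: bool = False,
) -> tuple[pd.DataFrame, dict[str, VetReport], VetReport]:
    """Vet a whole annotation table, family by family.

    ``domain_of_taxon`` maps taxon id -> domain label (UNASSIGNED allowed);
    the domains a family spans are computed from it. Returns the vetted
    table, per-family reports, and the aggregate report.
    """
    per_family: dict[str, VetReport] = {}
    kept_frames: list[pd.DataFrame] = []
    total = VetReport()
    for fam, group in annotations.groupby("family_accession", sort=True):
        meta = families.get(str(fam))
        if meta is None:
            raise KeyError(f"no family metadata for {fam}")
        records = records_from_frame(group)
        spanned = {domain_of_taxon.get(r.taxon_id, UNASSIGNED) for r in records}
        if vet_all:
            spanned = spanned | {"__forced_a__", "__forced_b__"}
        kept, report = vet_family(records, meta, spanned, config)
        per_family[str(fam)] = report
        total = total + report
        if kept:
            kept_frames.append(frame_from_records(kept))
    vetted = (
        pd.concat(kept_frames, ignore_index=True)
        if kept_frames
        else pd.DataFrame(columns=ANNOTATION_COLUMNS)
    )
    return vetted, per_family, total


def write_vet_report(report: VetReport, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report.to_dict(), indent=2) + "\n")
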