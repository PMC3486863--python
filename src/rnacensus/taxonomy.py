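"""Taxonomic hierarchy loading and domain / division resolution.

An annotation census across the tree of life needs every sequence taxon
binned into one of the three domains of life (Archaea, Bacteria, Eukaryota)
or Viruses, and, within a domain, into a "major taxonomic division": the
top-level child of the domain node for prokaryotes, or a configured
supergroup (Adl-style scheme) for eukaryotes. This module loads an
NCBI-dump-dialect taxonomy (or a simplified 4-column TSV), applies
configurable merge rules (e.g. Thaumarchaeota binned with Crenarchaeota),
and resolves any taxon id to a :class:`DivisionAssignment`.

Unknown or retired taxon ids degrade to ``UNASSIGNED`` instead of raising,
so a multi-million-row run is never aborted by a stale id; the counts of
unassigned records are surfaced by the pipeline report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

logger = logging.getLogger(__name__)

UNASSIGNED = "UNASSIGNED"
#: The four top-level sets of the census. Viruses are a fourth set in the
#: Venn analysis, not a domain of life.
DOMAIN_LABELS = ("Archaea", "Bacteria", "Eukaryota", "Viruses")
DOMAINS_OF_LIFE = ("Archaea", "Bacteria", "Eukaryota")


class TaxonomyError(Exception):
    """Base class for taxonomy problems."""


class TaxonomyStructureError(TaxonomyError):
    """The node table itself is malformed (missing root, cycles, duplicates)."""


class TaxonomyConfigError(TaxonomyError):
    """The division-mapping configuration does not match the taxonomy."""


@dataclass(frozen=True)
class TaxNode:
    parent: int
    rank: str
    name: str


@dataclass(frozen=True)
class DivisionAssignment:
    """Resolved placement of one taxon id.

    ``division`` is non-UNASSIGNED only when ``domain`` is: a division is
    always a subdivision of a resolved domain.
    """

    taxon_id: int
    domain: str
    division: str

    def __post_init__(self) -> None:
        if self.domain == UNASSIGNED and self.division != UNASSIGNED:
            raise ValueError("division requires a resolved domain")


@dataclass
class TaxonomyIndex:
    """Validated rooted taxonomy with domain and division resolution.

    Parameters
    ----------
    nodes
        taxon id -> :class:`TaxNode` (parent id, rank, scientific name).
    root_id
        The single root node (its parent is itself).
    domain_ids
        Domain label -> taxon id of the domain node. Only labels found in
        the taxonomy appear here.
    merge_map
        taxon id -> taxon id applied before division resolution; targets
        must be valid nodes and must not themselves be merge keys.
    supergroup_map
        taxon id -> supergroup label, used for eukaryote division lookup.
    """

    nodes: dict[int, TaxNode]
    root_id: int
    domain_ids: dict[str, int]
    merge_map: dict[int, int] = field(default_factory=dict)
    supergroup_map: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()
        self._domain_of_id = {v: k for k, v in self.domain_ids.items()}

    # -- structural validation -------------------------------------------

    def validate(self) -> None:
        if self.root_id not in self.nodes:
            raise TaxonomyStructureError(f"root id {self.root_id} not in nodes")
        max_depth = len(self.nodes)
        for tid in self.nodes:
            cur, steps = tid, 0
            while cur != self.root_id:
                node = self.nodes.get(cur)
                if node is None:
                    raise TaxonomyStructureError(
                        f"parent chain of taxon {tid} leaves the table at {cur}"
                    )
                if node.parent == cur:  # a second self-parent = second root
                    raise TaxonomyStructureError(
                        f"taxon {cur} is a root but root is {self.root_id}"
                    )
                cur = node.parent
                steps += 1
                if steps > max_depth:
                    raise TaxonomyStructureError(f"cycle on parent chain of {tid}")
        for src, dst in self.merge_map.items():
            if dst not in self.nodes:
                raise TaxonomyStructureError(f"merge target {dst} is not a node")
            if dst in self.merge_map:
                raise TaxonomyStructureError(
                    f"chained merge {src} -> {dst} -> {self.merge_map[dst]}"
                )
        if len(set(self.domain_ids.values())) != len(self.domain_ids):
            raise TaxonomyStructureError("domain ids are not distinct")
        for label, did in self.domain_ids.items():
            if did not in self.nodes:
                raise TaxonomyStructureError(f"domain {label} id {did} unknown")

    # -- resolution -------------------------------------------------------

    def lineage(self, taxon_id: int) -> list[int]:
        """Parent chain from ``taxon_id`` up to and including the root."""
        chain = [taxon_id]
        cur = taxon_id
        while cur != self.root_id:
            cur = self.nodes[cur].parent
            chain.append(cur)
        return chain

    def assign(self, taxon_id: int) -> DivisionAssignment:
        """Resolve a taxon id to its domain and major division.

        The domain is the unique domain node on the parent chain. For
        Archaea/Bacteria the division is the chain node directly below the
        domain node (its top-level classification), with the merge map
        applied; for Eukaryota, the nearest supergroup hit walking up the
        chain; for Viruses, the division is "Viruses". Unknown ids resolve
        to UNASSIGNED/UNASSIGNED with a log message, never an exception.
        """
        tid = self.merge_map.get(taxon_id, taxon_id)
        if tid not in self.nodes:
            logger.warning("unknown taxon id %s; assigning UNASSIGNED", taxon_id)
            return DivisionAssignment(taxon_id, UNASSIGNED, UNASSIGNED)
        chain = self.lineage(tid)
        domain, pos = UNASSIGNED, None
        for i, nid in enumerate(chain):
            if nid in self._domain_of_id:
                domain, pos = self._domain_of_id[nid], i
                break
        if domain == UNASSIGNED:
            return DivisionAssignment(taxon_id, UNASSIGNED, UNASSIGNED)
        if domain == "Viruses":
            division = "Viruses"
        elif domain == "Eukaryota":
            division = UNASSIGNED
            for nid in chain[:pos]:
                merged = self.merge_map.get(nid, nid)
                if merged in self.supergroup_map:
                    division = self.supergroup_map[merged]
                    break
        else:  # Archaea / Bacteria: child of the domain node on the chain
            if pos == 0:
                division = UNASSIGNED
            else:
                div_id = self.merge_map.get(chain[pos - 1], chain[pos - 1])
                division = self.nodes[div_id].name
        return DivisionAssignment(taxon_id, domain, division)

    def divisions_of(self, domain: str) -> list[str]:
        """All known major divisions of a domain (the denominator of the
        broad-distribution rule), independent of annotation occupancy."""
        if domain == "Viruses":
            return ["Viruses"]
        if domain == "Eukaryota":
            return sorted(set(self.supergroup_map.values()))
        did = self.domain_ids.get(domain)
        if did is None:
            raise TaxonomyConfigError(f"domain {domain!r} not resolved in taxonomy")
        names = set()
        for tid, node in self.nodes.items():
            if node.parent == did and tid != did and tid not in self.merge_map:
                names.add(self.nodes[self.merge_map.get(tid, tid)].name)
        return sorted(names)


# -- configuration --------------------------------------------------------


def default_config() -> dict:
    """The packaged division-mapping config (four domains, Thaumarchaeota
    merge, Adl-style eukaryote supergroups)."""
    text = (
        resources.files("rnacensus.data")
        .joinpath("default_taxonomy_config.yaml")
        .read_text()
    )
    return yaml.safe_load(text)


def load_config(path: str | Path | None) -> dict:
    if path is None:
        return default_config()
    with open(path) as fh:
        return yaml.safe_load(fh)


# -- file loading ---------------------------------------------------------


def _read_nodes_table(path: str | Path) -> pd.DataFrame:
    """Read a node table, auto-detecting NCBI pipe dialect vs plain TSV.

    NCBI ``nodes.dmp`` rows look like ``1\t|\t1\t|\tno rank\t|...``; the
    simplified dialect is a headered TSV ``taxon_id, parent_id, rank, name``.
    """
    with open(path) as fh:
        first = fh.readline()
    if "\t|" in first or "|" in first.split("\t")[1:2]:
        df = pd.read_csv(path, sep=r"\t\|\t?", engine="python", header=None)
        df = df.iloc[:, :3]
        df.columns = ["taxon_id", "parent_id", "rank"]
        df["rank"] = df["rank"].astype(str).str.strip("\t|")
        return df
    return pd.read_csv(path, sep="\t")


def _read_names_table(path: str | Path) -> pd.DataFrame:
    with open(path) as fh:
        first = fh.readline()
    if "\t|" in first:
        df = pd.read_csv(path, sep=r"\t\|\t?", engine="python", header=None)
        df = df.iloc[:, :4]
        df.columns = ["taxon_id", "name", "unique_name", "name_class"]
        df["name_class"] = df["name_class"].astype(str).str.strip("\t|")
        df = df[df["name_class"] == "scientific name"]
        return df[["taxon_id", "name"]]
    return pd.read_csv(path, sep="\t")[["taxon_id", "name"]]


def _resolve(ref, name_to_id: Mapping[str, int]) -> int | None:
    """A config entry may reference a node by integer id or scientific name."""
    if isinstance(ref, int):
        return ref
    try:
        return int(ref)
    except (TypeError, ValueError):
        return name_to_id.get(str(ref))


def load_taxonomy(
    nodes_path: str | Path,
    names_path: str | Path | None = None,
    config: dict | str | Path | None = None,
    strict_domains: bool = False,
) -> TaxonomyIndex:
    """Load and validate a taxonomy from disk.

    Parameters
    ----------
    nodes_path
        ``nodes.dmp``-dialect file, or a simplified TSV with columns
        ``taxon_id, parent_id, rank`` and (if ``names_path`` is omitted)
        ``name``.
    names_path
        ``names.dmp``-dialect file; unnecessary for the simplified TSV.
    config
        Division-mapping configuration (dict, or YAML path); defaults to
        the packaged config.
    strict_domains
        If true, a configured domain name absent from the taxonomy raises
        :class:`TaxonomyConfigError`; otherwise it is skipped with a
        warning (toy taxonomies rarely carry all four sets).
    """
    if not isinstance(config, dict):
        config = load_config(config)
    nodes_df = _read_nodes_table(nodes_path)
    if "name" in nodes_df.columns and names_path is None:
        names_df = nodes_df[["taxon_id", "name"]]
    elif names_path is not None:
        names_df = _read_names_table(names_path)
    else:
        raise TaxonomyConfigError("no names table and nodes table has no name column")

    if nodes_df["taxon_id"].duplicated().any():
        dups = nodes_df.loc[nodes_df["taxon_id"].duplicated(), "taxon_id"].tolist()
        raise TaxonomyStructureError(f"duplicate taxon ids: {dups}")

    name_of = dict(zip(names_df["taxon_id"].astype(int), names_df["name"].astype(str)))
    nodes: dict[int, TaxNode] = {}
    roots = []
    for row in nodes_df.itertuples(index=False):
        tid, pid = int(row.taxon_id), int(row.parent_id)
        nodes[tid] = TaxNode(pid, str(row.rank), name_of.get(tid, ""))
        if pid == tid:
            roots.append(tid)
    if len(roots) != 1:
        raise TaxonomyStructureError(f"expected exactly one root, found {roots}")

    name_to_id: dict[str, int] = {}
    for tid, node in nodes.items():
        name_to_id.setdefault(node.name, tid)

    domain_ids: dict[str, int] = {}
    for label, ref in (config.get("domains") or {}).items():
        did = _resolve(ref, name_to_id)
        if did is None or did not in nodes:
            if strict_domains:
                raise TaxonomyConfigError(f"domain {label}={ref!r} not in taxonomy")
            logger.warning("domain %s (%r) not found in taxonomy; skipped", label, ref)
            continue
        domain_ids[label] = did

    merge_map: dict[int, int] = {}
    for pair in config.get("merges") or []:
        src, dst = (_resolve(pair[0], name_to_id), _resolve(pair[1], name_to_id))
        if src is None or dst is None or dst not in nodes:
            logger.warning("merge pair %r unresolved; skipped", pair)
            continue
        merge_map[src] = dst

    supergroup_map: dict[int, str] = {}
    for ref, label in (config.get("supergroups") or {}).items():
        tid = _resolve(ref, name_to_id)
        if tid is None or tid not in nodes:
            logger.warning("supergroup entry %r unresolved; skipped", ref)
            continue
        supergroup_map[tid] = str(label)

    return TaxonomyIndex(nodes, roots[0], domain_ids, merge_map, supergroup_map)


# -- bulk assignment ------------------------------------------------------


def assign_table(index: TaxonomyIndex, taxon_ids: Iterable[int]) -> pd.DataFrame:
    """Assignment table for a collection of taxon ids (deduplicated)."""
    rows = []
    for tid in sorted(set(int(t) for t in taxon_ids)):
        a = index.assign(tid)
        rows.append((a.taxon_id, a.domain, a.division))
    return pd.DataFrame(rows, columns=["taxon_id", "domain", "division"])


def write_assignments(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_assignments(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
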