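"""RNA families as binary characters on a species phylogeny.

Under the assumption of vertical inheritance a homologous family arises
once: Dollo parsimony allows a single gain and any number of losses. For
a presence pattern on the tips of a rooted species tree the reconstruction
is then fully determined — the gain sits at the MRCA of the present tips,
and each maximal subtree under the gain containing no present tip accounts
for exactly one loss. Mapping presence onto a phylogeny (rather than onto
flat taxonomic divisions) lets sparsely sampled but deeply placed families
be nominated as candidates for ancestral presence in a domain.

Trees are read from newick via dendropy; reconstruction runs on a light
parent/children representation so that scanning hundreds of families over
a large tree stays cheap.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import dendropy
import pandas as pd


class TreeError(Exception):
    pass


class SpeciesTree:
    """Rooted tree with stable node ids and an optional tip→taxon map.

    Tips keep their labels as ids; unnamed internal nodes get ids
    ``node0, node1, ...`` in preorder (root first). Polytomies are allowed.
    """

    def __init__(
        self,
        tree: dendropy.Tree,
        tip_taxa: Mapping[str, int] | None = None,
        force_rooted: bool = False,
    ) -> None:
        if not tree.is_rooted and not force_rooted:
            raise TreeError(
                "tree is unrooted; rooting changes the MRCA and is never "
                "guessed — reroot it or pass force_rooted=True to accept "
                "the file's orientation as the rooting"
            )
        self._dendropy = tree
        self.parent: dict[str, str | None] = {}
        self.children: dict[str, tuple[str, ...]] = {}
        counter = 0
        ids: dict[dendropy.Node, str] = {}
        for node in tree.preorder_node_iter():
            if node.is_leaf():
                if node.taxon is None or not node.taxon.label:
                    raise TreeError("unlabeled tip")
                nid = node.taxon.label
            elif node.label:
                nid = node.label
            else:
                nid = f"node{counter}"
                counter += 1
            if nid in self.children or nid in self.parent:
                raise TreeError(f"duplicate node id {nid!r}")
            ids[node] = nid
            self.parent[nid] = ids[node.parent_node] if node.parent_node else None
            self.children[nid] = ()
        for node in tree.preorder_node_iter():
            self.children[ids[node]] = tuple(ids[c] for c in node.child_nodes())
        self.root_id: str = ids[tree.seed_node]
        self.tips: frozenset[str] = frozenset(
            nid for nid, ch in self.children.items() if not ch
        )
        self.tip_taxa: dict[str, int] = dict(tip_taxa or {})
        unknown = set(self.tip_taxa) - self.tips
        if unknown:
            raise TreeError(f"tip_taxa keys not in tree: {sorted(unknown)}")

    @classmethod
    def from_children(
        cls,
        children: Mapping[str, tuple[str, ...] | list[str]],
        root: str,
        tip_taxa: Mapping[str, int] | None = None,
    ) -> "SpeciesTree":
        """Build directly from a children map (node id -> child ids);
        handy for programmatic tree construction without newick."""
        obj = cls.__new__(cls)
        obj._dendropy = None
        obj.children = {k: tuple(v) for k, v in children.items()}
        obj.parent = {root: None}
        for p, cs in obj.children.items():
            for c in cs:
                if c in obj.parent:
                    raise TreeError(f"node {c!r} has two parents")
                obj.parent[c] = p
        if set(obj.parent) != set(obj.children):
            raise TreeError("children map is not a single rooted tree")
        obj.root_id = root
        obj.tips = frozenset(n for n, ch in obj.children.items() if not ch)
        obj.tip_taxa = dict(tip_taxa or {})
        return obj

    @classmethod
    def from_newick(
        cls,
        source: str | Path,
        tip_taxa: Mapping[str, int] | None = None,
        force_rooted: bool = False,
    ) -> "SpeciesTree":
        path = Path(source)
        if path.exists():
            tree = dendropy.Tree.get(
                path=str(path), schema="newick", preserve_underscores=True
            )
        else:
            tree = dendropy.Tree.get(
                data=str(source), schema="newick", preserve_underscores=True
            )
        return cls(tree, tip_taxa=tip_taxa, force_rooted=force_rooted)

    def postorder(self) -> list[str]:
        order, stack = [], [self.root_id]
        while stack:
            nid = stack.pop()
            order.append(nid)
            stack.extend(self.children[nid])
        order.reverse()
        return order

    def leafset(self, node_id: str) -> frozenset[str]:
        if node_id not in self.children:
            raise TreeError(f"unknown node {node_id!r}")
        out, stack = set(), [node_id]
        while stack:
            nid = stack.pop()
            if not self.children[nid]:
                out.add(nid)
            else:
                stack.extend(self.children[nid])
        return frozenset(out)


@dataclass
class DolloReconstruction:
    """Single-gain reconstruction of one family on the species tree.

    ``node_states`` marks a node present iff it lies in the gain clade and
    its subtree retains at least one present tip; ``loss_count`` is the
    number of maximal absent subtrees under the gain node (each pruned by
    one loss event on its stem; a polytomy's absent children each count
    one loss).
    """

    unit_id: str
    gain_node: str
    loss_count: int
    node_states: dict[str, bool]


def dollo_reconstruct(
    tree: SpeciesTree, presence: Iterable[str], unit_id: str = ""
) -> DolloReconstruction:
    """Reconstruct gain and minimal losses for one presence pattern.

    The gain node is the MRCA of the present tips; this placement is
    loss-minimal because moving the gain above the MRCA can only add
    absent subtrees, and no lower node contains all present tips.
    """
    pres = set(presence)
    if not pres:
        raise ValueError("presence set is empty")
    unknown = pres - tree.tips
    if unknown:
        raise ValueError(f"presence tips not in tree: {sorted(unknown)}")

    order = tree.postorder()
    ntips: dict[str, int] = {}
    for nid in order:
        ch = tree.children[nid]
        if not ch:
            ntips[nid] = 1 if nid in pres else 0
        else:
            ntips[nid] = sum(ntips[c] for c in ch)

    # MRCA: walk up from any present tip to the first node covering all.
    gain = next(iter(pres))
    while ntips[gain] < len(pres):
        gain = tree.parent[gain]

    # Maximal absent subtrees strictly below the gain node.
    losses = 0
    stack = list(tree.children[gain])
    in_gain_clade = {gain}
    while stack:
        nid = stack.pop()
        in_gain_clade.add(nid)
        if ntips[nid] == 0:
            losses += 1  # whole subtree absent: one loss on its stem
        else:
            stack.extend(tree.children[nid])

    states = {
        nid: (nid in in_gain_clade and ntips.get(nid, 0) > 0) for nid in tree.children
    }
    return DolloReconstruction(unit_id, gain, losses, states)


def nominate_candidates(
    tree: SpeciesTree,
    unit_presence: Mapping[str, Iterable[str]],
    domain_root: str | None = None,
    max_losses: int | None = None,
    clade_coverage: float = 0.5,
) -> list[str]:
    """Nominate units consistent with vertical inheritance from the domain
    ancestor.

    A unit is nominated when its Dollo gain node is the domain root, or
    when at least ``clade_coverage`` of the domain root's immediate child
    clades contain a present tip (mirroring the >=50%-of-divisions rule,
    but on the tree). ``max_losses`` optionally caps the implied loss
    count. Output is sorted by accession.
    """
    root = domain_root if domain_root is not None else tree.root_id
    if root not in tree.children:
        raise TreeError(f"domain root {root!r} not in tree")
    domain_tips = tree.leafset(root)
    child_leafsets = {c: tree.leafset(c) for c in tree.children[root]}
    nominated = []
    for unit in sorted(unit_presence):
        pres = set(unit_presence[unit]) & domain_tips
        if not pres:
            continue
        rec = dollo_reconstruct(tree, pres, unit_id=unit)
        covered = sum(1 for ls in child_leafsets.values() if pres & ls)
        ok = rec.gain_node == root or (
            child_leafsets and covered / len(child_leafsets) >= clade_coverage
        )
        if ok and max_losses is not None and rec.loss_count > max_losses:
            ok = False
        if ok:
            nominated.append(unit)
    return nominated


def unit_tip_presence(
    records: pd.DataFrame, tip_taxa: Mapping[str, int]
) -> dict[str, set[str]]:
    """family accession -> tips whose taxon carries >=1 annotation."""
    taxon_tips: dict[int, set[str]] = {}
    for tip, taxon in tip_taxa.items():
        taxon_tips.setdefault(int(taxon), set()).add(tip)
    out: dict[str, set[str]] = {}
    for fam, group in records.groupby("family_accession"):
        tips: set[str] = set()
        for taxon in group["taxon_id"].unique():
            tips |= taxon_tips.get(int(taxon), set())
        if tips:
            out[str(fam)] = tips
    return out


def read_tip_taxa(path: str | Path) -> dict[str, int]:
    """Tip-to-taxon TSV with columns ``tip`` and ``taxon_id``."""
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["tip"].astype(str), df["taxon_id"].astype(int)))


def reconstruction_frame(
    tree: SpeciesTree,
    unit_presence: Mapping[str, Iterable[str]],
    nominated: Iterable[str] = (),
) -> pd.DataFrame:
    nom = set(nominated)
    rows = []
    for unit in sorted(unit_presence):
        rec = dollo_reconstruct(tree, unit_presence[unit], unit_id=unit)
        rows.append((unit, rec.gain_node, rec.loss_count, unit in nom))
    return pd.DataFrame(rows, columns=["unit", "gain_node", "loss_count", "nominated"])
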