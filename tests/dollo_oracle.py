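"""Independent brute-force oracle for Dollo loss minimisation.

Enumerates every possible gain-node placement and counts maximal absent
subtrees under it directly from leaf sets — no shared code with the
implementation's single-pass MRCA algorithm. Also enumerates all rooted
binary labeled tree shapes by sequential leaf insertion, for exhaustive
small-tree checks.
"""

from __future__ import annotations

from rnacensus.phylo import SpeciesTree


def _subtree_has_presence(tree: SpeciesTree, node: str, presence: set[str]) -> bool:
    stack = [node]
    while stack:
        n = stack.pop()
        if not tree.children[n]:
            if n in presence:
                return True
        else:
            stack.extend(tree.children[n])
    return False


def _losses_for_gain(tree: SpeciesTree, gain: str, presence: set[str]) -> int:
    losses = 0
    stack = list(tree.children[gain])
    while stack:
        n = stack.pop()
        if _subtree_has_presence(tree, n, presence):
            stack.extend(tree.children[n])
        else:
            losses += 1
    return losses


def brute_force_min_losses(tree: SpeciesTree, presence: set[str]) -> tuple[str, int]:
    """Minimise losses over every gain node whose clade covers the
    presence set; ties broken toward fewer tips in the gain clade (the
    MRCA), so the returned gain matches the unique minimal placement."""
    best = None
    for gain in tree.children:
        if not presence <= tree.leafset(gain):
            continue
        losses = _losses_for_gain(tree, gain, presence)
        size = len(tree.leafset(gain))
        if best is None or (losses, size) < (best[1], best[2]):
            best = (gain, losses, size)
    assert best is not None
    return best[0], best[1]


# -- tree shape enumeration ------------------------------------------------


def _insert_leaf(tree, leaf):
    """Yield every tree obtained by attaching ``leaf`` on an edge of
    ``tree`` (including above the root)."""
    yield (tree, leaf)
    if isinstance(tree, tuple):
        a, b = tree
        for sub in _insert_leaf(a, leaf):
            yield (sub, b)
        for sub in _insert_leaf(b, leaf):
            yield (a, sub)


def all_rooted_binary_trees(labels: list[str]):
    """All (2n-3)!! rooted binary shapes on the given labeled tips,
    as nested 2-tuples."""
    if len(labels) == 1:
        yield labels[0]
        return
    if len(labels) == 2:
        yield (labels[0], labels[1])
        return
    for t in all_rooted_binary_trees(labels[:-1]):
        yield from _insert_leaf(t, labels[-1])


def random_binary_tree(rng, labels: list[str]):
    """One uniform-ish random shape by random sequential insertion."""
    tree = (labels[0], labels[1])
    for leaf in labels[2:]:
        options = list(_insert_leaf(tree, leaf))
        tree = options[int(rng.integers(len(options)))]
    return tree


def tuple_tree_to_species_tree(tree) -> SpeciesTree:
    children: dict[str, tuple[str, ...]] = {}
    counter = [0]

    def build(node) -> str:
        if isinstance(node, str):
            children[node] = ()
            return node
        nid = f"i{counter[0]}"
        counter[0] += 1
        kids = tuple(build(c) for c in node)
        children[nid] = kids
        return nid

    root = build(tree)
    return SpeciesTree.from_children(children, root)
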