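"""Copy-number tabulation and duplication detection on species-labeled gene trees.

A gene tree carries one (species, gene) pair per tip. Two questions are asked
of it: how many gene copies does each species hold, and which internal nodes
are duplication events. Duplications are called by the *species-overlap*
criterion — a node is a duplication iff the species sets of at least two of
its child subtrees intersect. When no gene loss has occurred this criterion is
exact; with losses it can under- or mis-count, and no species-tree
reconciliation is attempted here.

Tip labels encode the species as one delimited field (default ``Species|gene``);
a tip→species mapping may be supplied instead to override label parsing.
Branch lengths and support values are carried but ignored.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import IO, Optional, Union

import dendropy

__all__ = [
    "GeneTree",
    "DuplicationReport",
    "TreeParseError",
    "UnrootedTreeError",
    "parse_newick_genetree",
    "copy_number_table",
    "label_duplications",
    "sister_paralog_pairs",
]


class TreeParseError(ValueError):
    """Bad Newick input or unparsable tip label."""


class UnrootedTreeError(ValueError):
    """Basal multifurcation: the tree must be rooted before analysis."""


@dataclass
class GeneTree:
    """Rooted gene tree; each leaf node has ``.species`` and ``.gene_name`` set.

    Wraps a :class:`dendropy.Tree`; internal node ids are stable preorder
    indices assigned at parse time (``node.node_index``).
    """

    tree: dendropy.Tree

    @property
    def leaves(self) -> list[dendropy.Node]:
        return list(self.tree.leaf_node_iter())

    def __len__(self) -> int:
        return len(self.leaves)


def parse_newick_genetree(
    source: Union[str, IO[str]],
    delimiter: str = "|",
    species_field: int = 0,
    species_map: Optional[dict[str, str]] = None,
) -> GeneTree:
    """Parse a Newick gene tree whose tip labels encode the species.

    ``source`` is a path, an open stream, or a Newick string (detected by a
    terminal ``;``). ``species_map`` (full tip label → species) overrides
    delimiter parsing. A basal trifurcation is rejected as unrooted.
    """
    if hasattr(source, "read"):
        text = source.read()
    elif isinstance(source, str) and source.rstrip().endswith(";"):
        text = source
    else:
        with open(source, "rt") as fh:
            text = fh.read()
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True
        )
    except Exception as exc:
        raise TreeParseError(f"Newick parse failed: {exc}") from exc

    root = tree.seed_node
    if len(root.child_nodes()) > 2:
        raise UnrootedTreeError(
            "basal multifurcation: the input tree appears unrooted; "
            "root it (e.g. on an outgroup) before duplication analysis"
        )
    leaves = list(tree.leaf_node_iter())
    if len(leaves) < 2:
        raise TreeParseError("gene tree must have at least 2 tips")

    seen: set[str] = set()
    for leaf in leaves:
        label = leaf.taxon.label if leaf.taxon is not None else None
        if not label:
            raise TreeParseError("unlabeled tip in gene tree")
        if label in seen:
            raise TreeParseError(f"duplicate tip label {label!r}")
        seen.add(label)
        if species_map is not None:
            if label not in species_map:
                raise TreeParseError(f"tip {label!r} missing from species map")
            species, gene_name = species_map[label], label
        else:
            parts = label.split(delimiter)
            if len(parts) < 2:
                raise TreeParseError(
                    f"tip {label!r}: expected delimiter {delimiter!r} separating "
                    "species and gene fields"
                )
            if species_field >= len(parts):
                raise TreeParseError(
                    f"tip {label!r}: species field index {species_field} out of range"
                )
            species = parts[species_field]
            rest = parts[:species_field] + parts[species_field + 1:]
            gene_name = delimiter.join(rest)
        if not species:
            raise TreeParseError(f"tip {label!r}: empty species name")
        leaf.species = species
        leaf.gene_name = gene_name

    for i, node in enumerate(tree.preorder_node_iter()):
        node.node_index = i
    return GeneTree(tree)


@dataclass
class DuplicationReport:
    """Per-species copy counts plus species-overlap duplication calls."""

    copy_table: dict[str, int]
    n_multi_copy: int
    duplication_nodes: set[int] = field(default_factory=set)
    n_duplications: int = 0

    def __post_init__(self) -> None:
        assert self.n_multi_copy == sum(1 for c in self.copy_table.values() if c >= 2)
        assert self.n_duplications == len(self.duplication_nodes)


def copy_number_table(
    gtree: GeneTree, clade_filter: Optional[set[str]] = None
) -> dict[str, int]:
    """Tip count per species, optionally restricted to a set of species."""
    counts = Counter(
        leaf.species
        for leaf in gtree.leaves
        if clade_filter is None or leaf.species in clade_filter
    )
    return dict(counts)


def _species_sets(gtree: GeneTree) -> dict[int, frozenset[str]]:
    sets: dict[int, frozenset[str]] = {}
    for node in gtree.tree.postorder_node_iter():
        if node.is_leaf():
            sets[node.node_index] = frozenset([node.species])
        else:
            acc: set[str] = set()
            for child in node.child_nodes():
                acc |= sets[child.node_index]
            sets[node.node_index] = frozenset(acc)
    return sets


def label_duplications(gtree: GeneTree) -> DuplicationReport:
    """Flag every internal node whose child subtrees share a species.

    Overlap is tested pairwise across all children, so multifurcations are
    handled. Exact when the tree contains no gene losses.
    """
    sets = _species_sets(gtree)
    dup_nodes: set[int] = set()
    for node in gtree.tree.preorder_internal_node_iter():
        children = node.child_nodes()
        flagged = False
        for i in range(len(children)):
            for j in range(i + 1, len(children)):
                if sets[children[i].node_index] & sets[children[j].node_index]:
                    flagged = True
                    break
            if flagged:
                break
        if flagged:
            dup_nodes.add(node.node_index)
    table = copy_number_table(gtree)
    return DuplicationReport(
        copy_table=table,
        n_multi_copy=sum(1 for c in table.values() if c >= 2),
        duplication_nodes=dup_nodes,
        n_duplications=len(dup_nodes),
    )


def sister_paralog_pairs(gtree: GeneTree) -> list[tuple[str, str, str]]:
    """Within-species cherries: (species, gene_a, gene_b), genes sorted.

    These are the tightest topological paralog pairs — two gene copies whose
    closest relative in the whole tree is each other.
    """
    pairs: list[tuple[str, str, str]] = []
    for node in gtree.tree.preorder_internal_node_iter():
        children = node.child_nodes()
        if len(children) == 2 and all(c.is_leaf() for c in children):
            a, b = children
            if a.species == b.species:
                g1, g2 = sorted([a.gene_name, b.gene_name])
                pairs.append((a.species, g1, g2))
    return sorted(pairs)
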