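"""Newick trees bound to genes: parsing, leaf binding, pruning, layout.

The leaf order of an uploaded tree drives the top-to-bottom order of
context rows, so tree and gene-neighborhood panels stay aligned. Leaf
labels bind to genes when the whole label, or a delimited token inside it
(split on ``|``, ``_`` and whitespace), matches a known identifier.
Trees are kept exactly as uploaded: no re-rooting, no ladderizing unless
asked for.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import dendropy

from .context import ContextWindow, extract_context, placeholder_window
from .errors import ContextmapError, ParseError
from .genome_io import IdentifierIndex

_COARSE_SPLIT = re.compile(r"[|\s]+")     # keeps underscore-bearing locus tags whole
_FINE_SPLIT = re.compile(r"[|_\s]+")


@dataclass
class GeneTree:
    """A rooted tree plus leaf-label -> (accession, feature) bindings."""

    tree: dendropy.Tree
    leaf_bindings: dict = field(default_factory=dict)

    def leaf_labels(self):
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def serialize(self) -> str:
        text = self.tree.as_string(schema="newick", unquoted_underscores=True,
                                   suppress_rooting=True)
        return text.strip()


@dataclass
class TreeLayout:
    """Drawable coordinates: x from depth or cumulative branch length,
    leaf y at 0, 1, 2, ... top to bottom, internal y = mean of children."""

    leaf_order: list
    node_positions: dict      # node id -> (x, y)
    edges: list               # ((x_parent, y_parent), (x_child, y_child))
    max_x: float
    mode: str


def parse_newick(text: str) -> GeneTree:
    """Parse a Newick string (must end in ';'), keeping branch lengths,
    internal labels and polytomies."""
    stripped = text.strip()
    if not stripped.endswith(";"):
        raise ParseError("Newick text must end with ';'", offset=len(stripped))
    if stripped.count("(") != stripped.count(")"):
        first = min(stripped.find("("), stripped.find(")"))
        raise ParseError("unbalanced parentheses in Newick text", offset=first)
    try:
        tree = dendropy.Tree.get(
            data=stripped, schema="newick", preserve_underscores=True,
            suppress_internal_node_taxa=False,
        )
    except Exception as exc:
        raise ParseError(f"Newick parse failure: {exc}") from None
    return GeneTree(tree=tree)


def bind_leaves(tree: GeneTree, index: IdentifierIndex):
    """Bind each leaf label to a gene.

    An exact whole-label match wins; otherwise the label is split on
    ``|``, ``_`` and whitespace and each token is tried. Leaves matching
    zero or several distinct features are reported, never guessed.
    Returns ``(bound_tree, unbound_report)`` where the report maps
    label -> 'unmatched' or 'ambiguous'.
    """
    bindings = {}
    report = {}
    for label in tree.leaf_labels():
        hits = index.lookup(label)
        if not hits:
            # coarse split first so locus tags containing '_' stay intact,
            # then the fine split for labels like '12345_geneA'
            for splitter in (_COARSE_SPLIT, _FINE_SPLIT):
                tokens = [t for t in splitter.split(label) if t]
                seen = {}
                for tok in tokens:
                    for acc, feat in index.lookup(tok):
                        seen[(acc, id(feat))] = (acc, feat)
                hits = list(seen.values())
                if hits:
                    break
        distinct = {(acc, id(f)): (acc, f) for acc, f in hits}
        if len(distinct) == 1:
            bindings[label] = next(iter(distinct.values()))
        elif not distinct:
            report[label] = "unmatched"
        else:
            report[label] = "ambiguous"
    return GeneTree(tree=tree.tree, leaf_bindings=bindings), report


def prune_tree(tree: GeneTree, keep) -> GeneTree:
    """Restrict the tree to ``keep`` leaves; single-child internals are
    suppressed with their branch lengths summed; kept-leaf order is preserved."""
    keep = set(keep)
    if not keep:
        raise ContextmapError("prune_tree requires a non-empty keep set")
    labels = set(tree.leaf_labels())
    unknown = sorted(keep - labels)
    if unknown:
        raise ContextmapError(f"prune_tree: unknown leaf labels {unknown}")
    clone = dendropy.Tree(tree.tree)
    clone.retain_taxa_with_labels(sorted(keep))
    # dendropy suppresses unifurcations during retain; root may still be one
    seed = clone.seed_node
    while len(seed.child_nodes()) == 1 and seed.child_nodes()[0].child_nodes():
        child = seed.child_nodes()[0]
        clone.seed_node = child
        child.parent_node = None
        seed = child
    bindings = {k: v for k, v in tree.leaf_bindings.items() if k in keep}
    return GeneTree(tree=clone, leaf_bindings=bindings)


def layout_tree(tree: GeneTree, mode: str = "phylogram") -> TreeLayout:
    """Compute drawable coordinates.

    ``phylogram`` x = cumulative branch length from the root (missing
    lengths default to 1); ``cladogram`` x = node depth. Leaves get
    y = 0, 1, 2, ... in depth-first left-to-right order; an internal
    node's y is the mean of its children's y.
    """
    if mode not in ("phylogram", "cladogram"):
        raise ContextmapError(f"unknown layout mode '{mode}'")
    t = tree.tree
    leaves = [leaf for leaf in t.leaf_node_iter()]
    if not leaves:
        raise ContextmapError("layout_tree requires at least one leaf")
    positions = {}
    # x by preorder accumulation
    for node in t.preorder_node_iter():
        parent = node.parent_node
        if parent is None:
            x = 0.0
        else:
            step = 1.0 if mode == "cladogram" else (
                node.edge.length if node.edge.length is not None else 1.0)
            x = positions[id(parent)][0] + step
        positions[id(node)] = [x, None]
    # y: leaves in order, internals postorder mean
    for i, leaf in enumerate(leaves):
        positions[id(leaf)][1] = float(i)
    for node in t.postorder_node_iter():
        kids = node.child_nodes()
        if kids:
            positions[id(node)][1] = sum(positions[id(k)][1] for k in kids) / len(kids)
    edges = []
    for node in t.preorder_node_iter():
        parent = node.parent_node
        if parent is not None:
            px, py = positions[id(parent)]
            cx, cy = positions[id(node)]
            edges.append(((px, py), (cx, cy)))
    max_x = max(p[0] for p in positions.values())
    return TreeLayout(
        leaf_order=[leaf.taxon.label for leaf in leaves],
        node_positions={k: tuple(v) for k, v in positions.items()},
        edges=edges, max_x=max_x, mode=mode,
    )


def contexts_in_tree_order(tree: GeneTree, layout: TreeLayout, genomes,
                           range_nt: int):
    """One context window per leaf, in layout order; unbound leaves yield
    placeholder rows so the drawn tree never disagrees with the row stack."""
    by_acc = {g.accession: g for g in genomes}
    rows = []
    for label in layout.leaf_order:
        binding = tree.leaf_bindings.get(label)
        if binding is None:
            rows.append(placeholder_window(label=label))
            continue
        accession, feature = binding
        genome = by_acc.get(accession)
        if genome is None:
            raise ContextmapError(
                f"leaf '{label}' binds to genome {accession}, which is not loaded"
            )
        window = extract_context(genome, feature, range_nt)
        window.label = label
        rows.append(window)
    return rows
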