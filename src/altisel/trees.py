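"""Phylogeny container for codon-model fitting and simulation.

A tree is held rooted (the root may be a polytomy); every non-root node
defines the branch to its parent, and branches are addressed by the name
of their child node — the taxon name for terminal branches, a stable
``nodeK`` label for internal ones. Because the substitution models here
are time-reversible, likelihoods do not depend on root placement.

Foreground branches (the lineages tested for positive selection) may be
flagged inline in newick with the ``#1`` convention familiar from PAML,
e.g. ``(out,(low,high #1));``, or set programmatically.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field

import dendropy

_FG_SENTINEL = "__FOREGROUND__"


@dataclass
class _Node:
    index: int
    name: str
    length: float
    parent: "_Node | None" = None
    children: list = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


class Phylogeny:
    """Rooted tree with branch lengths and optional foreground flags."""

    def __init__(self, root: _Node, foreground: set[str] | None = None):
        self.root = root
        self.postorder: list[_Node] = []
        self._collect_postorder(root)
        self.nodes_by_name = {n.name: n for n in self.postorder}
        if len(self.nodes_by_name) != len(self.postorder):
            raise ValueError("duplicate node names in tree")
        self.taxa = tuple(n.name for n in self.postorder if n.is_leaf)
        # every non-root node labels the branch above it
        self.branches = tuple(
            n.name for n in self.postorder if n.parent is not None
        )
        self.foreground: set[str] = set(foreground or ())
        unknown = self.foreground - set(self.branches)
        if unknown:
            raise ValueError(f"foreground branches not in tree: {sorted(unknown)}")

    def _collect_postorder(self, node: _Node) -> None:
        for child in node.children:
            self._collect_postorder(child)
        self.postorder.append(node)

    # -- construction ------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        """Parse a newick string; ``#1`` marks foreground branches."""
        # "#1" may follow the label or the branch length; reattach to the label
        marked = re.sub(
            r"([^\s,()#:]*)((?::[^,()#]*)?)\s*#\s*1",
            rf"\1{_FG_SENTINEL}\2",
            newick,
        )
        tree = dendropy.Tree.get(
            data=marked, schema="newick", suppress_internal_node_taxa=False,
            preserve_underscores=True,
        )
        counter = [0]

        def convert(dnode, parent):
            label = None
            if dnode.taxon is not None:
                label = dnode.taxon.label
            elif dnode.label:
                label = dnode.label
            fg = False
            if label and label.endswith(_FG_SENTINEL):
                label = label[: -len(_FG_SENTINEL)] or None
                fg = True
            if not label or not dnode.is_leaf():
                # internal labels are regenerated for stability
                label = f"node{counter[0]}"
                counter[0] += 1
            length = dnode.edge.length if dnode.edge.length is not None else 0.0
            if length < 0:
                raise ValueError(f"negative branch length on {label!r}")
            node = _Node(0, label, float(length), parent)
            if parent is not None:
                parent.children.append(node)
            fgs = []
            if fg and parent is not None:
                fgs.append(label)
            for child in dnode.child_nodes():
                fgs.extend(convert(child, node))
            return fgs if parent is not None else (node, fgs)

        root, fgs = convert(tree.seed_node, None)
        phylo = cls(root, foreground=set(fgs))
        for i, n in enumerate(phylo.postorder):
            n.index = i
        return phylo

    # -- accessors ---------------------------------------------------

    @property
    def branch_lengths(self) -> dict[str, float]:
        return {
            n.name: n.length for n in self.postorder if n.parent is not None
        }

    def set_branch_length(self, branch: str, length: float) -> None:
        if length < 0:
            raise ValueError("branch length must be >= 0")
        self.nodes_by_name[branch].length = float(length)

    def set_foreground(self, branches) -> None:
        branches = set(branches)
        unknown = branches - set(self.branches)
        if unknown:
            raise ValueError(f"foreground branches not in tree: {sorted(unknown)}")
        self.foreground = branches

    def n_leaves(self) -> int:
        return len(self.taxa)

    def copy(self) -> "Phylogeny":
        return Phylogeny.from_newick(self.to_newick())

    # -- serialisation -----------------------------------------------

    def to_newick(self, mark_foreground: bool = True) -> str:
        def fmt(node: _Node) -> str:
            mark = "#1" if mark_foreground and node.name in self.foreground else ""
            if node.is_leaf:
                core = node.name + mark
            else:
                inner = ",".join(fmt(c) for c in node.children)
                label = "" if node.name.startswith("node") else node.name
                core = f"({inner}){label}{mark}"
            if node.parent is None:
                return core
            return f"{core}:{node.length:.10g}"

        return fmt(self.root) + ";"

    def __repr__(self) -> str:  # pragma: no cover
        return f"Phylogeny({self.to_newick()!r})"


def star_tree(taxa, branch_length: float = 0.1) -> Phylogeny:
    """Star topology — used by enumeration oracles and toy fixtures."""
    parts = ",".join(f"{t}:{branch_length:.10g}" for t in taxa)
    return Phylogeny.from_newick(f"({parts});")
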