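"""Fixed five-primate species tree.

The topology is the standard catarrhine one — (((human, chimpanzee),
gorilla), orangutan, macaque) — with branch lengths in expected
substitutions per codon site.  Lengths are configurable; the defaults are
round numbers on a primate-divergence scale (human and chimpanzee 0.004
each, their stem 0.004, gorilla 0.008, the great-ape stem 0.012, orangutan
0.02, macaque 0.03).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

from Bio import Phylo

SPECIES = ("human", "chimpanzee", "gorilla", "orangutan", "macaque")

DEFAULT_NEWICK = (
    "(((human:0.004,chimpanzee:0.004):0.004,gorilla:0.008):0.012,"
    "orangutan:0.02,macaque:0.03);"
)


@dataclass
class TreeNode:
    """A node of the rooted species tree; ``length`` is the branch above."""

    name: str | None
    length: float
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def postorder(self) -> list["TreeNode"]:
        out = []
        for c in self.children:
            out.extend(c.postorder())
        out.append(self)
        return out


def _from_clade(clade) -> TreeNode:
    node = TreeNode(clade.name, clade.branch_length or 0.0)
    node.children = [_from_clade(c) for c in clade.clades]
    return node


def _resolve_binary(node: TreeNode) -> TreeNode:
    """Arbitrarily resolve multifurcations with zero-length edges.

    Parsimony scores are unchanged by this resolution, so Fitch counting
    can assume a binary tree.
    """
    children = [_resolve_binary(c) for c in node.children]
    while len(children) > 2:
        merged = TreeNode(None, 0.0, [children[0], children[1]])
        children = [merged] + children[2:]
    out = TreeNode(node.name, node.length, children)
    return out


class SpeciesTree:
    """The five-taxon primate tree used throughout the pipeline."""

    def __init__(self, newick: str = DEFAULT_NEWICK):
        handle = io.StringIO(newick)
        phylo = Phylo.read(handle, "newick")
        self.newick = newick
        self.root = _from_clade(phylo.root)
        names = sorted(leaf.name for leaf in self.root.leaves())
        if len(names) != 5 or len(set(names)) != 5:
            raise ValueError("species tree must have exactly 5 uniquely named leaves")
        if set(names) != set(SPECIES):
            raise ValueError(f"unexpected species names: {names}")
        self.binary_root = _resolve_binary(self.root)

    @classmethod
    def default(cls) -> "SpeciesTree":
        return cls()

    def scaled(self, factor: float) -> "SpeciesTree":
        """A copy with every branch length multiplied by ``factor``."""
        tree = SpeciesTree(self.newick)

        def scale(node: TreeNode) -> None:
            node.length *= factor
            for c in node.children:
                scale(c)

        scale(tree.root)
        scale(tree.binary_root)
        return tree

    @property
    def total_length(self) -> float:
        return sum(n.length for n in self.root.postorder() if n is not self.root)

    def leaf_names(self) -> list[str]:
        return [leaf.name for leaf in self.root.leaves()]
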