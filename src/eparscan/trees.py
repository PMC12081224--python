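"""Rooted haplogroup trees with branch-defining SNPs.

The male-specific region of the Y chromosome (MSY) phylogeny is a rooted
tree whose branches are defined by SNPs: a derived call at a branch SNP
places a chromosome inside the clade below that branch.  This module keeps
a deliberately small tree structure (labels, parent/children, branch ->
SNP sets) because downstream operations -- haplogroup assignment and
irreversible-parsimony origin counting -- need explicit branch semantics
that general-purpose tree libraries do not carry.  Newick text is parsed
with dendropy and converted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping

import dendropy

__all__ = ["BranchSNP", "Clade", "HaplogroupTree"]


@dataclass(frozen=True)
class BranchSNP:
    """A SNP defining one branch of the phylogeny."""

    snp_id: str
    branch: str
    ancestral: str
    derived: str


@dataclass
class Clade:
    label: str
    parent: "Clade | None" = None
    children: list["Clade"] = field(default_factory=list)

    @property
    def is_tip(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Clade({self.label!r}, tips={len(list(self.tips()))})"

    def preorder(self) -> Iterator["Clade"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def tips(self) -> Iterator["Clade"]:
        for node in self.preorder():
            if node.is_tip:
                yield node


class HaplogroupTree:
    """Rooted tree with unique node labels and a branch -> SNP map.

    Every node label doubles as the name of the branch immediately above
    it (the root has no branch).  ``snp_map`` sends each SNP id to exactly
    one branch together with its ancestral/derived alleles.
    """

    def __init__(self, root: Clade, snps: Mapping[str, BranchSNP] | None = None):
        self.root = root
        self._nodes: dict[str, Clade] = {}
        for node in root.preorder():
            if node.label in self._nodes:
                raise ValueError(f"duplicate node label {node.label!r}")
            self._nodes[node.label] = node
        self.snp_map: dict[str, BranchSNP] = dict(snps or {})
        for snp in self.snp_map.values():
            if snp.branch not in self._nodes:
                raise ValueError(
                    f"SNP {snp.snp_id!r} maps to unknown branch {snp.branch!r}"
                )

    # -- construction ------------------------------------------------

    @classmethod
    def from_newick(
        cls, newick: str, snps: Mapping[str, BranchSNP] | None = None
    ) -> "HaplogroupTree":
        """Build a tree from a Newick string (or file contents).

        Unlabelled internal nodes receive deterministic ``N<k>`` labels in
        preorder so every branch is addressable.
        """
        dtree = dendropy.Tree.get(data=newick, schema="newick")
        counter = 0

        def convert(dnode, parent):
            nonlocal counter
            label = dnode.taxon.label if dnode.taxon else dnode.label
            if not label:
                label = f"N{counter}"
                counter += 1
            node = Clade(label=str(label).replace(" ", "_"), parent=parent)
            for child in dnode.child_nodes():
                node.children.append(convert(child, node))
            return node

        return cls(convert(dtree.seed_node, None), snps)

    # -- queries -----------------------------------------------------

    def node(self, label: str) -> Clade:
        try:
            return self._nodes[label]
        except KeyError:
            raise KeyError(f"no node labelled {label!r} in tree") from None

    def __contains__(self, label: str) -> bool:
        return label in self._nodes

    @property
    def labels(self) -> list[str]:
        return list(self._nodes)

    def tip_labels(self) -> list[str]:
        return [n.label for n in self.root.tips()]

    def path_to(self, label: str) -> list[Clade]:
        """Nodes from the root down to ``label`` inclusive."""
        node = self.node(label)
        path = []
        while node is not None:
            path.append(node)
            node = node.parent
        return path[::-1]

    def tips_below(self, label: str) -> set[str]:
        return {n.label for n in self.node(label).tips()}

    def snps_on_branch(self, label: str) -> list[BranchSNP]:
        return [s for s in self.snp_map.values() if s.branch == label]

    def to_newick(self) -> str:
        def render(node: Clade) -> str:
            if node.is_tip:
                return node.label
            inner = ",".join(render(c) for c in node.children)
            return f"({inner}){node.label}"

        return render(self.root) + ";"
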