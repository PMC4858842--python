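"""Species-tree handling for presence/absence dating.

Branches are identified by the label of the node *below* them (child node):
terminal branches carry the taxon name, internal branches the internal-node
label from the Newick string (auto-labelled ``nodeK`` in preorder when
absent).  Branch lengths are interpreted as time (MY in the default tree),
so an ultrametric tree yields an age span ``[child_age, parent_age]`` for
every branch.

The default tree mirrors an 11-taxon rice-like phylogeny: an Asian crown
clade (four taxa, crown 0.8 MY), an AA-genome clade (crown 2.5 MY), a BB
outgroup splitting 6.8 MY ago, a distant FF-like outgroup at 26 MY and an
outgroup genus at 30 MY.
"""
from __future__ import annotations

from typing import Iterable, Optional

import dendropy

#: 11-taxon default phylogeny (branch lengths in MY, ultrametric).
DEFAULT_TREE_NEWICK = (
    "(Lper:30.0,((Opun:6.8,(Omer:2.5,(Oglum:2.0,((Ogla:0.6,Obar:0.6)African:0.9,"
    "(Oniv:0.8,((Osj:0.2,Osi:0.2)Sativa:0.2,Oruf:0.4)JapRuf:0.4)Asian:0.7)"
    "Core:0.5)AA2:0.5)AAcrown:4.3)AABB:19.2,Obra:26.0)Outer:4.0)Root;"
)

#: clade definitions used by the default age-group map
DEFAULT_ASIAN_TAXA = frozenset({"Osj", "Osi", "Oruf", "Oniv"})
DEFAULT_AA_TAXA = DEFAULT_ASIAN_TAXA | {"Ogla", "Obar", "Oglum", "Omer"}
DEFAULT_BB_TAXA = frozenset({"Opun"})


class SpeciesTree:
    """Rooted, branch-labelled species tree."""

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._label_to_node: dict[str, dendropy.Node] = {}
        self._leafsets: dict[str, frozenset[str]] = {}
        counter = 0
        for node in tree.preorder_node_iter():
            if node.is_leaf():
                label = node.taxon.label
            else:
                label = node.label
                if not label:
                    label = f"node{counter}"
                    node.label = label
            counter += 1
            if label in self._label_to_node:
                raise ValueError(f"duplicate branch label {label!r}")
            self._label_to_node[label] = node
        for label, node in self._label_to_node.items():
            self._leafsets[label] = frozenset(
                lf.taxon.label for lf in node.leaf_iter()
            )
        taxa = [lf.taxon.label for lf in tree.leaf_node_iter()]
        if len(set(taxa)) != len(taxa):
            raise ValueError("duplicate taxa in tree")
        self.taxa: list[str] = taxa
        self._ages = self._compute_ages()

    # -- construction -------------------------------------------------------
    @classmethod
    def from_newick(cls, text: str) -> "SpeciesTree":
        tree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True
        )
        return cls(tree)

    @classmethod
    def from_file(cls, path: str) -> "SpeciesTree":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    @classmethod
    def default(cls) -> "SpeciesTree":
        return cls.from_newick(DEFAULT_TREE_NEWICK)

    def to_newick(self) -> str:
        return self._tree.as_string(schema="newick", suppress_rooting=True).strip()

    # -- branch queries ------------------------------------------------------
    @property
    def branch_labels(self) -> list[str]:
        return list(self._label_to_node)

    @property
    def root_label(self) -> str:
        return self._tree.seed_node.label or next(iter(self._label_to_node))

    def leaf_set(self, branch: str) -> frozenset[str]:
        """Taxa descending from the branch (inclusive of terminal taxon)."""
        try:
            return self._leafsets[branch]
        except KeyError:
            raise KeyError(f"unknown branch label {branch!r}") from None

    def is_terminal(self, branch: str) -> bool:
        return self._label_to_node[branch].is_leaf()

    def mrca_branch(self, taxa: Iterable[str]) -> str:
        """Label of the branch above the MRCA of the given taxa."""
        want = frozenset(taxa)
        unknown = want - set(self.taxa)
        if unknown:
            raise KeyError(f"taxa not in tree: {sorted(unknown)}")
        if not want:
            raise ValueError("empty taxon set has no MRCA")
        best: Optional[str] = None
        best_size = None
        for label, leaves in self._leafsets.items():
            if want <= leaves and (best_size is None or len(leaves) < best_size):
                best, best_size = label, len(leaves)
        assert best is not None
        return best

    def is_same_or_descendant(self, branch: str, ancestor: str) -> bool:
        """True if ``branch``'s node lies in the subtree rooted at ``ancestor``."""
        return self.leaf_set(branch) <= self.leaf_set(ancestor)

    def _compute_ages(self) -> dict[str, tuple[float, float]]:
        # depth from root, then age = height - depth (sensible for ultrametric
        # trees; for non-ultrametric input the numbers are nominal)
        depth: dict[int, float] = {id(self._tree.seed_node): 0.0}
        for node in self._tree.preorder_node_iter():
            if node.parent_node is not None:
                depth[id(node)] = depth[id(node.parent_node)] + (
                    node.edge.length or 0.0
                )
        height = max(
            depth[id(lf)] for lf in self._tree.leaf_node_iter()
        )
        ages = {}
        for label, node in self._label_to_node.items():
            child_age = height - depth[id(node)]
            if node.parent_node is None:
                parent_age = child_age  # root branch has no stem here
            else:
                parent_age = height - depth[id(node.parent_node)]
            ages[label] = (child_age, parent_age)
        return ages

    def branch_age_span(self, branch: str) -> tuple[float, float]:
        """(younger, older) end ages of the branch, in branch-length units."""
        return self._ages[branch]

    def branches_preorder(self) -> list[str]:
        return [
            (n.taxon.label if n.is_leaf() else n.label)
            for n in self._tree.preorder_node_iter()
        ]
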