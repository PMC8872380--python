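"""Species-tree helpers: Newick I/O, MRCA lookup and branch labelling.

A branch (edge) is identified by the clade below it. The label of a
branch is the internal node's own label when the Newick provides one,
otherwise the sorted leaf names of the clade joined with '+'; a terminal
branch is labelled with its leaf name. Both the simulator's planted
truth and the screening module's placement use this convention, so the
two are directly comparable.
"""

from __future__ import annotations

import dendropy

__all__ = ["load_tree", "branch_label", "mrca_branch", "leaf_names"]


def load_tree(newick: str) -> dendropy.Tree:
    """Parse a Newick string (or read a file path ending in .nwk/.tre)."""
    if newick.strip().endswith((".nwk", ".tre", ".newick")):
        with open(newick.strip()) as fh:
            newick = fh.read()
    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    tree.is_rooted = True
    return tree


def leaf_names(tree: dendropy.Tree) -> list[str]:
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


def branch_label(node: dendropy.Node) -> str:
    if node.is_leaf():
        return node.taxon.label
    if node.label:
        return node.label
    leaves = sorted(lf.taxon.label for lf in node.leaf_iter())
    return "+".join(leaves)


def mrca_branch(tree: dendropy.Tree, species: set[str] | list[str]) -> str:
    """Label of the edge above the MRCA of the given leaves (single-gain placement)."""
    species = sorted(set(species))
    if not species:
        raise ValueError("species set must be non-empty")
    known = set(leaf_names(tree))
    missing = set(species) - known
    if missing:
        raise ValueError(f"species not in tree: {sorted(missing)}")
    if len(species) == 1:
        node = tree.find_node_with_taxon_label(species[0])
    else:
        node = tree.mrca(taxon_labels=species)
    return branch_label(node)
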