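"""Newick I/O and tree pruning helpers built on dendropy.

All trees handled by this package are rooted trees with branch lengths.
Newick files are read with forced rooting because downstream covariance
computations are defined relative to the root.
"""

from __future__ import annotations

from typing import Iterable

import dendropy

__all__ = ["read_tree", "write_tree", "prune_tree", "tip_labels"]


def read_tree(path_or_str: str, *, from_string: bool = False) -> dendropy.Tree:
    """Read a rooted Newick tree from a file path or a literal string."""
    kwargs = dict(schema="newick", rooting="force-rooted",
                  preserve_underscores=True)
    if from_string:
        return dendropy.Tree.get(data=path_or_str, **kwargs)
    return dendropy.Tree.get(path=path_or_str, **kwargs)


def write_tree(tree: dendropy.Tree, path: str) -> None:
    tree.write(path=path, schema="newick", suppress_rooting=True,
               unquoted_underscores=True)


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def prune_tree(tree: dendropy.Tree, keep: Iterable[str]) -> dendropy.Tree:
    """Return a copy of ``tree`` restricted to the tips in ``keep``.

    Unifurcations created by pruning are suppressed with their branch
    lengths summed, so all pairwise root-to-MRCA depths among the
    surviving tips are preserved.
    """
    keep = set(keep)
    missing = keep - set(tip_labels(tree))
    if missing:
        raise ValueError(
            f"species not in tree: {sorted(missing)}")
    pruned = tree.extract_tree_with_taxa_labels(
        labels=keep, suppress_unifurcations=True)
    pruned.is_rooted = True
    return pruned
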