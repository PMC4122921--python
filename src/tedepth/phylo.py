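"""Species-specific TE amplifications from element phylogenies.

Leaves of an element tree are labelled ``<species><delim><element>``; the unit
of a species-specific amplification is the *maximal monospecific clade*: the
deepest node whose leaves all come from one species while its parent's do not.
These clades are pairwise disjoint and partition the leaf set.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable

import dendropy
import pandas as pd

from .model import CladeReport


@dataclass
class ElementTree:
    tree: dendropy.Tree
    species: dict[str, str]  # leaf label -> species

    @property
    def n_leaves(self) -> int:
        return len(self.species)


def read_tree_with_species(source, delimiter: str = "_", species_field: int = 0) -> ElementTree:
    """Read a newick tree and parse the species of every leaf from its label.

    ``source`` may be a path or a newick string.  Labels that do not yield a
    non-empty species under the delimiter rule are reported together in one
    error.
    """
    text = None
    if isinstance(source, (str, os.PathLike)) and os.path.exists(os.fspath(source)):
        with open(source) as fh:
            text = fh.read()
    elif isinstance(source, str):
        text = source
    else:
        raise ValueError(f"cannot read tree from {source!r}")
    tree = dendropy.Tree.get(data=text, schema="newick", preserve_underscores=True)
    species: dict[str, str] = {}
    bad: list[str] = []
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label if leaf.taxon else (leaf.label or "")
        parts = label.split(delimiter)
        if delimiter not in label or len(parts) <= species_field or not parts[species_field]:
            bad.append(label or "<unlabelled>")
        else:
            species[label] = parts[species_field]
    if bad:
        raise ValueError(
            f"leaf labels not parseable with delimiter {delimiter!r}, field {species_field}: {bad}"
        )
    return ElementTree(tree, species)


def _maybe_reroot(etree: ElementTree, outgroup_species: str | None) -> dendropy.Tree:
    tree = etree.tree
    if outgroup_species is not None:
        taxa = [
            leaf.taxon
            for leaf in tree.leaf_node_iter()
            if etree.species[leaf.taxon.label] == outgroup_species
        ]
        if not taxa:
            raise ValueError(f"outgroup species {outgroup_species!r} not found among leaves")
        if len(taxa) == len(etree.species):
            raise ValueError("outgroup species covers the whole tree")
        tree.is_rooted = True
        mrca = tree.mrca(taxa=taxa)
        if mrca is not tree.seed_node:
            tree.reroot_at_edge(mrca.edge, update_bipartitions=False)
        return tree
    root = tree.seed_node
    unrooted = len(root.child_nodes()) > 2
    has_lengths = all(
        e.length is not None for e in tree.preorder_edge_iter() if e.head_node is not root
    )
    if unrooted and has_lengths:
        tree.reroot_at_midpoint(update_bipartitions=False)
    return tree


def maximal_monospecific_clades(
    etree: ElementTree, outgroup_species: str | None = None
) -> list[CladeReport]:
    """Tag the deepest nodes containing only elements from one species.

    Returns one report per maximal monospecific clade (a leaf counts as a
    clade; the root is reported when the whole tree is one species).  A
    multifurcating node is monospecific iff all its children are.  The reports
    partition the leaves; this is asserted before returning.
    """
    tree = _maybe_reroot(etree, outgroup_species)
    spset: dict[int, set[str]] = {}
    leaves: dict[int, list[str]] = {}
    for node in tree.postorder_node_iter():
        nid = id(node)
        if node.is_leaf():
            label = node.taxon.label if node.taxon else node.label
            spset[nid] = {etree.species[label]}
            leaves[nid] = [label]
        else:
            spset[nid] = set().union(*(spset[id(c)] for c in node.child_nodes()))
            leaves[nid] = [x for c in node.child_nodes() for x in leaves[id(c)]]
    reports: list[CladeReport] = []
    counter = 0
    for node in tree.preorder_node_iter():
        nid = id(node)
        if len(spset[nid]) != 1:
            continue
        parent = node.parent_node
        if parent is not None and len(spset[id(parent)]) == 1:
            continue
        counter += 1
        members = leaves[nid]
        reports.append(
            CladeReport(next(iter(spset[nid])), len(members), f"clade{counter:04d}", list(members))
        )
    covered = [m for r in reports for m in r.members]
    assert len(covered) == etree.n_leaves and len(set(covered)) == len(covered), (
        "maximal monospecific clades must partition the leaves"
    )
    return reports


def amplification_summary(
    reports: Iterable[CladeReport], min_size: int = 2
) -> tuple[pd.DataFrame, float]:
    """Per-species amplification table plus the tree-level fraction of elements
    inside species-specific clades of at least ``min_size`` members."""
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    reports = list(reports)
    total = sum(r.size for r in reports)
    rows = []
    in_big_total = 0
    for sp in sorted({r.species for r in reports}):
        mine = [r for r in reports if r.species == sp]
        big = [r for r in mine if r.size >= min_size]
        elements = sum(r.size for r in mine)
        in_big = sum(r.size for r in big)
        in_big_total += in_big
        rows.append(
            {
                "species": sp,
                "n_clades": len(mine),
                "n_clades_min_size": len(big),
                "largest_clade": max(r.size for r in mine),
                "total_elements": elements,
                "fraction_in_clades": in_big / elements if elements else 0.0,
            }
        )
    df = pd.DataFrame(rows).set_index("species")
    return df, (in_big_total / total if total else 0.0)
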