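"""Species-by-species phylogenetic correlation matrices from Newick trees.

Under a Brownian-motion model of trait evolution the covariance between two
species is the branch length shared on their root-to-tip paths, i.e. the
depth of their most recent common ancestor.  The model here needs a
*correlation* matrix, so the shared depth is standardised by the geometric
mean of the two tip depths: A[i, j] = depth(MRCA) / sqrt(depth_i * depth_j).
This absorbs the slight tip-height variation of published supertrees, which
are not exactly ultrametric.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "PhyloCorrelation",
    "SpeciesMappingError",
    "read_trees",
    "correlation_from_tree",
    "map_species",
    "prune_to_species",
]

log = logging.getLogger("ornmeta")

#: ridge added to the diagonal when the matrix fails a numerical PSD check
PSD_RIDGE = 1e-8
PSD_TOL = -1e-10


class SpeciesMappingError(ValueError):
    """Dataset species that match no tree tip (message lists them)."""


@dataclass
class PhyloCorrelation:
    """A species-order list and the matching correlation matrix ``A``."""

    species: list[str]
    A: np.ndarray
    tree_id: str = ""
    ridged: bool = field(default=False)

    def submatrix(self, species_subset: list[str]) -> "PhyloCorrelation":
        idx = [self.species.index(s) for s in species_subset]
        return PhyloCorrelation(list(species_subset), self.A[np.ix_(idx, idx)], self.tree_id)


def _norm(name: str) -> str:
    return "_".join(str(name).strip().split())


def read_trees(path) -> list[dendropy.Tree]:
    """Read one or more Newick trees (one per line or concatenated) from a file."""
    trees = dendropy.TreeList.get(path=str(path), schema="newick",
                                  preserve_underscores=True)
    if len(trees) == 0:
        raise ValueError(f"no trees found in {path}")
    return list(trees)


def map_species(dataset_species, tree: dendropy.Tree, aliases=None) -> dict:
    """Exact-match species -> tip-label mapping (after underscore normalisation).

    Returns {"matched": {species: tip label}, "unmatched": [...],
    "suggestions": {species: [nearest tips]}}.  Raises
    :class:`SpeciesMappingError` when any species is unmatched and no alias
    resolves it.
    """
    import difflib

    aliases = {(_norm(k)): _norm(v) for k, v in (aliases or {}).items()}
    tips = {_norm(leaf.taxon.label): leaf.taxon.label
            for leaf in tree.leaf_node_iter()}
    matched, unmatched, suggestions = {}, [], {}
    for sp in dataset_species:
        key = _norm(sp)
        key = aliases.get(key, key)
        if key in tips:
            matched[sp] = tips[key]
        else:
            unmatched.append(sp)
            suggestions[sp] = difflib.get_close_matches(key, tips.keys(), n=3)
    if unmatched:
        raise SpeciesMappingError(
            f"species not found in tree: {unmatched}; nearest tips: {suggestions}"
        )
    return {"matched": matched, "unmatched": unmatched, "suggestions": suggestions}


def prune_to_species(tree: dendropy.Tree, species, aliases=None) -> dendropy.Tree:
    """Copy of ``tree`` retaining only the tips matching ``species``."""
    mapping = map_species(species, tree, aliases)["matched"]
    pruned = tree.clone(depth=1)
    keep = set(mapping.values())
    taxa = [t for t in pruned.taxon_namespace if t.label in keep]
    pruned.retain_taxa(taxa)
    return pruned


def correlation_from_tree(
    tree: dendropy.Tree, species_order, aliases=None, tree_id: str = ""
) -> PhyloCorrelation:
    """Phylogenetic correlation matrix for ``species_order`` from one tree.

    Shared depths are accumulated in one postorder sweep: at each internal
    node, every tip pair whose paths split there shares the node's depth.
    Polytomies and zero-length internal branches are handled as-is.  If the
    result fails a numerical PSD check a ridge of ``PSD_RIDGE`` is added to
    the diagonal (and renormalised); the event is logged.
    """
    mapping = map_species(species_order, tree, aliases)["matched"]
    tip_to_idx = {tip: i for i, (sp, tip) in enumerate(
        (sp, mapping[sp]) for sp in species_order)}
    S = len(species_order)
    C = np.zeros((S, S))

    # root-to-node depths
    depth: dict = {}
    for node in tree.preorder_node_iter():
        el = node.edge.length or 0.0
        depth[node] = (depth[node.parent_node] if node.parent_node else 0.0) + el

    # postorder: collect tip indices per subtree; cross-child pairs share this depth
    tips_below: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label
            idx = tip_to_idx.get(label)
            tips_below[node] = [idx] if idx is not None else []
            if idx is not None:
                if depth[node] <= 0:
                    raise ValueError(f"zero-depth tip {label!r}: degenerate tree")
                C[idx, idx] = depth[node]
        else:
            children = [tips_below.pop(ch) for ch in node.child_nodes()]
            d = depth[node]
            for a in range(len(children)):
                for b in range(a + 1, len(children)):
                    for i in children[a]:
                        for j in children[b]:
                            C[i, j] = C[j, i] = d
            tips_below[node] = [i for ch in children for i in ch]

    diag = np.diag(C).copy()
    A = C / np.sqrt(np.outer(diag, diag))
    np.fill_diagonal(A, 1.0)

    ridged = False
    if np.linalg.eigvalsh(A).min() < PSD_TOL:
        A = A + PSD_RIDGE * np.eye(S)
        A /= 1.0 + PSD_RIDGE
        ridged = True
        log.warning("correlation matrix for tree %s required a PSD ridge", tree_id)
    return PhyloCorrelation(list(species_order), A, tree_id=tree_id, ridged=ridged)
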