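"""Rooted, branch-length-bearing phylogenies.

A thin wrapper around :class:`dendropy.Tree` that exposes exactly what the
comparative analyses need: tip labels, root-to-tip depths, patristic
distances, and the Brownian-motion covariance implied by shared ancestry.
Branch lengths are mandatory — a missing length is an error, never silently
defaulted, because every downstream covariance matrix is built from them.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np

from .errors import FormatError, ValidationError

__all__ = ["PhyloTree", "read_tree"]


class PhyloTree:
    """Rooted tree over species labels with branch lengths in common units.

    Parameters
    ----------
    tree:
        A dendropy tree.  Every edge except the root edge must carry a
        branch length >= 0, and tip labels must be unique.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._validate()
        self._depths: dict[str, float] = {}
        for leaf in tree.leaf_node_iter():
            depth = 0.0
            node = leaf
            while node.parent_node is not None:
                depth += node.edge.length
                node = node.parent_node
            self._depths[leaf.taxon.label] = depth
        self._pdm_cache: dict[tuple[str, ...], np.ndarray] = {}

    def _validate(self) -> None:
        labels = []
        for leaf in self._tree.leaf_node_iter():
            if leaf.taxon is None or not leaf.taxon.label:
                raise ValidationError("tree contains an unlabeled tip")
            labels.append(leaf.taxon.label)
        if len(set(labels)) != len(labels):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise ValidationError(f"duplicate tip labels: {dupes}")
        for edge in self._tree.preorder_edge_iter():
            if edge.head_node is self._tree.seed_node:
                continue
            if edge.length is None:
                raise ValidationError(
                    "tree has an edge without a branch length; lengths are required"
                )
            if edge.length < 0:
                raise ValidationError(f"negative branch length {edge.length}")

    # ------------------------------------------------------------------
    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        """Parse a Newick string (single rooted tree, branch lengths)."""
        try:
            tree = dendropy.Tree.get(
                data=newick,
                schema="newick",
                suppress_internal_node_taxa=True,
                terminating_semicolon_required=True,
            )
        except Exception as exc:  # dendropy raises several parse error types
            raise FormatError(f"unparseable Newick: {exc}") from exc
        return cls(tree)

    @classmethod
    def from_file(cls, path: str | Path) -> "PhyloTree":
        return cls.from_newick(Path(path).read_text())

    def to_newick(self) -> str:
        return self._tree.as_string(schema="newick", suppress_rooting=True).strip()

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_newick() + "\n")

    # ------------------------------------------------------------------
    @property
    def tip_labels(self) -> list[str]:
        return sorted(self._depths)

    @property
    def n_tips(self) -> int:
        return len(self._depths)

    def depth(self, label: str) -> float:
        """Root-to-tip path length of one tip."""
        return self._depths[label]

    def depths(self, order: Sequence[str] | None = None) -> np.ndarray:
        order = list(order) if order is not None else self.tip_labels
        return np.array([self._depths[t] for t in order])

    def check_species(self, species: Sequence[str]) -> None:
        """Raise listing every requested species missing from the tree."""
        missing = sorted(set(species) - set(self._depths))
        if missing:
            raise ValidationError(
                f"species present in data but absent from tree: {missing}"
            )

    def patristic_matrix(self, order: Sequence[str] | None = None) -> np.ndarray:
        """Pairwise tip-to-tip path lengths in the given tip order."""
        order = tuple(order) if order is not None else tuple(self.tip_labels)
        if order in self._pdm_cache:
            return self._pdm_cache[order]
        self.check_species(order)
        pdm = self._tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in self._tree.taxon_namespace}
        n = len(order)
        out = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d = pdm.patristic_distance(taxa[order[i]], taxa[order[j]])
                out[i, j] = out[j, i] = d
        self._pdm_cache[order] = out
        return out

    def bm_covariance(self, order: Sequence[str] | None = None) -> np.ndarray:
        """Brownian-motion covariance: C_ij = root-to-MRCA shared path length.

        Recovered from depths and patristic distances via
        ``C_ij = (depth_i + depth_j - d_ij) / 2`` and ``C_ii = depth_i``.
        """
        order = list(order) if order is not None else self.tip_labels
        d = self.depths(order)
        p = self.patristic_matrix(order)
        cov = (d[:, None] + d[None, :] - p) / 2.0
        np.fill_diagonal(cov, d)
        return cov

    def is_ultrametric(self, tol: float = 1e-9) -> bool:
        d = self.depths()
        return float(d.max() - d.min()) <= tol

    def __repr__(self) -> str:  # pragma: no cover
        return f"PhyloTree(n_tips={self.n_tips})"


def read_tree(path: str | Path) -> PhyloTree:
    """Read a rooted Newick tree with branch lengths from ``path``."""
    return PhyloTree.from_file(path)
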