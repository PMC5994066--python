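"""Edge-matrix representation of a rooted phylogeny.

Faith PD and both UniFrac variants reduce to sums over tree edges once
each edge is annotated with the set of tips below it.  We precompute a
dense boolean (edges x tips) incidence matrix plus the branch-length
vector in one postorder pass; every diversity computation is then plain
matrix algebra over community presence/abundance matrices.  Dense is the
right trade-off here: airway OTU tables have a few hundred to a few
thousand taxa, so the incidence matrix is small.
"""

from __future__ import annotations

import numpy as np
from skbio import TreeNode

__all__ = ["TreeIndex"]


class TreeIndex:
    """Precomputed per-edge tip incidence for a rooted tree.

    Parameters
    ----------
    tree : skbio.TreeNode
        Rooted tree; every edge except the root's (nonexistent) edge is
        indexed.  Missing branch lengths are treated as zero.
    taxa : sequence of str, optional
        Column ordering for the incidence matrix.  Defaults to the
        tree's tip names in postorder.  Must be a subset-free match of
        the tip set when provided.
    """

    def __init__(self, tree: TreeNode, taxa=None):
        tips = [t.name for t in tree.tips()]
        if len(set(tips)) != len(tips):
            raise ValueError("tree tip labels are not unique")
        if taxa is None:
            taxa = sorted(tips)
        missing = set(taxa) - set(tips)
        if missing:
            raise ValueError(f"taxa absent from tree: {sorted(missing)[:5]}")
        self.taxa = list(taxa)
        self._col = {name: j for j, name in enumerate(self.taxa)}
        keep = set(self.taxa)

        rows: list[np.ndarray] = []
        lengths: list[float] = []
        below: dict[int, np.ndarray] = {}
        n = len(self.taxa)
        for node in tree.postorder(include_self=True):
            if node.is_tip():
                vec = np.zeros(n, dtype=bool)
                if node.name in keep:
                    vec[self._col[node.name]] = True
                below[id(node)] = vec
            else:
                vec = np.zeros(n, dtype=bool)
                for child in node.children:
                    vec |= below[id(child)]
                below[id(node)] = vec
            if node.parent is not None:
                rows.append(vec)
                lengths.append(float(node.length or 0.0))

        self.incidence = np.array(rows, dtype=bool)       # edges x taxa
        self.lengths = np.array(lengths, dtype=float)     # edges
        self.total_branch_length = float(self.lengths.sum())

    # ------------------------------------------------------------------

    def edge_presence(self, presence: np.ndarray) -> np.ndarray:
        """Map sample x taxa presence to sample x edge presence (an edge
        is 'present' when any tip below it is present)."""
        presence = np.asarray(presence, dtype=bool)
        return presence @ self.incidence.T

    def faith_pd(self, presence: np.ndarray) -> np.ndarray:
        """Root-inclusive Faith PD for each row of a presence matrix.

        An edge contributes its length whenever at least one tip below
        it is present, which makes PD the length of the minimal subtree
        connecting the present tips *and the root*.
        """
        presence = np.atleast_2d(np.asarray(presence, dtype=bool))
        if presence.shape[1] != len(self.taxa):
            raise ValueError("presence matrix has wrong number of taxa")
        return self.edge_presence(presence).astype(float) @ self.lengths

    def faith_pd_set(self, present_taxa) -> float:
        """Faith PD of a single taxon set (convenience wrapper)."""
        present_taxa = list(present_taxa)
        if not present_taxa:
            raise ValueError("present_taxa is empty")
        vec = np.zeros(len(self.taxa), dtype=bool)
        for name in present_taxa:
            if name not in self._col:
                raise KeyError(f"unknown taxon {name!r}")
            vec[self._col[name]] = True
        return float(self.faith_pd(vec)[0])

    def edge_proportions(self, abundance: np.ndarray) -> np.ndarray:
        """Per-edge relative abundance (sum of tip proportions below the
        edge) for each row of a sample x taxa abundance matrix."""
        abundance = np.asarray(abundance, dtype=float)
        totals = abundance.sum(axis=1, keepdims=True)
        if (totals == 0).any():
            raise ValueError("sample with zero total abundance")
        return (abundance / totals) @ self.incidence.T

    def tip_root_depths(self) -> np.ndarray:
        """Root-to-tip path length for every indexed taxon (the weighted
        UniFrac normalizer weights)."""
        # each edge on the path from tip j to root has incidence[e, j] = True
        return self.incidence.T.astype(float) @ self.lengths

    def unweighted_unifrac(self, presence: np.ndarray) -> np.ndarray:
        """Pairwise unweighted UniFrac over the rows of a presence matrix:
        unique branch length / total covered branch length per pair."""
        ep = self.edge_presence(np.asarray(presence, dtype=bool)).astype(float)
        weighted = ep * self.lengths
        shared = weighted @ ep.T                 # length on edges present in both
        own = weighted.sum(axis=1)               # length on edges present in each
        either = own[:, None] + own[None, :] - shared
        unique = either - shared
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.where(either > 0, unique / either, 0.0)
        np.fill_diagonal(d, 0.0)
        return d

    def weighted_unifrac_normalized(self, abundance: np.ndarray) -> np.ndarray:
        """Pairwise normalized weighted UniFrac:
        sum_e b_e |p_A(e) - p_B(e)|  /  sum_j d_j (p_Aj + p_Bj)."""
        abundance = np.asarray(abundance, dtype=float)
        props = self.edge_proportions(abundance)
        tip_props = abundance / abundance.sum(axis=1, keepdims=True)
        depth_mass = tip_props @ self.tip_root_depths()   # sum_j d_j p_j per sample
        n = props.shape[0]
        num = np.zeros((n, n))
        for i in range(n):
            diff = np.abs(props[i] - props[i + 1:])       # (n-i-1) x edges
            if diff.size:
                num[i, i + 1:] = diff @ self.lengths
        num += num.T
        denom = depth_mass[:, None] + depth_mass[None, :]
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.where(denom > 0, num / denom, 0.0)
        np.fill_diagonal(d, 0.0)
        return d
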