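"""Distance, neighbor-joining tree and PCA over genotype matrices.

The distance between accessions is one minus the simple matching
coefficient (fraction of comparable markers with identical calls). Trees
are built with canonical Saitou-Nei neighbor joining using the
Studier-Keppler Q-criterion, with deterministic tie-breaking and negative
branch lengths clamped to zero. Simple-matching distances need not satisfy
the triangle inequality and the algorithm does not assume it.

Trees are held as :class:`skbio.TreeNode` (parent links, newick IO); the
joining algorithm itself is implemented here.
"""

from __future__ import annotations

import logging
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode
from sklearn.decomposition import PCA

from .codec import GenotypeMatrix, homology_counts

logger = logging.getLogger(__name__)

__all__ = [
    "simple_matching_distance",
    "nj_tree",
    "to_newick",
    "from_newick",
    "pca_coordinates",
    "export_structure",
    "write_distance_csv",
]


def simple_matching_distance(
    m: GenotypeMatrix, missing_policy: str = "exclude"
) -> DistanceMatrix:
    """Pairwise d(i,j) = 1 - (matching markers)/(compared markers).

    Markers with a missing call in either profile are excluded under the
    default policy; a pair with zero comparable markers is an error naming
    the pair.
    """
    if len(m.profiles) < 2:
        raise ValueError("need at least 2 accessions for a distance matrix")
    n = len(m.profiles)
    d = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        p1, p2 = m.profiles[i], m.profiles[j]
        matches, compared = homology_counts(p1, p2, missing_policy)
        if compared == 0:
            raise ValueError(
                f"no comparable markers between {p1.accession_id} and {p2.accession_id}"
            )
        d[i, j] = d[j, i] = 1.0 - matches / compared
    return DistanceMatrix(d, m.accession_ids)


def _clade_key(node: TreeNode) -> str:
    """Lexicographically smallest leaf label under a node (tie-break key)."""
    if node.is_tip():
        return node.name
    return min(t.name for t in node.tips())


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Canonical Saitou-Nei neighbor joining.

    Uses the Studier-Keppler criterion Q(i,j) = (r-2) d(i,j) - R_i - R_j,
    joining the pair with minimal Q; among exact ties the pair whose sorted
    clade labels are lexicographically smallest is joined. Limb lengths
    that come out negative are clamped to 0 and the deficit is logged. The
    result is the standard unrooted NJ topology, returned with a trifurcating
    root for n >= 3 leaves.
    """
    labels = list(dm.ids)
    n = len(labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    D = dm.data.astype(float).copy()
    if not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("distance matrix is not symmetric")

    nodes: list[TreeNode] = [TreeNode(name=lab) for lab in labels]
    keys = [_clade_key(nd) for nd in nodes]
    active = list(range(n))

    def set_length(node: TreeNode, length: float, context: str) -> None:
        if length < 0:
            logger.info("clamping negative branch length %.6g at %s", length, context)
            length = 0.0
        node.length = float(length)

    while len(active) > 3:
        r = len(active)
        idx = np.array(active)
        sub = D[np.ix_(idx, idx)]
        R = sub.sum(axis=1)
        Q = (r - 2) * sub - R[:, None] - R[None, :]
        np.fill_diagonal(Q, np.inf)
        # Q[a,b] and Q[b,a] may differ in the last ulp (broadcast summation
        # order), so collect candidates from both triangles and normalize
        qmin = Q.min()
        ties = sorted({(min(a, b), max(a, b)) for a, b in np.argwhere(Q == qmin)})
        a, b = min(ties, key=lambda p: tuple(sorted((keys[idx[p[0]]], keys[idx[p[1]]]))))
        i, j = idx[a], idx[b]
        dij = D[i, j]
        li = 0.5 * dij + (R[a] - R[b]) / (2 * (r - 2))
        lj = dij - li
        parent = TreeNode()
        set_length(nodes[i], li, f"join({keys[i]},{keys[j]})")
        set_length(nodes[j], lj, f"join({keys[i]},{keys[j]})")
        parent.extend([nodes[i], nodes[j]])
        # distances from the new node to every other active node
        new_row = np.zeros(D.shape[0])
        for k in active:
            if k in (i, j):
                continue
            new_row[k] = 0.5 * (D[i, k] + D[j, k] - dij)
        D = np.vstack([D, new_row])
        new_col = np.append(new_row, 0.0)
        D = np.column_stack([D, new_col])
        nodes.append(parent)
        keys.append(min(keys[i], keys[j]))
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]

    # terminal 3-node star: closed-form limb lengths
    i, j, k = active
    vi = 0.5 * (D[i, j] + D[i, k] - D[j, k])
    vj = 0.5 * (D[i, j] + D[j, k] - D[i, k])
    vk = 0.5 * (D[i, k] + D[j, k] - D[i, j])
    root = TreeNode()
    order = sorted([(keys[i], i, vi), (keys[j], j, vj), (keys[k], k, vk)])
    for key, m_, v in order:
        set_length(nodes[m_], v, f"star({key})")
        root.append(nodes[m_])
    root.length = None
    return root


def _newick_node(node: TreeNode, fmt: str) -> str:
    if node.is_tip():
        label = node.name or ""
    else:
        inner = ",".join(_newick_node(c, fmt) for c in node.children)
        label = f"({inner})" + (node.name or "")
    if node.length is not None:
        label += ":" + (fmt % node.length)
    return label


def to_newick(tree: TreeNode, fmt: str = "%.6g") -> str:
    """Serialize a tree to newick with branch lengths (6 significant digits)."""
    return _newick_node(tree, fmt) + ";"


def from_newick(s: str) -> TreeNode:
    """Parse a newick string back into a tree."""
    return TreeNode.read([s])


def write_distance_csv(dm: DistanceMatrix, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids)).to_csv(path)
    return path


_PCA_CODE = {"a": 0.0, "b": 1.0, "h": 0.5}


def genotype_design_matrix(m: GenotypeMatrix) -> pd.DataFrame:
    """Numeric accession x marker matrix: a=0, b=1, h=0.5, '-' mean-imputed."""
    X = np.empty((len(m.profiles), len(m.marker_ids)))
    for i, p in enumerate(m.profiles):
        X[i] = [_PCA_CODE.get(c, np.nan) for c in p.calls]
    col_mean = np.nanmean(X, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    nan_r, nan_c = np.nonzero(np.isnan(X))
    X[nan_r, nan_c] = col_mean[nan_c]
    return pd.DataFrame(X, index=m.accession_ids, columns=m.marker_ids)


def pca_coordinates(
    m: GenotypeMatrix, n_components: int = 2
) -> tuple[pd.DataFrame, np.ndarray]:
    """Principal-component coordinates of accessions from the 0/1 genotype matrix.

    Columns are centered; the sign of each component is fixed so that its
    largest-magnitude marker loading is positive. Returns (coordinates
    indexed by accession with columns PC1..PCk, explained-variance
    fractions).
    """
    if n_components > len(m.profiles):
        raise ValueError(
            f"{n_components} components requested for {len(m.profiles)} accessions"
        )
    X = genotype_design_matrix(m).to_numpy()
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(X)
    for k in range(n_components):
        load = pca.components_[k]
        if load[np.argmax(np.abs(load))] < 0:
            coords[:, k] *= -1
    cols = [f"PC{k + 1}" for k in range(n_components)]
    return (
        pd.DataFrame(coords, index=m.accession_ids, columns=cols),
        pca.explained_variance_ratio_.copy(),
    )


_STRUCTURE_ALLELES = {"a": (1, 1), "b": (2, 2), "h": (1, 2), "-": (-9, -9)}


def export_structure(m: GenotypeMatrix, path: str | Path) -> Path:
    """Write the matrix in STRUCTURE format: two integer rows per accession.

    Reference-like calls are allele 1, variant calls allele 2, heterozygous
    1/2, missing -9.
    """
    path = Path(path)
    with open(path, "w") as fh:
        for p in m.profiles:
            pairs = [_STRUCTURE_ALLELES[c] for c in p.calls]
            for row in range(2):
                fields = [p.accession_id] + [str(pair[row]) for pair in pairs]
                fh.write("\t".join(fields) + "\n")
    return path
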