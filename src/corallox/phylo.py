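"""All-pairs identity matrices and neighbor-joining identity trees.

The curation workflow summarises a sequence panel as a symmetric matrix
of pairwise percent identities (global alignment, all-columns
denominator) and a neighbor-joining tree built on the linear distance
``d = 100 - identity``.  Trees are scikit-bio ``TreeNode`` objects, so
standard Newick reading/writing and tip-distance utilities apply.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from skbio import TreeNode

from .anchormap import AlignParams, DEFAULT_ALIGN_PARAMS, global_align
from .errors import ContractError, FormatError
from .seqio import ProteinCandidate


@dataclass
class IdentityMatrix:
    """Symmetric percent-identity matrix with a fixed label order."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise ContractError("duplicate labels in identity matrix")
        if self.values.shape != (n, n):
            raise ContractError("matrix shape does not match label count")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ContractError("identity matrix must be symmetric")
        if np.any(self.values < -1e-9) or np.any(self.values > 100 + 1e-9):
            raise ContractError("identities must lie in [0, 100]")

    def distance_matrix(self) -> np.ndarray:
        """Linear distance transform d = 100 - identity, zero diagonal."""
        d = 100.0 - self.values
        np.fill_diagonal(d, 0.0)
        return d

    def off_diagonal_range(self) -> tuple[float, float]:
        mask = ~np.eye(len(self.labels), dtype=bool)
        vals = self.values[mask]
        return float(vals.min()), float(vals.max())

    def to_tsv(self, path) -> None:
        """PHYLIP-like square TSV: label column + one column per label."""
        with open(path, "w") as fh:
            fh.write("label\t" + "\t".join(self.labels) + "\n")
            for lab, row in zip(self.labels, self.values):
                fh.write(lab + "\t" + "\t".join(f"{v:.4f}" for v in row) + "\n")


def identity_matrix(
    proteins: Sequence[ProteinCandidate],
    params: AlignParams = DEFAULT_ALIGN_PARAMS,
    labels: Sequence[str] | None = None,
) -> IdentityMatrix:
    """Percent identity for every pair under global alignment.

    Each pair is aligned once; the matrix is symmetric by construction.
    """
    if len(proteins) < 2:
        raise ContractError("need at least 2 sequences for an identity matrix")
    labs = list(labels) if labels is not None else [p.parent_id for p in proteins]
    if len(set(labs)) != len(labs):
        raise ContractError("duplicate sequence ids")
    n = len(proteins)
    values = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            pid = global_align(proteins[i], proteins[j], params).identity_pct
            values[i, j] = values[j, i] = pid
    return IdentityMatrix(labs, values)


def nj_tree(matrix: IdentityMatrix) -> TreeNode:
    """Neighbor joining on d = 100 - identity.

    Standard Q-criterion agglomeration with a deterministic tie-break
    (lowest label-index pair) and negative branch lengths clamped to
    zero.  On an additive distance matrix the generating topology and
    branch lengths are recovered exactly.  The returned tree is unrooted
    (trifurcating root node).
    """
    n = len(matrix.labels)
    if n < 3:
        raise ContractError("neighbor joining requires at least 3 labels")
    d = matrix.distance_matrix().astype(float)
    nodes: list[TreeNode] = [TreeNode(name=lab) for lab in matrix.labels]
    active = list(range(n))

    def clamp(x: float) -> float:
        return x if x > 0 else 0.0

    while len(active) > 3:
        m = len(active)
        r = {i: sum(d[i, k] for k in active if k != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * d[i, j] - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        parent = TreeNode()
        nodes[i].length = clamp(li)
        nodes[j].length = clamp(lj)
        parent.extend([nodes[i], nodes[j]])
        # distances from the new node to every other active node
        new_row = np.zeros(d.shape[0])
        for k in active:
            if k in (i, j):
                continue
            new_row[k] = 0.5 * (d[i, k] + d[j, k] - d[i, j])
        d = np.vstack([d, new_row[None, :]])
        col = np.append(new_row, 0.0)
        d = np.hstack([d, col[:, None]])
        nodes.append(parent)
        active = [k for k in active if k not in (i, j)] + [d.shape[0] - 1]

    i, j, k = active
    root = TreeNode()
    nodes[i].length = clamp(0.5 * (d[i, j] + d[i, k] - d[j, k]))
    nodes[j].length = clamp(0.5 * (d[i, j] + d[j, k] - d[i, k]))
    nodes[k].length = clamp(0.5 * (d[i, k] + d[j, k] - d[i, j]))
    root.extend([nodes[i], nodes[j], nodes[k]])
    return root


def write_newick(tree: TreeNode) -> str:
    """Serialise a tree to a single-line Newick string with branch lengths."""
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()


def read_newick(newick: str) -> TreeNode:
    """Parse a Newick string; malformed input raises a parse error."""
    import warnings

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # sniffer warns before the parse error
            return TreeNode.read(io.StringIO(newick), format="newick")
    except Exception as exc:
        raise FormatError(f"invalid Newick string ({exc})") from exc


def tip_distance_matrix(tree: TreeNode, labels: Sequence[str]) -> np.ndarray:
    """Patristic (leaf-to-leaf path length) matrix in the given label order."""
    dm = tree.tip_tip_distances()
    idx = [list(dm.ids).index(lab) for lab in labels]
    return np.asarray(dm.data)[np.ix_(idx, idx)]
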