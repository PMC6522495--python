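"""Module detection: average-linkage clustering, static tree cut, summaries.

Genes are clustered on a network dissimilarity (typically ``1 - TOM``) with
average linkage, the dendrogram is cut at a fixed fraction of its maximum
merge height, and the resulting subtrees become color-labelled modules.
Candidate modules smaller than ``min_module_size`` are relabelled ``grey``
(unassigned).  Colors are assigned largest-first from the conventional
palette, so the biggest module is always ``turquoise``.

The linkage is implemented directly (Lance-Williams update) so that ties are
broken deterministically by the lowest pair index; scipy's linkage serves as
an independent cross-check in the test-suite, never as the implementation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression_io import ExpressionMatrix, log2_standardize

GREY = "grey"

#: Conventional module color palette, assigned by decreasing module size.
PALETTE = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue",
)


@dataclass
class Dendrogram:
    """Merge history of an agglomerative clustering.

    ``merges[s] = (a, b)`` joins clusters ``a`` and ``b`` at ``heights[s]``;
    leaves are ``0 .. n-1`` and the cluster formed at step ``s`` has id
    ``n + s`` (the scipy convention).
    """

    n_leaves: int
    merges: np.ndarray
    heights: np.ndarray
    gene_ids: list[str] | None = field(default=None)

    def __post_init__(self) -> None:
        self.merges = np.asarray(self.merges, dtype=int)
        self.heights = np.asarray(self.heights, dtype=float)
        if self.merges.shape != (self.n_leaves - 1, 2):
            raise ValueError("need exactly n-1 merges for n leaves")
        if np.any(np.diff(self.heights) < -1e-12):
            raise ValueError("merge heights must be nondecreasing")

    @property
    def leaf_order(self) -> np.ndarray:
        """Left-to-right leaf permutation of the tree."""
        children = {
            self.n_leaves + s: tuple(pair) for s, pair in enumerate(self.merges)
        }
        order: list[int] = []
        stack = [self.n_leaves + len(self.merges) - 1] if len(self.merges) else [0]
        while stack:
            node = stack.pop()
            if node < self.n_leaves:
                order.append(node)
            else:
                left, right = children[node]
                stack.append(right)
                stack.append(left)
        return np.asarray(order, dtype=int)


@dataclass
class ModuleAssignment:
    """Partition of genes into color-labelled modules plus ``grey``."""

    gene_ids: list[str]
    labels: list[str]
    module_sizes: dict[str, int] = field(default=None)

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.gene_ids):
            raise ValueError("one label per gene required")
        sizes: dict[str, int] = {}
        for lab in self.labels:
            sizes[lab] = sizes.get(lab, 0) + 1
        if self.module_sizes is None:
            self.module_sizes = sizes
        elif self.module_sizes != sizes:
            raise ValueError("module_sizes inconsistent with labels")

    def genes_in(self, color: str) -> list[str]:
        return [g for g, lab in zip(self.gene_ids, self.labels) if lab == color]

    @property
    def colors(self) -> list[str]:
        """Non-grey module colors, by decreasing size."""
        return sorted(
            (c for c in self.module_sizes if c != GREY),
            key=lambda c: (-self.module_sizes[c], c),
        )


def hierarchical_cluster(
    d: np.ndarray, linkage: str = "average", gene_ids: list[str] | None = None
) -> Dendrogram:
    """Average-linkage dendrogram of a symmetric dissimilarity matrix.

    Ties in the minimum inter-cluster dissimilarity are broken by the lowest
    (row, column) pair index, making the merge order fully deterministic.
    """
    if linkage != "average":
        raise ValueError("only average linkage is supported")
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("dissimilarity must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("dissimilarity must be symmetric")
    if np.any(d < 0):
        raise ValueError("negative dissimilarities")
    if not np.allclose(np.diag(d), 0.0, atol=1e-10):
        raise ValueError("dissimilarity diagonal must be 0")
    n = d.shape[0]
    if n < 2:
        raise ValueError("need at least 2 items")
    cur = d.copy()
    np.fill_diagonal(cur, np.inf)
    size = np.ones(n)
    ids = np.arange(n)
    active = np.ones(n, dtype=bool)
    merges = np.empty((n - 1, 2), dtype=int)
    heights = np.empty(n - 1)
    for step in range(n - 1):
        flat = int(np.argmin(cur))  # row-major argmin = lowest pair index on ties
        i, j = divmod(flat, n)
        if i > j:
            i, j = j, i
        heights[step] = cur[i, j]
        merges[step] = (ids[i], ids[j])
        # Lance-Williams average-linkage update, merged cluster kept in slot i
        new = (size[i] * cur[i] + size[j] * cur[j]) / (size[i] + size[j])
        cur[i, :] = new
        cur[:, i] = new
        cur[i, i] = np.inf
        cur[j, :] = np.inf
        cur[:, j] = np.inf
        active[j] = False
        size[i] += size[j]
        ids[i] = n + step
    # guard against fp jitter breaking monotonicity of average linkage
    heights = np.maximum.accumulate(heights)
    return Dendrogram(n, merges, heights, gene_ids)


def tree_cut(
    dend: Dendrogram, cut_height: float = 0.98, min_module_size: int = 30
) -> ModuleAssignment:
    """Static tree cut at ``cut_height x max merge height``.

    Merges at or below the cut form candidate modules; candidates smaller
    than ``min_module_size`` become ``grey``.  Surviving modules are colored
    by decreasing size from the standard palette.
    """
    if not 0 < cut_height <= 1:
        raise ValueError("cut_height must be in (0, 1]")
    if min_module_size < 1:
        raise ValueError("min_module_size must be >= 1")
    n = dend.n_leaves
    gene_ids = dend.gene_ids if dend.gene_ids is not None else [f"g{i}" for i in range(n)]
    cut_value = cut_height * dend.heights.max()
    parent = np.arange(2 * n - 1)

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for step, (a, b) in enumerate(dend.merges):
        if dend.heights[step] <= cut_value:
            node = n + step
            parent[find(a)] = node
            parent[find(b)] = node
    roots = [find(i) for i in range(n)]
    clusters: dict[int, list[int]] = {}
    for leaf, root in enumerate(roots):
        clusters.setdefault(root, []).append(leaf)
    surviving = [
        members for members in clusters.values() if len(members) >= min_module_size
    ]
    # largest first; ties broken by the smallest member index for determinism
    surviving.sort(key=lambda mem: (-len(mem), min(mem)))
    labels = [GREY] * n
    for rank, members in enumerate(surviving):
        color = PALETTE[rank] if rank < len(PALETTE) else f"module{rank + 1}"
        for leaf in members:
            labels[leaf] = color
    return ModuleAssignment(list(gene_ids), labels)


@dataclass
class ModuleSummary:
    color: str
    size: int
    eigengene: np.ndarray  # per-sample first-PC profile, unit norm
    stage_profile: pd.Series  # mean expression per stage over module genes
    singleton: bool = False


def module_summary(
    assign: ModuleAssignment, m: ExpressionMatrix
) -> dict[str, ModuleSummary]:
    """Eigengene and mean stage profile for every non-grey module.

    The eigengene is the first right-singular vector of the module's z-scored
    submatrix, oriented so the mean correlation of module genes with it is
    positive.  Size-1 modules are flagged; their eigengene is the gene's own
    z-profile.
    """
    unknown = set(assign.gene_ids) - set(m.gene_ids)
    if unknown:
        raise KeyError(f"assignment genes missing from matrix: {sorted(unknown)[:5]}")
    z = log2_standardize(m, mode="zscore")
    stage_means = m.stage_means()
    out: dict[str, ModuleSummary] = {}
    for color in assign.colors:
        genes = assign.genes_in(color)
        sub = z.subset_genes(genes).values
        if len(genes) == 1:
            eig = sub[0] / np.linalg.norm(sub[0])
            out[color] = ModuleSummary(
                color, 1, eig, stage_means.loc[genes].mean(axis=0), singleton=True
            )
            continue
        _, _, vt = np.linalg.svd(sub, full_matrices=False)
        eig = vt[0]
        if (sub @ eig).mean() < 0:
            eig = -eig
        out[color] = ModuleSummary(
            color, len(genes), eig, stage_means.loc[genes].mean(axis=0)
        )
    return out
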