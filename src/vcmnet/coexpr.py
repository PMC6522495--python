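"""Weighted unsigned co-expression network construction.

The network is built in the classic weighted-network style: Pearson
correlations between gene expression profiles, a soft-threshold power
``beta`` chosen so the connectivity distribution approximates scale-free
topology, the unsigned power adjacency ``a(i, j) = |cor(x_i, x_j)|**beta``,
the topological overlap similarity, and the ``1 - similarity`` dissimilarity
used for clustering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: Candidate soft-threshold powers scanned by default (includes the commonly
#: selected beta = 9 for maturation-stage cardiomyocyte arrays).
DEFAULT_BETA_GRID = (1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 12, 14, 16, 18, 20)

_SYM_TOL = 1e-10


def _check_square_symmetric(x: np.ndarray, what: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[0] != x.shape[1]:
        raise ValueError(f"{what} must be square, got shape {x.shape}")
    if not np.allclose(x, x.T, atol=_SYM_TOL):
        raise ValueError(f"{what} must be symmetric")
    return x


@dataclass
class AdjacencyMatrix:
    """Unsigned power adjacency ``A = |cor|**beta`` with unit diagonal."""

    gene_ids: list[str]
    A: np.ndarray
    beta: float

    def __post_init__(self) -> None:
        self.A = _check_square_symmetric(self.A, "adjacency")
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if not np.allclose(np.diag(self.A), 1.0, atol=_SYM_TOL):
            raise ValueError("adjacency diagonal must be 1")
        if self.A.min() < -_SYM_TOL or self.A.max() > 1 + _SYM_TOL:
            raise ValueError("adjacency entries must lie in [0, 1]")
        if len(self.gene_ids) != self.A.shape[0]:
            raise ValueError("gene_ids length does not match matrix")


@dataclass
class TOMMatrix:
    """Topological overlap similarity, unit diagonal, entries in [0, 1]."""

    gene_ids: list[str]
    T: np.ndarray

    def __post_init__(self) -> None:
        self.T = _check_square_symmetric(self.T, "TOM")
        if not np.allclose(np.diag(self.T), 1.0, atol=_SYM_TOL):
            raise ValueError("TOM diagonal must be 1")
        if self.T.min() < -_SYM_TOL or self.T.max() > 1 + _SYM_TOL:
            raise ValueError("TOM entries must lie in [0, 1]")


@dataclass
class ScaleFreeFitTable:
    """Per-beta scale-free fit diagnostics and the selected power.

    ``table`` has one row per candidate beta with columns ``beta``, ``r2``
    (signed fit: forced to 0 when the log-log slope is positive), ``slope``
    and ``mean_connectivity``.
    """

    table: pd.DataFrame
    selected_beta: float


def pairwise_correlation(m) -> np.ndarray:
    """Pearson correlation matrix between gene expression profiles.

    Requires at least 3 samples and nonzero variance for every gene.
    """
    values = np.asarray(m.values, dtype=float)
    if values.shape[1] < 3:
        raise ValueError("need at least 3 samples for correlations")
    sd = values.std(axis=1)
    if np.any(sd == 0):
        raise ValueError("zero-variance gene in correlation input")
    corr = np.corrcoef(values)
    corr = np.clip(corr, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return corr


def adjacency(corr: np.ndarray, beta: float, gene_ids: list[str] | None = None) -> AdjacencyMatrix:
    """Unsigned power adjacency ``|corr| ** beta``."""
    corr = _check_square_symmetric(corr, "correlation")
    if not np.allclose(np.diag(corr), 1.0, atol=_SYM_TOL):
        raise ValueError("correlation diagonal must be 1")
    if beta <= 0:
        raise ValueError("beta must be positive")
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(corr.shape[0])]
    A = np.abs(corr) ** float(beta)
    np.fill_diagonal(A, 1.0)
    return AdjacencyMatrix(list(gene_ids), A, float(beta))


def _scale_free_fit(k: np.ndarray, n_bins: int) -> tuple[float, float]:
    """(r2, slope) of log10(frequency) on log10(mean k) over equal-width bins."""
    if np.ptp(k) == 0:
        raise ValueError("all connectivities identical: degenerate binning")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    log_k, log_freq = [], []
    for b in range(n_bins):
        members = k[which == b]
        if members.size == 0:
            continue  # empty bins dropped
        mean_k = members.mean()
        if mean_k <= 0:
            continue
        log_k.append(np.log10(mean_k))
        log_freq.append(np.log10(members.size))
    if len(log_k) < 3:
        raise ValueError("too few populated bins for a scale-free fit")
    fit = stats.linregress(log_k, log_freq)
    r2 = 0.0 if fit.slope > 0 else float(fit.rvalue**2)
    return r2, float(fit.slope)


def soft_threshold_scan(
    corr: np.ndarray,
    beta_candidates=DEFAULT_BETA_GRID,
    n_bins: int = 10,
    r2_target: float = 0.80,
) -> ScaleFreeFitTable:
    """Scan soft-threshold powers for approximate scale-free topology.

    For each candidate beta the whole-network connectivity
    ``k_i = sum_{j != i} a(i, j)`` is binned (equal-width, empty bins dropped)
    and log10(frequency) is regressed on log10(mean k per bin).  The selected
    power is the smallest beta reaching ``r2_target``, or the argmax of R2 if
    none does.
    """
    beta_candidates = list(beta_candidates)
    if not beta_candidates:
        raise ValueError("empty beta candidate list")
    if any(b <= 0 for b in beta_candidates):
        raise ValueError("beta candidates must be positive")
    if sorted(beta_candidates) != beta_candidates:
        raise ValueError("beta candidates must be sorted ascending")
    corr = _check_square_symmetric(corr, "correlation")
    if corr.shape[0] < 20:
        raise ValueError("need at least 20 genes for a meaningful scan")
    rows = []
    for beta in beta_candidates:
        A = np.abs(corr) ** float(beta)
        np.fill_diagonal(A, 0.0)
        k = A.sum(axis=1)
        r2, slope = _scale_free_fit(k, n_bins)
        rows.append(
            {"beta": beta, "r2": r2, "slope": slope, "mean_connectivity": k.mean()}
        )
    table = pd.DataFrame(rows)
    passing = table[table["r2"] >= r2_target]
    if len(passing):
        selected = float(passing["beta"].iloc[0])
    else:
        selected = float(table.loc[table["r2"].idxmax(), "beta"])
    return ScaleFreeFitTable(table, selected)


def topological_overlap(adj: AdjacencyMatrix) -> TOMMatrix:
    """Unsigned topological overlap of a power adjacency.

    ``T(i, j) = (L(i, j) + a(i, j)) / (min(k_i, k_j) + 1 - a(i, j))`` with
    ``L(i, j) = sum_{u not in {i, j}} a(i, u) a(u, j)`` and
    ``k_i = sum_{u != i} a(i, u)``; ``T(i, i) = 1``.
    """
    A0 = adj.A.copy()
    np.fill_diagonal(A0, 0.0)
    k = A0.sum(axis=1)
    L = A0 @ A0  # zero diagonal of A0 excludes u in {i, j} automatically
    denom = np.minimum.outer(k, k) + 1.0 - A0
    T = (L + A0) / denom
    np.fill_diagonal(T, 1.0)
    T = np.clip((T + T.T) / 2.0, 0.0, 1.0)
    return TOMMatrix(list(adj.gene_ids), T)


def dissimilarity(adj_or_tom, mode: str = "one_minus_tom") -> np.ndarray:
    """Clustering dissimilarity ``1 - similarity`` with zero diagonal."""
    if mode == "one_minus_adjacency":
        if not isinstance(adj_or_tom, AdjacencyMatrix):
            raise TypeError("mode one_minus_adjacency needs an AdjacencyMatrix")
        sim = adj_or_tom.A
    elif mode == "one_minus_tom":
        if not isinstance(adj_or_tom, TOMMatrix):
            raise TypeError("mode one_minus_tom needs a TOMMatrix")
        sim = adj_or_tom.T
    else:
        raise ValueError(f"unknown dissimilarity mode {mode!r}")
    d = 1.0 - sim
    np.fill_diagonal(d, 0.0)
    return d
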