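"""PCA over genes, loading-based gene ranking, and over-representation tests.

Genes are treated as observations and samples as variables, so every gene
gets a weight (loading) on each principal component and "the top k genes by
weight on component c" is well defined.  Module membership among top-ranked
genes is tested with a one-degree-of-freedom Pearson chi-square against the
in-module count expected under random sampling from the background; generic
annotation enrichment uses the hypergeometric upper tail (or resampling)
with Bonferroni correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .expression_io import ExpressionMatrix
from .modules import GREY, ModuleAssignment


@dataclass
class PCAResult:
    """Gene-wise PCA: orthonormal loadings (genes x components)."""

    gene_ids: list[str]
    loadings: np.ndarray
    variance_fraction: np.ndarray

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


@dataclass
class EnrichmentResult:
    """Module over-representation among a ranked gene set (1-df chi-square)."""

    module: str
    n_top: int
    observed: int
    expected: float
    chi2: float
    p_value: float


def pca(m: ExpressionMatrix) -> PCAResult:
    """Centered PCA with genes as observations.

    Sign convention: the largest-magnitude weight of each component is made
    positive, so loadings are deterministic.
    """
    if m.n_genes < 2 or m.n_samples < 2:
        raise ValueError("need at least 2 genes and 2 samples")
    x = m.values - m.values.mean(axis=0, keepdims=True)
    if np.allclose(x, 0):
        raise ValueError("degenerate matrix: all genes identical")
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    for c in range(u.shape[1]):
        pivot = int(np.argmax(np.abs(u[:, c])))
        if u[pivot, c] < 0:
            u[:, c] = -u[:, c]
    var = s**2
    return PCAResult(list(m.gene_ids), u, var / var.sum())


def top_loading_genes(p: PCAResult, component: int, k: int) -> list[str]:
    """The ``k`` genes with the largest |loading| on a 1-based component.

    Ties are broken by lexicographic gene id.
    """
    if not 1 <= component <= p.n_components:
        raise ValueError(f"component {component} out of range 1..{p.n_components}")
    if not 1 <= k <= len(p.gene_ids):
        raise ValueError(f"k={k} out of range 1..{len(p.gene_ids)}")
    weights = np.abs(p.loadings[:, component - 1])
    order = sorted(range(len(p.gene_ids)), key=lambda i: (-weights[i], p.gene_ids[i]))
    return [p.gene_ids[i] for i in order[:k]]


def overrepresentation_chi2(observed: int, expected: float, n: int) -> tuple[float, float]:
    """1-df Pearson chi-square for an observed vs expected in-set count.

    ``chi2 = (obs - exp)^2 / exp + ((n - obs) - (n - exp))^2 / (n - exp)``
    with the p-value from the chi-square upper tail at one degree of freedom.
    """
    if not 0 <= observed <= n:
        raise ValueError("observed count outside [0, n]")
    if expected <= 0 or expected >= n:
        raise ValueError("expected count must lie strictly inside (0, n)")
    chi2 = (observed - expected) ** 2 / expected + (
        (n - observed) - (n - expected)
    ) ** 2 / (n - expected)
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def module_overrepresentation(
    top: list[str],
    assign: ModuleAssignment,
    module: str,
    background: str = "all_genes",
) -> EnrichmentResult:
    """Chi-square over-representation of a module among top-ranked genes.

    ``background`` is ``all_genes`` or ``assigned_genes`` (non-grey only);
    the expected in-module count is ``|top| * module_size / background_size``.
    """
    if module not in assign.module_sizes:
        raise KeyError(f"module {module!r} absent from assignment")
    gene_set = set(assign.gene_ids)
    stray = [g for g in top if g not in gene_set]
    if stray:
        raise KeyError(f"top genes missing from assignment: {stray[:5]}")
    if background == "all_genes":
        bg_size = len(assign.gene_ids)
    elif background == "assigned_genes":
        bg_size = sum(v for c, v in assign.module_sizes.items() if c != GREY)
    else:
        raise ValueError(f"unknown background {background!r}")
    module_genes = set(assign.genes_in(module))
    n = len(top)
    observed = len(module_genes.intersection(top))
    expected = n * assign.module_sizes[module] / bg_size
    chi2, p = overrepresentation_chi2(observed, expected, n)
    return EnrichmentResult(module, n, observed, expected, chi2, p)


def annotation_enrichment(
    test_set: set[str],
    term_map: pd.DataFrame,
    background: set[str],
    method: str = "hypergeometric",
    n_resamples: int = 10_000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-term over-representation of ``test_set`` against ``background``.

    ``term_map`` is a two-column gene/term frame.  The hypergeometric method
    uses the exact upper tail; ``resampling`` draws equally sized random gene
    sets from the background and reports the add-one Monte-Carlo p-value.
    Bonferroni correction is applied across terms; terms are flagged
    significant at corrected p < 0.05.
    """
    test_set = set(test_set)
    background = set(background)
    if not test_set <= background:
        raise ValueError("test set must be a subset of the background")
    terms = {
        term: set(group["gene"]) & background
        for term, group in term_map.groupby("term")
    }
    terms = {t: g for t, g in terms.items() if g}
    if not terms:
        raise ValueError("term map shares no genes with the background")
    if method not in ("hypergeometric", "resampling"):
        raise ValueError(f"unknown method {method!r}")
    if method == "resampling" and n_resamples < 100:
        raise ValueError("n_resamples must be >= 100")
    m_total = len(background)
    n_draw = len(test_set)
    rows = []
    if method == "resampling":
        rng = np.random.default_rng(seed)
        bg_list = sorted(background)
        draws = [
            set(rng.choice(bg_list, size=n_draw, replace=False))
            for _ in range(n_resamples)
        ]
    for term, genes in sorted(terms.items()):
        overlap = len(test_set & genes)
        if method == "hypergeometric":
            p = float(stats.hypergeom.sf(overlap - 1, m_total, len(genes), n_draw))
        else:
            hits = sum(len(draw & genes) >= overlap for draw in draws)
            p = (1 + hits) / (1 + n_resamples)
        rows.append({"term": term, "overlap": overlap, "term_size": len(genes), "p": p})
    out = pd.DataFrame(rows)
    out["p_bonferroni"] = np.minimum(1.0, out["p"] * len(out))
    out["significant"] = out["p_bonferroni"] < 0.05
    return out.sort_values(["p", "term"], kind="stable").reset_index(drop=True)
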