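"""The candidate filter cascade: module -> regulators -> remodelers -> DE -> window.

Mirrors the discovery funnel that narrows a co-expression module down to a
handful of chromatin-remodeler candidates: intersect the module gene list
with annotated transcriptional regulators, then chromatin remodelers, keep
genes differentially expressed in the immature-stage cells versus either
mature stage, and finally keep genes whose standardized expression in the
immature stage falls inside a closed window (default [0, +1]).  Each stage's
survivor count is reported so the funnel (e.g. 2659 -> 544 -> 97 -> 30 -> 13)
is auditable.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .expression_io import ExpressionMatrix, GeneSetCollection, log2_standardize

CASCADE_STAGES = ("module", "regulators", "remodelers", "de", "window")


def differential_expression(
    m: ExpressionMatrix,
    contrast: tuple[str, str],
    alpha: float = 0.05,
    min_abs_lfc: float = 1.0,
) -> pd.DataFrame:
    """Per-gene pooled-variance two-sample t-test between two stages.

    Works on log2 values and returns a frame indexed by gene with ``lfc``
    (mean(stage_a) - mean(stage_b)), ``t``, ``p``, BH-adjusted ``q`` and a
    ``significant`` flag requiring both q < alpha and |lfc| >= min_abs_lfc.
    The pooled (equal-variance) t is used rather than Welch: with 3
    replicates per stage the Satterthwaite degrees of freedom collapse
    toward 2 whenever the two sample variances differ by chance, which makes
    even thousand-fold changes test unstably; the shared-variance design of
    replicate arrays makes the pooled test the standard choice.  Genes with
    zero variance in both groups get t = 0, p = 1 when the means agree and
    p = 0 otherwise.
    """
    stage_a, stage_b = contrast
    cols_a = m.stage_columns(stage_a)
    cols_b = m.stage_columns(stage_b)
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("both stages need at least 2 replicate samples")
    a = m.values[:, cols_a]
    b = m.values[:, cols_b]
    lfc = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=True)
        degenerate = ~np.isfinite(t)
        t = np.where(degenerate, np.where(lfc == 0, 0.0, np.inf * np.sign(lfc)), t)
        p = np.where(degenerate, np.where(lfc == 0, 1.0, 0.0), p)
    q = multipletests(p, method="fdr_bh")[1]
    out = pd.DataFrame(
        {
            "lfc": lfc,
            "t": t,
            "p": p,
            "q": q,
            "significant": (q < alpha) & (np.abs(lfc) >= min_abs_lfc),
        },
        index=pd.Index(m.gene_ids, name="gene"),
    )
    out.attrs["contrast"] = contrast
    return out


def significant_union(de_tables: Iterable[pd.DataFrame]) -> set[str]:
    """Genes significant in at least one contrast."""
    union: set[str] = set()
    for table in de_tables:
        union |= set(table.index[table["significant"]])
    return union


def expression_window_filter(
    m: ExpressionMatrix, stage: str, window: tuple[float, float] = (0.0, 1.0)
) -> set[str]:
    """Genes whose mean per-gene z-score at ``stage`` lies in the closed window.

    z-scores are computed per gene across all samples (population sd);
    constant genes are rejected upstream by the z-scoring step.
    """
    low, high = window
    if not low < high:
        raise ValueError("window low must be below high")
    z = log2_standardize(m, mode="zscore")
    cols = z.stage_columns(stage)
    stage_z = z.values[:, cols].mean(axis=1)
    keep = (stage_z >= low) & (stage_z <= high)
    return {g for g, ok in zip(m.gene_ids, keep) if ok}


def filter_cascade(
    module_genes: Sequence[str],
    sets: GeneSetCollection,
    de_tables: Sequence[pd.DataFrame],
    window_genes: set[str],
    enabled_filters: Sequence[str] = ("regulators", "remodelers", "de", "window"),
    m: ExpressionMatrix | None = None,
    regulator_set: str = "transcriptional_regulators",
    remodeler_set: str = "chromatin_remodelers",
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Sequentially intersect a module gene list with the candidate filters.

    Filters are applied in the fixed order regulators -> remodelers -> DE in
    either contrast -> expression window; any of them can be disabled.  The
    returned candidate table carries per-filter booleans for every module
    gene, and the cascade report maps each stage to its survivor count.
    Final candidates are ranked by max |lfc| across contrasts, descending.
    """
    module_genes = list(dict.fromkeys(module_genes))
    if not module_genes:
        raise ValueError("empty module gene list")
    unknown = set(enabled_filters) - set(CASCADE_STAGES[1:])
    if unknown:
        raise ValueError(f"unknown filters {sorted(unknown)}")
    regulators = sets[regulator_set] if "regulators" in enabled_filters else None
    remodelers = sets[remodeler_set] if "remodelers" in enabled_filters else None
    de_genes = significant_union(de_tables)
    max_lfc = pd.Series(0.0, index=pd.Index(module_genes, name="gene"))
    for table in de_tables:
        shared = table.index.intersection(max_lfc.index)
        max_lfc.loc[shared] = np.maximum(
            max_lfc.loc[shared], table.loc[shared, "lfc"].abs()
        )
    table = pd.DataFrame(
        {
            "is_regulator": [
                g in regulators if regulators is not None else True
                for g in module_genes
            ],
            "is_remodeler": [
                g in remodelers if remodelers is not None else True
                for g in module_genes
            ],
            "is_de": [g in de_genes for g in module_genes],
            "in_expression_window": [g in window_genes for g in module_genes],
            "max_abs_lfc": max_lfc,
        },
        index=pd.Index(module_genes, name="gene"),
    )
    survivors = table.index
    report = {"module": len(survivors)}
    masks = {
        "regulators": table["is_regulator"],
        "remodelers": table["is_remodeler"],
        "de": table["is_de"],
        "window": table["in_expression_window"],
    }
    for name in CASCADE_STAGES[1:]:
        if name in enabled_filters:
            survivors = survivors[masks[name].loc[survivors]]
        report[name] = len(survivors)
    candidates = table.loc[survivors].sort_values(
        ["max_abs_lfc", "gene"], ascending=[False, True], kind="stable"
    )
    candidates["rank"] = np.arange(1, len(candidates) + 1)
    if m is not None:
        stage_means = m.stage_means()
        for stage in m.stages:
            candidates[f"mean_{stage}"] = stage_means.loc[candidates.index, stage]
    return candidates, report


def cascade_percentage(numerator: int, denominator: int) -> int:
    """Integer percentage ``100 * numerator / denominator``, rounded half-up."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= numerator <= denominator:
        raise ValueError("numerator must lie in [0, denominator]")
    return int(math.floor(100.0 * numerator / denominator + 0.5))
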