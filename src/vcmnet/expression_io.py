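"""Plain-text I/O and basic transforms for stage-labelled expression matrices.

The central container is :class:`ExpressionMatrix`, a genes x samples matrix of
log2-scale expression values in which every sample carries a developmental
stage label (by default one of hESC, hESC-VCM, fetal-VCM, adult-VCM).  Matrices
are exchanged as TSV/CSV with a header row of sample ids and a first column of
gene ids; gene sets are one id per line, GO maps are two-column gene/term TSV.

Conventions fixed here and relied on everywhere downstream:

* delimiter is chosen from the file extension only (``.tsv`` -> tab,
  ``.csv`` -> comma); no content sniffing;
* gene-id normalization is whitespace trimming only -- symbol case is
  meaningful (SMYD1 vs Smyd1);
* z-scoring uses the population standard deviation (ddof=0);
* values are written with 12 significant digits, so write-then-read round
  trips reproduce a matrix to that precision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: The four developmental stages of the study design, in maturation order.
DEFAULT_STAGES = ("hESC", "hESC-VCM", "fetal-VCM", "adult-VCM")

_WRITE_FORMAT = "%.12g"


def _delimiter_for(path: Path) -> str:
    suffix = Path(path).suffix.lower()
    if suffix == ".tsv":
        return "\t"
    if suffix == ".csv":
        return ","
    raise ValueError(
        f"cannot infer delimiter from extension {suffix!r} (use .tsv or .csv)"
    )


@dataclass
class ExpressionMatrix:
    """Genes x samples expression matrix with one stage label per sample."""

    gene_ids: list[str]
    sample_ids: list[str]
    stage_labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g).strip() for g in self.gene_ids]
        self.sample_ids = [str(s).strip() for s in self.sample_ids]
        self.stage_labels = [str(s) for s in self.stage_labels]
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if self.values.ndim != 2 or self.values.shape != (
            len(self.gene_ids),
            len(self.sample_ids),
        ):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(self.stage_labels) != len(self.sample_ids):
            raise ValueError("every sample needs a stage label")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite expression values")

    # -- convenience -------------------------------------------------------

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def stages(self) -> list[str]:
        """Unique stage labels in order of first appearance."""
        seen: dict[str, None] = {}
        for s in self.stage_labels:
            seen.setdefault(s)
        return list(seen)

    def stage_columns(self, stage: str) -> np.ndarray:
        """Column indices of the samples belonging to ``stage``."""
        idx = np.flatnonzero(np.asarray(self.stage_labels) == stage)
        if idx.size == 0:
            raise KeyError(f"unknown stage {stage!r}")
        return idx

    def gene_index(self, gene_ids: Iterable[str]) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        try:
            return np.array([lookup[g] for g in gene_ids], dtype=int)
        except KeyError as exc:  # pragma: no cover - message only
            raise KeyError(f"unknown gene id {exc.args[0]!r}") from exc

    def subset_genes(self, gene_ids: Iterable[str]) -> "ExpressionMatrix":
        gene_ids = list(gene_ids)
        idx = self.gene_index(gene_ids)
        return ExpressionMatrix(
            gene_ids, list(self.sample_ids), list(self.stage_labels), self.values[idx]
        )

    def stage_means(self) -> pd.DataFrame:
        """Per-gene mean expression per stage (genes x stages)."""
        data = {
            stage: self.values[:, self.stage_columns(stage)].mean(axis=1)
            for stage in self.stages
        }
        return pd.DataFrame(data, index=self.gene_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class GeneSetCollection:
    """Named gene sets plus an optional many-to-many gene->term map."""

    sets: dict[str, set[str]]
    go_map: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        self.sets = {str(name): {str(g) for g in genes} for name, genes in self.sets.items()}
        if self.go_map is not None:
            if list(self.go_map.columns) != ["gene", "term"]:
                self.go_map = self.go_map.copy()
                self.go_map.columns = ["gene", "term"]

    def __getitem__(self, name: str) -> set[str]:
        return self.sets[name]

    def term_genes(self) -> dict[str, set[str]]:
        """Term -> gene-set view of the GO map."""
        if self.go_map is None:
            return {}
        return {
            term: set(group["gene"]) for term, group in self.go_map.groupby("term")
        }


# -- readers / writers -----------------------------------------------------


def write_expression_matrix(m: ExpressionMatrix, path: str | Path) -> None:
    """Write ``m`` as delimited text (12 significant digits)."""
    path = Path(path)
    m.to_frame().to_csv(
        path, sep=_delimiter_for(path), float_format=_WRITE_FORMAT, index_label="gene_id"
    )


def read_expression_matrix(
    path: str | Path, stage_map: Mapping[str, str] | pd.DataFrame
) -> ExpressionMatrix:
    """Read a genes x samples matrix and attach stage labels.

    ``stage_map`` maps sample id -> stage and must cover every sample in the
    header.  Rows containing any non-numeric cell raise, they are never
    silently dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if isinstance(stage_map, pd.DataFrame):
        stage_map = dict(zip(stage_map.iloc[:, 0].astype(str), stage_map.iloc[:, 1].astype(str)))
    delim = _delimiter_for(path)
    with open(path) as fh:
        header = [c.strip() for c in fh.readline().rstrip("\n").split(delim)][1:]
    if len(set(header)) != len(header):
        raise ValueError(f"duplicate sample id in header of {path}")
    raw = pd.read_csv(path, sep=delim, index_col=0, dtype=str)
    sample_ids = [str(s).strip() for s in raw.columns]
    gene_ids = [str(g).strip() for g in raw.index]
    if len(set(gene_ids)) != len(gene_ids):
        raise ValueError(f"duplicate gene id in {path}")
    missing = [s for s in sample_ids if s not in stage_map]
    if missing:
        raise ValueError(f"samples missing from stage_map: {missing}")
    try:
        values = raw.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"non-numeric cell in {path}: {exc}") from exc
    stages = [str(stage_map[s]) for s in sample_ids]
    return ExpressionMatrix(gene_ids, sample_ids, stages, values)


def write_gene_set(genes: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))


def write_go_map(go_map: pd.DataFrame, path: str | Path) -> None:
    go_map.to_csv(path, sep="\t", header=False, index=False)


def read_gene_sets(
    paths: Mapping[str, str | Path], go_map_path: str | Path | None = None
) -> GeneSetCollection:
    """Read named one-id-per-line gene lists and an optional two-column GO map.

    Blank lines are ignored; duplicates within a set are collapsed and the
    duplicate count is logged.
    """
    sets: dict[str, set[str]] = {}
    for name, path in paths.items():
        lines = [ln.strip() for ln in Path(path).read_text().splitlines()]
        genes = [ln for ln in lines if ln]
        if not genes:
            raise ValueError(f"empty gene set file {path}")
        unique = set(genes)
        n_dup = len(genes) - len(unique)
        if n_dup:
            log.info("gene set %s: collapsed %d duplicate entries", name, n_dup)
        sets[name] = unique
    go_map = None
    if go_map_path is not None:
        rows = []
        for i, ln in enumerate(Path(go_map_path).read_text().splitlines(), start=1):
            if not ln.strip():
                continue
            parts = ln.split("\t")
            if len(parts) != 2 or not parts[0].strip() or not parts[1].strip():
                raise ValueError(f"malformed two-column row {i} in {go_map_path}: {ln!r}")
            rows.append((parts[0].strip(), parts[1].strip()))
        go_map = pd.DataFrame(rows, columns=["gene", "term"]).drop_duplicates()
    return GeneSetCollection(sets, go_map)


# -- transforms ------------------------------------------------------------


def log2_standardize(m: ExpressionMatrix, mode: str = "zscore") -> ExpressionMatrix:
    """Apply log2 and/or per-gene z-scoring (population sd, ddof=0).

    ``mode`` is one of ``log2``, ``zscore`` or ``both`` (log2 first).
    """
    if mode not in ("log2", "zscore", "both"):
        raise ValueError(f"unknown mode {mode!r}")
    values = m.values
    if mode in ("log2", "both"):
        if np.any(values <= 0):
            raise ValueError("log2 requires strictly positive values")
        values = np.log2(values)
    if mode in ("zscore", "both"):
        mean = values.mean(axis=1, keepdims=True)
        sd = values.std(axis=1, ddof=0, keepdims=True)
        if np.any(sd == 0):
            bad = [m.gene_ids[i] for i in np.flatnonzero(sd[:, 0] == 0)[:5]]
            raise ValueError(f"zero-variance gene(s) under zscore, e.g. {bad}")
        values = (values - mean) / sd
    return ExpressionMatrix(
        list(m.gene_ids), list(m.sample_ids), list(m.stage_labels), values
    )
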