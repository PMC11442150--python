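"""Readers, writers and normalization helpers.

All dense text formats follow the genes-as-rows, cells-as-columns convention.
Gene and cell identifiers are matched by exact string everywhere; a mismatch
between an expression matrix and a label file is an error, never a silent
intersection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger("drugresc")

SCORE_CSV_COLUMNS = [
    "instance_id",
    "drug_name",
    "method",
    "raw_score",
    "standardized_score",
    "rank",
]


@dataclass
class ExpressionMatrix:
    """Log-scale gene-by-cell expression values.

    Parameters
    ----------
    genes : list of str
        Unique gene symbols, one per row of ``values``.
    cells : list of str
        Unique cell identifiers, one per column of ``values``.
    values : ndarray of shape (n_genes, n_cells)
        Finite log2-scale expression values (e.g. log2(CPM + 1)).
    """

    genes: list[str]
    cells: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        if self.values.shape != (len(self.genes), len(self.cells)):
            raise ValueError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.cells)} cells"
            )
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene symbols in ExpressionMatrix")
        if len(set(self.cells)) != len(self.cells):
            raise ValueError("duplicate cell identifiers in ExpressionMatrix")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.cells)


@dataclass
class CellLabels:
    """Binary phenotype per cell: 1 = disease-associated, 0 = other."""

    cells: list[str]
    phenotype: np.ndarray

    def __post_init__(self) -> None:
        self.phenotype = np.asarray(self.phenotype, dtype=int)
        if self.phenotype.shape != (len(self.cells),):
            raise ValueError("phenotype length does not match cell list")
        if not np.isin(self.phenotype, (0, 1)).all():
            raise ValueError("phenotype values must be 0 or 1")
        if len(set(self.cells)) != len(self.cells):
            raise ValueError("duplicate cell identifiers in CellLabels")

    def aligned_to(self, cells: Sequence[str]) -> np.ndarray:
        """Phenotype vector reordered to ``cells``; any mismatch is an error."""
        if set(cells) != set(self.cells):
            missing = set(cells) - set(self.cells)
            extra = set(self.cells) - set(cells)
            raise ValueError(
                f"cell identifiers do not match labels: {len(missing)} cells "
                f"unlabeled, {len(extra)} labels without cells"
            )
        pos = {c: i for i, c in enumerate(self.cells)}
        return self.phenotype[[pos[c] for c in cells]]


@dataclass
class RunConfig:
    """Pipeline parameters with the published defaults.

    ``alpha`` is the rank-weight exponent of the enrichment walk,
    ``de_p_threshold`` the significance cutoff for signature membership,
    ``ntree`` the forest size and ``n_negative_samplings`` the number of
    negative-control replicates for evaluation.
    """

    alpha: float = 0.25
    de_p_threshold: float = 0.01
    ntree: int = 100
    mtry_grid: list[int] | None = None
    n_negative_samplings: int = 10
    master_seed: int = 0
    importance_method: str = "random_forest"
    pseudocount: float = 1.0

    _METHODS = (
        "random_forest",
        "wilcoxon",
        "anova",
        "logistic_l1",
        "svm_sensitivity",
        "gboost_gain",
        "vote",
    )

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise ValueError("alpha must be > 0")
        if not 0 < self.de_p_threshold < 1:
            raise ValueError("de_p_threshold must lie in (0, 1)")
        if self.ntree < 1:
            raise ValueError("ntree must be >= 1")
        if self.n_negative_samplings < 1:
            raise ValueError("n_negative_samplings must be >= 1")
        if self.importance_method not in self._METHODS:
            raise ValueError(f"unknown importance method {self.importance_method!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def collapse_duplicate_genes(table: pd.DataFrame) -> pd.DataFrame:
    """Average rows sharing a gene symbol (index), preserving first-seen order.

    Idempotent; tables without duplicates pass through unchanged.
    """
    if table.shape[0] < 1:
        raise ValueError("empty expression table")
    if table.index.is_unique:
        return table
    order = table.index.drop_duplicates()
    return table.groupby(level=0, sort=False).mean().loc[order]


def read_expression(path: str | Path, format: str = "dense_table") -> ExpressionMatrix:
    """Read a gene-by-cell expression matrix.

    ``dense_table``: TSV/CSV with gene symbols in the first column and a
    header row of cell identifiers.  ``mtx_triplet``: MatrixMarket file with
    companion ``<stem>.genes.txt`` and ``<stem>.cells.txt`` identifier lists
    (one per line).  Duplicate gene symbols are collapsed by averaging.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "dense_table":
        sep = "," if path.suffix.lower() == ".csv" else "\t"
        table = pd.read_csv(path, sep=sep, index_col=0)
        try:
            table = table.astype(float)
        except ValueError as exc:
            raise ValueError(f"non-numeric entries in {path}: {exc}") from None
    elif format == "mtx_triplet":
        genes_path = path.with_suffix("").with_suffix(".genes.txt")
        cells_path = path.with_suffix("").with_suffix(".cells.txt")
        for companion in (genes_path, cells_path):
            if not companion.exists():
                raise FileNotFoundError(companion)
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        genes = genes_path.read_text().split()
        cells = cells_path.read_text().split()
        if mat.shape != (len(genes), len(cells)):
            raise ValueError(
                f"matrix shape {mat.shape} inconsistent with {len(genes)} genes "
                f"and {len(cells)} cells"
            )
        table = pd.DataFrame(np.asarray(mat, dtype=float), index=genes, columns=cells)
    else:
        raise ValueError(f"unknown expression format {format!r}")
    table = collapse_duplicate_genes(table)
    return ExpressionMatrix(list(table.index), list(table.columns), table.to_numpy())


def write_expression(expr: ExpressionMatrix, path: str | Path, format: str = "dense_table") -> None:
    path = Path(path)
    if format == "dense_table":
        sep = "," if path.suffix.lower() == ".csv" else "\t"
        expr.to_frame().to_csv(path, sep=sep)
    elif format == "mtx_triplet":
        scipy.io.mmwrite(str(path), scipy.sparse.csr_matrix(expr.values))
        path.with_suffix("").with_suffix(".genes.txt").write_text("\n".join(expr.genes) + "\n")
        path.with_suffix("").with_suffix(".cells.txt").write_text("\n".join(expr.cells) + "\n")
    else:
        raise ValueError(f"unknown expression format {format!r}")


def log_normalize(
    counts: np.ndarray | pd.DataFrame,
    scale: str = "tpm_like_total_count",
    pseudocount: float = 1.0,
) -> np.ndarray:
    """Total-count scale each cell (column) to 1e6, then log2(x + pseudocount).

    A length-corrected TPM is not computed here; matrices normalized upstream
    may be supplied directly to the scoring pipeline instead.
    """
    if scale != "tpm_like_total_count":
        raise ValueError(f"unknown scale {scale!r}")
    values = np.asarray(counts, dtype=float)
    if (values < 0).any():
        raise ValueError("counts must be nonnegative")
    totals = values.sum(axis=0)
    if (totals == 0).any():
        raise ValueError("cell with zero total count cannot be normalized")
    scaled = values / totals * 1e6
    return np.log2(scaled + pseudocount)


def read_labels(path: str | Path) -> CellLabels:
    """Read a two-column (cell_id, phenotype) TSV, with or without header."""
    path = Path(path)
    first = path.read_text().splitlines()[0].split("\t")
    header = 0 if first and first[-1] not in ("0", "1") else None
    table = pd.read_csv(path, sep="\t", header=header, dtype={0: str})
    if table.shape[1] != 2:
        raise ValueError("label file must have exactly two columns")
    values = table.iloc[:, 1].to_numpy()
    if not np.isin(values, (0, 1)).all():
        bad = sorted(set(values) - {0, 1})
        raise ValueError(f"label values outside {{0,1}}: {bad}")
    return CellLabels(list(table.iloc[:, 0]), values)


def write_labels(labels: CellLabels, path: str | Path) -> None:
    pd.DataFrame({"cell_id": labels.cells, "phenotype": labels.phenotype}).to_csv(
        path, sep="\t", index=False
    )


def read_gmt(path: str | Path) -> list[tuple[str, str, set[str]]]:
    """Parse a GMT file into (name, description, gene set) records."""
    records = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
        name, desc, genes = fields[0], fields[1], fields[2:]
        records.append((name, desc, {g for g in genes if g}))
    return records


def write_gmt(sets: Sequence[tuple[str, str, set[str]]], path: str | Path) -> None:
    lines = []
    for name, desc, genes in sets:
        lines.append("\t".join([name, desc, *sorted(genes)]))
    Path(path).write_text("\n".join(lines) + "\n")


def write_score_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a drug score table as CSV with the canonical column order."""
    missing = [c for c in SCORE_CSV_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"score table missing columns: {missing}")
    table[SCORE_CSV_COLUMNS].to_csv(path, index=False)


def read_score_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, dtype={"instance_id": str, "drug_name": str, "method": str})
    missing = [c for c in SCORE_CSV_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"score table missing columns: {missing}")
    return table


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
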