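"""Drug-to-cell (D2C) reversal scoring via a per-cell enrichment walk.

For each cell, genes are ranked by absolute expression: the gene with the
largest |expression| receives integer rank N, the smallest rank 1 (ties
broken by lexicographic gene symbol so the order is total and runs are
reproducible).  For a gene signature G of size NG the walk visits positions
i = 1..N in rank-descending order and accumulates

    P_hit(G, i) = sum_{j in G, pos(j) <= i} r_j^alpha / sum_{j in G} r_j^alpha
    P_miss(G, i) = #{j not in G, pos(j) <= i} / (N - NG)

The enrichment score ES is the signed value of P_hit - P_miss at the
position of maximal absolute deviation (earliest such position on ties),
so ES lies in [-1, 1].  The D2C score of a drug instance in a cell is
ES(up-signature) - ES(down-signature): positive when the cell's profile is
concordant with the drug-induced changes, negative when the drug reverses
them.  D2C therefore lies in [-2, 2].

``enrichment_score`` is the optimized cumulative-sum implementation;
``enrichment_score_reference`` is a deliberately plain position-by-position
walk kept as an independent cross-check (the two must agree to 1e-12).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import ExpressionMatrix
from .signatures import DrugSignature

logger = logging.getLogger("drugresc")


@dataclass
class CellRanking:
    """One cell's total gene ordering by absolute expression.

    ``ordered_genes`` runs from the highest-ranked gene (rank value N) to the
    lowest (rank value 1); ``rank_values[i]`` is the integer rank N - i of
    ``ordered_genes[i]``.
    """

    cell_id: str
    ordered_genes: list[str]
    rank_values: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ordered_genes)
        self.rank_values = np.asarray(self.rank_values, dtype=int)
        if sorted(self.rank_values) != list(range(1, n + 1)):
            raise ValueError("rank values must be a permutation of 1..N")

    @property
    def n_genes(self) -> int:
        return len(self.ordered_genes)


@dataclass
class D2CMatrix:
    """Drug instances x cells matrix of D2C reversal scores."""

    instances: list[str]
    cells: list[str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.instances), len(self.cells)):
            raise ValueError("score matrix shape does not match instances x cells")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("D2C scores must be finite")
        if np.abs(self.scores).max(initial=0.0) > 2 + 1e-9:
            raise ValueError("D2C scores must lie in [-2, 2]")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.scores, index=self.instances, columns=self.cells)


def rank_cell(genes: list[str], expression: np.ndarray, cell_id: str = "") -> CellRanking:
    """Rank one cell's genes by absolute expression, largest first."""
    values = np.asarray(expression, dtype=float)
    n = len(genes)
    if n < 2:
        raise ValueError("ranking needs at least 2 genes")
    if values.shape != (n,):
        raise ValueError("expression vector does not match gene list")
    if not np.all(np.isfinite(values)):
        raise ValueError("expression values must be finite")
    order = sorted(range(n), key=lambda i: (-abs(values[i]), genes[i]))
    ordered_genes = [genes[i] for i in order]
    return CellRanking(cell_id, ordered_genes, np.arange(n, 0, -1))


def _signature_positions(ranking: CellRanking, signature_genes: set[str]) -> np.ndarray:
    members = np.fromiter(
        (g in signature_genes for g in ranking.ordered_genes), dtype=bool, count=ranking.n_genes
    )
    return members


def enrichment_score(
    ranking: CellRanking, signature_genes: set[str], alpha: float = 0.25
) -> float:
    """Signed maximum deviation of the running P_hit - P_miss difference."""
    hit = _signature_positions(ranking, signature_genes)
    return _es_from_indicator(hit, ranking.rank_values, alpha)


def _es_from_indicator(
    hit: np.ndarray, rank_values: np.ndarray, alpha: float, preweighted: bool = False
) -> float:
    n = hit.size
    ng = int(hit.sum())
    if ng == 0:
        raise ValueError("signature has no genes in the ranking")
    if ng == n:
        raise ValueError("signature covers every ranked gene; P_miss undefined")
    if preweighted:
        weights = np.where(hit, rank_values, 0.0)
    else:
        weights = np.where(hit, np.abs(rank_values).astype(float) ** alpha, 0.0)
    p_hit = np.cumsum(weights) / weights.sum()
    p_miss = np.cumsum(~hit) / (n - ng)
    return _signed_extreme(p_hit - p_miss)


# Exact ties between a positive and a negative extreme are real (both are
# rational when they bracket the hit run); they resolve to the earliest
# position.  The tolerance absorbs float noise so independent evaluation
# orders of the same walk pick the same position.
_TIE_TOL = 1e-9


def _signed_extreme(diff: np.ndarray) -> float:
    cutoff = np.abs(diff).max() - _TIE_TOL
    idx = int(np.argmax(np.abs(diff) >= cutoff))
    return float(diff[idx])


def enrichment_score_reference(
    ranking: CellRanking, signature_genes: set[str], alpha: float = 0.25
) -> float:
    """Plain position-by-position evaluation of the walk (cross-check oracle)."""
    genes = ranking.ordered_genes
    ranks = ranking.rank_values
    in_sig = [g in signature_genes for g in genes]
    n = len(genes)
    ng = sum(in_sig)
    if ng == 0:
        raise ValueError("signature has no genes in the ranking")
    if ng == n:
        raise ValueError("signature covers every ranked gene; P_miss undefined")
    denom = sum(abs(ranks[j]) ** alpha for j in range(n) if in_sig[j])
    diffs = []
    for i in range(1, n + 1):
        p_hit = sum(abs(ranks[j]) ** alpha for j in range(i) if in_sig[j]) / denom
        p_miss = sum(1 for j in range(i) if not in_sig[j]) / (n - ng)
        diffs.append(p_hit - p_miss)
    best_abs = max(abs(d) for d in diffs)
    for d in diffs:  # earliest position whose |deviation| attains the maximum
        if abs(d) >= best_abs - _TIE_TOL:
            return d
    raise AssertionError("unreachable")


def d2c_score(ranking: CellRanking, signature: DrugSignature, alpha: float = 0.25) -> float:
    """D2C = ES(up) - ES(down); an empty side contributes 0 with a warning."""
    genes_present = set(ranking.ordered_genes)
    up = signature.up & genes_present
    down = signature.down & genes_present
    if not up and not down:
        raise ValueError(
            f"instance {signature.instance_id!r}: neither signature side overlaps the ranking"
        )
    es_up = enrichment_score(ranking, up, alpha) if up else 0.0
    es_down = enrichment_score(ranking, down, alpha) if down else 0.0
    if not up or not down:
        side = "up" if not up else "down"
        logger.warning(
            "instance %s: empty %s-signature after intersection; side contributes 0",
            signature.instance_id,
            side,
        )
    return es_up - es_down


def build_d2c_matrix(
    expr: ExpressionMatrix, signatures: list[DrugSignature], alpha: float = 0.25
) -> D2CMatrix:
    """Score every (instance, cell) pair, streaming cell by cell.

    Instances with no signature gene present in the expression matrix are
    dropped with a log message.  The computation materializes per-cell
    cumulative sums only (never all cells at once).
    """
    if expr.n_cells < 2:
        raise ValueError("need at least 2 cells")
    gene_set = set(expr.genes)
    usable: list[DrugSignature] = []
    up_members = []
    down_members = []
    gene_index = {g: i for i, g in enumerate(expr.genes)}
    for sig in signatures:
        up = sig.up & gene_set
        down = sig.down & gene_set
        if not up and not down:
            logger.info("dropping instance %s: no signature genes in matrix", sig.instance_id)
            continue
        if len(up) == expr.n_genes or len(down) == expr.n_genes:
            logger.info(
                "dropping instance %s: a signature side covers all genes", sig.instance_id
            )
            continue
        usable.append(sig)
        up_members.append(np.fromiter((gene_index[g] for g in up), dtype=int, count=len(up)))
        down_members.append(
            np.fromiter((gene_index[g] for g in down), dtype=int, count=len(down))
        )
    if not usable:
        raise ValueError("no usable signatures against this expression matrix")

    n_genes, n_cells = expr.n_genes, expr.n_cells
    n_inst = len(usable)
    scores = np.empty((n_inst, n_cells))
    rank_values = np.arange(n_genes, 0, -1, dtype=float)
    # lexicographic tie-break on gene symbol: secondary sort key
    sym_order = np.argsort(np.asarray(expr.genes, dtype=object), kind="stable")
    sym_rank = np.empty(n_genes, dtype=int)
    sym_rank[sym_order] = np.arange(n_genes)

    weights = rank_values**alpha
    hit = np.zeros(n_genes, dtype=bool)
    for c in range(n_cells):
        col = np.abs(expr.values[:, c])
        order = np.lexsort((sym_rank, -col))  # descending |expr|, symbol ties
        pos = np.empty(n_genes, dtype=int)
        pos[order] = np.arange(n_genes)
        for d in range(n_inst):
            es_up = _es_at_positions(pos[up_members[d]], weights, hit)
            es_down = _es_at_positions(pos[down_members[d]], weights, hit)
            scores[d, c] = es_up - es_down
    return D2CMatrix([s.instance_id for s in usable], list(expr.cells), scores)


def _es_at_positions(positions: np.ndarray, weights: np.ndarray, scratch: np.ndarray) -> float:
    """ES given 0-based signature positions in rank-descending order.

    ``scratch`` is a reusable boolean buffer of length N (zeroed on exit).
    """
    if positions.size == 0:
        return 0.0
    scratch[positions] = True
    try:
        return _es_from_indicator(scratch, weights, 1.0, preweighted=True)
    finally:
        scratch[positions] = False
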