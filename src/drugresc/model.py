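"""The DrugReSC model: fit drug-instance importance to labeled single cells.

The model is built from a log-scale expression matrix, binary cell labels
(1 = disease-associated) and per-instance drug signatures.  Construction
materializes the drug-by-cell (D2C) reversal-score matrix; ``fit`` scores
every instance's contribution to the phenotype classification with the
requested backend and returns a results object carrying raw and
standardized scores, ranks and diagnostics.

Example
-------
>>> from drugresc import DrugReSC, SimConfig, simulate, build_signature
>>> data = simulate(SimConfig(seed=1))
>>> sigs = [build_signature(p) for p in data.profiles]
>>> res = DrugReSC(data.expression, data.labels, sigs).fit(seed=1)
>>> res.scores.head()          # doctest: +SKIP
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import importance as imp
from .enrichment import D2CMatrix, build_d2c_matrix
from .io import CellLabels, ExpressionMatrix, RunConfig
from .signatures import DrugSignature, flag_empty

logger = logging.getLogger("drugresc")


class DrugReSC:
    """Drug-repurposing model over a labeled single-cell expression matrix.

    Parameters
    ----------
    expression : ExpressionMatrix
        Log-scale genes x cells matrix.
    labels : CellLabels
        Binary phenotype per cell; must cover exactly the matrix's cells.
    signatures : list of DrugSignature
        Per-instance up/down gene sets; empty instances are excluded with a
        log message.
    config : RunConfig, optional
        Pipeline parameters (alpha, ntree, ...); defaults are the published
        values.
    """

    def __init__(
        self,
        expression: ExpressionMatrix,
        labels: CellLabels,
        signatures: list[DrugSignature],
        config: RunConfig | None = None,
    ):
        self.config = config or RunConfig()
        self.expression = expression
        self.labels = labels
        labels.aligned_to(expression.cells)  # fail fast on mismatch
        usable, dropped = [], []
        for sig in signatures:
            (dropped if flag_empty(sig) else usable).append(sig)
        for sig in dropped:
            logger.info("excluding instance %s: empty signature", sig.instance_id)
        if not usable:
            raise ValueError("no non-empty signatures supplied")
        self.signatures = usable
        self.dropped_instances = [s.instance_id for s in dropped]
        self.drug_names = {s.instance_id: s.drug_name for s in usable}
        self.d2c: D2CMatrix = build_d2c_matrix(
            expression, usable, alpha=self.config.alpha
        )

    @classmethod
    def from_files(
        cls,
        expression_path,
        labels_path,
        gmt_path,
        config: RunConfig | None = None,
        expression_format: str = "dense_table",
    ) -> "DrugReSC":
        from .io import read_expression, read_labels
        from .signatures import signatures_from_gmt

        return cls(
            read_expression(expression_path, format=expression_format),
            read_labels(labels_path),
            signatures_from_gmt(gmt_path),
            config=config,
        )

    def fit(self, method: str | None = None, seed: int | None = None, **kwargs) -> "DrugReSCResults":
        """Score every drug instance with the requested importance backend.

        ``method`` defaults to the config's ``importance_method``
        (random_forest).  ``seed`` overrides the config's master seed.
        ``vote`` runs every core backend and combines them by majority vote.
        """
        method = method or self.config.importance_method
        seed = self.config.master_seed if seed is None else seed
        mtry = None
        if method == "random_forest":
            mtry = kwargs.pop("mtry", None)
            if mtry is None:
                mtry = imp.select_mtry(
                    self.d2c,
                    self.labels,
                    grid=self.config.mtry_grid,
                    ntree=self.config.ntree,
                    seed=seed,
                )
            forest = imp.fit_forest(
                self.d2c, self.labels, ntree=self.config.ntree, mtry=mtry, seed=seed
            )
            table = imp.oob_permutation_importance(
                forest, self.d2c, self.labels, seed=seed + 1, **kwargs
            )
        elif method == "wilcoxon":
            table = imp.wilcoxon_importance(self.d2c, self.labels)
        elif method == "anova":
            table = imp.anova_importance(self.d2c, self.labels)
        elif method == "logistic_l1":
            table = imp.logistic_l1_importance(self.d2c, self.labels, seed=seed)
        elif method == "svm_sensitivity":
            table = imp.svm_sensitivity_importance(self.d2c, self.labels, seed=seed)
        elif method == "gboost_gain":
            table = imp.gboost_gain_importance(self.d2c, self.labels, seed=seed)
        elif method == "vote":
            k = kwargs.pop("k", 3)
            tables = [
                self.fit(method=m, seed=seed, **kwargs).table
                for m in ("random_forest", "wilcoxon", "anova", "logistic_l1")
            ]
            table = imp.ensemble_vote(tables, k=k)
        else:
            raise ValueError(f"unknown importance method {method!r}")
        table.insert(1, "drug_name", [self.drug_names[i] for i in table["instance_id"]])
        return DrugReSCResults(self, table, method=method, seed=seed, mtry=mtry)


class DrugReSCResults:
    """Fitted drug importance scores and diagnostics.

    Attributes
    ----------
    scores : DataFrame
        One row per instance, sorted by rank: instance_id, drug_name,
        method, raw_score, standardized_score, rank.
    d2c : D2CMatrix
        The drug-by-cell reversal matrix the scores were computed from.
    """

    def __init__(self, model: DrugReSC, table: pd.DataFrame, method: str, seed: int, mtry=None):
        self.model = model
        self.table = table
        self.method = method
        self.seed = seed
        self.mtry = mtry

    @property
    def scores(self) -> pd.DataFrame:
        return self.table.sort_values("rank").reset_index(drop=True)

    @property
    def d2c(self) -> D2CMatrix:
        return self.model.d2c

    def score_dict(self, standardized: bool = False) -> dict[str, float]:
        col = "standardized_score" if standardized else "raw_score"
        return dict(zip(self.table["instance_id"], self.table[col]))

    def top(self, n: int = 10) -> pd.DataFrame:
        return self.scores.head(n)

    def manifest(self) -> dict:
        """JSON-serializable run provenance."""
        return {
            "method": self.method,
            "seed": int(self.seed),
            "mtry": None if self.mtry is None else int(self.mtry),
            "alpha": self.model.config.alpha,
            "ntree": self.model.config.ntree,
            "n_instances": len(self.table),
            "n_cells": self.model.expression.n_cells,
            "n_genes": self.model.expression.n_genes,
            "dropped_instances": self.model.dropped_instances,
        }

    def summary(self) -> str:
        cfg = self.model.config
        head = [
            "DrugReSC results",
            "================",
            f"method: {self.method}    seed: {self.seed}",
            f"cells: {self.model.expression.n_cells} "
            f"({int(self.model.labels.phenotype.sum())} disease-associated)    "
            f"genes: {self.model.expression.n_genes}",
            f"drug instances: {len(self.table)} scored, "
            f"{len(self.model.dropped_instances)} excluded (empty signature)",
            f"alpha: {cfg.alpha}    ntree: {cfg.ntree}"
            + (f"    mtry: {self.mtry}" if self.mtry is not None else ""),
            "",
        ]
        cols = ["rank", "instance_id", "drug_name", "raw_score", "standardized_score"]
        body = self.scores[cols].head(10).to_string(index=False, float_format="%.4f")
        return "\n".join(head) + "\n" + body

    def plot_d2c_heatmap(self, ax=None):
        """Heatmap of D2C scores with cells grouped by phenotype."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 4))
        y = self.model.labels.aligned_to(self.d2c.cells)
        order = np.argsort(-y, kind="stable")
        im = ax.imshow(self.d2c.scores[:, order], aspect="auto", cmap="RdBu_r", vmin=-2, vmax=2)
        ax.axvline(int(y.sum()) - 0.5, color="k", lw=0.8)
        ax.set_xlabel("cells (disease-associated | other)")
        ax.set_ylabel("drug instances")
        ax.figure.colorbar(im, ax=ax, label="D2C score")
        return ax
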