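"""Self-contained synthetic fixtures with a planted reversal structure.

The generator emulates the statistical shape the pipeline assumes, on the
log2 scale the scorer consumes:

* baseline expression per gene ~ Normal(mean_g, noise_sd), with gene means
  drawn once from Uniform(1, 8) (a plausible log2-abundance range), clipped
  at 0;
* a disease program of ``program_size`` genes split into an up-half
  (+effect_size in disease cells) and a down-half (-effect_size);
* each positive drug's DE profile *reverses* the program: its down-signature
  covers a ``reversal_strength`` fraction of the program's up-half and its
  up-signature the matching fraction of the down-half.  Signature genes get
  |logfc| ~ |Normal(effect_size, 0.2)| with the appropriate sign and
  p ~ Uniform(1e-6, 0.009) — strictly below the 0.01 cutoff so signature
  recovery is exact; non-signature genes get logfc ~ Normal(0, 0.1) and
  p ~ Uniform(0.2, 1);
* negative drugs carry signatures of matched sizes over random non-program
  genes.

Every draw flows from a single seed, so identical configurations reproduce
identical fixtures byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .io import CellLabels, ExpressionMatrix
from .signatures import DEProfile


@dataclass
class SimConfig:
    n_genes: int = 2000
    n_cells: int = 300
    frac_disease_cells: float = 0.10
    program_size: int = 100
    effect_size: float = 2.0
    noise_sd: float = 1.0
    n_positive_drugs: int = 5
    n_negative_drugs: int = 15
    reversal_strength: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.frac_disease_cells < 1:
            raise ValueError("frac_disease_cells must lie in (0, 1)")
        if self.program_size >= self.n_genes:
            raise ValueError("program_size must be smaller than n_genes")
        if not 0 < self.reversal_strength <= 1:
            raise ValueError("reversal_strength must lie in (0, 1]")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")


@dataclass
class SyntheticDataset:
    expression: ExpressionMatrix
    labels: CellLabels
    profiles: list[DEProfile]
    positives: list[str]
    program_up: list[str]
    program_down: list[str]
    config: SimConfig


def simulate(config: SimConfig) -> SyntheticDataset:
    """Generate expression, labels and drug DE profiles per the config."""
    rng = np.random.default_rng(config.seed)
    genes = [f"G{i:05d}" for i in range(config.n_genes)]
    cells = [f"C{i:04d}" for i in range(config.n_cells)]

    gene_means = rng.uniform(1.0, 8.0, size=config.n_genes)
    values = rng.normal(
        gene_means[:, None], config.noise_sd, size=(config.n_genes, config.n_cells)
    )

    n_disease = max(1, int(round(config.frac_disease_cells * config.n_cells)))
    disease_idx = rng.choice(config.n_cells, size=n_disease, replace=False)
    phenotype = np.zeros(config.n_cells, dtype=int)
    phenotype[disease_idx] = 1

    program_idx = rng.choice(config.n_genes, size=config.program_size, replace=False)
    half = config.program_size // 2
    up_idx = program_idx[:half]
    down_idx = program_idx[half:]
    values[np.ix_(up_idx, disease_idx)] += config.effect_size
    values[np.ix_(down_idx, disease_idx)] -= config.effect_size
    values = np.clip(values, 0.0, None)

    program_up = [genes[i] for i in up_idx]
    program_down = [genes[i] for i in down_idx]
    non_program = np.setdiff1d(np.arange(config.n_genes), program_idx)

    n_rev_up = max(1, int(round(config.reversal_strength * len(up_idx))))
    n_rev_down = max(1, int(round(config.reversal_strength * len(down_idx))))

    profiles: list[DEProfile] = []
    positives: list[str] = []
    for p in range(config.n_positive_drugs):
        instance_id = f"POS{p:03d}"
        positives.append(instance_id)
        down_sig = rng.choice(up_idx, size=n_rev_up, replace=False)  # reverses up-half
        up_sig = rng.choice(down_idx, size=n_rev_down, replace=False)
        profiles.append(
            _make_profile(instance_id, f"posdrug{p}", genes, up_sig, down_sig, config, rng)
        )
    for q in range(config.n_negative_drugs):
        instance_id = f"NEG{q:03d}"
        chosen = rng.choice(non_program, size=n_rev_up + n_rev_down, replace=False)
        profiles.append(
            _make_profile(
                instance_id,
                f"negdrug{q}",
                genes,
                chosen[:n_rev_down],
                chosen[n_rev_down:],
                config,
                rng,
            )
        )

    expression = ExpressionMatrix(genes, cells, values)
    labels = CellLabels(cells, phenotype)
    return SyntheticDataset(
        expression, labels, profiles, positives, program_up, program_down, config
    )


def _make_profile(
    instance_id: str,
    drug_name: str,
    genes: list[str],
    up_sig_idx: np.ndarray,
    down_sig_idx: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator,
) -> DEProfile:
    n = len(genes)
    logfc = rng.normal(0.0, 0.1, size=n)
    pvals = rng.uniform(0.2, 1.0, size=n)
    mag = max(config.effect_size, 1.0)  # keep signatures recoverable at effect 0
    logfc[up_sig_idx] = np.abs(rng.normal(mag, 0.2, size=up_sig_idx.size))
    logfc[down_sig_idx] = -np.abs(rng.normal(mag, 0.2, size=down_sig_idx.size))
    pvals[up_sig_idx] = rng.uniform(1e-6, 0.009, size=up_sig_idx.size)
    pvals[down_sig_idx] = rng.uniform(1e-6, 0.009, size=down_sig_idx.size)
    return DEProfile(
        instance_id=instance_id,
        drug_name=drug_name,
        dose=10.0,
        dose_unit="uM",
        tissue="synthetic",
        genes=list(genes),
        logfc=logfc,
        pvalues=pvals,
    )


def make_worked_example():
    """Tiny hand-evaluable fixture: 3 genes x 2 cells, 2 drug instances.

    In cell ``c1`` the ranking by absolute expression is a > c > b (integer
    ranks 3, 2, 1).  Instance ``rev`` has up = {a} (top gene, ES = 1) and
    down = {b} (bottom gene, ES = -1), so its D2C score in c1 is 2.
    Instance ``self`` has up == down == {a}, so its D2C score is 0.
    """
    from .signatures import DrugSignature

    expr = ExpressionMatrix(
        genes=["a", "b", "c"],
        cells=["c1", "c2"],
        values=np.array([[4.0, 1.0], [1.0, 4.0], [2.0, 2.0]]),
    )
    labels = CellLabels(["c1", "c2"], np.array([1, 0]))
    rev = DrugSignature("rev", "reversal-drug", up={"a"}, down={"b"})
    self_sig = DrugSignature("self", "null-drug", up={"a"}, down={"a"})
    return expr, labels, [rev, self_sig]
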