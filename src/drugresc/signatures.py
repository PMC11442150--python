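"""Per-drug-instance up/down gene signatures from differential expression.

Each drug *instance* (one replicate of a treatment condition: dose, cell
line, duration) carries a vector of log-scale differential expression values
``c`` and aligned p-values ``p`` over genes.  The up-signature is the set of
genes with c > 0 and p below a significance cutoff; the down-signature the
set with c < 0 and p below the cutoff.  Both inequalities are strict, and no
multiple-testing correction is applied to the per-gene p-values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import read_gmt, write_gmt

logger = logging.getLogger("drugresc")

DE_TABLE_COLUMNS = ["instance_id", "drug_name", "dose", "tissue", "gene", "logfc", "pvalue"]


@dataclass
class DEProfile:
    """Differential-expression vectors for one drug instance."""

    instance_id: str
    drug_name: str
    dose: float
    dose_unit: str
    tissue: str
    genes: list[str]
    logfc: np.ndarray
    pvalues: np.ndarray

    def __post_init__(self) -> None:
        self.logfc = np.asarray(self.logfc, dtype=float)
        self.pvalues = np.asarray(self.pvalues, dtype=float)
        n = len(self.genes)
        if self.logfc.shape != (n,) or self.pvalues.shape != (n,):
            raise ValueError("logfc, pvalues and genes must be aligned")
        if len(set(self.genes)) != n:
            raise ValueError("duplicate genes in DE profile")
        if ((self.pvalues < 0) | (self.pvalues > 1)).any():
            raise ValueError("p-values must lie in [0, 1]")


@dataclass
class DrugSignature:
    """Up- and down-regulated gene sets for one drug instance."""

    instance_id: str
    drug_name: str
    up: set[str]
    down: set[str]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        # Signatures derived from DE vectors are disjoint by construction
        # (a gene cannot have both c > 0 and c < 0); hand-built overlapping
        # sets are tolerated since the score is well defined for them.
        if self.up & self.down:
            logger.warning(
                "instance %s: up and down signatures share %d gene(s)",
                self.instance_id,
                len(self.up & self.down),
            )


def build_signature(profile: DEProfile, p_threshold: float = 0.01) -> DrugSignature:
    """Extract up/down signatures: strict c > 0 (resp. c < 0) and p < threshold."""
    if not 0 < p_threshold < 1:
        raise ValueError("p_threshold must lie in (0, 1)")
    sig = profile.pvalues < p_threshold
    genes = np.asarray(profile.genes, dtype=object)
    up = set(genes[sig & (profile.logfc > 0)])
    down = set(genes[sig & (profile.logfc < 0)])
    return DrugSignature(
        instance_id=profile.instance_id,
        drug_name=profile.drug_name,
        up=up,
        down=down,
        metadata={"dose": profile.dose, "dose_unit": profile.dose_unit, "tissue": profile.tissue},
    )


def filter_instances(
    profiles: list[DEProfile], dose_value: float, dose_unit: str
) -> list[DEProfile]:
    """Retain instances measured at the requested dose (order preserved)."""
    kept = [
        p
        for p in profiles
        if p.dose == dose_value and p.dose_unit.lower() == dose_unit.lower()
    ]
    if profiles and not kept:
        logger.warning(
            "no instance measured at %g %s among %d profiles",
            dose_value,
            dose_unit,
            len(profiles),
        )
    return kept


def flag_empty(signature: DrugSignature) -> bool:
    """True iff both sides are empty; flagged instances are excluded from scoring."""
    return not signature.up and not signature.down


def read_de_table(path: str | Path) -> list[DEProfile]:
    """Read a long-format DE table (TSV) into per-instance profiles.

    Expected columns: instance_id, drug_name, dose (e.g. "10uM"), tissue,
    gene, logfc, pvalue.
    """
    table = pd.read_csv(path, sep="\t", dtype={"instance_id": str, "drug_name": str})
    missing = [c for c in DE_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"DE table missing columns: {missing}")
    profiles = []
    for instance_id, grp in table.groupby("instance_id", sort=False):
        dose_value, dose_unit = _parse_dose(str(grp["dose"].iloc[0]))
        profiles.append(
            DEProfile(
                instance_id=str(instance_id),
                drug_name=str(grp["drug_name"].iloc[0]),
                dose=dose_value,
                dose_unit=dose_unit,
                tissue=str(grp["tissue"].iloc[0]),
                genes=list(grp["gene"]),
                logfc=grp["logfc"].to_numpy(),
                pvalues=grp["pvalue"].to_numpy(),
            )
        )
    return profiles


def write_de_table(profiles: list[DEProfile], path: str | Path) -> None:
    frames = []
    for p in profiles:
        frames.append(
            pd.DataFrame(
                {
                    "instance_id": p.instance_id,
                    "drug_name": p.drug_name,
                    "dose": f"{p.dose:g}{p.dose_unit}",
                    "tissue": p.tissue,
                    "gene": p.genes,
                    "logfc": p.logfc,
                    "pvalue": p.pvalues,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def _parse_dose(text: str) -> tuple[float, str]:
    text = text.strip()
    i = 0
    while i < len(text) and (text[i].isdigit() or text[i] in ".+-eE"):
        i += 1
    value = float(text[:i]) if i else float("nan")
    return value, text[i:].strip()


def signatures_to_gmt(signatures: list[DrugSignature], path: str | Path) -> None:
    """Write signatures as GMT: two records per instance, <id>__UP / <id>__DOWN."""
    records = []
    for sig in signatures:
        # a record needs >= 1 gene to satisfy the GMT dialect; an absent
        # record reads back as an empty side
        if sig.up:
            records.append((f"{sig.instance_id}__UP", sig.drug_name, sig.up))
        if sig.down:
            records.append((f"{sig.instance_id}__DOWN", sig.drug_name, sig.down))
    write_gmt(records, path)


def signatures_from_gmt(path: str | Path) -> list[DrugSignature]:
    """Read signatures from GMT, pairing <id>__UP / <id>__DOWN records."""
    ups: dict[str, tuple[str, set[str]]] = {}
    downs: dict[str, tuple[str, set[str]]] = {}
    for name, desc, genes in read_gmt(path):
        if name.endswith("__UP"):
            ups[name[: -len("__UP")]] = (desc, genes)
        elif name.endswith("__DOWN"):
            downs[name[: -len("__DOWN")]] = (desc, genes)
        else:
            raise ValueError(f"GMT record {name!r} lacks __UP/__DOWN suffix")
    signatures = []
    for instance_id in ups.keys() | downs.keys():
        desc_up, up = ups.get(instance_id, ("", set()))
        desc_down, down = downs.get(instance_id, ("", set()))
        signatures.append(
            DrugSignature(
                instance_id=instance_id,
                drug_name=desc_up or desc_down,
                up=up,
                down=down,
            )
        )
    signatures.sort(key=lambda s: s.instance_id)
    return signatures
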