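"""Core/variable gene classification from presence frequencies.

Genes are binned by the fraction of accessions carrying them:

    cloud     [0, 0.05)      — rare dispensable genes
    shell     [0.05, 0.95]   — segregating variable genes
    softcore  (0.95, 0.99]   — nearly universal
    hardcore  (0.99, 1]      — present in >99% of accessions

Core = hardcore + softcore (loss rate < 0.05); variable = shell + cloud
(loss rate >= 0.05). Frequencies are kept as exact rationals so boundary
genes (e.g. 202 of 204 accessions) never misclassify through floating point.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd

from .io import PavMatrix

CATEGORY_ORDER = ("cloud", "shell", "softcore", "hardcore")


@dataclass(frozen=True)
class ClassificationConfig:
    hardcore_min_excl: Fraction = Fraction(99, 100)
    softcore_min_excl: Fraction = Fraction(95, 100)
    cloud_max_excl: Fraction = Fraction(5, 100)

    def __post_init__(self):
        if not 0 < self.cloud_max_excl < self.softcore_min_excl < self.hardcore_min_excl < 1:
            raise ValueError("classification bounds must satisfy 0 < cloud < softcore < hardcore < 1")


def presence_frequency(matrix: PavMatrix) -> pd.Series:
    """Per-gene presence frequency as exact Fractions, indexed by gene id."""
    if matrix.n_accessions < 1:
        raise ValueError("need at least one accession")
    counts = matrix.presence.sum(axis=1)
    n = matrix.n_accessions
    return pd.Series([Fraction(int(c), n) for c in counts], index=matrix.gene_ids, name="frequency")


def categorize(freq, cfg: ClassificationConfig = ClassificationConfig()) -> tuple[str, str]:
    """Category and superclass for one presence frequency.

    Accepts a float or Fraction; Fractions give exact boundary behaviour.
    """
    f = freq if isinstance(freq, Fraction) else Fraction(freq).limit_denominator(10**12)
    if not 0 <= f <= 1:
        raise ValueError(f"frequency {float(f)} outside [0,1]")
    if f < cfg.cloud_max_excl:
        cat = "cloud"
    elif f <= cfg.softcore_min_excl:
        cat = "shell"
    elif f <= cfg.hardcore_min_excl:
        cat = "softcore"
    else:
        cat = "hardcore"
    superclass = "core" if f > cfg.softcore_min_excl else "variable"
    return cat, superclass


def classify_matrix(matrix: PavMatrix, cfg: ClassificationConfig = ClassificationConfig()) -> pd.DataFrame:
    """Per-gene category table: presence_count, frequency, category, superclass."""
    counts = matrix.presence.sum(axis=1)
    n = matrix.n_accessions
    cats, supers = [], []
    for c in counts:
        cat, sup = categorize(Fraction(int(c), n), cfg)
        cats.append(cat)
        supers.append(sup)
    return pd.DataFrame(
        {
            "presence_count": counts.astype(int),
            "frequency": counts / n,
            "category": pd.Categorical(cats, categories=CATEGORY_ORDER),
            "superclass": pd.Categorical(supers, categories=("core", "variable")),
        },
        index=pd.Index(matrix.gene_ids, name="gene_id"),
    )


def category_summary(table: pd.DataFrame) -> dict:
    """Counts and percentages per category and superclass."""
    total = len(table)
    out = {"n_genes": total, "categories": {}, "superclasses": {}}
    for cat, k in table["category"].value_counts().items():
        out["categories"][str(cat)] = {"count": int(k), "pct": 100.0 * k / total}
    for sup, k in table["superclass"].value_counts().items():
        out["superclasses"][str(sup)] = {"count": int(k), "pct": 100.0 * k / total}
    return out


def per_accession_composition(matrix: PavMatrix, table: pd.DataFrame) -> pd.DataFrame:
    """Gene-content composition of each accession.

    ``pct_core`` / ``pct_variable``: of the genes an accession carries, the
    percentage that are core / variable genes (sums to 100). ``core_set_frac``:
    the fraction of the panel's core gene set present in that accession —
    the two readings of "contains X% of the core genes" are both reported.
    """
    core_mask = (table["superclass"].to_numpy() == "core")
    pres = matrix.presence.astype(bool)
    n_present = pres.sum(axis=0)
    n_core_present = pres[core_mask].sum(axis=0)
    n_core_total = int(core_mask.sum())
    pct_core = np.where(n_present > 0, 100.0 * n_core_present / np.maximum(n_present, 1), 0.0)
    return pd.DataFrame(
        {
            "n_present": n_present,
            "pct_core": pct_core,
            "pct_variable": np.where(n_present > 0, 100.0 - pct_core, 0.0),
            "core_set_frac": n_core_present / n_core_total if n_core_total else np.nan,
        },
        index=pd.Index(matrix.accession_ids, name="accession_id"),
    )


def gene_loss_counts(matrix: PavMatrix) -> pd.Series:
    """Number of absent genes per accession (column-wise zero count)."""
    losses = (matrix.presence == 0).sum(axis=0)
    return pd.Series(losses.astype(int), index=matrix.accession_ids, name="gene_loss")
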