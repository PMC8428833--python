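"""Map-to-pan PAV calling: coverage breadth -> binary gene presence.

A gene is called present in an accession when the breadth of coverage of its
gene body is >= 0.75 and of its CDS union is >= 0.95 (both thresholds
inclusive). Breadth is computed at read depth >= depth_min (default 1); the
calling is agnostic to how deep the covered positions are beyond that.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .intervals import Interval, IntervalIndex, merge_intervals, total_length
from .io import CoverageProfile, GeneModel, PavMatrix

logger = logging.getLogger("panpav")


@dataclass(frozen=True)
class PresenceRule:
    """Inclusive breadth thresholds for declaring a gene present."""

    min_gene_body_cov: float = 0.75
    min_cds_cov: float = 0.95

    def __post_init__(self):
        for v in (self.min_gene_body_cov, self.min_cds_cov):
            if not 0 < v <= 1:
                raise ValueError("thresholds must lie in (0,1]")


def covered_fraction(region: Sequence[Interval], profile: CoverageProfile, seq_id: str) -> float:
    """Fraction of the region's positions covered by the profile on seq_id."""
    region = merge_intervals(region)
    n = total_length(region)
    if n == 0:
        raise ValueError("zero-length region union")
    cov = profile.covered.get(seq_id)
    if not cov:
        return 0.0
    return IntervalIndex(cov).covered_length(region) / n


@dataclass(frozen=True)
class PresenceCall:
    present: bool
    body_fraction: float
    cds_fraction: float


def call_presence(gene: GeneModel, profile: CoverageProfile, rule: PresenceRule = PresenceRule()) -> PresenceCall:
    """Apply the presence rule to one gene in one accession.

    A gene on a sequence absent from the profile has no coverage evidence and
    is called absent (with a warning).
    """
    if gene.seq_id not in profile.covered:
        logger.warning(
            "sequence %s not in coverage profile of %s; gene %s called absent",
            gene.seq_id, profile.accession_id, gene.gene_id,
        )
        return PresenceCall(False, 0.0, 0.0)
    idx = IntervalIndex(profile.covered[gene.seq_id])
    body = idx.covered_length([gene.gene_interval]) / gene.body_length
    cds = idx.covered_length(gene.cds_intervals) / gene.cds_length
    present = body >= rule.min_gene_body_cov and cds >= rule.min_cds_cov
    return PresenceCall(present, body, cds)


def build_pav_matrix(
    genes: Sequence[GeneModel],
    profiles: Sequence[CoverageProfile],
    rule: PresenceRule = PresenceRule(),
    return_fractions: bool = False,
) -> PavMatrix | tuple[PavMatrix, pd.DataFrame]:
    """Call presence for every gene x accession pair.

    Input ordering of genes and accessions is preserved. Optionally also
    returns the per-call body/CDS fractions as a long-format DataFrame.
    """
    if not genes or not profiles:
        raise ValueError("need at least one gene and one coverage profile")
    acc_ids = [p.accession_id for p in profiles]
    if len(set(acc_ids)) != len(acc_ids):
        raise ValueError("duplicate accession ids among coverage profiles")
    presence = np.zeros((len(genes), len(profiles)), dtype=np.uint8)
    rows = [] if return_fractions else None
    for a, prof in enumerate(profiles):
        indexes = {seq: IntervalIndex(ivs) for seq, ivs in prof.covered.items()}
        for g, gene in enumerate(genes):
            idx = indexes.get(gene.seq_id)
            if idx is None:
                body = cds = 0.0
            else:
                body = idx.covered_length([gene.gene_interval]) / gene.body_length
                cds = idx.covered_length(gene.cds_intervals) / gene.cds_length
            ok = body >= rule.min_gene_body_cov and cds >= rule.min_cds_cov
            presence[g, a] = 1 if ok else 0
            if rows is not None:
                rows.append((gene.gene_id, prof.accession_id, body, cds, int(ok)))
    matrix = PavMatrix([g.gene_id for g in genes], acc_ids, presence)
    if rows is not None:
        frac = pd.DataFrame(rows, columns=["gene_id", "accession_id", "body_cov", "cds_cov", "present"])
        return matrix, frac
    return matrix
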