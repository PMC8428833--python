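"""Long-read cross-validation of short-read PAV calls.

Two checks mirror how long-read structural variants corroborate map-to-pan
absence calls: (1) an absence call is *supported* when a long-read deletion
overlaps the gene body (partial or complete overlap, >=1 bp by default);
(2) novel nonreference sequences are *recovered* when enough of their k-mers
occur in the long-read insertion sequences (strand-insensitive canonical
k-mers stand in for read mapping).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import GeneModel, PavMatrix, SvCallSet

_COMP = str.maketrans("ACGT", "TGCA")


@dataclass
class SupportResult:
    per_gene: pd.DataFrame        # gene_id, supported
    n_absent: int
    n_supported: int
    rate: float | None            # None when no absent genes (not applicable)


def deletion_support(
    absent_genes: Sequence[GeneModel],
    deletions: SvCallSet,
    min_overlap_bp: int = 1,
) -> SupportResult:
    """Flag each absence call supported by >= min_overlap_bp of deletion overlap."""
    by_seq: dict[str, list[tuple[int, int]]] = {}
    for seq_id, iv in deletions.deletions:
        by_seq.setdefault(seq_id, []).append(iv)
    starts_ends = {
        seq: (np.array(sorted(s for s, _ in ivs)), sorted(ivs))
        for seq, ivs in by_seq.items()
    }
    rows = []
    n_supported = 0
    for gene in absent_genes:
        gs, ge = gene.gene_interval
        supported = False
        if gene.seq_id in starts_ends:
            for ds, de in starts_ends[gene.seq_id][1]:
                if min(ge, de) - max(gs, ds) >= min_overlap_bp:
                    supported = True
                    break
        rows.append((gene.gene_id, supported))
        n_supported += supported
    per_gene = pd.DataFrame(rows, columns=["gene_id", "supported"])
    n_absent = len(absent_genes)
    rate = n_supported / n_absent if n_absent else None
    return SupportResult(per_gene, n_absent, n_supported, rate)


def pav_deletion_support(
    genes: Sequence[GeneModel],
    matrix: PavMatrix,
    sv_by_accession: Mapping[str, SvCallSet],
    min_overlap_bp: int = 1,
) -> dict:
    """Support rates across validated accessions: per accession, pooled, averaged."""
    gene_by_id = {g.gene_id: g for g in genes}
    per_acc = {}
    pooled_sup = pooled_abs = 0
    for acc, calls in sv_by_accession.items():
        a = matrix.accession_ids.index(acc)
        absent = [gene_by_id[matrix.gene_ids[gi]] for gi in np.flatnonzero(matrix.presence[:, a] == 0)]
        res = deletion_support(absent, calls, min_overlap_bp)
        per_acc[acc] = res
        pooled_sup += res.n_supported
        pooled_abs += res.n_absent
    rates = [r.rate for r in per_acc.values() if r.rate is not None]
    return {
        "per_accession": per_acc,
        "pooled_rate": pooled_sup / pooled_abs if pooled_abs else None,
        "mean_rate": float(np.mean(rates)) if rates else None,
    }


def _canonical_kmers(seq: str, k: int) -> set[str]:
    seq = seq.upper()
    rc = seq.translate(_COMP)[::-1]
    out = set()
    for i in range(len(seq) - k + 1):
        fwd = seq[i : i + k]
        rev = rc[len(seq) - k - i : len(seq) - i]
        out.add(min(fwd, rev))
    return out


@dataclass
class RecoveryResult:
    per_sequence: pd.DataFrame    # name, length, containment, recovered
    recovered_bp_fraction: float


def insertion_recovery(
    novel_sequences: Mapping[str, str],
    insertions: SvCallSet,
    k: int = 31,
    min_containment: float = 0.8,
) -> RecoveryResult:
    """Fraction of novel sequence recovered among long-read insertions.

    A sequence is recovered when >= min_containment of its canonical k-mers
    occur in the union of insertion sequences; sequences shorter than k fall
    back to exact substring search (either strand). The aggregate statistic is
    recovered bp / total bp.
    """
    ins_kmers: set[str] = set()
    ins_seqs = []
    for _seq_id, _pos, _len, seq in insertions.insertions:
        ins_kmers |= _canonical_kmers(seq, k)
        ins_seqs.append(seq.upper())
    rows = []
    rec_bp = tot_bp = 0
    for name, seq in novel_sequences.items():
        seq_u = seq.upper()
        if len(seq_u) < k:
            rc = seq_u.translate(_COMP)[::-1]
            containment = 1.0 if any(seq_u in s or rc in s for s in ins_seqs) else 0.0
        else:
            kms = _canonical_kmers(seq_u, k)
            containment = len(kms & ins_kmers) / len(kms) if kms else 0.0
        recovered = containment >= min_containment
        rows.append((name, len(seq_u), containment, recovered))
        tot_bp += len(seq_u)
        if recovered:
            rec_bp += len(seq_u)
    df = pd.DataFrame(rows, columns=["name", "length", "containment", "recovered"])
    return RecoveryResult(df, rec_bp / tot_bp if tot_bp else 0.0)
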