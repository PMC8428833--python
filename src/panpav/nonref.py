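"""Nonreference ("novel") sequence extraction and accumulation.

Stages of building a pan-genome's nonreference component from per-accession
assemblies aligned to the reference: classify each contig from its alignment
summary (>=500 bp contigs; fully unaligned, or partially unaligned with
unaligned fragments >450 bp), excise those fragments, collapse redundancy by
greedy identity clustering (CD-HIT-like, longest sequence first), drop
contaminants using precomputed taxon-classified best hits, and summarise each
accession's novel-sequence contribution as an accumulation curve over random
accession orderings.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align

from .intervals import Interval, complement, merge_intervals

TAXON_CLASSES = ("viridiplantae_nuclear", "organellar", "microbial", "non_viridiplantae")
# priority used only to break exact e-value ties, most damning class first
_CLASS_PRIORITY = {"organellar": 0, "microbial": 1, "non_viridiplantae": 2, "viridiplantae_nuclear": 3}


@dataclass(frozen=True)
class ExtractionConfig:
    min_contig_bp: int = 500
    min_unaligned_fragment_bp: int = 450
    identity_max_to_reference: float = 0.90
    redundancy_identity: float = 0.90

    def __post_init__(self):
        if self.min_contig_bp <= 0 or self.min_unaligned_fragment_bp <= 0:
            raise ValueError("length thresholds must be positive")
        for f in (self.identity_max_to_reference, self.redundancy_identity):
            if not 0 < f <= 1:
                raise ValueError("identity thresholds must lie in (0,1]")


@dataclass
class ContigAlignmentSummary:
    contig_id: str
    length: int
    aligned_intervals: list[Interval]
    best_identity: float | None = None

    def __post_init__(self):
        if self.length < 1:
            raise ValueError(f"{self.contig_id}: non-positive length")
        merged = merge_intervals(self.aligned_intervals)
        for s, e in merged:
            if s < 0 or e > self.length:
                raise ValueError(f"{self.contig_id}: aligned interval ({s},{e}) outside contig")
        self.aligned_intervals = merged


class ContigClass(str, Enum):
    TOO_SHORT = "too_short"
    FULLY_UNALIGNED = "fully_unaligned"
    PARTIALLY_UNALIGNED = "partially_unaligned"
    ALIGNED = "aligned"


@dataclass(frozen=True)
class ContigClassification:
    label: ContigClass
    fragments: tuple[Interval, ...] = ()


def classify_contig(summary: ContigAlignmentSummary, cfg: ExtractionConfig = ExtractionConfig()) -> ContigClassification:
    """Assign exactly one label; unaligned fragments must be strictly >450 bp."""
    if summary.length < cfg.min_contig_bp:
        return ContigClassification(ContigClass.TOO_SHORT)
    if not summary.aligned_intervals:
        return ContigClassification(ContigClass.FULLY_UNALIGNED, ((0, summary.length),))
    frags = tuple(
        (s, e)
        for s, e in complement(summary.aligned_intervals, summary.length)
        if e - s > cfg.min_unaligned_fragment_bp
    )
    if frags:
        return ContigClassification(ContigClass.PARTIALLY_UNALIGNED, frags)
    return ContigClassification(ContigClass.ALIGNED)


def excise_fragments(contig_id: str, sequence: str, fragments: Sequence[Interval]) -> list[tuple[str, str]]:
    """Cut fragment subsequences, named ``contig_id:start-end``, in contig order."""
    out = []
    for s, e in sorted(fragments):
        if s < 0 or e > len(sequence):
            raise ValueError(f"{contig_id}: fragment ({s},{e}) out of bounds")
        out.append((f"{contig_id}:{s}-{e}", sequence[s:e]))
    return out


_aligner = Align.PairwiseAligner(
    mode="local", match_score=1, mismatch_score=-1, open_gap_score=-2, extend_gap_score=-1
)


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def pairwise_identity(a: str, b: str, word_k: int = 11) -> float:
    """Identity of the best local alignment: matches / alignment columns.

    When the sequences differ more than twofold in length, identity is
    approximated by k-mer containment of the shorter in the longer (a CD-HIT
    style shortcut for fragment-of-longer cases).
    """
    if not a or not b:
        return 0.0
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    if len(long_) > 2 * len(short):
        ks = _kmers(short, word_k)
        if not ks:
            return 1.0 if short in long_ else 0.0
        kl = _kmers(long_, word_k)
        return len(ks & kl) / len(ks)
    aln = _aligner.align(a, b)[0]
    c = aln.counts()
    cols = c.identities + c.mismatches + c.gaps
    return c.identities / cols if cols else 0.0


def remove_redundancy(
    sequences: Mapping[str, str] | Iterable[tuple[str, str]],
    identity_threshold: float = 0.90,
    word_k: int = 11,
) -> tuple[list[str], dict[str, str]]:
    """Greedy longest-first clustering at an identity threshold.

    Returns (representative ids ordered longest-first, member -> representative
    map covering every input id). Ties in length break by id, so output is
    deterministic.
    """
    items = list(sequences.items()) if isinstance(sequences, Mapping) else list(sequences)
    order = sorted(items, key=lambda kv: (-len(kv[1]), kv[0]))
    reps: list[tuple[str, str]] = []
    membership: dict[str, str] = {}
    for name, seq in order:
        home = None
        for rname, rseq in reps:
            if pairwise_identity(seq, rseq, word_k) >= identity_threshold:
                home = rname
                break
        if home is None:
            reps.append((name, seq))
            membership[name] = name
        else:
            membership[name] = home
    return [r for r, _ in reps], membership


@dataclass(frozen=True)
class HitRecord:
    contig_id: str
    subject_taxon_class: str
    e_value: float
    identity: float

    def __post_init__(self):
        if self.subject_taxon_class not in TAXON_CLASSES:
            raise ValueError(f"unknown taxon class {self.subject_taxon_class!r}")
        if self.e_value < 0:
            raise ValueError("e_value must be >= 0")


def filter_contaminants(contig_ids: Sequence[str], hits: Sequence[HitRecord]) -> list[str]:
    """Drop contigs whose best (lowest e-value) hit is not nuclear plant.

    Exact e-value ties resolve by class priority (organellar > microbial >
    non-Viridiplantae > nuclear plant), then by lower identity, so the removal
    decision is deterministic. Contigs without hits are retained.
    """
    by_contig: dict[str, list[HitRecord]] = {}
    for h in hits:
        by_contig.setdefault(h.contig_id, []).append(h)
    retained = []
    for cid in contig_ids:
        hs = by_contig.get(cid)
        if not hs:
            retained.append(cid)
            continue
        best = min(hs, key=lambda h: (h.e_value, _CLASS_PRIORITY[h.subject_taxon_class], h.identity))
        if best.subject_taxon_class == "viridiplantae_nuclear":
            retained.append(cid)
    return retained


def accumulation_curve(
    per_accession_novel: Mapping[str, set[str]],
    lengths: Mapping[str, int],
    step: int = 20,
    n_orders: int = 100,
    seed: int | None = None,
    exhaustive: bool = False,
) -> pd.DataFrame:
    """Mean cumulative novel sequence (bp) over random accession orderings.

    For each ordering, the union length of representative sequences is recorded
    at accession counts step, 2*step, ..., N (N always included). With
    ``exhaustive`` every ordering is enumerated instead of sampled.
    """
    accs = list(per_accession_novel)
    n = len(accs)
    if n == 0:
        raise ValueError("no accessions")
    checkpoints = list(range(step, n + 1, step)) if step <= n else []
    if not checkpoints or checkpoints[-1] != n:
        checkpoints.append(n)

    if exhaustive:
        orders: Iterable[Sequence[int]] = itertools.permutations(range(n))
    else:
        rng = np.random.default_rng(seed)
        orders = [rng.permutation(n) for _ in range(n_orders)]

    totals: list[list[int]] = []
    for order in orders:
        seen: set[str] = set()
        row = []
        cum = 0
        ck = iter(checkpoints)
        nxt = next(ck)
        for i, ai in enumerate(order, start=1):
            for rid in per_accession_novel[accs[ai]]:
                if rid not in seen:
                    seen.add(rid)
                    cum += lengths[rid]
            if i == nxt:
                row.append(cum)
                nxt = next(ck, None)
        totals.append(row)
    arr = np.asarray(totals, dtype=float)
    return pd.DataFrame(
        {
            "n_accessions": checkpoints,
            "mean_bp": arr.mean(axis=0),
            "min_bp": arr.min(axis=0),
            "max_bp": arr.max(axis=0),
        }
    )
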