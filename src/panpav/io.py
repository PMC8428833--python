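"""Domain types and readers/writers for every on-disk format the pipeline touches.

Internal coordinates are always 0-based half-open; GFF3 and depth tables use
their native 1-based conventions at the boundary. Every reader/writer pair is
a bijection on valid inputs (round-trip tested).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .intervals import Interval, merge_intervals, total_length

logger = logging.getLogger("panpav")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneModel:
    """One annotated gene: its body interval and the union of its CDS intervals.

    ``gene_interval`` and ``cds_intervals`` are 0-based half-open on ``seq_id``.
    Strand is carried for bookkeeping but ignored by all coverage computations.
    """

    gene_id: str
    seq_id: str
    strand: str
    gene_interval: Interval
    cds_intervals: tuple[Interval, ...]

    def __post_init__(self):
        s, e = self.gene_interval
        if not s < e:
            raise ValueError(f"{self.gene_id}: empty gene interval {self.gene_interval}")
        for cs, ce in self.cds_intervals:
            if cs < s or ce > e:
                raise ValueError(f"{self.gene_id}: CDS ({cs},{ce}) outside gene body")
        if total_length(self.cds_intervals) < 1:
            raise ValueError(f"{self.gene_id}: empty CDS union")

    @property
    def body_length(self) -> int:
        return self.gene_interval[1] - self.gene_interval[0]

    @property
    def cds_length(self) -> int:
        return total_length(self.cds_intervals)


@dataclass
class CoverageProfile:
    """Per-accession covered positions (read depth >= depth_min) by sequence."""

    accession_id: str
    covered: dict[str, list[Interval]]
    depth_min: int = 1

    def __post_init__(self):
        self.covered = {k: merge_intervals(v) for k, v in self.covered.items()}


@dataclass
class PavMatrix:
    """Genes x accessions binary presence matrix (1 = present, 0 = absent)."""

    gene_ids: list[str]
    accession_ids: list[str]
    presence: np.ndarray

    def __post_init__(self):
        self.presence = np.asarray(self.presence, dtype=np.uint8)
        if self.presence.shape != (len(self.gene_ids), len(self.accession_ids)):
            raise ValueError("presence matrix shape does not match id lists")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        if len(set(self.accession_ids)) != len(self.accession_ids):
            raise ValueError("duplicate accession ids")
        bad = ~np.isin(self.presence, (0, 1))
        if bad.any():
            g, a = np.argwhere(bad)[0]
            raise ValueError(
                f"non-binary cell at ({self.gene_ids[g]}, {self.accession_ids[a]})"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_accessions(self) -> int:
        return len(self.accession_ids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.presence, index=self.gene_ids, columns=self.accession_ids)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, PavMatrix)
            and self.gene_ids == other.gene_ids
            and self.accession_ids == other.accession_ids
            and np.array_equal(self.presence, other.presence)
        )


@dataclass
class SvCallSet:
    """Long-read structural variants for one accession.

    deletions: (seq_id, (start, end)) 0-based half-open.
    insertions: (seq_id, position, length, sequence).
    """

    accession_id: str
    deletions: list[tuple[str, Interval]] = field(default_factory=list)
    insertions: list[tuple[str, int, int, str]] = field(default_factory=list)

    def __post_init__(self):
        for seq_id, (s, e) in self.deletions:
            if e - s <= 0:
                raise ValueError(f"{self.accession_id}: non-positive deletion ({s},{e}) on {seq_id}")
        for seq_id, pos, length, seq in self.insertions:
            if length <= 0 or abs(len(seq) - length) > 1:
                raise ValueError(f"{self.accession_id}: insertion length mismatch at {seq_id}:{pos}")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def read_gff3(path: str | Path) -> list[GeneModel]:
    """Parse gene + CDS features into GeneModel objects.

    GFF3 1-based inclusive coordinates become 0-based half-open. CDS features
    are collected from any descendant level (direct children or via mRNA) and
    unioned per gene. A CDS outside its parent gene is dropped with a warning;
    a gene with no usable CDS is excluded with a warning.
    """
    path = Path(path)
    if path.stat().st_size == 0:
        return []
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        g_iv = (gene.start - 1, gene.end)
        cds: list[Interval] = []
        for c in db.children(gene, featuretype="CDS"):
            iv = (c.start - 1, c.end)
            if iv[0] < g_iv[0] or iv[1] > g_iv[1]:
                logger.warning("CDS %s outside gene %s; record rejected", iv, gene.id)
                continue
            cds.append(iv)
        cds = merge_intervals(cds)
        if not cds:
            logger.warning("gene %s has no CDS; excluded", gene.id)
            continue
        genes.append(
            GeneModel(
                gene_id=gene.id,
                seq_id=gene.seqid,
                strand=gene.strand if gene.strand in "+-" else ".",
                gene_interval=g_iv,
                cds_intervals=tuple(cds),
            )
        )
    return genes


def write_gff3(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Emit gene + CDS features (CDS as direct children of the gene)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            s, e = g.gene_interval
            fh.write(
                f"{g.seq_id}\tpanpav\tgene\t{s + 1}\t{e}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )
            for i, (cs, ce) in enumerate(g.cds_intervals):
                fh.write(
                    f"{g.seq_id}\tpanpav\tCDS\t{cs + 1}\t{ce}\t.\t{g.strand}\t0\t"
                    f"ID={g.gene_id}.cds{i};Parent={g.gene_id}\n"
                )


# ---------------------------------------------------------------------------
# Depth tables (samtools-depth-like TSV: seq_id, 1-based position, depth)
# ---------------------------------------------------------------------------

def read_depth_table(path: str | Path, depth_min: int = 1, accession_id: str | None = None) -> CoverageProfile:
    """Collapse a per-base depth table into covered intervals at depth >= depth_min.

    Positions must be sorted within each sequence; an unsorted position raises
    with the offending line number.
    """
    covered: dict[str, list[Interval]] = {}
    last: dict[str, int] = {}
    cur: dict[str, list[int] | None] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            seq_id, pos_s, depth_s = line.split("\t")
            pos, depth = int(pos_s), int(depth_s)
            if seq_id in last and pos <= last[seq_id]:
                raise ValueError(f"unsorted position at line {lineno}: {seq_id}:{pos}")
            last[seq_id] = pos
            ivs = covered.setdefault(seq_id, [])
            p0 = pos - 1  # 0-based
            if depth >= depth_min:
                run = cur.get(seq_id)
                if run is not None and run[1] == p0:
                    run[1] = p0 + 1
                else:
                    if run is not None:
                        ivs.append((run[0], run[1]))
                    cur[seq_id] = [p0, p0 + 1]
            else:
                run = cur.get(seq_id)
                if run is not None:
                    ivs.append((run[0], run[1]))
                    cur[seq_id] = None
    for seq_id, run in cur.items():
        if run is not None:
            covered[seq_id].append((run[0], run[1]))
    covered = {k: v for k, v in covered.items() if v}
    acc = accession_id if accession_id is not None else Path(path).stem
    return CoverageProfile(accession_id=acc, covered=covered, depth_min=depth_min)


def write_depth_table(profile: CoverageProfile, path: str | Path, depth: int = 1) -> None:
    """Write covered positions as a 1-based per-base depth table."""
    with open(path, "w") as fh:
        for seq_id in sorted(profile.covered):
            for s, e in profile.covered[seq_id]:
                for p in range(s, e):
                    fh.write(f"{seq_id}\t{p + 1}\t{depth}\n")


def read_coverage_intervals(path: str | Path, accession_id: str | None = None, depth_min: int = 1) -> CoverageProfile:
    """Covered-interval table: seq_id, start, end (0-based half-open TSV).

    The compact alternative to a per-base depth table for the same evidence.
    """
    covered: dict[str, list[Interval]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            seq_id, s, e = line.split("\t")[:3]
            covered.setdefault(seq_id, []).append((int(s), int(e)))
    acc = accession_id if accession_id is not None else Path(path).stem
    return CoverageProfile(accession_id=acc, covered=covered, depth_min=depth_min)


def write_coverage_intervals(profile: CoverageProfile, path: str | Path) -> None:
    with open(path, "w") as fh:
        for seq_id in sorted(profile.covered):
            for s, e in profile.covered[seq_id]:
                fh.write(f"{seq_id}\t{s}\t{e}\n")


# ---------------------------------------------------------------------------
# PAV matrix TSV (genes as rows, accessions as columns by default)
# ---------------------------------------------------------------------------

def read_pav_matrix(path: str | Path, transposed: bool = False) -> PavMatrix:
    """Read a tab-separated PAV matrix; set ``transposed`` if accessions are rows."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    vals = df.to_numpy()
    ok = np.isin(vals, ("0", "1"))
    if not ok.all():
        r, c = np.argwhere(~ok)[0]
        raise ValueError(f"non-binary cell at ({df.index[r]}, {df.columns[c]}): {vals[r, c]!r}")
    mat = vals.astype(np.uint8)
    if transposed:
        return PavMatrix(list(df.columns), [str(i) for i in df.index], mat.T)
    return PavMatrix([str(i) for i in df.index], list(df.columns), mat)


def write_pav_matrix(matrix: PavMatrix, path: str | Path) -> None:
    matrix.to_dataframe().to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# Square distance matrix TSV
# ---------------------------------------------------------------------------

def read_distance_matrix(path: str | Path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError("distance matrix row and column labels differ")
    return [str(i) for i in df.index], df.to_numpy(dtype=float)


def write_distance_matrix(labels: Sequence[str], values: np.ndarray, path: str | Path) -> None:
    pd.DataFrame(values, index=labels, columns=labels).to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# SV calls: deletion BED + insertion FASTA
# ---------------------------------------------------------------------------

def read_deletion_bed(path: str | Path, accession_id: str | None = None) -> SvCallSet:
    """BED3 of deletions: seq_id, start, end (0-based half-open)."""
    dels: list[tuple[str, Interval]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            dels.append((parts[0], (int(parts[1]), int(parts[2]))))
    acc = accession_id if accession_id is not None else Path(path).stem
    return SvCallSet(accession_id=acc, deletions=dels)


def write_deletion_bed(calls: SvCallSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for seq_id, (s, e) in calls.deletions:
            fh.write(f"{seq_id}\t{s}\t{e}\n")


def read_insertion_fasta(path: str | Path, accession_id: str = "") -> SvCallSet:
    """Insertions as FASTA with headers ``seq_id|position`` (0-based)."""
    ins = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq_id, pos = rec.id.rsplit("|", 1)
        seq = str(rec.seq)
        ins.append((seq_id, int(pos), len(seq), seq))
    return SvCallSet(accession_id=accession_id, insertions=ins)


def write_insertion_fasta(calls: SvCallSet, path: str | Path) -> None:
    recs = [
        SeqRecord(Seq(seq), id=f"{seq_id}|{pos}", description="")
        for seq_id, pos, _length, seq in calls.insertions
    ]
    SeqIO.write(recs, str(path), "fasta")


# ---------------------------------------------------------------------------
# FASTA helpers
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str] | Iterable[tuple[str, str]], path: str | Path) -> None:
    items = sequences.items() if isinstance(sequences, Mapping) else sequences
    recs = [SeqRecord(Seq(s), id=name, description="") for name, s in items]
    SeqIO.write(recs, str(path), "fasta")
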