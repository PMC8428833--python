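"""Ground-truthed synthetic pan-genomes for end-to-end pipeline testing.

The generator emulates the statistical structure of a crop pan-genome built
from ~200 resequenced accessions: a gene presence-frequency spectrum dominated
by (hard)core genes, coverage breadth concentrated near 1 for present genes and
near 0 for absent ones, a two-clade population structure expressed as frequency
shifts on shell genes, long-read deletion calls with boundary jitter, and an
SNP distance matrix correlated with the PAV distances. It does not simulate
reads, sequence mutation, or genotypes.

All randomness flows from a single seeded ``numpy.random.Generator``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .intervals import complement, merge_intervals
from .io import CoverageProfile, GeneModel, PavMatrix, SvCallSet

CATEGORIES = ("hardcore", "softcore", "shell", "cloud")


@dataclass
class SimConfig:
    """Study conditions for the synthetic pan-genome.

    Defaults mirror a 204-accession soybean-scale survey at desk scale:
    category fractions are the observed pan-genome spectrum (90.6% hardcore,
    2.6% softcore, 6.2% shell, 0.5% cloud), with 2,000 genes standing in for
    the full annotation.
    """

    n_accessions: int = 204
    n_genes: int = 2000
    frac_hardcore: float = 49431 / 54531
    frac_softcore: float = 1401 / 54531
    frac_shell: float = 3402 / 54531
    frac_cloud: float = 297 / 54531
    coverage_noise: float = 0.0
    clade_split: float = 0.5
    clade_bias: float = 0.3
    clade_informative_frac: float = 0.5
    seed: int = 0
    # genome layout
    n_seqs: int = 20
    gene_length: int = 1200
    cds_fraction: float = 0.5
    intergenic_gap: int = 300

    def __post_init__(self):
        fr = self.fractions
        if any(f < 0 or f > 1 for f in fr):
            raise ValueError("category fractions must lie in [0,1]")
        if abs(sum(fr) - 1.0) > 1e-2:
            raise ValueError(f"category fractions sum to {sum(fr):.4f}, not 1")
        if not 0 <= self.coverage_noise < 1:
            raise ValueError("coverage_noise must be in [0,1)")
        if self.n_accessions < 1 or self.n_genes < 1:
            raise ValueError("need at least one accession and one gene")

    @property
    def fractions(self) -> tuple[float, float, float, float]:
        return (self.frac_hardcore, self.frac_softcore, self.frac_shell, self.frac_cloud)


@dataclass
class SimulatedPangenome:
    genes: list[GeneModel]
    truth_frequency: np.ndarray            # per-gene base presence probability
    truth_category: list[str]              # generating category per gene
    truth_matrix: PavMatrix
    clade_assignment: dict[str, str]       # accession -> {"I", "II"}
    config: SimConfig = field(repr=False, default=None)


def _category_counts(n_genes: int, fractions: Sequence[float]) -> list[int]:
    """Largest-remainder apportionment: counts sum to n_genes exactly."""
    raw = np.asarray(fractions, dtype=float) * n_genes / sum(fractions)
    counts = np.floor(raw).astype(int)
    rem = raw - counts
    for i in np.argsort(-rem)[: n_genes - counts.sum()]:
        counts[i] += 1
    return list(counts)


def _layout_genes(cfg: SimConfig) -> list[GeneModel]:
    """Tandem genes on n_seqs sequences; two CDS exons per gene."""
    genes: list[GeneModel] = []
    per_seq = -(-cfg.n_genes // cfg.n_seqs)
    pitch = cfg.gene_length + cfg.intergenic_gap
    cds_total = max(2, int(round(cfg.gene_length * cfg.cds_fraction)))
    exon = cds_total // 2
    for i in range(cfg.n_genes):
        seq = i // per_seq
        slot = i % per_seq
        start = cfg.intergenic_gap + slot * pitch
        end = start + cfg.gene_length
        # exon 1 at the gene start, exon 2 ending at the gene end
        cds = ((start, start + exon), (end - (cds_total - exon), end))
        genes.append(
            GeneModel(
                gene_id=f"gene{i:05d}",
                seq_id=f"chr{seq + 1:02d}",
                strand="+" if i % 2 == 0 else "-",
                gene_interval=(start, end),
                cds_intervals=cds,
            )
        )
    return genes


def simulate_pangenome(config: SimConfig) -> SimulatedPangenome:
    """Draw per-gene presence frequencies by category and sample the truth matrix.

    Category assignment is deterministic by count (largest remainder), so the
    simulated spectrum matches the configured fractions exactly. Frequencies:
    hardcore exactly 1.0; softcore U(0.955, 0.99); shell U(0.06, 0.94); cloud
    U(1/n, 0.045). Guard margins keep sampling noise at n~200 from crossing
    class boundaries. Clade-informative shell genes get frequencies shifted by
    ±clade_bias/2 between the two clades (clade II keeps more genes). Any gene
    sampled absent everywhere is resampled: every pan-genome gene is present in
    at least one accession.
    """
    rng = np.random.default_rng(config.seed)
    n, g = config.n_accessions, config.n_genes
    counts = _category_counts(g, config.fractions)
    category = [c for c, k in zip(CATEGORIES, counts) for _ in range(k)]

    freq = np.ones(g)
    cat = np.asarray(category)
    n_soft = (cat == "softcore").sum()
    n_shell = (cat == "shell").sum()
    n_cloud = (cat == "cloud").sum()
    freq[cat == "softcore"] = rng.uniform(0.955, 0.99, n_soft)
    freq[cat == "shell"] = rng.uniform(0.06, 0.94, n_shell)
    cloud_lo = min(1.0 / n, 0.044)
    freq[cat == "cloud"] = rng.uniform(cloud_lo, 0.045, n_cloud)

    accession_ids = [f"acc{i:03d}" for i in range(n)]
    n_clade2 = int(round(config.clade_split * n))
    clade2 = np.zeros(n, dtype=bool)
    if n_clade2:
        clade2[-n_clade2:] = True
    clades = {a: ("II" if c2 else "I") for a, c2 in zip(accession_ids, clade2)}

    # per-gene per-accession presence probability
    prob = np.repeat(freq[:, None], n, axis=1)
    shell_idx = np.flatnonzero(cat == "shell")
    n_inf = int(round(config.clade_informative_frac * len(shell_idx)))
    informative = shell_idx[:n_inf]
    half = config.clade_bias / 2.0
    for gi in informative:
        prob[gi, ~clade2] = np.clip(freq[gi] - half, 0.01, 0.99)
        prob[gi, clade2] = np.clip(freq[gi] + half, 0.01, 0.99)

    presence = (rng.random((g, n)) < prob).astype(np.uint8)
    # every gene must survive somewhere in the panel
    for gi in np.flatnonzero(presence.sum(axis=1) == 0):
        for _ in range(100):
            row = (rng.random(n) < prob[gi]).astype(np.uint8)
            if row.any():
                presence[gi] = row
                break
        else:
            presence[gi, rng.integers(n)] = 1

    genes = _layout_genes(config)
    matrix = PavMatrix([g_.gene_id for g_ in genes], accession_ids, presence)
    return SimulatedPangenome(
        genes=genes,
        truth_frequency=freq,
        truth_category=category,
        truth_matrix=matrix,
        clade_assignment=clades,
        config=config,
    )


def _realize_cover(gene: GeneModel, cds_cov: int, noncds_cov: int) -> list[tuple[int, int]]:
    """Turn target covered-position counts into intervals inside the gene."""
    out: list[tuple[int, int]] = []
    rem = cds_cov
    for s, e in gene.cds_intervals:
        if rem <= 0:
            break
        take = min(e - s, rem)
        out.append((s, s + take))
        rem -= take
    rem = noncds_cov
    for s, e in complement(list(gene.cds_intervals), gene.gene_interval[1]):
        if s < gene.gene_interval[0]:
            s = gene.gene_interval[0]
        if rem <= 0 or e <= s:
            continue
        take = min(e - s, rem)
        out.append((s, s + take))
        rem -= take
    return out


def simulate_coverage(sim: SimulatedPangenome, config: SimConfig | None = None) -> list[CoverageProfile]:
    """Coverage evidence consistent with the truth matrix.

    Present genes draw gene-body breadth U(0.90, 1) and CDS breadth U(0.97, 1);
    absent genes draw U(0, 0.40) and U(0, 0.50). With probability
    ``coverage_noise`` a gene/accession pair draws from the opposite regime, so
    the expected downstream PAV-call error rate equals ``coverage_noise``
    exactly. Present-regime position counts round up and absent-regime counts
    round down, so noise-free calls reproduce the truth matrix bit-exactly.
    """
    cfg = config or sim.config
    rng = np.random.default_rng(cfg.seed + 1)
    genes = sim.genes
    pres = sim.truth_matrix.presence.astype(bool)
    g, n = pres.shape

    flip = rng.random((g, n)) < cfg.coverage_noise
    regime_present = pres ^ flip
    body_f = np.where(regime_present, rng.uniform(0.90, 1.0, (g, n)), rng.uniform(0.0, 0.40, (g, n)))
    cds_f = np.where(regime_present, rng.uniform(0.97, 1.0, (g, n)), rng.uniform(0.0, 0.50, (g, n)))

    body_len = np.array([gm.body_length for gm in genes])
    cds_len = np.array([gm.cds_length for gm in genes])
    cds_cov = np.where(
        regime_present,
        np.ceil(cds_f * cds_len[:, None]),
        np.floor(cds_f * cds_len[:, None]),
    ).astype(int)
    body_target = np.where(
        regime_present,
        np.ceil(body_f * body_len[:, None]),
        np.floor(body_f * body_len[:, None]),
    ).astype(int)
    noncds_cov = np.clip(body_target - cds_cov, 0, (body_len - cds_len)[:, None])

    profiles = []
    acc_ids = sim.truth_matrix.accession_ids
    for a, acc in enumerate(acc_ids):
        covered: dict[str, list[tuple[int, int]]] = {}
        for gi, gm in enumerate(genes):
            ivs = _realize_cover(gm, int(cds_cov[gi, a]), int(noncds_cov[gi, a]))
            if ivs:
                covered.setdefault(gm.seq_id, []).extend(ivs)
        profiles.append(
            CoverageProfile(accession_id=acc, covered={k: merge_intervals(v) for k, v in covered.items()}, depth_min=1)
        )
    return profiles


def simulate_sv_calls(
    sim: SimulatedPangenome,
    accession_id: str,
    jitter_bp: int = 50,
    dropout: float = 0.0,
    n_insertions: int = 0,
    insertion_length: int = 1000,
    seed: int | None = None,
) -> SvCallSet:
    """Long-read SV calls for one accession: one deletion per absent gene.

    Each absent gene yields a deletion spanning its gene body with endpoints
    jittered outward by U{0..jitter_bp}, omitted with probability ``dropout``
    (emulating imperfect long-read sensitivity). Insertions are random novel
    sequences at random positions.
    """
    try:
        a = sim.truth_matrix.accession_ids.index(accession_id)
    except ValueError:
        raise KeyError(f"unknown accession {accession_id!r}") from None
    rng = np.random.default_rng(sim.config.seed + 7 if seed is None else seed)
    dels: list[tuple[str, tuple[int, int]]] = []
    for gi in np.flatnonzero(sim.truth_matrix.presence[:, a] == 0):
        if dropout > 0 and rng.random() < dropout:
            continue
        gm = sim.genes[gi]
        s, e = gm.gene_interval
        s = max(0, s - int(rng.integers(0, jitter_bp + 1)))
        e = e + int(rng.integers(0, jitter_bp + 1))
        dels.append((gm.seq_id, (s, e)))
    ins = []
    for _ in range(n_insertions):
        seq = "".join(rng.choice(list("ACGT"), insertion_length))
        pos = int(rng.integers(0, 10_000_000))
        ins.append(("chr01", pos, insertion_length, seq))
    return SvCallSet(accession_id=accession_id, deletions=dels, insertions=ins)


def simulate_snp_distance(sim: SimulatedPangenome, mixing: float = 0.6, seed: int | None = None) -> np.ndarray:
    """SNP-like distance matrix correlated with the PAV distances.

    Returns ``mixing * D_pav + (1 - mixing) * noise`` where the noise is a
    random symmetric matrix rescaled to the PAV distances' mean, symmetrized,
    zero diagonal. The Mantel statistic against D_pav increases monotonically
    with ``mixing`` (1 -> r = 1, 0 -> r ~ 0).
    """
    if not 0 <= mixing <= 1:
        raise ValueError("mixing must be in [0,1]")
    from scipy.spatial.distance import pdist, squareform

    rng = np.random.default_rng(sim.config.seed + 13 if seed is None else seed)
    d_pav = squareform(pdist(sim.truth_matrix.presence.T, metric="hamming"))
    n = d_pav.shape[0]
    tri = np.triu_indices(n, k=1)
    scale = 2.0 * d_pav[tri].mean() if d_pav[tri].mean() > 0 else 1.0
    noise = np.zeros_like(d_pav)
    noise[tri] = rng.uniform(0, scale, len(tri[0]))
    noise = noise + noise.T
    out = mixing * d_pav + (1.0 - mixing) * noise
    np.fill_diagonal(out, 0.0)
    return out
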