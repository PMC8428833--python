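"""PAV-based population structure.

Accession-by-accession distances from the binary PAV matrix (simple matching
by default, Jaccard over present-gene sets optionally), PCA on the centred
binary matrix, a neighbor-joining tree, a Mantel permutation test against an
independent (SNP) distance matrix, and the Welch t contrast of gene loss
between clades.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj as _skbio_nj

from .io import PavMatrix


def pav_distance(
    matrix: PavMatrix,
    metric: str = "simple_matching",
    gene_subset: list[str] | None = None,
) -> DistanceMatrix:
    """Pairwise accession distances from gene presence/absence.

    simple_matching: fraction of genes whose presence state differs.
    jaccard: 1 - |A∩B| / |A∪B| over the accessions' present-gene sets.
    """
    if matrix.n_accessions < 2:
        raise ValueError("need at least 2 accessions")
    pres = matrix.presence
    if gene_subset is not None:
        idx = [matrix.gene_ids.index(g) for g in gene_subset]
        if not idx:
            raise ValueError("empty gene subset")
        pres = pres[idx]
    x = pres.T.astype(bool)
    if metric == "simple_matching":
        d = pdist(x, metric="hamming")
    elif metric == "jaccard":
        d = pdist(x, metric="jaccard")
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return DistanceMatrix(squareform(d), ids=matrix.accession_ids)


def pav_pca(matrix: PavMatrix, n_components: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of accessions on the column-centred binary matrix (genotype-PCA style).

    Columns (genes) are centred but not scaled. Component signs follow a
    deterministic convention: the loading of largest magnitude is positive.
    Returns (coordinates indexed by accession, explained-variance fractions).
    """
    if matrix.n_accessions < 2:
        raise ValueError("need at least 2 accessions")
    x = matrix.presence.T.astype(float)            # accessions x genes
    x -= x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    rank = int(np.sum(s > 1e-10))
    k = min(n_components, rank) if rank else min(n_components, len(s))
    # sign convention on loadings
    for i in range(len(s)):
        j = np.argmax(np.abs(vt[i]))
        if vt[i, j] < 0:
            vt[i] *= -1
            u[:, i] *= -1
    coords = u[:, :k] * s[:k]
    var = s**2
    explained = var / var.sum() if var.sum() > 0 else var
    df = pd.DataFrame(
        coords,
        index=pd.Index(matrix.accession_ids, name="accession_id"),
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    return df, explained[:k]


def nj_tree(dist: DistanceMatrix) -> TreeNode:
    """Neighbor-joining tree; negative branch lengths are clamped to zero."""
    if dist.shape[0] < 3:
        raise ValueError("need at least 3 taxa for NJ")
    if not np.isfinite(dist.data).all():
        raise ValueError("non-finite distances")
    return _skbio_nj(dist, neg_as_zero=True)


def clades_from_tree(tree: TreeNode) -> dict[str, str]:
    """Two-clade assignment: the bipartition across the longest internal edge.

    Falls back to the first internal edge when all internal branch lengths tie
    at zero. Returns accession -> {"I", "II"}; clade I is the side containing
    the lexicographically smallest tip name (deterministic labelling).
    """
    tips = {t.name for t in tree.tips()}
    best, best_len = None, -1.0
    for node in tree.non_tips(include_self=False):
        length = node.length or 0.0
        side = {t.name for t in node.tips()}
        if 0 < len(side) < len(tips) and length >= best_len:
            best_len, best = length, side
    if best is None:
        raise ValueError("tree has no internal edge to split on")
    other = tips - best
    anchor = min(tips)
    clade1 = best if anchor in best else other
    return {name: ("I" if name in clade1 else "II") for name in tips}


def _condensed(d: np.ndarray) -> np.ndarray:
    return squareform(np.asarray(d, dtype=float), checks=False)


@dataclass(frozen=True)
class MantelResult:
    statistic: float
    p_value: float
    n_permutations: int
    alternative: str


def mantel_test(
    d1: DistanceMatrix | np.ndarray,
    d2: DistanceMatrix | np.ndarray,
    n_perm: int = 9999,
    seed: int | None = None,
    alternative: str = "greater",
    exact: bool = False,
) -> MantelResult:
    """Mantel permutation test between two distance matrices.

    r is the Pearson correlation of the upper-triangle entries. The p-value
    permutes rows and columns of d2 simultaneously:
    p = (1 + #{permuted r as or more extreme}) / (1 + n_perm). With
    ``exact=True`` all n! label permutations are enumerated (identity
    included) and p = #{r as extreme} / n!.
    """
    m1 = d1.data if isinstance(d1, DistanceMatrix) else np.asarray(d1, float)
    m2 = d2.data if isinstance(d2, DistanceMatrix) else np.asarray(d2, float)
    if isinstance(d1, DistanceMatrix) and isinstance(d2, DistanceMatrix):
        if list(d1.ids) != list(d2.ids):
            raise ValueError("distance matrices must share labels in the same order")
    if m1.shape != m2.shape:
        raise ValueError("distance matrices must have the same shape")
    v1 = _condensed(m1)
    if v1.std() == 0 or _condensed(m2).std() == 0:
        raise ValueError("constant distance matrix: Mantel correlation undefined")

    def corr(perm: np.ndarray) -> float:
        v2 = _condensed(m2[np.ix_(perm, perm)])
        return float(np.corrcoef(v1, v2)[0, 1])

    n = m1.shape[0]
    observed = corr(np.arange(n))

    def extreme(r: float) -> bool:
        if alternative == "greater":
            return r >= observed
        if alternative == "less":
            return r <= observed
        return abs(r) >= abs(observed)

    if exact:
        perms = [np.array(p) for p in itertools.permutations(range(n))]
        hits = sum(extreme(corr(p)) for p in perms)
        return MantelResult(observed, hits / len(perms), len(perms), alternative)

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        if extreme(corr(rng.permutation(n))):
            hits += 1
    return MantelResult(observed, (1 + hits) / (1 + n_perm), n_perm, alternative)


@dataclass(frozen=True)
class WelchResult:
    statistic: float
    df: float
    p_value: float
    mean_a: float
    mean_b: float


def welch_t(a, b) -> WelchResult:
    """Welch two-sample t-test (unequal variances), two-sided."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        raise ValueError("both samples have zero variance")
    res = stats.ttest_ind(a, b, equal_var=False)
    return WelchResult(float(res.statistic), float(res.df), float(res.pvalue), a.mean(), b.mean())


def clade_gene_loss_contrast(matrix: PavMatrix, clades: dict[str, str]) -> dict:
    """Welch contrast of per-accession gene-loss counts between two clades."""
    from .classify import gene_loss_counts

    losses = gene_loss_counts(matrix)
    a = losses[[acc for acc in matrix.accession_ids if clades[acc] == "I"]]
    b = losses[[acc for acc in matrix.accession_ids if clades[acc] == "II"]]
    w = welch_t(a.to_numpy(), b.to_numpy())
    return {
        "clade_I_mean_loss": w.mean_a,
        "clade_II_mean_loss": w.mean_b,
        "t": w.statistic,
        "df": w.df,
        "p_value": w.p_value,
        "n_clade_I": int(len(a)),
        "n_clade_II": int(len(b)),
    }
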