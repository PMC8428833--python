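"""Nei-Gojobori (1986) dN/dS from pairwise codon alignments.

Synonymous site counts follow the classic scheme: at each codon position the
synonymous fraction is the share of the three possible nucleotide changes that
preserve the amino acid (changes creating a stop codon count as
nonsynonymous); site totals are averaged over the two sequences, and S + N
always equals the nucleotide length. Observed differences are resolved by
averaging the synonymous/nonsynonymous step counts over all minimal
mutational pathways between each codon pair, excluding pathways that pass
through a stop codon (all pathways are used if every one is blocked).
Proportions are Jukes-Cantor corrected, d = -(3/4)ln(1 - (4/3)p); the ratio
is undefined when dS = 0 or when a proportion reaches the correction's 3/4
divergence ceiling.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

from Bio.Data import CodonTable

_table = CodonTable.unambiguous_dna_by_id[1]
CODON_TO_AA = dict(_table.forward_table)
for _stop in _table.stop_codons:
    CODON_TO_AA[_stop] = "*"
_BASES = "ACGT"


def _is_valid_codon(c: str) -> bool:
    return len(c) == 3 and all(b in _BASES for b in c)


def syn_fraction_per_site(codon: str) -> tuple[float, float, float]:
    """Synonymous fraction of the 3 possible changes at each codon position."""
    aa = CODON_TO_AA[codon]
    out = []
    for pos in range(3):
        syn = 0
        for b in _BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            if CODON_TO_AA[mut] == aa and CODON_TO_AA[mut] != "*":
                syn += 1
        out.append(syn / 3.0)
    return tuple(out)


def codon_sites(codon: str) -> tuple[float, float]:
    """(S, N) site counts for one codon; S + N = 3 exactly."""
    s = sum(syn_fraction_per_site(codon))
    return s, 3.0 - s


def codon_differences(c1: str, c2: str) -> tuple[float, float]:
    """(Sd, Nd) averaged over all minimal mutational pathways between codons.

    Pathways with an intermediate (or endpoint-reached-mid-path) stop codon
    are excluded; if every pathway is blocked, all are averaged.
    """
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff_pos):
        cur = c1
        steps = []
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if CODON_TO_AA[nxt] == "*" and nxt != c2:
                blocked = True
            steps.append(1.0 if CODON_TO_AA[nxt] == CODON_TO_AA[cur] else 0.0)
            cur = nxt
        paths.append((blocked, steps))
    usable = [steps for blocked, steps in paths if not blocked] or [s for _, s in paths]
    sd = sum(sum(steps) for steps in usable) / len(usable)
    return sd, len(diff_pos) - sd


def jukes_cantor(p: float) -> float:
    """JC69 multiple-hit correction; undefined at p >= 3/4."""
    if p >= 0.75:
        raise ValueError(f"proportion {p:.4f} >= 3/4: Jukes-Cantor correction undefined")
    return -0.75 * math.log(1.0 - (4.0 / 3.0) * p)


@dataclass(frozen=True)
class CodonAlignment:
    """A gap-free pairwise codon alignment (equal length, multiple of 3)."""

    seq1: str
    seq2: str

    def __post_init__(self):
        s1, s2 = self.seq1.upper(), self.seq2.upper()
        object.__setattr__(self, "seq1", s1)
        object.__setattr__(self, "seq2", s2)
        if len(s1) != len(s2):
            raise ValueError("sequences differ in length")
        if len(s1) % 3 != 0 or len(s1) < 3:
            raise ValueError("alignment length must be a positive multiple of 3")
        n_codons = len(s1) // 3
        for i in range(n_codons - 1):  # terminal stop tolerated
            for s in (s1, s2):
                c = s[3 * i : 3 * i + 3]
                if _is_valid_codon(c) and CODON_TO_AA[c] == "*":
                    raise ValueError(f"internal stop codon {c} at codon {i + 1}")

    def codon_pairs(self):
        for i in range(0, len(self.seq1), 3):
            yield self.seq1[i : i + 3], self.seq2[i : i + 3]


@dataclass(frozen=True)
class DnDsResult:
    dn: float | None
    ds: float | None
    ratio: float | None
    s_sites: float
    n_sites: float
    sd: float
    nd: float
    n_codons_used: int


def ng86_dnds(aln: CodonAlignment) -> DnDsResult:
    """NG86 dN and dS with Jukes-Cantor correction; ratio None when dS = 0.

    Codon pairs containing ambiguity characters (or a terminal stop in either
    sequence) are skipped pairwise. Symmetric in its two sequences.
    """
    s_sites = n_sites = sd = nd = 0.0
    used = 0
    for c1, c2 in aln.codon_pairs():
        if not (_is_valid_codon(c1) and _is_valid_codon(c2)):
            continue
        if CODON_TO_AA[c1] == "*" or CODON_TO_AA[c2] == "*":
            continue
        s1, n1 = codon_sites(c1)
        s2, n2 = codon_sites(c2)
        s_sites += (s1 + s2) / 2.0
        n_sites += (n1 + n2) / 2.0
        dsd, dnd = codon_differences(c1, c2)
        sd += dsd
        nd += dnd
        used += 1
    if used == 0:
        raise ValueError("no usable codons in alignment")
    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    try:
        ds = jukes_cantor(ps)
        dn = jukes_cantor(pn)
    except ValueError:
        return DnDsResult(None, None, None, s_sites, n_sites, sd, nd, used)
    ratio = dn / ds if ds > 0 else None
    return DnDsResult(dn, ds, ratio, s_sites, n_sites, sd, nd, used)
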