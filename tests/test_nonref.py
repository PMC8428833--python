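"""Contig classification rules, redundancy clustering, contaminant filtering,
and the novel-sequence accumulation curve."""

import itertools

import numpy as np
import pytest

from panpav.nonref import (
    ContigAlignmentSummary,
    ContigClass,
    ExtractionConfig,
    HitRecord,
    accumulation_curve,
    classify_contig,
    excise_fragments,
    filter_contaminants,
    pairwise_identity,
    remove_redundancy,
)


# ---------------------------------------------------------------------------
# classification (500 bp contig / 450 bp fragment rules)
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "length, aligned, label, fragments",
    [
        (400, [], ContigClass.TOO_SHORT, ()),
        (499, [(0, 100)], ContigClass.TOO_SHORT, ()),
        (500, [], ContigClass.FULLY_UNALIGNED, ((0, 500),)),
        (1000, [], ContigClass.FULLY_UNALIGNED, ((0, 1000),)),
        (1000, [(0, 400)], ContigClass.PARTIALLY_UNALIGNED, ((400, 1000),)),   # 600 > 450
        (1000, [(0, 600)], ContigClass.ALIGNED, ()),                           # residual 400 <= 450
        (1000, [(0, 550)], ContigClass.ALIGNED, ()),                           # residual 450: not strictly longer
        (2000, [(500, 1000)], ContigClass.PARTIALLY_UNALIGNED, ((0, 500), (1000, 2000))),
        (1000, [(0, 1000)], ContigClass.ALIGNED, ()),
    ],
)
def test_classify_contig_rule_sweep(length, aligned, label, fragments):
    res = classify_contig(ContigAlignmentSummary("c", length, aligned))
    assert res.label == label
    assert res.fragments == fragments


def test_classify_contig_residual_451_is_partially_unaligned():
    res = classify_contig(ContigAlignmentSummary("c", 1000, [(0, 549)]))
    # 451 bp residual is strictly longer than 450
    assert res.label == ContigClass.PARTIALLY_UNALIGNED
    assert res.fragments == ((549, 1000),)


def test_classify_partitions_and_fragment_lengths(rng):
    cfg = ExtractionConfig()
    for _ in range(200):
        length = int(rng.integers(100, 3000))
        n_aln = int(rng.integers(0, 4))
        ivs = []
        for _ in range(n_aln):
            s = int(rng.integers(0, length))
            ivs.append((s, min(length, s + int(rng.integers(1, 1200)))))
        res = classify_contig(ContigAlignmentSummary("c", length, ivs), cfg)
        assert res.label in set(ContigClass)
        for s, e in res.fragments:
            assert e - s > cfg.min_unaligned_fragment_bp


def test_overlapping_aligned_intervals_merged():
    summ = ContigAlignmentSummary("c", 1000, [(0, 300), (200, 520)])
    assert summ.aligned_intervals == [(0, 520)]
    # merged alignment leaves a 480 bp residual, still > 450
    res = classify_contig(summ)
    assert res.label == ContigClass.PARTIALLY_UNALIGNED
    assert res.fragments == ((520, 1000),)


# ---------------------------------------------------------------------------
# fragment excision
# ---------------------------------------------------------------------------

def test_excise_fragments_substrings(rng):
    seq = "".join(rng.choice(list("ACGT"), 1000))
    frags = excise_fragments("c1", seq, [(0, 100), (800, 1000)])
    assert frags == [("c1:0-100", seq[:100]), ("c1:800-1000", seq[800:])]
    assert excise_fragments("c1", seq, [(0, len(seq))]) == [(f"c1:0-{len(seq)}", seq)]
    assert excise_fragments("c1", seq, []) == []
    with pytest.raises(ValueError):
        excise_fragments("c1", seq, [(900, 1100)])


# ---------------------------------------------------------------------------
# redundancy removal
# ---------------------------------------------------------------------------

def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


def _mutate(rng, seq, rate):
    s = list(seq)
    for pos in rng.choice(len(s), size=max(1, int(rate * len(s))), replace=False):
        s[pos] = rng.choice([b for b in "ACGT" if b != s[pos]])
    return "".join(s)


def test_identical_sequences_collapse():
    reps, members = remove_redundancy({"a": "ACGTACGTACGT" * 10, "b": "ACGTACGTACGT" * 10})
    assert reps == ["a"]
    assert members == {"a": "a", "b": "a"}


def test_unrelated_sequences_stay_apart(rng):
    reps, _ = remove_redundancy({"a": _random_seq(rng, 1000), "b": _random_seq(rng, 1000)})
    assert sorted(reps) == ["a", "b"]


def test_planted_pairs_cluster_with_their_source(rng):
    seqs = {}
    truth = {}
    for i in range(5):
        base = _random_seq(rng, 900 + 50 * i)
        seqs[f"s{i}"] = base
        seqs[f"s{i}m"] = _mutate(rng, base, 0.03)  # ~97% identity
        truth[f"s{i}"] = truth[f"s{i}m"] = f"s{i}"
    reps, members = remove_redundancy(seqs, identity_threshold=0.90)
    assert len(reps) == 5
    clusters = {}
    for member, rep in members.items():
        clusters.setdefault(rep, set()).add(member)
    expect = {}
    for member, src in truth.items():
        expect.setdefault(src, set()).add(member)
    assert sorted(map(sorted, clusters.values())) == sorted(map(sorted, expect.values()))
    # representatives mutually below the threshold
    for a, b in itertools.combinations(reps, 2):
        assert pairwise_identity(seqs[a], seqs[b]) < 0.90
    # union of clusters covers the input
    assert set(members) == set(seqs)


def test_kmer_containment_path_for_length_mismatch(rng):
    long_seq = _random_seq(rng, 3000)
    fragment = long_seq[1000:1900]  # 900 bp inside 3000 bp: >2x length ratio
    assert pairwise_identity(fragment, long_seq) == pytest.approx(1.0)
    reps, members = remove_redundancy({"long": long_seq, "frag": fragment})
    assert reps == ["long"] and members["frag"] == "long"


def test_deterministic_output_order(rng):
    seqs = {f"s{i}": _random_seq(rng, 600) for i in range(6)}
    r1, m1 = remove_redundancy(dict(sorted(seqs.items())))
    r2, m2 = remove_redundancy(dict(sorted(seqs.items(), reverse=True)))
    assert r1 == r2 and m1 == m2


# ---------------------------------------------------------------------------
# contaminant filtering
# ---------------------------------------------------------------------------

def test_no_hits_all_retained():
    assert filter_contaminants(["c1", "c2"], []) == ["c1", "c2"]


def test_best_hit_organellar_removed():
    hits = [
        HitRecord("c1", "organellar", 1e-50, 0.98),
        HitRecord("c1", "viridiplantae_nuclear", 1e-10, 0.95),
    ]
    assert filter_contaminants(["c1"], hits) == []


def test_best_hit_plant_retained_despite_microbial_hit():
    hits = [
        HitRecord("c1", "viridiplantae_nuclear", 1e-80, 0.99),
        HitRecord("c1", "microbial", 1e-20, 0.90),
    ]
    assert filter_contaminants(["c1"], hits) == ["c1"]


def test_evalue_tie_resolved_by_class_priority():
    hits = [
        HitRecord("c1", "viridiplantae_nuclear", 1e-30, 0.99),
        HitRecord("c1", "organellar", 1e-30, 0.99),
    ]
    assert filter_contaminants(["c1"], hits) == []


def test_mixed_table_matches_argmin_scan(rng):
    classes = ["viridiplantae_nuclear", "organellar", "microbial", "non_viridiplantae"]
    contigs = [f"c{i}" for i in range(30)]
    hits = []
    for cid in contigs:
        for _ in range(int(rng.integers(0, 5))):
            hits.append(HitRecord(cid, classes[int(rng.integers(4))],
                                  float(10.0 ** -rng.integers(5, 60)), float(rng.uniform(0.5, 1.0))))
    got = filter_contaminants(contigs, hits)
    prio = {"organellar": 0, "microbial": 1, "non_viridiplantae": 2, "viridiplantae_nuclear": 3}
    expect = []
    for cid in contigs:
        mine = [h for h in hits if h.contig_id == cid]
        if not mine:
            expect.append(cid)
            continue
        best = min(mine, key=lambda h: (h.e_value, prio[h.subject_taxon_class], h.identity))
        if best.subject_taxon_class == "viridiplantae_nuclear":
            expect.append(cid)
    assert got == expect


# ---------------------------------------------------------------------------
# accumulation curve
# ---------------------------------------------------------------------------

def test_single_accession_flat_curve():
    sets = {"a1": {"r1", "r2"}}
    lengths = {"r1": 100, "r2": 50}
    df = accumulation_curve(sets, lengths, step=20)
    assert list(df.n_accessions) == [1]
    assert df.mean_bp.iloc[0] == 150


def test_disjoint_equal_sets_linear_curve():
    sets = {f"a{i}": {f"r{i}"} for i in range(6)}
    lengths = {f"r{i}": 100 for i in range(6)}
    df = accumulation_curve(sets, lengths, step=2, n_orders=5, seed=0)
    assert list(df.n_accessions) == [2, 4, 6]
    np.testing.assert_allclose(df.mean_bp, [200, 400, 600])
    np.testing.assert_allclose(df.min_bp, df.max_bp)


def test_exhaustive_mean_matches_bruteforce_n4(rng):
    universe = [f"r{i}" for i in range(8)]
    lengths = {r: int(rng.integers(50, 500)) for r in universe}
    sets = {f"a{j}": {r for r in universe if rng.random() < 0.5} for j in range(4)}
    df = accumulation_curve(sets, lengths, step=1, exhaustive=True)
    accs = list(sets)
    oracle = {n: [] for n in range(1, 5)}
    for order in itertools.permutations(range(4)):
        seen = set()
        for i, ai in enumerate(order, start=1):
            seen |= sets[accs[ai]]
            oracle[i].append(sum(lengths[r] for r in seen))
    np.testing.assert_allclose(df.mean_bp, [np.mean(oracle[n]) for n in range(1, 5)])
    np.testing.assert_allclose(df.min_bp, [min(oracle[n]) for n in range(1, 5)])
    np.testing.assert_allclose(df.max_bp, [max(oracle[n]) for n in range(1, 5)])


def test_curve_monotone_and_order_independent_total(rng):
    universe = [f"r{i}" for i in range(20)]
    lengths = {r: int(rng.integers(10, 300)) for r in universe}
    sets = {f"a{j}": {r for r in universe if rng.random() < 0.4} for j in range(9)}
    df = accumulation_curve(sets, lengths, step=3, n_orders=50, seed=1)
    assert (np.diff(df.mean_bp) >= 0).all()
    total = sum(lengths[r] for s in sets.values() for r in s if True)
    union_total = sum(lengths[r] for r in set().union(*sets.values()))
    assert df.min_bp.iloc[-1] == df.max_bp.iloc[-1] == union_total
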