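"""NJ correctness, bootstrap, clade assignment, pseudo-outgroup."""

import numpy as np
import pytest

from sdrpipe import phylo
from sdrpipe._codec import decode, encode

from conftest import random_seq


def _matrix_from_seqs(seqs: dict):
    ids = list(seqs)
    mat = np.stack([encode(seqs[i]) for i in ids])
    return phylo.AlignmentMatrix(ids, mat, {i: 0.0 for i in ids})


def _mutate_seq(seq, rng, n):
    out = list(seq)
    for p in rng.choice(len(seq), n, replace=False):
        out[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[p]]
    return "".join(out)


def island_seqs(rng, n_clades=3, per_clade=3, length=2000, clade_muts=25,
                tip_muts=4, shared_pattern=None):
    """Star-truth sequences: one ancestor, independent clade branches."""
    anc = random_seq(rng, length)
    seqs, truth = {}, {}
    for ci in range(n_clades):
        clade_seq = _mutate_seq(anc, rng, clade_muts)
        for t in range(per_clade):
            tid = f"c{ci}t{t}"
            seqs[tid] = _mutate_seq(clade_seq, rng, tip_muts)
            truth[tid] = ci
    return anc, seqs, truth


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def test_nj_recovers_all_three_quartets():
    # additive distances for ((a,b),(c,d)) and its two relabelings
    for pair in (("a", "b"), ("a", "c"), ("a", "d")):
        names = ["a", "b", "c", "d"]
        other = [n for n in names if n not in pair]
        D = np.zeros((4, 4))
        for i, x in enumerate(names):
            for j, y in enumerate(names):
                if i == j:
                    continue
                same = {x, y} == set(pair) or {x, y} == set(other)
                D[i, j] = 0.2 if same else 0.5
        adj = phylo.nj_adjacency(D)
        bips = phylo.tree_bipartitions(adj, names, "a")
        assert frozenset(other) in bips


def _random_additive_matrix(rng, n):
    """Pairwise path distances on a random binary tree."""
    D = np.zeros((n, n))
    clusters = [{i: 0.0} for i in range(n)]
    while len(clusters) > 1:
        i, j = sorted(rng.choice(len(clusters), 2, replace=False))
        b = clusters.pop(j)
        a = clusters.pop(i)
        ba, bb = rng.uniform(0.05, 0.5, 2)
        for x, dx in a.items():
            for y, dy in b.items():
                D[x, y] = D[y, x] = dx + ba + dy + bb
        clusters.append({**{x: d + ba for x, d in a.items()},
                         **{y: d + bb for y, d in b.items()}})
    return D


def test_nj_matches_skbio_on_random_additive_trees(rng):
    pytest.importorskip("skbio")
    from skbio import DistanceMatrix
    from skbio.tree import nj as skbio_nj

    for _ in range(4):
        n = 7
        names = [f"t{i}" for i in range(n)]
        D = _random_additive_matrix(rng, n)
        ours = phylo.tree_bipartitions(phylo.nj_adjacency(D), names, names[0])
        theirs = skbio_nj(DistanceMatrix(D, names))
        their_bips = set()
        for node in theirs.non_tips():
            tips = frozenset(t.name for t in node.tips())
            if names[0] in tips:
                tips = frozenset(names) - tips
            if 2 <= len(tips) <= n - 2:
                their_bips.add(tips)
        assert set(ours) == their_bips


def test_nj_recovers_generating_topology(rng):
    """On additive data NJ equals the minimum-evolution tree = truth."""
    _, seqs, truth = island_seqs(rng, n_clades=2, per_clade=3)
    aln = _matrix_from_seqs(seqs)
    D = phylo.jc_distance_matrix(aln.matrix)
    bips = phylo.tree_bipartitions(phylo.nj_adjacency(D), aln.ids, aln.ids[0])
    clade1 = frozenset(t for t, c in truth.items() if c == 1)
    assert clade1 in bips


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def test_jc_pairwise_deletion_ignores_missing(rng):
    a = encode("ACGTACGTAC")
    b = a.copy()
    b[0] = 4  # N: excluded
    c = a.copy()
    c[1] = (c[1] + 1) % 4
    mat = np.stack([a, b, c])
    D = phylo.jc_distance_matrix(mat)
    assert D[0, 1] == 0.0
    assert D[0, 2] > 0.0


# ---------------------------------------------------------------------------
# build_tree
# ---------------------------------------------------------------------------

def test_bootstrap_support_is_100_on_clean_signal(rng):
    anc, seqs, truth = island_seqs(rng, n_clades=2, per_clade=3,
                                   clade_muts=40, tip_muts=2)
    og = _mutate_seq(anc, rng, 200)
    aln = _matrix_from_seqs({**seqs, "out": og})
    tree = phylo.build_tree(aln, "out", bootstrap_n=50, seed=1)
    clade_sets = {c.tips: c.support for c in tree.clades}
    for ci in (0, 1):
        tips = frozenset(t for t, c in truth.items() if c == ci)
        assert clade_sets.get(tips) == 100.0


def test_identical_sequences_star_flagged(rng):
    seq = random_seq(rng, 500)
    aln = _matrix_from_seqs({f"t{i}": seq for i in range(4)})
    tree = phylo.build_tree(aln, "t0", bootstrap_n=10, seed=0)
    assert any("star" in f for f in tree.flags)
    assert tree.clades == []


def test_build_tree_needs_four_tips(rng):
    aln = _matrix_from_seqs({"a": "ACGT", "b": "ACGT", "c": "ACGA"})
    with pytest.raises(ValueError):
        phylo.build_tree(aln, "a")


# ---------------------------------------------------------------------------
# assign_clades
# ---------------------------------------------------------------------------

def _tree_from_islands(rng, **kw):
    anc, seqs, truth = island_seqs(rng, **kw)
    og = _mutate_seq(anc, rng, 200)
    aln = _matrix_from_seqs({**seqs, "out": og})
    return phylo.build_tree(aln, "out", bootstrap_n=60, seed=2), truth


def test_three_islands_give_three_clades(rng):
    tree, truth = _tree_from_islands(rng, n_clades=3, per_clade=3)
    labels, clades = phylo.assign_clades(tree)
    assert len(clades) == 3
    # each reported clade is exactly one planted island
    for tips in clades:
        assert len({truth[t] for t in tips}) == 1
    assert sorted(len(t) for t in clades) == [3, 3, 3]


def test_clade_assignment_invariant_to_tip_order(rng):
    anc, seqs, truth = island_seqs(rng, n_clades=3, per_clade=3)
    og = _mutate_seq(anc, rng, 200)
    order1 = dict(seqs)
    order2 = dict(sorted(seqs.items(), reverse=True))
    res = []
    for ordering in (order1, order2):
        aln = _matrix_from_seqs({**ordering, "out": og})
        tree = phylo.build_tree(aln, "out", bootstrap_n=60, seed=2)
        _, clades = phylo.assign_clades(tree)
        res.append({frozenset(t) for t in clades})
    assert res[0] == res[1]


def test_single_clade_with_two_outgroups(rng):
    anc, seqs, _ = island_seqs(rng, n_clades=1, per_clade=4, clade_muts=60)
    og1 = _mutate_seq(anc, rng, 200)
    og2 = _mutate_seq(og1, rng, 30)
    aln = _matrix_from_seqs({**seqs, "o1": og1, "o2": og2})
    # two outgroup tips make the whole ingroup a supported proper clade
    tree = phylo.build_tree(aln, ("o1", "o2"), bootstrap_n=40, seed=3)
    labels, clades = phylo.assign_clades(tree)
    assert len(clades) == 1
    assert set(labels.values()) == {"clade_1"}


def test_stray_tip_is_unassigned(rng):
    anc, seqs, truth = island_seqs(rng, n_clades=2, per_clade=3)
    seqs["stray"] = _mutate_seq(anc, rng, 120)  # long lone branch
    og = _mutate_seq(anc, rng, 250)
    aln = _matrix_from_seqs({**seqs, "out": og})
    tree = phylo.build_tree(aln, "out", bootstrap_n=60, seed=4)
    labels, clades = phylo.assign_clades(tree)
    assert labels["stray"] == "unassigned"
    assert len(clades) == 2


# ---------------------------------------------------------------------------
# extract_window / pseudo-outgroup
# ---------------------------------------------------------------------------

def test_extract_window_consensus_and_exclusion(rng):
    from sdrpipe.simdata import ReadSet, simulate_reads
    from conftest import small_config

    hap = encode(random_seq(rng, 6000))
    cfg = small_config(error_rate=0.0)
    reads = {}
    for fid in ("F1", "F2", "F3"):
        reads[fid] = simulate_reads([("h", hap, 1)], cfg,
                                    np.random.default_rng(hash(fid) % 1000))
    foreign = encode(random_seq(rng, 150))
    reads["F4"] = ReadSet(["x"], foreign[None, :], foreign[None, :].copy())
    with pytest.warns(UserWarning):
        aln = phylo.extract_window(reads, hap, (1000, 3000))
    assert "F4" not in aln.ids
    for fid in ("F1", "F2", "F3"):
        assert aln.missing[fid] < 0.05
        row = aln.row(fid)
        ok = row < 4
        np.testing.assert_array_equal(row[ok], hap[1000:3000][ok])


def test_pseudo_outgroup_single_locus(rng):
    from sdrpipe import paint

    ref = {"c1": random_seq(rng, 5000)}
    hap = ref["c1"][1000:4000]
    painting = paint.paint_haplotype(hap, ref)
    og = phylo.build_pseudo_outgroup(hap, (500, 2500), painting, ref)
    np.testing.assert_array_equal(og, encode(ref["c1"][1500:3500]))


def test_pseudo_outgroup_unpainted_gap_raises(rng):
    from sdrpipe import paint

    ref = {"c1": random_seq(rng, 5000)}
    hap = ref["c1"][1000:2000] + random_seq(rng, 500) + ref["c1"][2000:3000]
    painting = paint.paint_haplotype(hap, ref)
    with pytest.raises(ValueError, match="unpainted"):
        phylo.build_pseudo_outgroup(hap, (800, 1700), painting, ref)


# ---------------------------------------------------------------------------
# retrogene_monophyly
# ---------------------------------------------------------------------------

def test_retro_monophyly_single_origin(rng):
    paralog1 = random_seq(rng, 900)
    paralog2 = _mutate_seq(paralog1, rng, 80)
    retro_anc = _mutate_seq(paralog1, rng, 15)
    retros = {f"retro_{c}": _mutate_seq(retro_anc, rng, 5)
              for c in ("a", "b", "g")}
    res = phylo.retrogene_monophyly(retros, {"p1": paralog1, "p2": paralog2})
    assert res.monophyletic is True


def test_retro_two_origins_not_monophyletic(rng):
    paralog1 = random_seq(rng, 900)
    paralog2 = _mutate_seq(paralog1, rng, 100)
    retros = {
        "retro_a": _mutate_seq(paralog1, rng, 5),
        "retro_b": _mutate_seq(paralog2, rng, 5),
    }
    res = phylo.retrogene_monophyly(retros, {"p1": paralog1, "p2": paralog2})
    assert res.monophyletic is False


def test_retro_zero_divergence_unresolved(rng):
    s = random_seq(rng, 600)
    res = phylo.retrogene_monophyly({"r1": s, "r2": s}, {"p1": s, "p2": s})
    assert res.monophyletic is None
    assert res.flags


def test_retro_needs_enough_tips(rng):
    s = random_seq(rng, 600)
    with pytest.raises(ValueError):
        phylo.retrogene_monophyly({"r1": s}, {"p1": s, "p2": s})
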