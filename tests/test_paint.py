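"""Alignment engine vs brute force; window densities; segment painting."""

import numpy as np
import pytest

from sdrpipe import paint
from sdrpipe._codec import revcomp

from conftest import random_seq


def _mutated(seq, positions):
    out = list(seq)
    flip = {"A": "C", "C": "G", "G": "T", "T": "A"}
    for p in positions:
        out[p] = flip[out[p]]
    return "".join(out)


@pytest.fixture(scope="module")
def small_ref():
    rng = np.random.default_rng(7)
    return {"c1": random_seq(rng, 3000), "c2": random_seq(rng, 2000)}


def test_exact_hit_and_filters(small_ref):
    ref = small_ref
    queries = [
        ref["c1"][100:131],                  # exact, unique
        _mutated(ref["c1"][500:531], [5, 20]),     # 2 mismatches: retained
        _mutated(ref["c1"][800:831], [3, 15, 27]),  # 3 mismatches: dropped
        ref["c2"][300:315] + ref["c2"][338:354],    # spans a 23 bp ref gap
        revcomp(ref["c1"][1000:1031]),       # reverse strand
    ]
    hits, unaligned = paint.align_kmers(queries, ref)
    by_q = {q: g for q, g in hits.groupby("kmer_idx")}
    assert by_q[0].iloc[0][["chrom", "start", "matched_bases"]].tolist() == ["c1", 100, 31]
    assert int(by_q[0].iloc[0]["n_locations"]) == 1
    assert int(by_q[1].iloc[0]["matched_bases"]) == 29
    assert 2 in unaligned
    row3 = by_q[3].iloc[0]
    assert (row3["chrom"], row3["start"], row3["gap"]) == ("c2", 300, 23)
    assert by_q[4].iloc[0]["strand"] == "-"


def test_engine_equals_bruteforce(small_ref):
    rng = np.random.default_rng(13)
    ref = small_ref
    queries = []
    for _ in range(6):
        s = int(rng.integers(0, 1900))
        q = ref["c2"][s : s + 31]
        nmut = int(rng.integers(0, 4))
        q = _mutated(q, list(rng.choice(31, nmut, replace=False)))
        if rng.random() < 0.5:
            q = revcomp(q)
        queries.append(q)
    queries.append(random_seq(rng, 31))
    hits, _ = paint.align_kmers(queries, ref)
    bf = paint.brute_force_align_kmers(queries, ref)
    cols = ["kmer_idx", "chrom", "start", "strand", "matched_bases"]
    assert set(map(tuple, hits[cols].values.tolist())) == \
        set(map(tuple, bf[cols].values.tolist()))


def test_min_match_validation(small_ref):
    with pytest.raises(ValueError):
        paint.align_kmers(["ACGTACGTACG"], small_ref, min_match=50)


def test_multi_map_fraction(small_ref):
    rng = np.random.default_rng(3)
    # reference with a planted exact segmental duplication
    dup = random_seq(rng, 400)
    ref = {"c1": small_ref["c1"] + dup, "c2": small_ref["c2"] + dup}
    unique_qs = [small_ref["c1"][i : i + 31] for i in (50, 400, 900)]
    dup_qs = [dup[i : i + 31] for i in (10, 100, 200)]
    h1, _ = paint.align_kmers(unique_qs, ref)
    assert paint.multi_map_fraction(h1) == 0.0
    h2, _ = paint.align_kmers(dup_qs, ref)
    assert paint.multi_map_fraction(h2) == 1.0
    with pytest.warns(UserWarning):
        empty = paint.multi_map_fraction(h1.iloc[0:0])
    assert np.isnan(empty)


def test_window_density_rules():
    import pandas as pd

    hits = pd.DataFrame({
        "kmer_idx": [0, 1, 1, 2],
        "chrom": ["c1", "c1", "c1", "c1"],
        "start": [2500, 2600, 2900, 5000],
    })
    dens = paint.window_density(hits, window=2000)
    d = {(r["chrom"], r["window_start"]): r["count"] for _, r in dens.iterrows()}
    assert d[("c1", 2000)] == 2  # k-mer 1 deduped within the window
    assert d[("c1", 4000)] == 1
    nodedup = paint.window_density(hits, window=2000, dedupe=False)
    assert int(nodedup["count"].sum()) == 4
    # conservation: sum of counts = distinct (k-mer, window) incidences
    assert int(dens["count"].sum()) == 3


def test_window_density_peaks_locate_planted_loci():
    """Alpha-specific k-mers align at the cassette source and the
    retrogene source (and its paralog); gamma adds the later SDR
    locations.  Error-free reads: at three samples per sex, coincident
    sequencing errors can survive the intersection, which nine samples
    (the study design) filter out."""
    from sdrpipe import kmers
    from sdrpipe.simdata import Cohort
    from conftest import small_config

    def fs_hits(clade):
        cohort = Cohort(small_config(error_rate=0.0, seed=9,
                                     clade_of_female=(clade,) * 3))
        tables = {s.id: kmers.count_kmers(s.reads, 31) for s in cohort.samples}
        spec = kmers.group_specific_kmers(
            tables, [s.id for s in cohort.females()],
            [s.id for s in cohort.males()])
        hits, _ = paint.align_kmers(spec, cohort.reference)
        return cohort, paint.window_density(hits, window=1000)

    cohort, dens = fs_hits("alpha")
    lay = cohort.truth.layout
    gene_wins = {(c, (p // 1000) * 1000)
                 for c in ("chr5", "chr7")
                 for p in range(lay.retro_gene_start, lay.retro_gene_start + 2000, 500)}
    cass_wins = {("chr6", (p // 1000) * 1000)
                 for p in range(lay.loc1, lay.loc1 + lay.src_len + 500, 500)}
    expected_alpha = gene_wins | cass_wins
    got = {(r["chrom"], r["window_start"]) for _, r in dens.iterrows()
           if r["count"] >= 3}
    assert got and got <= expected_alpha
    assert any(c == "chr7" for c, _ in got)

    _, dens_g = fs_hits("gamma")
    chr6_wins = {r["window_start"] for _, r in dens_g.iterrows()
                 if r["chrom"] == "chr6" and r["count"] >= 3}
    assert any(abs(w - lay.loc13) <= 1000 for w in chr6_wins)
    assert any(abs(w - lay.loc37) <= 1000 for w in chr6_wins)


# ---------------------------------------------------------------------------
# paint_haplotype
# ---------------------------------------------------------------------------

def test_paint_verbatim_copy(small_ref):
    hap = small_ref["c1"][500:1500]
    p = paint.paint_haplotype(hap, small_ref)
    segs = p.painted()
    assert len(segs) == 1
    s = segs[0]
    assert (s.chrom, s.start, s.end) == ("c1", 0, 1000)
    assert s.identity == 100.0
    assert (s.ref_start, s.ref_end) == (500, 1500)


def test_paint_coverage_invariant(small_gamma_cohort):
    c = small_gamma_cohort
    fid = c.females()[0].id
    ft = c.truth.females[fid]
    h0, h1 = ft.hemizygous
    hap = c.w_haplotypes[fid][h0 - 500 : h1 + 500]
    p = paint.paint_haplotype(hap, c.reference)
    total = sum(s.end - s.start for s in p.segments)
    assert total == hap.shape[0]
    starts = [s.start for s in p.segments]
    assert starts == sorted(starts)
    for a, b in zip(p.segments[:-1], p.segments[1:]):
        assert a.end == b.start


def test_paint_short_haplotype_unplaced(small_ref):
    p = paint.paint_haplotype("ACGT" * 10, small_ref, min_segment=200)
    assert len(p.segments) == 1 and p.segments[0].chrom is None


def test_paint_tie_break_deterministic(small_ref):
    # two identical source chromosomes: the lower name wins
    ref = {"b": small_ref["c1"], "a": small_ref["c1"]}
    hap = small_ref["c1"][100:900]
    p = paint.paint_haplotype(hap, ref)
    assert p.painted()[0].chrom == "a"


def test_paint_recovers_truth_breakpoints(small_beta_cohort):
    """Painting of the true beta W region recovers cassette and retro
    segments with breakpoints within 50 bp of the planted truth."""
    c = small_beta_cohort
    fid = c.females()[0].id
    ft = c.truth.females[fid]
    h0, h1 = ft.hemizygous
    off = h0 - 500
    hap = c.w_haplotypes[fid][off : h1 + 500]
    p = paint.paint_haplotype(hap, c.reference)
    retro_truth = next(s for s in ft.sections if s.section == "retro_insert")
    retro_segs = [s for s in p.painted() if s.chrom == "chr7"]
    assert retro_segs
    lo = min(s.start for s in retro_segs) + off
    hi = max(s.end for s in retro_segs) + off
    assert abs(lo - retro_truth.start) <= 50
    assert abs(hi - retro_truth.end) <= 50
    lay = c.truth.layout
    cass = [s for s in p.painted()
            if s.chrom == "chr6" and lay.loc1 - 50 <= s.ref_start <= lay.loc1 + lay.src_len]
    assert sum(s.end - s.start for s in cass) >= 0.9 * (lay.src_len - 300)
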