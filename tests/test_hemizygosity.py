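"""Seams, far pairs, dose ratios, deletion and stop-codon calls."""

import numpy as np
import pandas as pd
import pytest

from sdrpipe import hemizygosity as hz
from sdrpipe import kmers
from sdrpipe._codec import encode, revcomp

from conftest import random_seq


def _pairs_df(rows):
    """rows: (name, s1, e1, s2, e2) with mates on the forward strand."""
    recs = []
    mates = []
    for i, (name, s1, e1, s2, e2) in enumerate(rows):
        left, right = min(s1, s2), max(e1, e2)
        recs.append((name, i, s1, e1, "+", 1.0, s2, e2, "-", 1.0,
                     left, right, right - left))
        mates.append((name, i, 1, s1, e1, "+", 1.0))
        mates.append((name, i, 2, s2, e2, "-", 1.0))
    df = pd.DataFrame(recs, columns=[
        "name", "pair_idx", "s1", "e1", "strand1", "identity1",
        "s2", "e2", "strand2", "identity2", "left", "right", "span"])
    df.attrs["mates"] = pd.DataFrame(
        mates, columns=["name", "pair_idx", "mate", "s", "e", "strand", "identity"])
    return df


# ---------------------------------------------------------------------------
# map_pairs_to_haplotype
# ---------------------------------------------------------------------------

def test_mapping_places_exact_pairs_and_skips_foreign(rng):
    from sdrpipe.simdata import ReadSet

    hap = encode(random_seq(rng, 4000))
    s1, ins = 1200, 400
    m1 = hap[s1 : s1 + 150]
    m2 = hap[s1 + ins - 150 : s1 + ins][::-1].copy()
    m2[m2 < 4] = 3 - m2[m2 < 4]
    foreign = encode(random_seq(rng, 150))
    rs = ReadSet(["good", "bad"],
                 np.stack([m1, foreign]),
                 np.stack([m2, foreign.copy()]))
    df = hz.map_pairs_to_haplotype(rs, hap, 0.95)
    assert list(df["name"]) == ["good"]
    row = df.iloc[0]
    assert (row["s1"], row["e1"]) == (s1, s1 + 150)
    assert row["span"] == ins


def test_mapping_drops_ties(rng):
    from sdrpipe.simdata import ReadSet

    unit = random_seq(rng, 1000)
    hap = encode(unit + unit)  # exact duplication: every placement ties
    m1 = encode(unit[100:250])
    m2 = encode(revcomp(unit[400:550]))
    rs = ReadSet(["p"], m1[None, :], m2[None, :])
    df = hz.map_pairs_to_haplotype(rs, hap, 0.95)
    assert len(df) == 0


# ---------------------------------------------------------------------------
# detect_seams
# ---------------------------------------------------------------------------

def test_seam_classification_toy():
    fem = _pairs_df([("f1", 750, 900, 1100, 1250, )])
    male_empty = _pairs_df([])
    male_span = _pairs_df([("m1", 800, 950, 1050, 1200)])
    # female-only spanning support at the junction
    seams = hz.detect_seams({"F": fem, "M": male_empty},
                            {"F": "female", "M": "male"}, 2000,
                            candidates=[1000, 1700])
    by_pos = {s.position: s for s in seams}
    assert by_pos[1000].status == "female_specific"
    assert by_pos[1700].status == "unsupported"
    # male support makes it shared
    seams2 = hz.detect_seams({"F": fem, "M": male_span},
                             {"F": "female", "M": "male"}, 2000,
                             candidates=[1000])
    assert {s.position: s.status for s in seams2}[1000] == "shared"


def test_far_pairs_do_not_support_seams():
    # a pair spanning 5 kb witnesses autosomal contiguity, not a W seam
    fem = _pairs_df([("f1", 100, 250, 5100, 5250)])
    seams = hz.detect_seams({"F": fem}, {"F": "female"}, 6000, candidates=[3000])
    assert seams[0].status == "unsupported"


# ---------------------------------------------------------------------------
# detect_far_pairs
# ---------------------------------------------------------------------------

def test_far_pairs_empty_when_spans_normal():
    df = _pairs_df([(f"p{i}", 100 + i, 250 + i, 400 + i, 550 + i)
                    for i in range(10)])
    assert hz.detect_far_pairs({"S": df}, {"S": "female"}) == []


def test_far_pair_cluster_and_skip_estimate():
    rows = [(f"p{i}", 900 + 7 * i, 1050 + 7 * i, 4000 + 5 * i, 4150 + 5 * i)
            for i in range(8)]
    df = _pairs_df(rows)
    recs = hz.detect_far_pairs({"S": df}, {"S": "female"})
    assert len(recs) == 1
    s, e = recs[0].skipped
    assert abs(s - 1099) <= 15 and abs(e - 4000) <= 15


def test_nested_junctions_stay_separate():
    inner = [(f"i{k}", 2000 + 9 * k, 2150 + 9 * k, 3500 + 9 * k, 3650 + 9 * k)
             for k in range(6)]
    outer = [(f"o{k}", 400 + 9 * k, 550 + 9 * k, 5200 + 9 * k, 5350 + 9 * k)
             for k in range(6)]
    df = _pairs_df(inner + outer)
    recs = hz.detect_far_pairs({"S": df}, {"S": "female"})
    spans = sorted(r.skipped[1] - r.skipped[0] for r in recs)
    assert len(recs) == 2
    assert spans[0] < 1500 and spans[1] > 4000


# ---------------------------------------------------------------------------
# depth and dose
# ---------------------------------------------------------------------------

def test_read_depth_arithmetic():
    df = _pairs_df([("p0", 0, 100, 200, 300), ("p1", 0, 100, 200, 300)])
    assert hz.read_depth(df, [(0, 100)], 1000) == 2.0
    assert hz.read_depth(df, [(100, 200)], 1000) == 0.0
    assert hz.read_depth(df, [(0, 100)], 1000, names={"p0"}) == 1.0


def test_coverage_ratio_rules():
    assert hz.coverage_ratio(4.0, 4.0) == 1.0
    with pytest.warns(UserWarning):
        assert np.isnan(hz.coverage_ratio(4.0, 0.0))
    with pytest.raises(ValueError):
        hz.coverage_ratio(0.0, 4.0)


def test_dose_scales_with_copy_number():
    """Far-anchor vs W-specific depth tracks planted copy number: a
    tetraploid (4 copies) gives ~half the octoploid ratio."""
    from sdrpipe.simdata import Cohort, SimConfig
    from sdrpipe.pipeline import PipelineConfig, analyze_cohort

    ratios = {}
    for n_sub in (4, 2):
        # full-size sections: the geometry must dwarf the insert length
        c = Cohort(SimConfig(seed=21, n_subgenomes=n_sub,
                             n_females=3, n_males=3,
                             clade_of_female=("gamma",) * 3))
        res = analyze_cohort(c.samples, c.reference, c.truth.annotation,
                             PipelineConfig(seed=21, max_missing=0, verbosity=0,
                                            expected_copies=2 * n_sub))
        ratios[n_sub] = res.single_copy.dose_ratio
    assert 6.0 <= ratios[4] <= 10.5
    assert 2.5 <= ratios[2] <= 5.5
    assert ratios[2] < ratios[4]


# ---------------------------------------------------------------------------
# female_specific_intervals
# ---------------------------------------------------------------------------

def test_intervals_runs_and_skip_intersection():
    pos = list(range(0, 2000, 25)) + list(range(5000, 6000, 25))
    prof = hz.female_specific_intervals(pos, k=31, clade="x",
                                        far_skips=[(500, 5500)])
    assert prof.intervals == [(0, 2006), (5000, 6006)]
    assert prof.hemizygous_intervals == [(500, 2006), (5000, 5500)]
    assert prof.total_span == (2006 - 500) + 500
    assert prof.female_specific_span == 2006 + 1006


def test_intervals_merge_across_seam():
    seam = hz.SeamRecord(2500, {}, 2, 0, "female_specific")
    pos = list(range(0, 2000, 30)) + list(range(3000, 4000, 30))
    prof = hz.female_specific_intervals(pos, seams=[seam], k=31)
    assert prof.intervals == [(0, 3990 + 31)]
    assert prof.evidence == ["kmer+seam"]


def test_intervals_low_power_flag():
    prof = hz.female_specific_intervals(range(0, 500, 20), k=31,
                                        n_clade_females=1)
    assert "low_power" in prof.flags


# ---------------------------------------------------------------------------
# detect_diagnostic_deletion
# ---------------------------------------------------------------------------

def test_deletion_identical_sequences_no_call(rng):
    seq = random_seq(rng, 2000)
    assert hz.detect_diagnostic_deletion(seq, seq) == []


def test_deletion_planted_23bp(rng):
    ref = random_seq(rng, 3000)
    w = ref[:1500] + ref[1523:]
    calls = hz.detect_diagnostic_deletion(w, ref)
    assert len(calls) == 1
    d = calls[0]
    assert d.length == 23 and d.ref_start == 1500 and d.w_junction == 1500


def test_deletion_diagnostic_flag_needs_all_females(rng):
    ref = random_seq(rng, 2000)
    w = ref[:1000] + ref[1023:]
    junction_reads = [w[960 : 1080]]
    undeleted_reads = [ref[960 : 1100]]
    tables = {
        "F1": kmers.count_kmers(junction_reads, 31),
        "F2": kmers.count_kmers(junction_reads, 31),
        "M1": kmers.count_kmers(undeleted_reads, 31),
    }
    sexes = {"F1": "female", "F2": "female", "M1": "male"}
    calls = hz.detect_diagnostic_deletion(w, ref, sample_tables=tables, sexes=sexes)
    assert calls[0].diagnostic
    # half the females lack the junction: not diagnostic
    tables["F2"] = tables["M1"]
    calls = hz.detect_diagnostic_deletion(w, ref, sample_tables=tables, sexes=sexes)
    assert not calls[0].diagnostic


def test_deletion_unalignable_raises(rng):
    with pytest.raises(ValueError):
        hz.detect_diagnostic_deletion(random_seq(rng, 1000), random_seq(rng, 1000))


# ---------------------------------------------------------------------------
# detect_premature_stop
# ---------------------------------------------------------------------------

def _orf(n_codons, rng):
    from sdrpipe.simdata import _random_orf
    from sdrpipe._codec import decode

    return decode(_random_orf(n_codons, rng))


def test_stop_codon_worked_example(rng):
    ref = _orf(376, rng)
    mutant = ref[: 222 * 3] + "TAA" + ref[223 * 3 :]
    call = hz.detect_premature_stop(mutant, ref)
    assert (call.reference_residues, call.observed_residues) == (376, 222)
    assert call.premature and call.stop_codon == 223


def test_stop_codon_identical_and_edge(rng):
    ref = _orf(50, rng)
    same = hz.detect_premature_stop(ref, ref)
    assert not same.premature and same.observed_residues == 50
    first = "ATG" + "TAA" + ref[6:]
    call = hz.detect_premature_stop(first, ref)
    assert call.premature and call.observed_residues == 1
    edge = "TAA" + ref[3:]
    with pytest.raises(ValueError):
        hz.detect_premature_stop(edge, ref)
    with pytest.raises(ValueError):
        hz.detect_premature_stop(ref[:-1], ref)
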