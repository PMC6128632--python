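"""k-mer counting and group-specific set arithmetic, against brute force."""

import itertools

import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from sdrpipe import kmers
from sdrpipe._codec import canonical_kmer, revcomp


def brute_count(reads, k, canonical):
    """Independent oracle: dict-based window counting."""
    out = {}
    for r in reads:
        for i in range(len(r) - k + 1):
            w = r[i : i + k]
            if set(w) - set("ACGT"):
                continue
            if canonical:
                w = canonical_kmer(w)
            out[w] = out.get(w, 0) + 1
    return out


def brute_specific(groups_a, groups_b, k, min_count=1, max_missing=0):
    """Oracle for group-specific sets over all 4^k possible k-mers."""
    counts_a = [brute_count([r], k, True) if isinstance(r, str)
                else brute_count(r, k, True) for r in groups_a]
    counts_b = [brute_count(r if not isinstance(r, str) else [r], k, True)
                for r in groups_b]
    out = set()
    for kmer in map("".join, itertools.product("ACGT", repeat=k)):
        ck = canonical_kmer(kmer)
        if ck != kmer:
            continue
        n_have = sum(1 for c in counts_a if c.get(ck, 0) >= min_count)
        if n_have < len(groups_a) - max_missing:
            continue
        if any(c.get(ck, 0) > 0 for c in counts_b):
            continue
        out.add(ck)
    return out


def test_hand_enumerated_counts():
    t = kmers.count_kmers(["AAACCCGG"], k=5, canonical=True)
    assert dict(t.items()) == {"AAACC": 1, "AACCC": 1, "ACCCG": 1, "CCCGG": 1}


def test_read_shorter_than_k_is_empty():
    assert len(kmers.count_kmers(["ACGT"], k=5)) == 0


def test_total_count_closed_form(rng):
    reads = ["".join(rng.choice(list("ACGT"), int(n))) for n in rng.integers(3, 40, 25)]
    k = 7
    t = kmers.count_kmers(reads, k=k)
    assert t.total() == sum(max(0, len(r) - k + 1) for r in reads)


def test_even_k_rejected():
    with pytest.raises(ValueError):
        kmers.count_kmers(["ACGTACGT"], k=4)


def test_empty_input_warns():
    with pytest.warns(UserWarning):
        t = kmers.count_kmers([], k=5)
    assert len(t) == 0


def test_canonical_closure(rng):
    reads = ["".join(rng.choice(list("ACGT"), 60)) for _ in range(20)]
    t = kmers.count_kmers(reads, k=5, canonical=True)
    seen = {km for km, _ in t.items()}
    for km in seen:
        rc = revcomp(km)
        assert rc == km or rc not in seen


def test_group_specific_toy_example():
    tables = {
        "F1": kmers.count_kmers(["AAACCCGG"], k=5),
        "M1": kmers.count_kmers(["AAACCCGA"], k=5),
    }
    spec = kmers.group_specific_kmers(tables, ["F1"], ["M1"])
    assert set(spec.kmers()) == {"CCCGG"}
    # identical read sets in both groups: self-difference is empty
    same = kmers.group_specific_kmers(
        {"a": tables["F1"], "b": tables["F1"]}, ["a"], ["b"])
    assert len(same) == 0


@settings(max_examples=25, deadline=None)
@given(st.lists(st.text(alphabet="ACGT", min_size=5, max_size=10),
                min_size=1, max_size=4),
       st.lists(st.text(alphabet="ACGT", min_size=5, max_size=10),
                min_size=1, max_size=4),
       st.integers(0, 1))
def test_group_specific_matches_bruteforce(pres, absn, max_missing):
    assume(max_missing < len(pres))
    k = 5
    tables = {}
    for i, r in enumerate(pres):
        tables[f"F{i}"] = kmers.count_kmers([r], k=k)
    for i, r in enumerate(absn):
        tables[f"M{i}"] = kmers.count_kmers([r], k=k)
    spec = kmers.group_specific_kmers(
        tables, [f"F{i}" for i in range(len(pres))],
        [f"M{i}" for i in range(len(absn))], max_missing=max_missing)
    oracle = brute_specific(pres, absn, k, max_missing=max_missing)
    assert set(spec.kmers()) == oracle


def test_monotonicity(rng):
    reads_f = [["".join(rng.choice(list("ACGT"), 30))] for _ in range(3)]
    reads_m = [["".join(rng.choice(list("ACGT"), 30))] for _ in range(2)]
    tables = {f"F{i}": kmers.count_kmers(r, k=5) for i, r in enumerate(reads_f)}
    tables.update({f"M{i}": kmers.count_kmers(r, k=5) for i, r in enumerate(reads_m)})
    fids = ["F0", "F1", "F2"]
    base = kmers.group_specific_kmers(tables, fids, ["M0"], max_missing=1)
    stricter = kmers.group_specific_kmers(tables, fids, ["M0"], min_count=2, max_missing=1)
    fewer_missing = kmers.group_specific_kmers(tables, fids, ["M0"], max_missing=0)
    more_absence = kmers.group_specific_kmers(tables, fids, ["M0", "M1"], max_missing=1)
    base_set = set(base.kmers())
    assert set(stricter.kmers()) <= base_set
    assert set(fewer_missing.kmers()) <= base_set
    assert set(more_absence.kmers()) <= base_set


def test_table_tsv_roundtrip(tmp_path, rng):
    t = kmers.count_kmers(["".join(rng.choice(list("ACGT"), 50))], k=7)
    path = tmp_path / "t.tsv"
    t.to_tsv(path)
    back = kmers.KmerTable.from_tsv(path)
    assert dict(back.items()) == dict(t.items())


# ---------------------------------------------------------------------------
# recruit_reads
# ---------------------------------------------------------------------------

def _readset(pairs):
    from sdrpipe._codec import encode
    from sdrpipe.simdata import ReadSet

    names = [f"p{i}" for i in range(len(pairs))]
    m1 = np.stack([encode(a) for a, _ in pairs])
    m2 = np.stack([encode(b) for _, b in pairs])
    return ReadSet(names, m1, m2)


def test_recruit_membership_and_order():
    rs = _readset([("AAACCCGG", "TTTTTTTT"),
                   ("TTTTTTTT", "GGGGGGGG"),
                   ("CCGGGTTT", "AAAAAAAA")])
    tables = {"F": kmers.count_kmers(["AAACCCGG"], k=5),
              "M": kmers.count_kmers(["AAACCCGA"], k=5)}
    spec = kmers.group_specific_kmers(tables, ["F"], ["M"])  # {CCCGG}
    rec, idx = kmers.recruit_reads(rs, spec)
    # pair 0 via mate1; pair 2 via revcomp CCGGG in mate1; order stable
    assert list(idx) == [0, 2]
    assert rec.names == ["p0", "p2"]


def test_recruit_empty_set_rejected():
    rs = _readset([("AAACCCGG", "TTTTTTTT")])
    spec = kmers.GroupSpecificKmerSet(5, True, np.empty(0, np.int64), ("F",), ("M",))
    with pytest.raises(ValueError):
        kmers.recruit_reads(rs, spec)


def test_recruitment_is_local_to_planted_region():
    """>=95% of recruited pairs originate within 2 insert lengths of the
    planted (modified) region, per the read-name truth channel.

    Error-free reads and six samples per sex, so that neither error
    k-mers nor chromosome-edge coverage dropouts survive the group
    intersection (at study scale the all-but-one rule and nine males do
    the same filtering)."""
    from sdrpipe.simdata import Cohort
    from conftest import small_config

    c = Cohort(small_config(error_rate=0.0, seed=7, n_females=6, n_males=6,
                            clade_of_female=("beta",) * 6))
    tables = {s.id: kmers.count_kmers(s.reads, 31) for s in c.samples}
    spec = kmers.group_specific_kmers(
        tables, [s.id for s in c.females()], [s.id for s in c.males()],
        max_missing=1)
    fem = c.females()[0]
    rec, _ = kmers.recruit_reads(fem.reads, spec)
    m0, m1 = c.truth.females[fem.id].modified_span
    pad = 2 * c.config.insert_mean
    good = 0
    for nm in rec.names:
        _, hap, start, ins = nm.split(":")[:4]
        if hap.endswith("chr6W") and m0 - pad <= int(start) and int(start) + int(ins) <= m1 + pad:
            good += 1
    assert good / len(rec) >= 0.95


def test_permuted_sex_labels_yield_near_empty_sets(small_gamma_cohort):
    """The discovery is asymmetric: with permuted labels both 'specific'
    sets collapse to (nearly) nothing, mirroring the male-specific control."""
    c = small_gamma_cohort
    tables = {s.id: kmers.count_kmers(s.reads, 31) for s in c.samples}
    fids = [s.id for s in c.females()]
    mids = [s.id for s in c.males()]
    true_fs = kmers.group_specific_kmers(tables, fids, mids)
    assert len(true_fs) > 500  # real signal present
    # permute: swap one female with one male in each group
    g1 = [fids[0], fids[1], mids[0]]
    g2 = [fids[2], mids[1], mids[2]]
    a = kmers.group_specific_kmers(tables, g1, g2)
    b = kmers.group_specific_kmers(tables, g2, g1)
    assert len(a) < 0.05 * len(true_fs)
    assert len(b) < 0.05 * len(true_fs)
    # and the two null sets are of comparable (tiny) size
    assert abs(len(a) - len(b)) < 0.05 * len(true_fs) + 50
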