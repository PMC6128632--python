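"""Hemizygosity inference on the assembled W haplotype.

Three strands of evidence decide which parts of the W haplotype have no
Z/autosomal counterpart in a clade:

* female-specific k-mers aligned to the haplotype (density runs);
* "seams" — positions bridged by normally-spaced read pairs in females
  only, witnessing adjacencies that exist on the W alone;
* "far pairs" — pairs whose mates land on the haplotype much farther
  apart than any plausible insert.  Such pairs arise from autosomal or Z
  copies in which the flanking sequence is contiguous, so the interval
  they skip is precisely the sequence those copies lack: the hemizygous
  insertion.  The hemizygous span of a clade is the female-specific
  k-mer territory intersected with the union of far-pair skip
  intervals; female-specific sequence outside every skip (the "outer"
  neighbourhood of an insertion site) has a Z counterpart and is
  reported as linked but not hemizygous.

Read-pair depth over the skip anchors (all chromosome copies) versus
depth of W-specific (k-mer-recruited) pairs inside the insertion gives
the copy-dose ratio — 8 for one W insertion among eight homoeologous
copies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy import stats

from ._codec import encode, kmer_scan, kmer_scan_matrix
from .paint import SeqIndex, anchored_global_align
from .simdata import ReadSet

_PAIR_SEED = 13


# ---------------------------------------------------------------------------
# [OP] map_pairs_to_haplotype
# ---------------------------------------------------------------------------

def map_pairs_to_haplotype(reads: ReadSet, haplotype, min_identity: float = 0.95,
                           index: SeqIndex | None = None) -> pd.DataFrame:
    """Place both mates of every pair on the haplotype.

    Placement is exact-seed + full-read comparison; each mate takes its
    best-identity location, with ties dropped.  Only pairs with both
    mates placed are returned, with the implied insert span.
    """
    hap = encode(haplotype) if isinstance(haplotype, str) else haplotype
    if index is None:
        index = SeqIndex(hap, _PAIR_SEED)
    p1 = _place_mates(reads.mate1, index, min_identity)
    p2 = _place_mates(reads.mate2, index, min_identity)
    rows = []
    mate_rows = []
    for mate, placed in ((1, p1), (2, p2)):
        for i, (s, e, st, ident) in placed.items():
            mate_rows.append((reads.names[i], i, mate, s, e, st, ident))
    for i in range(len(reads)):
        a, b = p1.get(i), p2.get(i)
        if a is None or b is None:
            continue
        (s1, e1, st1, id1), (s2, e2, st2, id2) = a, b
        left = min(s1, s2)
        right = max(e1, e2)
        rows.append((reads.names[i], i, s1, e1, st1, id1, s2, e2, st2, id2,
                     left, right, right - left))
    df = pd.DataFrame(rows, columns=[
        "name", "pair_idx", "s1", "e1", "strand1", "identity1",
        "s2", "e2", "strand2", "identity2", "left", "right", "span",
    ])
    # every placed mate, pair-complete or not: the substrate for depth
    df.attrs["mates"] = pd.DataFrame(
        mate_rows, columns=["name", "pair_idx", "mate", "s", "e", "strand",
                            "identity"])
    return df


def _place_mates(mat: np.ndarray, index: SeqIndex, min_identity: float) -> dict:
    n, rl = mat.shape
    if n == 0:
        return {}
    min_match = int(np.ceil(min_identity * rl))
    ref = index.concat
    results: dict[int, tuple] = {}
    ties: set[int] = set()
    bestm = np.zeros(n, np.int64)
    for strand in "+-":
        probe = mat if strand == "+" else _rc_mat(mat)
        codes, qrow, qoff = kmer_scan_matrix(probe, _PAIR_SEED, canonical=False)
        qi, rpos = index.lookup(codes)
        if qi.shape[0] == 0:
            continue
        row = qrow[qi]
        diag = rpos - qoff[qi]
        key = row * (ref.shape[0] + rl + 2) + diag
        _, first = np.unique(key, return_index=True)
        row_u, diag_u = row[first], diag[first]
        ok = index.in_bounds(diag_u, rl)
        row_u, diag_u = row_u[ok], diag_u[ok]
        for c0 in range(0, row_u.shape[0], 500_000):
            r = row_u[c0 : c0 + 500_000]
            d = diag_u[c0 : c0 + 500_000]
            win = ref[d[:, None] + np.arange(rl)]
            # assembly-gap Ns are wildcards, but a placement must still
            # rest mostly on called sequence
            is_n = win == 4
            matched = (win == probe[r]).sum(axis=1) + is_n.sum(axis=1)
            good = (matched >= min_match) & (is_n.sum(axis=1) <= 0.3 * rl)
            for rr, dd, mm in zip(r[good].tolist(), d[good].tolist(),
                                  matched[good].tolist()):
                if mm > bestm[rr]:
                    bestm[rr] = mm
                    results[rr] = (dd, dd + rl, strand, mm / rl)
                    ties.discard(rr)
                elif mm == bestm[rr] and rr in results and results[rr][0] != dd:
                    ties.add(rr)
    for rr in ties:
        results.pop(rr, None)
    return results


def _rc_mat(mat: np.ndarray) -> np.ndarray:
    out = mat[:, ::-1].copy()
    ok = out < 4
    out[ok] = 3 - out[ok]
    return out


# ---------------------------------------------------------------------------
# [OP] detect_seams
# ---------------------------------------------------------------------------

@dataclass
class SeamRecord:
    position: int
    counts: dict[str, int]
    n_females_with_support: int
    n_males_with_support: int
    status: str  # female_specific | shared | unsupported


def _gap_coverage(placements: pd.DataFrame, length: int, far_threshold: int) -> np.ndarray:
    """Per-position count of normally-spaced pairs whose inter-mate gap
    covers the position (mates aligned on either side)."""
    cov = np.zeros(length + 1, np.int64)
    if not len(placements):
        return cov[:-1]
    norm = placements[placements["span"] <= far_threshold]
    gs = np.minimum(norm[["e1", "e2"]].min(axis=1).to_numpy(np.int64), length)
    ge = np.maximum(norm[["s1", "s2"]].max(axis=1).to_numpy(np.int64), 0)
    ok = gs < ge
    np.add.at(cov, gs[ok], 1)
    np.add.at(cov, ge[ok], -1)
    return np.cumsum(cov)[:-1]


def detect_seams(placements: dict[str, pd.DataFrame], sexes: dict[str, str],
                 haplotype_length: int, candidates=(), min_females: int = 1,
                 far_threshold: int = 1000) -> list[SeamRecord]:
    """Classify candidate seam positions by sex-wise spanning-pair support.

    ``candidates`` are known junctions (e.g. painted section borders);
    additional female-specific seams are discovered as maximal runs of
    positions with female-only support, reported at the run midpoint.
    """
    if not placements:
        warnings.warn("no placements given: no seams to detect")
        return []
    fem_cov = np.zeros(haplotype_length, np.int64)
    male_cov = np.zeros(haplotype_length, np.int64)
    per_sample = {}
    for sid, df in placements.items():
        cov = _gap_coverage(df, haplotype_length, far_threshold)
        per_sample[sid] = cov
        if sexes[sid] == "female":
            fem_cov += cov > 0
        else:
            male_cov += cov > 0

    positions = sorted(set(int(c) for c in candidates))
    fs = (fem_cov >= min_females) & (male_cov == 0)
    edges = np.diff(fs.astype(np.int8))
    starts = np.nonzero(edges == 1)[0] + 1
    ends = np.nonzero(edges == -1)[0] + 1
    if fs[0]:
        starts = np.concatenate(([0], starts))
    if fs[-1]:
        ends = np.concatenate((ends, [haplotype_length]))
    for s, e in zip(starts, ends):
        mid = int((s + e) // 2)
        if mid not in positions:
            positions.append(mid)
    positions.sort()

    records = []
    for p in positions:
        counts = {sid: int(per_sample[sid][p]) if p < haplotype_length else 0
                  for sid in placements}
        nf = sum(1 for sid, c in counts.items() if c > 0 and sexes[sid] == "female")
        nm = sum(1 for sid, c in counts.items() if c > 0 and sexes[sid] == "male")
        if nf == 0 and nm == 0:
            status = "unsupported"
        elif nf >= min_females and nm == 0:
            status = "female_specific"
        else:
            status = "shared"
        records.append(SeamRecord(p, counts, nf, nm, status))
    return records


# ---------------------------------------------------------------------------
# [OP] detect_far_pairs
# ---------------------------------------------------------------------------

@dataclass
class FarPairRecord:
    left_interval: tuple[int, int]
    right_interval: tuple[int, int]
    span: float  # median implied span
    skipped: tuple[int, int]  # interval absent from the pairs' source copies
    counts: dict[str, int]
    female_mean: float
    male_mean: float


def detect_far_pairs(placements: dict[str, pd.DataFrame], sexes: dict[str, str],
                     far_threshold: int = 1000, min_cluster: int = 3,
                     cluster_tol: int = 700) -> list[FarPairRecord]:
    """Group far-spaced pairs into junction clusters.

    Pairs whose implied span exceeds ``far_threshold`` witness sequence
    that is contiguous in their source copy but interrupted on the W.
    Two pairs belong to the same junction iff *both* gap endpoints agree
    within ``cluster_tol`` (roughly the library insert): nested junctions
    (e.g. the retro insertion inside a larger translocated element)
    produce distinct, concentric clusters rather than one blurred one.
    """
    rows = []
    for sid, df in placements.items():
        if not len(df):
            continue
        far = df[df["span"] > far_threshold]
        for _, r in far.iterrows():
            gs = int(min(r["e1"], r["e2"]))
            ge = int(max(r["s1"], r["s2"]))
            if gs < ge:
                rows.append((sid, int(r["left"]), gs, ge, int(r["right"])))
    if not rows:
        return []
    rows.sort(key=lambda t: (t[2], t[3]))
    clusters: list[dict] = []
    for row in rows:
        home = None
        for cl in clusters:
            if (abs(row[2] - cl["gs"] / cl["n"]) <= cluster_tol
                    and abs(row[3] - cl["ge"] / cl["n"]) <= cluster_tol):
                home = cl
                break
        if home is None:
            clusters.append({"rows": [row], "gs": row[2], "ge": row[3], "n": 1})
        else:
            home["rows"].append(row)
            home["gs"] += row[2]
            home["ge"] += row[3]
            home["n"] += 1
    clusters = [cl["rows"] for cl in clusters]

    nf = sum(1 for s in sexes.values() if s == "female") or 1
    nm = sum(1 for s in sexes.values() if s == "male") or 1
    records = []
    for cl in clusters:
        if len(cl) < min_cluster:
            continue
        gs = np.array([c[2] for c in cl])
        ge = np.array([c[3] for c in cl])
        lefts = np.array([c[1] for c in cl])
        rights = np.array([c[4] for c in cl])
        counts: dict[str, int] = {}
        for c in cl:
            counts[c[0]] = counts.get(c[0], 0) + 1
        fcount = sum(v for s, v in counts.items() if sexes[s] == "female")
        mcount = sum(v for s, v in counts.items() if sexes[s] == "male")
        records.append(FarPairRecord(
            (int(lefts.min()), int(np.quantile(gs, 0.95))),
            (int(np.quantile(ge, 0.05)), int(rights.max())),
            float(np.median(ge - lefts + (rights - ge))),
            (int(np.quantile(gs, 0.95)), int(np.quantile(ge, 0.05))),
            counts, fcount / nf, mcount / nm,
        ))
    return records


# ---------------------------------------------------------------------------
# [OP] coverage_ratio and depth accounting
# ---------------------------------------------------------------------------

def read_depth(placements: pd.DataFrame, intervals, length: int,
               names: set | None = None) -> float:
    """Mean per-base read coverage over ``intervals`` from placed mates
    (pair-complete or not), optionally restricted to pairs whose name is
    in ``names``."""
    cov = np.zeros(length + 1, np.int64)
    mates = placements.attrs.get("mates")
    if mates is not None:
        df = mates
        if names is not None:
            df = df[df["name"].isin(names)]
        spans = [("s", "e")]
    else:
        df = placements
        if names is not None:
            df = df[df["name"].isin(names)]
        spans = [("s1", "e1"), ("s2", "e2")]
    for col_s, col_e in spans:
        s = np.clip(df[col_s].to_numpy(np.int64), 0, length)
        e = np.clip(df[col_e].to_numpy(np.int64), 0, length)
        np.add.at(cov, s, 1)
        np.add.at(cov, e, -1)
    cov = np.cumsum(cov)[:-1]
    tot, nbp = 0, 0
    for s, e in intervals:
        s, e = max(0, s), min(length, e)
        if e > s:
            tot += int(cov[s:e].sum())
            nbp += e - s
    return tot / nbp if nbp else float("nan")


def coverage_ratio(far_depth: float, w_depth: float) -> float:
    """Fold ratio of junction-anchor depth (all chromosome copies) to
    W-specific depth (one copy); 8 is the octoploid expectation."""
    if not np.isfinite(w_depth) or w_depth <= 0:
        warnings.warn("W-specific depth is zero: ratio undefined")
        return float("nan")
    if not np.isfinite(far_depth) or far_depth <= 0:
        raise ValueError("far-pair depth must be positive")
    return far_depth / w_depth


def sex_depth_ttest(depths: dict[str, float], sexes: dict[str, str]) -> float:
    """Two-sided equal-variance t test of per-sample depth between sexes."""
    f = [d for s, d in depths.items() if sexes[s] == "female" and np.isfinite(d)]
    m = [d for s, d in depths.items() if sexes[s] == "male" and np.isfinite(d)]
    if len(f) < 2 or len(m) < 2:
        return float("nan")
    return float(stats.ttest_ind(f, m, equal_var=True).pvalue)


# ---------------------------------------------------------------------------
# [OP] female_specific_intervals
# ---------------------------------------------------------------------------

@dataclass
class HemizygosityProfile:
    clade: str
    intervals: list[tuple[int, int]]  # female-specific k-mer territory
    hemizygous_intervals: list[tuple[int, int]]
    evidence: list[str] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)

    @property
    def total_span(self) -> int:
        """The hemizygous portion, in bp."""
        return sum(e - s for s, e in self.hemizygous_intervals)

    @property
    def female_specific_span(self) -> int:
        return sum(e - s for s, e in self.intervals)


def female_specific_intervals(kmer_positions, seams=None, min_kmer_density: float = 5.0,
                              far_skips=None, k: int = 31, clade: str = "",
                              n_clade_females: int | None = None,
                              min_run_kmers: int = 3) -> HemizygosityProfile:
    """Merge aligned female-specific k-mers into intervals; intersect with
    far-pair skip intervals to isolate the hemizygous portion.

    k-mer runs break where consecutive aligned starts are farther apart
    than 1000/``min_kmer_density`` bp; runs separated by a
    female-specific seam are merged.
    """
    pos = np.unique(np.asarray(list(kmer_positions), np.int64))
    flags: list[str] = []
    if n_clade_females is not None and n_clade_females < 2:
        flags.append("low_power")
    if pos.shape[0] == 0:
        return HemizygosityProfile(clade, [], [], [], flags + ["no_kmers"])
    max_gap = 1000.0 / min_kmer_density
    brk = np.nonzero(np.diff(pos) > max_gap)[0] + 1
    bounds = np.concatenate(([0], brk, [pos.shape[0]]))
    runs = []
    for b0, b1 in zip(bounds[:-1], bounds[1:]):
        if b1 - b0 >= min_run_kmers:
            runs.append((int(pos[b0]), int(pos[b1 - 1]) + k))
    seam_pos = sorted(
        s.position for s in (seams or []) if s.status == "female_specific"
    )
    merged: list[tuple[int, int]] = []
    evidence: list[str] = []
    for run in runs:
        if merged and any(merged[-1][1] <= sp <= run[0] for sp in seam_pos):
            merged[-1] = (merged[-1][0], run[1])
            evidence[-1] = "kmer+seam"
        else:
            merged.append(run)
            evidence.append("kmer")
    if far_skips is None:
        flags.append("no_far_pair_evidence")
        hemi = list(merged)
    else:
        skips = _merge_intervals([tuple(s) for s in far_skips])
        hemi = []
        for s, e in merged:
            for ks, ke in skips:
                lo, hi = max(s, ks), min(e, ke)
                if hi > lo:
                    hemi.append((lo, hi))
        hemi = _merge_intervals(hemi)
    return HemizygosityProfile(clade, merged, hemi, evidence, flags)


def _merge_intervals(ivs):
    ivs = sorted(ivs)
    out: list[tuple[int, int]] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


# ---------------------------------------------------------------------------
# [OP] detect_diagnostic_deletion
# ---------------------------------------------------------------------------

@dataclass
class DeletionCall:
    ref_chrom: str
    ref_start: int  # within the supplied reference window
    length: int
    w_junction: int  # position on the W segment
    sample_support: dict[str, bool]
    diagnostic: bool


def detect_diagnostic_deletion(w_segment, reference_window, min_len: int = 10,
                               sample_tables=None, sexes=None,
                               ref_chrom: str = "ref",
                               edge_buffer: int = 50) -> list[DeletionCall]:
    """Deletions in the W segment relative to its source-locus window.

    Global (anchored, affine-gap) alignment; runs of reference bases
    absent from the W of length >= ``min_len`` are reported.  Per-sample
    junction support asks each sample's k-mer table for any k-mer
    spanning the deletion breakpoint; the diagnostic flag is set iff all
    females support the junction and no male does.
    """
    w = w_segment if isinstance(w_segment, str) else str(w_segment)
    ref = reference_window if isinstance(reference_window, str) else str(reference_window)
    ops, matches = anchored_global_align(w, ref)
    columns = sum(n for _, n in ops)
    if columns == 0 or matches / columns < 0.5:
        raise ValueError("W segment does not align to the reference window")
    calls = []
    apos = bpos = 0
    for op, n in ops:
        if op == "M":
            apos += n
            bpos += n
        elif op == "I":
            apos += n
        else:  # D: in reference, absent from W
            # near-terminal runs are window-margin artifacts, not deletions
            if n >= min_len and edge_buffer <= apos <= len(w) - edge_buffer:
                calls.append((bpos, n, apos))
            bpos += n
    out = []
    min_flank = 5  # junction k-mers must span the breakpoint by >= this
    for ref_start, length, w_junction in calls:
        support: dict[str, bool] = {}
        if sample_tables:
            k = next(iter(sample_tables.values())).k
            # k-mers overlapping the breakpoint by fewer than min_flank
            # bases can coincide with the undeleted allele by chance
            lo = max(0, w_junction - k + min_flank)
            hi = min(len(w) - k, w_junction - min_flank)
            for sid, table in sample_tables.items():
                support[sid] = any(
                    table.get(w[i : i + k]) > 0 for i in range(lo, hi + 1)
                )
        diagnostic = False
        if support and sexes:
            females = [s for s in support if sexes[s] == "female"]
            males = [s for s in support if sexes[s] == "male"]
            diagnostic = (
                bool(females)
                and all(support[s] for s in females)
                and not any(support[s] for s in males)
            )
        out.append(DeletionCall(ref_chrom, ref_start, length, w_junction,
                                support, diagnostic))
    return out


# ---------------------------------------------------------------------------
# [OP] detect_premature_stop
# ---------------------------------------------------------------------------

@dataclass
class StopCodonCall:
    reference_residues: int
    observed_residues: int
    stop_codon: int | None  # 1-based codon index of the first stop
    premature: bool


def detect_premature_stop(cds: str, reference_cds: str) -> StopCodonCall:
    """Translate both sequences and compare lengths to the first stop."""
    for name, seq in (("query", cds), ("reference", reference_cds)):
        if len(seq) % 3 != 0:
            raise ValueError(f"{name} CDS length is not a multiple of 3")
        if not seq.upper().startswith("ATG"):
            raise ValueError(f"{name} CDS does not begin with ATG")
    ref_aa = str(Seq(reference_cds).translate())
    obs_aa = str(Seq(cds).translate())
    ref_len = ref_aa.index("*") if "*" in ref_aa else len(ref_aa)
    obs_len = obs_aa.index("*") if "*" in obs_aa else len(obs_aa)
    stop = obs_len + 1 if "*" in obs_aa else None
    return StopCodonCall(ref_len, obs_len, stop, obs_len < ref_len)
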