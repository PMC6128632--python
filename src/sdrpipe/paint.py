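"""Alignment of k-mers and haplotype segments to a reference.

The engine is an internal seed-and-extend: exact seed matches (8-mers
for k-mer alignment, so that any hit passing the 29-matched-bases filter
is guaranteed a clean seed; 15-mers for long collinear segments) are
grouped by diagonal and evaluated in numpy batches.  The retention
filter — at least ``min_match`` matching bases and no internal gap over
``max_gap`` — is enforced after extension, so hit sets are engine
independent and can be checked against a brute-force scan on small
references.

Percent identity is matches / alignment columns x 100, gaps counted as
columns.  Coordinates are 0-based half-open on the forward strand.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align

from ._codec import SEP, decode, encode, kmer_scan, revcomp_codes

_KMER_SEED = 8  # guarantees completeness at min_match=29, max_gap<=30 for k=31
_SEGMENT_SEED = 15


def _expand_ranges(lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Concatenate arange(lo[i], hi[i]) for all i, vectorised."""
    counts = hi - lo
    nz = counts > 0
    lo, counts = lo[nz], counts[nz]
    if lo.shape[0] == 0:
        return np.empty(0, np.int64)
    total = int(counts.sum())
    step = np.ones(total, np.int64)
    step[0] = lo[0]
    pos = np.cumsum(counts)[:-1]
    step[pos] = lo[1:] - (lo[:-1] + counts[:-1] - 1)
    return np.cumsum(step)


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -4
    aligner.extend_gap_score = -1
    return aligner


class SeqIndex:
    """Exact-seed index over one or more sequences (forward strand)."""

    def __init__(self, seqs, seed_len: int):
        if isinstance(seqs, np.ndarray):
            seqs = {"seq": seqs}
        elif isinstance(seqs, dict) and seqs and isinstance(next(iter(seqs.values())), str):
            seqs = {n: encode(s) for n, s in seqs.items()}
        self.seed_len = seed_len
        self.names = list(seqs)
        parts, offsets, pos = [], [], 0
        for name in self.names:
            offsets.append(pos)
            parts.append(seqs[name])
            parts.append(np.array([SEP], np.uint8))
            pos += seqs[name].shape[0] + 1
        self.concat = np.concatenate(parts) if parts else np.empty(0, np.uint8)
        self.offsets = np.asarray(offsets, np.int64)
        self.lengths = np.asarray([seqs[n].shape[0] for n in self.names], np.int64)
        codes, starts = kmer_scan(self.concat, seed_len, canonical=False)
        order = np.argsort(codes, kind="stable")
        self._codes = codes[order]
        self._starts = starts[order]
        # direct-address membership filter: 4^seed_len bytes, cheap for
        # seeds up to 13 and far faster than searchsorted on big queries
        self._member = None
        if seed_len <= 13:
            self._member = np.zeros(4 ** seed_len, bool)
            self._member[self._codes] = True

    def lookup(self, query_codes: np.ndarray):
        """For each query seed code, the matching reference positions.

        Returns ``(q_idx, ref_pos)`` expanded arrays.
        """
        qids = np.arange(query_codes.shape[0])
        if self._member is not None and query_codes.shape[0] > 4096:
            keep = self._member[query_codes]
            qids = qids[keep]
            query_codes = query_codes[keep]
        lo = np.searchsorted(self._codes, query_codes, "left")
        hi = np.searchsorted(self._codes, query_codes, "right")
        counts = hi - lo
        q_idx = np.repeat(qids, counts)
        if q_idx.shape[0] == 0:
            return q_idx, np.empty(0, np.int64)
        take = _expand_ranges(lo, hi)
        return q_idx, self._starts[take]

    def chrom_of(self, gpos: int):
        i = int(np.searchsorted(self.offsets, gpos, "right")) - 1
        local = gpos - int(self.offsets[i])
        if local >= int(self.lengths[i]):
            return None, -1
        return self.names[i], local

    def in_bounds(self, gstart: np.ndarray, span: int) -> np.ndarray:
        """Windows [gstart, gstart+span) lying wholly inside one sequence."""
        ok = (gstart >= 0) & (gstart + span <= self.concat.shape[0])
        idx = np.searchsorted(self.offsets, gstart, "right") - 1
        idx = np.clip(idx, 0, len(self.names) - 1)
        ok &= gstart - self.offsets[idx] + span <= self.lengths[idx]
        ok &= gstart >= self.offsets[idx]
        return ok


# ---------------------------------------------------------------------------
# [OP] align_kmers
# ---------------------------------------------------------------------------

def align_kmers(kmer_set, reference, min_match: int = 29, max_gap: int = 30,
                index: SeqIndex | None = None):
    """All reference locations of each k-mer passing the retention filter.

    ``kmer_set`` is a GroupSpecificKmerSet, a list of k-mer strings, or a
    packed-code array plus k via ``(codes, k)``.  Both strands of every
    query are searched against the forward reference.  Returns
    ``(hits, unaligned)``: a DataFrame with one row per retained hit
    (kmer_idx, kmer, chrom, start, strand, matched_bases, gap,
    n_locations) and the list of query indices with no retained hit.
    """
    qmat, k, labels = _query_matrix(kmer_set)
    if min_match > k:
        raise ValueError("min_match cannot exceed k")
    if index is None:
        index = SeqIndex(reference, _KMER_SEED)
    nq = qmat.shape[0]
    found: dict[int, dict] = {}
    for strand, mat in (("+", qmat), ("-", np.ascontiguousarray(_revcomp_matrix(qmat)))):
        _collect_hits(mat, index, k, min_match, max_gap, strand, found)
    rows = []
    for qi in sorted(found):
        hits = found[qi]
        for (gstart, strand), (matched, gap) in sorted(hits.items()):
            chrom, local = index.chrom_of(gstart)
            if chrom is None:
                continue
            rows.append((qi, labels[qi], chrom, local, strand, matched, gap))
    df = pd.DataFrame(rows, columns=["kmer_idx", "kmer", "chrom", "start",
                                     "strand", "matched_bases", "gap"])
    if len(df):
        df["n_locations"] = df.groupby("kmer_idx")["kmer_idx"].transform("size")
    else:
        df["n_locations"] = pd.Series(dtype=np.int64)
    aligned = set(df["kmer_idx"].tolist())
    unaligned = [i for i in range(nq) if i not in aligned]
    return df, unaligned


def _query_matrix(kmer_set):
    from .kmers import GroupSpecificKmerSet, _decode_codes

    if isinstance(kmer_set, GroupSpecificKmerSet):
        labels = kmer_set.kmers()
    elif isinstance(kmer_set, tuple) and len(kmer_set) == 2:
        codes, k = kmer_set
        labels = _decode_codes(np.asarray(codes, np.int64), k)
    else:
        labels = list(kmer_set)
    if not labels:
        raise ValueError("empty k-mer set")
    k = len(labels[0])
    mat = np.stack([encode(s) for s in labels])
    return mat, k, labels


def _revcomp_matrix(mat: np.ndarray) -> np.ndarray:
    out = mat[:, ::-1].copy()
    ok = out < 4
    out[ok] = 3 - out[ok]
    return out


def _collect_hits(qmat, index: SeqIndex, k, min_match, max_gap, strand, found):
    nq = qmat.shape[0]
    s = index.seed_len
    # seed all query offsets
    cat = np.full((nq, k + 1), SEP, np.uint8)
    cat[:, :k] = qmat
    codes, starts = kmer_scan(cat.ravel(), s, canonical=False)
    qrow = starts // (k + 1)
    qoff = starts % (k + 1)
    qi, rpos = index.lookup(codes)
    if qi.shape[0] == 0:
        return
    row = qrow[qi]
    diag = rpos - qoff[qi]
    key = row * (index.concat.shape[0] + k + 64) + (diag + k + 32)
    uniq_key, first = np.unique(key, return_index=True)
    row_u = row[first]
    diag_u = diag[first]
    ok = index.in_bounds(diag_u, k)
    row_u, diag_u = row_u[ok], diag_u[ok]
    # ungapped evaluation in chunks
    ref = index.concat
    for c0 in range(0, row_u.shape[0], 1_000_000):
        r = row_u[c0 : c0 + 1_000_000]
        d = diag_u[c0 : c0 + 1_000_000]
        win = ref[d[:, None] + np.arange(k)]
        matched = (win == qmat[r]).sum(axis=1)
        good = matched >= min_match
        for rr, dd, mm in zip(r[good].tolist(), d[good].tolist(), matched[good].tolist()):
            _keep(found, rr, dd, strand, mm, 0)
    # gapped evaluation: diagonal pairs within max_gap for the same query
    order = np.lexsort((diag_u, row_u))
    row_s, diag_s = row_u[order], diag_u[order]
    close = (np.diff(row_s) == 0) & (np.abs(np.diff(diag_s)) <= max_gap) & (np.diff(diag_s) != 0)
    for i in np.nonzero(close)[0]:
        rr = int(row_s[i])
        d1, d2 = int(diag_s[i]), int(diag_s[i + 1])
        q = qmat[rr]
        eq1 = ref[d1 : d1 + k] == q if d1 + k <= ref.shape[0] else None
        eq2 = ref[d2 : d2 + k] == q if d2 + k <= ref.shape[0] else None
        if eq1 is None or eq2 is None:
            continue
        matched = _best_split(eq1, eq2)
        if matched >= min_match:
            gstart = min(d1, d2)
            _keep(found, rr, gstart, strand, matched, abs(d2 - d1))


#: a gapped hit must anchor at least this many matched bases on each side
#: of the gap (otherwise every ungapped hit spawns shifted phantom twins)
_MIN_GAP_SIDE = 8


def _best_split(eq1, eq2) -> int:
    """Best internal-gap split of a query across two diagonals: prefix on
    one diagonal + suffix on the other, both sides matching at least
    ``_MIN_GAP_SIDE`` bases."""
    p1 = np.concatenate(([0], np.cumsum(eq1)))
    p2 = np.concatenate(([0], np.cumsum(eq2)))
    best = 0
    for pa, pb in ((p1, p2), (p2, p1)):
        pre = pa[:-1]
        suf = pb[-1] - pb[:-1]
        ok = (pre >= _MIN_GAP_SIDE) & (suf >= _MIN_GAP_SIDE)
        if ok.any():
            best = max(best, int((pre[ok] + suf[ok]).max()))
    return best


def _keep(found, qi, gstart, strand, matched, gap):
    hits = found.setdefault(qi, {})
    key = (gstart, strand)
    old = hits.get(key)
    if old is None or matched > old[0]:
        hits[key] = (matched, gap)


def brute_force_align_kmers(kmers, reference, min_match: int = 29, max_gap: int = 30):
    """Oracle: score every offset/strand/gap explicitly (small refs only)."""
    if isinstance(reference, dict):
        items = reference.items()
    else:
        items = [("seq", reference)]
    rows = []
    for qi, kmer in enumerate(kmers):
        k = len(kmer)
        best: dict[tuple, tuple] = {}
        for strand in "+-":
            q = encode(kmer) if strand == "+" else revcomp_codes(encode(kmer))
            for chrom, seq in items:
                ref = encode(seq) if isinstance(seq, str) else seq
                L = ref.shape[0]
                for st in range(0, L - k + 1):
                    m = int((ref[st : st + k] == q).sum())
                    if m >= min_match:
                        _keep2(best, (chrom, st, strand), m, 0)
                for gap in range(1, max_gap + 1):
                    for st in range(0, L - k - gap + 1):
                        eq1 = ref[st : st + k] == q
                        eq2 = ref[st + gap : st + gap + k] == q
                        m = _best_split(eq1, eq2)
                        if m >= min_match:
                            _keep2(best, (chrom, st, strand), m, gap)
        for (chrom, st, strand), (m, gap) in sorted(best.items()):
            rows.append((qi, kmer, chrom, st, strand, m, gap))
    df = pd.DataFrame(rows, columns=["kmer_idx", "kmer", "chrom", "start",
                                     "strand", "matched_bases", "gap"])
    if len(df):
        df["n_locations"] = df.groupby("kmer_idx")["kmer_idx"].transform("size")
    return df


def _keep2(best, key, m, gap):
    old = best.get(key)
    if old is None or m > old[0]:
        best[key] = (m, gap)


# ---------------------------------------------------------------------------
# [OP] multi_map_fraction / window_density
# ---------------------------------------------------------------------------

def multi_map_fraction(hits: pd.DataFrame, n_queries: int | None = None,
                       include_unaligned: bool = False) -> float:
    """Fraction of k-mers with more than one retained location.

    Denominator is the aligned k-mers by default; pass
    ``include_unaligned=True`` (with ``n_queries``) for the alternative
    reading.  Undefined (empty denominator) returns NaN with a warning.
    """
    aligned = hits["kmer_idx"].nunique() if len(hits) else 0
    denom = n_queries if include_unaligned else aligned
    if not denom:
        warnings.warn("multi-map fraction undefined: no aligned k-mers")
        return float("nan")
    multi = hits.loc[hits["n_locations"] > 1, "kmer_idx"].nunique() if len(hits) else 0
    return multi / denom


def window_density(hits: pd.DataFrame, window: int = 2000, dedupe: bool = True,
                   lengths: dict[str, int] | None = None) -> pd.DataFrame:
    """Distinct k-mers per half-open genomic window.

    With ``dedupe`` each k-mer counts once per window regardless of how
    many times (or at what depth) it hits inside it.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if not len(hits):
        return pd.DataFrame(columns=["chrom", "window_start", "count"])
    df = hits.copy()
    df["window_start"] = (df["start"] // window) * window
    cols = ["chrom", "window_start"]
    if dedupe:
        df = df.drop_duplicates(["kmer_idx", *cols])
    out = df.groupby(cols, as_index=False).size().rename(columns={"size": "count"})
    if lengths:
        full = []
        for chrom, L in lengths.items():
            ws = np.arange(0, L, window)
            full.append(pd.DataFrame({"chrom": chrom, "window_start": ws}))
        grid = pd.concat(full, ignore_index=True)
        out = grid.merge(out, on=cols, how="left").fillna({"count": 0})
        out["count"] = out["count"].astype(int)
    return out.sort_values(cols, ignore_index=True)


# ---------------------------------------------------------------------------
# segment painting
# ---------------------------------------------------------------------------

@dataclass
class Segment:
    start: int  # haplotype coords, 0-based half-open
    end: int
    chrom: str | None
    ref_start: int
    ref_end: int
    strand: str
    identity: float  # percent, 0..100
    section_class: str = "unplaced"


@dataclass
class SegmentPainting:
    segments: list[Segment]
    haplotype_length: int

    def painted(self) -> list[Segment]:
        return [s for s in self.segments if s.chrom is not None]

    def to_bed(self, path, name: str = "haplotype") -> None:
        with open(path, "w") as fh:
            for s in self.segments:
                fh.write(f"{name}\t{s.start}\t{s.end}\t{s.section_class}\t"
                         f"{s.identity:.1f}\t{s.strand}\n")

    def class_of(self, pos: int) -> str:
        for s in self.segments:
            if s.start <= pos < s.end:
                return s.section_class
        return "unplaced"


def paint_haplotype(haplotype, reference, min_segment: int = 200,
                    locus_classes=None, band: int = 60,
                    max_anchor_gap: int = 400) -> SegmentPainting:
    """Partition a haplotype into reference-homology segments.

    Exact 15-mer anchors are clustered by diagonal (within ``band``, so
    short indels do not split a segment) and chained while consecutive
    anchors are less than ``max_anchor_gap`` apart.  Each chained cluster
    becomes a candidate segment scored by anchored identity; candidates
    are accepted greedily (longest first, ties broken by lowest source
    chromosome name then start) with overlaps trimmed, and remaining
    stretches are labelled unplaced.  ``locus_classes`` — an iterable of
    ``(chrom, start, end, class)`` — assigns section classes by best
    source-locus overlap.
    """
    hap = encode(haplotype) if isinstance(haplotype, str) else haplotype
    n = hap.shape[0]
    if n < min_segment:
        return SegmentPainting([Segment(0, n, None, -1, -1, ".", 0.0)], n)
    index = SeqIndex(reference, _SEGMENT_SEED)
    cands = []
    for strand in "+-":
        probe = hap if strand == "+" else revcomp_codes(hap)
        codes, starts = kmer_scan(probe, _SEGMENT_SEED, canonical=False)
        qi, rpos = index.lookup(codes)
        if qi.shape[0] == 0:
            continue
        hpos = starts[qi]
        cands.extend(_cluster_anchors(hpos, rpos, probe, index, strand, n,
                                      min_segment, band, max_anchor_gap))
    segments = _greedy_select(cands, n)
    _fill_unplaced(segments, n)
    if locus_classes:
        _assign_classes(segments, locus_classes)
    return SegmentPainting(segments, n)


def _cluster_anchors(hpos, rpos, probe, index, strand, n, min_segment, band,
                     max_anchor_gap):
    diag = rpos - hpos
    order = np.lexsort((hpos, diag))
    hpos, rpos, diag = hpos[order], rpos[order], diag[order]
    out = []
    start = 0
    brk = np.nonzero(np.diff(diag) > band)[0] + 1
    bounds = np.concatenate(([0], brk, [diag.shape[0]]))
    for b0, b1 in zip(bounds[:-1], bounds[1:]):
        h = hpos[b0:b1]
        r = rpos[b0:b1]
        ho = np.argsort(h, kind="stable")
        h, r = h[ho], r[ho]
        keep = np.concatenate(([True], np.diff(h) > 0))
        h, r = h[keep], r[keep]
        gaps = np.nonzero(np.diff(h) > max_anchor_gap)[0] + 1
        sub = np.concatenate(([0], gaps, [h.shape[0]]))
        for s0, s1 in zip(sub[:-1], sub[1:]):
            hh, rr = h[s0:s1], r[s0:s1]
            span = int(hh[-1]) + _SEGMENT_SEED - int(hh[0])
            if span < min_segment:
                continue
            ident, cols = _anchored_identity(probe, index.concat, hh, rr)
            h0, h1 = int(hh[0]), int(hh[-1]) + _SEGMENT_SEED
            if strand == "+":
                seg_h0, seg_h1 = h0, h1
            else:
                seg_h0, seg_h1 = n - h1, n - h0
            chrom, local0 = index.chrom_of(int(rr[0]))
            _, local1 = index.chrom_of(int(rr[-1]) + _SEGMENT_SEED - 1)
            if chrom is None:
                continue
            out.append(Segment(seg_h0, seg_h1, chrom, local0, local1 + 1,
                               strand, ident))
    return out


def _anchored_identity(probe, ref, hh, rr):
    """Identity over a chained anchor run, aligning between-anchor blocks."""
    matches = 0
    columns = 0
    aligner = None
    prev_h, prev_r = int(hh[0]), int(rr[0])
    matches += _SEGMENT_SEED
    columns += _SEGMENT_SEED
    for h, r in zip(hh[1:].tolist(), rr[1:].tolist()):
        dh = h - prev_h
        dr = r - prev_r
        if dh <= 0 or dr <= 0:
            continue
        if dh == dr:
            a = probe[prev_h + 1 : h + 1]
            b = ref[prev_r + 1 : r + 1]
            matches += int((a == b).sum())
            columns += dh
        else:
            a = decode(probe[prev_h + _SEGMENT_SEED : h])
            b = decode(ref[prev_r + _SEGMENT_SEED : r])
            if aligner is None:
                aligner = _make_aligner()
            m, c = _block_identity(aligner, a, b)
            matches += m + _SEGMENT_SEED
            columns += c + _SEGMENT_SEED
        prev_h, prev_r = h, r
    return 100.0 * matches / max(columns, 1), columns


def _block_identity(aligner, a: str, b: str):
    if not a and not b:
        return 0, 0
    if not a or not b:
        return 0, max(len(a), len(b))
    aln = aligner.align(a, b)[0]
    s1, s2 = str(aln[0]), str(aln[1])
    m = sum(1 for x, y in zip(s1, s2) if x == y and x != "-")
    return m, len(s1)


def _greedy_select(cands: list[Segment], n: int) -> list[Segment]:
    cands = sorted(
        cands,
        key=lambda s: (-(s.end - s.start), -s.identity, s.chrom or "", s.ref_start),
    )
    taken: list[Segment] = []
    for c in cands:
        s0, s1 = c.start, c.end
        for t in taken:
            if s0 < t.end and t.start < s1:  # overlap: trim
                if s0 >= t.start and s1 <= t.end:
                    s0, s1 = 0, 0
                    break
                if s0 < t.start:
                    s1 = min(s1, t.start)
                else:
                    s0 = max(s0, t.end)
        if s1 - s0 >= max(50, 1):
            trimmed = Segment(s0, s1, c.chrom,
                              c.ref_start + (s0 - c.start) if c.strand == "+"
                              else c.ref_start + (c.end - s1),
                              c.ref_end - (c.end - s1) if c.strand == "+"
                              else c.ref_end - (s0 - c.start),
                              c.strand, c.identity, c.section_class)
            taken.append(trimmed)
    taken.sort(key=lambda s: s.start)
    return taken


def _fill_unplaced(segments: list[Segment], n: int) -> None:
    out = []
    pos = 0
    for s in segments:
        if s.start > pos:
            out.append(Segment(pos, s.start, None, -1, -1, ".", 0.0))
        out.append(s)
        pos = s.end
    if pos < n:
        out.append(Segment(pos, n, None, -1, -1, ".", 0.0))
    segments[:] = out


def _assign_classes(segments: list[Segment], locus_classes) -> None:
    loci = [(c, int(s), int(e), cls) for c, s, e, cls in locus_classes]
    for seg in segments:
        if seg.chrom is None:
            continue
        best, best_ov = None, 0
        for chrom, s, e, cls in loci:
            if chrom != seg.chrom:
                continue
            lo = max(min(seg.ref_start, seg.ref_end), s)
            hi = min(max(seg.ref_start, seg.ref_end), e)
            if hi - lo > best_ov:
                best, best_ov = cls, hi - lo
        if best is not None:
            seg.section_class = best


# ---------------------------------------------------------------------------
# anchored global alignment (shared plumbing)
# ---------------------------------------------------------------------------

def anchored_global_align(a, b, seed_len: int = 15):
    """Global alignment of two long collinear sequences.

    Unique exact seeds shared in order anchor the alignment; blocks in
    between are aligned with affine-gap Needleman-Wunsch.  Returns a list
    of ``(op, length)`` with op in ``M`` (aligned columns, match or
    mismatch), ``I`` (present only in ``a``), ``D`` (present only in
    ``b``), plus the match count.
    """
    ac = encode(a) if isinstance(a, str) else a
    bc = encode(b) if isinstance(b, str) else b
    anchors = _unique_shared_anchors(ac, bc, seed_len)
    aligner = _make_aligner()
    ops: list[tuple[str, int]] = []
    matches = 0
    pa = pb = 0
    for ha, hb in anchors + [(ac.shape[0], bc.shape[0])]:
        sub_a = decode(ac[pa:ha])
        sub_b = decode(bc[pb:hb])
        m = _block_ops(aligner, sub_a, sub_b, ops)
        matches += m
        if ha < ac.shape[0]:
            _push(ops, "M", seed_len)
            matches += seed_len
            pa, pb = ha + seed_len, hb + seed_len
    return ops, matches


def _unique_shared_anchors(ac, bc, seed_len):
    ca, sa = kmer_scan(ac, seed_len, canonical=False)
    cb, sb = kmer_scan(bc, seed_len, canonical=False)
    ua, ia, na = np.unique(ca, return_index=True, return_counts=True)
    ub, ib, nb = np.unique(cb, return_index=True, return_counts=True)
    ua_u = ua[na == 1]
    ia_u = ia[na == 1]
    common, ai, bi = np.intersect1d(ua_u, ub[nb == 1], return_indices=True)
    if common.shape[0] == 0:
        return []
    apos = sa[ia_u[ai]]
    bpos = sb[ib[nb == 1][bi]]
    order = np.argsort(apos)
    apos, bpos = apos[order], bpos[order]
    # thin to ~one anchor per 32 bp so the chaining stays cheap
    if apos.shape[0] > 2:
        keep = [0]
        for i in range(1, apos.shape[0]):
            if apos[i] - apos[keep[-1]] >= 32:
                keep.append(i)
        apos, bpos = apos[keep], bpos[keep]
    # longest increasing chain in bpos, non-overlapping in both
    chain = _lis_chain(apos, bpos, seed_len)
    return chain


def _lis_chain(apos, bpos, seed_len):
    n = apos.shape[0]
    if n == 0:
        return []
    best_len = np.ones(n, np.int64)
    prev = np.full(n, -1, np.int64)
    bp = bpos
    ap = apos
    for i in range(n):
        lo = np.nonzero((bp[:i] + seed_len <= bp[i]) & (ap[:i] + seed_len <= ap[i]))[0]
        if lo.shape[0]:
            j = lo[np.argmax(best_len[lo])]
            if best_len[j] + 1 > best_len[i]:
                best_len[i] = best_len[j] + 1
                prev[i] = j
    i = int(np.argmax(best_len))
    chain = []
    while i >= 0:
        chain.append((int(ap[i]), int(bp[i])))
        i = int(prev[i])
    return chain[::-1]


def _block_ops(aligner, a: str, b: str, ops: list) -> int:
    if not a and not b:
        return 0
    if not a:
        _push(ops, "D", len(b))
        return 0
    if not b:
        _push(ops, "I", len(a))
        return 0
    aln = aligner.align(a, b)[0]
    s1, s2 = str(aln[0]), str(aln[1])
    m = 0
    for x, y in zip(s1, s2):
        if x == "-":
            _push(ops, "D", 1)
        elif y == "-":
            _push(ops, "I", 1)
        else:
            _push(ops, "M", 1)
            if x == y:
                m += 1
    return m


def _push(ops: list, op: str, length: int) -> None:
    if length <= 0:
        return
    if ops and ops[-1][0] == op:
        ops[-1] = (op, ops[-1][1] + length)
    else:
        ops.append((op, length))
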