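"""Greedy anchor-and-extend assembly of recruited reads into a W haplotype.

The W-specific reads recruited by k-mer membership are assembled outward
from an anchor (by convention a sequence spanning the diagnostic
deletion), extending a seed contig left and right with reads that
overlap by at least ``min_overlap`` bases at ``min_identity``.  The
consensus is a per-column majority over all reads placed on the draft;
ties are called N.  Read order is deterministic (lexicographic read id),
so the same input always yields the same contigs.

Scaffolding orders and orients contigs by their guide (reference
homology) coordinates and represents inter-contig gaps as runs of N of
the estimated length, bounded at 500 bp.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._codec import decode, encode, kmer_scan, revcomp_codes
from .paint import SegmentPainting
from .simdata import ReadSet

_PROBE = 25  # exact probe length for overlap detection and read placement


@dataclass
class Contig:
    codes: np.ndarray  # uint8 over {A,C,G,T,N}
    support: np.ndarray  # per-base read depth
    anchored: bool = False

    @property
    def sequence(self) -> str:
        return decode(self.codes)

    def __len__(self) -> int:
        return int(self.codes.shape[0])


@dataclass
class WHaplotype:
    """Ordered, oriented contigs joined with estimated gaps."""

    contigs: list[Contig]
    order: list[int]  # indices into contigs, placement order
    orientations: list[str]
    gaps: list[int]  # len(order) - 1 gap estimates, >= 0
    codes: np.ndarray = field(default=None)  # joined sequence with N gaps
    offsets: list[int] = field(default_factory=list)
    flagged: list[int] = field(default_factory=list)  # conflicting-guide contigs

    @property
    def sequence(self) -> str:
        return decode(self.codes)

    @property
    def total_span(self) -> int:
        return int(self.codes.shape[0])


def _read_pool(reads) -> list[tuple[str, np.ndarray]]:
    """(id, codes) for every mate, sorted by read id."""
    pool = []
    if isinstance(reads, ReadSet):
        for i, name in enumerate(reads.names):
            pool.append((f"{name}/1", reads.mate1[i]))
            pool.append((f"{name}/2", reads.mate2[i]))
    else:
        for i, r in enumerate(reads):
            if isinstance(r, tuple):
                pool.append((r[0], encode(r[1])))
            else:
                pool.append((f"read{i:08d}", encode(r)))
    pool.sort(key=lambda t: t[0])
    return pool


class _ProbeIndex:
    """Exact probe-kmer lookup across a read pool."""

    def __init__(self, pool):
        self.pool = pool
        codes_all, where = [], []
        for ri, (_, codes) in enumerate(pool):
            km, st = kmer_scan(codes, _PROBE, canonical=False)
            codes_all.append(km)
            where.append(np.stack([np.full(st.shape[0], ri), st], axis=1))
            rc = revcomp_codes(codes)
            km2, st2 = kmer_scan(rc, _PROBE, canonical=False)
            codes_all.append(km2)
            # mark reverse-orientation entries with negative read index - 1
            where.append(np.stack([np.full(st2.shape[0], -ri - 1), st2], axis=1))
        cat = np.concatenate(codes_all) if codes_all else np.empty(0, np.int64)
        wcat = np.concatenate(where) if where else np.empty((0, 2), np.int64)
        order = np.argsort(cat, kind="stable")
        self._codes = cat[order]
        self._where = wcat[order]

    def lookup(self, code: int):
        lo = np.searchsorted(self._codes, code, "left")
        hi = np.searchsorted(self._codes, code, "right")
        for ri, off in self._where[lo:hi]:
            ri = int(ri)
            if ri < 0:
                yield -ri - 1, int(off), "-"
            else:
                yield ri, int(off), "+"

    def oriented(self, ri: int, orient: str) -> np.ndarray:
        codes = self.pool[ri][1]
        return revcomp_codes(codes) if orient == "-" else codes


def _overlap_identity(a: np.ndarray, b: np.ndarray) -> float:
    n = min(a.shape[0], b.shape[0])
    if n == 0:
        return 0.0
    return float((a[:n] == b[:n]).sum()) / n


def assemble_contigs(reads, anchor: str, min_overlap: int = 50,
                     min_identity: float = 0.98) -> list[Contig]:
    """Anchor-seeded greedy overlap assembly with majority consensus.

    ``reads`` is a ReadSet or an iterable of read strings / (id, seq)
    pairs.  The contig containing the anchor is extended first; leftover
    reads seed further contigs.  Raises if the anchor occurs in no read.
    """
    pool = _read_pool(reads)
    if not pool:
        raise ValueError("no reads to assemble")
    index = _ProbeIndex(pool)
    anchor_codes = encode(anchor)
    seed_ri, seed_orient = _find_anchor_read(pool, anchor_codes)
    if seed_ri is None:
        raise ValueError(f"anchor not found in any read: {anchor[:40]}...")

    used = np.zeros(len(pool), bool)
    contigs: list[Contig] = []
    draft = index.oriented(seed_ri, seed_orient).copy()
    used[seed_ri] = True
    draft = _extend(draft, index, used, min_overlap, min_identity)
    contigs.append(_polish(draft, index, used, anchored=True))

    while True:
        free = np.nonzero(~used)[0]
        if free.shape[0] == 0:
            break
        ri = int(free[0])  # pool is id-sorted: deterministic seed choice
        used[ri] = True
        draft = index.oriented(ri, "+").copy()
        draft = _extend(draft, index, used, min_overlap, min_identity)
        contigs.append(_polish(draft, index, used, anchored=False))
    return contigs


def _find_anchor_read(pool, anchor_codes):
    a = anchor_codes
    rc = revcomp_codes(a)
    for ri, (_, codes) in enumerate(pool):
        if _contains(codes, a):
            return ri, "+"
        if _contains(codes, rc):
            return ri, "-"
    return None, None


def _contains(hay: np.ndarray, needle: np.ndarray) -> bool:
    n, m = hay.shape[0], needle.shape[0]
    if m > n:
        return False
    # probe by first PROBE bases then verify
    w = min(m, _PROBE)
    view = np.lib.stride_tricks.sliding_window_view(hay, w)
    cand = np.nonzero((view == needle[:w]).all(axis=1))[0]
    for c in cand:
        if c + m <= n and (hay[c : c + m] == needle).all():
            return True
    return False


def _extend(draft: np.ndarray, index: _ProbeIndex, used: np.ndarray,
            min_overlap: int, min_identity: float) -> np.ndarray:
    for direction in ("right", "left"):
        while True:
            work = draft if direction == "right" else revcomp_codes(draft)
            ext = _best_extension(work, index, used, min_overlap, min_identity)
            if ext is None:
                break
            work = np.concatenate([work, ext])
            draft = work if direction == "right" else revcomp_codes(work)
    return draft


def _best_extension(contig: np.ndarray, index: _ProbeIndex, used, min_overlap,
                    min_identity):
    """Unused read overlapping the contig 3' end; returns appended codes."""
    L = contig.shape[0]
    best = None  # (extension_len, read_id, ri, tail)
    for probe_at in (L - _PROBE, L - _PROBE - 15, L - _PROBE - 30):
        if probe_at < 0:
            continue
        window = contig[probe_at : probe_at + _PROBE]
        if (window >= 4).any():
            continue
        code = 0
        for c in window:
            code = (code << 2) | int(c)
        for ri, off, orient in index.lookup(code):
            if used[ri]:
                continue
            read = index.oriented(ri, orient)
            start = probe_at - off  # read start on contig coords
            if start < 0:
                continue
            overlap = L - start
            if overlap < min_overlap or start + read.shape[0] <= L:
                continue
            ident = _overlap_identity(contig[start:], read[: L - start])
            if ident < min_identity:
                continue
            ext_len = start + read.shape[0] - L
            rid = index.pool[ri][0]
            cand = (ext_len, rid)
            if best is None or (cand[0], ) > (best[0], ) or (
                cand[0] == best[0] and rid < best[1]
            ):
                best = (ext_len, rid, ri, read[L - start :])
        if best is not None:
            break
    if best is None:
        return None
    used[best[2]] = True
    return best[3]


def _polish(draft: np.ndarray, index: _ProbeIndex, used: np.ndarray,
            anchored: bool) -> Contig:
    """Place every pool read on the draft and take the column majority."""
    L = draft.shape[0]
    votes = np.zeros((L, 4), np.int32)
    support = np.zeros(L, np.int32)
    km, st = kmer_scan(draft, _PROBE, canonical=False)
    # draft probe -> position (first occurrence wins)
    placed = set()
    for code, pos in zip(km.tolist(), st.tolist()):
        lo = np.searchsorted(index._codes, code, "left")
        hi = np.searchsorted(index._codes, code, "right")
        for ri, off in index._where[lo:hi]:
            ri = int(ri)
            orient = "-" if ri < 0 else "+"
            rdx = -ri - 1 if ri < 0 else ri
            if (rdx, orient) in placed:
                continue
            read = index.oriented(rdx, orient)
            start = pos - int(off)
            if start < 0 or start + read.shape[0] > L:
                continue
            ident = _overlap_identity(draft[start : start + read.shape[0]], read)
            if ident < 0.90:
                continue
            placed.add((rdx, orient))
            seg = read
            ok = seg < 4
            idx = np.arange(start, start + seg.shape[0])[ok]
            votes[idx, seg[ok]] += 1
            support[idx] += 1
            used[rdx] = True
    consensus = draft.copy()
    has_votes = support > 0
    top = votes.argmax(axis=1)
    maxv = votes.max(axis=1)
    nties = (votes == maxv[:, None]).sum(axis=1)
    consensus[has_votes] = top[has_votes].astype(np.uint8)
    consensus[has_votes & (nties > 1)] = 4  # tie -> N
    return Contig(consensus, np.maximum(support, 1), anchored)


# ---------------------------------------------------------------------------
# [OP] scaffold_contigs
# ---------------------------------------------------------------------------

def scaffold_contigs(contigs: list[Contig], paintings: list[SegmentPainting],
                     reads=None, insert_mean: int = 400,
                     max_gap_run: int = 500) -> WHaplotype:
    """Order and orient contigs into a unified haplotype.

    When ``reads`` (the recruited pool) is given, read pairs whose mates
    land near the ends of two different contigs order and orient them
    directly — the only signal that works across a chimeric haplotype
    whose contigs descend from different source loci.  Contigs without
    link evidence, or all contigs when no reads are given, fall back to
    guide-homology coordinates (longest painted segment).  Contigs whose
    painted segments disagree on the source chromosome are flagged and
    left out rather than placed silently.
    """
    if len(contigs) != len(paintings):
        raise ValueError("one painting per contig required")
    placeable, flagged = [], []
    for i, (contig, painting) in enumerate(zip(contigs, paintings)):
        painted = painting.painted()
        if not painted:
            flagged.append(i)
            continue
        best = max(painted, key=lambda s: s.end - s.start)
        span = sum(s.end - s.start for s in painted)
        other = sum(s.end - s.start for s in painted if s.chrom != best.chrom)
        if other > 0.5 * span and len(painted) > 1:
            flagged.append(i)
            continue
        placeable.append((best.chrom, min(best.ref_start, best.ref_end), i, best))
    if not placeable:
        raise ValueError("no contig paints to any guide locus")

    chains = None
    if reads is not None and len(placeable) > 1:
        chains = _link_chains([i for _, _, i, _ in placeable], contigs, reads,
                              insert_mean)
    if chains:
        # links fix only relative orientation: flip any chain that is
        # mostly reverse with respect to its guide loci
        strand_of = {i: seg.strand for _, _, i, seg in placeable}
        fixed = []
        for ch in chains:
            score = sum((1 if strand_of.get(i, o) == o else -1) * len(contigs[i])
                        for i, o in ch)
            if score < 0:
                ch = [(i, "-" if o == "+" else "+") for i, o in reversed(ch)]
            fixed.append(ch)
        chains = fixed
    if not chains:
        placeable.sort(key=lambda t: (t[0], t[1]))
        chains = [[(i, seg.strand) for _, _, i, seg in placeable]]
    else:
        # order chains (and leftover contigs) by their guide coordinates
        guide = {i: (c, p, seg) for c, p, i, seg in placeable}
        chained = {i for ch in chains for i, _ in ch}
        for c, p, i, seg in sorted(placeable, key=lambda t: (t[0], t[1])):
            if i not in chained:
                chains.append([(i, seg.strand)])
        chains.sort(key=lambda ch: min(guide[i][:2] for i, _ in ch if i in guide))

    order, orientations, gaps, parts, offsets = [], [], [], [], []
    pos = 0
    flat = [ic for ch in chains for ic in ch]
    for j, (i, orient) in enumerate(flat):
        order.append(i)
        orientations.append(orient)
        offsets.append(pos)
        codes = contigs[i].codes
        if orient == "-":
            codes = revcomp_codes(codes)
        parts.append(codes)
        pos += codes.shape[0]
        if j < len(flat) - 1:
            gap = _guide_gap(placeable, contigs, flat[j][0], flat[j + 1][0],
                             max_gap_run)
            gaps.append(gap)
            if gap > 0:
                parts.append(np.full(gap, 4, np.uint8))
                pos += gap
    joined = np.concatenate(parts)
    return WHaplotype(contigs, order, orientations, gaps, joined, offsets, flagged)


def _guide_gap(placeable, contigs, i1, i2, max_gap_run) -> int:
    guide = {i: (c, p) for c, p, i, _ in placeable}
    if i1 not in guide or i2 not in guide or guide[i1][0] != guide[i2][0]:
        return min(100, max_gap_run)
    end1 = guide[i1][1] + len(contigs[i1])
    return int(min(max(0, guide[i2][1] - end1), max_gap_run))


def _link_chains(ids, contigs, reads, insert_mean):
    """Greedy contig chaining from read-pair links.

    Returns chains as lists of ``(contig_index, orientation)``; contigs
    with no links are left to the guide fallback.
    """
    from .paint import SeqIndex

    idx = {i: SeqIndex(contigs[i].codes, _PROBE) for i in ids}
    end_zone = insert_mean + 150
    votes: dict[tuple, int] = {}
    pool = _read_pool(reads)
    placements = []
    for rid, codes in pool:
        hit = None
        for i in ids:
            hit_i = _quick_place(codes, idx[i])
            if hit_i is not None:
                if hit is not None:
                    hit = None  # ambiguous across contigs
                    break
                hit = (i, *hit_i)
        placements.append(hit)
    by_pair: dict[str, list] = {}
    for (rid, _), hit in zip(pool, placements):
        if hit is not None:
            by_pair.setdefault(rid[:-2], []).append((rid[-1], hit))
    for mates in by_pair.values():
        if len(mates) != 2:
            continue
        (_, (ci, pi, si)), (_, (cj, pj, sj)) = mates
        if ci == cj:
            continue
        _vote(votes, contigs, ci, pi, si, cj, pj, sj, end_zone)
        _vote(votes, contigs, cj, pj, sj, ci, pi, si, end_zone)
    edges = sorted(votes.items(), key=lambda kv: (-kv[1], kv[0]))
    right_of: dict[int, tuple] = {}
    left_of: dict[int, tuple] = {}
    orient: dict[int, str] = {}
    for (a, oa, b, ob), n in edges:
        if n < 2:
            continue
        if a in right_of or b in left_of:
            continue
        if a in orient and orient[a] != oa:
            continue
        if b in orient and orient[b] != ob:
            continue
        right_of[a] = (b, ob)
        left_of[b] = (a, oa)
        orient[a] = oa
        orient[b] = ob
    if not right_of:
        return None
    chains = []
    starts = [i for i in orient if i not in left_of]
    for s in sorted(starts):
        chain = [(s, orient[s])]
        seen = {s}
        while chain[-1][0] in right_of:
            nxt, onxt = right_of[chain[-1][0]]
            if nxt in seen:
                break
            chain.append((nxt, onxt))
            seen.add(nxt)
        chains.append(chain)
    return chains


def _vote(votes, contigs, a, pa, sa, b, pb, sb, end_zone):
    """Vote for 'a placed left of b' if the mate geometry allows it."""
    la, lb = len(contigs[a]), len(contigs[b])
    oa = "+" if sa == "+" else "-"  # orientation making mate-on-a forward
    ob = "+" if sb == "-" else "-"  # orientation making mate-on-b reverse
    da = la - pa if oa == "+" else pa + 150  # distance to a's right end
    db = pb + 150 if ob == "+" else lb - pb  # distance from b's left end
    if da <= end_zone and db <= end_zone:
        key = (a, oa, b, ob)
        votes[key] = votes.get(key, 0) + 1


def _quick_place(codes, index):
    """Exact-probe placement of one read on one contig (None if absent)."""
    from ._codec import kmer_scan

    for probe_at in (0, 40, 80):
        if probe_at + _PROBE > codes.shape[0]:
            break
        window = codes[probe_at : probe_at + _PROBE]
        if (window >= 4).any():
            continue
        code = 0
        for c in window:
            code = (code << 2) | int(c)
        for strand, qc in (("+", code), ("-", None)):
            if strand == "-":
                rc = revcomp_codes(window)
                qc = 0
                for c in rc:
                    qc = (qc << 2) | int(c)
            lo = np.searchsorted(index._codes, qc)
            if lo < index._codes.shape[0] and index._codes[lo] == qc:
                pos = int(index._starts[lo])
                if strand == "+":
                    return pos - probe_at, "+"
                return pos - (codes.shape[0] - probe_at - _PROBE), "-"
    return None


# ---------------------------------------------------------------------------
# [OP] spacing_stats
# ---------------------------------------------------------------------------

@dataclass
class SpacingStats:
    defined: bool
    median_span: float = float("nan")
    frac_below: float = float("nan")
    n_spans: int = 0
    threshold: int = 500


def spacing_stats(kmer_positions, k: int = 31, threshold: int = 500,
                  exclude=()) -> SpacingStats:
    """Median span between consecutive non-overlapping k-mer starts and the
    fraction of spans under ``threshold``; intervals in ``exclude`` (e.g.
    assembly gaps) are skipped."""
    pos = np.unique(np.asarray(list(kmer_positions), np.int64))
    picked = []
    last = -10**12
    for p in pos.tolist():
        if p >= last + k:
            picked.append(p)
            last = p
    if len(picked) < 2:
        warnings.warn("fewer than two non-overlapping k-mers: spacing undefined")
        return SpacingStats(False, threshold=threshold)
    spans = []
    for a, b in zip(picked[:-1], picked[1:]):
        if any(s < b and a < e for s, e in exclude):
            continue
        spans.append(b - a)
    if not spans:
        return SpacingStats(False, threshold=threshold)
    spans = np.asarray(spans)
    return SpacingStats(True, float(np.median(spans)),
                        float((spans < threshold).mean()), len(spans), threshold)
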