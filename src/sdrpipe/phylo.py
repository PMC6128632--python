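"""Clade phylogenetics of the W cassette window.

Per-female consensus sequences over a cassette window (by default the
~2.7 kb around the retrogene and the diagnostic deletion) are compared
by neighbor-joining on Jukes-Cantor distances with pairwise deletion of
missing sites, supported by a nonparametric bootstrap over columns, and
rooted on a pseudo-outgroup stitched from the source loci of each
painted sub-segment (the retrogene's source contributing its exons
only, so the outgroup is collinear with the intron-less W copy).

The neighbor-joining implementation is internal and deliberately plain;
it is cross-checked in the test suite against an independent
implementation and against brute-force minimum-evolution enumeration on
small tip sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._codec import decode, encode, revcomp_codes
from .hemizygosity import map_pairs_to_haplotype
from .paint import SegmentPainting, SeqIndex, anchored_global_align

GAP = np.uint8(5)  # alignment gap; 4 = N/unknown


# ---------------------------------------------------------------------------
# [TYPE] AlignmentMatrix
# ---------------------------------------------------------------------------

@dataclass
class AlignmentMatrix:
    ids: list[str]
    matrix: np.ndarray  # (n, L) codes: 0..3 bases, 4 N, 5 gap
    missing: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.ids):
            raise ValueError("matrix shape does not match ids")

    @property
    def n_columns(self) -> int:
        return int(self.matrix.shape[1])

    def row(self, sid: str) -> np.ndarray:
        return self.matrix[self.ids.index(sid)]

    def to_fasta(self, path) -> None:
        from ._codec import write_fasta

        sym = np.frombuffer(b"ACGTN-", dtype=np.uint8)
        write_fasta(path, ((i, sym[r].tobytes().decode()) for i, r in
                           zip(self.ids, self.matrix)))

    def with_row(self, sid: str, row: np.ndarray) -> "AlignmentMatrix":
        mat = np.vstack([self.matrix, row[None, :]])
        missing = dict(self.missing)
        missing[sid] = float((row >= 4).mean())
        return AlignmentMatrix(self.ids + [sid], mat, missing)


# ---------------------------------------------------------------------------
# [OP] extract_window
# ---------------------------------------------------------------------------

def extract_window(reads_per_female: dict, haplotype, window: tuple[int, int],
                   min_identity: float = 0.90) -> AlignmentMatrix:
    """Per-female majority consensus over a haplotype window.

    ``reads_per_female`` maps female id to her recruited
    :class:`~sdrpipe.simdata.ReadSet`; reads are placed on the haplotype
    and votes are taken per column (ties and zero coverage call N).
    Females with 100% missing data are excluded with a warning.
    """
    hap = encode(haplotype) if isinstance(haplotype, str) else haplotype
    w0, w1 = window
    if not (0 <= w0 < w1 <= hap.shape[0]):
        raise ValueError("window outside haplotype")
    if len(reads_per_female) < 3:
        raise ValueError("need at least three females")
    index = SeqIndex(hap, 13)
    ids, rows, missing = [], [], {}
    for fid in sorted(reads_per_female):
        reads = reads_per_female[fid]
        placements = map_pairs_to_haplotype(reads, hap, min_identity, index=index)
        row = _window_consensus(reads, placements, w0, w1)
        miss = float((row >= 4).mean())
        if miss >= 1.0:
            warnings.warn(f"female {fid} has no data in the window: excluded")
            continue
        ids.append(fid)
        rows.append(row)
        missing[fid] = miss
    return AlignmentMatrix(ids, np.vstack(rows), missing)


def _window_consensus(reads, placements, w0, w1) -> np.ndarray:
    L = w1 - w0
    votes = np.zeros((L, 4), np.int32)
    for _, r in placements.iterrows():
        for mate, (s, strand) in enumerate(((r["s1"], r["strand1"]),
                                            (r["s2"], r["strand2"]))):
            codes = reads.mate1[r["pair_idx"]] if mate == 0 else reads.mate2[r["pair_idx"]]
            if strand == "-":
                codes = revcomp_codes(codes)
            s = int(s)
            e = s + codes.shape[0]
            lo, hi = max(s, w0), min(e, w1)
            if hi <= lo:
                continue
            seg = codes[lo - s : hi - s]
            ok = seg < 4
            idx = np.arange(lo - w0, hi - w0)[ok]
            votes[idx, seg[ok]] += 1
    total = votes.sum(axis=1)
    top = votes.argmax(axis=1).astype(np.uint8)
    maxv = votes.max(axis=1)
    ties = (votes == maxv[:, None]).sum(axis=1) > 1
    out = top
    out[(total == 0) | ties] = 4
    return out


# ---------------------------------------------------------------------------
# [OP] build_pseudo_outgroup
# ---------------------------------------------------------------------------

def build_pseudo_outgroup(haplotype, window: tuple[int, int],
                          painting: SegmentPainting, reference,
                          max_unpainted: int = 80) -> np.ndarray:
    """Source-locus concatenation projected onto the window columns.

    For every painted sub-segment overlapping the window, the source
    sequence is aligned back to the haplotype piece and written into the
    corresponding columns (gaps where the haplotype has no source
    column).  Sub-segments left unpainted beyond ``max_unpainted`` bp
    raise an error listing the gaps.
    """
    hap = encode(haplotype) if isinstance(haplotype, str) else haplotype
    ref = {c: (encode(s) if isinstance(s, str) else s) for c, s in reference.items()}
    w0, w1 = window
    out = np.full(w1 - w0, 4, np.uint8)
    covered = np.zeros(w1 - w0, bool)
    for seg in painting.painted():
        lo, hi = max(seg.start, w0), min(seg.end, w1)
        if hi <= lo:
            continue
        src = ref[seg.chrom][min(seg.ref_start, seg.ref_end): max(seg.ref_start, seg.ref_end)]
        if seg.strand == "-":
            src = revcomp_codes(src)
        hap_piece = hap[seg.start : seg.end]
        proj = _project(hap_piece, src)
        out[lo - w0 : hi - w0] = proj[lo - seg.start : hi - seg.start]
        covered[lo - w0 : hi - w0] = True
    gaps = _uncovered_runs(covered)
    big = [(s + w0, e + w0) for s, e in gaps if e - s > max_unpainted]
    if big:
        raise ValueError(f"unpainted window sub-segments: {big}")
    return out


def _project(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """For each position of ``a``, the aligned base of ``b`` (gap -> 5)."""
    ops, _ = anchored_global_align(a, b)
    out = np.full(a.shape[0], GAP, np.uint8)
    pa = pb = 0
    for op, n in ops:
        if op == "M":
            out[pa : pa + n] = b[pb : pb + n]
            pa += n
            pb += n
        elif op == "I":
            out[pa : pa + n] = GAP
            pa += n
        else:
            pb += n
    return out


def _uncovered_runs(covered: np.ndarray):
    runs = []
    in_run = False
    for i, c in enumerate(covered):
        if not c and not in_run:
            start, in_run = i, True
        elif c and in_run:
            runs.append((start, i))
            in_run = False
    if in_run:
        runs.append((start, covered.shape[0]))
    return runs


# ---------------------------------------------------------------------------
# distances and neighbor joining
# ---------------------------------------------------------------------------

def jc_distance_matrix(matrix: np.ndarray, max_d: float = 5.0) -> np.ndarray:
    """Jukes-Cantor distances with pairwise deletion of missing sites."""
    n = matrix.shape[0]
    D = np.zeros((n, n))
    valid = matrix < 4
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            nb = int(both.sum())
            if nb == 0:
                D[i, j] = D[j, i] = max_d
                continue
            p = float((matrix[i, both] != matrix[j, both]).mean())
            if p >= 0.75:
                d = max_d
            else:
                d = -0.75 * np.log(1 - 4 * p / 3)
            D[i, j] = D[j, i] = min(d, max_d)
    return D


def nj_adjacency(D: np.ndarray):
    """Classic neighbor joining; returns an unrooted adjacency map
    {node: [(neighbor, branch_length), ...]} with leaves 0..n-1."""
    n = D.shape[0]
    if n < 3:
        adj: dict[int, list] = {i: [] for i in range(n)}
        if n == 2:
            adj[0].append((1, float(D[0, 1])))
            adj[1].append((0, float(D[0, 1])))
        return adj
    active = list(range(n))
    dist = {(i, j): float(D[i, j]) for i in range(n) for j in range(n) if i != j}
    adj = {i: [] for i in range(n)}
    nxt = n
    while len(active) > 3:
        m = len(active)
        r = {i: sum(dist[(i, j)] for j in active if j != i) for i in active}
        best, bq = None, np.inf
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * dist[(i, j)] - r[i] - r[j]
                if q < bq - 1e-12:
                    bq, best = q, (i, j)
        i, j = best
        u = nxt
        nxt += 1
        li = 0.5 * dist[(i, j)] + (r[i] - r[j]) / (2 * (m - 2))
        lj = dist[(i, j)] - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        adj[u] = []
        _link(adj, u, i, li)
        _link(adj, u, j, lj)
        for x in active:
            if x in (i, j):
                continue
            d = 0.5 * (dist[(i, x)] + dist[(j, x)] - dist[(i, j)])
            dist[(u, x)] = dist[(x, u)] = max(d, 0.0)
        active = [x for x in active if x not in (i, j)] + [u]
    if len(active) == 3:
        i, j, k = active
        u = nxt
        adj[u] = []
        li = 0.5 * (dist[(i, j)] + dist[(i, k)] - dist[(j, k)])
        lj = 0.5 * (dist[(i, j)] + dist[(j, k)] - dist[(i, k)])
        lk = 0.5 * (dist[(i, k)] + dist[(j, k)] - dist[(i, j)])
        _link(adj, u, i, max(li, 0.0))
        _link(adj, u, j, max(lj, 0.0))
        _link(adj, u, k, max(lk, 0.0))
    return adj


def _link(adj, u, v, length):
    adj[u].append((v, length))
    adj[v].append((u, length))


def tree_bipartitions(adj, names, anchor: str) -> dict[frozenset, float]:
    """Nontrivial bipartitions as the tip set NOT containing ``anchor``,
    mapped to the corresponding branch length."""
    n = len(names)
    out: dict[frozenset, float] = {}
    seen = set()
    for u in adj:
        for v, length in adj[u]:
            if (v, u) in seen:
                continue
            seen.add((u, v))
            side = _tips_beyond(adj, v, u, n)
            tipset = frozenset(names[t] for t in side)
            if len(tipset) < 2 or len(tipset) > n - 2:
                continue
            if names.index(anchor) in side:
                tipset = frozenset(names) - tipset
            if 2 <= len(tipset) <= n - 2:
                out[tipset] = length
    return out


def _tips_beyond(adj, start, block, n):
    stack, seen, tips = [start], {block, start}, []
    while stack:
        u = stack.pop()
        if u < n:
            tips.append(u)
        for v, _ in adj[u]:
            if v not in seen:
                seen.add(v)
                stack.append(v)
    return tips


# ---------------------------------------------------------------------------
# rooted tree container
# ---------------------------------------------------------------------------

@dataclass
class Clade:
    tips: frozenset
    support: float
    length: float


@dataclass
class Phylogeny:
    tips: list[str]
    outgroup: tuple[str, ...]
    newick: str
    clades: list[Clade]  # rooted ingroup clades with bootstrap support
    flags: list[str] = field(default_factory=list)

    def ingroup(self) -> list[str]:
        return [t for t in self.tips if t not in self.outgroup]

    def supported_clades(self, support_min: float) -> list[Clade]:
        ing = frozenset(self.ingroup())
        return [c for c in self.clades
                if c.support >= support_min and c.tips < ing]


def build_tree(alignment: AlignmentMatrix, outgroup, bootstrap_n: int = 100,
               seed: int = 0, max_gap_frac: float = 0.5) -> Phylogeny:
    """NJ + JC + column bootstrap, rooted on the (pseudo-)outgroup.

    Support of a rooted clade is the percentage of bootstrap replicates
    whose unrooted tree contains the matching bipartition.  Columns with
    more than ``max_gap_frac`` missing data are excluded from the
    bootstrap resampling pool (flagged).
    """
    if isinstance(outgroup, str):
        outgroup = (outgroup,)
    names = alignment.ids
    if len(names) < 4:
        raise ValueError("need at least four tips")
    mat = alignment.matrix
    flags = []
    D = jc_distance_matrix(mat)
    if D.max() == 0:
        flags.append("no_variation_star_tree")
        ing = [t for t in names if t not in outgroup]
        nwk = "(" + ",".join(f"{t}:0" for t in names) + ");"
        return Phylogeny(list(names), tuple(outgroup), nwk, [], flags)
    adj = nj_adjacency(D)
    anchor = outgroup[0]
    main_bips = tree_bipartitions(adj, names, anchor)

    good_cols = np.nonzero((mat >= 4).mean(axis=0) <= max_gap_frac)[0]
    if good_cols.shape[0] < mat.shape[1]:
        flags.append(f"{mat.shape[1] - good_cols.shape[0]}_columns_excluded_from_bootstrap")
    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {b: 0 for b in main_bips}
    for _ in range(bootstrap_n):
        cols = rng.choice(good_cols, good_cols.shape[0], replace=True)
        Db = jc_distance_matrix(mat[:, cols])
        bips = tree_bipartitions(nj_adjacency(Db), names, anchor)
        for b in counts:
            if b in bips:
                counts[b] += 1
    clades = [Clade(b, 100.0 * counts[b] / bootstrap_n, main_bips[b])
              for b in main_bips]
    clades.sort(key=lambda c: (len(c.tips), sorted(c.tips)))
    nwk = _rooted_newick(adj, names, outgroup,
                         {c.tips: c.support for c in clades})
    return Phylogeny(list(names), tuple(outgroup), nwk, clades, flags)


def _rooted_newick(adj, names, outgroup, supports) -> str:
    n = len(names)
    og = names.index(outgroup[0])
    parent, length = adj[og][0]

    def render(u, block) -> str:
        if u < n:
            return f"{names[u]}"
        kids = [(v, l) for v, l in adj[u] if v != block]
        tipset = frozenset(names[t] for t in _tips_beyond(adj, u, block, n))
        sup = supports.get(tipset)
        label = f"{sup:.0f}" if sup is not None else ""
        inner = ",".join(f"{render(v, u)}:{l:.6f}" for v, l in kids)
        return f"({inner}){label}"

    return f"({names[og]}:{length:.6f},{render(parent, og)}:0);"


# ---------------------------------------------------------------------------
# [OP] assign_clades
# ---------------------------------------------------------------------------

def assign_clades(phylogeny: Phylogeny, support_min: float = 75.0,
                  min_stem: float = 1e-3):
    """Partition ingroup tips into the maximal supported clades.

    Candidates are the proper, supported (bootstrap >= ``support_min``)
    sub-clades of the ingroup whose stem branch exceeds ``min_stem``
    substitutions/site — edges shorter than that are treated as an
    unresolved polytomy (on clean near-additive data NJ must resolve a
    polytomy somehow, and the bootstrap can reproduce that arbitrary
    resolution with high support, but only ever on a near-zero stem).
    The maximal candidates are reported and any tip outside all of them
    is "unassigned".  If no proper sub-clade qualifies, all ingroup tips
    fall back to a single clade when the ingroup itself is resolved
    (multi-tip outgroup), otherwise they are unassigned.
    """
    ing = frozenset(phylogeny.ingroup())
    cands = [c.tips for c in phylogeny.clades
             if c.support >= support_min and c.tips <= ing
             and c.length >= min_stem]
    proper = [t for t in cands if t < ing]
    if not proper:
        if ing in cands:
            return {t: "clade_1" for t in ing}, [ing]
        return {t: "unassigned" for t in ing}, []
    maximal = [t for t in proper if not any(t < o for o in proper)]
    maximal.sort(key=lambda t: sorted(t)[0])
    labels: dict[str, str] = {}
    for i, tips in enumerate(maximal):
        for t in tips:
            labels[t] = f"clade_{i + 1}"
    for t in ing:
        labels.setdefault(t, "unassigned")
    return labels, maximal


# ---------------------------------------------------------------------------
# [OP] retrogene_monophyly
# ---------------------------------------------------------------------------

@dataclass
class MonophylyResult:
    monophyletic: bool | None
    newick: str
    flags: list[str] = field(default_factory=list)


def retrogene_monophyly(retro_seqs: dict[str, str],
                        paralog_seqs: dict[str, str]) -> MonophylyResult:
    """Do the retrogene copies form a single clade against the paralogs?

    Sequences are projected onto the first retro copy's coordinates, an
    NJ tree is built, and monophyly holds iff some edge bipartitions the
    retro copies from all paralogs.  Zero divergence among all tips is
    flagged unresolved.
    """
    if len(retro_seqs) < 2 or len(paralog_seqs) < 2:
        raise ValueError("need >=2 retro copies and >=2 paralogs")
    names = list(retro_seqs) + list(paralog_seqs)
    seqs = {**retro_seqs, **paralog_seqs}
    anchor_name = names[0]
    anchor = encode(seqs[anchor_name])
    rows = [anchor]
    for nm in names[1:]:
        rows.append(_project(anchor, encode(seqs[nm])))
    mat = np.vstack(rows)
    D = jc_distance_matrix(mat)
    if D.max() == 0:
        return MonophylyResult(None, "", ["no_divergence_unresolved"])
    adj = nj_adjacency(D)
    retro_set = frozenset(retro_seqs)
    bips = tree_bipartitions(adj, names, next(iter(paralog_seqs)))
    nwk = _rooted_newick(adj, names, (next(iter(paralog_seqs)),), {})
    return MonophylyResult(retro_set in bips, nwk, [])
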