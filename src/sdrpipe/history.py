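"""Ordering SDR translocations from clade composition ("souvenir" logic),
plus the transposon-signature scan at insertion borders.

Each translocation of the sex-determining region carries along sequence
adjacent to its previous location, so younger SDRs contain nested
souvenirs of every earlier address.  When the clade x section presence
matrix forms a chain under the subset relation, the chain *is* the
temporal order: the universally shared section marks the ancestral
location and each enlargement marks one move.  Terminal inverted
repeats flanked by target-site duplications at the borders of the moved
segment are the classic footprint of a class-2 (cut-and-paste)
transposition mechanism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._codec import decode, encode, revcomp_codes
from .hemizygosity import read_depth, sex_depth_ttest
from .paint import SegmentPainting


# ---------------------------------------------------------------------------
# [TYPE] CompositionMatrix
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Section:
    name: str  # cassette | flanking | outer | retro_insert | ...
    locus: str  # source-locus label, e.g. "chr6:2000" or "location-1"
    chrom: str
    intervals: tuple[tuple[int, int], ...] = ()  # on the haplotype


@dataclass
class CompositionMatrix:
    clades: list[str]
    sections: list[Section]
    presence: np.ndarray  # bool (n_clades, n_sections)
    evidence: dict[tuple[str, str], str] = field(default_factory=dict)

    def __post_init__(self):
        for i, clade in enumerate(self.clades):
            if not self.presence[i].any():
                raise ValueError(f"clade {clade} has an all-false row")
        loci = [s.locus for s in self.sections]
        if len(set(loci)) != len(loci):
            raise ValueError("sections must have unique source loci")

    def row(self, clade: str) -> set[str]:
        i = self.clades.index(clade)
        return {s.name for s, p in zip(self.sections, self.presence[i]) if p}

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.presence, index=self.clades,
                            columns=[s.name for s in self.sections])


def composition_matrix(profiles: dict, painting: SegmentPainting,
                       min_overlap_frac: float = 0.5) -> CompositionMatrix:
    """Clade x section presence from female-specific intervals.

    A cell is true iff the clade's female-specific intervals cover at
    least ``min_overlap_frac`` of the section's haplotype span.  Sections
    are the classed, painted portions of the reference W haplotype.
    """
    secs = _sections_from_painting(painting)
    if not secs:
        raise ValueError("painting has no classed sections")
    clades = sorted(profiles)
    pres = np.zeros((len(clades), len(secs)), bool)
    evidence: dict[tuple[str, str], str] = {}
    for ci, clade in enumerate(clades):
        prof = profiles[clade]
        ivs = prof.intervals if hasattr(prof, "intervals") else list(prof)
        for si, sec in enumerate(secs):
            span = sum(e - s for s, e in sec.intervals)
            cov = sum(
                max(0, min(e, ie) - max(s, is_))
                for s, e in sec.intervals
                for is_, ie in ivs
            )
            if span and cov / span >= min_overlap_frac:
                pres[ci, si] = True
                evidence[(clade, sec.name)] = "kmer_intervals"
    return CompositionMatrix(clades, secs, pres, evidence)


def _sections_from_painting(painting: SegmentPainting) -> list[Section]:
    by_class: dict[str, list] = {}
    for seg in painting.painted():
        if seg.section_class in ("unplaced", "unclassified"):
            continue
        by_class.setdefault(seg.section_class, []).append(seg)
    out = []
    for cls, segs in by_class.items():
        main = max(segs, key=lambda s: s.end - s.start)
        locus = f"{main.chrom}:{min(main.ref_start, main.ref_end)}"
        out.append(Section(cls, locus, main.chrom,
                           tuple((s.start, s.end) for s in sorted(segs, key=lambda x: x.start))))
    out.sort(key=lambda s: s.intervals[0][0] if s.intervals else 0)
    return out


# ---------------------------------------------------------------------------
# [OP] infer_order
# ---------------------------------------------------------------------------

@dataclass
class TranslocationOrder:
    steps: list[tuple[str, tuple[str, ...]]]  # (location label, sections gained)
    ancestral: str
    n_events: int  # lower bound: steps - 1
    origin_ambiguous: tuple[str, ...] = ()

    def render(self) -> str:
        chain = " -> ".join(loc for loc, _ in self.steps)
        lines = [f"SDR location chain: {chain}  (>= {self.n_events} moves)"]
        for loc, gained in self.steps:
            lines.append(f"  at {loc}: gained {', '.join(gained)}")
        if self.origin_ambiguous:
            lines.append(f"  origin-ambiguous sections: {', '.join(self.origin_ambiguous)}")
        return "\n".join(lines)


def infer_order(matrix: CompositionMatrix) -> TranslocationOrder:
    """Temporal order of SDR movements from subset nesting.

    Deduplicated clade rows must form a chain under the subset relation;
    the section shared by every clade anchors the ancestral location
    (preferring a source locus on the same chromosome as the later map
    locations — souvenirs from other chromosomes, such as a
    retro-inserted gene copy, cannot be SDR addresses and are reported
    origin-ambiguous), and each enlargement step's location is the
    source locus of its newly gained sections.
    """
    rows = {clade: frozenset(matrix.row(clade)) for clade in matrix.clades}
    uniq = sorted(set(rows.values()), key=len)
    for a, b in zip(uniq[:-1], uniq[1:]):
        if len(a) == len(b) or not a < b:
            raise ValueError("non-nested composition: souvenir ordering inapplicable")
    by_name = {s.name: s for s in matrix.sections}
    shared = uniq[0]
    gained_per_step = [shared] + [b - a for a, b in zip(uniq[:-1], uniq[1:])]

    later_chroms = [by_name[n].chrom for step in gained_per_step[1:] for n in step]
    chain_chrom = max(set(later_chroms), key=later_chroms.count) if later_chroms else None

    anchors = sorted(n for n in shared
                     if chain_chrom is None or by_name[n].chrom == chain_chrom)
    ambiguous = tuple(sorted(n for n in shared if n not in anchors))
    if not anchors:
        anchors = sorted(shared)
        ambiguous = ()
    anchor_locus = by_name[_largest(anchors, by_name)].locus

    steps = [(anchor_locus, tuple(sorted(shared)))]
    for gained in gained_per_step[1:]:
        locus = by_name[_largest(sorted(gained), by_name)].locus
        steps.append((locus, tuple(sorted(gained))))
    return TranslocationOrder(steps, anchor_locus, len(steps) - 1, ambiguous)


def _largest(names, by_name) -> str:
    def span(n):
        return sum(e - s for s, e in by_name[n].intervals)

    return max(names, key=lambda n: (span(n), n))


# ---------------------------------------------------------------------------
# [OP] detect_tir
# ---------------------------------------------------------------------------

@dataclass
class TirCall:
    boundary: tuple[int, int]
    arm_length: int
    mismatches: int
    left_arm: tuple[int, int]
    right_arm: tuple[int, int]
    left_seq: str
    right_seq: str
    tsd: str | None
    tsd_length: int


def detect_tir(haplotype, boundaries, min_arm: int = 10, max_arm: int = 40,
               max_mismatch: int = 0, tsd_range: tuple[int, int] = (2, 10),
               slop: int = 0) -> list[TirCall]:
    """Terminal-inverted-repeat + target-site-duplication scan.

    For each candidate boundary pair ``(start, end)`` of a putative
    mobile segment, report the longest arm (min_arm..max_arm, up to
    ``max_mismatch`` mismatches) such that the segment's 5' terminus is
    the reverse complement of its 3' terminus, together with the longest
    exact direct repeat immediately outside both arms within
    ``tsd_range``.  ``slop`` searches +-slop bp around each boundary
    (boundaries estimated from read evidence are only insert-accurate)
    and keeps the longest arm, ties resolved toward the given estimate.
    """
    hap = encode(haplotype) if isinstance(haplotype, str) else haplotype
    L = hap.shape[0]
    calls = []
    for s0, e0 in boundaries:
        s0, e0 = int(s0), int(e0)
        cands = []
        for ds in range(-slop, slop + 1):
            for de in range(-slop, slop + 1):
                s, e = s0 + ds, e0 + de
                if not (0 <= s < e <= L) or e - s < 2 * min_arm:
                    continue
                for a in range(min(max_arm, (e - s) // 2), min_arm - 1, -1):
                    left = hap[s : s + a]
                    right_rc = revcomp_codes(hap[e - a : e])
                    mm = int((left != right_rc).sum())
                    if mm <= max_mismatch:
                        tsd, tlen = _find_tsd(hap, s, e, tsd_range)
                        cands.append((s, e, a, mm, tsd, tlen,
                                      abs(ds) + abs(de)))
                        break
        best = _pick_tir(cands)
        if best is None:
            continue
        s, e, a, mm, tsd, tlen, _ = best
        calls.append(TirCall((s, e), a, mm, (s, s + a), (e - a, e),
                             decode(hap[s : s + a]), decode(hap[e - a : e]),
                             tsd, tlen))
    return calls


def _find_tsd(hap, s, e, tsd_range):
    L = hap.shape[0]
    lo, hi = tsd_range
    for t in range(min(hi, s, L - e), lo - 1, -1):
        if t <= 0:
            break
        if (hap[s - t : s] == hap[e : e + t]).all():
            return decode(hap[s - t : s]), t
    return None, 0


def _pick_tir(cands):
    """Best TIR candidate: prefer TSD-bearing calls, drop telescoped
    variants, then take the longest arm nearest the boundary estimate.

    A palindromic duplication (the classic TA target site) reads equally
    well as part of the inverted arms, so a call at (s, e) with the TSD
    outside always has a twin at (s - t, e + t) whose arms absorbed the
    duplication; the twin is redundant and removed.
    """
    if not cands:
        return None
    with_tsd = [c for c in cands if c[4] is not None]
    pool = with_tsd or cands
    if with_tsd:
        keep = []
        for x in pool:
            telescoped = False
            for y in with_tsd:
                if y is x:
                    continue
                d = y[0] - x[0]
                if 1 <= d <= y[5] and x[1] - y[1] == d:
                    telescoped = True
                    break
            if not telescoped:
                keep.append(x)
        pool = keep or pool
    return min(pool, key=lambda c: (-c[2], c[6], c[3]))


# ---------------------------------------------------------------------------
# [OP] single_copy_check
# ---------------------------------------------------------------------------

@dataclass
class SingleCopyReport:
    sex_ttest_p: float
    dose_ratio: float
    interior_shared_ratio: float
    flags: list[str] = field(default_factory=list)


def single_copy_check(placements: dict, sexes: dict, skip_intervals,
                      recruited_names: dict, hap_len: int,
                      expected_copies: float = 8.0, anchor_margin: int = 200,
                      anchor_offset: int = 150,
                      interior_flag_ratio: float = 0.88) -> SingleCopyReport:
    """Dose bookkeeping for 'exactly one W insertion'.

    (i) junction-anchor depth should not differ between sexes (all
    chromosome copies carry the anchors); (ii) W-specific (recruited)
    depth inside the insertion should be ~1/``expected_copies`` of the
    anchor depth; (iii) substantial non-recruited read depth inside the
    insertion, relative to anchors, indicates a second (possibly
    degraded) copy somewhere in the genome.  The interior flag threshold
    is calibrated on the generator's default divergence model, where the
    known homologous copies explain an interior/anchor ratio of ~0.75
    and one extra diploid copy raises it to ~1.0.
    """
    flags: list[str] = []
    skips = [tuple(s) for s in skip_intervals]
    if not skips or not placements:
        return SingleCopyReport(float("nan"), float("nan"), float("nan"),
                                ["inconclusive_no_junctions"])
    # anchor windows sit a read length clear of the junction: reads that
    # straddle the junction on other copies cannot place on the haplotype,
    # so the shadow within `anchor_offset` of the junction undercounts
    anchors = []
    for s, e in skips:
        anchors.append((max(0, s - anchor_offset - anchor_margin), s - anchor_offset))
        anchors.append((e + anchor_offset, min(hap_len, e + anchor_offset + anchor_margin)))
    interior = [(s + anchor_margin, e - anchor_margin) for s, e in skips
                if e - s > 3 * anchor_margin]

    anchor_depth = {sid: read_depth(df, anchors, hap_len)
                    for sid, df in placements.items()}
    p = sex_depth_ttest(anchor_depth, sexes)

    fem = [sid for sid, sx in sexes.items() if sx == "female" and sid in placements]
    if not fem or not interior:
        return SingleCopyReport(p, float("nan"), float("nan"),
                                flags + ["inconclusive_no_female_interior"])
    w_depth = np.mean([
        read_depth(placements[sid], interior, hap_len, names=recruited_names.get(sid, set()))
        for sid in fem
    ])
    far_depth = np.mean([anchor_depth[sid] for sid in fem])
    if not np.isfinite(w_depth) or w_depth <= 0:
        return SingleCopyReport(p, float("nan"), float("nan"),
                                flags + ["inconclusive_no_w_depth"])
    dose = far_depth / w_depth
    if not (0.6 * expected_copies <= dose <= 1.5 * expected_copies):
        flags.append("dose_anomaly")

    shared_interior = np.mean([
        _nonrecruited_depth(placements[sid], interior, hap_len,
                            recruited_names.get(sid, set()))
        for sid in placements
    ])
    mean_anchor = np.mean([d for d in anchor_depth.values() if np.isfinite(d)])
    ratio = shared_interior / mean_anchor if mean_anchor > 0 else float("nan")
    if np.isfinite(ratio) and ratio > interior_flag_ratio:
        flags.append("possible_extra_copy")
    if np.isfinite(p) and p < 0.05:
        flags.append("sex_depth_difference")
    return SingleCopyReport(p, float(dose), float(ratio), flags)


def _nonrecruited_depth(df, intervals, hap_len, recruited) -> float:
    rest = df[~df["name"].isin(recruited)]
    return read_depth(rest, intervals, hap_len)
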