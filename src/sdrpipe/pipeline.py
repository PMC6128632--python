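"""End-to-end orchestration: reads -> k-mers -> haplotype -> hemizygosity
-> phylogeny -> translocation history.

`analyze_cohort` drives the whole chain on in-memory samples (the shape
produced by :mod:`sdrpipe.simdata`); `run_pipeline` is the file-based
wrapper behind the CLI, reading a sample manifest and writing every
stage product plus a machine-readable run report.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import _codec, assembly, hemizygosity, history, kmers, paint, phylo
from ._codec import decode, encode
from .simdata import ReadSet, SexedSample


@dataclass
class PipelineConfig:
    """Paths plus every stage parameter, all defaulting to the values the
    individual modules document."""

    reference: str | None = None
    manifest: str | None = None
    outdir: str = "sdrpipe_out"
    annotation: str | None = None  # reference gene exons (BED)
    seed: int = 0
    verbosity: int = 1
    # k-mer stage
    k: int = 31
    canonical: bool = True
    min_count: int = 1
    max_missing: int = 1
    # alignment filters
    min_match: int = 29
    max_gap: int = 30
    window: int = 2000
    # assembly
    min_overlap: int = 50
    min_identity: float = 0.98
    min_contig: int = 500  # unanchored contigs below this are stray-read noise
    # pair mapping / hemizygosity
    pair_min_identity: float = 0.95
    far_map_identity: float = 0.90  # autosomal recruitment for dose analysis
    far_threshold: int = 1000
    min_females: int = 1
    min_kmer_density: float = 5.0
    # phylogeny
    bootstrap_n: int = 100
    support_min: float = 75.0
    phylo_window: tuple[int, int] | None = None
    # history
    min_arm: int = 10
    max_arm: int = 40
    max_mismatch: int = 0
    expected_copies: float = 8.0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


@dataclass
class PipelineResult:
    config: PipelineConfig
    samples: list[SexedSample]
    fs_sets: dict[str, kmers.GroupSpecificKmerSet]
    control_sizes: dict[str, int]
    haplotype: str
    scaffold: assembly.WHaplotype
    painting: paint.SegmentPainting
    placements: dict[str, pd.DataFrame]
    recruited_names: dict[str, set]
    far_records: dict[str, list]
    skips: dict[str, list]
    seams: list
    profiles: dict[str, hemizygosity.HemizygosityProfile]
    deletions: list
    stop_call: hemizygosity.StopCodonCall | None
    tree: phylo.Phylogeny | None
    clade_labels: dict[str, str]
    matrix: history.CompositionMatrix | None
    order: history.TranslocationOrder | None
    tir_calls: list
    tir_absent: list
    single_copy: history.SingleCopyReport | None
    monophyly: phylo.MonophylyResult | None
    report: dict = field(default_factory=dict)
    alignment: phylo.AlignmentMatrix | None = None


def _log(cfg: PipelineConfig, msg: str) -> None:
    if cfg.verbosity:
        print(f"[sdrpipe] {msg}", flush=True)


def _concat_readsets(readsets: list[ReadSet]) -> ReadSet:
    readsets = [r for r in readsets if len(r)]
    names = [n for r in readsets for n in r.names]
    m1 = np.concatenate([r.mate1 for r in readsets])
    m2 = np.concatenate([r.mate2 for r in readsets])
    return ReadSet(names, m1, m2, None)


def analyze_cohort(samples: list[SexedSample], reference: dict,
                   annotation: dict | None, cfg: PipelineConfig) -> PipelineResult:
    """Run the full inference chain on in-memory samples.

    ``reference`` maps chromosome name to sequence (str or codes);
    ``annotation`` optionally describes the retrogene source/paralog exon
    structure and the cassette ORF, enabling the retrogene tests.
    """
    t0 = time.time()
    reference = {c: (encode(s) if isinstance(s, str) else s) for c, s in reference.items()}
    females = [s for s in samples if s.sex == "female"]
    males = [s for s in samples if s.sex == "male"]
    if not females or not males:
        raise ValueError("manifest must list at least one female and one male")
    clades = sorted({s.clade for s in females if s.clade} or {"all"})

    # ---- k-mer discovery --------------------------------------------------
    _log(cfg, f"counting {cfg.k}-mers in {len(samples)} samples")
    tables = {s.id: kmers.count_kmers(s.reads, cfg.k, cfg.canonical) for s in samples}
    fs_sets: dict[str, kmers.GroupSpecificKmerSet] = {}
    control_sizes: dict[str, int] = {}
    for clade in clades:
        fem_ids = [s.id for s in females if (s.clade or "all") == clade]
        male_ids = [s.id for s in males]
        # the all-but-one relaxation is only sound when "all but one"
        # still demands >=3 samples: two-way coincident sequencing
        # errors are common, three-way ones are not
        mm = min(cfg.max_missing, max(0, len(fem_ids) - 3))
        fs_sets[clade] = kmers.group_specific_kmers(
            tables, fem_ids, male_ids, cfg.min_count, mm)
        ctrl_m = [s.id for s in males if (s.clade or "all") == clade] or male_ids
        ctrl = kmers.group_specific_kmers(
            tables, ctrl_m, [s.id for s in females],
            cfg.min_count, min(mm, max(0, len(ctrl_m) - 3)))
        control_sizes[clade] = len(ctrl)
        _log(cfg, f"clade {clade}: {len(fs_sets[clade])} female-specific "
                  f"k-mers ({control_sizes[clade]} male-specific control)")

    # ---- read recruitment -------------------------------------------------
    recruited: dict[str, ReadSet] = {}
    for s in females:
        fs = fs_sets[s.clade or "all"]
        if len(fs) == 0:
            continue
        recruited[s.id], _ = kmers.recruit_reads(s.reads, fs)
    recruited_names = {sid: set(r.names) for sid, r in recruited.items()}

    # ---- assembly of the W haplotype -------------------------------------
    ref_clade = max(clades, key=lambda c: len(fs_sets[c]))
    pool_ids = [s.id for s in females if (s.clade or "all") == ref_clade]
    pool = _concat_readsets([recruited[i] for i in pool_ids if i in recruited])
    anchor = _best_anchor(fs_sets[ref_clade], [tables[i] for i in pool_ids])
    _log(cfg, f"assembling from {len(pool)} recruited pairs of clade {ref_clade}")
    contigs = assembly.assemble_contigs(pool, anchor, cfg.min_overlap, cfg.min_identity)
    contigs = [c for c in contigs if len(c) >= cfg.min_contig or c.anchored]
    paintings = [paint.paint_haplotype(c.codes, reference) for c in contigs]
    keep = [i for i, p in enumerate(paintings) if p.painted() or contigs[i].anchored]
    scaffold = assembly.scaffold_contigs([contigs[i] for i in keep],
                                         [paintings[i] for i in keep],
                                         reads=pool)
    hap_codes = scaffold.codes
    _log(cfg, f"W haplotype: {len(contigs)} contigs, {scaffold.total_span} bp scaffold")

    painting = paint.paint_haplotype(hap_codes, reference)

    # ---- pair mapping, far pairs, seams ----------------------------------
    hap_index = paint.SeqIndex(hap_codes, 13)
    placements = {}
    for s in samples:
        placements[s.id] = hemizygosity.map_pairs_to_haplotype(
            s.reads, hap_codes, cfg.far_map_identity, index=hap_index)
    sexes = {s.id: s.sex for s in samples}
    borders = sorted({seg.start for seg in painting.painted()}
                     | {seg.end for seg in painting.painted()})
    seams = hemizygosity.detect_seams(placements, sexes, len(hap_codes),
                                      candidates=borders,
                                      min_females=cfg.min_females,
                                      far_threshold=cfg.far_threshold)

    far_records: dict[str, list] = {}
    skips: dict[str, list] = {}
    for clade in clades:
        ids = [s.id for s in samples
               if (s.clade or "all") == clade or s.sex == "male"]
        sub = {i: placements[i] for i in ids}
        recs = hemizygosity.detect_far_pairs(sub, sexes, cfg.far_threshold)
        far_records[clade] = recs
        skips[clade] = [r.skipped for r in recs]

    # ---- hemizygosity profiles -------------------------------------------
    profiles = {}
    for clade in clades:
        hits, _ = paint.align_kmers(fs_sets[clade], {"hap": hap_codes},
                                    cfg.min_match, cfg.max_gap)
        pos = hits["start"].to_numpy() if len(hits) else np.empty(0, np.int64)
        nf = sum(1 for s in females if (s.clade or "all") == clade)
        profiles[clade] = hemizygosity.female_specific_intervals(
            pos, seams, cfg.min_kmer_density, far_skips=skips[clade],
            k=cfg.k, clade=clade, n_clade_females=nf)
        _log(cfg, f"clade {clade}: hemizygous span {profiles[clade].total_span} bp")

    # ---- diagnostic deletion and stop codon ------------------------------
    deletions, stop_call = [], None
    cass_seg = None
    for seg in painting.painted():
        if seg.end - seg.start < 1000:
            continue
        w_seg = decode(hap_codes[seg.start : seg.end])
        if seg.strand == "-":
            w_seg = _codec.revcomp(w_seg)
        r0 = max(0, min(seg.ref_start, seg.ref_end) - 100)
        r1 = min(reference[seg.chrom].shape[0],
                 max(seg.ref_start, seg.ref_end) + 100)
        ref_win = decode(reference[seg.chrom][r0:r1])
        try:
            calls = hemizygosity.detect_diagnostic_deletion(
                w_seg, ref_win, sample_tables=tables, sexes=sexes,
                ref_chrom=seg.chrom)
        except ValueError:
            continue
        for d in calls:
            d.w_junction += seg.start  # haplotype coordinates
            d.ref_start += r0
            deletions.append(d)
            if cass_seg is None:
                cass_seg = seg
    if annotation and "gmew" in annotation:
        stop_call = _stop_codon_check(hap_codes, reference, annotation)

    # ---- phylogeny --------------------------------------------------------
    tree, clade_labels, monophyly = None, {}, None
    window = cfg.phylo_window or _default_window(painting, annotation, deletions,
                                                 cass_seg, len(hap_codes))
    aln = None
    if window is not None and len(recruited) >= 3:
        aln = phylo.extract_window(recruited, hap_codes, window)
        try:
            og = phylo.build_pseudo_outgroup(hap_codes, window, painting,
                                             {c: s for c, s in reference.items()})
            aln = aln.with_row("outgroup", og)
            tree = phylo.build_tree(aln, "outgroup", cfg.bootstrap_n, cfg.seed)
            clade_labels, _ = phylo.assign_clades(tree, cfg.support_min)
        except ValueError as exc:
            _log(cfg, f"phylogeny skipped: {exc}")
    if annotation and "retro_source" in annotation and len(clades) >= 2:
        monophyly = _retro_monophyly(recruited, samples, hap_codes, painting,
                                     reference, annotation)

    # ---- composition, order, borders, copy number ------------------------
    matrix = order = None
    if len(clades) >= 2:
        _classify_sections(painting, profiles, annotation)
        try:
            matrix = history.composition_matrix(profiles, painting)
            order = history.infer_order(matrix)
        except ValueError as exc:
            _log(cfg, f"souvenir ordering inapplicable: {exc}")
    ref_skips = skips.get(ref_clade, [])
    # the outermost skip is the whole hemizygous element; nested skips are
    # interior junctions (souvenir borders), used for absence checks
    outer_skip = [max(ref_skips, key=lambda s: s[1] - s[0])] if ref_skips else []
    borders_refined = [_refine_skip(hap_codes, painting, reference, sk)
                       for sk in outer_skip]
    tir_calls = history.detect_tir(hap_codes, borders_refined, cfg.min_arm,
                                   cfg.max_arm, cfg.max_mismatch, slop=3)
    inner = _inner_borders(painting, outer_skip)
    tir_absent = history.detect_tir(hap_codes, inner, cfg.min_arm,
                                    cfg.max_arm, cfg.max_mismatch, slop=3)
    single_copy = history.single_copy_check(
        placements, sexes, outer_skip, recruited_names, len(hap_codes),
        expected_copies=cfg.expected_copies)

    report = {
        "parameters": dataclasses.asdict(cfg),
        "seed": cfg.seed,
        "n_samples": len(samples),
        "clades": clades,
        "fs_set_sizes": {c: len(fs_sets[c]) for c in clades},
        "control_sizes": control_sizes,
        "haplotype_span": scaffold.total_span,
        "hemizygous_spans_bp": {c: profiles[c].total_span for c in clades},
        "deletions": [(d.length, d.diagnostic) for d in deletions],
        "tir": [(c.arm_length, c.tsd) for c in tir_calls],
        "runtime_s": round(time.time() - t0, 2),
    }
    return PipelineResult(
        cfg, samples, fs_sets, control_sizes, decode(hap_codes), scaffold,
        painting, placements, recruited_names, far_records, skips, seams,
        profiles, deletions, stop_call, tree, clade_labels, matrix, order,
        tir_calls, tir_absent, single_copy, monophyly, report, aln,
    )


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _best_anchor(fs_set: kmers.GroupSpecificKmerSet, tables) -> str:
    """The female-specific k-mer with the highest summed count: a reliable
    assembly seed analogous to anchoring at the diagnostic deletion."""
    total = np.zeros(fs_set.codes.shape[0], np.int64)
    for t in tables:
        idx = np.searchsorted(t.codes, fs_set.codes)
        ok = idx < t.codes.shape[0]
        ok[ok] &= t.codes[idx[ok]] == fs_set.codes[ok]
        total[ok] += t.counts[idx[ok]]
    best = int(np.argmax(total))
    return kmers._decode_codes(fs_set.codes[best : best + 1], fs_set.k)[0]


def _stop_codon_check(hap_codes, reference, annotation):
    g = annotation["gmew"]
    ref_cds = reference[g["chrom"]][g["start"] : g["end"]]
    index = paint.SeqIndex(hap_codes, 13)
    d = _locate_ungapped(ref_cds, index)
    if d is None:
        return None
    cds = hap_codes[d : d + ref_cds.shape[0]]
    if (cds >= 4).any():
        return None
    try:
        return hemizygosity.detect_premature_stop(decode(cds), decode(ref_cds))
    except ValueError:
        return None


def _locate_ungapped(target: np.ndarray, index: paint.SeqIndex):
    """Modal diagonal of exact 13-mer hits: position of an indel-free copy."""
    codes, starts = _codec.kmer_scan(target, 13, canonical=False)
    qi, rpos = index.lookup(codes)
    if qi.shape[0] == 0:
        return None
    diag = rpos - starts[qi]
    vals, counts = np.unique(diag, return_counts=True)
    d = int(vals[np.argmax(counts)])
    # a copy split by an assembly gap scatters hits over diagonals; frame
    # integrity needs one dominant diagonal covering the whole span
    if counts.max() < 3 or counts.max() < 0.5 * counts.sum():
        return None
    if d < 0 or d + target.shape[0] > index.concat.shape[0]:
        return None
    on_d = starts[qi][diag == d]
    if on_d.min() > 100 or on_d.max() < target.shape[0] - 100 - 13:
        return None
    return d


def _default_window(painting, annotation, deletions, cass_seg, hap_len):
    """Cassette analysis window: from the retrogene segment through the
    diagnostic deletion (plus margin)."""
    retro_chrom = annotation["retro_source"]["chrom"] if annotation else None
    retro_segs = [s for s in painting.painted()
                  if retro_chrom and s.chrom == retro_chrom]
    if not retro_segs:
        return None
    w0 = min(s.start for s in retro_segs)
    w1 = max(s.end for s in retro_segs) + 100
    if deletions:
        j = deletions[0].w_junction
        if j > w1:
            w1 = min(j + 100, hap_len)
    return (w0, min(w1, hap_len))


def _retro_monophyly(recruited, samples, hap_codes, painting, reference, annotation):
    retro_chrom = annotation["retro_source"]["chrom"]
    segs = [s for s in painting.painted() if s.chrom == retro_chrom]
    if not segs:
        return None
    r0 = min(s.start for s in segs)
    r1 = max(s.end for s in segs)
    by_clade: dict[str, dict] = {}
    for s in samples:
        if s.sex == "female" and s.id in recruited:
            by_clade.setdefault(s.clade or "all", {})[s.id] = recruited[s.id]
    retro_seqs = {}
    for clade, fem in by_clade.items():
        try:
            aln = phylo.extract_window(fem, hap_codes, (r0, r1)) if len(fem) >= 3 else None
        except ValueError:
            aln = None
        if aln is None:
            pooled = _concat_readsets(list(fem.values()))
            aln = phylo.extract_window({"a": pooled, "b": pooled, "c": pooled},
                                       hap_codes, (r0, r1))
        cons = _column_majority(aln.matrix)
        retro_seqs[f"retro_{clade}"] = decode(np.where(cons < 4, cons, 0).astype(np.uint8))
    paralogs = {}
    for gene in ("retro_source", "retro_paralog"):
        if gene not in annotation:
            continue
        g = annotation[gene]
        pieces = [reference[g["chrom"]][s:e] for s, e in g["exons"]]
        paralogs[gene] = decode(np.concatenate(pieces))
    if len(retro_seqs) < 2 or len(paralogs) < 2:
        return None
    return phylo.retrogene_monophyly(retro_seqs, paralogs)


def _column_majority(mat: np.ndarray) -> np.ndarray:
    out = np.full(mat.shape[1], 4, np.uint8)
    for j in range(mat.shape[1]):
        col = mat[:, j]
        col = col[col < 4]
        if col.shape[0] == 0:
            continue
        vals, counts = np.unique(col, return_counts=True)
        out[j] = vals[np.argmax(counts)]
    return out


def _classify_sections(painting, profiles, annotation) -> None:
    """Assign section classes by how many clades share each segment:
    shared by all -> cassette (or retro_insert by source), by a proper
    subset -> flanking, by exactly one -> outer."""
    retro_chrom = annotation["retro_source"]["chrom"] if annotation else None
    nclades = len(profiles)
    for seg in painting.painted():
        length = seg.end - seg.start
        if length == 0:
            continue
        present = 0
        for prof in profiles.values():
            cov = sum(max(0, min(e, seg.end) - max(s, seg.start))
                      for s, e in prof.intervals)
            if cov / length >= 0.5:
                present += 1
        if retro_chrom and seg.chrom == retro_chrom:
            seg.section_class = "retro_insert"
        elif present == nclades and present > 0:
            seg.section_class = "cassette"
        elif present > 1:
            seg.section_class = "flanking"
        elif present == 1:
            seg.section_class = "outer"
        else:
            seg.section_class = "unclassified"


def _refine_skip(hap_codes, painting, reference, skip, halfwin: int = 60):
    """Sharpen far-pair junction estimates to base precision.

    Outside the insertion the haplotype tracks its painted source locus
    (a few percent divergence); inside, the element is unrelated to the
    source context.  The mismatch changepoint against the source locus
    therefore marks the exact element boundary — which also resolves the
    arm/TSD ambiguity a palindromic target duplication creates.
    """
    s_est, e_est = int(skip[0]), int(skip[1])
    s = _refine_edge(hap_codes, painting, reference, s_est, left=True,
                     halfwin=halfwin)
    e = _refine_edge(hap_codes, painting, reference, e_est, left=False,
                     halfwin=halfwin)
    return (s if s is not None else s_est, e if e is not None else e_est)


def _refine_edge(hap, painting, reference, est, left, halfwin):
    probe = est - (halfwin + 40) if left else est + (halfwin + 40)
    seg = next((g for g in painting.painted()
                if g.start <= probe < g.end and g.strand == "+"), None)
    if seg is None:
        return None
    o = seg.ref_start - seg.start
    ref = reference[seg.chrom]
    w0, w1 = est - halfwin, est + halfwin
    if w0 < 0 or w1 > hap.shape[0] or w0 + o < 0 or w1 + o > ref.shape[0]:
        return None
    mis = (hap[w0:w1] != ref[w0 + o : w1 + o]).astype(np.float64)
    pre = np.concatenate(([0.0], np.cumsum(mis)))
    i = np.arange(pre.shape[0])
    # CUSUM against rate 0.5: outside the element mismatches are rare
    # (divergence), inside they approach 3/4 (unrelated sequence)
    if left:  # matches then mismatches: boundary starts the high-rate run
        score = 0.5 * i - pre
    else:  # mismatches then matches: boundary ends the high-rate run
        score = pre - 0.5 * i
    return w0 + int(np.argmax(score))


def _inner_borders(painting, skips):
    """Candidate borders inside the hemizygous element (e.g. the
    cassette/flanking junction): used to document TIR absence."""
    if not skips:
        return []
    out = []
    for s, e in skips:
        inner = sorted({seg.start for seg in painting.painted()
                        if s + 50 < seg.start < e - 50})
        for b in inner[:2]:
            out.append((b, e - (b - s)))
    return out


# ---------------------------------------------------------------------------
# [OP] run_pipeline (file-based)
# ---------------------------------------------------------------------------

def load_manifest(path) -> list[SexedSample]:
    df = pd.read_csv(path, sep="\t")
    samples = []
    for _, r in df.iterrows():
        samples.append(SexedSample(str(r["id"]), str(r["sex"]), str(r.get("taxon", "")),
                                   (str(r["clade"]) or None) if "clade" in df.columns else None,
                                   str(r["fastq1"]), str(r["fastq2"])))
    return samples


def _load_reads(sample: SexedSample) -> None:
    names, m1, m2 = [], [], []
    for name, seq in _codec.read_fastq(sample.fastq1):
        names.append(name)
        m1.append(encode(seq))
    for _, seq in _codec.read_fastq(sample.fastq2):
        m2.append(encode(seq))
    if len(m1) != len(m2):
        raise ValueError(f"{sample.id}: mate files have different record counts")
    rl = max((a.shape[0] for a in m1 + m2), default=0)
    mat1 = np.full((len(m1), rl), 4, np.uint8)
    mat2 = np.full((len(m2), rl), 4, np.uint8)
    for i, a in enumerate(m1):
        mat1[i, : a.shape[0]] = a
    for i, a in enumerate(m2):
        mat2[i, : a.shape[0]] = a
    sample.reads = ReadSet(names, mat1, mat2, None)


def load_annotation_bed(path) -> dict:
    ann: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            chrom, s, e, name = line.split()[:4]
            s, e = int(s), int(e)
            if name.endswith("_exon"):
                gene = name[: -len("_exon")]
                g = ann.setdefault(gene, {"chrom": chrom, "exons": []})
                g["exons"].append((s, e))
            elif name == "gmew_orf":
                ann["gmew"] = {"chrom": chrom, "start": s, "end": e}
    for g in ann.values():
        if "exons" in g:
            g["exons"].sort()
            g["span"] = (g["exons"][0][0], g["exons"][-1][1])
    return ann


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Execute every stage from a manifest and write a results directory."""
    if not cfg.reference or not cfg.manifest:
        raise ValueError("config must set reference and manifest paths")
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    reference = {c: encode(s) for c, s in _codec.read_fasta(cfg.reference).items()}
    annotation = load_annotation_bed(cfg.annotation) if cfg.annotation else None
    samples = load_manifest(cfg.manifest)
    if not any(s.sex == "female" for s in samples) or not any(s.sex == "male" for s in samples):
        raise ValueError("manifest must list at least one female and one male")
    for s in samples:
        _load_reads(s)
    result = analyze_cohort(samples, reference, annotation, cfg)
    write_results(result, outdir)
    return outdir


def write_results(result: PipelineResult, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}

    def reg(name, path):
        files[name] = str(path)
        return path

    _codec.write_fasta(reg("haplotype", outdir / "w_haplotype.fa"),
                       [("w_haplotype", result.haplotype)])
    result.painting.to_bed(reg("painting", outdir / "painting.bed"), "w_haplotype")
    with open(reg("profiles", outdir / "profiles.tsv"), "w") as fh:
        fh.write("clade\tkind\tstart\tend\n")
        for clade, prof in result.profiles.items():
            for s, e in prof.intervals:
                fh.write(f"{clade}\tfemale_specific\t{s}\t{e}\n")
            for s, e in prof.hemizygous_intervals:
                fh.write(f"{clade}\themizygous\t{s}\t{e}\n")
    with open(reg("seams", outdir / "seams.tsv"), "w") as fh:
        fh.write("position\tstatus\tn_females\tn_males\n")
        for rec in result.seams:
            fh.write(f"{rec.position}\t{rec.status}\t{rec.n_females_with_support}"
                     f"\t{rec.n_males_with_support}\n")
    with open(reg("deletions", outdir / "deletions.tsv"), "w") as fh:
        fh.write("ref_chrom\tref_start\tlength\tw_junction\tdiagnostic\n")
        for d in result.deletions:
            fh.write(f"{d.ref_chrom}\t{d.ref_start}\t{d.length}\t{d.w_junction}"
                     f"\t{d.diagnostic}\n")
    with open(reg("tir", outdir / "tir_calls.tsv"), "w") as fh:
        fh.write("start\tend\tarm\tmismatches\ttsd\n")
        for c in result.tir_calls:
            fh.write(f"{c.boundary[0]}\t{c.boundary[1]}\t{c.arm_length}"
                     f"\t{c.mismatches}\t{c.tsd}\n")
    if result.tree is not None:
        with open(reg("tree", outdir / "cassette_window.nwk"), "w") as fh:
            fh.write(result.tree.newick + "\n")
    if result.matrix is not None:
        result.matrix.to_frame().to_csv(reg("matrix", outdir / "composition.tsv"), sep="\t")
    if result.order is not None:
        with open(reg("order", outdir / "translocation_order.txt"), "w") as fh:
            fh.write(result.order.render() + "\n")
    result.report["outputs"] = files
    with open(outdir / "run_report.json", "w") as fh:
        json.dump(result.report, fh, indent=2, default=str)
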