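"""Synthetic octoploid ZW cohorts with a planted, nested SDR insertion.

The generator emulates the study system the pipeline is built for: an
octoploid with four diverged subgenomes (disomic inheritance), a
seven-chromosome diploid-like reference, and a single W haplotype per
female carrying a female-determining "SDR cassette" whose composition
depends on the female's clade:

* ``alpha``   -- the cassette sits at its ancestral location (the
  "location-1" analog on the chr6 analog).  Only the retro-inserted,
  intron-less gene copy inside it is hemizygous (~1.2 kb).
* ``beta``    -- the whole cassette (~13 kb) has translocated to the
  "location-13" analog and is hemizygous there; the W's native flanking
  sequence around the insertion carries clade variants in linkage
  disequilibrium with sex but has a Z counterpart.
* ``gamma``   -- cassette plus captured ("souvenir") flanking sequence
  (~23 kb) have moved again, to the "location-37" analog, bordered by
  25 bp terminal inverted repeats and TA target-site duplications; the
  native "outer" sequence around the new site carries LD variants.

The cassette itself contains a 23 bp diagnostic deletion relative to the
reference, a 376-codon ORF with an optional premature stop at codon 223,
and the retrogene (the chr7-analog gene's exons, introns removed).

Every planted feature is recorded in a :class:`SimTruth` so downstream
stages can be tested by parameter recovery.  All randomness flows from
``SimConfig.seed``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._codec import SEP, decode, encode, revcomp_codes, write_fasta, write_fastq

CLADES = ("alpha", "beta", "gamma")

#: subgenome carrying the W chromosome in each clade
W_SUBGENOME = {"alpha": "B2", "beta": "B1", "gamma": "Av"}
SUBGENOMES = ("Av", "B1", "B2", "Bi")

def resolve_w_subgenome(clade: str, subgenomes) -> str:
    """The subgenome carrying the W in this clade; reduced-ploidy runs
    fall back to the last subgenome built."""
    name = W_SUBGENOME[clade]
    return name if name in subgenomes else list(subgenomes)[-1]


_STOP_CODONS = {"TAA", "TAG", "TGA"}
_STOP_CODES = {tuple(encode(c)) for c in _STOP_CODONS}


def _default_sections() -> dict[str, int]:
    return {
        "retro_insert": 1_200,
        "cassette_total": 13_000,
        "flanking_total": 10_000,
        "outer_total": 5_000,
    }


@dataclass
class SimConfig:
    """All tunables of the cohort generator.

    Sizes are absolute base pairs; chromosomes default to 50 kb scaled
    stand-ins for Mb-scale chromosomes, while the planted section sizes
    keep their real-world values so printed quantities (13 kb, 23 kb,
    1.2 kb, 23 bp, 25 bp) are recoverable verbatim.
    """

    n_chromosomes: int = 7
    chrom_length: int = 50_000
    n_subgenomes: int = 4
    subgenome_divergence: float = 0.02
    within_subgenome_het: float = 0.0
    n_females: int = 9
    n_males: int = 9
    clade_of_female: tuple[str, ...] | None = None  # None -> all gamma
    section_sizes: dict[str, int] = field(default_factory=_default_sections)
    deletion_length: int = 23
    tir_arm: int = 25
    tsd: str = "TA"
    coverage_per_chromosome_copy: float = 4.0
    read_length: int = 150
    insert_mean: float = 400.0
    insert_sd: float = 40.0
    error_rate: float = 0.002
    seed: int = 0
    # divergence model (per-site substitution probabilities)
    divergence_cassette: float = 0.05
    divergence_retro: float = 0.01
    ld_variant_rate: float = 0.01
    clade_divergence: float = 0.01
    female_divergence: float = 0.001
    # cassette gene model
    gmew_codons: int = 376
    stop_codon_at: int | None = 223  # 1-based codon replaced by TAA
    # robustness/off-label options
    extra_cassette_copy: bool = False
    n_lowcomplexity_gaps: int = 0

    def __post_init__(self) -> None:
        if self.n_chromosomes < 7:
            raise ValueError("need >=7 chromosomes for the chr5/chr6/chr7 analogs")
        if not (0 <= self.subgenome_divergence < 1):
            raise ValueError("subgenome_divergence must be in [0, 1)")
        if self.n_subgenomes < 1 or self.n_subgenomes > len(SUBGENOMES):
            raise ValueError("n_subgenomes must be in 1..4")
        for name, size in self.section_sizes.items():
            if size <= 0:
                raise ValueError(f"section size {name} must be positive")
        if self.deletion_length <= 0 or self.tir_arm <= 0:
            raise ValueError("deletion_length and tir_arm must be positive")
        if self.read_length >= self.insert_mean:
            raise ValueError("insert_mean must exceed read_length")
        lay = self.layout()  # validates geometry
        if lay.src_len < 3 * (self.gmew_codons + 1):
            raise ValueError("cassette too small for the ORF")
        if self.clade_of_female is not None:
            if len(self.clade_of_female) != self.n_females:
                raise ValueError("clade_of_female length != n_females")
            for c in self.clade_of_female:
                if c not in CLADES:
                    raise ValueError(f"unknown clade {c!r}")

    # ---- derived geometry -------------------------------------------------

    def layout(self) -> "Layout":
        L = self.chrom_length
        s = self.section_sizes
        retro = s["retro_insert"]
        src_len = s["cassette_total"] - retro + self.deletion_length
        lay = Layout(
            loc1=round(0.04 * L),
            loc13=round(0.48 * L),
            loc37=round(0.80 * L),
            retro_gene_start=round(0.36 * L),
            src_len=src_len,
            retro_src_off=round(0.3383 * src_len),
            del_src_off=round(0.4567 * src_len),
            gmew_src_off=round(0.7612 * src_len),
            flank_each=s["flanking_total"] // 2,
            outer_each=s["outer_total"] // 2,
            n_exons=5,
            intron_len=max(40, round(0.125 * retro)),
        )
        orf_len = 3 * (self.gmew_codons + 1)
        if not (lay.retro_src_off < lay.del_src_off < lay.gmew_src_off):
            raise ValueError("cassette internal layout does not fit")
        if lay.gmew_src_off + orf_len > src_len:
            raise ValueError("ORF does not fit inside the cassette")
        if lay.loc1 + src_len > lay.loc13 - lay.flank_each:
            raise ValueError("cassette source overlaps the location-13 analog")
        if lay.loc13 + lay.flank_each > lay.loc37 - lay.outer_each:
            raise ValueError("flanking source overlaps the location-37 analog")
        if lay.loc37 + lay.outer_each + 100 > L:
            raise ValueError("outer section does not fit on the chromosome")
        if lay.retro_gene_start + retro + (lay.n_exons - 1) * lay.intron_len > L:
            raise ValueError("retrogene source does not fit on the chr7 analog")
        return lay

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]


@dataclass(frozen=True)
class Layout:
    """Reference coordinates of every planted locus (0-based)."""

    loc1: int
    loc13: int
    loc37: int
    retro_gene_start: int
    src_len: int
    retro_src_off: int
    del_src_off: int
    gmew_src_off: int
    flank_each: int
    outer_each: int
    n_exons: int
    intron_len: int

    @property
    def locations(self) -> dict[str, int]:
        return {"location-1": self.loc1, "location-13": self.loc13, "location-37": self.loc37}


@dataclass
class TruthSection:
    """One planted section on a female's W chromosome."""

    section: str  # retro_insert | cassette | flanking | outer
    start: int  # on the W chr6-analog haplotype, 0-based half-open
    end: int
    source_chrom: str
    source_start: int
    source_end: int


@dataclass
class FemaleTruth:
    clade: str
    w_subgenome: str
    sections: list[TruthSection]
    hemizygous: tuple[int, int]  # insertion interval on the W haplotype
    modified_span: tuple[int, int]  # everything touched incl. LD zones
    cassette_start: int  # W coordinate of cassette position 0
    deletion_junction: int  # W coordinate
    stop_variant: int | None  # W coordinate of the planted stop codon
    tir_arms: list[tuple[int, int]]
    tsd_sites: list[tuple[int, int]]
    phylo_window: tuple[int, int]  # W coords of the cassette analysis window


@dataclass
class SimTruth:
    layout: Layout
    reference_paths: dict[str, str] = field(default_factory=dict)
    genome_paths: dict[str, str] = field(default_factory=dict)
    females: dict[str, FemaleTruth] = field(default_factory=dict)
    annotation: dict[str, dict] = field(default_factory=dict)
    deletion_length: int = 0
    cassette_sequences: dict[str, str] = field(default_factory=dict)


@dataclass
class SexedSample:
    """A cohort member; reads may live in memory, on disk, or both."""

    id: str
    sex: str  # "female" | "male"
    taxon: str
    clade: str | None
    fastq1: str | None = None
    fastq2: str | None = None
    reads: "ReadSet | None" = None

    def __post_init__(self) -> None:
        if self.sex not in ("female", "male"):
            raise ValueError(f"sex must be female or male, got {self.sex!r}")


class ReadSet:
    """Paired reads as code matrices, with a truth channel in the names."""

    def __init__(self, names, mate1, mate2, origin=None):
        self.names = names
        self.mate1 = mate1  # (n, read_length) uint8
        self.mate2 = mate2
        self.origin = origin  # (hap_label, frag_start, insert) per pair

    def __len__(self) -> int:
        return self.mate1.shape[0]

    def to_fastq(self, path1, path2) -> None:
        write_fastq(path1, ((n, decode(r)) for n, r in zip(self.names, self.mate1)))
        write_fastq(path2, ((n, decode(r)) for n, r in zip(self.names, self.mate2)))

    def concat_codes(self) -> np.ndarray:
        """All reads joined with separator bytes, for k-mer scanning."""
        n, rl = self.mate1.shape
        out = np.full((2 * n, rl + 1), SEP, dtype=np.uint8)
        out[:n, :rl] = self.mate1
        out[n:, :rl] = self.mate2
        return out.ravel()


# ---------------------------------------------------------------------------
# mutation helpers
# ---------------------------------------------------------------------------

def _mutate(codes: np.ndarray, rate: float, rng, protect=()) -> np.ndarray:
    """Random substitutions at ``rate`` per site, sparing ``protect`` intervals."""
    out = codes.copy()
    if rate <= 0:
        return out
    hit = rng.random(out.shape[0]) < rate
    for s, e in protect:
        hit[max(0, s) : max(0, e)] = False
    idx = np.nonzero(hit & (out < 4))[0]
    out[idx] = (out[idx] + rng.integers(1, 4, idx.shape[0])) % 4
    return out


def _mutate_orf_stopsafe(codes: np.ndarray, orf_start: int, n_codons: int,
                         rate: float, rng, frozen_codons=()) -> None:
    """In-place third-position substitutions that never create a stop codon.

    ``rate`` is the per-site rate over the whole ORF; third positions are
    hit at 3x that rate so the overall density matches flanking sequence.
    """
    if rate <= 0:
        return
    frozen = set(frozen_codons) | {0, n_codons}
    for ci in range(n_codons + 1):  # includes the terminal stop (frozen)
        if ci in frozen or rng.random() >= 3 * rate:
            continue
        pos = orf_start + 3 * ci
        codon = codes[pos : pos + 3]
        for nb in rng.permutation(4):
            if nb == codon[2]:
                continue
            trial = (int(codon[0]), int(codon[1]), int(nb))
            if trial not in _STOP_CODES:
                codes[pos + 2] = nb
                break


def _random_orf(n_codons: int, rng) -> np.ndarray:
    """ATG + ``n_codons - 1`` random non-stop codons + TAA."""
    codons = [encode("ATG")]
    while len(codons) < n_codons:
        c = rng.integers(0, 4, 3).astype(np.uint8)
        if tuple(int(x) for x in c) not in _STOP_CODES:
            codons.append(c)
    codons.append(encode("TAA"))
    return np.concatenate(codons)


# ---------------------------------------------------------------------------
# [OP] build_reference
# ---------------------------------------------------------------------------

def build_reference(config: SimConfig, rng=None):
    """Random uniform-composition reference with the planted gene models.

    Returns ``(chromosomes, annotation)``: chromosomes as a name->codes
    mapping; the annotation records the chr7-analog retrogene source (a
    4-intron gene), its chr5-analog paralog, and the ORF at the
    location-1 analog, the way a curated reference annotation would.
    """
    lay = config.layout()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    chroms: dict[str, np.ndarray] = {}
    for name in config.chrom_names():
        chroms[name] = rng.integers(0, 4, config.chrom_length).astype(np.uint8)

    retro_total = config.section_sizes["retro_insert"]
    exon_len = retro_total // lay.n_exons
    exon_lens = [exon_len] * (lay.n_exons - 1) + [retro_total - exon_len * (lay.n_exons - 1)]
    exons = []
    pos = lay.retro_gene_start
    for el in exon_lens:
        exons.append((pos, pos + el))
        pos += el + lay.intron_len
    gene_end = exons[-1][1]

    # paralog: same gene structure, diverged, on the chr5 analog
    g7 = chroms["chr7"][lay.retro_gene_start : gene_end].copy()
    paralog = _mutate(g7, 0.08, rng)
    chroms["chr5"][lay.retro_gene_start : gene_end] = paralog
    shift = lay.retro_gene_start
    par_exons = [(s, e) for s, e in exons]

    # ORF at the location-1 analog (the cassette's source window)
    orf = _random_orf(config.gmew_codons, rng)
    orf_start = lay.loc1 + lay.gmew_src_off
    chroms["chr6"][orf_start : orf_start + orf.shape[0]] = orf

    annotation = {
        "retro_source": {"chrom": "chr7", "exons": exons, "span": (lay.retro_gene_start, gene_end)},
        "retro_paralog": {"chrom": "chr5", "exons": par_exons, "span": (shift, gene_end)},
        "gmew": {"chrom": "chr6", "start": orf_start, "end": orf_start + orf.shape[0],
                 "codons": config.gmew_codons},
    }
    return chroms, annotation


# ---------------------------------------------------------------------------
# [OP] make_octoploid
# ---------------------------------------------------------------------------

def make_octoploid(reference: dict[str, np.ndarray], config: SimConfig, rng=None):
    """Four subgenomes derived from the reference by independent substitution.

    Each individual carries two identical copies of every subgenome
    haplotype (disomic inheritance; within-subgenome heterozygosity is
    added per individual at read-simulation time if configured).
    """
    if not (0 <= config.subgenome_divergence < 1):
        raise ValueError("divergence must be in [0, 1)")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    subgenomes: dict[str, dict[str, np.ndarray]] = {}
    for sg in SUBGENOMES[: config.n_subgenomes]:
        subgenomes[sg] = {
            chrom: _mutate(seq, config.subgenome_divergence, rng)
            for chrom, seq in reference.items()
        }
    return subgenomes


# ---------------------------------------------------------------------------
# [OP] plant_sdr
# ---------------------------------------------------------------------------

def _build_ancestral_cassette(reference, subgenomes, config: SimConfig, rng):
    """The shared W-allele cassette: source window + divergence + deletion +
    premature stop + retro insertion.  Returns (codes, feature offsets)."""
    lay = config.layout()
    src_sg = W_SUBGENOME["alpha"]
    if src_sg not in subgenomes:  # reduced-ploidy runs: use the last one
        src_sg = list(subgenomes)[-1]
    src = subgenomes[src_sg]["chr6"][lay.loc1 : lay.loc1 + lay.src_len]

    orf_off = lay.gmew_src_off
    orf_len = 3 * (config.gmew_codons + 1)
    protect = [
        (lay.del_src_off - 31, lay.del_src_off + config.deletion_length + 31),
        (orf_off, orf_off + orf_len),
    ]
    mut = _mutate(src, config.divergence_cassette, rng, protect=protect)
    _mutate_orf_stopsafe(mut, orf_off, config.gmew_codons, config.divergence_cassette, rng)

    if config.stop_codon_at is not None:
        stop_pos = orf_off + 3 * (config.stop_codon_at - 1)
        mut[stop_pos : stop_pos + 3] = encode("TAA")

    retro = _build_retro_copy(reference, config, rng)

    d0 = lay.del_src_off
    dl = config.deletion_length
    r0 = lay.retro_src_off
    cassette = np.concatenate([mut[:r0], retro, mut[r0:d0], mut[d0 + dl :]])

    feats = {
        "retro": (r0, r0 + retro.shape[0]),
        "junction": r0 + retro.shape[0] + (d0 - r0),
        "orf": orf_off + retro.shape[0] - dl,
        "stop": (orf_off + retro.shape[0] - dl + 3 * (config.stop_codon_at - 1))
        if config.stop_codon_at is not None
        else None,
    }

    if config.n_lowcomplexity_gaps:
        cassette, feats = _insert_lowcomplexity(cassette, feats, config, rng)
    return cassette, feats


def _build_retro_copy(reference, config: SimConfig, rng):
    """Intron-less copy of the chr7-analog gene, lightly diverged."""
    lay = config.layout()
    retro_total = config.section_sizes["retro_insert"]
    exon_len = retro_total // lay.n_exons
    exon_lens = [exon_len] * (lay.n_exons - 1) + [retro_total - exon_len * (lay.n_exons - 1)]
    pieces, pos = [], lay.retro_gene_start
    for el in exon_lens:
        pieces.append(reference["chr7"][pos : pos + el])
        pos += el + lay.intron_len
    cdna = np.concatenate(pieces)
    return _mutate(cdna, config.divergence_retro, rng)


def _insert_lowcomplexity(cassette, feats, config: SimConfig, rng):
    """Optional AT-repeat stretches to exercise assembly-gap handling."""
    piece = encode("AT" * 150)
    for _ in range(config.n_lowcomplexity_gaps):
        at = int(rng.integers(feats["retro"][1] + 50, feats["junction"] - 50))
        cassette = np.concatenate([cassette[:at], piece, cassette[at:]])
        shift = piece.shape[0]
        feats = {
            "retro": tuple(v + shift if v > at else v for v in feats["retro"]),
            "junction": feats["junction"] + (shift if feats["junction"] > at else 0),
            "orf": feats["orf"] + (shift if feats["orf"] > at else 0),
            "stop": (feats["stop"] + shift if feats["stop"] and feats["stop"] > at else feats["stop"]),
        }
    return cassette, feats


def _protected_zones(feats, config: SimConfig, cassette_off: int = 0):
    """Mutation-free zones inside a cassette (junction, ORF) in cassette coords."""
    orf_len = 3 * (config.gmew_codons + 1)
    zones = [
        (feats["junction"] - 31, feats["junction"] + 31),
        (feats["orf"], feats["orf"] + orf_len),
    ]
    return [(s + cassette_off, e + cassette_off) for s, e in zones]


def _clade_cassette(cassette, feats, config: SimConfig, rng):
    out = _mutate(cassette, config.clade_divergence, rng, protect=_protected_zones(feats, config))
    _mutate_orf_stopsafe(out, feats["orf"], config.gmew_codons, config.clade_divergence, rng,
                         frozen_codons=() if config.stop_codon_at is None
                         else (config.stop_codon_at - 1,))
    return out


def _find_tsd_site(chrom: np.ndarray, near: int, tsd: np.ndarray) -> int:
    """Nearest occurrence of the target motif at/after ``near``."""
    t = tsd.shape[0]
    for q in range(near, chrom.shape[0] - t):
        if (chrom[q : q + t] == tsd).all():
            return q
    raise ValueError("no target-site motif found near the insertion point")


def plant_sdr(reference, subgenomes, config: SimConfig, rng=None):
    """Plant the clade-specific W haplotype for every female.

    Returns ``(w_haplotypes, truth)`` where ``w_haplotypes`` maps female id
    to her W chr6-analog code array.  Males receive no modification.
    """
    lay = config.layout()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    clades = config.clade_of_female or tuple(["gamma"] * config.n_females)
    for c in clades:
        if c not in CLADES:
            raise ValueError(f"unknown clade label {c!r}")

    cassette0, feats = _build_ancestral_cassette(reference, subgenomes, config, rng)
    truth = SimTruth(layout=lay, deletion_length=config.deletion_length)
    truth.cassette_sequences["ancestral"] = decode(cassette0)

    # shared flanking variants: the location-13 neighbourhood as it was on
    # the W when the cassette lived there (beta's flanks, gamma's souvenir)
    flank_src = subgenomes[resolve_w_subgenome("beta", subgenomes)]["chr6"]
    fL0 = _mutate(flank_src[lay.loc13 - lay.flank_each : lay.loc13], config.ld_variant_rate, rng)
    fR0 = _mutate(flank_src[lay.loc13 : lay.loc13 + lay.flank_each], config.ld_variant_rate, rng)

    clade_state: dict[str, dict] = {}
    for clade in CLADES:
        if clade not in clades:
            continue
        crng = np.random.default_rng(np.random.SeedSequence([config.seed, 4, CLADES.index(clade)]))
        clade_state[clade] = _build_clade_w(
            clade, reference, subgenomes, cassette0, feats, fL0, fR0, config, crng
        )
        truth.cassette_sequences[clade] = decode(clade_state[clade]["cassette"])

    w_haps: dict[str, np.ndarray] = {}
    for fi, clade in enumerate(clades):
        fid = f"F{fi + 1:02d}"
        frng = np.random.default_rng(np.random.SeedSequence([config.seed, 5, fi]))
        st = clade_state[clade]
        w = st["w"].copy()
        h0, h1 = st["hemizygous"]
        protect = _protected_zones(feats, config, st["cassette_start"])
        protect += [(s, e) for s, e in st["tir_arms"]]
        protect += [(s, e) for s, e in st["tsd_sites"]]
        sub = _mutate(w[h0:h1], config.female_divergence, frng,
                      protect=[(s - h0, e - h0) for s, e in protect])
        w[h0:h1] = sub
        w_haps[fid] = w
        truth.females[fid] = FemaleTruth(
            clade=clade,
            w_subgenome=resolve_w_subgenome(clade, subgenomes),
            sections=st["sections"],
            hemizygous=st["hemizygous"],
            modified_span=st["modified_span"],
            cassette_start=st["cassette_start"],
            deletion_junction=st["cassette_start"] + feats["junction"],
            stop_variant=(st["cassette_start"] + feats["stop"]) if feats["stop"] else None,
            tir_arms=st["tir_arms"],
            tsd_sites=st["tsd_sites"],
            phylo_window=(
                st["cassette_start"] + feats["retro"][0],
                min(st["cassette_start"] + feats["junction"] + 100,
                    st["cassette_start"] + cassette0.shape[0]),
            ),
        )

    if config.extra_cassette_copy:
        degraded = _mutate(cassette0, 0.05, rng)
        at = config.chrom_length // 2
        sg = subgenomes[SUBGENOMES[config.n_subgenomes - 1]]
        sg["chr2"] = np.concatenate([sg["chr2"][:at], degraded, sg["chr2"][at:]])
        truth.annotation["extra_cassette_copy"] = {
            "subgenome": SUBGENOMES[config.n_subgenomes - 1],
            "chrom": "chr2", "start": at, "end": at + degraded.shape[0],
        }

    return w_haps, truth


def _build_clade_w(clade, reference, subgenomes, cassette0, feats, fL0, fR0, config, rng):
    """Assemble one clade's W chr6-analog haplotype and its truth record."""
    lay = config.layout()
    native = subgenomes[resolve_w_subgenome(clade, subgenomes)]["chr6"]
    cassette = _clade_cassette(cassette0, feats, config, rng)
    clen = cassette.shape[0]
    src_chrom = "chr6"

    def cassette_sections(c0):
        r0, r1 = feats["retro"]
        return [
            TruthSection("cassette", c0, c0 + clen, src_chrom, lay.loc1, lay.loc1 + lay.src_len),
            TruthSection("retro_insert", c0 + r0, c0 + r1, "chr7",
                         lay.retro_gene_start, lay.retro_gene_start
                         + config.section_sizes["retro_insert"] + (lay.n_exons - 1) * lay.intron_len),
        ]

    if clade == "alpha":
        w = native.copy()
        w = np.concatenate([w[: lay.loc1], cassette, w[lay.loc1 + lay.src_len :]])
        c0 = lay.loc1
        r0, r1 = feats["retro"]
        return {
            "w": w,
            "cassette": cassette,
            "cassette_start": c0,
            "sections": cassette_sections(c0),
            "hemizygous": (c0 + r0, c0 + r1),
            "modified_span": (c0, c0 + clen),
            "tir_arms": [],
            "tsd_sites": [],
        }

    if clade == "beta":
        w = native.copy()
        w[lay.loc13 - lay.flank_each : lay.loc13] = fL0
        w[lay.loc13 : lay.loc13 + lay.flank_each] = fR0
        w = np.concatenate([w[: lay.loc13], cassette, w[lay.loc13 :]])
        c0 = lay.loc13
        secs = cassette_sections(c0)
        secs.append(TruthSection("flanking", c0 - lay.flank_each, c0, src_chrom,
                                 lay.loc13 - lay.flank_each, lay.loc13))
        secs.append(TruthSection("flanking", c0 + clen, c0 + clen + lay.flank_each, src_chrom,
                                 lay.loc13, lay.loc13 + lay.flank_each))
        return {
            "w": w,
            "cassette": cassette,
            "cassette_start": c0,
            "sections": secs,
            "hemizygous": (c0, c0 + clen),
            "modified_span": (c0 - lay.flank_each, c0 + clen + lay.flank_each),
            "tir_arms": [],
            "tsd_sites": [],
        }

    # gamma: mobile element = flankL + cassette + flankR with TIR arms,
    # inserted at a TA site near the location-37 analog, TSD duplicated
    fL = _mutate(fL0, config.clade_divergence, rng)
    fR = _mutate(fR0, config.clade_divergence, rng)
    arm = config.tir_arm
    # keep the planted border signature unambiguous: the arm must not
    # begin with the last target base (A) or with a self-complementary
    # dinucleotide, otherwise the palindromic TA duplication telescopes
    # into the arm and its true length becomes ill-defined
    if fR[-1] == 0:  # arm[0] = comp(fR[-1]) must not be T
        fR[-1] = 1 + rng.integers(0, 3)
    if fR[-2] == 3 - fR[-1]:  # arm[1] must not complement arm[0]
        fR[-2] = (fR[-2] + 1 + rng.integers(0, 2)) % 4
        if fR[-2] == 3 - fR[-1]:
            fR[-2] = (fR[-2] + 1) % 4
    fL[:arm] = revcomp_codes(fR[-arm:])
    # stop the arm at exactly `arm` bases: break the next complementary pair
    if fL[arm] == 3 - fR[-arm - 1]:
        fR[-arm - 1] = (fR[-arm - 1] + 1 + rng.integers(0, 3)) % 4
        if fL[arm] == 3 - fR[-arm - 1]:
            fR[-arm - 1] = (fR[-arm - 1] + 1) % 4
        fL[:arm] = revcomp_codes(fR[-arm:])
    element = np.concatenate([fL, cassette, fR])
    tsd = encode(config.tsd)
    t = tsd.shape[0]
    q = _find_tsd_site(native, lay.loc37, tsd)
    w = np.concatenate([native[: q + t], element, tsd, native[q + t :]])
    ins0 = q + t  # element start on W
    elen = element.shape[0]
    c0 = ins0 + lay.flank_each
    secs = cassette_sections(c0)
    secs.append(TruthSection("flanking", ins0, c0, src_chrom,
                             lay.loc13 - lay.flank_each, lay.loc13))
    secs.append(TruthSection("flanking", c0 + clen, ins0 + elen, src_chrom,
                             lay.loc13, lay.loc13 + lay.flank_each))
    secs.append(TruthSection("outer", ins0 - lay.outer_each, ins0, src_chrom,
                             q - lay.outer_each, q))
    secs.append(TruthSection("outer", ins0 + elen + t, ins0 + elen + t + lay.outer_each,
                             src_chrom, q + t, q + t + lay.outer_each))
    # LD variants on the native outer neighbourhood (W copy only)
    out_l = _mutate(w[ins0 - lay.outer_each : q], config.ld_variant_rate, rng)
    w[ins0 - lay.outer_each : q] = out_l
    out_r = _mutate(w[ins0 + elen + t : ins0 + elen + t + lay.outer_each],
                    config.ld_variant_rate, rng)
    w[ins0 + elen + t : ins0 + elen + t + lay.outer_each] = out_r
    return {
        "w": w,
        "cassette": cassette,
        "cassette_start": c0,
        "sections": secs,
        "hemizygous": (ins0, ins0 + elen),
        "modified_span": (ins0 - lay.outer_each, ins0 + elen + t + lay.outer_each),
        "tir_arms": [(ins0, ins0 + arm), (ins0 + elen - arm, ins0 + elen)],
        "tsd_sites": [(q, q + t), (ins0 + elen, ins0 + elen + t)],
    }


# ---------------------------------------------------------------------------
# [OP] simulate_reads
# ---------------------------------------------------------------------------

def simulate_reads(haplotypes, config: SimConfig, rng, sample_id: str = "S") -> ReadSet:
    """Illumina-like paired-end reads from a set of haplotypes.

    ``haplotypes`` is an iterable of ``(label, codes, copy_number)``.
    Fragments are sampled uniformly per haplotype copy, insert sizes are
    Normal(insert_mean, insert_sd) truncated at read_length, mates point
    inward, and substitution errors occur at ``error_rate`` per base.
    Read names encode the fragment of origin.
    """
    rl = config.read_length
    m1_parts, m2_parts, names, origin = [], [], [], []
    for label, codes, copies in haplotypes:
        L = codes.shape[0]
        if rl > L:
            raise ValueError(f"haplotype {label} shorter than read length")
        exp_pairs = copies * config.coverage_per_chromosome_copy * L / (2 * rl)
        n = int(rng.poisson(exp_pairs))
        if n == 0:
            continue
        ins = rng.normal(config.insert_mean, config.insert_sd, n)
        ins = np.maximum(np.round(ins).astype(np.int64), rl)
        ins = np.minimum(ins, L)
        starts = (rng.random(n) * (L - ins + 1)).astype(np.int64)
        idx = starts[:, None] + np.arange(rl)
        m1 = codes[idx]
        idx2 = (starts + ins - rl)[:, None] + np.arange(rl)
        m2 = codes[idx2][:, ::-1]
        m2[m2 < 4] = 3 - m2[m2 < 4]
        m1_parts.append(m1)
        m2_parts.append(m2)
        names.extend(
            f"{sample_id}:{label}:{s}:{i_}:{k}"
            for k, (s, i_) in enumerate(zip(starts.tolist(), ins.tolist()))
        )
        origin.append(
            np.rec.fromarrays(
                [np.repeat(np.array([label]), n), starts, ins],
                names=["hap", "start", "insert"],
            )
        )
    if not m1_parts:
        return ReadSet([], np.empty((0, rl), np.uint8), np.empty((0, rl), np.uint8), None)
    m1 = np.concatenate(m1_parts)
    m2 = np.concatenate(m2_parts)
    if config.error_rate > 0:
        for m in (m1, m2):
            hit = rng.random(m.shape) < config.error_rate
            hit &= m < 4
            m[hit] = (m[hit] + rng.integers(1, 4, int(hit.sum()))) % 4
    return ReadSet(names, m1, m2, np.concatenate(origin) if origin else None)


# ---------------------------------------------------------------------------
# cohort orchestration
# ---------------------------------------------------------------------------

_TAXON = {"alpha": "sim_east", "beta": "sim_central", "gamma": "sim_west"}


class Cohort:
    """A fully simulated cohort: reference, subgenomes, samples, truth."""

    def __init__(self, config: SimConfig):
        self.config = config
        self.reference, annotation = build_reference(config)
        self.subgenomes = make_octoploid(self.reference, config)
        self.w_haplotypes, self.truth = plant_sdr(self.reference, self.subgenomes, config)
        self.truth.annotation.update(annotation)
        self.samples: list[SexedSample] = []
        clades = config.clade_of_female or tuple(["gamma"] * config.n_females)
        present = sorted(set(clades), key=CLADES.index) or ["gamma"]
        for fi, clade in enumerate(clades):
            fid = f"F{fi + 1:02d}"
            self.samples.append(SexedSample(fid, "female", _TAXON[clade], clade))
        for mi in range(config.n_males):
            clade = present[mi % len(present)]
            self.samples.append(SexedSample(f"M{mi + 1:02d}", "male", _TAXON[clade], clade))
        self._simulate_all_reads()

    # -- haplotype inventory ------------------------------------------------

    def haplotypes_of(self, sample: SexedSample):
        """(label, codes, copy_number) triples making up one individual."""
        cfg = self.config
        for sg in SUBGENOMES[: cfg.n_subgenomes]:
            for chrom, codes in self.subgenomes[sg].items():
                label = f"{sg}.{chrom}"
                if (
                    sample.sex == "female"
                    and chrom == "chr6"
                    and sg == resolve_w_subgenome(sample.clade or "gamma",
                                                   self.subgenomes)
                ):
                    yield f"{sg}.chr6W", self.w_haplotypes[sample.id], 1
                    yield label, codes, 1
                else:
                    yield label, codes, 2

    def _simulate_all_reads(self) -> None:
        cfg = self.config
        for si, sample in enumerate(self.samples):
            rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 6, si]))
            haps = list(self.haplotypes_of(sample))
            if cfg.within_subgenome_het > 0:
                haps = [
                    (lab, _mutate(codes, cfg.within_subgenome_het, rng), cp)
                    for lab, codes, cp in haps
                ]
            sample.reads = simulate_reads(haps, cfg, rng, sample.id)

    # -- persistence --------------------------------------------------------

    def write(self, outdir) -> Path:
        """Materialise reference, genomes, FASTQs, truth BED and manifest."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        ref_path = outdir / "reference.fa"
        write_fasta(ref_path, {c: decode(s) for c, s in self.reference.items()})
        self.truth.reference_paths["reference"] = str(ref_path)
        exon_bed = outdir / "reference_genes.bed"
        with open(exon_bed, "w") as fh:
            for gene in ("retro_source", "retro_paralog"):
                g = self.truth.annotation[gene]
                for s, e in g["exons"]:
                    fh.write(f"{g['chrom']}\t{s}\t{e}\t{gene}_exon\n")
            g = self.truth.annotation["gmew"]
            fh.write(f"{g['chrom']}\t{g['start']}\t{g['end']}\tgmew_orf\n")
        man_path = outdir / "manifest.tsv"
        bed_path = outdir / "truth.bed"
        with open(man_path, "w") as man, open(bed_path, "w") as bed:
            man.write("id\tsex\ttaxon\tclade\tfastq1\tfastq2\n")
            for sample in self.samples:
                f1 = outdir / f"{sample.id}_1.fastq"
                f2 = outdir / f"{sample.id}_2.fastq"
                sample.reads.to_fastq(f1, f2)
                sample.fastq1, sample.fastq2 = str(f1), str(f2)
                man.write(
                    f"{sample.id}\t{sample.sex}\t{sample.taxon}\t{sample.clade or ''}"
                    f"\t{f1}\t{f2}\n"
                )
                if sample.sex == "female":
                    ft = self.truth.females[sample.id]
                    for sec in ft.sections:
                        bed.write(
                            f"{sample.id}.W\t{sec.start}\t{sec.end}\t{sec.section}\n"
                        )
                    gpath = outdir / f"{sample.id}_genome.fa"
                    write_fasta(
                        gpath,
                        ((lab, decode(codes))
                         for lab, codes, _ in self.haplotypes_of(sample)),
                    )
                    self.truth.genome_paths[sample.id] = str(gpath)
        return outdir

    def females(self) -> list[SexedSample]:
        return [s for s in self.samples if s.sex == "female"]

    def males(self) -> list[SexedSample]:
        return [s for s in self.samples if s.sex == "male"]
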