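# Methods

This note documents the models and procedures behind `sdrpipe`, the
parameters that matter, what the synthetic cohorts do and do not
emulate, and the numerical choices made where the design was open.

## The inference problem

A female-heterogametic (ZW) species with a young, homomorphic sex
chromosome: males are ZZ, females ZW, and the only strictly
female-specific DNA is the sex-determining region (SDR) itself — a
short hemizygous insertion on the W with no Z partner. In a polyploid
with several highly similar subgenomes, none of the homoeologous copies
can be assembled apart, but the SDR can still be isolated because its
sequence occurs in every female and in no male. When linkage maps place
the SDR at different chromosomal positions in different populations,
the question becomes whether one cassette has translocated repeatedly —
and in what order.

## Sex-specific k-mers

Each sample's reads are decomposed into canonical 31-mers (both-strand
collapsing; windows containing non-ACGT are dropped) and counted
exactly. The female-specific set contains every k-mer with count >=
`min_count` (default 1) in at least `n_females - max_missing` females
and count 0 in every male. `max_missing = 1` reproduces the
all-but-one relaxation appropriate for low per-copy coverage, but the
pipeline only applies it when "all but one" still requires presence in
at least three samples: two samples sharing a sequencing error at the
same position (and to the same base) is a common event at ~30x
aggregate coverage, three samples is not. The male-specific set,
computed by the same operation with the groups swapped, is the
false-positive control; on label-permuted cohorts both sets collapse to
(near) zero.

Canonical counting is the default because a W k-mer must not escape the
male filter via its reverse complement; a non-canonical mode exists for
replication experiments. Counting is exact set arithmetic throughout —
no sketches — with tables held as sorted packed 2-bit codes.

## Alignment engine

All alignment is an internal seed-and-extend. For 31-mer alignment the
seeds are exact 8-mers: any hit with >= 29 matched bases and one
internal gap <= 30 bp necessarily contains a clean 8-mer (worst case:
29 matched bases in four runs), so the engine is complete with respect
to the retention filter, and the test suite verifies equality with a
brute-force scan of every offset, strand and gap on small references.
Gapped hits must anchor at least 8 matched bases on each side of the
gap; without that constraint every ungapped hit has shifted phantom
twins. Percent identity is matches / alignment columns x 100 with gaps
counted as columns. Long collinear alignments (segment painting,
deletion detection, outgroup projection) chain unique exact 15-mer
anchors and align the blocks between anchors with affine-gap
Needleman-Wunsch (match 1, mismatch -1, open -4, extend -1, via
Biopython's PairwiseAligner). Coordinates are 0-based half-open
everywhere.

## Assembly and scaffolding

Recruited read pairs (either mate containing a female-specific k-mer)
are pooled across the females of the reference clade and assembled by a
deterministic greedy anchor-and-extend: the seed is the read containing
the anchor k-mer (the pipeline anchors on the highest-count
female-specific k-mer, the automated analogue of anchoring at the
diagnostic deletion), extension requires >= 50 bp overlap at >= 98%
identity, reads are ordered lexicographically by id, and the final
consensus is a per-column majority over all placed reads with ties
called N. Contigs below 500 bp (unless anchor-bearing) are stray-read
noise and dropped.

Contigs are ordered and oriented into the unified W haplotype by
read-pair links — pairs whose mates land near the ends of two different
contigs. Link evidence is essential because the W haplotype is a
chimera of source loci: guide (reference-homology) coordinates cannot
order a cassette sourced from one locus against flanking sourced from
another. Guide coordinates remain the fallback and provide gap-length
estimates, bounded at 500 bp and represented as N runs. Chains whose
orientation is only fixed relatively are canonicalised to the majority
guide strand.

## Hemizygosity

Three evidence streams are combined on the assembled haplotype:

* **k-mer territory** — clade female-specific k-mers aligned to the
  haplotype, merged into runs wherever consecutive starts are closer
  than `1000 / min_kmer_density` bp (default density 5 distinct
  k-mers/kb, chosen so a 1.2 kb insertion is callable at 4x per-copy
  coverage); runs separated by a female-specific seam are merged.
* **seams** — positions whose inter-mate gap is covered by
  normally-spaced pairs in >= `min_females` females and no male. Far
  pairs are excluded from seam support: they witness contiguity in
  *other* copies, not a W adjacency.
* **far pairs** — pairs whose implied span exceeds 1 kb. Mates anchor
  in shared sequence on either side of an insertion junction; the
  interval they skip is precisely the sequence their source copy lacks.
  Pairs are clustered by both gap endpoints (tolerance ~ one insert
  length) so that nested junctions — the retro-insertion inside the
  cassette inside the translocated element — yield concentric clusters
  rather than one blurred one.

The *hemizygous* span of a clade is the female-specific k-mer territory
intersected with the union of far-pair skip intervals. Female-specific
sequence outside every skip — the "outer" neighbourhood of an insertion
site, which carries variants in linkage disequilibrium with sex but has
a Z counterpart — is reported as linked but not hemizygous. This is
what makes the recovered spans nest strictly across clades (retro
insert < cassette < cassette + flanking).

**Dose.** Read depth is measured from all placed mates (placement is
exact-seed + full-read comparison at >= 90% identity for this analysis;
reads from homoeologous copies are ~4-5% divergent from the W haplotype
and a 95% cut-off would discard half of them and break the dose logic).
Junction-anchor windows sit one read length clear of the junction —
reads that straddle the junction on other copies cannot place, so the
150 bp shadow next to the junction systematically undercounts. Anchor
depth (all 2N copies) divided by k-mer-recruited depth inside the
insertion (the single W copy) gives the copy dose: ~8 in the octoploid,
~4 in a tetraploid variant, and it does not differ between sexes
(two-sided equal-variance t test on per-sample anchor depth).
`single_copy_check` additionally flags interior non-recruited depth
above 0.88 of anchor depth as a possible extra cassette copy; the
threshold is calibrated on the generator's default divergence model,
where the known homoeologous copies explain ~0.75 and one extra diploid
degraded copy raises it to ~1.0.

**Diagnostic deletion.** Every painted segment >= 1 kb is
globally aligned to its source window; reference runs >= 10 bp absent
from the W (away from segment edges) are reported with per-sample
junction support: a sample supports the deletion if its k-mer table
contains any 31-mer spanning the breakpoint by at least 5 bp on each
side (shorter overlaps coincide with the undeleted allele by chance).
The call is diagnostic iff all females support it and no male does.

**Premature stop.** The cassette ORF is located on the haplotype by its
dominant exact-13-mer diagonal (bailing out if an assembly gap splits
the copy, which would shift the frame), excised, and translated against
the reference ORF; a 376-codon ORF with a stop substituted at codon 223
yields a 222-residue product.

## Phylogenetics

Per-female consensus sequences over the cassette window (default: from
the retrogene segment through the diagnostic deletion, ~2.7 kb) are
built from each female's recruited reads by per-column majority (ties
and zero coverage are N). The pseudo-outgroup concatenates the source
locus of every painted sub-segment, projected onto the window columns —
the retrogene's source contributes its exons only, keeping the outgroup
collinear with the intron-less W copy.

Trees are neighbor joining on Jukes-Cantor distances with pairwise
deletion of missing sites, a nonparametric bootstrap over columns
(columns > 50% missing are excluded from the resampling pool and
flagged), and rooting on the pseudo-outgroup. NJ is implemented
internally and cross-checked in the tests against an independent
implementation (scikit-bio) and against topology recovery on random
additive trees. Maximum-likelihood search and SH-like supports are
deliberately out of scope: at > 99% within-clade identity, clade
recovery is method-insensitive, and the analysis surface here is clade
membership, not likelihoods.

Clades are the maximal supported (bootstrap >= 75%) proper sub-clades of
the ingroup whose stem branch exceeds `min_stem` = 1e-3
substitutions/site, i.e. about three substitutions over the window.
The stem filter is essential on clean simulated data: a perfect
three-origin star gives exactly additive distances, NJ must resolve the
polytomy somehow, and the bootstrap then reproduces that arbitrary
resolution with high support — but always on a near-zero stem, whereas
genuine clade stems in the cohorts are an order of magnitude longer.
Tips covered by no qualifying clade are "unassigned"; if no proper
sub-clade qualifies and the ingroup itself is resolved (multi-tip
outgroup), the ingroup is one clade.

Retrogene monophyly is an NJ tree over the per-clade retro consensus
plus the reference paralogs (exon concatenations from the annotation);
single origin holds iff some edge bipartitions the retro copies from
all paralogs.

## Translocation history

Section classes are assigned comparatively: painted segments covered by
the female-specific intervals of all clades are the cassette (segments
sourced from the annotated retrogene are `retro_insert`), of a proper
subset are flanking, of exactly one clade are outer. The composition
matrix marks a clade as possessing a section when its female-specific
intervals cover >= 50% of it. Deduplicated rows must form a chain under
the subset relation; the chain is the temporal order, with at least
`steps - 1` moves. The ancestral location is the source locus of the
universally shared section *on the chromosome of the later map
locations*; shared sections sourced from other chromosomes (the
retrogene) cannot be SDR addresses and are reported origin-ambiguous.

**TIR/TSD scan.** For a candidate element boundary pair, the longest
arm (10-40 bp, mismatch budget 0 by default) such that the 5' terminus
is the reverse complement of the 3' terminus is reported together with
the longest exact direct repeat immediately outside both arms (TSD,
2-10 bp). Two subtleties: (i) read-estimated boundaries are only
insert-accurate, so the pipeline first refines them to base precision
by a CUSUM mismatch changepoint against the painted source locus
(outside the element the haplotype tracks its source at a few percent
divergence; inside, the sequence is unrelated); (ii) a palindromic TSD
— TA, the classic dinucleotide target — reads equally well as part of
the arms, so candidates whose arms absorb another candidate's TSD are
dropped as telescoped variants. Boundary refinement against the
reference target site is what makes the arm-25-plus-TA decomposition
unique. No arms are found at the cassette/flanking border, consistent
with the souvenir (rather than independent-element) interpretation of
the inner junctions.

## The synthetic cohorts

The generator emulates: a 7-chromosome uniform-composition reference
(50 kb chromosomes by default — scaled stand-ins for Mb-scale
chromosomes, with section sizes kept at real-world absolute values so
the printed quantities are recoverable verbatim); four subgenomes at 2%
divergence each, inherited disomically; a chr7-analog source gene with
four introns plus a chr5-analog paralog (8% diverged); per-clade W
haplotypes built by a coherent event history — an ancestral cassette
(source window at 5% W-allele divergence, the 23 bp deletion, the stop
codon, the 1%-diverged intron-less retro copy), a first translocation
inserting it at the location-13 analog, and a second moving cassette +
captured flanking to the location-37 analog behind 25 bp arms and TA
duplications; 1% linkage-disequilibrium variants in the native
neighbourhoods of each insertion site; 1% clade branches (a star: three
independent origins from the shared ancestor), 0.1% per-female
variation; and Illumina-like 150 bp pairs, insert 400 +/- 40, 0.2%
substitution error, 4x per chromosome copy.

Divergence defaults were chosen once from the homology levels the
analysis must reproduce (cassette ~93% to the reference including
subgenome divergence, retrogene ~99%) and from what the discrimination
steps require (the cassette must be > 5% from all male copies so
95%-identity placement cannot cross it; LD variants must mark the outer
neighbourhoods without making them hemizygous). The insert mean of
400 bp exceeds twice the read length so that inter-mate gaps exist —
with a 300 bp insert the gap is zero and spanning-pair evidence is
impossible by construction. Planted diagnostic structures (TIR arms,
TSDs, the deletion junction +/- 31 bp, the ORF) are excluded from
random mutation, and arm termini avoid the specific coincidences (a T
start, a self-complementary start, chance extensions) that would make
the planted arm length ill-defined; the signature is planted exactly,
by design.

What the generator does not model: recombination and pedigrees,
pseudoautosomal recombination gradients, indel sequencing errors,
quality-score profiles, repeat families, and within-subgenome
heterozygosity (default 0, configurable). Consequently, passing tests
demonstrate the pipeline's logic under clean polyploid structure and
substitution noise; on real data, repeat content and heterozygosity
would mainly inflate the k-mer sets and blur far-pair clusters, which
the min-count, density and cluster-size parameters exist to absorb.
Chromosome-edge coverage dropouts are real artefacts of uniform
fragment sampling and do appear as rare spurious "specific" k-mers in
very small cohorts; study-scale cohorts (9 + 9) filter them, and so do
real genomes' larger chromosomes.

## Numerical choices and degenerate inputs

* Ties in consensus columns are N; ties in mate placement drop the
  mate; ties in painting sources go to the lowest chromosome name, then
  the lowest start.
* Jukes-Cantor distances are capped at 5 substitutions/site (p >= 0.75).
* Empty inputs: empty read sets warn and return empty tables; an
  all-identical alignment returns a flagged star tree; a clade with
  fewer than two females is profiled but flagged low-power; zero
  W-specific depth flags the dose undefined; cohorts without both sexes
  are refused.
* Determinism: every stage is a pure function of its inputs and the
  master seed; per-sample and per-clade RNG streams are spawned from
  it. Re-running a configuration reproduces byte-identical FASTQ and
  identical reports.

## Problem sizes

Defaults were sized so a full cohort analysis (18 samples, ~0.7 M read
pairs) runs in about a minute on one CPU: 50 kb chromosomes preserve
every absolute length the method must recover (31-mers, 23 bp deletion,
25 bp arms, 1.2/13/23 kb spans) while keeping the shared sequence small
enough for exact k-mer arithmetic in memory. The acceptance script runs
three such cohorts; the test suite adds one multi-clade cohort and a
set of miniature cohorts (12 kb chromosomes, proportionally shrunk
sections) for unit-level checks — the miniatures sit near the
geometric floor of the method (sections comparable to the insert
length) and are used only where that does not matter.
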