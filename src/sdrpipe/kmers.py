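"""Per-sample k-mer counting and exact group-specific set arithmetic.

The discovery step of the pipeline: count k-mers (default 31) in every
sample's reads, then take the k-mers present in (nearly) all samples of
one sex and absent from every sample of the other.  All set operations
are exact — no sketches, no probabilistic filters — mirroring the
sort/join approach the counts are modelled on, with counts held as
sorted packed-code arrays.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import _codec
from ._codec import SEP, encode, kmer_scan, kmer_scan_matrix, pack_kmer, unpack_kmer
from .simdata import ReadSet


def _in_sorted(values: np.ndarray, table: np.ndarray) -> np.ndarray:
    """Boolean membership of ``values`` in the sorted array ``table``."""
    if table.shape[0] == 0 or values.shape[0] == 0:
        return np.zeros(values.shape[0], bool)
    idx = np.searchsorted(table, values)
    ok = idx < table.shape[0]
    ok[ok] = table[idx[ok]] == values[ok]
    return ok


def _decode_codes(codes: np.ndarray, k: int) -> list[str]:
    shifts = 2 * np.arange(k - 1, -1, -1, dtype=np.int64)
    mat = ((codes[:, None] >> shifts[None, :]) & 3).astype(np.uint8)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    rows = bases[mat]
    return [r.tobytes().decode("ascii") for r in rows]


@dataclass
class KmerTable:
    """k-mer -> count map for one sample, stored as sorted packed codes."""

    k: int
    canonical: bool
    codes: np.ndarray  # sorted int64
    counts: np.ndarray  # int64, parallel to codes

    def __len__(self) -> int:
        return int(self.codes.shape[0])

    def total(self) -> int:
        return int(self.counts.sum())

    def get(self, kmer: str) -> int:
        if len(kmer) != self.k:
            raise ValueError(f"expected a {self.k}-mer, got {len(kmer)} bases")
        if self.canonical:
            kmer = _codec.canonical_kmer(kmer)
        code = pack_kmer(kmer)
        i = np.searchsorted(self.codes, code)
        if i < self.codes.shape[0] and self.codes[i] == code:
            return int(self.counts[i])
        return 0

    def __contains__(self, kmer: str) -> bool:
        return self.get(kmer) > 0

    def items(self):
        for kmer, count in zip(_decode_codes(self.codes, self.k), self.counts):
            yield kmer, int(count)

    def present_codes(self, min_count: int = 1) -> np.ndarray:
        return self.codes[self.counts >= min_count]

    def to_tsv(self, path) -> None:
        """Sorted two-column text (k-mer, count)."""
        with open(path, "w") as fh:
            for kmer, count in self.items():
                fh.write(f"{kmer}\t{count}\n")

    @classmethod
    def from_tsv(cls, path, canonical: bool = True) -> "KmerTable":
        codes, counts, k = [], [], None
        with open(path) as fh:
            for line in fh:
                kmer, count = line.split()
                if k is None:
                    k = len(kmer)
                codes.append(pack_kmer(kmer))
                counts.append(int(count))
        codes = np.asarray(codes, np.int64)
        counts = np.asarray(counts, np.int64)
        order = np.argsort(codes)
        return cls(k or 0, canonical, codes[order], counts[order])


def _reads_to_codes(reads) -> np.ndarray:
    """Flatten any supported read source into SEP-joined code arrays."""
    if isinstance(reads, ReadSet):
        return reads.concat_codes()
    if isinstance(reads, np.ndarray):
        return reads
    if isinstance(reads, (str, bytes)):
        raise TypeError("pass a list of read strings, a ReadSet, or file paths")
    parts = []
    for item in reads:
        if isinstance(item, str) and ("/" in item or item.endswith(".fastq")):
            for _, seq in _codec.read_fastq(item):
                parts.append(encode(seq))
                parts.append(np.array([SEP], np.uint8))
        else:
            parts.append(encode(item))
            parts.append(np.array([SEP], np.uint8))
    if not parts:
        return np.empty(0, np.uint8)
    return np.concatenate(parts)


def count_kmers(reads, k: int = 31, canonical: bool = True) -> KmerTable:
    """Count every length-k window of every read.

    ``reads`` may be a :class:`~sdrpipe.simdata.ReadSet`, an iterable of
    read strings, or an iterable of FASTQ paths.  Windows containing
    non-ACGT symbols are skipped; reverse-complement collapsing happens
    iff ``canonical``.
    """
    if k % 2 == 0:
        raise ValueError("k must be odd (canonical form would be ambiguous)")
    if not 3 <= k <= 63:
        raise ValueError("k must be in [3, 63]")
    if isinstance(reads, ReadSet):
        if len(reads) == 0:
            warnings.warn("empty read input: returning an empty k-mer table")
            return KmerTable(k, canonical, np.empty(0, np.int64), np.empty(0, np.int64))
        mat = np.concatenate([reads.mate1, reads.mate2])
        kmer_codes, _, _ = kmer_scan_matrix(mat, k, canonical)
    else:
        codes = _reads_to_codes(reads)
        if codes.shape[0] == 0:
            warnings.warn("empty read input: returning an empty k-mer table")
            return KmerTable(k, canonical, np.empty(0, np.int64), np.empty(0, np.int64))
        kmer_codes, _ = kmer_scan(codes, k, canonical)
    uniq, counts = np.unique(kmer_codes, return_counts=True)
    return KmerTable(k, canonical, uniq, counts.astype(np.int64))


@dataclass
class GroupSpecificKmerSet:
    """k-mers present in (nearly) all of one group, absent in the other."""

    k: int
    canonical: bool
    codes: np.ndarray  # sorted int64
    presence_group: tuple[str, ...]
    absence_group: tuple[str, ...]
    min_count: int = 1
    max_missing: int = 0

    def __len__(self) -> int:
        return int(self.codes.shape[0])

    def kmers(self) -> list[str]:
        return _decode_codes(self.codes, self.k)

    def __contains__(self, kmer: str) -> bool:
        if self.canonical:
            kmer = _codec.canonical_kmer(kmer)
        return bool(_in_sorted(np.array([pack_kmer(kmer)], np.int64), self.codes)[0])


def group_specific_kmers(
    tables: dict[str, KmerTable],
    presence_group,
    absence_group,
    min_count: int = 1,
    max_missing: int = 0,
) -> GroupSpecificKmerSet:
    """Exact set arithmetic: keep k-mers with count >= ``min_count`` in at
    least ``len(presence_group) - max_missing`` presence samples and count 0
    in every absence sample.

    The operation is symmetric: swapping the groups yields the
    male-specific control set.
    """
    presence = tuple(presence_group)
    absence = tuple(absence_group)
    if not presence or not absence:
        raise ValueError("presence and absence groups must be non-empty")
    if set(presence) & set(absence):
        raise ValueError("presence and absence groups must be disjoint")
    if not 0 <= max_missing < len(presence):
        raise ValueError("max_missing must be smaller than the presence group")
    ks = {tables[s].k for s in presence + absence}
    cans = {tables[s].canonical for s in presence + absence}
    if len(ks) != 1 or len(cans) != 1:
        raise ValueError("all tables must share k and canonical flag")
    k, canonical = ks.pop(), cans.pop()

    parts = [tables[s].present_codes(min_count) for s in presence]
    allc = np.concatenate(parts) if parts else np.empty(0, np.int64)
    uniq, nseen = np.unique(allc, return_counts=True)
    need = len(presence) - max_missing
    cand = uniq[nseen >= need]
    for s in absence:
        if cand.shape[0] == 0:
            break
        cand = cand[~_in_sorted(cand, tables[s].codes)]
    return GroupSpecificKmerSet(k, canonical, cand, presence, absence, min_count, max_missing)


def recruit_reads(reads: ReadSet, kmer_set: GroupSpecificKmerSet):
    """Extract the read pairs in which either mate contains a set k-mer.

    Both mates of a qualifying pair are emitted, input order is kept, and
    no pair is emitted twice.  Returns ``(recruited ReadSet, pair index
    array)``.
    """
    if len(kmer_set) == 0:
        raise ValueError("k-mer set is empty; nothing to recruit with")
    n = len(reads)
    if n == 0:
        return ReadSet([], reads.mate1, reads.mate2, None), np.empty(0, np.int64)
    mat = np.concatenate([reads.mate1, reads.mate2])
    kmer_codes, rows, _ = kmer_scan_matrix(mat, kmer_set.k, kmer_set.canonical)
    hit = _in_sorted(kmer_codes, kmer_set.codes)
    rows = rows[hit]
    pair_idx = np.unique(np.where(rows < n, rows, rows - n))
    sub = ReadSet(
        [reads.names[i] for i in pair_idx],
        reads.mate1[pair_idx],
        reads.mate2[pair_idx],
        reads.origin[pair_idx] if reads.origin is not None else None,
    )
    return sub, pair_idx
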