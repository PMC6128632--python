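"""2-bit sequence codec and vectorised k-mer extraction.

Internal helpers shared by every stage. Sequences are held as numpy uint8
arrays with A=0, C=1, G=2, T=3 and 4 for any other symbol (N, gap,
record separator). k-mers are packed big-endian into int64 codes, so for
fixed k the numeric order of codes equals the lexicographic order of the
k-mer strings.
"""

from __future__ import annotations

import numpy as np

_LUT = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _LUT[_b] = _i
    _LUT[ord(chr(_b).lower())] = _i

_BASES = np.frombuffer(b"ACGTN", dtype=np.uint8)

#: separator / unknown code
SEP = np.uint8(4)


def encode(seq: str | bytes) -> np.ndarray:
    """Encode a sequence string to a uint8 code array (A=0..T=3, other=4)."""
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    return _LUT[np.frombuffer(seq, dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    """Inverse of :func:`encode`; code 4 decodes to ``N``."""
    return _BASES[codes].tobytes().decode("ascii")


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    out = codes[::-1].copy()
    acgt = out < 4
    out[acgt] = 3 - out[acgt]
    return out


def revcomp(seq: str) -> str:
    return decode(revcomp_codes(encode(seq)))


def kmer_scan(codes: np.ndarray, k: int, canonical: bool):
    """All k-mer codes of a code array, skipping windows containing non-ACGT.

    Returns ``(kmers, starts)`` where ``kmers`` are packed int64 codes (the
    canonical form if requested) and ``starts`` the 0-based window starts.
    Multiple sequences may be scanned in one call by concatenating them with
    a SEP byte between; windows crossing the separator are dropped.
    """
    n = codes.shape[0]
    if n < k:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    m = n - k + 1
    fwd = np.zeros(m, np.int64)
    rc = np.zeros(m, np.int64) if canonical else None
    c64 = codes.astype(np.int64)
    for j in range(k):
        col = c64[j : j + m]
        fwd += col << (2 * (k - 1 - j))
        if canonical:
            rc += (3 - col) << (2 * j)
    bad = np.concatenate(([0], np.cumsum(codes >= 4)))
    ok = (bad[k:] - bad[:-k]) == 0
    starts = np.nonzero(ok)[0]
    fwd = fwd[starts]
    if canonical:
        fwd = np.minimum(fwd, rc[starts])
    return fwd, starts


def kmer_scan_matrix(mat: np.ndarray, k: int, canonical: bool):
    """Rolling k-mer scan over equal-length rows (e.g. a read matrix).

    Returns ``(kmers, rows, cols)`` where ``cols`` are window starts
    within each row.  Much faster than :func:`kmer_scan` on large read
    sets because the rolling value is carried across columns.
    """
    n, L = mat.shape
    if L < k or n == 0:
        e = np.empty(0, np.int64)
        return e, e.copy(), e.copy()
    mask = (np.int64(1) << (2 * k)) - np.int64(1)
    hi = 2 * (k - 1)
    v = np.zeros(n, np.int64)
    rc = np.zeros(n, np.int64)
    run = np.zeros(n, np.int32)
    out_k, out_r, out_c = [], [], []
    for j in range(L):
        col = mat[:, j].astype(np.int64)
        valid = col < 4
        colv = np.where(valid, col, 0)
        v = ((v << 2) | colv) & mask
        rc = (rc >> 2) | ((3 - colv) << hi)
        run = np.where(valid, run + 1, 0)
        if j >= k - 1:
            ok = run >= k
            if ok.any():
                kk = v[ok]
                if canonical:
                    kk = np.minimum(kk, rc[ok] & mask)
                rows = np.nonzero(ok)[0]
                out_k.append(kk)
                out_r.append(rows)
                out_c.append(np.full(rows.shape[0], j - k + 1, np.int64))
    if not out_k:
        e = np.empty(0, np.int64)
        return e, e.copy(), e.copy()
    return (np.concatenate(out_k), np.concatenate(out_r), np.concatenate(out_c))


def pack_kmer(kmer: str) -> int:
    codes = encode(kmer)
    if (codes >= 4).any():
        raise ValueError(f"k-mer contains non-ACGT symbols: {kmer}")
    val = 0
    for c in codes:
        val = (val << 2) | int(c)
    return val


def unpack_kmer(code: int, k: int) -> str:
    out = bytearray(k)
    for i in range(k - 1, -1, -1):
        out[i] = b"ACGT"[code & 3]
        code >>= 2
    return out.decode("ascii")


def canonical_kmer(kmer: str) -> str:
    rc = revcomp(kmer)
    return min(kmer, rc)


# ---------------------------------------------------------------------------
# plain-text FASTA / FASTQ helpers (performance paths use raw code arrays)
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    """Ordered name -> sequence map from a FASTA file."""
    seqs: dict[str, list[str]] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0]
                seqs[name] = []
            else:
                seqs[name].append(line)
    return {n: "".join(parts) for n, parts in seqs.items()}


def write_fasta(path, records, width: int = 80) -> None:
    """Write ``(name, seq)`` pairs (or a mapping) as FASTA."""
    if hasattr(records, "items"):
        records = records.items()
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fastq(path):
    """Yield ``(name, seq)`` from an uncompressed FASTQ file."""
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline().strip()
            fh.readline()
            fh.readline()
            yield header[1:].strip().split()[0], seq


def write_fastq(path, records) -> None:
    """Write ``(name, seq)`` pairs as FASTQ with uniform quality."""
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")
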