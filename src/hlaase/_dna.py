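"""Integer encoding of nucleotide sequences and vectorised k-mer extraction.

Bases are mapped A,C,G,T -> 0..3; anything else (N, IUPAC ambiguity codes,
padding) maps to the sentinel 4.  k-mers are packed two bits per base into
uint64 values, which caps k at 31 — the package default.  Canonical k-mers
are the lexicographic minimum of a k-mer and its reverse complement so that
read strand never matters.
"""

from __future__ import annotations

import numpy as np

MAX_K = 31
_SENTINEL = 4

_CODE = np.full(256, _SENTINEL, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_BASES = np.frombuffer(b"ACGTN", dtype=np.uint8)


def encode_seq(seq: str) -> np.ndarray:
    """Encode one sequence as a 1-D uint8 array (4 = ambiguous base)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _CODE[raw]


def encode_batch(seqs) -> np.ndarray:
    """Encode sequences into an (n, max_len) matrix, right-padded with 4."""
    encoded = [encode_seq(s) for s in seqs]
    n = len(encoded)
    width = max((len(e) for e in encoded), default=0)
    mat = np.full((n, width), _SENTINEL, dtype=np.uint8)
    for i, e in enumerate(encoded):
        mat[i, : len(e)] = e
    return mat


def decode(mat: np.ndarray) -> list[str]:
    """Inverse of :func:`encode_batch`; padding decodes as N and is kept."""
    mat = np.atleast_2d(mat)
    chars = _BASES[np.minimum(mat, _SENTINEL)]
    return [row.tobytes().decode("ascii") for row in chars]


def revcomp(mat: np.ndarray) -> np.ndarray:
    """Reverse-complement encoded sequences (last axis); sentinel preserved."""
    comp = np.where(mat < _SENTINEL, 3 - mat, _SENTINEL).astype(np.uint8)
    return comp[..., ::-1]


def window_codes(mat: np.ndarray, k: int):
    """Canonical k-mer codes of every window of every row.

    Parameters
    ----------
    mat : (n, L) uint8 matrix from :func:`encode_batch`.
    k : k-mer length, 1..31.

    Returns
    -------
    codes : (n, L-k+1) uint64 canonical codes (junk where invalid)
    valid : (n, L-k+1) bool, False for windows containing an ambiguous base
        or padding.  If L < k both arrays have zero columns.
    """
    if not 1 <= k <= MAX_K:
        raise ValueError(f"k must be in [1, {MAX_K}], got {k}")
    mat = np.atleast_2d(mat)
    n, length = mat.shape
    width = length - k + 1
    if width <= 0:
        return (np.zeros((n, 0), dtype=np.uint64), np.zeros((n, 0), dtype=bool))
    bad = mat >= _SENTINEL
    m = np.where(bad, 0, mat).astype(np.uint64)
    fwd = np.zeros((n, width), dtype=np.uint64)
    rev = np.zeros((n, width), dtype=np.uint64)
    three = np.uint64(3)
    for j in range(k):
        fwd = (fwd << np.uint64(2)) | m[:, j : j + width]
        rev |= (three - m[:, j : j + width]) << np.uint64(2 * j)
    canon = np.minimum(fwd, rev)
    # window is valid iff it contains no bad base
    csum = np.zeros((n, length + 1), dtype=np.int32)
    np.cumsum(bad, axis=1, out=csum[:, 1:])
    valid = (csum[:, k:] - csum[:, :width]) == 0
    return canon, valid
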