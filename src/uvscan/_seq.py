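"""Low-level nucleotide encoding and vectorised k-mer extraction.

Sequences are handled as uint8 arrays over the 2-bit alphabet
A=0, C=1, G=2, T=3; any other letter maps to the sentinel 4 and every
k-mer touching it is dropped. k-mers are packed into int64 codes
(2 bits/base, first base in the high bits), which keeps k ≤ 31.
"""
from __future__ import annotations

import numpy as np

_BASES = b"ACGT"

# ASCII -> 2-bit code, 4 for anything that is not an unambiguous base
_ENC = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENC[_b] = _i
    _ENC[ord(chr(_b).lower())] = _i

_DEC = np.frombuffer(_BASES, dtype=np.uint8)

COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N preserved)."""
    return seq.translate(COMPLEMENT)[::-1]


def encode(seq: str | bytes) -> np.ndarray:
    """Encode a sequence into the 2-bit alphabet (4 = ambiguous)."""
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    return _ENC[np.frombuffer(seq, dtype=np.uint8)]


def decode(arr: np.ndarray) -> str:
    return _DEC[arr].tobytes().decode("ascii")


def kmer_codes(enc: np.ndarray, k: int, canonical: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Pack every k-mer of an encoded sequence into int64 codes.

    Returns ``(codes, valid)`` of length ``len(enc) - k + 1``: ``codes[i]``
    is the (canonical) code of the k-mer starting at i and ``valid[i]`` is
    False when the window covers an ambiguous base. Positions with
    ``valid == False`` carry an arbitrary code and must be masked out.
    """
    if not 1 <= k <= 31:
        raise ValueError(f"k must be in [1, 31], got {k}")
    n = enc.shape[0]
    m = n - k + 1
    if m <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    bad = (enc >= 4)
    if bad.any():
        cs = np.concatenate([[0], np.cumsum(bad)])
        valid = (cs[k:] - cs[:-k]) == 0
    else:
        valid = np.ones(m, dtype=bool)
    b = np.where(bad, 0, enc).astype(np.int64)
    fwd = np.zeros(m, dtype=np.int64)
    for i in range(k):
        fwd = (fwd << 2) | b[i : i + m]
    if not canonical:
        return fwd, valid
    rev = np.zeros(m, dtype=np.int64)
    for i in range(k):
        # complement (3 - base) of offset i lands at reversed position i
        rev |= (3 - b[i : i + m]) << (2 * i)
    return np.minimum(fwd, rev), valid


def code_to_kmer(code: int, k: int) -> str:
    out = bytearray(k)
    for i in range(k - 1, -1, -1):
        out[i] = _BASES[code & 3]
        code >>= 2
    return out.decode("ascii")


def kmer_to_code(kmer: str) -> int:
    enc = encode(kmer)
    if (enc >= 4).any():
        raise ValueError(f"ambiguous base in k-mer {kmer!r}")
    code = 0
    for v in enc:
        code = (code << 2) | int(v)
    return code


def canonical(kmer: str) -> str:
    rc = revcomp(kmer)
    return min(kmer.upper(), rc.upper())


def aggregate_codes(codes: np.ndarray, counts: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Collapse repeated codes into sorted unique codes with summed counts."""
    if counts is None:
        return np.unique(codes, return_counts=True)
    uniq, inv = np.unique(codes, return_inverse=True)
    summed = np.bincount(inv, weights=counts.astype(np.float64)).astype(np.int64)
    return uniq, summed


def write_fasta(path, records, width: int = 80) -> None:
    """Write (id, sequence) pairs as wrapped FASTA."""
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path) -> list[tuple[str, str]]:
    from Bio import SeqIO

    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
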