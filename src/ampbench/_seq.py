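"""Low-level sequence utilities shared across the package.

DNA sequences are plain upper-case ``str`` of A/C/G/T at the API surface;
hot loops encode them as ``uint8`` arrays (A=0, C=1, G=2, T=3).
"""

from __future__ import annotations

import edlib
import numpy as np

BASES = "ACGT"
_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENCODE[ord(_b)] = _i
_DECODE = np.frombuffer(BASES.encode(), dtype=np.uint8)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as a uint8 array (A=0, C=1, G=2, T=3)."""
    arr = _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr == 255).any():
        bad = sorted(set(seq) - set(BASES))
        raise ValueError(f"non-ACGT symbol(s) in sequence: {bad}")
    return arr


def decode(arr: np.ndarray) -> str:
    return _DECODE[arr].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def levenshtein(a: str, b: str, max_dist: int | None = None) -> int:
    """Edit distance between two sequences.

    With ``max_dist`` set, returns ``max_dist + 1`` when the true distance
    exceeds it (banded alignment; much faster for large cutoffs).
    """
    if max_dist is not None and max_dist >= max(len(a), len(b)):
        max_dist = None  # cutoff beyond any possible distance: unbanded
    k = -1 if max_dist is None else max_dist
    d = edlib.align(a, b, mode="NW", task="distance", k=k)["editDistance"]
    if d == -1:
        return max_dist + 1
    return d


def identity(a: str, b: str) -> float:
    """Pairwise identity 1 - Levenshtein / alignment_length.

    The alignment length is taken as the longer of the two sequence
    lengths, the convention used by greedy OTU clustering tools.
    """
    if not a or not b:
        raise ValueError("identity of empty sequence is undefined")
    return 1.0 - levenshtein(a, b) / max(len(a), len(b))


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length sequences")
    return int((encode(a) != encode(b)).sum())
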