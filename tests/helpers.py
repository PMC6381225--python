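"""Independent oracles and small builders shared across test modules.

Everything here is deliberately written without using the package's own
sequence machinery (plain DP edit distance, direct transcription of the
greedy-clustering definition) so it can serve as an independent check.
"""

from __future__ import annotations

import numpy as np

from ampbench.preprocess import DerepEntry, DereplicatedSet


def levenshtein_dp(a: str, b: str) -> int:
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def greedy_otu_oracle(
    entries: list[tuple[str, int]], radius: float
) -> dict[str, list[str]]:
    """Literal transcription of abundance-sorted greedy clustering: each
    sequence joins the first seed with identity >= 1 - radius, where
    identity = 1 - d/max(len); otherwise it seeds. Input must already be
    sorted by (-abundance, sequence)."""
    clusters: dict[str, list[str]] = {}
    for seq, _ab in entries:
        home = None
        for seed in clusters:
            d = levenshtein_dp(seq, seed)
            if 1.0 - d / max(len(seq), len(seed)) >= 1.0 - radius:
                home = seed
                break
        if home is None:
            clusters[seq] = [seq]
        else:
            clusters[home].append(seq)
    return clusters


def make_derep(
    entries: list[tuple[str, int]], sample: str = "s1", quals: int = 30
) -> DereplicatedSet:
    """Build a DereplicatedSet from (sequence, abundance) pairs."""
    built = [
        DerepEntry(
            seq,
            ab,
            {sample: ab},
            np.full(len(seq), quals, dtype=np.int16),
        )
        for seq, ab in entries
    ]
    built.sort(key=lambda e: (-e.abundance, e.sequence))
    return DereplicatedSet(tuple(built))


def make_derep_multisample(
    entries: list[tuple[str, dict[str, int]]]
) -> DereplicatedSet:
    built = [
        DerepEntry(
            seq,
            sum(counts.values()),
            dict(counts),
            np.full(len(seq), 30, dtype=np.int16),
        )
        for seq, counts in entries
    ]
    built.sort(key=lambda e: (-e.abundance, e.sequence))
    return DereplicatedSet(tuple(built))


def random_seqs(rng: np.random.Generator, n: int, length: int) -> list[str]:
    return [
        "".join(rng.choice(list("ACGT"), length)) for _ in range(n)
    ]


def mutate(seq: str, positions: list[int]) -> str:
    out = list(seq)
    for p in positions:
        out[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[p]]
    return "".join(out)
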