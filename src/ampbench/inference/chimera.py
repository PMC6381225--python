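"""De novo bimera (two-parent PCR chimera) detection and removal.

A candidate is a bimera when it can be written exactly as a prefix of one
parent followed by a suffix of another, with both parents distinct from
the candidate and at least ``min_parent_fold`` times more abundant — the
exact two-segment crossover model used by de novo chimera filters.
"""

from __future__ import annotations

from typing import Sequence

from ._table import Feature, FeatureTable


def _longest_common_prefix(a: str, b: str) -> int:
    n = min(len(a), len(b))
    for i in range(n):
        if a[i] != b[i]:
            return i
    return n


def _longest_common_suffix(a: str, b: str) -> int:
    n = min(len(a), len(b))
    for i in range(1, n + 1):
        if a[-i] != b[-i]:
            return i - 1
    return n


def is_bimera(
    candidate: str,
    candidate_abundance: int,
    parents: Sequence[tuple[str, int]],
    min_parent_fold: float = 2.0,
) -> bool:
    """True iff candidate = prefix(P1) + suffix(P2) for two distinct,
    sufficiently abundant parents and an interior breakpoint.

    The breakpoint test reduces to lcp(candidate, P1) + lcs(candidate, P2)
    >= len(candidate), requiring a non-empty segment from each parent.
    """
    floor = min_parent_fold * candidate_abundance
    eligible = [
        seq for seq, ab in parents if ab >= floor and seq != candidate
    ]
    if len(eligible) < 2:
        return False
    n = len(candidate)
    lcp = [_longest_common_prefix(candidate, p) for p in eligible]
    lcs = [_longest_common_suffix(candidate, p) for p in eligible]
    for i, p1 in enumerate(eligible):
        if lcp[i] == 0:
            continue
        for j, p2 in enumerate(eligible):
            if i == j or lcs[j] == 0:
                continue
            # need breakpoint b with 1 <= b <= n-1, b <= lcp_i, n-b <= lcs_j
            if min(lcp[i], n - 1) + min(lcs[j], n - 1) >= n:
                return True
    return False


def remove_chimeras(
    table: FeatureTable, min_parent_fold: float = 2.0
) -> tuple[FeatureTable, int]:
    """Drop features flagged as bimeras of more abundant retained features.

    Features are scanned in decreasing abundance so parents are always
    features that themselves survived. Returns the filtered table and the
    number of features removed.
    """
    kept: list[Feature] = []
    removed = 0
    for f in table.features:  # already in decreasing-abundance order
        parents = [(k.sequence, k.abundance) for k in kept]
        if is_bimera(f.sequence, f.abundance, parents, min_parent_fold):
            removed += 1
        else:
            kept.append(f)
    return (
        FeatureTable(tuple(kept), method=table.method, scope=table.scope),
        removed,
    )
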