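"""Minimum-entropy decomposition of an amplicon data set.

Sequences (gap-padded to a common length) start in one cluster. The
Shannon entropy of every alignment column is computed; while any column's
entropy exceeds the cluster's threshold, the cluster is split by the
symbol at its highest-entropy column, which drives that column's entropy
to zero in each child. Clusters whose final abundance falls below a
fraction of the whole data set (0.02% by default) are discarded as noise
— note the floor is *data-set relative*, which is what makes this method
sensitive to pooled versus per-sample processing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .._seq import encode
from ..preprocess import DereplicatedSet
from ._table import FeatureTable, build_table

_GAP = 4  # symbol code for terminal padding
_SYMBOLS = 5

EntropyThresholdRule = Callable[[np.ndarray], float]


def shannon_column_entropy(column: Sequence[str]) -> float:
    """Shannon entropy (natural log) of one alignment column's symbols."""
    values, counts = np.unique(np.asarray(list(column)), return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


def _weighted_column_entropies(mat: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Abundance-weighted per-column entropies for an encoded matrix."""
    n_cols = mat.shape[1]
    counts = np.zeros((n_cols, _SYMBOLS))
    for s in range(_SYMBOLS):
        counts[:, s] = ((mat == s) * weights[:, None]).sum(axis=0)
    totals = counts.sum(axis=1, keepdims=True)
    p = counts / totals
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -np.where(p > 0, p * np.log(p), 0.0).sum(axis=1)
    return h


def fixed_threshold(value: float = 0.2) -> EntropyThresholdRule:
    """A constant per-column entropy threshold in nats (default 0.2).

    The dynamic per-cluster rule of the original entropy-decomposition
    tool is not published in closed form; this fixed default is this
    package's own choice and is pluggable via ``MedParams``.
    """
    return lambda weights: value


@dataclass(frozen=True)
class MedParams:
    min_substantive_abundance_frac: float = 0.0002
    entropy_threshold_rule: EntropyThresholdRule = field(
        default_factory=fixed_threshold
    )

    def __post_init__(self):
        if not 0.0 <= self.min_substantive_abundance_frac < 1.0:
            raise ValueError("abundance fraction must be in [0, 1)")


def med_clusters(
    derep: DereplicatedSet, params: MedParams | None = None
) -> list[list[str]]:
    """Final cluster memberships (lists of member sequences) before the
    abundance floor is applied."""
    params = params or MedParams()
    if not derep.entries:
        return []
    rows_list = _decompose_rows(derep, params)
    return [[derep.entries[r].sequence for r in rows] for rows in rows_list]


def _decompose_rows(derep: DereplicatedSet, params: MedParams) -> list[np.ndarray]:
    max_len = max(len(e.sequence) for e in derep.entries)
    # terminal gap padding to a common alignment length
    mat = np.full((len(derep.entries), max_len), _GAP, dtype=np.uint8)
    for i, e in enumerate(derep.entries):
        mat[i, : len(e.sequence)] = encode(e.sequence)
    weights = np.array([e.abundance for e in derep.entries], dtype=float)

    final_clusters: list[np.ndarray] = []
    stack: list[np.ndarray] = [np.arange(len(derep.entries))]
    while stack:
        rows = stack.pop()
        h = _weighted_column_entropies(mat[rows], weights[rows])
        threshold = params.entropy_threshold_rule(weights[rows])
        col = int(np.argmax(h))
        if h[col] <= threshold or len(rows) == 1:
            final_clusters.append(rows)
            continue
        symbols = mat[rows, col]
        for s in np.unique(symbols):
            stack.append(rows[symbols == s])
    return final_clusters


def decompose_med(
    derep: DereplicatedSet,
    params: MedParams | None = None,
    total_reads: int | None = None,
) -> FeatureTable:
    """Recursive entropy decomposition followed by the abundance floor.

    ``total_reads`` anchors the relative floor; it defaults to the derep
    total but should be the full data-set read count when the caller
    filters or splits the data beforehand.
    """
    params = params or MedParams()
    if not derep.entries:
        return build_table({}, method="med")
    if total_reads is None:
        total_reads = derep.total_abundance
    floor = params.min_substantive_abundance_frac * total_reads
    weights = np.array([e.abundance for e in derep.entries], dtype=float)
    final_clusters = _decompose_rows(derep, params)

    counts: dict[str, dict[str, int]] = {}
    for rows in final_clusters:
        cluster_abundance = weights[rows].sum()
        if cluster_abundance < floor:
            continue
        # rows index an abundance-sorted list, so the minimum index is the
        # most abundant member (ties already lexicographic)
        top = int(rows.min())
        feat_seq = derep.entries[top].sequence
        dest = counts.setdefault(feat_seq, {})
        for r in rows:
            for smp, c in derep.entries[r].sample_counts.items():
                dest[smp] = dest.get(smp, 0) + c
    return build_table(counts, method="med")


def max_cluster_entropy(
    derep: DereplicatedSet, member_sequences: Sequence[str]
) -> float:
    """Largest abundance-weighted column entropy within one cluster
    (diagnostic used by the post-condition tests)."""
    idx = {e.sequence: i for i, e in enumerate(derep.entries)}
    rows = [idx[s] for s in member_sequences]
    max_len = max(len(derep.entries[r].sequence) for r in rows)
    mat = np.full((len(rows), max_len), _GAP, dtype=np.uint8)
    for j, r in enumerate(rows):
        seq = derep.entries[r].sequence
        mat[j, : len(seq)] = encode(seq)
    w = np.array([derep.entries[r].abundance for r in rows], dtype=float)
    return float(_weighted_column_entropies(mat, w).max())
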