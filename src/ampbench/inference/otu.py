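"""Greedy de novo OTU clustering (97%-identity style), with an optional
inline chimera check emulating the stricter OTU pipeline variant."""

from __future__ import annotations

from dataclasses import dataclass

from .._seq import identity, levenshtein
from ..preprocess import DereplicatedSet
from ._table import FeatureTable, build_table
from .chimera import is_bimera


@dataclass(frozen=True)
class OtuParams:
    """radius: the fraction of variation allowed around a seed (0.03 means
    members must be >= 97% identical to their seed)."""

    radius: float = 0.03
    inline_chimera_check: bool = False
    min_parent_fold: float = 2.0

    def __post_init__(self):
        if not 0.0 <= self.radius < 1.0:
            raise ValueError("radius must be in [0, 1)")


def cluster_greedy_otu(
    derep: DereplicatedSet, params: OtuParams | None = None
) -> FeatureTable:
    """Abundance-sorted greedy clustering.

    Each sequence joins the first (i.e. most abundant) existing seed whose
    identity 1 - Levenshtein/alignment_length is >= 1 - radius; otherwise
    it becomes a new seed. The OTU representative is the seed sequence.
    """
    params = params or OtuParams()
    table, _ = _greedy(derep, params, uparse=False)
    return table


def cluster_uparse(
    derep: DereplicatedSet, params: OtuParams | None = None
) -> tuple[FeatureTable, int]:
    """Greedy OTU clustering with an inline de novo bimera check: a
    candidate that is best explained as a crossover of two existing seeds
    is discarded and never becomes a seed. Returns (table, n_chimeric)."""
    params = params or OtuParams(inline_chimera_check=True)
    return _greedy(derep, params, uparse=True)


def _greedy(
    derep: DereplicatedSet, params: OtuParams, uparse: bool
) -> tuple[FeatureTable, int]:
    seeds: list[str] = []
    seed_abund: list[int] = []
    counts: dict[str, dict[str, int]] = {}
    n_chimeric = 0
    for entry in derep.entries:
        assigned = None
        for seed in seeds:
            if identity(entry.sequence, seed) >= 1.0 - params.radius:
                assigned = seed
                break
        if assigned is None:
            if uparse and is_bimera(
                entry.sequence,
                entry.abundance,
                list(zip(seeds, seed_abund)),
                params.min_parent_fold,
            ):
                n_chimeric += 1
                continue
            seeds.append(entry.sequence)
            seed_abund.append(entry.abundance)
            assigned = entry.sequence
        dest = counts.setdefault(assigned, {})
        for s, c in entry.sample_counts.items():
            dest[s] = dest.get(s, 0) + c
    method = "uparse" if uparse else "uclust"
    return build_table(counts, method=method), n_chimeric
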