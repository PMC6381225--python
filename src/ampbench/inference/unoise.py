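"""UNOISE-style ASV denoising with the parametric abundance-skew model.

The error model says a sequence at Levenshtein distance d from a true
template can reach at most a fraction beta(d) = 1 / 2**(alpha*d + 1) of
the template's abundance; anything below that skew is absorbed as noise,
anything above it is called a distinct biological sequence.
"""

from __future__ import annotations

from dataclasses import dataclass

from .._seq import levenshtein
from ..preprocess import DereplicatedSet
from ._table import FeatureTable, build_table


@dataclass(frozen=True)
class UnoiseParams:
    alpha: float = 2.0

    def __post_init__(self):
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")


def unoise_beta(d: int, alpha: float = 2.0) -> float:
    """Maximum abundance skew beta(d) = 1 / 2**(alpha*d + 1)."""
    if d < 0:
        raise ValueError("distance must be >= 0")
    exponent = alpha * d + 1.0
    if exponent > 1074.0:  # below double-precision underflow
        return 0.0
    return 1.0 / 2.0**exponent


def denoise_unoise(
    derep: DereplicatedSet, params: UnoiseParams | None = None
) -> FeatureTable:
    """Greedy centroid formation in decreasing abundance order.

    A sequence joins the most abundant centroid c whose error model is
    consistent with it — abundance(s)/abundance(c) <= beta(d(s, c)) — and
    becomes a new centroid when no centroid qualifies. Centroids are kept
    in decreasing abundance, so the first qualifying one is taken (ties
    already resolved lexicographically by the dereplication ordering).
    """
    params = params or UnoiseParams()
    centroids: list[tuple[str, int]] = []  # (sequence, abundance at seeding)
    counts: dict[str, dict[str, int]] = {}
    import math

    for entry in derep.entries:
        assigned = None
        for cseq, cab in centroids:
            skew = entry.abundance / cab
            # skew <= beta(d) iff d <= (log2(1/skew) - 1)/alpha: band the
            # alignment at that distance instead of computing it in full
            d_max = math.floor((math.log2(1.0 / skew) - 1.0) / params.alpha)
            if d_max < 0:
                continue
            d = levenshtein(entry.sequence, cseq, max_dist=d_max)
            if d <= d_max and skew <= unoise_beta(d, params.alpha):
                assigned = cseq
                break
        if assigned is None:
            centroids.append((entry.sequence, entry.abundance))
            assigned = entry.sequence
        dest = counts.setdefault(assigned, {})
        for s, c in entry.sample_counts.items():
            dest[s] = dest.get(s, 0) + c
    return build_table(counts, method="unoise")
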