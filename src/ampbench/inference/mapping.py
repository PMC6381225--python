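"""Map reads (or dereplicated uniques) back onto inferred features to
obtain sample-wise abundances."""

from __future__ import annotations

from .._seq import identity, levenshtein
from ..preprocess import DereplicatedSet
from ._table import FeatureTable, build_table


def map_reads_to_features(
    derep: DereplicatedSet,
    table: FeatureTable,
    radius: float = 0.0,
) -> tuple[FeatureTable, int]:
    """Assign each unique sequence to the nearest feature within radius.

    ``radius`` is the allowed fraction of variation (0.03 for OTU-style
    mapping); 0 demands an exact match, the default for ASV features.
    Ties go to the more abundant feature. Returns the re-counted table
    and the number of unmapped reads.
    """
    feats = table.sequences()
    counts: dict[str, dict[str, int]] = {s: {} for s in feats}
    unmapped = 0
    for entry in derep.entries:
        best = None
        if entry.sequence in counts:
            best = entry.sequence
        elif radius > 0:
            best_d = None
            for fs in feats:  # decreasing abundance: ties keep the first
                if identity(entry.sequence, fs) >= 1.0 - radius:
                    d = levenshtein(entry.sequence, fs)
                    if best_d is None or d < best_d:
                        best, best_d = fs, d
        if best is None:
            unmapped += entry.abundance
            continue
        dest = counts[best]
        for s, c in entry.sample_counts.items():
            dest[s] = dest.get(s, 0) + c
    return (
        build_table(
            {s: c for s, c in counts.items() if sum(c.values()) > 0},
            method=table.method,
            scope=table.scope,
        ),
        unmapped,
    )
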