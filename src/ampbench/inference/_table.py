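"""The feature table shared by every inference method."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd


@dataclass(frozen=True)
class Feature:
    sequence: str
    counts: dict[str, int] = field(compare=False)

    @property
    def abundance(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class FeatureTable:
    """Inferred ASV/OTU sequences x samples -> integer read counts.

    Features are ordered by decreasing total abundance (ties broken
    lexicographically), duplicate sequences are rejected, and negative
    counts are rejected.
    """

    features: tuple[Feature, ...]
    method: str = ""
    scope: str = "pooled"

    def __post_init__(self):
        seqs = [f.sequence for f in self.features]
        if len(set(seqs)) != len(seqs):
            raise ValueError("duplicate feature sequences")
        for f in self.features:
            if any(c < 0 for c in f.counts.values()):
                raise ValueError("negative count")

    def __len__(self) -> int:
        return len(self.features)

    @property
    def total_count(self) -> int:
        return sum(f.abundance for f in self.features)

    def sequences(self) -> list[str]:
        return [f.sequence for f in self.features]

    def samples(self) -> list[str]:
        out: set[str] = set()
        for f in self.features:
            out.update(f.counts)
        return sorted(out)

    def to_dataframe(self) -> pd.DataFrame:
        samples = self.samples()
        rows = []
        for i, f in enumerate(self.features):
            row = {"feature_id": f"{self.method or 'feature'}_{i + 1}",
                   "sequence": f.sequence}
            for s in samples:
                row[s] = f.counts.get(s, 0)
            rows.append(row)
        return pd.DataFrame(rows)


def build_table(
    raw: dict[str, dict[str, int]], method: str, scope: str = "pooled"
) -> FeatureTable:
    """Assemble a FeatureTable from {sequence: {sample: count}}, dropping
    zero-total features and applying the canonical ordering."""
    feats = [
        Feature(seq, dict(counts))
        for seq, counts in raw.items()
        if sum(counts.values()) > 0
    ]
    feats.sort(key=lambda f: (-f.abundance, f.sequence))
    return FeatureTable(tuple(feats), method=method, scope=scope)
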