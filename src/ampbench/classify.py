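"""Five-category classification of inferred features.

Every feature of a table is placed in exactly one category, evaluated in
decreasing feature abundance with the precedence:

1. **Reference** — exact match to a known-community allele;
2. **RefNoisy** — within ``max_noisy_dist`` (Levenshtein, default 10 nt)
   of a strictly more abundant Reference-classified feature;
3. **Contaminant** — exact match to a contaminant-database sequence;
4. **ContamNoisy** — within ``max_noisy_dist`` of a Contaminant-classified
   feature (no abundance ordering required);
5. **Other** — everything else (unexplained noise, residual chimeras).

The contaminant database here is a supplied FASTA/pool of sequences; on
synthetic data it is the simulator's own contaminant pool, which makes
Reference/Contaminant unambiguous whenever the two pools are well
separated in sequence space.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import pandas as pd

from ._seq import levenshtein
from .inference import FeatureTable
from .simulate import ContaminantPool, ReferenceSet


class Category(str, Enum):
    REFERENCE = "Reference"
    REF_NOISY = "RefNoisy"
    CONTAMINANT = "Contaminant"
    CONTAM_NOISY = "ContamNoisy"
    OTHER = "Other"


CATEGORIES = tuple(c.value for c in Category)


@dataclass(frozen=True)
class ClassifyParams:
    max_noisy_dist: int = 10
    #: measure the RefNoisy distance to the more abundant Reference
    #: *feature* (default) rather than to the reference FASTA directly
    require_lower_abundance_for_noisy: bool = True

    def __post_init__(self):
        if self.max_noisy_dist < 0:
            raise ValueError("max_noisy_dist must be >= 0")


@dataclass(frozen=True)
class ClassifiedFeature:
    sequence: str
    counts: dict[str, int]
    category: Category
    matched_id: str | None
    distance: int | None

    @property
    def abundance(self) -> int:
        return sum(self.counts.values())


def classify_features(
    table: FeatureTable,
    refs: ReferenceSet,
    contamdb: ContaminantPool,
    params: ClassifyParams | None = None,
) -> list[ClassifiedFeature]:
    params = params or ClassifyParams()
    if not refs.strains:
        raise ValueError("empty reference set")
    ref_lookup = {seq: aid for aid, seq in refs.alleles()}
    contam_lookup = {seq: cid for cid, seq, _ in contamdb.members}

    feats = list(table.features)  # decreasing abundance already
    results: list[ClassifiedFeature | None] = [None] * len(feats)

    # pass 1: exact matches are order-independent
    exact_ref = {i for i, f in enumerate(feats) if f.sequence in ref_lookup}
    exact_contam = {
        i for i, f in enumerate(feats) if f.sequence in contam_lookup
    }

    # pass 2: precedence, in decreasing abundance
    contam_classified: list[int] = []
    refnoisy_pending: list[int] = []
    for i, f in enumerate(feats):
        if i in exact_ref:
            results[i] = ClassifiedFeature(
                f.sequence, f.counts, Category.REFERENCE,
                ref_lookup[f.sequence], 0,
            )
            continue
        noisy = _nearest_reference_feature(
            i, feats, exact_ref, params
        )
        if noisy is not None:
            j, d = noisy
            results[i] = ClassifiedFeature(
                f.sequence, f.counts, Category.REF_NOISY,
                ref_lookup[feats[j].sequence], d,
            )
            continue
        if i in exact_contam:
            results[i] = ClassifiedFeature(
                f.sequence, f.counts, Category.CONTAMINANT,
                contam_lookup[f.sequence], 0,
            )
            contam_classified.append(i)
            continue
        refnoisy_pending.append(i)

    # pass 3: ContamNoisy needs the final set of Contaminant features,
    # which pass 2 has now fixed
    for i in refnoisy_pending:
        f = feats[i]
        best: tuple[int, int] | None = None
        for j in contam_classified:
            d = levenshtein(
                f.sequence, feats[j].sequence, max_dist=params.max_noisy_dist
            )
            if d <= params.max_noisy_dist and (best is None or d < best[1]):
                best = (j, d)
        if best is not None:
            j, d = best
            results[i] = ClassifiedFeature(
                f.sequence, f.counts, Category.CONTAM_NOISY,
                contam_lookup[feats[j].sequence], d,
            )
        else:
            results[i] = ClassifiedFeature(
                f.sequence, f.counts, Category.OTHER, None, None
            )
    return [r for r in results if r is not None]


def _nearest_reference_feature(i, feats, exact_ref, params):
    """Closest more abundant Reference-classified feature within the noisy
    radius, or None."""
    f = feats[i]
    best: tuple[int, int] | None = None
    for j in exact_ref:
        other = feats[j]
        if params.require_lower_abundance_for_noisy and not (
            other.abundance > f.abundance
        ):
            continue
        d = levenshtein(f.sequence, other.sequence, max_dist=params.max_noisy_dist)
        if d <= params.max_noisy_dist and (best is None or d < best[1]):
            best = (j, d)
    return best


def category_counts(classified: Iterable[ClassifiedFeature]) -> dict[str, int]:
    """Feature counts per category; always contains all five keys."""
    out = {c: 0 for c in CATEGORIES}
    for cf in classified:
        out[cf.category.value] += 1
    return out


def category_read_fractions(
    classified: Sequence[ClassifiedFeature],
) -> dict[str, float]:
    """Fraction of mapped reads per category (sums to 1)."""
    out = {c: 0 for c in CATEGORIES}
    for cf in classified:
        out[cf.category.value] += cf.abundance
    total = sum(out.values())
    if total == 0:
        raise ValueError("no reads in classified features")
    return {c: n / total for c, n in out.items()}


def classification_table(
    classified: Sequence[ClassifiedFeature],
) -> pd.DataFrame:
    samples = sorted({s for cf in classified for s in cf.counts})
    rows = []
    for i, cf in enumerate(classified):
        row = {
            "feature_id": f"f{i + 1}",
            "sequence": cf.sequence,
            "category": cf.category.value,
            "matched_id": cf.matched_id or "",
            "distance": "" if cf.distance is None else cf.distance,
        }
        for s in samples:
            row[s] = cf.counts.get(s, 0)
        rows.append(row)
    return pd.DataFrame(rows)
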