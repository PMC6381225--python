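"""Summary statistics: recall, precision, read fractions, alpha diversity.

Percent statistics are reported as integers rounded half-away-from-zero
(21/40 -> 52.5 -> 53); banker's rounding would not reproduce the published
mock-community precision tables this package checks itself against.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .classify import CATEGORIES, Category, ClassifiedFeature, category_read_fractions


def round_half_up_percent(numerator: int, denominator: int) -> int:
    """round_half_up(100 * numerator / denominator), in exact integer
    arithmetic so 0.5 cases never depend on float representation."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if numerator < 0:
        raise ValueError("numerator must be non-negative")
    return (200 * numerator + denominator) // (2 * denominator)


# ---------------------------------------------------------------------------
# recall / precision


def recall(detected_strains: int, expected_strains: int) -> int:
    """Percent of known community members detected.

    A strain counts as detected when any of its alleles is recovered, so
    the denominator is the strain count, not the allele count.
    """
    if not 0 <= detected_strains <= expected_strains:
        raise ValueError("need 0 <= detected <= expected")
    return round_half_up_percent(detected_strains, expected_strains)


def overall_precision(counts: Mapping[str, int]) -> int:
    """Percent of features that match the known community exactly; every
    non-Reference feature counts as a false positive."""
    total = sum(counts.get(c, 0) for c in CATEGORIES)
    if total == 0:
        raise ValueError("empty feature table")
    return round_half_up_percent(counts.get("Reference", 0), total)


def technical_precision(counts: Mapping[str, int]) -> int:
    """Precision counting only technical noise (RefNoisy) as false
    positives; Contaminant/ContamNoisy/Other are excluded as ambiguous."""
    ref = counts.get("Reference", 0)
    noisy = counts.get("RefNoisy", 0)
    if ref + noisy == 0:
        return 100
    return round_half_up_percent(ref, ref + noisy)


def detected_strains(
    classified: Sequence[ClassifiedFeature], strain_of_allele
) -> set[str]:
    """Strains with at least one Reference-classified feature."""
    return {
        strain_of_allele(cf.matched_id)
        for cf in classified
        if cf.category is Category.REFERENCE
    }


def reference_read_fraction(
    classified: Sequence[ClassifiedFeature],
) -> float:
    """Percent of mapped reads in Reference features, to 1 decimal."""
    fracs = category_read_fractions(classified)
    return round(1000.0 * fracs["Reference"]) / 10.0


# ---------------------------------------------------------------------------
# alpha diversity


def _props(counts: Sequence[float]) -> np.ndarray:
    arr = np.asarray(counts, dtype=float)
    arr = arr[arr > 0]
    if arr.size == 0:
        raise ValueError("no positive counts")
    return arr / arr.sum()


def shannon(counts: Sequence[float]) -> float:
    """Shannon index H = -sum p ln p (natural log)."""
    p = _props(counts)
    return float(-(p * np.log(p)).sum())


def inv_simpson(counts: Sequence[float]) -> float:
    """Inverse Simpson index 1 / sum p^2."""
    p = _props(counts)
    return float(1.0 / (p**2).sum())


def fisher_alpha(s: int, n: int, tol: float = 1e-9) -> float:
    """The alpha of Fisher's log-series: solves S = alpha * ln(1 + N/alpha).

    Undefined (raises) for S = 0 or S >= N, where the log-series model
    degenerates.
    """
    if s <= 0:
        raise ValueError("Fisher alpha undefined for zero features")
    if s >= n:
        raise ValueError("Fisher alpha diverges as S approaches N")

    def f(a: float) -> float:
        return a * np.log1p(n / a) - s

    lo = 1e-12
    hi = 1.0
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e12:  # pragma: no cover - s >= n is rejected above
            raise RuntimeError("failed to bracket Fisher alpha")
    return float(optimize.brentq(f, lo, hi, xtol=tol))


def alpha_diversity(counts: Sequence[float]) -> dict[str, float | None]:
    """Shannon / inverse Simpson / Fisher triple for one sample's counts."""
    s = int(sum(1 for c in counts if c > 0))
    n = int(sum(counts))
    out: dict[str, float | None] = {
        "shannon": shannon(counts),
        "inv_simpson": inv_simpson(counts),
    }
    try:
        out["fisher"] = fisher_alpha(s, n)
    except ValueError:
        out["fisher"] = None
    return out


def expected_alpha(
    proportions: Sequence[float], n_reads: int | None = None
) -> dict[str, float | None]:
    """Alpha diversity expected from the design's strain proportions.

    Fisher's alpha additionally needs a library size; it is None when
    ``n_reads`` is omitted or fewer than two strains are present (the
    log-series fit is meaningless for a single-species design).
    """
    p = _props(proportions)
    out: dict[str, float | None] = {
        "shannon": shannon(p),
        "inv_simpson": inv_simpson(p),
        "fisher": None,
    }
    if n_reads is not None and p.size >= 2 and p.size < n_reads:
        out["fisher"] = fisher_alpha(p.size, n_reads)
    return out


# ---------------------------------------------------------------------------
# depth normalization and signal/noise summaries


def normalized_feature_total(
    total_features: int,
    sample_reads: int,
    median_reads: float,
    invert: bool = False,
) -> float:
    """Depth-adjusted feature total.

    The default multiplies by sample reads and divides by the median read
    count across samples. The ``invert`` option divides by sample reads
    instead, which *corrects* for depth rather than amplifying it; both
    forms are provided because either convention appears in practice.
    """
    if sample_reads <= 0 or median_reads <= 0:
        raise ValueError("read counts must be positive")
    ratio = sample_reads / median_reads
    return total_features * (1.0 / ratio if invert else ratio)


@dataclass(frozen=True)
class GroupSummary:
    n: int
    median: float
    q1: float
    q3: float

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1


def signal_noise_summary(
    classified: Sequence[ClassifiedFeature],
) -> dict[str, GroupSummary | float | None]:
    """log10-abundance distribution summaries for Reference (signal)
    versus all non-Reference (noise) features.

    Zero-abundance features are excluded. ``gap`` is the difference of the
    group medians; ``overlap`` is min(signal) - Q3(noise); both are None
    when either group is empty.
    """
    sig = [cf.abundance for cf in classified
           if cf.category is Category.REFERENCE and cf.abundance > 0]
    noi = [cf.abundance for cf in classified
           if cf.category is not Category.REFERENCE and cf.abundance > 0]

    def summarize(vals: list[int]) -> GroupSummary | None:
        if not vals:
            return None
        logs = np.log10(np.asarray(vals, dtype=float))
        q1, med, q3 = np.percentile(logs, [25, 50, 75])
        return GroupSummary(n=len(vals), median=float(med), q1=float(q1), q3=float(q3))

    signal = summarize(sig)
    noise = summarize(noi)
    gap = overlap = None
    if signal is not None and noise is not None:
        gap = signal.median - noise.median
        overlap = float(np.log10(min(sig))) - noise.q3
    return {"signal": signal, "noise": noise, "gap": gap, "overlap": overlap}


# ---------------------------------------------------------------------------
# published mock-community tables (packaged transcriptions)


def load_mock_category_counts() -> pd.DataFrame:
    """Published per-category feature counts for four high-biomass mock
    communities (8/21/57/53-strain standards) under all six methods."""
    ref = importlib.resources.files("ampbench.data") / "mock_category_counts.tsv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def load_mock_precision() -> pd.DataFrame:
    """Published recall / overall precision / technical precision for the
    same communities and methods."""
    ref = importlib.resources.files("ampbench.data") / "mock_precision.tsv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")
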