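"""The two simulation studies at the heart of the benchmark.

* :func:`parameter_recovery_study` — high-biomass conditions: a uniform
  8-strain community, deep sequencing at Q30, no contamination. Every
  abundance-aware method should recover the community exactly; a
  similarity-radius method loses strains that sit inside its radius
  (:func:`otu_lumping_study`).
* :func:`dilution_trend_study` — a 9-sample 3-fold dilution series with a
  fixed-mass contaminant pool: contaminant features rise along the series
  and the signal/noise abundance separation collapses.

Study sizes are desk-scale by design (tens of thousands of reads rather
than hundreds of thousands); the qualitative contrasts they probe are
depth-robust.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .classify import category_counts, classify_features
from .inference import OtuParams, cluster_greedy_otu, run_method
from .metrics import (
    detected_strains,
    recall,
    signal_noise_summary,
    technical_precision,
)
from .preprocess import PreprocessParams, dereplicate, preprocess_reads
from .simulate import (
    ContaminantPool,
    DilutionDesign,
    ErrorModel,
    QualityProfile,
    ReferenceSet,
    StrainReference,
    generate_contaminant_pool,
    generate_reference_set,
    simulate_dilution_series,
)
from ._seq import encode, decode

ASV_METHODS = ("unoise", "deblur", "dada", "med")
TREND_METHODS = ("unoise", "deblur", "dada")


def _spawn_seeds(seed: int, n: int) -> list[int]:
    return [
        int(ss.generate_state(1)[0] % (2**31))
        for ss in np.random.SeedSequence(seed).spawn(n)
    ]


def q30_error_model(read_length: int = 251) -> ErrorModel:
    """Flat Q30 on both mates (0.001 substitutions/base), no chimeras."""
    return ErrorModel(
        quality_profile_fwd=QualityProfile.flat(30.0, read_length),
        quality_profile_rev=QualityProfile.flat(30.0, read_length),
        chimera_rate=0.0,
    )


def parameter_recovery_study(
    seed: int,
    depth: int = 50_000,
    n_strains: int = 8,
    methods: Sequence[str] = ASV_METHODS,
) -> dict:
    """Simulate clean high-biomass data and score every method against
    the known community."""
    s_refs, s_reads = _spawn_seeds(seed, 2)
    refs = generate_reference_set(
        n_strains=n_strains, amplicon_len=252, min_pairwise_dist=20, seed=s_refs
    )
    design = DilutionDesign(
        n_samples=1, contaminant_mass=0.0, depth_per_sample=(depth,)
    )
    contam = ContaminantPool(())
    reads = simulate_dilution_series(
        refs, contam, design, q30_error_model(), seed=s_reads
    )[1]
    merged, ledger = preprocess_reads(reads, PreprocessParams())
    derep = dereplicate(merged, "pooled")
    refs_region = refs.trimmed(PreprocessParams().head_trim)
    out = {
        "refs": refs,
        "refs_region": refs_region,
        "contam": contam,
        "derep": derep,
        "ledger": ledger,
        "tables": {},
        "metrics": {},
    }
    for method in methods:
        table = run_method(method, derep, total_reads=derep.total_abundance)
        classified = classify_features(table, refs_region, contam)
        counts = category_counts(classified)
        det = detected_strains(classified, refs_region.strain_of_allele)
        out["tables"][method] = table
        out["metrics"][method] = {
            "classified": classified,
            "counts": counts,
            "n_detected_strains": len(det),
            "recall_pct": recall(min(len(det), n_strains), n_strains),
            "technical_precision_pct": technical_precision(counts),
        }
    return out


def otu_lumping_study(
    seed: int, depth: int = 10_000, n_diffs: int = 5
) -> dict:
    """Two strains ~2% apart under greedy 97%-identity clustering.

    The pairwise distance (default 5 substitutions over the 222-nt merged
    region, 2.3%) sits inside the 3% radius, so the radius-based method
    merges the strains and recall drops below 100%.
    """
    s_refs, s_reads = _spawn_seeds(seed, 2)
    base = generate_reference_set(1, 252, 20, seed=s_refs)
    a = base.strains[0].alleles[0]
    arr = encode(a).copy()
    positions = np.linspace(25, 225, n_diffs).astype(int)
    arr[positions] = (arr[positions] + 1) % 4
    b = decode(arr)
    refs = ReferenceSet(
        (
            StrainReference("strainA", (a,), 0.5),
            StrainReference("strainB", (b,), 0.5),
        )
    )
    design = DilutionDesign(
        n_samples=1, contaminant_mass=0.0, depth_per_sample=(depth,)
    )
    reads = simulate_dilution_series(
        refs, ContaminantPool(()), design, q30_error_model(), seed=s_reads
    )[1]
    merged, _ = preprocess_reads(reads, PreprocessParams())
    derep = dereplicate(merged, "pooled")
    table = cluster_greedy_otu(derep, OtuParams(radius=0.03))
    refs_region = refs.trimmed(15)
    classified = classify_features(table, refs_region, ContaminantPool(()))
    det = detected_strains(classified, refs_region.strain_of_allele)
    return {
        "n_features": len(table),
        "n_detected_strains": len(det),
        "recall_pct": recall(min(len(det), 2), 2),
        "table": table,
    }


def dilution_trend_study(
    seed: int,
    depth: int = 5_000,
    n_contaminants: int = 30,
    methods: Sequence[str] = TREND_METHODS,
    chimera_rate: float = 0.005,
) -> dict:
    """Simulate the full dilution series and track per-method category
    counts and signal/noise separation along the dilution axis."""
    s_refs, s_contam, s_reads = _spawn_seeds(seed, 3)
    refs = generate_reference_set(8, 252, 20, seed=s_refs)
    contam = generate_contaminant_pool(
        n_contaminants, refs, amplicon_len=252, min_dist=20, seed=s_contam
    )
    design = DilutionDesign(n_samples=9, fold=3.0, contaminant_mass=0.001)
    error_model = ErrorModel(chimera_rate=chimera_rate)
    reads = simulate_dilution_series(
        refs, contam, design, error_model, seed=s_reads, default_depth=depth
    )
    merged = []
    for k in sorted(reads):
        m, _ = preprocess_reads(reads[k], PreprocessParams())
        merged.extend(m)
    derep_by_sample = dereplicate(merged, "per-sample")
    head = PreprocessParams().head_trim
    refs_region = refs.trimmed(head)
    contam_region = contam.trimmed(head)

    results: dict[str, dict[int, dict]] = {m: {} for m in methods}
    for method in methods:
        for k in range(1, design.n_samples + 1):
            ds = derep_by_sample[f"s{k}"]
            table = run_method(method, ds, total_reads=ds.total_abundance)
            classified = classify_features(table, refs_region, contam_region)
            results[method][k] = {
                "table": table,
                "counts": category_counts(classified),
                "snr": signal_noise_summary(classified),
            }
    return {
        "refs": refs,
        "refs_region": refs_region,
        "contam": contam,
        "contam_region": contam_region,
        "design": design,
        "derep_by_sample": derep_by_sample,
        "results": results,
    }


def contaminant_trend_spearman(study: dict, method: str) -> float:
    ks = sorted(study["results"][method])
    counts = [study["results"][method][k]["counts"]["Contaminant"] for k in ks]
    return float(stats.spearmanr(ks, counts).statistic)


def signal_noise_gaps(study: dict, method: str) -> list[float | None]:
    ks = sorted(study["results"][method])
    return [study["results"][method][k]["snr"]["gap"] for k in ks]
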