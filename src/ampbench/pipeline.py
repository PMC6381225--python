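"""End-to-end orchestration: simulate -> preprocess -> infer -> classify
-> metrics, with strict configuration, per-stage seed fan-out, and a run
ledger enforcing read conservation.

The pipeline is fully deterministic for a fixed config + seed: per-stage
seeds are spawned from the master seed with ``numpy.random.SeedSequence``,
so stages are independently re-runnable, and no output embeds timestamps.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml

from . import io
from .classify import (
    CATEGORIES,
    ClassifyParams,
    classification_table,
    classify_features,
    category_counts,
)
from .inference import (
    DadaParams,
    DeblurParams,
    FeatureTable,
    MedParams,
    METHODS,
    OtuParams,
    UnoiseParams,
    build_table,
    run_method,
)
from .metrics import (
    alpha_diversity,
    expected_alpha,
    overall_precision,
    recall,
    reference_read_fraction,
    signal_noise_summary,
    technical_precision,
)
from .metrics import detected_strains as _detected_strains
from .preprocess import PreprocessParams, dereplicate, preprocess_reads
from .simulate import (
    ContaminantPool,
    DilutionDesign,
    ErrorModel,
    QualityProfile,
    ReferenceSet,
    expected_contaminant_fraction,
    generate_contaminant_pool,
    generate_reference_set,
    simulate_dilution_series,
    write_origin_table,
    write_sample_fastq,
)

Scope = Literal["per-sample", "pooled", "both"]


@dataclass(frozen=True)
class CommunityConfig:
    n_strains: int = 8
    amplicon_len: int = 252
    min_pairwise_dist: int = 20
    allele_spec: dict[str, int] = field(default_factory=dict)


@dataclass(frozen=True)
class ContaminantConfig:
    n_contaminants: int = 30
    min_dist: int = 20
    mass_ratio: float = 0.75


@dataclass(frozen=True)
class ErrorConfig:
    read_length: int = 251
    q_start_fwd: float = 37.0
    q_end_fwd: float = 27.0
    q_start_rev: float = 35.0
    q_end_rev: float = 24.0
    jitter_sd: float = 2.0
    chimera_rate: float = 0.005

    def build(self) -> ErrorModel:
        return ErrorModel(
            quality_profile_fwd=QualityProfile(
                self.read_length, self.q_start_fwd, self.q_end_fwd, self.jitter_sd
            ),
            quality_profile_rev=QualityProfile(
                self.read_length, self.q_start_rev, self.q_end_rev, self.jitter_sd
            ),
            chimera_rate=self.chimera_rate,
        )


@dataclass(frozen=True)
class DilutionConfig:
    n_samples: int = 9
    fold: float = 3.0
    template_mass0: float = 1.0
    contaminant_mass: float = 0.001
    depth_per_sample: tuple[int, ...] = ()
    default_depth: int = 10_000

    def build(self) -> DilutionDesign:
        return DilutionDesign(
            n_samples=self.n_samples,
            fold=self.fold,
            template_mass0=self.template_mass0,
            contaminant_mass=self.contaminant_mass,
            depth_per_sample=tuple(self.depth_per_sample),
        )


@dataclass(frozen=True)
class RunConfig:
    seed: int
    methods: tuple[str, ...] = METHODS
    scope: Scope = "per-sample"
    branch: Literal["merged", "dada"] = "merged"
    community: CommunityConfig = CommunityConfig()
    contaminants: ContaminantConfig = ContaminantConfig()
    dilution: DilutionConfig = DilutionConfig()
    errors: ErrorConfig = ErrorConfig()
    preprocess: PreprocessParams = PreprocessParams()
    otu: OtuParams = OtuParams()
    unoise: UnoiseParams = UnoiseParams()
    deblur: DeblurParams = DeblurParams()
    dada: DadaParams = DadaParams()
    med: MedParams = MedParams()
    classify: ClassifyParams = ClassifyParams()

    def __post_init__(self):
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")

    def config_hash(self) -> str:
        blob = json.dumps(_as_plain(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


_NESTED = {
    "community": CommunityConfig,
    "contaminants": ContaminantConfig,
    "dilution": DilutionConfig,
    "errors": ErrorConfig,
    "preprocess": PreprocessParams,
    "otu": OtuParams,
    "unoise": UnoiseParams,
    "deblur": DeblurParams,
    "dada": DadaParams,
    "med": MedParams,
    "classify": ClassifyParams,
}


def _build_strict(cls, data: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    coerced = {
        k: tuple(v) if isinstance(v, list) else v for k, v in data.items()
    }
    return cls(**coerced)


def load_config(path: str | Path) -> RunConfig:
    """Parse a YAML run configuration with a strict schema: any unknown
    key fails before any stage runs."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "seed" not in raw:
        raise ValueError("config must set an explicit seed")
    kwargs = {}
    for key, value in raw.items():
        if key in _NESTED:
            if not isinstance(value, dict):
                raise ValueError(f"{key} must be a mapping")
            kwargs[key] = _build_strict(_NESTED[key], value)
        elif key in {"seed", "methods", "scope", "branch"}:
            kwargs[key] = tuple(value) if isinstance(value, list) else value
        else:
            raise ValueError(f"unknown config key: {key}")
    return RunConfig(**kwargs)


def _as_plain(obj):
    if dataclasses.is_dataclass(obj):
        return {
            f.name: _as_plain(getattr(obj, f.name))
            for f in dataclasses.fields(obj)
        }
    if isinstance(obj, (list, tuple)):
        return [_as_plain(x) for x in obj]
    if isinstance(obj, dict):
        return {k: _as_plain(v) for k, v in obj.items()}
    if callable(obj):
        return getattr(obj, "__name__", "callable")
    return obj


# ---------------------------------------------------------------------------
# stages


def simulate_stage(config: RunConfig):
    """Ground truth + reads. Seeds fan out as (refs, contaminants, reads)."""
    s_refs, s_contam, s_reads = (
        int(ss.generate_state(1)[0] % (2**31))
        for ss in np.random.SeedSequence(config.seed).spawn(3)
    )
    refs = generate_reference_set(
        n_strains=config.community.n_strains,
        amplicon_len=config.community.amplicon_len,
        min_pairwise_dist=config.community.min_pairwise_dist,
        allele_spec=config.community.allele_spec,
        seed=s_refs,
    )
    contam = generate_contaminant_pool(
        config.contaminants.n_contaminants,
        refs,
        amplicon_len=config.community.amplicon_len,
        min_dist=config.contaminants.min_dist,
        mass_ratio=config.contaminants.mass_ratio,
        seed=s_contam,
    )
    design = config.dilution.build()
    reads = simulate_dilution_series(
        refs, contam, design, config.errors.build(), seed=s_reads,
        default_depth=config.dilution.default_depth,
    )
    return refs, contam, design, reads


def infer_tables(
    config: RunConfig,
    derep_pooled,
    derep_by_sample,
    total_reads: int,
    scope: str,
) -> dict[str, FeatureTable]:
    """Run every configured method under one scope."""
    kwargs = dict(
        otu_params=config.otu,
        unoise_params=config.unoise,
        deblur_params=config.deblur,
        dada_params=config.dada,
        med_params=config.med,
    )
    tables: dict[str, FeatureTable] = {}
    for method in config.methods:
        if method == "dada":
            # always per-sample: this method is scope-invariant
            tables[method] = run_method(method, derep_by_sample, **kwargs)
        elif scope == "pooled":
            tables[method] = run_method(
                method, derep_pooled, total_reads=total_reads, **kwargs
            )
        else:
            merged: dict[str, dict[str, int]] = {}
            for sample in sorted(derep_by_sample):
                ds = derep_by_sample[sample]
                t = run_method(
                    method, ds, total_reads=ds.total_abundance, **kwargs
                )
                for f in t.features:
                    dest = merged.setdefault(f.sequence, {})
                    for s, c in f.counts.items():
                        dest[s] = dest.get(s, 0) + c
            tables[method] = build_table(merged, method=method, scope=scope)
    return tables


def per_sample_table(table: FeatureTable, sample: str) -> FeatureTable:
    """Restrict a table to one sample's nonzero features."""
    raw = {
        f.sequence: {sample: f.counts.get(sample, 0)}
        for f in table.features
        if f.counts.get(sample, 0) > 0
    }
    return build_table(raw, method=table.method, scope=table.scope)


def analyze_tables(
    tables: dict[str, FeatureTable],
    refs: ReferenceSet,
    contam: ContaminantPool,
    design: DilutionDesign,
    classify_params: ClassifyParams,
    samples: list[str],
) -> pd.DataFrame:
    """Per (sample, method) metrics report rows."""
    n_strains = len(refs.strains)
    proportions = [s.genomic_proportion for s in refs.strains]
    rows = []
    for method, table in tables.items():
        for sample in samples:
            sub = per_sample_table(table, sample)
            if len(sub) == 0:
                continue
            classified = classify_features(sub, refs, contam, classify_params)
            counts = category_counts(classified)
            det = _detected_strains(classified, refs.strain_of_allele)
            snr = signal_noise_summary(classified)
            alpha = alpha_diversity([f.abundance for f in sub.features])
            k = int(sample.lstrip("s"))
            exp_alpha = expected_alpha(proportions, sub.total_count)
            row = {
                "sample": sample,
                "dilution_step": k,
                "relative_concentration": design.relative_concentration(k),
                "expected_contaminant_fraction": expected_contaminant_fraction(
                    design, k
                ),
                "method": method,
                "scope": table.scope,
                "n_features": len(sub),
                "total_reads": sub.total_count,
                "recall_pct": recall(min(len(det), n_strains), n_strains),
                "overall_precision_pct": overall_precision(counts),
                "technical_precision_pct": technical_precision(counts),
                "reference_read_fraction_pct": reference_read_fraction(classified),
                "signal_noise_gap_log10": snr["gap"],
            }
            for cat in CATEGORIES:
                row[f"n_{cat}"] = counts[cat]
            for name, val in alpha.items():
                row[f"alpha_{name}"] = val
            for name, val in exp_alpha.items():
                row[f"expected_alpha_{name}"] = val
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# entry points


def run_all(config: RunConfig, outdir: str | Path) -> pd.DataFrame:
    """Execute every stage and write all artifacts under ``outdir``.

    Artifacts: reference/contaminant FASTA, per-sample FASTQ pairs, the
    read-origin truth table, per-method feature FASTA + count TSV,
    per-method classification TSV, the metrics report TSV, and a JSON run
    ledger with provenance (config hash, seed, stage conservation).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    refs, contam, design, reads = simulate_stage(config)
    head = config.preprocess.head_trim
    refs_region = refs.trimmed(head)
    contam_region = contam.trimmed(head)
    refs.write_fasta(outdir / "references.fasta")
    refs_region.write_fasta(outdir / "references_region.fasta")
    contam_region.write_fasta(outdir / "contaminants_region.fasta")
    contam.write_fasta(outdir / "contaminants.fasta")
    all_reads = []
    for k in sorted(reads):
        write_sample_fastq(reads[k], outdir / "fastq", k)
        all_reads.extend(reads[k])
    write_origin_table(all_reads, outdir / "read_origins.tsv")

    merged_all = []
    ledger_stages = {}
    for k in sorted(reads):
        merged, ledger = preprocess_reads(
            reads[k], config.preprocess, branch=config.branch
        )
        merged_all.extend(merged)
        ledger_stages[f"s{k}"] = dataclasses.asdict(ledger)
    derep_pooled = dereplicate(merged_all, "pooled")
    derep_by_sample = dereplicate(merged_all, "per-sample")
    total_reads = derep_pooled.total_abundance

    scopes = (
        ["per-sample", "pooled"] if config.scope == "both" else [config.scope]
    )
    samples = sorted({r.sample for r in merged_all}, key=lambda s: int(s[1:]))
    reports = []
    method_ledger = {}
    for scope in scopes:
        tables = infer_tables(
            config, derep_pooled, derep_by_sample, total_reads, scope
        )
        for method, table in tables.items():
            tag = f"{method}_{scope}"
            io.write_fasta(
                outdir / f"features_{tag}.fasta",
                [(f"{method}_{i + 1}", f.sequence)
                 for i, f in enumerate(table.features)],
            )
            table.to_dataframe().to_csv(
                outdir / f"feature_table_{tag}.tsv", sep="\t", index=False
            )
            classified = classify_features(
                table, refs_region, contam_region, config.classify
            )
            classification_table(classified).to_csv(
                outdir / f"classified_{tag}.tsv", sep="\t", index=False
            )
            method_ledger[tag] = {
                "n_features": len(table),
                "mapped_reads": table.total_count,
                "unassigned_reads": total_reads - table.total_count,
            }
        report = analyze_tables(
            tables, refs_region, contam_region, design, config.classify, samples
        )
        reports.append(report)
    report = pd.concat(reports, ignore_index=True)
    report.to_csv(outdir / "report.tsv", sep="\t", index=False)

    ledger = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "parameters": _as_plain(config),
        "preprocess": ledger_stages,
        "methods": method_ledger,
    }
    (outdir / "run_ledger.json").write_text(json.dumps(ledger, indent=2))
    return report


def compare_scopes(config: RunConfig, outdir: str | Path | None = None) -> pd.DataFrame:
    """Pooled minus per-sample feature totals and category deltas.

    Methods with data-set-relative abundance floors (the entropy method)
    or data-set-level clustering change their per-sample output when other
    samples are processed alongside; the per-sample divisive partitioner
    is invariant by construction.
    """
    refs, contam, design, reads = simulate_stage(config)
    refs = refs.trimmed(config.preprocess.head_trim)
    contam = contam.trimmed(config.preprocess.head_trim)
    merged_all = []
    for k in sorted(reads):
        merged, _ = preprocess_reads(reads[k], config.preprocess, config.branch)
        merged_all.extend(merged)
    derep_pooled = dereplicate(merged_all, "pooled")
    derep_by_sample = dereplicate(merged_all, "per-sample")
    total = derep_pooled.total_abundance

    rows = []
    tables = {
        scope: infer_tables(config, derep_pooled, derep_by_sample, total, scope)
        for scope in ("per-sample", "pooled")
    }
    samples = sorted(derep_by_sample, key=lambda s: int(s[1:]))
    for method in config.methods:
        for sample in samples:
            per = per_sample_table(tables["per-sample"][method], sample)
            pool = per_sample_table(tables["pooled"][method], sample)
            row = {
                "method": method,
                "sample": sample,
                "n_features_per_sample": len(per),
                "n_features_pooled": len(pool),
                "delta_features": len(pool) - len(per),
                "identical_feature_sets": set(per.sequences())
                == set(pool.sequences()),
            }
            cc_per = category_counts(
                classify_features(per, refs, contam, config.classify)
            ) if len(per) else {c: 0 for c in CATEGORIES}
            cc_pool = category_counts(
                classify_features(pool, refs, contam, config.classify)
            ) if len(pool) else {c: 0 for c in CATEGORIES}
            for cat in CATEGORIES:
                row[f"delta_{cat}"] = cc_pool[cat] - cc_per[cat]
            rows.append(row)
    df = pd.DataFrame(rows)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        df.to_csv(outdir / "scope_comparison.tsv", sep="\t", index=False)
    return df
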