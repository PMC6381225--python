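# ampbench

Benchmarking 16S rRNA amplicon sequence inference under falling
microbial biomass.

Low-biomass samples (urine, airway mucosa, blood, built environments)
break a silent assumption of microbiome sequencing: that community DNA
overwhelms the trace contamination carried by extraction kits and
laboratory plasticware. As input biomass falls, a fixed mass of reagent
contaminants claims a growing share of the sequencing library, and the
question of which analysis method to trust becomes acute. `ampbench`
re-creates the classic way of studying this — a mock-community dilution
series — entirely in silico, as a tested, reusable pipeline:

1. **simulate** a known community (8 uniform strains by default, ≥ 20 nt
   apart) plus a long-tailed contaminant pool, diluted 3-fold per step
   over 9 samples with the contaminant mass held fixed, sequenced as
   2×251 bp paired reads with per-cycle quality decay, quality-dependent
   substitutions, and PCR bimeras;
2. **preprocess**: head/tail trimming, overlap merging with posterior
   qualities (≤ 10 overlap differences), a merged-length window, and an
   expected-error filter (EE = Σ 10^(−q/10) ≤ 2);
3. **infer** features with six re-implemented de novo strategies —
   greedy 97%-identity OTU clustering (`uclust`), the same with inline
   bimera rejection (`uparse`), the parametric-skew denoiser
   β(d) = 1/2^(αd+1) (`unoise`, α = 2), per-Hamming-distance
   error subtraction (`deblur`), divisive partitioning with a
   self-trained error model and Poisson abundance p-values at
   Ω = 10⁻⁴⁰ (`dada`), and minimum-entropy decomposition with a 0.02%
   abundance floor (`med`);
4. **classify** every inferred feature against the ground truth:
   Reference (exact community match), Ref Noisy (≤ 10 nt from a more
   abundant Reference feature), Contaminant (exact match to the
   contaminant database), Contam Noisy (≤ 10 nt from a Contaminant
   feature), Other;
5. **score**: recall over strains, overall precision
   (Reference/total), technical precision
   (Reference/(Reference+RefNoisy)), reference read fraction, and alpha
   diversity (Shannon H = −Σ p ln p, inverse Simpson 1/Σ p², Fisher's α
   from S = α·ln(1 + N/α)).

Everything is generated by code — no downloads — and every stage is
deterministic for a fixed seed. See `docs/methods.md` for the models,
simplifications, and limitations.

## Worked example

The two headline experiments live behind one-function entry points and
numbered analysis drivers. High-biomass parameter recovery
(`analysis/02_high_biomass_recovery.py`, 50 000 reads at Q30):

```
          method  n_features  recall_pct  technical_precision_pct  n_Reference  n_RefNoisy
          unoise           8         100                    100.0          8.0         0.0
          deblur           8         100                    100.0          8.0         0.0
            dada           8         100                    100.0          8.0         0.0
             med           8         100                    100.0          8.0         0.0
uclust_2pct_pair           2          50                      NaN          NaN         NaN
```

All four abundance-aware methods return exactly the 8 planted strains —
perfect recall and no technical noise. The last row is the contrast
experiment: two strains only 2% apart (5 substitutions over the 222-nt
merged region) fall inside the 3% similarity radius, so greedy OTU
clustering merges them and recall drops to 50%; its second "OTU" is an
error-split artifact, not the missing strain.

The dilution series (`analysis/03_dilution_series_trends.py`, 9 samples,
5 000 reads each, 30 contaminants at fixed total mass):

```
method  dilution_step  n_features  n_Reference  n_Contaminant  signal_noise_gap_log10
unoise              3          23            8             10                2.494119
unoise              4          30            8             14                2.783903
unoise              5          28            8             17                1.980378
unoise              6          34            8             21                1.879012
unoise              7          34            8             22                1.434038
unoise              8          35            8             23                1.034671
unoise              9          45            8             27                1.027048
unoise: Spearman rho(contaminant count, step) = 0.996
deblur: Spearman rho(contaminant count, step) = 0.996
dada:   Spearman rho(contaminant count, step) = 1.000
```

All 8 community strains stay detected at every dilution, but the number
of Contaminant-classified features climbs nearly monotonically with the
dilution step (Spearman ρ ≈ 1 for every ASV method), and the gap between
the median log₁₀ abundance of community features and that of everything
else collapses from ~2.5 decades toward ~1 — the signal/noise
convergence that makes naive abundance filters useless at low biomass.

Other drivers: `01_validate_published_tables.py` (checks the accuracy
formulas against published benchmark tables shipped as package data),
`04_pooled_vs_per_sample.py` (scope reproducibility: the per-sample
divisive partitioner is byte-identical under pooling, the
relative-floor and data-set-level methods are not), and
`05_full_pipeline_run.py` (end-to-end artifact production). The same
functionality is exposed as a CLI:

```bash
ampbench run-all --seed 11 --outdir out/
ampbench simulate --seed 11 --outdir out/
ampbench infer --derep out/derep.tsv --method unoise --outdir out/
ampbench compare-scopes --seed 11 --outdir out/
```

with YAML configuration (`--config`) validated against a strict schema.

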