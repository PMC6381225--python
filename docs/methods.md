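# Methods

`ampbench` re-creates, at desk scale and as tested code, a benchmarking
analysis of 16S rRNA amplicon sequence inference under falling microbial
biomass: a known mock community is serially diluted while reagent-style
contamination stays at fixed mass, reads are simulated with realistic
sequencer noise, six de novo inference strategies are run on the result,
and every inferred feature is scored against the ground truth. This note
records the models, the parameters that matter, the deliberate
simplifications, and what the synthetic data can and cannot show.

## The synthetic community and dilution design

**Community.** `generate_reference_set` draws random amplicon-length
(default 252 nt) sequences for `n_strains` strains subject to a minimum
pairwise Levenshtein distance (default 20 nt, ~9%), with optional extra
alleles per strain at 1–3 substitutions from the primary allele. The
distance floor makes the Reference/Contaminant categories unambiguous by
construction; an unsatisfiable constraint raises after a bounded number
of retries rather than being silently relaxed. Genomic proportions
default to uniform (the 8-strain, equal-proportion community standard
that motivates the defaults).

**Dilution.** Sample k (1-based) of a `DilutionDesign` carries community
template mass `T·fold^-(k-1)` (defaults T=1, fold=3, 9 samples, so the
series ends at 1/6561) and a constant contaminant mass C. The expected
contaminant read share is the closed form

    f(k) = C / (C + T·fold^-(k-1)),

strictly increasing in k whenever C>0. The default C=0.001 places the
series in the regime where contaminants dominate the lowest dilutions
(f = 0.42, 0.69, 0.87 at k = 7, 8, 9) while remaining a trace component
(f ≈ 0.1%) in the undiluted sample — the canonical signature of reagent
contamination in low-biomass sequencing. C is a free parameter of the
design, not a measured property of any particular reagent lot.

**Contaminant pool.** `generate_contaminant_pool` draws `n_contaminants`
(default 30) random templates, each ≥ 20 nt from every reference allele
and from each other, with geometric relative masses (ratio 0.75). The
long-tailed mass ladder emulates the many-species, highly skewed
composition of real reagent contamination: as f(k) grows, progressively
rarer members cross the detection floor, so the number of detectable
contaminants rises smoothly along the series instead of saturating at
the first diluted sample.

**Reads.** `sequence_reads` draws each read's template multinomially
from the sample mixture. With probability `chimera_rate` (default 0.005
in the pipeline; 0 in the clean high-biomass study) the read instead
derives from a two-parent crossover at a uniform interior breakpoint,
tagged `chimera:<p1>|<p2>@<bp>` so downstream bimera removal can be
scored. Per-cycle Phred means decay linearly (defaults 37→27 forward,
35→24 reverse over 251 cycles) with Gaussian jitter (sd 2), clamped to
[2, 41]; each base substitutes with probability `10^(-q/10)`, uniformly
over the three alternatives. Indels are not simulated — the sequencer
model is substitution-only — but all downstream distance computations
use Levenshtein distance, so indel support costs nothing if enabled
later. Origin tags are retained for every read purely for evaluation.

## Preprocessing

The default (merge-first) branch is: 5′ head trim of 15 nt on both
mates, 3′ truncation at configurable cycle positions (defaults 230
forward / 210 reverse), ungapped pair merging, a merged-length window
(default [220, 225]), then an expected-error filter EE = Σ 10^(-q/10) ≤
2.0 on the merged posterior qualities. The `dada` branch instead filters
the mates independently (EE ≤ 2.5 each by default) before merging, the
ordering used by per-read-filtering workflows; in this package both
branches merge before inference, and the independent-mate thresholds are
what distinguish them. Every stage reports a drop count and the ledger
identity `input = output + Σ dropped` is enforced, not assumed.

Merging selects the ungapped overlap (minimum 16 nt — a package choice;
tiny overlaps are statistically unreliable under the
maximal-match criterion) that maximizes matched bases, preferring the
longer overlap on ties, and discards pairs whose best overlap carries
more than `max_merge_diffs` (default 10) mismatches. Posterior qualities
use the simple product/ratio forms: agreeing bases get error `e1·e2`
(capped at Phred 41), disagreeing bases keep the higher-quality base
with error `e_hi/(e_hi+e_lo)` (floored at Phred 2). These are a
documented simplification of the full Bayesian posteriors used by the
tool that popularized paired-end merging with posterior scores; they are
isolated in one function (`_posterior_merge_arrays`) so they can be
swapped without touching anything else. Phred cap 41 / floor 2 is the
Illumina 1.8+ convention.

Dereplication groups exact sequences, orders by decreasing abundance
with lexicographic tie-breaks (this ordering fixes every downstream
iteration order, making all six methods bit-reproducible), keeps
per-sample counts for pooled processing, and retains the mean
per-position Phred of each unique sequence for error-model estimation.

## The six inference strategies

All methods consume a `DereplicatedSet` and emit a `FeatureTable`.

* **uclust** — abundance-sorted greedy clustering: a sequence joins the
  first (most abundant) seed with identity `1 − Levenshtein/max(len)` ≥
  97% (radius 3%), else seeds. * **uparse** — the same, but a candidate
  seed is first tested as an exact two-parent crossover of existing
  seeds (both ≥ 2× its abundance) and discarded if so.
* **unoise** — the parametric skew model β(d) = 1/2^(αd+1) (α = 2):
  a sequence joins the most abundant centroid whose
  abundance ratio satisfies `a_s/a_c ≤ β(Levenshtein(s,c))`, else
  becomes a centroid. Distance is measured directly to the candidate
  centroid, not along a merge chain; the banded alignment is cut off at
  the largest d that could still satisfy the inequality.
* **deblur** — positional (Hamming) per-distance subtraction: in
  decreasing abundance, each sequence subtracts `a·profile[d]` from
  every neighbor at Hamming distance d ≤ 11, using its *current*
  abundance; survivors with positive residual are the ASVs. The default
  profile (0.06, 0.02, 0.02, 0.01, 3×0.005, 3×0.001, 0.0005) is a
  configuration default of this package — the published method
  distributes its own profile — and all tests use the zero profile or
  explicit values. Requires equal-length input (hence the trim window).
* **dada** — divisive partitioning with a self-trained error model over
  (template base, read base, quality). The abundance statistic is a
  Poisson tail conditioned on at least one read:
  `p = P(X ≥ a_s | X ~ Poisson(λ·a_c)) / P(X ≥ 1)`, with
  `λ = Π_i M[c_i, s_i, q_i]`; a cluster splits while the smallest p
  falls below Ω = 10⁻⁴⁰. The conditional Poisson tail is a deliberate
  simplification of the source method's abundance p-value; the
  qualitative behavior (singletons never split; repeated sequences with
  negligible expected reads always split) is identical. The matrix
  starts from a pessimistic quality-independent 1% substitution rate and
  is re-estimated from within-cluster transitions (pseudocounts shaped
  like the prior) until L∞ change < 10⁻⁷ or `max_iterations` (8);
  hitting the cap sets a non-convergence flag rather than failing
  silently. Samples are always processed independently, which is what
  makes this method scope-invariant.
* **med** — minimum-entropy decomposition: gap-pad to equal length,
  compute abundance-weighted Shannon entropy (natural log) per column,
  split the cluster on the symbol at the highest-entropy column while
  any column exceeds the threshold, then drop clusters below 0.02% of
  total data-set reads. The per-cluster threshold rule is pluggable; the
  default is a fixed 0.2 nats per column, which is this package's own
  choice (the original tool computes its threshold dynamically by an
  unpublished rule). A fixed threshold means a minority lineage below
  ~5% of its cluster does not trigger a split; tests that exercise the
  abundance floor therefore lower the threshold explicitly.

Chimera handling follows each method's native placement: inline for
uparse; as a post-inference filter (exact two-parent crossover test,
parents ≥ 2× candidate abundance, scanned in decreasing abundance so
parents are themselves retained features) for the others.
`map_reads_to_features` re-derives per-sample counts by nearest-feature
assignment — exact for ASV methods, within the 3% radius for OTU
methods — with unmapped reads counted, never dropped silently.

## Classification and metrics

Features are classified in decreasing abundance with strict precedence:
Reference (exact allele match) → RefNoisy (≤ 10 nt Levenshtein from a
strictly more abundant Reference-classified *feature*) → Contaminant
(exact contaminant-database match) → ContamNoisy (≤ 10 nt from a
Contaminant-classified feature, no abundance requirement — deliberately
asymmetric with RefNoisy) → Other. Because inferred features cover the
merged-read window, truth matching uses references and contaminants
trimmed to the same window (`ReferenceSet.trimmed`). On synthetic data
the contaminant database is the simulator's own pool, standing in for
the nucleotide-database search a real study would run.

Metrics: recall counts strains (any allele suffices), not alleles;
overall precision = Reference/total features; technical precision =
Reference/(Reference+RefNoisy). Percentages round half away from zero in
exact integer arithmetic — the convention that reproduces the published
benchmark tables this package checks itself against (23 of the 24
published technical-precision cells reproduce exactly; the 24th is
internally inconsistent with its own category counts by one unit, and
the package asserts that discrepancy rather than papering over it).
Alpha diversity uses natural-log Shannon, inverse Simpson, and Fisher's
log-series α solved from `S = α·ln(1 + N/α)` by bracketed Brent
iteration to 10⁻⁹ (undefined for S = 0 or S ≥ N, raised explicitly).
The depth-normalization helper implements the printed convention
(multiply by sample reads, divide by the median) *and* an `invert`
option, because the printed form amplifies rather than corrects depth
differences; the default follows the printed text and this is flagged
to users.

## Study sizes and determinism

The two canonical studies (`ampbench.studies`) run at deliberately
desk-scale sizes chosen so the full test suite and the acceptance script
complete in minutes on one core: parameter recovery uses 50 000 reads
(8 strains, flat Q30, no contamination — expected errors ≈ 0.2/read, so
roughly a third of raw reads carry ≥ 1 error before posterior-quality
correction), and the dilution series uses 5 000 reads per sample × 9
samples with 30 contaminants. The qualitative contrasts these studies
probe — exact community recovery by abundance-aware methods, radius
lumping at 2% strain distance, monotone contaminant growth, signal/noise
collapse — are depth-robust; absolute feature counts are not and are
never asserted.

All randomness flows through `numpy.random.SeedSequence` fan-out: the
pipeline spawns (references, contaminants, reads) seeds from the master
seed, and the read stage spawns one child per sample, so any stage or
sample can be re-run independently and a fixed config + seed yields
byte-identical artifacts (no timestamps are written). Every iteration
order is fixed by the dereplication ordering.

## What the simulator does not capture

* No indels, homopolymer artifacts, or quality-score miscalibration;
  substitution probability is exactly the nominal Phred conversion.
* No PCR amplification bias (a per-template multiplier is accepted in
  the mixture but defaults to neutral) and no primer-sequence modeling.
* Chimeras are exact two-parent crossovers; real bimera spectra include
  multi-segment and near-exact variants that the exact-crossover
  detector would miss.
* Contaminants are random sequences far from the community; real
  contamination is phylogenetically structured and can sit near
  community members, which would blur the Reference/Contaminant
  boundary that is clean here by construction.
* The error-matrix estimation in the divisive partitioner sees mean
  per-unique qualities, not per-read qualities.

Consequently, passing tests demonstrate that the algorithms implement
their models correctly and that the models interact with falling biomass
as described; they do not certify performance on real MiSeq data, where
error structure is richer and truth is never exact.

## Known limitations

* The entropy method's fixed default threshold under-splits extremely
  imbalanced clusters (see above); its scope-sensitivity behavior at
  default settings therefore arises both from the relative floor and
  from imbalance-dependent splitting, whereas with a sensitive threshold
  it isolates the floor mechanism.
* The uparse variant implements inline bimera rejection but not the
  stricter pre-clustering quality filter of its namesake; under the
  simulator's EE-filtered inputs the additional filter would be nearly
  a no-op.
* `map_reads_to_features` maps dereplicated uniques, not raw reads, so
  its ledger is in read units but its distance computations are per
  unique sequence.
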