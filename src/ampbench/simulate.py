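"""Synthetic mock-community dilution series with reagent-style contamination.

This module generates everything a desk-scale benchmark of amplicon
sequence inference needs, without any external data:

* a ground-truth community of named strains with one or more 16S-like
  amplicon alleles each (a stand-in for a mock community standard such as
  an 8-strain, uniform-proportion product);
* a pool of contaminant templates with a fixed total mass, emulating the
  reagent/laboratory contamination that dominates low-biomass samples;
* a serial dilution design in which the community template mass shrinks
  by a constant fold per step while the contaminant mass stays constant,
  so the expected contaminant read share grows along the series;
* paired-end reads with per-cycle Phred quality profiles,
  quality-dependent substitution errors, and PCR bimeras.

All randomness flows through :class:`numpy.random.Generator` seeded from a
single integer, so every artifact is byte-reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np

from . import io
from ._seq import BASES, decode, encode, levenshtein, revcomp

PHRED_MIN = 2
PHRED_MAX = 41

# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class StrainReference:
    """One community member: a strain with >= 1 amplicon allele."""

    strain_id: str
    alleles: tuple[str, ...]
    genomic_proportion: float

    def __post_init__(self):
        if not self.alleles:
            raise ValueError(f"{self.strain_id}: at least one allele required")
        if len(set(self.alleles)) != len(self.alleles):
            raise ValueError(f"{self.strain_id}: alleles must be distinct")
        if not 0.0 <= self.genomic_proportion <= 1.0:
            raise ValueError(f"{self.strain_id}: proportion outside [0, 1]")


@dataclass(frozen=True)
class ReferenceSet:
    strains: tuple[StrainReference, ...]

    def __post_init__(self):
        total = sum(s.genomic_proportion for s in self.strains)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"genomic proportions sum to {total}, expected 1")

    def alleles(self) -> list[tuple[str, str]]:
        """All (allele_id, sequence) pairs; allele_id = '<strain>/a<i>'."""
        out = []
        for s in self.strains:
            for i, seq in enumerate(s.alleles):
                out.append((f"{s.strain_id}/a{i + 1}", seq))
        return out

    def allele_sequences(self) -> set[str]:
        return {seq for _, seq in self.alleles()}

    def strain_of_allele(self, allele_id: str) -> str:
        return allele_id.rsplit("/a", 1)[0]

    def write_fasta(self, path: str | Path) -> None:
        io.write_fasta(path, self.alleles())

    def trimmed(self, head: int, tail: int | None = None) -> "ReferenceSet":
        """References cut to the merged-read window [head, len - tail).

        Inferred features cover the amplicon region that survives head
        trimming of both mates, so truth matching must use the same
        window.
        """
        tail = head if tail is None else tail
        return ReferenceSet(
            tuple(
                StrainReference(
                    s.strain_id,
                    tuple(a[head: len(a) - tail] for a in s.alleles),
                    s.genomic_proportion,
                )
                for s in self.strains
            )
        )


@dataclass(frozen=True)
class ContaminantPool:
    """Contaminant templates with relative masses summing to 1."""

    members: tuple[tuple[str, str, float], ...]  # (contam_id, sequence, rel_mass)
    total_mass: float = 1.0

    def __post_init__(self):
        if self.total_mass < 0:
            raise ValueError("total_mass must be non-negative")
        if self.members:
            s = sum(m for _, _, m in self.members)
            if abs(s - 1.0) > 1e-9:
                raise ValueError(f"relative masses sum to {s}, expected 1")

    def sequences(self) -> set[str]:
        return {seq for _, seq, _ in self.members}

    def write_fasta(self, path: str | Path) -> None:
        io.write_fasta(path, [(cid, seq) for cid, seq, _ in self.members])

    def trimmed(self, head: int, tail: int | None = None) -> "ContaminantPool":
        tail = head if tail is None else tail
        return ContaminantPool(
            members=tuple(
                (cid, seq[head: len(seq) - tail], mass)
                for cid, seq, mass in self.members
            ),
            total_mass=self.total_mass,
        )


@dataclass(frozen=True)
class DilutionDesign:
    """A serial dilution: community template diluted, contaminant mass fixed.

    Sample k (1-based) carries community template mass
    ``template_mass0 * fold**-(k-1)`` and contaminant mass
    ``contaminant_mass`` (identical across samples).
    """

    n_samples: int = 9
    fold: float = 3.0
    template_mass0: float = 1.0
    contaminant_mass: float = 0.001
    depth_per_sample: tuple[int, ...] = ()

    def __post_init__(self):
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.fold <= 1.0:
            raise ValueError("fold must be > 1")
        if self.template_mass0 <= 0 and self.contaminant_mass <= 0:
            raise ValueError("sample would be empty: both masses are zero")
        if self.depth_per_sample and len(self.depth_per_sample) != self.n_samples:
            raise ValueError("depth_per_sample length must equal n_samples")

    def relative_concentration(self, k: int) -> float:
        self._check_k(k)
        return self.fold ** -(k - 1)

    def depth(self, k: int, default: int = 10_000) -> int:
        self._check_k(k)
        return self.depth_per_sample[k - 1] if self.depth_per_sample else default

    def _check_k(self, k: int) -> None:
        if not 1 <= k <= self.n_samples:
            raise ValueError(f"sample index {k} outside 1..{self.n_samples}")


@dataclass(frozen=True)
class QualityProfile:
    """Per-cycle mean Phred: linear decay from q_start to q_end plus
    Gaussian jitter, clamped to [2, 41]."""

    read_length: int = 251
    q_start: float = 37.0
    q_end: float = 27.0
    jitter_sd: float = 2.0

    def means(self) -> np.ndarray:
        return np.linspace(self.q_start, self.q_end, self.read_length)

    @classmethod
    def flat(cls, q: float, read_length: int = 251) -> "QualityProfile":
        return cls(read_length=read_length, q_start=q, q_end=q, jitter_sd=0.0)


def phred_to_error(q) -> np.ndarray | float:
    return 10.0 ** (-np.asarray(q, dtype=float) / 10.0)


@dataclass(frozen=True)
class ErrorModel:
    """Sequencer + PCR noise: quality-driven substitutions and bimeras.

    ``substitution_prob`` maps Phred q to the per-base substitution
    probability (default the nominal 10^(-q/10)), uniform over the three
    alternative bases. Indels are not modeled.
    """

    quality_profile_fwd: QualityProfile = QualityProfile()
    quality_profile_rev: QualityProfile = dataclasses.field(
        default_factory=lambda: QualityProfile(q_start=35.0, q_end=24.0)
    )
    substitution_prob: Callable[[np.ndarray], np.ndarray] = phred_to_error
    chimera_rate: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.chimera_rate < 1.0:
            raise ValueError("chimera_rate must be in [0, 1)")
        qs = np.arange(PHRED_MIN, PHRED_MAX + 1)
        ps = np.asarray(self.substitution_prob(qs), dtype=float)
        if (np.diff(ps) > 1e-12).any():
            raise ValueError("substitution_prob must be non-increasing in q")

    @classmethod
    def noiseless(cls, read_length: int = 251) -> "ErrorModel":
        return cls(
            quality_profile_fwd=QualityProfile.flat(PHRED_MAX, read_length),
            quality_profile_rev=QualityProfile.flat(PHRED_MAX, read_length),
            substitution_prob=lambda q: np.zeros_like(np.asarray(q, dtype=float)),
            chimera_rate=0.0,
        )


@dataclass(frozen=True)
class ReadPair:
    """A simulated paired-end read with its provenance tag.

    ``origin`` is a template id, or ``"chimera:<p1>|<p2>"`` for bimeras,
    and exists only so downstream stages can be tested against truth.
    """

    read_id: str
    fwd_seq: str
    fwd_quals: tuple[int, ...]
    rev_seq: str
    rev_quals: tuple[int, ...]
    origin: str
    sample: str = "s1"

    def __post_init__(self):
        for seq, quals in ((self.fwd_seq, self.fwd_quals), (self.rev_seq, self.rev_quals)):
            if len(seq) != len(quals):
                raise ValueError("sequence/quality length mismatch")
            if quals and not (PHRED_MIN <= min(quals) and max(quals) <= PHRED_MAX):
                raise ValueError("Phred values outside [2, 41]")

    @property
    def origin_class(self) -> str:
        if self.origin.startswith("chimera:"):
            return "chimera"
        return "contaminant" if self.origin.startswith("contam") else "reference"


# ---------------------------------------------------------------------------
# ground-truth generation


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return decode(rng.integers(0, 4, size=length).astype(np.uint8))


def _mutate(rng: np.random.Generator, seq: str, n_subs: int) -> str:
    arr = encode(seq).copy()
    pos = rng.choice(len(arr), size=n_subs, replace=False)
    shift = rng.integers(1, 4, size=n_subs).astype(np.uint8)
    arr[pos] = (arr[pos] + shift) % 4
    return decode(arr)


def generate_reference_set(
    n_strains: int,
    amplicon_len: int = 252,
    min_pairwise_dist: int = 20,
    allele_spec: Mapping[str, int] | None = None,
    seed: int = 0,
    proportions: Sequence[float] | None = None,
    max_tries: int = 200,
) -> ReferenceSet:
    """Generate a community of random amplicons with guaranteed separation.

    Inter-strain allele Levenshtein distances are all >= min_pairwise_dist;
    intra-strain alleles differ by 1-3 substitutions. Proportions default
    to uniform. Raises RuntimeError if the distance constraint cannot be
    satisfied within ``max_tries`` draws per strain (never silently relaxed).
    """
    if n_strains < 1:
        raise ValueError("n_strains must be >= 1")
    if min_pairwise_dist < 1 or amplicon_len < min_pairwise_dist:
        raise ValueError("require 1 <= min_pairwise_dist <= amplicon_len")
    rng = np.random.default_rng(seed)
    if proportions is None:
        proportions = [1.0 / n_strains] * n_strains
    if len(proportions) != n_strains:
        raise ValueError("proportions length must equal n_strains")
    # renormalize to kill accumulated float error in uniform defaults
    total = float(sum(proportions))
    proportions = [p / total for p in proportions]

    strain_ids = [f"strain{i + 1:02d}" for i in range(n_strains)]
    allele_spec = dict(allele_spec or {})
    primaries: list[str] = []
    for sid in strain_ids:
        for _ in range(max_tries):
            cand = _random_seq(rng, amplicon_len)
            if all(
                levenshtein(cand, p, max_dist=min_pairwise_dist - 1)
                >= min_pairwise_dist
                for p in primaries
            ):
                primaries.append(cand)
                break
        else:
            raise RuntimeError(
                f"could not place {sid} at distance >= {min_pairwise_dist} "
                f"after {max_tries} tries"
            )
    strains = []
    for sid, primary, prop in zip(strain_ids, primaries, proportions):
        alleles = [primary]
        others = [p for p in primaries if p != primary]
        for _ in range(allele_spec.get(sid, 1) - 1):
            for _ in range(max_tries):
                var = _mutate(rng, primary, int(rng.integers(1, 4)))
                if var not in alleles and all(
                    levenshtein(var, o, max_dist=min_pairwise_dist - 1)
                    >= min_pairwise_dist
                    for o in others
                ):
                    alleles.append(var)
                    break
            else:
                raise RuntimeError(f"could not generate distinct allele for {sid}")
        strains.append(StrainReference(sid, tuple(alleles), prop))
    return ReferenceSet(tuple(strains))


def generate_contaminant_pool(
    n_contaminants: int,
    refs: ReferenceSet,
    amplicon_len: int = 252,
    min_dist: int = 20,
    mass_ratio: float = 0.75,
    seed: int = 1,
    max_tries: int = 200,
) -> ContaminantPool:
    """Random contaminant templates, each >= min_dist from every reference
    allele and from each other, with geometric relative masses.

    A geometric mass ladder (``mass_ratio`` < 1) emulates the long-tailed
    abundance structure of reagent contamination: as the contaminant read
    share grows along a dilution series, progressively rarer members rise
    above the detection floor, so the number of detectable contaminants
    grows smoothly rather than saturating at once.
    """
    if n_contaminants < 0:
        raise ValueError("n_contaminants must be >= 0")
    rng = np.random.default_rng(seed)
    ref_alleles = list(refs.allele_sequences())
    seqs: list[str] = []
    for i in range(n_contaminants):
        for _ in range(max_tries):
            cand = _random_seq(rng, amplicon_len)
            if all(
                levenshtein(cand, other, max_dist=min_dist - 1) >= min_dist
                for other in ref_alleles + seqs
            ):
                seqs.append(cand)
                break
        else:
            raise RuntimeError(
                f"could not place contaminant {i + 1} at distance >= {min_dist}"
            )
    if n_contaminants == 0:
        return ContaminantPool(members=())
    masses = mass_ratio ** np.arange(n_contaminants)
    masses /= masses.sum()
    members = tuple(
        (f"contam{i + 1:03d}", seq, float(m))
        for i, (seq, m) in enumerate(zip(seqs, masses))
    )
    return ContaminantPool(members=members)


# ---------------------------------------------------------------------------
# sample composition


def expected_contaminant_fraction(design: DilutionDesign, k: int) -> float:
    """Closed-form contaminant read-share C / (C + T * fold**-(k-1))."""
    design._check_k(k)
    c = design.contaminant_mass
    t = design.template_mass0 * design.relative_concentration(k)
    if c + t <= 0:
        raise ValueError("empty sample: no template and no contaminant mass")
    return c / (c + t)


def compose_sample(
    refs: ReferenceSet,
    contam: ContaminantPool,
    design: DilutionDesign,
    k: int,
) -> dict[str, float]:
    """Expected read fraction per template id in dilution sample k.

    The contaminant group takes the closed-form fraction above; within each
    group, fractions are proportional to genomic proportion (split equally
    across a strain's alleles) or to contaminant relative mass.
    """
    f_contam = expected_contaminant_fraction(design, k) if contam.members else 0.0
    if not contam.members and design.contaminant_mass > 0:
        f_contam = 0.0
    mixture: dict[str, float] = {}
    f_ref = 1.0 - f_contam
    for strain in refs.strains:
        share = f_ref * strain.genomic_proportion / len(strain.alleles)
        for i in range(len(strain.alleles)):
            mixture[f"{strain.strain_id}/a{i + 1}"] = share
    for cid, _, mass in contam.members:
        mixture[cid] = f_contam * mass
    total = sum(mixture.values())
    if total <= 0:
        raise ValueError("empty sample: zero total mixture mass")
    return {tid: frac / total for tid, frac in mixture.items()}


# ---------------------------------------------------------------------------
# read simulation


def _simulate_strand(
    rng: np.random.Generator,
    template_arrs: list[np.ndarray],
    assignment: np.ndarray,
    profile: QualityProfile,
    sub_prob: Callable[[np.ndarray], np.ndarray],
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-strand simulation: returns (seq, qual) uint8 arrays."""
    n = len(assignment)
    read_len = profile.read_length
    seqs = np.empty((n, read_len), dtype=np.uint8)
    for t, arr in enumerate(template_arrs):
        mask = assignment == t
        if mask.any():
            seqs[mask] = arr[None, :read_len]
    means = profile.means()
    quals = means[None, :] + rng.normal(0.0, profile.jitter_sd, size=(n, read_len))
    quals = np.clip(np.rint(quals), PHRED_MIN, PHRED_MAX).astype(np.int16)
    p = np.asarray(sub_prob(quals), dtype=float)
    hit = rng.random((n, read_len)) < p
    shift = rng.integers(1, 4, size=(n, read_len)).astype(np.uint8)
    seqs = np.where(hit, (seqs + shift) % 4, seqs)
    return seqs, quals


def sequence_reads(
    mixture: Mapping[str, float],
    templates: Mapping[str, str],
    error_model: ErrorModel,
    depth: int,
    seed: int,
    sample: str = "s1",
) -> list[ReadPair]:
    """Draw paired-end reads from a mixture under the error model.

    Templates are drawn multinomially from ``mixture``; with probability
    ``chimera_rate`` a read instead derives from a two-parent crossover at
    a uniform interior breakpoint. Per-base substitutions follow
    ``substitution_prob(q)`` with q from the per-cycle quality profile.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    tids = sorted(mixture)
    probs = np.array([mixture[t] for t in tids], dtype=float)
    if abs(probs.sum() - 1.0) > 1e-6:
        raise ValueError("mixture fractions must sum to 1")
    probs = probs / probs.sum()
    missing = [t for t in tids if t not in templates]
    if missing:
        raise ValueError(f"mixture references unknown templates: {missing[:3]}")
    lengths = {len(templates[t]) for t in tids}
    if len(lengths) != 1:
        raise ValueError("all templates must share one amplicon length")
    amp_len = lengths.pop()
    fwd_len = error_model.quality_profile_fwd.read_length
    rev_len = error_model.quality_profile_rev.read_length
    if amp_len < max(fwd_len, rev_len):
        raise ValueError("amplicon shorter than read length")

    rng = np.random.default_rng(seed)
    assignment = rng.choice(len(tids), size=depth, p=probs)
    is_chimera = rng.random(depth) < error_model.chimera_rate

    # build per-read amplicon templates; chimeras get a bespoke template
    origins: list[str] = [tids[a] for a in assignment]
    fwd_templates = [encode(templates[t]) for t in tids]
    chim_arrs: list[np.ndarray] = []
    chim_index: dict[str, int] = {}
    for i in np.flatnonzero(is_chimera):
        p1, p2 = rng.choice(len(tids), size=2, replace=False, p=probs)
        bp = int(rng.integers(1, amp_len))
        tag = f"chimera:{tids[p1]}|{tids[p2]}@{bp}"
        origins[i] = tag
        if tag not in chim_index:
            chim_index[tag] = len(fwd_templates) + len(chim_arrs)
            chim_arrs.append(
                np.concatenate(
                    [fwd_templates[p1][:bp], fwd_templates[p2][bp:]]
                )
            )
        assignment[i] = chim_index[tag]
    all_arrs = fwd_templates + chim_arrs
    rev_arrs = [encode(revcomp(decode(a))) for a in all_arrs]

    fwd_seqs, fwd_quals = _simulate_strand(
        rng, all_arrs, assignment, error_model.quality_profile_fwd,
        error_model.substitution_prob,
    )
    rev_seqs, rev_quals = _simulate_strand(
        rng, rev_arrs, assignment, error_model.quality_profile_rev,
        error_model.substitution_prob,
    )

    reads = []
    for i in range(depth):
        reads.append(
            ReadPair(
                read_id=f"{sample}_r{i + 1:06d}",
                fwd_seq=decode(fwd_seqs[i]),
                fwd_quals=tuple(int(q) for q in fwd_quals[i]),
                rev_seq=decode(rev_seqs[i]),
                rev_quals=tuple(int(q) for q in rev_quals[i]),
                origin=origins[i],
                sample=sample,
            )
        )
    return reads


def write_sample_fastq(
    reads: Sequence[ReadPair], outdir: str | Path, k: int, gzipped: bool = False
) -> tuple[Path, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    suffix = ".fastq.gz" if gzipped else ".fastq"
    r1 = outdir / f"sample_{k}_R1{suffix}"
    r2 = outdir / f"sample_{k}_R2{suffix}"
    io.write_fastq(r1, ((r.read_id, r.fwd_seq, list(r.fwd_quals)) for r in reads))
    io.write_fastq(r2, ((r.read_id, r.rev_seq, list(r.rev_quals)) for r in reads))
    return r1, r2


def write_origin_table(reads: Sequence[ReadPair], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\torigin_id\torigin_class\n")
        for r in reads:
            fh.write(f"{r.read_id}\t{r.origin}\t{r.origin_class}\n")


def simulate_dilution_series(
    refs: ReferenceSet,
    contam: ContaminantPool,
    design: DilutionDesign,
    error_model: ErrorModel,
    seed: int,
    default_depth: int = 10_000,
) -> dict[int, list[ReadPair]]:
    """Simulate all samples of the design; per-sample seeds are spawned
    from the master seed so samples are independently re-runnable."""
    templates = dict(refs.alleles())
    templates.update({cid: seq for cid, seq, _ in contam.members})
    child_seeds = np.random.SeedSequence(seed).spawn(design.n_samples)
    out = {}
    for k in range(1, design.n_samples + 1):
        mixture = compose_sample(refs, contam, design, k)
        sample_seed = int(child_seeds[k - 1].generate_state(1)[0] % (2**31))
        out[k] = sequence_reads(
            mixture,
            templates,
            error_model,
            design.depth(k, default_depth),
            seed=sample_seed,
            sample=f"s{k}",
        )
    return out
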