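"""Ground-truth generation, sample composition, and read simulation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ampbench import io
from ampbench.simulate import (
    ContaminantPool,
    DilutionDesign,
    ErrorModel,
    QualityProfile,
    ReadPair,
    compose_sample,
    expected_contaminant_fraction,
    generate_contaminant_pool,
    generate_reference_set,
    sequence_reads,
    write_sample_fastq,
)


def _levenshtein_dp(a: str, b: str) -> int:
    """Plain DP edit distance, the oracle for generated separations."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


class TestGenerateReferenceSet:
    def test_pairwise_distances_meet_floor(self):
        refs = generate_reference_set(8, 225, min_pairwise_dist=20, seed=7)
        seqs = [s.alleles[0] for s in refs.strains]
        assert len(seqs) == 8 and all(len(s) == 225 for s in seqs)
        for i in range(len(seqs)):
            for j in range(i + 1, len(seqs)):
                assert _levenshtein_dp(seqs[i], seqs[j]) >= 20

    def test_single_strain(self):
        refs = generate_reference_set(1, 50, min_pairwise_dist=1, seed=0)
        assert len(refs.strains) == 1
        assert len(refs.strains[0].alleles[0]) == 50

    def test_deterministic_for_fixed_seed(self, tmp_path):
        a = generate_reference_set(5, 120, 15, seed=7)
        b = generate_reference_set(5, 120, 15, seed=7)
        a.write_fasta(tmp_path / "a.fasta")
        b.write_fasta(tmp_path / "b.fasta")
        assert (tmp_path / "a.fasta").read_bytes() == (tmp_path / "b.fasta").read_bytes()

    def test_multi_allele_strains_stay_close(self):
        refs = generate_reference_set(
            4, 200, 20, allele_spec={"strain01": 3}, seed=3
        )
        alleles = refs.strains[0].alleles
        assert len(alleles) == 3
        for extra in alleles[1:]:
            assert 1 <= _levenshtein_dp(alleles[0], extra) <= 3
        # proportions still sum to 1 and ids resolve to strains
        assert refs.strain_of_allele("strain01/a3") == "strain01"

    def test_unsatisfiable_distance_fails_loudly(self):
        with pytest.raises(RuntimeError):
            generate_reference_set(
                50, 8, min_pairwise_dist=8, seed=0, max_tries=5
            )


class TestContaminantPool:
    def test_separated_from_references_and_each_other(self):
        refs = generate_reference_set(4, 150, 20, seed=1)
        pool = generate_contaminant_pool(6, refs, 150, min_dist=20, seed=2)
        ref_seqs = [s.alleles[0] for s in refs.strains]
        contam_seqs = [seq for _, seq, _ in pool.members]
        for c in contam_seqs:
            for r in ref_seqs:
                assert _levenshtein_dp(c, r) >= 20
        assert abs(sum(m for _, _, m in pool.members) - 1.0) < 1e-9

    def test_geometric_masses_decrease(self):
        refs = generate_reference_set(2, 100, 10, seed=1)
        pool = generate_contaminant_pool(5, refs, 100, min_dist=10, seed=2)
        masses = [m for _, _, m in pool.members]
        assert masses == sorted(masses, reverse=True)


class TestComposeSample:
    @pytest.fixture()
    def community(self):
        refs = generate_reference_set(2, 60, 5, seed=5)
        pool = generate_contaminant_pool(2, refs, 60, min_dist=5, seed=6)
        return refs, pool

    def test_contaminant_fraction_closed_form(self, community):
        refs, pool = community
        design = DilutionDesign(
            n_samples=9, fold=3.0, template_mass0=1.0, contaminant_mass=0.01
        )
        mix = compose_sample(refs, pool, design, 1)
        contam_frac = sum(mix[c] for c, _, _ in pool.members)
        assert contam_frac == pytest.approx(0.01 / 1.01, abs=1e-12)
        mix7 = compose_sample(refs, pool, design, 7)
        contam_frac7 = sum(mix7[c] for c, _, _ in pool.members)
        assert contam_frac7 == pytest.approx(0.01 / (0.01 + 3.0**-6), rel=1e-9)

    def test_no_contamination_limit(self, community):
        refs, pool = community
        design = DilutionDesign(n_samples=9, contaminant_mass=0.0)
        for k in (1, 5, 9):
            mix = compose_sample(refs, pool, design, k)
            assert sum(mix[c] for c, _, _ in pool.members) == 0.0

    @given(
        k=st.integers(1, 9),
        c=st.floats(0.0, 10.0),
        fold=st.floats(1.5, 10.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_mixture_sums_to_one(self, k, c, fold):
        refs = generate_reference_set(3, 40, 3, seed=2)
        pool = generate_contaminant_pool(2, refs, 40, min_dist=3, seed=3)
        design = DilutionDesign(n_samples=9, fold=fold, contaminant_mass=c)
        mix = compose_sample(refs, pool, design, k)
        assert sum(mix.values()) == pytest.approx(1.0, abs=1e-9)

    def test_empty_sample_fails(self):
        with pytest.raises(ValueError):
            DilutionDesign(template_mass0=0.0, contaminant_mass=0.0)


class TestExpectedContaminantFraction:
    def test_strictly_increasing_when_contaminated(self):
        design = DilutionDesign(n_samples=9, contaminant_mass=0.01)
        fracs = [expected_contaminant_fraction(design, k) for k in range(1, 10)]
        assert all(b > a for a, b in zip(fracs, fracs[1:]))

    def test_dominates_by_series_end(self):
        design = DilutionDesign(
            n_samples=9, fold=3.0, template_mass0=1.0, contaminant_mass=0.01
        )
        assert expected_contaminant_fraction(design, 9) > 0.9

    def test_degenerate_fold_constant(self):
        design = DilutionDesign(n_samples=5, fold=1.0 + 1e-9, contaminant_mass=0.5)
        fracs = [expected_contaminant_fraction(design, k) for k in range(1, 6)]
        assert max(fracs) - min(fracs) < 1e-6


class TestSequenceReads:
    def _setup(self, depth, error_model, seed=3, n_templates=2):
        refs = generate_reference_set(n_templates, 100, 10, seed=5)
        templates = dict(refs.alleles())
        mix = {tid: 1.0 / len(templates) for tid in templates}
        return sequence_reads(mix, templates, error_model, depth, seed=seed)

    def test_zero_error_reads_match_template(self):
        em = ErrorModel.noiseless(read_length=90)
        reads = self._setup(50, em)
        refs = generate_reference_set(2, 100, 10, seed=5)
        templates = dict(refs.alleles())
        for r in reads:
            assert r.fwd_seq == templates[r.origin][:90]
            assert all(q == 41 for q in r.fwd_quals)

    def test_substitution_count_matches_binomial(self):
        # Q20 flat => p = 0.01/base; 10_000 reads x 90 bases
        em = ErrorModel(
            quality_profile_fwd=QualityProfile.flat(20.0, 90),
            quality_profile_rev=QualityProfile.flat(20.0, 90),
        )
        reads = self._setup(10_000, em, n_templates=1)
        refs = generate_reference_set(1, 100, 10, seed=5)
        template = refs.strains[0].alleles[0]
        n_subs = sum(
            sum(a != b for a, b in zip(r.fwd_seq, template[:90])) for r in reads
        )
        n, p = 10_000 * 90, 0.01
        sigma = np.sqrt(n * p * (1 - p))
        assert abs(n_subs - n * p) < 3 * sigma

    def test_chimera_rate_matches_binomial(self):
        em = ErrorModel(
            quality_profile_fwd=QualityProfile.flat(41.0, 90),
            quality_profile_rev=QualityProfile.flat(41.0, 90),
            substitution_prob=lambda q: np.zeros_like(np.asarray(q, float)),
            chimera_rate=0.05,
        )
        reads = self._setup(10_000, em)
        n_chim = sum(1 for r in reads if r.origin_class == "chimera")
        n, p = 10_000, 0.05
        sigma = np.sqrt(n * p * (1 - p))
        assert abs(n_chim - n * p) < 3 * sigma
        # chimeric sequences really are two-parent crossovers
        refs = generate_reference_set(2, 100, 10, seed=5)
        templates = dict(refs.alleles())
        chim = next(r for r in reads if r.origin_class == "chimera")
        inner = chim.origin.split(":", 1)[1]
        parents, bp = inner.rsplit("@", 1)
        p1, p2 = parents.split("|")
        bp = int(bp)
        expected = templates[p1][:bp] + templates[p2][bp:]
        assert chim.fwd_seq == expected[:90]

    def test_zero_depth_rejected(self):
        with pytest.raises(ValueError):
            self._setup(0, ErrorModel.noiseless(90))

    def test_invalid_phred_rejected(self):
        with pytest.raises(ValueError):
            ReadPair("r", "ACGT", (41, 41, 41, 99), "ACGT", (41,) * 4, origin="x")


class TestFastqRoundTrip:
    def test_written_then_read_identical(self, tmp_path):
        em = ErrorModel(
            quality_profile_fwd=QualityProfile(90, 38.0, 20.0, 3.0),
            quality_profile_rev=QualityProfile(90, 35.0, 18.0, 3.0),
        )
        refs = generate_reference_set(2, 100, 10, seed=5)
        mix = {tid: 0.5 for tid, _ in refs.alleles()}
        reads = sequence_reads(mix, dict(refs.alleles()), em, 40, seed=9)
        r1, r2 = write_sample_fastq(reads, tmp_path, k=1)
        back = list(io.read_fastq(r1))
        assert [(r.read_id, r.fwd_seq, list(r.fwd_quals)) for r in reads] == back
        # and gzip round-trips identically too
        g1, _ = write_sample_fastq(reads, tmp_path / "gz", k=1, gzipped=True)
        assert list(io.read_fastq(g1)) == back
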