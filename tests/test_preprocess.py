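"""Trimming, merging, filtering and dereplication behavior."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ampbench._seq import revcomp
from ampbench.preprocess import (
    DereplicatedSet,
    MergedRead,
    PreprocessParams,
    dereplicate,
    expected_error_filter,
    expected_errors,
    length_filter,
    merge_pairs,
    preprocess_reads,
    trim_reads,
)
from ampbench.simulate import (
    DilutionDesign,
    ErrorModel,
    QualityProfile,
    ReadPair,
    generate_reference_set,
    sequence_reads,
)


def _pair(fwd, rev, fq=30, rq=30, rid="r1", sample="s1"):
    fq = (fq,) * len(fwd) if isinstance(fq, int) else tuple(fq)
    rq = (rq,) * len(rev) if isinstance(rq, int) else tuple(rq)
    return ReadPair(rid, fwd, fq, rev, rq, origin="t")


def _pair_from_template(template, fwd_len, rev_len, fq=30, rq=30, rid="r1"):
    return _pair(
        template[:fwd_len], revcomp(template)[:rev_len], fq, rq, rid=rid
    )


class TestTrim:
    def test_head_and_tail_trim_lengths(self):
        p = _pair("A" * 251, "C" * 251)
        params = PreprocessParams(head_trim=15, trim_fwd=230, trim_rev=210)
        [t], dropped = trim_reads([p], params)
        assert dropped == 0
        assert len(t.fwd_seq) == 215 and len(t.rev_seq) == 195
        assert len(t.fwd_quals) == 215

    def test_identity_when_no_trim(self):
        p = _pair("ACGTACGT", "TTTTGGGG")
        params = PreprocessParams(
            head_trim=0, trim_fwd=8, trim_rev=8, length_window=(1, 100)
        )
        [t], dropped = trim_reads([p], params)
        assert t.fwd_seq == p.fwd_seq and t.rev_seq == p.rev_seq

    def test_degenerate_window_drops_and_counts(self):
        p = _pair("A" * 50, "C" * 50)
        params = PreprocessParams(head_trim=15, trim_fwd=10, trim_rev=40)
        kept, dropped = trim_reads([p], params)
        assert kept == [] and dropped == 1


def _random_template(length, seed=0):
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGT"), length))


class TestMerge:
    def test_perfect_overlap_length(self):
        template = _random_template(80)
        p = _pair_from_template(template, 60, 60)
        params = PreprocessParams(length_window=(1, 200))
        [m], dropped = merge_pairs([p], params)
        assert dropped == 0
        assert len(m.sequence) == 60 + 60 - 40
        assert m.sequence == template

    def test_too_many_overlap_mismatches_discarded(self):
        template = _random_template(140)
        fwd = template[:100]
        rev_template = list(template)
        # 11 mismatches inside the 60-base overlap [40, 100)
        for pos in range(45, 56):
            rev_template[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[
                rev_template[pos]
            ]
        rev = revcomp("".join(rev_template))[:100]
        params = PreprocessParams(max_merge_diffs=10, length_window=(1, 300))
        kept, dropped = merge_pairs([_pair(fwd, rev)], params)
        assert kept == [] and dropped == 1
        # at 10 mismatches the pair is retained
        rev_template[45] = template[45]
        rev = revcomp("".join(rev_template))[:100]
        kept, dropped = merge_pairs([_pair(fwd, rev)], params)
        assert len(kept) == 1 and dropped == 0

    def test_posterior_quality_of_agreeing_bases(self):
        # two Q20 bases agreeing: error 1e-2 * 1e-2 = 1e-4 -> Phred 40
        template = _random_template(64)
        p = _pair_from_template(template, 48, 48, fq=20, rq=20)
        params = PreprocessParams()
        [m], _ = merge_pairs([p], params)
        overlap = slice(64 - 48, 48)
        assert all(q == 40 for q in m.quals[overlap])
        # non-overlap keeps the original quality
        assert m.quals[0] == 20

    def test_disagreeing_base_keeps_higher_quality(self):
        template = _random_template(80)
        fwd = template[:60]
        rev_t = list(template)
        assert template[40] != "G"  # holds for this seed
        rev_t[40] = "G"  # inside overlap [20, 60)
        rev = revcomp("".join(rev_t))[:60]
        p = _pair(fwd, rev, fq=35, rq=20)
        [m], _ = merge_pairs([p], PreprocessParams())
        assert m.sequence[40] == template[40]  # forward base wins at Q35
        # posterior error e_hi/(e_hi + e_lo) with e=10^-3.5 vs 10^-2
        e_hi, e_lo = 10**-3.5, 10**-2.0
        expected_q = round(-10 * np.log10(e_hi / (e_hi + e_lo)))
        assert m.quals[40] == expected_q

    def test_error_free_simulated_pairs_reconstruct_template(self):
        refs = generate_reference_set(3, 252, 20, seed=4)
        templates = dict(refs.alleles())
        mix = {t: 1 / 3 for t in templates}
        reads = sequence_reads(
            mix, templates, ErrorModel.noiseless(251), 60, seed=8
        )
        trimmed, _ = trim_reads(reads, PreprocessParams())
        merged, dropped = merge_pairs(trimmed, PreprocessParams())
        assert dropped == 0
        for m in merged:
            assert m.sequence == templates[m.origin][15:237]


class TestFilters:
    def test_length_window_boundaries(self):
        params = PreprocessParams(length_window=(220, 225))
        recs = [
            MergedRead("a", "A" * 222, (30,) * 222),
            MergedRead("b", "A" * 226, (30,) * 226),
            MergedRead("c", "A" * 219, (30,) * 219),
        ]
        kept, dropped = length_filter(recs, params)
        assert [r.read_id for r in kept] == ["a"] and dropped == 2

    def test_expected_errors_arithmetic(self):
        assert expected_errors((20,) * 100) == pytest.approx(1.0)
        assert expected_errors((20,) * 300) == pytest.approx(3.0)
        with pytest.raises(ValueError):
            expected_errors(())

    def test_ee_filter_thresholds(self):
        r100 = MergedRead("a", "A" * 100, (20,) * 100)  # EE = 1
        r300 = MergedRead("b", "A" * 300, (20,) * 300)  # EE = 3
        kept, dropped = expected_error_filter([r100, r300], 2.0)
        assert [r.read_id for r in kept] == ["a"] and dropped == 1
        kept, _ = expected_error_filter([r100, r300], np.inf)
        assert len(kept) == 2

    @given(st.floats(0.0, 5.0), st.floats(0.0, 5.0))
    @settings(max_examples=30, deadline=None)
    def test_ee_filter_monotone(self, ee_a, ee_b):
        lo, hi = sorted((ee_a, ee_b))
        rng = np.random.default_rng(0)
        recs = [
            MergedRead(f"r{i}", "A" * 50, tuple(rng.integers(2, 42, 50)))
            for i in range(30)
        ]
        kept_lo, _ = expected_error_filter(recs, lo)
        kept_hi, _ = expected_error_filter(recs, hi)
        assert {r.read_id for r in kept_lo} <= {r.read_id for r in kept_hi}


class TestDereplicate:
    def _rec(self, seq, sample="s1", rid="r"):
        return MergedRead(rid, seq, (30,) * len(seq), sample=sample)

    def test_grouping_and_order(self):
        recs = [self._rec("AAAA"), self._rec("AAAA"), self._rec("CCCC")]
        derep = dereplicate(recs)
        assert [(e.sequence, e.abundance) for e in derep.entries] == [
            ("AAAA", 2), ("CCCC", 1),
        ]

    def test_tie_broken_lexicographically(self):
        recs = [self._rec("TTTT"), self._rec("AAAA"), self._rec("GGGG")]
        derep = dereplicate(recs)
        assert derep.sequences() == ["AAAA", "GGGG", "TTTT"]

    def test_pooled_scope_conserves_per_sample_counts(self):
        recs = [
            self._rec("AAAA", "s1"), self._rec("AAAA", "s2"),
            self._rec("AAAA", "s2"), self._rec("CCCC", "s1"),
        ]
        pooled = dereplicate(recs, "pooled")
        assert pooled.entries[0].sample_counts == {"s1": 1, "s2": 2}
        per = dereplicate(recs, "per-sample")
        assert per["s1"].total_abundance == 2
        assert per["s2"].total_abundance == 2
        assert pooled.total_abundance == 4

    def test_invalid_abundance_rejected(self):
        from ampbench.preprocess import DerepEntry

        with pytest.raises(ValueError):
            DereplicatedSet((DerepEntry("AAAA", 2, {"s1": 1}),))


class TestLedger:
    @given(
        depth=st.integers(30, 120),
        max_ee=st.floats(0.05, 3.0),
        seed=st.integers(0, 50),
    )
    @settings(max_examples=10, deadline=None)
    def test_conservation_identity(self, depth, max_ee, seed):
        """input = output + dropped at every stage, whatever the settings."""
        refs = generate_reference_set(3, 252, 20, seed=4)
        templates = dict(refs.alleles())
        mix = {t: 1 / 3 for t in templates}
        em = ErrorModel(
            quality_profile_fwd=QualityProfile(251, 36.0, 22.0, 3.0),
            quality_profile_rev=QualityProfile(251, 33.0, 18.0, 3.0),
        )
        reads = sequence_reads(mix, templates, em, depth, seed=seed)
        params = PreprocessParams(max_expected_errors_merged=max_ee)
        merged, ledger = preprocess_reads(reads, params)
        ledger.check()  # raises on violation
        assert ledger.input == depth
        assert ledger.output == len(merged)

    def test_dada_branch_filters_mates_independently(self):
        refs = generate_reference_set(2, 252, 20, seed=4)
        templates = dict(refs.alleles())
        mix = {t: 0.5 for t in templates}
        em = ErrorModel(
            quality_profile_fwd=QualityProfile(251, 30.0, 12.0, 4.0),
            quality_profile_rev=QualityProfile(251, 28.0, 10.0, 4.0),
        )
        reads = sequence_reads(mix, templates, em, 300, seed=2)
        strict = PreprocessParams(max_ee_fwd=0.5, max_ee_rev=0.5)
        merged, ledger = preprocess_reads(reads, strict, branch="dada")
        ledger.check()
        assert ledger.dropped_ee > 0
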