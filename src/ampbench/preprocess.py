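"""Read preprocessing: trimming, pair merging, filtering, dereplication.

The default branch follows the merge-first protocol: 5' head trim and
per-dataset 3' trims, ungapped pair merging with posterior qualities and a
maximum number of overlap differences, a merged-length window, then an
expected-error (EE) filter on the merged posterior qualities. The ``dada``
branch instead filters the two mates independently (with their own EE
ceilings) before merging, mirroring per-read-filtering workflows.

Every stage returns explicit drop counts; ``PreprocessLedger`` enforces the
conservation identity input = output + sum(dropped).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

from ._seq import decode, encode, revcomp
from .simulate import PHRED_MAX, PHRED_MIN, ReadPair, phred_to_error


@dataclass(frozen=True)
class PreprocessParams:
    head_trim: int = 15
    trim_fwd: int = 230
    trim_rev: int = 210
    max_merge_diffs: int = 10
    min_overlap: int = 16
    length_window: tuple[int, int] = (220, 225)
    max_expected_errors_merged: float = 2.0
    max_ee_fwd: float = 2.5
    max_ee_rev: float = 2.5

    def __post_init__(self):
        lo, hi = self.length_window
        if lo > hi:
            raise ValueError("length_window min must be <= max")
        for name in (
            "head_trim", "max_merge_diffs", "min_overlap",
            "max_expected_errors_merged", "max_ee_fwd", "max_ee_rev",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class PreprocessLedger:
    input: int = 0
    dropped_trim: int = 0
    dropped_merge: int = 0
    dropped_length: int = 0
    dropped_ee: int = 0
    output: int = 0

    def check(self) -> None:
        lost = (
            self.dropped_trim + self.dropped_merge
            + self.dropped_length + self.dropped_ee
        )
        if self.input != self.output + lost:
            raise AssertionError(
                f"ledger violation: {self.input} != {self.output} + {lost}"
            )


@dataclass(frozen=True)
class MergedRead:
    read_id: str
    sequence: str
    quals: tuple[int, ...]
    sample: str = "s1"
    origin: str = ""

    def __post_init__(self):
        if len(self.sequence) != len(self.quals):
            raise ValueError("sequence/quality length mismatch")


def expected_errors(quals: Sequence[int]) -> float:
    """EE = sum of per-base error probabilities 10^(-q/10)."""
    if len(quals) == 0:
        raise ValueError("empty quality string")
    return float(phred_to_error(np.asarray(quals)).sum())


# ---------------------------------------------------------------------------
# trimming


def trim_reads(
    pairs: Iterable[ReadPair], params: PreprocessParams
) -> tuple[list[ReadPair], int]:
    """Remove the 5' head and 3' tail of both mates; qualities in lockstep.

    Keeps forward cycles (head_trim, trim_fwd] and reverse cycles
    (head_trim, trim_rev], 1-based. A window that empties either mate
    drops the pair (counted, never silent).
    """
    kept, dropped = [], 0
    for p in pairs:
        f_end = min(params.trim_fwd, len(p.fwd_seq))
        r_end = min(params.trim_rev, len(p.rev_seq))
        if f_end <= params.head_trim or r_end <= params.head_trim:
            dropped += 1
            continue
        kept.append(
            ReadPair(
                read_id=p.read_id,
                fwd_seq=p.fwd_seq[params.head_trim:f_end],
                fwd_quals=p.fwd_quals[params.head_trim:f_end],
                rev_seq=p.rev_seq[params.head_trim:r_end],
                rev_quals=p.rev_quals[params.head_trim:r_end],
                origin=p.origin,
                sample=p.sample,
            )
        )
    return kept, dropped


# ---------------------------------------------------------------------------
# merging


def _posterior_merge_arrays(ov_f, qf, ov_r, qr):
    """Consensus bases and posterior Phred scores for an overlap region.

    Agreement: error = e1*e2 (capped at Phred 41). Disagreement: keep the
    higher-quality base with error e_hi/(e_hi+e_lo) (floored at Phred 2).
    """
    ef = phred_to_error(qf)
    er = phred_to_error(qr)
    agree = ov_f == ov_r
    take_f = qf >= qr
    base = np.where(agree, ov_f, np.where(take_f, ov_f, ov_r))
    e_hi = np.minimum(ef, er)
    with np.errstate(divide="ignore"):
        e_post = np.where(agree, ef * er, e_hi / (ef + er))
        phred = -10.0 * np.log10(np.maximum(e_post, 1e-30))
    phred = np.clip(np.rint(phred), PHRED_MIN, PHRED_MAX).astype(np.int16)
    return base, phred


def merge_pairs(
    pairs: Sequence[ReadPair], params: PreprocessParams
) -> tuple[list[MergedRead], int]:
    """Merge mates at the ungapped overlap maximizing matched bases.

    Pairs whose best overlap carries more than ``max_merge_diffs``
    mismatches, or that admit no overlap >= ``min_overlap``, are discarded
    and counted. Merged length = len_fwd + len_rev - overlap.
    """
    merged: list[MergedRead] = []
    dropped = 0
    groups: dict[tuple[int, int], list[int]] = {}
    pairs = list(pairs)
    for i, p in enumerate(pairs):
        groups.setdefault((len(p.fwd_seq), len(p.rev_seq)), []).append(i)

    for (lf, lr), idxs in groups.items():
        omax = min(lf, lr)
        if omax < params.min_overlap:
            dropped += len(idxs)
            continue
        n = len(idxs)
        F = np.empty((n, lf), dtype=np.uint8)
        QF = np.empty((n, lf), dtype=np.int16)
        R = np.empty((n, lr), dtype=np.uint8)
        QR = np.empty((n, lr), dtype=np.int16)
        for row, i in enumerate(idxs):
            p = pairs[i]
            F[row] = encode(p.fwd_seq)
            QF[row] = p.fwd_quals
            R[row] = encode(revcomp(p.rev_seq))
            QR[row] = p.rev_quals[::-1]

        overlaps = np.arange(omax, params.min_overlap - 1, -1)  # prefer long
        matches = np.empty((n, len(overlaps)), dtype=np.int32)
        mismatches = np.empty_like(matches)
        for j, o in enumerate(overlaps):
            mm = (F[:, lf - o:] != R[:, :o]).sum(axis=1)
            mismatches[:, j] = mm
            matches[:, j] = o - mm
        best_j = np.argmax(matches, axis=1)
        best_o = overlaps[best_j]
        best_mm = mismatches[np.arange(n), best_j]

        for o in np.unique(best_o):
            rows = np.flatnonzero(
                (best_o == o) & (best_mm <= params.max_merge_diffs)
            )
            if rows.size == 0:
                continue
            ov_base, ov_phred = _posterior_merge_arrays(
                F[rows, lf - o:], QF[rows, lf - o:],
                R[rows, :o], QR[rows, :o],
            )
            seq_arr = np.concatenate([F[rows, : lf - o], ov_base, R[rows, o:]], axis=1)
            qual_arr = np.concatenate(
                [QF[rows, : lf - o], ov_phred, QR[rows, o:]], axis=1
            )
            for row, s, q in zip(rows, seq_arr, qual_arr):
                p = pairs[idxs[row]]
                merged.append(
                    MergedRead(
                        read_id=p.read_id,
                        sequence=decode(s),
                        quals=tuple(int(x) for x in q),
                        sample=p.sample,
                        origin=p.origin,
                    )
                )
        dropped += int((best_mm > params.max_merge_diffs).sum())
    return merged, dropped


# ---------------------------------------------------------------------------
# filters


def length_filter(
    records: Iterable[MergedRead], params: PreprocessParams
) -> tuple[list[MergedRead], int]:
    lo, hi = params.length_window
    kept = [r for r in records if lo <= len(r.sequence) <= hi]
    records = list(records) if not isinstance(records, list) else records
    return kept, len(records) - len(kept)


def expected_error_filter(
    records: Iterable[MergedRead], max_ee: float
) -> tuple[list[MergedRead], int]:
    records = list(records)
    kept = [r for r in records if expected_errors(r.quals) <= max_ee]
    return kept, len(records) - len(kept)


def mate_ee_filter(
    pairs: Iterable[ReadPair], max_ee_fwd: float, max_ee_rev: float
) -> tuple[list[ReadPair], int]:
    """Independent per-mate EE filter (the per-read branch); a pair is
    dropped when either mate exceeds its ceiling."""
    pairs = list(pairs)
    kept = [
        p
        for p in pairs
        if expected_errors(p.fwd_quals) <= max_ee_fwd
        and expected_errors(p.rev_quals) <= max_ee_rev
    ]
    return kept, len(pairs) - len(kept)


# ---------------------------------------------------------------------------
# dereplication


@dataclass(frozen=True)
class DerepEntry:
    sequence: str
    abundance: int
    sample_counts: dict[str, int] = field(compare=False)
    mean_quals: np.ndarray | None = field(default=None, compare=False, repr=False)


@dataclass(frozen=True)
class DereplicatedSet:
    """Unique sequences with abundances, ordered by decreasing abundance
    (ties broken lexicographically by sequence)."""

    entries: tuple[DerepEntry, ...]

    def __post_init__(self):
        for e in self.entries:
            if e.abundance < 1:
                raise ValueError("abundances must be >= 1")
            if e.abundance != sum(e.sample_counts.values()):
                raise ValueError("abundance must equal sum of sample counts")

    @property
    def total_abundance(self) -> int:
        return sum(e.abundance for e in self.entries)

    def sequences(self) -> list[str]:
        return [e.sequence for e in self.entries]


def dereplicate(
    records: Iterable[MergedRead],
    scope: Literal["pooled", "per-sample"] = "pooled",
) -> DereplicatedSet | dict[str, DereplicatedSet]:
    """Collapse identical sequences; pooled scope keeps per-sample counts.

    Per-sample scope returns one DereplicatedSet per sample (keyed by
    sample id). Mean per-position Phred scores are retained for error-model
    estimation downstream.
    """
    records = list(records)
    if scope == "per-sample":
        by_sample: dict[str, list[MergedRead]] = {}
        for r in records:
            by_sample.setdefault(r.sample, []).append(r)
        return {s: dereplicate(rs, "pooled") for s, rs in sorted(by_sample.items())}

    buckets: dict[str, list[MergedRead]] = {}
    for r in records:
        buckets.setdefault(r.sequence, []).append(r)
    entries = []
    for seq, rs in buckets.items():
        counts: dict[str, int] = {}
        for r in rs:
            counts[r.sample] = counts.get(r.sample, 0) + 1
        quals = np.rint(
            np.mean([r.quals for r in rs], axis=0)
        ).astype(np.int16)
        entries.append(
            DerepEntry(
                sequence=seq,
                abundance=len(rs),
                sample_counts=counts,
                mean_quals=quals,
            )
        )
    entries.sort(key=lambda e: (-e.abundance, e.sequence))
    return DereplicatedSet(tuple(entries))


# ---------------------------------------------------------------------------
# orchestration


def preprocess_reads(
    pairs: Sequence[ReadPair],
    params: PreprocessParams,
    branch: Literal["merged", "dada"] = "merged",
) -> tuple[list[MergedRead], PreprocessLedger]:
    """Run the full preprocessing chain under the chosen filter ordering."""
    ledger = PreprocessLedger(input=len(pairs))
    trimmed, ledger.dropped_trim = trim_reads(pairs, params)
    if branch == "merged":
        merged, ledger.dropped_merge = merge_pairs(trimmed, params)
        merged, ledger.dropped_length = length_filter(merged, params)
        merged, ledger.dropped_ee = expected_error_filter(
            merged, params.max_expected_errors_merged
        )
    elif branch == "dada":
        trimmed, ledger.dropped_ee = mate_ee_filter(
            trimmed, params.max_ee_fwd, params.max_ee_rev
        )
        merged, ledger.dropped_merge = merge_pairs(trimmed, params)
        merged, ledger.dropped_length = length_filter(merged, params)
    else:
        raise ValueError(f"unknown branch {branch!r}")
    ledger.output = len(merged)
    ledger.check()
    return merged, ledger
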