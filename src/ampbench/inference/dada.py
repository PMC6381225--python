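"""Divisive partitioning denoiser with a self-trained error model.

The algorithm alternates two loops:

* inner (partitioning): all unique sequences start in one cluster seeded
  by the most abundant sequence. For every non-centroid sequence s with
  centroid c, the probability lambda(s | c) of reading s when the true
  template is c is the product over positions of the error-matrix entry
  for (template base, read base, quality). The expected number of reads
  E = lambda * abundance(c) gives an abundance p-value
  P(X >= abundance(s) | X ~ Poisson(E), X >= 1); if the smallest p-value
  falls below the threshold omega, that sequence seeds a new cluster and
  every sequence reassigns to the centroid maximizing lambda. Repeats to
  a fixpoint.
* outer (error-model estimation): the per-(template base, read base,
  quality) substitution rates are re-estimated from within-cluster base
  transitions, and partitioning repeats, until the matrix stabilizes
  (L-inf change < 1e-7) or ``max_iterations`` is hit (returned as a
  non-convergence flag, never silently).

The abundance p-value uses a Poisson tail conditioned on observing at
least one read — a deliberate simplification of the source method's
abundance statistic. Samples are processed independently by default,
which is what makes this method's output invariant to pooling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .._seq import encode
from ..preprocess import DereplicatedSet
from ..simulate import PHRED_MAX
from ._table import FeatureTable, build_table

_NQ = PHRED_MAX + 1  # quality axis 0..41


@dataclass(frozen=True)
class DadaParams:
    omega: float = 1e-40
    max_iterations: int = 8
    #: pessimistic initial total substitution rate per base (split evenly
    #: over the three alternatives), independent of quality
    initial_error_rate: float = 0.01
    matrix_tol: float = 1e-7

    def __post_init__(self):
        if not 0.0 <= self.omega < 1.0:
            raise ValueError("omega must be in [0, 1)")
        if not 0.0 < self.initial_error_rate < 1.0:
            raise ValueError("initial_error_rate must be in (0, 1)")


@dataclass
class DadaResult:
    table: FeatureTable
    converged: bool
    n_iterations: int


def _initial_matrix(rate: float) -> np.ndarray:
    """Error matrix M[from, to, q] = P(read 'to' | template 'from', q)."""
    m = np.full((4, 4, _NQ), rate / 3.0)
    for b in range(4):
        m[b, b, :] = 1.0 - rate
    return m


def _log_lambda(
    log_m: np.ndarray, seqs: np.ndarray, quals: np.ndarray, centroid: np.ndarray
) -> np.ndarray:
    """log lambda of every row sequence given one centroid sequence."""
    ll = log_m[centroid[None, :], seqs, quals]
    return ll.sum(axis=1)


def _partition(
    seqs: np.ndarray,
    quals: np.ndarray,
    abund: np.ndarray,
    log_m: np.ndarray,
    omega: float,
) -> list[int]:
    """Inner loop: returns the centroid row index for every sequence."""
    n = len(abund)
    centroids = [0]  # row 0 is the most abundant (derep ordering)
    assign = np.zeros(n, dtype=int)
    ll_rows = [_log_lambda(log_m, seqs, quals, seqs[0])]
    while True:
        ll = np.stack(ll_rows)  # (n_clusters, n)
        # reassign everyone to the centroid with maximal lambda; centroids
        # stay their own cluster by construction (lambda is maximal at 0
        # mismatches for any sane matrix)
        assign = np.argmax(ll, axis=0)
        for ci, c in enumerate(centroids):
            assign[c] = ci
        # abundance p-values within clusters
        lam = np.exp(ll[assign, np.arange(n)])
        cab = abund[np.array(centroids)]
        expected = lam * cab[assign]
        pvals = np.ones(n)
        member = np.ones(n, dtype=bool)
        for ci, c in enumerate(centroids):
            member[c] = False
        idx = np.flatnonzero(member)
        if idx.size:
            e = expected[idx]
            a = abund[idx]
            with np.errstate(divide="ignore", invalid="ignore"):
                tail = stats.poisson.sf(a - 1, e)
                norm = -np.expm1(-e)
            p = np.where(norm > 0, tail / np.maximum(norm, 1e-300), 1.0)
            # in the E -> 0 limit the conditional tail is 1 for a single
            # read and 0 for any repeated sequence (maximally surprising)
            p = np.where(a <= 1, 1.0, np.where(e <= 0, 0.0, p))
            pvals[idx] = np.minimum(p, 1.0)
        worst = int(np.argmin(pvals))
        if pvals[worst] < omega and worst not in centroids:
            centroids.append(worst)
            ll_rows.append(_log_lambda(log_m, seqs, quals, seqs[worst]))
        else:
            break
    return [centroids[a] for a in assign]


def _estimate_matrix(
    seqs: np.ndarray,
    quals: np.ndarray,
    abund: np.ndarray,
    assign: list[int],
    prior_rate: float,
) -> np.ndarray:
    """Outer loop: per-(from, to, q) transition rates from the clustering,
    with a light pseudocount toward the prior to avoid zeros."""
    counts = np.zeros((4, 4, _NQ))
    assign_arr = np.asarray(assign)
    for c in np.unique(assign_arr):
        rows = np.flatnonzero(assign_arr == c)
        cen = seqs[c]
        for r in rows:
            np.add.at(counts, (cen, seqs[r], quals[r]), abund[r])
    prior = _initial_matrix(prior_rate)
    counts += 0.5 * prior  # pseudocounts shaped like the prior
    totals = counts.sum(axis=1, keepdims=True)
    return counts / totals


def denoise_dada(
    derep: DereplicatedSet, params: DadaParams | None = None
) -> DadaResult:
    """Run the full alternating algorithm on one sample's dereplicated set."""
    params = params or DadaParams()
    if not derep.entries:
        return DadaResult(build_table({}, method="dada"), True, 0)
    lengths = {len(e.sequence) for e in derep.entries}
    if len(lengths) != 1:
        raise ValueError("dada partitioning requires equal-length sequences")
    seqs = np.stack([encode(e.sequence) for e in derep.entries])
    quals = np.stack(
        [
            np.clip(e.mean_quals, 0, PHRED_MAX)
            if e.mean_quals is not None
            else np.full(len(e.sequence), 30, dtype=np.int16)
            for e in derep.entries
        ]
    ).astype(int)
    abund = np.array([e.abundance for e in derep.entries], dtype=float)

    m = _initial_matrix(params.initial_error_rate)
    assign: list[int] = [0] * len(abund)
    converged = False
    it = 0
    for it in range(1, params.max_iterations + 1):
        log_m = np.log(np.maximum(m, 1e-300))
        assign = _partition(seqs, quals, abund, log_m, params.omega)
        m_new = _estimate_matrix(
            seqs, quals, abund, assign, params.initial_error_rate
        )
        if np.max(np.abs(m_new - m)) < params.matrix_tol:
            converged = True
            m = m_new
            break
        m = m_new

    counts: dict[str, dict[str, int]] = {}
    for row, c in enumerate(assign):
        dest = counts.setdefault(derep.entries[c].sequence, {})
        for s, cnt in derep.entries[row].sample_counts.items():
            dest[s] = dest.get(s, 0) + cnt
    return DadaResult(build_table(counts, method="dada"), converged, it)


def denoise_dada_per_sample(
    derep_by_sample: dict[str, DereplicatedSet], params: DadaParams | None = None
) -> DadaResult:
    """Run the denoiser independently on each sample and merge the tables.

    Per-sample processing is the default mode; it guarantees that a
    sample's inferred features do not depend on which other samples were
    processed alongside it.
    """
    merged: dict[str, dict[str, int]] = {}
    converged = True
    iters = 0
    for sample in sorted(derep_by_sample):
        res = denoise_dada(derep_by_sample[sample], params)
        converged &= res.converged
        iters = max(iters, res.n_iterations)
        for f in res.table.features:
            dest = merged.setdefault(f.sequence, {})
            for s, c in f.counts.items():
                dest[s] = dest.get(s, 0) + c
    return DadaResult(build_table(merged, method="dada"), converged, iters)
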