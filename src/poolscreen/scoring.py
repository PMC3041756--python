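"""Gene scoring: Poisson-tail p-values, Bonferroni, and yield at FDR.

A gene observed with ``m`` mutations across the sequenced strains is
scored against the null hypothesis that it is *not* a target: its count is
then Poisson with mean equal to ``S`` times its effective size, and the
p-value is the upper tail ``P(X >= m)``.  Note that ``m = 0`` gives a
p-value of exactly 1.

The *yield at FDR* is the number of true targets that can be reported
while keeping the fraction of non-targets in the reported list strictly
below the specified false discovery rate; with equal-size genes this is a
mutation-count threshold, and in general a p-value cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "GeneScore",
    "gene_pvalue",
    "bonferroni_correct",
    "yield_from_counts",
    "yield_from_scores",
    "yields_from_batches",
    "calibration_curve",
    "rank_scores",
]


@dataclass
class GeneScore:
    """Score record for one gene."""

    gene_id: str
    hit_count: int
    expected: float
    p_raw: float
    p_corrected: float = 1.0
    is_target: bool | None = None


def gene_pvalue(hit_count: int, expected: float) -> float:
    """Upper-tail Poisson p-value ``P(X >= m)`` for an observed count.

    ``expected`` is the gene's null mean (``S`` strains times the gene's
    effective size).  ``m = 0`` returns exactly 1.
    """
    if hit_count < 0 or expected < 0:
        raise ValueError("hit_count and expected must be >= 0")
    if hit_count == 0:
        return 1.0
    return float(stats.poisson.sf(hit_count - 1, expected))


def bonferroni_correct(p_raw: float, n_tests: int) -> float:
    """Multiply by the number of tests, capping the result at 1."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return min(1.0, p_raw * n_tests)


# ---------------------------------------------------------------------------
# Yield at a specified FDR
# ---------------------------------------------------------------------------

def yields_from_batches(target_counts: np.ndarray,
                        nontarget_hist: np.ndarray,
                        fdr: float) -> np.ndarray:
    """Vectorised count-threshold yield for replicate experiments.

    Parameters
    ----------
    target_counts
        ``(R, T)`` per-target-gene counts.
    nontarget_hist
        ``(R, M)`` histogram; column ``m`` counts non-target genes with
        exactly ``m`` mutations.
    fdr
        False discovery rate bound (strict comparison).

    For each replicate, finds the smallest count threshold ``m*`` such
    that for every ``m >= m*`` the fraction of non-targets among all genes
    with at least ``m`` mutations is strictly below ``fdr`` (cutoffs where
    no gene at all is reported satisfy the bound vacuously), and returns
    the number of targets with count ``>= m*`` (0 when no threshold
    qualifies).
    """
    if not (0.0 < fdr < 1.0):
        raise ValueError("fdr must lie in (0, 1)")
    target_counts = np.asarray(target_counts)
    nontarget_hist = np.asarray(nontarget_hist)
    n_reps = target_counts.shape[0]
    m_max = max(int(target_counts.max(initial=0)),
                nontarget_hist.shape[1] - 1)
    # Suffix (>= m) gene counts for m = 0..m_max+1 (last column all zero).
    nt_dense = np.zeros((n_reps, m_max + 2), dtype=np.int64)
    nt_dense[:, : nontarget_hist.shape[1]] = nontarget_hist
    nt_ge = np.flip(np.cumsum(np.flip(nt_dense, axis=1), axis=1), axis=1)
    onehot = np.zeros((n_reps, m_max + 2), dtype=np.int64)
    np.add.at(onehot, (np.repeat(np.arange(n_reps), target_counts.shape[1]),
                       target_counts.ravel()), 1)
    t_ge = np.flip(np.cumsum(np.flip(onehot, axis=1), axis=1), axis=1)
    total = nt_ge + t_ge
    cond = (nt_ge < fdr * total) | (total == 0)
    # ok[m] == condition holds for every m' >= m.
    ok = np.flip(np.logical_and.accumulate(np.flip(cond, axis=1), axis=1),
                 axis=1)
    ok[:, 0] = False  # m* >= 1: reporting the whole genome is not a cutoff
    any_ok = ok[:, 1:].any(axis=1)
    m_star = np.where(any_ok, np.argmax(ok[:, 1:], axis=1) + 1, m_max + 1)
    return np.where(any_ok, np.take_along_axis(
        t_ge, m_star[:, None], axis=1)[:, 0], 0)


def yield_from_counts(target_counts: Sequence[int],
                      nontarget_histogram: dict[int, int],
                      fdr: float) -> int:
    """Count-threshold yield for a single experiment (see batch version)."""
    counts = np.asarray(list(target_counts), dtype=np.int64)[None, :]
    m_max = max(nontarget_histogram, default=0)
    hist = np.zeros((1, m_max + 1), dtype=np.int64)
    for m, c in nontarget_histogram.items():
        if m < 0 or c < 0:
            raise ValueError("histogram entries must be non-negative")
        hist[0, m] = c
    return int(yields_from_batches(counts, hist, fdr)[0])


def yield_from_scores(scores: Sequence[GeneScore], fdr: float) -> int:
    """P-value-cutoff yield for variable-size genes.

    Sorts genes by raw p-value and finds the largest cutoff ``p*`` such
    that, at this and every stricter observed cutoff, the fraction of
    non-targets among genes with ``p < cutoff`` stays strictly below
    ``fdr``; returns the number of true targets with ``p < p*``.
    """
    if not (0.0 < fdr < 1.0):
        raise ValueError("fdr must lie in (0, 1)")
    scores = list(scores)
    if not scores:
        return 0
    if any(s.is_target is None for s in scores):
        raise ValueError("yield_from_scores requires is_target labels")
    p = np.array([s.p_raw for s in scores])
    is_t = np.array([bool(s.is_target) for s in scores])
    order = np.argsort(p, kind="stable")
    p, is_t = p[order], is_t[order]
    cum_t = np.cumsum(is_t)
    cum_nt = np.cumsum(~is_t)
    # Candidate cutoffs: each distinct observed p (reporting genes with
    # strictly smaller p) plus +inf (reporting everything).
    boundaries = np.flatnonzero(np.diff(p) > 0)  # index i: genes 0..i reported
    sizes = np.concatenate([boundaries + 1, [p.size]])
    best_yield = 0
    for n_rep in sizes:
        nt = cum_nt[n_rep - 1]
        if not (nt < fdr * n_rep):
            break
        best_yield = int(cum_t[n_rep - 1])
    return best_yield


def rank_scores(scores: Sequence[GeneScore]) -> list[GeneScore]:
    """Deterministic ranking: p ascending, hits descending, gene_id."""
    return sorted(scores, key=lambda s: (s.p_raw, -s.hit_count, s.gene_id))


# ---------------------------------------------------------------------------
# P-value calibration diagnostic
# ---------------------------------------------------------------------------

def calibration_curve(config, rng: np.random.Generator,
                      genes=None,
                      replicates: int | None = None
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Expected vs. observed negative-log survival of null p-values.

    Samples mutation counts for every gene under the non-target null
    (plain Poisson with mean ``S`` times the gene's effective size, or the
    uniform ``S * mu_per_gene`` when ``genes`` is None), computes each
    p-value, sorts ascending, and pairs each ``-log p`` with the negative
    log of its empirical rank fraction ``(i + 1) / N``.

    With uniform gene sizes the curve lies on the ``y = x`` diagonal up to
    sampling error; with variable sizes it lies on or above it (the
    p-values are slightly conservative, because a large gene's near-1
    p-value understates how often small genes reach the same count).

    ``genes`` may be a list of :class:`~poolscreen.screen_model.GeneModel`
    or a list of ``(mean_lambda, count)`` size-class bins.
    """
    replicates = config.replicates if replicates is None else replicates
    if genes is None:
        lams = np.full(config.n_genes, config.mu_per_gene)
    elif genes and isinstance(genes[0], tuple):
        lams = np.concatenate([np.full(n, lam) for lam, n in genes])
    else:
        lams = np.array([g.lambda_per_strain for g in genes])
    means = config.n_strains * lams
    counts = rng.poisson(means, size=(replicates, means.size))
    p = stats.poisson.sf(counts - 1, means[None, :])
    p[counts == 0] = 1.0
    p = np.sort(p.ravel())
    n = p.size
    emp = (np.arange(n) + 1.0) / n
    return -np.log(p), -np.log(emp)
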