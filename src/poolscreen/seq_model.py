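"""Binomial model of SNP calling in pooled libraries.

When ``P`` strains are pooled into one library and sequenced at mean
coverage ``c``, a mutation carried by one strain appears in a fraction
``(1 - eps) / P`` of the reads covering its site, while a sequencing error
produces a specific wrong nucleotide in a fraction ``eps`` of reads.  A
site is called mutant when at least ``k`` reads support the alternate
base, so

* the *mutation detection failure rate* (false negative) is the lower
  binomial tail ``P(X < k)`` with ``X ~ Binomial(c, (1 - eps)/P)``;
* the *mutation false positive rate* per site is the upper tail
  ``P(X >= k)`` with ``X ~ Binomial(c, eps)``.

Raising ``k`` suppresses false positives but loses real mutations; for
typical parameters (``c = 75``, ``P <= 5``, ``eps = 0.01``) there is an
"ideal zone" of thresholds where both genome-wide expected counts are
below one.  These rates feed back into the screen simulator as a
detection-failure category and per-gene false-positive Poisson calls.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .screen_model import (
    DEFAULT_GENOME_LENGTH,
    ScreenConfig,
    simulate_screens,
)
from .scoring import yields_from_batches

__all__ = [
    "SeqDesign",
    "ErrorProfile",
    "detection_failure_rate",
    "false_positive_rate",
    "expected_false_calls",
    "error_profile",
    "apply_sequencing_effects",
    "min_threshold_fp_below",
    "ideal_zone",
    "scan_thresholds",
]


@dataclass(frozen=True)
class SeqDesign:
    """Sequencing design for one pooled library.

    ``error_rate`` is the probability of reading one *specific* wrong
    nucleotide (a third or so of the total miscall probability), exactly
    as it enters the binomial tails; no factor of three is applied
    anywhere.
    """

    coverage: float
    pool_factor: int = 1
    error_rate: float = 0.01
    call_threshold: int = 1
    genome_length: int = DEFAULT_GENOME_LENGTH
    tag_pool: int = 1
    lane_capacity: float = 1.5e9

    def __post_init__(self) -> None:
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")
        if self.pool_factor < 1:
            raise ValueError("pool_factor must be >= 1")
        if not (0.0 <= self.error_rate < 1.0):
            raise ValueError("error_rate must lie in [0, 1)")
        if self.call_threshold < 1:
            raise ValueError("call_threshold must be >= 1")

    @property
    def n_trials(self) -> int:
        """Binomial trial count: coverage rounded to the nearest read."""
        return int(round(self.coverage))


@dataclass(frozen=True)
class ErrorProfile:
    """Derived per-design error rates, computed once and reused."""

    fail_rate: float
    fp_site_rate: float
    fp_genome_expect: float


def detection_failure_rate(design: SeqDesign) -> float:
    """Probability a real pooled mutation gathers fewer than ``k`` reads.

    Lower tail ``P(X < k)`` of ``Binomial(round(c), (1 - eps)/P)``.
    """
    p = (1.0 - design.error_rate) / design.pool_factor
    return float(stats.binom.cdf(design.call_threshold - 1, design.n_trials, p))


def false_positive_rate(design: SeqDesign) -> float:
    """Per-site probability that sequencing error alone yields a call.

    Upper tail ``P(X >= k)`` of ``Binomial(round(c), eps)``.
    """
    return float(stats.binom.sf(design.call_threshold - 1, design.n_trials,
                                design.error_rate))


def expected_false_calls(fp_site_rate: float, genome_length: float) -> float:
    """Expected number of false mutation calls over the whole genome."""
    if fp_site_rate < 0 or genome_length < 0:
        raise ValueError("inputs must be >= 0")
    return fp_site_rate * genome_length


def error_profile(design: SeqDesign) -> ErrorProfile:
    """Compute the design's failure and false-positive rates."""
    fp = false_positive_rate(design)
    return ErrorProfile(
        fail_rate=detection_failure_rate(design),
        fp_site_rate=fp,
        fp_genome_expect=expected_false_calls(fp, design.genome_length),
    )


def apply_sequencing_effects(target_probs: np.ndarray,
                             nontarget_lambda_total: np.ndarray,
                             gene_lengths: np.ndarray,
                             design: SeqDesign
                             ) -> tuple[np.ndarray, np.ndarray]:
    """Adjust screen parameters for detection failure and false positives.

    Returns ``(adjusted_target_probs, adjusted_nontarget_means)`` where
    the target probability vector is rescaled by ``1 - fail_rate`` with a
    final detection-failure category appended (counts drawn there are
    discarded by the simulator), and each non-target gene's total expected
    count becomes ``lambda_total * (1 - fail_rate) + length * fp_site_rate``.
    """
    prof = error_profile(design)
    target_probs = np.asarray(target_probs, dtype=float)
    probs = np.append(target_probs * (1.0 - prof.fail_rate), prof.fail_rate)
    adjusted = (np.asarray(nontarget_lambda_total, dtype=float)
                * (1.0 - prof.fail_rate)
                + np.asarray(gene_lengths, dtype=float) * prof.fp_site_rate)
    return probs, adjusted


def min_threshold_fp_below(design: SeqDesign, max_expected: float = 1.0,
                           k_max: int | None = None) -> int | None:
    """Lowest call threshold with genome-wide expected false calls below a bound."""
    k_max = design.n_trials if k_max is None else k_max
    for k in range(1, k_max + 1):
        d = replace(design, call_threshold=k)
        if expected_false_calls(false_positive_rate(d), design.genome_length) < max_expected:
            return k
    return None


def ideal_zone(design: SeqDesign, n_mutations: float = 1.0
               ) -> tuple[int, int] | None:
    """Threshold interval with both error regimes under control.

    Returns the (inclusive) range of ``k`` for which the genome-wide
    expected false-positive count is below one *and* the expected number
    of missed real mutations (``n_mutations * fail_rate``) is below one,
    or ``None`` if no such threshold exists.
    """
    ks = []
    for k in range(1, design.n_trials + 1):
        d = replace(design, call_threshold=k)
        fp_ok = expected_false_calls(false_positive_rate(d),
                                     design.genome_length) < 1.0
        fn_ok = n_mutations * detection_failure_rate(d) < 1.0
        if fp_ok and fn_ok:
            ks.append(k)
    if not ks:
        return None
    return min(ks), max(ks)


def scan_thresholds(config: ScreenConfig,
                    coverage: float,
                    pool_factors,
                    k_values,
                    rng: np.random.Generator,
                    error_rate: float = 0.01,
                    genome_length: int = DEFAULT_GENOME_LENGTH,
                    replicates: int | None = None,
                    genes=None):
    """Mean target yield for each (pool factor, call threshold) pair.

    For each ``(P, k)`` the screen is simulated ``replicates`` times with
    the corresponding error profile injected, and the mean yield at the
    configured FDR is recorded.  Returns a pandas DataFrame with columns
    ``(P, k, fail_rate, fp_genome, mean_yield, se_yield)``; the per-P
    optimum is ``df.loc[df.groupby("P")["mean_yield"].idxmax()]``.
    """
    import pandas as pd

    pool_factors = list(pool_factors)
    k_values = [int(k) for k in k_values]
    if not pool_factors or not k_values:
        raise ValueError("pool_factors and k_values must be non-empty")
    replicates = config.replicates if replicates is None else replicates
    rows = []
    for pool in pool_factors:
        for k in k_values:
            design = SeqDesign(coverage=coverage, pool_factor=pool,
                               error_rate=error_rate, call_threshold=k,
                               genome_length=genome_length)
            prof = error_profile(design)
            counts, hist = simulate_screens(config, rng, replicates,
                                            genes=genes, seq_effects=prof,
                                            genome_length=genome_length)
            y = yields_from_batches(counts, hist, config.fdr)
            rows.append({
                "P": pool, "k": k,
                "fail_rate": prof.fail_rate,
                "fp_genome": prof.fp_genome_expect,
                "mean_yield": float(y.mean()),
                "se_yield": float(y.std(ddof=1) / np.sqrt(len(y)))
                if len(y) > 1 else 0.0,
            })
    return pd.DataFrame(rows)


def optimal_threshold(scan: "pd.DataFrame", pool: int) -> tuple[int, float]:
    """Best call threshold and its mean yield for one pooling level."""
    sub = scan[scan["P"] == pool]
    row = sub.loc[sub["mean_yield"].idxmax()]
    return int(row["k"]), float(row["mean_yield"])
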