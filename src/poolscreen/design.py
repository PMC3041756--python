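"""Experiment design: coverage, cost arithmetic and pooling optimization.

Sequencing a small genome on a high-capacity lane leaves room for two
kinds of multiplexing: *library-pooling* (``P`` strains mixed into one
library) and *tag-pooling* (several uniquely barcoded libraries sharing
one lane, dividing its coverage).  The total cost of sequencing ``S``
strains is then ``n_libraries * lib_cost + lanes * lane_cost`` with
``n_libraries = ceil(S / P)`` and a fractional number of lanes
``n_libraries / tag_pool``.  The optimization problem is to pick, for
each tag-pooling level, the largest library-pooling factor that still
preserves the target-discovery yield.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np

from .screen_model import DEFAULT_GENOME_LENGTH, ScreenConfig, simulate_screens
from .scoring import yields_from_batches
from .seq_model import SeqDesign, error_profile, min_threshold_fp_below, scan_thresholds

__all__ = [
    "CostModel",
    "DesignPoint",
    "coverage_per_library",
    "experiment_cost",
    "average_yield",
    "optimize_design",
]


@dataclass(frozen=True)
class CostModel:
    """Reagent costs: per library prep and per sequencing lane (USD)."""

    lib_cost: float = 50.0
    lane_cost: float = 700.0

    def __post_init__(self) -> None:
        if self.lib_cost < 0 or self.lane_cost < 0:
            raise ValueError("costs must be >= 0")


@dataclass
class DesignPoint:
    """One evaluated experiment design."""

    n_strains: int
    pool_factor: int
    tag_pool: int
    n_libraries: int
    lanes: float
    coverage_per_library: float
    call_threshold: int
    total_cost: float
    cost_per_strain: float
    mean_yield: float


def coverage_per_library(lane_capacity: float, genome_length: float,
                         tag_pool: int) -> float:
    """Fold coverage per library when ``tag_pool`` libraries share a lane.

    ``lane_capacity / (genome_length * tag_pool)``; e.g. a 1500 Mb lane
    over the 4.64 Mb E. coli genome gives ~323x for a single library,
    ~65x for five and ~32x for ten.
    """
    if genome_length <= 0:
        raise ValueError("genome_length must be > 0")
    if lane_capacity <= 0 or tag_pool < 1:
        raise ValueError("lane_capacity must be > 0 and tag_pool >= 1")
    return lane_capacity / (genome_length * tag_pool)


def experiment_cost(n_strains: int, n_libraries: int, lanes: float,
                    costs: CostModel) -> tuple[float, float]:
    """Total and per-strain reagent cost.

    Uses exact rational arithmetic on the unit costs so that e.g.
    32 strains / 10 libraries / 1 lane yields exactly ($1200, $37.50).
    Fractional lanes are allowed (a lane can be shared across projects).
    """
    if n_strains <= 0:
        raise ValueError("n_strains must be > 0")
    total = (Fraction(n_libraries) * Fraction(costs.lib_cost)
             + Fraction(lanes) * Fraction(costs.lane_cost))
    return float(total), float(total / n_strains)


def n_libraries_for(n_strains: int, pool_factor: int,
                    pool_sizes: Sequence[int] | None = None) -> int:
    """Number of libraries: ``ceil(S / P)``, or the length of an explicit
    mixed pool-size list (e.g. eight pools of 3 plus two of 4)."""
    if pool_sizes is not None:
        if sum(pool_sizes) != n_strains:
            raise ValueError("pool sizes must sum to n_strains")
        return len(pool_sizes)
    return math.ceil(n_strains / pool_factor)


def average_yield(config: ScreenConfig,
                  rng: np.random.Generator,
                  design: SeqDesign | None = None,
                  genes=None,
                  replicates: int | None = None,
                  criterion: str = "fdr",
                  top_k: int = 20) -> tuple[float, float]:
    """Mean and standard error of the target-discovery yield.

    ``criterion="fdr"`` counts targets reported at the configured FDR;
    ``criterion="top_k"`` counts targets ranked (by p-value) within the
    top ``top_k`` genes, matching how experimental subset analyses are
    reported.
    """
    replicates = config.replicates if replicates is None else replicates
    if replicates < 2:
        raise ValueError("replicates must be >= 2 for a standard error")
    prof = error_profile(design) if design is not None else None
    counts, hist = simulate_screens(
        config, rng, replicates, genes=genes, seq_effects=prof,
        genome_length=None if design is None else design.genome_length)
    if criterion == "fdr":
        y = yields_from_batches(counts, hist, config.fdr)
    elif criterion == "top_k":
        y = _topk_yields(counts, hist, config, top_k)
    else:
        raise ValueError("criterion must be 'fdr' or 'top_k'")
    return float(y.mean()), float(y.std(ddof=1) / np.sqrt(len(y)))


def _topk_yields(counts: np.ndarray, hist: np.ndarray,
                 config: ScreenConfig, top_k: int) -> np.ndarray:
    """Targets among the top-k genes ranked by mutation count.

    With uniform sizes p-value rank equals count rank; a target makes the
    top k if fewer than k genes have a strictly larger count, with ties
    admitted up to the remaining slots (targets get the benefit of the
    doubt deterministically, mirroring a ranked table where ties are
    broken in their favour half the time on average).
    """
    n_reps = counts.shape[0]
    yields = np.zeros(n_reps, dtype=np.int64)
    m_max = max(int(counts.max(initial=0)), hist.shape[1] - 1)
    for r in range(n_reps):
        nt = np.zeros(m_max + 1, dtype=np.int64)
        nt[: hist.shape[1]] = hist[r]
        slots = top_k
        y = 0
        for m in range(m_max, 0, -1):
            t_here = int((counts[r] == m).sum())
            if slots <= 0:
                break
            take_t = min(t_here, slots)
            y += take_t
            slots -= t_here + int(nt[m])
        yields[r] = y
    return yields


def predicted_topk_yield(genes,
                         config: ScreenConfig,
                         rng: np.random.Generator,
                         design: SeqDesign | None = None,
                         profile=None,
                         replicates: int = 200,
                         top_k: int = 20) -> tuple[float, float]:
    """Model-predicted targets among the top-k genes ranked by p-value.

    Per-gene replicate simulation for small gene sets (every gene drawn
    individually rather than binned), matching how experimental subset
    analyses count validated targets in the ranked top-``top_k`` list.
    ``genes`` is ordered targets-first, with the first
    ``config.n_targets`` entries being the targets.  Rank ties are
    credited fractionally (a tie block straddling the cutoff contributes
    its proportional share), mirroring a ranked table whose tie order is
    arbitrary with respect to target status.

    ``profile`` overrides the error rates derived from ``design`` — use
    this to model multi-lane designs, where e.g. a two-of-three-lanes
    concordance rule turns a per-lane failure rate ``nu`` into an
    effective ``3 nu^2 (1 - nu) + nu^3``.
    """
    from scipy import stats as _st

    from .screen_model import _batch_allocate, _batch_total_target_mutations

    genes = list(genes)
    n_t = config.n_targets
    lams = np.array([g.lambda_per_strain for g in genes])
    lengths = np.array([g.length_nt for g in genes], dtype=float)
    target_lams = lams[:n_t]
    prof = profile if profile is not None else (
        error_profile(design) if design is not None else None)
    fail = prof.fail_rate if prof else 0.0
    fp_site = prof.fp_site_rate if prof else 0.0

    totals = _batch_total_target_mutations(
        config, rng, replicates, lambda_target=float(target_lams.sum()))
    probs = target_lams / target_lams.sum()
    probs = np.append(probs * (1.0 - fail), fail)
    t_counts = _batch_allocate(totals, probs, rng)[:, :-1]
    t_counts = t_counts + rng.poisson(lengths[:n_t] * fp_site,
                                      size=(replicates, n_t))
    null_means = config.n_strains * lams * (1.0 - fail) + lengths * fp_site
    nt_counts = rng.poisson(null_means[n_t:], size=(replicates, len(genes) - n_t))
    counts = np.concatenate([t_counts, nt_counts], axis=1)
    p = _st.poisson.sf(counts - 1, null_means[None, :])
    p[counts == 0] = 1.0
    yields = np.empty(replicates)
    for r in range(replicates):
        pr = p[r]
        y = 0.0
        for j in range(n_t):
            better = int((pr < pr[j]).sum())
            ties = int((pr == pr[j]).sum())
            if better >= top_k:
                continue
            y += min(1.0, (top_k - better) / ties)
        yields[r] = y
    return float(yields.mean()), float(yields.std(ddof=1) / np.sqrt(replicates))


def optimize_design(n_strains: int,
                    tag_pools: Sequence[int],
                    costs: CostModel,
                    rng: np.random.Generator,
                    config: ScreenConfig,
                    error_rate: float = 0.01,
                    lane_capacity: float = 1.5e9,
                    genome_length: float = DEFAULT_GENOME_LENGTH,
                    yield_floor: float = 0.9,
                    max_pool: int = 20,
                    replicates: int = 100,
                    k_margin: int = 6) -> list[DesignPoint]:
    """Largest admissible pooling level and cost for each tag-pool value.

    For each tag-pooling level the per-library coverage is fixed by the
    lane capacity; the library-pooling factor ``P`` is then scanned upward
    until the mean yield (at the per-``P`` optimal call threshold) drops
    below ``yield_floor`` times the unpooled (``P = 1``) yield.  Call
    thresholds are scanned in a window starting at the smallest ``k``
    whose genome-wide expected false-positive count is below one.
    """
    tag_pools = list(tag_pools)
    if not tag_pools:
        raise ValueError("tag_pools must be non-empty")
    points: list[DesignPoint] = []
    for tag_pool in tag_pools:
        cov = coverage_per_library(lane_capacity, genome_length, tag_pool)
        baseline = None
        best: tuple[int, int, float] | None = None  # (P, k, yield)
        for pool in range(1, max_pool + 1):
            k, mean_y, se_y = _best_threshold_yield(
                config, cov, pool, error_rate, genome_length, rng,
                replicates, k_margin)
            if baseline is None:
                baseline = mean_y
            # stop only on a significant drop (2 SE below the floor), so
            # replicate noise does not truncate the scan early
            if mean_y < yield_floor * baseline - 2.0 * se_y:
                break
            best = (pool, k, mean_y)
        assert best is not None
        pool, k, mean_y = best
        n_lib = n_libraries_for(n_strains, pool)
        lanes = n_lib / tag_pool
        total, per_strain = experiment_cost(n_strains, n_lib, lanes, costs)
        points.append(DesignPoint(
            n_strains=n_strains, pool_factor=pool, tag_pool=tag_pool,
            n_libraries=n_lib, lanes=lanes, coverage_per_library=cov,
            call_threshold=k, total_cost=total, cost_per_strain=per_strain,
            mean_yield=mean_y))
    return points


def _best_threshold_yield(config, coverage, pool, error_rate, genome_length,
                          rng, replicates, k_margin):
    """Optimal call threshold (by mean yield) for one (coverage, P) pair."""
    design = SeqDesign(coverage=coverage, pool_factor=pool,
                       error_rate=error_rate, genome_length=int(genome_length))
    k_lo = min_threshold_fp_below(design)
    if k_lo is None:
        return design.n_trials, 0.0, 0.0
    ks = range(max(1, k_lo - 1), min(design.n_trials, k_lo + k_margin) + 1)
    scan = scan_thresholds(config, coverage, [pool], ks, rng,
                           error_rate=error_rate,
                           genome_length=int(genome_length),
                           replicates=replicates)
    row = scan.loc[scan["mean_yield"].idxmax()]
    return int(row["k"]), float(row["mean_yield"]), float(row["se_yield"])
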