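"""Generative model of a phenotype-sequencing screen.

A phenotype screen selects independent mutant strains that each carry at
least one mutation in a *target* gene (a gene in which mutations can cause
the screened phenotype).  This module samples the per-gene mutation counts
that such an experiment would observe:

* the number of mutations landing in the target region across ``S`` strains
  follows the sum of ``S`` draws from a zero-truncated Poisson (each strain
  must carry >= 1 causal mutation to pass the screen);
* those mutations are allocated among the ``T`` target genes by a
  multinomial whose probabilities are proportional to each gene's effective
  size;
* every non-target gene accumulates mutations as a plain Poisson, realised
  efficiently by binning genes of similar size and drawing each bin's genes
  from a multinomial over a truncated Poisson support.

Gene "size" is an effective target size: the expected number of mutations
per strain, combining length and base-composition mutability (chemical
mutagens such as NTG hit G:C pairs far more often than A:T pairs).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "GeneModel",
    "ScreenConfig",
    "MutationCountSample",
    "conditional_target_distribution",
    "truncated_poisson_pmf",
    "sample_target_counts",
    "sample_nontarget_histogram",
    "bin_genes_by_size",
    "effective_gene_size",
    "simulate_screen",
    "simulate_screens",
    "read_gene_table",
    "write_gene_table",
]

#: Default number of genes in the E. coli K-12 annotation used throughout.
DEFAULT_N_GENES = 4244

#: Fraction of random coding mutations expected to be non-synonymous.  A
#: strain with 50-100 total mutations carries roughly 30-70 non-synonymous
#: ones; configs stated as total mutations per genome are converted with
#: this factor.
NONSYNONYMOUS_FRACTION = 2.0 / 3.0


@dataclass(frozen=True)
class GeneModel:
    """One gene's identity, length, composition and effective target size.

    ``lambda_per_strain`` is the expected number of mutations in this gene
    in a single mutant strain (the gene's effective size times the
    mutation density).
    """

    gene_id: str
    length_nt: int
    n_gc: int
    n_at: int
    lambda_per_strain: float

    def __post_init__(self) -> None:
        if self.length_nt <= 0:
            raise ValueError("gene length must be positive")
        if self.n_gc < 0 or self.n_at < 0:
            raise ValueError("composition counts must be non-negative")
        if self.n_gc + self.n_at != self.length_nt:
            raise ValueError("n_gc + n_at must equal length_nt")
        if self.lambda_per_strain < 0:
            raise ValueError("lambda_per_strain must be >= 0")


@dataclass(frozen=True)
class ScreenConfig:
    """Parameters of a simulated phenotype screen.

    Parameters
    ----------
    n_strains
        Number of independent mutant strains sequenced (S).
    mu_per_gene
        Expected mutations per gene per strain (mutation density divided by
        the number of genes).
    n_targets
        Number of target genes (T) among which the causal signal is split.
    n_genes
        Total number of genes in the genome (G).
    fdr
        False discovery rate used for yield computation; 0.67 means at
        least one of every three reported genes must be a true target.
    tail_mass_cutoff
        Poisson supports are truncated once the remaining tail mass falls
        below this threshold, then renormalised.
    replicates
        Default number of replicate experiments for averaged quantities.
    """

    n_strains: int
    mu_per_gene: float
    n_targets: int
    n_genes: int = DEFAULT_N_GENES
    fdr: float = 0.67
    tail_mass_cutoff: float = 1e-10
    replicates: int = 1000
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_strains < 0:
            raise ValueError("n_strains must be >= 0")
        if self.mu_per_gene < 0:
            raise ValueError("mu_per_gene must be >= 0")
        if not (0 < self.n_targets < self.n_genes):
            raise ValueError("need 0 < n_targets < n_genes")
        if not (0.0 < self.fdr < 1.0):
            raise ValueError("fdr must lie in (0, 1)")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    @property
    def lambda_target(self) -> float:
        """Expected mutations per strain in the whole target region."""
        return self.mu_per_gene * self.n_targets


@dataclass
class MutationCountSample:
    """Mutation counts observed in one simulated experiment.

    ``target_counts`` holds the per-target-gene mutation counts;
    ``nontarget_histogram`` maps a mutation count ``m`` to the number of
    non-target genes observed with exactly ``m`` mutations.
    """

    target_counts: np.ndarray
    nontarget_histogram: dict[int, int] = field(default_factory=dict)

    def n_nontarget_genes(self) -> int:
        return int(sum(self.nontarget_histogram.values()))


# ---------------------------------------------------------------------------
# Truncated Poisson supports
# ---------------------------------------------------------------------------

def _poisson_support(mean: float, tail_mass_cutoff: float, m_min: int = 0
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Support ``m_min..m_max`` and pmf of a Poisson truncated at both ends.

    ``m_max`` is the smallest count such that the remaining upper-tail mass
    (relative to the mass at ``m >= m_min``) is below ``tail_mass_cutoff``.
    The returned vector is renormalised to sum to exactly 1.
    """
    if mean < 0:
        raise ValueError("Poisson mean must be >= 0")
    if mean == 0.0:
        if m_min > 0:
            raise ValueError("zero mean incompatible with m >= %d" % m_min)
        return np.array([0]), np.array([1.0])
    # Generous initial bound on the support, grown if the tail is still fat.
    hi = max(int(mean + 10.0 * np.sqrt(mean) + 20), m_min + 1)
    base = stats.poisson.cdf(m_min - 1, mean) if m_min > 0 else 0.0
    denom = 1.0 - base
    if denom <= 0.0:
        raise ValueError("no probability mass at m >= %d" % m_min)
    while stats.poisson.sf(hi, mean) / denom >= tail_mass_cutoff:
        hi *= 2
    m = np.arange(m_min, hi + 1)
    pmf = stats.poisson.pmf(m, mean) / denom
    # Trim to the smallest m_max with tail mass below the cutoff.
    tail = 1.0 - np.cumsum(pmf)
    cut = int(np.argmax(tail < tail_mass_cutoff))
    m, pmf = m[: cut + 1], pmf[: cut + 1]
    return m, pmf / pmf.sum()


def truncated_poisson_pmf(mean: float, tail_mass_cutoff: float
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Truncated, renormalised Poisson pmf over ``m = 0..m_max``."""
    return _poisson_support(mean, tail_mass_cutoff, m_min=0)


def conditional_target_distribution(lambda_target: float,
                                    tail_mass_cutoff: float = 1e-10
                                    ) -> tuple[np.ndarray, np.ndarray]:
    """Distribution of target-region mutations in one screened strain.

    Conditioning on passing the screen requires at least one mutation in
    the target region, i.e. a zero-truncated Poisson:
    ``P(m) = Poisson(m; lambda) / (1 - exp(-lambda))`` for ``m >= 1``.

    Returns ``(support, probabilities)`` with the support truncated where
    the remaining tail mass drops below ``tail_mass_cutoff``.

    Raises
    ------
    ValueError
        If ``lambda_target <= 0``: a screen with zero causal-mutation rate
        cannot be conditioned on success.
    """
    if lambda_target <= 0:
        raise ValueError(
            "lambda_target must be > 0: a screen with no causal mutation "
            "rate cannot produce surviving strains")
    return _poisson_support(lambda_target, tail_mass_cutoff, m_min=1)


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------

def _check_probability_vector(p: np.ndarray, atol: float = 1e-9) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("probability vector must be 1-D and non-empty")
    if np.any(p < 0) or abs(p.sum() - 1.0) > atol:
        raise ValueError("probability vector must be non-negative and sum to 1")
    return p


def _batch_total_target_mutations(config: ScreenConfig, rng: np.random.Generator,
                                  n_reps: int,
                                  lambda_target: float | None = None
                                  ) -> np.ndarray:
    """Total target-region mutations K for ``n_reps`` replicate screens.

    Realised as one multinomial draw of S counts over the truncated
    zero-truncated-Poisson support per replicate, so the cost is
    O(support), not O(S).
    """
    if config.n_strains == 0:
        return np.zeros(n_reps, dtype=np.int64)
    if lambda_target is None:
        lambda_target = config.lambda_target
    support, probs = conditional_target_distribution(
        lambda_target, config.tail_mass_cutoff)
    counts = rng.multinomial(config.n_strains, probs, size=n_reps)
    return counts @ support


def _batch_allocate(totals: np.ndarray, probs: np.ndarray,
                    rng: np.random.Generator) -> np.ndarray:
    """Multinomial allocation of per-replicate totals across categories.

    ``totals`` may differ between replicates, which rules out a single
    vectorised ``multinomial`` call; we instead split sequentially with
    conditional binomials (exact, and vectorised across replicates).
    """
    totals = np.asarray(totals, dtype=np.int64)
    n_cat = probs.size
    out = np.zeros((totals.size, n_cat), dtype=np.int64)
    remaining = totals.copy()
    tail_p = 1.0
    for j in range(n_cat - 1):
        if tail_p <= 0:
            break
        p_j = min(max(probs[j] / tail_p, 0.0), 1.0)
        draw = rng.binomial(remaining, p_j)
        out[:, j] = draw
        remaining = remaining - draw
        tail_p -= probs[j]
    out[:, n_cat - 1] = remaining
    return out


def sample_target_counts(config: ScreenConfig,
                         target_probs: Sequence[float],
                         rng: np.random.Generator,
                         n_reps: int = 1) -> np.ndarray:
    """Sample per-target-gene mutation counts for replicate screens.

    The total K over the target region is the sum of ``n_strains`` draws
    from the screen-conditioned distribution; K is then split among target
    genes by a multinomial with ``target_probs`` (uniform for equal-size
    genes, proportional to effective size otherwise).

    Returns an ``(n_reps, n_targets)`` array (squeezed to 1-D when
    ``n_reps == 1``).
    """
    probs = _check_probability_vector(np.asarray(target_probs, dtype=float))
    if probs.size != config.n_targets:
        raise ValueError("target_probs length must equal n_targets")
    totals = _batch_total_target_mutations(config, rng, n_reps)
    counts = _batch_allocate(totals, probs, rng)
    return counts[0] if n_reps == 1 else counts


def sample_nontarget_histogram(config: ScreenConfig,
                               bins: Sequence[tuple[float, int]],
                               rng: np.random.Generator,
                               n_reps: int = 1,
                               extra_mean: float = 0.0,
                               rate_scale: float = 1.0) -> np.ndarray | dict[int, int]:
    """Sample the histogram of mutation counts over non-target genes.

    Each bin ``(mean_lambda, n_genes_in_bin)`` groups genes of similar
    effective size; the count distribution for one gene over S strains is
    Poisson with mean ``S * mean_lambda * rate_scale + extra_mean`` (the
    last two let sequencing effects rescale true-mutation rates and add a
    false-positive intensity).  The bin's genes are distributed over the
    truncated support by one multinomial draw, and histograms are summed
    across bins.

    Returns, for ``n_reps == 1``, a dict ``{m: gene count}``; otherwise an
    ``(n_reps, m_max + 1)`` dense array whose column ``m`` counts genes
    with exactly ``m`` mutations.
    """
    bins = list(bins)
    if not bins:
        raise ValueError("bins must be non-empty")
    n_nontargets = config.n_genes - config.n_targets
    if sum(n for _, n in bins) != n_nontargets:
        raise ValueError("bin gene counts must sum to n_genes - n_targets")
    per_bin = []
    m_max = 0
    for mean_lambda, n_bin in bins:
        mean = config.n_strains * mean_lambda * rate_scale + extra_mean
        support, probs = truncated_poisson_pmf(mean, config.tail_mass_cutoff)
        per_bin.append((support, probs, n_bin))
        m_max = max(m_max, int(support[-1]))
    hist = np.zeros((n_reps, m_max + 1), dtype=np.int64)
    for support, probs, n_bin in per_bin:
        draws = rng.multinomial(n_bin, probs, size=n_reps)
        hist[:, support[0]: support[-1] + 1] += draws
    if n_reps == 1:
        row = hist[0]
        return {int(m): int(c) for m, c in enumerate(row) if c > 0}
    return hist


def bin_genes_by_size(genes: Sequence[GeneModel], n_bins: int
                      ) -> list[tuple[float, int]]:
    """Group genes into size classes for the binned non-target model.

    Genes are sorted ascending by effective size and split into
    ``n_bins`` consecutive groups of ``len(genes) // n_bins``; remainder
    genes join the last (largest-size) bin, which slightly inflates that
    bin and is therefore conservative.  Each bin is represented by the
    arithmetic mean effective size of its members.
    """
    genes = list(genes)
    if not genes:
        raise ValueError("genes must be non-empty")
    if n_bins < 1 or n_bins > len(genes):
        raise ValueError("need 1 <= n_bins <= number of genes")
    lams = np.sort(np.array([g.lambda_per_strain for g in genes]))
    per_bin = len(genes) // n_bins
    out: list[tuple[float, int]] = []
    for b in range(n_bins):
        lo = b * per_bin
        hi = (b + 1) * per_bin if b < n_bins - 1 else len(genes)
        out.append((float(lams[lo:hi].mean()), hi - lo))
    return out


def effective_gene_size(n_gc: float, n_at: float,
                        mu_gc: float, mu_at: float) -> float:
    """Expected mutations per strain for a region, weighting composition.

    ``n_gc`` and ``n_at`` count G:C and A:T sites in the region; ``mu_gc``
    and ``mu_at`` are the genome-wide observed per-base mutation rates at
    each class.  The effective size is ``n_gc * mu_gc + n_at * mu_at``;
    with equal rates it reduces to length times the uniform rate.
    """
    if min(n_gc, n_at, mu_gc, mu_at) < 0:
        raise ValueError("all arguments must be >= 0")
    return n_gc * mu_gc + n_at * mu_at


# ---------------------------------------------------------------------------
# Full experiment simulation
# ---------------------------------------------------------------------------

def _screen_parameters(config: ScreenConfig,
                       genes: Sequence[GeneModel] | None,
                       n_bins: int):
    """Target probability vector and non-target bins for a screen.

    With ``genes=None`` every gene has the uniform effective size
    ``mu_per_gene``; otherwise the first ``n_targets`` genes with
    ``is_target``-style designation are not assumed — the caller passes
    genes ordered targets-first.
    """
    if genes is None:
        target_probs = np.full(config.n_targets, 1.0 / config.n_targets)
        bins = [(config.mu_per_gene, config.n_genes - config.n_targets)]
        target_lams = np.full(config.n_targets, config.mu_per_gene)
        return target_probs, bins, target_lams
    genes = list(genes)
    if len(genes) != config.n_genes:
        raise ValueError("gene list must cover all n_genes genes")
    targets = genes[: config.n_targets]
    nontargets = genes[config.n_targets:]
    target_lams = np.array([g.lambda_per_strain for g in targets])
    if target_lams.sum() <= 0:
        raise ValueError("target genes have zero total effective size")
    target_probs = target_lams / target_lams.sum()
    bins = bin_genes_by_size(nontargets, min(n_bins, len(nontargets)))
    return target_probs, bins, target_lams


def simulate_screens(config: ScreenConfig,
                     rng: np.random.Generator,
                     n_reps: int,
                     genes: Sequence[GeneModel] | None = None,
                     seq_effects=None,
                     n_bins: int = 10,
                     genome_length: float | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised replicate screens.

    Returns ``(target_counts, nontarget_hist)`` of shapes
    ``(n_reps, n_targets)`` and ``(n_reps, m_max + 1)``.

    ``seq_effects`` is an :class:`poolscreen.seq_model.ErrorProfile` (or
    anything exposing ``fail_rate``, ``fp_site_rate``); when given, target
    allocation probabilities are rescaled by ``1 - fail_rate`` with a
    discarded detection-failure category, per-gene false-positive calls
    are added as Poisson draws with mean ``length * fp_site_rate``, and
    non-target rates are adjusted the same way.
    """
    target_probs, bins, target_lams = _screen_parameters(config, genes, n_bins)
    # With explicit genes the conditional rate is the summed effective
    # size of the targets; the uniform model uses T * mu_per_gene.
    lambda_t = float(target_lams.sum()) if genes is not None else None
    totals = _batch_total_target_mutations(config, rng, n_reps,
                                           lambda_target=lambda_t)
    if seq_effects is None:
        counts = _batch_allocate(totals, target_probs, rng)
        hist = sample_nontarget_histogram(config, bins, rng, n_reps=n_reps)
    else:
        fail = float(seq_effects.fail_rate)
        fp_site = float(seq_effects.fp_site_rate)
        probs = np.append(target_probs * (1.0 - fail), fail)
        counts = _batch_allocate(totals, probs, rng)[:, :-1]
        # Per-gene false positives: gene length in nt times per-site rate.
        lengths = _gene_lengths(config, genes, genome_length)
        fp_means = lengths[: config.n_targets] * fp_site
        counts = counts + rng.poisson(fp_means, size=(n_reps, config.n_targets))
        mean_nontarget_len = float(lengths[config.n_targets:].mean())
        extra = mean_nontarget_len * fp_site
        hist = sample_nontarget_histogram(
            config, bins, rng, n_reps=n_reps,
            extra_mean=extra, rate_scale=1.0 - fail)
    if isinstance(hist, dict):  # n_reps == 1 path
        m_max = max(hist) if hist else 0
        dense = np.zeros((1, m_max + 1), dtype=np.int64)
        for m, c in hist.items():
            dense[0, m] = c
        hist = dense
    return counts, hist


def _gene_lengths(config: ScreenConfig,
                  genes: Sequence[GeneModel] | None,
                  genome_length: float | None = None) -> np.ndarray:
    """Gene lengths in nt; uniform model assumes genes tile the genome."""
    if genes is not None:
        return np.array([g.length_nt for g in genes], dtype=float)
    if genome_length is None:
        genome_length = DEFAULT_GENOME_LENGTH
    return np.full(config.n_genes, genome_length / config.n_genes)


#: E. coli K-12 MG1655 genome length in nt.
DEFAULT_GENOME_LENGTH = 4_641_652


def simulate_screen(config: ScreenConfig,
                    rng: np.random.Generator,
                    genes: Sequence[GeneModel] | None = None,
                    seq_effects=None,
                    n_bins: int = 10,
                    genome_length: float | None = None) -> MutationCountSample:
    """Sample one full phenotype-screen experiment.

    Combines the screen-conditioned target allocation with the binned
    non-target Poisson histogram; ``seq_effects`` injects detection
    failures and false-positive calls (see :mod:`poolscreen.seq_model`).
    """
    counts, hist = simulate_screens(config, rng, 1, genes=genes,
                                    seq_effects=seq_effects, n_bins=n_bins,
                                    genome_length=genome_length)
    histogram = {int(m): int(c) for m, c in enumerate(hist[0]) if c > 0}
    return MutationCountSample(target_counts=counts[0],
                               nontarget_histogram=histogram)


# ---------------------------------------------------------------------------
# Gene-table I/O
# ---------------------------------------------------------------------------

def write_gene_table(genes: Iterable, path) -> None:
    """Write a tab-separated gene table.

    Accepts annotation records with ``gene_id/start/end/strand/n_gc/n_at``
    attributes (missing coordinate fields default to 0-length placement).
    """
    import pandas as pd

    rows = []
    for g in genes:
        rows.append({
            "gene_id": g.gene_id,
            "start": getattr(g, "start", 0),
            "end": getattr(g, "end", getattr(g, "length_nt", 0)),
            "strand": getattr(g, "strand", "+"),
            "length": getattr(g, "length_nt", getattr(g, "end", 0) - getattr(g, "start", 0)),
            "n_gc": g.n_gc,
            "n_at": g.n_at,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_gene_table(path, mu_gc: float, mu_at: float) -> list[GeneModel]:
    """Read a tab-separated gene table into :class:`GeneModel` objects."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    return [
        GeneModel(gene_id=str(r.gene_id), length_nt=int(r.length),
                  n_gc=int(r.n_gc), n_at=int(r.n_at),
                  lambda_per_strain=effective_gene_size(
                      r.n_gc, r.n_at, mu_gc, mu_at))
        for r in df.itertuples()
    ]
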