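"""VCF-based candidate-gene ranking for pooled mutant sequencing.

Consumes one VCF per tagged library per lane replicate (as produced by a
standard mpileup/bcftools workflow upstream), together with the reference
genome and CDS annotation, and

1. loads biallelic SNVs, splitting multi-allelic records;
2. filters candidate SNPs: allele frequency at most 0.5 in a pooled
   library, and concordant detection in at least two of three lane
   replicates (frequency filter only for single-lane analyses);
3. removes parental variants (seen at ~100% allele frequency in every
   library — present in the common ancestor, not induced by mutagenesis);
4. annotates each SNP with its gene and coding effect (synonymous /
   non-synonymous / intergenic) via codon translation;
5. scores genes by the Poisson-tail statistic with GC-bias-weighted
   effective sizes and ranks them;
6. optionally enumerates all library subsets to measure how discovery
   yield grows with the number of strains sequenced.

Coordinates: VCF and GenBank are 1-based; internally SNP positions stay
1-based (as loaded) and CDS intervals are 0-based half-open, with the
conversions centralised in :func:`annotate_effect`.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, replace, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from intervaltree import IntervalTree

from .design import CostModel
from .scoring import bonferroni_correct, gene_pvalue

logger = logging.getLogger(__name__)

__all__ = [
    "SNPRecord",
    "CdsFeature",
    "ExperimentLayout",
    "load_genome",
    "load_annotation",
    "load_snvs",
    "filter_concordant",
    "remove_parental",
    "annotate_effect",
    "annotate_effects",
    "gc_mutation_rates",
    "genome_composition",
    "GeneContext",
    "prepare_gene_context",
    "score_genes",
    "write_score_table",
    "subset_yield_analysis",
]

_GC = frozenset("GCgc")


@dataclass(frozen=True)
class SNPRecord:
    """One called single-nucleotide variant in one library."""

    position: int  # 1-based genomic coordinate
    ref_base: str
    alt_base: str
    library_id: str
    lane_id: str
    allele_frequency: float
    chrom: str = "chr1"
    gene_id: str | None = None
    effect: str | None = None  # synonymous | nonsynonymous | intergenic
    aa_change: str | None = None

    def __post_init__(self) -> None:
        if self.ref_base == self.alt_base:
            raise ValueError("ref and alt base must differ")
        if not (0.0 <= self.allele_frequency <= 1.0):
            raise ValueError("allele_frequency must lie in [0, 1]")


@dataclass(frozen=True)
class CdsFeature:
    """A protein-coding region: 0-based half-open interval with strand."""

    gene_id: str
    start: int
    end: int
    strand: str = "+"
    chrom: str = "chr1"

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ExperimentLayout:
    """Pooling layout of an experiment: which strains sit in which library."""

    libraries: list[tuple[str, int]]  # (library_id, strain count)
    lanes: list[str] = field(default_factory=lambda: ["lane1"])
    validated_targets: set[str] | None = None
    top_k: int = 20

    def __post_init__(self) -> None:
        if any(n < 1 for _, n in self.libraries):
            raise ValueError("strain counts must be >= 1")

    @property
    def n_strains(self) -> int:
        return sum(n for _, n in self.libraries)


# ---------------------------------------------------------------------------
# Input loading
# ---------------------------------------------------------------------------

def load_genome(path) -> str:
    """Read the (single-contig) reference genome from FASTA."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no sequences in {path}")
    return str(records[0].seq).upper()


def load_annotation(path, fmt: str | None = None) -> list[CdsFeature]:
    """Read CDS features from a GenBank flat file or GFF3.

    The format is inferred from the extension when not given.  CDS whose
    length is not a multiple of 3 are skipped with a warning.
    """
    path = Path(path)
    if fmt is None:
        fmt = "genbank" if path.suffix.lower() in {".gb", ".gbk", ".genbank"} \
            else "gff3"
    feats: list[CdsFeature] = []
    if fmt == "genbank":
        for rec in SeqIO.parse(str(path), "genbank"):
            for f in rec.features:
                if f.type != "CDS":
                    continue
                quals = f.qualifiers
                gene_id = (quals.get("gene") or quals.get("locus_tag")
                           or [f"cds_{len(feats)}"])[0]
                strand = "-" if f.location.strand == -1 else "+"
                feats.append(CdsFeature(gene_id=str(gene_id),
                                        start=int(f.location.start),
                                        end=int(f.location.end),
                                        strand=strand, chrom=rec.id))
    elif fmt == "gff3":
        import gffutils

        db = gffutils.create_db(str(path), ":memory:", force=True,
                                merge_strategy="create_unique")
        for f in db.features_of_type("CDS"):
            gene_id = (f.attributes.get("gene") or f.attributes.get("ID")
                       or [f.id])[0]
            feats.append(CdsFeature(gene_id=str(gene_id), start=f.start - 1,
                                    end=f.end, strand=f.strand or "+",
                                    chrom=f.seqid))
    else:
        raise ValueError(f"unknown annotation format {fmt!r}")
    good = []
    for f in feats:
        if f.length % 3 != 0:
            logger.warning("skipping CDS %s: length %d not divisible by 3",
                           f.gene_id, f.length)
            continue
        good.append(f)
    return good


def load_snvs(vcf_paths: Mapping[tuple[str, str], object],
              af_field: str = "AF") -> list[SNPRecord]:
    """Load biallelic SNVs from per-(library, lane) VCF files.

    Multi-allelic SNV records are split into one record per alternate
    allele; indels and other non-SNV records are skipped and counted in
    the log.  The allele-frequency estimate is read from the configurable
    INFO field ``af_field``.
    """
    from cyvcf2 import VCF

    records: list[SNPRecord] = []
    for (library_id, lane_id), path in vcf_paths.items():
        n_skipped = 0
        try:
            vcf = VCF(str(path))
        except Exception as exc:  # pragma: no cover - cyvcf2 error text varies
            raise ValueError(f"malformed VCF {path}: {exc}") from exc
        for var in vcf:
            alts = var.ALT or []
            af = var.INFO.get(af_field)
            if af is None:
                af_list = [0.0] * len(alts)
            elif isinstance(af, (tuple, list)):
                af_list = [float(a) for a in af]
            else:
                af_list = [float(af)] * len(alts)
            for alt, alt_af in zip(alts, af_list):
                if len(var.REF) != 1 or len(alt) != 1 or alt not in "ACGT":
                    n_skipped += 1
                    continue
                if alt == var.REF:
                    n_skipped += 1
                    logger.warning("%s: identical ref and alt at %s:%d",
                                   path, var.CHROM, var.POS)
                    continue
                records.append(SNPRecord(
                    position=var.POS, ref_base=var.REF, alt_base=alt,
                    library_id=library_id, lane_id=lane_id,
                    allele_frequency=min(max(alt_af, 0.0), 1.0),
                    chrom=var.CHROM))
        if n_skipped:
            logger.info("%s: skipped %d non-SNV/invalid allele records",
                        path, n_skipped)
    logger.info("loaded %d SNV records from %d files", len(records),
                len(vcf_paths))
    return records


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def filter_concordant(records: Sequence[SNPRecord],
                      max_af: float = 0.5,
                      min_lanes: int = 2,
                      n_lanes: int | None = None) -> list[SNPRecord]:
    """Allele-frequency and lane-concordance filter.

    Keeps records whose allele frequency is at most ``max_af`` and whose
    (library, position, alt) call is reproduced in at least ``min_lanes``
    distinct lanes.  For single-lane analyses (``n_lanes == 1`` or
    ``min_lanes <= 1``) only the frequency filter applies.  Idempotent:
    surviving records still carry their full lane support.
    """
    records = list(records)
    if n_lanes is None:
        n_lanes = len({r.lane_id for r in records}) or 1
    if min_lanes > n_lanes:
        raise ValueError("min_lanes cannot exceed the number of lanes")
    passing = [r for r in records if r.allele_frequency <= max_af]
    if n_lanes == 1 or min_lanes <= 1:
        out = passing
    else:
        lanes_by_call: dict[tuple, set[str]] = {}
        for r in passing:
            key = (r.library_id, r.chrom, r.position, r.alt_base)
            lanes_by_call.setdefault(key, set()).add(r.lane_id)
        out = [r for r in passing
               if len(lanes_by_call[(r.library_id, r.chrom, r.position,
                                     r.alt_base)]) >= min_lanes]
    logger.info("concordance filter: %d -> %d records", len(records), len(out))
    return out


def remove_parental(records: Sequence[SNPRecord],
                    parental_af_floor: float = 0.95,
                    libraries: Iterable[str] | None = None
                    ) -> list[SNPRecord]:
    """Drop variants present at ~100% allele frequency in every library.

    Such variants were present in the parent strain before mutagenesis
    (or are reference/parent mismatches) and carry no screen signal.  The
    floor defaults to 0.95 rather than a literal 100% to tolerate caller
    noise.  Idempotent.
    """
    records = list(records)
    libs = set(libraries) if libraries is not None \
        else {r.library_id for r in records}
    high: dict[tuple, set[str]] = {}
    for r in records:
        if r.allele_frequency >= parental_af_floor:
            high.setdefault((r.chrom, r.position, r.alt_base),
                            set()).add(r.library_id)
    parental = {key for key, in_libs in high.items() if in_libs >= libs}
    out = [r for r in records
           if (r.chrom, r.position, r.alt_base) not in parental]
    logger.info("parental filter: removed %d sites, %d -> %d records",
                len(parental), len(records), len(out))
    return out


# ---------------------------------------------------------------------------
# Effect annotation
# ---------------------------------------------------------------------------

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def _build_tree(annotation: Sequence[CdsFeature]) -> IntervalTree:
    tree = IntervalTree()
    for f in annotation:
        if f.length % 3 != 0:
            logger.warning("skipping CDS %s: length %d not divisible by 3",
                           f.gene_id, f.length)
            continue
        tree[f.start: f.end] = f
    return tree


def _annotate_one(record: SNPRecord, cds: CdsFeature, genome: str
                  ) -> SNPRecord:
    pos0 = record.position - 1  # to 0-based
    if cds.strand == "+":
        idx = pos0 - cds.start
        ref_allele, alt_allele = record.ref_base, record.alt_base
    else:
        idx = cds.end - 1 - pos0
        ref_allele = record.ref_base.translate(_COMPLEMENT)
        alt_allele = record.alt_base.translate(_COMPLEMENT)
    codon_i, within = divmod(idx, 3)
    if cds.strand == "+":
        codon = genome[cds.start + 3 * codon_i: cds.start + 3 * codon_i + 3]
    else:
        chunk = genome[cds.end - 3 * codon_i - 3: cds.end - 3 * codon_i]
        codon = chunk.translate(_COMPLEMENT)[::-1]
    if codon[within].upper() != ref_allele.upper():
        logger.warning("reference mismatch at %s:%d in %s", record.chrom,
                       record.position, cds.gene_id)
    alt_codon = codon[:within] + alt_allele + codon[within + 1:]
    aa_ref = str(Seq(codon).translate())
    aa_alt = str(Seq(alt_codon).translate())
    effect = "synonymous" if aa_ref == aa_alt else "nonsynonymous"
    return replace(record, gene_id=cds.gene_id, effect=effect,
                   aa_change=f"{aa_ref}{codon_i + 1}{aa_alt}")


def annotate_effect(record: SNPRecord, annotation: Sequence[CdsFeature],
                    genome: str, first_only: bool = False
                    ) -> list[SNPRecord]:
    """Annotate one SNP with gene assignment and coding effect.

    Returns one record per overlapping CDS (or a single intergenic record
    when the position lies outside every CDS).  ``first_only`` restricts a
    SNP inside overlapping CDS to the first annotated gene.
    """
    tree = _build_tree(annotation)
    return _annotate_with_tree(record, tree, genome, first_only)


def _annotate_with_tree(record, tree, genome, first_only) -> list[SNPRecord]:
    hits = sorted(tree[record.position - 1], key=lambda iv: iv.begin)
    if not hits:
        return [replace(record, gene_id=None, effect="intergenic",
                        aa_change=None)]
    if first_only:
        hits = hits[:1]
    return [_annotate_one(record, iv.data, genome) for iv in hits]


def annotate_effects(records: Sequence[SNPRecord],
                     annotation: Sequence[CdsFeature],
                     genome: str, first_only: bool = False
                     ) -> list[SNPRecord]:
    """Annotate many SNPs, building the CDS interval index once."""
    tree = _build_tree(annotation)
    out: list[SNPRecord] = []
    for r in records:
        out.extend(_annotate_with_tree(r, tree, genome, first_only))
    return out


# ---------------------------------------------------------------------------
# GC-bias mutation rates and gene scoring
# ---------------------------------------------------------------------------

def genome_composition(genome: str) -> tuple[int, int]:
    """Counts of G/C and A/T sites in the genome."""
    n_gc = sum(1 for b in genome if b in _GC)
    return n_gc, len(genome) - n_gc


def _unique_events(records: Sequence[SNPRecord]) -> list[SNPRecord]:
    """One record per distinct (library, site, alt, gene) mutation event.

    Lane replicates report the same event several times; counting an
    event once per library preserves the independent-strain statistics.
    """
    seen: dict[tuple, SNPRecord] = {}
    for r in records:
        key = (r.library_id, r.chrom, r.position, r.alt_base, r.gene_id)
        seen.setdefault(key, r)
    return list(seen.values())


def gc_mutation_rates(records: Sequence[SNPRecord], genome: str
                      ) -> tuple[float, float]:
    """Genome-wide per-base mutation rates at G/C vs A/T sites.

    Counts unique mutation events whose reference base is G or C against
    the number of G/C sites, and likewise for A/T; the ratio of the two
    rates measures mutagen bias (NTG gives roughly 36).
    """
    n_gc, n_at = genome_composition(genome)
    if n_gc == 0 or n_at == 0:
        raise ValueError("genome must contain both GC and AT sites")
    events = _unique_events([replace(r, gene_id=None) for r in records])
    hits_gc = sum(1 for r in events if r.ref_base in _GC)
    hits_at = len(events) - hits_gc
    return hits_gc / n_gc, hits_at / n_at


@dataclass
class GeneContext:
    """Precomputed per-gene composition, reused across subset scoring."""

    gene_ids: list[str]
    n_gc: np.ndarray
    n_at: np.ndarray
    genome_gc: int
    genome_at: int


def prepare_gene_context(annotation: Sequence[CdsFeature], genome: str
                         ) -> GeneContext:
    ids, gcs, ats = [], [], []
    for f in annotation:
        seq = genome[f.start: f.end]
        n_gc = sum(1 for b in seq if b in _GC)
        ids.append(f.gene_id)
        gcs.append(n_gc)
        ats.append(len(seq) - n_gc)
    g_gc, g_at = genome_composition(genome)
    return GeneContext(gene_ids=ids, n_gc=np.array(gcs), n_at=np.array(ats),
                       genome_gc=g_gc, genome_at=g_at)


def score_genes(records: Sequence[SNPRecord],
                annotation: Sequence[CdsFeature] | GeneContext,
                genome: str,
                nonsyn_only: bool = False,
                bonferroni_mode: str = "mutated",
                include_unmutated: bool = False) -> pd.DataFrame:
    """Rank genes by mutation-burden significance.

    Per-gene hit counts (optionally restricted to non-synonymous SNPs)
    are compared against a Poisson null whose mean is the gene's
    GC-weighted effective size, normalised so that expected counts sum to
    the number of observed in-scope SNPs.  ``bonferroni_mode`` selects the
    correction multiplier: ``"mutated"`` (genes observed mutated at least
    once, the default) or ``"all"`` (every annotated gene).

    Returns a DataFrame with columns
    ``(rank, gene_id, hits, expected, p_raw, p_corrected)``, sorted by
    p-value ascending with deterministic tie-breaking.
    """
    if bonferroni_mode not in {"mutated", "all"}:
        raise ValueError("bonferroni_mode must be 'mutated' or 'all'")
    records = list(records)
    if records and any(r.effect is None for r in records):
        if isinstance(annotation, GeneContext):
            raise ValueError("records must be annotated when only a "
                             "GeneContext is supplied")
        records = annotate_effects(records, annotation, genome)
    ctx = annotation if isinstance(annotation, GeneContext) \
        else prepare_gene_context(annotation, genome)
    events = _unique_events(records)
    mu_gc, mu_at = gc_mutation_rates(events, genome) if events else (0.0, 0.0)

    scored = [e for e in events if not nonsyn_only
              or e.effect == "nonsynonymous"]
    in_scope = [e for e in scored if e.gene_id is not None] if nonsyn_only \
        else scored
    n_total = len(in_scope)
    eff_gene = ctx.n_gc * mu_gc + ctx.n_at * mu_at
    if nonsyn_only:
        eff_norm = eff_gene.sum()
    else:
        eff_norm = ctx.genome_gc * mu_gc + ctx.genome_at * mu_at
    expected = (n_total * eff_gene / eff_norm) if eff_norm > 0 \
        else np.zeros_like(eff_gene)

    hits = {g: 0 for g in ctx.gene_ids}
    for e in scored:
        if e.gene_id is not None and e.gene_id in hits:
            hits[e.gene_id] += 1
    rows = []
    for gid, exp in zip(ctx.gene_ids, expected):
        m = hits[gid]
        if m == 0 and not include_unmutated:
            continue
        p = gene_pvalue(m, float(exp))
        rows.append({"gene_id": gid, "hits": m, "expected": float(exp),
                     "p_raw": p})
    df = pd.DataFrame(rows, columns=["gene_id", "hits", "expected", "p_raw"])
    n_tests = int((df["hits"] > 0).sum()) if bonferroni_mode == "mutated" \
        else len(ctx.gene_ids)
    n_tests = max(n_tests, 1)
    df["p_corrected"] = [bonferroni_correct(p, n_tests) for p in df["p_raw"]]
    df = df.sort_values(["p_raw", "hits", "gene_id"],
                        ascending=[True, False, True],
                        kind="stable").reset_index(drop=True)
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    return df


def write_score_table(df: pd.DataFrame, path) -> None:
    """Write the ranked gene table as tab-separated text."""
    cols = ["rank", "gene_id", "hits", "expected", "p_raw", "p_corrected"]
    df.to_csv(path, sep="\t", index=False, columns=cols,
              float_format="%.6g")


# ---------------------------------------------------------------------------
# Library-subset yield analysis
# ---------------------------------------------------------------------------

def subset_yield_analysis(records: Sequence[SNPRecord],
                          layout: ExperimentLayout,
                          costs: CostModel,
                          annotation: Sequence[CdsFeature] | GeneContext,
                          genome: str,
                          rng: np.random.Generator | None = None,
                          nonsyn_only: bool = False,
                          max_enumerate: int = 20,
                          n_samples: int = 2000) -> pd.DataFrame:
    """Average discovery yield versus number of strains sequenced.

    Enumerates every non-empty subset of the tagged libraries (2^L - 1
    sub-experiments; Monte-Carlo sampled with ``rng`` beyond
    ``max_enumerate`` libraries), scores each subset's records alone,
    counts how many validated target genes appear in its top-``top_k``
    list, and averages over subsets with the same total strain count.

    Costs attribute the full experiment's per-strain rate (libraries plus
    lanes) to each subset proportionally to its strain count.

    Returns a DataFrame ``(n_strains, n_subsets, mean_yield, se_yield,
    cost)``.
    """
    if not layout.validated_targets:
        raise ValueError("layout.validated_targets must be non-empty")
    ctx = annotation if isinstance(annotation, GeneContext) \
        else prepare_gene_context(annotation, genome)
    records = list(records)
    if records and any(r.effect is None for r in records):
        raise ValueError("records must be annotated before subset analysis")
    by_lib: dict[str, list[SNPRecord]] = {lib: [] for lib, _ in layout.libraries}
    for r in records:
        by_lib.setdefault(r.library_id, []).append(r)

    libs = layout.libraries
    n_libs = len(libs)
    if n_libs <= max_enumerate:
        subsets = [s for k in range(1, n_libs + 1)
                   for s in itertools.combinations(range(n_libs), k)]
    else:
        if rng is None:
            raise ValueError("rng required to sample subsets for > "
                             f"{max_enumerate} libraries")
        subsets = []
        for _ in range(n_samples):
            mask = rng.random(n_libs) < 0.5
            if mask.any():
                subsets.append(tuple(np.flatnonzero(mask)))

    # Full-experiment per-strain cost rate (single shared lane set).
    n_lanes = max(len(layout.lanes), 1)
    total, per_strain = _full_cost(layout, costs, n_lanes)
    rows = []
    for subset in subsets:
        recs = [r for i in subset for r in by_lib[libs[i][0]]]
        strains = sum(libs[i][1] for i in subset)
        if recs:
            table = score_genes(recs, ctx, genome, nonsyn_only=nonsyn_only)
            top = set(table.head(layout.top_k)["gene_id"])
        else:
            top = set()
        found = len(top & layout.validated_targets)
        rows.append({"n_strains": strains, "found": found})
    df = pd.DataFrame(rows)
    grouped = df.groupby("n_strains")["found"]
    out = pd.DataFrame({
        "n_strains": grouped.mean().index,
        "n_subsets": grouped.size().to_numpy(),
        "mean_yield": grouped.mean().to_numpy(),
        "se_yield": (grouped.std(ddof=1).fillna(0.0)
                     / np.sqrt(grouped.size())).to_numpy(),
    })
    out["cost"] = per_strain * out["n_strains"]
    return out.reset_index(drop=True)


def _full_cost(layout: ExperimentLayout, costs: CostModel, n_lanes: int
               ) -> tuple[float, float]:
    from .design import experiment_cost

    return experiment_cost(layout.n_strains, len(layout.libraries),
                           n_lanes, costs)
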