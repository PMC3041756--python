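"""Self-contained synthetic fixtures for the whole pipeline.

Generates a toy annotated genome, mutant strains conditioned on passing
the phenotype screen, and per-library pooled VCFs with sequencing error,
together with a ground-truth manifest — so every pipeline stage can be
exercised without any external data.

The strain simulator is the *forward* version of the screen model:
Poisson mutations scattered over sites with GC-biased per-base rates,
with rejection until the strain carries at least one mutation in a target
gene.  The VCF writer is the forward version of the pooled-sequencing
error model: each mutant site gathers ``Binomial(c, carriers*(1-eps)/P)``
supporting reads, every other site can produce ``Binomial(c, eps)`` error
reads, and a site is emitted when the alternate count reaches the call
threshold ``k``.

What the fixtures deliberately do *not* emulate: read-level artifacts
(quality strings, mapping bias, indels) and depth variation (depth is
fixed at ``c`` per site by default; a negative-binomial option exists for
robustness testing).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .seq_model import SeqDesign, error_profile
from .snp_pipeline import CdsFeature

__all__ = [
    "ToyGenome",
    "Mutation",
    "TruthManifest",
    "make_toy_genome",
    "simulate_strains",
    "write_pooled_vcfs",
    "parse_pools",
    "make_fixtures",
]

_BASES = np.array(list("ACGT"))
_STOP = "TAA"
_START = "ATG"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass
class ToyGenome:
    """A random annotated genome: sequence plus non-overlapping CDS."""

    sequence: str
    features: list[CdsFeature]
    chrom: str = "chr1"

    def __len__(self) -> int:
        return len(self.sequence)

    def gene_table(self) -> pd.DataFrame:
        rows = []
        for f in self.features:
            seq = self.sequence[f.start: f.end]
            n_gc = seq.count("G") + seq.count("C")
            rows.append({"gene_id": f.gene_id, "start": f.start,
                         "end": f.end, "strand": f.strand,
                         "length": f.length, "n_gc": n_gc,
                         "n_at": f.length - n_gc})
        return pd.DataFrame(rows)

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f">{self.chrom} synthetic toy genome\n")
            for i in range(0, len(self.sequence), 70):
                fh.write(self.sequence[i: i + 70] + "\n")

    def write_gff3(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            fh.write(f"##sequence-region {self.chrom} 1 {len(self)}\n")
            for f in self.features:
                fh.write("\t".join([
                    self.chrom, "poolscreen", "CDS", str(f.start + 1),
                    str(f.end), ".", f.strand, "0",
                    f"ID={f.gene_id};gene={f.gene_id}"]) + "\n")


@dataclass(frozen=True)
class Mutation:
    """One induced point mutation in one strain (0-based position)."""

    strain: int
    position: int
    ref: str
    alt: str
    gene_id: str | None
    causal: bool


@dataclass
class TruthManifest:
    """Ground truth for a synthetic experiment."""

    mutations: list[Mutation]
    target_genes: list[str]
    n_strains: int
    params: dict = field(default_factory=dict)
    layout: list[list[int]] | None = None  # pools of strain indices

    def per_strain(self) -> list[list[Mutation]]:
        out: list[list[Mutation]] = [[] for _ in range(self.n_strains)]
        for m in self.mutations:
            out[m.strain].append(m)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "strain": m.strain, "position": m.position, "ref": m.ref,
            "alt": m.alt, "gene_id": m.gene_id or "", "causal": m.causal,
        } for m in self.mutations])

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Toy genome construction
# ---------------------------------------------------------------------------

def make_toy_genome(n_genes: int = 40,
                    mean_gene_length: int = 900,
                    gc_fraction: float = 0.5,
                    intergenic_fraction: float = 0.2,
                    seed: int = 0) -> ToyGenome:
    """Random genome with non-overlapping CDS features.

    Gene lengths vary uniformly between 0.6x and 1.4x the mean, rounded
    to a multiple of 3; each CDS gets a start codon and a terminal stop
    codon on its strand.  Deterministic for a fixed seed.
    """
    if n_genes < 1 or mean_gene_length < 30:
        raise ValueError("need n_genes >= 1 and mean_gene_length >= 30")
    if not (0.0 < gc_fraction < 1.0) or not (0.0 <= intergenic_fraction < 1.0):
        raise ValueError("fractions out of range")
    rng = np.random.default_rng(seed)
    lengths = rng.integers(int(0.6 * mean_gene_length),
                           int(1.4 * mean_gene_length) + 1, size=n_genes)
    lengths = np.maximum((lengths // 3) * 3, 30)
    coding = int(lengths.sum())
    total = int(round(coding / (1.0 - intergenic_fraction)))
    gap_total = total - coding
    if gap_total < 0:
        raise ValueError("genes do not fit in the requested genome")
    gaps = rng.multinomial(gap_total, np.full(n_genes + 1, 1.0 / (n_genes + 1)))
    p = np.array([(1 - gc_fraction) / 2, gc_fraction / 2,
                  gc_fraction / 2, (1 - gc_fraction) / 2])
    seq = rng.choice(_BASES, size=total, p=p)
    features: list[CdsFeature] = []
    pos = 0
    for i, length in enumerate(lengths):
        pos += int(gaps[i])
        start, end = pos, pos + int(length)
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "+":
            seq[start: start + 3] = list(_START)
            seq[end - 3: end] = list(_STOP)
        else:
            seq[end - 3: end] = list(_START.translate(_COMPLEMENT)[::-1])
            seq[start: start + 3] = list(_STOP.translate(_COMPLEMENT)[::-1])
        features.append(CdsFeature(gene_id=f"gene{i + 1:03d}", start=start,
                                   end=end, strand=strand))
        pos = end
    return ToyGenome(sequence="".join(seq), features=features)


# ---------------------------------------------------------------------------
# Strain simulation (forward screen model)
# ---------------------------------------------------------------------------

def simulate_strains(genome: ToyGenome,
                     target_genes: Sequence[str],
                     theta_total: float,
                     n_strains: int,
                     seed: int,
                     gc_bias: float = 36.0,
                     max_retries: int = 10_000) -> TruthManifest:
    """Simulate screened mutant strains over a toy genome.

    Each strain draws ``Poisson(theta_total)`` mutations at sites chosen
    with GC-biased per-base rates (``gc_bias`` is the GC/AT rate ratio;
    NTG mutagenesis shows roughly 36) and an alternate base uniform over
    the three possibilities; strains without a mutation in a target gene
    fail the screen and are redrawn.

    Raises if rejection exceeds ``max_retries`` for one strain — the
    target rate is then too low; raise ``theta_total`` or add targets.
    """
    targets = set(target_genes)
    unknown = targets - {f.gene_id for f in genome.features}
    if unknown:
        raise ValueError(f"unknown target genes: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    seq = np.frombuffer(genome.sequence.encode(), dtype="S1")
    is_gc = (seq == b"G") | (seq == b"C")
    gc_sites = np.flatnonzero(is_gc)
    at_sites = np.flatnonzero(~is_gc)
    w_gc = gc_bias * gc_sites.size
    p_gc_class = w_gc / (w_gc + at_sites.size)
    gene_of = np.full(len(genome.sequence), -1, dtype=np.int64)
    for gi, f in enumerate(genome.features):
        gene_of[f.start: f.end] = gi
    target_idx = {gi for gi, f in enumerate(genome.features)
                  if f.gene_id in targets}

    mutations: list[Mutation] = []
    for strain in range(n_strains):
        for attempt in range(max_retries):
            n = rng.poisson(theta_total)
            if n == 0:
                continue
            n_gc = rng.binomial(n, p_gc_class)
            pos = np.concatenate([
                rng.choice(gc_sites, size=n_gc, replace=False)
                if n_gc else np.empty(0, dtype=np.int64),
                rng.choice(at_sites, size=n - n_gc, replace=False)
                if n - n_gc else np.empty(0, dtype=np.int64)])
            genes = gene_of[pos]
            if not any(int(g) in target_idx for g in genes):
                continue
            for p_i, g_i in zip(pos, genes):
                ref = genome.sequence[p_i]
                alt = rng.choice([b for b in "ACGT" if b != ref])
                gid = genome.features[g_i].gene_id if g_i >= 0 else None
                mutations.append(Mutation(
                    strain=strain, position=int(p_i), ref=ref, alt=str(alt),
                    gene_id=gid, causal=int(g_i) in target_idx))
            break
        else:
            raise ValueError(
                "screen rejection exceeded retry cap; increase theta_total "
                "or the number/size of target genes")
    params = {"theta_total": theta_total, "gc_bias": gc_bias,
              "n_strains": n_strains, "seed": seed}
    return TruthManifest(mutations=mutations, target_genes=list(target_genes),
                         n_strains=n_strains, params=params)


# ---------------------------------------------------------------------------
# Pooled VCF generation (forward sequencing-error model)
# ---------------------------------------------------------------------------

def parse_pools(spec: str, n_strains: int) -> list[list[int]]:
    """Parse a pooling layout like ``"8x3,2x4"`` into strain-index pools."""
    sizes: list[int] = []
    for part in spec.split(","):
        n, size = part.lower().split("x")
        sizes.extend([int(size)] * int(n))
    if sum(sizes) != n_strains:
        raise ValueError(f"pool sizes sum to {sum(sizes)}, not {n_strains}")
    pools, at = [], 0
    for size in sizes:
        pools.append(list(range(at, at + size)))
        at += size
    return pools


def _vcf_header(chrom: str, length: int) -> str:
    return "\n".join([
        "##fileformat=VCFv4.2",
        f"##contig=<ID={chrom},length={length}>",
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##INFO=<ID=AF,Number=A,Type=Float,Description="Allele frequency">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]) + "\n"


def write_pooled_vcfs(manifest: TruthManifest,
                      genome: ToyGenome,
                      layout: list[list[int]],
                      coverage: float,
                      error_rate: float,
                      out_dir,
                      n_lanes: int = 1,
                      call_threshold: int = 1,
                      seed: int = 0,
                      parental_sites: Sequence[int] = (),
                      depth_dispersion: float | None = None
                      ) -> tuple[dict[tuple[str, str], Path], pd.DataFrame]:
    """Write per-(library, lane) VCFs for a pooled experiment.

    Each pool of ``P`` strains is sequenced on ``n_lanes`` independent
    lanes at per-site depth ``c`` (fixed by default; negative-binomial
    with the given dispersion when ``depth_dispersion`` is set).  True
    mutant sites receive ``Binomial(c, carriers * (1 - eps) / P)``
    alternate reads, all other sites ``Binomial(c, eps)`` error reads for
    one random wrong base, and a site enters the VCF when its alternate
    count reaches ``call_threshold``, with ``AF = alt reads / depth``.

    ``parental_sites`` are planted at allele frequency 1.0 in every
    library.  Returns the path map and a per-library expectation report
    (detection-failure and genome-wide false-positive rates from the
    analytic error model).
    """
    strain_pool = {}
    for pi, pool in enumerate(layout):
        for s in pool:
            if s in strain_pool:
                raise ValueError(f"strain {s} assigned to two pools")
            strain_pool[s] = pi
    if set(strain_pool) != set(range(manifest.n_strains)):
        raise ValueError("every strain must be in exactly one pool")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    L = len(genome.sequence)
    parental_set = set(int(p) for p in parental_sites)
    c_int = int(round(coverage))
    paths: dict[tuple[str, str], Path] = {}
    report_rows = []
    for pi, pool in enumerate(layout):
        lib_id = f"lib{pi + 1}"
        P = len(pool)
        carriers: dict[tuple[int, str], int] = {}
        for m in manifest.mutations:
            if strain_pool[m.strain] == pi:
                carriers[(m.position, m.alt)] = \
                    carriers.get((m.position, m.alt), 0) + 1
        mut_pos = {pos for pos, _ in carriers}
        design = SeqDesign(coverage=coverage, pool_factor=P,
                           error_rate=error_rate,
                           call_threshold=call_threshold, genome_length=L)
        prof = error_profile(design)
        report_rows.append({
            "library_id": lib_id, "pool_factor": P,
            "n_true_sites": len(carriers),
            "expected_detected": len(carriers) * (1 - prof.fail_rate),
            "expected_false_positives": prof.fp_genome_expect,
        })
        for lane in range(n_lanes):
            lane_id = f"lane{lane + 1}"
            if depth_dispersion is None:
                depths = np.full(L, c_int)
            else:
                r = depth_dispersion
                depths = rng.negative_binomial(r, r / (r + coverage), size=L)
            calls: list[tuple[int, str, str, int, int]] = []
            for (pos, alt), n_car in sorted(carriers.items()):
                if pos in parental_set:
                    continue
                depth = int(depths[pos])
                p_read = min(1.0, n_car * (1.0 - error_rate) / P)
                alt_reads = int(rng.binomial(depth, p_read)) if depth else 0
                if alt_reads >= call_threshold:
                    calls.append((pos, genome.sequence[pos], alt,
                                  alt_reads, depth))
            err_reads = rng.binomial(depths, error_rate)
            fp_sites = np.flatnonzero(err_reads >= call_threshold)
            for pos in fp_sites:
                pos = int(pos)
                if pos in mut_pos or pos in parental_set:
                    continue
                ref = genome.sequence[pos]
                alt = str(rng.choice([b for b in "ACGT" if b != ref]))
                calls.append((pos, ref, alt, int(err_reads[pos]),
                              int(depths[pos])))
            for pos in sorted(parental_set):
                ref = genome.sequence[pos]
                alt = "A" if ref != "A" else "G"
                calls.append((pos, ref, alt, int(depths[pos]),
                              int(depths[pos])))
            calls.sort()
            path = out_dir / f"{lib_id}_{lane_id}.vcf"
            with open(path, "w") as fh:
                fh.write(_vcf_header(genome.chrom, L))
                for pos, ref, alt, alt_reads, depth in calls:
                    af = alt_reads / depth if depth else 0.0
                    fh.write(f"{genome.chrom}\t{pos + 1}\t.\t{ref}\t{alt}"
                             f"\t.\tPASS\tDP={depth};AF={af:.4f}\n")
            paths[(lib_id, lane_id)] = path
    return paths, pd.DataFrame(report_rows)


# ---------------------------------------------------------------------------
# One-call fixture factory
# ---------------------------------------------------------------------------

def make_fixtures(out_dir,
                  n_genes: int = 40,
                  mean_gene_length: int = 900,
                  n_strains: int = 32,
                  pools: str = "8x3,2x4",
                  n_targets: int = 3,
                  theta_total: float = 50.0,
                  coverage: float = 32.0,
                  error_rate: float = 0.01,
                  call_threshold: int | None = None,
                  n_lanes: int = 3,
                  gc_bias: float = 36.0,
                  seed: int = 17) -> dict:
    """Generate a complete fixture set on disk and return its pieces.

    Writes FASTA, GFF3, a gene table, the truth manifest (TSV + JSON
    parameters) and one VCF per library per lane under ``out_dir``.
    ``call_threshold=None`` picks the lowest threshold whose genome-wide
    expected false-positive count stays below one (the analytic model's
    recommended operating point).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    genome = make_toy_genome(n_genes=n_genes,
                             mean_gene_length=mean_gene_length, seed=seed)
    if call_threshold is None:
        from .seq_model import min_threshold_fp_below

        probe = SeqDesign(coverage=coverage, pool_factor=1,
                          error_rate=error_rate,
                          genome_length=len(genome.sequence))
        call_threshold = min_threshold_fp_below(probe) or int(round(coverage))
    # Targets: spread across the size range, deterministically.
    rng = np.random.default_rng(seed + 1)
    target_ids = [genome.features[i].gene_id for i in
                  sorted(rng.choice(n_genes, size=n_targets, replace=False))]
    manifest = simulate_strains(genome, target_ids, theta_total=theta_total,
                                n_strains=n_strains, seed=seed + 2,
                                gc_bias=gc_bias)
    layout = parse_pools(pools, n_strains)
    manifest.layout = layout
    paths, report = write_pooled_vcfs(
        manifest, genome, layout, coverage=coverage, error_rate=error_rate,
        out_dir=out_dir, n_lanes=n_lanes, call_threshold=call_threshold,
        seed=seed + 3)
    genome.write_fasta(out_dir / "genome.fa")
    genome.write_gff3(out_dir / "genes.gff3")
    genome.gene_table().to_csv(out_dir / "gene_table.tsv", sep="\t",
                               index=False)
    manifest.write_tsv(out_dir / "manifest.tsv")
    with open(out_dir / "params.json", "w") as fh:
        json.dump({**manifest.params, "targets": target_ids, "pools": pools,
                   "coverage": coverage, "error_rate": error_rate,
                   "call_threshold": call_threshold, "n_lanes": n_lanes},
                  fh, indent=2)
    report.to_csv(out_dir / "expected_calls.tsv", sep="\t", index=False)
    return {"genome": genome, "manifest": manifest, "layout": layout,
            "vcf_paths": paths, "report": report, "targets": target_ids}
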