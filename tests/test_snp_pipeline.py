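"""Tests of the VCF pipeline: loading, filters, effect annotation, scoring.

Codon-effect annotation is cross-checked against an independent oracle:
translate the whole mutated CDS with Biopython and diff the proteins.
"""

import numpy as np
import pytest
from Bio.Seq import Seq

from poolscreen.design import CostModel
from poolscreen.snp_pipeline import (
    CdsFeature,
    ExperimentLayout,
    SNPRecord,
    annotate_effect,
    annotate_effects,
    filter_concordant,
    gc_mutation_rates,
    genome_composition,
    load_annotation,
    load_genome,
    load_snvs,
    remove_parental,
    score_genes,
    subset_yield_analysis,
)
from poolscreen.synthetic_data import (
    parse_pools,
    simulate_strains,
    write_pooled_vcfs,
)

#       0123456789                        (fwd1: ATG CTG AAA TAA at 10..22)
MINI = ("A" * 10 + "ATGCTGAAATAA" + "A" * 18
        + "TTAGGGTTTCAT" + "A" * 8)  # rev1: revcomp(ATG AAA CCC TAA) at 40..52
MINI_ANN = [CdsFeature("fwd1", 10, 22, "+"),
            CdsFeature("rev1", 40, 52, "-")]


def _rec(pos1, ref, alt, lib="lib1", lane="lane1", af=0.3):
    return SNPRecord(position=pos1, ref_base=ref, alt_base=alt,
                     library_id=lib, lane_id=lane, allele_frequency=af)


VCF_HEADER = """##fileformat=VCFv4.2
##contig=<ID=chr1,length=60>
##INFO=<ID=DP,Number=1,Type=Integer,Description="depth">
##INFO=<ID=AF,Number=A,Type=Float,Description="allele freq">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


class TestLoadSnvs:
    def test_header_only_vcf_loads_nothing(self, tmp_path):
        p = tmp_path / "empty.vcf"
        p.write_text(VCF_HEADER)
        assert load_snvs({("lib1", "lane1"): p}) == []

    def test_snvs_loaded_indels_skipped_multiallelic_split(self, tmp_path):
        lines = []
        # 10 plain SNVs
        for i in range(10):
            lines.append(f"chr1\t{i + 2}\t.\tA\tG\t.\tPASS\tDP=30;AF=0.30")
        # one multi-allelic SNV record -> 2 more records
        lines.append("chr1\t20\t.\tC\tA,T\t.\tPASS\tDP=30;AF=0.25,0.10")
        # two indels, skipped
        lines.append("chr1\t30\t.\tA\tAT\t.\tPASS\tDP=30;AF=0.30")
        lines.append("chr1\t40\t.\tCT\tC\t.\tPASS\tDP=30;AF=0.30")
        p = tmp_path / "mix.vcf"
        p.write_text(VCF_HEADER + "\n".join(lines) + "\n")
        records = load_snvs({("lib1", "lane1"): p})
        assert len(records) == 12
        multi = sorted((r for r in records if r.position == 20),
                       key=lambda r: r.alt_base)
        assert [r.alt_base for r in multi] == ["A", "T"]
        assert [r.allele_frequency for r in multi] == \
            pytest.approx([0.25, 0.10])


class TestFilters:
    def _lane_records(self):
        recs = []
        # high-frequency call in all lanes: dropped by the AF filter
        for lane in ("lane1", "lane2", "lane3"):
            recs.append(_rec(5, "A", "G", lane=lane, af=0.6))
        # concordant call (2 of 3 lanes) at sensible AF: kept
        for lane in ("lane1", "lane2"):
            recs.append(_rec(9, "A", "C", lane=lane, af=0.33))
        # lone-lane call: dropped by concordance
        recs.append(_rec(13, "A", "T", lane="lane3", af=0.33))
        return recs

    def test_af_and_concordance_rules(self):
        kept = filter_concordant(self._lane_records(), n_lanes=3)
        assert {r.position for r in kept} == {9}
        assert len(kept) == 2  # both lane copies survive

    def test_single_lane_mode_applies_af_only(self):
        recs = [_rec(5, "A", "G", af=0.6), _rec(9, "A", "C", af=0.33)]
        kept = filter_concordant(recs, n_lanes=1, min_lanes=1)
        assert {r.position for r in kept} == {9}

    def test_idempotence(self):
        once = filter_concordant(self._lane_records(), n_lanes=3)
        twice = filter_concordant(once, n_lanes=3)
        assert once == twice

    def test_min_lanes_exceeding_lanes_rejected(self):
        with pytest.raises(ValueError):
            filter_concordant([_rec(5, "A", "G")], min_lanes=2, n_lanes=1)

    def test_parental_removed_only_when_fixed_everywhere(self):
        recs = []
        for lib in ("lib1", "lib2", "lib3"):
            recs.append(_rec(7, "A", "G", lib=lib, af=1.0))  # parental
        recs.append(_rec(11, "A", "G", lib="lib1", af=1.0))  # one library only
        recs.append(_rec(15, "A", "C", lib="lib2", af=0.3))
        kept = remove_parental(recs)
        assert {r.position for r in kept} == {11, 15}
        assert remove_parental(kept) == kept  # idempotent


class TestEffectAnnotation:
    def test_start_codon_third_position_is_nonsynonymous(self):
        [r] = annotate_effect(_rec(13, "G", "A"), MINI_ANN, MINI)
        assert (r.gene_id, r.effect, r.aa_change) == ("fwd1", "nonsynonymous",
                                                      "M1I")

    def test_leucine_wobble_is_synonymous(self):
        [r] = annotate_effect(_rec(16, "G", "A"), MINI_ANN, MINI)
        assert (r.gene_id, r.effect, r.aa_change) == ("fwd1", "synonymous",
                                                      "L2L")

    def test_intergenic_position(self):
        [r] = annotate_effect(_rec(5, "A", "G"), MINI_ANN, MINI)
        assert r.gene_id is None and r.effect == "intergenic"

    def test_reverse_strand_codon(self):
        # genome pos0 47 sits in codon 2 (AAA) of the reverse-strand gene
        [r] = annotate_effect(_rec(48, "T", "C"), MINI_ANN, MINI)
        assert (r.gene_id, r.effect, r.aa_change) == ("rev1", "nonsynonymous",
                                                      "K2R")

    def test_whole_cds_translation_oracle(self, toy_genome):
        """Every planted coding mutation's effect must agree with an
        independent full-CDS translate-and-diff oracle."""
        manifest = simulate_strains(toy_genome, ["gene005", "gene020"],
                                    theta_total=40, n_strains=4, seed=3)
        feats = {f.gene_id: f for f in toy_genome.features}
        n_checked = 0
        for m in manifest.mutations:
            if m.gene_id is None:
                continue
            [r] = annotate_effect(_rec(m.position + 1, m.ref, m.alt),
                                  toy_genome.features, toy_genome.sequence)
            f = feats[m.gene_id]
            cds = toy_genome.sequence[f.start: f.end]
            mutated = (toy_genome.sequence[: m.position] + m.alt
                       + toy_genome.sequence[m.position + 1:])
            cds_mut = mutated[f.start: f.end]
            if f.strand == "-":
                cds = str(Seq(cds).reverse_complement())
                cds_mut = str(Seq(cds_mut).reverse_complement())
            oracle = ("synonymous" if Seq(cds).translate() ==
                      Seq(cds_mut).translate() else "nonsynonymous")
            assert r.gene_id == m.gene_id
            assert r.effect == oracle
            n_checked += 1
        assert n_checked > 20


class TestGcMutationRates:
    def test_rate_arithmetic(self):
        genome = "G" * 500 + "C" * 500 + "A" * 1500 + "T" * 1500
        recs = [_rec(i + 1, genome[i], "A" if genome[i] != "A" else "G",
                     lib=f"lib{i % 3}")
                for i in range(90)]  # 90 hits at GC sites
        recs += [_rec(1001 + i, "A", "G") for i in range(10)]  # 10 AT hits
        mu_gc, mu_at = gc_mutation_rates(recs, genome)
        assert mu_gc == pytest.approx(0.09)
        assert mu_at == pytest.approx(10 / 3000)
        assert mu_gc / mu_at == pytest.approx(27.0)

    def test_all_gc_hits_give_zero_at_rate(self):
        genome = "GCGC" + "AT" * 10
        recs = [_rec(1, "G", "A"), _rec(2, "C", "T")]
        _, mu_at = gc_mutation_rates(recs, genome)
        assert mu_at == 0.0

    def test_homogeneous_genome_rejected(self):
        with pytest.raises(ValueError):
            gc_mutation_rates([], "AAAA")

    def test_bias_recovered_from_manifest(self, toy_genome):
        """Planted GC/AT bias is recovered within 3 binomial SEs."""
        bias = 12.0
        manifest = simulate_strains(toy_genome, ["gene001"], theta_total=60,
                                    n_strains=30, seed=5, gc_bias=bias)
        recs = [_rec(m.position + 1, m.ref, m.alt, lib=f"lib{m.strain}")
                for m in manifest.mutations]
        mu_gc, mu_at = gc_mutation_rates(recs, toy_genome.sequence)
        n_gc, n_at = genome_composition(toy_genome.sequence)
        n = len(manifest.mutations)
        p_gc = bias * n_gc / (bias * n_gc + n_at)  # planted class fraction
        frac = mu_gc * n_gc / (mu_gc * n_gc + mu_at * n_at)
        se = np.sqrt(p_gc * (1 - p_gc) / n)
        assert abs(frac - p_gc) < 3 * se


class TestScoreGenes:
    def test_no_records_gives_empty_table(self, toy_genome):
        df = score_genes([], toy_genome.features, toy_genome.sequence)
        assert len(df) == 0

    def test_planted_burden_ranks_first(self, toy_genome):
        f = toy_genome.features[8]
        recs = [
            _rec(f.start + 4 + 3 * i, toy_genome.sequence[f.start + 3 + 3 * i],
                 "A" if toy_genome.sequence[f.start + 3 + 3 * i] != "A"
                 else "G", lib=f"lib{i}")
            for i in range(5)
        ]
        # scattered single-hit background
        for j, g in enumerate(toy_genome.features[:4]):
            base = toy_genome.sequence[g.start + 6]
            recs.append(_rec(g.start + 7, base,
                             "A" if base != "A" else "G", lib="lib9"))
        df = score_genes(recs, toy_genome.features, toy_genome.sequence)
        assert df.iloc[0]["gene_id"] == f.gene_id
        assert df.iloc[0]["hits"] == 5

    def test_strong_screen_recovers_all_targets_in_top20(self, toy_genome):
        """Low mutagenesis density: all 3 planted targets make the top 20."""
        targets = ["gene006", "gene018", "gene031"]
        manifest = simulate_strains(toy_genome, targets, theta_total=12,
                                    n_strains=32, seed=21)
        recs = [_rec(m.position + 1, m.ref, m.alt,
                     lib=f"lib{m.strain // 4}")
                for m in manifest.mutations]
        recs = annotate_effects(recs, toy_genome.features,
                                toy_genome.sequence)
        df = score_genes(recs, toy_genome.features, toy_genome.sequence)
        assert set(targets) <= set(df.head(20)["gene_id"])


@pytest.fixture(scope="module")
def experiment(toy_genome, toy_context, tmp_path_factory):
    targets = ["gene006", "gene018", "gene031"]
    manifest = simulate_strains(toy_genome, targets, theta_total=30,
                                n_strains=32, seed=9)
    layout = parse_pools("8x3,2x4", 32)
    out = tmp_path_factory.mktemp("subset_vcfs")
    paths, _ = write_pooled_vcfs(manifest, toy_genome, layout,
                                 coverage=75, error_rate=0.01,
                                 out_dir=out, n_lanes=1,
                                 call_threshold=9, seed=33)
    records = load_snvs(paths)
    records = filter_concordant(records, n_lanes=1, min_lanes=1)
    records = annotate_effects(records, toy_genome.features,
                               toy_genome.sequence)
    lay = ExperimentLayout(
        libraries=[(f"lib{i + 1}", len(p)) for i, p in enumerate(layout)],
        lanes=["lane1"], validated_targets=set(targets), top_k=20)
    return records, lay


class TestSubsetYield:
    def test_subset_enumeration_and_grouping(self, experiment, toy_genome,
                                             toy_context):
        records, lay = experiment
        df = subset_yield_analysis(records, lay, CostModel(), toy_context,
                                   toy_genome.sequence)
        assert int(df["n_subsets"].sum()) == 2**10 - 1
        assert int(df.loc[df["n_strains"] == 3, "n_subsets"].iloc[0]) == 8
        assert (df["mean_yield"] <= 3.0).all()
        # cost attribution: full experiment = 10 libs + 1 lane = $1200
        full = df.loc[df["n_strains"] == 32, "cost"].iloc[0]
        assert full == pytest.approx(1200.0)

    def test_requires_validated_targets(self, experiment, toy_genome,
                                        toy_context):
        records, lay = experiment
        lay_missing = ExperimentLayout(libraries=lay.libraries,
                                       lanes=lay.lanes,
                                       validated_targets=None)
        with pytest.raises(ValueError):
            subset_yield_analysis(records, lay_missing, CostModel(),
                                  toy_context, toy_genome.sequence)


class TestFileLoading:
    def test_genome_and_gff_round_trip(self, toy_genome, tmp_path):
        fa = tmp_path / "g.fa"
        gff = tmp_path / "g.gff3"
        toy_genome.write_fasta(fa)
        toy_genome.write_gff3(gff)
        genome = load_genome(fa)
        assert genome == toy_genome.sequence
        ann = load_annotation(gff)
        assert len(ann) == len(toy_genome.features)
        by_id = {f.gene_id: f for f in ann}
        for f in toy_genome.features:
            got = by_id[f.gene_id]
            assert (got.start, got.end, got.strand) == (f.start, f.end,
                                                        f.strand)
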