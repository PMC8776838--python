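"""Domain-hit filtering, co-localization gap rule, completeness classes."""

import random

import pytest

from sidescan import io
from sidescan.bgc import (
    DomainHit,
    Gene,
    OrphanHitError,
    classify_cluster,
    filter_domain_hits,
    find_colocalized,
    find_loci,
    load_annotations,
    normalize_pfam,
    screen_genome_set,
)
from sidescan.io import DomtblRow
from sidescan.simulate import SimConfig, gen_genome
from conftest import write_annotations

SYN = "PF04183"
DEH = "PF01261"


def make_genes(n, contig="c1"):
    return [
        Gene(f"g{i:03d}", contig, 1000 * i + 1, 1000 * i + 900, "+", i)
        for i in range(n)
    ]


def hit(gene_id, pfam, evalue=1e-20):
    return DomainHit(gene_id, pfam, evalue, 100.0)


class TestNormalizePfam:
    @pytest.mark.parametrize(
        "raw", ["pfam04183", "PF04183", "PF04183.14", "pf04183"]
    )
    def test_aliases_collapse(self, raw):
        assert normalize_pfam(raw) == "PF04183"

    def test_garbage_rejected(self):
        with pytest.raises(ValueError):
            normalize_pfam("PFAM-X")


class TestFilterDomainHits:
    def test_filter_then_best(self):
        rows = [
            DomtblRow("g1", "syn", "PF04183.1", 1e-10, 50.0),
            DomtblRow("g1", "syn", "PF04183.1", 1e-3, 20.0),
            DomtblRow("g1", "syn", "PF04183.1", 1e-20, 90.0),
        ]
        kept = filter_domain_hits(rows, evalue_max=1e-5)
        assert len(kept) == 1 and kept[0].full_sequence_evalue == 1e-20

    def test_empty_input(self):
        assert filter_domain_hits([], 1e-5) == []

    def test_boundary_evalue_retained(self):
        rows = [DomtblRow("g1", "syn", "PF04183.1", 1e-5, 50.0)]
        assert len(filter_domain_hits(rows, evalue_max=1e-5)) == 1


class TestFindColocalized:
    def test_contiguous_planted_cluster_single_candidate(self):
        genes = make_genes(10)
        hits = [hit("g003", SYN), hit("g004", SYN), hit("g005", DEH)]
        cands = find_colocalized(genes, hits)
        assert len(cands) == 1
        assert cands[0].carrier_gene_ids == ("g003", "g004", "g005")

    def test_domains_on_different_contigs_never_colocalize(self):
        genes = [
            Gene("a2", "cA", 100, 200, "+", 2),
            Gene("b3", "cB", 100, 200, "+", 3),
        ]
        hits = [hit("a2", SYN), hit("b3", DEH)]
        assert find_colocalized(genes, hits) == []

    @pytest.mark.parametrize("gap,n_loci,n_cand", [(3, 1, 1), (4, 2, 0)])
    def test_gap_rule_boundary(self, gap, n_loci, n_cand):
        # carriers at ordinals 2 and 2+gap+1: `gap` intervening genes
        genes = make_genes(12)
        hits = [hit("g002", SYN), hit(f"g{3 + gap:03d}", DEH)]
        loci = find_loci(genes, hits, max_gene_gap=3)
        cands = [l for l in loci if l.is_candidate]
        assert len(loci) == n_loci and len(cands) == n_cand

    def test_window_monotonicity(self):
        # widening the gene gap can only merge runs, so the set of carrier
        # genes covered by candidate loci grows monotonically
        genes = make_genes(30)
        hits = [hit("g002", SYN), hit("g008", DEH), hit("g015", SYN), hit("g020", DEH)]
        covered = [
            {
                g for l in find_colocalized(genes, hits, max_gene_gap=gap)
                for g in l.carrier_gene_ids
            }
            for gap in range(0, 15)
        ]
        assert all(a <= b for a, b in zip(covered, covered[1:]))

    def test_strand_neutrality(self):
        genes = make_genes(10)
        flipped = [
            Gene(g.gene_id, g.contig_id, g.start, g.end, "-", g.ordinal) for g in genes
        ]
        hits = [hit("g003", SYN), hit("g004", SYN), hit("g005", DEH)]
        a = find_colocalized(genes, hits)
        b = find_colocalized(flipped, hits)
        assert [l.carrier_gene_ids for l in a] == [l.carrier_gene_ids for l in b]


class TestClassifyCluster:
    def _cluster(self, hits):
        genes = make_genes(10)
        locus = find_loci(genes, hits)[0]
        return classify_cluster(locus, genes, hits)

    def test_two_synthases_plus_dehydratase_is_complete(self):
        c = self._cluster([hit("g003", SYN), hit("g004", SYN), hit("g005", DEH)])
        assert c.completeness_class == "complete" and c.n_synthase == 2

    def test_one_synthase_plus_dehydratase_is_partial(self):
        c = self._cluster([hit("g003", SYN), hit("g005", DEH)])
        assert c.completeness_class == "partial"

    def test_synthases_without_dehydratase(self):
        c = self._cluster([hit("g003", SYN), hit("g004", SYN)])
        assert c.completeness_class == "synthase_only"

    def test_accessory_transporter_reported_not_required(self):
        hits = [
            hit("g003", SYN), hit("g004", SYN), hit("g005", DEH),
            hit("g006", "PF00593"),
        ]
        c = self._cluster(hits)
        assert c.completeness_class == "complete"
        assert c.accessory_labels == {"g006": "PF00593"}


class TestAnnotationsRoundTrip:
    def test_load_planted_genome(self, annotated_genome):
        genome, gff, dom = annotated_genome
        genes, hits = load_annotations(gff, dom)
        assert len(genes) == len(genome.genes)
        assert {h.pfam_accession for h in hits} == {"PF04183", "PF01261", "PF00593"}
        cands = find_colocalized(genes, hits)
        assert len(cands) == 1
        carrier_set = set(cands[0].carrier_gene_ids)
        truth_carriers = {
            gid for gid, pf in zip(genome.truth.gene_ids, genome.truth.pfam_labels)
            if pf in ("pfam04183", "pfam01261")
        }
        assert truth_carriers <= set(cands[0].all_gene_ids)
        assert carrier_set >= truth_carriers

    def test_orphan_hits_rejected(self, tmp_path):
        genome = gen_genome(SimConfig(seed=4), genome_id="G4")
        gff, dom = write_annotations(genome, str(tmp_path))
        io.write_domtblout(
            str(tmp_path / "orphan.dom"),
            list(genome.domain_hits)
            + [DomtblRow("ghost_gene", "syn", "PF04183.1", 1e-30, 99.0)],
        )
        with pytest.raises(OrphanHitError, match="ghost_gene"):
            load_annotations(gff, str(tmp_path / "orphan.dom"))

    def test_record_order_invariance(self, tmp_path):
        genome = gen_genome(SimConfig(seed=8), genome_id="G8")
        gff, dom = write_annotations(genome, str(tmp_path))
        ref_genes, ref_hits = load_annotations(gff, dom)
        ref_loci = find_colocalized(ref_genes, ref_hits)

        rng = random.Random(0)
        shuffled_genes = list(genome.genes)
        rng.shuffle(shuffled_genes)
        shuffled_hits = list(genome.domain_hits)
        rng.shuffle(shuffled_hits)
        io.write_gff3(str(tmp_path / "s.gff3"), shuffled_genes)
        io.write_domtblout(str(tmp_path / "s.dom"), shuffled_hits)
        genes, hits = load_annotations(str(tmp_path / "s.gff3"), str(tmp_path / "s.dom"))
        loci = find_colocalized(genes, hits)
        assert [l.carrier_gene_ids for l in loci] == [
            l.carrier_gene_ids for l in ref_loci
        ]


class TestScreenGenomeSet:
    def test_mixed_set_counts(self, tmp_path):
        complete_spec = (
            ("asbA", "pfam04183"), ("asbB", "pfam04183"), ("asbF", "pfam01261")
        )
        synthase_only_spec = (("iucA", "pfam04183"),)
        pairs = {}
        for i, spec in enumerate([complete_spec, synthase_only_spec, ()]):
            g = gen_genome(SimConfig(seed=20 + i, cluster_spec=spec), genome_id=f"M{i}")
            pairs[f"M{i}"] = write_annotations(g, str(tmp_path))
        summary, report = screen_genome_set(pairs)
        assert summary.n_with_synthase == 2
        assert summary.n_with_colocalization == 1
        assert summary.n_complete == 1
        assert set(report["completeness_class"]) == {"complete", "synthase_only"}

    def test_planted_recovery_over_seeds(self, tmp_path):
        pairs = {}
        truths = {}
        for seed in range(1, 21):
            g = gen_genome(SimConfig(seed=seed), genome_id=f"S{seed}")
            pairs[f"S{seed}"] = write_annotations(g, str(tmp_path))
            truths[f"S{seed}"] = g.truth
        summary, report = screen_genome_set(pairs)
        assert summary.n_complete == 20  # sensitivity 1.0
        assert len(report) == 20  # no false-positive loci
        for genome_id, truth in truths.items():
            row = report[report["genome"] == genome_id].iloc[0]
            # reported locus lies within the planted span and contains
            # every diagnostic (synthase/dehydratase) gene
            assert truth.start <= row["start"] <= row["end"] <= truth.end
            diagnostic = {
                gid for gid, pf in zip(truth.gene_ids, truth.pfam_labels)
                if pf in ("pfam04183", "pfam01261")
            }
            assert diagnostic <= set(row["gene_ids"].split(","))

    def test_failed_genome_reported_not_fatal(self, tmp_path):
        g = gen_genome(SimConfig(seed=30), genome_id="OK")
        ok_pair = write_annotations(g, str(tmp_path))
        bad_gff = tmp_path / "bad.gff3"
        bad_gff.write_text("this is not gff\n")
        summary, report = screen_genome_set(
            {"OK": ok_pair, "BAD": (str(bad_gff), ok_pair[1])}
        )
        assert summary.n_complete == 1
        assert len(summary.failures) == 1 and "BAD" in summary.failures[0]
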