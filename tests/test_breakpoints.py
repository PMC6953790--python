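import numpy as np
import pandas as pd
import pytest

from segstack.breakpoints import (
    CATEGORIES,
    PermutationNull,
    category_counts,
    classify_edges,
    enrichment,
    genes_at_edges,
    permute_isochromosomal,
    track_extent_bp,
)
from segstack.genome_model import (
    GeneRegion,
    GenomeAnnotation,
    GenomeBuild,
    ValidationError,
)
from segstack.reduced_segments import CnaCall


def loss(chrom, start, end, sample="s1"):
    return CnaCall(sample, chrom, start, end, -0.5, "loss")


class TestClassifyEdges:
    def test_edge_near_chromosome_start_is_telomeric(self, annotation):
        build = GenomeBuild("big", {"1": 100_000_000})
        ann = GenomeAnnotation(build=build, telomere_window_bp=2_000_000)
        edges = classify_edges([loss("1", 1_500_000, 50_000_000)], ann)
        start_edge = next(e for e in edges if e.which == "start")
        assert start_edge.telomeric
        end_edge = next(e for e in edges if e.which == "end")
        assert not end_edge.telomeric

    def test_edge_at_window_boundary_not_telomeric(self):
        build = GenomeBuild("big", {"1": 100_000_000})
        ann = GenomeAnnotation(build=build, telomere_window_bp=2_000_000)
        edges = classify_edges([loss("1", 2_000_000, 50_000_000)], ann)
        assert not next(e for e in edges if e.which == "start").telomeric

    def test_intragenic_edge_reports_gene(self):
        build = GenomeBuild("big", {"1": 100_000_000})
        ann = GenomeAnnotation(
            build=build, genes=[GeneRegion("G", "1", 49_000_000, 51_000_000)]
        )
        edges = classify_edges([loss("1", 50_000_000, 60_000_000)], ann)
        start_edge = next(e for e in edges if e.which == "start")
        assert start_edge.intragenic
        assert start_edge.genes_hit == ("G",)

    def test_centromeric_window_extends_both_flanks(self, annotation):
        # centromere of chr1 is [5.0, 5.2] Mb, window 2 Mb
        for pos, expected in [
            (3_000_001, True), (5_100_000, True), (7_199_999, True),
            (2_999_999, False), (7_200_000, False),
        ]:
            edges = classify_edges([loss("1", pos, pos + 10)], annotation)
            assert edges[0].centromeric is expected, pos

    def test_flags_not_mutually_exclusive(self, annotation):
        # GENE3 on chr2 spans [1,3] Mb; position 1.5 Mb is telomeric too
        edges = classify_edges([loss("2", 1_500_000, 7_000_000)], annotation)
        start_edge = edges[0]
        assert start_edge.telomeric and start_edge.intragenic

    def test_unknown_chromosome_errors(self, annotation):
        with pytest.raises(ValidationError, match="absent"):
            classify_edges([loss("9", 0, 100)], annotation)

    def test_equals_brute_force_membership(self, annotation):
        """500 random edges vs direct interval-membership over all tracks."""
        rng = np.random.default_rng(17)
        build = annotation.build
        calls = []
        for i in range(250):
            chrom = str(rng.choice(build.chroms))
            length = build.chrom_lengths[chrom]
            start = int(rng.integers(0, length - 1))
            end = int(rng.integers(start + 1, length, endpoint=True))
            calls.append(loss(chrom, start, end, sample=f"s{i}"))
        edges = classify_edges(calls, annotation)
        assert len(edges) == 500
        w = annotation.telomere_window_bp
        for e in edges:
            chrom, pos = e.call.chrom, e.position
            length = build.chrom_lengths[chrom]
            telo = any(
                lo <= pos < hi for lo, hi in annotation.telomere_windows(chrom)
            )
            cen = False
            if chrom in annotation.centromeres:
                cs, ce = annotation.centromeres[chrom]
                cen = max(cs - w, 0) <= pos < min(ce + w, length)
            genes = [
                g.gene_id for g in annotation.genes
                if g.chrom == chrom and g.start <= pos < g.end
            ]
            frag = any(
                c == chrom and s <= pos < en
                for c, s, en in annotation.fragile_sites
            )
            stab = any(
                c == chrom and s <= pos < en
                for c, s, en in annotation.stable_sites
            )
            assert e.telomeric == telo
            assert e.centromeric == cen
            assert e.intragenic == bool(genes)
            assert sorted(e.genes_hit) == sorted(genes)
            assert e.fragile == frag
            assert e.stable == stab


class TestGenesAtEdges:
    def test_edge_in_small_gene_reports_size(self, annotation):
        edges = classify_edges([loss("1", 200, 2_000_000)], annotation)
        sizes, exprs = genes_at_edges(edges, annotation)
        assert 400 in sizes  # GENE1 is 400 bp
        assert 5.0 in exprs

    def test_edge_in_no_gene_contributes_nothing(self, annotation):
        edges = classify_edges([loss("1", 600, 1_000)], annotation)
        sizes, exprs = genes_at_edges(edges, annotation)
        assert sizes == [] and exprs == []

    def test_gene_without_expression_omitted_from_expression_list(self, annotation):
        # GENE2 has no expression entry
        edges = classify_edges([loss("1", 4_010_000, 4_020_000)], annotation)
        sizes, exprs = genes_at_edges(edges, annotation)
        assert sizes == [50_000, 50_000]
        assert exprs == []

    def test_totals_equal_brute_force(self, annotation):
        rng = np.random.default_rng(23)
        build = annotation.build
        calls = []
        for i in range(100):
            chrom = str(rng.choice(build.chroms))
            length = build.chrom_lengths[chrom]
            start = int(rng.integers(0, length - 1))
            end = int(rng.integers(start + 1, length, endpoint=True))
            calls.append(loss(chrom, start, end, sample=f"s{i}"))
        edges = classify_edges(calls, annotation)
        sizes, exprs = genes_at_edges(edges, annotation)
        expected_sizes = []
        expected_exprs = []
        for call in calls:
            for pos in (call.start, call.end):
                for g in annotation.genes:
                    if g.chrom == call.chrom and g.start <= pos < g.end:
                        expected_sizes.append(g.length)
                        if g.gene_id in annotation.expression:
                            expected_exprs.append(annotation.expression[g.gene_id])
        assert sorted(sizes) == sorted(expected_sizes)
        assert sorted(exprs) == sorted(expected_exprs)


class TestPermuteIsochromosomal:
    def test_forced_placement_when_call_spans_chromosome(self):
        build = GenomeBuild("b", {"1": 1_000})
        ann = GenomeAnnotation(build=build, telomere_window_bp=10)
        null = permute_isochromosomal([loss("1", 0, 1_000)], ann, n=20, seed=1)
        assert (null.starts == 0).all()

    def test_call_longer_than_chromosome_errors(self):
        build = GenomeBuild("b", {"1": 1_000, "2": 10_000})
        ann = GenomeAnnotation(build=build, telomere_window_bp=10)
        call = loss("2", 0, 5_000)
        bad = CnaCall("s1", "1", 0, 5_000, -0.5, "loss")
        with pytest.raises(ValidationError, match="longer than its chromosome"):
            permute_isochromosomal([call, bad], ann, n=5, seed=1)

    def test_length_and_chromosome_conserved(self, annotation):
        rng = np.random.default_rng(3)
        calls = []
        for i in range(10):
            chrom = str(rng.choice(annotation.build.chroms))
            length = annotation.build.chrom_lengths[chrom]
            start = int(rng.integers(0, length - 100))
            end = int(rng.integers(start + 1, length, endpoint=True))
            calls.append(loss(chrom, start, end, sample=f"s{i}"))
        null = permute_isochromosomal(calls, annotation, n=100, seed=7)
        assert null.starts.shape == (100, 10)
        for j, call in enumerate(calls):
            assert null.call_chroms[j] == call.chrom
            assert null.call_lengths[j] == call.length
            chrom_len = annotation.build.chrom_lengths[call.chrom]
            assert (null.starts[:, j] >= 0).all()
            assert (null.starts[:, j] + call.length <= chrom_len).all()

    def test_seed_determinism(self, annotation):
        calls = [loss("1", 100_000, 400_000)]
        n1 = permute_isochromosomal(calls, annotation, n=50, seed=11)
        n2 = permute_isochromosomal(calls, annotation, n=50, seed=11)
        assert (n1.starts == n2.starts).all()
        assert n1.category_counts.equals(n2.category_counts)
        n3 = permute_isochromosomal(calls, annotation, n=50, seed=12)
        assert not (n1.starts == n3.starts).all()

    def test_null_intragenic_fraction_matches_genic_fraction(self):
        """Genes tiling 50% of the chromosome uniformly: the expected
        intragenic-edge fraction under uniform placement is ~0.5."""
        length = 10_000_000
        build = GenomeBuild("b", {"1": length})
        genes = [
            GeneRegion(f"g{i}", "1", i * 200_000, i * 200_000 + 100_000)
            for i in range(50)
        ]
        ann = GenomeAnnotation(build=build, genes=genes, telomere_window_bp=1_000)
        calls = [loss("1", 0, 1_000, sample=f"s{i}") for i in range(10)]
        null = permute_isochromosomal(calls, ann, n=1_000, seed=5)
        per_perm_fraction = null.category_counts["intragenic"].to_numpy() / 20
        mean = per_perm_fraction.mean()
        se = per_perm_fraction.std(ddof=1) / np.sqrt(len(per_perm_fraction))
        assert abs(mean - 0.5) < 3 * max(se, 1e-3)


class TestEnrichment:
    def _null(self, counts, category="telomeric"):
        n = len(counts)
        table = pd.DataFrame(0, index=range(n), columns=list(CATEGORIES))
        table[category] = counts
        return PermutationNull(
            n_permutations=n, seed=0, category_counts=table,
            gene_sizes=[], expressions=[], n_calls=1,
        )

    def _observed(self, annotation, telomeric_count):
        calls = [
            loss("1", 100, 1_000, sample=f"s{i}") for i in range(telomeric_count)
        ]
        edges = classify_edges(calls, annotation)
        return [e for e in edges if e.which == "start"]

    def test_observed_below_all_null_gives_p_one(self, annotation):
        observed = self._observed(annotation, 1)  # telomeric count 1
        null = self._null([5] * 10)
        table = enrichment(observed, null)
        p = table.set_index("category").loc["telomeric", "p_value"]
        assert p == pytest.approx(1.0)

    def test_observed_at_null_max_with_single_tie(self, annotation):
        observed = self._observed(annotation, 4)
        null = self._null([0, 1, 2, 3, 4])  # exactly one tie at 4
        table = enrichment(observed, null)
        p = table.set_index("category").loc["telomeric", "p_value"]
        assert p == pytest.approx(2 / 6)

    def test_p_value_bounds(self, annotation):
        observed = self._observed(annotation, 3)
        null = self._null(list(range(100)))
        table = enrichment(observed, null)
        n = null.n_permutations
        assert ((table["p_value"] >= 1 / (n + 1)) & (table["p_value"] <= 1)).all()

    def test_two_sided_doubles_smaller_tail(self, annotation):
        observed = self._observed(annotation, 4)
        null = self._null([0, 1, 2, 3, 4])
        g = enrichment(observed, null, alternative="greater").set_index("category")
        t = enrichment(observed, null, alternative="two-sided").set_index("category")
        assert t.loc["telomeric", "p_value"] == pytest.approx(
            min(1.0, 2 * g.loc["telomeric", "p_value"])
        )

    def test_telomeric_bias_detected(self, annotation):
        """A 5x telomere-biased call set shows telomeric enrichment."""
        from segstack.synthetic import SimConfig, simulate_biased_breakpoint_calls

        cfg = SimConfig(
            seed=2, n_breakpoint_events=40, bias_track="telomeric",
            bias_weight=5.0, event_length_range=(10_000, 1_000_000),
            chrom_lengths=dict(annotation.build.chrom_lengths),
        )
        calls, _ = simulate_biased_breakpoint_calls(cfg, annotation)
        observed = classify_edges(calls, annotation)
        null = permute_isochromosomal(calls, annotation, n=200, seed=3)
        table = enrichment(observed, null).set_index("category")
        assert table.loc["telomeric", "p_value"] < 0.05


class TestTrackExtent:
    def test_extents(self, annotation):
        ext = track_extent_bp(annotation)
        # two 2 Mb windows per chromosome (all three are longer than 4 Mb)
        assert ext["telomeric"] == 3 * 4_000_000
        assert ext["fragile"] == 200_000
        assert ext["stable"] == 500_000
        assert ext["intragenic"] == 400 + 50_000 + 2_000_000
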