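import numpy as np
import pytest

from ecgi.intervals import GeneModel, GenomicInterval, promoter_window
from ecgi.targets import (
    ChiaLink,
    assign_nearest,
    assign_targets,
    compare_link_strength,
    expression_fold_change,
    filter_links,
    read_links,
    target_multiplicity,
    write_links,
    TargetAssignment,
)

from conftest import brute_force_overlap


def _link(s1, e1, s2, e2, tags, chrom="chr1"):
    return ChiaLink(
        GenomicInterval(chrom, s1, e1), GenomicInterval(chrom, s2, e2), tags
    )


def _gene(tss, gid, chrom="chr1"):
    return GeneModel(GenomicInterval(chrom, tss, tss + 2000, "+"), gid)


class TestFilterLinks:
    def test_threshold(self):
        links = [_link(0, 10, 100, 110, t) for t in (1, 2, 3, 4)]
        assert len(filter_links(links, 3)) == 2

    def test_min_one_is_identity(self):
        links = [_link(0, 10, 100, 110, t) for t in (1, 5)]
        assert filter_links(links, 1) == links

    def test_subset_and_idempotent(self, rng):
        links = [_link(0, 10, 100, 110, int(t)) for t in rng.integers(1, 10, size=10_000)]
        once = filter_links(links, 3)
        assert set(id(x) for x in once) <= set(id(x) for x in links)
        assert filter_links(once, 3) == once
        assert len(once) == sum(1 for ln in links if ln.tag_count >= 3)

    def test_round_trip_io(self, tmp_path):
        links = [_link(0, 10, 100, 110, 3), _link(5, 15, 200, 210, 7, chrom="chr2")]
        path = tmp_path / "links.bedpe"
        write_links(links, path)
        assert read_links(path) == links


class TestAssignTargets:
    def test_basic_assignment(self):
        region = GenomicInterval("chr1", 5000, 6000, ".", "R")
        gene = _gene(20_000, "G")
        link = _link(5100, 5200, 19_500, 19_600, 4)
        (a,) = assign_targets([region], [link], [gene])
        assert (a.region_id, a.gene_id, a.tag_count, a.evidence) == ("R", "G", 4, "chia")

    def test_self_loop_no_assignment(self):
        region = GenomicInterval("chr1", 5000, 6000, ".", "R")
        gene = _gene(50_000, "G")
        link = _link(5100, 5200, 5300, 5400, 4)  # both anchors inside R
        assert assign_targets([region], [link], [gene]) == []

    def test_anchor_order_symmetric(self, rng):
        regions, links, genes = self._random_instance(rng)
        swapped = [ChiaLink(ln.anchor2, ln.anchor1, ln.tag_count) for ln in links]
        assert assign_targets(regions, links, genes) == assign_targets(
            regions, swapped, genes
        )

    def test_max_aggregation_over_supporting_links(self):
        region = GenomicInterval("chr1", 5000, 6000, ".", "R")
        gene = _gene(20_000, "G")
        links = [_link(5100, 5200, 19_500, 19_600, 4), _link(5300, 5400, 19_700, 19_800, 9)]
        (a,) = assign_targets([region], links, [gene])
        assert a.tag_count == 9
        (a_sum,) = assign_targets([region], links, [gene], aggregate="sum")
        assert a_sum.tag_count == 13

    @staticmethod
    def _random_instance(rng, n_regions=50, n_genes=30, n_links=200):
        regions = [
            GenomicInterval(
                "chr1", int(s := rng.integers(0, 500_000)), int(s + rng.integers(100, 2000)),
                ".", f"R{i}",
            )
            for i, _ in enumerate(range(n_regions))
        ]
        genes = [_gene(int(rng.integers(0, 500_000)), f"G{i}") for i in range(n_genes)]
        links = [
            _link(
                int(s1 := rng.integers(0, 500_000)), int(s1 + rng.integers(50, 500)),
                int(s2 := rng.integers(0, 500_000)), int(s2 + rng.integers(50, 500)),
                int(rng.integers(3, 10)),
            )
            for _ in range(n_links)
        ]
        return regions, links, genes

    def test_matches_all_triples_bruteforce(self, rng):
        regions, links, genes = self._random_instance(rng)
        promoters = {g.gene_id: promoter_window(g, 1000) for g in genes}
        expected = {}
        for ln in links:
            for ra, ga in ((ln.anchor1, ln.anchor2), (ln.anchor2, ln.anchor1)):
                for r in regions:
                    if not brute_force_overlap(ra, r):
                        continue
                    for g in genes:
                        if brute_force_overlap(ga, promoters[g.gene_id]):
                            key = (r.name, g.gene_id)
                            expected[key] = max(expected.get(key, 0), ln.tag_count)
        got = {(a.region_id, a.gene_id): a.tag_count for a in assign_targets(regions, links, genes)}
        assert got == expected


class TestMultiplicity:
    def _assign(self, counts):
        return [
            TargetAssignment(f"R{i}", f"G{i}_{j}", 3, "chia")
            for i, c in enumerate(counts)
            for j in range(c)
        ]

    def test_counting(self):
        single, multiple = target_multiplicity(self._assign([1, 1, 2]))
        assert (single, multiple) == (pytest.approx(2 / 3), pytest.approx(1 / 3))

    def test_all_single(self):
        assert target_multiplicity(self._assign([1, 1, 1])) == (1.0, 0.0)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            target_multiplicity([])

    def test_planted_multi_target_fraction_recovered(self):
        """Generator planted with 60% multi-target eCGIs: recovered fraction
        within +/-0.05 at ~500 eCGIs."""
        from ecgi.synth import SynthConfig, generate

        config = SynthConfig(
            seed=23, n_cgis=1250, n_genes=500,
            class_mix={"pCGI": 0.3, "npCGI": 0.1, "eCGI": 0.4, "orphan_inactive": 0.2},
            chrom_sizes={"chr1": 15_000_000, "chr2": 15_000_000, "chr3": 15_000_000},
        )
        ds = generate(config)
        assigns = assign_targets(ds.cgis_labeled("eCGI"), filter_links(ds.links, 3), ds.genes)
        _, multiple = target_multiplicity(assigns)
        assert abs(multiple - 0.6) <= 0.05


class TestCompareLinkStrength:
    def test_paired_variant(self):
        res = compare_link_strength([5, 6, 7, 8], [1, 2, 3, 4], paired=True)
        assert res.method.startswith("signed-rank")
        assert res.p_greater == pytest.approx(1 / 16)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            compare_link_strength([], [1])

    def test_planted_tag_shift_detected(self):
        """eCGI pairs with tag counts shifted +2 over enhancer pairs are
        detected at 0.05 in >=95% of replicates (n=200 per class)."""
        hits = 0
        n_rep = 100
        for seed in range(n_rep):
            r = np.random.default_rng(seed)
            ecgi_tags = 5 + r.poisson(1.0, size=200)
            te_tags = 3 + r.poisson(1.0, size=200)
            if compare_link_strength(ecgi_tags, te_tags).p_greater < 0.05:
                hits += 1
        assert hits >= 0.95 * n_rep


class TestExpressionFold:
    ASSIGN = [TargetAssignment("R", "G", 3, "chia")]

    def test_equal_expression_fold_one(self):
        folds = expression_fold_change(self.ASSIGN, {"G": 10.0}, {"G": 10.0}, 0.1)
        assert folds["G"] == pytest.approx(1.0)

    def test_ratio_without_pseudocount(self):
        folds = expression_fold_change(self.ASSIGN, {"G": 5.88}, {"G": 1.0}, 0.0)
        assert folds["G"] == pytest.approx(5.88)

    def test_missing_gene_excluded(self):
        folds = expression_fold_change(self.ASSIGN, {"G": 1.0}, {}, 0.1)
        assert folds == {}

    def test_negative_expression_raises(self):
        with pytest.raises(ValueError):
            expression_fold_change(self.ASSIGN, {"G": -1.0}, {"G": 1.0}, 0.1)

    def test_planted_upregulation_recovered(self, dataset):
        """Cell-A eCGI targets planted 4x higher than in cell B: median fold
        lands in [3, 5]."""
        assigns = assign_targets(
            dataset.cgis_labeled("eCGI"), filter_links(dataset.links, 3), dataset.genes
        )
        folds = expression_fold_change(
            assigns, dataset.expr_normal, dataset.expr_cell_b, 0.1
        )
        assert 3.0 <= np.median(list(folds.values())) <= 5.0


class TestAssignNearest:
    def test_nearest_fallback(self):
        regions = [GenomicInterval("chr1", 1000, 1100, ".", "R")]
        genes = [_gene(900, "close"), _gene(50_000, "far")]
        (a,) = assign_nearest(regions, genes)
        assert (a.gene_id, a.evidence) == ("close", "nearest")
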