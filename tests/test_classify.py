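import numpy as np
import pytest

from ecgi.classify import (
    CGIRecord,
    call_typical_enhancers,
    cell_specific_sets,
    class_counts,
    classify_cgis,
    sequence_stats,
)
from ecgi.intervals import GeneModel, GenomicInterval

from conftest import brute_force_overlap, random_intervals


def _gene(tss, chrom="chr1", coding=True, gid="g1"):
    return GeneModel(GenomicInterval(chrom, tss, tss + 5000, "+"), gid, coding)


def oracle_classify(cgis, genes, k27, dhs, cage, denovo, flank=1000):
    """Independent nested-loop rendering of the classification cascade."""
    from ecgi.intervals import promoter_window

    promoters = [promoter_window(g, flank) for g in genes if g.coding]
    tss_ev = list(cage) + [
        GenomicInterval(t.chrom, max(0, t.start - flank), t.end + flank)
        for t in denovo
    ]
    labels = []
    for cgi in cgis:
        if any(brute_force_overlap(cgi, p) for p in promoters):
            labels.append("pCGI")
        elif not (
            any(brute_force_overlap(cgi, p) for p in k27)
            and any(brute_force_overlap(cgi, p) for p in dhs)
        ):
            labels.append("orphan_inactive")
        elif any(brute_force_overlap(cgi, t) for t in tss_ev):
            labels.append("npCGI")
        else:
            labels.append("eCGI")
    return labels


class TestCascade:
    CGI = GenomicInterval("chr1", 9500, 10500, ".", "c")
    PEAK = [GenomicInterval("chr1", 9000, 11000)]

    def test_promoter_rule_wins_over_activity(self):
        recs = classify_cgis([self.CGI], [_gene(10_000)], self.PEAK, self.PEAK, [], [])
        assert recs[0].label == "pCGI"

    def test_missing_dhs_makes_orphan_inactive(self):
        recs = classify_cgis([self.CGI], [], self.PEAK, [], [], [])
        assert recs[0].label == "orphan_inactive"

    def test_noncoding_gene_does_not_define_pcgi(self):
        recs = classify_cgis(
            [self.CGI], [_gene(10_000, coding=False)], self.PEAK, self.PEAK, [], []
        )
        assert recs[0].label == "eCGI"

    def test_cage_evidence_makes_npcgi(self):
        cage = [GenomicInterval("chr1", 10_000, 10_050)]
        recs = classify_cgis([self.CGI], [], self.PEAK, self.PEAK, cage, [])
        assert recs[0].label == "npCGI"

    def test_active_orphan_without_tss_is_ecgi(self):
        recs = classify_cgis([self.CGI], [], self.PEAK, self.PEAK, [], [])
        assert recs[0].label == "eCGI"

    def test_empty_cgi_list_gives_empty_result(self):
        assert classify_cgis([], [], self.PEAK, self.PEAK, [], []) == []

    def test_labels_partition_input(self, rng):
        cgis = random_intervals(rng, 300)
        recs = classify_cgis(
            cgis, [_gene(5000)], random_intervals(rng, 100), random_intervals(rng, 100),
            random_intervals(rng, 50), random_intervals(rng, 50),
        )
        assert len(recs) == 300
        assert sum(class_counts(recs).values()) == 300

    def test_matches_bruteforce_oracle_on_random_fixtures(self, rng):
        for _ in range(5):
            cgis = random_intervals(rng, 200)
            genes = [
                _gene(int(rng.integers(0, 100_000)), gid=f"g{i}", coding=i % 4 != 0)
                for i in range(30)
            ]
            k27 = random_intervals(rng, 80)
            dhs = random_intervals(rng, 80)
            cage = random_intervals(rng, 40)
            denovo = random_intervals(rng, 40)
            got = [r.label for r in classify_cgis(cgis, genes, k27, dhs, cage, denovo)]
            assert got == oracle_classify(cgis, genes, k27, dhs, cage, denovo)

    def test_adding_h3k27ac_only_rescues_orphan_inactive(self, rng):
        """More H3K27ac peaks can move CGIs out of orphan_inactive but never
        change a pCGI call (the promoter rule is evaluated first)."""
        cgis = random_intervals(rng, 200)
        genes = [_gene(int(rng.integers(0, 100_000)), gid=f"g{i}") for i in range(20)]
        dhs = random_intervals(rng, 150)
        k27_small = random_intervals(rng, 30)
        k27_big = k27_small + random_intervals(rng, 100)
        before = [r.label for r in classify_cgis(cgis, genes, k27_small, dhs, [], [])]
        after = [r.label for r in classify_cgis(cgis, genes, k27_big, dhs, [], [])]
        for b, a in zip(before, after):
            if b != a:
                assert b == "orphan_inactive" and a == "eCGI"
            if b == "pCGI":
                assert a == "pCGI"


class TestTypicalEnhancers:
    def test_clean_dhs_peak_retained(self):
        dhs = [GenomicInterval("chr1", 1000, 2000, ".", "d0")]
        k27 = [GenomicInterval("chr1", 900, 2100)]
        (te,) = call_typical_enhancers(k27, dhs, [], [], [])
        assert te.interval == dhs[0]

    def test_cgi_overlap_excluded(self):
        dhs = [GenomicInterval("chr1", 1000, 2000)]
        k27 = [GenomicInterval("chr1", 900, 2100)]
        assert call_typical_enhancers(k27, dhs, [], [], [GenomicInterval("chr1", 1500, 1600)]) == []

    def test_no_h3k27ac_excluded(self):
        assert call_typical_enhancers([], [GenomicInterval("chr1", 0, 10)], [], [], []) == []

    def test_count_matches_bruteforce_filter(self, rng):
        dhs = random_intervals(rng, 150)
        k27 = random_intervals(rng, 150)
        cage = random_intervals(rng, 60)
        denovo = random_intervals(rng, 60)
        cgis = random_intervals(rng, 80)
        flank = 1000
        tss_ev = list(cage) + [
            GenomicInterval(t.chrom, max(0, t.start - flank), t.end + flank) for t in denovo
        ]
        expected = sum(
            1
            for p in dhs
            if any(brute_force_overlap(p, q) for q in k27)
            and not any(brute_force_overlap(p, q) for q in cgis)
            and not any(brute_force_overlap(p, q) for q in tss_ev)
        )
        assert len(call_typical_enhancers(k27, dhs, cage, denovo, cgis)) == expected


class TestSequenceStats:
    def test_cgcg(self):
        assert sequence_stats("CGCG") == (4, 100.0, 2.0)

    def test_no_gc(self):
        length, gc, ratio = sequence_stats("ATAT")
        assert (length, gc, ratio) == (4, 0.0, 0.0)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            sequence_stats("")

    def test_invalid_alphabet_raises(self):
        with pytest.raises(ValueError):
            sequence_stats("ACGU")

    def test_matches_sliding_window_counter(self, rng):
        bases = np.array(list("ACGTN"))
        for _ in range(100):
            seq = "".join(bases[rng.integers(0, 5, size=500)])
            length, gc, ratio = sequence_stats(seq)
            eff = sum(1 for b in seq if b != "N")
            n_c, n_g = seq.count("C"), seq.count("G")
            n_cpg = sum(1 for i in range(len(seq) - 1) if seq[i : i + 2] == "CG")
            assert length == 500
            assert gc == pytest.approx(100 * (n_c + n_g) / eff)
            expected = (n_cpg * eff) / (n_c * n_g) if n_c and n_g else 0.0
            assert ratio == pytest.approx(expected)


def _records(ids):
    return [
        CGIRecord(GenomicInterval("chr1", 100 * i + 1, 100 * i + 50), cid, "eCGI")
        for i, cid in enumerate(ids)
    ]


class TestCellSpecificSets:
    def test_identical_inputs(self):
        res = cell_specific_sets(_records(["a", "b"]), _records(["a", "b"]))
        assert res["a_specific"] == res["b_specific"] == set()
        assert res["common"] == {"a", "b"}
        assert res["a_specific_pct"] == 0.0

    def test_duplicate_id_raises(self):
        with pytest.raises(ValueError):
            cell_specific_sets(_records(["a", "a"]), _records(["b"]))

    def test_partition_invariant(self, rng):
        ids = [f"c{i}" for i in range(200)]
        a = list(rng.choice(ids, size=120, replace=False))
        b = list(rng.choice(ids, size=90, replace=False))
        res = cell_specific_sets(_records(a), _records(b))
        assert len(res["a_specific"]) + len(res["common"]) == 120
        assert len(res["b_specific"]) + len(res["common"]) == 90
        assert res["a_specific"] | res["b_specific"] | res["common"] == set(a) | set(b)
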