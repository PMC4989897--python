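import numpy as np
import pandas as pd
import pytest

from ecgi.intervals import GenomicInterval
from ecgi.methylation import (
    MethylSite,
    RegionMethylation,
    aggregate_region_dm,
    class_dm_contrast,
    differential_methylation,
    dm_matrix,
    select_hypermethylated,
    target_silencing,
)
from ecgi.targets import TargetAssignment


def _beta_df(rows):
    return pd.DataFrame(rows, columns=["chrom", "position", "beta"])


def _site(pos, bn, bt, chrom="chr1"):
    return MethylSite(GenomicInterval(chrom, pos, pos + 1), bn, bt)


class TestDifferentialMethylation:
    def test_subtraction(self):
        (site,) = differential_methylation(
            _beta_df([("chr1", 100, 0.1)]), _beta_df([("chr1", 100, 0.8)])
        )
        assert site.dm == pytest.approx(0.7)

    def test_identical_tables_zero_dm(self):
        df = _beta_df([("chr1", 100, 0.3), ("chr1", 200, 0.6)])
        sites = differential_methylation(df, df)
        assert all(s.dm == 0 for s in sites)

    def test_out_of_range_beta_names_position(self):
        with pytest.raises(ValueError, match="chr1:100"):
            differential_methylation(
                _beta_df([("chr1", 100, 1.5)]), _beta_df([("chr1", 100, 0.5)])
            )

    def test_unmatched_and_missing_positions_dropped(self, rng):
        pos_n = set(map(int, rng.choice(10_000, size=300, replace=False)))
        pos_t = set(map(int, rng.choice(10_000, size=300, replace=False)))
        dfn = _beta_df([("chr1", p, 0.2) for p in sorted(pos_n)])
        dft = _beta_df(
            [("chr1", p, np.nan if p % 7 == 0 else 0.9) for p in sorted(pos_t)]
        )
        sites = differential_methylation(dfn, dft)
        expected = {p for p in pos_n & pos_t if p % 7 != 0}
        assert {s.position.start for s in sites} == expected

    def test_antisymmetric_under_condition_swap(self, rng):
        rows = [("chr1", int(p), float(b)) for p, b in
                zip(rng.choice(10_000, 50, replace=False), rng.random(50))]
        rows2 = [("chr1", p, float(b)) for (_, p, _), b in zip(rows, rng.random(50))]
        fwd = differential_methylation(_beta_df(rows), _beta_df(rows2))
        rev = differential_methylation(_beta_df(rows2), _beta_df(rows))
        assert all(f.dm == pytest.approx(-r.dm) for f, r in zip(fwd, rev))


class TestAggregateRegionDm:
    def test_mean_over_contained_cpgs(self):
        sites = [_site(100, 0.1, 0.3), _site(150, 0.1, 0.7)]
        (r,) = aggregate_region_dm(sites, [GenomicInterval("chr1", 50, 200, ".", "A")])
        assert (r.n_cpgs, r.mean_dm) == (2, pytest.approx(0.4))

    def test_region_without_cpgs_dropped(self):
        out = aggregate_region_dm([_site(100, 0.1, 0.3)], [GenomicInterval("chr1", 500, 600)])
        assert out == []

    def test_matches_bruteforce_scan(self, rng):
        sites = [
            _site(int(p), float(b), float(t))
            for p, b, t in zip(
                rng.choice(50_000, 400, replace=False), rng.random(400), rng.random(400)
            )
        ]
        regions = [
            GenomicInterval("chr1", int(s := rng.integers(0, 50_000)), int(s + 500), ".", f"r{i}")
            for i, _ in enumerate(range(50))
        ]
        got = {r.region_id: (r.n_cpgs, r.mean_dm) for r in aggregate_region_dm(sites, regions)}
        for region in regions:
            dms = [s.dm for s in sites if region.start <= s.position.start < region.end]
            if dms:
                n, mean = got[region.name]
                assert n == len(dms) and mean == pytest.approx(np.mean(dms), abs=1e-12)
            else:
                assert region.name not in got


class TestSelectHypermethylated:
    def _rm(self, vals):
        return [RegionMethylation(f"r{i}", 5, v) for i, v in enumerate(vals)]

    def test_strict_inequality_at_threshold(self):
        out = select_hypermethylated(self._rm([0.5, 0.50001]), 0.5)
        assert [r.region_id for r in out] == ["r1"]
        assert all(r.hyper for r in out)

    def test_threshold_domain(self):
        with pytest.raises(ValueError):
            select_hypermethylated(self._rm([0.2]), 0.0)

    def test_monotone_nesting_in_threshold(self, rng):
        rms = self._rm(rng.uniform(-1, 1, size=200))
        prev = None
        for t in (0.1, 0.3, 0.5, 0.7):
            ids = {r.region_id for r in select_hypermethylated(rms, t)}
            if prev is not None:
                assert ids <= prev
            prev = ids

    def test_any_cpg_mode(self):
        sites = [_site(100, 0.1, 0.8), _site(150, 0.1, 0.15)]
        regions = [GenomicInterval("chr1", 50, 200, ".", "r0")]
        rms = aggregate_region_dm(sites, regions)
        assert select_hypermethylated(rms, 0.5) == []  # mean is 0.375
        out = select_hypermethylated(rms, 0.5, mode="any", sites=sites, regions=regions)
        assert [r.region_id for r in out] == ["r0"]


class TestClassContrast:
    def test_identical_distributions(self):
        a = [RegionMethylation(f"a{i}", 3, v) for i, v in enumerate([0.1, 0.2, 0.3])]
        b = [RegionMethylation(f"b{i}", 3, v) for i, v in enumerate([0.3, 0.1, 0.2])]
        res, med_a, med_b = class_dm_contrast(a, b)
        assert res.p_two_sided == 1.0 and med_a == med_b

    def test_fully_separated_exact_p(self):
        import math

        a = [RegionMethylation(f"a{i}", 3, 0.6) for i in range(5)]
        b = [RegionMethylation(f"b{i}", 3, 0.0) for i in range(5)]
        res, _, _ = class_dm_contrast(a, b)
        assert res.p_greater == pytest.approx(1 / math.comb(10, 5))

    def test_power_at_planted_shift(self):
        """Shift of 0.2 dm units at n=100 per class is detected at 0.05 in
        >=95% of 200 seeded replicates."""
        hits = 0
        for seed in range(200):
            r = np.random.default_rng(seed)
            a = [RegionMethylation(f"a{i}", 3, v) for i, v in enumerate(r.normal(0.2, 0.3, 100))]
            b = [RegionMethylation(f"b{i}", 3, v) for i, v in enumerate(r.normal(0.0, 0.3, 100))]
            res, _, _ = class_dm_contrast(a, b)
            hits += res.p_greater < 0.05
        assert hits >= 190


class TestTargetSilencing:
    def _hyper(self):
        return [RegionMethylation("R0", 5, 0.6, hyper=True)]

    def _assign(self, genes, region="R0"):
        return [TargetAssignment(region, g, 3, "chia") for g in genes]

    def test_null_expression(self):
        expr = {f"G{i}": 10.0 for i in range(5)}
        res = target_silencing(self._hyper(), self._assign(expr), expr, expr)
        assert all(f == pytest.approx(1.0) for f in res.fold_changes.values())
        assert res.one_sample.p_less == 1.0

    def test_all_folds_below_one_exact_p(self):
        genes = [f"G{i}" for i in range(12)]
        normal = {g: 10.0 for g in genes}
        tumor = {g: 10.0 / (2 + i) for i, g in enumerate(genes)}
        res = target_silencing(self._hyper(), self._assign(genes), normal, tumor, pseudocount=0)
        assert res.one_sample.p_less == pytest.approx(1 / 2**12)

    def test_no_targets_raises(self):
        with pytest.raises(ValueError):
            target_silencing(self._hyper(), [], {}, {})

    def test_hyper_vs_other_contrast_present(self):
        normal = {"A": 10.0, "B": 10.0}
        tumor = {"A": 2.0, "B": 10.0}
        assigns = self._assign(["A"]) + self._assign(["B"], region="R1")
        res = target_silencing(self._hyper(), assigns, normal, tumor)
        assert res.hyper_vs_other is not None
        assert res.fold_changes.keys() == {"A"}


class TestDmMatrix:
    SITES = [_site(100, 0.1, 0.8), _site(150, 0.1, 0.2), _site(5000, 0.0, 1.0)]
    REGIONS = [GenomicInterval("chr1", 50, 200, ".", "r0")]

    def test_threshold_filters(self):
        df = dm_matrix(self.SITES, self.REGIONS, 0.5)
        assert list(df["position"]) == [100]

    def test_no_cpg_passes_empty_not_error(self):
        df = dm_matrix(self.SITES, self.REGIONS, 0.99)
        assert df.empty

    def test_threshold_zero_keeps_all_in_region(self):
        df = dm_matrix(self.SITES, self.REGIONS, 0)
        assert list(df["position"]) == [100, 150]

    def test_count_matches_filter_scan(self, rng):
        sites = [
            _site(int(p), float(b), float(t))
            for p, b, t in zip(
                rng.choice(20_000, 200, replace=False), rng.random(200), rng.random(200)
            )
        ]
        regions = [
            GenomicInterval("chr1", int(s := rng.integers(0, 20_000)), int(s + 800), ".", f"r{i}")
            for i, _ in enumerate(range(20))
        ]
        df = dm_matrix(sites, regions, 0.3)
        expected = sum(
            1
            for r in regions
            for s in sites
            if r.start <= s.position.start < r.end and abs(s.dm) > 0.3
        )
        assert len(df) == expected
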