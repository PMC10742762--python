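"""Hypergeometric enrichment, BH-FDR, rank tests and permutation overlap."""

import math

import numpy as np
import pytest

from g4snv.io_formats import GenomicInterval
from g4snv.stats_enrichment import (
    bh_fdr,
    dunn_posthoc,
    geneset_enrichment,
    hypergeom_upper,
    interval_enrichment,
    kruskal_wallis,
    read_gene_sets,
    stability_crosstab,
    titv,
    titv_chisq,
)


class TestHypergeomUpper:
    def test_k_zero_is_one(self):
        assert hypergeom_upper(0, 5, 4, 10) == 1.0

    def test_exact_small_case(self):
        # C(5,4) C(5,0) / C(10,4) = 5/210
        assert hypergeom_upper(4, 5, 4, 10) == pytest.approx(5 / 210, abs=1e-14)

    def test_degenerate_universe(self):
        assert hypergeom_upper(4, 10, 4, 10) == pytest.approx(1.0)

    def test_bounds_violation_errors(self):
        with pytest.raises(ValueError):
            hypergeom_upper(5, 4, 4, 10)
        with pytest.raises(ValueError):
            hypergeom_upper(1, 11, 4, 10)


class TestBhFdr:
    def test_step_up_arithmetic(self):
        out = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_single_and_identical_unchanged(self):
        assert bh_fdr([0.2]) == pytest.approx([0.2])
        assert np.allclose(bh_fdr([0.5, 0.5, 0.5]), [0.5, 0.5, 0.5])

    def test_permutation_equivariance(self):
        p = np.array([0.001, 0.2, 0.04, 0.9, 0.04])
        perm = np.array([3, 0, 4, 1, 2])
        assert np.allclose(bh_fdr(p)[perm], bh_fdr(p[perm]))

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


class TestKruskalWallis:
    def test_identical_groups_h_zero(self):
        h, df, p = kruskal_wallis([[1, 2, 3], [1, 2, 3]])
        assert h == pytest.approx(0.0, abs=1e-12)
        assert df == 1

    def test_matches_direct_rank_formula(self):
        groups = [[1, 2, 3], [10, 11, 12]]
        # no ties: H = 12/(N(N+1)) * sum n_i (Rbar_i - (N+1)/2)^2
        n = 6
        rbar = [2.0, 5.0]
        expected = 12 / (n * (n + 1)) * sum(3 * (r - 3.5) ** 2 for r in rbar)
        h, df, _ = kruskal_wallis(groups)
        assert h == pytest.approx(expected)
        assert df == 1

    def test_monotone_invariance(self):
        rng = np.random.default_rng(3)
        groups = [rng.normal(size=20), rng.normal(1, 1, size=15), rng.normal(2, 1, 25)]
        h0, _, _ = kruskal_wallis(groups)
        for transform in (np.exp, np.cbrt, lambda x: 3 * x + 7):
            h1, _, _ = kruskal_wallis([transform(g) for g in groups])
            assert h1 == pytest.approx(h0, rel=1e-12)

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2], []])


class TestDunnPosthoc:
    def test_identical_groups_not_significant(self):
        df = dunn_posthoc([[1, 2, 3, 4], [1, 2, 3, 4]])
        assert abs(df["z"].iloc[0]) < 1e-12
        assert df["p"].iloc[0] == pytest.approx(1.0)

    def test_pair_count(self):
        groups = [[1, 2], [3, 4], [5, 6], [7, 8]]
        assert len(dunn_posthoc(groups)) == math.comb(4, 2)

    def test_shifted_group_pattern(self):
        a = list(range(30))
        b = list(range(30))
        c = [x + 100 for x in range(30)]
        df = dunn_posthoc([a, b, c], labels=["a", "b", "c"])
        rows = {(r.group_a, r.group_b): r for r in df.itertuples()}
        assert rows[("a", "b")].fdr > 0.9
        assert rows[("a", "c")].fdr < 0.001
        assert rows[("b", "c")].fdr < 0.001


class TestTiTv:
    def test_ratio(self):
        effects = [{"is_transition": True}] * 102 + [{"is_transition": False}] * 100
        ratio, ts, tv = titv(effects)
        assert (round(ratio, 2), ts, tv) == (1.02, 102, 100)

    def test_no_transversions_missing(self):
        ratio, ts, tv = titv([{"is_transition": True}] * 5)
        assert ratio is None and (ts, tv) == (5, 0)

    def test_empty(self):
        assert titv([]) == (None, 0, 0)


class TestTiTvChisq:
    def test_no_association(self):
        chi2, p = titv_chisq(50, 50, 50, 50)
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_strong_association(self):
        chi2, _ = titv_chisq(90, 10, 10, 90)
        assert chi2 == pytest.approx(128.0)

    def test_negative_count_errors(self):
        with pytest.raises(ValueError):
            titv_chisq(-1, 10, 10, 10)

    def test_zero_margin_errors(self):
        with pytest.raises(ValueError):
            titv_chisq(0, 0, 10, 10)


class TestIntervalEnrichment:
    lengths = {"chr1": 10_000}

    def test_identical_sets_minimal_p(self):
        regions = [GenomicInterval("chr1", i * 100, i * 100 + 50) for i in range(20)]
        observed, _, p = interval_enrichment(regions, regions, self.lengths, 999, seed=1)
        assert observed == 20
        assert p == pytest.approx(1 / 1000)

    def test_empty_features(self):
        regions = [GenomicInterval("chr1", 0, 50)]
        observed, _, p = interval_enrichment(regions, [], self.lengths, 99, seed=1)
        assert observed == 0 and p == 1.0

    def test_tiling_features_saturate(self):
        regions = [GenomicInterval("chr1", i * 100, i * 100 + 50) for i in range(10)]
        features = [GenomicInterval("chr1", 0, 10_000)]
        observed, expected, p = interval_enrichment(regions, features, self.lengths, 99, seed=1)
        assert observed == 10 and expected == 10.0 and p == 1.0

    def test_region_longer_than_chromosome_errors(self):
        with pytest.raises(ValueError):
            interval_enrichment(
                [GenomicInterval("chr1", 0, 20_000)], [], self.lengths, 9, seed=1
            )

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(0)
        regions = [GenomicInterval("chr1", int(s), int(s) + 30) for s in rng.integers(0, 9000, 25)]
        features = [GenomicInterval("chr1", int(s), int(s) + 200) for s in rng.integers(0, 9000, 15)]
        r1 = interval_enrichment(regions, features, self.lengths, 199, seed=42)
        r2 = interval_enrichment(regions, features, self.lengths, 199, seed=42)
        assert r1 == r2


class TestStabilityCrosstab:
    @staticmethod
    def _effects(counts):
        order = [
            (True, "further_stabilized"), (True, "destabilized"), (True, "no_change"),
            (False, "further_stabilized"), (False, "destabilized"), (False, "no_change"),
        ]
        out = []
        for (flag, stab), n in zip(order, counts):
            out.extend({"is_transition": flag, "stability_class": stab} for _ in range(n))
        return out

    def test_percentages(self):
        df = stability_crosstab(self._effects([10, 20, 30, 40, 50, 60]))
        assert df["count"].tolist() == [10, 20, 30, 40, 50, 60]
        assert df["percentage"].tolist() == pytest.approx(
            [4.761905, 9.523810, 14.285714, 19.047619, 23.809524, 28.571429], abs=1e-4
        )
        assert df["percentage"].sum() == pytest.approx(100.0)

    def test_empty_gives_six_zero_rows(self):
        df = stability_crosstab([])
        assert len(df) == 6 and (df["count"] == 0).all()

    def test_single_class_is_100(self):
        df = stability_crosstab(self._effects([0, 7, 0, 0, 0, 0]))
        assert df.loc[df["count"] > 0, "percentage"].iloc[0] == 100.0


class TestGenesetEnrichment:
    def test_matches_hypergeometric(self):
        universe = [f"g{i}" for i in range(10)]
        terms = {"termA": {"g0", "g1"}, "termB": {"g5", "g6", "g7"}}
        df = geneset_enrichment(["g0", "g1", "g2"], terms, universe)
        row = df[df["term"] == "termA"].iloc[0]
        assert row["k"] == 2 and row["K"] == 2 and row["n"] == 3 and row["N"] == 10
        assert row["p"] == pytest.approx(hypergeom_upper(2, 2, 3, 10))
        assert df["p"].is_monotonic_increasing

    def test_gene_set_readers(self, tmp_path):
        tsv = tmp_path / "sets.tsv"
        tsv.write_text("termA\tg1\ntermA\tg2\ntermB\tg3\n")
        gmt = tmp_path / "sets.gmt"
        gmt.write_text("termA\tdesc\tg1\tg2\ntermB\tdesc\tg3\n")
        assert read_gene_sets(str(tsv)) == read_gene_sets(str(gmt))
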