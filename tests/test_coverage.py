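"""Coverage accumulation, position categories, background subtraction."""

import numpy as np
import pandas as pd
import pytest

import depthgauge as dg
from depthgauge.coverage import (
    CAT_AS, CAT_IGR, CAT_NCRNA, CAT_ORF, CAT_RRNA, CoverageTrack,
)
from depthgauge.model import AnnotationSet, Feature, fragments_frame

from conftest import brute_force_coverage, random_fragments


def frame(*rows):
    return fragments_frame(rows)


class TestComputeCoverage:
    def test_single_fragment(self):
        frags = frame(("chr", 10, 20, "+", "f1", "pair"))
        t = dg.compute_coverage(frags, 100)
        assert t.plus[10:20].tolist() == [1] * 10
        assert t.plus.sum() == 10 and t.minus.sum() == 0
        assert t.csum == 10

    def test_additivity(self):
        frags = frame(("chr", 10, 20, "-", "f1", "pair"),
                      ("chr", 10, 20, "-", "f2", "pair"))
        t = dg.compute_coverage(frags, 100)
        assert (t.minus[10:20] == 2).all()

    def test_out_of_bounds_names_fragment(self):
        frags = frame(("chr", 90, 120, "+", "runaway", "pair"))
        with pytest.raises(ValueError, match="runaway"):
            dg.compute_coverage(frags, 100)

    def test_matches_brute_force_recount(self):
        rng = np.random.default_rng(42)
        frags = random_fragments(rng, 5_000, 2_000, max_len=300)
        t = dg.compute_coverage(frags, 5_000)
        plus, minus = brute_force_coverage(frags, 5_000)
        assert np.array_equal(t.plus, plus)
        assert np.array_equal(t.minus, minus)
        assert t.csum == int((frags["end"] - frags["start"]).sum())


class TestCategorizePositions:
    def test_empty_annotation_all_igr(self):
        ann = AnnotationSet("chr", 100, [])
        cats = dg.categorize_positions(ann)
        assert (cats.plus == CAT_IGR).all() and (cats.minus == CAT_IGR).all()

    def test_single_orf_sense_as_igr_partition(self):
        ann = AnnotationSet("chr", 100, [Feature("o1", "ORF", 10, 20, "+")])
        cats = dg.categorize_positions(ann)
        assert (cats.plus[10:20] == CAT_ORF).all()
        assert (cats.minus[10:20] == CAT_AS).all()
        sizes = cats.sizes()
        assert sizes == {"IGR": 180, "ORF": 10, "ncRNA": 0, "rRNA": 0,
                         "AS": 10, "Total": 200}

    def test_opposite_strand_overlap_has_no_antisense(self):
        ann = AnnotationSet("chr", 100, [Feature("o1", "ORF", 10, 30, "+"),
                                         Feature("o2", "ORF", 20, 40, "-")])
        cats = dg.categorize_positions(ann)
        # Shared interval [20,30): a gene on each strand, so ORF both, AS none.
        assert (cats.plus[20:30] == CAT_ORF).all()
        assert (cats.minus[20:30] == CAT_ORF).all()
        assert (cats.plus[30:40] == CAT_AS).all()
        assert (cats.minus[10:20] == CAT_AS).all()

    def test_sense_precedence_rrna_over_ncrna_over_orf(self):
        ann = AnnotationSet("chr", 100, [Feature("o", "ORF", 0, 60, "+"),
                                         Feature("n", "ncRNA", 10, 40, "+"),
                                         Feature("r", "rRNA", 20, 30, "+")])
        cats = dg.categorize_positions(ann)
        assert (cats.plus[0:10] == CAT_ORF).all()
        assert (cats.plus[10:20] == CAT_NCRNA).all()
        assert (cats.plus[20:30] == CAT_RRNA).all()
        assert (cats.plus[30:40] == CAT_NCRNA).all()
        assert (cats.plus[40:60] == CAT_ORF).all()


def uniform_track(length, c_plus, c_minus):
    return CoverageTrack(np.full(length, c_plus, dtype=np.int64),
                         np.full(length, c_minus, dtype=np.int64))


class TestSubtractBackground:
    def test_zero_pct_is_identity(self, sim, genome):
        t = dg.compute_coverage(sim.fragments, genome.length)
        bm = dg.subtract_background(t, 0.0, seed=1)
        assert bm.cbkg == 0.0
        assert np.array_equal(bm.ceff.plus, t.plus)
        assert np.array_equal(bm.ceff.minus, t.minus)

    def test_floor_branch(self):
        # C=5 everywhere; Csum=10L so pct=40 gives Cbkg exactly 2.0 -> Ceff=3.
        t = uniform_track(1_000, 5, 5)
        bm = dg.subtract_background(t, 40.0, seed=1)
        assert bm.cbkg == pytest.approx(2.0)
        assert (bm.ceff.plus == 3).all() and (bm.ceff.minus == 3).all()

    def test_bernoulli_branch_expectation(self):
        # C=2 everywhere; Csum=4L so pct=62.5 gives Cbkg=1.25, d=0.75.
        L = 50_000
        t = uniform_track(L, 2, 2)
        bm = dg.subtract_background(t, 62.5, seed=5)
        assert bm.cbkg == pytest.approx(1.25)
        vals = np.concatenate([bm.ceff.plus, bm.ceff.minus])
        assert set(np.unique(vals)) <= {0, 1}
        sigma = np.sqrt(0.75 * 0.25 / (2 * L))
        assert abs(vals.mean() - 0.75) <= 3 * sigma

    def test_wipeout_branch(self):
        # C=1 everywhere; Csum=2L so pct=100 gives Cbkg=1.0, d=0 -> Ceff=0.
        t = uniform_track(100, 1, 1)
        bm = dg.subtract_background(t, 100.0, seed=1)
        assert bm.cbkg == pytest.approx(1.0)
        assert bm.ceff.plus.sum() == 0 and bm.ceff.minus.sum() == 0

    def test_negative_pct_rejected(self):
        with pytest.raises(ValueError, match="pct_bkg"):
            dg.subtract_background(uniform_track(10, 1, 1), -1.0)

    def test_literal_formula_mode(self):
        t = uniform_track(1_000, 3, 3)
        bm = dg.subtract_background(t, 0.2, literal_formula=True)
        assert bm.cbkg == pytest.approx(t.csum * 0.2 / 1000.0)

    def test_ceff_never_exceeds_c(self, sim, genome):
        t = dg.compute_coverage(sim.fragments, genome.length)
        bm = dg.subtract_background(t, 1.0, seed=2)
        assert (bm.ceff.plus <= t.plus).all() and (bm.ceff.minus <= t.minus).all()

    def test_seed_reproducibility(self):
        t = uniform_track(10_000, 2, 2)
        a = dg.subtract_background(t, 62.5, seed=9)
        b = dg.subtract_background(t, 62.5, seed=9)
        assert np.array_equal(a.ceff.plus, b.ceff.plus)
        assert np.array_equal(a.ceff.minus, b.ceff.minus)

    def test_total_expectation_over_seeds(self):
        # E[sum Ceff] = sum over positions of the piecewise expectation.
        rng = np.random.default_rng(0)
        plus = rng.integers(0, 4, 2_000).astype(np.int64)
        minus = rng.integers(0, 4, 2_000).astype(np.int64)
        t = CoverageTrack(plus, minus)
        pct = 30.0
        cbkg = t.csum * (pct / 100) / (2 * t.genome_length)
        d = np.concatenate([plus, minus]) - cbkg
        expect = np.where(d >= 1, np.floor(d), np.where(d > 0, d, 0.0)).sum()
        var = (np.where((d > 0) & (d < 1), d * (1 - d), 0.0)).sum()
        totals = [
            dg.subtract_background(t, pct, seed=s).ceff.plus.sum()
            + dg.subtract_background(t, pct, seed=s).ceff.minus.sum()
            for s in range(100)
        ]
        sigma = np.sqrt(var / 100)
        assert abs(np.mean(totals) - expect) <= 3 * sigma


class TestCoverageSummary:
    def test_all_zero_track(self, genome):
        cats = dg.categorize_positions(genome)
        t = uniform_track(genome.length, 0, 0)
        s = dg.coverage_summary(t, cats, [1, 5])
        assert (s["fraction"].dropna() == 0).all()

    def test_uniform_one(self, genome):
        cats = dg.categorize_positions(genome)
        t = uniform_track(genome.length, 1, 1)
        s = dg.coverage_summary(t, cats, [1, 2])
        assert (s.loc[s["threshold"] == 1, "fraction"] == 1.0).all()
        assert (s.loc[s["threshold"] == 2, "fraction"] == 0.0).all()

    def test_empty_category_reports_nan(self):
        ann = AnnotationSet("chr", 100, [Feature("o1", "ORF", 10, 20, "+")])
        cats = dg.categorize_positions(ann)
        s = dg.coverage_summary(uniform_track(100, 1, 1), cats, [1])
        assert np.isnan(s.set_index("category").loc["rRNA", "fraction"])

    def test_matches_brute_force(self):
        rng = np.random.default_rng(3)
        ann = dg.generate_genome(8_000, n_orfs=4, n_ncrnas=2, rrna_operons=0, seed=3)
        frags = random_fragments(rng, 8_000, 500, max_len=200)
        t = dg.compute_coverage(frags, 8_000)
        cats = dg.categorize_positions(ann)
        s = dg.coverage_summary(t, cats, [1, 3])
        cov = {"+": t.plus, "-": t.minus}
        cmap = {"+": cats.plus, "-": cats.minus}
        from depthgauge.coverage import CATEGORY_NAMES
        for _, row in s.iterrows():
            n_hit = n_tot = 0
            for strand in "+-":
                for pos in range(8_000):
                    name = CATEGORY_NAMES[cmap[strand][pos]]
                    if row["category"] == "Total" or name == row["category"]:
                        n_tot += 1
                        if cov[strand][pos] >= row["threshold"]:
                            n_hit += 1
            if n_tot == 0:
                assert np.isnan(row["fraction"])
            else:
                assert row["fraction"] == pytest.approx(n_hit / n_tot, rel=1e-9)

    def test_threshold_below_one_rejected(self, genome):
        cats = dg.categorize_positions(genome)
        with pytest.raises(ValueError):
            dg.coverage_summary(uniform_track(genome.length, 1, 1), cats, [0])


class TestSubtractionMonotonicity:
    def test_fractions_decrease_with_subtraction_level(self, sim, genome):
        t = dg.compute_coverage(sim.fragments, genome.length)
        cats = dg.categorize_positions(genome)
        raw = dg.coverage_summary(t, cats, [1]).set_index("category")["fraction"]
        half = dg.coverage_summary(
            dg.subtract_background(t, 0.5, seed=1), cats, [1]
        ).set_index("category")["fraction"]
        one = dg.coverage_summary(
            dg.subtract_background(t, 1.0, seed=1), cats, [1]
        ).set_index("category")["fraction"]
        for cat in raw.index:
            if np.isnan(raw[cat]):
                continue
            assert one[cat] <= half[cat] + 1e-12
            assert half[cat] <= raw[cat] + 1e-12

    def test_nested_subset_coverage_monotone(self, sim, genome):
        cats = dg.categorize_positions(genome)
        small = sim.fragments.head(5_000)
        t_small = dg.compute_coverage(small, genome.length)
        t_full = dg.compute_coverage(sim.fragments, genome.length)
        s_small = dg.coverage_summary(t_small, cats, [1, 5]).set_index(
            ["category", "threshold"])["fraction"]
        s_full = dg.coverage_summary(t_full, cats, [1, 5]).set_index(
            ["category", "threshold"])["fraction"]
        mask = ~s_small.isna()
        assert (s_full[mask] >= s_small[mask]).all()
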