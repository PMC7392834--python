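"""HK scans, permutation thresholds, peaks, support intervals and effects."""

import numpy as np
import pandas as pd
import pytest

from aileqtl.datatypes import CovariateTable, GeneticMap, GenotypeMatrix
from aileqtl.linkage import genotype_probs
from aileqtl.scan import (
    LodCurve,
    ThresholdSet,
    _permutation_maxima,
    call_peaks,
    cis_window,
    estimate_effects,
    hk_scan,
    lod_interval,
    peak_prob_triples,
    permutation_thresholds,
    scan_all,
)


class TestHkScan:
    def test_single_marker_equals_direct_regression(self, single_marker_setup, rng):
        g, gmap, gm, cov, grid = single_marker_setup
        n = len(g)
        y = rng.normal(size=n) + 0.8 * (g == "WW")
        curve = hk_scan(y, grid, cov)
        X = np.column_stack([np.ones(n), (g == "WW").astype(float) - (g == "RR"),
                             (g == "RW").astype(float)])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        rss1 = float(((y - X @ beta) ** 2).sum())
        rss0 = float(((y - y.mean()) ** 2).sum())
        expected = n / 2 * np.log10(rss0 / rss1)
        assert curve.lod_additive[0] == pytest.approx(expected, abs=1e-8)

    def test_constant_phenotype_gives_zero_lod(self, single_marker_setup):
        g, gmap, gm, cov, grid = single_marker_setup
        curve = hk_scan(np.ones(len(g)), grid, cov)
        assert np.all(curve.lod_additive == 0)
        assert np.all(curve.lod_interactive == 0)

    def test_interactive_dominates_additive(self, small_cross, small_grid):
        cross, _ = small_cross
        Y = cross.expression.values.to_numpy(float)
        res = scan_all(Y, cross.expression.probesets, small_grid, cross.covariates)
        assert np.all(res.lod_int >= res.lod_add - 1e-8)

    def test_casewise_deletion_counts(self, small_cross, small_grid):
        cross, _ = small_cross
        Y = cross.expression.values.to_numpy(float).copy()
        Y[0, :2] = np.nan
        res = scan_all(Y, cross.expression.probesets, small_grid, cross.covariates)
        assert res.n_used[0] == cross.n_individuals - 2
        assert res.n_used[1] == cross.n_individuals


class TestThresholds:
    def test_constant_expression_gives_zero_thresholds(self, small_cross, small_grid):
        cross, _ = small_cross
        Y = np.ones((5, cross.n_individuals))
        ts = permutation_thresholds(Y, [f"p{i}" for i in range(5)], small_grid,
                                    cross.covariates, n_perm=20, n_probesets=5,
                                    iterations=1, seed=1)
        assert ts.trans_suggestive == (0.0, 0.0)
        assert ts.trans_significant == (0.0, 0.0)

    def test_ordering_invariants(self, small_cross, small_grid):
        cross, _ = small_cross
        Y = cross.expression.values.to_numpy(float)[:20]
        ts = permutation_thresholds(Y, cross.expression.probesets[:20], small_grid,
                                    cross.covariates, n_perm=60, n_probesets=20,
                                    iterations=2, seed=3)
        for tier in ("suggestive", "significant"):
            pair = getattr(ts, f"trans_{tier}")
            assert pair[1] >= pair[0]          # sex model has more df
        assert ts.trans_significant[0] >= ts.trans_suggestive[0]
        assert ts.trans_significant[1] >= ts.trans_suggestive[1]

    def test_bit_reproducible_under_seed(self, small_cross, small_grid):
        cross, _ = small_cross
        Y = cross.expression.values.to_numpy(float)[:10]
        kw = dict(n_perm=30, n_probesets=10, iterations=1, seed=7)
        a = permutation_thresholds(Y, cross.expression.probesets[:10], small_grid,
                                   cross.covariates, **kw)
        b = permutation_thresholds(Y, cross.expression.probesets[:10], small_grid,
                                   cross.covariates, **kw)
        assert a.trans_suggestive == b.trans_suggestive
        assert a.trans_significant == b.trans_significant

    def test_cis_window_maxima_never_exceed_genomewide(self, small_cross, small_grid):
        cross, _ = small_cross
        Y = cross.expression.values.to_numpy(float)[:8]
        full = np.ones((8, sum(small_grid.chroms[c].positions.size
                               for c in small_grid.chromosomes)), bool)
        half = full.copy()
        half[:, half.shape[1] // 2:] = False
        rng_a, rng_b = np.random.default_rng(9), np.random.default_rng(9)
        ma_full, _ = _permutation_maxima(Y, small_grid, cross.covariates, 10, rng_a)
        ma_half, _ = _permutation_maxima(Y, small_grid, cross.covariates, 10, rng_b,
                                         window_mask=half)
        assert np.all(ma_half <= ma_full + 1e-12)
        # window covering everything reproduces the genome-wide maxima exactly
        rng_c = np.random.default_rng(9)
        ma_all, _ = _permutation_maxima(Y, small_grid, cross.covariates, 10, rng_c,
                                        window_mask=full)
        np.testing.assert_array_equal(ma_all, ma_full)


class TestCisWindow:
    def test_window_extends_to_flanking_markers(self):
        markers = np.arange(0.0, 201.0, 10.0)
        lo, hi = cis_window(100.0, markers, 50.0)
        assert (lo, hi) == (50.0, 150.0)
        lo, hi = cis_window(95.0, markers, 50.0)
        assert (lo, hi) == (40.0, 150.0)  # nearest marker at least 50 away

    def test_clamped_at_chromosome_ends(self):
        markers = np.arange(0.0, 101.0, 10.0)
        lo, hi = cis_window(10.0, markers, 50.0)
        assert lo == 0.0 and hi == 60.0
        lo, hi = cis_window(95.0, markers, 50.0)
        assert lo == 40.0 and hi == 100.0


def _toy_curve(lods, positions=None, chrom="1"):
    lods = np.asarray(lods, float)
    positions = np.asarray(positions if positions is not None
                           else np.arange(lods.size), float)
    return LodCurve(id="p", chromosomes=[chrom], chrom_slices={chrom: slice(0, lods.size)},
                    positions=positions, lod_additive=lods, lod_interactive=lods,
                    n_used=59)


class TestLodInterval:
    def test_flat_curve_spans_all_markers(self):
        gmap = GeneticMap(pd.DataFrame({"marker": ["a", "b", "c"], "chrom": ["1"] * 3,
                                        "pos_cm": [0.0, 50.0, 100.0]}))
        curve = _toy_curve(np.full(101, 3.0), np.arange(101.0))
        assert lod_interval(curve, "1", 50, gmap) == (0.0, 100.0)

    def test_triangular_curve_expands_to_flanking_markers(self):
        gmap = GeneticMap(pd.DataFrame({"marker": [f"m{k}" for k in range(11)],
                                        "chrom": ["1"] * 11,
                                        "pos_cm": np.arange(0.0, 101.0, 10.0)}))
        pos = np.arange(101.0)
        lods = 5.0 - 0.36 * np.abs(pos - 50.0)   # drops 1.8 within 5 cM
        curve = _toy_curve(np.maximum(lods, 0.0), pos)
        # region >= 3.2 is [45, 55]; outward markers are 40 and 60
        assert lod_interval(curve, "1", 50, gmap) == (40.0, 60.0)

    def test_terminal_peak_clamps_to_chromosome_end(self):
        gmap = GeneticMap(pd.DataFrame({"marker": ["a", "b"], "chrom": ["1"] * 2,
                                        "pos_cm": [0.0, 100.0]}))
        pos = np.arange(101.0)
        curve = _toy_curve(np.maximum(6.0 - 0.1 * pos, 0.0), pos)
        lo, hi = lod_interval(curve, "1", 0, gmap)
        assert lo == 0.0
        assert hi == 100.0  # 1.8-drop point at 18 cM expands out to marker at 100


class TestCallPeaks:
    THR = ThresholdSet(trans_suggestive=(3.0, 4.5), trans_significant=(4.0, 6.0))

    def _gmap(self, chroms=("1", "2")):
        rows = []
        for c in chroms:
            for k, p in enumerate(np.arange(0.0, 101.0, 10.0)):
                rows.append({"marker": f"c{c}m{k}", "chrom": c, "pos_cm": p})
        return GeneticMap(pd.DataFrame(rows))

    def test_flat_zero_curve_yields_nothing(self):
        curve = _toy_curve(np.zeros(101), np.arange(101.0))
        assert call_peaks(curve, self.THR, None, self._gmap(("1",))) == []

    def test_two_chromosomes_two_peaks(self):
        pos = np.concatenate([np.arange(101.0), np.arange(101.0)])
        lods = np.concatenate([
            np.maximum(5.0 - 0.2 * np.abs(np.arange(101.0) - 30), 0.0),
            np.maximum(3.5 - 0.2 * np.abs(np.arange(101.0) - 70), 0.0)])
        curve = LodCurve(id="p", chromosomes=["1", "2"],
                         chrom_slices={"1": slice(0, 101), "2": slice(101, 202)},
                         positions=pos, lod_additive=lods, lod_interactive=lods,
                         n_used=59)
        peaks = call_peaks(curve, self.THR, None, self._gmap())
        assert [(p.chrom, p.peak_cm) for p in peaks] == [("1", 30.0), ("2", 70.0)]
        assert peaks[0].tier == "significant" and peaks[1].tier == "suggestive"

    def test_subthreshold_peak_not_called(self):
        curve = _toy_curve(np.maximum(2.5 - 0.1 * np.abs(np.arange(101.0) - 50), 0),
                           np.arange(101.0))
        assert call_peaks(curve, self.THR, None, self._gmap(("1",))) == []


class TestEffects:
    def test_direction_sign_convention(self, single_marker_setup, rng):
        g, gmap, gm, cov, grid = single_marker_setup
        y = 1.0 * (g == "WW") - 1.0 * (g == "RR") + rng.normal(0, 0.1, size=len(g))
        triples = peak_prob_triples(grid, "1", 0.0)
        eff = estimate_effects(y, triples, cov, lod=5.0)
        assert eff["direction"] == "WL"
        eff2 = estimate_effects(-y, triples, cov, lod=5.0)
        assert eff2["direction"] == "RJF"

    def test_planted_additive_recovered(self, rng):
        n = 400
        ids = [f"i{k}" for k in range(n)]
        g = rng.choice(["RR", "RW", "WW"], p=[0.25, 0.5, 0.25], size=n)
        gmap = GeneticMap(pd.DataFrame({"marker": ["m1"], "chrom": ["1"], "pos_cm": [0.0]}))
        gm = GenotypeMatrix(pd.DataFrame(g[:, None], index=ids, columns=["m1"]))
        cov = CovariateTable(pd.DataFrame({"sex": ["F"] * n, "batch": ["b1"] * n}, index=ids))
        grid = genotype_probs(gm, gmap, step_cm=0, error_prob=0.0)
        a_true = 0.5
        x = (g == "WW").astype(float) - (g == "RR")
        y = a_true * x + rng.normal(size=n)
        eff = estimate_effects(y, peak_prob_triples(grid, "1", 0.0), cov, lod=5.0)
        se = 1.0 / np.sqrt((x ** 2).sum())
        assert abs(eff["additive"] - a_true) < 2 * se * 2  # generous 2x(2 SE)

    def test_pct_var_zero_at_lod_zero_and_monotone(self, single_marker_setup, rng):
        g, gmap, gm, cov, grid = single_marker_setup
        y = rng.normal(size=len(g))
        triples = peak_prob_triples(grid, "1", 0.0)
        vals = [estimate_effects(y, triples, cov, lod=l)["pct_var"]
                for l in (0.0, 1.0, 3.0, 7.0)]
        assert vals[0] == 0.0
        assert np.all(np.diff(vals) > 0)
        assert 0 <= vals[-1] <= 100
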