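import numpy as np
import pandas as pd
import pytest

import regulon2t as r2t
from regulon2t.dataio import PeakSet, TssAnnotation


def make_annotation(rows, lengths=None):
    return TssAnnotation(
        table=pd.DataFrame(rows, columns=["gene_id", "chrom", "strand",
                                          "tss"]),
        chrom_lengths=lengths)


def make_peaks(rows):
    return PeakSet(intervals=pd.DataFrame(rows,
                                          columns=["chrom", "start", "end"]))


def brute_force_distance(annotation, peaks, window):
    """All-pairs scan oracle for the signed strand-aware distance."""
    out = {}
    iv = peaks.intervals
    for _, g in annotation.table.iterrows():
        best = None
        for _, p in iv[iv["chrom"] == g["chrom"]].iterrows():
            if p["start"] <= g["tss"] < p["end"]:
                best = 0
                break
            if g["tss"] < p["start"]:
                d = p["start"] - g["tss"]
            else:
                d = (p["end"] - 1) - g["tss"]
            if best is None or abs(d) < abs(best):
                best = d
        if best is None or abs(best) > window:
            out[g["gene_id"]] = np.nan
        else:
            out[g["gene_id"]] = best if g["strand"] == "+" else -best
    return out


class TestNearestPeakDistance:
    def test_plus_strand_downstream_positive(self):
        ann = make_annotation([("g1", "chr1", "+", 1000)])
        peaks = make_peaks([("chr1", 1200, 1300)])
        dist = r2t.nearest_peak_distance(ann, peaks, window=10_000)
        assert dist["g1"] == 200

    def test_minus_strand_flips_sign(self):
        ann = make_annotation([("g1", "chr1", "-", 1000)])
        peaks = make_peaks([("chr1", 1200, 1300)])
        dist = r2t.nearest_peak_distance(ann, peaks, window=10_000)
        assert dist["g1"] == -200

    def test_tss_inside_peak_zero(self):
        ann = make_annotation([("g1", "chr1", "+", 1050)])
        peaks = make_peaks([("chr1", 1000, 1100)])
        assert r2t.nearest_peak_distance(ann, peaks, 1000)["g1"] == 0

    def test_outside_window_is_nan(self):
        ann = make_annotation([("g1", "chr1", "+", 1000)])
        peaks = make_peaks([("chr1", 50_000, 50_100)])
        assert np.isnan(r2t.nearest_peak_distance(ann, peaks, 10_000)["g1"])

    def test_matches_brute_force_random_layouts(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            n_genes, n_peaks = 40, 30
            ann = make_annotation([
                (f"g{i}", f"chr{rng.integers(1, 3)}",
                 "+" if rng.random() < 0.5 else "-",
                 int(rng.integers(0, 100_000)))
                for i in range(n_genes)])
            starts = rng.integers(0, 100_000, n_peaks)
            peaks = make_peaks([
                (f"chr{rng.integers(1, 3)}", int(s),
                 int(s + rng.integers(1, 500)))
                for s in starts])
            got = r2t.nearest_peak_distance(ann, peaks, window=30_000)
            want = brute_force_distance(ann, peaks, 30_000)
            for g in ann.gene_ids:
                if np.isnan(want[g]):
                    assert np.isnan(got[g])
                else:
                    assert got[g] == want[g]

    def test_translation_invariance(self):
        rng = np.random.default_rng(1)
        ann_rows = [(f"g{i}", "chr1", "+", int(rng.integers(0, 50_000)))
                    for i in range(20)]
        peak_rows = [("chr1", int(s), int(s) + 100)
                     for s in rng.integers(0, 50_000, 15)]
        shift = 7919
        d0 = r2t.nearest_peak_distance(make_annotation(ann_rows),
                                       make_peaks(peak_rows), 20_000)
        d1 = r2t.nearest_peak_distance(
            make_annotation([(g, c, s, t + shift)
                             for g, c, s, t in ann_rows]),
            make_peaks([(c, a + shift, b + shift)
                        for c, a, b in peak_rows]), 20_000)
        pd.testing.assert_series_equal(d0, d1)

    def test_invalid_window_rejected(self):
        ann = make_annotation([("g1", "chr1", "+", 100)])
        with pytest.raises(ValueError):
            r2t.nearest_peak_distance(ann, make_peaks([("chr1", 0, 10)]), 0)


class TestBindingDensity:
    def test_point_mass_at_zero(self):
        dist = pd.Series(np.zeros(20))
        prof = r2t.binding_density(dist, window=10_000, bandwidth=500)
        assert prof.grid[np.argmax(prof.density)] == pytest.approx(
            0.0, abs=prof.grid[1] - prof.grid[0])
        assert prof.integral == pytest.approx(1.0, abs=1e-6)

    def test_half_missing_integral_half(self):
        vals = np.concatenate([np.zeros(10), np.full(10, np.nan)])
        prof = r2t.binding_density(pd.Series(vals), window=10_000,
                                   bandwidth=500)
        assert prof.integral == pytest.approx(0.5, abs=1e-6)

    def test_matches_fine_histogram(self):
        rng = np.random.default_rng(2)
        d = rng.laplace(0, 5000, 500)
        d = d[np.abs(d) <= 250_000]
        prof = r2t.binding_density(pd.Series(d), window=250_000)
        hist, edges = np.histogram(d, bins=64, range=(-250_000, 250_000),
                                   density=True)
        centers = (edges[:-1] + edges[1:]) / 2
        kde_at = np.interp(centers, prof.grid, prof.density)
        assert np.abs(kde_at - hist).max() <= 0.1 * prof.density.max()

    def test_grid_is_512_points(self):
        prof = r2t.binding_density(pd.Series([0.0, 100.0, -50.0]), 10_000)
        assert len(prof.grid) == 512
        assert prof.grid[0] == -10_000 and prof.grid[-1] == 10_000

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            r2t.binding_density(pd.Series([np.nan, np.nan]), 10_000)


class TestRegulonPeakEnrichment:
    def test_planted_signal_minimal_p(self):
        ann = r2t.simulate_tss_annotation(1000, seed=3)
        regulon = ann.gene_ids[:100]
        peaks = r2t.simulate_peaks(ann, regulon, offset_scale=5000,
                                   n_background=100, seed=4)
        v = r2t.regulon_peak_enrichment(ann, peaks, regulon, n_null=999,
                                        seed=5)
        assert v.p_empirical == pytest.approx(1 / 1000)
        assert v.observed_fraction == 1.0

    def test_unplanted_regulon_p_centred(self):
        # with no planted signal the observed statistic is exchangeable
        # with the nulls, so p averages ~0.5 over repeated draws
        ann = r2t.simulate_tss_annotation(2000, seed=6)
        peaks = r2t.simulate_peaks(ann, [], n_background=150, seed=7)
        rng = np.random.default_rng(8)
        ps = []
        for _ in range(50):
            regulon = list(rng.choice(ann.gene_ids, size=200,
                                      replace=False))
            v = r2t.regulon_peak_enrichment(ann, peaks, regulon, n_null=99,
                                            seed=int(rng.integers(2 ** 31)))
            ps.append(v.p_empirical)
        assert 0.35 <= np.mean(ps) <= 0.65

    def test_random_positions_null_calibrated(self):
        ann = r2t.simulate_tss_annotation(500, seed=10)
        peaks = r2t.simulate_peaks(ann, [], n_background=120, seed=11)
        rng = np.random.default_rng(12)
        regulon = list(rng.choice(ann.gene_ids, size=80, replace=False))
        v = r2t.regulon_peak_enrichment(ann, peaks, regulon,
                                        null_type="random_positions",
                                        n_null=99, seed=13)
        assert 0.05 <= v.p_empirical <= 1.0

    def test_oversized_regulon_warns(self):
        ann = r2t.simulate_tss_annotation(100, seed=14)
        peaks = r2t.simulate_peaks(ann, [], n_background=50, seed=15)
        with pytest.warns(UserWarning, match="half"):
            r2t.regulon_peak_enrichment(ann, peaks, ann.gene_ids[:60],
                                        n_null=99, seed=16)

    def test_density_integral_matches_fraction(self):
        ann = r2t.simulate_tss_annotation(400, seed=17)
        peaks = r2t.simulate_peaks(ann, ann.gene_ids[:150],
                                   offset_scale=20_000, n_background=40,
                                   seed=18)
        dist = r2t.nearest_peak_distance(ann, peaks, window=100_000)
        prof = r2t.binding_density(dist, window=100_000)
        finite = int(np.isfinite(dist).sum())
        assert prof.integral == pytest.approx(finite / len(dist), abs=1e-6)
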