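"""ROI extraction, normalization, distribution averaging, ROC, and reporting."""

import numpy as np
import pytest
from scipy import stats

import qtimcd as q
from qtimcd.classify import RoiSample, build_report, histogram_edges


def sample_from(values, contrast="MKA", roi_id="r", ltype="cortex"):
    return RoiSample(roi_id, ltype, contrast, np.asarray(values, dtype=float))


def gaussian_dist(mean, sigma, edges, tissue_class, contrast="T1w"):
    """Analytic Gaussian discretized onto bins (bin mass from the CDF)."""
    cdf = stats.norm.cdf(edges, mean, sigma)
    mass = np.diff(cdf)
    density = mass / mass.sum() / np.diff(edges)
    return q.AveragedDistribution(contrast, tissue_class, edges, density, n_rois=1)


class TestExtractNormalize:
    def test_constant_volume(self):
        vol = np.full((3, 3, 1), 4.0)
        s = q.extract_roi(vol, np.ones((3, 3, 1), bool), "r", "cortex", "T1w")
        assert (s.values == 4.0).all() and s.values.size == 9

    def test_single_voxel(self):
        vol = np.arange(8.0).reshape(2, 2, 2)
        mask = np.zeros((2, 2, 2), bool)
        mask[1, 0, 1] = True
        s = q.extract_roi(vol, mask, "r", "WM", "FA")
        assert s.values.tolist() == [5.0]

    def test_grid_mismatch_and_empty(self):
        vol = np.ones((2, 2, 2))
        with pytest.raises(ValueError, match="grid"):
            q.extract_roi(vol, np.ones((3, 2, 2), bool), "r", "WM", "FA")
        with pytest.raises(ValueError, match="empty"):
            q.extract_roi(vol, np.zeros((2, 2, 2), bool), "r", "WM", "FA")

    def test_normalize_by_reference_mean(self):
        s = sample_from([1.0, 3.0], contrast="T1w")
        ref = sample_from([2.0, 2.0], contrast="T1w", roi_id="ref")
        out = q.normalize_intensity(s, ref)
        assert out.values.tolist() == [0.5, 1.5]
        assert out.reference_id == "ref"

    def test_self_normalization_unit_mean(self):
        s = sample_from([2.0, 4.0, 6.0], contrast="FLAIR")
        assert np.isclose(q.normalize_intensity(s, s).values.mean(), 1.0)

    def test_dimensionless_passthrough(self):
        s = sample_from([0.1, 0.9], contrast="FA")
        out = q.normalize_intensity(s, sample_from([5.0], contrast="FA"))
        assert out is s

    def test_nonpositive_reference_rejected(self):
        s = sample_from([1.0], contrast="T1w")
        with pytest.raises(ValueError, match="nonpositive"):
            q.normalize_intensity(s, sample_from([0.0, 0.0], contrast="T1w"))


class TestAverageDistributions:
    def test_single_roi_is_own_histogram(self):
        rng = np.random.default_rng(0)
        s = sample_from(rng.normal(0, 1, 500))
        d = q.average_distributions([s], n_bins=32)
        counts, _ = np.histogram(
            np.clip(s.values, d.bin_edges[0], d.bin_edges[-1]), bins=d.bin_edges
        )
        expected = counts / counts.sum() / np.diff(d.bin_edges)
        assert np.allclose(d.density, expected)

    def test_equal_roi_weight(self):
        """A large and a small ROI with identical value sets average to the
        same distribution as a single ROI."""
        big = sample_from(np.repeat([1.0, 2.0, 3.0], 100))
        small = sample_from([1.0, 2.0, 3.0])
        edges = np.linspace(0.5, 3.5, 7)
        d2 = q.average_distributions([big, small], bin_edges=edges)
        d1 = q.average_distributions([small], bin_edges=edges)
        assert np.allclose(d2.density, d1.density)

    def test_disjoint_uniform_rois_bimodal(self):
        """Two disjoint uniform ROIs average to equal masses on each support."""
        a = sample_from(np.linspace(0.0, 1.0, 200))
        b = sample_from(np.linspace(3.0, 4.0, 50))
        edges = np.linspace(0.0, 4.0, 9)
        d = q.average_distributions([a, b], bin_edges=edges)
        mass = d.bin_masses
        assert abs(mass[:2].sum() - 0.5) < 0.02
        assert abs(mass[-2:].sum() - 0.5) < 0.02
        assert mass[3:5].sum() < 1e-12

    def test_degenerate_range_single_bin(self):
        d = q.average_distributions([sample_from([2.0] * 10)], n_bins=16)
        assert d.degenerate and len(d.density) == 1

    def test_mixed_contrasts_rejected(self):
        with pytest.raises(ValueError, match="contrast"):
            q.average_distributions(
                [sample_from([1.0], contrast="FA"), sample_from([1.0], contrast="MKA")]
            )


class TestRocThreshold:
    def test_fully_separated(self):
        edges = np.linspace(0.0, 2.0, 65)
        ctx = q.average_distributions([sample_from(np.linspace(0.05, 0.4, 100))], bin_edges=edges)
        wm = q.average_distributions([sample_from(np.linspace(1.2, 1.9, 100))], bin_edges=edges)
        r = q.roc_threshold(ctx, wm)
        assert abs(r.auc - 1.0) < 1e-12
        assert 0.4 < r.threshold < 1.2 and r.polarity == "high"

    def test_identical_distributions(self):
        edges = np.linspace(0.0, 1.0, 33)
        s = sample_from(np.linspace(0.1, 0.9, 100))
        d1 = q.average_distributions([s], bin_edges=edges)
        d2 = q.average_distributions([s], bin_edges=edges, tissue_class="WM")
        assert abs(q.roc_threshold(d1, d2).auc - 0.5) < 1e-12

    def test_gaussian_pair_closed_form(self):
        """Two Gaussians (means 0 and 1, sigma 0.5) on 256 bins: AUC within
        0.01 of Phi(1/(sigma*sqrt(2))) and the Youden threshold matches an
        exhaustive search over all bin edges."""
        sigma = 0.5
        edges = np.linspace(-2.0, 3.0, 257)
        ctx = gaussian_dist(0.0, sigma, edges, "cortex")
        wm = gaussian_dist(1.0, sigma, edges, "WM")
        r = q.roc_threshold(ctx, wm)
        assert abs(r.auc - stats.norm.cdf(1.0 / (sigma * np.sqrt(2)))) < 0.01
        # independent exhaustive-threshold oracle
        wm_tail = np.concatenate(([1.0], 1.0 - np.cumsum(wm.bin_masses)))
        ctx_tail = np.concatenate(([1.0], 1.0 - np.cumsum(ctx.bin_masses)))
        j = wm_tail - ctx_tail
        best = edges[np.argmax(j)]
        assert abs(r.threshold - best) <= np.diff(edges)[0] + 1e-12
        assert abs(r.threshold - 0.5) < 0.05  # symmetric crossing point

    def test_auc_equals_pairwise_estimator(self):
        """Trapezoidal AUC agrees with the pairwise-comparison estimator
        P(wm > ctx) + 0.5 P(tie) on the binned data within one bin."""
        rng = np.random.default_rng(4)
        edges = np.linspace(-3, 4, 65)
        ctx = gaussian_dist(0.0, 0.8, edges, "cortex")
        wm = gaussian_dist(1.2, 0.6, edges, "WM")
        r = q.roc_threshold(ctx, wm)
        mw, mc = wm.bin_masses, ctx.bin_masses
        lower = np.tril(np.ones((len(mw), len(mw))), -1)
        pairwise = mw @ (lower @ mc) + 0.5 * mw @ mc
        assert abs(r.auc - pairwise) < 1.0 / 64

    def test_agrees_with_sklearn_on_samples(self):
        """Cross-check against sklearn's ROC AUC on raw voxel samples."""
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(5)
        a = rng.normal(0.0, 0.5, 4000)
        b = rng.normal(1.0, 0.5, 4000)
        edges = np.linspace(-2, 3, 257)
        ctx = q.average_distributions([sample_from(a)], bin_edges=edges)
        wm = q.average_distributions([sample_from(b)], bin_edges=edges, tissue_class="WM")
        r = q.roc_threshold(ctx, wm)
        ref = roc_auc_score(np.r_[np.zeros(4000), np.ones(4000)], np.r_[a, b])
        assert abs(r.auc - ref) < 0.01

    def test_inverted_polarity_resolved(self):
        """When WM is darker (FLAIR-like), polarity flips and AUC stays >= 0.5."""
        edges = np.linspace(0.0, 2.0, 65)
        ctx = gaussian_dist(1.5, 0.1, edges, "cortex", contrast="FLAIR")
        wm = gaussian_dist(0.5, 0.1, edges, "WM", contrast="FLAIR")
        r = q.roc_threshold(ctx, wm)
        assert r.polarity == "low" and r.auc > 0.99

    def test_mismatched_bins_rejected(self):
        e1, e2 = np.linspace(0, 1, 11), np.linspace(0, 1, 12)
        d1 = gaussian_dist(0.5, 0.2, e1, "cortex")
        d2 = gaussian_dist(0.5, 0.2, e2, "WM")
        with pytest.raises(ValueError, match="bin edges"):
            q.roc_threshold(d1, d2)


class TestClassification:
    thr_high = q.ThresholdResult("MKA", threshold=0.5, polarity="high", auc=0.9)

    def test_all_wm_side(self):
        pct, labels = q.classify_wm_percent(sample_from([0.6, 0.7, 2.0]), self.thr_high)
        assert pct == 100.0 and labels.all()

    def test_all_cortex_side(self):
        pct, _ = q.classify_wm_percent(sample_from([0.1, 0.2]), self.thr_high)
        assert pct == 0.0

    def test_tie_is_cortex_like(self):
        pct, labels = q.classify_wm_percent(sample_from([0.5, 0.6]), self.thr_high)
        assert pct == 50.0 and not labels[0]

    def test_low_polarity(self):
        thr = q.ThresholdResult("FLAIR", threshold=1.0, polarity="low", auc=0.8)
        pct, _ = q.classify_wm_percent(sample_from([0.5, 1.5]), thr)
        assert pct == 50.0

    def test_monotone_transform_invariance(self):
        """WM% is invariant under strictly increasing transforms applied
        jointly to the values and the threshold."""
        rng = np.random.default_rng(6)
        vals = rng.uniform(0, 2, 100)
        pct0, _ = q.classify_wm_percent(sample_from(vals), self.thr_high)
        for f in (np.exp, lambda x: 3 * x - 1, lambda x: x**3):
            thr = q.ThresholdResult("MKA", float(f(0.5)), "high", 0.9)
            pct, _ = q.classify_wm_percent(sample_from(f(vals)), thr)
            assert pct == pct0


class TestReport:
    def test_mean_sd_aggregate(self):
        rows = [
            {"lesion_id": "a", "lesion_type": "SH", "n_voxels": 100, "MKA": 10.0},
            {"lesion_id": "b", "lesion_type": "SH", "n_voxels": 200, "MKA": 30.0},
        ]
        df = build_report(rows, contrasts=("MKA",))
        agg = df[df.lesion_id == "M (SD)"].iloc[0]
        assert agg["MKA"] == 20.0
        assert np.isclose(agg["MKA_sd"], np.sqrt(200.0))

    def test_singleton_sd_zero(self):
        rows = [{"lesion_id": "a", "lesion_type": "PMG", "n_voxels": 10, "FA": 42.0}]
        df = build_report(rows, contrasts=("FA",))
        agg = df[df.lesion_id == "M (SD)"].iloc[0]
        assert agg["FA"] == 42.0 and agg["FA_sd"] == 0.0

    def test_aggregates_recomputable(self):
        rng = np.random.default_rng(7)
        rows = [
            {
                "lesion_id": f"l{i}",
                "lesion_type": "SH" if i < 3 else "PH",
                "n_voxels": 50,
                "MKA": float(rng.uniform(0, 100)),
            }
            for i in range(5)
        ]
        df = build_report(rows, contrasts=("MKA",))
        for ltype in ("SH", "PH"):
            lesions = df[(df.lesion_type == ltype) & (df.lesion_id != "M (SD)")]
            agg = df[(df.lesion_type == ltype) & (df.lesion_id == "M (SD)")].iloc[0]
            assert np.isclose(agg["MKA"], lesions["MKA"].mean())

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            build_report([])
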