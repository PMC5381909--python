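"""Local fuzzy thresholding stages and the global rigid baseline."""

import numpy as np
import pytest

from polseg import (DepolarizationMap, LabelMap, MembershipField,
                    SegmentationConfig, aggregate, classify, fit_mixture,
                    global_cutoffs, memberships, preprocess, segment_global,
                    segment_local_fuzzy)
from polseg.segmentation import (LABEL_CORE, LABEL_HEALTHY, LABEL_RIM,
                                 count_isolated_pixels)


def full_map(values: np.ndarray) -> DepolarizationMap:
    values = np.asarray(values, dtype=float)
    return DepolarizationMap(delta=values, mask=np.ones(values.shape, bool))


class TestPreprocess:
    def test_constant_is_fixed_point(self):
        dmap = full_map(np.full((16, 16), 0.9))
        out = preprocess(dmap, smooth_sigma=2.0)
        assert np.allclose(out.values(), 0.9)

    def test_sigma_zero_is_identity(self):
        rng = np.random.default_rng(0)
        dmap = full_map(rng.uniform(0.5, 1.0, (8, 8)))
        out = preprocess(dmap, 0.0)
        assert np.array_equal(out.delta, dmap.delta)

    def test_spike_pulled_toward_neighbors(self):
        vals = np.full((9, 9), 0.8)
        vals[4, 4] = 0.9
        out = preprocess(full_map(vals), 1.0)
        assert 0.8 < out.delta[4, 4] < 0.9

    def test_background_never_bleeds_into_tissue(self):
        """Normalized convolution against a brute-force masked average."""
        rng = np.random.default_rng(1)
        vals = rng.uniform(0.2, 0.9, (9, 9))
        mask = np.zeros((9, 9), bool)
        mask[:, :5] = True  # hard mask edge
        vals_masked = np.where(mask, vals, np.nan)
        dmap = DepolarizationMap(delta=vals_masked, mask=mask)
        out = preprocess(dmap, 1.0)

        # brute force: Gaussian-weighted mean over masked pixels only
        from scipy.ndimage import gaussian_filter
        sigma = 1.0
        coords = np.arange(9)
        for r in range(9):
            for c in range(5):
                rr, cc = np.meshgrid(coords, coords, indexing="ij")
                wgt = np.exp(-((rr - r) ** 2 + (cc - c) ** 2) / (2 * sigma**2))
                wgt[~mask] = 0
                expected = np.sum(wgt * np.where(mask, vals, 0)) / wgt.sum()
                assert out.delta[r, c] == pytest.approx(expected, abs=2e-3)

    def test_empty_mask_rejected(self):
        dmap = DepolarizationMap(delta=np.full((4, 4), np.nan),
                                 mask=np.zeros((4, 4), bool))
        with pytest.raises(ValueError, match="empty"):
            preprocess(dmap, 1.0)


class TestFitMixture:
    def test_three_zone_parameter_recovery(self):
        """EM recovers the ablation-zone mixture from 3000 draws."""
        rng = np.random.default_rng(1)
        x = np.concatenate([
            rng.normal(0.833, 0.035, 1000),
            rng.normal(0.877, 0.014, 1000),
            rng.normal(0.915, 0.013, 1000),
        ])
        model = fit_mixture(x, L=3, seed=1)
        assert np.allclose(model.means, [0.833, 0.877, 0.915], atol=0.01)
        assert np.allclose(model.weights, 1 / 3, atol=0.05)

    def test_well_separated_two_component_recovery(self):
        rng = np.random.default_rng(2)
        x = np.concatenate([rng.normal(0.2, 0.01, 500),
                            rng.normal(0.8, 0.01, 500)])
        model = fit_mixture(x, L=2)
        assert np.allclose(model.means, [0.2, 0.8], atol=0.005)

    def test_agrees_with_reference_em(self):
        """Independent cross-check against scikit-learn's mixture fit."""
        sklearn = pytest.importorskip("sklearn.mixture")
        rng = np.random.default_rng(3)
        x = np.concatenate([rng.normal(0.3, 0.03, 800),
                            rng.normal(0.6, 0.02, 700),
                            rng.normal(0.9, 0.02, 500)])
        ours = fit_mixture(x, L=3)
        ref = sklearn.GaussianMixture(3, n_init=5, random_state=0).fit(x[:, None])
        order = np.argsort(ref.means_.ravel())
        assert np.allclose(ours.means, ref.means_.ravel()[order], atol=0.005)
        assert np.allclose(ours.weights, ref.weights_[order], atol=0.02)

    def test_constant_data_rejected(self):
        with pytest.raises(ValueError, match="not multimodal"):
            fit_mixture(np.full(100, 0.5), L=2)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            fit_mixture(np.linspace(0, 1, 25), L=3)

    def test_log_likelihood_is_finite_and_recorded(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0.5, 0.1, 200)
        model = fit_mixture(x, L=2)
        assert np.isfinite(model.log_likelihood)
        assert model.n_iter >= 1


class TestMemberships:
    def _model(self):
        from polseg import MixtureModel
        return MixtureModel(weights=[1 / 3, 1 / 3, 1 / 3],
                            means=[0.2, 0.5, 0.8],
                            variances=[0.01**2, 0.01**2, 0.01**2])

    def test_value_at_mean_is_crisp(self):
        model = self._model()
        dmap = full_map(np.full((2, 2), 0.5))
        mu = memberships(dmap, model)
        assert np.all(mu.mu[..., 1] > 0.99)

    def test_equidistant_value_splits_evenly(self):
        model = self._model()
        dmap = full_map(np.full((1, 1), 0.35))
        mu = memberships(dmap, model)
        assert mu.mu[0, 0, 0] == pytest.approx(mu.mu[0, 0, 1], abs=1e-9)

    def test_normalization_everywhere(self):
        model = self._model()
        rng = np.random.default_rng(5)
        dmap = full_map(rng.uniform(0, 1, (100, 100)))
        mu = memberships(dmap, model)
        assert np.allclose(mu.mu.sum(axis=-1), 1.0, atol=1e-9)

    def test_extreme_values_fall_back_to_nearest_mean(self):
        # far outside every component: densities underflow, nearest wins
        model = self._model()
        mu = memberships(full_map(np.full((1, 1), 1.0)), model)
        assert mu.mu[0, 0, 2] == pytest.approx(1.0)


class TestAggregate:
    def test_uniform_field_is_fixed_point(self):
        mask = np.ones((8, 8), bool)
        mu = np.tile([0.2, 0.3, 0.5], (8, 8, 1))
        fld = MembershipField(mu=mu, mask=mask)
        out = aggregate(fld, window=3, passes=5)
        assert np.allclose(out.mu, mu)

    def test_isolated_pixel_absorbed(self):
        """A lone (1,0,0) pixel in a (0,0,1) region drops to 1/9 after one
        3x3 pass and classifies with its surroundings."""
        mask = np.ones((7, 7), bool)
        mu = np.zeros((7, 7, 3))
        mu[..., 2] = 1.0
        mu[3, 3] = [1.0, 0.0, 0.0]
        out = aggregate(MembershipField(mu=mu, mask=mask), window=3, passes=1)
        assert out.mu[3, 3, 0] == pytest.approx(1 / 9)
        labels = classify(out)
        assert labels.labels[3, 3] == LABEL_HEALTHY

    def test_renormalized_after_each_pass(self):
        rng = np.random.default_rng(6)
        mask = rng.random((12, 12)) > 0.3
        mask[0, 0] = True
        raw = rng.random((12, 12, 3))
        raw /= raw.sum(-1, keepdims=True)
        raw[~mask] = 0
        out = aggregate(MembershipField(mu=raw, mask=mask), window=3, passes=3)
        assert np.allclose(out.mu[mask].sum(-1), 1.0, atol=1e-9)

    def test_window_larger_than_image_rejected(self):
        fld = MembershipField(mu=np.full((4, 4, 2), 0.5), mask=np.ones((4, 4), bool))
        with pytest.raises(ValueError, match="window"):
            aggregate(fld, window=9, passes=1)

    def test_even_window_rejected(self):
        fld = MembershipField(mu=np.full((4, 4, 2), 0.5), mask=np.ones((4, 4), bool))
        with pytest.raises(ValueError, match="odd"):
            aggregate(fld, window=2, passes=1)


class TestClassify:
    def test_argmax_labeling(self):
        mask = np.ones((1, 3), bool)
        mu = np.array([[[0.1, 0.2, 0.7], [0.5, 0.5, 0.0], [0.2, 0.7, 0.1]]])
        labels = classify(MembershipField(mu=mu, mask=mask))
        assert labels.labels.tolist() == [[LABEL_HEALTHY, LABEL_CORE, LABEL_RIM]]

    def test_background_stays_background(self):
        mask = np.zeros((3, 3), bool)
        labels = classify(MembershipField(mu=np.zeros((3, 3, 3)), mask=mask))
        assert not labels.labels.any()


class TestPosteriorOracle:
    def test_matches_exhaustive_per_pixel_posterior(self):
        """classify(memberships(...)) equals an independent brute-force
        posterior argmax on a small two-class image."""
        from polseg import MixtureModel
        model = MixtureModel(weights=[0.4, 0.6], means=[0.3, 0.7],
                             variances=[0.05**2, 0.1**2])
        rng = np.random.default_rng(7)
        vals = rng.uniform(0, 1, (16, 16))
        labels = classify(memberships(full_map(vals), model))

        def normal_pdf(x, m, v):
            return np.exp(-0.5 * (x - m) ** 2 / v) / np.sqrt(2 * np.pi * v)

        for r in range(16):
            for c in range(16):
                post = [w * normal_pdf(vals[r, c], m, v)
                        for w, m, v in zip(model.weights, model.means,
                                           model.variances)]
                assert labels.labels[r, c] == int(np.argmax(post)) + 1


class TestEndToEnd:
    def test_noiseless_phantom_is_perfectly_recovered(self):
        """Zones at exactly 0.833 / 0.877 / 0.915 with no noise and no
        transition blur segment to 100% agreement with ground truth."""
        from polseg import PhantomSpec, make_delta, make_labels
        spec = PhantomSpec(zone_stats={LABEL_CORE: (0.833, 0.0),
                                       LABEL_RIM: (0.877, 0.0),
                                       LABEL_HEALTHY: (0.915, 0.0)},
                           transition_sigma=0.0)
        gt = make_labels(spec)
        dmap = make_delta(gt, spec)
        cfg = SegmentationConfig(smooth_sigma=0.0, n_aggregation_passes=0)
        labels = segment_local_fuzzy(dmap, cfg)
        assert np.array_equal(labels.labels, gt.labels)

    def test_deterministic(self, default_phantom):
        a = segment_local_fuzzy(default_phantom.delta)
        b = segment_local_fuzzy(default_phantom.delta)
        assert np.array_equal(a.labels, b.labels)

    def test_label_completeness(self, default_phantom, default_fuzzy_labels):
        labels = default_fuzzy_labels
        mask = default_phantom.delta.mask
        assert np.all(np.isin(labels.labels[mask],
                              [LABEL_CORE, LABEL_RIM, LABEL_HEALTHY]))
        assert np.all(labels.labels[~mask] == 0)

    def test_dsc_degrades_as_separation_shrinks(self):
        """Shrinking the inter-zone mean separation never improves DSC."""
        from polseg import PhantomSpec, confusion, generate
        base = {LABEL_CORE: (0.833, 0.035), LABEL_RIM: (0.877, 0.014),
                LABEL_HEALTHY: (0.915, 0.013)}
        dscs = []
        for factor in (1.0, 0.5, 0.25):
            stats = {k: (0.915 - (0.915 - m) * factor, sd)
                     for k, (m, sd) in base.items()}
            ph = generate(PhantomSpec(zone_stats=stats), seed=9)
            labels = segment_local_fuzzy(ph.delta)
            dscs.append(confusion(ph.gt, labels, LABEL_CORE).dsc)
        assert dscs[0] >= dscs[1] - 1e-9 >= dscs[2] - 2e-9

    def test_aggregation_never_increases_isolated_components(self, default_phantom):
        res = segment_local_fuzzy(default_phantom.delta,
                                  return_intermediates=True)
        before = classify(res.memberships_initial)
        after = res.labels
        for cls in (LABEL_CORE, LABEL_RIM, LABEL_HEALTHY):
            assert (count_isolated_pixels(after, cls)
                    <= count_isolated_pixels(before, cls))


class TestGlobalBaseline:
    def test_midpoint_cutoffs_from_roi_means(self):
        vals = np.empty((150, 50))
        vals[0:50] = 0.833
        vals[50:100] = 0.877
        vals[100:150] = 0.915
        dmap = full_map(vals)
        cuts = global_cutoffs(dmap, [(0, 0), (50, 0), (100, 0)])
        assert cuts == (pytest.approx(0.855), pytest.approx(0.896))

    def test_roi_order_invariance(self):
        vals = np.empty((150, 50))
        vals[0:50] = 0.833
        vals[50:100] = 0.877
        vals[100:150] = 0.915
        dmap = full_map(vals)
        a = global_cutoffs(dmap, [(0, 0), (50, 0), (100, 0)])
        b = global_cutoffs(dmap, [(100, 0), (0, 0), (50, 0)])
        assert a == b

    def test_identical_roi_means_rejected(self):
        dmap = full_map(np.full((100, 100), 0.9))
        with pytest.raises(ValueError, match="not separable"):
            global_cutoffs(dmap, [(0, 0), (0, 50), (50, 0)])

    def test_roi_outside_image_rejected(self):
        dmap = full_map(np.full((60, 60), 0.9))
        with pytest.raises(ValueError, match="outside"):
            global_cutoffs(dmap, [(0, 0), (0, 5), (30, 30)])

    def test_interval_assignment(self):
        dmap = full_map(np.array([[0.84, 0.855, 0.88, 0.93]]))
        labels = segment_global(dmap, (0.855, 0.896))
        # exact lower cutoff belongs to rim (half-open intervals)
        assert labels.labels.tolist() == [[LABEL_CORE, LABEL_RIM, LABEL_RIM,
                                           LABEL_HEALTHY]]

    def test_bad_cutoff_order_rejected(self):
        dmap = full_map(np.full((4, 4), 0.9))
        with pytest.raises(ValueError, match="cutoff"):
            segment_global(dmap, (0.9, 0.8))

    def test_global_has_more_isolated_rim_pixels_than_fuzzy(
            self, default_phantom, default_fuzzy_labels):
        """Hard thresholding shows the isolated-pixel artifact; the fuzzy
        method's neighborhood aggregation suppresses it."""
        from polseg import suggest_rois
        ph = default_phantom
        cuts = global_cutoffs(ph.delta, suggest_rois(ph.gt))
        glob = segment_global(ph.delta, cuts)
        n_glob = count_isolated_pixels(glob, LABEL_RIM)
        n_fuzzy = count_isolated_pixels(default_fuzzy_labels, LABEL_RIM)
        assert n_glob > n_fuzzy
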