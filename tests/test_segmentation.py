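"""Constrained mixture EM: oracles, constraints, bias recovery."""

import numpy as np
import pytest

from midas.io import Volume3D
from midas.phantom import LABELS
from midas.priors import CLASS_NAMES, TissuePriorSet, build_prior_set
from midas.segmentation import (
    ConstrainedGaussianMixture,
    EMConfig,
    MixtureModel,
    _estep_numpy,
    _fit_em,
    constrain_means,
    estimate_bias,
    fit_constrained_mixture,
)


def _toy_model(gwm_means, csf_means, cmb_means):
    n = dict(gwm=len(gwm_means), csf=len(csf_means), cmb=len(cmb_means))
    return MixtureModel(
        class_names=("gwm", "csf", "cmb"),
        n_gaussians=n,
        means=dict(
            gwm=np.array(gwm_means, float),
            csf=np.array(csf_means, float),
            cmb=np.array(cmb_means, float),
        ),
        variances={k: np.ones(v) for k, v in n.items()},
        weights={k: np.full(v, 1.0 / v) for k, v in n.items()},
    )


class TestConstrainMeans:
    def test_satisfying_model_unchanged(self):
        m = _toy_model([90, 100, 110], [150, 180], [20, 40])
        out = constrain_means(m)
        np.testing.assert_array_equal(out.means["csf"], [150, 180])
        np.testing.assert_array_equal(out.means["cmb"], [20, 40])

    def test_cmb_mean_clipped_to_half_gwm(self):
        m = _toy_model([100], [150], [80, 30])  # 0.8 * GWM violates
        out = constrain_means(m, eps=1e-3)
        assert out.means["cmb"][0] == pytest.approx(0.5 * 100 * (1 - 1e-3))
        assert out.means["cmb"][1] == 30

    def test_csf_mean_clipped_above_gwm(self):
        m = _toy_model([100], [90, 150], [30])
        out = constrain_means(m, eps=1e-3)
        assert out.means["csf"][0] == pytest.approx(100 * (1 + 1e-3))
        assert out.means["csf"][1] == 150


class TestEMOracles:
    def test_single_gaussian_flat_prior_matches_closed_form(self, rng):
        """EM on a 1-class, 1-Gaussian problem equals the sample moments."""
        y = rng.normal(50.0, 8.0, size=(12, 12, 12)).astype(np.float32)
        prior = np.ones((1,) + y.shape, np.float32)
        brain = np.ones(y.size, bool)
        cfg = EMConfig(bias=False, sampling_step=1, max_iter=50)
        model, _, _, _ = _fit_em(
            y.reshape(-1),
            prior.reshape(1, -1),
            ("all",),
            {"all": 1},
            brain,
            cfg,
            y.shape,
            apply_constraints=False,
        )
        assert model.means["all"][0] == pytest.approx(float(y.mean()), abs=1e-4)
        assert model.variances["all"][0] == pytest.approx(
            float(y.var()), rel=1e-4
        )

    def test_estep_numpy_matches_direct_bayes(self, rng):
        """Responsibilities equal the hand-computed Bayes rule."""
        N, K = 500, 4
        y = rng.normal(10, 3, N).astype(np.float32)
        y2 = y * y
        log_prior = np.log(
            rng.dirichlet(np.ones(2), N).astype(np.float32)
        ).astype(np.float32)  # (n_vox, n_class)
        comp_class = np.array([0, 0, 1, 1])
        mus = np.array([5, 10, 15, 20], np.float32)
        var = np.array([4, 9, 4, 9], np.float32)
        ws = np.array([0.3, 0.7, 0.5, 0.5], np.float32)
        A = (-0.5 / var).astype(np.float32)
        B = (mus / var).astype(np.float32)
        C = (
            np.log(ws) - 0.5 * np.log(2 * np.pi * var) - 0.5 * mus**2 / var
        ).astype(np.float32)
        R = np.empty((N, K), np.float32)
        _estep_numpy(y, y2, log_prior, comp_class, A, B, C, R)
        # oracle: direct normal pdfs
        from scipy.stats import norm

        pdf = np.stack(
            [
                np.exp(log_prior[:, comp_class[c]])
                * ws[c]
                * norm.pdf(y, mus[c], np.sqrt(var[c]))
                for c in range(K)
            ],
            axis=1,
        )
        expected = pdf / pdf.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(R, expected, atol=2e-6)

    def test_numba_kernel_matches_numpy_reference(self, rng):
        from midas.segmentation import _estep_dispatch

        N, K = 4000, 16
        y = rng.normal(100, 25, N).astype(np.float32)
        y2 = y * y
        log_prior = rng.uniform(-8, 0, (N, 6)).astype(np.float32)
        comp_class = np.repeat(np.arange(6), [3, 2, 2, 3, 2, 4])
        mus = np.linspace(5, 180, K).astype(np.float32)
        var = np.full(K, 64, np.float32)
        ws = np.full(K, 1 / K, np.float32)
        A = (-0.5 / var).astype(np.float32)
        B = (mus / var).astype(np.float32)
        C = (np.log(ws) - 0.5 * np.log(2 * np.pi * var) - 0.5 * mus**2 / var).astype(np.float32)
        R1 = np.empty((N, K), np.float32)
        R2 = np.empty((N, K), np.float32)
        out1 = _estep_dispatch(y, y2, log_prior, comp_class, A, B, C, R1)
        out2 = _estep_numpy(y, y2, log_prior, comp_class, A, B, C, R2)
        np.testing.assert_allclose(R1, R2, atol=5e-5)
        assert out1[3] == pytest.approx(out2[3], rel=1e-6)
        np.testing.assert_allclose(out1[0], out2[0], rtol=1e-4, atol=1e-3)


@pytest.fixture(scope="module")
def fitted(request):
    """Full constrained fit on the noisy, biased lesion phantom."""
    from midas.io import resample_isotropic
    from midas.phantom import make_phantom
    from midas.pipeline import _resample_priors_like
    from midas.priors import priors_from_labels
    from midas.phantom import CMBSpec
    from conftest import small_spec

    spec = small_spec(
        cmb_list=[
            CMBSpec((20.0, 10.0, 0.0), 6.0, 0.3),
            CMBSpec((-25.0, 15.0, 6.5), 5.0, 0.3),
            CMBSpec((0.0, -30.0, 0.0), 7.0, 0.3),
        ],
        noise_sigma=5.0,
        bias_amplitude=0.1,
        seed=7,
    )
    vol, gt = make_phantom(spec)
    work = resample_isotropic(vol, 1.5)
    priors = _resample_priors_like(priors_from_labels(gt.tissue_label_map), work)
    res = ConstrainedGaussianMixture(work, priors, EMConfig()).fit()
    return work, priors, res


class TestConstrainedFit:
    def test_constraints_hold_after_fit(self, fitted):
        _, _, res = fitted
        mix = res.mixture
        m_gwm = mix.mean_gwm()
        assert mix.means["cmb"].max() < 0.5 * m_gwm
        assert mix.means["csf"].min() > m_gwm

    def test_posteriors_normalised(self, fitted):
        _, _, res = fitted
        stack = res.posteriors.stack()
        np.testing.assert_allclose(stack.sum(axis=0), 1.0, atol=1e-6)
        assert stack.min() >= 0 and stack.max() <= 1 + 1e-9

    def test_class_means_recover_ground_truth_sample_means(self, fitted):
        # oracle: sample mean of the working-grid intensities over each
        # class's ground-truth label region (thick-slice partial volume
        # affects oracle and fit identically)
        from midas.io import resample_like, resample_isotropic
        from midas.phantom import make_phantom
        from conftest import small_spec
        from midas.phantom import CMBSpec

        spec = small_spec(
            cmb_list=[
                CMBSpec((20.0, 10.0, 0.0), 6.0, 0.3),
                CMBSpec((-25.0, 15.0, 6.5), 5.0, 0.3),
                CMBSpec((0.0, -30.0, 0.0), 7.0, 0.3),
            ],
            noise_sigma=5.0,
            bias_amplitude=0.1,
            seed=7,
        )
        _, gt = make_phantom(spec)
        work, _, res = fitted
        labels = resample_like(
            gt.tissue_label_map, work, order="nearest"
        ).data
        mix = res.mixture
        # GWM: posterior-weighted intensity mean against the sample mean of
        # the ground-truth parenchyma voxels, and the mixture mean against
        # the generative value
        p = res.posteriors.maps["gwm"]
        pw_mean = float((p * work.data).sum() / p.sum())
        truth_gwm = float(work.data[labels == LABELS["gwm"]].mean())
        assert pw_mean == pytest.approx(truth_gwm, rel=0.05)
        assert mix.mean_gwm() == pytest.approx(100.0, rel=0.05)
        # CSF splits into a pure and a partial-volume component on thick
        # slices; the pure component must sit at the generative CSF value
        assert np.abs(mix.means["csf"] - 180.0).min() < 0.05 * 180.0

    def test_loglik_monotone_outside_projection_and_bias_events(self, fitted):
        _, _, res = fitted
        tr = np.array(res.mixture.loglik_trace)
        events = set(res.mixture.projection_events) | set(
            res.mixture.bias_events
        )
        slack = 1e-8 * np.abs(tr).max()
        for i in range(1, len(tr)):
            if (i - 1) not in events:
                assert tr[i] >= tr[i - 1] - slack

    def test_permutation_of_within_class_components_invariant(self, fitted):
        work, priors, res = fitted
        mix = res.mixture.copy()
        # swap the two CSF Gaussians and refit posteriors at fixed params
        for key in ("means", "variances", "weights"):
            getattr(mix, key)["csf"] = getattr(mix, key)["csf"][::-1].copy()
        cfg = EMConfig(max_iter=0, bias=False, sampling_step=1)
        _, post, _ = fit_constrained_mixture(work, priors, cfg, init_model=mix)
        _, post0, _ = fit_constrained_mixture(
            work, priors, cfg, init_model=res.mixture
        )
        np.testing.assert_allclose(
            post.maps["csf"], post0.maps["csf"], atol=1e-6
        )

    def test_summary_mentions_constraint_bound(self, fitted):
        _, _, res = fitted
        text = res.summary()
        assert "CMB bound" in text and "log-likelihood" in text


class TestDegenerateInputs:
    def _flat_priors(self, shape):
        zeros = Volume3D(np.zeros(shape, np.float32), np.eye(4))
        ones_third = Volume3D(np.full(shape, 0.3, np.float32), np.eye(4))
        brain = np.ones(shape, bool)
        return build_prior_set(
            gm=ones_third,
            wm=zeros,
            csf=Volume3D(np.full(shape, 0.2, np.float32), np.eye(4)),
            skull=Volume3D(np.full(shape, 0.1, np.float32), np.eye(4)),
            scalp=Volume3D(np.full(shape, 0.1, np.float32), np.eye(4)),
            brain_mask=brain,
        )

    def test_constant_volume_converges_to_renormalised_priors(self):
        # the likelihood carries no information; the mean-ordering
        # constraints push the CMB class away from the constant value, so
        # its posterior vanishes and the remaining classes reproduce their
        # renormalised priors
        shape = (10, 10, 10)
        vol = Volume3D(np.full(shape, 77.0, np.float32), np.eye(4))
        priors = self._flat_priors(shape)
        cfg = EMConfig(bias=False, sampling_step=1, max_iter=30)
        model, post, _ = fit_constrained_mixture(vol, priors, cfg)
        assert post.maps["cmb"].max() < 1e-6
        remaining = [n for n in CLASS_NAMES if n != "cmb"]
        mass = sum(priors.maps[n] for n in remaining)
        for name in remaining:
            np.testing.assert_allclose(
                post.maps[name], priors.maps[name] / mass, atol=0.02
            )

    def test_tiny_brain_rejected(self):
        shape = (4, 4, 4)
        vol = Volume3D(np.zeros(shape, np.float32), np.eye(4))
        priors = self._flat_priors(shape)
        with pytest.raises(ValueError, match="brain mask"):
            fit_constrained_mixture(vol, priors, EMConfig())


class TestBiasRecovery:
    def test_null_bias_recovered_near_unity(self):
        from midas.io import resample_isotropic
        from midas.phantom import make_phantom
        from midas.pipeline import _resample_priors_like
        from midas.priors import priors_from_labels
        from conftest import small_spec

        spec = small_spec(noise_sigma=3.0, seed=21)
        vol, gt = make_phantom(spec)
        work = resample_isotropic(vol, 1.5)
        priors = _resample_priors_like(
            priors_from_labels(gt.tissue_label_map), work
        )
        res = ConstrainedGaussianMixture(work, priors, EMConfig()).fit()
        brain = priors.brain_mask
        field = res.bias_field.data[brain]
        assert np.abs(field - 1.0).max() < 0.02

    def test_imposed_20pc_bias_recovered_within_5pc(self):
        from midas.io import resample_isotropic
        from midas.phantom import make_phantom
        from midas.pipeline import _resample_priors_like
        from midas.priors import priors_from_labels
        from midas.io import resample_like
        from conftest import small_spec

        spec = small_spec(noise_sigma=3.0, bias_amplitude=0.2, seed=13)
        vol, gt = make_phantom(spec)
        work = resample_isotropic(vol, 1.5)
        priors = _resample_priors_like(
            priors_from_labels(gt.tissue_label_map), work
        )
        res = ConstrainedGaussianMixture(work, priors, EMConfig()).fit()
        truth = resample_like(gt.bias_field, work, order="linear")
        brain = priors.brain_mask
        est = np.log(res.bias_field.data[brain])
        tru = np.log(truth.data[brain])
        # align the free mean-log offset before comparing
        est -= est.mean()
        tru -= tru.mean()
        err = np.abs(np.exp(est - tru) - 1.0)
        assert np.corrcoef(est, tru)[0, 1] > 0.95
        assert err.max() < 0.05

    def test_estimate_bias_standalone_matches_fit_field(self, fitted):
        work, priors, res = fitted
        bias = estimate_bias(
            work,
            res.posteriors,
            res.mixture,
            order=3,
            brain_mask=priors.brain_mask,
        )
        brain = priors.brain_mask
        ratio = bias.data[brain] / res.bias_field.data[brain]
        # same basis, responsibilities near the fit's: fields agree closely
        assert np.abs(ratio - 1.0).max() < 0.05
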