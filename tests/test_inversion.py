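import numpy as np
import pytest

from dcmnet import design, generative, synthetic
from dcmnet.design import ALL_CONDITIONS, Epoch, EpochSchedule, build_session
from dcmnet.generative import HemodynamicParameters, ROITimeSeries, simulate_session
from dcmnet.inversion import (
    InversionOptions,
    ParameterMap,
    Posterior,
    Prior,
    dct_confounds,
    default_priors,
    free_energy,
    invert,
)

FAST_OPTS = InversionOptions(max_iter=24, bins_per_tr=8)


@pytest.fixture(scope="module")
def short_session():
    """A 2-task-epoch mini-design (60 s, 20 volumes) for mechanics tests."""
    epochs = (
        Epoch("rest", None, 12.0),
        Epoch("task", ALL_CONDITIONS[0], 12.0),  # exec+hand
        Epoch("rest", None, 12.0),
        Epoch("task", ALL_CONDITIONS[5], 12.0),  # obs+nohand
        Epoch("rest", None, 12.0),
    )
    run = EpochSchedule(epochs=epochs, tr=3.0)
    return build_session([run], discard=0)


class TestDefaultPriors:
    def test_model1_has_78_free_parameters(self, model1):
        prior = default_priors(model1)
        assert prior.pmap.n_params == 25 + 2 * 25 + 3 == 78

    def test_minimal_model_has_70_free_parameters(self, space):
        prior = default_priors(space[16])
        assert prior.pmap.n_params == 23 + 2 * 23 + 1 == 70

    def test_prior_moments(self, model1):
        prior = default_priors(model1)
        assert np.allclose(prior.mean, 0.0)
        sl = prior.pmap.slices
        assert np.allclose(prior.variance[sl["A"]], 0.25)
        assert np.allclose(prior.variance[sl["B_exec"]], 0.25)
        assert np.allclose(prior.variance[sl["B_hand"]], 0.25)
        assert np.allclose(prior.variance[sl["C"]], 1.0)

    def test_disabled_edges_not_in_map(self, space):
        # model 16 has no PMv<->pSTS edges and no exec/hand inputs
        pmap = default_priors(space[16]).pmap
        assert "A:PMv->pSTS" not in pmap.names
        assert "C:exec->PMv" not in pmap.names


class TestParameterMap:
    def test_scatter_gather_round_trip(self, model1, rng):
        pmap = ParameterMap.from_model(model1)
        theta = rng.normal(size=pmap.n_params)
        p = pmap.to_matrices(theta)
        assert np.allclose(pmap.from_matrices(p), theta)

    def test_diagonal_fixed(self, model1):
        pmap = ParameterMap.from_model(model1)
        p = pmap.to_matrices(np.zeros(pmap.n_params))
        assert np.allclose(np.diag(p.A), generative.A_DIAGONAL)

    def test_disabled_cells_stay_zero(self, space, rng):
        pmap = ParameterMap.from_model(space[16])
        p = pmap.to_matrices(rng.normal(size=pmap.n_params))
        ridx = {r: i for i, r in enumerate(p.regions)}
        assert p.A[ridx["pSTS"], ridx["PMv"]] == 0.0
        assert p.C[ridx["PMv"], 1] == 0.0


class TestDctConfounds:
    def test_includes_constant(self):
        X = dct_confounds(133, 3.0)
        assert np.allclose(X[:, 0], X[0, 0])

    def test_order_matches_cutoff(self):
        # 133 volumes at TR 3: floor(2*133*3/128) = 6 cosines + constant
        assert dct_confounds(133, 3.0).shape == (133, 7)

    def test_columns_orthonormal(self):
        X = dct_confounds(50, 3.0)
        assert np.allclose(X.T @ X, np.eye(X.shape[1]), atol=1e-10)


class TestInvertMechanics:
    def test_prior_mean_self_consistency(self, model1, short_session):
        """Noise-free data generated at the prior mean stays there."""
        prior = default_priors(model1)
        p0 = prior.pmap.to_matrices(prior.mean)
        data = simulate_session(p0, HemodynamicParameters(), short_session, bins_per_tr=8)
        post = invert(model1, data, short_session, prior=prior, opts=FAST_OPTS)
        assert np.max(np.abs(post.mean - prior.mean)) < 1e-3

    def test_pure_noise_shrinks_to_zero(self, model1, short_session, rng):
        noise = rng.normal(0, 0.01, size=(7, short_session.retained_volumes))
        data = ROITimeSeries(
            regions=tuple(synthetic.REGIONS), values=noise, tr=3.0
        )
        post = invert(model1, data, short_session, prior=None, opts=FAST_OPTS)
        # average magnitude below the truth-free prior SD (0.5)
        assert np.mean(np.abs(post.mean)) < 0.5

    def test_f_trace_monotone(self, model1, one_run_session):
        truth = synthetic.default_truth(n_subjects=1, snr=5.0, seed=3)
        series, _, _ = synthetic.generate_group(truth, one_run_session, bins_per_tr=8)
        post = invert(model1, series[0], one_run_session, opts=FAST_OPTS)
        diffs = np.diff(post.f_trace)
        # within an iteration steps are accepted only if F increases; the
        # re-linearization and noise-precision EM between iterations may
        # move the recorded value by a fraction of a nat
        assert np.all(diffs >= -0.5)
        assert post.f_trace[-1] > post.f_trace[0]

    def test_posterior_cov_diagonal_positive(self, model1, short_session, rng):
        noise = rng.normal(0, 0.01, size=(7, short_session.retained_volumes))
        data = ROITimeSeries(regions=tuple(synthetic.REGIONS), values=noise, tr=3.0)
        post = invert(model1, data, short_session, opts=FAST_OPTS)
        assert np.all(np.diag(post.cov) > 0)
        assert np.allclose(post.cov, post.cov.T)

    def test_volume_mismatch_rejected(self, model1, short_session, rng):
        data = ROITimeSeries(
            regions=tuple(synthetic.REGIONS),
            values=rng.normal(size=(7, 5)), tr=3.0,
        )
        with pytest.raises(ValueError):
            invert(model1, data, short_session, opts=FAST_OPTS)

    def test_region_mismatch_rejected(self, model1, short_session, rng):
        data = ROITimeSeries(
            regions=("a", "b", "c", "d", "e", "f", "g"),
            values=rng.normal(size=(7, short_session.retained_volumes)), tr=3.0,
        )
        with pytest.raises(ValueError):
            invert(model1, data, short_session, opts=FAST_OPTS)

    def test_posterior_json_round_trip(self, model1, short_session, rng, tmp_path):
        noise = rng.normal(0, 0.01, size=(7, short_session.retained_volumes))
        data = ROITimeSeries(regions=tuple(synthetic.REGIONS), values=noise, tr=3.0)
        post = invert(model1, data, short_session, opts=FAST_OPTS)
        path = tmp_path / "post.json"
        post.save(path)
        import json

        with open(path) as fh:
            d = json.load(fh)
        assert d["model_id"] == 1
        assert len(d["mean"]) == 78


class TestRecovery:
    def test_posterior_calibration_at_snr5(self, model1):
        """Full 798-volume session at SNR 5: at least 90% of parameters fall
        within 2 posterior SDs of the subject's truth."""
        sess = design.default_session(seed=2)
        truth = synthetic.default_truth(n_subjects=1, snr=5.0, seed=2)
        series, params, _ = synthetic.generate_group(truth, sess, bins_per_tr=8)
        prior = default_priors(model1)
        post = invert(model1, series[0], sess, prior=prior,
                      opts=InversionOptions(max_iter=48, bins_per_tr=8))
        th = prior.pmap.from_matrices(params[0])
        z = np.abs(th - post.mean) / np.sqrt(np.diag(post.cov))
        assert np.mean(z < 2.0) >= 0.9


class TestFreeEnergy:
    @pytest.fixture(scope="class")
    @staticmethod
    def inverted(model1, one_run_session):
        truth = synthetic.default_truth(n_subjects=1, snr=5.0, seed=5)
        series, _, _ = synthetic.generate_group(truth, one_run_session, bins_per_tr=8)
        post = invert(model1, series[0], one_run_session, opts=FAST_OPTS)
        return series[0], post

    def test_recomputed_f_is_consistent(self, model1, one_run_session, inverted):
        data, post = inverted
        f = free_energy(post, model1, data, one_run_session, opts=FAST_OPTS)
        assert f == pytest.approx(post.free_energy, abs=1.0)

    def test_identical_inputs_identical_f(self, model1, one_run_session, inverted):
        data, post = inverted
        f1 = free_energy(post, model1, data, one_run_session, opts=FAST_OPTS)
        f2 = free_energy(post, model1, data, one_run_session, opts=FAST_OPTS)
        assert f1 == f2

    def test_wrong_noise_precision_lowers_f(self, model1, one_run_session, inverted):
        data, post = inverted
        f_good = free_energy(post, model1, data, one_run_session, opts=FAST_OPTS)
        import dataclasses

        wrong = dataclasses.replace(post, noise_precision=post.noise_precision * 100.0)
        f_bad = free_energy(wrong, model1, data, one_run_session, opts=FAST_OPTS)
        assert f_bad < f_good

    def test_irrelevant_parameters_cost_complexity(self, space, one_run_session):
        """Data from the minimal model: richer models (extra parameters whose
        true value is 0) do not improve F on average."""
        minimal = space[16]
        richer = space[12]  # extra pSTS->PMv edge, extra input
        gaps = []
        for seed in (0, 1, 2):
            truth = synthetic.default_truth(
                n_subjects=1, snr=5.0, seed=seed, model=minimal
            )
            series, _, _ = synthetic.generate_group(
                truth, one_run_session, bins_per_tr=8
            )
            f_min = invert(minimal, series[0], one_run_session, opts=FAST_OPTS).free_energy
            f_rich = invert(richer, series[0], one_run_session, opts=FAST_OPTS).free_energy
            gaps.append(f_rich - f_min)
        assert np.mean(gaps) < 10.0


class TestIdentifiabilitySmoke:
    def test_generating_model_beats_minimal(self, space, one_run_session):
        """Data from the dual-input model: F(model 1) > F(minimal) in most
        seeded replicates (reduced scale: one run, 3 replicates)."""
        model1, minimal = space[1], space[16]
        wins = 0
        for seed in (11, 12, 13):
            truth = synthetic.default_truth(n_subjects=1, snr=3.0, seed=seed)
            series, _, _ = synthetic.generate_group(
                truth, one_run_session, bins_per_tr=8
            )
            f1 = invert(model1, series[0], one_run_session, opts=FAST_OPTS).free_energy
            f0 = invert(minimal, series[0], one_run_session, opts=FAST_OPTS).free_energy
            wins += int(f1 > f0)
        assert wins >= 2
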