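import numpy as np
import pytest

from burstrf import (
    LNModel1D,
    LNModel2D,
    compute_psth,
    estimate_nonlinearity_1d,
    estimate_nonlinearity_2d,
    filter_output,
    make_gaussian_noise,
    optimize_bins,
    simulate_response,
)
from burstrf.datatypes import SpikeRecord, StimulusMovie, SubunitFilter
from burstrf.lnmodel import PSTH, _lookup_1d, _lookup_2d
from burstrf.pipeline import slice_stimulus, train_test_split_frames
from burstrf.synthetic import default_neuron


class TestFilterOutput:
    def test_embedded_filter_gives_plus_one(self):
        rng = np.random.default_rng(0)
        w = rng.normal(size=(3, 2, 2))
        w /= np.linalg.norm(w)
        frames = rng.normal(0, 0.1, size=(30, 2, 2))
        frames[10:13] = 5.0 * w  # strong same-sign copy ending at frame 12
        frames[20:23] = -5.0 * w  # reversed copy ending at frame 22
        stim = StimulusMovie(frames=frames, frame_duration=0.02)
        out = filter_output(stim, SubunitFilter(weights=w))
        assert np.argmax(out.values) == 12 and np.isclose(out.values[12], 1.0)
        assert np.isclose(out.values[22], -1.0, atol=0.05)

    def test_orthogonal_window_gives_zero(self):
        w = np.zeros((1, 2, 2))
        w[0, 0, 0] = 1.0
        frames = np.zeros((5, 2, 2))
        frames[:, 1, 1] = np.linspace(-1, 1, 5)  # orthogonal pixel only
        frames[2, 0, 0] = 1.0  # one aligned frame so the max is nonzero
        stim = StimulusMovie(frames=frames, frame_duration=0.02)
        out = filter_output(stim, SubunitFilter(weights=w))
        assert np.allclose(np.delete(out.values, 2), 0.0)

    def test_zero_filter_signalled(self, stim4x4):
        with pytest.raises(ValueError):
            filter_output(stim4x4, SubunitFilter(weights=np.zeros((2, 4, 4))))


class TestPSTH:
    def test_single_spike_single_repeat(self):
        rec = SpikeRecord(repeats=[np.array([3 * 0.02 + 0.001])])
        psth = compute_psth(rec, 6, 0.02)
        want = np.zeros(6)
        want[3] = 1.0
        assert np.array_equal(psth.rate, want)

    def test_identical_repeats_average_to_any_single(self):
        t = np.array([0.001, 0.045, 0.095])
        psth = compute_psth(SpikeRecord(repeats=[t, t, t]), 5, 0.02)
        single = compute_psth(SpikeRecord(repeats=[t]), 5, 0.02)
        assert np.array_equal(psth.rate, single.rate)

    def test_poisson_mean_recovered(self):
        rng = np.random.default_rng(1)
        lam, n_frames, R = 0.3, 2000, 16
        repeats = []
        for _ in range(R):
            counts = rng.poisson(lam, n_frames)
            t = np.concatenate([
                f * 0.02 + np.sort(rng.uniform(0, 0.02, c))
                for f, c in enumerate(counts) if c])
            repeats.append(np.sort(t))
        psth = compute_psth(SpikeRecord(repeats=repeats), n_frames, 0.02)
        se = np.sqrt(lam / (R * n_frames))
        assert abs(psth.rate.mean() - lam) < 4 * se


class TestNonlinearity1D:
    def test_uncorrelated_output_gives_flat_curve(self):
        rng = np.random.default_rng(2)
        v = np.clip(rng.normal(0, 0.3, 20000), -1, 1)
        r = rng.poisson(0.5, 20000).astype(float)
        nl = estimate_nonlinearity_1d(v, r, 8)
        occupied = nl.mean_rate[nl.occupied]
        assert np.all(np.abs(occupied - r.mean()) < 0.1)

    def test_recovers_halfwave_rectifier(self, stim4x4):
        neuron = default_neuron("lgn_linear", seed=4, burst_profile="none")
        rec = simulate_response(neuron, stim4x4, n_repeats=8, seed=30)
        psth = compute_psth(rec, stim4x4.n_frames, stim4x4.frame_duration)
        out = filter_output(stim4x4, neuron.linear_filter)
        nl = estimate_nonlinearity_1d(out, psth, 10)
        # oracle: the generator's true rate averaged within each bin
        true_rate = neuron.rate_trace(stim4x4) * stim4x4.frame_duration
        idx = np.clip(np.searchsorted(nl.bin_edges, out.values,
                                      side="right") - 1, 0, 9)
        truth = np.array([true_rate[idx == i].mean() if np.any(idx == i)
                          else np.nan for i in range(10)])
        ok = nl.occupied & ~np.isnan(truth)
        rmse = np.sqrt(np.mean((nl.mean_rate[ok] - truth[ok]) ** 2))
        assert rmse < 0.10 * np.nanmax(truth)

    def test_stc_output_nonlinearity_is_u_shaped(self, stim4x4_long,
                                                 energy_recording):
        neuron, rec = energy_recording
        psth = compute_psth(rec, stim4x4_long.n_frames,
                            stim4x4_long.frame_duration)
        out = filter_output(stim4x4_long, neuron.quad_filter)
        nl = estimate_nonlinearity_1d(out, psth, 10)
        mid = nl.mean_rate[4:6].mean()
        assert nl.mean_rate[0] > 2 * mid and nl.mean_rate[-1] > 2 * mid

    def test_bad_bin_count_rejected(self):
        with pytest.raises(ValueError):
            estimate_nonlinearity_1d(np.zeros(4), np.zeros(4), 1)


class TestNonlinearity2D:
    @staticmethod
    def _deterministic(rate_fn, n=40000, seed=3):
        rng = np.random.default_rng(seed)
        a = np.clip(rng.normal(0, 0.4, n), -1, 1)
        b = np.clip(rng.normal(0, 0.4, n), -1, 1)
        return a, b, rate_fn(a, b)

    def test_additive_drives_give_additive_map(self):
        a, b, r = self._deterministic(lambda a, b: np.maximum(a, 0)
                                      + np.maximum(b, 0))
        nl = estimate_nonlinearity_2d(a, b, r, 8)
        nla = estimate_nonlinearity_1d(a, r, 8)
        nlb = estimate_nonlinearity_1d(b, r, 8)
        ok = nl.occupied & (nl.occupancy > 30)
        pred = (nla.mean_rate[:, None] + nlb.mean_rate[None, :]
                - r.mean())
        assert np.nanmax(np.abs(nl.mean_rate[ok] - pred[ok])) < 0.08

    def test_rate_depending_only_on_a_gives_constant_rows(self):
        a, b, r = self._deterministic(lambda a, b: 1.0 + np.maximum(a, 0))
        nl = estimate_nonlinearity_2d(a, b, r, 6)
        for i in range(6):
            row = nl.mean_rate[i][nl.occupied[i]]
            if row.size > 1:
                assert np.ptp(row) < 0.05

    def test_multiplicative_truth_has_rank_two_log_map(self):
        a, b, r = self._deterministic(
            lambda a, b: (0.3 + np.maximum(a, 0)) * (0.3 + np.maximum(b, 0)))
        nl = estimate_nonlinearity_2d(a, b, r, 8)
        grid = np.where(nl.occupied & (nl.mean_rate > 0), nl.mean_rate, np.nan)
        # fill the rare empty cells with the separable expectation
        log_grid = np.log(np.where(np.isnan(grid), np.nanmean(grid), grid))
        s = np.linalg.svd(log_grid, compute_uv=False)
        assert s[1] / s[0] > 0.02      # genuinely two-dimensional...
        assert s[2] / s[0] < 0.02      # ...but log-separable (not axis-aligned)


class TestOptimizeBins:
    def _split(self, stim, lag=5):
        tr, te = train_test_split_frames(stim.n_frames, lag)
        return (slice_stimulus(stim, tr), slice_stimulus(stim, te), tr, te)

    def test_non_improving_response_returns_minimum(self):
        # a response with no stimulus-locked variance cannot improve with
        # more bins: the search must stop at its starting value
        rng = np.random.default_rng(4)
        v_tr, v_te = rng.uniform(-1, 1, 2000), rng.uniform(-1, 1, 2000)
        p_tr = PSTH(np.full((4, 2000), 0.5), 0.02)
        p_te = PSTH(np.full((4, 2000), 0.5), 0.02)
        assert optimize_bins(v_tr, p_tr, v_te, p_te, start=4, step=2,
                             max_bins=20) == 4
        # and pure-noise responses stay at/near the minimum on average
        chosen = []
        for s in range(5):
            r = np.random.default_rng(s)
            p_tr = PSTH(r.poisson(0.5, (4, 2000)).astype(float), 0.02)
            p_te = PSTH(r.poisson(0.5, (4, 2000)).astype(float), 0.02)
            chosen.append(optimize_bins(r.uniform(-1, 1, 2000), p_tr,
                                        r.uniform(-1, 1, 2000), p_te,
                                        start=4, step=2, max_bins=20))
        assert np.median(chosen) == 4

    def test_noiseless_sharp_nonlinearity_keeps_improving(self):
        rng = np.random.default_rng(5)
        v_tr = np.clip(rng.normal(0, 0.4, 30000), -1, 1)
        v_te = np.clip(rng.normal(0, 0.4, 30000), -1, 1)
        rate = lambda v: np.exp(3 * v)
        p_tr = PSTH(rate(v_tr)[None, :], 0.02)
        p_te = PSTH(rate(v_te)[None, :], 0.02)
        n = optimize_bins(v_tr, p_tr, v_te, p_te, start=4, step=2,
                          max_bins=16)
        assert n >= 14  # last improving value at/near the search bound

    def test_mid_noise_neuron_lands_near_paper_range(self, stim4x4):
        stim_tr, stim_te, tr, te = self._split(stim4x4)
        chosen = []
        for s in range(10):
            neuron = default_neuron("lgn_linear", seed=30 + s,
                                    burst_profile="none")
            rec = simulate_response(neuron, stim4x4, n_repeats=8, seed=70 + s)
            psth = compute_psth(rec, stim4x4.n_frames,
                                stim4x4.frame_duration)
            out_tr = filter_output(stim_tr, neuron.linear_filter)
            out_te = filter_output(stim_te, neuron.linear_filter,
                                   norm=out_tr.norm)
            chosen.append(optimize_bins(out_tr, psth.slice(tr), out_te,
                                        psth.slice(te), max_bins=20))
        chosen = np.array(chosen)
        assert 8 <= np.median(chosen) <= 14
        assert np.count_nonzero((chosen >= 8) & (chosen <= 14)) >= 7


class TestLNModels:
    def test_training_reconstruction_is_binned_conditional_mean(self, stim4x4):
        neuron = default_neuron("lgn_linear", seed=6, burst_profile="none")
        rec = simulate_response(neuron, stim4x4, n_repeats=4, seed=31)
        psth = compute_psth(rec, stim4x4.n_frames, stim4x4.frame_duration)
        model = LNModel1D(filt=neuron.linear_filter, n_bins=10)
        model.fit(stim4x4, psth)
        pred = model.predict(stim4x4)
        nl = model.nonlinearity_
        out = filter_output(stim4x4, neuron.linear_filter, norm=model.norm_)
        idx = np.clip(np.searchsorted(nl.bin_edges, out.values,
                                      side="right") - 1, 0, nl.n_bins - 1)
        assert np.allclose(pred, nl.mean_rate[idx])
        # occupancy-weighted mean equals the overall training mean rate
        assert np.isclose(np.nansum(nl.mean_rate * nl.occupancy)
                          / nl.occupancy.sum(), psth.rate.mean())

    def test_constant_nonlinearity_predicts_constant(self, stim4x4):
        neuron = default_neuron("lgn_linear", seed=6, burst_profile="none")
        flat_psth = PSTH(np.full((2, stim4x4.n_frames), 0.25), 0.02)
        model = LNModel1D(filt=neuron.linear_filter, n_bins=6)
        model.fit(stim4x4, flat_psth)
        assert np.allclose(model.predict(stim4x4), 0.25)

    def test_2d_model_beats_1d_on_two_subunit_cells(self, stim4x4_long):
        from burstrf import (build_ensemble, compute_sta, compute_stc,
                             explained_variance_corrected)
        from burstrf.pipeline import slice_record
        lag = 5
        tr, te = train_test_split_frames(stim4x4_long.n_frames, lag)
        stim_tr = slice_stimulus(stim4x4_long, tr)
        stim_te = slice_stimulus(stim4x4_long, te)
        fd = stim4x4_long.frame_duration
        for s in range(3):
            neuron = default_neuron("pgn_two_subunit", seed=40 + s,
                                    burst_profile="none")
            rec = simulate_response(neuron, stim4x4_long, n_repeats=8,
                                    seed=80 + s)
            psth = compute_psth(rec, stim4x4_long.n_frames, fd)
            rec_tr = slice_record(rec, 0, tr.stop * fd)
            ens = build_ensemble(stim_tr, rec_tr, lag, "all")
            sta = compute_sta(ens)
            stc1 = compute_stc(ens).filter_at(0)
            m1 = LNModel1D(filt=sta, n_bins=10).fit(stim_tr, psth.slice(tr))
            m2 = LNModel2D(filt_a=sta, filt_b=stc1,
                           n_bins=10).fit(stim_tr, psth.slice(tr))
            g1 = explained_variance_corrected(
                psth.slice(te), m1.predict(stim_te), m1.n_free_params_)
            g2 = explained_variance_corrected(
                psth.slice(te), m2.predict(stim_te), m2.n_free_params_)
            assert g2.gamma_corrected >= g1.gamma_corrected

    def test_sklearn_protocol(self):
        model = LNModel1D(n_bins=8)
        assert model.get_params()["n_bins"] == 8
        model.set_params(n_bins=12)
        assert model.n_bins == 12

    def test_empty_bin_lookup_falls_back_to_nearest(self):
        from burstrf.lnmodel import Nonlinearity1D
        edges = np.linspace(-1, 1, 5)
        nl = Nonlinearity1D(bin_edges=edges,
                            mean_rate=np.array([1.0, np.nan, np.nan, 4.0]),
                            occupancy=np.array([10.0, 0.0, 0.0, 10.0]))
        got = _lookup_1d(nl, np.array([-0.9, -0.3, 0.3, 0.9]))
        assert np.array_equal(got, [1.0, 1.0, 4.0, 4.0])
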