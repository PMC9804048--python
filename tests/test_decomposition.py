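import numpy as np
import pytest

from dfnc import (
    GroupICA,
    ICSelectionCriteria,
    PostprocessConfig,
    postprocess_timecourse,
    select_components,
    spectral_metrics,
    static_fc,
)
from dfnc._utils import fisher_z
from dfnc.exceptions import InvalidConfigError


def _block_maps(n, shape=(8, 8, 6), density=0.15):
    """Overlapping random sparse spatial maps with amplitude structure.

    Each voxel belongs to each map independently (sparse, high-kurtosis,
    mutually independent sources — the regime spatial ICA identifies).
    Disjoint flat maps tiling the volume would be mutually exclusive
    indicators, which ICA provably cannot separate.
    """
    v = int(np.prod(shape))
    rng = np.random.default_rng(99)
    maps = (rng.random((n, v)) < density) * (
        np.abs(rng.standard_normal((n, v))) + 0.5
    )
    return maps.reshape(n, *shape)


def _lowfreq_tc(rng, T, n, tr=2.0):
    """Low-frequency (< 0.1 Hz) smooth signals, unit variance."""
    from scipy import signal

    b, a = signal.butter(4, 0.08 / (0.5 / tr))
    x = signal.filtfilt(b, a, rng.standard_normal((T, n)), axis=0)
    return x / x.std(axis=0)


def _matched_corr(est_maps, true_maps):
    """Best |correlation| match of each true map to some estimated map."""
    est = est_maps.reshape(est_maps.shape[0], -1)
    true = true_maps.reshape(true_maps.shape[0], -1)
    out = []
    for t in true:
        out.append(max(abs(np.corrcoef(t, e)[0, 1]) for e in est))
    return np.asarray(out)


class TestGroupICA:
    def test_recovers_planted_maps_at_high_snr(self, rng):
        maps = _block_maps(4)
        sessions = {}
        truth_tc = {}
        for s in range(3):
            tc = _lowfreq_tc(rng, 120, 4)
            truth_tc[s] = tc
            sessions[s] = tc @ maps.reshape(4, -1) + 0.02 * rng.standard_normal(
                (120, maps[0].size)
            )
        ica = GroupICA(n_components=4, random_state=0).fit(sessions)
        assert np.all(_matched_corr(ica.group_maps_, maps) >= 0.9)

    def test_noiseless_mixing_reconstructs_exactly(self, rng):
        maps = _block_maps(3)
        sessions = {
            s: _lowfreq_tc(rng, 100, 3) @ maps.reshape(3, -1) for s in range(2)
        }
        ica = GroupICA(n_components=3, random_state=1).fit(sessions)
        assert ica.reconstruction_residual() <= 0.01

    def test_single_session_back_reconstruction_matches_truth(self, rng):
        maps = _block_maps(3, shape=(12, 12, 12))
        tc = _lowfreq_tc(rng, 150, 3)
        ica = GroupICA(n_components=3, random_state=2).fit(
            {"only": tc @ maps.reshape(3, -1)}
        )
        _, rec_tc = ica.back_reconstruct("only")
        for c in range(3):
            best = max(
                abs(np.corrcoef(tc[:, c], rec_tc[:, j])[0, 1]) for j in range(3)
            )
            assert best >= 0.999

    def test_seed_determinism_up_to_nothing(self, rng):
        maps = _block_maps(3)
        sessions = {
            s: _lowfreq_tc(rng, 90, 3) @ maps.reshape(3, -1)
            + 0.05 * np.random.default_rng(s).standard_normal((90, maps[0].size))
            for s in range(2)
        }
        a = GroupICA(n_components=3, random_state=7).fit(sessions)
        b = GroupICA(n_components=3, random_state=7).fit(sessions)
        np.testing.assert_allclose(a.group_maps_, b.group_maps_, atol=1e-10)

    def test_unknown_session_rejected(self, rng):
        maps = _block_maps(2)
        ica = GroupICA(n_components=2, random_state=0).fit(
            {"a": _lowfreq_tc(rng, 80, 2) @ maps.reshape(2, -1)}
        )
        with pytest.raises(KeyError):
            ica.back_reconstruct("b")

    def test_recovery_improves_with_snr(self, rng):
        maps = _block_maps(3)
        scores = []
        for snr in (0.05, 1.0, 20.0):
            sessions = {}
            for s in range(2):
                tc = _lowfreq_tc(np.random.default_rng(100 + s), 100, 3)
                sig = tc @ maps.reshape(3, -1)
                noise = np.random.default_rng(200 + s).standard_normal(sig.shape)
                sessions[s] = sig + noise * sig.std() / snr
            ica = GroupICA(n_components=3, random_state=3).fit(sessions)
            scores.append(_matched_corr(ica.group_maps_, maps).mean())
        assert scores[0] < scores[1] < scores[2] or scores[1] >= 0.99

    def test_empty_input_rejected(self):
        with pytest.raises(InvalidConfigError):
            GroupICA(n_components=2).fit({})


class TestSpectralMetrics:
    def test_low_frequency_sinusoid_dominates_lf_band(self):
        t = np.arange(256) * 2.0
        lf_ratio, _ = spectral_metrics(np.sin(2 * np.pi * 0.05 * t), 2.0)
        assert lf_ratio > 100

    def test_mid_band_sinusoid_fails_lf_ratio(self):
        t = np.arange(256) * 2.0
        lf_ratio, _ = spectral_metrics(np.sin(2 * np.pi * 0.2 * t), 2.0)
        assert lf_ratio < 0.01

    def test_white_noise_ratio_near_one(self):
        """Both bands are 0.1 Hz wide, so a flat spectrum gives ratio ~1."""
        ratios = [
            spectral_metrics(np.random.default_rng(s).standard_normal(4096), 2.0)[0]
            for s in range(5)
        ]
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.25)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            spectral_metrics(np.ones(32), 2.0)

    def test_band_beyond_nyquist_rejected(self):
        with pytest.raises(InvalidConfigError):
            spectral_metrics(np.zeros(128), 4.0)  # Nyquist 0.125 < 0.25


class TestSelectComponents:
    def _fitted_ica(self, rng, n_info=4, n_noise=4):
        n = n_info + n_noise
        maps = _block_maps(n)
        sessions = {}
        for s in range(3):
            tc = np.column_stack([
                _lowfreq_tc(rng, 160, n_info),
                rng.standard_normal((160, n_noise)),
            ])
            sessions[s] = tc @ maps.reshape(n, -1) + 0.02 * rng.standard_normal(
                (160, maps[0].size)
            )
        return GroupICA(n_components=n, random_state=0).fit(sessions), maps

    def test_informative_components_selected_and_labeled(self, rng):
        ica, maps = self._fitted_ica(rng)
        criteria = ICSelectionCriteria(
            min_lf_ratio=2.0, min_dynamic_range=0.01,
            template_maps={f"NET{i}": maps[i] for i in range(8)},
        )
        report = select_components(ica, 2.0, criteria)
        # informative = low-frequency sources (planted as NET0..NET3)
        kept_nets = set(report[report["kept"]]["network"])
        info_nets = {f"NET{i}" for i in range(4)}
        assert len(kept_nets & info_nets) >= 3
        noise_kept = kept_nets - info_nets
        assert len(noise_kept) <= 1
        # labels of matched components are exact (orthogonal maps)
        assert (report["template_r"] > 0.9).sum() >= 6

    def test_impossible_thresholds_select_nothing(self, rng):
        ica, maps = self._fitted_ica(rng, n_info=2, n_noise=2)
        criteria = ICSelectionCriteria(
            min_lf_ratio=1e9, min_dynamic_range=1e9,
            template_maps={"T": maps[0]},
        )
        with pytest.warns(UserWarning, match="no component"):
            report = select_components(ica, 2.0, criteria)
        assert not report["kept"].any()

    def test_template_required(self, rng):
        ica, _ = self._fitted_ica(rng, n_info=2, n_noise=2)
        with pytest.raises(InvalidConfigError):
            select_components(ica, 2.0, ICSelectionCriteria())


class TestPostprocess:
    def test_detrend_removes_exact_line(self):
        x = 3.0 + 0.5 * np.arange(100)
        out = postprocess_timecourse(
            x, None, 2.0,
            PostprocessConfig(despike=False, regress_motion=False, lowpass_hz=0),
        )
        assert np.max(np.abs(out)) < 1e-8

    def test_despike_tames_outlier(self, rng):
        x = rng.standard_normal(200)
        x[70] += 10 * x.std()
        out = postprocess_timecourse(
            x, None, 2.0,
            PostprocessConfig(detrend=False, regress_motion=False, lowpass_hz=0),
        )
        z = (out - out.mean()) / out.std()
        assert np.max(np.abs(z)) < 4.0

    def test_lowpass_attenuates_mid_band(self):
        t = np.arange(400) * 2.0
        x = np.sin(2 * np.pi * 0.2 * t)
        out = postprocess_timecourse(
            x, None, 2.0, PostprocessConfig(despike=False, regress_motion=False)
        )
        assert np.max(np.abs(out[50:-50])) <= 0.1  # >= 20 dB down

    def test_motion_regressors_removed(self, rng):
        motion = np.cumsum(rng.standard_normal((150, 6)) * 0.01, axis=0)
        x = rng.standard_normal(150) + motion @ rng.standard_normal(6)
        out = postprocess_timecourse(
            x, motion, 2.0, PostprocessConfig(despike=False, lowpass_hz=0)
        )
        design = np.column_stack([np.ones(150), motion])
        assert np.max(np.abs(design.T @ out)) < 1e-6

    def test_motion_length_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            postprocess_timecourse(rng.standard_normal(100),
                                   np.zeros((80, 6)), 2.0)


class TestStaticFC:
    def test_duplicated_series_hits_positive_clamp(self, rng):
        x = rng.standard_normal(100)
        z = static_fc(np.column_stack([x, x]))
        clamp = float(fisher_z(1.0))
        assert z[0, 1] == pytest.approx(clamp)
        assert clamp == pytest.approx(np.arctanh(1 - 1e-7))

    def test_antiphase_hits_negative_clamp(self):
        t = np.linspace(0, 8 * np.pi, 200)
        z = static_fc(np.column_stack([np.sin(t), -np.sin(t)]))
        assert z[0, 1] == pytest.approx(-float(fisher_z(1.0)), abs=1e-6)

    def test_independent_noise_stays_small(self):
        zs = [
            np.abs(static_fc(np.random.default_rng(s).standard_normal((230, 4))))
            for s in range(10)
        ]
        offdiag = np.concatenate([z[np.triu_indices(4, 1)] for z in zs])
        assert np.median(offdiag) < 0.1
        assert np.quantile(offdiag, 0.9) < 0.2

    def test_symmetry(self, rng):
        z = static_fc(rng.standard_normal((120, 5)))
        np.testing.assert_allclose(z, z.T)

    def test_zero_variance_component_named(self):
        x = np.random.default_rng(0).standard_normal((50, 3))
        x[:, 1] = 2.0
        with pytest.raises(ValueError, match="component 2"):
            static_fc(x)
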