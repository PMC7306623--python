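import numpy as np
import pytest

from errmon.behavior import classify_trials
from errmon.io_formats import Recording
from errmon.preprocessing import (CsdParams, EpochSet, PipelineOrderError,
                                  UnitsError, csd_transform, extract_epochs,
                                  regress_ocular, reject_artifacts)
from errmon.synthetic_data import NoiseSpec, synthesize_recording
from tests.conftest import make_epochs, make_trials

QUIET = NoiseSpec(background_rms=0.0, blink_rate=0.0)


def recording_with_eog(scalp, veog, extra_labels=("F1", "F2")):
    """Two scalp channels + one vertical EOG channel."""
    data = np.vstack([scalp, veog])
    labels = list(extra_labels) + ["VEOGu"]
    return Recording(labels, ["scalp"] * len(extra_labels) + ["eog"], 500.0,
                     data, [])


class TestOcularRegression:
    def test_perfect_propagation_removed(self):
        rng = np.random.default_rng(0)
        veog = rng.normal(size=1000)
        rec = recording_with_eog(np.vstack([0.5 * veog, -0.2 * veog]), veog)
        out = regress_ocular(rec)
        assert np.abs(out.data[:2]).max() < 1e-9
        np.testing.assert_array_equal(out.data[2], veog)  # EOG untouched

    def test_orthogonal_channel_unchanged(self):
        n = 1000
        t = np.arange(n)
        veog = np.sin(2 * np.pi * t / 50)
        ortho = np.cos(2 * np.pi * t / 50)  # zero inner product over full cycles
        rec = recording_with_eog(np.vstack([ortho, 0 * t]), veog)
        out = regress_ocular(rec)
        np.testing.assert_allclose(out.data[0], ortho, atol=1e-9)

    def test_blink_amplitude_reduced(self, montage, trials_factory):
        trials = classify_trials(trials_factory([("go", 400.0, None)] * 3))
        noise = NoiseSpec(background_rms=1.0, blink_rate=30.0,
                          blink_amplitude=200.0, blink_propagation=0.3)
        rec = synthesize_recording(trials, montage, [], noise, seed=2)
        front = rec.channel_labels.index("Fpz")
        before = np.abs(rec.data[front]).max()
        assert before > 20.0  # blinks actually reached the frontal site
        out = regress_ocular(rec)
        after = np.abs(out.data[front]).max()
        assert after < 0.1 * before

    def test_missing_eog_channel(self):
        rec = recording_with_eog(np.zeros((2, 10)), np.zeros(10))
        with pytest.raises(ValueError, match="HEOGl"):
            regress_ocular(rec, eog_labels=["HEOGl"])


class TestEpoching:
    @pytest.mark.parametrize("lock,window,n_samples", [
        ("stimulus", (-100.0, 800.0), 450),
        ("response", (-100.0, 600.0), 350),
        ("response", (-100.0, 300.0), 200),  # decoding epoch: 40 x 5 samples
    ])
    def test_sample_counts(self, montage, trials_factory, lock, window, n_samples):
        trials = classify_trials(trials_factory([("go", 420.0, None)] * 2))
        rec = synthesize_recording(trials, montage, [], QUIET, seed=0)
        ep = extract_epochs(rec, lock, window, trials)
        assert ep.data.shape[2] == n_samples
        assert ep.times[0] == window[0]

    def test_edge_epoch_flagged_not_dropped(self, montage):
        trials = classify_trials(make_trials([("go", 420.0, None)] * 2))
        trials.loc[0, "stimulus_onset_ms"] = 30.0  # window would start < 0
        rec = synthesize_recording(trials, montage, [], QUIET, seed=0)
        ep = extract_epochs(rec, "stimulus", (-100.0, 800.0), trials)
        assert ep.qc[0] == "rejected:edge"
        assert ep.qc[1] == "kept"
        assert len(ep.qc) == 2

    def test_baseline_mean_is_zero(self, montage, trials_factory):
        trials = classify_trials(trials_factory([("go", 400.0, None)] * 3))
        rec = synthesize_recording(trials, montage, [],
                                   NoiseSpec(background_rms=8.0, blink_rate=0.0),
                                   seed=1)
        ep = extract_epochs(rec, "stimulus", (-100.0, 800.0), trials)
        bl = (ep.times >= -100.0) & (ep.times < 0.0)
        means = ep.data[ep.kept][:, :, bl].mean(axis=2)
        np.testing.assert_allclose(means, 0.0, atol=1e-9)

    def test_response_lock_skips_trials_without_press(self, montage, trials_factory):
        trials = classify_trials(trials_factory([("go", 420.0, None),
                                                 ("go", None, None),
                                                 ("nogo", 350.0, 1500.0)]))
        rec = synthesize_recording(trials, montage, [], QUIET, seed=0)
        ep = extract_epochs(rec, "response", (-100.0, 600.0), trials)
        assert ep.labels == ["correct_go", "detected_error"]

    def test_unclassified_trials_rejected(self, montage, trials_factory):
        trials = trials_factory([("go", 420.0, None)])
        rec = synthesize_recording(classify_trials(trials), montage, [], QUIET, seed=0)
        with pytest.raises(ValueError, match="classified"):
            extract_epochs(rec, "stimulus", (-100.0, 800.0), trials)


class TestArtifactRejection:
    @pytest.mark.parametrize("peak,expected", [
        (151.0, "rejected:amplitude"),
        (150.0, "kept"),      # threshold read strictly: touching 150 passes
        (0.0, "kept"),
        (-151.0, "rejected:amplitude"),
    ])
    def test_threshold_boundary(self, peak, expected):
        data = np.zeros((1, 2, 50))
        data[0, 0, 10] = peak
        ep = make_epochs(data, checked=False)
        out = reject_artifacts(ep, threshold=150.0)
        assert out.qc[0] == expected

    def test_kept_data_bitwise_identical(self):
        rng = np.random.default_rng(3)
        data = rng.normal(scale=30.0, size=(5, 3, 40))
        ep = make_epochs(data.copy(), checked=False)
        out = reject_artifacts(ep, threshold=150.0)
        assert np.array_equal(out.data, data)

    def test_eog_channels_not_screened(self):
        data = np.zeros((1, 2, 10))
        data[0, 1, 0] = 500.0
        ep = make_epochs(data, checked=False)
        ep.channel_kinds[1] = "eog"
        assert reject_artifacts(ep, 150.0).qc[0] == "kept"

    def test_refuses_csd_data(self, montage):
        data = np.zeros((1, len(montage.labels), 10))
        ep = make_epochs(data, channel_labels=list(montage.labels), checked=True)
        csd = csd_transform(ep, montage)
        with pytest.raises(UnitsError):
            reject_artifacts(csd, 150.0)


class TestCsd:
    def make(self, montage, data, checked=True):
        return make_epochs(data, channel_labels=list(montage.labels),
                           checked=checked)

    def test_constant_potential_maps_to_zero(self, montage):
        n = len(montage.labels)
        ep = self.make(montage, np.full((1, n, 5), 7.3))
        out = csd_transform(ep, montage)
        assert np.abs(out.data).max() < 1e-6 * 7.3
        assert out.units == "uV/m2" and out.csd_applied

    def test_rereferencing_invariance(self, montage):
        n = len(montage.labels)
        rng = np.random.default_rng(0)
        X = rng.normal(scale=10.0, size=(1, n, 8))
        shift = rng.normal(size=8)  # arbitrary per-sample reference shift
        a = csd_transform(self.make(montage, X), montage).data
        b = csd_transform(self.make(montage, X + shift), montage).data
        np.testing.assert_allclose(a, b, atol=1e-9 * np.abs(a).max())

    def test_linearity(self, montage):
        n = len(montage.labels)
        rng = np.random.default_rng(1)
        X, Y = rng.normal(size=(2, 1, n, 4))
        f = lambda Z: csd_transform(self.make(montage, Z), montage).data
        np.testing.assert_allclose(f(2.0 * X + 3.0 * Y), 2.0 * f(X) + 3.0 * f(Y),
                                   atol=1e-9 * np.abs(f(X)).max())

    def test_degree2_spherical_harmonic_eigenvalue(self, montage):
        # surface Laplacian of Y_2 on a sphere of radius r is l(l+1)/r^2 * Y_2;
        # small lambda isolates the interpolant from the regularizer
        P = montage.positions
        y = 3.0 * P[:, 2] ** 2 - 1.0
        ep = self.make(montage, np.tile(y[:, None], (1, 2))[None])
        params = CsdParams(m=4, legendre_terms=50, lam=1e-6, head_radius=0.09)
        out = csd_transform(ep, montage, params).data[0, :, 0]
        expected = 6.0 * y / 0.09 ** 2
        interior = P[:, 2] > 0.2
        err = np.abs(out[interior] - expected[interior]) / np.abs(expected).max()
        assert err.max() < 0.02

    def test_matches_mne_implementation(self, montage):
        mne = pytest.importorskip("mne")
        n = len(montage.labels)
        rng = np.random.default_rng(5)
        X = rng.normal(scale=10.0, size=(2, n, 10))
        ours = csd_transform(self.make(montage, X), montage,
                             CsdParams(4, 50, 1e-5, 0.09)).data
        info = mne.create_info(list(montage.labels), 500.0, "eeg")
        dig = mne.channels.make_dig_montage(
            ch_pos={lab: p * 0.09 for lab, p in zip(montage.labels,
                                                    montage.positions)},
            coord_frame="head")
        epo = mne.EpochsArray(X * 1e-6, info, verbose="error")
        epo.set_montage(dig)
        theirs = mne.preprocessing.compute_current_source_density(
            epo, sphere=(0.0, 0.0, 0.0, 0.09), lambda2=1e-5, stiffness=4,
            verbose="error").get_data() * 1e6
        np.testing.assert_allclose(ours, theirs, rtol=1e-8,
                                   atol=1e-8 * np.abs(theirs).max())

    def test_order_enforced(self, montage):
        n = len(montage.labels)
        ep = self.make(montage, np.zeros((1, n, 5)), checked=False)
        with pytest.raises(PipelineOrderError, match="reject_artifacts"):
            csd_transform(ep, montage)
        checked = reject_artifacts(ep, 150.0)
        once = csd_transform(checked, montage)
        with pytest.raises(PipelineOrderError, match="already"):
            csd_transform(once, montage)

    def test_duplicate_positions_singular(self, montage):
        import copy
        bad = copy.deepcopy(montage)
        bad.positions[1] = bad.positions[0]
        n = len(montage.labels)
        ep = self.make(montage, np.zeros((1, n, 5)))
        with pytest.raises(np.linalg.LinAlgError, match="duplicate"):
            csd_transform(ep, bad)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            CsdParams(m=1).validate()
        with pytest.raises(ValueError):
            CsdParams(legendre_terms=5).validate()
        with pytest.raises(ValueError):
            CsdParams(lam=-1.0).validate()
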