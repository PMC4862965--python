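"""Preprocessing: saccade masking, QC, SSP artefact removal, SVD screen."""

import numpy as np
import pytest

from pursuitdcm.preprocessing import (
    SensorEpochs,
    average_and_normalize,
    cycle_qc,
    epoch_baseline_average,
    reduce_to_modes,
    regress_out_eye_artefact,
    remove_saccades,
    subject_svd_screen,
)


def make_epochs(rng, n_ch=16, n_t=81, n_tr=10):
    times = np.linspace(-300, 500, n_t)
    labels = np.array(["smooth"] * (n_tr // 2) + ["noisy"] * (n_tr - n_tr // 2))
    data = rng.normal(size=(n_ch, n_t, n_tr))
    eye = rng.normal(size=(n_t, n_tr))
    return SensorEpochs(data, times, labels, eye)


class TestRemoveSaccades:
    def test_subthreshold_series_untouched(self):
        v = np.sin(np.linspace(0, 6, 100)) * 20.0
        out, mask = remove_saccades(v)
        assert not mask.any()
        assert np.array_equal(out, v)

    def test_spike_masked_exactly(self):
        v = np.full(50, 5.0)
        v[20:24] = 100.0
        out, mask = remove_saccades(v)
        assert mask.sum() == 4
        assert np.isnan(out[20:24]).all()
        assert np.array_equal(out[:20], v[:20])

    def test_masked_fraction_matches_injected_saccades(self, rng):
        v = rng.normal(0, 5, 2000)
        starts = [100, 700, 1500]
        dur = 30
        for s in starts:
            v[s:s + dur] = 80.0
        _, mask = remove_saccades(v)
        injected = len(starts) * dur
        assert abs(mask.sum() - injected) <= len(starts)


class TestCycleQC:
    def test_perfect_tracking_keeps_all(self):
        t = np.linspace(0, 4 * np.pi, 400)
        eye = np.cos(t)
        table = cycle_qc(eye, eye, rmse_threshold=0.1, cycle_len=200)
        assert not table["flagged"].any()
        assert np.allclose(table["rmse"], 0.0)

    def test_constant_offset_gives_rmse_equal_to_offset(self):
        eye = np.zeros(300) + 0.25
        tgt = np.zeros(300)
        table = cycle_qc(eye, tgt, rmse_threshold=0.2, cycle_len=100)
        assert np.allclose(table["rmse"], 0.25)
        assert table["flagged"].all()

    def test_flagged_fraction_matches_injected_corruption(self, rng):
        n_cycles, m = 200, 50
        tgt = np.tile(np.cos(np.linspace(0, 2 * np.pi, m)), n_cycles)
        eye = tgt + rng.normal(0, 0.01, n_cycles * m)
        bad = rng.choice(n_cycles, size=10, replace=False)
        for c in bad:
            eye[c * m:(c + 1) * m] += 1.0
        table = cycle_qc(eye, tgt, rmse_threshold=0.5, cycle_len=m)
        assert set(table.index[table["flagged"]]) == set(bad)


class TestAverageAndNormalize:
    def test_identical_cycles_return_rescaled_cycle(self):
        tgt = 2.0 * np.cos(np.linspace(0, 2 * np.pi, 60))
        eye = tgt * 0.9
        out = average_and_normalize(np.tile(eye, (5, 1)),
                                    np.tile(tgt, (5, 1)))
        assert np.max(np.abs(out["target"])) == pytest.approx(1.0)
        assert np.allclose(out["eye"], out["target"] * 0.9)

    def test_antiphase_artefacts_cancel(self):
        base = np.cos(np.linspace(0, 2 * np.pi, 60))
        art = np.sin(np.linspace(0, 6 * np.pi, 60))
        eye = np.stack([base + art, base - art])
        tgt = np.tile(base, (2, 1))
        out = average_and_normalize(eye, tgt)
        assert np.allclose(out["eye"], out["target"], atol=1e-12)

    def test_average_variance_shrinks_as_one_over_n(self, rng):
        base = np.cos(np.linspace(0, 2 * np.pi, 80))
        n = 50
        single_var = []
        avg_var = []
        for _ in range(40):
            cycles = base + rng.normal(0, 0.3, (n, 80))
            single_var.append(np.var(cycles[0] - base))
            out = average_and_normalize(cycles, np.tile(base, (n, 1)))
            avg_var.append(np.var(out["eye"] - base))
        ratio = np.mean(avg_var) / np.mean(single_var)
        assert ratio == pytest.approx(1.0 / n, rel=0.2)


class TestEyeArtefactRemoval:
    def test_rank_one_leakage_removed_signal_kept(self, rng):
        n_ch, n_t, n_tr = 24, 120, 12
        times = np.linspace(-300, 500, n_t)
        eye = np.cos(np.linspace(0, 2 * np.pi, n_t))
        topo = rng.normal(size=n_ch)
        topo /= np.linalg.norm(topo)
        # orthogonal signal topography
        sig_topo = rng.normal(size=n_ch)
        sig_topo -= sig_topo @ topo * topo
        sig_topo /= np.linalg.norm(sig_topo)
        sig_t = np.sin(np.linspace(0, 4 * np.pi, n_t))
        data = np.zeros((n_ch, n_t, n_tr))
        for j in range(n_tr):
            data[:, :, j] = (3.0 * np.outer(topo, eye)
                             + np.outer(sig_topo, sig_t))
        epochs = SensorEpochs(
            data, times, np.array(["smooth"] * n_tr),
            np.tile(eye[:, None], (1, n_tr)),
        )
        cleaned, u = regress_out_eye_artefact(epochs)
        leak_before = np.sum((topo @ data.reshape(n_ch, -1)) ** 2)
        leak_after = np.sum((topo @ cleaned.data.reshape(n_ch, -1)) ** 2)
        assert leak_after < 0.01 * leak_before
        sig_before = np.outer(sig_topo, sig_t)
        sig_after = np.tensordot(sig_topo, cleaned.data, axes=(0, 0))
        err = np.sqrt(np.mean((sig_after[:, 0] - sig_t) ** 2))
        assert err < 0.05 * np.sqrt(np.mean(sig_t**2))

    def test_no_leakage_is_identity(self, rng):
        epochs = make_epochs(rng)
        # eye orthogonal to every channel on average: regression slope ~ 0
        epochs.eye = np.tile(
            np.cos(np.linspace(0, 2 * np.pi, len(epochs.times)))[:, None],
            (1, epochs.data.shape[2]))
        epochs.data[:] = 1e-3  # constant channels: zero covariance
        cleaned, _ = regress_out_eye_artefact(epochs)
        assert np.allclose(cleaned.data, epochs.data, atol=1e-12)

    def test_projection_is_idempotent(self, rng):
        epochs = make_epochs(rng)
        once, u1 = regress_out_eye_artefact(epochs)
        twice, _ = regress_out_eye_artefact(
            SensorEpochs(once.data, once.times, once.labels,
                         np.tile(epochs.eye.mean(axis=1, keepdims=True),
                                 (1, epochs.data.shape[2]))))
        # projecting the same component again changes nothing
        proj = once.data - np.einsum(
            "c,ctn->tn", u1, once.data)[None] * u1[:, None, None]
        assert np.allclose(proj, once.data, atol=1e-10)

    def test_degenerate_eye_rejected(self, rng):
        epochs = make_epochs(rng)
        epochs.eye[:] = 0.7
        with pytest.raises(ValueError):
            regress_out_eye_artefact(epochs)


class TestSubjectSVDScreen:
    def test_identical_subjects_give_no_outliers(self):
        topo = np.linspace(-1, 1, 30)
        M = np.tile(topo[:, None], (1, 17))
        out = subject_svd_screen(M)
        assert not out["outliers"].any()
        assert np.allclose(out["projection"], out["projection"][0],
                           atol=1e-9)

    def test_three_planted_outliers_flagged_exactly(self, rng):
        n_ch, n_sub = 48, 17
        common = rng.normal(size=n_ch)
        M = (common[:, None]
             + 0.05 * rng.normal(size=(n_ch, n_sub)))
        distinct = rng.normal(size=n_ch)
        distinct -= distinct @ common / (common @ common) * common
        bad = [3, 9, 14]
        for j in bad:
            M[:, j] += 1.5 * distinct
        out = subject_svd_screen(M)
        assert set(np.where(out["outliers"])[0]) == set(bad)

    def test_projection_preserves_gram_structure(self, rng):
        M = rng.normal(size=(20, 8))
        norms = np.sqrt((M**2).sum(axis=0))
        Mn = M / norms
        Mn = Mn - Mn.mean(axis=1, keepdims=True)
        out = subject_svd_screen(M)
        P = out["projection"]
        assert np.allclose(P @ P.T, Mn.T @ Mn, atol=1e-10)


class TestEpochBaselineAverage:
    def test_constant_offset_channel_zeroed(self, rng):
        epochs = make_epochs(rng)
        epochs.data[3, :, :] = 7.7
        out = epoch_baseline_average(epochs)
        assert np.allclose(out["smooth"][3], 0.0, atol=1e-12)

    def test_baseline_window_mean_is_zero(self, rng):
        epochs = make_epochs(rng)
        out = epoch_baseline_average(epochs)
        sel = (epochs.times >= -300) & (epochs.times <= 0)
        for cond in out:
            assert np.allclose(out[cond][:, sel].mean(axis=1), 0.0,
                               atol=1e-12)

    def test_evoked_component_recovered_within_noise(self, rng):
        n_ch, n_t, n_tr = 8, 81, 200
        times = np.linspace(-300, 500, n_t)
        evoked = np.zeros(n_t)
        evoked[(times >= 0) & (times <= 200)] = 1.0
        data = rng.normal(0, 1.0, (n_ch, n_t, n_tr))
        data[0] += evoked[:, None]
        epochs = SensorEpochs(data, times,
                              np.array(["smooth"] * n_tr),
                              rng.normal(size=(n_t, n_tr)))
        out = epoch_baseline_average(epochs)
        window = (times > 0) & (times < 200)
        amp = out["smooth"][0, window].mean()
        # demeaning/baselining shifts the square wave; compare contrast
        contrast = amp - out["smooth"][0, ~window].mean()
        assert contrast == pytest.approx(1.0, abs=4.0 / np.sqrt(n_tr))


def test_sensor_epochs_roundtrip_via_delimited_dir(tmp_path, rng):
    epochs = make_epochs(rng, n_ch=6, n_t=21, n_tr=4)
    epochs.save_dir(tmp_path / "epochs")
    back = SensorEpochs.load_dir(tmp_path / "epochs")
    assert np.allclose(back.data, epochs.data)
    assert np.allclose(back.times, epochs.times)
    assert np.allclose(back.eye, epochs.eye)
    assert list(back.labels) == list(epochs.labels)


class TestReduceToModes:
    def test_rank_three_data_lossless_with_eight_modes(self, rng):
        U = np.linalg.qr(rng.normal(size=(32, 3)))[0]
        ts = rng.normal(size=(3, 100))
        evoked = U @ ts
        out = reduce_to_modes(evoked, n_modes=8)
        recon = out["projector"] @ out["modes"]
        assert np.sqrt(np.mean((recon - evoked) ** 2)) < 1e-10

    def test_retained_variance_nondecreasing_in_modes(self, rng):
        evoked = rng.normal(size=(32, 100))
        fracs = [reduce_to_modes(evoked, k)["retained_variance"]
                 for k in (1, 2, 4, 8, 16)]
        assert np.all(np.diff(fracs) >= 0)

    def test_window_extraction(self, rng):
        times = np.arange(-100, 301, 10.0)
        evoked = rng.normal(size=(16, len(times)))
        out = reduce_to_modes(evoked, 4, times=times)
        assert out["times"][0] >= 0 and out["times"][-1] <= 200
        assert out["modes"].shape == (4, len(out["times"]))
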