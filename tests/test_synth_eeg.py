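"""Synthetic-EEG generator: montage geometry, power scaling, attention
symmetry, entrainment pull and behavioural model."""

import numpy as np
import pytest

from alphakit import alpha_metrics as am
from alphakit import spectral, stimgen, synth_eeg
from alphakit.synth_eeg import (SubjectParams, make_cohort,
                                make_symmetric_montage, simulate_behavior,
                                simulate_peri, simulate_recording)


def _cluster_band_power_db(rec, idx, lo, hi):
    ps = spectral.power_spectrum(spectral.epoch_data(rec))
    db = spectral.to_log_power(ps)
    sel = (db.freqs >= lo) & (db.freqs <= hi)
    return db.values[idx][:, sel].mean()


# ---------------------------------------------------------------- montage

def test_montage_positions_unit_norm_and_mirrored():
    m = make_symmetric_montage(32)
    np.testing.assert_allclose(np.linalg.norm(m.pos, axis=1), 1.0, atol=1e-9)
    n_half = 16
    right, left = m.pos[:n_half], m.pos[n_half:2 * n_half]
    np.testing.assert_allclose(left, right * [-1, 1, 1], atol=1e-12)


def test_montage_clusters_disjoint_and_symmetric():
    m = make_symmetric_montage(64)
    assert not set(m.left_cluster) & set(m.right_cluster)
    li, ri = m.cluster_indices("left"), m.cluster_indices("right")
    np.testing.assert_allclose(m.pos[li], m.pos[ri] * [-1, 1, 1], atol=1e-12)
    # clusters sit over posterior scalp
    assert np.all(m.pos[li][:, 1] < 0)


def test_montage_sfp_export(tmp_path):
    m = make_symmetric_montage(16)
    path = tmp_path / "montage.sfp"
    m.to_sfp(path)
    lines = path.read_text().strip().split("\n")
    assert len(lines) == 16
    lab, x, y, z = lines[0].split("\t")
    assert lab == m.labels[0]
    assert np.isclose(float(x) ** 2 + float(y) ** 2 + float(z) ** 2, 1.0, atol=1e-4)


def test_subject_params_invariants():
    with pytest.raises(ValueError):
        SubjectParams(iaf_true=5.0)
    with pytest.raises(ValueError):
        SubjectParams(alpha_amp=-1.0)
    with pytest.raises(ValueError):
        SubjectParams(entrain_coupling=-0.1)


# ------------------------------------------------------------- recordings

@pytest.fixture(scope="module")
def alpha_trials():
    return [stimgen.make_trial("alpha", "left" if i % 2 else "right", seed=300 + i)
            for i in range(12)]


def test_recording_determinism(montage16, alpha_trials):
    sub = SubjectParams(iaf_true=10.0)
    a = simulate_recording(sub, alpha_trials[:3], montage16, fs=256, seed=5)
    b = simulate_recording(sub, alpha_trials[:3], montage16, fs=256, seed=5)
    np.testing.assert_array_equal(a.data, b.data)


def test_symmetric_null_has_balanced_cluster_power(montage16, cluster_idx,
                                                   alpha_trials):
    # no attention effect, no drive: left/right alpha power equal within
    # sampling error
    sub = SubjectParams(iaf_true=10.0, alpha_amp=3.0, attn_modulation=0.0,
                        drive_snr=0.0)
    diffs = []
    for seed in range(6):
        rec = simulate_recording(sub, alpha_trials, montage16, fs=256, seed=seed)
        l = _cluster_band_power_db(rec, cluster_idx["left"], 8, 12)
        r = _cluster_band_power_db(rec, cluster_idx["right"], 8, 12)
        diffs.append(l - r)
    assert abs(np.mean(diffs)) < 0.5


def test_attention_modulation_lateralizes_power(montage16, cluster_idx):
    # attending left suppresses the contralateral (right-hemisphere) alpha
    sub = SubjectParams(iaf_true=10.0, alpha_amp=4.0, attn_modulation=3.0,
                        drive_snr=0.0)
    trials = [stimgen.make_trial("alpha", "left", seed=400 + i) for i in range(10)]
    rec = simulate_recording(sub, trials, montage16, fs=256, seed=2)
    l = _cluster_band_power_db(rec, cluster_idx["left"], 8, 12)
    r = _cluster_band_power_db(rec, cluster_idx["right"], 8, 12)
    assert l - r > 2.0


def test_power_conservation_doubling_amplitude(montage16, cluster_idx,
                                               alpha_trials):
    # noise-free: doubling alpha_amp raises cluster alpha power by 6.02 dB
    kw = dict(iaf_true=10.0, attn_modulation=0.0, drive_snr=0.0, noise_scale=0.0)
    r1 = simulate_recording(SubjectParams(alpha_amp=2.0, **kw),
                            alpha_trials[:6], montage16, fs=256, seed=9)
    r2 = simulate_recording(SubjectParams(alpha_amp=4.0, **kw),
                            alpha_trials[:6], montage16, fs=256, seed=9)
    p1 = _cluster_band_power_db(r1, cluster_idx["left"], 8, 12)
    p2 = _cluster_band_power_db(r2, cluster_idx["left"], 8, 12)
    assert p2 - p1 == pytest.approx(20 * np.log10(2), abs=0.1)


def test_recording_requires_trials_and_valid_fs(montage16, alpha_trials):
    with pytest.raises(ValueError):
        simulate_recording(SubjectParams(), [], montage16)
    with pytest.raises(ValueError):
        simulate_recording(SubjectParams(), alpha_trials[:1], montage16, fs=128)


# ------------------------------------------------------------------ peri

def test_peri_segmentation_feasibility(montage16):
    # 16 segments of 6 s = 96 s -> 191 one-second epochs at 0.5-s overlap,
    # comfortably above the >=102 epochs retained per participant
    rec = simulate_peri(SubjectParams(), 96.0, montage16, fs=256, seed=0)
    ep = spectral.epoch_data(rec, "peri")
    assert rec.duration == 96.0
    assert ep.n_epochs == 191
    assert ep.n_epochs >= 102


def test_peri_rejects_short_segments(montage16):
    with pytest.raises(ValueError):
        simulate_peri(SubjectParams(), 3.0, montage16)


def test_peri_no_alpha_gives_no_peak(montage16, both_clusters):
    rec = simulate_peri(SubjectParams(iaf_true=10.0, alpha_amp=0.0), 30.0,
                        montage16, fs=256, seed=1)
    ps = spectral.power_spectrum(spectral.epoch_data(rec, "peri"))
    iaf = am.detect_iaf(ps, both_clusters, 6.0, 14.0)
    # either nothing, or a curvature blip well away from a real peak's
    # prominence: check the raw spectrum has no prominent 6-14 Hz peak
    p = ps.mean_over(both_clusters)
    sel = (ps.freqs >= 6) & (ps.freqs <= 14)
    flank = (ps.freqs >= 3) & (ps.freqs < 6)
    assert p[sel].max() < 3 * np.median(p[flank])


def test_peri_strong_alpha_argmax_matches_truth(montage16, both_clusters):
    # direct FFT oracle: raw-spectrum argmax in 8-12 Hz equals iaf_true ± 0.5
    rec = simulate_peri(SubjectParams(iaf_true=10.0, alpha_amp=5.0), 30.0,
                        montage16, fs=256, seed=3)
    ps = spectral.power_spectrum(spectral.epoch_data(rec, "peri"))
    p = ps.mean_over(both_clusters)
    sel = (ps.freqs >= 8) & (ps.freqs <= 12)
    f_peak = ps.freqs[sel][np.argmax(p[sel])]
    assert abs(f_peak - 10.0) <= 0.5


# ----------------------------------------------------------- entrainment

def test_adler_coupling_pulls_downstream_iaf(montage16, both_clusters):
    """Alpha-band stimulation with strong phase coupling pulls the measured
    IAF toward the stimulation centre (10.5 Hz) by at least one grid step."""
    trials = [stimgen.make_trial("alpha", "left" if i % 2 else "right",
                                 seed=500 + i) for i in range(20)]

    def downstream_iaf(eps, seed):
        sub = SubjectParams(iaf_true=9.0, alpha_amp=3.0, drive_snr=0.5,
                            entrain_coupling=eps)
        rec = simulate_recording(sub, trials, montage16, fs=256, seed=seed)
        ps = spectral.power_spectrum(
            spectral.scalp_current_density(spectral.epoch_data(rec)))
        return am.detect_iaf(ps, both_clusters)

    free = downstream_iaf(0.0, seed=4)
    locked = downstream_iaf(2 * np.pi * 1.5, seed=4)
    assert free == pytest.approx(9.0, abs=0.5)
    assert locked - free >= 0.5


def test_adler_mean_frequency_matches_phase_equation_oracle():
    """The generator's phase integration reproduces the Adler-equation
    prediction: a constant drive within the locking range enslaves the
    oscillator's mean instantaneous frequency."""
    fs, dur = 512.0, 20.0
    n = int(fs * dur)
    f_drive, iaf, eps = 10.0, 9.0, 2 * np.pi * 1.5
    stim_phase = 2 * np.pi * f_drive * np.arange(n) / fs
    phi = synth_eeg._integrate_adler(iaf, np.array([eps]),
                                     stim_phase[None, :], np.array([0.0]), fs)[0]
    # independent oracle: dense RK-style integration of the same ODE
    t = np.arange(n) / fs
    phi_o = np.zeros(n)
    for k in range(1, n):
        mid = phi_o[k - 1] + 0.5 / fs * (2 * np.pi * iaf + eps * np.sin(
            2 * np.pi * f_drive * t[k - 1] - phi_o[k - 1]))
        phi_o[k] = phi_o[k - 1] + 1 / fs * (2 * np.pi * iaf + eps * np.sin(
            2 * np.pi * f_drive * (t[k - 1] + 0.5 / fs) - mid))
    f_mean = (phi[-1] - phi[n // 2]) / (2 * np.pi * (dur / 2))
    f_mean_o = (phi_o[-1] - phi_o[n // 2]) / (2 * np.pi * (dur / 2))
    # detuning (1 Hz) < locking range (1.5 Hz): both lock onto the drive
    assert f_mean == pytest.approx(f_drive, abs=0.05)
    assert f_mean == pytest.approx(f_mean_o, abs=0.05)


# ------------------------------------------------------------- behaviour

def test_behavior_null_slope_recovery():
    subs = [SubjectParams(behavior_slope=0.0) for _ in range(17)]
    rng = np.random.default_rng(0)
    iap_z = rng.standard_normal(17)
    acc = simulate_behavior(subs, iap_z, seed=1)
    assert np.all((acc > 0) & (acc < 1))
    beta = np.polyfit(iap_z, np.log(acc / (1 - acc)), 1)
    se = 0.3 / np.sqrt(np.sum((iap_z - iap_z.mean()) ** 2))
    assert abs(beta[0]) <= 2 * se + 0.2


def test_behavior_saturates_with_large_intercept():
    subs = [SubjectParams(behavior_intercept=30.0) for _ in range(5)]
    acc = simulate_behavior(subs, np.zeros(5), seed=0)
    assert np.all(acc > 0.999)


def test_behavior_negative_slope_recovered_by_robust_fit():
    """With the generator slope set to -0.664 and low noise, the robust fit
    recovers it within its bootstrapped 95% CI in most replications."""
    from alphakit import stats
    hits = 0
    n_rep = 40
    for seed in range(n_rep):
        subs = [SubjectParams(behavior_slope=-0.664) for _ in range(16)]
        rng = np.random.default_rng(100 + seed)
        iap_z = rng.standard_normal(16)
        acc = simulate_behavior(subs, iap_z, seed=seed, noise_sd=0.15)
        y = np.log(acc / (1 - acc))
        ci = stats.bca_bootstrap_ci(
            lambda a, b, axis=-1: stats.robust_line(a, b)[1],
            (iap_z, y), n_boot=600, seed=seed, vectorized=True)
        hits += ci[0] <= -0.664 <= ci[1]
    assert hits / n_rep >= 0.9


def test_make_cohort_bounds_and_determinism():
    c1 = make_cohort(17, seed=3)
    c2 = make_cohort(17, seed=3)
    assert all(8.0 <= s.iaf_true <= 13.0 for s in c1)
    assert [s.iaf_true for s in c1] == [s.iaf_true for s in c2]
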