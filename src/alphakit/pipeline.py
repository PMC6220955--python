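"""End-to-end study orchestration on synthetic cohorts.

``run_study`` wires the full chain — stimulus synthesis → synthetic EEG →
epoching/SCD/spectra → alpha metrics → inference battery — and returns a
:class:`StudyReport` whose every number is traceable to the config seed.
Two regimes matter: the null regime (no entrainment coupling), in which
attention modulates alpha but stimulation frequency must not; and the
counterfactual (coupling on in the alpha condition), in which the IAF is
pulled toward the 10.5-Hz centre of the alpha-band stimulation.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from . import alpha_metrics as am
from . import spectral, stats, stimgen, synth_eeg

__all__ = ["StudyConfig", "StudyReport", "run_study", "compare_regression_tables"]

#: centre frequency of the alpha-band stimulation, Hz
ALPHA_STIM_CENTRE = 10.5


@dataclass
class StudyConfig:
    """All knobs of a simulated study; defaults mirror the emulated design."""

    n_subjects: int = 17
    conditions: tuple = ("theta", "alpha", "beta")
    trials_per_cell: int = 48          # per condition × attended side
    rejection_rate: float = 0.25       # simulated artifact rejection
    fs: float = 512.0
    n_channels: int = 128
    cluster_size: int | None = None
    peri_duration: float = 96.0        # 16 segments of 6 s
    # generator parameters
    attn_modulation: float = 2.0       # dB
    drive_snr: float = 0.5
    entrain_coupling: float = 0.0      # rad/s
    entrain_conditions: tuple = ("alpha",)
    behavior_slope: float = 0.0
    # analysis constants
    alpha_band: tuple = (8.0, 12.0)
    iap_halfwidth: float = 1.0
    iaf_search: tuple = (6.0, 14.0)
    n_perm: int = 1000
    cluster_alpha: float = 0.05
    n_boot: int = 10_000
    n_mc: int = 100_000
    r_fixed: float = 0.5
    run_cluster_test: bool = True
    run_bootstrap_cis: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("conditions", "entrain_conditions", "alpha_band", "iaf_search"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        import yaml
        d = asdict(self)
        for key in ("conditions", "entrain_conditions", "alpha_band", "iaf_search"):
            d[key] = list(d[key])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


@dataclass
class StudyReport:
    """All study-level results plus provenance."""

    profiles: pd.DataFrame              # subject × condition alpha observables
    anova: stats.AnovaResult
    bayes: stats.BayesAnovaResult
    cluster: stats.ClusterTestResult | None
    regressions: dict                   # (measure, condition) -> RegressionFit
    slope_differences: dict             # (measure, cond_a, cond_b) -> dict
    friedman: stats.FriedmanResult
    behavior: dict                      # condition -> RegressionFit (logit acc ~ IAP z)
    behavior_lat: dict                  # condition -> RegressionFit (~ lateralization z)
    iaf_pull: pd.DataFrame              # per subject: |IAF−10.5| peri + per band
    n_no_peak: int
    config: StudyConfig
    seed: int

    def save(self, out_dir) -> None:
        from pathlib import Path
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.profiles.to_csv(out / "alpha_profiles.csv", index=False)
        self.anova.to_frame().to_csv(out / "anova.csv", index=False)
        self.iaf_pull.to_csv(out / "iaf_distances.csv", index=False)
        compare_regression_tables(self).to_csv(out / "regression_table.csv",
                                               index=False)
        summary = {
            "seed": self.seed,
            "n_no_peak": self.n_no_peak,
            "friedman": asdict(self.friedman),
            "bayes": {k: {"bf10": v.bf10, "mc_error_pct": v.mc_error_pct}
                      for k, v in self.bayes.effects.items()},
            "cluster_min_p": self.cluster.min_p if self.cluster else None,
        }
        with open(out / "report.json", "w") as fh:
            json.dump(summary, fh, indent=2)


def _attend_topographies(spectra_db: dict, band: tuple, freqs: np.ndarray,
                         conditions: tuple) -> dict:
    """Per attended side, channel topography of mean dB power in ``band``
    pooled over stimulation conditions."""
    sel = (freqs >= band[0] - 1e-9) & (freqs <= band[1] + 1e-9)
    out = {}
    for side in ("left", "right"):
        maps = [spectra_db[(cond, side)][:, sel].mean(axis=1)
                for cond in conditions if (cond, side) in spectra_db]
        out[side] = np.mean(maps, axis=0)
    return out


def _subject_analysis(subject, montage, config, seed_seq):
    """Simulate and decompose one subject; return spectra and metrics inputs."""
    s_trials, s_rec, s_peri, s_rej = seed_seq.spawn(4)
    trial_rng = np.random.default_rng(s_trials.generate_state(1)[0] % 2**31)
    rej_rng = np.random.default_rng(s_rej.generate_state(1)[0] % 2**31)

    trials = []
    for cond in config.conditions:
        for side in ("left", "right"):
            n_cell = config.trials_per_cell
            events = stimgen.place_events(
                n_cell, seed=int(trial_rng.integers(2**31)))
            kept = []
            for k in range(n_cell):
                if k >= 2 and rej_rng.random() < config.rejection_rate:
                    continue      # simulated artifact rejection
                kept.append(k)
            # guarantee two analysable (event-free) trials per cell
            for k in kept[:2]:
                events[k] = []
            for k in kept:
                trials.append(stimgen.make_trial(
                    cond, side, seed=int(trial_rng.integers(2**31)),
                    events=events[k]))
    rec = synth_eeg.simulate_recording(
        subject, trials, montage, fs=config.fs,
        seed=int(s_rec.generate_state(1)[0] % 2**31),
        entrain_conditions=config.entrain_conditions)
    epochs = spectral.scalp_current_density(spectral.epoch_data(rec, "during"))

    spectra_raw, spectra_db = {}, {}
    for cond in config.conditions:
        for side in ("left", "right"):
            mask = (epochs.condition == cond) & (epochs.attended_side == side)
            if not mask.any():
                continue
            ps = spectral.power_spectrum(epochs.select(mask))
            spectra_raw[(cond, side)] = ps
            spectra_db[(cond, side)] = spectral.to_log_power(ps).values

    peri = synth_eeg.simulate_peri(
        subject, config.peri_duration, montage, fs=config.fs,
        seed=int(s_peri.generate_state(1)[0] % 2**31))
    peri_ps = spectral.power_spectrum(
        spectral.scalp_current_density(spectral.epoch_data(peri, "peri")))
    return spectra_raw, spectra_db, peri_ps


def _pooled_spectrum(spectra_raw: dict, cond: str) -> spectral.PowerSpectrum:
    """Average the raw spectra of both attended sides for one condition."""
    pss = [spectra_raw[(cond, s)] for s in ("left", "right")
           if (cond, s) in spectra_raw]
    vals = np.mean([ps.values for ps in pss], axis=0)
    ps0 = pss[0]
    return spectral.PowerSpectrum(freqs=ps0.freqs, values=vals, scale="raw",
                                  channels=ps0.channels,
                                  n_epochs=sum(ps.n_epochs for ps in pss))


def run_study(config: StudyConfig) -> StudyReport:
    """Execute the full simulated experiment and analysis chain."""
    root = np.random.SeedSequence(config.seed)
    s_cohort, s_subjects, s_stats, s_behav = root.spawn(4)
    cohort = synth_eeg.make_cohort(
        config.n_subjects, seed=int(s_cohort.generate_state(1)[0] % 2**31),
        attn_modulation=config.attn_modulation, drive_snr=config.drive_snr,
        entrain_coupling=config.entrain_coupling,
        behavior_slope=config.behavior_slope)
    montage = synth_eeg.make_symmetric_montage(config.n_channels,
                                               config.cluster_size)
    cl_idx = {s: montage.cluster_indices(s) for s in ("left", "right")}
    both_idx = np.concatenate([cl_idx["left"], cl_idx["right"]])

    rows, anova_rows = [], []
    topo = {"left": [], "right": []}
    freqs = None
    subj_seqs = s_subjects.spawn(len(cohort))
    for si, (subject, sseq) in enumerate(zip(cohort, subj_seqs)):
        spectra_raw, spectra_db, peri_ps = _subject_analysis(
            subject, montage, config, sseq)
        freqs = peri_ps.freqs

        maps = _attend_topographies(spectra_db, config.alpha_band, freqs,
                                    config.conditions)
        topo["left"].append(maps["left"])
        topo["right"].append(maps["right"])

        # hemisphere × position × frequency cell means (dB, fixed 8-12 band)
        sel = (freqs >= config.alpha_band[0] - 1e-9) & \
              (freqs <= config.alpha_band[1] + 1e-9)
        for cond in config.conditions:
            for hemi in ("left", "right"):
                for side in ("left", "right"):
                    pos = "contra" if hemi != side else "ipsi"
                    val = spectra_db[(cond, side)][cl_idx[hemi]][:, sel].mean()
                    anova_rows.append({"subject": si, "hemisphere": hemi,
                                       "position": pos, "frequency": cond,
                                       "value": val})

        # IAF / IAP / lateralization per condition (+ peri)
        peri_db = spectral.to_log_power(peri_ps)
        iaf_peri = am.detect_iaf(peri_ps, both_idx, *config.iaf_search)
        iap_peri = (am.compute_iap(peri_db, iaf_peri, both_idx,
                                   config.iap_halfwidth)
                    if iaf_peri is not None else None)
        rows.append({"subject": si, "condition": "peri", "iaf": iaf_peri,
                     "iap": iap_peri, "lateralization": None,
                     "iaf_true": subject.iaf_true})
        for cond in config.conditions:
            ps = _pooled_spectrum(spectra_raw, cond)
            ps_db = spectral.to_log_power(ps)
            iaf = am.detect_iaf(ps, both_idx, *config.iaf_search)
            iap = lat = None
            if iaf is not None:
                iap = am.compute_iap(ps_db, iaf, both_idx, config.iap_halfwidth)
                lats = []
                for side in ("left", "right"):
                    db = spectral.PowerSpectrum(
                        freqs=freqs, values=spectra_db[(cond, side)],
                        scale="db", channels=list(montage.labels))
                    contra = "right" if side == "left" else "left"
                    lats.append(am.lateralization_index(
                        am.compute_iap(db, iaf, cl_idx[contra]),
                        am.compute_iap(db, iaf, cl_idx[side])))
                lat = float(np.mean(lats))
            rows.append({"subject": si, "condition": cond, "iaf": iaf,
                         "iap": iap, "lateralization": lat,
                         "iaf_true": subject.iaf_true})

    profiles = pd.DataFrame(rows)
    anova_df = pd.DataFrame(anova_rows)

    # listwise exclusion of subjects without a detectable peak anywhere
    iaf_wide = profiles.pivot(index="subject", columns="condition", values="iaf")
    complete = iaf_wide.dropna().index.to_numpy()
    n_no_peak = config.n_subjects - complete.size
    iaf_wide = iaf_wide.loc[complete]
    iap_wide = profiles.pivot(index="subject", columns="condition",
                              values="iap").loc[complete]
    lat_wide = profiles.pivot(index="subject", columns="condition",
                              values="lateralization").loc[complete]

    stat_seed = int(s_stats.generate_state(1)[0] % 2**31)
    cluster = None
    if config.run_cluster_test:
        cluster = stats.cluster_permutation_test(
            np.asarray(topo["left"]), np.asarray(topo["right"]), montage,
            n_perm=config.n_perm, cluster_alpha=config.cluster_alpha,
            seed=stat_seed)
    anova = stats.rm_anova_gg(anova_df, within=["hemisphere", "position",
                                                "frequency"])
    bayes = stats.jzs_anova_bf(anova_df,
                               within=["hemisphere", "position", "frequency"],
                               r_fixed=config.r_fixed, n_mc=config.n_mc,
                               seed=stat_seed)

    def zscore(v):
        v = np.asarray(v, dtype=float)
        return (v - v.mean()) / v.std(ddof=1)

    regressions, slope_diffs = {}, {}
    for measure, wide in (("iaf", iaf_wide), ("iap", iap_wide)):
        fits = {}
        for ci_, cond in enumerate(config.conditions):
            x = wide["peri"].to_numpy(dtype=float)
            y = wide[cond].to_numpy(dtype=float)
            if measure == "iaf":        # intercept has no meaning for IAF
                x, y = zscore(x), zscore(y)
            fit = stats.robust_fit(x, y, remove_outliers=False)
            if config.run_bootstrap_cis:
                fit.ci_beta1 = stats.bca_bootstrap_ci(
                    lambda a, b, axis=-1: stats.robust_line(a, b)[1],
                    (x, y), n_boot=config.n_boot, seed=stat_seed + ci_,
                    vectorized=True)
                fit.ci_beta0 = stats.bca_bootstrap_ci(
                    lambda a, b, axis=-1: stats.robust_line(a, b)[0],
                    (x, y), n_boot=config.n_boot, seed=stat_seed + ci_ + 100,
                    vectorized=True)
                fit.ci_level = 0.95
            fits[cond] = (x, y, fit)
            regressions[(measure, cond)] = fit
        if config.run_bootstrap_cis:
            for (ca, cb) in [("theta", "alpha"), ("alpha", "beta"),
                             ("theta", "beta")]:
                if ca in fits and cb in fits:
                    xa, ya, _ = fits[ca]
                    xb, yb, _ = fits[cb]
                    slope_diffs[(measure, ca, cb)] = stats.slope_difference_test(
                        xa, ya, xb, yb, n_boot=config.n_boot, seed=stat_seed)

    # distances of IAF from the alpha-stimulation centre frequency
    dist_cols = ["peri"] + list(config.conditions)
    dist = np.abs(iaf_wide[dist_cols].to_numpy(dtype=float) - ALPHA_STIM_CENTRE)
    iaf_pull = pd.DataFrame(dist, columns=dist_cols)
    iaf_pull.insert(0, "subject", complete)
    friedman = stats.friedman_test(dist)

    # behavioural accuracies with logit-linear dependence on alpha power
    iap_z = np.column_stack([zscore(iap_wide[c]) for c in config.conditions])
    subjects_used = [cohort[i] for i in complete]
    acc = synth_eeg.simulate_behavior(
        subjects_used, iap_z, seed=int(s_behav.generate_state(1)[0] % 2**31))
    n_events = max(8, round(2 * config.trials_per_cell / 3))
    behavior, behavior_lat = {}, {}
    for j, cond in enumerate(config.conditions):
        perf = zscore(stats.logit_transform(acc[:, j], n_trials=n_events))
        behavior[cond] = stats.robust_fit(iap_z[:, j], perf)
        behavior_lat[cond] = stats.robust_fit(
            zscore(lat_wide[cond].to_numpy(dtype=float)), perf)

    return StudyReport(profiles=profiles, anova=anova, bayes=bayes,
                       cluster=cluster, regressions=regressions,
                       slope_differences=slope_diffs, friedman=friedman,
                       behavior=behavior, behavior_lat=behavior_lat,
                       iaf_pull=iaf_pull, n_no_peak=n_no_peak,
                       config=config, seed=config.seed)


def compare_regression_tables(report: StudyReport) -> pd.DataFrame:
    """Tabulate the during-vs-peri regressions per measure and condition:
    R², β0 [CI], β1 [CI] — one row per (measure, stimulation band)."""
    rows = []
    for (measure, cond), fit in report.regressions.items():
        rows.append({
            "measure": measure.upper(), "stimulation": cond, "R2": fit.r2,
            "beta0": fit.beta0,
            "beta0_ci_lo": fit.ci_beta0[0] if fit.ci_beta0 else np.nan,
            "beta0_ci_hi": fit.ci_beta0[1] if fit.ci_beta0 else np.nan,
            "beta1": fit.beta1,
            "beta1_ci_lo": fit.ci_beta1[0] if fit.ci_beta1 else np.nan,
            "beta1_ci_hi": fit.ci_beta1[1] if fit.ci_beta1 else np.nan,
            "F_vs_constant": fit.f_stat, "p": fit.f_p, "n": fit.n,
        })
    return pd.DataFrame(rows)
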