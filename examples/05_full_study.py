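"""Run the full simulated study end to end (reduced problem size).

Simulates a cohort, generates quasi-rhythmic stimuli and synthetic EEG,
runs the complete analysis chain and prints the study-level pattern:
attention lateralizes alpha power, stimulation frequency does not change
it, and rest measurements predict during-stimulation measurements with
slopes near 1 (the no-entrainment regime).
"""

import numpy as np

from alphakit import StudyConfig, compare_regression_tables, run_study

config = StudyConfig(n_subjects=12, trials_per_cell=8, rejection_rate=0.0,
                     fs=256.0, n_channels=32, peri_duration=30.0,
                     n_perm=1000, n_boot=1000, n_mc=50_000, seed=2024)
report = run_study(config)

print("=== attention effect ===")
pos = report.anova.effects["position"]
print(f"position  : F({pos.df[0]},{pos.df[1]}) = {pos.F:.2f}, "
      f"p_GG = {pos.p_gg:.2g}, w2p = {pos.omega_p2:.3f}, "
      f"BF10 = {report.bayes.effects['position'].bf10:.3g}")
sig = [c for c in report.cluster.clusters if c.p < 0.05]
print(f"cluster test: {len(sig)} significant cluster(s), "
      f"min p = {report.cluster.min_p:.4f}")

print("=== stimulation-frequency effect (expected null) ===")
freq = report.anova.effects["frequency"]
print(f"frequency : F({freq.df[0]},{freq.df[1]}) = {freq.F:.2f}, "
      f"p_GG = {freq.p_gg:.3f}, BF10 = "
      f"{report.bayes.effects['frequency'].bf10:.3f} "
      f"(BF01 = {report.bayes.effects['frequency'].bf01:.2f})")

print("=== rest -> during-stimulation regressions ===")
table = compare_regression_tables(report)
cols = ["measure", "stimulation", "R2", "beta1", "beta1_ci_lo", "beta1_ci_hi"]
print(table[cols].round(3).to_string(index=False))

d = report.iaf_pull
print("=== IAF distance from the 10.5-Hz stimulation centre ===")
print("median |IAF-10.5|:",
      {c: float(np.median(d[c])) for c in ("peri", "theta", "alpha", "beta")})
print(f"friedman: chi2({report.friedman.df}) = {report.friedman.statistic:.3f},"
      f" p = {report.friedman.p:.3f}")
# With entrain_coupling = 0 the IAF slopes include 1, the frequency factor's
# BF10 favours the null, and the distance distributions are exchangeable —
# the signature of NO stimulation-frequency influence on intrinsic alpha.
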