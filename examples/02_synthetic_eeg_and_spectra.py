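"""Simulate one subject's EEG and decompose it into log-power spectra.

A 32-channel synthetic recording (alpha oscillators over both
parieto-occipital clusters + 1/f noise) is epoched into overlapping 1-s
windows, converted to scalp current densities and Fourier-transformed onto
a 0.5-Hz grid.
"""

import numpy as np

from alphakit import spectral, stimgen, synth_eeg

montage = synth_eeg.make_symmetric_montage(32)
subject = synth_eeg.SubjectParams(iaf_true=9.8, alpha_amp=3.5,
                                  attn_modulation=2.0, drive_snr=0.5)

trials = [stimgen.make_trial("alpha", side, seed=10 + k)
          for k, side in enumerate(["left", "right"] * 6)]
rec = synth_eeg.simulate_recording(subject, trials, montage, fs=512, seed=7)
print(f"recording  : {rec.data.shape[0]} channels × {rec.n_samples} samples "
      f"({rec.duration:.0f} s at {rec.fs:.0f} Hz)")

epochs = spectral.epoch_data(rec)            # 3-s windows -> 1-s epochs
print(f"epochs     : {epochs.n_epochs} (event trials excluded)")

scd = spectral.scalp_current_density(epochs)     # spherical-spline Laplacian
ps = spectral.power_spectrum(scd)                # raw power, 0.5-Hz grid
db = spectral.to_log_power(ps)

cluster = np.concatenate([montage.cluster_indices("left"),
                          montage.cluster_indices("right")])
spec = db.mean_over(cluster)
sel = (db.freqs >= 6) & (db.freqs <= 14)
peak = db.freqs[sel][np.argmax(spec[sel])]
print(f"grid       : {ps.freqs[1] - ps.freqs[0]:.1f} Hz spacing")
print(f"peak freq  : {peak:.1f} Hz over the parieto-occipital clusters "
      f"(ground truth {subject.iaf_true} Hz)")
# The cluster-averaged log-power spectrum peaks at the subject's intrinsic
# alpha frequency; the 0.5-Hz grid quantizes the estimate.
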