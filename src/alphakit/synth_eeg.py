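"""Synthetic multi-channel EEG with controllable alpha parameters.

The generator emulates the statistical structure that the analysis chain
assumes in parieto-occipital recordings: per-hemisphere alpha oscillators
with an individual peak frequency (IAF) and a slow amplitude envelope,
1/f background noise, a retinotopic attention effect (alpha suppression
contralateral / enhancement ipsilateral to the attended hemifield), an
optional stimulus-driven frequency-following response locked to the
contrast-modulation phase, and an optional Adler-type phase coupling that
lets the alpha oscillator entrain to the stimulation.  Behavioural
accuracies follow a configurable logit-linear dependence on alpha power.

None of this claims biophysical realism (no volume conduction, no
artifacts); it provides ground truth for recovery tests of every
downstream stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .stimgen import TrialSpec

__all__ = [
    "SubjectParams",
    "Montage",
    "Recording",
    "TrialRecord",
    "make_symmetric_montage",
    "simulate_recording",
    "simulate_peri",
    "simulate_behavior",
    "make_cohort",
]

#: EEG sampling rate of the emulated acquisition system, Hz
FS_DEFAULT = 512.0
#: cue period preceding each stimulation interval, s
CUE_DURATION = 0.5


@dataclass
class SubjectParams:
    """Ground-truth generative parameters of one synthetic participant."""

    iaf_true: float = 10.0          # Hz, intrinsic alpha peak frequency
    alpha_amp: float = 3.0          # a.u., oscillator amplitude (noise RMS = 1)
    attn_modulation: float = 2.0    # dB, contralateral power suppression per side
    noise_exponent: float = 1.0     # 1/f^exponent background slope
    noise_scale: float = 1.0        # a.u., RMS of the background noise
    drive_snr: float = 0.0          # a.u., frequency-following response amplitude
    entrain_coupling: float = 0.0   # rad/s, Adler coupling strength (0 = off)
    behavior_intercept: float = 1.4  # logit units
    behavior_slope: float = 0.0      # logit units per z-unit of alpha power
    envelope_depth: float = 0.4      # modulation depth of the slow alpha envelope

    def __post_init__(self):
        if not 6.0 <= self.iaf_true <= 14.0:
            raise ValueError("iaf_true must lie in [6, 14] Hz")
        if self.alpha_amp < 0:
            raise ValueError("alpha_amp must be >= 0")
        if self.entrain_coupling < 0:
            raise ValueError("entrain_coupling must be >= 0")


@dataclass
class Montage:
    """Channel labels and unit-sphere positions with two lateral clusters."""

    labels: list
    pos: np.ndarray                 # (n_channels, 3), unit radius
    left_cluster: list              # labels of the left parieto-occipital cluster
    right_cluster: list

    def __post_init__(self):
        norms = np.linalg.norm(self.pos, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("montage positions must be normalized to unit radius")
        if set(self.left_cluster) & set(self.right_cluster):
            raise ValueError("clusters must be disjoint")
        missing = (set(self.left_cluster) | set(self.right_cluster)) - set(self.labels)
        if missing:
            raise ValueError(f"cluster labels not in montage: {missing}")

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    def cluster_indices(self, side: str) -> np.ndarray:
        labels = self.left_cluster if side == "left" else self.right_cluster
        index = {lab: i for i, lab in enumerate(self.labels)}
        return np.array([index[lab] for lab in labels], dtype=int)

    def cluster_direction(self, side: str) -> np.ndarray:
        """Unit direction of the cluster centroid (used as source location)."""
        v = self.pos[self.cluster_indices(side)].mean(axis=0)
        return v / np.linalg.norm(v)

    def to_sfp(self, path) -> None:
        """Write electrode positions as .sfp-style text (label x y z)."""
        with open(path, "w") as fh:
            for lab, (x, y, z) in zip(self.labels, self.pos):
                fh.write(f"{lab}\t{x:.6f}\t{y:.6f}\t{z:.6f}\n")


@dataclass
class TrialRecord:
    """A trial's spec plus its sample-accurate stimulation onset."""

    spec: TrialSpec
    onset_sample: int               # first sample of the stimulation interval


@dataclass
class Recording:
    """Continuous synthetic EEG: channels × samples plus trial metadata."""

    data: np.ndarray                # (n_channels, n_samples), a.u. ("μV")
    fs: float
    montage: Montage
    trials: list = field(default_factory=list)   # list[TrialRecord]
    subject: SubjectParams | None = None
    segment_kind: str = "during"    # during | peri

    def __post_init__(self):
        if np.any(~np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


def make_symmetric_montage(n_channels: int = 32, cluster_size: int | None = None
                           ) -> Montage:
    """Build a laterally symmetric unit-sphere cap montage.

    Channels are laid out on the right half of a spherical cap with a
    golden-angle spiral and mirrored across the sagittal plane, so every
    channel has an exact left/right partner (an odd remainder goes on the
    vertex).  The two parieto-occipital clusters are the ``cluster_size``
    mirrored channel pairs nearest to canonical PO7/PO8-like directions.
    Coordinates: +x right, +y anterior, +z up.
    """
    if n_channels < 8:
        raise ValueError("need at least 8 channels")
    if cluster_size is None:
        cluster_size = max(2, n_channels // 8)
    n_half = n_channels // 2
    golden = (np.sqrt(5) - 1) / 2
    i = np.arange(n_half)
    z = 0.95 - (i + 0.5) / n_half * 1.10          # cap from near vertex to below equator
    rho = np.sqrt(1.0 - z**2)
    azim = np.pi * (0.06 + 0.88 * ((i * golden) % 1.0))  # (0, π): right half only
    x = rho * np.sin(azim)
    y = rho * np.cos(azim)
    right = np.stack([x, y, z], axis=1)
    left = right * np.array([-1.0, 1.0, 1.0])
    pos = [right, left]
    if n_channels % 2:
        pos.append(np.array([[0.0, 0.0, 1.0]]))
    pos = np.concatenate(pos, axis=0)
    pos /= np.linalg.norm(pos, axis=1, keepdims=True)
    labels = [f"R{k+1:03d}" for k in range(n_half)] + \
             [f"L{k+1:03d}" for k in range(n_half)]
    if n_channels % 2:
        labels.append("VERTEX")

    po_right = np.array([0.45, -0.70, 0.40])
    po_right /= np.linalg.norm(po_right)
    d = right @ po_right
    order = np.argsort(-d)[:cluster_size]
    right_cluster = [labels[k] for k in order]
    left_cluster = [labels[k + n_half] for k in order]   # exact mirror partners
    return Montage(labels=labels, pos=pos,
                   left_cluster=left_cluster, right_cluster=right_cluster)


def _one_over_f_noise(rng: np.random.Generator, n_rows: int, n_samples: int,
                      fs: float, exponent: float) -> np.ndarray:
    """Rows of unit-RMS 1/f^exponent noise via spectral shaping of white noise."""
    white = rng.standard_normal((n_rows, n_samples))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samples, 1.0 / fs)
    shape = np.zeros_like(freqs)
    nz = freqs > 0
    shape[nz] = freqs[nz] ** (-exponent / 2.0)
    out = np.fft.irfft(spec * shape, n=n_samples, axis=1)
    sd = out.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return out / sd


def _slow_envelope(rng: np.random.Generator, shape: tuple, fs: float,
                   depth: float, bandwidth: float = 1.0) -> np.ndarray:
    """Positive slow amplitude envelopes, mean ≈ 1, ~`bandwidth` Hz wide."""
    n_rows = int(np.prod(shape[:-1]))
    n = shape[-1]
    white = rng.standard_normal((n_rows, n))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    spec *= np.exp(-0.5 * (freqs / (bandwidth / 2.0)) ** 2)
    slow = np.fft.irfft(spec, n=n, axis=1)
    sd = slow.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    env = 1.0 + depth * slow / sd
    return np.clip(env, 0.05, None).reshape(shape)


def _spatial_gains(montage: Montage, direction: np.ndarray,
                   sigma: float = 0.35) -> np.ndarray:
    """Gaussian-on-the-sphere forward kernel from a source direction."""
    cosang = np.clip(montage.pos @ direction, -1.0, 1.0)
    ang = np.arccos(cosang)
    return np.exp(-0.5 * (ang / sigma) ** 2)


def _integrate_adler(iaf: float, coupling: np.ndarray, stim_phase: np.ndarray,
                     phi0: np.ndarray, fs: float) -> np.ndarray:
    """Euler-integrate dφ/dt = 2π·iaf + ε·sin(φ_stim − φ) for a batch.

    ``coupling``: (n_rows,) rad/s (0 rows follow the free-running solution),
    ``stim_phase``: (n_rows, n_samples), ``phi0``: (n_rows,).
    """
    n_rows, n = stim_phase.shape
    dt = 1.0 / fs
    omega = 2.0 * np.pi * iaf
    if np.all(coupling == 0):
        return phi0[:, None] + omega * dt * np.arange(n)[None, :]
    phi = np.empty((n_rows, n))
    phi[:, 0] = phi0
    for k in range(1, n):
        dphi = omega + coupling * np.sin(stim_phase[:, k - 1] - phi[:, k - 1])
        phi[:, k] = phi[:, k - 1] + dphi * dt
    return phi


def simulate_recording(subject: SubjectParams, trials: list[TrialSpec],
                       montage: Montage, fs: float = FS_DEFAULT, seed: int = 0,
                       entrain_conditions: tuple = ("theta", "alpha", "beta"),
                       cue_duration: float = CUE_DURATION,
                       kernel_sigma: float = 0.35) -> Recording:
    """Simulate a during-stimulation recording for one subject.

    Trials (``cue_duration`` + stimulation) are synthesized back to back.
    Per hemisphere, an amplitude-modulated alpha oscillator at ``iaf_true``
    is projected onto the montage through a Gaussian spatial kernel centred
    on the corresponding parieto-occipital cluster; the hemisphere
    contralateral to the attended side is attenuated by ``attn_modulation``
    dB (power) and the ipsilateral one enhanced symmetrically.  A
    frequency-following component of amplitude ``drive_snr`` tracks the
    attended patch's contrast-modulation phase.  If ``entrain_coupling`` > 0
    and the trial's condition is in ``entrain_conditions``, both alpha
    phases obey the Adler equation with the attended stimulus phase as the
    driver during stimulation.
    """
    if not trials:
        raise ValueError("during-recordings require at least one trial")
    if fs < 256:
        raise ValueError("fs must be >= 256 Hz")
    if not montage.left_cluster or not montage.right_cluster:
        raise ValueError("montage must define left and right clusters")

    rng = np.random.default_rng(seed)
    n_trials = len(trials)
    stim_dur = trials[0].duration
    if any(abs(tr.duration - stim_dur) > 1e-9 for tr in trials):
        raise ValueError("all trials must share the same stimulation duration")
    n_cue = int(round(cue_duration * fs))
    n_stim = int(round(stim_dur * fs))
    n_t = n_cue + n_stim
    t_stim = np.arange(n_stim) / fs

    # attended-stimulus phase, resampled from the frame grid to fs
    stim_phase = np.empty((n_trials, n_stim))
    for j, tr in enumerate(trials):
        cmf = tr.cmf_left if tr.attended_side == "left" else tr.cmf_right
        stim_phase[j] = np.interp(t_stim, cmf.t, cmf.phase)

    coupling = np.array([
        subject.entrain_coupling if tr.condition in entrain_conditions else 0.0
        for tr in trials])

    # per-trial, per-hemisphere alpha phase during stimulation
    phi0 = rng.uniform(0, 2 * np.pi, size=(2, n_trials))
    phases = np.empty((2, n_trials, n_t))
    for h in range(2):
        cue_phase = phi0[h][:, None] + \
            2 * np.pi * subject.iaf_true * np.arange(n_cue)[None, :] / fs
        phi_start = phi0[h] + 2 * np.pi * subject.iaf_true * n_cue / fs
        stim_part = _integrate_adler(subject.iaf_true, coupling, stim_phase,
                                     phi_start, fs)
        phases[h] = np.concatenate([cue_phase, stim_part], axis=1)

    env = _slow_envelope(rng, (2, n_trials, n_t), fs, subject.envelope_depth)

    # attention gain (amplitude scale): contralateral suppressed, ipsilateral enhanced
    att = np.empty((2, n_trials))       # hemisphere 0 = left, 1 = right
    for j, tr in enumerate(trials):
        contra_hemi = 1 if tr.attended_side == "left" else 0
        att[contra_hemi, j] = 10.0 ** (-subject.attn_modulation / 20.0)
        att[1 - contra_hemi, j] = 10.0 ** (subject.attn_modulation / 20.0)

    alpha = subject.alpha_amp * att[:, :, None] * env * np.sin(phases)

    # frequency-following response, stimulation interval only
    ffr = np.zeros((n_trials, n_t))
    if subject.drive_snr > 0:
        ffr[:, n_cue:] = subject.drive_snr * np.sin(stim_phase)

    gains = np.stack([_spatial_gains(montage, montage.cluster_direction(s),
                                     kernel_sigma) for s in ("left", "right")])
    n_ch = montage.n_channels
    n_total = n_trials * n_t
    data = np.zeros((n_ch, n_total))
    for h in range(2):
        data += gains[h][:, None] * alpha[h].reshape(1, n_total)
    data += (gains.sum(axis=0))[:, None] * ffr.reshape(1, n_total)

    if subject.noise_scale > 0:
        noise = _one_over_f_noise(rng, n_ch + 1, n_total, fs, subject.noise_exponent)
        data += subject.noise_scale * (noise[:n_ch] + 0.3 * noise[-1][None, :])

    recs = [TrialRecord(spec=tr, onset_sample=j * n_t + n_cue)
            for j, tr in enumerate(trials)]
    return Recording(data=data, fs=fs, montage=montage, trials=recs,
                     subject=subject, segment_kind="during")


def simulate_peri(subject: SubjectParams, duration: float, montage: Montage,
                  fs: float = FS_DEFAULT, seed: int = 0,
                  kernel_sigma: float = 0.35) -> Recording:
    """Simulate a peri-stimulation (rest) recording: same generative model
    with no stimulus drive, no entrainment and no attentional modulation."""
    if duration < 6:
        raise ValueError("peri segments are at least 6 s long")
    if fs < 256:
        raise ValueError("fs must be >= 256 Hz")
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    gains = np.stack([_spatial_gains(montage, montage.cluster_direction(s),
                                     kernel_sigma) for s in ("left", "right")])
    env = _slow_envelope(rng, (2, n), fs, subject.envelope_depth)
    phi0 = rng.uniform(0, 2 * np.pi, size=2)
    data = np.zeros((montage.n_channels, n))
    for h in range(2):
        src = subject.alpha_amp * env[h] * np.sin(
            phi0[h] + 2 * np.pi * subject.iaf_true * t)
        data += gains[h][:, None] * src[None, :]
    if subject.noise_scale > 0:
        noise = _one_over_f_noise(rng, montage.n_channels + 1, n, fs,
                                  subject.noise_exponent)
        data += subject.noise_scale * (noise[:montage.n_channels]
                                       + 0.3 * noise[-1][None, :])
    return Recording(data=data, fs=fs, montage=montage, trials=[],
                     subject=subject, segment_kind="peri")


def simulate_behavior(subjects: list[SubjectParams], iap_z: np.ndarray,
                      seed: int = 0, noise_sd: float = 0.3) -> np.ndarray:
    """Accuracies with logit(accuracy) = intercept + slope·iap_z + noise.

    ``iap_z``: standardized alpha power, shape (n_subjects,) or
    (n_subjects, n_conditions); the returned proportions match its shape
    and always lie strictly inside (0, 1).
    """
    iap_z = np.asarray(iap_z, dtype=float)
    if not np.all(np.isfinite(iap_z)):
        raise ValueError("iap_z must be finite")
    rng = np.random.default_rng(seed)
    intercept = np.array([s.behavior_intercept for s in subjects], dtype=float)
    slope = np.array([s.behavior_slope for s in subjects], dtype=float)
    if iap_z.ndim == 2:
        intercept = intercept[:, None]
        slope = slope[:, None]
    logit_acc = intercept + slope * iap_z + noise_sd * rng.standard_normal(iap_z.shape)
    return expit(logit_acc)


def make_cohort(n_subjects: int = 17, seed: int = 0, *,
                iaf_mean: float = 10.2, iaf_sd: float = 0.9,
                iaf_bounds: tuple = (8.0, 13.0),
                alpha_amp_range: tuple = (2.0, 5.0),
                attn_modulation: float = 2.0, drive_snr: float = 0.5,
                entrain_coupling: float = 0.0, behavior_slope: float = 0.0,
                behavior_intercept_sd: float = 0.2,
                **overrides) -> list[SubjectParams]:
    """Draw a cohort of synthetic participants.

    IAFs are Normal(``iaf_mean``, ``iaf_sd``) truncated to ``iaf_bounds``
    (resampling), alpha amplitudes uniform over ``alpha_amp_range``;
    remaining fields are shared across subjects unless overridden.
    """
    rng = np.random.default_rng(seed)
    cohort = []
    for _ in range(n_subjects):
        while True:
            iaf = rng.normal(iaf_mean, iaf_sd)
            if iaf_bounds[0] <= iaf <= iaf_bounds[1]:
                break
        cohort.append(SubjectParams(
            iaf_true=float(iaf),
            alpha_amp=float(rng.uniform(*alpha_amp_range)),
            attn_modulation=attn_modulation,
            drive_snr=drive_snr,
            entrain_coupling=entrain_coupling,
            behavior_slope=behavior_slope,
            behavior_intercept=float(1.4 + behavior_intercept_sd
                                     * rng.standard_normal()),
            **overrides))
    return cohort
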