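"""Quasi-rhythmic visual stimulation synthesis.

Builds the frequency-modulation (FM) trajectories and contrast-modulation
functions (CMFs) used to drive two peripheral checkerboard patches:
the instantaneous contrast-modulation rate wanders randomly inside one of
three frequency bands (theta 4-7 Hz, alpha 8-13 Hz, beta 14-20 Hz) under a
rate-of-change limit of one bandwidth per second, and the two concurrently
presented patches are kept maximally decorrelated (|Pearson r| < 0.05
between their FM traces).  Peak luminance follows a sinusoid of the
integrated FM phase between fixed bounds (7.5-29.1 cd/m²).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StimulusBand",
    "FMFunction",
    "ContrastTimecourse",
    "TrialSpec",
    "BANDS",
    "generate_fm_function",
    "fm_to_cmf",
    "generate_decorrelated_pair",
    "place_events",
    "make_trial",
    "validate_stimulus",
    "GenerationError",
]

#: display refresh rate used for all stimulus timecourses, frames/s
FRAME_RATE = 100.0
#: luminance bounds of the contrast modulation, cd/m²
LUM_MIN = 7.5
LUM_MAX = 29.1
#: background luminance, cd/m²
LUM_BACKGROUND = 6.5
#: stimulation duration per trial, s
STIM_DURATION = 3.5
#: transient target/distracter events
EVENT_DURATION = 0.3
EVENT_MIN_GAP = 0.8
P_EVENT_TRIAL = 1.0 / 3.0
#: decorrelation criterion for concurrently presented FM traces
R_MAX = 0.05


class GenerationError(RuntimeError):
    """Raised when rejection sampling cannot satisfy a stimulus constraint."""


@dataclass(frozen=True)
class StimulusBand:
    """A stimulation frequency band with hard lower/upper rate bounds."""

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self):
        if self.f_lo > self.f_hi:
            raise ValueError(f"f_lo must be <= f_hi, got ({self.f_lo}, {self.f_hi})")

    @property
    def bandwidth(self) -> float:
        return self.f_hi - self.f_lo

    @property
    def centre(self) -> float:
        return 0.5 * (self.f_lo + self.f_hi)


#: the three quasi-rhythmic stimulation bands
BANDS = {
    "theta": StimulusBand("theta", 4.0, 7.0),
    "alpha": StimulusBand("alpha", 8.0, 13.0),
    "beta": StimulusBand("beta", 14.0, 20.0),
}


@dataclass
class FMFunction:
    """Instantaneous contrast-modulation frequency on the frame grid."""

    t: np.ndarray        # s, frame centres
    f: np.ndarray        # Hz, instantaneous frequency
    band: StimulusBand
    seed: int
    frame_rate: float = FRAME_RATE

    def __len__(self) -> int:
        return self.f.size

    def max_rate_of_change(self) -> float:
        """Largest |df/dt| over the trajectory, Hz/s."""
        if self.f.size < 2:
            return 0.0
        return float(np.max(np.abs(np.diff(self.f))) * self.frame_rate)


@dataclass
class ContrastTimecourse:
    """Peak-luminance timecourse of one patch, with its unwrapped phase."""

    t: np.ndarray
    phase: np.ndarray      # rad, unwrapped, strictly increasing
    luminance: np.ndarray  # cd/m²
    lum_min: float = LUM_MIN
    lum_max: float = LUM_MAX
    background: float = LUM_BACKGROUND
    frame_rate: float = FRAME_RATE


@dataclass
class TrialSpec:
    """One trial: condition, attended side, both patch CMFs and events."""

    condition: str                 # theta|alpha|beta
    attended_side: str             # left|right
    fm_left: FMFunction
    fm_right: FMFunction
    cmf_left: ContrastTimecourse
    cmf_right: ContrastTimecourse
    events: list = field(default_factory=list)  # (kind, onset_s, duration_s)

    @property
    def duration(self) -> float:
        return len(self.fm_left) / self.fm_left.frame_rate

    @property
    def has_event(self) -> bool:
        return len(self.events) > 0


def _slew_limit_py(x: np.ndarray, max_step: float) -> np.ndarray:
    y = np.empty_like(x)
    y[:, 0] = x[:, 0]
    lo, hi = -max_step, max_step
    for i in range(1, x.shape[1]):
        step = x[:, i] - y[:, i - 1]
        np.maximum(step, lo, out=step)
        np.minimum(step, hi, out=step)
        y[:, i] = y[:, i - 1] + step
    return y


try:                                    # tight per-frame recursion: jit it
    from numba import njit

    @njit(cache=True)
    def _slew_limit_jit(x, max_step):   # pragma: no cover - numba kernel
        y = np.empty_like(x)
        for r in range(x.shape[0]):
            y[r, 0] = x[r, 0]
            for i in range(1, x.shape[1]):
                step = x[r, i] - y[r, i - 1]
                if step > max_step:
                    step = max_step
                elif step < -max_step:
                    step = -max_step
                y[r, i] = y[r, i - 1] + step
        return y
except ImportError:                     # pragma: no cover
    _slew_limit_jit = None


def _slew_limit_batch(x: np.ndarray, max_step: float) -> np.ndarray:
    """Forward slew-rate limiter on rows: output chases x with per-sample
    steps bounded by max_step; stays within each row's [min, max]."""
    if _slew_limit_jit is not None:
        return _slew_limit_jit(np.ascontiguousarray(x), float(max_step))
    return _slew_limit_py(x, max_step)


def _fm_batch(band: StimulusBand, duration: float, frame_rate: float,
              n_traces: int, rng: np.random.Generator) -> np.ndarray:
    """(n_traces, n_frames) random FM trajectories inside ``band``:
    uniform knots at ~1-s spacing, PCHIP interpolation to the frame grid,
    then slew-rate limiting to one bandwidth per second."""
    from scipy.interpolate import PchipInterpolator

    n = int(round(duration * frame_rate))
    t = np.arange(n) / frame_rate
    if band.bandwidth == 0:
        return np.full((n_traces, n), band.f_lo)
    # knots at ~1 s spacing, padded at both ends to avoid edge extrapolation
    knot_t = np.arange(-1.0, duration + 2.0, 1.0)
    knot_f = rng.uniform(band.f_lo, band.f_hi, size=(knot_t.size, n_traces))
    f = PchipInterpolator(knot_t, knot_f, axis=0)(t).T
    # PCHIP between in-band knots stays in-band, but clip defensively;
    # clipping is 1-Lipschitz so it cannot create rate violations
    f = np.clip(f, band.f_lo, band.f_hi)
    return _slew_limit_batch(f, band.bandwidth / frame_rate)


def generate_fm_function(band: StimulusBand, duration: float = STIM_DURATION,
                         frame_rate: float = FRAME_RATE, seed: int = 0) -> FMFunction:
    """Generate one random FM trajectory inside ``band``.

    Uniform noise is drawn on the band at ~1 Hz temporal resolution,
    interpolated to the frame grid with a shape-preserving (PCHIP) smooth
    interpolant, then passed through a slew-rate limiter so that the
    instantaneous frequency never changes faster than one bandwidth per
    second.  Deterministic given ``seed``.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if frame_rate <= 0:
        raise ValueError("frame_rate must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration * frame_rate))
    t = np.arange(n) / frame_rate
    f = _fm_batch(band, duration, frame_rate, 1, rng)[0]
    return FMFunction(t=t, f=f, band=band, seed=seed, frame_rate=frame_rate)


def fm_to_cmf(fm: FMFunction, lum_min: float = LUM_MIN, lum_max: float = LUM_MAX,
              phase0: float = 0.0, oversample: int = 8) -> ContrastTimecourse:
    """Integrate an FM trajectory into a luminance contrast modulation.

    phase(t) = phase0 + 2π ∫ f dt (integrated on an ``oversample``-times finer
    grid, then decimated back to the frame grid, to keep the phase integral
    accurate at beta-band rates); luminance maps the sine of that phase onto
    [lum_min, lum_max].
    """
    if lum_min >= lum_max:
        raise ValueError("lum_min must be < lum_max")
    dt = 1.0 / (fm.frame_rate * oversample)
    # piecewise-constant-per-frame frequency on the fine grid
    f_fine = np.repeat(fm.f, oversample)
    dphase = 2.0 * np.pi * f_fine * dt
    phase_fine = phase0 + np.concatenate(([0.0], np.cumsum(dphase)[:-1]))
    phase = phase_fine[::oversample]
    luminance = lum_min + (lum_max - lum_min) * 0.5 * (1.0 + np.sin(phase))
    return ContrastTimecourse(t=fm.t.copy(), phase=phase, luminance=luminance,
                              lum_min=lum_min, lum_max=lum_max,
                              frame_rate=fm.frame_rate)


def generate_decorrelated_pair(band: StimulusBand, duration: float = STIM_DURATION,
                               frame_rate: float = FRAME_RATE, r_max: float = R_MAX,
                               seed: int = 0, max_tries: int = 1000,
                               member_seeds: tuple[int, int] | None = None
                               ) -> tuple[FMFunction, FMFunction]:
    """Rejection-sample a pair of FM trajectories with |Pearson r| < r_max.

    The correlation criterion is evaluated on the instantaneous-frequency
    traces of the two patches, mirroring how concurrently presented stimuli
    were controlled to be maximally uncorrelated.  ``member_seeds`` pins the
    two member seeds explicitly (mainly for failure-mode checks); otherwise
    fresh seeds are spawned from ``seed`` on every attempt.
    """
    if not 0.0 < r_max <= 1.0:
        raise ValueError("r_max must be in (0, 1]")
    if band.bandwidth == 0:
        raise GenerationError("zero-bandwidth band: both traces are constant, "
                              "correlation undefined/degenerate")
    n = int(round(duration * frame_rate))
    t = np.arange(n) / frame_rate
    best_r = np.inf

    if member_seeds is not None:
        # pinned member seeds: plain per-attempt rejection sampling
        for _ in range(max_tries):
            fm_l = generate_fm_function(band, duration, frame_rate,
                                        seed=member_seeds[0])
            fm_r = generate_fm_function(band, duration, frame_rate,
                                        seed=member_seeds[1])
            if np.std(fm_l.f) == 0 or np.std(fm_r.f) == 0:
                continue
            r = float(np.corrcoef(fm_l.f, fm_r.f)[0, 1])
            best_r = min(best_r, abs(r))
            if abs(r) < r_max:
                return fm_l, fm_r
        raise GenerationError(
            f"no FM pair with |r| < {r_max} in {max_tries} tries "
            f"(best |r| = {best_r:.3f})")

    # batched rejection sampling: draw candidate traces per side, scan
    # left×right combinations in fixed order, accept the first under r_max
    rng = np.random.default_rng(seed)
    batch = 8
    tried = 0
    while tried < max_tries:
        cand = _fm_batch(band, duration, frame_rate, 2 * batch, rng)
        cand_l, cand_r = cand[:batch], cand[batch:]
        zl = cand_l - cand_l.mean(axis=1, keepdims=True)
        zr = cand_r - cand_r.mean(axis=1, keepdims=True)
        sl = np.linalg.norm(zl, axis=1)
        sr = np.linalg.norm(zr, axis=1)
        sl[sl == 0] = np.inf
        sr[sr == 0] = np.inf
        R = (zl / sl[:, None]) @ (zr / sr[:, None]).T
        for i in range(batch):
            for j in range(batch):
                tried += 1
                r = float(R[i, j])
                best_r = min(best_r, abs(r))
                if abs(r) < r_max:
                    fm_l = FMFunction(t=t, f=cand_l[i], band=band, seed=seed,
                                      frame_rate=frame_rate)
                    fm_r = FMFunction(t=t, f=cand_r[j], band=band, seed=seed,
                                      frame_rate=frame_rate)
                    return fm_l, fm_r
                if tried >= max_tries:
                    break
            else:
                continue
            break
    raise GenerationError(
        f"no FM pair with |r| < {r_max} in {max_tries} tries "
        f"(best |r| = {best_r:.3f})")


def place_events(n_trials: int, p_event_trial: float = P_EVENT_TRIAL,
                 duration: float = STIM_DURATION, min_gap: float = EVENT_MIN_GAP,
                 event_dur: float = EVENT_DURATION, seed: int = 0,
                 p_target: float = 0.5) -> list[list[tuple[str, float, float]]]:
    """Draw per-trial target/distracter event lists.

    A third of trials carry events; event trials contain one or two brief
    flashes (equal odds) whose onsets are at least ``min_gap`` apart and
    which end before stimulation offset.  Each event is independently a
    target (on the cued patch) or a distracter with probability ``p_target``.
    """
    if duration <= event_dur:
        raise ValueError("duration must exceed event duration")
    two_feasible = duration - event_dur >= min_gap + event_dur
    rng = np.random.default_rng(seed)
    out: list[list[tuple[str, float, float]]] = []
    latest = duration - event_dur
    for _ in range(n_trials):
        events: list[tuple[str, float, float]] = []
        if rng.random() < p_event_trial:
            n_ev = 1 if not two_feasible else int(rng.integers(1, 3))
            if n_ev == 1:
                onsets = [rng.uniform(0.0, latest)]
            else:
                # draw until the gap constraint holds (feasible region is large)
                while True:
                    a, b = np.sort(rng.uniform(0.0, latest, size=2))
                    if b - a >= min_gap:
                        onsets = [a, b]
                        break
            for onset in onsets:
                kind = "target" if rng.random() < p_target else "distracter"
                events.append((kind, float(onset), event_dur))
        out.append(events)
    return out


def make_trial(condition: str, attended_side: str, seed: int,
               duration: float = STIM_DURATION, frame_rate: float = FRAME_RATE,
               events: list | None = None) -> TrialSpec:
    """Assemble a full trial: decorrelated FM pair, CMFs with random initial
    phases, and (optionally pre-drawn) transient events."""
    band = BANDS[condition]
    ss = np.random.SeedSequence(seed)
    pair_seed, phase_seed = (int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(2))
    fm_l, fm_r = generate_decorrelated_pair(band, duration, frame_rate, seed=pair_seed)
    rng = np.random.default_rng(phase_seed)
    phi_l, phi_r = rng.uniform(0, 2 * np.pi, size=2)
    cmf_l = fm_to_cmf(fm_l, phase0=phi_l)
    cmf_r = fm_to_cmf(fm_r, phase0=phi_r)
    return TrialSpec(condition=condition, attended_side=attended_side,
                     fm_left=fm_l, fm_right=fm_r, cmf_left=cmf_l, cmf_right=cmf_r,
                     events=list(events) if events else [])


def validate_stimulus(trial: TrialSpec, r_max: float = R_MAX,
                      lum_tol: float = 1e-9) -> list[str]:
    """Check every stimulus invariant; return a report per violation.

    Empty list means the trial satisfies band containment, the one-bandwidth
    per second rate limit, luminance bounds, FM-pair decorrelation and the
    event-placement rules.
    """
    reports: list[str] = []
    band = BANDS[trial.condition]
    for side, fm in (("left", trial.fm_left), ("right", trial.fm_right)):
        below = np.flatnonzero(fm.f < band.f_lo - 1e-12)
        above = np.flatnonzero(fm.f > band.f_hi + 1e-12)
        if below.size:
            reports.append(f"band violation ({side}): f < {band.f_lo} Hz "
                           f"first at frame {below[0]}")
        if above.size:
            reports.append(f"band violation ({side}): f > {band.f_hi} Hz "
                           f"first at frame {above[0]}")
        rates = np.abs(np.diff(fm.f)) * fm.frame_rate
        bad = np.flatnonzero(rates > band.bandwidth + 1e-9)
        if bad.size:
            reports.append(f"rate violation ({side}): |df/dt| > {band.bandwidth} Hz/s "
                           f"first at frame {bad[0]}")
    if np.std(trial.fm_left.f) > 0 and np.std(trial.fm_right.f) > 0:
        r = float(np.corrcoef(trial.fm_left.f, trial.fm_right.f)[0, 1])
        if abs(r) >= r_max:
            reports.append(f"decorrelation violation: |r| = {abs(r):.3f} >= {r_max}")
    for side, cmf in (("left", trial.cmf_left), ("right", trial.cmf_right)):
        lo = np.flatnonzero(cmf.luminance < cmf.lum_min - lum_tol)
        hi = np.flatnonzero(cmf.luminance > cmf.lum_max + lum_tol)
        if lo.size:
            reports.append(f"luminance violation ({side}): below {cmf.lum_min} "
                           f"first at frame {lo[0]}")
        if hi.size:
            reports.append(f"luminance violation ({side}): above {cmf.lum_max} "
                           f"first at frame {hi[0]}")
        if np.any(np.diff(cmf.phase) <= 0):
            reports.append(f"phase violation ({side}): not strictly increasing")
    if len(trial.events) > 2:
        reports.append(f"event violation: {len(trial.events)} events > 2")
    onsets = sorted(e[1] for e in trial.events)
    for a, b in zip(onsets, onsets[1:]):
        if b - a < EVENT_MIN_GAP - 1e-9:
            reports.append(f"event violation: inter-onset interval {b - a:.3f} s "
                           f"< {EVENT_MIN_GAP} s")
    for kind, onset, dur in trial.events:
        if onset < 0 or onset + dur > trial.duration + 1e-9:
            reports.append(f"event violation: {kind} at {onset:.3f}s leaves the "
                           f"stimulation window")
    return reports
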