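"""Synthetic cohorts of paired PPG/ABP records and rPPG-style RGB traces.

The generator emulates the statistical structure that makes the downstream
pipeline testable without clinical data:

* per-subject continuous pulse waveforms with beat-to-beat morphology
  variation (two-bump systolic-peak + dicrotic-notch template);
* a population-level linear mapping from instantaneous (SBP, DBP, HR) to
  template parameters, plus a fixed subject-specific offset on that mapping
  (the offset is what makes train/test subject leakage detectable);
* slowly drifting SBP/DBP (sinusoid + first-order autoregressive jitter)
  within plausible ranges;
* additive white noise of controllable level;
* record lengths drawn from a long-tailed (log-normal) distribution;
* camera-style three-channel traces with channel-specific pulse modulation
  strongest in green, motion-artifact transients, and reference BP emitted
  on a one-minute grid (inclusive endpoints).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace as _dc_replace

import numpy as np

from ppgbp.preprocess import WaveformRecord

__all__ = [
    "SyntheticSubjectProfile",
    "CohortConfig",
    "Cohort",
    "RgbTrace",
    "generate_subject_record",
    "generate_cohort",
    "generate_rppg_trace",
    "POPULATION_MORPHOLOGY",
    "MORPHOLOGY_BP_MAP",
    "RGB_MODULATION",
]

# ---------------------------------------------------------------------------
# morphology model
# ---------------------------------------------------------------------------

#: population-baseline pulse template parameters:
#: (systolic peak position, systolic width, dicrotic-notch amplitude,
#:  dicrotic-notch delay) in beat-phase units
POPULATION_MORPHOLOGY = np.array([0.30, 0.10, 0.45, 0.30])

#: linear map from standardized (SBP, DBP, HR) to template-parameter shifts.
#: Rows: template parameters; columns: z-scored SBP, DBP, HR.  The map is
#: deliberately strong so that morphology carries a learnable BP signal.
MORPHOLOGY_BP_MAP = np.array([
    [-0.030, 0.010, 0.015],   # peak position: earlier at high SBP
    [-0.025, -0.010, 0.005],  # peak width: narrower at high SBP
    [0.160, -0.080, 0.000],   # notch amplitude: grows with pulse pressure
    [-0.060, 0.030, -0.020],  # notch delay
])

#: centering/scale used to standardize (SBP, DBP, HR) for the map
_BP_CENTER = np.array([120.0, 60.0, 75.0])
_BP_SCALE = np.array([25.0, 15.0, 25.0])

#: clip ranges keeping the template physiological and well-conditioned
_PARAM_LO = np.array([0.15, 0.04, 0.02, 0.12])
_PARAM_HI = np.array([0.45, 0.20, 0.95, 0.50])

#: relative pulse-modulation strengths of the R, G, B channels
RGB_MODULATION = np.array([0.33, 0.77, 0.53])


@dataclass
class SyntheticSubjectProfile:
    """Ground-truth generative parameters of one synthetic subject."""

    subject_id: str
    base_hr: float = 75.0            # beats/min
    hr_jitter_sd: float = 1.5        # beats/min, beat-to-beat AR(1)
    base_sbp: float = 120.0          # mmHg
    base_dbp: float = 60.0           # mmHg
    bp_drift_amplitude: float = 5.0  # mmHg
    bp_drift_period: float = 60.0    # s
    morphology_params: np.ndarray = field(
        default_factory=lambda: POPULATION_MORPHOLOGY.copy())
    subject_offset: np.ndarray = field(
        default_factory=lambda: np.zeros(4))
    noise_sd: float = 0.02           # signal units
    record_duration: float = 300.0   # s
    seed: int = 0

    def __post_init__(self) -> None:
        self.morphology_params = np.asarray(self.morphology_params, dtype=float)
        self.subject_offset = np.asarray(self.subject_offset, dtype=float)
        if self.record_duration <= 0:
            raise ValueError("record_duration must be positive")
        if self.base_dbp >= self.base_sbp:
            raise ValueError("base_dbp must be below base_sbp")
        if self.base_sbp - self.base_dbp < 20.0:
            raise ValueError("pulse pressure must be at least 20 mmHg")


def _template_params(profile: SyntheticSubjectProfile, sbp: float, dbp: float,
                     hr: float) -> np.ndarray:
    """Instantaneous template parameters for one beat."""
    z = (np.array([sbp, dbp, hr]) - _BP_CENTER) / _BP_SCALE
    theta = profile.morphology_params + MORPHOLOGY_BP_MAP @ z + profile.subject_offset
    return np.clip(theta, _PARAM_LO, _PARAM_HI)


def _pulse_template(phase: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Smooth two-bump pulse: systolic peak plus dicrotic notch."""
    m1, s1, a2, delay = theta
    m2 = m1 + delay
    s2 = 0.6 * s1 + 0.03
    return (np.exp(-0.5 * ((phase - m1) / s1) ** 2)
            + a2 * np.exp(-0.5 * ((phase - m2) / s2) ** 2))


#: fixed in-beat ABP shape parameters (min-max normalized per beat)
_ABP_THETA = np.array([0.25, 0.12, 0.35, 0.28])


def _drift(rng: np.random.Generator, profile: SyntheticSubjectProfile,
           duration: float):
    """SBP/DBP drift trajectories: sinusoid + AR(1) jitter on a 1 s grid.

    Returns callables sbp(t), dbp(t).  With zero drift amplitude both are
    exactly constant (no jitter), which downstream exactness tests rely on.
    """
    phase0 = rng.uniform(0.0, 2.0 * np.pi)
    n_grid = int(np.ceil(duration)) + 2
    jit_sd = 0.10 * profile.bp_drift_amplitude
    jit_s = np.zeros(n_grid)
    jit_d = np.zeros(n_grid)
    if jit_sd > 0.0:
        eps_s = rng.normal(0.0, jit_sd, n_grid)
        eps_d = rng.normal(0.0, jit_sd, n_grid)
        rho = 0.95
        for i in range(1, n_grid):
            jit_s[i] = rho * jit_s[i - 1] + eps_s[i]
            jit_d[i] = rho * jit_d[i - 1] + eps_d[i]
    grid = np.arange(n_grid, dtype=float)
    amp = profile.bp_drift_amplitude
    omega = 2.0 * np.pi / profile.bp_drift_period

    def sbp(t):
        return (profile.base_sbp + amp * np.sin(omega * t + phase0)
                + np.interp(t, grid, jit_s))

    def dbp(t):
        return (profile.base_dbp + 0.5 * amp * np.sin(omega * t + phase0)
                + np.interp(t, grid, jit_d))

    return sbp, dbp


def _beat_train(profile: SyntheticSubjectProfile, fs: float, duration: float,
                rng: np.random.Generator,
                template_shift: np.ndarray | None = None):
    """Generate paired PPG/ABP sample streams beat by beat."""
    sbp_t, dbp_t = _drift(rng, profile, duration)
    n_total = int(round(duration * fs))
    ppg = np.empty(n_total)
    abp = np.empty(n_total)
    filled = 0
    t = 0.0
    hr_jit = 0.0
    while filled < n_total:
        if profile.hr_jitter_sd > 0.0:
            hr_jit = 0.8 * hr_jit + rng.normal(0.0, profile.hr_jitter_sd)
        hr = float(np.clip(profile.base_hr + hr_jit, 30.0, 200.0))
        n_beat = max(4, int(round(60.0 / hr * fs)))
        phase = np.arange(n_beat) / n_beat
        sbp = float(sbp_t(t))
        dbp = float(dbp_t(t))
        theta = _template_params(profile, sbp, dbp, hr)
        if template_shift is not None:
            theta = np.clip(theta + template_shift, _PARAM_LO, _PARAM_HI)
        beat_ppg = _pulse_template(phase, theta)
        shape = _pulse_template(phase, _ABP_THETA)
        shape = (shape - shape.min()) / (shape.max() - shape.min())
        beat_abp = dbp + (sbp - dbp) * shape
        take = min(n_beat, n_total - filled)
        ppg[filled:filled + take] = beat_ppg[:take]
        abp[filled:filled + take] = beat_abp[:take]
        filled += take
        t += n_beat / fs
    if profile.noise_sd > 0.0:
        ppg = ppg + rng.normal(0.0, profile.noise_sd, n_total)
    return ppg, abp, sbp_t, dbp_t


def generate_subject_record(profile: SyntheticSubjectProfile,
                            fs: float = 125.0) -> WaveformRecord:
    """Generate one subject's paired PPG/ABP record.

    ABP oscillates beat-synchronously between the instantaneous DBP and SBP
    trajectories (per-beat discrete min/max are exact).  PPG morphology is
    the population template modulated by instantaneous (SBP, DBP, HR) plus
    the fixed subject offset, plus white noise.  Deterministic for identical
    (profile, fs).
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    if fs <= 2.0 * (profile.base_hr / 60.0 * 4.0):
        raise ValueError("fs too low for the pulse and its harmonics")
    if profile.record_duration < 10.0:
        raise ValueError("record_duration must be at least 10 s")
    rng = np.random.default_rng(profile.seed)
    ppg, abp, _, _ = _beat_train(profile, fs, profile.record_duration, rng)
    return WaveformRecord(subject_id=profile.subject_id, ppg=ppg, abp=abp, fs=fs)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass
class CohortConfig:
    """Parameters of a synthetic cohort.

    ``subject_size_distribution`` is a log-normal on record duration in
    seconds (``{"median_s": ..., "sigma_log": ...}``), clipped to
    ``[min_duration_s, max_duration_s]``, emulating the long-tailed spread
    of samples per subject seen in large waveform databases.
    ``fraction_reject_material`` subjects are engineered to violate the
    plausibility ranges (SBP above 165 mmHg) so filter behaviour is
    testable.
    """

    n_subjects: int = 10
    seed: int = 0
    fraction_reject_material: float = 0.0
    subject_size_distribution: dict = field(
        default_factory=lambda: {"median_s": 300.0, "sigma_log": 0.8})
    min_duration_s: float = 60.0
    max_duration_s: float = 3600.0
    subject_offset_sd: float = 1.2   # in units of one z-score of the BP map
    noise_sd: float = 0.02
    bp_drift_amplitude: float = 5.0
    fs: float = 125.0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if not 0.0 <= self.fraction_reject_material <= 1.0:
            raise ValueError("fraction_reject_material must lie in [0, 1]")


@dataclass
class Cohort:
    records: list[WaveformRecord]
    profiles: list[SyntheticSubjectProfile]
    config: CohortConfig


def _subject_seed(cohort_seed: int, subject_id: str) -> int:
    digest = hashlib.sha256(f"{cohort_seed}:{subject_id}".encode()).digest()
    return int.from_bytes(digest[:4], "little")


def sample_profile(config: CohortConfig, index: int) -> SyntheticSubjectProfile:
    """Draw one subject profile; deterministic in (config.seed, index)."""
    sid = f"S{index:04d}"
    rng = np.random.default_rng(_subject_seed(config.seed, sid))
    reject = rng.random() < config.fraction_reject_material
    if reject:
        base_sbp = rng.uniform(172.0, 185.0)
        base_dbp = rng.uniform(60.0, 78.0)
    else:
        base_sbp = float(np.clip(rng.normal(120.0, 16.0), 85.0, 160.0))
        base_dbp = float(np.clip(rng.normal(60.0, 8.0), 45.0, 78.0))
        base_dbp = min(base_dbp, base_sbp - 25.0)
    dist = config.subject_size_distribution
    duration = float(np.clip(
        dist["median_s"] * np.exp(rng.normal(0.0, dist["sigma_log"])),
        config.min_duration_s, config.max_duration_s))
    # subject-specific shift of the morphology<->BP map, fixed for life
    offset = rng.normal(0.0, config.subject_offset_sd, 4) \
        * np.abs(MORPHOLOGY_BP_MAP[:, 0])
    return SyntheticSubjectProfile(
        subject_id=sid,
        base_hr=rng.uniform(55.0, 100.0),
        hr_jitter_sd=rng.uniform(0.5, 2.0),
        base_sbp=base_sbp,
        base_dbp=base_dbp,
        bp_drift_amplitude=config.bp_drift_amplitude,
        bp_drift_period=rng.uniform(40.0, 120.0),
        subject_offset=offset,
        noise_sd=config.noise_sd,
        record_duration=duration,
        seed=int(rng.integers(0, 2 ** 31 - 1)),
    )


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate a full cohort; byte-identical under the same config."""
    profiles = [sample_profile(config, i) for i in range(config.n_subjects)]
    records = [generate_subject_record(p, config.fs) for p in profiles]
    return Cohort(records=records, profiles=profiles, config=config)


# ---------------------------------------------------------------------------
# rPPG traces
# ---------------------------------------------------------------------------

@dataclass
class RgbTrace:
    """Per-frame ROI-mean RGB triplets with minute-grid reference BP.

    ``hidden_pulse`` is the embedded ground-truth pulse (zero mean, unit
    max amplitude) kept for verification of downstream extractors.
    """

    subject_id: str
    rgb: np.ndarray              # (n, 3)
    fs: float
    hidden_pulse: np.ndarray     # (n,)
    ref_times_s: np.ndarray      # minute grid, inclusive endpoints
    ref_sbp: np.ndarray
    ref_dbp: np.ndarray


def generate_rppg_trace(profile: SyntheticSubjectProfile, fs: float = 32.0,
                        pulse_strength: float = 0.05,
                        artifact_rate: float = 0.0,
                        template_shift: np.ndarray | None = None) -> RgbTrace:
    """Generate a camera-style RGB trace with an embedded pulse.

    The three channels are a slowly varying baseline intensity times
    ``(1 + channel_modulation * pulse_strength * pulse)``, strongest in
    green, plus motion-artifact transients at ``artifact_rate`` events/min
    and white noise.  Reference BP is sampled on the one-minute grid
    (inclusive endpoints: a 120 min trace yields 121 readings).
    ``template_shift`` perturbs the pulse template, injecting a
    morphology domain shift relative to contact PPG.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    if not 0.0 <= pulse_strength <= 1.0:
        raise ValueError("pulse_strength must lie in [0, 1]")
    rng = np.random.default_rng(profile.seed)
    duration = profile.record_duration
    n = int(round(duration * fs))
    pulse, _, sbp_t, dbp_t = _beat_train(
        replace_noise(profile, 0.0), fs, duration, rng,
        template_shift=template_shift)
    pulse = pulse - pulse.mean()
    peak = np.abs(pulse).max()
    if peak > 0.0:
        pulse = pulse / peak
    t = np.arange(n) / fs
    # shared illumination baseline times static per-channel gains: a pure
    # common-mode component that the POS projection cancels exactly
    illum = 1.0 + 0.05 * np.sin(2.0 * np.pi * t / 97.0 + rng.uniform(0, 2 * np.pi))
    gains = np.array([0.9, 1.0, 0.8])
    rgb = (illum[:, None] * gains) \
        * (1.0 + RGB_MODULATION * pulse_strength * pulse[:, None])
    n_events = rng.poisson(artifact_rate * duration / 60.0)
    for _ in range(n_events):
        center = rng.uniform(0.0, duration)
        width = rng.uniform(0.3, 1.5)
        amp = rng.uniform(0.2, 0.6)
        weights = rng.uniform(0.5, 1.0, 3)
        bump = amp * np.exp(-0.5 * ((t - center) / width) ** 2)
        rgb += bump[:, None] * weights
    if profile.noise_sd > 0.0:
        rgb = rgb + rng.normal(0.0, profile.noise_sd, rgb.shape)
    ref_times = np.arange(0.0, duration + 1e-9, 60.0)
    return RgbTrace(
        subject_id=profile.subject_id, rgb=rgb, fs=fs, hidden_pulse=pulse,
        ref_times_s=ref_times,
        ref_sbp=np.array([sbp_t(x) for x in ref_times], dtype=float),
        ref_dbp=np.array([dbp_t(x) for x in ref_times], dtype=float),
    )


def replace_noise(profile: SyntheticSubjectProfile,
                  noise_sd: float) -> SyntheticSubjectProfile:
    """Copy of a profile with a different noise level."""
    return _dc_replace(profile, noise_sd=noise_sd)
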