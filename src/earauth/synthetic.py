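"""Synthetic multi-subject, multi-task in-ear EEG generator.

The generator produces labeled corpora with the statistical structure the
authentication analysis relies on, so the whole pipeline can be exercised
without access to recorded EEG:

* a 1/f^2 pink-ish background whose band powers (delta/theta/alpha/beta/
  gamma) carry a subject-specific spectral fingerprint — the inherence
  factor;
* stable individual rhythms: an alpha oscillation with a per-person peak
  frequency, amplitude level and channel topography, plus a sparse
  "comb" of idiosyncratic narrowband oscillations at subject-specific
  frequencies in the 10-30 Hz range with stepped amplitudes — together
  these make identities separable window by window;
* eyes-closed alpha (8-12 Hz) elevation, attenuated by a subject-specific
  factor when the task is performed with eyes open;
* a 40 Hz auditory steady-state component for the *listen* task;
* per-(subject, task) "secret" sinusoidal signatures for tasks that carry
  a chosen passthought — the knowledge factor — rendered through a
  per-subject expression pattern, so a stolen secret is still expressed
  with the thief's own topography;
* white sensor noise, and optional >32 Hz EMG-like contamination for the
  muscle-artifact control analysis.

Channels are synthesized directly as left-mastoid-referenced microvolt
series; the reference channel is not emitted.  Everything is deterministic
given (seed, config): the same inputs reproduce the same corpus bit for bit.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .recording import CHANNEL_LABELS, Corpus, ProtocolConfig, Recording
from .tasks import TASK_BATTERY, TaskSpec, get_task

BAND_NAMES: tuple[str, ...] = ("delta", "theta", "alpha", "beta", "gamma")

# Fixed stream tags keep profile draws, imposter draws and trial noise
# statistically independent even when the same integer seed is reused.
_STREAM_PROFILE = 101
_STREAM_IMPOSTER = 202
_STREAM_TRIAL = 303


def _crc(text: str) -> int:
    return zlib.crc32(text.encode("utf-8"))


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic-EEG model.

    Amplitudes are in µV, frequencies in Hz.  ``base_gains`` set the mean
    relative band power; ``gain_spread`` is the log-normal sigma of the
    between-subject fingerprint in each band.  Gamma spread defaults to 0
    so that, with EMG disabled, no subject-discriminative structure lives
    above 32 Hz (the premise of the EMG control analysis).
    """

    band_edges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "delta": (1.0, 4.0),
            "theta": (4.0, 8.0),
            "alpha": (8.0, 12.0),
            "beta": (12.0, 30.0),
            "gamma": (30.0, 50.0),
        }
    )
    base_gains: dict[str, float] = field(
        default_factory=lambda: {
            "delta": 1.2,
            "theta": 1.0,
            "alpha": 1.2,
            "beta": 0.7,
            "gamma": 0.25,
        }
    )
    gain_spread: dict[str, float] = field(
        default_factory=lambda: {
            "delta": 1.0,
            "theta": 1.0,
            "alpha": 1.0,
            "beta": 1.0,
            "gamma": 0.0,
        }
    )
    channel_scales: dict[str, float] = field(
        default_factory=lambda: {
            "L_concha": 1.0,
            "L_front": 1.0,
            "L_back": 1.0,
            "R_concha": 1.0,
            "R_front": 1.0,
            "R_back": 1.0,
            "Fp1": 0.9,
            "R_mastoid": 0.5,
        }
    )
    bg_scale: float = 20.0          # background amplitude at 1 Hz, µV/√Hz
    psd_slope: float = 2.0          # background PSD ∝ f^-slope
    out_of_band_gain: float = 0.1   # gain applied above the gamma band
    alpha_attenuation_range: tuple[float, float] = (0.4, 0.7)
    assr_freq: float = 40.0
    assr_amplitude: float = 2.0
    assr_spread: float = 0.0        # log-normal sigma of per-subject ASSR amplitude
    secret_n_components: int = 2
    secret_freq_range: tuple[float, float] = (5.0, 28.0)
    secret_amp_range: tuple[float, float] = (2.5, 5.0)
    secret_weight_range: tuple[float, float] = (0.3, 1.0)
    alpha_peak_range: tuple[float, float] = (8.2, 11.8)  # individual alpha peak frequency
    alpha_amp_levels: tuple[float, ...] = (10.0, 16.0, 24.0)  # alpha amplitude levels, µV
    n_idio_oscillations: int = 5                         # size of the idiosyncratic comb
    idio_freq_grid: tuple[float, float, float] = (10.0, 30.0, 2.0)  # lo, hi, step (Hz)
    idio_amp_levels: tuple[float, ...] = (8.0, 14.0, 24.0)  # comb amplitude levels, µV
    osc_weight_levels: tuple[float, ...] = (0.6, 1.0, 1.4)  # per-channel topography levels
    expression_weight_range: tuple[float, float] = (0.5, 1.5)  # per-channel secret expression
    rhythm_trial_jitter: float = 0.1  # per-trial waxing/waning of rhythm amplitudes
    noise_sigma: float = 0.5        # white sensor noise, µV
    emg_enabled: bool = False
    emg_band: tuple[float, float] = (35.0, 80.0)
    emg_sigma_uv: float = 3.0       # RMS of the EMG-like component when enabled
    emg_subject_sigma: float = 0.0  # >0 makes the EMG band subject-specific

    def __post_init__(self) -> None:
        for name in BAND_NAMES:
            lo, hi = self.band_edges[name]
            if not 0 <= lo < hi:
                raise ValueError(f"invalid band edges for {name}: ({lo}, {hi})")
            if self.base_gains[name] <= 0:
                raise ValueError(f"base gain for {name} must be > 0")
            if self.gain_spread[name] < 0:
                raise ValueError(f"gain spread for {name} must be >= 0")
        if self.bg_scale <= 0 or self.noise_sigma < 0:
            raise ValueError("bg_scale must be > 0 and noise_sigma >= 0")
        lo, hi = self.alpha_attenuation_range
        if not 0 < lo <= hi <= 1:
            raise ValueError("alpha_attenuation_range must satisfy 0 < lo <= hi <= 1")
        if self.secret_n_components < 1:
            raise ValueError("secret_n_components must be >= 1")
        if self.assr_amplitude <= 0:
            raise ValueError("assr_amplitude must be > 0")

    def with_spread_factor(self, factor: float) -> "GeneratorConfig":
        """Copy of the config with every band's subject spread scaled."""
        return replace(
            self,
            gain_spread={b: s * factor for b, s in self.gain_spread.items()},
        )


@dataclass(frozen=True)
class TaskSecret:
    """Sinusoidal signature of one subject's chosen passthought for a task."""

    freqs_hz: tuple[float, ...]
    amps_uv: tuple[float, ...]
    channel_weights: tuple[float, ...]


@dataclass
class SubjectProfile:
    """A synthetic participant: spectral fingerprint plus task secrets."""

    subject_id: str
    fingerprint_gains: np.ndarray  # (n_channels, n_bands), dimensionless > 0
    alpha_open_attenuation: float
    alpha_peak_hz: float
    alpha_osc_uv: float
    alpha_osc_weights: np.ndarray  # per-channel rhythm topography
    idio_freqs_hz: np.ndarray      # comb of idiosyncratic oscillation frequencies
    idio_amps_uv: np.ndarray
    idio_weights: np.ndarray       # (n_osc, n_channels) topographies
    secret_expression: np.ndarray  # how this brain renders a chosen secret, per channel
    assr_amplitude: float
    task_secrets: dict[str, TaskSecret]
    seed: int
    fit_noise: float = 1.0
    emg_gains: np.ndarray | None = None  # per-channel, used when EMG is subject-specific

    def __post_init__(self) -> None:
        self.fingerprint_gains = np.asarray(self.fingerprint_gains, dtype=np.float64)
        if np.any(self.fingerprint_gains <= 0):
            raise ValueError("fingerprint gains must be strictly positive")
        if not 0 < self.alpha_open_attenuation <= 1:
            raise ValueError("alpha_open_attenuation must lie in (0, 1]")
        if self.assr_amplitude <= 0:
            raise ValueError("assr_amplitude must be > 0")
        if self.fit_noise < 1.0:
            raise ValueError("fit_noise is a degradation multiplier, must be >= 1")


def _draw_secret(rng: np.random.Generator, config: GeneratorConfig) -> TaskSecret:
    k = config.secret_n_components
    freqs = rng.uniform(*config.secret_freq_range, size=k)
    amps = rng.uniform(*config.secret_amp_range, size=k)
    weights = rng.uniform(*config.secret_weight_range, size=len(CHANNEL_LABELS))
    return TaskSecret(tuple(freqs), tuple(amps), tuple(weights))


def _build_profile(
    rng: np.random.Generator,
    subject_id: str,
    seed: int,
    config: GeneratorConfig,
) -> SubjectProfile:
    n_ch = len(CHANNEL_LABELS)
    n_bands = len(BAND_NAMES)
    # Raw normal draws come first so that rescaling the configured spreads
    # moves every subject's fingerprint along a common axis (the
    # separability knob is monotone under shared seeds).
    z = rng.standard_normal((n_ch, n_bands))
    sigmas = np.array([config.gain_spread[b] for b in BAND_NAMES])
    bases = np.array([config.base_gains[b] for b in BAND_NAMES])
    scales = np.array([config.channel_scales[lbl] for lbl in CHANNEL_LABELS])
    gains = bases[None, :] * scales[:, None] * np.exp(sigmas[None, :] * z)

    attenuation = rng.uniform(*config.alpha_attenuation_range)
    # Individual rhythms: each subject carries an alpha oscillation and a
    # beta-range idiosyncrasy rhythm whose center frequency and amplitude
    # are part of the fingerprint (the alpha peak frequency is a classic
    # per-person EEG trait).
    alpha_peak_hz = rng.uniform(*config.alpha_peak_range)
    alpha_osc_uv = float(rng.choice(config.alpha_amp_levels))
    # Each rhythm has its own spatial topography across channels, so two
    # subjects with colliding peak frequencies still differ in pattern.
    alpha_osc_weights = rng.choice(config.osc_weight_levels, size=n_ch)
    # Idiosyncratic comb: a sparse set of stable narrowband oscillations
    # at subject-specific frequencies with stepped amplitudes and
    # topographies.  A foreign brain almost surely misses part of the
    # comb and puts power where this subject has none, which is what
    # makes identities separable and outsiders rejectable.
    k = config.n_idio_oscillations
    lo, hi, step = config.idio_freq_grid
    grid_f = np.arange(lo, hi + step / 2, step)
    idio_freqs = rng.choice(grid_f, size=min(k, grid_f.size), replace=False)
    idio_amps = rng.choice(config.idio_amp_levels, size=idio_freqs.size)
    idio_weights = rng.choice(config.osc_weight_levels, size=(idio_freqs.size, n_ch))
    # The neural rendering of a chosen secret is part of the wearer's
    # identity: even a copied passthought is expressed with this pattern.
    secret_expression = rng.uniform(*config.expression_weight_range, size=n_ch)
    assr = config.assr_amplitude * float(np.exp(config.assr_spread * rng.standard_normal()))
    z_emg = rng.standard_normal(n_ch)
    emg_gains = np.exp(config.emg_subject_sigma * z_emg)

    secrets: dict[str, TaskSecret] = {}
    for task in TASK_BATTERY:
        if task.has_secret:
            secrets[task.name] = _draw_secret(rng, config)

    return SubjectProfile(
        subject_id=subject_id,
        fingerprint_gains=gains,
        alpha_open_attenuation=attenuation,
        alpha_peak_hz=alpha_peak_hz,
        alpha_osc_uv=alpha_osc_uv,
        alpha_osc_weights=alpha_osc_weights,
        idio_freqs_hz=idio_freqs,
        idio_amps_uv=idio_amps,
        idio_weights=idio_weights,
        secret_expression=secret_expression,
        assr_amplitude=assr,
        task_secrets=secrets,
        seed=seed,
        emg_gains=emg_gains,
    )


def make_subject_profile(
    seed: int,
    config: GeneratorConfig | None = None,
    subject_id: str | None = None,
) -> SubjectProfile:
    """Draw one synthetic participant, deterministically per (seed, config)."""
    if seed < 0:
        raise ValueError("seed must be a non-negative integer")
    config = config or GeneratorConfig()
    rng = np.random.default_rng(np.random.SeedSequence([_STREAM_PROFILE, seed]))
    return _build_profile(rng, subject_id or f"P{seed}", seed, config)


def make_imposter_profile(
    target: SubjectProfile,
    knowledge_level: float,
    seed: int,
    config: GeneratorConfig | None = None,
    fit_noise: float = 1.0,
    subject_id: str | None = None,
) -> SubjectProfile:
    """An attacker who may know the target's secrets but never their brain.

    ``knowledge_level`` interpolates the imposter's task secrets between
    independent draws (0: knows nothing) and the target's exact secret
    parameters (1: has the written-down passthought list).  The spectral
    fingerprint is always the imposter's own.  ``fit_noise`` > 1 models a
    borrowed earpiece fitting poorly (extra sensor noise).
    """
    if not 0 <= knowledge_level <= 1:
        raise ValueError("knowledge_level must lie in [0, 1]")
    config = config or GeneratorConfig()
    rng = np.random.default_rng(np.random.SeedSequence([_STREAM_IMPOSTER, seed]))
    own = _build_profile(rng, subject_id or f"X{seed}", seed, config)

    blended: dict[str, TaskSecret] = {}
    for name, own_secret in own.task_secrets.items():
        tgt = target.task_secrets.get(name)
        if tgt is None:
            blended[name] = own_secret
            continue
        lam = knowledge_level
        blended[name] = TaskSecret(
            tuple(lam * t + (1 - lam) * o for t, o in zip(tgt.freqs_hz, own_secret.freqs_hz)),
            tuple(lam * t + (1 - lam) * o for t, o in zip(tgt.amps_uv, own_secret.amps_uv)),
            tuple(
                lam * t + (1 - lam) * o
                for t, o in zip(tgt.channel_weights, own_secret.channel_weights)
            ),
        )
    own.task_secrets = blended
    own.fit_noise = fit_noise
    return own


def _band_gain_per_freq(
    freqs: np.ndarray, profile: SubjectProfile, config: GeneratorConfig, eyes_open: bool
) -> np.ndarray:
    """(n_channels, n_freqs) gain map from the banded fingerprint."""
    n_ch = len(CHANNEL_LABELS)
    gains = np.full((n_ch, freqs.size), config.out_of_band_gain)
    fp = profile.fingerprint_gains.copy()
    if eyes_open:
        fp[:, BAND_NAMES.index("alpha")] *= profile.alpha_open_attenuation
    lo0 = config.band_edges[BAND_NAMES[0]][0]
    for bi, band in enumerate(BAND_NAMES):
        lo, hi = config.band_edges[band]
        mask = (freqs >= lo) & (freqs < hi)
        gains[:, mask] = fp[:, bi : bi + 1]
    below = (freqs > 0) & (freqs < lo0)  # sub-delta rolloff inherits the delta gain
    gains[:, below] = fp[:, 0:1]
    return gains


def _colored_noise(
    rng: np.random.Generator,
    psd: np.ndarray,
    n_samples: int,
    fs: float,
) -> np.ndarray:
    """Gaussian noise with one-sided PSD ``psd`` (µV²/Hz), rows = channels.

    Synthesized in the frequency domain: each rFFT bin gets a complex
    Gaussian with variance chosen so the inverse transform has variance
    ∫ PSD df (Parseval).
    """
    n_ch, n_freq = psd.shape
    df = fs / n_samples
    sigma = n_samples * np.sqrt(psd * df / 2.0)
    zr = rng.standard_normal((n_ch, n_freq))
    zi = rng.standard_normal((n_ch, n_freq))
    spectrum = sigma * (zr + 1j * zi) / np.sqrt(2.0)
    spectrum[:, 0] = 0.0
    return np.fft.irfft(spectrum, n=n_samples, axis=1)


def synthesize_trial(
    profile: SubjectProfile,
    task: TaskSpec | str,
    protocol: ProtocolConfig | None = None,
    trial_index: int = 0,
    seed: int = 0,
    config: GeneratorConfig | None = None,
) -> Recording:
    """Generate one labeled 10 s (by default) trial for a subject and task."""
    if isinstance(task, str):
        task = get_task(task)
    protocol = protocol or ProtocolConfig()
    config = config or GeneratorConfig()
    if protocol.trial_duration_s <= 0:
        raise ValueError("trial duration must be positive")

    n = protocol.samples_per_trial
    fs = protocol.fs
    rng = np.random.default_rng(
        np.random.SeedSequence(
            [_STREAM_TRIAL, seed, _crc(profile.subject_id), _crc(task.name), trial_index]
        )
    )

    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    gains = _band_gain_per_freq(freqs, profile, config, task.eyes_open)
    # Background PSD: (bg_scale * gain)^2 * f^-slope, clamped below 1 Hz.
    f_eff = np.maximum(freqs, 1.0)
    psd = (config.bg_scale * gains) ** 2 * f_eff ** (-config.psd_slope)
    psd[:, 0] = 0.0
    data = _colored_noise(rng, psd, n, fs)

    t = np.arange(n) / fs
    scales = np.array([config.channel_scales[lbl] for lbl in CHANNEL_LABELS])

    # Subject-specific rhythms (inherence factor): present in every task.
    att = profile.alpha_open_attenuation if task.eyes_open else 1.0
    j = config.rhythm_trial_jitter
    rhythms = [(profile.alpha_peak_hz, att * profile.alpha_osc_uv, profile.alpha_osc_weights)]
    rhythms += [
        (f0, a, w)
        for f0, a, w in zip(profile.idio_freqs_hz, profile.idio_amps_uv, profile.idio_weights)
    ]
    for f0, amp, weights in rhythms:
        phase = rng.uniform(0, 2 * np.pi)
        # Rhythms wax and wane between attempts: per-trial amplitude jitter.
        amp_t = amp * rng.uniform(1.0 - j, 1.0 + j)
        w = scales * np.asarray(weights)
        data += w[:, None] * (amp_t * np.sin(2 * np.pi * f0 * t + phase))[None, :]

    if task.name == "listen":
        phase = rng.uniform(0, 2 * np.pi)
        assr = profile.assr_amplitude * np.sin(2 * np.pi * config.assr_freq * t + phase)
        data += scales[:, None] * assr[None, :]

    secret = profile.task_secrets.get(task.name)
    if task.has_secret and secret is not None:
        # The secret's parameters are its content; the per-channel
        # expression pattern belongs to the subject performing it.
        w = np.asarray(secret.channel_weights) * np.asarray(profile.secret_expression)
        for f0, amp in zip(secret.freqs_hz, secret.amps_uv):
            phase = rng.uniform(0, 2 * np.pi)
            amp_t = amp * rng.uniform(1.0 - config.rhythm_trial_jitter,
                                      1.0 + config.rhythm_trial_jitter)
            data += w[:, None] * (amp_t * np.sin(2 * np.pi * f0 * t + phase))[None, :]

    if config.emg_enabled:
        lo, hi = config.emg_band
        in_band = (freqs >= lo) & (freqs <= hi)
        bw = max(in_band.sum() * fs / n, 1e-9)
        emg_psd = np.where(in_band, config.emg_sigma_uv**2 / bw, 0.0)
        emg_psd = np.tile(emg_psd, (len(CHANNEL_LABELS), 1))
        emg = _colored_noise(rng, emg_psd, n, fs)
        if config.emg_subject_sigma > 0 and profile.emg_gains is not None:
            emg *= np.asarray(profile.emg_gains)[:, None]
        data += emg

    if config.noise_sigma > 0:
        data += rng.normal(0.0, config.noise_sigma * profile.fit_noise, data.shape)

    return Recording(
        data=data,
        fs=fs,
        channel_labels=CHANNEL_LABELS,
        subject_id=profile.subject_id,
        task_name=task.name,
        trial_index=trial_index,
    )


def synthesize_corpus(
    profiles: Sequence[SubjectProfile],
    protocol: ProtocolConfig | None = None,
    seed: int = 0,
    config: GeneratorConfig | None = None,
    tasks: Sequence[TaskSpec] = TASK_BATTERY,
) -> Corpus:
    """Generate the full recording protocol for every profile.

    Each (subject, task) pair receives ``protocol.n_trials`` trials with
    indices 0..n-1; the result holds n_profiles x n_tasks x n_trials
    recordings and is reproducible bit for bit per (seed, config).
    """
    if len(profiles) == 0:
        raise ValueError("need at least one subject profile")
    ids = [p.subject_id for p in profiles]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate subject ids: {ids}")
    protocol = protocol or ProtocolConfig()
    config = config or GeneratorConfig()
    recs = []
    for profile in profiles:
        for task in tasks:
            for trial in range(protocol.n_trials):
                recs.append(
                    synthesize_trial(profile, task, protocol, trial, seed=seed, config=config)
                )
    return Corpus(recordings=recs)


def make_study_profiles(
    n_subjects: int = 7,
    seed: int = 0,
    config: GeneratorConfig | None = None,
) -> list[SubjectProfile]:
    """Draw a study cohort (default 7 subjects, P1..Pn) from a master seed."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([_STREAM_PROFILE, 7, seed]))
    child_seeds = rng.integers(0, 2**31 - 1, size=n_subjects)
    return [
        make_subject_profile(int(s), config=config, subject_id=f"P{i + 1}")
        for i, s in enumerate(child_seeds)
    ]


def make_study_corpus(
    n_subjects: int = 7,
    seed: int = 0,
    config: GeneratorConfig | None = None,
    protocol: ProtocolConfig | None = None,
) -> tuple[list[SubjectProfile], Corpus]:
    """Cohort + full protocol corpus in one call (the default study setup)."""
    profiles = make_study_profiles(n_subjects, seed=seed, config=config)
    corpus = synthesize_corpus(profiles, protocol=protocol, seed=seed, config=config)
    return profiles, corpus
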