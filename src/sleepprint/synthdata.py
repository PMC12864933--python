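"""Seeded synthetic two-night sleep-EEG cohorts.

The generator plants the statistical structure the downstream analysis is
designed to detect (or to show absent):

* **Individual spectral fingerprints** — each subject owns an aperiodic
  spectrum ``log10 P(f) = b - log10(k + f^chi)`` plus Gaussian oscillatory
  peaks and per-channel gains; the *same* fingerprint is reused for both
  nights, giving trait-like structure, with a small per-night drift.
* **Group-level hypnogram dynamics** — first-order Markov chains over the
  five AASM stages with a transition matrix per ISI severity group.
* **No group spectral effect by default** — matching the null finding the
  analysis is built around: insomnia severity does not shift the spectrum,
  individuals do.
* **Nuisance structure** — rare high-amplitude artifact epochs and 50 Hz
  line noise, for the rejection and interpolation stages to remove.

Signals are synthesized by spectral shaping: complex-Gaussian Fourier
coefficients with expected power equal to the target PSD, inverted to the
time domain.  This gives exact control of the expected Welch spectrum, so
planted parameters can be recovered and asserted downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .recording import DEFAULT_CHANNELS, STAGES, EpochedRecording

ISI_GROUPS: tuple[str, ...] = ("GSC", "MI", "MSI")

#: ISI questionnaire score interval per severity category (inclusive).
ISI_INTERVALS: dict[str, tuple[int, int]] = {
    "GSC": (0, 7),
    "MI": (8, 14),
    "MSI": (15, 28),
}


class ConfigurationError(ValueError):
    """A generator specification violates its invariants."""


# ----------------------------------------------------------------------
# specs
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class CohortSpec:
    """Size and sampling layout of a synthetic cohort."""

    n_subjects_per_group: int = 6
    n_nights: int = 2
    epochs_per_night: int = 960
    sampling_rate: float = 200.0
    n_channels: int = 20
    channel_names: tuple[str, ...] | None = None
    epoch_s: float = 30.0
    seed: int = 0

    def channels(self) -> tuple[str, ...]:
        names = (
            self.channel_names
            if self.channel_names is not None
            else DEFAULT_CHANNELS[: self.n_channels]
        )
        if len(names) != self.n_channels:
            raise ConfigurationError(
                f"need {self.n_channels} channel labels, got {len(names)}"
            )
        if len(set(names)) != len(names):
            raise ConfigurationError("channel labels must be unique")
        return tuple(names)

    def validate(self) -> None:
        for name in ("n_subjects_per_group", "n_nights", "epochs_per_night",
                     "n_channels"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if self.sampling_rate < 2 * 100.0:
            raise ConfigurationError(
                "sampling_rate must be at least twice the highest synthesized "
                "frequency (100 Hz)"
            )
        self.channels()


@dataclass
class SubjectFingerprint:
    """A subject's trait-like spectral identity.

    The aperiodic backbone is ``log10 P(f) = offset - log10(knee + f**exponent)``
    (power in uV^2/Hz); ``peaks`` are ``(center_hz, height_log10, sd_hz)``
    Gaussians added in log10 space; ``channel_gain`` scales power per channel;
    ``stage_offset``/``stage_exponent`` are additive per-stage modulations
    relative to the REM baseline.
    """

    offset: float
    knee: float
    exponent: float
    peaks: list[tuple[float, float, float]] = field(default_factory=list)
    channel_gain: np.ndarray | None = None
    stage_offset: dict[str, float] = field(default_factory=dict)
    stage_exponent: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        if self.knee < 0:
            raise ConfigurationError("knee must be >= 0")
        if self.exponent <= 0:
            raise ConfigurationError("exponent must be > 0")
        for cf, height, sd in self.peaks:
            if not (0.5 <= cf <= 100.0):
                raise ConfigurationError(
                    f"peak center {cf} Hz outside [0.5, 100]"
                )
            if height < 0:
                raise ConfigurationError("peak height must be >= 0")
            if sd <= 0:
                raise ConfigurationError("peak sd must be > 0")
        for stage, dchi in self.stage_exponent.items():
            if self.exponent + dchi <= 0:
                raise ConfigurationError(
                    f"stage {stage} modulation drives the exponent non-positive"
                )

    def log10_psd(self, freqs: np.ndarray, stage: str = "R",
                  channel: int | None = None) -> np.ndarray:
        """Target log10 PSD (uV^2/Hz) on ``freqs`` for one stage/channel.

        Frequencies below 0.5 Hz are clamped to the 0.5 Hz value so the
        k = 0 (pure power-law) mode stays finite at DC.
        """
        f = np.maximum(np.asarray(freqs, dtype=float), 0.5)
        b = self.offset + self.stage_offset.get(stage, 0.0)
        chi = self.exponent + self.stage_exponent.get(stage, 0.0)
        out = b - np.log10(self.knee + f**chi)
        for cf, height, sd in self.peaks:
            out = out + height * np.exp(-((f - cf) ** 2) / (2 * sd**2))
        if channel is not None and self.channel_gain is not None:
            out = out + np.log10(self.channel_gain[channel])
        return out


@dataclass(frozen=True)
class GroupDynamics:
    """First-order Markov hypnogram dynamics for one severity group."""

    transition: np.ndarray  # (5, 5), rows ordered as STAGES
    initial: np.ndarray  # (5,)

    def validate(self) -> None:
        t = np.asarray(self.transition, dtype=float)
        p0 = np.asarray(self.initial, dtype=float)
        if t.shape != (5, 5) or p0.shape != (5,):
            raise ConfigurationError("transition must be 5x5 and initial 5-long")
        if np.any(t < 0) or np.any(t > 1) or np.any(p0 < 0):
            raise ConfigurationError("probabilities must lie in [0, 1]")
        if not np.allclose(t.sum(axis=1), 1.0, atol=1e-9):
            raise ConfigurationError("each transition row must sum to 1")
        if not np.isclose(p0.sum(), 1.0, atol=1e-9):
            raise ConfigurationError("initial distribution must sum to 1")


@dataclass(frozen=True)
class ArtifactSpec:
    """Planted nuisance structure.

    ``transient_amplitude_uv`` is the peak amplitude of the 25 Hz square
    transient added (on every channel) to an artifact epoch; at a 200 Hz
    working rate its mean adjacent-sample difference is ``amplitude / 2``,
    which is the score the rejection rule sees.  ``line_noise_amplitude_uv``
    is the peak amplitude of the common-mode mains sinusoid.
    """

    epoch_probability: float = 0.02
    transient_amplitude_uv: float = 20.0
    line_noise_hz: float = 50.0
    line_noise_amplitude_uv: float = 2.0

    def validate(self) -> None:
        if not (0.0 <= self.epoch_probability <= 1.0):
            raise ConfigurationError("artifact probability must be in [0, 1]")
        if self.transient_amplitude_uv < 0 or self.line_noise_amplitude_uv < 0:
            raise ConfigurationError("amplitudes must be >= 0")


@dataclass(frozen=True)
class FingerprintPrior:
    """Population distribution the per-subject fingerprints are drawn from.

    Defaults reflect typical adult sleep EEG shape: a REM-baseline exponent
    around 2.0 with NREM (N2, N3) raised by ~0.4 in offset and ~0.3 in
    exponent; alpha and sigma oscillatory peaks; between-subject spreads of
    ~0.4 (offset) and ~0.2 (exponent).  The absolute offset scale is set so
    that typical clean epochs score well below the 5 uV amplitude-difference
    rejection threshold (the simulated montage's reference gain is
    arbitrary; only log-power contrasts matter downstream).  The
    night-to-night drift is a small re-draw of offset/exponent per night —
    large enough that a classifier generalizes imperfectly across nights,
    far smaller than the between-subject spread.
    """

    offset_mean: float = 1.2
    offset_sd: float = 0.4
    knee_mean: float = 10.0
    knee_sd: float = 3.0
    exponent_mean: float = 2.0
    exponent_sd: float = 0.2
    # (cf_mean, cf_sd, height_mean, height_sd, sd_mean, sd_sd) per template
    peak_templates: tuple[tuple[float, ...], ...] = (
        (10.0, 0.8, 0.35, 0.12, 1.2, 0.2),   # alpha
        (13.5, 0.5, 0.30, 0.10, 1.0, 0.15),  # sigma / slow spindle
    )
    channel_gain_log10_sd: float = 0.08
    nrem_offset_delta: float = 0.4
    nrem_exponent_delta: float = 0.3
    night_drift_offset_sd: float = 0.10
    night_drift_exponent_sd: float = 0.06
    epoch_offset_jitter_sd: float = 0.03

    def draw(self, n_channels: int, rng: np.random.Generator
             ) -> SubjectFingerprint:
        offset = rng.normal(self.offset_mean, self.offset_sd)
        knee = max(0.0, rng.normal(self.knee_mean, self.knee_sd))
        exponent = max(0.2, rng.normal(self.exponent_mean, self.exponent_sd))
        peaks = []
        for cf_m, cf_s, h_m, h_s, sd_m, sd_s in self.peak_templates:
            cf = float(np.clip(rng.normal(cf_m, cf_s), 0.5, 100.0))
            height = max(0.0, rng.normal(h_m, h_s))
            sd = max(0.3, rng.normal(sd_m, sd_s))
            peaks.append((cf, height, sd))
        gain = 10.0 ** rng.normal(0.0, self.channel_gain_log10_sd, n_channels)
        fp = SubjectFingerprint(
            offset=offset,
            knee=knee,
            exponent=exponent,
            peaks=peaks,
            channel_gain=gain,
            stage_offset={
                "W": 0.0,
                "N1": self.nrem_offset_delta / 2,
                "N2": self.nrem_offset_delta,
                "N3": self.nrem_offset_delta,
                "R": 0.0,
            },
            stage_exponent={
                "W": 0.0,
                "N1": self.nrem_exponent_delta / 2,
                "N2": self.nrem_exponent_delta,
                "N3": self.nrem_exponent_delta,
                "R": 0.0,
            },
        )
        fp.validate()
        return fp

    def drift(self, fp: SubjectFingerprint, rng: np.random.Generator
              ) -> SubjectFingerprint:
        """One night's perturbation of a trait fingerprint."""
        out = replace(
            fp,
            offset=fp.offset + rng.normal(0.0, self.night_drift_offset_sd),
            exponent=max(
                0.2, fp.exponent + rng.normal(0.0, self.night_drift_exponent_sd)
            ),
        )
        return out


def gamma_focus_prior() -> FingerprintPrior:
    """A prior whose between-subject variance is concentrated in the gamma
    range: common low-frequency spectrum, subject-specific gamma peaks.

    Used to probe whether feature attribution recovers the planted location
    of identity information.
    """
    return FingerprintPrior(
        offset_sd=0.02,
        knee_sd=0.5,
        exponent_sd=0.02,
        peak_templates=(
            (10.0, 0.05, 0.30, 0.01, 1.2, 0.05),   # shared alpha
            (40.0, 3.0, 0.45, 0.15, 3.0, 0.5),     # subject gamma peak
            (70.0, 8.0, 0.40, 0.15, 5.0, 0.8),     # subject high-gamma peak
        ),
        channel_gain_log10_sd=0.01,
    )


# ----------------------------------------------------------------------
# default group dynamics
# ----------------------------------------------------------------------
def _normalize_rows(m: np.ndarray) -> np.ndarray:
    return m / m.sum(axis=1, keepdims=True)


def default_group_dynamics() -> dict[str, GroupDynamics]:
    """Per-ISI-group transition matrices over (W, N1, N2, N3, R).

    The matrices encode the sleep-fragmentation gradient reported for
    insomnia: with increasing severity, higher wake continuity, lower N2/N3
    continuity, more N2<->N3 shuttling, and a lower probability of leaving
    wake into sleep.  Nights begin in wake.
    """
    gsc = np.array([
        #  W     N1     N2     N3     R
        [0.800, 0.130, 0.040, 0.005, 0.025],  # W
        [0.100, 0.550, 0.300, 0.005, 0.045],  # N1
        [0.014, 0.020, 0.926, 0.030, 0.010],  # N2
        [0.005, 0.005, 0.050, 0.935, 0.005],  # N3
        [0.020, 0.030, 0.020, 0.002, 0.928],  # R
    ])
    mi = np.array([
        [0.840, 0.110, 0.025, 0.004, 0.021],
        [0.140, 0.530, 0.280, 0.005, 0.045],
        [0.022, 0.026, 0.902, 0.040, 0.010],
        [0.008, 0.007, 0.075, 0.900, 0.010],
        [0.025, 0.032, 0.020, 0.002, 0.921],
    ])
    msi = np.array([
        [0.870, 0.095, 0.018, 0.003, 0.014],
        [0.160, 0.520, 0.270, 0.005, 0.045],
        [0.026, 0.028, 0.896, 0.038, 0.012],
        [0.009, 0.008, 0.070, 0.903, 0.010],
        [0.028, 0.034, 0.020, 0.002, 0.916],
    ])
    initial = np.array([1.0, 0.0, 0.0, 0.0, 0.0])
    out = {}
    for name, mat in (("GSC", gsc), ("MI", mi), ("MSI", msi)):
        dyn = GroupDynamics(_normalize_rows(mat), initial)
        dyn.validate()
        out[name] = dyn
    return out


# ----------------------------------------------------------------------
# generation
# ----------------------------------------------------------------------
def generate_hypnogram(dynamics: GroupDynamics, epochs: int,
                       rng: np.random.Generator) -> list[str]:
    """Sample a stage sequence from a first-order Markov chain.

    The first stage is drawn from the initial distribution; each subsequent
    stage from the transition row of its predecessor.
    """
    dynamics.validate()
    if epochs < 1:
        raise ConfigurationError("epochs must be >= 1")
    t = np.asarray(dynamics.transition, dtype=float)
    cum = np.cumsum(t, axis=1)
    cum_init = np.cumsum(np.asarray(dynamics.initial, dtype=float))
    u = rng.random(epochs)
    states = np.empty(epochs, dtype=np.int64)
    states[0] = np.searchsorted(cum_init, u[0], side="right")
    for i in range(1, epochs):
        states[i] = np.searchsorted(cum[states[i - 1]], u[i], side="right")
    states = np.minimum(states, 4)  # guard against u == 1.0 edge
    return [STAGES[s] for s in states]


def _shaped_noise(log10_psd: np.ndarray, n_samples: int, sfreq: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Zero-mean Gaussian signals with expected one-sided PSD ``10**log10_psd``.

    ``log10_psd`` has shape ``(..., n_rfft)`` on the rfft frequency grid of
    ``n_samples`` at ``sfreq``; returns shape ``(..., n_samples)``.
    """
    psd = 10.0 ** np.asarray(log10_psd, dtype=float)
    # E|X_k|^2 = P(f_k) * fs * N / 2 for interior bins of an rfft
    scale = np.sqrt(psd * sfreq * n_samples / 4.0)
    shape = psd.shape
    re = rng.standard_normal(shape)
    im = rng.standard_normal(shape)
    coeffs = (re + 1j * im) * scale
    coeffs[..., 0] = 0.0  # zero mean
    if n_samples % 2 == 0:
        coeffs[..., -1] = re[..., -1] * np.sqrt(2.0) * scale[..., -1]
    return np.fft.irfft(coeffs, n=n_samples, axis=-1)


def generate_epoch_signal(fingerprint: SubjectFingerprint, stage: str,
                          channel: int, duration: float, sampling_rate: float,
                          rng: np.random.Generator) -> np.ndarray:
    """One epoch of one channel, microvolts, by spectral shaping.

    The expected Welch log10 PSD equals the fingerprint's target spectrum
    for ``stage`` and ``channel``.  Deterministic given the rng state.
    """
    fingerprint.validate()
    n = int(round(duration * sampling_rate))
    if n < 2:
        raise ConfigurationError("duration x rate must give >= 2 samples")
    freqs = np.fft.rfftfreq(n, 1.0 / sampling_rate)
    target = fingerprint.log10_psd(freqs, stage=stage, channel=channel)
    return _shaped_noise(target, n, sampling_rate, rng)


def _transient_wave(n_samples: int, sfreq: float, amplitude: float
                    ) -> np.ndarray:
    """25 Hz square transient; mean |adjacent diff| ~= amplitude/2 at 200 Hz."""
    t = np.arange(n_samples) / sfreq
    return amplitude * np.sign(np.sin(2 * np.pi * 25.0 * t) + 1e-12)


def generate_recording(
    fingerprint: SubjectFingerprint,
    hypnogram: list[str],
    spec: CohortSpec,
    artifacts: ArtifactSpec | None,
    rng: np.random.Generator,
    epoch_offset_jitter_sd: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthesize the full signal matrix for one night.

    Returns ``(data, artifact_truth)`` with ``data`` of shape
    ``(n_channels, n_epochs * samples_per_epoch)`` in microvolts and
    ``artifact_truth`` a per-epoch boolean array.
    """
    n_ch = spec.n_channels
    spe = int(round(spec.epoch_s * spec.sampling_rate))
    n_ep = len(hypnogram)
    freqs = np.fft.rfftfreq(spe, 1.0 / spec.sampling_rate)
    data = np.empty((n_ch, n_ep * spe), dtype=np.float64)

    # per-stage Fourier amplitude scales for all channels: (n_ch, n_freq)
    stage_scale = {}
    for stage in set(hypnogram):
        base = fingerprint.log10_psd(freqs, stage=stage)
        gains = (
            np.log10(fingerprint.channel_gain)[:, None]
            if fingerprint.channel_gain is not None
            else np.zeros((n_ch, 1))
        )
        target = base[None, :] + gains
        scale = np.sqrt(10.0**target * spec.sampling_rate * spe / 4.0)
        scale[:, 0] = 0.0  # zero mean
        stage_scale[stage] = scale

    jitter = (
        rng.normal(0.0, epoch_offset_jitter_sd, n_ep)
        if epoch_offset_jitter_sd > 0
        else np.zeros(n_ep)
    )
    nf = len(freqs)
    for i, stage in enumerate(hypnogram):
        re = rng.standard_normal((n_ch, nf))
        im = rng.standard_normal((n_ch, nf))
        coeffs = (re + 1j * im) * (stage_scale[stage] * 10 ** (jitter[i] / 2))
        if spe % 2 == 0:  # Nyquist bin must be real
            coeffs[:, -1] = (
                re[:, -1] * np.sqrt(2.0)
                * stage_scale[stage][:, -1] * 10 ** (jitter[i] / 2)
            )
        data[:, i * spe : (i + 1) * spe] = np.fft.irfft(
            coeffs, n=spe, axis=-1
        )

    artifact_truth = np.zeros(n_ep, dtype=bool)
    if artifacts is not None:
        artifacts.validate()
        if artifacts.line_noise_amplitude_uv > 0:
            t = np.arange(data.shape[1]) / spec.sampling_rate
            data += artifacts.line_noise_amplitude_uv * np.sin(
                2 * np.pi * artifacts.line_noise_hz * t
            )
        if artifacts.epoch_probability > 0:
            artifact_truth = rng.random(n_ep) < artifacts.epoch_probability
            wave = _transient_wave(
                spe, spec.sampling_rate, artifacts.transient_amplitude_uv
            )
            for i in np.flatnonzero(artifact_truth):
                data[:, i * spe : (i + 1) * spe] += wave
    return data, artifact_truth


def random_spectrum_params(
    rng: np.random.Generator,
    offset_range: tuple[float, float] = (1.0, 3.0),
    knee_range: tuple[float, float] = (0.0, 30.0),
    exponent_range: tuple[float, float] = (1.5, 3.0),
    n_peaks_range: tuple[int, int] = (0, 3),
    center_range: tuple[float, float] = (8.0, 30.0),
    height_range: tuple[float, float] = (0.15, 0.7),
    sd_range: tuple[float, float] = (0.8, 2.0),
    min_separation: float = 4.0,
) -> tuple[float, float, float, list[tuple[float, float, float]]]:
    """Draw aperiodic + peak parameters for a random synthetic periodogram.

    Peak centers are kept at least ``min_separation`` Hz apart and above
    the knee-curvature region (alpha and up by default) so the planted
    rhythms are distinct and the decomposition identifiable: a small peak
    riding the knee bend is absorbed into the backbone by any fitter whose
    detection floor it undercuts.  Returns ``(offset, knee, exponent,
    peaks)``.
    """
    b = rng.uniform(*offset_range)
    k = rng.uniform(*knee_range)
    chi = rng.uniform(*exponent_range)
    n_peaks = int(rng.integers(n_peaks_range[0], n_peaks_range[1] + 1))
    centers: list[float] = []
    tries = 0
    while len(centers) < n_peaks and tries < 100:
        c = rng.uniform(*center_range)
        if all(abs(c - c0) >= min_separation for c0 in centers):
            centers.append(c)
        tries += 1
    peaks = [
        (c, rng.uniform(*height_range), rng.uniform(*sd_range))
        for c in sorted(centers)
    ]
    return b, k, chi, peaks


def synthetic_log_periodogram(
    freqs: np.ndarray, offset: float, knee: float, exponent: float,
    peaks: list[tuple[float, float, float]], noise_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Noisy log10 spectrum from explicit aperiodic + Gaussian parameters."""
    f = np.asarray(freqs, dtype=float)
    p = offset - np.log10(knee + f**exponent)
    for c, h, s in peaks:
        p = p + h * np.exp(-((f - c) ** 2) / (2 * s**2))
    return p + rng.normal(0.0, noise_sd, len(f))


@dataclass
class Cohort:
    """A generated cohort plus its planted ground truth."""

    recordings: list[EpochedRecording]
    metadata: pd.DataFrame  # subject_id, night, group, isi_score, seed
    fingerprints: dict[str, SubjectFingerprint]  # trait (pre-drift) truth
    dynamics: dict[str, GroupDynamics]
    spec: CohortSpec


def generate_cohort(
    spec: CohortSpec,
    prior: FingerprintPrior | None = None,
    dynamics: dict[str, GroupDynamics] | None = None,
    artifacts: ArtifactSpec | None = None,
) -> Cohort:
    """Generate one EpochedRecording per subject-night.

    The same trait fingerprint is reused for every night of a subject (with
    the prior's night drift applied per night); ISI scores are drawn
    uniformly inside the category interval; planted fingerprints and
    transition matrices are returned for recovery tests.  Fully
    deterministic given ``spec.seed``.
    """
    spec.validate()
    prior = prior if prior is not None else FingerprintPrior()
    dynamics = dynamics if dynamics is not None else default_group_dynamics()
    if artifacts is None:
        artifacts = ArtifactSpec()
    rng = np.random.default_rng(spec.seed)

    recordings: list[EpochedRecording] = []
    fingerprints: dict[str, SubjectFingerprint] = {}
    rows = []
    for group in ISI_GROUPS:
        dyn = dynamics[group]
        lo, hi = ISI_INTERVALS[group]
        for j in range(spec.n_subjects_per_group):
            subject_id = f"{group}{j + 1:02d}"
            trait = prior.draw(spec.n_channels, rng)
            fingerprints[subject_id] = trait
            isi_score = int(rng.integers(lo, hi + 1))
            for night in range(1, spec.n_nights + 1):
                night_fp = prior.drift(trait, rng)
                hyp = generate_hypnogram(dyn, spec.epochs_per_night, rng)
                data, art_truth = generate_recording(
                    night_fp, hyp, spec, artifacts, rng,
                    epoch_offset_jitter_sd=prior.epoch_offset_jitter_sd,
                )
                recordings.append(
                    EpochedRecording(
                        data=data.astype(np.float32),
                        sfreq=spec.sampling_rate,
                        ch_names=spec.channels(),
                        hypnogram=hyp,
                        subject_id=subject_id,
                        night=night,
                        group=group,
                        isi_score=isi_score,
                        epoch_s=spec.epoch_s,
                        artifact_truth=art_truth,
                    )
                )
                rows.append(
                    dict(subject_id=subject_id, night=night, group=group,
                         isi_score=isi_score, seed=spec.seed)
                )
    metadata = pd.DataFrame(rows)
    return Cohort(recordings, metadata, fingerprints, dynamics, spec)
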