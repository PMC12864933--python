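"""Filtering and artifact-epoch rejection.

Filtering is a zero-phase Hamming-windowed-sinc FIR band-pass (0.5-100 Hz,
-6 dB points at 0.25 and 112.5 Hz) plus a 50 Hz notch, delegated to MNE's
FIR routines.  Artifact rejection implements an amplitude-difference rule:
signals are brought to a 200 Hz working rate, the absolute difference of
adjacent samples is averaged per channel within each 30-s epoch, the epoch
score is the maximum over channels, and epochs scoring above 5 uV are
rejected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .recording import EpochedRecording

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    from mne.filter import filter_data, notch_filter


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass + notch contract.

    Transition bandwidths are chosen so the -6 dB points land at
    ``l_freq - l_trans/2`` and ``h_freq + h_trans/2`` (0.25 and 112.5 Hz at
    the defaults).
    """

    l_freq: float = 0.5
    h_freq: float = 100.0
    l_trans_bandwidth: float = 0.5
    h_trans_bandwidth: float = 25.0
    notch_hz: float = 50.0

    def validate(self) -> None:
        if not self.l_freq < self.h_freq:
            raise ValueError("low edge must be below high edge")
        if not (self.l_freq < self.notch_hz < self.h_freq):
            raise ValueError("notch frequency must lie inside the passband")


def bandpass_notch(recording: EpochedRecording,
                   spec: FilterSpec | None = None) -> EpochedRecording:
    """Zero-phase FIR band-pass + mains notch; same shape out as in."""
    spec = spec if spec is not None else FilterSpec()
    spec.validate()
    fs = recording.sfreq
    min_rate = 2.0 * spec.h_freq
    if fs <= min_rate:
        raise ValueError(
            f"sampling rate {fs:g} Hz too low for a {spec.h_freq:g} Hz "
            f"passband edge; need more than {min_rate:g} Hz"
        )
    data = recording.data.astype(np.float64)
    out = filter_data(
        data, fs, spec.l_freq, spec.h_freq,
        l_trans_bandwidth=spec.l_trans_bandwidth,
        h_trans_bandwidth=spec.h_trans_bandwidth,
        fir_design="firwin", fir_window="hamming", phase="zero",
        verbose="error",
    )
    out = notch_filter(
        out, fs, spec.notch_hz, notch_widths=2.0, fir_design="firwin",
        phase="zero", verbose="error",
    )
    return recording.with_data(out)


@dataclass
class ArtifactMask:
    """Per-epoch rejection decision plus the amplitude-difference score."""

    rejected: np.ndarray  # bool, per epoch
    score_uv: np.ndarray  # float, per epoch (max over channels)
    threshold_uv: float

    @property
    def n_rejected(self) -> int:
        return int(self.rejected.sum())

    @property
    def retained(self) -> np.ndarray:
        return ~self.rejected

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch_index": np.arange(len(self.rejected)),
                "score_uV": self.score_uv,
                "rejected": self.rejected,
            }
        )


def reject_artifacts(recording: EpochedRecording, threshold: float = 5.0,
                     work_rate: float = 200.0) -> ArtifactMask:
    """Flag epochs whose mean adjacent-sample amplitude difference is large.

    When the native rate exceeds ``work_rate`` the signal is band-limited
    (0.5 Hz to at most 145 Hz, capped below the working Nyquist) and
    polyphase-resampled first; at the native rate the differences are taken
    directly.  Per channel, ``mean |x[t+1] - x[t]|`` is computed within each
    epoch; the epoch score is the maximum over channels and an epoch is
    rejected iff its score exceeds ``threshold``.
    """
    if work_rate > recording.sfreq:
        raise ValueError("work_rate must not exceed the native sampling rate")
    spe = recording.samples_per_epoch
    if spe < 2:
        raise ValueError("epochs must contain at least 2 samples")
    data = recording.data.astype(np.float64)
    if work_rate < recording.sfreq:
        h_edge = min(145.0, 0.475 * work_rate)
        data = filter_data(
            data, recording.sfreq, 0.5, h_edge, fir_design="firwin",
            phase="zero", verbose="error",
        )
        up, down = _resample_fraction(work_rate, recording.sfreq)
        data = sps.resample_poly(data, up, down, axis=-1)
        spe = int(round(recording.epoch_s * work_rate))
    n_ep = recording.n_epochs
    data = data[:, : n_ep * spe]
    epochs = data.reshape(data.shape[0], n_ep, spe)
    diffs = np.abs(np.diff(epochs, axis=-1)).mean(axis=-1)  # (ch, ep)
    score = diffs.max(axis=0)
    return ArtifactMask(
        rejected=score > threshold, score_uv=score, threshold_uv=threshold
    )


def _resample_fraction(target: float, native: float) -> tuple[int, int]:
    from fractions import Fraction

    frac = Fraction(target / native).limit_denominator(1000)
    return frac.numerator, frac.denominator
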