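"""Welch spectra per 30-s epoch and the 9-band x 20-channel feature table.

Band powers are natural-log mean PSD over inclusive band edges on a 0.25 Hz
Welch grid (4-s Hann windows, 50% overlap).  The feature table has one row
per retained N2/N3/R epoch, columns ordered channel-major then band-minor
(``Fp1_delta, Fp1_theta, ..., Cz_high_gamma``), with subject / night /
stage / ISI-group label columns; stage is collapsed to the NREM (N2+N3) vs
REM analysis dichotomy.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .preprocess import ArtifactMask
from .recording import EpochedRecording

logger = logging.getLogger(__name__)

#: Band name -> [low, high] Hz.  Overlap between alpha and low-sigma is
#: intentional (slow-spindle vs alpha contrast); the 3-4 and 48-52 Hz gaps
#: are honored, the latter keeping mains-notch residue out of gamma.
DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 3.0),
    "theta": (4.0, 7.0),
    "alpha": (8.0, 12.5),
    "low_sigma": (9.0, 12.5),
    "high_sigma": (12.5, 16.0),
    "low_beta": (16.0, 24.0),
    "high_beta": (25.0, 35.0),
    "low_gamma": (35.0, 48.0),
    "high_gamma": (52.0, 100.0),
}

LABEL_COLUMNS = ("subject", "night", "stage", "isi_group")


@dataclass(frozen=True)
class BandScheme:
    """Ordered mapping of band names to inclusive frequency ranges."""

    bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BANDS)
    )

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.bands.items():
            if not lo < hi:
                raise ValueError(f"band {name}: low must be below high")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.bands)

    def band_group(self, name: str) -> str:
        """Collapse low_/high_ variants to the broad band family."""
        return name.split("_")[-1] if "_" in name else name


def welch_psd(x: np.ndarray, sampling_rate: float, window_s: float = 4.0,
              overlap: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Welch PSD of an epoch (last axis = time), Hann taper, uV^2/Hz.

    Resolution is ``1/window_s`` (0.25 Hz at the 4-s default).
    """
    nperseg = int(round(sampling_rate * window_s))
    if not np.isclose(nperseg, sampling_rate * window_s):
        raise ValueError("sampling_rate x window_s must be an integer")
    if np.asarray(x).shape[-1] < nperseg:
        raise ValueError(
            f"epoch shorter than one {window_s:g}-s window ({nperseg} samples)"
        )
    freqs, psd = sps.welch(
        x, fs=sampling_rate, window="hann", nperseg=nperseg,
        noverlap=int(nperseg * overlap), detrend="constant", axis=-1,
    )
    return freqs, psd


def band_features(psd: np.ndarray, freqs: np.ndarray,
                  scheme: BandScheme | None = None,
                  floor: float = 1e-12) -> np.ndarray:
    """Natural-log mean PSD per band (last axis of ``psd`` = frequency).

    Values below ``floor`` are floored before the log; band edges are
    inclusive on both sides.
    """
    scheme = scheme if scheme is not None else BandScheme()
    freqs = np.asarray(freqs)
    out = []
    for name, (lo, hi) in scheme.bands.items():
        sel = (freqs >= lo) & (freqs <= hi)
        if not sel.any():
            raise ValueError(
                f"band {name} [{lo}, {hi}] Hz has no bins on the grid"
            )
        out.append(np.log(np.maximum(psd[..., sel].mean(axis=-1), floor)))
    return np.stack(out, axis=-1)


def feature_columns(ch_names: tuple[str, ...],
                    scheme: BandScheme | None = None) -> list[str]:
    """Channel-major, band-minor feature column names."""
    scheme = scheme if scheme is not None else BandScheme()
    return [f"{ch}_{band}" for ch in ch_names for band in scheme.names]


def band_of_column(col: str, scheme: BandScheme | None = None) -> str:
    """Band name of a ``<channel>_<band>`` feature column."""
    scheme = scheme if scheme is not None else BandScheme()
    for band in sorted(scheme.names, key=len, reverse=True):
        if col.endswith("_" + band):
            return band
    raise ValueError(f"column {col!r} does not end in a known band name")


def epoch_band_table(recording: EpochedRecording,
                     scheme: BandScheme | None = None,
                     window_s: float = 4.0, floor: float = 1e-12,
                     relative: bool = False) -> np.ndarray:
    """(n_epochs, n_channels * n_bands) log band powers for one recording.

    Absolute features are the natural log of the mean PSD over the band's
    bins.  The relative variant logs each band's *share* of total power
    (band bin-sum over the 0.5-100 Hz bin-sum), so shares of disjoint
    bands exponentiate-and-sum to at most 1.
    """
    scheme = scheme if scheme is not None else BandScheme()
    epochs = recording.epochs()  # (ep, ch, t)
    freqs, psd = welch_psd(epochs, recording.sfreq, window_s=window_s)
    if relative:
        total_sel = (freqs >= 0.5) & (freqs <= 100.0)
        total = psd[..., total_sel].sum(axis=-1)
        out = []
        for name, (lo, hi) in scheme.bands.items():
            sel = (freqs >= lo) & (freqs <= hi)
            if not sel.any():
                raise ValueError(
                    f"band {name} [{lo}, {hi}] Hz has no bins on the grid"
                )
            share = psd[..., sel].sum(axis=-1) / np.maximum(total, floor)
            out.append(np.log(np.maximum(share, floor)))
        feats = np.stack(out, axis=-1)
    else:
        feats = band_features(psd, freqs, scheme, floor=floor)
    return feats.reshape(feats.shape[0], -1)


def build_feature_table(
    recordings: list[EpochedRecording],
    masks: dict | list | None = None,
    scheme: BandScheme | None = None,
    stages: tuple[str, ...] = ("N2", "N3", "R"),
    relative: bool = False,
    window_s: float = 4.0,
) -> pd.DataFrame:
    """Band-power feature table over all retained sleep epochs.

    ``masks`` maps ``(subject_id, night)`` to an :class:`ArtifactMask` (or is
    a parallel list); wake and N1 epochs are excluded; N2/N3 rows carry the
    analysis stage "NREM", R rows "REM".  Subjects losing every epoch of a
    stage are simply absent from that stage subset (a warning is logged).
    """
    scheme = scheme if scheme is not None else BandScheme()
    frames = []
    for i, rec in enumerate(recordings):
        if isinstance(masks, dict):
            mask = masks.get((rec.subject_id, rec.night))
        elif masks is not None:
            mask = masks[i]
        else:
            mask = None
        retained = (
            mask.retained
            if isinstance(mask, ArtifactMask)
            else np.ones(rec.n_epochs, dtype=bool)
        )
        hyp = np.asarray(rec.hypnogram)
        keep = retained & np.isin(hyp, stages)
        if not keep.any():
            logger.warning(
                "subject %s night %d: no retained epochs in stages %s",
                rec.subject_id, rec.night, stages,
            )
            continue
        feats = epoch_band_table(
            rec, scheme, window_s=window_s, relative=relative
        )[keep]
        stage_col = np.where(np.isin(hyp[keep], ("N2", "N3")), "NREM", "REM")
        frame = pd.DataFrame(
            feats, columns=feature_columns(rec.ch_names, scheme)
        )
        frame.insert(0, "subject", rec.subject_id)
        frame.insert(1, "night", rec.night)
        frame.insert(2, "stage", stage_col)
        frame.insert(3, "isi_group", rec.group)
        frames.append(frame)
    if not frames:
        warnings.warn("feature table is empty: no retained epochs at all")
        return pd.DataFrame(columns=list(LABEL_COLUMNS))
    return pd.concat(frames, ignore_index=True)


def feature_matrix(table: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Split a feature table into (values, feature column names)."""
    cols = [c for c in table.columns if c not in LABEL_COLUMNS]
    return table[cols].to_numpy(dtype=float), cols
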