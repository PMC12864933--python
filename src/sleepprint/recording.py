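"""Epoched multichannel sleep-EEG recordings and their on-disk form.

A recording is one subject-night: a channel x sample matrix in microvolts,
a sampling rate, and a stage-per-epoch hypnogram scored in 30-s epochs with
AASM labels (W, N1, N2, N3, R).  Serialization is plain-text friendly:
float32 channel-major binary plus a JSON sidecar, and one stage label per
line for the hypnogram.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

#: Canonical AASM stage alphabet, in fixed order (REM written as "R").
STAGES: tuple[str, ...] = ("W", "N1", "N2", "N3", "R")

_STAGE_ALIASES = {"REM": "R", "WAKE": "W", "N4": "N3"}

#: The 20-channel scalp montage used throughout the analysis.
DEFAULT_CHANNELS: tuple[str, ...] = (
    "Fp1", "Fp2", "F3", "F4", "C3", "C4", "P3", "P4", "O1", "O2",
    "F7", "F8", "T7", "T8", "P7", "P8", "Fz", "Pz", "Oz", "Cz",
)


def canonical_stage(label: str) -> str:
    """Map a stage label to the canonical 5-letter alphabet, or raise."""
    lab = label.strip()
    lab = _STAGE_ALIASES.get(lab.upper(), lab)
    if lab not in STAGES:
        raise ValueError(f"unknown sleep stage label: {label!r}")
    return lab


@dataclass
class EpochedRecording:
    """One subject-night of epoched EEG plus its labels.

    Parameters
    ----------
    data
        Signal matrix, shape ``(n_channels, n_samples)``, microvolts.
    sfreq
        Sampling rate in Hz.
    ch_names
        Channel labels, one per row of ``data``.
    hypnogram
        One canonical stage label per 30-s epoch.
    subject_id, night, group, isi_score
        Cohort metadata (night is 1-based).
    artifact_truth
        Optional per-epoch boolean array marking epochs where an artifact
        transient was planted by the generator (ground truth for rejection
        tests); ``None`` for real data.
    """

    data: np.ndarray
    sfreq: float
    ch_names: tuple[str, ...]
    hypnogram: list[str]
    subject_id: str = ""
    night: int = 1
    group: str = ""
    isi_score: int = -1
    epoch_s: float = 30.0
    artifact_truth: np.ndarray | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if len(self.ch_names) != self.data.shape[0]:
            raise ValueError("ch_names length must match data rows")
        if len(set(self.ch_names)) != len(self.ch_names):
            raise ValueError("channel labels must be unique")
        self.hypnogram = [canonical_stage(s) for s in self.hypnogram]
        n_ep = self.n_epochs
        if len(self.hypnogram) != n_ep:
            raise ValueError(
                f"hypnogram has {len(self.hypnogram)} labels but the signal "
                f"holds {n_ep} complete {self.epoch_s:g}-s epochs"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def samples_per_epoch(self) -> int:
        return int(round(self.epoch_s * self.sfreq))

    @property
    def n_epochs(self) -> int:
        return self.data.shape[1] // self.samples_per_epoch

    def epochs(self) -> np.ndarray:
        """View of the signal as ``(n_epochs, n_channels, samples_per_epoch)``."""
        spe = self.samples_per_epoch
        n_ep = self.n_epochs
        return (
            self.data[:, : n_ep * spe]
            .reshape(self.n_channels, n_ep, spe)
            .transpose(1, 0, 2)
        )

    def with_data(self, data: np.ndarray) -> "EpochedRecording":
        """Copy of the recording with the signal matrix replaced."""
        out = EpochedRecording(
            data=data,
            sfreq=self.sfreq,
            ch_names=self.ch_names,
            hypnogram=list(self.hypnogram),
            subject_id=self.subject_id,
            night=self.night,
            group=self.group,
            isi_score=self.isi_score,
            epoch_s=self.epoch_s,
            artifact_truth=None
            if self.artifact_truth is None
            else self.artifact_truth.copy(),
            extras=dict(self.extras),
        )
        return out

    # ------------------------------------------------------------------
    # serialization: float32 binary + JSON sidecar + hypnogram text
    # ------------------------------------------------------------------
    def save(self, stem: Path | str) -> None:
        """Write ``<stem>.dat`` (float32 channel-major), ``<stem>.json``,
        and ``<stem>.hypnogram.txt`` (one AASM label per line)."""
        stem = Path(stem)
        stem.parent.mkdir(parents=True, exist_ok=True)
        self.data.astype("<f4").tofile(stem.with_suffix(".dat"))
        sidecar = {
            "sfreq": self.sfreq,
            "ch_names": list(self.ch_names),
            "n_samples": int(self.data.shape[1]),
            "units": "uV",
            "dtype": "<f4",
            "order": "channel-major",
            "epoch_s": self.epoch_s,
            "subject_id": self.subject_id,
            "night": self.night,
            "group": self.group,
            "isi_score": self.isi_score,
        }
        stem.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
        hyp = stem.parent / (stem.name + ".hypnogram.txt")
        hyp.write_text("\n".join(self.hypnogram) + "\n")

    @classmethod
    def load(cls, stem: Path | str) -> "EpochedRecording":
        stem = Path(stem)
        meta = json.loads(stem.with_suffix(".json").read_text())
        raw = np.fromfile(stem.with_suffix(".dat"), dtype="<f4")
        data = raw.reshape(len(meta["ch_names"]), meta["n_samples"])
        hyp_path = stem.parent / (stem.name + ".hypnogram.txt")
        hypnogram = [
            line for line in hyp_path.read_text().splitlines() if line.strip()
        ]
        return cls(
            data=data,
            sfreq=meta["sfreq"],
            ch_names=tuple(meta["ch_names"]),
            hypnogram=hypnogram,
            subject_id=meta.get("subject_id", ""),
            night=meta.get("night", 1),
            group=meta.get("group", ""),
            isi_score=meta.get("isi_score", -1),
            epoch_s=meta.get("epoch_s", 30.0),
        )


def read_hypnogram(path: Path | str) -> list[str]:
    """Read a one-stage-per-line hypnogram text file."""
    return [
        canonical_stage(line)
        for line in Path(path).read_text().splitlines()
        if line.strip()
    ]
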