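"""In-memory containers for multichannel EEG and fixed-length epochs,
plus plain-text matrix I/O and optional EDF ingestion."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


@dataclass
class EEGRecording:
    """A labelled multichannel time series.

    ``data`` is channels x samples; row *i* belongs to ``channel_labels[i]``.
    """

    channel_labels: list[str]
    sampling_rate: float
    data: np.ndarray
    annotations: list[tuple[float, float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D channels x samples matrix")
        if self.data.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"{self.data.shape[0]} data rows for "
                f"{len(self.channel_labels)} labels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in recording") from None

    def copy_with(self, data: np.ndarray, labels: list[str] | None = None) -> "EEGRecording":
        return EEGRecording(
            channel_labels=list(labels if labels is not None else self.channel_labels),
            sampling_rate=self.sampling_rate,
            data=data,
            annotations=list(self.annotations),
        )


@dataclass
class EpochSet:
    """Non-overlapping fixed-length segments of one recording.

    ``epochs`` is epoch x channel x sample; ``kept_epoch_indices`` maps each
    row back to its position in the original segmentation so that artifact
    rejection stays traceable.
    """

    epochs: np.ndarray
    epoch_length: float
    sampling_rate: float
    channel_labels: list[str]
    kept_epoch_indices: np.ndarray

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        self.kept_epoch_indices = np.asarray(self.kept_epoch_indices, dtype=int)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be epoch x channel x sample")
        if self.epochs.shape[1] != len(self.channel_labels):
            raise ValueError("channel count does not match labels")
        expected = round(self.epoch_length * self.sampling_rate)
        if self.epochs.shape[2] != expected:
            raise ValueError(
                f"epoch has {self.epochs.shape[2]} samples, expected {expected}"
            )
        if len(self.kept_epoch_indices) != self.epochs.shape[0]:
            raise ValueError("kept_epoch_indices length mismatch")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.epochs.shape[1]


# ---------------------------------------------------------------------------
# Plain-text fixture format: a whitespace-separated matrix with one header
# row of channel labels (one column per channel, samples as rows) and a JSON
# sidecar holding the sampling rate.
# ---------------------------------------------------------------------------

def write_matrix(rec: EEGRecording, path: str | Path, fmt: str = "%.8g") -> None:
    """Write a recording as a text matrix (samples x channels, label header)."""
    path = Path(path)
    np.savetxt(
        path,
        rec.data.T,
        fmt=fmt,
        header="\t".join(rec.channel_labels),
        comments="",
        delimiter="\t",
    )
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps({"sampling_rate": rec.sampling_rate}, indent=0) + "\n"
    )


def read_matrix(path: str | Path, sampling_rate: float | None = None) -> EEGRecording:
    """Read the text matrix format written by :func:`write_matrix`."""
    path = Path(path)
    with open(path) as fh:
        labels = fh.readline().split()
    data = np.loadtxt(path, skiprows=1)
    if data.ndim == 1:
        data = data[:, None]
    if sampling_rate is None:
        sidecar = path.with_suffix(path.suffix + ".json")
        if not sidecar.exists():
            raise ValueError(
                f"no sampling rate given and sidecar {sidecar} not found"
            )
        sampling_rate = float(json.loads(sidecar.read_text())["sampling_rate"])
    return EEGRecording(channel_labels=labels, sampling_rate=sampling_rate, data=data.T)


def read_edf(path: str | Path, label_map: dict[str, str] | None = None) -> EEGRecording:
    """Read an EDF file into an :class:`EEGRecording` (requires ``mne``).

    ``label_map`` renames EDF signal labels to montage names, e.g.
    ``{"EEG Fp1-REF": "Fp1"}``.
    """
    import mne  # local import: optional dependency

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    labels = list(raw.ch_names)
    if label_map:
        labels = [label_map.get(name, name) for name in labels]
    return EEGRecording(
        channel_labels=labels,
        sampling_rate=float(raw.info["sfreq"]),
        data=raw.get_data(),
    )
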