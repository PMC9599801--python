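"""Resting-EEG preprocessing: linked-mastoid re-reference, zero-phase
band-pass and line-noise notch, downsampling, epoching and amplitude-based
epoch rejection.

All filters are 4th-order Butterworth applied forward-backward (zero
phase): downstream phase estimates must not be biased by filter phase
delay.  Each second-order section is run through ``filtfilt`` with
Gustafsson initial conditions — the 0.1 Hz high-pass corner has a
seconds-long impulse response, and padding-based edge handling would leak
slow transients across short recordings.  The fixed stage order is

    drop EOG -> re-reference -> band-pass -> notch -> downsample
             -> segment -> reject

Artifactual epochs are removed by a peak-amplitude threshold; component-based
artifact decomposition is deliberately out of scope (see the methods note).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .montage import EOG_LABELS, MASTOID_SYNONYMS, MASTOIDS
from .recording import EEGRecording, EpochSet

FILTER_ORDER = 4


def _butter_sos(low: float, high: float, fs: float, btype: str) -> np.ndarray:
    nyq = fs / 2.0
    if not (0 < low < high < nyq):
        raise ValueError(
            f"corner frequencies ({low}, {high}) invalid for fs={fs}"
        )
    return signal.butter(FILTER_ORDER, [low / nyq, high / nyq], btype=btype, output="sos")


def zero_phase_filter(sos: np.ndarray, data: np.ndarray, axis: int = -1) -> np.ndarray:
    """Forward-backward filtering, one second-order section at a time, with
    Gustafsson initial conditions (minimal edge transients)."""
    out = np.asarray(data, dtype=float)
    for section in sos:
        out = signal.filtfilt(section[:3], section[3:], out, axis=axis, method="gust")
    return out


def drop_channels(rec: EEGRecording, labels: tuple[str, ...] = EOG_LABELS) -> EEGRecording:
    """Remove the named channels if present (used for the EOG pair)."""
    keep = [i for i, lab in enumerate(rec.channel_labels) if lab not in labels]
    return rec.copy_with(rec.data[keep], [rec.channel_labels[i] for i in keep])


def rereference_mastoid(
    rec: EEGRecording,
    left_label: str = MASTOIDS[0],
    right_label: str = MASTOIDS[1],
) -> EEGRecording:
    """Re-reference every channel to the average of the two mastoids.

    The mastoid channels themselves are dropped from the output (they are
    identically their own reference residual and carry no signal afterwards).
    A1/A2 are accepted as synonyms for M1/M2.
    """
    labels = [MASTOID_SYNONYMS.get(lab, lab) for lab in rec.channel_labels]
    for want in (left_label, right_label):
        if want not in labels:
            raise ValueError(f"mastoid channel {want!r} not found in recording")
    li, ri = labels.index(left_label), labels.index(right_label)
    reference = 0.5 * (rec.data[li] + rec.data[ri])
    data = rec.data - reference
    keep = [i for i in range(rec.n_channels) if i not in (li, ri)]
    return rec.copy_with(data[keep], [rec.channel_labels[i] for i in keep])


def bandpass(rec: EEGRecording, low: float = 0.1, high: float = 30.0) -> EEGRecording:
    """Zero-phase Butterworth band-pass (default 0.1-30 Hz)."""
    sos = _butter_sos(low, high, rec.sampling_rate, "bandpass")
    return rec.copy_with(zero_phase_filter(sos, rec.data))


def notch(rec: EEGRecording, low: float = 48.0, high: float = 52.0) -> EEGRecording:
    """Zero-phase Butterworth band-stop for line noise (default 48-52 Hz)."""
    sos = _butter_sos(low, high, rec.sampling_rate, "bandstop")
    return rec.copy_with(zero_phase_filter(sos, rec.data))


def downsample(rec: EEGRecording, target: float = 500.0) -> EEGRecording:
    """Decimate to ``target`` Hz by integer sample picking.

    Requires an integer decimation factor.  No extra anti-alias filter is
    applied here: the pipeline band-passes to 30 Hz before this stage, far
    below the post-decimation Nyquist frequency.
    """
    factor = rec.sampling_rate / target
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError(
            f"sampling rate {rec.sampling_rate} not divisible by target {target}"
        )
    factor = int(round(factor))
    if factor == 1:
        return rec.copy_with(rec.data.copy())
    out = rec.copy_with(rec.data[:, ::factor])
    out.sampling_rate = float(target)
    return out


def segment_epochs(rec: EEGRecording, length: float = 3.0) -> EpochSet:
    """Cut into consecutive non-overlapping epochs of ``length`` seconds.

    A trailing partial epoch is discarded.
    """
    samples_per_epoch = round(length * rec.sampling_rate)
    n_epochs = rec.n_samples // samples_per_epoch
    if n_epochs < 1:
        raise ValueError(
            f"recording of {rec.duration:.3f}s shorter than one {length}s epoch"
        )
    trimmed = rec.data[:, : n_epochs * samples_per_epoch]
    epochs = trimmed.reshape(rec.n_channels, n_epochs, samples_per_epoch)
    epochs = np.moveaxis(epochs, 1, 0)
    return EpochSet(
        epochs=epochs.copy(),
        epoch_length=length,
        sampling_rate=rec.sampling_rate,
        channel_labels=list(rec.channel_labels),
        kept_epoch_indices=np.arange(n_epochs),
    )


def reject_epochs(es: EpochSet, amplitude_threshold: float = 100.0) -> EpochSet:
    """Drop epochs whose peak absolute amplitude on any channel exceeds the
    threshold; at least one epoch must survive."""
    if amplitude_threshold <= 0:
        raise ValueError("amplitude_threshold must be positive")
    peak = np.max(np.abs(es.epochs), axis=(1, 2))
    keep = peak <= amplitude_threshold
    if not keep.any():
        raise ValueError(
            f"all {es.n_epochs} epochs exceed amplitude threshold "
            f"{amplitude_threshold}"
        )
    return EpochSet(
        epochs=es.epochs[keep],
        epoch_length=es.epoch_length,
        sampling_rate=es.sampling_rate,
        channel_labels=list(es.channel_labels),
        kept_epoch_indices=es.kept_epoch_indices[keep],
    )


@dataclass
class PreprocessParams:
    """Stage parameters for the standard chain, in execution order."""

    bandpass_low: float = 0.1
    bandpass_high: float = 30.0
    notch_low: float = 48.0
    notch_high: float = 52.0
    downsample_to: float = 500.0
    epoch_length: float = 3.0
    reject_threshold: float = 100.0
    rereference: bool = True


def preprocess(rec: EEGRecording, params: PreprocessParams | None = None) -> EpochSet:
    """Run the full fixed-order preprocessing chain on one raw recording."""
    p = params or PreprocessParams()
    rec = drop_channels(rec, EOG_LABELS)
    if p.rereference:
        labels = {MASTOID_SYNONYMS.get(lab, lab) for lab in rec.channel_labels}
        if set(MASTOIDS) <= labels:
            rec = rereference_mastoid(rec)
    rec = bandpass(rec, p.bandpass_low, p.bandpass_high)
    if p.notch_high < rec.sampling_rate / 2:
        rec = notch(rec, p.notch_low, p.notch_high)
    if p.downsample_to < rec.sampling_rate:
        rec = downsample(rec, p.downsample_to)
    es = segment_epochs(rec, p.epoch_length)
    return reject_epochs(es, p.reject_threshold)
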