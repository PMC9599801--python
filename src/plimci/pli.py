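"""Phase lag index (PLI) connectivity.

The PLI between two signals quantifies the asymmetry of their instantaneous
phase-difference distribution:

    PLI = | < sign(delta_phi(t_k)) >_k |,      delta_phi wrapped to (-pi, pi]

It is 0 when phase differences are symmetric around zero — including the
spurious zero-lag coupling produced by volume conduction — and 1 for a
perfectly consistent non-zero phase lead or lag.  Instantaneous phase is
taken from the analytic signal (Hilbert transform) of the band-filtered
epoch, with a trimmed fraction of samples at each epoch edge to suppress
filter and Hilbert end effects.

Convention notes: sign(0) = 0 (exact zeros arise only in degenerate
fixtures); PLI is computed within each epoch and averaged across epochs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .preprocess import FILTER_ORDER
from .recording import EpochSet

DEFAULT_EDGE_TRIM = 0.1


@dataclass(frozen=True)
class FrequencyBand:
    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError(f"band {self.name}: low must be < high")


#: The four classical EEG rhythms used throughout the analysis.
BANDS: dict[str, FrequencyBand] = {
    "delta": FrequencyBand("delta", 1.0, 4.0),
    "theta": FrequencyBand("theta", 4.0, 8.0),
    "alpha": FrequencyBand("alpha", 8.0, 13.0),
    "beta": FrequencyBand("beta", 13.0, 30.0),
}

ALPHA = BANDS["alpha"]


@dataclass
class PhaseSeries:
    """Instantaneous phase per epoch/channel/sample for one band."""

    phases: np.ndarray  # epoch x channel x sample, radians in (-pi, pi]
    band: FrequencyBand
    channel_labels: list[str]
    sampling_rate: float

    @property
    def n_epochs(self) -> int:
        return self.phases.shape[0]


@dataclass
class ConnectivityMatrix:
    """Symmetric channel x channel PLI matrix with zero diagonal."""

    values: np.ndarray
    band: FrequencyBand
    channel_labels: list[str]
    n_epochs_averaged: int

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape[0] != v.shape[1] or v.shape[0] != len(self.channel_labels):
            raise ValueError("matrix shape does not match channel labels")
        if not np.allclose(v, v.T):
            raise ValueError("connectivity matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("connectivity matrix diagonal must be zero")
        if v.min() < 0 or v.max() > 1:
            raise ValueError("PLI values must lie in [0, 1]")
        self.values = v

    def pair(self, a: str, b: str) -> float:
        ia = self.channel_labels.index(a)
        ib = self.channel_labels.index(b)
        return float(self.values[ia, ib])


def wrap_phase(phi: np.ndarray) -> np.ndarray:
    """Wrap angles to (-pi, pi]."""
    out = np.mod(-np.asarray(phi) + np.pi, 2 * np.pi)
    return np.pi - out


def band_phase(
    es: EpochSet,
    band: FrequencyBand,
    edge_trim: float = DEFAULT_EDGE_TRIM,
    amplitude_floor: float = 1e-12,
) -> PhaseSeries:
    """Band-filter each epoch (zero phase) and extract instantaneous phase.

    ``edge_trim`` is the fraction of samples removed from each end of every
    epoch after the Hilbert transform.  Raises if the band does not fit
    under the Nyquist frequency, or if a channel is essentially silent in
    the band (undefined phase).
    """
    if not 0 <= edge_trim < 0.5:
        raise ValueError("edge_trim must be in [0, 0.5)")
    nyq = es.sampling_rate / 2.0
    if not (0 < band.low < band.high < nyq):
        raise ValueError(f"band {band.name} ({band.low}-{band.high} Hz) "
                         f"outside Nyquist range for fs={es.sampling_rate}")
    sos = signal.butter(
        FILTER_ORDER, [band.low / nyq, band.high / nyq], btype="bandpass", output="sos"
    )
    filtered = signal.sosfiltfilt(sos, es.epochs, axis=-1)
    analytic = signal.hilbert(filtered, axis=-1)
    n = es.epochs.shape[-1]
    trim = int(np.floor(edge_trim * n))
    if trim:
        analytic = analytic[..., trim : n - trim]
    amplitude = np.abs(analytic)
    if np.any(amplitude.max(axis=-1) < amplitude_floor):
        raise ValueError("undefined phase: a channel has ~zero band amplitude")
    return PhaseSeries(
        phases=np.angle(analytic),
        band=band,
        channel_labels=list(es.channel_labels),
        sampling_rate=es.sampling_rate,
    )


def pli_pair(phase_i: np.ndarray, phase_j: np.ndarray) -> float:
    """PLI of two equal-length phase sequences (radians).

    |mean_k sign(delta_phi_k)| with the difference wrapped to (-pi, pi].
    """
    phase_i = np.asarray(phase_i, dtype=float)
    phase_j = np.asarray(phase_j, dtype=float)
    if phase_i.shape != phase_j.shape:
        raise ValueError("phase sequences must have equal length")
    if phase_i.size == 0:
        raise ValueError("empty phase sequences")
    delta = wrap_phase(phase_i - phase_j)
    return float(abs(np.mean(np.sign(delta))))


def connectivity_matrix(
    es: EpochSet,
    band: FrequencyBand,
    edge_trim: float = DEFAULT_EDGE_TRIM,
    pool_epochs: bool = False,
) -> ConnectivityMatrix:
    """Per-pair PLI for all channel pairs of an epoch set.

    PLI is computed within each epoch and averaged across epochs; with
    ``pool_epochs`` the signs of all epochs are pooled into one average
    before the absolute value (the alternative aggregation).
    """
    if es.n_channels < 2:
        raise ValueError("connectivity needs at least 2 channels")
    if es.n_epochs < 1:
        raise ValueError("connectivity needs at least 1 epoch")
    ps = band_phase(es, band, edge_trim)
    # signs of pairwise wrapped phase differences, epoch x pair x sample
    phases = ps.phases
    n_ch = phases.shape[1]
    iu, ju = np.triu_indices(n_ch, k=1)
    delta = wrap_phase(phases[:, iu, :] - phases[:, ju, :])
    signs = np.sign(delta)
    if pool_epochs:
        pli_upper = np.abs(signs.mean(axis=(0, 2)))
    else:
        pli_upper = np.abs(signs.mean(axis=2)).mean(axis=0)
    values = np.zeros((n_ch, n_ch))
    values[iu, ju] = pli_upper
    values[ju, iu] = pli_upper
    return ConnectivityMatrix(
        values=values,
        band=band,
        channel_labels=list(es.channel_labels),
        n_epochs_averaged=es.n_epochs,
    )


def global_pli(cm: ConnectivityMatrix) -> float:
    """Mean PLI over all unordered channel pairs (strict upper triangle)."""
    n = cm.values.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    return float(cm.values[iu, ju].mean())


def extract_pairs(
    cm: ConnectivityMatrix, pairs: list[tuple[str, str]] | None = None
) -> list[float]:
    """Matrix entries for named electrode pairs, order preserved.

    Defaults to the eight inter/intra-hemispheric pairs of the alpha-band
    comparison (:data:`plimci.montage.NAMED_PAIRS`).
    """
    from .montage import NAMED_PAIRS

    if pairs is None:
        pairs = list(NAMED_PAIRS)
    out = []
    for a, b in pairs:
        for lab in (a, b):
            if lab not in cm.channel_labels:
                raise KeyError(f"channel {lab!r} not in connectivity matrix")
        out.append(cm.pair(a, b))
    return out
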