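"""Re-referencing, band-pass filtering, trimming and GFP machinery.

Mirrors the standard microstate preprocessing chain: common average
reference, zero-phase 2-20 Hz band-pass applied per epoch, trimming every
subject to the same analyzed length, then the global field power (GFP) time
course whose local maxima provide the highest-SNR topographies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .recording import EEGRecording

__all__ = [
    "GFPSeries",
    "average_reference",
    "bandpass",
    "trim_to_length",
    "compute_gfp",
    "detect_gfp_peaks",
]


@dataclass
class GFPSeries:
    """Per-sample global field power and (optionally) its peak positions.

    GFP at sample t is the population standard deviation of the potential
    over the E electrodes — a reference-free index of global field strength.
    """

    values: np.ndarray
    peak_indices: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.peak_indices = np.asarray(self.peak_indices, dtype=int)


def average_reference(rec: EEGRecording) -> EEGRecording:
    """Subtract each sample's channel mean (common average reference)."""
    if rec.n_channels < 2:
        raise ValueError("average reference needs at least 2 channels")
    return rec.with_data(rec.data - rec.data.mean(axis=0, keepdims=True))


def _design_bandpass(lo_hz: float, hi_hz: float, fs_hz: float, order: int) -> np.ndarray:
    if not (0 < lo_hz < hi_hz < fs_hz / 2):
        raise ValueError(
            f"band ({lo_hz}, {hi_hz}) Hz invalid for fs={fs_hz} Hz (need 0 < lo < hi < fs/2)"
        )
    return butter(order, [lo_hz, hi_hz], btype="bandpass", fs=fs_hz, output="sos")


def bandpass(
    rec: EEGRecording, lo_hz: float = 2.0, hi_hz: float = 20.0, order: int = 4
) -> EEGRecording:
    """Zero-phase Butterworth band-pass, applied independently per epoch.

    Epochs were excised from a longer record, so no continuity across epoch
    boundaries is assumed.  Forward-backward application (filtfilt) doubles
    the effective order and cancels phase distortion.
    """
    sos = _design_bandpass(lo_hz, hi_hz, rec.fs_hz, order)
    padlen = 3 * (2 * sos.shape[0] + 1)  # sosfiltfilt default
    out = rec.data.copy()
    for i, (start, stop) in enumerate(rec.epochs):
        if stop - start <= padlen:
            raise ValueError(
                f"epoch {i} ({start}:{stop}) too short for the filter "
                f"(needs > {padlen} samples)"
            )
        out[:, start:stop] = sosfiltfilt(sos, rec.data[:, start:stop], axis=1)
    return rec.with_data(out)


def trim_to_length(recs: list[EEGRecording], seconds: float) -> list[EEGRecording]:
    """Trim every recording to exactly ``floor(seconds * fs)`` epoched samples.

    Samples are retained epoch-by-epoch from the start; the epoch whose
    boundary the cut falls inside is shortened, later epochs are dropped.
    Data outside epochs is discarded, so trimmed recordings are contiguous.
    """
    out = []
    for rec in recs:
        n_keep = int(np.floor(seconds * rec.fs_hz + 1e-9))
        if rec.n_epoch_samples < n_keep:
            raise ValueError(
                f"subject {rec.subject_id}: {rec.n_epoch_samples} epoched samples "
                f"< requested {n_keep}"
            )
        chunks, new_epochs, kept = [], [], 0
        for start, stop in rec.epochs:
            if kept >= n_keep:
                break
            take = min(stop - start, n_keep - kept)
            chunks.append(rec.data[:, start : start + take])
            new_epochs.append((kept, kept + take))
            kept += take
        out.append(rec.with_data(np.concatenate(chunks, axis=1), epochs=new_epochs))
    return out


def compute_gfp(rec: EEGRecording) -> GFPSeries:
    """GFP time course: population SD across electrodes at each sample."""
    if rec.n_channels < 2:
        raise ValueError("GFP needs at least 2 channels")
    return GFPSeries(values=rec.data.std(axis=0, ddof=0))


def detect_gfp_peaks(
    gfp: GFPSeries, epochs: list[tuple[int, int]]
) -> GFPSeries:
    """Locate strict local maxima of the GFP within each epoch.

    A peak is a sample t with values[t-1] < values[t] > values[t+1]; flat
    runs count once, at their first sample.  Epoch edges can never be peaks
    (their true prominence is unknowable), and epochs are scanned
    independently so no peak spans a boundary.
    """
    v = gfp.values
    peaks: list[int] = []
    for start, stop in epochs:
        t = start + 1
        while t < stop - 1:
            if v[t] > v[t - 1]:
                # scan the plateau of equal values starting at t
                u = t
                while u + 1 < stop and v[u + 1] == v[t]:
                    u += 1
                if u + 1 < stop and v[u + 1] < v[t]:
                    peaks.append(t)
                t = u + 1
            else:
                t += 1
    return GFPSeries(values=v, peak_indices=np.array(peaks, dtype=int))
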