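"""The in-memory EEG container used by every pipeline stage."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .montage import Montage

__all__ = ["EEGRecording"]


@dataclass
class EEGRecording:
    """Multi-channel EEG: an E x T matrix in microvolts plus metadata.

    ``epochs`` are half-open sample intervals ``(start, stop)`` marking the
    artifact-free segments; stages that cannot assume continuity (filtering,
    peak detection, segmentation) operate within epochs only.
    """

    data: np.ndarray  # (E, T), microvolts
    fs_hz: float
    montage: Montage
    epochs: list[tuple[int, int]] = field(default_factory=list)
    subject_id: str = "s0"
    group: str = ""
    migraine: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2D channels x samples matrix")
        if self.data.shape[0] != self.montage.n_channels:
            raise ValueError(
                f"data has {self.data.shape[0]} channels but montage has "
                f"{self.montage.n_channels}"
            )
        if not np.isfinite(self.data).all():
            raise ValueError("data contains non-finite values")
        if self.fs_hz <= 0:
            raise ValueError("sampling rate must be positive")
        if not self.epochs:
            self.epochs = [(0, self.data.shape[1])]
        self._check_epochs()

    def _check_epochs(self) -> None:
        T = self.data.shape[1]
        prev_stop = 0
        for start, stop in self.epochs:
            if not (0 <= start < stop <= T):
                raise ValueError(f"epoch ({start}, {stop}) out of range [0, {T})")
            if start < prev_stop:
                raise ValueError("epochs must be sorted and disjoint")
            prev_stop = stop

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def n_epoch_samples(self) -> int:
        """Total number of samples inside epochs."""
        return sum(stop - start for start, stop in self.epochs)

    def with_data(self, data: np.ndarray, epochs: list[tuple[int, int]] | None = None) -> "EEGRecording":
        """Copy of this recording with new data (and optionally new epochs)."""
        return replace(self, data=data, epochs=list(epochs if epochs is not None else self.epochs))
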