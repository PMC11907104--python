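"""Electrode montages.

The default montage is the 25-electrode clinical array recommended by the
IFCN (Fz, Fp1/2, F3/4, F7/8, F9/10, C3/4, Cz, Pz, T3/4, T5/6, T9/10, P3/4,
P9/10, O1/2).  Positions are schematic 2D head-layout coordinates (x grows
to the subject's right, y toward the front; unitless) — sufficient for
constructing canonical topographic gradients, not for source modelling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Montage", "ifcn25"]


@dataclass(frozen=True)
class Montage:
    """Ordered electrode names with optional 2D layout positions."""

    labels: tuple[str, ...]
    positions: dict[str, tuple[float, float]] | None = field(default=None)

    def __post_init__(self) -> None:
        if len(self.labels) < 2:
            raise ValueError("a montage needs at least 2 electrodes")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("electrode labels must be unique")

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    def position_array(self) -> np.ndarray:
        """(E, 2) array of positions in label order.

        Raises ``ValueError`` naming the first electrode without a position.
        """
        if self.positions is None:
            raise ValueError("montage has no positions")
        out = np.empty((len(self.labels), 2))
        for i, lab in enumerate(self.labels):
            if lab not in self.positions:
                raise ValueError(f"no position for electrode {lab!r}")
            out[i] = self.positions[lab]
        return out


# Schematic top-view layout.  Inner 10-20 ring at radius 1, inferior
# (F9/10, T9/10, P9/10) ring at ~1.15.
_IFCN25_POSITIONS: dict[str, tuple[float, float]] = {
    "Fp1": (-0.31, 0.95),
    "Fp2": (0.31, 0.95),
    "F7": (-0.81, 0.59),
    "F3": (-0.40, 0.50),
    "Fz": (0.00, 0.50),
    "F4": (0.40, 0.50),
    "F8": (0.81, 0.59),
    "F9": (-0.93, 0.68),
    "F10": (0.93, 0.68),
    "T3": (-1.00, 0.00),
    "C3": (-0.50, 0.00),
    "Cz": (0.00, 0.00),
    "C4": (0.50, 0.00),
    "T4": (1.00, 0.00),
    "T9": (-1.15, 0.00),
    "T10": (1.15, 0.00),
    "T5": (-0.81, -0.59),
    "P3": (-0.40, -0.50),
    "Pz": (0.00, -0.50),
    "P4": (0.40, -0.50),
    "T6": (0.81, -0.59),
    "P9": (-0.93, -0.68),
    "P10": (0.93, -0.68),
    "O1": (-0.31, -0.95),
    "O2": (0.31, -0.95),
}


def ifcn25() -> Montage:
    """The standard 25-channel IFCN clinical montage with layout positions."""
    return Montage(labels=tuple(_IFCN25_POSITIONS), positions=dict(_IFCN25_POSITIONS))
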