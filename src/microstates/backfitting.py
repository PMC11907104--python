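"""Backfitting sorted class templates to a subject's recording.

Class membership is decided at GFP peaks only (the highest-SNR samples):
each peak map takes the label of the template it correlates best with,
polarity ignored, and every intermediate sample inherits the label of its
nearest peak within the same epoch.  Maximal same-label runs become
segments; a segment touching an epoch boundary is flagged truncated because
its true duration is unknowable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .clustering import TemplateSet, gev
from .preprocessing import GFPSeries
from .recording import EEGRecording

__all__ = ["Segment", "Segmentation", "backfit", "assignment_quality"]

logger = logging.getLogger(__name__)

UNASSIGNED = -1


@dataclass
class Segment:
    start: int
    stop: int  # half-open
    cls: int
    truncated: bool
    mean_gfp: float
    peak_count: int

    @property
    def n_samples(self) -> int:
        return self.stop - self.start

    def duration_ms(self, fs_hz: float) -> float:
        return 1000.0 * self.n_samples / fs_hz


@dataclass
class Segmentation:
    """Per-sample labels plus the segment list assembled from them."""

    labels: np.ndarray  # (T,) int, UNASSIGNED where no peak informs the sample
    segments: list[Segment]
    fs_hz: float
    epochs: list[tuple[int, int]]
    k: int

    @property
    def n_assigned(self) -> int:
        return int(np.sum(self.labels >= 0))


def backfit(rec: EEGRecording, gfp: GFPSeries, templates: TemplateSet) -> Segmentation:
    """Label the recording with the given (sorted) templates.

    Peaks with a zero-variance map are skipped with a warning; epochs
    containing no usable peak stay unassigned.  Between adjacent peaks the
    label switches at the midpoint; an exactly equidistant sample opens the
    later peak's run.
    """
    T = rec.n_samples
    labels = np.full(T, UNASSIGNED, dtype=int)
    peak_list = np.asarray(gfp.peak_indices, dtype=int)

    X = rec.data[:, peak_list].T
    X = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(X, axis=1)
    usable = norms > 0
    if not usable.all():
        logger.warning(
            "subject %s: skipped %d zero-variance GFP peak map(s)",
            rec.subject_id,
            int((~usable).sum()),
        )
    corr = np.zeros((peak_list.size, templates.k))
    corr[usable] = np.abs((X[usable] / norms[usable, None]) @ templates.maps.T)
    peak_cls = np.argmax(corr, axis=1)

    for start, stop in rec.epochs:
        in_ep = (peak_list >= start) & (peak_list < stop) & usable
        pk = peak_list[in_ep]
        pc = peak_cls[in_ep]
        if pk.size == 0:
            continue
        # nearest-peak interpolation: the label switches at the midpoint of
        # adjacent peaks; an exactly equidistant sample starts the later run
        bounds = [start] + [(a + b + 1) // 2 for a, b in zip(pk[:-1], pk[1:])] + [stop]
        for i in range(pk.size):
            labels[bounds[i] : bounds[i + 1]] = pc[i]

    segments = _assemble_segments(labels, gfp.values, rec.epochs, peak_list)
    return Segmentation(
        labels=labels, segments=segments, fs_hz=rec.fs_hz, epochs=list(rec.epochs), k=templates.k
    )


def _assemble_segments(
    labels: np.ndarray,
    gfp_values: np.ndarray,
    epochs: list[tuple[int, int]],
    peak_list: np.ndarray,
) -> list[Segment]:
    segments: list[Segment] = []
    for start, stop in epochs:
        t = start
        while t < stop:
            cls = labels[t]
            u = t
            while u < stop and labels[u] == cls:
                u += 1
            if cls != UNASSIGNED:
                n_peaks = int(np.sum((peak_list >= t) & (peak_list < u)))
                segments.append(
                    Segment(
                        start=t,
                        stop=u,
                        cls=int(cls),
                        truncated=(t == start or u == stop),
                        mean_gfp=float(np.mean(gfp_values[t:u])),
                        peak_count=n_peaks,
                    )
                )
            t = u
    return segments


def assignment_quality(
    seg: Segmentation, rec: EEGRecording, gfp: GFPSeries, templates: TemplateSet
) -> tuple[np.ndarray, float]:
    """GEV of the backfit assignment, evaluated over GFP-peak maps.

    Same formula as the clustering stage: the squared GFP-weighted
    correlation of each peak map with its assigned template, relative to the
    total squared GFP at peaks.
    """
    peaks = np.asarray(gfp.peak_indices, dtype=int)
    maps = rec.data[:, peaks].T
    weights = gfp.values[peaks]
    assignment = seg.labels[peaks]
    return gev(maps, weights, templates, assignment)
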