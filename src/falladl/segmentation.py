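"""Sliding-window segmentation with mode labeling.

Canonical 50 Hz streams are cut into fixed-length windows with a fixed
fractional overlap (default 80%). Each window receives a single class
label: the mode of its per-sample labels, ties resolved in favor of the
tied label whose last occurrence in the window is latest (biasing toward
the activity the subject is entering, which matters for transitions and
falls). Windows never span recording boundaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from falladl.harmonize import CANONICAL_RATE_HZ, UNLABELED, CanonicalStream
from falladl.taxonomy import TAXONOMY

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SegmentationConfig:
    """Window length and hop, derived from seconds and overlap fraction.

    ``L = round(window_s * 50)`` samples; ``H = max(1, round(L * (1 - overlap)))``.
    The default 1 s window with 80% overlap gives L = 50, H = 10.
    """

    window_s: float = 1.0
    overlap: float = 0.8

    def __post_init__(self) -> None:
        if not (0.0 <= self.overlap < 1.0):
            raise ValueError("overlap must be in [0, 1)")
        if self.length < 2:
            raise ValueError("window too short: need at least 2 samples")

    @property
    def length(self) -> int:
        return int(round(self.window_s * CANONICAL_RATE_HZ))

    @property
    def hop(self) -> int:
        return max(1, int(round(self.length * (1.0 - self.overlap))))


@dataclass
class WindowSet:
    """Stack of labeled windows: (W, L, 6) values plus per-window metadata."""

    windows: np.ndarray                 # (W, L, 6)
    labels: np.ndarray                  # (W,)
    subject_ids: np.ndarray             # (W,) object/str
    dataset_ids: np.ndarray             # (W,)
    config: SegmentationConfig = field(default_factory=SegmentationConfig)

    def __post_init__(self) -> None:
        w = self.windows.shape[0]
        if self.windows.ndim != 3 or self.windows.shape[2] != 6:
            raise ValueError("windows must have shape (W, L, 6)")
        for name, arr in (("labels", self.labels), ("subject_ids", self.subject_ids),
                          ("dataset_ids", self.dataset_ids)):
            if len(arr) != w:
                raise ValueError(f"{name} length {len(arr)} != W = {w}")
        TAXONOMY.validate_labels(self.labels)

    @property
    def n_windows(self) -> int:
        return self.windows.shape[0]

    @staticmethod
    def concatenate(sets: Sequence["WindowSet"]) -> "WindowSet":
        sets = [s for s in sets if s.n_windows > 0]
        if not sets:
            raise ValueError("no non-empty window sets to concatenate")
        cfg = sets[0].config
        return WindowSet(
            windows=np.concatenate([s.windows for s in sets]),
            labels=np.concatenate([s.labels for s in sets]),
            subject_ids=np.concatenate([s.subject_ids for s in sets]),
            dataset_ids=np.concatenate([s.dataset_ids for s in sets]),
            config=cfg,
        )


def n_windows(n_samples: int, length: int, hop: int) -> int:
    """Closed-form window count for a stream of ``n_samples`` samples."""
    return max(0, (n_samples - length) // hop + 1)


def mode_label(sample_labels: Sequence[int] | np.ndarray) -> int:
    """Most frequent label in a window (the mode labeling method).

    Ties are broken in favor of the tied label whose last occurrence in
    the window is latest.
    """
    arr = np.asarray(sample_labels, dtype=int)
    if arr.size == 0:
        raise ValueError("mode_label requires at least one sample label")
    values, counts = np.unique(arr, return_counts=True)
    best = values[counts == counts.max()]
    if best.size == 1:
        return int(best[0])
    last_pos = {int(v): int(np.flatnonzero(arr == v)[-1]) for v in best}
    return max(last_pos, key=last_pos.get)


def segment(stream: CanonicalStream, cfg: SegmentationConfig | None = None) -> WindowSet:
    """Cut one canonical stream into overlapping windows.

    Window ``k`` covers samples ``[k*H, k*H + L)``. Streams shorter than
    one window contribute zero windows (logged, not an error). Windows
    whose mode label is the unlabeled marker are dropped.
    """
    cfg = cfg or SegmentationConfig()
    L, H = cfg.length, cfg.hop
    n = stream.n_samples
    w = n_windows(n, L, H)
    if w == 0:
        logger.info("stream %s/%s shorter than one window (%d < %d samples): skipped",
                    stream.dataset_id, stream.subject_id, n, L)
        return WindowSet(
            windows=np.empty((0, L, 6)), labels=np.empty(0, dtype=int),
            subject_ids=np.empty(0, dtype=object), dataset_ids=np.empty(0, dtype=object),
            config=cfg,
        )
    chans = stream.channels
    starts = np.arange(w) * H
    windows = np.stack([chans[s:s + L] for s in starts])
    labels = np.array([mode_label(stream.labels[s:s + L]) for s in starts])
    keep = labels != UNLABELED
    return WindowSet(
        windows=windows[keep],
        labels=labels[keep],
        subject_ids=np.full(int(keep.sum()), stream.subject_id, dtype=object),
        dataset_ids=np.full(int(keep.sum()), stream.dataset_id, dtype=object),
        config=cfg,
    )


def segment_streams(streams: Iterable[CanonicalStream],
                    cfg: SegmentationConfig | None = None) -> WindowSet:
    """Segment many streams and stack the results in stream order."""
    cfg = cfg or SegmentationConfig()
    return WindowSet.concatenate([segment(s, cfg) for s in streams])
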