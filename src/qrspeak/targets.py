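"""Training-label generation with positive / negative / ignore semantics.

Each heat-map resolution gets an integer label vector over {1, 0, -1}:

* 1 (positive)  - the point lies within 75 ms of the nearest beat;
* 0 (negative)  - the point lies between the first and last beat and is
  more than 150 ms from every beat;
* -1 (ignore)   - everything else: the 75-150 ms border zone around each
  beat (where a fixed-range label would mislabel samples of similar
  morphology), the region before the first and after the last beat, and
  the first and last 200 ms of each vector (incomplete edge beats).

Ignored points contribute nothing to the loss.  Both thresholds are
strict, so a point at exactly 75 ms or 150 ms is ignored.  Coarse
resolutions are computed directly on their own (left-aligned) time grid,
never by subsampling the fine vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .records import RecordError

POSITIVE_RADIUS_S = 0.075
NEGATIVE_RADIUS_S = 0.150
EDGE_MASK_S = 0.200
STRIDES = (1, 2, 4)


@dataclass
class TargetSet:
    """Three label vectors over {1, 0, -1} at strides 1, 2 and 4."""

    labels: list[np.ndarray]
    fs_per_map: tuple[float, float, float]

    def __iter__(self):
        return iter(self.labels)


def _labels_one_resolution(
    ann_times: np.ndarray, n_points: int, dt: float
) -> np.ndarray:
    labels = np.full(n_points, -1, dtype=np.int8)
    t = np.arange(n_points) * dt
    if ann_times.size:
        # distance to nearest annotation via searchsorted on the sorted list
        idx = np.searchsorted(ann_times, t)
        left = ann_times[np.clip(idx - 1, 0, ann_times.size - 1)]
        right = ann_times[np.clip(idx, 0, ann_times.size - 1)]
        d = np.minimum(np.abs(t - left), np.abs(t - right))
        in_span = (t >= ann_times[0]) & (t <= ann_times[-1])
        labels[(d > NEGATIVE_RADIUS_S) & in_span] = 0
        labels[d < POSITIVE_RADIUS_S] = 1
    # mask the first/last 0.2 s of the vector: floor(0.2 * map_rate) points
    edge = min(int(np.floor(EDGE_MASK_S / dt)), n_points)
    labels[:edge] = -1
    labels[n_points - edge :] = -1
    return labels


def make_targets(annotations, l: int, fs: float = 250.0) -> TargetSet:
    """Build the three-resolution label vectors for a segment.

    Parameters
    ----------
    annotations:
        Sorted beat sample indices (ints) within ``[0, l)``.
    l:
        Full-resolution segment length in samples.
    fs:
        Full-resolution sampling rate, Hz.
    """
    ann = np.asarray(annotations, dtype=np.int64)
    if ann.size and np.any(np.diff(ann) <= 0):
        raise RecordError("annotations must be strictly increasing")
    if ann.size and (ann[0] < 0 or ann[-1] >= l):
        raise RecordError("annotation outside segment")
    ann_times = ann / fs
    labels = [
        _labels_one_resolution(ann_times, -(-l // r), r / fs) for r in STRIDES
    ]
    return TargetSet(labels=labels, fs_per_map=tuple(fs / r for r in STRIDES))
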