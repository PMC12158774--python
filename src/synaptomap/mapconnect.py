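"""Mapping synapse detections onto a labelled neurite segmentation.

A detection is first assigned to the segment under its rounded centroid; if
that voxel is background, the single z plane of the point is searched within
a square half-window for the nearest non-zero voxel, accepted only when the
in-plane squared distance stays below ``max_sq_dist`` and (optionally) the
segment class matches the synaptic side (pre -> axon, post -> dendrite).
Edges of the matching matrix with both endpoints assigned then accumulate
into a sparse segment-level connectivity matrix.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.morphology import ball

from .assemble import MatchingMatrix
from .errors import ConfigurationError
from .volcore import PointAnnotation, Volume

SEGMENT_CLASSES = ("axon", "dendrite", "glia", "other")

#: Synaptic side -> segment class it may attach to when class checking is on.
KIND_TO_CLASS = {"pre": "axon", "post": "dendrite"}


@dataclass
class SegmentVolume:
    """Integer label volume (0 = background) with per-segment classes."""

    labels: Volume
    class_of: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.labels.data.dtype.kind not in "ui":
            raise ConfigurationError("segment labels must be an integer volume")
        for sid, cls in self.class_of.items():
            if cls not in SEGMENT_CLASSES:
                raise ConfigurationError(f"unknown class {cls!r} for segment {sid}")


@dataclass
class MapParams:
    inplane_search: int = 10  # half-window: a 20 x 20-voxel neighbourhood
    max_sq_dist: float = 30.0  # squared in-plane distance bound, voxel^2
    ball_radius: int = 6  # 5-voxel alternative accepted
    require_class: bool = True

    def __post_init__(self) -> None:
        if self.inplane_search < 1 or self.max_sq_dist <= 0 or self.ball_radius < 1:
            raise ConfigurationError("MapParams entries must be positive")


def assign_point_to_segment(
    p: PointAnnotation, segs: SegmentVolume, params: MapParams | None = None
) -> int | None:
    """Segment id owning a point, or None when unassigned."""
    params = params or MapParams()
    labels = segs.labels.data
    z, y, x = (int(round(c)) for c in p.location)
    z = min(max(z, 0), labels.shape[0] - 1)
    y = min(max(y, 0), labels.shape[1] - 1)
    x = min(max(x, 0), labels.shape[2] - 1)

    def _class_ok(sid: int) -> bool:
        if not params.require_class:
            return True
        want = KIND_TO_CLASS.get(p.kind)
        return want is not None and segs.class_of.get(sid) == want

    sid = int(labels[z, y, x])
    if sid != 0:
        return sid if _class_ok(sid) else None
    # search the single plane of the point within the window
    w = params.inplane_search
    y0, y1 = max(y - w, 0), min(y + w, labels.shape[1] - 1) + 1
    x0, x1 = max(x - w, 0), min(x + w, labels.shape[2] - 1) + 1
    window = labels[z, y0:y1, x0:x1]
    yy, xx = np.nonzero(window)
    if yy.size == 0:
        return None
    sq = (yy + y0 - y) ** 2.0 + (xx + x0 - x) ** 2.0
    ids = window[yy, xx]
    if params.require_class:
        ok = np.array([_class_ok(int(s)) for s in ids])
        if not ok.any():
            return None
        sq, ids = sq[ok], ids[ok]
    order = np.lexsort((ids, sq))  # nearest first, ties to lowest segment id
    best = order[0]
    if sq[best] < params.max_sq_dist:
        return int(ids[best])
    return None


@dataclass
class ConnectivityMatrix:
    """Sparse (axon segment, dendrite segment) -> synapse count."""

    counts: Counter = field(default_factory=Counter)

    def total(self) -> int:
        return sum(self.counts.values())

    def out_degree(self, pre_segment: int) -> int:
        return sum(c for (a, _), c in self.counts.items() if a == pre_segment)

    def in_degree(self, post_segment: int) -> int:
        return sum(c for (_, d), c in self.counts.items() if d == post_segment)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"pre_segment": a, "post_segment": d, "count": c}
            for (a, d), c in sorted(self.counts.items())
        ]
        return pd.DataFrame(rows, columns=["pre_segment", "post_segment", "count"])


def build_connectivity(
    M: MatchingMatrix,
    pre_assignments: dict[int, int | None],
    post_assignments: dict[int, int | None],
) -> ConnectivityMatrix:
    """Accumulate M's edges into segment-level connectivity.

    Edges with an unassigned endpoint are skipped; the matrix total is
    therefore at most the number of edges of M, with equality iff every
    endpoint found a segment.
    """
    cm = ConnectivityMatrix()
    for i, j in M.edges:
        pre_seg = pre_assignments.get(j)
        post_seg = post_assignments.get(i)
        if pre_seg is None or post_seg is None:
            continue
        cm.counts[(pre_seg, post_seg)] += 1
    return cm


def synapses_on_segment(
    seg_id: int,
    segs: SegmentVolume,
    pre: list[PointAnnotation],
    post: list[PointAnnotation],
    M: MatchingMatrix,
    params: MapParams | None = None,
) -> pd.DataFrame:
    """Synapse table restricted to one segment, via mask dilation.

    The segment mask is dilated with a ball of ``ball_radius`` voxels;
    detections whose rounded centroid falls inside the dilated mask are
    selected, and their partners pulled from M. For a dendrite these are its
    inputs (post side on the segment), for an axon its outputs.
    """
    params = params or MapParams()
    labels = segs.labels.data
    if not (labels == seg_id).any():
        raise LookupError(f"segment {seg_id} not present in the label volume")
    mask = ndimage.binary_dilation(labels == seg_id, structure=ball(params.ball_radius))

    def _inside(p: PointAnnotation) -> bool:
        idx = tuple(
            min(max(int(round(c)), 0), s - 1) for c, s in zip(p.location, labels.shape)
        )
        return bool(mask[idx])

    rows = []
    for i, j in sorted(M.edges):
        pre_in = _inside(pre[j])
        post_in = _inside(post[i])
        if pre_in or post_in:
            rows.append(
                {
                    "pre_id": j,
                    "post_id": i,
                    "side_on_segment": "pre" if pre_in else "post",
                    "direction": "output" if pre_in else "input",
                }
            )
    return pd.DataFrame(rows, columns=["pre_id", "post_id", "side_on_segment", "direction"])
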