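"""Scoring of detections and assembled synapses against ground truth.

Point-level scoring solves a one-to-one minimum-total-distance assignment
(Hungarian algorithm) between automated and ground-truth points, with
distances above ``r_matching`` replaced by a large sentinel; any pair the
solver realizes above the cutoff is dissolved into a false positive plus a
false negative. Synapse-level scoring classifies each automated edge from
the point-level assignments plus the ground-truth edge list.

``summary_metrics`` houses the percentage / rate / density arithmetic used
for reported quantities, with round-half-up rounding at the printed
precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .errors import ComputationError, ConfigurationError
from .volcore import PointAnnotation


@dataclass
class EvalConfig:
    r_matching: float = 30.0
    border_planes: int = 10
    big_cost: float = 1e6

    def __post_init__(self) -> None:
        if self.r_matching <= 0 or self.border_planes < 0:
            raise ConfigurationError("r_matching must be > 0 and border_planes >= 0")


@dataclass
class Assignment:
    """One-to-one matches between automated and ground-truth points."""

    pairs: list[tuple[int, int, float]] = field(default_factory=list)  # (auto, gt, dist)
    unmatched_auto: list[int] = field(default_factory=list)  # false positives
    unmatched_gt: list[int] = field(default_factory=list)  # false negatives

    @property
    def tp(self) -> int:
        return len(self.pairs)

    @property
    def fp(self) -> int:
        return len(self.unmatched_auto)

    @property
    def fn(self) -> int:
        return len(self.unmatched_gt)

    def auto_to_gt(self) -> dict[int, int]:
        return {a: g for a, g, _ in self.pairs}


def match_points(
    auto: list[PointAnnotation] | np.ndarray,
    gt: list[PointAnnotation] | np.ndarray,
    cfg: EvalConfig | None = None,
) -> Assignment:
    """Optimal one-to-one point matching with a distance cutoff."""
    cfg = cfg or EvalConfig()
    A = np.asarray([p.location for p in auto] if auto and isinstance(auto[0], PointAnnotation) else auto, dtype=float).reshape(-1, 3) if len(auto) else np.empty((0, 3))
    G = np.asarray([p.location for p in gt] if gt and isinstance(gt[0], PointAnnotation) else gt, dtype=float).reshape(-1, 3) if len(gt) else np.empty((0, 3))
    if A.shape[0] == 0 or G.shape[0] == 0:
        return Assignment([], list(range(A.shape[0])), list(range(G.shape[0])))
    C = cdist(A, G)
    cost = np.where(C > cfg.r_matching, cfg.big_cost, C)
    rows, cols = linear_sum_assignment(cost)
    pairs = [
        (int(a), int(g), float(C[a, g]))
        for a, g in zip(rows, cols)
        if C[a, g] <= cfg.r_matching
    ]
    matched_a = {a for a, _, _ in pairs}
    matched_g = {g for _, g, _ in pairs}
    return Assignment(
        pairs,
        [a for a in range(A.shape[0]) if a not in matched_a],
        [g for g in range(G.shape[0]) if g not in matched_g],
    )


def classify_synapses(
    auto_edges: set[tuple[int, int]] | list[tuple[int, int]],
    gt_edges: set[tuple[int, int]] | list[tuple[int, int]],
    pre_assign: Assignment,
    post_assign: Assignment,
) -> tuple[int, int, int]:
    """Full-synapse TP/FP/FN counts.

    Edges are (pre index, post index) pairs — automated indices for
    ``auto_edges`` and ground-truth indices for ``gt_edges``. An automated
    edge is a true positive iff its presynaptic point is a true positive,
    its postsynaptic point is a true positive, and the corresponding
    ground-truth edge exists; otherwise it is one false positive (an edge
    failing several rules still counts once). Every ground-truth edge
    without a true-positive counterpart is a false negative.
    """
    pre_map = pre_assign.auto_to_gt()
    post_map = post_assign.auto_to_gt()
    gt_set = set(tuple(e) for e in gt_edges)
    tp_gt_edges: set[tuple[int, int]] = set()
    tp = fp = 0
    for pre_i, post_i in set(tuple(e) for e in auto_edges):
        gt_pre = pre_map.get(pre_i)
        gt_post = post_map.get(post_i)
        if gt_pre is not None and gt_post is not None and (gt_pre, gt_post) in gt_set:
            tp += 1
            tp_gt_edges.add((gt_pre, gt_post))
        else:
            fp += 1
    fn = len(gt_set - tp_gt_edges)
    return tp, fp, fn


def border_revision(
    gt_points: list[PointAnnotation],
    filtered_assign: Assignment,
    unfiltered_assign: Assignment,
    n_planes: int,
    cfg: EvalConfig | None = None,
) -> tuple[int, int, list[int]]:
    """Promote border false negatives recoverable without the z-extent filter.

    A ground-truth point counts as an extra true positive iff it is (i)
    matched in the assignment against the unfiltered detection list, (ii) a
    false negative against the filtered list, and (iii) located within the
    first or last ``border_planes`` imaging planes. Returns (extra_tp,
    removed_fn, promoted ground-truth ids); both count deltas are equal.
    """
    cfg = cfg or EvalConfig()
    matched_unfiltered = {g for _, g, _ in unfiltered_assign.pairs}
    promoted = []
    for g in filtered_assign.unmatched_gt:
        if g not in matched_unfiltered:
            continue
        z = gt_points[g].location[0]
        if z < cfg.border_planes or z >= n_planes - cfg.border_planes:
            promoted.append(g)
    return len(promoted), len(promoted), promoted


def prf_scores(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    """Precision, recall and F1, with 0 for empty denominators."""
    if min(tp, fp, fn) < 0:
        raise ConfigurationError("counts must be nonnegative")
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, f1


@dataclass
class EvalReport:
    """TP/FP/FN and precision/recall/F1 per class, plus a revision log."""

    counts: dict[str, tuple[int, int, int]] = field(default_factory=dict)
    revision_log: dict[str, list[int]] = field(default_factory=dict)

    def add(self, name: str, tp: int, fp: int, fn: int) -> None:
        self.counts[name] = (int(tp), int(fp), int(fn))

    def scores(self, name: str) -> tuple[float, float, float]:
        return prf_scores(*self.counts[name])

    def as_dict(self) -> dict:
        out = {}
        for name, (tp, fp, fn) in self.counts.items():
            p, r, f1 = prf_scores(tp, fp, fn)
            out[name] = {
                "tp": tp, "fp": fp, "fn": fn,
                "precision": p, "recall": r, "f1": f1,
            }
        if self.revision_log:
            out["revision_log"] = {k: list(v) for k, v in self.revision_log.items()}
        return out


# ---------------------------------------------------------------------------
# Summary arithmetic for reported quantities
# ---------------------------------------------------------------------------

def round_half_up(value: float, ndigits: int = 0) -> float:
    """Decimal round-half-up at the reported precision."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def _require_positive(denominator: float, name: str) -> None:
    if denominator <= 0:
        raise ComputationError(f"{name} must be positive, got {denominator}")


def percent_of(n: float, total: float, ndigits: int = 1) -> float:
    _require_positive(total, "total")
    return round_half_up(100.0 * n / total, ndigits)


def percent_reduction(before: float, after: float, ndigits: int = 1) -> float:
    _require_positive(before, "before")
    return round_half_up(100.0 * (before - after) / before, ndigits)


def rate_per_um(n: float, length_um: float, ndigits: int = 2) -> float:
    _require_positive(length_um, "length_um")
    return round_half_up(n / length_um, ndigits)


def rate_per_mm(n: float, length_mm: float, ndigits: int = 2) -> float:
    _require_positive(length_mm, "length_mm")
    return round_half_up(n / length_mm, ndigits)


def density_per_um3(n: float, volume_um3: float, ndigits: int = 2) -> float:
    _require_positive(volume_um3, "volume_um3")
    return round_half_up(n / volume_um3, ndigits)


def effective_voxel_nm(imaging_nm: float, expansion_factor: float, ndigits: int = 1) -> float:
    _require_positive(expansion_factor, "expansion_factor")
    return round_half_up(imaging_nm / expansion_factor, ndigits)


def expanded_volume(pre_volume: float, expansion_factor: float) -> float:
    _require_positive(expansion_factor, "expansion_factor")
    return pre_volume * expansion_factor**3
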