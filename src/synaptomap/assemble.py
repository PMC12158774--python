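"""Pairing of pre- and postsynaptic points into full synapses, plus rescue.

Pairing follows a two-pass nearest-first rule rather than one-to-one optimal
assignment, so that one-to-many synaptic motifs (one bouton contacting two
spines, or two boutons converging on one spine) are representable:

pass 1
    every postsynaptic point is connected to its nearest presynaptic point,
    provided the Euclidean distance is strictly below ``d_matching``;
pass 2
    every presynaptic point left without a partner is connected to its
    nearest postsynaptic point under the same cutoff (even if that post
    already holds an edge).

Distances are Euclidean in voxel-index space, because the matching cutoffs
are stated in voxels; physical (nm) distances are reported alongside in the
synapse table using the grid's anisotropic voxel sizes. Nearest-neighbour
ties break toward the lowest point index.

``rescue_unpaired`` revisits unpaired detections and searches the structural
(protein-density) channel around them for a bright partner feature — a
prominent postsynaptic density or presynaptic bouton whose molecular signal
fell below threshold — and, when found, adds an opposite-kind point and
re-runs the pairing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial.distance import cdist
from skimage.morphology import ball

from . import volcore
from .detect import DetectionSet, otsu_threshold, weighted_centroid
from .errors import ConfigurationError
from .volcore import PointAnnotation, Volume, VoxelGrid

logger = logging.getLogger(__name__)


@dataclass
class PairingConfig:
    """Maximum pre/post matching distance, in voxel units."""

    d_matching: float = 30.0

    def __post_init__(self) -> None:
        if self.d_matching <= 0:
            raise ConfigurationError("d_matching must be positive")


@dataclass
class MatchingMatrix:
    """Binary pre x post relation stored as a sparse edge set.

    Edges are (post index i, pre index j) pairs into the point lists that
    produced them. The Euclidean cost of any edge is recomputable from the
    points and is strictly below ``d_matching`` by construction.
    """

    n_post: int
    n_pre: int
    edges: set[tuple[int, int]] = field(default_factory=set)

    def paired_pre(self) -> set[int]:
        return {j for _, j in self.edges}

    def paired_post(self) -> set[int]:
        return {i for i, _ in self.edges}

    def unpaired_pre(self) -> list[int]:
        return sorted(set(range(self.n_pre)) - self.paired_pre())

    def unpaired_post(self) -> list[int]:
        return sorted(set(range(self.n_post)) - self.paired_post())

    def pre_degree(self, j: int) -> int:
        return sum(1 for _, jj in self.edges if jj == j)

    def post_degree(self, i: int) -> int:
        return sum(1 for ii, _ in self.edges if ii == i)


def _locations(points) -> np.ndarray:
    return np.array([p.location for p in points], dtype=float).reshape(len(points), 3)


def pair_synapses(
    pre: list[PointAnnotation],
    post: list[PointAnnotation],
    cfg: PairingConfig | None = None,
) -> MatchingMatrix:
    """Two-pass nearest-first association of pre and post points."""
    cfg = cfg or PairingConfig()
    M = MatchingMatrix(n_post=len(post), n_pre=len(pre))
    if not pre or not post:
        return M
    S = cdist(_locations(post), _locations(pre))  # S[i, j]
    # pass 1: each post takes its nearest pre (argmin breaks ties low)
    for i in range(len(post)):
        j = int(np.argmin(S[i]))
        if S[i, j] < cfg.d_matching:
            M.edges.add((i, j))
    # pass 2: each still-floating pre takes its nearest post
    paired = M.paired_pre()
    for j in range(len(pre)):
        if j in paired:
            continue
        i = int(np.argmin(S[:, j]))
        if S[i, j] < cfg.d_matching:
            M.edges.add((i, j))
    return M


def synapse_table(
    M: MatchingMatrix,
    pre: list[PointAnnotation],
    post: list[PointAnnotation],
    grid: VoxelGrid,
) -> pd.DataFrame:
    """Edge-list view of M: one row per assembled synapse.

    Columns: pre_id, post_id, dist_vox (Euclidean in voxel indices),
    dist_nm (anisotropy-aware) and the pre/post degrees flagging
    one-to-many motifs.
    """
    scale = np.asarray(grid.voxel_size_nm, dtype=float)
    rows = []
    for i, j in sorted(M.edges):
        d = np.asarray(post[i].location) - np.asarray(pre[j].location)
        rows.append(
            {
                "pre_id": j,
                "post_id": i,
                "dist_vox": float(np.linalg.norm(d)),
                "dist_nm": float(np.linalg.norm(d * scale)),
                "pre_degree": M.pre_degree(j),
                "post_degree": M.post_degree(i),
            }
        )
    return pd.DataFrame(
        rows, columns=["pre_id", "post_id", "dist_vox", "dist_nm", "pre_degree", "post_degree"]
    )


@dataclass
class RescueParams:
    """Parameters of the structural-channel rescue of unpaired detections."""

    box: tuple[int, int, int] = (100, 100, 100)
    rescale_lo_percentile: float = 1.0
    rescale_hi_percentile: float = 99.95
    sigma_signal: float = 2.0
    sigma_background: float = 10.0
    thr_coefficient: float = 0.4  # 0.5 variant in one dataset
    opening_radius: int = 2
    min_voxels: int = 20
    accept_radius: float = 30.0
    percentile_source: str = "dog"  # or "raw"

    def __post_init__(self) -> None:
        if not 0 < self.thr_coefficient < 1:
            raise ConfigurationError("thr_coefficient must lie in (0, 1)")
        if any(b <= 0 for b in self.box) or self.min_voxels < 1 or self.accept_radius <= 0:
            raise ConfigurationError("rescue parameters must be positive")


def rescue_threshold(p95: float, p100: float, coefficient: float = 0.4) -> float:
    """thr = p95 + c * (p100 - p95)."""
    return p95 + coefficient * (p100 - p95)


def _rescue_at_seed(
    seed: PointAnnotation,
    new_kind: str,
    structural: Volume,
    exclusion: np.ndarray,
    params: RescueParams,
) -> tuple[list[PointAnnotation], dict]:
    """Search one crop box around an unpaired seed for bright partner features."""
    shape = structural.grid.shape
    centre = np.round(seed.location).astype(int)
    half = np.asarray(params.box) // 2
    lo = np.maximum(centre - half, 0)
    hi = np.minimum(centre + half, shape)
    log: dict = {"seed": seed.location, "new_kind": new_kind, "accepted": [], "rejected": 0}
    if np.any(lo >= hi):
        log["skipped"] = "box outside grid"
        return [], log
    slc = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    crop = structural.astype_float().data[slc]
    crop_grid = VoxelGrid(crop.shape, structural.grid.voxel_size_nm)
    rescaled = volcore.rescale_intensity(
        Volume(crop_grid, crop, role="structural"),
        lo_percentile=params.rescale_lo_percentile,
        hi_percentile=params.rescale_hi_percentile,
    )
    dog = volcore.dog_subtract(rescaled, params.sigma_signal, params.sigma_background)
    source = dog.data if params.percentile_source == "dog" else rescaled.data
    p95, p100 = np.percentile(source, [95.0, 100.0])
    thr = rescue_threshold(float(p95), float(p100), params.thr_coefficient)
    mask = dog.data > thr
    mask &= ~exclusion[slc]
    mask = ndimage.binary_opening(mask, structure=ball(params.opening_radius))
    labels, n = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=bool))
    new_points: list[PointAnnotation] = []
    for rid in range(1, n + 1):
        coords = np.stack(np.nonzero(labels == rid), axis=1)
        if coords.shape[0] < params.min_voxels:
            continue
        weights = crop[tuple(coords.T)]
        centroid_local = weighted_centroid(coords, weights)
        centroid = tuple(float(c) + float(o) for c, o in zip(centroid_local, lo))
        dist = float(np.linalg.norm(np.asarray(centroid) - np.asarray(seed.location)))
        if dist < params.accept_radius:
            new_points.append(
                PointAnnotation(centroid, new_kind, source="rescue", region_id=None)
            )
            log["accepted"].append({"centroid": centroid, "distance": dist})
        else:
            log["rejected"] += 1
    return new_points, log


def rescue_unpaired(
    M: MatchingMatrix,
    pre_det: DetectionSet,
    post_det: DetectionSet,
    structural: Volume,
    params: RescueParams | None = None,
    pairing: PairingConfig | None = None,
) -> tuple[list[PointAnnotation], list[PointAnnotation], list[dict], MatchingMatrix]:
    """Rescue unpaired detections from the structural channel and re-pair.

    For every all-zero row of M (unpaired post) a presynaptic candidate is
    sought, and for every all-zero column (unpaired pre) a postsynaptic
    candidate, inside a crop box around the seed. Voxels already claimed by
    existing pre/post detection labels are excluded before thresholding.
    Returns the augmented pre and post point lists, the rescue log, and the
    matching matrix recomputed on the augmented lists (existing detections
    are never removed).
    """
    params = params or RescueParams()
    pairing = pairing or PairingConfig()
    exclusion = (pre_det.label_volume.data > 0) | (post_det.label_volume.data > 0)
    pre_points = list(pre_det.points)
    post_points = list(post_det.points)
    logs: list[dict] = []
    for i in M.unpaired_post():
        found, log = _rescue_at_seed(post_points[i], "pre", structural, exclusion, params)
        pre_points.extend(found)
        logs.append(log)
    for j in M.unpaired_pre():
        found, log = _rescue_at_seed(pre_det.points[j], "post", structural, exclusion, params)
        post_points.extend(found)
        logs.append(log)
    M_new = pair_synapses(pre_points, post_points, pairing)
    return pre_points, post_points, logs, M_new
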