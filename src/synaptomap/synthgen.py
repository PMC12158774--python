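"""Seeded generators for synthetic expansion-microscopy scenes.

``generate_scene`` builds a three-channel volume emulating the measured
geometry of excitatory synapses in protein-density expansion data:

* presynaptic marker channel — per synapse, a cluster of 2–5 nanoscale
  puncta arranged in the active-zone plane with ~97 nm spacing (the
  lattice-like arrangement of dense projections);
* postsynaptic marker channel — a disc-like feature (the postsynaptic
  density, PSD) offset ~154 nm from the presynaptic cluster centroid along
  the synapse axis;
* structural (pan-protein) channel — bright features co-located with both
  (dense projections and PSD bar) on top of a smoothed-noise neurite
  background, so that the structural gate of the detection chain has a real
  foil: non-specific molecular puncta are planted only where the structural
  background is below its median.

All channels carry a camera offset and optional Poisson–Gaussian noise.
Ground-truth point and edge tables use the same conventions as the
assembly/evaluation modules, and the whole scene is bit-reproducible from
``SceneParams.seed`` (placement and noise draw from independent
sub-streams, so switching noise on does not reshuffle placements).

The module also provides a labelled axon/dendrite tube phantom for the
segment-mapping stage and a displacement-field phantom with a known global
similarity for the distortion statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.special import erf

from .distort import DisplacementField, LandmarkSet
from .errors import ConfigurationError
from .mapconnect import SegmentVolume
from .volcore import PointAnnotation, Volume, VoxelGrid

#: Default effective voxel size (dz, dy, dx) in nm — a 300-nm imaging z step
#: and 150-nm pixels divided by a ~15.5x expansion factor.
DEFAULT_VOXEL_NM = (19.4, 9.7, 9.7)

MOTIFS = ("1:1", "1:2", "2:1")


def make_grid(extent_um: float | tuple[float, float, float],
              voxel_size_nm: tuple[float, float, float] = DEFAULT_VOXEL_NM,
              z_step_nm_imaging: float | None = 300.0) -> VoxelGrid:
    """Grid covering a physical extent (µm, biological scale)."""
    if np.isscalar(extent_um):
        extent_um = (extent_um, extent_um, extent_um)
    shape = tuple(
        max(int(round(e * 1000.0 / v)), 1) for e, v in zip(extent_um, voxel_size_nm)
    )
    return VoxelGrid(shape, voxel_size_nm, z_step_nm_imaging)


@dataclass
class SceneParams:
    """Study conditions of a synthetic scene.

    Geometry defaults reproduce the measured synapse morphology: puncta
    spacing 97 ± 28 nm, pre-to-post offset 154 ± 19 nm, spine density on
    the order of 1 µm⁻³. Amplitudes are in camera counts above the offset.
    """

    grid: VoxelGrid
    seed: int
    synapse_density: float = 1.0  # µm^-3, Poisson count unless exact_count
    exact_count: int | None = None
    motif_fractions: dict[str, float] = field(default_factory=lambda: {"1:1": 1.0})
    pre_cluster_spacing_nm: float = 97.0
    pre_cluster_spacing_sd_nm: float = 28.0
    pre_post_offset_nm: float = 154.0
    pre_post_offset_sd_nm: float = 19.0
    psd_disc_radius_nm: float = 150.0
    # SHANK2 occupies a ~120-nm-thick postsynaptic slab; convolved with the
    # ~50-nm axial PSF this gives a Gaussian cross-section of sigma ~60 nm
    psd_thickness_sigma_nm: float = 60.0
    psd_edge_softness_nm: float = 30.0
    # PSDs of distinct synapses never abut; resample the synapse axis until
    # the disc centre clears neighbouring discs by this distance
    post_min_separation_nm: float = 450.0
    puncta_per_cluster: tuple[int, int] = (2, 5)
    # single punctum = ~80-nm nanocluster convolved with the effective
    # PSF (~20 nm lateral / ~50 nm axial resolution)
    punctum_sigma_nm: tuple[float, float, float] = (45.0, 35.0, 35.0)  # (z, y, x)
    nonspecific_density: float = 0.5  # µm^-3 per molecular channel
    # non-specific background blobs are antibody aggregates, larger than
    # single synaptic puncta; size factor drawn uniformly from this range
    nonspecific_sigma_scale: tuple[float, float] = (1.2, 2.2)
    camera_offset: float = 100.0
    noise_model: str = "none"  # none | gaussian | poisson-gaussian
    read_noise_sd: float = 3.0
    margin_nm: float = 500.0
    min_separation_nm: float = 600.0
    structural_bg_counts: tuple[float, float] = (8.0, 60.0)  # above offset
    structural_pre_amp: float = 1200.0
    structural_psd_amp: float = 1600.0
    mol_pre_amp: float = 2000.0
    mol_post_amp: float = 1800.0
    nonspecific_amp: float = 1200.0
    drop_post_marker: tuple[int, ...] = ()  # synapse units lacking the post marker

    def __post_init__(self) -> None:
        if self.synapse_density < 0 or self.nonspecific_density < 0:
            raise ConfigurationError("densities must be nonnegative")
        if self.camera_offset < 0:
            raise ConfigurationError("camera offset must be nonnegative")
        if self.noise_model not in ("none", "gaussian", "poisson-gaussian"):
            raise ConfigurationError(f"unknown noise model {self.noise_model!r}")
        if abs(sum(self.motif_fractions.values()) - 1.0) > 1e-9 or any(
            m not in MOTIFS for m in self.motif_fractions
        ):
            raise ConfigurationError("motif fractions must be over {'1:1','1:2','2:1'} and sum to 1")
        margin_vox = self._margin_vox()
        if any(2 * m >= s for m, s in zip(margin_vox, self.grid.shape)):
            raise ConfigurationError("grid too small for the PSF/feature margin")

    def _margin_vox(self) -> tuple[int, ...]:
        return tuple(
            int(math.ceil(self.margin_nm / v)) for v in self.grid.voxel_size_nm
        )


@dataclass
class SyntheticScene:
    structural: Volume
    pre_channel: Volume
    post_channel: Volume
    gt_pre: list[PointAnnotation]
    gt_post: list[PointAnnotation]
    gt_edges: list[tuple[int, int]]  # (pre index, post index)
    params: SceneParams


# ------------------------------------------------------------------
# geometry helpers (all positions in nm, axis order (z, y, x))
# ------------------------------------------------------------------

def _unit_vector(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    n = np.linalg.norm(v)
    while n < 1e-9:  # pragma: no cover
        v = rng.normal(size=3)
        n = np.linalg.norm(v)
    return v / n


def _orthobasis(n: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.array([1.0, 0.0, 0.0]) if abs(n[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(n, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    return e1, e2


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float, lo: float = 1e-6) -> float:
    for _ in range(100):
        v = rng.normal(mean, sd)
        if v > lo:
            return v
    return max(mean, lo)  # pragma: no cover


def _nm_to_vox(p_nm: np.ndarray, voxel: np.ndarray) -> np.ndarray:
    return np.asarray(p_nm, float) / voxel


def _add_gaussian_blob(arr, centre_vox, sigma_vox, peak) -> None:
    """Add an anisotropic Gaussian blob inside a +/-4 sigma window."""
    shape = arr.shape
    lo = [max(int(math.floor(c - 4 * s)), 0) for c, s in zip(centre_vox, sigma_vox)]
    hi = [min(int(math.ceil(c + 4 * s)) + 1, n) for c, s, n in zip(centre_vox, sigma_vox, shape)]
    if any(a >= b for a, b in zip(lo, hi)):
        return
    zz, yy, xx = np.ogrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    q = (
        (zz - centre_vox[0]) ** 2 / (2 * sigma_vox[0] ** 2)
        + (yy - centre_vox[1]) ** 2 / (2 * sigma_vox[1] ** 2)
        + (xx - centre_vox[2]) ** 2 / (2 * sigma_vox[2] ** 2)
    )
    arr[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += peak * np.exp(-q)


def _add_disc(arr, centre_nm, normal, radius_nm, sigma_h_nm, edge_nm, peak, voxel) -> None:
    """Add a soft-edged disc of given orientation (analytic, windowed)."""
    half_nm = radius_nm + 3 * edge_nm + 3 * sigma_h_nm
    shape = arr.shape
    lo = [max(int(math.floor((c - half_nm) / v)), 0) for c, v in zip(centre_nm, voxel)]
    hi = [min(int(math.ceil((c + half_nm) / v)) + 1, n) for c, v, n in zip(centre_nm, voxel, shape)]
    if any(a >= b for a, b in zip(lo, hi)):
        return
    zz, yy, xx = np.meshgrid(
        np.arange(lo[0], hi[0]) * voxel[0] - centre_nm[0],
        np.arange(lo[1], hi[1]) * voxel[1] - centre_nm[1],
        np.arange(lo[2], hi[2]) * voxel[2] - centre_nm[2],
        indexing="ij",
    )
    h = zz * normal[0] + yy * normal[1] + xx * normal[2]
    r_sq = np.maximum(zz**2 + yy**2 + xx**2 - h**2, 0.0)
    r_in = np.sqrt(r_sq)
    profile = np.exp(-(h**2) / (2 * sigma_h_nm**2)) * 0.5 * (
        1.0 - erf((r_in - radius_nm) / (math.sqrt(2.0) * edge_nm))
    )
    arr[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += peak * profile


def _place_centres(rng, params: SceneParams, count: int) -> np.ndarray:
    """Dart-throwing placement with a minimum pairwise separation (nm)."""
    extent_nm = np.array(params.grid.shape) * np.array(params.grid.voxel_size_nm)
    lo = np.full(3, params.margin_nm)
    hi = extent_nm - params.margin_nm
    centres: list[np.ndarray] = []
    attempts = 0
    while len(centres) < count:
        attempts += 1
        if attempts > 200 * max(count, 1):
            raise ConfigurationError(
                f"cannot place {count} synapses at {params.min_separation_nm} nm separation"
            )
        c = rng.uniform(lo, hi)
        if all(np.linalg.norm(c - p) >= params.min_separation_nm for p in centres):
            centres.append(c)
    return np.array(centres).reshape(count, 3)


def _motif_schedule(params: SceneParams, count: int, rng) -> list[str]:
    """Exact motif counts from requested fractions (largest remainder)."""
    fracs = [(m, params.motif_fractions.get(m, 0.0)) for m in MOTIFS]
    base = {m: int(math.floor(f * count)) for m, f in fracs}
    rem = count - sum(base.values())
    by_frac = sorted(fracs, key=lambda mf: -(mf[1] * count - base[mf[0]]))
    for k in range(rem):
        base[by_frac[k % len(by_frac)][0]] += 1
    schedule = [m for m in MOTIFS for _ in range(base[m])]
    rng.shuffle(schedule)
    return schedule


def generate_scene(params: SceneParams) -> SyntheticScene:
    """Render a scene and its ground truth from ``SceneParams``."""
    rng_place = np.random.default_rng([params.seed, 1])
    rng_noise = np.random.default_rng([params.seed, 2])
    rng_nonspec = np.random.default_rng([params.seed, 3])
    grid = params.grid
    voxel = np.asarray(grid.voxel_size_nm)
    shape = grid.shape

    if params.exact_count is not None:
        count = int(params.exact_count)
    else:
        count = int(rng_place.poisson(params.synapse_density * grid.volume_um3))

    structural = np.zeros(shape, dtype=np.float32)
    pre_ch = np.zeros(shape, dtype=np.float32)
    post_ch = np.zeros(shape, dtype=np.float32)

    # smoothed-noise neurite background in the structural channel
    bg = ndimage.gaussian_filter(
        rng_place.random(shape).astype(np.float32), sigma=(2.0, 4.0, 4.0)
    )
    bg -= bg.min()
    if bg.max() > 0:
        bg /= bg.max()
    b_lo, b_hi = params.structural_bg_counts
    structural += b_lo + (b_hi - b_lo) * bg

    centres = _place_centres(rng_place, params, count)
    schedule = _motif_schedule(params, count, rng_place)
    punctum_sigma_vox = np.asarray(params.punctum_sigma_nm) / voxel

    gt_pre: list[PointAnnotation] = []
    gt_post: list[PointAnnotation] = []
    gt_edges: list[tuple[int, int]] = []

    def _render_pre(centre_nm: np.ndarray, normal: np.ndarray) -> int:
        """Render one presynaptic cluster; returns its gt_pre index."""
        k = int(rng_place.integers(params.puncta_per_cluster[0], params.puncta_per_cluster[1] + 1))
        # spacing floor: dense projections are ~80-nm bodies and cannot
        # interpenetrate, so the truncated normal is cut at 50 nm
        s = _trunc_normal(
            rng_place, params.pre_cluster_spacing_nm, params.pre_cluster_spacing_sd_nm, lo=50.0
        )
        e1, e2 = _orthobasis(normal)
        lattice = [
            (0.0, 0.0), (1.0, 0.0), (0.5, math.sqrt(3) / 2),
            (-0.5, math.sqrt(3) / 2), (-1.0, 0.0),
        ][:k]
        offsets = np.array([a * s * e1 + b * s * e2 for a, b in lattice])
        offsets -= offsets.mean(axis=0)
        for off in offsets:
            p_vox = _nm_to_vox(centre_nm + off, voxel)
            amp = float(np.clip(1.0 + 0.2 * rng_place.standard_normal(), 0.7, 1.3))
            _add_gaussian_blob(pre_ch, p_vox, punctum_sigma_vox, params.mol_pre_amp * amp)
            _add_gaussian_blob(
                structural, p_vox, punctum_sigma_vox, params.structural_pre_amp * amp
            )
        gt_pre.append(
            PointAnnotation(tuple(_nm_to_vox(centre_nm, voxel)), "pre", source="gt")
        )
        return len(gt_pre) - 1

    def _render_post(centre_nm: np.ndarray, normal: np.ndarray, unit_idx: int) -> int:
        """Render one PSD disc; returns its gt_post index."""
        if unit_idx not in params.drop_post_marker:
            _add_disc(
                post_ch, centre_nm, normal, params.psd_disc_radius_nm,
                params.psd_thickness_sigma_nm, params.psd_edge_softness_nm,
                params.mol_post_amp, voxel,
            )
        _add_disc(
            structural, centre_nm, normal, params.psd_disc_radius_nm,
            params.psd_thickness_sigma_nm, params.psd_edge_softness_nm,
            params.structural_psd_amp, voxel,
        )
        gt_post.append(
            PointAnnotation(tuple(_nm_to_vox(centre_nm, voxel)), "post", source="gt")
        )
        return len(gt_post) - 1

    placed_posts: list[np.ndarray] = []

    def _clears_posts(candidate: np.ndarray) -> bool:
        return all(
            np.linalg.norm(candidate - q) >= params.post_min_separation_nm
            for q in placed_posts
        )

    def _pick_axis(centre_nm: np.ndarray, d: float) -> np.ndarray:
        n = _unit_vector(rng_place)
        for _ in range(50):
            if _clears_posts(centre_nm + d * n):
                break
            n = _unit_vector(rng_place)
        return n

    for unit_idx, (centre, motif) in enumerate(zip(centres, schedule)):
        d = _trunc_normal(rng_place, params.pre_post_offset_nm, params.pre_post_offset_sd_nm)
        if motif == "1:1":
            n = _pick_axis(centre, d)
            pi = _render_pre(centre, n)
            post_nm = centre + d * n
            qi = _render_post(post_nm, n, unit_idx)
            placed_posts.append(post_nm)
            gt_edges.append((pi, qi))
        elif motif == "1:2":
            n = _pick_axis(centre, d)
            pi = _render_pre(centre, n)
            e1, _ = _orthobasis(n)
            for sign in (+1.0, -1.0):
                axis = n * math.cos(math.radians(35)) + sign * e1 * math.sin(math.radians(35))
                axis /= np.linalg.norm(axis)
                d2 = _trunc_normal(
                    rng_place, params.pre_post_offset_nm, params.pre_post_offset_sd_nm
                )
                post_nm = centre + d2 * axis
                qi = _render_post(post_nm, axis, unit_idx)
                placed_posts.append(post_nm)
                gt_edges.append((pi, qi))
        else:  # 2:1 — two boutons converging on one spine
            n = _unit_vector(rng_place)
            qi = _render_post(centre, n, unit_idx)
            placed_posts.append(np.asarray(centre, dtype=float))
            e1, _ = _orthobasis(n)
            for sign in (+1.0, -1.0):
                axis = n * math.cos(math.radians(45)) + sign * e1 * math.sin(math.radians(45))
                axis /= np.linalg.norm(axis)
                d2 = _trunc_normal(
                    rng_place, params.pre_post_offset_nm, params.pre_post_offset_sd_nm
                )
                pi = _render_pre(centre - d2 * axis, axis)
                gt_edges.append((pi, qi))

    # non-specific molecular puncta over dim structural background: the
    # underlay must carry no synaptic-feature light, so the structural gate
    # sees a cleanly bimodal list of per-region maxima
    dim_cap = 1.2 * params.structural_bg_counts[1]
    extent_nm = np.array(shape) * voxel
    for channel in (pre_ch, post_ch):
        n_ns = int(rng_nonspec.poisson(params.nonspecific_density * grid.volume_um3))
        placed = 0
        guard = 0
        while placed < n_ns and guard < 50 * max(n_ns, 1):
            guard += 1
            p_nm = rng_nonspec.uniform(params.margin_nm, extent_nm - params.margin_nm)
            p_vox = np.round(_nm_to_vox(p_nm, voxel)).astype(int)
            size = rng_nonspec.uniform(*params.nonspecific_sigma_scale)
            sigma = punctum_sigma_vox * size
            # the structural underlay must be dim over the blob's whole
            # footprint, not just its centre, so the gate sees a clean foil
            w = np.ceil(2 * sigma).astype(int)
            win = structural[
                max(p_vox[0] - w[0], 0):p_vox[0] + w[0] + 1,
                max(p_vox[1] - w[1], 0):p_vox[1] + w[1] + 1,
                max(p_vox[2] - w[2], 0):p_vox[2] + w[2] + 1,
            ]
            if win.max() >= dim_cap:
                continue
            amp = params.nonspecific_amp * (0.7 + 0.6 * rng_nonspec.random())
            _add_gaussian_blob(channel, _nm_to_vox(p_nm, voxel), sigma, amp)
            placed += 1

    def _finish(signal: np.ndarray) -> np.ndarray:
        if params.noise_model == "none":
            out = signal + params.camera_offset
        elif params.noise_model == "gaussian":
            out = (
                signal
                + params.camera_offset
                + rng_noise.normal(0.0, params.read_noise_sd, size=signal.shape)
            )
        else:  # poisson-gaussian: shot noise on signal, additive read noise
            out = (
                rng_noise.poisson(np.clip(signal, 0, None)).astype(np.float32)
                + params.camera_offset
                + rng_noise.normal(0.0, params.read_noise_sd, size=signal.shape)
            )
        return np.clip(out, 0, None).astype(np.float32)

    return SyntheticScene(
        structural=Volume(grid, _finish(structural), role="structural"),
        pre_channel=Volume(grid, _finish(pre_ch), role="molecular"),
        post_channel=Volume(grid, _finish(post_ch), role="molecular"),
        gt_pre=gt_pre,
        gt_post=gt_post,
        gt_edges=gt_edges,
        params=params,
    )


# ------------------------------------------------------------------
# segmentation phantom
# ------------------------------------------------------------------

@dataclass
class SegmentationPhantom:
    segments: SegmentVolume
    pre_points: list[PointAnnotation]
    post_points: list[PointAnnotation]
    edges: list[tuple[int, int]]  # (pre idx, post idx)
    true_pre_segment: dict[int, int]  # pre point idx -> axon id
    true_post_segment: dict[int, int]  # post point idx -> dendrite id


def generate_segmentation_phantom(
    shape: tuple[int, int, int] = (64, 128, 128),
    n_axons: int = 2,
    n_dendrites: int = 2,
    tube_radius: int = 5,
    synapses_per_crossing: int = 1,
    point_offset: int = 2,
    voxel_size_nm: tuple[float, float, float] = DEFAULT_VOXEL_NM,
    seed: int = 0,
) -> SegmentationPhantom:
    """Non-overlapping axon (along x) and dendrite (along y) tube phantom.

    Axons occupy a low-z slab and dendrites a high-z slab so tubes never
    intersect. At each axon/dendrite crossing, ``synapses_per_crossing``
    pre/post point pairs are planted ``point_offset`` voxels outside the
    respective tube surface, in the tube's own plane, with known owners.
    """
    rng = np.random.default_rng(seed)
    nz, ny, nx = shape
    slab = 2 * tube_radius + 4
    if (n_axons + n_dendrites) * slab > nz:
        raise ConfigurationError("phantom grid too small for the requested tubes")
    labels = np.zeros(shape, dtype=np.int32)
    class_of: dict[int, str] = {}
    zz = np.arange(nz)[:, None, None]
    yy = np.arange(ny)[None, :, None]
    xx = np.arange(nx)[None, None, :]

    axon_pos = []  # (id, z, y)
    for i in range(n_axons):
        z_c = tube_radius + 2 + i * slab
        y_c = int(rng.integers(tube_radius + 2, ny - tube_radius - 2))
        sid = i + 1
        labels[((zz - z_c) ** 2 + (yy - y_c) ** 2 <= tube_radius**2) & (xx == xx)] = sid
        class_of[sid] = "axon"
        axon_pos.append((sid, z_c, y_c))
    dend_pos = []  # (id, z, x)
    for j in range(n_dendrites):
        z_c = nz - tube_radius - 3 - j * slab
        x_c = int(rng.integers(tube_radius + 2, nx - tube_radius - 2))
        sid = n_axons + j + 1
        labels[((zz - z_c) ** 2 + (xx - x_c) ** 2 <= tube_radius**2) & (yy == yy)] = sid
        class_of[sid] = "dendrite"
        dend_pos.append((sid, z_c, x_c))

    grid = VoxelGrid(shape, voxel_size_nm)
    segments = SegmentVolume(Volume(grid, labels, role="label"), class_of)

    pre_points: list[PointAnnotation] = []
    post_points: list[PointAnnotation] = []
    edges: list[tuple[int, int]] = []
    true_pre: dict[int, int] = {}
    true_post: dict[int, int] = {}
    for a_id, a_z, a_y in axon_pos:
        for d_id, d_z, d_x in dend_pos:
            for _ in range(synapses_per_crossing):
                # pre: in the axon's plane, offset in +y; post: in the
                # dendrite's plane, offset in +x — both at the crossing
                pre = PointAnnotation(
                    (float(a_z), float(a_y + tube_radius + point_offset), float(d_x)),
                    "pre", source="phantom",
                )
                post = PointAnnotation(
                    (float(d_z), float(a_y), float(d_x + tube_radius + point_offset)),
                    "post", source="phantom",
                )
                pre_points.append(pre)
                post_points.append(post)
                true_pre[len(pre_points) - 1] = a_id
                true_post[len(post_points) - 1] = d_id
                edges.append((len(pre_points) - 1, len(post_points) - 1))
    return SegmentationPhantom(segments, pre_points, post_points, edges, true_pre, true_post)


# ------------------------------------------------------------------
# distortion phantom
# ------------------------------------------------------------------

def generate_distortion_phantom(
    shape: tuple[int, int] = (200, 200),
    scale: float = 15.44,
    rotation_deg: float = 7.0,
    translation: tuple[float, float] = (3.0, -2.0),
    perturbation_amp: float = 0.0,
    perturbation_sigma: float = 25.0,
    n_landmarks: int = 25,
    seed: int = 0,
) -> tuple[DisplacementField, LandmarkSet, dict]:
    """Displacement field + landmarks for a known global similarity.

    The field is u(p) = (s·R·p + t) − p plus an optional smooth
    low-frequency perturbation; landmarks are sampled on the grid with the
    exact (unperturbed) transform applied, so similarity fitting must
    recover ``scale`` exactly.
    """
    rng = np.random.default_rng(seed)
    th = math.radians(rotation_deg)
    R = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
    t = np.asarray(translation, dtype=float)
    H, W = shape
    yy, xx = np.meshgrid(np.arange(H, dtype=float), np.arange(W, dtype=float), indexing="ij")
    P = np.stack([yy, xx])  # (2, H, W)
    transformed = scale * np.einsum("ij,jhw->ihw", R, P) + t[:, None, None]
    u = transformed - P
    if perturbation_amp > 0:
        pert = np.stack(
            [ndimage.gaussian_filter(rng.standard_normal(shape), perturbation_sigma) for _ in range(2)]
        )
        peak = np.abs(pert).max()
        if peak > 0:
            pert *= perturbation_amp / peak
        u = u + pert
    field = DisplacementField(u, np.ones(shape, dtype=bool))
    pre = rng.uniform([0, 0], [H - 1, W - 1], size=(n_landmarks, 2))
    post = scale * pre @ R.T + t
    lm = LandmarkSet(pre, post)
    truth = {"scale": scale, "rotation_deg": rotation_deg, "translation": tuple(t)}
    return field, lm, truth
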