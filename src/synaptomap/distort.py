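"""Expansion-factor extraction and distortion (measurement-error) statistics.

The expansion factor of a hydrogel-expanded sample is the isotropic scale of
the least-squares similarity transform fitted to landmark correspondences
between pre- and post-expansion images (closed-form Procrustes/Umeyama
solution). Residual non-uniform distortion is quantified from a dense
displacement field: point pairs are sampled inside a structure mask, and the
length of the difference between each pre-expansion vector and its
field-transformed counterpart is binned by measurement length, giving the
classic measurement-error-versus-length curve and its RMS summary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import medfilt

from .errors import ComputationError, ConfigurationError


@dataclass
class LandmarkSet:
    """Paired pre/post coordinates, (n, d) with d in {2, 3}, pixel units."""

    pre: np.ndarray
    post: np.ndarray

    def __post_init__(self) -> None:
        self.pre = np.asarray(self.pre, dtype=float)
        self.post = np.asarray(self.post, dtype=float)
        if self.pre.shape != self.post.shape or self.pre.ndim != 2:
            raise ConfigurationError("pre and post landmark arrays must have equal (n, d) shape")
        n, d = self.pre.shape
        if d not in (2, 3):
            raise ConfigurationError("landmarks must be 2D or 3D")
        if n < d + 1:
            raise ConfigurationError(f"need at least {d + 1} landmarks in {d}D, got {n}")
        if len(np.unique(self.pre, axis=0)) != n:
            raise ConfigurationError("duplicated pre-expansion landmarks")


@dataclass
class SimilarityTransform:
    """post ~= scale * rotation @ pre + translation."""

    scale: float
    rotation: np.ndarray
    translation: np.ndarray
    rms_residual: float

    def apply(self, points: np.ndarray) -> np.ndarray:
        return self.scale * np.asarray(points, float) @ self.rotation.T + self.translation


def fit_similarity(lm: LandmarkSet) -> SimilarityTransform:
    """Least-squares similarity fit (isotropic scale, rotation, translation).

    Closed-form Umeyama solution; the fitted scale is the expansion factor.
    Degenerate (collinear / coincident) landmark configurations raise
    ComputationError.
    """
    X, Y = lm.pre, lm.post  # map X -> Y
    n, d = X.shape
    mx, my = X.mean(axis=0), Y.mean(axis=0)
    Xc, Yc = X - mx, Y - my
    var_x = (Xc**2).sum() / n
    if var_x == 0:
        raise ComputationError("coincident landmarks: similarity fit is degenerate")
    cov = Yc.T @ Xc / n
    U, s, Vt = np.linalg.svd(cov)
    if s[-1] < 1e-12 * s[0] and d == 3:
        # rank-deficient covariance: points collinear (3D) -> rotation not unique
        raise ComputationError("degenerate (collinear) landmark configuration")
    S = np.eye(d)
    if np.linalg.det(U) * np.linalg.det(Vt) < 0:
        S[-1, -1] = -1.0
    R = U @ S @ Vt
    scale = float(np.trace(np.diag(s) @ S) / var_x)
    if scale <= 0:
        raise ComputationError("non-positive fitted scale")
    t = my - scale * R @ mx
    resid = Y - (scale * X @ R.T + t)
    rms = float(np.sqrt((resid**2).sum(axis=1).mean()))
    return SimilarityTransform(scale, R, t, rms)


def fit_affine(lm: LandmarkSet) -> tuple[np.ndarray, np.ndarray, float]:
    """Ordinary least-squares affine fit: post ~= A @ pre + t.

    Returns (A, t, rms_residual).
    """
    X, Y = lm.pre, lm.post
    n, d = X.shape
    H = np.hstack([X, np.ones((n, 1))])
    coef, *_ = np.linalg.lstsq(H, Y, rcond=None)
    A = coef[:d].T
    t = coef[d]
    resid = Y - (X @ A.T + t)
    rms = float(np.sqrt((resid**2).sum(axis=1).mean()))
    return A, t, rms


@dataclass
class DisplacementField:
    """Per-pixel 2D displacement (u_y, u_x) with a validity mask."""

    u: np.ndarray  # shape (2, H, W)
    mask: np.ndarray  # shape (H, W), bool

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.u.ndim != 3 or self.u.shape[0] != 2 or self.u.shape[1:] != self.mask.shape:
            raise ConfigurationError("field must be (2, H, W) with a matching (H, W) mask")
        if not np.isfinite(self.u[:, self.mask]).all():
            raise ConfigurationError("displacement field not finite inside the mask")


@dataclass
class ErrorCurve:
    """Mean +/- sd measurement error per measurement-length bin."""

    lengths: np.ndarray  # bin centres, pixels
    mean_error: np.ndarray
    sd_error: np.ndarray
    n_per_bin: np.ndarray

    def smoothed(self, kernel: int = 5) -> np.ndarray:
        """1D median-filtered mean error, for display."""
        return medfilt(self.mean_error, kernel_size=kernel)


def measurement_error_curve(
    field: DisplacementField,
    n_pairs: int = 200_000,
    seed: int | np.random.Generator = 0,
    bin_width: float = 1.0,
) -> ErrorCurve:
    """Distortion (measurement error) versus measurement length.

    ``n_pairs`` point pairs are sampled uniformly (both endpoints
    independent) from the masked area. For a pair (p1, p2) the pre vector is
    v = p2 - p1 and the transformed vector v' = (p2 + u(p2)) - (p1 + u(p1));
    the error is |v' - v|, binned by |v| in bins of ``bin_width`` pixels.
    With a fixed seed the curve is bit-reproducible.
    """
    if n_pairs < 1:
        raise ConfigurationError("n_pairs must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = np.stack(np.nonzero(field.mask), axis=1)
    if idx.shape[0] == 0:
        raise ConfigurationError("empty mask")
    p1 = idx[rng.integers(0, idx.shape[0], size=n_pairs)]
    p2 = idx[rng.integers(0, idx.shape[0], size=n_pairs)]
    u1 = field.u[:, p1[:, 0], p1[:, 1]].T
    u2 = field.u[:, p2[:, 0], p2[:, 1]].T
    v = (p2 - p1).astype(float)
    err = np.linalg.norm(u2 - u1, axis=1)  # |v' - v| = |u(p2) - u(p1)|
    length = np.linalg.norm(v, axis=1)
    bins = np.floor(length / bin_width).astype(int)
    nbins = int(bins.max()) + 1
    counts = np.bincount(bins, minlength=nbins)
    sums = np.bincount(bins, weights=err, minlength=nbins)
    sqsums = np.bincount(bins, weights=err**2, minlength=nbins)
    keep = counts > 0
    mean = sums[keep] / counts[keep]
    var = np.maximum(sqsums[keep] / counts[keep] - mean**2, 0.0)
    centres = (np.nonzero(keep)[0] + 0.5) * bin_width
    return ErrorCurve(centres, mean, np.sqrt(var), counts[keep])


def rms_error(curve: ErrorCurve) -> float:
    """RMS of the per-bin mean errors across measurement scales."""
    if curve.mean_error.size == 0:
        raise ComputationError("empty error curve")
    return float(np.sqrt((curve.mean_error**2).mean()))
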