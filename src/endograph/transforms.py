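"""Planar affine transforms between frames: estimation, algebra, warping.

Conventions
-----------
An :class:`AffineTransform` is a 3x3 homogeneous matrix acting on column
vectors ``(x, y, 1)`` with x = column, y = row, 0-based pixel centers.  A
transform "from frame a to frame b" maps a point's coordinates in frame a to
the coordinates of the corresponding physical point in frame b.

``warp_image(src, t, shape)`` produces an image in the *target* frame, where
``t`` maps target coordinates into ``src`` coordinates (inverse mapping with
bilinear interpolation); no matrix inversion happens inside the warp.

``compose([f, g])`` is sequential application — apply ``f`` first, then ``g``
(matrix product ``g @ f``) — so composing the hops of a graph pathway in
travel order yields the end-to-end point map.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .exceptions import (
    DegenerateGeometryError,
    InsufficientCorrespondencesError,
    InsufficientOverlapError,
    InvalidInputError,
)

__all__ = [
    "AffineTransform",
    "WarpResult",
    "RegistrationScore",
    "identity_transform",
    "translation",
    "estimate_affine",
    "fit_affine_lstsq",
    "invert",
    "compose",
    "warp_image",
    "ncc_score",
    "ssd_score",
]

_MIN_DET = 1e-8
DEFAULT_MIN_OVERLAP = 0.25


@dataclass(frozen=True)
class AffineTransform:
    """Invertible planar affine map as a 3x3 homogeneous matrix.

    The last row must be exactly (0, 0, 1) and the upper-left 2x2 block must
    have |det| > 1e-8.
    """

    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=np.float64)
        if m.shape != (3, 3):
            raise InvalidInputError(f"affine matrix must be 3x3, got {m.shape}")
        m = m.copy()
        m[2] = (0.0, 0.0, 1.0)
        if abs(np.linalg.det(m[:2, :2])) <= _MIN_DET:
            raise DegenerateGeometryError("affine 2x2 block is (near-)singular")
        m.setflags(write=False)
        object.__setattr__(self, "matrix", m)

    def apply(self, points) -> np.ndarray:
        """Map an (N, 2) array of (x, y) points through the transform."""
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
        ones = np.ones((pts.shape[0], 1))
        out = np.hstack([pts, ones]) @ self.matrix.T
        return out[:, :2]

    @property
    def linear(self) -> np.ndarray:
        """The 2x2 linear block."""
        return self.matrix[:2, :2]

    @property
    def offset(self) -> np.ndarray:
        """The translation part (dx, dy)."""
        return self.matrix[:2, 2]

    def to_list(self) -> list[float]:
        """Row-major 9-number representation for serialization."""
        return [float(v) for v in self.matrix.ravel()]

    @classmethod
    def from_list(cls, values) -> "AffineTransform":
        arr = np.asarray(values, dtype=np.float64)
        if arr.size != 9:
            raise InvalidInputError("affine serialization must hold 9 numbers")
        return cls(arr.reshape(3, 3))

    def almost_equal(self, other: "AffineTransform", tol: float = 1e-9) -> bool:
        return bool(np.allclose(self.matrix, other.matrix, atol=tol))


@dataclass
class WarpResult:
    """A warped image plus the mask of pixels with an in-source preimage."""

    image: np.ndarray
    validity_mask: np.ndarray

    def __post_init__(self):
        if self.image.shape != self.validity_mask.shape:
            raise InvalidInputError("image and validity_mask shapes differ")


@dataclass
class RegistrationScore:
    """NCC validation outcome for one warped pair.

    ``dif_h`` is the zero-normalized cross correlation over the valid overlap
    (in [-1, 1]; values near 1 validate the affine-similarity assumption),
    ``overlap_fraction`` the valid-pixel share of the reference frame.
    """

    dif_h: float
    overlap_fraction: float


def identity_transform() -> AffineTransform:
    return AffineTransform(np.eye(3))


def translation(dx: float, dy: float) -> AffineTransform:
    m = np.eye(3)
    m[0, 2], m[1, 2] = dx, dy
    return AffineTransform(m)


def fit_affine_lstsq(src_pts, dst_pts) -> AffineTransform:
    """Least-squares affine from (N>=3, 2) correspondences src -> dst."""
    src = np.asarray(src_pts, dtype=np.float64)
    dst = np.asarray(dst_pts, dtype=np.float64)
    if src.shape[0] < 3:
        raise InsufficientCorrespondencesError("need at least 3 correspondences")
    A = np.hstack([src, np.ones((src.shape[0], 1))])
    sol, _, rank, _ = np.linalg.lstsq(A, dst, rcond=None)
    if rank < 3:
        raise DegenerateGeometryError("correspondences are collinear")
    m = np.eye(3)
    m[:2, :3] = sol.T
    return AffineTransform(m)


def _sample_is_degenerate(pts: np.ndarray, eps: float = 1e-6) -> bool:
    (x1, y1), (x2, y2), (x3, y3) = pts
    area2 = abs((x2 - x1) * (y3 - y1) - (x3 - x1) * (y2 - y1))
    return area2 < eps


def estimate_affine(
    matches,
    a,
    b,
    inlier_tol: float = 3.0,
    max_iter: int = 2000,
    seed: int = 0,
    confidence: float = 0.995,
):
    """RANSAC affine estimate from matched keypoints of frames a and b.

    Draws 3-point minimal samples (seeded, hence deterministic), scores by
    reprojection error in frame b, and re-fits by least squares on the largest
    inlier set.  Returns ``(transform_a_to_b, inlier_indices)`` where inlier
    indices refer to positions in ``matches.pairs``.

    Raises InsufficientCorrespondencesError for fewer than 3 matches and
    DegenerateGeometryError when every sample (or the winning consensus set)
    is collinear.
    """
    n = len(matches)
    if n < 3:
        raise InsufficientCorrespondencesError(
            f"RANSAC needs >= 3 matches, got {n}"
        )
    coords_a = a.coordinates()
    coords_b = b.coordinates()
    src = np.array([coords_a[i] for i, _ in matches.pairs])
    dst = np.array([coords_b[j] for _, j in matches.pairs])

    rng = np.random.default_rng(seed)
    best_inliers: np.ndarray | None = None
    best_count = 0
    n_iter = max_iter
    it = 0
    saw_valid_sample = False
    while it < n_iter:
        it += 1
        idx = rng.choice(n, size=3, replace=False)
        s, d = src[idx], dst[idx]
        if _sample_is_degenerate(s) or _sample_is_degenerate(d):
            continue
        try:
            model = _exact_affine(s, d)
        except DegenerateGeometryError:
            continue
        saw_valid_sample = True
        err = np.linalg.norm(model.apply(src) - dst, axis=1)
        inliers = np.nonzero(err < inlier_tol)[0]
        if len(inliers) > best_count or (
            len(inliers) == best_count
            and best_inliers is not None
            and tuple(inliers) < tuple(best_inliers)
        ):
            best_count = len(inliers)
            best_inliers = inliers
            # adaptive iteration bound at the requested confidence
            w = best_count / n
            if w > 0:
                denom = np.log1p(-min(w**3, 1 - 1e-12))
                if denom < 0:
                    n_iter = min(
                        max_iter, int(np.ceil(np.log(1 - confidence) / denom))
                    )
    if not saw_valid_sample or best_inliers is None or best_count < 3:
        raise DegenerateGeometryError(
            "no non-collinear consensus found by RANSAC"
        )
    refit = fit_affine_lstsq(src[best_inliers], dst[best_inliers])
    # final inlier set under the refit model
    err = np.linalg.norm(refit.apply(src) - dst, axis=1)
    inliers = np.nonzero(err < inlier_tol)[0]
    if len(inliers) >= 3:
        try:
            refit = fit_affine_lstsq(src[inliers], dst[inliers])
        except DegenerateGeometryError:
            inliers = best_inliers
    else:
        inliers = best_inliers
    return refit, [int(i) for i in inliers]


def _exact_affine(src: np.ndarray, dst: np.ndarray) -> AffineTransform:
    A = np.hstack([src, np.ones((3, 1))])
    try:
        sol = np.linalg.solve(A, dst)
    except np.linalg.LinAlgError as exc:
        raise DegenerateGeometryError(str(exc)) from exc
    m = np.eye(3)
    m[:2, :3] = sol.T
    return AffineTransform(m)


def invert(t: AffineTransform) -> AffineTransform:
    """Matrix inverse with the homogeneous row re-fixed to (0, 0, 1)."""
    try:
        inv = np.linalg.inv(t.matrix)
    except np.linalg.LinAlgError as exc:
        raise DegenerateGeometryError(str(exc)) from exc
    inv[2] = (0.0, 0.0, 1.0)
    return AffineTransform(inv)


def compose(chain) -> AffineTransform:
    """Sequential composition of a non-empty transform chain.

    ``compose([f, g, h])`` applies f, then g, then h — the end-to-end map of
    a pathway's hops listed in travel order.
    """
    chain = list(chain)
    if not chain:
        raise InvalidInputError("cannot compose an empty transform chain")
    m = np.eye(3)
    for t in chain:
        m = t.matrix @ m
    return AffineTransform(m)


def warp_image(src, t: AffineTransform, target_shape) -> WarpResult:
    """Warp ``src`` into a target frame by inverse mapping.

    ``t`` maps target-frame coordinates to src coordinates; the output pixel
    at (x, y) is the bilinear sample of ``src`` at ``t(x, y)``.  The validity
    mask is False wherever the preimage falls outside ``src``.
    """
    rows, cols = int(target_shape[0]), int(target_shape[1])
    if rows <= 0 or cols <= 0:
        raise InvalidInputError("target_shape must be positive")
    src = np.asarray(src, dtype=np.float64)
    xx, yy = np.meshgrid(np.arange(cols, dtype=np.float64),
                         np.arange(rows, dtype=np.float64))
    m = t.matrix
    sx = m[0, 0] * xx + m[0, 1] * yy + m[0, 2]
    sy = m[1, 0] * xx + m[1, 1] * yy + m[1, 2]
    h, w = src.shape
    mask = (sx >= 0.0) & (sx <= w - 1.0) & (sy >= 0.0) & (sy <= h - 1.0)
    warped = ndimage.map_coordinates(
        src, [sy, sx], order=1, mode="constant", cval=0.0, prefilter=False
    )
    warped[~mask] = 0.0
    return WarpResult(image=warped, validity_mask=mask)


def ncc_score(
    reference,
    moving,
    t: AffineTransform,
    min_overlap: float = DEFAULT_MIN_OVERLAP,
) -> RegistrationScore:
    """Zero-normalized cross correlation of ``moving`` warped onto ``reference``.

    ``t`` is the transform from the reference frame to the moving frame (its
    point map), used directly as the inverse-mapping warp.  The correlation is
    computed over valid-mask pixels only; an overlap fraction below
    ``min_overlap`` raises InsufficientOverlapError.
    """
    ref = np.asarray(reference, dtype=np.float64)
    mov = np.asarray(moving, dtype=np.float64)
    if ref.size == 0 or mov.size == 0:
        raise InvalidInputError("images must be non-empty")
    warped = warp_image(mov, t, ref.shape)
    mask = warped.validity_mask
    overlap = float(mask.sum()) / mask.size
    if overlap < min_overlap:
        raise InsufficientOverlapError(
            f"overlap {overlap:.3f} below minimum {min_overlap:.3f}"
        )
    x = ref[mask]
    y = warped.image[mask]
    x = x - x.mean()
    y = y - y.mean()
    denom = np.sqrt((x * x).sum() * (y * y).sum())
    if denom == 0.0:
        # constant overlap region: define perfect correlation for identical
        # constants, zero otherwise
        dif_h = 1.0 if np.allclose(ref[mask], warped.image[mask]) else 0.0
    else:
        dif_h = float(np.clip((x * y).sum() / denom, -1.0, 1.0))
    return RegistrationScore(dif_h=dif_h, overlap_fraction=overlap)


def ssd_score(a: WarpResult, b: WarpResult) -> float:
    """Mean squared intensity difference over the joint validity mask.

    Normalising by overlap pixel count keeps edge weights comparable between
    pairs with different overlaps.  Symmetric; empty overlap raises
    InsufficientOverlapError.
    """
    if a.image.shape != b.image.shape:
        raise InvalidInputError("warp results must share shape")
    mask = a.validity_mask & b.validity_mask
    n = int(mask.sum())
    if n == 0:
        raise InsufficientOverlapError("validity masks do not intersect")
    diff = a.image[mask] - b.image[mask]
    return float((diff * diff).sum() / n)
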