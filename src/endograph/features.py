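"""Scale-restricted SIFT-style keypoints with simplified 32-D descriptors.

Endoscope optics keep the image scale of gastric mucosa nearly constant: the
focal length is fixed and the scope's travel is bounded by the gastric cavity,
so almost all usable features live between image scale degrees 1 and 3.  The
detector here exploits that: a single-octave difference-of-Gaussians (DoG)
pyramid whose layer scales sigma lie in [1, 3] relative to the input image
(no downsampling, no extra octaves).  "Scale" of a keypoint is the Gaussian
sigma of the DoG layer it was detected on.

The descriptor is a reduced SIFT layout — a 2x2 spatial grid of 8-bin gradient
orientation histograms (32 dimensions instead of 128) — computed in a rotated,
scale-proportional window.  After unit-L2 normalisation, every element larger
than 0.4 is clamped to 1 (strictly larger; no re-normalisation afterwards),
which suppresses, rather than removes, illumination effects.

Everything here is deterministic: identical input bytes give bitwise-identical
feature sets.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial.distance import cdist

from .exceptions import InvalidInputError, UndefinedSimilarityError
from .imageutils import to_grayscale

__all__ = [
    "Keypoint",
    "FeatureSet",
    "MatchSet",
    "extract_features",
    "clamp_normalize",
    "match_features",
    "similarity",
    "DESCRIPTOR_SIZE",
    "SCALE_MIN",
    "SCALE_MAX",
]

DESCRIPTOR_SIZE = 32
SCALE_MIN = 1.0
SCALE_MAX = 3.0

# Clamp threshold for descriptor elements (strictly-greater rule).
_CLAMP = 0.4

# Single-octave pyramid: sigma_i = 0.8 * 2**(i/3).  Interior DoG layers then
# carry scales {1.01, 1.27, 1.60, 2.02, 2.54}, covering the [1, 3] band.
_SIGMA_BASE = 0.8
_N_LEVELS = 8

_PEAK_THRESHOLD = 0.004  # on [0,1]-intensity DoG values
_EDGE_RATIO = 10.0       # principal-curvature ratio limit, SIFT convention

_N_ORI_BINS = 36         # orientation-assignment histogram
_DESC_GRID = 2           # 2x2 spatial cells
_DESC_ORI_BINS = 8
_DESC_CELL_WIDTH = 6.0   # cell half... full cell width in units of sigma


@dataclass(frozen=True)
class Keypoint:
    """A detected interest point.

    x, y are 0-based pixel-center coordinates (x = column, y = row), scale is
    the Gaussian sigma of the detection layer (in [1, 3]), orientation is the
    dominant local gradient direction in radians in [0, 2*pi), and response is
    the absolute DoG value used for ranking.
    """

    x: float
    y: float
    scale: float
    orientation: float
    response: float = 0.0


@dataclass
class FeatureSet:
    """Keypoints plus a parallel (N, 32) descriptor array for one frame.

    ``len(fs)`` is the frame's feature count Fp (the denominator side of the
    similarity statistic).
    """

    keypoints: list[Keypoint] = field(default_factory=list)
    descriptors: np.ndarray = field(
        default_factory=lambda: np.empty((0, DESCRIPTOR_SIZE))
    )
    source_frame_id: str | None = None

    def __post_init__(self):
        self.descriptors = np.asarray(self.descriptors, dtype=np.float64)
        if self.descriptors.ndim != 2 or self.descriptors.shape[1] != DESCRIPTOR_SIZE:
            if self.descriptors.size == 0:
                self.descriptors = np.empty((0, DESCRIPTOR_SIZE))
            else:
                raise InvalidInputError(
                    f"descriptors must be (N, {DESCRIPTOR_SIZE}), "
                    f"got {self.descriptors.shape}"
                )
        if len(self.keypoints) != self.descriptors.shape[0]:
            raise InvalidInputError(
                "keypoints and descriptors must have equal length"
            )

    def __len__(self) -> int:
        return len(self.keypoints)

    def coordinates(self) -> np.ndarray:
        """(N, 2) array of (x, y) keypoint positions."""
        return np.array([(k.x, k.y) for k in self.keypoints]).reshape(-1, 2)

    def to_dict(self) -> dict:
        """JSON-serialisable record (for on-disk feature caching)."""
        return {
            "source_frame_id": self.source_frame_id,
            "keypoints": [
                [k.x, k.y, k.scale, k.orientation, k.response]
                for k in self.keypoints
            ],
            "descriptors": self.descriptors.tolist(),
        }

    @classmethod
    def from_dict(cls, record: dict) -> "FeatureSet":
        kps = [Keypoint(*row) for row in record["keypoints"]]
        return cls(
            keypoints=kps,
            descriptors=np.asarray(record["descriptors"], dtype=np.float64),
            source_frame_id=record.get("source_frame_id"),
        )


@dataclass
class MatchSet:
    """One-to-one index pairs between two feature sets; ``len`` is M_p."""

    pairs: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        left = [i for i, _ in self.pairs]
        right = [j for _, j in self.pairs]
        if len(set(left)) != len(left) or len(set(right)) != len(right):
            raise InvalidInputError("matches must be one-to-one on both sides")

    def __len__(self) -> int:
        return len(self.pairs)


def clamp_normalize(raw) -> np.ndarray:
    """Apply the illumination-suppressing clamp to a 32-vector.

    Elements strictly greater than 0.4 become 1; all others are kept.  The
    vector is *not* re-normalised afterwards.  Input is expected to be
    unit-L2-normalised (the standard SIFT convention before clamping).
    """
    vec = np.asarray(raw, dtype=np.float64)
    if vec.ndim != 1 or vec.shape[0] != DESCRIPTOR_SIZE:
        raise InvalidInputError(
            f"descriptor must have length {DESCRIPTOR_SIZE}, got shape {vec.shape}"
        )
    out = vec.copy()
    out[out > _CLAMP] = 1.0
    return out


def extract_features(image, max_features: int = 200) -> FeatureSet:
    """Detect scale-restricted keypoints and simplified 32-D descriptors.

    Returns at most ``max_features`` keypoints ordered by decreasing detection
    response (ties by (y, x) ascending).  Constant or too-small images yield
    an empty FeatureSet; non-2-D input raises InvalidInputError.
    """
    if max_features < 1:
        raise InvalidInputError("max_features must be >= 1")
    img = np.asarray(image)
    if img.ndim != 2:
        img = to_grayscale(img)  # raises InvalidInputError on non-image input
    else:
        img = to_grayscale(img)
    h, w = img.shape
    if h < 16 or w < 16 or np.ptp(img) == 0.0:
        return FeatureSet()

    sigmas = _SIGMA_BASE * 2.0 ** (np.arange(_N_LEVELS) / 3.0)
    gauss = np.stack([ndimage.gaussian_filter(img, s, mode="nearest") for s in sigmas])
    dog = gauss[1:] - gauss[:-1]  # layer l has scale sigmas[l]

    cand = _find_extrema(dog, sigmas)
    if cand.shape[0] == 0:
        return FeatureSet()

    # Precompute gradient fields per Gaussian level (used by orientation and
    # descriptor sampling at the keypoint's own scale).
    grad_y = np.gradient(gauss, axis=1)
    grad_x = np.gradient(gauss, axis=2)

    keypoints: list[Keypoint] = []
    raw_descriptors: list[np.ndarray] = []
    for layer, cy, cx, response, x, y in cand:
        layer = int(layer)
        scale = float(sigmas[layer])
        theta = _dominant_orientation(
            grad_x[layer], grad_y[layer], x, y, scale
        )
        if theta is None:
            continue
        desc = _descriptor(grad_x[layer], grad_y[layer], x, y, scale, theta)
        keypoints.append(
            Keypoint(x=float(x), y=float(y), scale=scale,
                     orientation=float(theta), response=float(response))
        )
        raw_descriptors.append(desc)
        if len(keypoints) >= max_features:
            break

    if not keypoints:
        return FeatureSet()
    return FeatureSet(
        keypoints=keypoints,
        descriptors=np.stack(raw_descriptors),
    )


def _find_extrema(dog: np.ndarray, sigmas: np.ndarray) -> np.ndarray:
    """Locate, screen and sub-pixel-refine DoG extrema.

    Returns rows (layer, cy, cx, response, x_refined, y_refined) sorted by
    decreasing response with (y, x) ascending tie-break.
    """
    n_layers = dog.shape[0]
    maxf = ndimage.maximum_filter(dog, size=3, mode="nearest")
    minf = ndimage.minimum_filter(dog, size=3, mode="nearest")
    is_ext = ((dog >= maxf) | (dog <= minf)) & (np.abs(dog) > _PEAK_THRESHOLD)
    # interior layers only, and only those whose scale lies in [1, 3]
    scale_ok = (sigmas[:n_layers] >= SCALE_MIN) & (sigmas[:n_layers] <= SCALE_MAX)
    is_ext[0] = is_ext[-1] = False
    is_ext[~scale_ok] = False
    is_ext[:, 0, :] = is_ext[:, -1, :] = False
    is_ext[:, :, 0] = is_ext[:, :, -1] = False

    layers, ys, xs = np.nonzero(is_ext)
    if layers.size == 0:
        return np.empty((0, 6))

    rows = []
    edge_lim = (_EDGE_RATIO + 1.0) ** 2 / _EDGE_RATIO
    h, w = dog.shape[1:]
    for l, cy, cx in zip(layers, ys, xs):
        d = dog[l]
        dxx = d[cy, cx + 1] + d[cy, cx - 1] - 2.0 * d[cy, cx]
        dyy = d[cy + 1, cx] + d[cy - 1, cx] - 2.0 * d[cy, cx]
        dxy = 0.25 * (
            d[cy + 1, cx + 1] - d[cy + 1, cx - 1]
            - d[cy - 1, cx + 1] + d[cy - 1, cx - 1]
        )
        tr, det = dxx + dyy, dxx * dyy - dxy * dxy
        if det <= 0 or tr * tr / det >= edge_lim:
            continue
        gx = 0.5 * (d[cy, cx + 1] - d[cy, cx - 1])
        gy = 0.5 * (d[cy + 1, cx] - d[cy - 1, cx])
        # one Newton step on the in-plane quadratic model, clamped to the cell
        denom = dxx * dyy - dxy * dxy
        ox = -(dyy * gx - dxy * gy) / denom
        oy = -(dxx * gy - dxy * gx) / denom
        ox = float(np.clip(ox, -0.5, 0.5))
        oy = float(np.clip(oy, -0.5, 0.5))
        x, y = cx + ox, cy + oy
        if not (0.0 <= x < w and 0.0 <= y < h):
            continue
        rows.append((l, cy, cx, abs(d[cy, cx]), x, y))

    if not rows:
        return np.empty((0, 6))
    arr = np.array(rows)
    order = np.lexsort((arr[:, 4], arr[:, 5], -arr[:, 3]))  # response desc, then y, x
    return arr[order]


def _dominant_orientation(gx, gy, x, y, scale):
    """Peak of the Gaussian-weighted 36-bin gradient orientation histogram."""
    h, w = gx.shape
    sig = 1.5 * scale
    radius = int(round(3.0 * sig))
    x0, y0 = int(round(x)), int(round(y))
    xs = np.arange(max(0, x0 - radius), min(w, x0 + radius + 1))
    ys = np.arange(max(0, y0 - radius), min(h, y0 + radius + 1))
    if xs.size == 0 or ys.size == 0:
        return None
    xx, yy = np.meshgrid(xs, ys)
    wgt = np.exp(-((xx - x) ** 2 + (yy - y) ** 2) / (2.0 * sig * sig))
    mag = np.hypot(gx[yy, xx], gy[yy, xx]) * wgt
    ang = np.mod(np.arctan2(gy[yy, xx], gx[yy, xx]), 2.0 * np.pi)
    hist = np.bincount(
        np.minimum((ang / (2.0 * np.pi) * _N_ORI_BINS).astype(int), _N_ORI_BINS - 1).ravel(),
        weights=mag.ravel(),
        minlength=_N_ORI_BINS,
    )
    if hist.sum() == 0.0:
        return None
    # circular smoothing, twice
    for _ in range(2):
        hist = (np.roll(hist, 1) + hist + np.roll(hist, -1)) / 3.0
    k = int(np.argmax(hist))
    left, mid, right = hist[k - 1], hist[k], hist[(k + 1) % _N_ORI_BINS]
    denom = left - 2.0 * mid + right
    offset = 0.0 if denom == 0.0 else 0.5 * (left - right) / denom
    return float(np.mod((k + 0.5 + offset) * 2.0 * np.pi / _N_ORI_BINS, 2.0 * np.pi))


def _descriptor(gx, gy, x, y, scale, theta):
    """Simplified SIFT descriptor: 2x2 spatial cells x 8 orientation bins.

    Gradients are sampled in a rotated window of half-width
    ``_DESC_GRID/2 * _DESC_CELL_WIDTH * scale`` around the keypoint, softly
    binned over cells and orientations, L2-normalised and clamped.
    """
    h, w = gx.shape
    half = 0.5 * _DESC_GRID * _DESC_CELL_WIDTH * scale
    radius = int(np.ceil(half * np.sqrt(2.0))) + 1
    x0, y0 = int(round(x)), int(round(y))
    xs = np.arange(max(0, x0 - radius), min(w, x0 + radius + 1))
    ys = np.arange(max(0, y0 - radius), min(h, y0 + radius + 1))
    xx, yy = np.meshgrid(xs, ys)
    dx = xx - x
    dy = yy - y
    c, s = np.cos(theta), np.sin(theta)
    # coordinates in the rotated frame, in units of cells, origin at window corner
    u = (c * dx + s * dy) / (_DESC_CELL_WIDTH * scale) + 0.5 * _DESC_GRID - 0.5
    v = (-s * dx + c * dy) / (_DESC_CELL_WIDTH * scale) + 0.5 * _DESC_GRID - 0.5
    inside = (u > -1.0) & (u < _DESC_GRID) & (v > -1.0) & (v < _DESC_GRID)

    mag = np.hypot(gx[yy, xx], gy[yy, xx])
    wgt = np.exp(
        -((u - 0.5 * (_DESC_GRID - 1)) ** 2 + (v - 0.5 * (_DESC_GRID - 1)) ** 2)
        / (0.5 * _DESC_GRID ** 2)
    )
    ang = np.mod(np.arctan2(gy[yy, xx], gx[yy, xx]) - theta, 2.0 * np.pi)
    o = ang / (2.0 * np.pi) * _DESC_ORI_BINS

    u, v, o = u[inside], v[inside], o[inside]
    contrib = (mag * wgt)[inside]

    hist = np.zeros((_DESC_GRID, _DESC_GRID, _DESC_ORI_BINS))
    u0 = np.floor(u).astype(int)
    v0 = np.floor(v).astype(int)
    o0 = np.floor(o).astype(int)
    fu, fv, fo = u - u0, v - v0, o - o0
    for du, wu in ((0, 1.0 - fu), (1, fu)):
        ui = u0 + du
        oku = (ui >= 0) & (ui < _DESC_GRID)
        for dv, wv in ((0, 1.0 - fv), (1, fv)):
            vi = v0 + dv
            ok = oku & (vi >= 0) & (vi < _DESC_GRID)
            for do, wo in ((0, 1.0 - fo), (1, fo)):
                oi = (o0 + do) % _DESC_ORI_BINS
                np.add.at(
                    hist,
                    (vi[ok], ui[ok], oi[ok]),
                    (contrib * wu * wv * wo)[ok],
                )
    vec = hist.ravel()
    norm = np.linalg.norm(vec)
    if norm > 0.0:
        vec = vec / norm
    return clamp_normalize(vec)


def match_features(a: FeatureSet, b: FeatureSet, ratio: float = 0.8) -> MatchSet:
    """Mutual-nearest-neighbour descriptor matches passing Lowe's ratio test.

    A pair (i, j) is kept when j is i's nearest neighbour in Euclidean
    descriptor space, i is j's nearest neighbour, and d1 < ratio * d2 strictly
    (d2 = distance to i's second-nearest neighbour; a lone candidate has
    d2 = inf).  Distance ties are broken by the lower index.  Either set
    empty gives an empty MatchSet.
    """
    if not 0.0 < ratio <= 1.0:
        raise InvalidInputError("ratio must be in (0, 1]")
    if len(a) == 0 or len(b) == 0:
        return MatchSet()
    dist = cdist(a.descriptors, b.descriptors)
    nn_ab = np.argmin(dist, axis=1)  # argmin takes the lowest index on ties
    nn_ba = np.argmin(dist, axis=0)
    pairs = []
    for i, j in enumerate(nn_ab):
        if nn_ba[j] != i:
            continue
        d1 = dist[i, j]
        rest = np.delete(dist[i], j)
        d2 = rest.min() if rest.size else np.inf
        if d1 < ratio * d2:
            pairs.append((i, int(j)))
    return MatchSet(pairs=pairs)


def similarity(a: FeatureSet, b: FeatureSet, matches: MatchSet) -> float:
    """Feature-match similarity S = M_p / max(Fp_a, Fp_b), in [0, 1].

    Symmetric in (a, b).  Raises UndefinedSimilarityError when both feature
    sets are empty.
    """
    denom = max(len(a), len(b))
    if denom == 0:
        raise UndefinedSimilarityError(
            "similarity undefined: both feature sets are empty"
        )
    return len(matches) / denom
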