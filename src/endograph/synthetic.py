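"""Synthetic textured sequences with known affine motion and landmarks.

No gastroscopic dataset ships with this package, so tests and examples run on
a desk-scale stand-in: a band-limited random texture (mimicking mucosal
surface detail) imaged through a smooth random walk in affine-parameter
space, with additive Gaussian sensor noise and ground-truth landmark
positions carried along every frame.  Frames default to 280x240 — half the
560x480 endoscope resolution, preserving aspect ratio.

The generator emulates what the graph method relies on: neighbouring frames
related by small affine motions with slowly accumulating deformation.  It
does not emulate specular highlights, fold occlusion, or illumination drift.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import transforms as tf
from .exceptions import (
    DegenerateSequenceError,
    InvalidParameterError,
    PlacementError,
)
from .graph import Frame
from .pathway import Marker

__all__ = [
    "SyntheticSequence",
    "MotionSpec",
    "make_texture",
    "make_sequence",
    "make_phantom_markers",
    "DEFAULT_FRAME_SHAPE",
]

# rows, cols — half the endoscope's 480x560 capture
DEFAULT_FRAME_SHAPE = (240, 280)

_SITE_NAMES = ("angularis", "antrum", "body", "fundus", "cardia")


@dataclass(frozen=True)
class MotionSpec:
    """Per-step bounds of the affine random walk.

    max_rotation in radians and max_translation in pixels bound the random
    jitter of each step; scale_range is the multiplicative per-step scale
    interval; ``drift`` is a deterministic per-step pan of the camera window
    across the textured surface (pixels, +x/+y in world coordinates).  The
    pan is what makes frame overlap — and with it feature-match similarity —
    decay with frame distance, the way distant gastroscopic frames show
    different mucosa.
    """

    max_rotation: float = 0.05
    max_translation: float = 5.0
    scale_range: tuple[float, float] = (0.98, 1.02)
    drift: tuple[float, float] = (20.0, 5.0)


@dataclass
class SyntheticSequence:
    """Frames, ground-truth step transforms and per-frame landmarks.

    ``true_transforms[k]`` maps frame-k coordinates to frame-(k+1)
    coordinates; ``landmarks[k]`` is the (L, 2) array of ground-truth marker
    centers in frame k (positions may leave the frame; no clipping).
    """

    frames: list[Frame]
    true_transforms: list[tf.AffineTransform]
    landmarks: list[np.ndarray]
    seed: int
    base: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        if len(self.true_transforms) != len(self.frames) - 1:
            raise InvalidParameterError(
                "need exactly n_frames - 1 step transforms"
            )

    @property
    def site_labels(self) -> list[str]:
        return [f.site_label for f in self.frames]

    def cumulative_transform(self, k: int) -> tf.AffineTransform:
        """Point map from frame 0 to frame k."""
        if k == 0:
            return tf.identity_transform()
        return tf.compose(self.true_transforms[:k])

    def true_position(self, center, k: int) -> np.ndarray:
        """Ground-truth frame-k position of a frame-0 point."""
        return self.cumulative_transform(k).apply(center)[0]


def make_texture(size=(400, 600), seed: int = 0) -> np.ndarray:
    """Band-limited multi-octave value noise with intensities in [0, 1].

    Several octaves of smoothed white noise are summed with amplitudes
    halving per octave, giving broad gradient content at all scales the
    detector uses.  Deterministic per seed; sizes below 64x64 are refused.
    """
    rows, cols = int(size[0]), int(size[1])
    if rows < 64 or cols < 64:
        raise InvalidParameterError("texture must be at least 64x64")
    rng = np.random.default_rng(seed)
    out = np.zeros((rows, cols))
    amp = 1.0
    for octave_sigma in (2.0, 4.0, 8.0, 16.0):
        layer = ndimage.gaussian_filter(
            rng.standard_normal((rows, cols)), octave_sigma, mode="wrap"
        )
        std = layer.std()
        if std > 0:
            layer /= std
        out += amp * layer
        amp *= 0.5
    lo, hi = out.min(), out.max()
    return (out - lo) / (hi - lo)


def _random_step(rng, motion: MotionSpec, center_xy) -> tf.AffineTransform:
    theta = rng.uniform(-motion.max_rotation, motion.max_rotation)
    s = rng.uniform(*motion.scale_range)
    # the camera window pans by +drift across the surface, so the imaged
    # content shifts by -drift, plus random jitter
    tx, ty = rng.uniform(-motion.max_translation, motion.max_translation, size=2)
    tx -= motion.drift[0]
    ty -= motion.drift[1]
    cx, cy = center_xy
    c, sn = np.cos(theta), np.sin(theta)
    m = np.eye(3)
    m[0, 0], m[0, 1] = s * c, -s * sn
    m[1, 0], m[1, 1] = s * sn, s * c
    # rotate/scale about the frame center, then translate
    m[0, 2] = cx - (m[0, 0] * cx + m[0, 1] * cy) + tx
    m[1, 2] = cy - (m[1, 0] * cx + m[1, 1] * cy) + ty
    return tf.AffineTransform(m)


def make_sequence(
    base: np.ndarray,
    n_frames: int,
    motion: MotionSpec | None = None,
    noise_sigma: float = 0.0,
    n_landmarks: int = 8,
    n_sites: int = 1,
    seed: int = 0,
    frame_shape=DEFAULT_FRAME_SHAPE,
) -> SyntheticSequence:
    """Render a smooth affine-motion sequence from a base texture.

    Frame 0 is the centered ``frame_shape`` crop of ``base``; each subsequent
    frame applies a bounded random affine step (rotation/scale about the
    frame center plus translation).  Landmarks start on a grid-jittered set
    of interior frame-0 points and follow the exact step transforms.  Site
    labels are assigned in contiguous blocks of ``n_sites`` anatomic names.

    Raises DegenerateSequenceError when the accumulated motion leaves less
    than 60% of a frame covered by the texture.
    """
    if n_frames < 2:
        raise InvalidParameterError("n_frames must be >= 2")
    if noise_sigma < 0:
        raise InvalidParameterError("noise_sigma must be >= 0")
    if not 1 <= n_sites <= len(_SITE_NAMES):
        raise InvalidParameterError(f"n_sites must be in [1, {len(_SITE_NAMES)}]")
    motion = motion or MotionSpec()
    rows, cols = frame_shape
    bh, bw = base.shape
    if bh < rows or bw < cols:
        raise InvalidParameterError("base texture smaller than frame_shape")
    rng = np.random.default_rng(seed)

    # world (= base texture) -> frame 0.  The camera window pans by +drift
    # per step, so start at the margin it pans away from; without drift the
    # crop is centered.
    margin = 40.0
    total_dx = motion.drift[0] * (n_frames - 1)
    total_dy = motion.drift[1] * (n_frames - 1)
    if bw < cols + abs(total_dx) + 2 * margin or bh < rows + abs(total_dy) + 2 * margin:
        raise DegenerateSequenceError(
            "base texture too small for the requested pan: need at least "
            f"{int(rows + abs(total_dy) + 2 * margin)}x"
            f"{int(cols + abs(total_dx) + 2 * margin)}, got {bh}x{bw}"
        )
    off_x = margin + max(0.0, -total_dx) + (bw - cols - abs(total_dx) - 2 * margin) / 2.0
    off_y = margin + max(0.0, -total_dy) + (bh - rows - abs(total_dy) - 2 * margin) / 2.0
    world_to_frame = [tf.translation(-off_x, -off_y)]
    steps: list[tf.AffineTransform] = []
    center = ((cols - 1) / 2.0, (rows - 1) / 2.0)
    for _ in range(n_frames - 1):
        step = _random_step(rng, motion, center)
        steps.append(step)
        world_to_frame.append(tf.compose([world_to_frame[-1], step]))

    frames: list[Frame] = []
    block = int(np.ceil(n_frames / n_sites))
    for k, w2f in enumerate(world_to_frame):
        warped = tf.warp_image(base, tf.invert(w2f), (rows, cols))
        if warped.validity_mask.mean() < 0.6:
            raise DegenerateSequenceError(
                f"frame {k}: texture covers only "
                f"{warped.validity_mask.mean():.0%} of the frame"
            )
        img = warped.image
        if noise_sigma > 0:
            img = np.clip(
                img + rng.normal(0.0, noise_sigma, img.shape), 0.0, 1.0
            )
        site = _SITE_NAMES[min(k // block, n_sites - 1)]
        frames.append(Frame(frame_id=f"frame{k:04d}", image=img, site_label=site))

    # landmarks: jittered interior grid on frame 0, propagated exactly
    margin_x, margin_y = 0.18 * cols, 0.18 * rows
    gx = np.linspace(margin_x, cols - 1 - margin_x, max(2, int(np.ceil(np.sqrt(n_landmarks)))))
    gy = np.linspace(margin_y, rows - 1 - margin_y, max(2, int(np.ceil(np.sqrt(n_landmarks)))))
    grid = np.array([(x, y) for y in gy for x in gx])
    pick = rng.permutation(len(grid))[:n_landmarks]
    pts0 = grid[pick] + rng.uniform(-4, 4, size=(n_landmarks, 2))
    landmarks = [pts0]
    for step in steps:
        landmarks.append(step.apply(landmarks[-1]))

    return SyntheticSequence(
        frames=frames, true_transforms=steps, landmarks=landmarks,
        seed=seed, base=base,
    )


def make_phantom_markers(
    sequence: SyntheticSequence,
    n_markers: int,
    radius: float = 10.0,
    seed: int = 0,
    max_retries: int = 200,
) -> list[Marker]:
    """Place non-overlapping circular markers at frame-0 landmark positions.

    Markers mimic the green circles an endoscopist draws on the reference
    image; their ground-truth positions in later frames come from the
    sequence's true transforms.  Raises PlacementError when ``n_markers``
    non-overlapping circles (center distance > 2*radius) cannot be chosen
    within the retry budget.
    """
    if n_markers < 1:
        raise InvalidParameterError("n_markers must be >= 1")
    rng = np.random.default_rng(seed)
    candidates = sequence.landmarks[0]
    for _ in range(max_retries):
        order = rng.permutation(len(candidates))
        chosen: list[np.ndarray] = []
        for idx in order:
            p = candidates[idx]
            if all(np.linalg.norm(p - q) > 2 * radius for q in chosen):
                chosen.append(p)
            if len(chosen) == n_markers:
                return [
                    Marker(center=(float(p[0]), float(p[1])), radius=radius, label=i + 1)
                    for i, p in enumerate(chosen)
                ]
    raise PlacementError(
        f"could not place {n_markers} non-overlapping markers of radius {radius}"
    )
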