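"""Image-graph construction: threshold search and the N x N adjacency.

Pre-observed frames become nodes; two frames are connected directly when
their feature-match similarity S exceeds a threshold h, and each connected
pair stores the RANSAC affine transform between them (both directions, with
H_ji = H_ij^-1).  The threshold is found by an iterative bracket search: start
near the top of the sampled similarity range, validate every connected pair
by warped normalized cross correlation, and raise the bracket floor until all
connected pairs validate.

Graphs are partitioned into anatomic subgraphs by each frame's site label
(angularis, antrum, body, ...); the partition prunes query-time matching.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from . import features as ft
from . import transforms as tf
from .exceptions import (
    InvalidParameterError,
    NoFeaturesError,
    NonconvergenceError,
    UndefinedSimilarityError,
    EndographError,
)
from .imageutils import to_grayscale

__all__ = [
    "Frame",
    "ImageGraph",
    "ThresholdSearchState",
    "ConnectivityReport",
    "VacuousThresholdWarning",
    "sample_similarities",
    "update_threshold",
    "find_threshold",
    "build_graph",
    "validate_connectivity",
]

logger = logging.getLogger(__name__)


class VacuousThresholdWarning(UserWarning):
    """No sampled pair exceeded h; the exit condition held vacuously."""


@dataclass
class Frame:
    """One endoscopic image with its identity and anatomic-site label."""

    frame_id: str
    image: np.ndarray | None = None
    site_label: str = "unlabeled"

    def __post_init__(self):
        if self.image is not None:
            self.image = to_grayscale(self.image)


@dataclass
class ThresholdSearchState:
    """Bracket state of the iterative connection-threshold search."""

    b_low: float
    b_high: float
    lam: float = 0.1
    h: float = 0.0
    iteration: int = 0


@dataclass
class ConnectivityReport:
    """Connected-component summary of a graph's edge set."""

    n_components: int
    components: list[set]
    n_edges: int


@dataclass
class ImageGraph:
    """Frames plus symmetric similarity matrix and directed edge transforms.

    ``transforms[(i, j)]`` maps frame-i coordinates to frame-j coordinates and
    is stored for both directions of every connected pair (inverses of each
    other).  Unconnected entries are simply absent — the (0, 0) sentinel of
    the adjacency-matrix formulation.
    """

    frames: list[Frame]
    similarity: np.ndarray
    transforms: dict[tuple[str, str], tf.AffineTransform] = field(default_factory=dict)
    threshold: float = 0.0
    feature_cache: dict[str, ft.FeatureSet] = field(default_factory=dict, repr=False)

    def __post_init__(self):
        ids = [f.frame_id for f in self.frames]
        if len(set(ids)) != len(ids):
            raise InvalidParameterError("frame_id values must be unique")
        self._index = {fid: k for k, fid in enumerate(ids)}
        self.similarity = np.asarray(self.similarity, dtype=np.float64)
        n = len(self.frames)
        if self.similarity.shape != (n, n):
            raise InvalidParameterError(
                f"similarity must be {n}x{n}, got {self.similarity.shape}"
            )

    @property
    def n_nodes(self) -> int:
        return len(self.frames)

    @property
    def node_ids(self) -> list[str]:
        return [f.frame_id for f in self.frames]

    def index(self, frame_id: str) -> int:
        return self._index[frame_id]

    def frame(self, frame_id: str) -> Frame:
        return self.frames[self._index[frame_id]]

    def has_edge(self, i: str, j: str) -> bool:
        return (i, j) in self.transforms

    def edge_transform(self, i: str, j: str) -> tf.AffineTransform:
        return self.transforms[(i, j)]

    def edge_similarity(self, i: str, j: str) -> float:
        return float(self.similarity[self._index[i], self._index[j]])

    def neighbors(self, frame_id: str) -> list[str]:
        """Directly connected node ids, sorted for determinism."""
        return sorted(j for (i, j) in self.transforms if i == frame_id)

    def edges(self) -> list[tuple[str, str]]:
        """Undirected edge list (i < j), sorted."""
        return sorted({tuple(sorted(p)) for p in self.transforms})

    def site_labels(self) -> list[str]:
        """Distinct site labels in first-appearance order."""
        seen: list[str] = []
        for f in self.frames:
            if f.site_label not in seen:
                seen.append(f.site_label)
        return seen

    def subgraph_nodes(self, site_label: str) -> list[str]:
        return [f.frame_id for f in self.frames if f.site_label == site_label]

    def features_of(self, frame_id: str, max_features: int = 200) -> ft.FeatureSet:
        """Cached feature extraction for a node image."""
        if frame_id not in self.feature_cache:
            frame = self.frame(frame_id)
            if frame.image is None:
                raise EndographError(f"frame {frame_id!r} has no image loaded")
            fs = ft.extract_features(frame.image, max_features=max_features)
            fs.source_frame_id = frame_id
            self.feature_cache[frame_id] = fs
        return self.feature_cache[frame_id]


def _pair_seed(seed: int, i: int, j: int) -> int:
    # stable per-pair RANSAC seed, independent of evaluation order
    return int((seed * 1000003 + (i + 1) * 10007 + (j + 1)) % (2**31 - 1))


def _get_features(frames, cache, max_features=200):
    out = []
    for k, frame in enumerate(frames):
        key = frame.frame_id
        if key not in cache:
            fs = ft.extract_features(frame.image, max_features=max_features)
            fs.source_frame_id = key
            cache[key] = fs
        out.append(cache[key])
    return out


def _sample_pairs(n_frames: int, n_samples: int, seed: int) -> list[tuple[int, int]]:
    all_pairs = [(i, j) for i in range(n_frames) for j in range(i + 1, n_frames)]
    if n_samples >= len(all_pairs):
        return all_pairs
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(all_pairs), size=n_samples, replace=False)
    return [all_pairs[k] for k in sorted(idx)]


def sample_similarities(frames, n_samples: int, seed: int):
    """Similarity over seeded random unordered frame pairs.

    Returns ``(values, b_low, b_high)`` where b_low/b_high bracket the sampled
    similarity range.  Pairs whose similarity is undefined (both frames
    featureless) are skipped; if every sampled pair is undefined, raises
    NoFeaturesError.
    """
    if len(frames) < 2:
        raise InvalidParameterError("need at least 2 frames")
    if n_samples < 1:
        raise InvalidParameterError("n_samples must be >= 1")
    cache: dict[str, ft.FeatureSet] = {}
    fsets = _get_features(frames, cache)
    values = []
    for i, j in _sample_pairs(len(frames), n_samples, seed):
        try:
            s = ft.similarity(fsets[i], fsets[j], ft.match_features(fsets[i], fsets[j]))
        except UndefinedSimilarityError:
            continue
        values.append(s)
    if not values:
        raise NoFeaturesError("every sampled pair had empty feature sets")
    return values, float(min(values)), float(max(values))


def update_threshold(state: ThresholdSearchState) -> float:
    """Bracket update h = B_high - lambda * (B_high - B_low)."""
    if not 0.0 < state.lam < 1.0:
        raise InvalidParameterError("lambda must lie in (0, 1)")
    if state.b_low > state.b_high:
        raise InvalidParameterError("b_low must not exceed b_high")
    return state.b_high - state.lam * (state.b_high - state.b_low)


def find_threshold(
    frames,
    lam: float = 0.1,
    dif_accept: float = 0.8,
    max_iter: int = 50,
    seed: int = 0,
    n_samples: int = 200,
    ratio: float = 0.8,
    inlier_tol: float = 3.0,
    ransac_iter: int = 2000,
    min_overlap: float = tf.DEFAULT_MIN_OVERLAP,
):
    """Iterative search for the optimal connection threshold h.

    Sampled pair similarities set the bracket [B_low, B_high]; each iteration
    proposes h = B_high - lam*(B_high - B_low) and validates every sampled
    pair with S > h by RANSAC affine + warped NCC.  A pair failing validation
    (dif_h <= dif_accept, or RANSAC/overlap failure) raises the floor
    (B_low = h) and the search repeats; when all connected pairs validate, h
    is returned together with the final ThresholdSearchState.

    Raises NonconvergenceError (carrying the state) when max_iter is
    exhausted.  If no sampled pair exceeds h the condition holds vacuously:
    a VacuousThresholdWarning is issued and h returned.
    """
    if len(frames) < 2:
        raise InvalidParameterError("need at least 2 frames")
    cache: dict[str, ft.FeatureSet] = {}
    fsets = _get_features(frames, cache)
    pairs = _sample_pairs(len(frames), n_samples, seed)
    match_cache: dict[tuple[int, int], ft.MatchSet] = {}
    sim: dict[tuple[int, int], float] = {}
    for i, j in pairs:
        try:
            m = ft.match_features(fsets[i], fsets[j], ratio=ratio)
            s = ft.similarity(fsets[i], fsets[j], m)
        except UndefinedSimilarityError:
            continue
        match_cache[(i, j)] = m
        sim[(i, j)] = s
    if not sim:
        raise NoFeaturesError("every sampled pair had empty feature sets")

    b_low, b_high = min(sim.values()), max(sim.values())
    state = ThresholdSearchState(b_low=b_low, b_high=b_high, lam=lam)
    dif_cache: dict[tuple[int, int], float] = {}

    def _validate(pair) -> float:
        if pair not in dif_cache:
            i, j = pair
            try:
                t, _ = tf.estimate_affine(
                    match_cache[pair], fsets[i], fsets[j],
                    inlier_tol=inlier_tol, max_iter=ransac_iter,
                    seed=_pair_seed(seed, i, j),
                )
                score = tf.ncc_score(
                    frames[i].image, frames[j].image, t, min_overlap=min_overlap
                )
                dif_cache[pair] = score.dif_h
            except EndographError:
                dif_cache[pair] = -np.inf
        return dif_cache[pair]

    for iteration in range(max_iter):
        state.iteration = iteration + 1
        state.h = update_threshold(state)
        connected = [p for p, s in sim.items() if s > state.h]
        if not connected:
            warnings.warn(
                "no sampled pair exceeds h; exit condition vacuously true",
                VacuousThresholdWarning,
            )
            return state.h, state
        if all(_validate(p) > dif_accept for p in connected):
            return state.h, state
        state.b_low = state.h
    raise NonconvergenceError(
        f"threshold search did not converge in {max_iter} iterations",
        state=state,
    )


def build_graph(
    frames,
    h: float,
    seed: int = 0,
    ratio: float = 0.8,
    inlier_tol: float = 3.0,
    ransac_iter: int = 2000,
    max_features: int = 200,
) -> ImageGraph:
    """Construct the image graph at connection threshold h.

    Runs exactly K(K-1)/2 similarity evaluations; every pair with S > h gets
    a RANSAC affine transform stored in both directions (H_ji = H_ij^-1).
    Pairs whose RANSAC fails are left unconnected and logged.
    """
    if not 0.0 <= h <= 1.0:
        raise InvalidParameterError("h must lie in [0, 1]")
    frames = list(frames)
    n = len(frames)
    cache: dict[str, ft.FeatureSet] = {}
    fsets = _get_features(frames, cache, max_features=max_features)
    sim = np.eye(n)
    transforms: dict[tuple[str, str], tf.AffineTransform] = {}
    for i in range(n):
        for j in range(i + 1, n):
            try:
                m = ft.match_features(fsets[i], fsets[j], ratio=ratio)
                s = ft.similarity(fsets[i], fsets[j], m)
            except UndefinedSimilarityError:
                s = 0.0
                m = ft.MatchSet()
            sim[i, j] = sim[j, i] = s
            if s > h:
                try:
                    t_ij, _ = tf.estimate_affine(
                        m, fsets[i], fsets[j],
                        inlier_tol=inlier_tol, max_iter=ransac_iter,
                        seed=_pair_seed(seed, i, j),
                    )
                except EndographError as exc:
                    logger.info(
                        "pair (%s, %s) exceeds h but RANSAC failed: %s",
                        frames[i].frame_id, frames[j].frame_id, exc,
                    )
                    continue
                transforms[(frames[i].frame_id, frames[j].frame_id)] = t_ij
                transforms[(frames[j].frame_id, frames[i].frame_id)] = tf.invert(t_ij)
    g = ImageGraph(
        frames=frames, similarity=sim, transforms=transforms, threshold=h,
        feature_cache=cache,
    )
    report = validate_connectivity(g)
    if report.n_components > 1:
        logger.warning(
            "graph has %d components; isolated nodes cannot support "
            "deformation estimation", report.n_components,
        )
    return g


def validate_connectivity(g: ImageGraph) -> ConnectivityReport:
    """Connected-component analysis of the graph's undirected edge set."""
    nxg = nx.Graph()
    nxg.add_nodes_from(g.node_ids)
    nxg.add_edges_from(g.edges())
    comps = [set(c) for c in nx.connected_components(nxg)]
    comps.sort(key=lambda c: sorted(c)[0])
    return ConnectivityReport(
        n_components=len(comps), components=comps, n_edges=len(g.edges())
    )
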