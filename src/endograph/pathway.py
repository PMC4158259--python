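"""Pathway search and marker retargeting.

Between a reference image's node and a moving image's node, the deformation
is estimated along the minimum-weight graph pathway: each candidate edge is
weighted by the mean squared difference (SSD) between two warps into the
tail node's frame — the head node's image, warped through the stored edge
transform, against the moving image, warped through its query-derived direct
transform.  Dijkstra's algorithm finds the pathway; composing the stored
edge transforms along it yields the node-to-node deformation, and the two
query-side transforms complete the end-to-end map that carries the
endoscopist's marked circles onto the moving image.
"""
from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass, field

import numpy as np

from . import transforms as tf
from .exceptions import (
    InvalidInputError,
    InvalidParameterError,
    InvalidPathwayError,
    InsufficientOverlapError,
    NoMatchError,
    NoPathwayError,
)
from .graph import Frame, ImageGraph
from .matching import match_query

__all__ = [
    "Marker",
    "PathwayResult",
    "TrackingRecord",
    "edge_weight",
    "shortest_pathway",
    "estimate_deformation",
    "retarget",
    "track_sequence",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Marker:
    """An endoscopist-marked circular region: center (x, y) px, radius px."""

    center: tuple[float, float]
    radius: float
    label: int = 0

    def __post_init__(self):
        if self.radius <= 0:
            raise InvalidParameterError("marker radius must be > 0")


@dataclass
class PathwayResult:
    """Minimum-weight node sequence and (optionally) its composed transform."""

    nodes: list[str]
    total_weight: float
    deformation: tf.AffineTransform | None = None


@dataclass
class TrackingRecord:
    """Retargeted markers for one moving frame.

    ``markers`` pairs each retargeted Marker with its visibility flag;
    ``computed`` is False for frames that reuse the previous stride's
    positions; ``node_id``/``pathway`` document the graph route used.
    """

    frame_id: str
    markers: list[tuple[Marker, bool]]
    computed: bool = True
    node_id: str | None = None
    pathway: list[str] = field(default_factory=list)
    total_weight: float = float("nan")


def edge_weight(
    g: ImageGraph,
    ref_image,
    node_i: str,
    node_k: str,
    moving_image,
    direct_transform,
) -> float:
    """SSD edge weight: candidate node k against the moving image, in frame i.

    Node k's image is warped into frame i through the stored graph transform
    H(i -> k); the moving image is warped into frame i through
    ``direct_transform`` (the point map frame i -> moving image).  The mean
    squared difference of the two warps over their joint validity mask is the
    weight — small when node k lies toward the moving image.  Insufficient
    overlap makes the edge unusable: +inf is returned and logged.
    """
    if not g.has_edge(node_i, node_k):
        raise InvalidInputError(f"nodes {node_i!r} and {node_k!r} not connected")
    ref = np.asarray(ref_image, dtype=np.float64)
    t_ik = g.edge_transform(node_i, node_k)
    img_k = g.frame(node_k).image
    warp_k = tf.warp_image(img_k, t_ik, ref.shape)
    warp_j = tf.warp_image(np.asarray(moving_image, dtype=np.float64),
                           direct_transform, ref.shape)
    try:
        return tf.ssd_score(warp_k, warp_j)
    except InsufficientOverlapError:
        logger.info(
            "edge (%s, %s): warped overlap empty; treating as absent",
            node_i, node_k,
        )
        return float("inf")


def shortest_pathway(g: ImageGraph, src: str, dst: str, weight_fn) -> PathwayResult:
    """Dijkstra's algorithm with deterministic tie-breaking.

    ``weight_fn(i, k)`` must return a non-negative weight (+inf to drop an
    edge).  Ties in total weight are broken by fewer hops, then by the
    lexicographically smaller node-id sequence.  Raises NoPathwayError when
    ``dst`` is unreachable.
    """
    for node in (src, dst):
        if node not in g.node_ids:
            raise InvalidInputError(f"node {node!r} not in graph")
    heap = [(0.0, 0, (src,))]
    settled: set[str] = set()
    while heap:
        dist, hops, path = heapq.heappop(heap)
        u = path[-1]
        if u in settled:
            continue
        settled.add(u)
        if u == dst:
            return PathwayResult(nodes=list(path), total_weight=dist)
        for v in g.neighbors(u):
            if v in settled:
                continue
            w = weight_fn(u, v)
            if w < 0:
                raise InvalidParameterError(
                    f"negative edge weight {w} on ({u}, {v})"
                )
            if not np.isfinite(w):
                continue
            heapq.heappush(heap, (dist + w, hops + 1, path + (v,)))
    raise NoPathwayError(f"{dst!r} unreachable from {src!r}")


def estimate_deformation(g: ImageGraph, pathway) -> tf.AffineTransform:
    """Compose stored edge transforms along a pathway (travel order).

    A single-node pathway gives the identity.  Raises InvalidPathwayError
    when a consecutive pair has no stored edge.
    """
    pathway = list(pathway)
    if not pathway:
        raise InvalidInputError("pathway must be non-empty")
    if len(pathway) == 1:
        return tf.identity_transform()
    chain = []
    for a, b in zip(pathway[:-1], pathway[1:]):
        if not g.has_edge(a, b):
            raise InvalidPathwayError(f"no stored edge ({a!r}, {b!r})")
        chain.append(g.edge_transform(a, b))
    return tf.compose(chain)


def retarget(markers, deformation: tf.AffineTransform, target_shape):
    """Map markers through a deformation onto a target frame.

    Centers go through the affine point map; radii scale by sqrt(|det|) of
    the linear block (circles stay circles; anisotropy is ignored for
    display).  A marker whose mapped center leaves the target frame is
    returned with visible=False.  Labels are preserved.
    """
    rows, cols = int(target_shape[0]), int(target_shape[1])
    scale = float(np.sqrt(abs(np.linalg.det(deformation.linear))))
    out = []
    for m in markers:
        x, y = deformation.apply(m.center)[0]
        visible = bool(0.0 <= x < cols and 0.0 <= y < rows)
        out.append(
            (Marker(center=(float(x), float(y)), radius=m.radius * scale,
                    label=m.label), visible)
        )
    return out


def _hop_path_transform(g: ImageGraph, src: str, dst: str) -> tf.AffineTransform:
    """Point map src -> dst composed along the minimum-hop path (BFS)."""
    if src == dst:
        return tf.identity_transform()
    prev: dict[str, str] = {src: src}
    frontier = [src]
    while frontier and dst not in prev:
        nxt = []
        for u in frontier:
            for v in g.neighbors(u):
                if v not in prev:
                    prev[v] = u
                    nxt.append(v)
        frontier = nxt
    if dst not in prev:
        raise NoPathwayError(f"{dst!r} unreachable from {src!r}")
    path = [dst]
    while path[-1] != src:
        path.append(prev[path[-1]])
    path.reverse()
    return estimate_deformation(g, path)


def track_sequence(
    g: ImageGraph,
    reference: Frame,
    markers,
    moving_frames,
    stride: int = 3,
    seed: int = 0,
    reject_dif: float = 0.2,
    accept_dif: float = 0.8,
    ratio: float = 0.8,
    inlier_tol: float = 3.0,
    ransac_iter: int = 2000,
    max_features: int = 200,
    min_overlap: float = tf.DEFAULT_MIN_OVERLAP,
) -> list[TrackingRecord]:
    """Retarget reference markers across a sequence of moving frames.

    The reference is matched to the graph once.  Every ``stride``-th moving
    frame is matched to the graph, the minimum-SSD pathway from the
    reference's node to the moving frame's node is searched, and the full
    deformation (reference -> its node -> pathway -> node -> moving image)
    retargets all markers; in-between frames reuse the last computed
    positions.  A moving frame that cannot be grouped to any node keeps its
    markers, flagged not visible, and tracking continues.
    """
    if stride < 1:
        raise InvalidParameterError("stride must be >= 1")
    markers = list(markers)
    if not markers:
        raise InvalidInputError("need at least one marker")
    match_kwargs = dict(
        reject_dif=reject_dif, accept_dif=accept_dif, seed=seed, ratio=ratio,
        inlier_tol=inlier_tol, ransac_iter=ransac_iter,
        max_features=max_features, min_overlap=min_overlap,
    )
    ref_match = match_query(reference.image, g, **match_kwargs)
    t_ref_to_node = ref_match.transform_query_to_node

    records: list[TrackingRecord] = []
    last: list[tuple[Marker, bool]] = [(m, True) for m in markers]
    for k, frame in enumerate(moving_frames):
        if k % stride != 0:
            records.append(
                TrackingRecord(frame_id=frame.frame_id, markers=list(last),
                               computed=False)
            )
            continue
        try:
            mov_match = match_query(frame.image, g, **match_kwargs)
        except NoMatchError:
            logger.info("frame %s: no graph match; markers hidden", frame.frame_id)
            hidden = [(m, False) for (m, _v) in last]
            records.append(
                TrackingRecord(frame_id=frame.frame_id, markers=hidden,
                               computed=True, node_id=None)
            )
            last = hidden
            continue
        t_mov_to_node = mov_match.transform_query_to_node
        t_node_to_mov = tf.invert(t_mov_to_node)

        weight_cache: dict[tuple[str, str], float] = {}
        direct_cache: dict[str, tf.AffineTransform] = {}

        def weight_fn(u, v, _node=mov_match.node_id, _t=t_node_to_mov,
                      _img=frame.image):
            key = (u, v)
            if key not in weight_cache:
                if u not in direct_cache:
                    # frame u -> moving image: hop-path to the moving node,
                    # then the query-side transform
                    t_u_node = _hop_path_transform(g, u, _node)
                    direct_cache[u] = tf.compose([t_u_node, _t])
                weight_cache[key] = edge_weight(
                    g, g.frame(u).image, u, v, _img, direct_cache[u]
                )
            return weight_cache[key]

        pathway = shortest_pathway(g, ref_match.node_id, mov_match.node_id, weight_fn)
        pathway.deformation = estimate_deformation(g, pathway.nodes)
        full = tf.compose([t_ref_to_node, pathway.deformation, t_node_to_mov])
        retargeted = retarget(markers, full, frame.image.shape)
        records.append(
            TrackingRecord(
                frame_id=frame.frame_id, markers=retargeted, computed=True,
                node_id=mov_match.node_id, pathway=pathway.nodes,
                total_weight=pathway.total_weight,
            )
        )
        last = retargeted
    return records
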