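"""Query-to-node matching with subgraph rejection and direction guidance.

A query (reference or moving) image is grouped to its most suitable graph
node by a greedy walk: start at a seeded random node of a seeded random
anatomic subgraph, score the node by warped NCC (dif_h), and step to the
neighbour whose stored edge transform is most consistent with the query's
current affine estimate.  A node scoring below the rejection threshold
(dif_h < 0.2) abandons the whole subgraph; a score above the acceptance
threshold (dif_h >= 0.8) ends the search immediately.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import features as ft
from . import transforms as tf
from .exceptions import EndographError, NoMatchError
from .graph import ImageGraph
from .imageutils import to_grayscale

__all__ = ["NodeMatch", "match_query", "direction_step"]

logger = logging.getLogger(__name__)


@dataclass
class NodeMatch:
    """Outcome of grouping a query image to a graph node.

    ``transform_query_to_node`` maps query coordinates to node coordinates;
    ``visited`` lists every node evaluated, in order; ``truncated`` is set
    when the visit budget ran out before the walk settled.
    """

    node_id: str
    transform_query_to_node: tf.AffineTransform
    dif_h: float
    visited: list[str] = field(default_factory=list)
    truncated: bool = False


def direction_step(
    query_transform: tf.AffineTransform, current_node: str, g: ImageGraph
):
    """Neighbour whose stored transform best matches the query's.

    Among the neighbours ``n_k`` of ``current_node``, each stored edge
    transform H(n_k -> current) is compared to the query's
    H(query -> current) by Frobenius distance of the 3x3 matrices; the
    argmin neighbour is returned (ties to the lexicographically smaller id),
    or None when the node has no neighbours.
    """
    best_id, best_d = None, np.inf
    for nk in g.neighbors(current_node):
        d = float(
            np.linalg.norm(
                g.edge_transform(nk, current_node).matrix - query_transform.matrix
            )
        )
        if d < best_d:
            best_id, best_d = nk, d
    return best_id


def match_query(
    query,
    g: ImageGraph,
    reject_dif: float = 0.2,
    accept_dif: float = 0.8,
    seed: int = 0,
    max_visits: int = 50,
    ratio: float = 0.8,
    inlier_tol: float = 3.0,
    ransac_iter: int = 2000,
    max_features: int = 200,
    min_overlap: float = tf.DEFAULT_MIN_OVERLAP,
) -> NodeMatch:
    """Group a query image to its most suitable node in the graph.

    Fully deterministic given ``seed`` (start subgraph/node choice and the
    subsequent walk).  Raises NoMatchError when every subgraph rejects the
    query.  Exceeding ``max_visits`` returns the best node so far with the
    ``truncated`` flag set.
    """
    if g.n_nodes == 0:
        raise NoMatchError("graph is empty")
    img = to_grayscale(query)
    query_fs = ft.extract_features(img, max_features=max_features)

    cache: dict[str, tuple[float, tf.AffineTransform | None]] = {}

    def evaluate(node_id: str):
        """dif_h of query against one node, with the query->node transform."""
        if node_id not in cache:
            node = g.frame(node_id)
            try:
                node_fs = g.features_of(node_id, max_features=max_features)
                matches = ft.match_features(query_fs, node_fs, ratio=ratio)
                t_qn, _ = tf.estimate_affine(
                    matches, query_fs, node_fs,
                    inlier_tol=inlier_tol, max_iter=ransac_iter, seed=seed,
                )
                # warp the node image into the query frame: the query->node
                # point map is exactly the pull-back for that warp
                score = tf.ncc_score(img, node.image, t_qn, min_overlap=min_overlap)
                cache[node_id] = (score.dif_h, t_qn)
            except EndographError as exc:
                logger.info("query vs node %s failed: %s", node_id, exc)
                cache[node_id] = (-np.inf, None)
        return cache[node_id]

    rng = np.random.default_rng(seed)
    labels = g.site_labels()
    start = int(rng.integers(len(labels)))
    label_order = labels[start:] + labels[:start]

    visited: list[str] = []
    best: NodeMatch | None = None
    truncated = False

    def consider(node_id, dif_h, t_qn):
        nonlocal best
        if t_qn is not None and (best is None or dif_h > best.dif_h):
            best = NodeMatch(
                node_id=node_id, transform_query_to_node=t_qn, dif_h=dif_h
            )

    for label in label_order:
        nodes = g.subgraph_nodes(label)
        current = nodes[int(rng.integers(len(nodes)))]
        walk_visited: set[str] = set()
        rejected = False
        while True:
            if len(visited) >= max_visits:
                truncated = True
                break
            dif_h, t_qn = evaluate(current)
            visited.append(current)
            walk_visited.add(current)
            consider(current, dif_h, t_qn)
            if dif_h < reject_dif:
                rejected = True
                logger.info(
                    "node %s rejected (dif_h=%.3f): abandoning subgraph %r",
                    current, dif_h, label,
                )
                break
            if dif_h >= accept_dif:
                best.visited = visited
                return best
            nxt = direction_step(t_qn, current, g)
            if nxt is None or nxt in walk_visited:
                break
            ndif, _ = evaluate(nxt)
            if ndif <= dif_h:
                # peek counts as a visit; record it before stopping
                if len(visited) < max_visits:
                    visited.append(nxt)
                    walk_visited.add(nxt)
                    consider(nxt, *evaluate(nxt))
                break
            current = nxt
        if truncated:
            break
        if not rejected:
            # walk settled without rejection: the best visited node wins
            break

    if best is not None and best.dif_h >= reject_dif:
        best.visited = visited
        best.truncated = truncated
        return best
    raise NoMatchError(
        "query cannot be grouped to any node (all subgraphs rejected)"
    )
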