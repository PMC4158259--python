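"""Edge weights, Dijkstra pathway search, deformation composition, retargeting."""
import itertools

import numpy as np
import pytest

import endograph as eg
from endograph import graph as gr
from endograph import transforms as tf
from endograph.exceptions import (
    InvalidInputError,
    InvalidParameterError,
    InvalidPathwayError,
    NoPathwayError,
)
from endograph.pathway import (
    Marker,
    edge_weight,
    estimate_deformation,
    retarget,
    shortest_pathway,
    track_sequence,
)
from conftest import random_affine


def abstract_graph(n, edges, transforms=None):
    """ImageGraph over n image-less nodes with the given undirected edges."""
    frames = [gr.Frame(f"n{k}") for k in range(n)]
    sim = np.eye(n)
    tmap = {}
    for idx, (i, j) in enumerate(edges):
        t = (transforms or {}).get((i, j), tf.identity_transform())
        tmap[(f"n{i}", f"n{j}")] = t
        tmap[(f"n{j}", f"n{i}")] = tf.invert(t)
        sim[i, j] = sim[j, i] = 1.0
    return gr.ImageGraph(frames=frames, similarity=sim, transforms=tmap,
                         threshold=0.5)


def brute_force_shortest(n, edges, weights, src, dst):
    """Oracle: enumerate every simple path, minimise (weight, hops, path)."""
    adj = {k: set() for k in range(n)}
    for i, j in edges:
        adj[i].add(j)
        adj[j].add(i)
    best = None
    stack = [(src, [src], 0.0)]
    while stack:
        node, path, w = stack.pop()
        if node == dst:
            key = (w, len(path), tuple(f"n{k}" for k in path))
            if best is None or key < best:
                best = key
            continue
        for nxt in adj[node]:
            if nxt not in path:
                stack.append((nxt, path + [nxt], w + weights[frozenset((node, nxt))]))
    return best


class TestEdgeWeight:
    def _image_graph(self, img_k):
        frames = [gr.Frame("ni", image=np.zeros((16, 16))),
                  gr.Frame("nk", image=img_k)]
        sim = np.ones((2, 2))
        tmap = {("ni", "nk"): tf.identity_transform(),
                ("nk", "ni"): tf.identity_transform()}
        return gr.ImageGraph(frames=frames, similarity=sim, transforms=tmap,
                             threshold=0.5)

    def test_identical_images_zero_weight(self):
        img = np.random.default_rng(0).uniform(0, 1, (16, 16))
        g = self._image_graph(img)
        w = edge_weight(g, img, "ni", "nk", img, tf.identity_transform())
        assert w == 0.0

    def test_constant_difference(self):
        g = self._image_graph(np.zeros((16, 16)))
        w = edge_weight(g, np.zeros((16, 16)), "ni", "nk",
                        np.full((16, 16), 10.0), tf.identity_transform())
        assert w == pytest.approx(100.0)

    def test_matches_naive_pixel_loop(self):
        rng = np.random.default_rng(4)
        img_k = rng.uniform(0, 1, (16, 16))
        img_j = rng.uniform(0, 1, (16, 16))
        g = self._image_graph(img_k)
        w = edge_weight(g, img_k, "ni", "nk", img_j, tf.identity_transform())
        total = sum(
            (img_k[r, c] - img_j[r, c]) ** 2
            for r in range(16) for c in range(16)
        )
        assert w == pytest.approx(total / 256, abs=1e-9)

    def test_unconnected_nodes_rejected(self):
        g = abstract_graph(3, [(0, 1)])
        with pytest.raises(InvalidInputError):
            edge_weight(g, np.zeros((8, 8)), "n0", "n2", np.zeros((8, 8)),
                        tf.identity_transform())

    def test_nonnegative(self):
        rng = np.random.default_rng(9)
        g = self._image_graph(rng.uniform(0, 1, (16, 16)))
        w = edge_weight(g, rng.uniform(0, 1, (16, 16)), "ni", "nk",
                        rng.uniform(0, 1, (16, 16)), tf.identity_transform())
        assert w >= 0.0


class TestShortestPathway:
    def test_trivial_self_path(self):
        g = abstract_graph(3, [(0, 1), (1, 2)])
        res = shortest_pathway(g, "n0", "n0", lambda u, v: 1.0)
        assert res.nodes == ["n0"] and res.total_weight == 0.0

    def test_two_hop_beats_direct(self):
        g = abstract_graph(3, [(0, 2), (0, 1), (1, 2)])
        w = {frozenset(("n0", "n2")): 5.0, frozenset(("n0", "n1")): 2.0,
             frozenset(("n1", "n2")): 2.0}
        res = shortest_pathway(g, "n0", "n2",
                               lambda u, v: w[frozenset((u, v))])
        assert res.nodes == ["n0", "n1", "n2"]
        assert res.total_weight == pytest.approx(4.0)

    def test_tie_broken_by_fewer_hops_then_lexicographic(self):
        # n0-n3 direct weight 4 vs n0-n1-n3 (2+2) vs n0-n2-n3 (2+2)
        g = abstract_graph(4, [(0, 3), (0, 1), (1, 3), (0, 2), (2, 3)])
        w = {frozenset(("n0", "n3")): 4.0, frozenset(("n0", "n1")): 2.0,
             frozenset(("n1", "n3")): 2.0, frozenset(("n0", "n2")): 2.0,
             frozenset(("n2", "n3")): 2.0}
        res = shortest_pathway(g, "n0", "n3",
                               lambda u, v: w[frozenset((u, v))])
        assert res.nodes == ["n0", "n3"]  # fewest hops wins the weight tie
        w[frozenset(("n0", "n3"))] = 10.0
        res = shortest_pathway(g, "n0", "n3",
                               lambda u, v: w[frozenset((u, v))])
        assert res.nodes == ["n0", "n1", "n3"]  # lexicographic among 2-hop ties

    def test_unreachable_destination(self):
        g = abstract_graph(4, [(0, 1), (2, 3)])
        with pytest.raises(NoPathwayError):
            shortest_pathway(g, "n0", "n3", lambda u, v: 1.0)

    def test_negative_weight_rejected(self):
        g = abstract_graph(2, [(0, 1)])
        with pytest.raises(InvalidParameterError):
            shortest_pathway(g, "n0", "n1", lambda u, v: -1.0)

    def test_random_graphs_match_brute_force(self):
        rng = np.random.default_rng(17)
        for _ in range(30):
            n = int(rng.integers(3, 9))
            edges = [
                (i, j) for i in range(n) for j in range(i + 1, n)
                if rng.uniform() < 0.5
            ]
            weights = {frozenset((i, j)): float(rng.uniform(0.1, 10))
                       for i, j in edges}
            g = abstract_graph(n, edges)
            src, dst = 0, n - 1
            expect = brute_force_shortest(n, edges, weights, src, dst)
            wfn = lambda u, v: weights[frozenset((int(u[1:]), int(v[1:])))]
            if expect is None:
                with pytest.raises(NoPathwayError):
                    shortest_pathway(g, f"n{src}", f"n{dst}", wfn)
                continue
            res = shortest_pathway(g, f"n{src}", f"n{dst}", wfn)
            assert res.total_weight == pytest.approx(expect[0])
            assert tuple(res.nodes) == expect[2]

    def test_total_weight_agrees_with_networkx(self):
        """Independent library cross-check of the minimum pathway weight."""
        import networkx as nx

        rng = np.random.default_rng(19)
        for _ in range(10):
            n = int(rng.integers(4, 9))
            edges = [(i, j) for i in range(n) for j in range(i + 1, n)
                     if rng.uniform() < 0.6]
            weights = {frozenset((i, j)): float(rng.uniform(0.1, 5))
                       for i, j in edges}
            nxg = nx.Graph()
            nxg.add_nodes_from(range(n))
            nxg.add_weighted_edges_from(
                (i, j, weights[frozenset((i, j))]) for i, j in edges
            )
            if not nx.has_path(nxg, 0, n - 1):
                continue
            g = abstract_graph(n, edges)
            res = shortest_pathway(
                g, "n0", f"n{n-1}",
                lambda u, v: weights[frozenset((int(u[1:]), int(v[1:])))],
            )
            expected = nx.dijkstra_path_length(nxg, 0, n - 1)
            assert res.total_weight == pytest.approx(expected, rel=1e-12)

    def test_symmetric_weights_give_symmetric_total(self):
        rng = np.random.default_rng(23)
        n = 7
        edges = [(i, j) for i in range(n) for j in range(i + 1, n)
                 if rng.uniform() < 0.6]
        weights = {frozenset((i, j)): float(rng.uniform(0.1, 5))
                   for i, j in edges}
        g = abstract_graph(n, edges)
        wfn = lambda u, v: weights[frozenset((int(u[1:]), int(v[1:])))]
        fwd = shortest_pathway(g, "n0", f"n{n-1}", wfn)
        rev = shortest_pathway(g, f"n{n-1}", "n0", wfn)
        assert fwd.total_weight == pytest.approx(rev.total_weight)


class TestEstimateDeformation:
    def test_single_node_identity(self):
        g = abstract_graph(2, [(0, 1)])
        assert estimate_deformation(g, ["n0"]).almost_equal(tf.identity_transform())

    def test_translation_chain(self):
        ts = {(0, 1): tf.translation(2, 0), (1, 2): tf.translation(0, 3)}
        g = abstract_graph(3, [(0, 1), (1, 2)], transforms=ts)
        d = estimate_deformation(g, ["n0", "n1", "n2"])
        assert d.almost_equal(tf.translation(2, 3))

    def test_missing_edge_rejected(self):
        g = abstract_graph(3, [(0, 1)])
        with pytest.raises(InvalidPathwayError):
            estimate_deformation(g, ["n0", "n1", "n2"])

    def test_reversed_pathway_is_inverse(self):
        rng = np.random.default_rng(31)
        ts = {(k, k + 1): random_affine(rng) for k in range(4)}
        g = abstract_graph(5, list(ts), transforms=ts)
        path = [f"n{k}" for k in range(5)]
        fwd = estimate_deformation(g, path)
        rev = estimate_deformation(g, path[::-1])
        assert np.abs(
            tf.compose([fwd, rev]).matrix - np.eye(3)
        ).max() < 1e-6

    def test_planted_chain_maps_landmarks(self):
        """Composed pathway transform reproduces ground-truth landmark motion."""
        rng = np.random.default_rng(37)
        ts = {(k, k + 1): random_affine(rng, max_rot=0.1, max_t=10)
              for k in range(5)}
        g = abstract_graph(6, list(ts), transforms=ts)
        pts = rng.uniform(0, 200, (10, 2))
        expected = pts.copy()
        for k in range(5):
            expected = ts[(k, k + 1)].apply(expected)
        d = estimate_deformation(g, [f"n{k}" for k in range(6)])
        assert np.abs(d.apply(pts) - expected).max() < 1.0


class TestRetarget:
    def test_identity_keeps_markers(self):
        ms = [Marker((30, 40), 10, label=1), Marker((80, 90), 8, label=2)]
        out = retarget(ms, tf.identity_transform(), (240, 280))
        assert all(vis for _, vis in out)
        assert [m.center for m, _ in out] == [(30.0, 40.0), (80.0, 90.0)]
        assert [m.label for m, _ in out] == [1, 2]

    def test_uniform_scale_doubles_center_and_radius(self):
        m = np.diag([2.0, 2.0, 1.0])
        out = retarget([Marker((10, 20), 5, label=3)],
                       eg.AffineTransform(m), (240, 280))
        marker, vis = out[0]
        assert marker.center == (20.0, 40.0) and marker.radius == pytest.approx(10.0)

    def test_offscreen_center_not_visible(self):
        ms = [Marker((10, 10), 5, label=1), Marker((270, 230), 5, label=2)]
        out = retarget(ms, tf.translation(20, 20), (240, 280))
        assert out[0][1] is True and out[1][1] is False

    def test_forward_then_inverse_returns_to_origin(self):
        rng = np.random.default_rng(41)
        t = random_affine(rng)
        ms = [Marker((50, 60), 7, label=1)]
        fwd = retarget(ms, t, (10_000, 10_000))
        back = retarget([fwd[0][0]], tf.invert(t), (10_000, 10_000))
        assert np.abs(np.array(back[0][0].center) - (50, 60)).max() < 1e-6
        assert back[0][0].radius == pytest.approx(7.0, abs=1e-9)

    def test_positive_radius_required(self):
        with pytest.raises(InvalidParameterError):
            Marker((0, 0), 0.0)


class TestTrackSequence:
    def test_reference_frame_tracks_to_itself(self, graph, sequence, markers6):
        recs = track_sequence(graph, sequence.frames[0], markers6,
                              [sequence.frames[0]], stride=1, seed=11)
        assert len(recs) == 1
        for (m, vis), orig in zip(recs[0].markers, markers6):
            assert np.abs(np.array(m.center) - orig.center).max() < 1.0
            assert vis

    def test_stride_semantics(self, graph, sequence, markers6):
        moving = sequence.frames[:10]
        recs = track_sequence(graph, sequence.frames[0], markers6, moving,
                              stride=3, seed=11)
        computed = [r.computed for r in recs]
        assert computed == [k % 3 == 0 for k in range(10)]
        # reused frames carry the previous computed positions verbatim
        assert recs[1].markers == recs[0].markers

    def test_stride_must_be_positive(self, graph, sequence, markers6):
        with pytest.raises(InvalidParameterError):
            track_sequence(graph, sequence.frames[0], markers6,
                           sequence.frames, stride=0)
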