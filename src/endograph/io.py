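"""Serialization: graph files, marker files, tracking records, overlays.

File formats (all JSON, versioned, with the run Config embedded for
provenance):

graph (``endograph-graph`` v1)
    ``{format, version, package_version, config?, threshold,
    frames: [{frame_id, site_label, image_path?}],
    edges: [{i, j, similarity, transform}]}``
    Edges are stored once per unordered pair (i < j by frame order) with the
    i->j transform as a row-major 9-float array; the loader restores the j->i
    direction as the inverse.  Edge similarities are written as decimal
    strings with 12 significant digits and restored bit-exactly at that
    precision.  Unconnected pair similarities are not stored (they are below
    threshold by construction and reload as 0).

markers (``endograph-markers`` v1)
    ``{format, version, config?, markers: [{label, x, y, radius, frame_id?}]}``
    A bare JSON list of marker objects is also accepted on read.

tracking (``endograph-tracking`` v1)
    JSON lines: a header object followed by one record per frame with the
    retargeted markers and visibility flags.

ground truth (``endograph-groundtruth`` v1)
    Written by ``simulate``: true step transforms, per-frame landmark and
    marker-center positions, site labels.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import __version__ as _pkg_version
from .config import Config
from .exceptions import GraphFormatError, InvalidInputError
from .graph import Frame, ImageGraph
from .imageutils import load_image
from .pathway import Marker, TrackingRecord
from .transforms import AffineTransform, invert

__all__ = [
    "save_graph",
    "load_graph",
    "save_markers",
    "load_markers",
    "write_tracking",
    "read_tracking",
    "load_frames_dir",
    "draw_marker_overlay",
]

_JSON_KW = dict(sort_keys=True, separators=(",", ":"))


def _dump(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, **_JSON_KW) + "\n")


def _parse(path, expected_format):
    try:
        record = json.loads(Path(path).read_text())
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise GraphFormatError(f"{path}: not valid JSON ({exc})") from exc
    if not isinstance(record, dict):
        return record  # bare lists handled by the marker loader
    fmt = record.get("format")
    if fmt != expected_format:
        raise GraphFormatError(
            f"{path}: expected format {expected_format!r}, got {fmt!r}",
            field="format",
        )
    if record.get("version") != 1:
        raise GraphFormatError(
            f"{path}: unsupported version {record.get('version')!r}",
            field="version",
        )
    return record


def save_graph(g: ImageGraph, path, image_paths=None, config: Config | None = None):
    """Write a graph file; ``image_paths`` maps frame_id to a relative path."""
    image_paths = image_paths or {}
    edges = []
    for i, j in g.edges():
        edges.append(
            {
                "i": i,
                "j": j,
                "similarity": format(g.edge_similarity(i, j), ".12g"),
                "transform": g.edge_transform(i, j).to_list(),
            }
        )
    record = {
        "format": "endograph-graph",
        "version": 1,
        "package_version": _pkg_version,
        "config": (config.to_dict() if config else None),
        "threshold": g.threshold,
        "frames": [
            {
                "frame_id": f.frame_id,
                "site_label": f.site_label,
                "image_path": image_paths.get(f.frame_id),
            }
            for f in g.frames
        ],
        "edges": edges,
    }
    _dump(record, path)


def load_graph(path, load_images: bool = True) -> ImageGraph:
    """Read a graph file; image paths resolve relative to the file."""
    record = _parse(path, "endograph-graph")
    root = Path(path).parent
    try:
        frames = []
        for k, fr in enumerate(record["frames"]):
            image = None
            if load_images and fr.get("image_path"):
                image = load_image(root / fr["image_path"])
            frames.append(
                Frame(
                    frame_id=fr["frame_id"],
                    image=image,
                    site_label=fr.get("site_label", "unlabeled"),
                )
            )
        n = len(frames)
        index = {f.frame_id: k for k, f in enumerate(frames)}
        sim = np.eye(n)
        transforms = {}
        for e, edge in enumerate(record["edges"]):
            i, j = edge["i"], edge["j"]
            if i not in index or j not in index:
                raise GraphFormatError(
                    f"{path}: edge references unknown frame",
                    field=f"edges[{e}]",
                )
            s = float(edge["similarity"])
            sim[index[i], index[j]] = sim[index[j], index[i]] = s
            t = AffineTransform.from_list(edge["transform"])
            transforms[(i, j)] = t
            transforms[(j, i)] = invert(t)
        return ImageGraph(
            frames=frames,
            similarity=sim,
            transforms=transforms,
            threshold=float(record["threshold"]),
        )
    except GraphFormatError:
        raise
    except (KeyError, TypeError, ValueError, InvalidInputError) as exc:
        raise GraphFormatError(f"{path}: malformed graph file ({exc})") from exc


def save_markers(markers, path, config: Config | None = None, frame_id=None):
    record = {
        "format": "endograph-markers",
        "version": 1,
        "package_version": _pkg_version,
        "config": (config.to_dict() if config else None),
        "markers": [
            {
                "label": m.label,
                "x": m.center[0],
                "y": m.center[1],
                "radius": m.radius,
                "frame_id": frame_id,
            }
            for m in markers
        ],
    }
    _dump(record, path)


def load_markers(path) -> list[Marker]:
    record = _parse(path, "endograph-markers")
    rows = record["markers"] if isinstance(record, dict) else record
    try:
        return [
            Marker(center=(float(r["x"]), float(r["y"])),
                   radius=float(r["radius"]), label=int(r.get("label", k + 1)))
            for k, r in enumerate(rows)
        ]
    except (KeyError, TypeError, ValueError) as exc:
        raise GraphFormatError(f"{path}: malformed marker file ({exc})") from exc


def write_tracking(records, path, config: Config | None = None):
    """Write tracking output as JSON lines (header + one record per frame)."""
    lines = [
        json.dumps(
            {
                "type": "header",
                "format": "endograph-tracking",
                "version": 1,
                "package_version": _pkg_version,
                "config": (config.to_dict() if config else None),
            },
            **_JSON_KW,
        )
    ]
    for rec in records:
        lines.append(
            json.dumps(
                {
                    "type": "record",
                    "frame_id": rec.frame_id,
                    "computed": rec.computed,
                    "node_id": rec.node_id,
                    "pathway": list(rec.pathway),
                    "total_weight": (
                        rec.total_weight if np.isfinite(rec.total_weight) else None
                    ),
                    "markers": [
                        {
                            "label": m.label,
                            "x": m.center[0],
                            "y": m.center[1],
                            "radius": m.radius,
                            "visible": vis,
                        }
                        for m, vis in rec.markers
                    ],
                },
                **_JSON_KW,
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_tracking(path):
    """Read tracking JSON lines; returns ``(records, header)``."""
    header = None
    records = []
    try:
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            if not line.strip():
                continue
            row = json.loads(line)
            if row.get("type") == "header":
                header = row
                continue
            markers = [
                (
                    Marker(center=(float(m["x"]), float(m["y"])),
                           radius=float(m["radius"]), label=int(m["label"])),
                    bool(m["visible"]),
                )
                for m in row["markers"]
            ]
            records.append(
                TrackingRecord(
                    frame_id=row["frame_id"],
                    markers=markers,
                    computed=bool(row.get("computed", True)),
                    node_id=row.get("node_id"),
                    pathway=row.get("pathway", []),
                    total_weight=(
                        float(row["total_weight"])
                        if row.get("total_weight") is not None
                        else float("nan")
                    ),
                )
            )
    except (json.JSONDecodeError, KeyError, TypeError, ValueError) as exc:
        raise GraphFormatError(f"{path}: malformed tracking file ({exc})") from exc
    return records, header


_IMAGE_SUFFIXES = (".png", ".jpg", ".jpeg")


def load_frames_dir(directory, sites: dict | None = None) -> list[Frame]:
    """Read a directory of image files as frames, lexicographically sorted.

    Frame ids are the file stems; ``sites`` optionally maps frame_id to an
    anatomic-site label.
    """
    directory = Path(directory)
    paths = sorted(
        p for p in directory.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES
    )
    if not paths:
        raise InvalidInputError(f"no image files in {directory}")
    sites = sites or {}
    return [
        Frame(
            frame_id=p.stem,
            image=load_image(p),
            site_label=sites.get(p.stem, "unlabeled"),
        )
        for p in paths
    ]


# 3x5 bitmap digits for overlay labels
_DIGITS = {
    "0": ("111", "101", "101", "101", "111"),
    "1": ("010", "110", "010", "010", "111"),
    "2": ("111", "001", "111", "100", "111"),
    "3": ("111", "001", "111", "001", "111"),
    "4": ("101", "101", "111", "001", "001"),
    "5": ("111", "100", "111", "001", "111"),
    "6": ("111", "100", "111", "101", "111"),
    "7": ("111", "001", "010", "010", "010"),
    "8": ("111", "101", "111", "101", "111"),
    "9": ("111", "101", "111", "001", "111"),
}


def draw_marker_overlay(image, markers_with_visibility) -> np.ndarray:
    """Render green numbered circles over a grayscale frame (RGB uint8).

    Hidden markers are skipped, mirroring how a workstation display only
    shows lesions currently in view.
    """
    gray = (np.clip(np.asarray(image, dtype=np.float64), 0, 1) * 255).astype(np.uint8)
    rgb = np.stack([gray, gray, gray], axis=-1)
    h, w = gray.shape
    yy, xx = np.mgrid[0:h, 0:w]
    green = np.array([0, 200, 0], dtype=np.uint8)
    for marker, visible in markers_with_visibility:
        if not visible:
            continue
        cx, cy = marker.center
        ring = np.abs(np.hypot(xx - cx, yy - cy) - marker.radius) <= 1.2
        rgb[ring] = green
        _draw_number(rgb, str(marker.label), cx, cy, green)
    return rgb


def _draw_number(rgb, text, cx, cy, color, scale=2):
    h, w = rgb.shape[:2]
    x0 = int(round(cx)) - (len(text) * 4 * scale) // 2
    y0 = int(round(cy)) - (5 * scale) // 2
    for ch in text:
        glyph = _DIGITS.get(ch)
        if glyph is None:
            continue
        for r, rowbits in enumerate(glyph):
            for c, bit in enumerate(rowbits):
                if bit == "1":
                    ys = slice(max(0, y0 + r * scale), min(h, y0 + (r + 1) * scale))
                    xs = slice(max(0, x0 + c * scale), min(w, x0 + (c + 1) * scale))
                    rgb[ys, xs] = color
        x0 += 4 * scale
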