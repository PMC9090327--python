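"""Dataset I/O: contour JSON, SVG import/export, response CSV tables.

A dataset directory holds ``contours.json`` (all shapes), the response
tables ``placements.csv``, ``choices.csv``, ``picks.csv`` and
``paintings.csv``, and a ``manifest.json`` with seeds and parameters.
SVG support covers line-only geometry: ``<polygon>``/``<polyline>``
elements and ``<path>`` data restricted to M/L/H/V/Z commands.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .contour import ClosedContour

__all__ = [
    "contour_to_dict",
    "contour_from_dict",
    "save_contours",
    "load_contours",
    "write_svg",
    "read_svg",
    "save_dataset",
    "load_dataset",
]


def contour_to_dict(contour: ClosedContour) -> dict:
    d = {"id": contour.shape_id, "category": contour.category,
         "points": np.round(contour.points, 4).tolist()}
    if contour.stroke_meta is not None:
        d["stroke_meta"] = [[m, int(s)] for m, s in contour.stroke_meta]
    return d


def contour_from_dict(d: dict) -> ClosedContour:
    meta = d.get("stroke_meta")
    if meta is not None:
        meta = [(str(m), int(s)) for m, s in meta]
    return ClosedContour(np.asarray(d["points"], dtype=float),
                         stroke_meta=meta, shape_id=d.get("id"),
                         category=d.get("category"))


def save_contours(contours: Sequence[ClosedContour], path) -> None:
    Path(path).write_text(json.dumps(
        [contour_to_dict(c) for c in contours]))


def load_contours(path) -> list[ClosedContour]:
    return [contour_from_dict(d) for d in json.loads(Path(path).read_text())]


# ---------------------------------------------------------------------------
# SVG

def write_svg(contours: Sequence[ClosedContour], path, *,
              point_colors: Optional[dict] = None,
              size: tuple = (500, 500)) -> None:
    """Write contours as SVG polygons; optional per-point colour overlay.

    ``point_colors`` maps shape id to a list of CSS colours, drawn as dots
    on the contour (used for correspondence / distinctiveness overlays).
    """
    w, h = size
    lines = [f'<svg xmlns="http://www.w3.org/2000/svg" '
             f'viewBox="0 0 {w} {h}">']
    for c in contours:
        pts = " ".join(f"{x:.2f},{y:.2f}" for x, y in c.points)
        lines.append(f'<polygon points="{pts}" fill="none" '
                     f'stroke="black" stroke-width="1.5"/>')
        if point_colors and c.shape_id in point_colors:
            for (x, y), col in zip(c.points, point_colors[c.shape_id]):
                lines.append(f'<circle cx="{x:.2f}" cy="{y:.2f}" r="1.8" '
                             f'fill="{col}"/>')
    lines.append("</svg>")
    Path(path).write_text("\n".join(lines))


_NUM = r"[-+]?(?:\d+\.?\d*|\.\d+)(?:[eE][-+]?\d+)?"


def _parse_path_d(d: str) -> np.ndarray:
    tokens = re.findall(rf"[A-Za-z]|{_NUM}", d)
    pts: list[list[float]] = []
    pos = [0.0, 0.0]
    i = 0
    cmd = None
    while i < len(tokens):
        t = tokens[i]
        if t.isalpha():
            if t not in "MmLlHhVvZz":
                raise ValueError(
                    f"only line-only path commands are supported, got {t!r}")
            cmd = t
            i += 1
            if cmd in "Zz":
                continue
        if cmd is None:
            raise ValueError("path data must start with a move command")
        if cmd in "Hh":
            x = float(tokens[i]); i += 1
            pos = [x + (pos[0] if cmd == "h" else 0.0), pos[1]]
        elif cmd in "Vv":
            y = float(tokens[i]); i += 1
            pos = [pos[0], y + (pos[1] if cmd == "v" else 0.0)]
        else:
            x, y = float(tokens[i]), float(tokens[i + 1]); i += 2
            if cmd in "ml":
                pos = [pos[0] + x, pos[1] + y]
            else:
                pos = [x, y]
            if cmd == "m":
                cmd = "l"
            elif cmd == "M":
                cmd = "L"
        pts.append(list(pos))
    if len(pts) > 1 and pts[0] == pts[-1]:
        pts.pop()
    return np.asarray(pts)


def read_svg(path) -> list[ClosedContour]:
    """Import closed contours from polygon/polyline/line-only path elements."""
    text = Path(path).read_text()
    out = []
    for k, m in enumerate(re.finditer(
            r'<(polygon|polyline)[^>]*points="([^"]+)"', text)):
        nums = [float(v) for v in re.findall(_NUM, m.group(2))]
        pts = np.asarray(nums, dtype=float).reshape(-1, 2)
        if len(pts) > 1 and np.allclose(pts[0], pts[-1]):
            pts = pts[:-1]
        out.append(ClosedContour(pts, shape_id=f"svg{k}"))
    for k, m in enumerate(re.finditer(r'<path[^>]*\bd="([^"]+)"', text)):
        pts = _parse_path_d(m.group(1))
        out.append(ClosedContour(pts, shape_id=f"svgpath{k}"))
    return out


# ---------------------------------------------------------------------------
# dataset directories

def save_dataset(path, *, contours: Sequence[ClosedContour],
                 manifest: dict, tables: Optional[dict] = None) -> None:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    save_contours(contours, p / "contours.json")
    (p / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                default=str))
    for name, df in (tables or {}).items():
        df.to_csv(p / f"{name}.csv", index=False)


def load_dataset(path) -> dict:
    p = Path(path)
    out = {"contours": load_contours(p / "contours.json"),
           "manifest": json.loads((p / "manifest.json").read_text())}
    for f in p.glob("*.csv"):
        out[f.stem] = pd.read_csv(f)
    return out


def paintings_to_frame(paintings: dict) -> pd.DataFrame:
    """Flatten {shape_id: [Painting, ...]} to (rater, shape, point_index,
    tier) rows; unpainted points are omitted."""
    rows = []
    for sid, plist in paintings.items():
        for p in plist:
            painted = np.nonzero(p.tiers)[0]
            for i in painted:
                rows.append((p.rater, sid, int(i), int(p.tiers[i])))
    return pd.DataFrame(rows, columns=["rater", "shape", "point_index",
                                       "tier"])


def frame_to_paintings(frame: pd.DataFrame, n_points: int) -> dict:
    """Inverse of :func:`paintings_to_frame`."""
    from .distinctiveness import Painting

    out: dict = {}
    for (rater, sid), grp in frame.groupby(["rater", "shape"]):
        tiers = np.zeros(n_points, dtype=int)
        tiers[grp["point_index"].to_numpy()] = grp["tier"].to_numpy()
        out.setdefault(sid, []).append(Painting(str(rater), str(sid), tiers))
    return out
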