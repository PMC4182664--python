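"""Landmark file formats (named JSON, CSV, TPS) and SVG scene export.

Coordinates are written with ``repr`` (shortest round-trip float
representation), so read(write(config)) reproduces every coordinate
bit-exactly in all three formats.

The TPS dialect is the plain geometric-morphometrics one::

    LM=12
    x y          (one line per landmark, canonical order)
    ...
    ID=optional

TPS files are positional: the twelve coordinate lines map onto
:data:`saberbite.skull.REQUIRED_LANDMARKS` in that canonical order,
which is documented there and versioned with the package.
"""

from __future__ import annotations

import csv
import json
import math
from pathlib import Path
from typing import Optional, Sequence, Union

from .geometry import GeometryError, Point2
from .skull import (
    DEFAULT_SEGMENTS,
    REQUIRED_LANDMARKS,
    SEGMENTS,
    LandmarkError,
    SkullConfiguration,
)
from .strike import StrikeState

PathLike = Union[str, Path]

FORMATS = ("json", "csv", "tps")


class ParseError(ValueError):
    """A landmark file failed to parse; the message carries the line."""


def _detect_format(path: Path, fmt: Optional[str]) -> str:
    if fmt is not None:
        if fmt not in FORMATS:
            raise ParseError(f"unknown format {fmt!r}; expected one of {FORMATS}")
        return fmt
    suffix = path.suffix.lower().lstrip(".")
    if suffix in FORMATS:
        return suffix
    raise ParseError(
        f"cannot infer format from {path.name!r}; pass format= explicitly")


def _finite_or_raise(name: str, x: float, y: float) -> Point2:
    if not (math.isfinite(x) and math.isfinite(y)):
        raise ParseError(f"non-finite coordinate for landmark {name!r}: ({x}, {y})")
    return Point2(x, y)


def _build_config(landmarks: dict[str, Point2],
                  segments: dict[str, str]) -> SkullConfiguration:
    missing = [n for n in REQUIRED_LANDMARKS if n not in landmarks]
    if missing:
        raise LandmarkError(
            "file is missing required landmarks: " + ", ".join(missing))
    for name in landmarks:
        segments.setdefault(name, DEFAULT_SEGMENTS.get(name, "derived"))
    return SkullConfiguration(landmarks, segments)


# ---------------------------------------------------------------------------
# readers / writers

def write_landmarks(config: SkullConfiguration, path: PathLike,
                    fmt: Optional[str] = None) -> Path:
    """Write a configuration to JSON, CSV or TPS (inferred from the
    extension unless ``fmt`` is given)."""
    path = Path(path)
    fmt = _detect_format(path, fmt)
    if fmt == "json":
        doc = {
            "format": "saberbite-landmarks",
            "units": "mm",
            "landmarks": [
                {"name": n, "x_mm": p.x, "y_mm": p.y,
                 "segment": config.segments[n]}
                for n, p in config.landmarks.items()
            ],
        }
        path.write_text(json.dumps(doc, indent=2) + "\n")
    elif fmt == "csv":
        with path.open("w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["name", "x_mm", "y_mm", "segment"])
            for n, p in config.landmarks.items():
                w.writerow([n, repr(p.x), repr(p.y), config.segments[n]])
    else:  # tps: required landmarks only, canonical order
        lines = [f"LM={len(REQUIRED_LANDMARKS)}"]
        for n in REQUIRED_LANDMARKS:
            p = config[n]
            lines.append(f"{p.x!r} {p.y!r}")
        lines.append("ID=saberbite")
        path.write_text("\n".join(lines) + "\n")
    return path


def read_landmarks(path: PathLike, fmt: Optional[str] = None) -> SkullConfiguration:
    """Read a configuration, validating required landmark names.

    Duplicate or missing landmarks, unknown segments and non-finite
    coordinates raise with the offending name or line number.
    """
    path = Path(path)
    fmt = _detect_format(path, fmt)
    if fmt == "json":
        return _read_json(path)
    if fmt == "csv":
        return _read_csv(path)
    return _read_tps(path)


def _read_json(path: Path) -> SkullConfiguration:
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path.name}: invalid JSON at line {exc.lineno}: "
                         f"{exc.msg}") from exc
    records = doc.get("landmarks")
    if not isinstance(records, list):
        raise ParseError(f"{path.name}: missing 'landmarks' array")
    landmarks: dict[str, Point2] = {}
    segments: dict[str, str] = {}
    for i, rec in enumerate(records):
        try:
            name = rec["name"]
            p = _finite_or_raise(name, float(rec["x_mm"]), float(rec["y_mm"]))
        except (KeyError, TypeError, ValueError) as exc:
            raise ParseError(f"{path.name}: bad landmark record #{i}: {exc}") from exc
        if name in landmarks:
            raise ParseError(f"{path.name}: duplicate landmark {name!r}")
        landmarks[name] = p
        if "segment" in rec:
            if rec["segment"] not in SEGMENTS:
                raise ParseError(
                    f"{path.name}: unknown segment {rec['segment']!r} "
                    f"for landmark {name!r}")
            segments[name] = rec["segment"]
    return _build_config(landmarks, segments)


def _read_csv(path: Path) -> SkullConfiguration:
    landmarks: dict[str, Point2] = {}
    segments: dict[str, str] = {}
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"name", "x_mm", "y_mm"} <= set(reader.fieldnames):
            raise ParseError(f"{path.name}: expected header name,x_mm,y_mm[,segment]")
        for lineno, row in enumerate(reader, start=2):
            name = row["name"]
            try:
                p = _finite_or_raise(name, float(row["x_mm"]), float(row["y_mm"]))
            except (TypeError, ValueError) as exc:
                raise ParseError(f"{path.name}: line {lineno}: {exc}") from exc
            if name in landmarks:
                raise ParseError(f"{path.name}: line {lineno}: duplicate "
                                 f"landmark {name!r}")
            landmarks[name] = p
            seg = row.get("segment")
            if seg:
                if seg not in SEGMENTS:
                    raise ParseError(f"{path.name}: line {lineno}: unknown "
                                     f"segment {seg!r}")
                segments[name] = seg
    return _build_config(landmarks, segments)


def _read_tps(path: Path) -> SkullConfiguration:
    lines = path.read_text().splitlines()
    n_expected = None
    coords: list[Point2] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        upper = line.upper()
        if upper.startswith("LM="):
            try:
                n_expected = int(line.split("=", 1)[1])
            except ValueError as exc:
                raise ParseError(f"{path.name}: line {lineno}: bad LM= header") from exc
            continue
        if upper.startswith(("ID=", "IMAGE=", "SCALE=")):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ParseError(
                f"{path.name}: line {lineno}: expected 'x y', got {line!r}")
        try:
            x, y = float(parts[0]), float(parts[1])
        except ValueError as exc:
            raise ParseError(f"{path.name}: line {lineno}: non-numeric "
                             f"coordinate") from exc
        coords.append(_finite_or_raise(f"landmark {len(coords)}", x, y))
    if n_expected is None:
        raise ParseError(f"{path.name}: missing LM= header")
    if n_expected != len(REQUIRED_LANDMARKS):
        raise ParseError(
            f"{path.name}: LM={n_expected}, but this reader requires the "
            f"{len(REQUIRED_LANDMARKS)} canonical landmarks")
    if len(coords) != n_expected:
        raise ParseError(f"{path.name}: LM={n_expected} but found "
                         f"{len(coords)} coordinate lines")
    landmarks = dict(zip(REQUIRED_LANDMARKS, coords))
    return _build_config(landmarks, {})


# ---------------------------------------------------------------------------
# SVG export
#
# SVG is plain XML; the scenes needed here (landmark markers, chain
# polylines, superimposed panels) are written directly.

_SEGMENT_COLORS = {"neck": "#7a5230", "cranium": "#1f77b4",
                   "mandible": "#d62728", "derived": "#555555"}

_CHAINS = (
    ("neck", ("CAUDAL_NECK", "MID_NECK", "AOJ")),
    ("cranium", ("AOJ", "TMJ", "UPPER_INCISOR_TIP")),
    ("canine", ("UPPER_CANINE_BASE", "UPPER_CANINE_MID", "UPPER_CANINE_TIP")),
    ("mandible", ("TMJ", "LOWER_INCISOR_TIP")),
)


def _config_group(config: SkullConfiguration, gid: str, color: Optional[str],
                  opacity: float = 1.0, marker: float = 3.0) -> list[str]:
    out = [f'<g id="{gid}" opacity="{opacity:g}">']
    for label, chain in _CHAINS:
        if not all(n in config for n in chain):
            continue
        pts = " ".join(f"{config[n].x:.3f},{-config[n].y:.3f}" for n in chain)
        stroke = color or _SEGMENT_COLORS.get(config.segments[chain[-1]], "#000")
        out.append(f'<polyline points="{pts}" fill="none" stroke="{stroke}" '
                   f'stroke-width="2"/>')
    for n, p in config.landmarks.items():
        fill = color or _SEGMENT_COLORS.get(config.segments[n], "#000")
        out.append(f'<circle class="landmark" data-name="{n}" cx="{p.x:.3f}" '
                   f'cy="{-p.y:.3f}" r="{marker:g}" fill="{fill}"/>')
    out.append("</g>")
    return out


def _svg_document(body: list[str], bounds: tuple[float, float, float, float]) -> str:
    xmin, ymin, xmax, ymax = bounds
    pad = 0.05 * max(xmax - xmin, ymax - ymin, 1.0) + 10.0
    vb = (f"{xmin - pad:.1f} {-(ymax + pad):.1f} "
          f"{(xmax - xmin) + 2 * pad:.1f} {(ymax - ymin) + 2 * pad:.1f}")
    return "\n".join(
        ['<?xml version="1.0" encoding="UTF-8"?>',
         f'<svg xmlns="http://www.w3.org/2000/svg" viewBox="{vb}">']
        + body + ["</svg>", ""])


def _bounds(configs: Sequence[SkullConfiguration]) -> tuple[float, float, float, float]:
    xs = [p.x for c in configs for p in c.landmarks.values()]
    ys = [p.y for c in configs for p in c.landmarks.values()]
    return min(xs), min(ys), max(xs), max(ys)


def export_svg(config: SkullConfiguration, path: PathLike) -> Path:
    """Write a single configuration as an SVG scene (one marker per
    landmark, segment chains as polylines)."""
    path = Path(path)
    body = _config_group(config, "configuration", None)
    path.write_text(_svg_document(body, _bounds([config])))
    return path


def export_superposition_svg(original: SkullConfiguration,
                             results: Sequence, path: PathLike) -> Path:
    """Superimpose rotation-experiment results over the original, one
    panel per trial (the four-pivot comparison figure), with pivot and
    TMJ markers."""
    results = list(results)
    if not results:
        raise GeometryError("no experiment results to export")
    path = Path(path)
    x0, y0, x1, y1 = _bounds([original] + [r.transformed for r in results])
    width = (x1 - x0) * 1.15 + 40.0
    body: list[str] = []
    for i, res in enumerate(results):
        dx = i * width
        shift = f'translate({dx:.1f},0)'
        body.append(f'<g class="panel" id="panel_{res.trial.pivot}" '
                    f'transform="{shift}">')
        body += _config_group(original, f"original_{i}", "#999999", opacity=0.5)
        body += _config_group(res.transformed, f"rotated_{i}", None)
        pivot = original[res.trial.pivot]
        body.append(f'<circle class="pivot-marker" cx="{pivot.x:.3f}" '
                    f'cy="{-pivot.y:.3f}" r="6" fill="none" stroke="#0000ff" '
                    f'stroke-width="2"/>')
        tmj = res.transformed["TMJ"]
        body.append(f'<circle class="tmj-marker" cx="{tmj.x:.3f}" '
                    f'cy="{-tmj.y:.3f}" r="4" fill="#ff0000"/>')
        body.append("</g>")
    bounds = (x0, y0, x0 + width * len(results), y1)
    path.write_text(_svg_document(body, bounds))
    return path


def export_strike_svg(states: Sequence[StrikeState], path: PathLike) -> Path:
    """Overlay strike frames (fading with progress) plus the canine-tip
    trace polyline."""
    states = list(states)
    if not states:
        raise GeometryError("empty trajectory: nothing to export")
    path = Path(path)
    body: list[str] = []
    n = len(states)
    for i, s in enumerate(states):
        opacity = 0.25 + 0.75 * (i + 1) / n
        body += _config_group(s.configuration, f"frame_{i}", None,
                              opacity=opacity, marker=2.0)
    trace = " ".join(f"{s.canine_tip.x:.3f},{-s.canine_tip.y:.3f}"
                     for s in states)
    body.append(f'<polyline id="canine_tip_trace" points="{trace}" '
                f'fill="none" stroke="#000000" stroke-dasharray="4 3" '
                f'stroke-width="1.5"/>')
    path.write_text(_svg_document(body, _bounds([s.configuration for s in states])))
    return path
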