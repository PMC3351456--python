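"""Planar Edwards "cogwheel" Venn geometry for 2-6 sets.

The Edwards construction realizes a valid Venn diagram for any number
of sets: after two orthogonal half-planes and a circle, each further
set is bounded by a wavy closed curve weaving across the circle with a
doubling number of teeth (the planar projection of a tennis-ball-seam
curve on a sphere).  Here the cog curves are the radial graphs

    rho < r * (1 + a_k * cos(m_k * theta + phi_k)),   k = 4, 5, 6

about the frame center, with teeth m = (2, 4, 8) and nested amplitudes
a_4 > a_5 > a_6.  With zero phases each cog's circle crossings sit
mid-quadrant and successive cogs' crossings interleave (zeros at
pi/4 + k*pi/2, pi/8 + k*pi/4, pi/16 + k*pi/8), which is what makes all
2**n membership patterns realizable; :func:`validate_layout` is the
arbiter and is run on every built layout.

Screen coordinates: y grows downward; "upper half" means y < cy.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy import ndimage

from .setcore import MAX_SETS, MIN_SETS, Partition, UnsupportedSetCountError, signature_names

#: teeth per cog set — each successive curve doubles the count
COG_TEETH = {4: 2, 5: 4, 6: 8}
#: default nested amplitudes, fraction of the circle radius
COG_AMPLITUDES = {4: 0.50, 5: 0.30, 6: 0.17}
#: default phases (radians); zero puts circle crossings mid-quadrant
COG_PHASES = {4: 0.0, 5: 0.0, 6: 0.0}

PALETTE = ("#1f77b4", "#d62728", "#2ca02c", "#9467bd", "#ff7f0e", "#8c564b")
FILL_OPACITY = 0.35


class LayoutValidationError(ValueError):
    """Raised when a layout's parameters fail the grid-sampling check."""

    def __init__(self, report: "LayoutReport"):
        self.report = report
        super().__init__(
            f"layout for n={report.n} misses {len(report.missing)} membership "
            f"pattern(s): {sorted(report.missing)}"
        )


class DisplayMode(str, Enum):
    COUNTS = "counts"
    INDEX = "index"
    TEXT = "text"


#: TEXT mode shows at most this many labels per region; the rest go to
#: the tooltip with an ellipsis marker.
TEXT_LINE_BUDGET = 12


@dataclass(frozen=True)
class EdwardsLayout:
    """Planar membership predicates plus canvas metadata for n sets."""

    n: int
    width: float = 600.0
    height: float = 600.0
    margin: float = 20.0
    circle_radius: float = 160.0
    cog_amplitudes: Tuple[float, ...] = (0.50, 0.30, 0.17)  # a_4, a_5, a_6
    cog_phases: Tuple[float, ...] = (0.0, 0.0, 0.0)  # phi_4, phi_5, phi_6
    colors: Tuple[str, ...] = PALETTE

    def __post_init__(self) -> None:
        if not MIN_SETS <= self.n <= MAX_SETS:
            raise UnsupportedSetCountError(f"n={self.n} outside {MIN_SETS}..{MAX_SETS}")

    @property
    def center(self) -> Tuple[float, float]:
        return self.width / 2.0, self.height / 2.0

    @property
    def frame(self) -> Tuple[float, float, float, float]:
        """(x0, y0, x1, y1) bounding rectangle of the diagram."""
        return (
            self.margin,
            self.margin,
            self.width - self.margin,
            self.height - self.margin,
        )

    def cog_params(self, set_index: int) -> Tuple[float, int, float]:
        """(amplitude, teeth, phase) for a cog set index in {4, 5, 6}."""
        if set_index not in COG_TEETH:
            raise ValueError(f"set {set_index} is not a cog set")
        return (
            self.cog_amplitudes[set_index - 4],
            COG_TEETH[set_index],
            self.cog_phases[set_index - 4],
        )

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "width": self.width,
            "height": self.height,
            "margin": self.margin,
            "circle_radius": self.circle_radius,
            "cog_amplitudes": list(self.cog_amplitudes),
            "cog_phases": list(self.cog_phases),
            "colors": list(self.colors),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EdwardsLayout":
        return cls(
            n=int(d["n"]),
            width=float(d["width"]),
            height=float(d["height"]),
            margin=float(d["margin"]),
            circle_radius=float(d["circle_radius"]),
            cog_amplitudes=tuple(float(a) for a in d["cog_amplitudes"]),
            cog_phases=tuple(float(p) for p in d["cog_phases"]),
            colors=tuple(d["colors"]),
        )


def membership_grid(layout: EdwardsLayout, X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """n-bit membership codes for arrays of canvas points (set 1 = LSB)."""
    cx, cy = layout.center
    code = np.zeros(np.broadcast(X, Y).shape, dtype=np.int64)
    code |= (X < cx).astype(np.int64)  # set 1: left half
    code |= (Y < cy).astype(np.int64) << 1  # set 2: upper half (y down)
    if layout.n >= 3:
        rho = np.hypot(X - cx, Y - cy)
        code |= (rho < layout.circle_radius).astype(np.int64) << 2
        if layout.n >= 4:
            theta = np.arctan2(Y - cy, X - cx)
            for k in range(4, layout.n + 1):
                a, m, phi = layout.cog_params(k)
                bound = layout.circle_radius * (1.0 + a * np.cos(m * theta + phi))
                code |= (rho < bound).astype(np.int64) << (k - 1)
    return code


def membership(point: Tuple[float, float], set_index: int, layout: EdwardsLayout) -> bool:
    """Whether a canvas point lies inside a given set's region."""
    if not 1 <= set_index <= layout.n:
        raise ValueError(f"set_index {set_index} outside 1..{layout.n}")
    x, y = point
    code = int(membership_grid(layout, np.asarray(x, float), np.asarray(y, float)))
    return bool(code >> (set_index - 1) & 1)


def point_signature(point: Tuple[float, float], layout: EdwardsLayout) -> int:
    x, y = point
    return int(membership_grid(layout, np.asarray(x, float), np.asarray(y, float)))


def _frame_grid(layout: EdwardsLayout, resolution: int) -> Tuple[np.ndarray, np.ndarray]:
    x0, y0, x1, y1 = layout.frame
    xs = np.linspace(x0, x1, resolution)
    ys = np.linspace(y0, y1, resolution)
    return np.meshgrid(xs, ys)


@dataclass
class LayoutReport:
    """Result of grid-sampling a layout over its frame."""

    n: int
    resolution: int
    realized_patterns: List[int]
    missing: List[int]
    min_region_sample_count: int

    @property
    def passed(self) -> bool:
        return not self.missing


def validate_layout(layout: EdwardsLayout, resolution: int = 1000) -> LayoutReport:
    """Check that every one of the 2**n membership patterns is realized.

    Samples a resolution x resolution grid over the frame and histograms
    the induced signatures; ``min_region_sample_count`` is over the
    2**n - 1 inside patterns (pattern 0, outside every set, always has
    mass in the frame corners).
    """
    if resolution * resolution < 10**5:
        raise ValueError("resolution too coarse: need >= 1e5 samples over the frame")
    X, Y = _frame_grid(layout, resolution)
    code = membership_grid(layout, X, Y)
    counts = np.bincount(code.ravel(), minlength=1 << layout.n)
    realized = [i for i in range(1 << layout.n) if counts[i] > 0]
    missing = [i for i in range(1 << layout.n) if counts[i] == 0]
    inside = counts[1:]
    min_inside = int(inside.min()) if len(inside) else 0
    return LayoutReport(
        n=layout.n,
        resolution=resolution,
        realized_patterns=realized,
        missing=missing,
        min_region_sample_count=min_inside,
    )


def build_layout(n: int, validate: bool = True, resolution: int = 1000, **overrides) -> EdwardsLayout:
    """Construct the default layout for n sets, grid-validated.

    ``overrides`` are :class:`EdwardsLayout` field values (e.g. a custom
    ``circle_radius`` or ``cog_phases``).  Raises
    :class:`LayoutValidationError` if the resulting geometry fails to
    realize all 2**n patterns.
    """
    layout = EdwardsLayout(n=n, **overrides)
    if validate:
        report = validate_layout(layout, resolution=resolution)
        if not report.passed:
            raise LayoutValidationError(report)
    return layout


@dataclass(frozen=True)
class Anchor:
    """A label anchor placed strictly inside its region."""

    signature: int
    point: Tuple[float, float]


def region_anchors(
    layout: EdwardsLayout, resolution: int = 600
) -> Dict[int, Anchor]:
    """Label anchors for every realizable region at the given resolution.

    Each anchor is the centroid of the region's largest connected sample
    component; if the centroid itself falls outside the region (possible
    for crescent-shaped cells) it snaps to the nearest region sample.
    """
    X, Y = _frame_grid(layout, resolution)
    code = membership_grid(layout, X, Y)
    anchors: Dict[int, Anchor] = {}
    for sig in range(1, 1 << layout.n):
        mask = code == sig
        if not mask.any():
            continue
        labels, n_comp = ndimage.label(mask)
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, range(1, n_comp + 1))
        comp = labels == (int(np.argmax(sizes)) + 1)
        cy_idx, cx_idx = ndimage.center_of_mass(comp)
        x0, y0, x1, y1 = layout.frame
        px = x0 + cx_idx * (x1 - x0) / (resolution - 1)
        py = y0 + cy_idx * (y1 - y0) / (resolution - 1)
        if point_signature((px, py), layout) != sig:
            ii, jj = np.nonzero(comp)
            d2 = (ii - cy_idx) ** 2 + (jj - cx_idx) ** 2
            k = int(np.argmin(d2))
            px = x0 + jj[k] * (x1 - x0) / (resolution - 1)
            py = y0 + ii[k] * (y1 - y0) / (resolution - 1)
        anchors[sig] = Anchor(signature=sig, point=(px, py))
    return anchors


def region_anchor(layout: EdwardsLayout, sig: int, resolution: int = 600) -> Anchor:
    """Anchor for a single region; raises if it has no samples."""
    anchors = region_anchors(layout, resolution)
    if sig not in anchors:
        raise ValueError(f"region {sig} has no samples at resolution {resolution}")
    return anchors[sig]


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _fmt(v: float) -> str:
    return f"{v:.2f}"


def _set_path(layout: EdwardsLayout, set_index: int, samples: int = 720) -> str:
    """SVG path data for one set's closed boundary (frame-clipped)."""
    x0, y0, x1, y1 = layout.frame
    cx, cy = layout.center
    if set_index == 1:  # left half of the frame
        pts = [(x0, y0), (cx, y0), (cx, y1), (x0, y1)]
    elif set_index == 2:  # upper half of the frame
        pts = [(x0, y0), (x1, y0), (x1, cy), (x0, cy)]
    elif set_index == 3:
        r = layout.circle_radius
        return (
            f"M {_fmt(cx - r)} {_fmt(cy)} "
            f"A {_fmt(r)} {_fmt(r)} 0 1 0 {_fmt(cx + r)} {_fmt(cy)} "
            f"A {_fmt(r)} {_fmt(r)} 0 1 0 {_fmt(cx - r)} {_fmt(cy)} Z"
        )
    else:
        a, m, phi = layout.cog_params(set_index)
        thetas = np.linspace(0.0, 2.0 * math.pi, samples, endpoint=False)
        rho = layout.circle_radius * (1.0 + a * np.cos(m * thetas + phi))
        pts = list(zip(cx + rho * np.cos(thetas), cy + rho * np.sin(thetas)))
    d = f"M {_fmt(pts[0][0])} {_fmt(pts[0][1])} " + " ".join(
        f"L {_fmt(x)} {_fmt(y)}" for x, y in pts[1:]
    )
    return d + " Z"


def _xml_escape(text: str) -> str:
    return (
        text.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;")
        .replace('"', "&quot;")
    )


def _region_label(mode: DisplayMode, sig: int, members: List[str]) -> List[str]:
    if mode is DisplayMode.COUNTS:
        return [str(len(members))]
    if mode is DisplayMode.INDEX:
        return [str(sig)]
    lines = members[:TEXT_LINE_BUDGET]
    extra = len(members) - len(lines)
    if extra > 0:
        lines.append(f"… (+{extra} more)")
    return lines


def render_svg(
    layout: EdwardsLayout,
    partition: Partition,
    mode: DisplayMode = DisplayMode.COUNTS,
    path: Optional[str | Path] = None,
    anchor_resolution: int = 600,
) -> str:
    """Render the populated diagram as an SVG 1.1 document.

    One closed path per set with translucent fill, a text element at
    each non-empty region's anchor, and a <title> tooltip per region
    listing the full membership (the hover analog of an interactive
    roll-over).  Identical inputs produce identical bytes.
    """
    if layout.n != partition.n:
        raise ValueError(f"layout n={layout.n} != partition n={partition.n}")
    anchors = region_anchors(layout, resolution=anchor_resolution)
    out: List[str] = []
    out.append('<?xml version="1.0" encoding="UTF-8"?>')
    out.append(
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{_fmt(layout.width)}" height="{_fmt(layout.height)}" '
        f'viewBox="0 0 {_fmt(layout.width)} {_fmt(layout.height)}">'
    )
    out.append(f"<desc>{_xml_escape(json.dumps(layout.to_dict(), sort_keys=True))}</desc>")
    x0, y0, x1, y1 = layout.frame
    out.append(
        f'<rect x="{_fmt(x0)}" y="{_fmt(y0)}" width="{_fmt(x1 - x0)}" '
        f'height="{_fmt(y1 - y0)}" fill="none" stroke="#333333" stroke-width="1"/>'
    )
    for i in range(1, layout.n + 1):
        color = layout.colors[i - 1]
        out.append(
            f'<path d="{_set_path(layout, i)}" fill="{color}" '
            f'fill-opacity="{FILL_OPACITY}" stroke="{color}" stroke-width="1.5"/>'
        )
    # set legend along the top edge
    for i, name in enumerate(partition.collection.names):
        out.append(
            f'<text x="{_fmt(x0 + 4)}" y="{_fmt(12 + 14 * i)}" font-size="11" '
            f'fill="{layout.colors[i]}">{_xml_escape(f"{i + 1}: {name}")}</text>'
        )
    for sig in sorted(partition.regions):
        members = partition.regions[sig]
        if not members:
            continue
        anchor = anchors[sig]
        ax, ay = anchor.point
        names = signature_names(sig, partition.collection)
        tooltip = f"[{sig}] {' ∩ '.join(names)}: {', '.join(members)}"
        lines = _region_label(mode, sig, members)
        out.append(f'<g class="region" data-signature="{sig}">')
        out.append(f"<title>{_xml_escape(tooltip)}</title>")
        for j, line in enumerate(lines):
            out.append(
                f'<text x="{_fmt(ax)}" y="{_fmt(ay + 10 * j)}" font-size="9" '
                f'text-anchor="middle" fill="#000000">{_xml_escape(line)}</text>'
            )
        out.append("</g>")
    out.append("</svg>")
    doc = "\n".join(out) + "\n"
    if path is not None:
        Path(path).write_text(doc, encoding="utf-8")
    return doc


def layout_from_svg(svg_path: str | Path) -> EdwardsLayout:
    """Recover the layout parameters embedded in a rendered SVG's <desc>."""
    text = Path(svg_path).read_text(encoding="utf-8")
    match = re.search(r"<desc>(.*?)</desc>", text, re.DOTALL)
    if not match:
        raise ValueError(f"{svg_path}: no layout metadata found")
    payload = match.group(1)
    for entity, char in (("&amp;", "&"), ("&lt;", "<"), ("&gt;", ">"), ("&quot;", '"')):
        payload = payload.replace(entity, char)
    return EdwardsLayout.from_dict(json.loads(payload))


def export_raster(svg_path: str | Path, png_path: str | Path, dpi: int = 96) -> Tuple[int, int]:
    """Rasterize a rendered diagram to PNG at the requested dpi.

    Re-rasterizes the set geometry from the layout metadata embedded in
    the SVG (pixel size = canvas x dpi/96), alpha-blending each set's
    fill over white.  Deterministic: the same SVG always yields the
    same bytes.  Returns the (width, height) in pixels.
    """
    from PIL import Image

    layout = layout_from_svg(svg_path)
    w_px = round(layout.width * dpi / 96.0)
    h_px = round(layout.height * dpi / 96.0)
    xs = (np.arange(w_px) + 0.5) * layout.width / w_px
    ys = (np.arange(h_px) + 0.5) * layout.height / h_px
    X, Y = np.meshgrid(xs, ys)
    code = membership_grid(layout, X, Y)
    img = np.full((h_px, w_px, 3), 255.0)
    for i in range(layout.n):
        rgb = np.array(
            [int(layout.colors[i][j : j + 2], 16) for j in (1, 3, 5)], dtype=float
        )
        inside = (code >> i & 1).astype(bool)
        img[inside] = (1 - FILL_OPACITY) * img[inside] + FILL_OPACITY * rgb
    x0, y0, x1, y1 = layout.frame
    out = Image.fromarray(np.clip(np.round(img), 0, 255).astype(np.uint8), "RGB")
    out.save(png_path, format="PNG")
    return w_px, h_px


def parse_geometry_config(path: str | Path) -> dict:
    """Read key=value geometry overrides from a plain-text config file.

    Recognized keys: width, height, margin, circle_radius, a4, a5, a6,
    phi4, phi5, phi6.  Blank lines and '#' comments are ignored.
    """
    values: dict = {}
    for raw in Path(path).read_text(encoding="utf-8").splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        key, _, val = line.partition("=")
        key, val = key.strip(), val.strip()
        if not val:
            raise ValueError(f"malformed geometry line: {raw!r}")
        values[key] = float(val)
    overrides: dict = {}
    for simple in ("width", "height", "margin", "circle_radius"):
        if simple in values:
            overrides[simple] = values.pop(simple)
    amps = [values.pop(f"a{k}", COG_AMPLITUDES[k]) for k in (4, 5, 6)]
    phases = [values.pop(f"phi{k}", COG_PHASES[k]) for k in (4, 5, 6)]
    if values:
        raise ValueError(f"unknown geometry keys: {sorted(values)}")
    overrides["cog_amplitudes"] = tuple(amps)
    overrides["cog_phases"] = tuple(phases)
    return overrides
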