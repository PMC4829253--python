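"""Virtual gel electrophoresis: fragment length -> migration distance, and
deterministic SVG rendering of predicted gels.

The migration model treats the agarose matrix as an electrical network:
each fragment size experiences a size-specific resistance, Ohm's law
(I·R = V) converts the applied voltage into a size-specific current, the
current is read as a velocity, and distance = velocity × time.  The
resistance is taken to grow logarithmically with fragment length,
R(L) = r0·ln(L), which reproduces the classic agarose behavior of
migration distance proportional to 1/log(size):

    d_raw(L) = c · V / (r0 · ln L) · t

With the default constants (V = 70 volts, t = 45 minutes, r0 = c = 1) the
raw distance is 3150/ln(L).  For rendering, raw distances are affinely
normalized per model so the largest renderable fragment sits at 0.05 and
the smallest at 0.95 of the lane height — larger fragments migrate less.
"""

from __future__ import annotations

import math
import warnings as _warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

from .digest import FragmentLane

__all__ = ["GelModel", "Band", "GelImage", "migration_distance", "render_gel", "ladder_lane"]


@dataclass(frozen=True)
class GelModel:
    """Physical constants of the virtual gel.

    voltage: applied potential, volts DC.
    run_time: electrophoresis duration, minutes.
    resistance_coeff: r0 in R(L) = r0·ln(L), ohm-like units per ln(bp).
    velocity_coeff: c converting current to migration velocity.
    min_len/max_len: rendering range in bp (2% agarose regime); lengths
        outside it clamp to the edge positions with a warning.
    """

    voltage: float = 70.0
    run_time: float = 45.0
    resistance_coeff: float = 1.0
    velocity_coeff: float = 1.0
    lane_height: float = 1.0
    min_len: int = 50
    max_len: int = 3000

    def __post_init__(self) -> None:
        if min(self.voltage, self.run_time, self.resistance_coeff,
               self.velocity_coeff, self.lane_height) <= 0:
            raise ValueError("all gel model constants must be positive")
        if not 1 < self.min_len < self.max_len:
            raise ValueError("require 1 < min_len < max_len")

    def raw_distance(self, length_bp: float) -> float:
        """Unnormalized migration distance c·V·t / (r0·ln L)."""
        return (self.velocity_coeff * self.voltage * self.run_time
                / (self.resistance_coeff * math.log(length_bp)))


def migration_distance(length_bp: int, model: GelModel = GelModel()) -> float:
    """Normalized migration distance of a fragment (fraction of lane height).

    Strictly decreasing in fragment length over [min_len, max_len]; equal
    lengths co-migrate exactly.  Lengths outside the rendering range clamp
    to the edges with a warning; lengths below 1 bp are an error.
    """
    if length_bp < 1:
        raise ValueError("fragment length must be >= 1 bp")
    clamped = min(max(length_bp, model.min_len), model.max_len)
    if clamped != length_bp:
        _warnings.warn(
            f"fragment of {length_bp} bp outside rendering range "
            f"[{model.min_len}, {model.max_len}]; clamped", stacklevel=2
        )
    d = model.raw_distance(clamped)
    d_min = model.raw_distance(model.max_len)   # slowest: largest fragment
    d_max = model.raw_distance(model.min_len)   # fastest: smallest fragment
    frac = (d - d_min) / (d_max - d_min)
    return (0.05 + 0.90 * frac) * model.lane_height


@dataclass(frozen=True)
class Band:
    lane: str
    distance: float
    length: int
    intensity: int  # multiplicity in the lane's multiset
    clamped: bool = False


@dataclass
class GelImage:
    lanes: list[str] = field(default_factory=list)
    bands: list[Band] = field(default_factory=list)

    def lane_bands(self, lane: str) -> list[Band]:
        return sorted((b for b in self.bands if b.lane == lane),
                      key=lambda b: b.distance)


def ladder_lane(ladder: Union[str, Sequence[int]] = "100bp") -> FragmentLane:
    """The molecular-marker lane: '100bp' gives 100–1000 bp in 100 bp steps."""
    if ladder == "100bp":
        lengths: Sequence[int] = range(100, 1001, 100)
    else:
        lengths = ladder
    return FragmentLane(label="MM", fragments=tuple(lengths), source="ladder")


def render_gel(
    lanes: Sequence[FragmentLane],
    model: GelModel = GelModel(),
    ladder: Optional[Union[str, Sequence[int]]] = "100bp",
    path: Optional[str] = None,
) -> tuple[GelImage, str]:
    """Render lanes (plus a flanking ladder) to a deterministic SVG.

    Band vertical position comes from :func:`migration_distance`; band
    thickness grows with multiplicity in the lane's multiset.  The same
    lanes and model always produce byte-identical SVG text.
    """
    if not lanes or all(not l.fragments for l in lanes):
        raise ValueError("render_gel requires at least one non-empty lane")
    drawn = list(lanes)
    if ladder is not None:
        drawn = [ladder_lane(ladder)] + drawn
    image = GelImage(lanes=[l.label for l in drawn])
    for lane in drawn:
        for length, mult in sorted(lane.multiset.items()):
            clamped = not model.min_len <= length <= model.max_len
            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore")
                d = migration_distance(length, model)
            image.bands.append(Band(lane.label, d, length, mult, clamped))
    svg = _to_svg(drawn, image, model)
    if path is not None:
        with open(path, "w", encoding="utf-8") as out:
            out.write(svg)
    return image, svg


# --- SVG serialization (deterministic text output) ---

_LANE_W = 60
_LANE_GAP = 20
_MARGIN = 40
_GEL_H = 400


def _to_svg(drawn: Sequence[FragmentLane], image: GelImage, model: GelModel) -> str:
    width = 2 * _MARGIN + len(drawn) * (_LANE_W + _LANE_GAP)
    parts = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" '
        f'height="{_GEL_H + 2 * _MARGIN}" '
        f'viewBox="0 0 {width} {_GEL_H + 2 * _MARGIN}">',
        f'<rect x="0" y="0" width="{width}" height="{_GEL_H + 2 * _MARGIN}" '
        'fill="#111111"/>',
    ]
    for i, lane in enumerate(drawn):
        x = _MARGIN + i * (_LANE_W + _LANE_GAP)
        parts.append(
            f'<text x="{x + _LANE_W // 2}" y="{_MARGIN - 10}" fill="#dddddd" '
            f'font-size="11" text-anchor="middle">{_esc(lane.label)}</text>'
        )
        for band in image.lane_bands(lane.label):
            y = _MARGIN + band.distance / model.lane_height * _GEL_H
            thickness = 2 + 2 * (band.intensity - 1)
            dash = ' stroke-dasharray="4,3"' if band.clamped else ""
            parts.append(
                f'<line x1="{x}" y1="{y:.3f}" x2="{x + _LANE_W}" y2="{y:.3f}" '
                f'stroke="#f5f5f5" stroke-width="{thickness}"{dash}>'
                f'<title>{band.length} bp</title></line>'
            )
    parts.append("</svg>")
    return "\n".join(parts) + "\n"


def _esc(text: str) -> str:
    return (text.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;"))
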