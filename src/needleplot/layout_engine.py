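"""Layout heuristics: the step between residue data and SVG geometry.

Everything that makes the diagram information-dense lives here:

* data-driven axis ticks — only positions that matter (variant sites,
  domain boundaries, the termini) are labelled, never regularly spaced
  filler, with label collisions resolved by priority;
* adaptive domain labels — full description, short name, or a
  ``..suffix`` abbreviation that drops a name prefix shared with
  sibling domains, whichever fits the box;
* lollipop staggering — closely positioned variants get successive
  stem-height slots so their heads never overlap;
* relative radius scaling — user-supplied magnitudes map through a
  square-root transform onto a bounded radius range, keeping extreme
  values informative instead of overwhelming.

Residue coordinates are 1-based inclusive; this module is the only
place they are converted to pixels.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

from .errors import LayoutError
from .pfam_client import DomainRegion, ProteinArchitecture
from .variant_parser import Variant

#: Default fill colors for structural motif kinds.
DEFAULT_MOTIF_COLORS = {
    "sig_p": "#F0A000",          # signal peptide: orange
    "low_complexity": "#00C0C0", # low complexity: cyan / light blue
    "disorder": "#555555",       # predicted disorder: dark grey
    "coiled_coil": "#7A8B99",    # muted grey-blue
    "transmembrane": "#6E7F9E",  # muted grey-blue
}

#: Priority classes for axis tick candidates (higher wins a collision).
PRIORITY_VARIANT = 3
PRIORITY_DOMAIN_BOUNDARY = 2
PRIORITY_TERMINUS = 1


@dataclass(frozen=True)
class DrawConfig:
    """All plot geometry, fonts, flags and default colors in one place.

    The defaults target a compact report-width diagram; every value can
    be overridden per render.  Pixel fields must be positive and the
    radius bounds must bracket ``base_radius``.
    """

    plot_width: float = 740.0
    pad: float = 15.0
    backbone_height: float = 14.0
    lollipop_zone_height: float = 90.0
    axis_height: float = 24.0
    font_size: float = 12.0
    base_radius: float = 5.0
    min_radius: float = 4.0
    max_radius: float = 12.0
    min_tick_gap: float = 4.0
    stem_base_height: float = 24.0
    slot_step: float = 12.0
    show_labels: bool = False
    hide_motifs: bool = False
    hide_axis: bool = False
    show_disordered: bool = False
    motif_colors: dict = field(default_factory=lambda: dict(DEFAULT_MOTIF_COLORS))
    backbone_color: str = "#BABDB6"
    lollipop_color: str = "#D40000"
    axis_color: str = "#333333"
    domain_text_color: str = "#FFFFFF"

    def __post_init__(self) -> None:
        for name in (
            "plot_width", "pad", "backbone_height", "lollipop_zone_height",
            "axis_height", "font_size", "base_radius", "min_radius",
            "max_radius", "min_tick_gap", "stem_base_height", "slot_step",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"DrawConfig.{name} must be > 0")
        if self.plot_width <= 2 * self.pad:
            raise ValueError("DrawConfig.plot_width must exceed 2*pad")
        if not (self.min_radius <= self.base_radius <= self.max_radius):
            raise ValueError("need min_radius <= base_radius <= max_radius")


@dataclass(frozen=True)
class Tick:
    position: int
    priority: int


@dataclass(frozen=True)
class TickSet:
    """Axis ticks sorted by position, already culled for label collisions."""

    ticks: tuple[Tick, ...]

    def positions(self) -> tuple[int, ...]:
        return tuple(t.position for t in self.ticks)


@dataclass(frozen=True)
class LabelChoice:
    """The text drawn inside one domain box, or none if nothing fits."""

    text: Optional[str]
    mode: str  # "description" | "name" | "abbreviated" | "hidden"


@dataclass(frozen=True)
class LollipopLayout:
    """Per-variant geometry, index-aligned with the input variant list.

    ``stem_top`` is the head-center height in px above the backbone top;
    the renderer turns it into document y coordinates.
    """

    x: tuple[float, ...]
    slot: tuple[int, ...]
    stem_top: tuple[float, ...]
    radius: tuple[float, ...]


# ---------------------------------------------------------------------------
# text metrics

_METRICS = None


def _metrics() -> tuple[dict, float]:
    global _METRICS
    if _METRICS is None:
        raw = json.loads(
            resources.files("needleplot.data")
            .joinpath("font_metrics.json")
            .read_text(encoding="utf-8")
        )
        advances = raw["advances"]
        average = sum(advances.values()) / len(advances)
        _METRICS = (advances, average)
    return _METRICS


def estimate_text_width(text: str, font_size: float) -> float:
    """Estimate rendered width of *text* in px at *font_size*.

    Sums per-character advance widths from a packaged metrics table for
    DejaVu Sans (a ubiquitous default sans-serif), scaled linearly by
    font size.  Characters absent from the table fall back to the
    average advance.  The estimate is approximate by design — viewers
    substitute fonts — and is used only for fit decisions, never drawn.
    """
    advances, average = _metrics()
    return font_size * sum(advances.get(ch, average) for ch in text)


# ---------------------------------------------------------------------------
# coordinate mapping


def aa_to_px(position: float, length: int, config: DrawConfig) -> float:
    """Map a 1-based residue *position* to the pixel x of its center.

    Residue ``i`` occupies a cell of width ``usable/length``; the
    mapping returns the cell center, so it is strictly increasing and
    stays inside the padded plot area for all positions in ``[1, L]``.
    """
    if not (1 <= position <= length):
        raise LayoutError(f"residue {position} outside protein 1..{length}")
    usable = config.plot_width - 2 * config.pad
    return config.pad + (position - 0.5) * usable / length


def residue_span_px(start: int, end: int, length: int, config: DrawConfig) -> tuple[float, float]:
    """Pixel extent ``(left, width)`` of the inclusive range ``start..end``."""
    usable = config.plot_width - 2 * config.pad
    left = config.pad + (start - 1) * usable / length
    width = (end - start + 1) * usable / length
    return left, width


# ---------------------------------------------------------------------------
# axis ticks


def select_ticks(
    architecture: ProteinArchitecture,
    variants: Sequence[Variant],
    config: DrawConfig,
) -> TickSet:
    """Choose the axis tick positions worth labelling.

    Candidates are every variant position (priority 3), every domain
    start and end (priority 2) and the two termini (priority 1) — no
    regularly spaced filler, since data-driven positions are what a
    reader actually needs to locate.  Identical positions deduplicate
    to the highest priority.  When two labels would sit closer than
    ``min_tick_gap``, the lower-priority tick is culled; at equal
    priority the leftmost survives.
    """
    length = architecture.length
    for variant in variants:
        if variant.position > length:
            raise LayoutError(
                f"variant {variant.change} at {variant.position} beyond protein length {length}"
            )

    best: dict[int, int] = {}
    def offer(position: int, priority: int) -> None:
        if best.get(position, 0) < priority:
            best[position] = priority

    for variant in variants:
        offer(variant.position, PRIORITY_VARIANT)
    for domain in architecture.domains:
        offer(domain.start, PRIORITY_DOMAIN_BOUNDARY)
        offer(domain.end, PRIORITY_DOMAIN_BOUNDARY)
    offer(1, PRIORITY_TERMINUS)
    offer(length, PRIORITY_TERMINUS)

    # Greedy placement in (priority desc, position asc) order: a tick is
    # kept only if its label clears every already-kept label, which makes
    # every culled tick attributable to a surviving >=-priority neighbor.
    candidates = sorted(best.items(), key=lambda item: (-item[1], item[0]))
    kept: list[tuple[float, float]] = []  # (left, right) label extents
    surviving: list[Tick] = []
    for position, priority in candidates:
        center = aa_to_px(position, length, config)
        half = estimate_text_width(str(position), config.font_size) / 2
        left, right = center - half, center + half
        if any(left < r + config.min_tick_gap and right > l - config.min_tick_gap
               for l, r in kept):
            continue
        kept.append((left, right))
        surviving.append(Tick(position=position, priority=priority))

    surviving.sort(key=lambda t: t.position)
    return TickSet(ticks=tuple(surviving))


# ---------------------------------------------------------------------------
# domain labels


def _shared_prefix_suffix(region: DomainRegion, siblings: Sequence[DomainRegion]) -> Optional[str]:
    """Suffix left after removing the longest underscore-delimited name
    prefix that >=2 sibling domains share; None when no such prefix or
    nothing would remain."""
    tokens = region.short_name.split("_")
    if len(tokens) < 2:
        return None
    names = [s.short_name.split("_") for s in siblings]
    for cut in range(len(tokens) - 1, 0, -1):
        prefix = tokens[:cut]
        sharers = sum(1 for name in names if name[:cut] == prefix)
        if sharers >= 2:
            return "_".join(tokens[cut:])
    return None


def choose_domain_label(
    region: DomainRegion,
    siblings: Sequence[DomainRegion],
    box_width: float,
    config: DrawConfig,
) -> LabelChoice:
    """Pick the most informative label that fits a domain box.

    Tried in order: the full description; the short name; the
    abbreviation ``..SUFFIX`` (short name minus the longest
    underscore-delimited prefix shared with at least one sibling, so
    e.g. three domains all starting ``Fib_`` label as ``..aC`` etc.);
    otherwise the label is hidden.  "Fits" allows 4 px total padding
    inside the box.
    """
    if box_width <= 0:
        raise LayoutError(f"domain {region.short_name}: box_width must be > 0")
    available = box_width - 4.0

    def fits(text: str) -> bool:
        return estimate_text_width(text, config.font_size) <= available

    if region.description and fits(region.description):
        return LabelChoice(text=region.description, mode="description")
    if fits(region.short_name):
        return LabelChoice(text=region.short_name, mode="name")
    suffix = _shared_prefix_suffix(region, siblings)
    if suffix:
        abbreviated = ".." + suffix
        if fits(abbreviated):
            return LabelChoice(text=abbreviated, mode="abbreviated")
    return LabelChoice(text=None, mode="hidden")


# ---------------------------------------------------------------------------
# lollipop geometry


def scale_radii(variants: Sequence[Variant], config: DrawConfig) -> list[float]:
    """Map variant magnitudes to head radii.

    Equal magnitudes (the common, undecorated case) all get
    ``base_radius``.  Otherwise radii interpolate between
    ``min_radius`` and ``max_radius`` by the square root of the
    normalized magnitude: area tracks magnitude roughly linearly while
    extremes stay bounded, keeping a 42x lollipop visible next to a 1x
    one without dwarfing it.
    """
    magnitudes = [v.magnitude for v in variants]
    for m in magnitudes:
        if m <= 0:
            raise LayoutError("variant magnitudes must be > 0")
    if not magnitudes:
        return []
    lo, hi = min(magnitudes), max(magnitudes)
    if lo == hi:
        return [config.base_radius] * len(magnitudes)
    span = config.max_radius - config.min_radius
    return [
        config.min_radius + span * math.sqrt((m - lo) / (hi - lo))
        for m in magnitudes
    ]


def stagger_lollipops(
    variants: Sequence[Variant],
    radii: Sequence[float],
    length: int,
    config: DrawConfig,
) -> LollipopLayout:
    """Assign stem heights so no two lollipop heads overlap.

    Variants are processed sorted by position (ties keep input order)
    and each takes the lowest slot whose head circle clears every head
    already placed.  Slot ``s`` puts the head center
    ``stem_base_height + s*slot_step`` px above the backbone.
    """
    if len(radii) != len(variants):
        raise LayoutError("radii must align index-wise with variants")
    max_slot = int(
        (config.lollipop_zone_height - config.stem_base_height - config.max_radius)
        // config.slot_step
    )
    order = sorted(range(len(variants)), key=lambda i: (variants[i].position, i))

    xs = [0.0] * len(variants)
    slots = [0] * len(variants)
    tops = [0.0] * len(variants)
    placed: list[tuple[float, float, float]] = []  # (x, stem_top, radius)

    for i in order:
        x = aa_to_px(variants[i].position, length, config)
        r = radii[i]
        slot = 0
        while True:
            top = config.stem_base_height + slot * config.slot_step
            if all(
                (x - px) ** 2 + (top - ptop) ** 2 >= (r + pr) ** 2 - 1e-9
                for px, ptop, pr in placed
            ):
                break
            slot += 1
            if slot > max_slot:
                raise LayoutError(
                    f"variant {variants[i].change}: no free stem slot within the "
                    "lollipop zone; widen the plot or raise lollipop_zone_height"
                )
        xs[i], slots[i], tops[i] = x, slot, config.stem_base_height + slot * config.slot_step
        placed.append((x, tops[i], r))

    return LollipopLayout(
        x=tuple(xs), slot=tuple(slots), stem_top=tuple(tops), radius=tuple(radii)
    )
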