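"""Parse and re-serialize protein variant spec strings.

A spec is a compact, shell-friendly description of one lollipop::

    CHANGE [ "#" RRGGBB ] [ "@" NUMBER ]

``CHANGE`` is an optional ``p.`` prefix, a one-letter amino-acid code,
an integer residue position, and an optional tail describing the event
(alternate residue, ``*`` stop, ``fs``, ``del``, ``ins``, ``dup``).
``#RRGGBB`` colors the lollipop head; ``@NUMBER`` scales it (e.g.
``@42`` for a lollipop representing 42x the standard size).  The ``@``
sigil keeps a magnitude unambiguous against trailing digits in the
change text.

Only one-letter amino-acid codes are accepted; three-letter specs such
as ``p.Arg273His`` are rejected with a pointer to the one-letter form.
Parsing never consults the network or the protein architecture —
positions beyond the protein length are a layout-stage concern.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional

from .errors import VariantSpecError

_CHANGE_RE = re.compile(
    r"""^(?:p\.)?
        (?P<ref>[A-Z\*])
        (?P<pos>\d+)
        (?P<tail>(?:[A-Z\*]|fs|del|ins|dup)*)$""",
    re.VERBOSE,
)
_THREE_LETTER_RE = re.compile(r"^(?:p\.)?[A-Z][a-z]{2}\d")
_COLOR_RE = re.compile(r"^#[0-9A-Fa-f]{6}$")


@dataclass(frozen=True)
class Variant:
    """One parsed lollipop.

    ``change`` is the canonical change text (``p.`` stripped);
    ``magnitude`` is the relative head size, 1 by default.
    """

    position: int
    change: str
    color: Optional[str] = None
    magnitude: float = 1.0

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("Variant.position must be >= 1")
        if self.magnitude <= 0:
            raise ValueError("Variant.magnitude must be > 0")
        if self.color is not None and not _COLOR_RE.match(self.color):
            raise ValueError(f"Variant.color {self.color!r} is not #RRGGBB")


def parse_variant(spec: str) -> Variant:
    """Parse one spec string into a :class:`Variant`.

    Raises :class:`VariantSpecError` naming the input when no residue
    position can be found, the color is malformed, or the magnitude is
    not a positive number.
    """
    original = spec
    spec = spec.strip()
    if not spec:
        raise VariantSpecError("empty variant spec")

    magnitude = 1.0
    if "@" in spec:
        spec, _, magnitude_text = spec.rpartition("@")
        try:
            magnitude = float(magnitude_text)
        except ValueError:
            raise VariantSpecError(
                f"{original!r}: magnitude {magnitude_text!r} is not a number"
            ) from None
        if magnitude <= 0:
            raise VariantSpecError(f"{original!r}: magnitude must be > 0")

    color: Optional[str] = None
    if "#" in spec:
        spec, _, color_text = spec.rpartition("#")
        color = "#" + color_text
        if not _COLOR_RE.match(color):
            raise VariantSpecError(
                f"{original!r}: color {color!r} is not a #RRGGBB hex color"
            )
        color = color.upper()

    match = _CHANGE_RE.match(spec)
    if not match:
        if _THREE_LETTER_RE.match(spec):
            raise VariantSpecError(
                f"{original!r}: three-letter amino-acid codes are not supported; "
                "use the one-letter form (e.g. R273H, not p.Arg273His)"
            )
        raise VariantSpecError(
            f"{original!r}: no residue position found (expected e.g. R273H)"
        )

    change = f"{match['ref']}{match['pos']}{match['tail']}"
    return Variant(
        position=int(match["pos"]),
        change=change,
        color=color,
        magnitude=magnitude,
    )


def parse_variants(specs: list[str]) -> list[Variant]:
    """Parse many specs, preserving order and duplicates.

    Duplicates are deliberately kept: two identical specs are two
    lollipops at one position, which height staggering then separates.
    """
    return [parse_variant(spec) for spec in specs]


def format_variant(variant: Variant) -> str:
    """Emit the canonical spec for *variant*.

    Defaults are omitted (no ``#`` for an unset color, no ``@`` for
    magnitude 1), so ``parse_variant(format_variant(v)) == v`` exactly
    and formatting a freshly parsed spec canonicalizes it.
    """
    parts = [variant.change]
    if variant.color is not None:
        parts.append(variant.color)
    if variant.magnitude != 1.0:
        magnitude = variant.magnitude
        text = str(int(magnitude)) if magnitude == int(magnitude) else repr(magnitude)
        parts.append("@" + text)
    return "".join(parts)
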