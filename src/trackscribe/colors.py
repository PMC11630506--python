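"""Colour naming for description output.

Some screen-reader users want to know the colours of a visualization to
build a mental image; others skip them.  Descriptions therefore report
colours by approximate English name, resolved from the hex values in the
bundled default theme (or any hex/named value found in a spec) via
nearest-neighbour lookup over a small fixed table of named colours.
"""

from __future__ import annotations

# default categorical palette of the bundled theme (Okabe-Ito derived,
# colour-blind safe), applied in order to nominal colour categories
DEFAULT_CATEGORICAL_PALETTE: tuple[str, ...] = (
    "#E79F00",  # orange
    "#029F73",  # green
    "#0072B2",  # blue
    "#CB7AA7",  # pink
    "#D45E00",  # vermilion
    "#57B4E9",  # sky blue
    "#EFE441",  # yellow
)

# small fixed lookup of named colours (sRGB)
NAMED_COLORS: dict[str, tuple[int, int, int]] = {
    "black": (0, 0, 0),
    "white": (255, 255, 255),
    "gray": (128, 128, 128),
    "light gray": (211, 211, 211),
    "red": (220, 20, 60),
    "dark red": (139, 0, 0),
    "orange": (255, 140, 0),
    "brown": (139, 69, 19),
    "yellow": (240, 230, 60),
    "green": (34, 139, 34),
    "teal": (0, 150, 136),
    "blue": (0, 90, 181),
    "sky blue": (86, 180, 233),
    "navy": (0, 0, 128),
    "purple": (128, 0, 128),
    "pink": (231, 132, 186),
    "steel blue": (70, 130, 180),
}


def _parse_hex(value: str) -> tuple[int, int, int] | None:
    v = value.lstrip("#")
    if len(v) == 3:
        v = "".join(ch * 2 for ch in v)
    if len(v) != 6:
        return None
    try:
        return tuple(int(v[i:i + 2], 16) for i in (0, 2, 4))  # type: ignore[return-value]
    except ValueError:
        return None


def color_name(value: str) -> str:
    """English name nearest to a colour value (hex or already a name)."""
    value = str(value).strip()
    if not value.startswith("#"):
        return value.lower()
    rgb = _parse_hex(value)
    if rgb is None:
        return value
    best, _ = min(
        NAMED_COLORS.items(),
        key=lambda kv: sum((a - b) ** 2 for a, b in zip(rgb, kv[1])),
    )
    return best


def palette_names(n: int) -> list[str]:
    """Names of the first ``n`` default categorical palette colours."""
    palette = [color_name(c) for c in DEFAULT_CATEGORICAL_PALETTE]
    return [palette[i % len(palette)] for i in range(n)]
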