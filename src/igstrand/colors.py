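"""Strand nomenclature colors and interaction-type colors for exports.

The nine canonical strands A..G (with C'/C'') take a 9-step rainbow from
dark violet to red; additional or split strands at a terminus inherit the
color of their canonical family (A', A-, A+ share A's dark violet; G+, G++
share G's red).  Other inserted strands render white, extensions cyan,
loops grey.  Interaction types use the conventional palette: hydrogen
bonds green, ionic cyan, van der Waals grey, halogen magenta, pi-cation
red, pi-stacking blue.

Named colors are authoritative; hex codes are presentation defaults and
may be overridden in configuration.
"""

from __future__ import annotations

STRAND_RAINBOW = {
    "A": "dark violet",
    "B": "indigo",
    "C": "blue",
    "C'": "cyan",
    "C''": "green",
    "D": "yellow",
    "E": "orange",
    "F": "orange red",
    "G": "red",
}

INTERACTION_COLORS = {
    "hbond": "green",
    "ionic": "cyan",
    "vdw": "grey",
    "halogen": "magenta",
    "pi_cation": "red",
    "pi_stacking": "blue",
}

SPECIAL_COLORS = {
    "loop": "grey",
    "nterm": "grey",
    "cterm": "grey",
    "extension": "cyan",
    "insertion": "white",
}

DEFAULT_HEX = {
    "dark violet": "#9400D3",
    "indigo": "#4B0082",
    "blue": "#0000FF",
    "cyan": "#00FFFF",
    "green": "#00FF00",
    "yellow": "#FFFF00",
    "orange": "#FFA500",
    "orange red": "#FF4500",
    "red": "#FF0000",
    "grey": "#808080",
    "magenta": "#FF00FF",
    "white": "#FFFFFF",
}


class UnknownEntityError(KeyError):
    pass


def _family(letter: str) -> str | None:
    """Canonical family of a strand letter: A- and A+ and A' map to A, etc."""
    if letter in STRAND_RAINBOW:
        return letter
    base = letter.rstrip("+-'")
    if base in STRAND_RAINBOW and base in ("A", "G"):
        return base
    if base in STRAND_RAINBOW:
        return None  # inserted strand elsewhere (E+, C-, ...) -> insertion color
    return None


def color_for(entity: str) -> str:
    """Color name of a strand letter, loop label or interaction type."""
    if entity in INTERACTION_COLORS:
        return INTERACTION_COLORS[entity]
    if entity in SPECIAL_COLORS:
        return SPECIAL_COLORS[entity]
    fam = _family(entity)
    if fam is not None:
        return STRAND_RAINBOW[fam]
    base = entity.rstrip("+-'")
    if base in STRAND_RAINBOW:
        return SPECIAL_COLORS["insertion"]
    raise UnknownEntityError(f"unknown strand or interaction {entity!r}")


def hex_for(entity: str, overrides: dict[str, str] | None = None) -> str:
    name = color_for(entity)
    table = dict(DEFAULT_HEX)
    if overrides:
        table.update(overrides)
    return table[name]
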