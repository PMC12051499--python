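"""Beta-sandwich topology specifications.

A :class:`TopologySpec` describes an idealized Ig-fold beta sandwich: the
strands in sequence order (each with its sheet, lateral slot, direction,
length and anchor position), the lengths of the connecting coils, and short
N/C tails.  The strand letters follow the classical Ig nomenclature
(A, A', B, C, C', C'', D, E, F, G) extended with inserted strands named
relative to their canonical neighbour (A-, A+, E+, G+, ...).

The four-digit strand code ``ij`` is fixed by the letter: the thousands digit
``i`` numbers the canonical strand family A..G as 1..9 and the hundreds digit
``j`` is 5 for canonical strands, 8 for the split A' strand, and moves
down/up from 5 for strands inserted before/after a canonical strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: strand letter -> (i_digit, j_digit)
STRAND_DIGITS: dict[str, tuple[int, int]] = {
    "A--": (1, 3),
    "A-": (1, 4),
    "A": (1, 5),
    "A+": (1, 6),
    "A++": (1, 7),
    "A'": (1, 8),
    "B": (2, 5),
    "C": (3, 5),
    "C-": (3, 4),
    "C'": (4, 5),
    "C''": (5, 5),
    "D": (6, 5),
    "E": (7, 5),
    "E+": (7, 6),
    "E++": (7, 7),
    "F": (8, 5),
    "G": (9, 5),
    "G+": (9, 6),
    "G++": (9, 7),
    "G+++": (9, 8),
}

#: The irreducible supersecondary signature of the fold: the four central
#: strands every Ig/Ig-like/Ig-extended domain must contain.
SIGNATURE_STRANDS = ("B", "C", "E", "F")


def strand_digits(letter: str) -> tuple[int, int]:
    try:
        return STRAND_DIGITS[letter]
    except KeyError:
        raise KeyError(f"unknown strand letter {letter!r}") from None


def anchor_number(letter: str) -> int:
    """The ij50 anchor number of a strand (e.g. B -> 2550, A' -> 1850)."""
    i, j = strand_digits(letter)
    return i * 1000 + j * 100 + 50


@dataclass(frozen=True)
class StrandDef:
    """One strand of a sandwich spec.

    sheet: 0 (the ABED face) or 1 (the GFCC' face).
    column: lateral slot within the sheet (0 = edge).
    direction: +1/-1, sign of the strand axis; adjacent antiparallel strands
        alternate sign.
    anchor_offset: 0-based index of the anchor residue within the strand.
    """

    letter: str
    length: int
    sheet: int
    column: int
    direction: int
    anchor_offset: int

    def __post_init__(self) -> None:
        strand_digits(self.letter)  # validates the letter
        if not 0 <= self.anchor_offset < self.length:
            raise ValueError(f"strand {self.letter}: anchor_offset outside strand")
        if self.sheet not in (0, 1):
            raise ValueError(f"strand {self.letter}: sheet must be 0 or 1")

    @property
    def i_digit(self) -> int:
        return strand_digits(self.letter)[0]

    @property
    def j_digit(self) -> int:
        return strand_digits(self.letter)[1]

    @property
    def anchor_igs(self) -> int:
        return anchor_number(self.letter)


@dataclass(frozen=True)
class TopologySpec:
    name: str
    strands: tuple[StrandDef, ...]
    loop_lengths: tuple[int, ...]
    nterm: int = 2
    cterm: int = 2

    def __post_init__(self) -> None:
        letters = {s.letter for s in self.strands}
        missing = [x for x in SIGNATURE_STRANDS if x not in letters]
        if missing:
            raise ValueError(
                f"topology {self.name!r} lacks signature strands {missing}; "
                "every Ig-fold spec must contain B, C, E and F"
            )
        if len(self.loop_lengths) != len(self.strands) - 1:
            raise ValueError(f"topology {self.name!r}: need one loop length per strand gap")
        occupied: set[tuple[int, int]] = set()
        for s in self.strands:
            slot = (s.sheet, s.column)
            if slot in occupied:
                raise ValueError(f"topology {self.name!r}: two strands share sheet slot {slot}")
            occupied.add(slot)

    @property
    def n_residues(self) -> int:
        return (
            self.nterm
            + sum(s.length for s in self.strands)
            + sum(self.loop_lengths)
            + self.cterm
        )

    def strand_ranges(self) -> list[tuple[StrandDef, int, int]]:
        """(strand, first_index, last_index) for each strand, 0-based inclusive."""
        out = []
        pos = self.nterm
        for k, s in enumerate(self.strands):
            out.append((s, pos, pos + s.length - 1))
            pos += s.length
            if k < len(self.loop_lengths):
                pos += self.loop_lengths[k]
        return out


def _mk(letters_and_geom, loops, name, nterm=2, cterm=2):
    strands = tuple(
        StrandDef(letter=L, length=n, sheet=sh, column=col, direction=d, anchor_offset=a)
        for (L, n, sh, col, d, a) in letters_and_geom
    )
    return TopologySpec(name=name, strands=strands, loop_lengths=tuple(loops), nterm=nterm, cterm=cterm)


# Canonical variants. Sheet 0 is the ABED face (columns A=0, B=1, E=2, D=3),
# sheet 1 the (A')GFCC'C'' face (columns A'=0, G=1, F=2, C=3, C'=4, C''=5).
# Anchor offsets put anchors mid-strand; D and E anchors sit two positions
# off the B-strand backbone register, mirroring how the sheet twist shifts
# those anchors in real domains.

#: 9-strand variable domain: (AA')BCC'C''DEFG
IGV = _mk(
    [
        ("A", 5, 0, 0, +1, 2),
        ("A'", 5, 1, 0, +1, 2),
        ("B", 7, 0, 1, -1, 3),
        ("C", 7, 1, 3, +1, 3),
        ("C'", 6, 1, 4, -1, 2),
        ("C''", 5, 1, 5, +1, 2),
        ("D", 6, 0, 3, -1, 2),
        ("E", 6, 0, 2, +1, 3),
        ("F", 7, 1, 2, -1, 3),
        ("G", 8, 1, 1, +1, 4),
    ],
    [3, 4, 5, 4, 3, 4, 3, 4, 4],
    "igv",
)

#: 8-strand I-set: (AA')BCC'DEFG
IGI = _mk(
    [
        ("A", 5, 0, 0, +1, 2),
        ("A'", 4, 1, 0, +1, 2),
        ("B", 6, 0, 1, -1, 3),
        ("C", 7, 1, 3, +1, 3),
        ("C'", 5, 1, 4, -1, 2),
        ("D", 6, 0, 3, -1, 2),
        ("E", 6, 0, 2, +1, 3),
        ("F", 7, 1, 2, -1, 3),
        ("G", 7, 1, 1, +1, 3),
    ],
    [3, 4, 5, 4, 4, 3, 4, 4],
    "igi",
)

#: 7-strand C1-set: ABCDEFG (straight A strand, D strand, no C'/C'')
IGC1 = _mk(
    [
        ("A", 6, 0, 0, +1, 3),
        ("B", 7, 0, 1, -1, 3),
        ("C", 7, 1, 2, +1, 3),
        ("D", 6, 0, 3, -1, 2),
        ("E", 6, 0, 2, +1, 3),
        ("F", 7, 1, 1, -1, 3),
        ("G", 7, 1, 0, +1, 3),
    ],
    [4, 5, 6, 3, 4, 4],
    "igc1",
)

#: 7-strand C2-set: ABCC'EFG (C' strand, no D)
IGC2 = _mk(
    [
        ("A", 6, 0, 0, +1, 3),
        ("B", 7, 0, 1, -1, 3),
        ("C", 7, 1, 2, +1, 3),
        ("C'", 6, 1, 3, -1, 2),
        ("E", 6, 0, 2, +1, 3),
        ("F", 7, 1, 1, -1, 3),
        ("G", 7, 1, 0, +1, 3),
    ],
    [4, 5, 4, 5, 4, 4],
    "igc2",
)

#: IgC2 with an extra G+ strand after G (as in CD3-gamma).
IGC2_GPLUS = _mk(
    [
        ("A", 6, 0, 0, +1, 3),
        ("B", 7, 0, 1, -1, 3),
        ("C", 7, 1, 2, +1, 3),
        ("C'", 6, 1, 3, -1, 2),
        ("E", 6, 0, 2, +1, 3),
        ("F", 7, 1, 1, -1, 3),
        ("G", 7, 1, 0, +1, 3),
        ("G+", 5, 0, 3, -1, 2),
    ],
    [4, 5, 4, 5, 4, 4, 3],
    "igc2_gplus",
)

#: FN3: ABCC'EFG with longer C'E cross-sheet loop
FN3 = _mk(
    [
        ("A", 5, 0, 0, +1, 2),
        ("B", 7, 0, 1, -1, 3),
        ("C", 7, 1, 2, +1, 3),
        ("C'", 7, 1, 3, -1, 3),
        ("E", 7, 0, 2, +1, 3),
        ("F", 8, 1, 1, -1, 4),
        ("G", 6, 1, 0, +1, 3),
    ],
    [5, 4, 4, 6, 4, 5],
    "fn3",
)

#: FN3-like with slightly different proportions (complement C3 / NaCa family)
FN3_LIKE = _mk(
    [
        ("A", 4, 0, 0, +1, 2),
        ("B", 6, 0, 1, -1, 3),
        ("C", 6, 1, 2, +1, 3),
        ("C'", 5, 1, 3, -1, 2),
        ("E", 6, 0, 2, +1, 3),
        ("F", 7, 1, 1, -1, 3),
        ("G", 8, 1, 0, +1, 4),
    ],
    [4, 3, 5, 5, 3, 6],
    "fn3_like",
)

#: Cadherin: A'BCDEFG (only the A' half of the split strand)
CADHERIN = _mk(
    [
        ("A'", 5, 1, 0, +1, 2),
        ("B", 7, 0, 1, -1, 3),
        ("C", 6, 1, 3, +1, 3),
        ("D", 5, 0, 3, -1, 2),
        ("E", 7, 0, 2, +1, 3),
        ("F", 7, 1, 2, -1, 3),
        ("G", 6, 1, 1, +1, 3),
    ],
    [4, 5, 5, 3, 4, 4],
    "cadherin",
)

#: Lamin tail domain: A- A B C C' E E+ F G, sheets ABEE+ and A-GFCC'
LAMIN = _mk(
    [
        ("A-", 6, 1, 0, -1, 2),
        ("A", 5, 0, 0, +1, 2),
        ("B", 7, 0, 1, -1, 3),
        ("C", 7, 1, 4, +1, 3),
        ("C'", 6, 1, 5, -1, 2),
        ("E", 6, 0, 2, +1, 3),
        ("E+", 5, 0, 3, +1, 2),
        ("F", 7, 1, 3, -1, 3),
        ("G", 7, 1, 2, +1, 3),
    ],
    [3, 3, 4, 5, 6, 4, 4, 4],
    "lamin",
)

#: Arrestin-like extended domain: A- A B C C' E E+ F G with long coils
ARRESTIN = _mk(
    [
        ("A-", 5, 1, 0, -1, 2),
        ("A", 6, 0, 0, +1, 3),
        ("B", 6, 0, 1, -1, 3),
        ("C", 6, 1, 4, +1, 3),
        ("C'", 6, 1, 5, -1, 3),
        ("E", 7, 0, 2, +1, 3),
        ("E+", 4, 0, 3, +1, 1),
        ("F", 6, 1, 3, -1, 3),
        ("G", 8, 1, 2, +1, 4),
    ],
    [4, 4, 6, 4, 5, 3, 5, 3],
    "arrestin",
)

#: Extended variant with both an A- strand and a C-terminal G+ hairpin.
EXT_GPLUS = _mk(
    [
        ("A-", 5, 1, 0, -1, 2),
        ("A", 5, 0, 0, +1, 2),
        ("B", 7, 0, 1, -1, 3),
        ("C", 6, 1, 3, +1, 3),
        ("C'", 5, 1, 4, -1, 2),
        ("E", 6, 0, 2, +1, 3),
        ("F", 7, 1, 2, -1, 3),
        ("G", 6, 1, 1, +1, 3),
        ("G+", 5, 0, 3, -1, 2),
    ],
    [3, 4, 5, 5, 4, 4, 4, 3],
    "ext_gplus",
)

#: Ig-extended fixture carrying A-, A+ and G+ insertions around an IgV-like
#: frame; exercises the inserted-strand hundreds digits (14xx/16xx/96xx).
EXT_FULL = _mk(
    [
        ("A-", 5, 1, 0, -1, 2),
        ("A", 5, 0, 0, +1, 2),
        ("A+", 4, 0, 4, -1, 1),
        ("B", 7, 0, 1, -1, 3),
        ("C", 7, 1, 3, +1, 3),
        ("C'", 6, 1, 4, -1, 2),
        ("E", 6, 0, 2, +1, 3),
        ("F", 7, 1, 2, -1, 3),
        ("G", 7, 1, 1, +1, 3),
        ("G+", 5, 0, 3, -1, 2),
    ],
    [3, 3, 4, 5, 5, 4, 4, 4, 3],
    "ext_full",
)

# Additional distinct geometries for the remaining registry clusters: same
# canonical families but with their own strand/loop proportions so the
# clusters are structurally separable.
IGC1_SHORT = _mk(
    [
        ("A", 5, 0, 0, +1, 2),
        ("B", 6, 0, 1, -1, 3),
        ("C", 6, 1, 2, +1, 3),
        ("D", 5, 0, 3, -1, 2),
        ("E", 5, 0, 2, +1, 2),
        ("F", 6, 1, 1, -1, 3),
        ("G", 6, 1, 0, +1, 3),
    ],
    [3, 4, 4, 3, 3, 3],
    "igc1_short",
    nterm=1,
    cterm=1,
)

BARREL_WIDE = _mk(
    [
        ("A", 7, 0, 0, +1, 3),
        ("B", 8, 0, 1, -1, 4),
        ("C", 8, 1, 2, +1, 4),
        ("C'", 7, 1, 3, -1, 3),
        ("E", 8, 0, 2, +1, 4),
        ("F", 8, 1, 1, -1, 4),
        ("G", 8, 1, 0, +1, 4),
    ],
    [6, 5, 7, 5, 6, 5],
    "barrel_wide",
    nterm=3,
    cterm=3,
)

SANDWICH_MIN = _mk(
    [
        ("B", 6, 0, 1, -1, 3),
        ("C", 6, 1, 2, +1, 3),
        ("C'", 5, 1, 3, -1, 2),
        ("E", 6, 0, 2, +1, 3),
        ("F", 6, 1, 1, -1, 3),
        ("G", 5, 1, 0, +1, 2),
    ],
    [4, 4, 5, 4, 4],
    "sandwich_min",
)

EXT_NEAT = _mk(
    [
        ("A-", 4, 1, 0, -1, 1),
        ("B", 7, 0, 1, -1, 3),
        ("C", 7, 1, 3, +1, 3),
        ("C'", 6, 1, 4, -1, 2),
        ("D", 5, 0, 3, -1, 2),
        ("E", 6, 0, 2, +1, 3),
        ("F", 7, 1, 2, -1, 3),
        ("G", 7, 1, 1, +1, 3),
    ],
    [5, 4, 5, 4, 3, 4, 4],
    "ext_neat",
)

EXT_TWIST = _mk(
    [
        ("A", 6, 0, 0, +1, 3),
        ("B", 8, 0, 1, -1, 4),
        ("C", 7, 1, 2, +1, 3),
        ("C'", 5, 1, 3, -1, 2),
        ("D", 6, 0, 3, -1, 3),
        ("E", 7, 0, 2, +1, 3),
        ("F", 8, 1, 1, -1, 4),
        ("G", 6, 1, 0, +1, 3),
    ],
    [5, 6, 4, 4, 4, 5, 5],
    "ext_twist",
    nterm=3,
    cterm=3,
)

TOPOLOGIES: dict[str, TopologySpec] = {
    t.name: t
    for t in (
        IGV,
        IGI,
        IGC1,
        IGC2,
        IGC2_GPLUS,
        FN3,
        FN3_LIKE,
        CADHERIN,
        LAMIN,
        ARRESTIN,
        EXT_GPLUS,
        EXT_FULL,
        IGC1_SHORT,
        BARREL_WIDE,
        SANDWICH_MIN,
        EXT_NEAT,
        EXT_TWIST,
    )
}
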