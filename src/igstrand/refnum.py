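"""Propagation of four-digit strand-anchored reference numbers.

Given the strand segments of a domain (each with the residue index of its
anchor and the anchor's ij50 number), every residue of the domain receives a
number by counting away from the anchors:

* within a strand, numbers run +/-1 per residue from the anchor;
* in the coil between two strands, the first half (rounded up) continues
  forward from the preceding strand and the second half counts backward from
  the following strand;
* residues before the first strand count backward from it, residues after
  the last strand count forward;
* a number that would leave its strand's hundreds block (below ij00 or above
  ij99), or that would break strict monotonicity, is left undefined.

The same routine numbers template residues (from their strand annotations)
and query residues (from strand segments recovered by alignment), which is
what makes template and query numberings directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["StrandSegment", "propagate_numbers"]


@dataclass(frozen=True)
class StrandSegment:
    """A strand's extent within a domain, 0-based inclusive indices."""

    letter: str
    start: int
    end: int
    anchor: int
    anchor_igs: int

    def __post_init__(self) -> None:
        if not self.start <= self.anchor <= self.end:
            raise ValueError(f"strand {self.letter}: anchor outside [start, end]")
        if self.anchor_igs % 100 != 50:
            raise ValueError(f"strand {self.letter}: anchor number must end in 50")

    @property
    def block_lo(self) -> int:
        return self.anchor_igs - 50

    @property
    def block_hi(self) -> int:
        return self.anchor_igs + 49


def _bounded(num: int, lo: int, hi: int) -> int | None:
    return num if lo <= num <= hi else None


def propagate_numbers(
    n: int,
    segments: list[StrandSegment],
    value_range: tuple[int, int] | None = None,
) -> tuple[list[int | None], list[str | None]]:
    """Number ``n`` residues from their strand segments.

    Returns ``(numbers, labels)`` where ``numbers[k]`` is the igs# of residue
    ``k`` (or None if undefined) and ``labels[k]`` is the strand letter, or
    ``"loop"`` / ``"nterm"`` / ``"cterm"`` for coil and tail residues.
    ``value_range`` optionally clamps numbers to the template's covered range
    (residues mapping outside it stay undefined).
    """
    if not segments:
        return [None] * n, [None] * n
    segs = sorted(segments, key=lambda s: s.start)
    for a, b in zip(segs, segs[1:]):
        if a.end >= b.start:
            raise ValueError(f"overlapping strand segments {a.letter}/{b.letter}")
    if segs[-1].end >= n:
        raise ValueError("strand segment extends past the domain")

    numbers: list[int | None] = [None] * n
    labels: list[str | None] = [None] * n

    for seg in segs:
        for idx in range(seg.start, seg.end + 1):
            numbers[idx] = _bounded(seg.anchor_igs + (idx - seg.anchor), seg.block_lo, seg.block_hi)
            labels[idx] = seg.letter

    # coils between consecutive strands: forward half then backward half
    for a, b in zip(segs, segs[1:]):
        gap = list(range(a.end + 1, b.start))
        if not gap:
            continue
        m = len(gap)
        fwd = (m + 1) // 2
        a_end = numbers[a.end]
        b_start = numbers[b.start]
        for t, idx in enumerate(gap[:fwd], start=1):
            labels[idx] = "loop"
            if a_end is not None:
                numbers[idx] = _bounded(a_end + t, a.block_lo, a.block_hi)
        back = gap[fwd:]
        for t, idx in enumerate(back):
            labels[idx] = "loop"
            if b_start is not None:
                numbers[idx] = _bounded(b_start - (len(back) - t), b.block_lo, b.block_hi)

    # tails
    first, last = segs[0], segs[-1]
    f_start = numbers[first.start]
    for t, idx in enumerate(range(first.start - 1, -1, -1), start=1):
        labels[idx] = "nterm"
        if f_start is not None:
            numbers[idx] = _bounded(f_start - t, first.block_lo, first.block_hi)
    l_end = numbers[last.end]
    for t, idx in enumerate(range(last.end + 1, n), start=1):
        labels[idx] = "cterm"
        if l_end is not None:
            numbers[idx] = _bounded(l_end + t, last.block_lo, last.block_hi)

    if value_range is not None:
        lo, hi = value_range
        numbers = [x if (x is not None and lo <= x <= hi) else None for x in numbers]

    # enforce strict monotonicity: drop any number not above the running max
    prev = None
    for idx in range(n):
        x = numbers[idx]
        if x is None:
            continue
        if prev is not None and x <= prev:
            numbers[idx] = None
        else:
            prev = x
    return numbers, labels
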