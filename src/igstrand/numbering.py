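"""Ig-domain detection and IgStrand number assignment.

Detection follows the two-step template search: a query segment is first
aligned against the 16 cluster representatives; when the best representative
scores above the cluster shortcut (TM > 0.85) only that cluster's templates
are tried in the second step, otherwise all templates of the five best
clusters are tried.  A domain is accepted when the best template TM-score
(template-length normalized) exceeds the acceptance threshold (0.4), its
residues are masked, and detection re-runs on the remainder of the chain
until nothing more is found.

Assignment transfers each template strand's anchor to the query residue
aligned with it (number ij50) and propagates numbers along the query
sequence: +/-1 per residue within strands, coils split half-forward /
half-backward between flanking strands, tails counted outward, residues
outside the template's covered number range left undefined.  Undefined
numbers are represented as ``None``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .align import AlignmentError, AlignParams, AlignmentResult, align_structures
from .model import Chain, ResidueKey
from .refnum import StrandSegment, propagate_numbers
from .registry import IgTemplate, TemplateRegistry

logger = logging.getLogger(__name__)

CONTACT_CUTOFF = 8.0  # A, Calpha-Calpha contact edge for domain splitting
NCUT_THRESHOLD = 0.20  # accept a chain split when its normalized cut is below this
MIN_ALIGN_LEN = 20  # residues; shorter fragments are not aligned


@dataclass
class DetectionParams:
    """Thresholds of the two-step template search."""

    tm_accept: float = 0.4
    tm_cluster_shortcut: float = 0.85
    top_clusters: int = 5
    min_segment: int = 50
    max_iterations: int = 20
    align: AlignParams = field(default_factory=AlignParams)

    def __post_init__(self) -> None:
        if not (0 < self.tm_accept < self.tm_cluster_shortcut <= 1):
            raise ValueError("require 0 < tm_accept < tm_cluster_shortcut <= 1")


@dataclass
class DomainHit:
    """An accepted Ig domain: its residues, winning template, and alignment.

    ``alignment.pairs`` are (domain-local residue index, template residue
    index); ``residues`` lists the domain's residue keys in chain order.
    """

    residues: list[ResidueKey]
    template_id: str
    ig_type: str
    template_class: str
    tm: float
    alignment: AlignmentResult
    n_anchors_matched: int = 0
    n_anchors_total: int = 0

    @property
    def low_confidence(self) -> bool:
        return self.n_anchors_matched * 2 < self.n_anchors_total


@dataclass
class NumberedDomain:
    """Per-residue IgStrand numbers for one detected domain."""

    hit: DomainHit
    numbers: dict[ResidueKey, int | None]
    strand_of: dict[ResidueKey, str | None]

    def defined(self) -> dict[ResidueKey, int]:
        return {k: v for k, v in self.numbers.items() if v is not None}

    def anchors(self) -> dict[ResidueKey, int]:
        return {k: v for k, v in self.defined().items() if v % 100 == 50}


# --- chain splitting ----------------------------------------------------------


def split_into_domains(trace: np.ndarray, params: DetectionParams | None = None) -> list[tuple[int, int]]:
    """Partition a Calpha trace into candidate domain segments.

    Recursive bisection of the chain's contact map (8 A Calpha edges,
    sequence neighbours excluded): a split point is accepted when its
    normalized cut falls below a fixed threshold and both sides keep at
    least ``min_segment`` residues.  Returns (start, end) inclusive 0-based
    segments in chain order; degenerate chains yield one segment.
    """
    params = params or DetectionParams()
    n = len(trace)
    if n < 2 * params.min_segment:
        return [(0, n - 1)]
    diff = trace[:, None, :] - trace[None, :, :]
    dist = np.sqrt((diff**2).sum(-1))
    contact = (dist <= CONTACT_CUTOFF).astype(float)
    for k in range(-2, 3):
        idx = np.arange(max(0, -k), min(n, n - k))
        contact[idx, idx + k] = 0.0

    def bisect(a: int, b: int, out: list[tuple[int, int]]) -> None:
        length = b - a + 1
        if length < 2 * params.min_segment:
            out.append((a, b))
            return
        sub = contact[a : b + 1, a : b + 1]
        degree = sub.sum()
        best = None
        col_cum = sub.cumsum(axis=1)
        for s in range(params.min_segment, length - params.min_segment + 1):
            cut = float(col_cum[:s, -1].sum() - col_cum[:s, s - 1].sum())
            assoc_a = float(col_cum[:s, -1].sum())
            assoc_b = degree - assoc_a
            if assoc_a <= 0 or assoc_b <= 0:
                continue
            ncut = cut / assoc_a + cut / assoc_b
            if best is None or ncut < best[0]:
                best = (ncut, s)
        if best is None or best[0] > NCUT_THRESHOLD:
            out.append((a, b))
            return
        s = a + best[1]
        bisect(a, s - 1, out)
        bisect(s, b, out)

    segments: list[tuple[int, int]] = []
    bisect(0, n - 1, segments)
    return segments


# --- two-step template search -------------------------------------------------


def _matched_anchors(alignment: AlignmentResult, template: IgTemplate) -> int:
    aligned_t = {ti for _, ti in alignment.pairs}
    return sum(1 for idx in template.anchor_indices().values() if idx in aligned_t)


def _two_step_search(
    trace: np.ndarray,
    registry: TemplateRegistry,
    params: DetectionParams,
) -> tuple[IgTemplate, AlignmentResult] | None:
    reps = registry.representative_templates()
    step1: list[tuple[float, int]] = []
    for rep in reps:
        try:
            res = align_structures(trace, rep.ca_trace, params.align)
        except AlignmentError:
            continue
        step1.append((res.tm_by_template, rep.cluster_id))
    if not step1:
        return None
    step1.sort(key=lambda t: (-t[0], t[1]))
    best_tm, best_cluster = step1[0]
    if best_tm > params.tm_cluster_shortcut:
        candidate_ids = registry.clusters[best_cluster]
    else:
        top = [cid for _, cid in step1[: params.top_clusters]]
        candidate_ids = [tid for cid in top for tid in registry.clusters[cid]]

    best: tuple[float, int, str, AlignmentResult] | None = None
    for tid in sorted(candidate_ids):
        template = registry[tid]
        try:
            res = align_structures(trace, template.ca_trace, params.align)
        except AlignmentError:
            continue
        anchors = _matched_anchors(res, template)
        key = (res.tm_by_template, anchors, tid)
        if best is None:
            best = (*key, res)
            continue
        # tie within 1e-4 on TM: prefer more matched anchors, then lexicographic id
        if res.tm_by_template > best[0] + 1e-4:
            best = (*key, res)
        elif abs(res.tm_by_template - best[0]) <= 1e-4 and (
            anchors > best[1] or (anchors == best[1] and tid < best[2])
        ):
            best = (*key, res)
    if best is None or best[0] <= params.tm_accept:
        return None
    return registry[best[2]], best[3]


def detect_ig_domains(
    chain: Chain,
    registry: TemplateRegistry,
    params: DetectionParams | None = None,
) -> list[DomainHit]:
    """Detect Ig domains in one chain by the masked two-step template search."""
    params = params or DetectionParams()
    if len(registry) == 0:
        raise ValueError("template registry is empty")
    residues = chain.ca_residues()
    trace = np.array([r.ca.coord for r in residues])
    if len(trace) < MIN_ALIGN_LEN:
        return []

    intervals = list(split_into_domains(trace, params))
    hits: list[DomainHit] = []
    for _ in range(params.max_iterations):
        if not intervals:
            break
        progressed = False
        next_intervals: list[tuple[int, int]] = []
        for a, b in intervals:
            if b - a + 1 < MIN_ALIGN_LEN:
                continue
            found = _two_step_search(trace[a : b + 1], registry, params)
            if found is None:
                continue
            template, alignment = found
            qa = min(qi for qi, _ in alignment.pairs)
            qb = max(qi for qi, _ in alignment.pairs)
            local_pairs = [(qi - qa, ti) for qi, ti in alignment.pairs]
            alignment.pairs = local_pairs
            span = [residues[a + k].key for k in range(qa, qb + 1)]
            hit = DomainHit(
                residues=span,
                template_id=template.template_id,
                ig_type=template.ig_type,
                template_class=template.template_class,
                tm=alignment.tm_by_template,
                alignment=alignment,
                n_anchors_matched=_matched_anchors(alignment, template),
                n_anchors_total=len(template.strands),
            )
            hits.append(hit)
            progressed = True
            logger.info(
                "detected Ig domain %s..%s template=%s tm=%.3f anchors=%d/%d",
                span[0], span[-1], template.template_id, hit.tm,
                hit.n_anchors_matched, hit.n_anchors_total,
            )
            if qa >= MIN_ALIGN_LEN:
                next_intervals.append((a, a + qa - 1))
            if (b - a) - qb >= MIN_ALIGN_LEN:
                next_intervals.append((a + qb + 1, b))
        intervals = next_intervals
        if not progressed:
            break
    hits.sort(key=lambda h: h.residues[0][1])
    return hits


# --- number assignment --------------------------------------------------------


def assign_reference_numbers(hit: DomainHit, registry: TemplateRegistry) -> NumberedDomain:
    """Assign IgStrand numbers to every residue of a detected domain.

    Query strand extents are the residues aligned into each template
    strand's range; anchors transfer as ij50 where aligned, and are
    extrapolated from the nearest aligned strand residue on anchor dropout.
    Numbers outside the template's covered range stay undefined.
    """
    template = registry[hit.template_id]
    n = len(hit.residues)
    pairs = hit.alignment.pairs
    segments: list[StrandSegment] = []
    for seg in template.segments():
        inside = [(qi, ti) for qi, ti in pairs if seg.start <= ti <= seg.end]
        if not inside:
            logger.warning(
                "domain %s: strand %s entirely unaligned; numbered as loop",
                hit.template_id, seg.letter,
            )
            continue
        qstart = inside[0][0]
        qend = inside[-1][0]
        exact = [qi for qi, ti in inside if ti == seg.anchor]
        if exact:
            q_anchor = exact[0]
        else:
            nearest = min(inside, key=lambda p: (abs(p[1] - seg.anchor), p[1]))
            q_anchor = nearest[0] + (seg.anchor - nearest[1])
            q_anchor = min(max(q_anchor, qstart), qend)
            logger.warning(
                "domain %s: anchor dropout on strand %s; extrapolated",
                hit.template_id, seg.letter,
            )
        segments.append(
            StrandSegment(
                letter=seg.letter,
                start=qstart,
                end=qend,
                anchor=q_anchor,
                anchor_igs=seg.anchor_igs,
            )
        )
    numbers, labels = propagate_numbers(n, segments, value_range=template.number_range())
    return NumberedDomain(
        hit=hit,
        numbers={key: numbers[k] for k, key in enumerate(hit.residues)},
        strand_of={key: labels[k] for k, key in enumerate(hit.residues)},
    )


def classify_domain(hit: DomainHit) -> dict:
    """Type labels inherited from the winning template, with a confidence note.

    Detection is reliable for the fold itself; the variant-type label is
    only as good as the structural fit to the winning template, so low
    anchor coverage is surfaced as low confidence.
    """
    return {
        "ig_type": hit.ig_type,
        "template_class": hit.template_class,
        "template_id": hit.template_id,
        "tm": hit.tm,
        "confidence": "low" if hit.low_confidence else "high",
    }


def number_chain(
    chain: Chain,
    registry: TemplateRegistry,
    params: DetectionParams | None = None,
) -> list[NumberedDomain]:
    """Detect and number all Ig domains of a chain (convenience pipeline)."""
    return [
        assign_reference_numbers(hit, registry)
        for hit in detect_ig_domains(chain, registry, params)
    ]
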