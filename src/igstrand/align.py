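"""Structural superposition and TM-score alignment.

The alignment kernel follows the familiar TM-align recipe: seed residue
correspondences (gapless threading at every offset, secondary-structure
strings, best local fragments), then refine each seed by alternating
least-squares superposition with dynamic-programming re-alignment under the
distance score 1/(1+(d/d0)^2), and keep the highest-scoring result.  It is
fully deterministic: no randomness, and ties between equal-scoring seeds are
broken by the earliest query offset.

An external TM-align binary can be used as a cross-check backend; its plain
text output is parsed into the same :class:`AlignmentResult`.
"""

from __future__ import annotations

import re
import subprocess
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

D0_FLOOR = 0.5  # A, lower bound of the TM-score normalization distance
DEFAULT_GAP_OPEN = 0.6  # DP gap-open penalty (TM-align convention)


class AlignmentError(ValueError):
    pass


class BackendError(RuntimeError):
    """The external aligner is missing or failed."""


@dataclass
class Superposition:
    """Rigid transform y ~ R x + t minimizing RMSD, with that minimum RMSD."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(x) @ self.rotation.T + self.translation


@dataclass
class AlignmentResult:
    """Residue pairing between query and template with TM-scores.

    ``pairs`` holds 0-based (query index, template index) tuples, strictly
    increasing in both coordinates.  ``tm_by_template`` / ``tm_by_query`` are
    the TM-scores normalized by template and query length respectively.
    """

    pairs: list[tuple[int, int]]
    tm_by_template: float
    tm_by_query: float
    superposition: Superposition
    rmsd_aligned: float
    seed_kind: str = "none"

    def query_of(self, template_index: int) -> int | None:
        for qi, ti in self.pairs:
            if ti == template_index:
                return qi
        return None


@dataclass
class AlignParams:
    gap_open: float = DEFAULT_GAP_OPEN
    max_iterations: int = 10
    n_thread_seeds: int = 3
    n_fragment_seeds: int = 2
    fragment_length: int = 20


def kabsch_superpose(x: np.ndarray, y: np.ndarray) -> Superposition:
    """Least-squares rigid fit of point set x onto y (SVD / Kabsch).

    Requires at least 3 non-collinear points in each equal-length set.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 2 or x.shape[1] != 3:
        raise AlignmentError("point sets must be equal-length lists of 3-vectors")
    if len(x) < 3:
        raise AlignmentError("need at least 3 points to superpose")
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    h = xc.T @ yc
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = y.mean(axis=0) - rot @ x.mean(axis=0)
    diff = x @ rot.T + trans - y
    rmsd = float(np.sqrt((diff**2).sum() / len(x)))
    return Superposition(rotation=rot, translation=trans, rmsd=rmsd)


def tm_d0(norm_length: int) -> float:
    """TM-score normalization distance d0(L), floored at 0.5 A."""
    if norm_length > 15:
        d0 = 1.24 * (norm_length - 15) ** (1.0 / 3.0) - 1.8
    else:
        d0 = D0_FLOOR
    return max(d0, D0_FLOOR)


def tm_score(distances: np.ndarray, norm_length: int) -> float:
    """TM-score of aligned pair distances (A) under a given normalization length."""
    distances = np.asarray(distances, dtype=float)
    if distances.size == 0:
        return 0.0
    d0 = tm_d0(norm_length)
    return float(np.sum(1.0 / (1.0 + (distances / d0) ** 2)) / norm_length)


# --- secondary structure from Calpha geometry ---------------------------------


def sse_string(trace: np.ndarray) -> str:
    """Per-residue E/H/C labels from Calpha i..i+3 distances.

    Extended (strand-like) geometry has d(i,i+3) above ~8.5 A, helical
    geometry below ~6.5 A; everything else is coil.  Crude, but strands are
    all that matters for seeding.
    """
    n = len(trace)
    labels = ["C"] * n
    if n < 4:
        return "".join(labels)
    d13 = np.linalg.norm(trace[3:] - trace[:-3], axis=1)
    for i in range(n - 3):
        if d13[i] > 8.5:
            labels[i] = labels[i + 1] = labels[i + 2] = labels[i + 3] = "E"
        elif d13[i] < 6.5:
            for k in range(4):
                if labels[i + k] == "C":
                    labels[i + k] = "H"
    return "".join(labels)


def strand_segments_from_sse(sse: str, min_len: int = 3) -> list[tuple[int, int]]:
    """(start, end) inclusive runs of E of at least min_len residues."""
    out = []
    i = 0
    while i < len(sse):
        if sse[i] == "E":
            j = i
            while j + 1 < len(sse) and sse[j + 1] == "E":
                j += 1
            if j - i + 1 >= min_len:
                out.append((i, j))
            i = j + 1
        else:
            i += 1
    return out


# --- dynamic programming ------------------------------------------------------


def _dp_align(score: np.ndarray, gap_open: float) -> list[tuple[int, int]]:
    """Semi-global alignment (free end gaps) maximizing sum(score) - gaps.

    Vectorized over anti-diagonals; traceback gives strictly increasing
    (query, template) pairs.
    """
    n, m = score.shape
    H = np.zeros((n + 1, m + 1))
    P = np.zeros((n + 1, m + 1), dtype=np.int8)  # 0 stop, 1 diag, 2 up, 3 left
    for d in range(2, n + m + 1):
        i_lo = max(1, d - m)
        i_hi = min(n, d - 1)
        if i_lo > i_hi:
            continue
        i = np.arange(i_lo, i_hi + 1)
        j = d - i
        diag = H[i - 1, j - 1] + score[i - 1, j - 1]
        up = H[i - 1, j] - np.where(j == m, 0.0, gap_open)
        left = H[i, j - 1] - np.where(i == n, 0.0, gap_open)
        best = np.maximum(diag, np.maximum(up, left))
        ptr = np.where(diag >= best, 1, np.where(up >= best, 2, 3)).astype(np.int8)
        H[i, j] = best
        P[i, j] = ptr
    # start traceback from the best boundary cell
    last_col = H[:, m]
    last_row = H[n, :]
    if last_col.max() >= last_row.max():
        i, j = int(last_col.argmax()), m
    else:
        i, j = n, int(last_row.argmax())
    pairs: list[tuple[int, int]] = []
    while i > 0 and j > 0:
        p = P[i, j]
        if p == 1:
            pairs.append((i - 1, j - 1))
            i, j = i - 1, j - 1
        elif p == 2:
            i -= 1
        elif p == 3:
            j -= 1
        else:
            break
    pairs.reverse()
    return pairs


# --- seeding ------------------------------------------------------------------


def _thread_seeds(query: np.ndarray, template: np.ndarray, k: int) -> list[tuple[str, list[tuple[int, int]]]]:
    n, m = len(query), len(template)
    min_overlap = min(20, n, m)
    scored = []
    for offset in range(-(m - min_overlap), n - min_overlap + 1):
        qi0 = max(0, offset)
        ti0 = max(0, -offset)
        ov = min(n - qi0, m - ti0)
        if ov < min_overlap:
            continue
        pairs = [(qi0 + t, ti0 + t) for t in range(ov)]
        sup = kabsch_superpose(query[qi0 : qi0 + ov], template[ti0 : ti0 + ov])
        d = np.linalg.norm(sup.apply(query[qi0 : qi0 + ov]) - template[ti0 : ti0 + ov], axis=1)
        scored.append((tm_score(d, m), offset, pairs))
    scored.sort(key=lambda t: (-t[0], t[1]))
    return [("thread", pairs) for _, _, pairs in scored[:k]]


def _sse_seed(query: np.ndarray, template: np.ndarray) -> list[tuple[str, list[tuple[int, int]]]]:
    qseg = strand_segments_from_sse(sse_string(query))
    tseg = strand_segments_from_sse(sse_string(template))
    if not qseg or not tseg:
        return []
    pairs: list[tuple[int, int]] = []
    for (qa, qb), (ta, tb) in zip(qseg, tseg):
        ln = min(qb - qa, tb - ta) + 1
        pairs.extend((qa + t, ta + t) for t in range(ln))
    if len(pairs) < 3:
        return []
    return [("sse", pairs)]


def _fragment_seeds(
    query: np.ndarray, template: np.ndarray, k: int, frag: int
) -> list[tuple[str, list[tuple[int, int]]]]:
    n, m = len(query), len(template)
    frag = min(frag, n, m)
    if frag < 8:
        return []
    scored = []
    for qi in range(0, n - frag + 1, 4):
        for ti in range(0, m - frag + 1, 4):
            sup = kabsch_superpose(query[qi : qi + frag], template[ti : ti + frag])
            scored.append((sup.rmsd, qi, ti))
    scored.sort(key=lambda t: (t[0], t[1], t[2]))
    return [
        ("fragment", [(qi + t, ti + t) for t in range(frag)])
        for _, qi, ti in scored[:k]
    ]


# --- main aligner -------------------------------------------------------------


def _refine(
    query: np.ndarray,
    template: np.ndarray,
    pairs: list[tuple[int, int]],
    params: AlignParams,
) -> tuple[list[tuple[int, int]], Superposition]:
    d0 = tm_d0(len(template))
    for _ in range(params.max_iterations):
        qi = [p[0] for p in pairs]
        ti = [p[1] for p in pairs]
        sup = kabsch_superpose(query[qi], template[ti])
        moved = sup.apply(query)
        dist = cdist(moved, template)
        score = 1.0 / (1.0 + (dist / d0) ** 2)
        new_pairs = _dp_align(score, params.gap_open)
        if len(new_pairs) < 3:
            break
        if new_pairs == pairs:
            break
        pairs = new_pairs
    qi = [p[0] for p in pairs]
    ti = [p[1] for p in pairs]
    sup = kabsch_superpose(query[qi], template[ti])
    return pairs, sup


def _tm_optimal(
    query: np.ndarray,
    template: np.ndarray,
    pairs: list[tuple[int, int]],
    norm_length: int,
) -> tuple[float, Superposition]:
    """Best TM over superpositions fitted on shrinking close-pair subsets."""
    qi = np.array([p[0] for p in pairs])
    ti = np.array([p[1] for p in pairs])
    best_tm, best_sup = -1.0, None
    subset = np.ones(len(pairs), dtype=bool)
    for cutoff in (None, 8.0, 5.0, max(tm_d0(norm_length), 2.0)):
        if subset.sum() < 3:
            break
        sup = kabsch_superpose(query[qi[subset]], template[ti[subset]])
        d = np.linalg.norm(sup.apply(query[qi]) - template[ti], axis=1)
        tm = tm_score(d, norm_length)
        if tm > best_tm:
            best_tm, best_sup = tm, sup
        if cutoff is not None:
            subset = d <= cutoff
    return best_tm, best_sup


def align_structures(
    query: np.ndarray,
    template: np.ndarray,
    params: AlignParams | None = None,
) -> AlignmentResult:
    """Heuristic TM-align-style alignment of two Calpha traces.

    Both traces must have at least 20 residues; the returned result is the
    seed+refinement outcome with the highest template-normalized TM-score.
    """
    params = params or AlignParams()
    query = np.asarray(query, dtype=float)
    template = np.asarray(template, dtype=float)
    if len(query) < 20 or len(template) < 20:
        raise AlignmentError("both traces must have at least 20 residues")

    seeds: list[tuple[str, list[tuple[int, int]]]] = []
    seeds.extend(_thread_seeds(query, template, params.n_thread_seeds))
    seeds.extend(_sse_seed(query, template))
    seeds.extend(_fragment_seeds(query, template, params.n_fragment_seeds, params.fragment_length))

    best: AlignmentResult | None = None
    for kind, seed_pairs in seeds:
        try:
            pairs, sup = _refine(query, template, seed_pairs, params)
        except AlignmentError:
            continue
        if len(pairs) < 3:
            continue
        tm_t, sup_t = _tm_optimal(query, template, pairs, len(template))
        tm_q, _ = _tm_optimal(query, template, pairs, len(query))
        qi = [p[0] for p in pairs]
        ti = [p[1] for p in pairs]
        d = np.linalg.norm(sup_t.apply(query[qi]) - template[ti], axis=1)
        res = AlignmentResult(
            pairs=pairs,
            tm_by_template=tm_t,
            tm_by_query=tm_q,
            superposition=sup_t,
            rmsd_aligned=float(np.sqrt(np.mean(d**2))),
            seed_kind=kind,
        )
        if best is None or res.tm_by_template > best.tm_by_template + 1e-12:
            best = res
    if best is None:
        raise AlignmentError("no seed produced a valid alignment")
    return best


# --- external backend ---------------------------------------------------------

_TM_LINE = re.compile(r"TM-score=\s*([0-9.]+)\s*\(.*normalized by length of (\w+)", re.I)


def parse_tmalign_output(text: str) -> dict:
    """Extract TM-scores and the aligned-column pairing from TM-align stdout."""
    tms: dict[str, float] = {}
    for m in _TM_LINE.finditer(text):
        which = "query" if "1" in m.group(2) or "chain_1" in m.group(2).lower() else "template"
        tms[which] = float(m.group(1))
    # fall back: first score = by query (Chain_1), second = by template (Chain_2)
    scores = [float(x) for x in re.findall(r"TM-score=\s*([0-9.]+)", text)]
    if "query" not in tms and scores:
        tms["query"] = scores[0]
    if "template" not in tms and len(scores) > 1:
        tms["template"] = scores[1]
    # aligned sequence block: last three non-empty lines of the alignment section
    lines = [ln for ln in text.splitlines()]
    pairs: list[tuple[int, int]] = []
    for k in range(len(lines) - 2):
        a, mid, b = lines[k], lines[k + 1], lines[k + 2]
        if a and b and mid and set(mid.strip()) <= {":", ".", " "} and len(a) == len(b) and mid.strip():
            qi = ti = 0
            for ca, cm, cb in zip(a, mid, b):
                if ca != "-" and cb != "-" and cm in ":.":
                    pairs.append((qi, ti))
                if ca != "-":
                    qi += 1
                if cb != "-":
                    ti += 1
            break
    return {"tm_by_query": tms.get("query"), "tm_by_template": tms.get("template"), "pairs": pairs}


def external_backend_align(
    query_path: str,
    template_path: str,
    executable: str = "TMalign",
) -> dict:
    """Run an external TM-align binary on two structure files and parse it.

    Raises :class:`BackendError` if the binary is absent or exits non-zero;
    the internal kernel remains usable either way.
    """
    try:
        proc = subprocess.run(
            [executable, str(query_path), str(template_path)],
            capture_output=True,
            text=True,
            check=False,
        )
    except FileNotFoundError as exc:
        raise BackendError(f"external aligner not found: {executable}") from exc
    if proc.returncode != 0:
        raise BackendError(
            f"external aligner failed (exit {proc.returncode}): {proc.stderr.strip()}"
        )
    return parse_tmalign_output(proc.stdout)
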