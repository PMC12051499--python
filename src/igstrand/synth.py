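"""Idealized beta-sandwich generator.

Builds synthetic Ig-fold domains with known strand topology and ground-truth
reference numbers, so detection, numbering and interface analysis can be
exercised end to end without any structure download.  Geometry is idealized,
not physical: flat antiparallel sheets with a 3.4 A Calpha rise, 4.8 A
inter-strand spacing and 10 A between the two sheets, coils as smooth arcs.

Side chains are reduced to minimal pseudo-atom sets sufficient for contact
analysis: each strand residue carries a CB placed 1.5 A toward the in- or
out-facing side of its sheet (alternating along the strand, anchors facing
in) and backbone N/O pseudo-atoms displaced 1.2 A laterally within the sheet
plane, which is where real beta-sheet backbone hydrogen bonds point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model import AtomRecord, Chain, Residue, StructureModel
from .refnum import StrandSegment, propagate_numbers
from .topologies import TopologySpec

RISE = 3.4  # A per residue along a strand
STRAND_SPACING = 4.8  # A between adjacent strands in a sheet
SHEET_SEP = 10.0  # A between the two sheet planes
SHEET0_STAGGER = 2.4  # lateral offset of the ABED sheet vs the GFCC' sheet
LOOP_STEP = 3.8  # target Calpha-Calpha spacing in coils

#: canonical residue identity placed at each strand's anchor position
ANCHOR_AA = {
    "A": "E",
    "A'": "I",
    "A-": "V",
    "A--": "V",
    "A+": "V",
    "B": "C",
    "C": "W",
    "C-": "T",
    "C'": "L",
    "C''": "Y",
    "D": "S",
    "E": "L",
    "E+": "T",
    "F": "C",
    "G": "K",
    "G+": "V",
    "G++": "V",
}
_DEFAULT_AA = "T"


@dataclass
class SandwichModel:
    """A generated sandwich plus its ground truth.

    ``truth`` maps residue key -> (igs number or None, strand letter or
    loop/tail label); ``spec`` is the topology it was built from.
    """

    model: StructureModel
    truth: dict[tuple[str, int, str], tuple[int | None, str | None]]
    spec: TopologySpec

    def ca_trace(self) -> np.ndarray:
        return self.model.chains[0].ca_trace()

    def truth_numbers(self) -> list[int | None]:
        return [self.truth[r.key][0] for r in self.model.chains[0]]


def _sheet_y(sheet: int, column: int) -> float:
    return column * STRAND_SPACING + (SHEET0_STAGGER if sheet == 0 else 0.0)


def _strand_ca(strand, t: int) -> np.ndarray:
    x = strand.direction * (t - (strand.length - 1) / 2.0) * RISE
    return np.array([x, _sheet_y(strand.sheet, strand.column), strand.sheet * SHEET_SEP])


def _bezier(p: np.ndarray, q: np.ndarray, m: np.ndarray, n_points: int) -> list[np.ndarray]:
    """n_points interior samples of the quadratic Bezier p -> m -> q."""
    out = []
    for k in range(1, n_points + 1):
        t = k / (n_points + 1)
        out.append((1 - t) ** 2 * p + 2 * t * (1 - t) * m + t**2 * q)
    return out


def _loop_coords(p: np.ndarray, q: np.ndarray, n: int) -> list[np.ndarray]:
    if n == 0:
        return []
    need = LOOP_STEP * (n + 1)
    span = float(np.linalg.norm(q - p))
    bulge = 0.6 * math.sqrt(max(need**2 - span**2, 1.0)) + 1.0
    sign = 1.0 if (p[0] + q[0]) >= 0 else -1.0
    mid = (p + q) / 2.0
    m = mid + np.array([sign * bulge, 0.0, 0.0])
    return _bezier(p, q, m, n)


def truth_segments(spec: TopologySpec) -> list[StrandSegment]:
    """Strand segments (0-based residue indices) implied by a topology spec."""
    return [
        StrandSegment(
            letter=s.letter,
            start=a,
            end=b,
            anchor=a + s.anchor_offset,
            anchor_igs=s.anchor_igs,
        )
        for s, a, b in spec.strand_ranges()
    ]


def spec_numbering(spec: TopologySpec) -> tuple[list[int | None], list[str | None]]:
    """Ground-truth igs numbers and strand labels for every residue of a spec."""
    return propagate_numbers(spec.n_residues, truth_segments(spec))


def make_ideal_sandwich(
    spec: TopologySpec,
    seed: int = 0,
    chain_id: str = "A",
    model_id: str | None = None,
) -> SandwichModel:
    """Build the idealized sandwich for ``spec``.

    Deterministic for a fixed seed; the seed only drives a tiny (0.01 A)
    symmetry-breaking jitter so that no four atoms are exactly coplanar.
    """
    rng = np.random.default_rng(seed)
    n = spec.n_residues
    coords = np.zeros((n, 3))
    is_strand = np.zeros(n, dtype=bool)
    cb_side: dict[int, float] = {}

    ranges = spec.strand_ranges()
    for strand, a, b in ranges:
        for t in range(strand.length):
            idx = a + t
            coords[idx] = _strand_ca(strand, t)
            is_strand[idx] = True
            # in-facing side: toward the opposite sheet; anchors face in
            inward = 1.0 if strand.sheet == 0 else -1.0
            facing = inward if (t - strand.anchor_offset) % 2 == 0 else -inward
            cb_side[idx] = facing

    # coils between strands
    for k in range(len(ranges) - 1):
        s_prev, a0, b0 = ranges[k]
        s_next, a1, b1 = ranges[k + 1]
        n_loop = a1 - b0 - 1
        for off, pt in enumerate(_loop_coords(coords[b0], coords[a1], n_loop), start=1):
            coords[b0 + off] = pt

    # tails: continue along the terminal strand axes
    _, first_a, _ = ranges[0]
    first_strand = ranges[0][0]
    for t in range(1, spec.nterm + 1):
        coords[first_a - t] = coords[first_a] - np.array(
            [first_strand.direction * LOOP_STEP * t, 0.0, 1.2]
        )
    last_strand, _, last_b = ranges[-1]
    for t in range(1, spec.cterm + 1):
        coords[last_b + t] = coords[last_b] + np.array(
            [last_strand.direction * LOOP_STEP * t, 0.0, 1.2]
        )

    coords = coords + rng.normal(scale=0.01, size=coords.shape)

    numbers, labels = spec_numbering(spec)
    letter_of: dict[int, str] = {}
    for strand, a, b in ranges:
        for idx in range(a, b + 1):
            letter_of[idx] = strand.letter

    anchor_aa = {
        a + s.anchor_offset: ANCHOR_AA.get(s.letter, _DEFAULT_AA) for s, a, _ in ranges
    }
    residues = []
    for idx in range(n):
        aa = anchor_aa.get(idx, _DEFAULT_AA)
        atoms = [AtomRecord("CA", "C", coords[idx])]
        if is_strand[idx]:
            atoms.append(AtomRecord("CB", "C", coords[idx] + np.array([0, 0, 1.5 * cb_side[idx]])))
            atoms.append(AtomRecord("O", "O", coords[idx] + np.array([0, 1.2, 0.0])))
            atoms.append(AtomRecord("N", "N", coords[idx] + np.array([0, -1.2, 0.0])))
        residues.append(Residue(chain_id, idx + 1, "", aa, atoms))

    model = StructureModel(model_id or f"synth_{spec.name}", [Chain(chain_id, residues)])
    truth = {
        residues[idx].key: (numbers[idx], labels[idx]) for idx in range(n)
    }
    return SandwichModel(model=model, truth=truth, spec=spec)


def _apply_rigid(coords: np.ndarray, rot: np.ndarray, trans: np.ndarray) -> np.ndarray:
    return coords @ rot.T + trans


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (quaternion method)."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def perturb(
    sm: SandwichModel,
    sigma: float = 0.0,
    rigid: bool = False,
    seed: int = 0,
) -> SandwichModel:
    """Gaussian per-atom displacement (sigma, A) plus optional random rigid motion.

    Ground truth is unchanged: noise moves atoms, not identities.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    rot = random_rotation(rng) if rigid else np.eye(3)
    trans = rng.uniform(-20, 20, size=3) if rigid else np.zeros(3)
    chain = sm.model.chains[0]
    new_residues = []
    for res in chain:
        atoms = []
        for a in res.atoms:
            c = a.coord + (rng.normal(scale=sigma, size=3) if sigma > 0 else 0.0)
            atoms.append(AtomRecord(a.name, a.element, _apply_rigid(c[None, :], rot, trans)[0]))
        new_residues.append(Residue(res.chain_id, res.seq_num, res.icode, res.aa, atoms))
    model = StructureModel(sm.model.id, [Chain(chain.chain_id, new_residues)])
    truth = {r.key: sm.truth[r.key] for r in new_residues}
    return SandwichModel(model=model, truth=truth, spec=sm.spec)


def transform_model(sm: SandwichModel, rot: np.ndarray, trans: np.ndarray) -> SandwichModel:
    """Apply a fixed rigid transform to every atom."""
    chain = sm.model.chains[0]
    new_residues = []
    for res in chain:
        atoms = [
            AtomRecord(a.name, a.element, _apply_rigid(a.coord[None, :], rot, trans)[0])
            for a in res.atoms
        ]
        new_residues.append(Residue(res.chain_id, res.seq_num, res.icode, res.aa, atoms))
    model = StructureModel(sm.model.id, [Chain(chain.chain_id, new_residues)])
    return SandwichModel(model=model, truth=dict(sm.truth), spec=sm.spec)


def _rename_chain(sm: SandwichModel, chain_id: str) -> SandwichModel:
    chain = sm.model.chains[0]
    new_residues = [
        Residue(chain_id, r.seq_num, r.icode, r.aa, list(r.atoms)) for r in chain
    ]
    model = StructureModel(sm.model.id, [Chain(chain_id, new_residues)])
    truth = {
        (chain_id, k[1], k[2]): v for k, v in sm.truth.items()
    }
    return SandwichModel(model=model, truth=truth, spec=sm.spec)


INTERFACE_MODES = ("parallel_GFCC", "antiparallel_ABED", "gstrand_zipper")

_ROT_Y = np.diag([-1.0, 1.0, -1.0])  # 180 deg about y: sheets face, columns stay in register
_ROT_Z = np.diag([-1.0, -1.0, 1.0])  # 180 deg about z: in-plane flip for the strand zipper


def make_dimer(
    spec_a: TopologySpec,
    spec_b: TopologySpec,
    interface: str = "parallel_GFCC",
    gap: float = 4.5,
    seed: int = 0,
) -> tuple[SandwichModel, SandwichModel]:
    """Two sandwiches in one coordinate frame, facing through a chosen interface.

    ``gap`` is the separation between the facing Calpha planes (parallel and
    antiparallel modes) or between the abutting G-strand axes (zipper mode).
    Chain ids are A and B.
    """
    if interface not in INTERFACE_MODES:
        raise ValueError(f"unknown interface mode {interface!r}")

    def _require_sheet(spec: TopologySpec, sheet: int) -> None:
        if not any(s.sheet == sheet for s in spec.strands):
            raise ValueError(f"spec {spec.name!r} has no strands on sheet {sheet}")

    def _require_edge_g(spec: TopologySpec) -> None:
        edge = [s for s in spec.strands if s.sheet == 1 and s.column == 0]
        if not edge or edge[0].letter != "G":
            raise ValueError(
                f"spec {spec.name!r}: G strand must be the sheet-1 edge for a zipper"
            )

    a = _rename_chain(make_ideal_sandwich(spec_a, seed=seed, chain_id="A", model_id="dimer"), "A")
    b0 = make_ideal_sandwich(spec_b, seed=seed + 1, chain_id="B", model_id="dimer")

    if interface == "parallel_GFCC":
        _require_sheet(spec_a, 1)
        _require_sheet(spec_b, 1)
        rot, trans = _ROT_Y, np.array([0.0, 0.0, 2 * SHEET_SEP + gap])
    elif interface == "antiparallel_ABED":
        _require_sheet(spec_a, 0)
        _require_sheet(spec_b, 0)
        rot, trans = _ROT_Y, np.array([0.0, 0.0, -gap])
    else:  # gstrand_zipper
        _require_edge_g(spec_a)
        _require_edge_g(spec_b)
        rot, trans = _ROT_Z, np.array([0.0, -gap, 0.0])

    b = _rename_chain(transform_model(b0, rot, trans), "B")
    return a, b


def make_tandem(
    spec_a: TopologySpec,
    spec_b: TopologySpec,
    linker_len: int = 10,
    seed: int = 0,
    chain_id: str = "A",
) -> tuple[StructureModel, int]:
    """Two sandwiches on one chain, joined by an extended linker.

    Returns the combined single-chain model and the 0-based index of the
    first linker residue (the ground-truth domain boundary lies inside the
    linker).
    """
    a = make_ideal_sandwich(spec_a, seed=seed, chain_id=chain_id)
    b = make_ideal_sandwich(spec_b, seed=seed + 1, chain_id=chain_id)
    # place the second domain beyond the first, linked along +x
    target_start = a.ca_trace()[-1] + np.array([LOOP_STEP * (linker_len + 1), 0.0, 0.0])
    b = transform_model(b, np.eye(3), target_start - b.ca_trace()[0])

    residues: list[Residue] = []
    num = 1
    for res in a.model.chains[0]:
        residues.append(Residue(chain_id, num, "", res.aa, list(res.atoms)))
        num += 1
    boundary = num - 1  # 0-based index of the first linker residue
    p = a.ca_trace()[-1]
    q = b.ca_trace()[0]
    step = (q - p) / (linker_len + 1)
    for t in range(1, linker_len + 1):
        residues.append(
            Residue(chain_id, num, "", _DEFAULT_AA, [AtomRecord("CA", "C", p + step * t)])
        )
        num += 1
    for res in b.model.chains[0]:
        residues.append(Residue(chain_id, num, "", res.aa, list(res.atoms)))
        num += 1
    model = StructureModel("tandem", [Chain(chain_id, residues)])
    return model, boundary


def combine(*sms: SandwichModel, model_id: str = "complex") -> StructureModel:
    """Merge single-chain sandwich models (already in one frame) into one structure."""
    return StructureModel(model_id, [sm.model.chains[0] for sm in sms])


def make_helix_bundle(
    n_helices: int = 4,
    helix_len: int = 20,
    seed: int = 0,
    chain_id: str = "A",
) -> StructureModel:
    """All-alpha decoy: an idealized four-helix bundle (negative control)."""
    rng = np.random.default_rng(seed)
    rise, radius, turn = 1.5, 2.3, math.radians(100.0)
    centers = [(0.0, 0.0), (10.0, 0.0), (10.0, 10.0), (0.0, 10.0)]
    coords: list[np.ndarray] = []
    for h in range(n_helices):
        cx, cy = centers[h % len(centers)]
        direction = 1 if h % 2 == 0 else -1
        for t in range(helix_len):
            z = direction * (t - helix_len / 2) * rise
            ang = t * turn
            coords.append(
                np.array([cx + radius * math.cos(ang), cy + radius * math.sin(ang), z])
            )
        if h < n_helices - 1:
            p, q = coords[-1], None
            # short connector to the next helix start
            nxt_cx, nxt_cy = centers[(h + 1) % len(centers)]
            ang0 = 0.0
            q = np.array(
                [
                    nxt_cx + radius,
                    nxt_cy,
                    -direction * (helix_len / 2) * rise,
                ]
            )
            coords.extend(_loop_coords(p, q, 3))
    arr = np.array(coords) + rng.normal(scale=0.01, size=(len(coords), 3))
    residues = [
        Residue(chain_id, i + 1, "", "A", [AtomRecord("CA", "C", arr[i])])
        for i in range(len(arr))
    ]
    return StructureModel("helix_decoy", [Chain(chain_id, residues)])
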