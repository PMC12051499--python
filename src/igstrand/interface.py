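"""Ig-Ig interface contacts in IgStrand coordinates.

Residue-residue contacts between two numbered domains are found with a
heavy-atom distance criterion and typed (van der Waals, hydrogen bond,
ionic, pi-stacking, pi-cation, halogen bond).  Because both partners carry
IgStrand numbers, contacts from different structures land on the same
(igs_a, igs_b) keys and can be aggregated across a dataset without any
multiple alignment — conservation percentages, symmetric-contact detection
and interactome comparisons all operate on those keys directly.

Hydrogen-bond typing uses donor/acceptor heavy atoms only (no angle term):
deposited structures mostly lack hydrogens, so an N/O pair within the
H-bond distance is counted.  All cutoffs are configurable.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .model import Residue, ResidueKey
from .numbering import NumberedDomain

INTERACTION_TYPES = ("vdw", "hbond", "ionic", "pi_stacking", "pi_cation", "halogen")


@dataclass(frozen=True)
class ContactCriteria:
    """Distance cutoffs (A) for contact detection and interaction typing."""

    heavy_atom_cutoff: float = 4.0
    hbond_donor_acceptor_max: float = 3.5
    ionic_max: float = 4.0
    pi_centroid_max: float = 5.5
    pi_cation_max: float = 6.0
    halogen_max: float = 3.6

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"{f.name} must be positive")


@dataclass
class ResidueContact:
    igs_a: int | None
    igs_b: int | None
    key_a: ResidueKey
    key_b: ResidueKey
    aa_a: str
    aa_b: str
    types: frozenset[str]
    min_dist: float


# --- chemistry tables ---------------------------------------------------------

_DONOR_ACCEPTOR_ELEMENTS = {"N", "O"}
_HALOGEN_ELEMENTS = {"F", "CL", "BR", "I"}
_HALOGEN_TARGETS = {"N", "O", "S"}

#: positively charged side-chain groups (residue -> atom names)
_CATION_ATOMS = {
    "K": {"NZ"},
    "R": {"NH1", "NH2", "NE"},
    "H": {"ND1", "NE2"},
}
#: negatively charged side-chain groups
_ANION_ATOMS = {
    "D": {"OD1", "OD2"},
    "E": {"OE1", "OE2"},
}
#: aromatic ring atoms used for centroids
_RING_ATOMS = {
    "F": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "Y": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "W": {"CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"},
    "H": {"CG", "ND1", "CD2", "CE1", "NE2"},
}


def _ring_centroid(res: Residue) -> np.ndarray | None:
    names = _RING_ATOMS.get(res.aa)
    if not names:
        return None
    coords = [a.coord for a in res.atoms if a.name in names]
    if len(coords) < 3:
        return None
    return np.mean(coords, axis=0)


def _group_coords(res: Residue, table: dict) -> list[np.ndarray]:
    names = table.get(res.aa, ())
    return [a.coord for a in res.atoms if a.name in names]


def classify_interaction(
    res_a: Residue,
    res_b: Residue,
    criteria: ContactCriteria | None = None,
) -> frozenset[str]:
    """Interaction types between two residues already known to be in contact.

    ``vdw`` is always present; the polar/aromatic types are added when the
    corresponding groups fall within their cutoffs.
    """
    criteria = criteria or ContactCriteria()
    types = {"vdw"}
    heavy_a = res_a.heavy_atoms()
    heavy_b = res_b.heavy_atoms()

    def _mindist(coords_a, coords_b):
        if not coords_a or not coords_b:
            return np.inf
        ca = np.asarray(coords_a)
        cb = np.asarray(coords_b)
        return float(np.sqrt(((ca[:, None, :] - cb[None, :, :]) ** 2).sum(-1)).min())

    polar_a = [a.coord for a in heavy_a if a.element in _DONOR_ACCEPTOR_ELEMENTS]
    polar_b = [a.coord for a in heavy_b if a.element in _DONOR_ACCEPTOR_ELEMENTS]
    if _mindist(polar_a, polar_b) <= criteria.hbond_donor_acceptor_max:
        types.add("hbond")

    for cat_res, an_res in ((res_a, res_b), (res_b, res_a)):
        cat = _group_coords(cat_res, _CATION_ATOMS)
        an = _group_coords(an_res, _ANION_ATOMS)
        if _mindist(cat, an) <= criteria.ionic_max:
            types.add("ionic")
        ring = _ring_centroid(an_res)
        if cat and ring is not None and _mindist(cat, [ring]) <= criteria.pi_cation_max:
            types.add("pi_cation")

    ring_a = _ring_centroid(res_a)
    ring_b = _ring_centroid(res_b)
    if ring_a is not None and ring_b is not None:
        if float(np.linalg.norm(ring_a - ring_b)) <= criteria.pi_centroid_max:
            types.add("pi_stacking")

    halo_a = [a.coord for a in heavy_a if a.element in _HALOGEN_ELEMENTS]
    tgt_b = [a.coord for a in heavy_b if a.element in _HALOGEN_TARGETS]
    halo_b = [a.coord for a in heavy_b if a.element in _HALOGEN_ELEMENTS]
    tgt_a = [a.coord for a in heavy_a if a.element in _HALOGEN_TARGETS]
    if (
        _mindist(halo_a, tgt_b) <= criteria.halogen_max
        or _mindist(halo_b, tgt_a) <= criteria.halogen_max
    ):
        types.add("halogen")
    return frozenset(types)


def find_interface_contacts(
    domain_a: NumberedDomain,
    domain_b: NumberedDomain,
    residues_by_key: dict[ResidueKey, Residue],
    criteria: ContactCriteria | None = None,
) -> list[ResidueContact]:
    """Typed residue contacts between two numbered domains of one structure.

    A contact exists when any heavy-atom pair lies within the heavy-atom
    cutoff; each contact is reported once per ordered (a, b) residue pair.
    ``residues_by_key`` supplies the atomic residues for both domains
    (e.g. ``{r.key: r for r in model.residues()}``).
    """
    criteria = criteria or ContactCriteria()
    keys_a = list(domain_a.numbers)
    keys_b = list(domain_b.numbers)
    if set(keys_a) & set(keys_b):
        raise ValueError("interface domains must be disjoint residue sets")

    atoms_a, owner_a = [], []
    for i, key in enumerate(keys_a):
        for atom in residues_by_key[key].heavy_atoms():
            atoms_a.append(atom.coord)
            owner_a.append(i)
    atoms_b, owner_b = [], []
    for j, key in enumerate(keys_b):
        for atom in residues_by_key[key].heavy_atoms():
            atoms_b.append(atom.coord)
            owner_b.append(j)
    if not atoms_a or not atoms_b:
        return []

    tree_b = cKDTree(np.asarray(atoms_b))
    pairs_min: dict[tuple[int, int], float] = {}
    for ia, coord in enumerate(np.asarray(atoms_a)):
        for ib in tree_b.query_ball_point(coord, criteria.heavy_atom_cutoff):
            d = float(np.linalg.norm(coord - atoms_b[ib]))
            key = (owner_a[ia], owner_b[ib])
            if d < pairs_min.get(key, np.inf):
                pairs_min[key] = d

    out: list[ResidueContact] = []
    for (i, j), dmin in sorted(pairs_min.items()):
        ka, kb = keys_a[i], keys_b[j]
        ra, rb = residues_by_key[ka], residues_by_key[kb]
        out.append(
            ResidueContact(
                igs_a=domain_a.numbers[ka],
                igs_b=domain_b.numbers[kb],
                key_a=ka,
                key_b=kb,
                aa_a=ra.aa,
                aa_b=rb.aa,
                types=classify_interaction(ra, rb, criteria),
                min_dist=dmin,
            )
        )
    return out


# --- dataset aggregation ------------------------------------------------------


@dataclass
class ConservationProfile:
    """Occurrence of (igs_a, igs_b) contacts across a dataset of structures."""

    dataset_id: str
    n_structures: int
    rows: pd.DataFrame  # indexed by (igs_a, igs_b)

    def filtered(self, threshold_percent: float) -> pd.DataFrame:
        return self.rows[self.rows["percent"] >= threshold_percent]

    def pair_set(self, threshold_percent: float) -> set[tuple[int, int]]:
        return set(self.filtered(threshold_percent).index)


def _residue_label(counter: Counter) -> str:
    """Tables-style residue label: types by descending frequency, e.g. "L/P"."""
    ranked = sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))
    return "/".join(aa for aa, _ in ranked)


def aggregate_dataset(
    interfaces: list[list[ResidueContact]],
    dataset_id: str = "dataset",
) -> ConservationProfile:
    """Aggregate per-structure contact lists into a conservation profile.

    Contacts must be expressed in igs# (contacts on undefined residues are
    skipped); aggregation is alignment-free and order-invariant.
    """
    if not interfaces:
        raise ValueError("empty dataset")
    n = len(interfaces)
    count: Counter = Counter()
    type_counts: dict[tuple[int, int], Counter] = defaultdict(Counter)
    aa_a: dict[tuple[int, int], Counter] = defaultdict(Counter)
    aa_b: dict[tuple[int, int], Counter] = defaultdict(Counter)
    for contacts in interfaces:
        seen: set[tuple[int, int]] = set()
        for c in contacts:
            if c.igs_a is None or c.igs_b is None:
                continue
            key = (c.igs_a, c.igs_b)
            if key in seen:
                continue
            seen.add(key)
            count[key] += 1
            aa_a[key][c.aa_a] += 1
            aa_b[key][c.aa_b] += 1
            for t in c.types:
                type_counts[key][t] += 1

    records = []
    for key in sorted(count):
        rec = {
            "igs_a": key[0],
            "igs_b": key[1],
            "count": count[key],
            "percent": 100.0 * count[key] / n,
            "aa_a": _residue_label(aa_a[key]),
            "aa_b": _residue_label(aa_b[key]),
        }
        for t in INTERACTION_TYPES:
            rec[t] = type_counts[key].get(t, 0)
        records.append(rec)
    df = pd.DataFrame.from_records(records)
    if len(df):
        df = df.set_index(["igs_a", "igs_b"])
    else:
        df = pd.DataFrame(
            columns=["count", "percent", "aa_a", "aa_b", *INTERACTION_TYPES],
            index=pd.MultiIndex.from_arrays([[], []], names=["igs_a", "igs_b"]),
        )
    return ConservationProfile(dataset_id=dataset_id, n_structures=n, rows=df)


def find_symmetric_pairs(
    profile: ConservationProfile,
    threshold_percent: float = 70.0,
) -> list[tuple[int, int]]:
    """Symmetric contact families above a threshold.

    (x, y) is symmetric when (y, x) also passes, or when x == y; each family
    is reported once with x <= y.
    """
    passing = profile.pair_set(threshold_percent)
    out = set()
    for x, y in passing:
        if x == y or (y, x) in passing:
            out.add((min(x, y), max(x, y)))
    return sorted(out)


def compare_interactomes(
    profiles: list[ConservationProfile],
    threshold_percent: float = 70.0,
    order_normalize: bool = False,
) -> dict:
    """Shared and distinct contact keys across conservation profiles.

    ``order_normalize`` sorts each (igs_a, igs_b) pair, for comparing
    homodimer interfaces where the partner order is arbitrary.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two profiles to compare")

    def norm(keys):
        if order_normalize:
            return {(min(a, b), max(a, b)) for a, b in keys}
        return set(keys)

    sets = [norm(p.pair_set(threshold_percent)) for p in profiles]
    shared = set.intersection(*sets)
    return {
        "shared": sorted(shared),
        "distinct": {
            p.dataset_id: sorted(s - shared) for p, s in zip(profiles, sets)
        },
    }
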