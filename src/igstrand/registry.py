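"""The annotated template registry.

A registry holds the reference set of Ig-fold topo-structural variant
templates that drives detection and numbering: each template carries its
strand annotations (letter, hundreds/thousands digits, residue range,
anchor residue) and a Calpha trace, and belongs to exactly one structural
cluster; each cluster has one representative used in the first detection
step.

The packaged default registry mirrors the published reference set: 55
templates in 16 clusters, annotated with per-strand anchors.  Its
coordinates are synthetic — idealized sandwich geometry generated
deterministically from each cluster's topology spec — because shipping
experimental coordinates is not practical here; the strand annotations and
anchors are consistent with those generated coordinates by construction.
Users can point ``load_registry`` at their own directory of real template
structures instead.
"""

from __future__ import annotations

import csv
import zlib
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .align import AlignParams, align_structures
from .refnum import StrandSegment, propagate_numbers
from .synth import make_ideal_sandwich, perturb
from .topologies import TOPOLOGIES, SIGNATURE_STRANDS

#: noise (A) added to generated template coordinates so templates of one
#: cluster are near- but not exactly identical
_TEMPLATE_SIGMA = 0.15

IG_TYPES = ("IgV", "IgC1", "IgC2", "IgI", "IgE", "IgFN3", "IgFN3-like", "other-Ig")
TEMPLATE_CLASSES = ("Ig", "Ig-like", "Ig-extended")


class RegistryError(ValueError):
    pass


@dataclass(frozen=True)
class StrandAnnotation:
    """One annotated strand of a template (residue indices are 1-based)."""

    letter: str
    i_digit: int
    j_digit: int
    start: int
    end: int
    anchor: int

    def __post_init__(self) -> None:
        if not self.start <= self.anchor <= self.end:
            raise RegistryError(
                f"strand {self.letter}: anchor {self.anchor} outside {self.start}..{self.end}"
            )
        if not (1 <= self.i_digit <= 9 and 1 <= self.j_digit <= 9):
            raise RegistryError(f"strand {self.letter}: digits out of range")

    @property
    def anchor_igs(self) -> int:
        return self.i_digit * 1000 + self.j_digit * 100 + 50


@dataclass
class IgTemplate:
    """An annotated reference structure."""

    template_id: str
    protein: str
    pdb_id: str
    chain: str
    ig_type: str
    template_class: str
    scop_label: str
    cluster_id: int
    strands: list[StrandAnnotation]
    ca_trace: np.ndarray
    topology: str = ""
    comment: str = ""

    def __post_init__(self) -> None:
        letters = {s.letter for s in self.strands}
        missing = [x for x in SIGNATURE_STRANDS if x not in letters]
        if missing:
            raise RegistryError(
                f"template {self.template_id}: missing signature strands {missing}"
            )
        ordered = sorted(self.strands, key=lambda s: s.start)
        for a, b in zip(ordered, ordered[1:]):
            if a.end >= b.start:
                raise RegistryError(
                    f"template {self.template_id}: strands {a.letter}/{b.letter} overlap"
                )
        if self.strands and max(s.end for s in self.strands) > len(self.ca_trace):
            raise RegistryError(
                f"template {self.template_id}: strand range beyond trace length"
            )

    @property
    def n_residues(self) -> int:
        return len(self.ca_trace)

    def segments(self) -> list[StrandSegment]:
        """Strand segments in 0-based residue indices."""
        return [
            StrandSegment(
                letter=s.letter,
                start=s.start - 1,
                end=s.end - 1,
                anchor=s.anchor - 1,
                anchor_igs=s.anchor_igs,
            )
            for s in sorted(self.strands, key=lambda s: s.start)
        ]

    def numbering(self) -> tuple[list[int | None], list[str | None]]:
        """The template's own igs numbers and strand labels, per residue."""
        return propagate_numbers(self.n_residues, self.segments())

    def anchor_indices(self) -> dict[str, int]:
        """strand letter -> 0-based residue index of its anchor."""
        return {s.letter: s.anchor - 1 for s in self.strands}

    def number_range(self) -> tuple[int, int]:
        nums = [x for x in self.numbering()[0] if x is not None]
        return min(nums), max(nums)


@dataclass
class TemplateRegistry:
    templates: list[IgTemplate]
    representatives: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [t.template_id for t in self.templates]
        if len(set(ids)) != len(ids):
            raise RegistryError("duplicate template ids")
        self._by_id = {t.template_id: t for t in self.templates}
        clusters = self.clusters
        for cid, members in clusters.items():
            if not members:
                raise RegistryError(f"cluster {cid} is empty")
        if not self.representatives:
            self.representatives = {
                cid: sorted(members)[0] for cid, members in clusters.items()
            }
        if set(self.representatives) != set(clusters):
            raise RegistryError("representatives do not cover the clusters exactly")
        for cid, rep in self.representatives.items():
            if rep not in clusters[cid]:
                raise RegistryError(f"representative {rep} not in cluster {cid}")

    @property
    def clusters(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for t in self.templates:
            out.setdefault(t.cluster_id, []).append(t.template_id)
        return {cid: sorted(members) for cid, members in sorted(out.items())}

    def __len__(self) -> int:
        return len(self.templates)

    def __getitem__(self, template_id: str) -> IgTemplate:
        return self._by_id[template_id]

    def __contains__(self, template_id: str) -> bool:
        return template_id in self._by_id

    def representative_templates(self) -> list[IgTemplate]:
        return [self._by_id[self.representatives[cid]] for cid in sorted(self.representatives)]

    def cluster_members(self, cluster_id: int) -> list[IgTemplate]:
        return [self._by_id[tid] for tid in self.clusters[cluster_id]]

    def subset(self, template_ids: list[str]) -> "TemplateRegistry":
        """A registry restricted to the given templates (clusters recomputed)."""
        keep = [self._by_id[tid] for tid in template_ids]
        return TemplateRegistry(templates=keep)


def template_seed(template_id: str) -> int:
    """Deterministic per-template seed (stable across sessions)."""
    return zlib.crc32(template_id.encode()) % (2**31)


def synthesize_trace(topology: str, template_id: str) -> np.ndarray:
    """Generate the synthetic Calpha trace for a packaged template."""
    spec = TOPOLOGIES[topology]
    seed = template_seed(template_id)
    sm = make_ideal_sandwich(spec, seed=seed, model_id=template_id)
    sm = perturb(sm, sigma=_TEMPLATE_SIGMA, rigid=False, seed=seed + 1)
    return sm.ca_trace()


def _read_tsv(path: Path) -> list[dict]:
    with open(path) as fh:
        return list(csv.DictReader(fh, delimiter="\t"))


def load_registry(path: str | Path | None = None) -> TemplateRegistry:
    """Load a registry directory; ``None`` loads the packaged default.

    A registry directory holds ``templates.tsv`` (one row per template),
    ``annotations.tsv`` (one row per strand) and ``clusters.tsv`` (one row
    per cluster with its representative).  Coordinates come from a
    ``<template_id>.pdb`` file when present, otherwise they are synthesized
    from the template's ``topology`` column.
    """
    if path is None:
        base = resources.files("igstrand").joinpath("data")
        with resources.as_file(base) as p:
            return _load_from_dir(Path(p))
    return _load_from_dir(Path(path))


def _load_from_dir(root: Path) -> TemplateRegistry:
    tpath, apath, cpath = (root / n for n in ("templates.tsv", "annotations.tsv", "clusters.tsv"))
    for p in (tpath, apath):
        if not p.exists():
            raise RegistryError(f"registry file missing: {p}")
    strand_rows: dict[str, list[dict]] = {}
    for row in _read_tsv(apath):
        strand_rows.setdefault(row["template_id"], []).append(row)

    templates: list[IgTemplate] = []
    for row in _read_tsv(tpath):
        tid = row["template_id"]
        rows = strand_rows.get(tid)
        if not rows:
            raise RegistryError(f"template {tid}: no strand annotations")
        strands = []
        for r in rows:
            if not r.get("anchor", "").strip():
                raise RegistryError(f"template {tid}, strand {r['letter']}: missing anchor")
            strands.append(
                StrandAnnotation(
                    letter=r["letter"],
                    i_digit=int(r["i_digit"]),
                    j_digit=int(r["j_digit"]),
                    start=int(r["start"]),
                    end=int(r["end"]),
                    anchor=int(r["anchor"]),
                )
            )
        pdb_file = root / f"{tid}.pdb"
        if pdb_file.exists():
            from .io import read_structure

            trace = read_structure(pdb_file).chains[0].ca_trace()
        else:
            if not row.get("topology"):
                raise RegistryError(f"template {tid}: no coordinates and no topology")
            trace = synthesize_trace(row["topology"], tid)
        templates.append(
            IgTemplate(
                template_id=tid,
                protein=row.get("protein", ""),
                pdb_id=row.get("pdb_id", ""),
                chain=row.get("chain", ""),
                ig_type=row.get("ig_type", "other-Ig"),
                template_class=row.get("template_class", "Ig"),
                scop_label=row.get("scop", ""),
                cluster_id=int(row["cluster_id"]),
                strands=strands,
                ca_trace=trace,
                topology=row.get("topology", ""),
                comment=row.get("comment", ""),
            )
        )

    representatives: dict[int, str] = {}
    if cpath.exists():
        for row in _read_tsv(cpath):
            representatives[int(row["cluster_id"])] = row["representative_id"]
    return TemplateRegistry(templates=templates, representatives=representatives)


@lru_cache(maxsize=1)
def default_registry() -> TemplateRegistry:
    return load_registry(None)


# --- clustering ---------------------------------------------------------------


def pairwise_tm_distance(
    registry: TemplateRegistry,
    params: AlignParams | None = None,
) -> tuple[np.ndarray, list[str]]:
    """All-vs-all distance d = 1 - TM between templates.

    The TM-score of each ordered pair is template-length normalized; the
    pair distance uses the larger of the two directions (``d = 1 - max``),
    making the matrix symmetric.
    """
    ids = [t.template_id for t in registry.templates]
    n = len(ids)
    dist = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            ta, tb = registry.templates[a], registry.templates[b]
            r_ab = align_structures(ta.ca_trace, tb.ca_trace, params)
            r_ba = align_structures(tb.ca_trace, ta.ca_trace, params)
            tm = max(r_ab.tm_by_template, r_ba.tm_by_template)
            dist[a, b] = dist[b, a] = 1.0 - tm
    return dist, ids


def cluster_templates(
    registry: TemplateRegistry,
    k: int,
    method: str = "average",
    distance: np.ndarray | None = None,
) -> dict[str, int]:
    """Agglomerative clustering of templates on d = 1 - TM, cut at k clusters.

    Returns template_id -> cluster label (1..k).  ``distance`` may carry a
    precomputed matrix (ordered like ``registry.templates``).
    """
    n = len(registry)
    if k > n:
        raise RegistryError(f"k={k} exceeds the number of templates ({n})")
    if distance is None:
        distance, ids = pairwise_tm_distance(registry)
    else:
        ids = [t.template_id for t in registry.templates]
    if n == 1:
        return {ids[0]: 1}
    z = linkage(squareform(distance, checks=False), method=method)
    labels = fcluster(z, t=k, criterion="maxclust")
    return dict(zip(ids, (int(x) for x in labels)))


def select_representatives(
    registry: TemplateRegistry,
    distance: np.ndarray | None = None,
) -> dict[int, str]:
    """Medoid of each cluster: minimal mean distance to the other members.

    Ties are broken by lexicographic template id.  With ``distance`` absent
    the all-vs-all TM distances are computed (slow for large registries).
    """
    if distance is None:
        distance, ids = pairwise_tm_distance(registry)
    else:
        ids = [t.template_id for t in registry.templates]
    pos = {tid: i for i, tid in enumerate(ids)}
    out: dict[int, str] = {}
    for cid, members in registry.clusters.items():
        if len(members) == 1:
            out[cid] = members[0]
            continue
        best = None
        for tid in sorted(members):
            others = [pos[m] for m in members if m != tid]
            mean_d = float(np.mean([distance[pos[tid], j] for j in others]))
            if best is None or mean_d < best[0] - 1e-12:
                best = (mean_d, tid)
        out[cid] = best[1]
    return out


def partitions_equal(a: dict[str, int], b: dict[str, int]) -> bool:
    """True when two cluster assignments agree up to relabeling."""
    if set(a) != set(b):
        return False
    groups_a = {}
    groups_b = {}
    for key in a:
        groups_a.setdefault(a[key], set()).add(key)
        groups_b.setdefault(b[key], set()).add(key)
    return {frozenset(g) for g in groups_a.values()} == {frozenset(g) for g in groups_b.values()}
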