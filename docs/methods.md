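# Methods

## The numbering model

An Ig-fold domain is modeled as an ordered set of β-strands on the two
sheets of a sandwich, each strand carrying one structurally conserved
*anchor* position. The reference number of a residue is `ijxx`:
thousands digit `i` = canonical strand family (A…G → 1…9), hundreds digit
`j` = insertion slot (5 canonical, 8 for the split A′ strand, 4/6…
for strands inserted before/after a canonical strand), and `xx` counted
from the anchor at 50. Anchors therefore sit at 1550, 2550, …, 9550 for
the nine canonical strands, 1850 for A′, 1450 for A⁻, 1650 for A⁺, 9650
for G⁺, and so on.

Assignment has two stages:

1. **Anchor transfer.** The query domain is structurally aligned to an
   annotated template; the query residue aligned with each template
   anchor receives that anchor's `ij50`. If an anchor column is a gap
   (anchor dropout), the anchor index is extrapolated from the nearest
   aligned residue of the same strand and a warning is logged; a domain
   with fewer than half its anchors directly matched is flagged low
   confidence.
2. **Propagation.** Within each strand, numbers run ±1 per residue from
   the anchor. For a coil of length *n* between two strands, the first
   ⌈n/2⌉ residues continue forward from the preceding strand and the
   remaining ⌊n/2⌋ count backward from the following strand (the extra
   residue of an odd coil goes to the N-terminal half — a deterministic
   choice the verbal rule "first half / second half" leaves open).
   Residues before the first and after the last strand count outward.
   A number that would leave its strand's hundreds block (below `ij00`
   or above `ij99`), fall outside the template's own covered number
   range, or break strict monotonicity is left undefined rather than
   invented. Undefined numbers are reported as `NA`.

The same propagation routine produces a template's own numbering from its
strand annotations, which is what makes template and query numberings
directly comparable and makes aggregation across structures
alignment-free: two residues with the same `ijxx` occupy the same
structural position by construction.

## Detection

Chains are first split into candidate segments by recursive bisection of
the Cα contact map (8 Å edges, ±2 sequence neighbors excluded): a split
is accepted when its normalized cut falls below 0.20 and both parts keep
at least `min_segment` = 50 residues. The splitter is a stand-in for an
unspecified 3D-domain parser and is validated only against the synthetic
generator's ground-truth boundaries.

Each segment then goes through the two-step template search: alignment
against the 16 cluster representatives; if the best representative scores
TM > 0.85 (`tm_cluster_shortcut`) only that cluster's templates enter the
second pass, otherwise all templates of the five best clusters do. The
best second-pass template accepts the domain when its template-normalized
TM exceeds `tm_accept` = 0.4. Accepted residues (the aligned span) are
masked and the search repeats on the flanking remainders (≥ 20 residues)
until nothing new is found or `max_iterations` = 20 is reached — each
iteration strictly shrinks the unassigned residue set, so termination is
guaranteed. TM-scores are normalized by template length throughout
detection: the permissive choice that lets a small domain inside a long
segment clear the threshold; both normalizations are reported on every
alignment result.

## The alignment kernel

Superposition is least-squares (Kabsch/SVD). The aligner is a
deterministic TM-align-style heuristic: seed correspondences from
(a) gapless threading at every offset (top 3 kept after scoring),
(b) paired strand segments of the two Cα-geometry secondary-structure
strings, and (c) the best RMSD local fragments (length 20, stride 4,
top 2); each seed is refined by alternating superposition with
semi-global dynamic programming under the score `1/(1+(d/d0)²)` and a
gap-open penalty of 0.6 (no gap-extension term), to convergence or 10
rounds. `d0(L) = 1.24·(L−15)^⅓ − 1.8`, floored at 0.5 Å. The final
TM-score maximizes over superpositions fitted on shrinking close-pair
subsets (all pairs, then d ≤ 8, 5, max(d0, 2) Å). There is no randomness
anywhere in the kernel; equal-scoring seeds resolve to the earliest query
offset, and template ties within 1e-4 TM resolve to more matched anchors,
then lexicographic template id. An external TM-align binary can be
invoked as a cross-check backend when available; its absence is a clean
error and never blocks the internal kernel.

## The template registry

The packaged registry holds 55 templates in 16 clusters with per-strand
annotations (letter, digits, residue range, anchor). The roster
transcribes the published reference set of topo-structural variants;
three entries marked `supplement` in the comment column are synthetic
additions completing the documented roster size. Because experimental
coordinates cannot be shipped here, each template's Cα trace is generated
at load time from its cluster's idealized topology spec plus a small
(0.15 Å) deterministic per-template perturbation; the strand annotations
are consistent with those coordinates by construction, and anchors sit
mid-strand, consistent with the described anchor criteria (B/F anchors at
the disulfide cysteine position, C anchor at the core tryptophan, E
anchor at the leucine packing against it, D/E anchors shifted off the
B-strand register). Per-template anchor residue numbers for the
experimental structures are not published, so a user registry of real
templates must supply its own `annotations.tsv`; `load_registry` accepts
any directory of `templates.tsv` + `annotations.tsv` (+ optional
`<id>.pdb` coordinate files) and validates all invariants at load.

Clustering is average-linkage agglomerative on `d = 1 − TM` (pairwise,
template-normalized, symmetrized by the larger of the two directions),
cut at k clusters; the shipped 16-cluster assignment is authoritative and
re-clustering is a convenience. Representatives are cluster medoids
(minimal mean distance, ties lexicographic).

## The synthetic generator

Fixtures are idealized, not physical: flat antiparallel sheets with a
3.4 Å Cα rise, 4.8 Å strand spacing, 10 Å sheet separation and a 2.4 Å
lateral stagger between the sheets; coils are Bézier arcs; a 0.01 Å
jitter breaks exact degeneracies. Side chains are minimal pseudo-atom
sets sufficient for contact typing: a CB 1.5 Å toward the alternating
in/out face (anchors face in) and backbone N/O pseudo-atoms displaced
±1.2 Å laterally in the sheet plane, where β-sheet backbone hydrogen
bonds actually point. Dimers place a partner copy against the GFCC′
face (parallel), the ABED face (antiparallel), or edge-to-edge along the
G strands (zipper), at a configurable gap; `gap` is the separation of
the facing Cα planes (or G-strand axes), so heavy-atom contacts appear
for gaps up to ~5 Å and vanish by 15 Å. An all-α four-helix bundle
serves as the negative control.

What passing tests on these fixtures shows: the detection thresholds,
anchor transfer, propagation rules, masking, and interface aggregation
behave as specified under realistic noise (σ up to 0.5 Å on atoms, random
rigid placement). What they do not show: robustness to real structural
idiosyncrasy — sheet twist, β-bulges, strand swaps, disorder, missing
residues — nor variant-type labeling accuracy, which is inherently
limited by template fit. Domain-type labels are therefore surfaced with a
confidence field rather than trusted blindly.

## Interface analysis

A residue contact exists when any heavy-atom pair between two disjoint
numbered domains lies within 4.0 Å. Types: hydrogen bond if a N/O pair is
within 3.5 Å (no angle term — deposited structures rarely resolve
hydrogens); ionic if opposite formally charged side-chain groups (Lys NZ,
Arg NH*/NE, His ring N vs Asp OD*, Glu OE*) are within 4.0 Å;
π-stacking if aromatic ring centroids (Phe/Tyr/Trp/His) are within
5.5 Å; π-cation if a cationic group is within 6.0 Å of a ring centroid;
halogen if a halogen atom is within 3.6 Å of N/O/S; van der Waals always.
These numeric cutoffs are this package's defaults — standard
structural-biology practice, fully exposed in `ContactCriteria` —
because the upstream analysis tool does not publish its internal
criterion; counts on real datasets are therefore comparable only up to
that choice. Aggregation keys contacts by `(igs_a, igs_b)`, counts each
key once per structure, and reports occurrence percentages with
frequency-ordered residue labels ("L/P"); heterodimer profiles keep the
first-listed partner as side *a*, homodimer comparisons can be
order-normalized.

## Problem sizes

The shipped tests and the acceptance script run entirely on synthetic
fixtures: single domains of 80–110 residues, dimers of ~200 residues,
datasets of 3–12 interfaces, 20-seed recovery sweeps, and registry
subsets of ≤ 10 templates for the re-clustering check — sizes chosen so
the whole suite completes in minutes on one core while still exercising
every code path at realistic noise levels.

## Known limitations

* Inserted strands present in a query but absent from the winning
  template are numbered as loop continuations; de-novo anchor placement
  for such strands is out of scope.
* The sheet identity of a strand is not encoded in the number.
* Jelly-roll nomenclature, sequence-only numbering, multi-model
  ensembles (only model 1 is read), nucleic acids and ligands are out of
  scope; biological assemblies must be pre-expanded.
* H-bond typing without an angle term over-counts marginally at the
  3.4–3.5 Å boundary.
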