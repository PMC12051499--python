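# igstrand

A universal, anchor-based residue numbering scheme for protein domains that
share the immunoglobulin fold — Ig, Ig-like and Ig-extended β-sandwich
domains — together with the machinery to apply it: template-based domain
detection by structural alignment, per-residue number assignment, and
alignment-free analysis of Ig–Ig interfaces.

## Who this is for

Structural bioinformaticians and antibody/receptor engineers who need to
compare *positions* across Ig domains that differ wildly in sequence,
strand topology and length: VH vs VL vs CD8 vs a lamin tail domain. The
classical numbering schemes (Kabat for antibody variable domains,
Ballesteros–Weinstein for GPCRs) solve this for one fixed topology; the
Ig fold needs a scheme that survives strand insertions, splits and swaps.

## The scheme

Every residue of a detected Ig domain receives a four-digit number `ijxx`:

* `i` (thousands) — the canonical strand, A…G numbered 1…9
  (A, B, C, C′, C″, D, E, F, G);
* `j` (hundreds) — the insertion slot: 5 for canonical strands, 8 for the
  split A′ strand, stepping below/above 5 for strands inserted before/after
  a canonical strand (A⁻ → 14xx, A⁺ → 16xx, G⁺ → 96xx, …);
* `xx` — the position within the strand, counted from the structurally
  conserved **anchor** residue of each strand, which is always `50`.

So the B-strand anchor (the disulfide cysteine in most canonical domains)
is 2550, the C-strand tryptophan is 3550, the residue right before the
A-strand anchor is 1549 and the one right after is 1551. Anchors are
assigned by structural alignment to an annotated template, then numbers
propagate ±1 per residue along the sequence; coil residues inherit numbers
half-forward from the preceding strand and half-backward from the
following one, so the numbering is continuous and strictly increasing
along the domain.

Detection uses a two-step TM-score template search against a packaged
registry of 55 annotated topo-structural variant templates grouped into 16
clusters: a query segment is aligned to the 16 cluster representatives
first; the winning cluster (TM > 0.85) or the top five clusters supply the
templates for the second pass, and a domain is accepted when the best
template-normalized TM-score exceeds 0.4. Accepted residues are masked and
detection repeats on the rest of the chain.

The packaged registry's strand annotations follow the published reference
set; its coordinates are synthetic idealized β-sandwich geometry generated
deterministically at load time (see `docs/methods.md`). Point
`load_registry()` at a directory of your own template structures to use
experimental coordinates.

## Worked example

```python
from igstrand import default_registry, make_ideal_sandwich, number_chain
from igstrand.topologies import IGV

fixture = make_ideal_sandwich(IGV, seed=7)           # synthetic 9-strand IgV
registry = default_registry()
dom = number_chain(fixture.model.chains[0], registry)[0]
for key, igs in sorted(dom.anchors().items(), key=lambda kv: kv[1]):
    print(key[1], dom.strand_of[key], igs)
```

prints the ten anchors of a canonical variable domain:

```
  5 A    1550
 13 A'   1850
 23 B    2550
 35 C    3550
 45 C'   4550
 54 C''  5550
 63 D    6550
 73 E    7550
 83 F    8550
 95 G    9550
```

i.e. one `ij50` anchor per strand, with the split A′ strand on 1850.
Interface analysis then works directly on these coordinates — a conserved
contact `(3553, 3553)` means "three past the C-strand anchor, on both
partners" in *any* pair of Ig domains, with no multiple alignment anywhere:

```bash
python examples/interface_contacts.py
python examples/dataset_profile.py
```

The `examples/` directory holds one short narrative script per capability
(numbering, interface contacts, dataset aggregation, registry
clustering), and the `igstrand` command exposes the same pipeline from the
shell (`igstrand number INPUT.pdb`, `igstrand interface`, `igstrand
dataset`, `igstrand synth`, `igstrand registry`).

## Scope

The package analyzes observed structures only: no interface prediction, no
energetics, no sequence-only numbering, and no de-novo anchor discovery
for unannotated templates. Strands inserted in a query but absent from the
winning template are numbered as loop continuations.
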