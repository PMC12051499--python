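"""Aggregate interfaces across a small synthetic dataset.

Numbers several noisy copies of an IgV:IgV dimer, pools their contacts by
(igs_a, igs_b) key, and prints the conservation profile with symmetric
contact families - the alignment-free workflow used for comparing
interfaces across many structures.
"""

from igstrand.interface import (
    aggregate_dataset,
    compare_interactomes,
    find_interface_contacts,
    find_symmetric_pairs,
)
from igstrand.numbering import number_chain
from igstrand.registry import default_registry
from igstrand.synth import combine, make_dimer
from igstrand.topologies import IGV

registry = default_registry()

def one_interface(seed):
    a, b = make_dimer(IGV, IGV, "parallel_GFCC", gap=4.5, seed=seed)
    model = combine(a, b)
    da = number_chain(model.chain("A"), registry)[0]
    db = number_chain(model.chain("B"), registry)[0]
    residues = {r.key: r for r in model.residues()}
    return find_interface_contacts(da, db, residues)

interfaces = [one_interface(seed) for seed in range(4)]
profile = aggregate_dataset(interfaces, dataset_id="synthetic_parallel")

conserved = profile.filtered(70.0)
print(f"{profile.n_structures} structures; {len(conserved)} pairs conserved at the 70% threshold")
print(conserved[["count", "percent", "aa_a", "aa_b", "vdw", "hbond"]].head(10))

sym = find_symmetric_pairs(profile, 70.0)
print(f"\nsymmetric contact families (C2 pseudo-symmetry of the dimer): {sym[:8]}")

# comparing two interactomes: shared keys survive the intersection
profile2 = aggregate_dataset([one_interface(seed) for seed in range(10, 13)], "second_set")
out = compare_interactomes([profile, profile2], threshold_percent=70.0)
print(f"\npairs shared by both datasets at 70%: {len(out['shared'])}")
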