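"""Reference-number propagation, domain detection and assignment."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from igstrand.numbering import (
    DetectionParams,
    assign_reference_numbers,
    classify_domain,
    detect_ig_domains,
    number_chain,
    split_into_domains,
)
from igstrand.refnum import StrandSegment, propagate_numbers
from igstrand.registry import synthesize_trace
from igstrand.synth import (
    make_helix_bundle,
    make_ideal_sandwich,
    make_tandem,
    perturb,
    random_rotation,
    spec_numbering,
    transform_model,
)
from igstrand.model import AtomRecord, Chain, Residue, StructureModel
from igstrand.topologies import IGC1, IGV, TOPOLOGIES


class TestPropagation:
    def test_anchor_neighbours(self):
        """The residue right before an anchor gets xx49, right after xx51."""
        nums, labels = spec_numbering(IGV)
        a_anchor = nums.index(1550)
        assert nums[a_anchor - 1] == 1549
        assert nums[a_anchor + 1] == 1551

    def test_canonical_anchor_sets(self):
        nums_v, _ = spec_numbering(IGV)
        anchors_v = {x for x in nums_v if x is not None and x % 100 == 50}
        assert anchors_v == {1550, 1850, 2550, 3550, 4550, 5550, 6550, 7550, 8550, 9550}
        nums_c1, _ = spec_numbering(IGC1)
        anchors_c1 = {x for x in nums_c1 if x is not None and x % 100 == 50}
        # 7-strand constant domain: no C'/C'' anchors
        assert anchors_c1 == {1550, 2550, 3550, 6550, 7550, 8550, 9550}

    def test_coil_halves_split_ceil_floor(self):
        """5-residue coil: 3 go forward from B, 2 count back from C.

        Hand check: B spans 0-4 (anchor 2, 2550) so B ends at 2552; C spans
        10-14 (anchor 12, 3550) so C starts at 3548.  Coil indices 5..9 get
        2553, 2554, 2555 then 3546, 3547.
        """
        segs = [
            StrandSegment("B", 0, 4, 2, 2550),
            StrandSegment("C", 10, 14, 12, 3550),
        ]
        nums, labels = propagate_numbers(15, segs)
        assert nums == [2548, 2549, 2550, 2551, 2552,
                        2553, 2554, 2555, 3546, 3547,
                        3548, 3549, 3550, 3551, 3552]
        assert labels[5] == "loop" and labels[9] == "loop"

    def test_tails_count_outward(self):
        segs = [StrandSegment("B", 2, 6, 4, 2550)]
        nums, labels = propagate_numbers(9, segs)
        assert nums[:2] == [2546, 2547]
        assert nums[-2:] == [2553, 2554]
        assert labels[0] == "nterm" and labels[-1] == "cterm"

    def test_hundreds_boundary_guard(self):
        """Propagation past ij99/ij00 leaves residues undefined instead of
        leaking into a neighbouring strand's block."""
        segs = [StrandSegment("B", 60, 64, 62, 2550)]
        nums, _ = propagate_numbers(130, segs)
        assert nums[62] == 2550
        assert nums[12] == 2500  # 50 before the anchor: block floor
        assert nums[11] is None  # would be 2499: outside the B block
        assert nums[62 + 49] == 2599
        assert nums[62 + 50] is None

    def test_value_range_clamp(self):
        segs = [StrandSegment("A-", 2, 7, 4, 1450)]
        # tail residues would be 1446, 1447; a template covering only 1448+
        # leaves them undefined
        nums, _ = propagate_numbers(10, segs, value_range=(1448, 1460))
        assert nums[0] is None and nums[1] is None
        assert nums[2] == 1448

    @given(st.sampled_from(sorted(TOPOLOGIES)))
    def test_numbers_strictly_increasing(self, name):
        nums, _ = spec_numbering(TOPOLOGIES[name])
        defined = [x for x in nums if x is not None]
        assert all(a < b for a, b in zip(defined, defined[1:]))

    def test_overlapping_segments_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            propagate_numbers(
                20,
                [StrandSegment("B", 0, 8, 4, 2550), StrandSegment("C", 5, 12, 8, 3550)],
            )


class TestSplitting:
    def test_single_domain_single_segment(self):
        trace = make_ideal_sandwich(IGV, seed=1).ca_trace()
        assert split_into_domains(trace) == [(0, len(trace) - 1)]

    def test_two_domain_chain_splits_in_linker(self):
        model, boundary = make_tandem(IGV, IGC1, linker_len=10, seed=7)
        trace = model.chains[0].ca_trace()
        segs = split_into_domains(trace)
        assert len(segs) == 2
        split_point = segs[1][0]
        assert abs(split_point - boundary) <= 3 or boundary <= split_point <= boundary + 10

    def test_short_peptide_single_candidate(self):
        trace = np.column_stack([np.arange(30) * 3.8, np.zeros(30), np.zeros(30)])
        assert split_into_domains(trace) == [(0, 29)]


class TestDetection:
    def test_noiseless_fixture_self_detects(self, registry):
        """A noiseless copy of a template's own trace detects that template."""
        tid = "FAB-HEAVY_5esv_V-n1"
        trace = synthesize_trace("igv", tid)
        residues = [
            Residue("A", i + 1, "", "T", [AtomRecord("CA", "C", c)])
            for i, c in enumerate(trace)
        ]
        hits = detect_ig_domains(Chain("A", residues), registry)
        assert len(hits) == 1
        assert hits[0].template_id == tid
        assert hits[0].tm >= 0.99

    def test_two_domain_chain_two_disjoint_hits(self, registry):
        model, boundary = make_tandem(IGV, IGC1, linker_len=10, seed=3)
        hits = detect_ig_domains(model.chains[0], registry)
        assert len(hits) == 2
        res_sets = [set(h.residues) for h in hits]
        assert not (res_sets[0] & res_sets[1])
        assert all(h.tm > 0.4 for h in hits)
        # first hit covers the first domain, second the second
        assert max(k[1] for k in hits[0].residues) <= boundary + 10
        assert min(k[1] for k in hits[1].residues) > boundary

    def test_helix_bundle_is_rejected(self, registry):
        decoy = make_helix_bundle(seed=11)
        assert detect_ig_domains(decoy.chains[0], registry) == []

    def test_decoy_specificity_across_seeds(self, registry):
        """All-helix decoys never clear the acceptance threshold."""
        for seed in range(20):
            decoy = make_helix_bundle(seed=seed)
            assert detect_ig_domains(decoy.chains[0], registry) == []

    def test_empty_registry_is_error(self):
        from igstrand.registry import TemplateRegistry

        sm = make_ideal_sandwich(IGV, seed=1)
        with pytest.raises(ValueError, match="empty"):
            detect_ig_domains(sm.model.chains[0], TemplateRegistry(templates=[]))

    def test_params_invariant(self):
        with pytest.raises(ValueError):
            DetectionParams(tm_accept=0.9, tm_cluster_shortcut=0.85)


class TestAssignment:
    def test_noiseless_igv_matches_truth(self, registry):
        sm = make_ideal_sandwich(IGV, seed=21)
        doms = number_chain(sm.model.chains[0], registry)
        assert len(doms) == 1
        nd = doms[0]
        for key, (num, label) in sm.truth.items():
            if label in (None, "loop", "nterm", "cterm"):
                continue
            assert nd.numbers[key] == num, (key, label)

    def test_anchor_residues_get_ij50(self, registry):
        sm = make_ideal_sandwich(IGV, seed=22)
        nd = number_chain(sm.model.chains[0], registry)[0]
        assert sorted(nd.anchors().values()) == [
            1550, 1850, 2550, 3550, 4550, 5550, 6550, 7550, 8550, 9550
        ]

    def test_numbers_strictly_increasing_along_domain(self, registry):
        sm = perturb(make_ideal_sandwich(IGV, seed=23), sigma=0.3, seed=5)
        nd = number_chain(sm.model.chains[0], registry)[0]
        nums = [nd.numbers[k] for k in nd.hit.residues if nd.numbers[k] is not None]
        assert all(a < b for a, b in zip(nums, nums[1:]))

    def test_rigid_invariance_of_numbering(self, registry):
        sm = make_ideal_sandwich(IGV, seed=24)
        rng = np.random.default_rng(6)
        moved = transform_model(sm, random_rotation(rng), rng.uniform(-25, 25, 3))
        nd_a = number_chain(sm.model.chains[0], registry)[0]
        nd_b = number_chain(moved.model.chains[0], registry)[0]
        assert nd_a.numbers == nd_b.numbers

    def test_anchor_dropout_propagates_from_neighbours(self, registry):
        sm = make_ideal_sandwich(IGV, seed=25)
        hit = detect_ig_domains(sm.model.chains[0], registry)[0]
        template = registry[hit.template_id]
        b_anchor = template.anchor_indices()["B"]
        hit.alignment.pairs = [(q, t) for q, t in hit.alignment.pairs if t != b_anchor]
        nd = assign_reference_numbers(hit, registry)
        # the B anchor igs# is still placed, via extrapolation from neighbours
        assert 2550 in nd.numbers.values()
        nums = [v for v in nd.numbers.values() if v is not None]
        assert all(a < b for a, b in zip(nums, nums[1:]))

    def test_low_confidence_flag(self, registry):
        sm = make_ideal_sandwich(IGV, seed=26)
        hit = detect_ig_domains(sm.model.chains[0], registry)[0]
        assert not hit.low_confidence
        hit.n_anchors_matched = hit.n_anchors_total // 2 - 1
        assert hit.low_confidence


class TestClassification:
    @pytest.mark.parametrize(
        "topology, tid, expected_class",
        [
            ("igv", "FAB-HEAVY_5esv_V-n1", "Ig"),
            ("cadherin", "ECadherin_4zt1A_human_n2", "Ig-like"),
            ("lamin", "LaminAC_1ifrA_human", "Ig-extended"),
        ],
    )
    def test_labels_inherited_from_winning_template(self, registry, topology, tid, expected_class):
        trace = synthesize_trace(topology, tid)
        residues = [
            Residue("A", i + 1, "", "T", [AtomRecord("CA", "C", c)])
            for i, c in enumerate(trace)
        ]
        hits = detect_ig_domains(Chain("A", residues), registry)
        assert hits and hits[0].template_id == tid
        labels = classify_domain(hits[0])
        assert labels["template_class"] == expected_class
        assert labels["confidence"] == "high"
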