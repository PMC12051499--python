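"""Contact detection, interaction typing, and dataset aggregation."""

import numpy as np
import pytest

from igstrand.interface import (
    ContactCriteria,
    ResidueContact,
    aggregate_dataset,
    classify_interaction,
    compare_interactomes,
    find_interface_contacts,
    find_symmetric_pairs,
)
from igstrand.model import AtomRecord, Residue
from igstrand.numbering import DomainHit, NumberedDomain


def _res(aa, chain, num, atoms):
    return Residue(chain, num, "", aa, [AtomRecord(n, e, c) for n, e, c in atoms])


def _domain(residues, numbers):
    keys = [r.key for r in residues]
    hit = DomainHit(
        residues=keys, template_id="toy", ig_type="IgV", template_class="Ig",
        tm=1.0, alignment=None,
    )
    return NumberedDomain(
        hit=hit,
        numbers=dict(zip(keys, numbers)),
        strand_of={k: "B" for k in keys},
    )


class TestClassification:
    def test_apolar_contact_is_vdw_only(self):
        a = _res("A", "A", 1, [("CA", "C", (0, 0, 0)), ("CB", "C", (1.5, 0, 0))])
        b = _res("A", "B", 1, [("CA", "C", (6.9, 0, 0)), ("CB", "C", (5.4, 0, 0))])
        assert classify_interaction(a, b) == {"vdw"}

    def test_gln_gln_hydrogen_bond(self):
        """Side-chain amide N/O at 2.9 A: donor-acceptor pair."""
        a = _res("Q", "A", 1, [("CA", "C", (0, 0, 0)), ("NE2", "N", (2.0, 0, 0)), ("OE1", "O", (1.8, 1.2, 0))])
        b = _res("Q", "B", 1, [("CA", "C", (6.9, 0, 0)), ("OE1", "O", (4.9, 0, 0)), ("NE2", "N", (5.1, 1.2, 0))])
        assert "hbond" in classify_interaction(a, b)

    def test_lys_glu_salt_bridge(self):
        a = _res("K", "A", 1, [("CA", "C", (0, 0, 0)), ("NZ", "N", (3.0, 0, 0))])
        b = _res("E", "B", 1, [("CA", "C", (9.0, 0, 0)), ("OE1", "O", (6.2, 0, 0)), ("OE2", "O", (6.5, 1.0, 0))])
        types = classify_interaction(a, b)
        assert "ionic" in types and "hbond" in types  # N-O pair also satisfies the H-bond distance

    def test_phe_phe_pi_stacking(self):
        ring = lambda cx: [("CG", "C", (cx, 1.4, 0)), ("CD1", "C", (cx + 1.2, 0.7, 0)),
                           ("CD2", "C", (cx - 1.2, 0.7, 0)), ("CE1", "C", (cx + 1.2, -0.7, 0)),
                           ("CE2", "C", (cx - 1.2, -0.7, 0)), ("CZ", "C", (cx, -1.4, 0))]
        a = _res("F", "A", 1, [("CA", "C", (0, 4, 0))] + ring(0.0))
        b = _res("F", "B", 1, [("CA", "C", (4.5, 4, 0))] + ring(4.5))
        assert "pi_stacking" in classify_interaction(a, b)

    def test_trp_arg_pi_cation(self):
        ring = [("CG", "C", (0, 1.0, 0)), ("CD1", "C", (1.0, 0.5, 0)), ("CD2", "C", (-1.0, 0.5, 0)),
                ("NE1", "N", (1.0, -0.5, 0)), ("CE2", "C", (-1.0, -0.5, 0)), ("CE3", "C", (0, -1.0, 0))]
        a = _res("W", "A", 1, [("CA", "C", (0, 4, 0))] + ring)
        b = _res("R", "B", 1, [("CA", "C", (8, 0, 0)), ("NH1", "N", (4.0, 0, 0)), ("NH2", "N", (4.5, 1.0, 0)), ("NE", "N", (5.5, 0, 0))])
        assert "pi_cation" in classify_interaction(a, b)

    def test_halogen_bond(self):
        a = _res("X", "A", 1, [("CA", "C", (0, 0, 0)), ("CL1", "CL", (3.0, 0, 0))])
        b = _res("S", "B", 1, [("CA", "C", (8, 0, 0)), ("OG", "O", (6.0, 0, 0))])
        assert "halogen" in classify_interaction(a, b)

    def test_criteria_must_be_positive(self):
        with pytest.raises(ValueError):
            ContactCriteria(heavy_atom_cutoff=-1.0)


class TestContacts:
    def _strand_pair(self, separation):
        res_a = [
            _res("T", "A", i + 1, [("CA", "C", (i * 3.4, 0, 0)), ("CB", "C", (i * 3.4, 0, 1.5))])
            for i in range(4)
        ]
        res_b = [
            _res("T", "B", i + 1, [("CA", "C", (i * 3.4, 0, separation)), ("CB", "C", (i * 3.4, 0, separation - 1.5))])
            for i in range(4)
        ]
        da = _domain(res_a, [2549, 2550, 2551, 2552])
        db = _domain(res_b, [8549, 8550, 8551, 8552])
        lookup = {r.key: r for r in res_a + res_b}
        return da, db, lookup

    def test_strands_beyond_cutoff_no_contacts(self):
        da, db, lookup = self._strand_pair(12.0)
        assert find_interface_contacts(da, db, lookup) == []

    def test_close_strands_contact_and_min_dist(self):
        da, db, lookup = self._strand_pair(6.0)
        contacts = find_interface_contacts(da, db, lookup)
        assert contacts
        crit = ContactCriteria()
        assert all(c.min_dist <= crit.heavy_atom_cutoff for c in contacts)
        assert all("vdw" in c.types for c in contacts)

    def test_contact_relation_is_symmetric(self):
        da, db, lookup = self._strand_pair(6.0)
        ab = find_interface_contacts(da, db, lookup)
        ba = find_interface_contacts(db, da, lookup)
        assert {(c.igs_a, c.igs_b) for c in ab} == {(c.igs_b, c.igs_a) for c in ba}
        assert {round(c.min_dist, 9) for c in ab} == {round(c.min_dist, 9) for c in ba}

    def test_shared_residues_rejected(self):
        da, db, lookup = self._strand_pair(6.0)
        db.numbers = da.numbers
        with pytest.raises(ValueError, match="disjoint"):
            find_interface_contacts(da, da, lookup)

    def test_matches_bruteforce_scan_on_dimer_toy(self, registry):
        """KD-tree contact search equals an all-pairs distance scan."""
        from igstrand.numbering import number_chain
        from igstrand.synth import combine, make_dimer
        from igstrand.topologies import IGV

        a, b = make_dimer(IGV, IGV, "parallel_GFCC", gap=4.5, seed=9)
        model = combine(a, b)
        da = number_chain(model.chain("A"), registry)[0]
        db = number_chain(model.chain("B"), registry)[0]
        lookup = {r.key: r for r in model.residues()}
        contacts = find_interface_contacts(da, db, lookup)

        crit = ContactCriteria()
        expected = {}
        for ka in da.numbers:
            for kb in db.numbers:
                best = np.inf
                for at_a in lookup[ka].heavy_atoms():
                    for at_b in lookup[kb].heavy_atoms():
                        best = min(best, float(np.linalg.norm(at_a.coord - at_b.coord)))
                if best <= crit.heavy_atom_cutoff:
                    expected[(ka, kb)] = best
        got = {(c.key_a, c.key_b): c.min_dist for c in contacts}
        assert set(got) == set(expected)
        for key in got:
            assert got[key] == pytest.approx(expected[key], abs=1e-9)


def _fake_contact(igs_a, igs_b, aa_a="L", aa_b="F", types=("vdw",)):
    return ResidueContact(
        igs_a=igs_a, igs_b=igs_b, key_a=("A", igs_a, ""), key_b=("B", igs_b, ""),
        aa_a=aa_a, aa_b=aa_b, types=frozenset(types), min_dist=3.5,
    )


class TestAggregation:
    def test_threshold_arithmetic(self):
        interfaces = [[_fake_contact(3553, 3553)] if i < 7 else [] for i in range(10)]
        profile = aggregate_dataset(interfaces)
        assert profile.pair_set(70.0) == {(3553, 3553)}
        assert profile.pair_set(90.0) == set()

    def test_full_presence_is_100_percent(self):
        interfaces = [[_fake_contact(4547, 9549)] for _ in range(8)]
        profile = aggregate_dataset(interfaces)
        assert profile.rows.loc[(4547, 9549), "percent"] == pytest.approx(100.0)
        assert profile.rows.loc[(4547, 9549), "count"] == 8

    def test_residue_label_ordered_by_frequency(self):
        interfaces = [
            [_fake_contact(4547, 9549, aa_a="L" if i < 6 else "P")] for i in range(10)
        ]
        profile = aggregate_dataset(interfaces)
        assert profile.rows.loc[(4547, 9549), "aa_a"] == "L/P"

    def test_threshold_nesting(self):
        rng = np.random.default_rng(0)
        interfaces = []
        for i in range(20):
            contacts = [_fake_contact(p, p) for p in (1550, 2550, 3553, 9549) if rng.random() < 0.8]
            interfaces.append(contacts)
        profile = aggregate_dataset(interfaces)
        assert profile.pair_set(90.0) <= profile.pair_set(70.0) <= profile.pair_set(0.0)

    def test_order_invariance(self):
        interfaces = [[_fake_contact(3553, 3553)], [], [_fake_contact(1549, 1557)]]
        p1 = aggregate_dataset(interfaces)
        p2 = aggregate_dataset(interfaces[::-1])
        assert p1.rows.equals(p2.rows)

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            aggregate_dataset([])

    def test_duplicate_pairs_in_one_structure_count_once(self):
        interfaces = [[_fake_contact(3553, 3553), _fake_contact(3553, 3553)]]
        profile = aggregate_dataset(interfaces)
        assert profile.rows.loc[(3553, 3553), "count"] == 1


class TestSymmetryAndComparison:
    def test_mirrored_pair_is_one_family(self):
        interfaces = [[_fake_contact(4547, 9549), _fake_contact(9549, 4547)] for _ in range(5)]
        profile = aggregate_dataset(interfaces)
        assert find_symmetric_pairs(profile, 70.0) == [(4547, 9549)]

    def test_self_pair_is_symmetric(self):
        interfaces = [[_fake_contact(3553, 3553)] for _ in range(5)]
        profile = aggregate_dataset(interfaces)
        assert find_symmetric_pairs(profile, 70.0) == [(3553, 3553)]

    def test_one_way_pair_is_not_symmetric(self):
        interfaces = [[_fake_contact(1549, 1557)] for _ in range(5)]
        profile = aggregate_dataset(interfaces)
        assert find_symmetric_pairs(profile, 70.0) == []

    def test_identical_profiles_share_everything(self):
        interfaces = [[_fake_contact(3553, 3553), _fake_contact(4547, 9549)] for _ in range(4)]
        p1 = aggregate_dataset(interfaces, "d1")
        p2 = aggregate_dataset(interfaces, "d2")
        out = compare_interactomes([p1, p2], 70.0)
        assert out["shared"] == [(3553, 3553), (4547, 9549)]
        assert out["distinct"] == {"d1": [], "d2": []}

    def test_disjoint_profiles_share_nothing(self):
        p1 = aggregate_dataset([[_fake_contact(3553, 3553)]] * 3, "d1")
        p2 = aggregate_dataset([[_fake_contact(1549, 1557)]] * 3, "d2")
        out = compare_interactomes([p1, p2], 70.0)
        assert out["shared"] == []

    def test_three_profiles_with_engineered_common_pairs(self):
        common = [(3553, 3553), (4547, 9549), (9546, 3551), (9550, 4546)]
        extras = [[(1111, 2222)], [(3333, 4444)], [(5555, 6666)]]
        profiles = []
        for i in range(3):
            pairs = common + extras[i]
            profiles.append(
                aggregate_dataset([[_fake_contact(a, b) for a, b in pairs]] * 4, f"d{i}")
            )
        out = compare_interactomes(profiles, 70.0)
        assert sorted(out["shared"]) == sorted(common)
        assert len(out["shared"]) == 4

    def test_order_normalized_comparison(self):
        p1 = aggregate_dataset([[_fake_contact(9549, 4547)]] * 3, "d1")
        p2 = aggregate_dataset([[_fake_contact(4547, 9549)]] * 3, "d2")
        out = compare_interactomes([p1, p2], 70.0, order_normalize=True)
        assert out["shared"] == [(4547, 9549)]
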