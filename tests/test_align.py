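"""Superposition, TM-score and the heuristic alignment kernel."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from igstrand.align import (
    AlignmentError,
    BackendError,
    align_structures,
    external_backend_align,
    kabsch_superpose,
    parse_tmalign_output,
    tm_d0,
    tm_score,
)
from igstrand.synth import make_ideal_sandwich, random_rotation, transform_model
from igstrand.topologies import IGV


def quaternion_superpose_rmsd(x: np.ndarray, y: np.ndarray) -> float:
    """Independent oracle: optimal RMSD via Horn's quaternion eigenvalue method."""
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    sxx, sxy, sxz = (xc[:, 0] * yc[:, 0]).sum(), (xc[:, 0] * yc[:, 1]).sum(), (xc[:, 0] * yc[:, 2]).sum()
    syx, syy, syz = (xc[:, 1] * yc[:, 0]).sum(), (xc[:, 1] * yc[:, 1]).sum(), (xc[:, 1] * yc[:, 2]).sum()
    szx, szy, szz = (xc[:, 2] * yc[:, 0]).sum(), (xc[:, 2] * yc[:, 1]).sum(), (xc[:, 2] * yc[:, 2]).sum()
    K = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    lam = np.linalg.eigvalsh(K)[-1]
    e = float((xc**2).sum() + (yc**2).sum() - 2.0 * lam)
    return math.sqrt(max(e, 0.0) / len(x))


class TestKabsch:
    def test_identity(self):
        x = np.random.default_rng(0).normal(size=(10, 3))
        sup = kabsch_superpose(x, x)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(sup.rotation, np.eye(3), atol=1e-9)

    def test_recovers_exact_rigid_motion(self):
        x = np.random.default_rng(1).normal(size=(8, 3))
        rot = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])  # 90 deg about z
        trans = np.array([1.0, 2.0, 3.0])
        y = x @ rot.T + trans
        sup = kabsch_superpose(x, y)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(sup.rotation, rot, atol=1e-9)
        np.testing.assert_allclose(sup.translation, trans, atol=1e-9)

    def test_matches_quaternion_oracle_on_noisy_cloud(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(10, 3))
        y = x @ random_rotation(rng).T + rng.normal(scale=0.1, size=(10, 3))
        sup = kabsch_superpose(x, y)
        assert sup.rmsd == pytest.approx(quaternion_superpose_rmsd(x, y), abs=1e-6)

    def test_rotation_is_proper_orthonormal(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(12, 3))
        y = rng.normal(size=(12, 3))
        sup = kabsch_superpose(x, y)
        np.testing.assert_allclose(sup.rotation @ sup.rotation.T, np.eye(3), atol=1e-6)
        assert np.linalg.det(sup.rotation) == pytest.approx(1.0, abs=1e-6)

    def test_argument_errors(self):
        with pytest.raises(AlignmentError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        with pytest.raises(AlignmentError):
            kabsch_superpose(np.zeros((4, 3)), np.zeros((5, 3)))


class TestTmScore:
    def test_perfect_superposition(self):
        assert tm_score(np.zeros(80), 80) == pytest.approx(1.0)

    def test_single_pair_at_d0(self):
        L = 100
        assert tm_score(np.array([tm_d0(L)]), L) == pytest.approx(1.0 / (2 * L))

    def test_d0_closed_form(self):
        # direct evaluation: 1.24 * 85^(1/3) - 1.8
        assert tm_d0(100) == pytest.approx(1.24 * 85 ** (1 / 3) - 1.8, abs=1e-9)
        assert tm_d0(100) == pytest.approx(3.652, abs=1e-3)

    def test_short_length_floor(self):
        assert tm_d0(16) == 0.5
        assert tm_d0(10) == 0.5

    def test_empty_pairs(self):
        assert tm_score(np.array([]), 50) == 0.0

    @given(
        st.lists(st.floats(min_value=0.0, max_value=30.0), min_size=2, max_size=30),
        st.integers(min_value=0, max_value=1),
        st.floats(min_value=0.1, max_value=10.0),
    )
    def test_monotone_nonincreasing_in_any_distance(self, dists, which, bump):
        """Increasing any single pair distance can only lower the score."""
        d = np.array(dists)
        before = tm_score(d, 60)
        d2 = d.copy()
        d2[which % len(d2)] += bump
        assert tm_score(d2, 60) <= before + 1e-12


class TestAlignStructures:
    def test_self_alignment_identity(self):
        trace = make_ideal_sandwich(IGV, seed=2).ca_trace()
        res = align_structures(trace, trace)
        assert res.tm_by_template == pytest.approx(1.0, abs=1e-6)
        assert res.pairs == [(i, i) for i in range(len(trace))]

    def test_rigid_invariance(self):
        sm = make_ideal_sandwich(IGV, seed=2)
        trace = sm.ca_trace()
        rng = np.random.default_rng(9)
        moved = transform_model(sm, random_rotation(rng), rng.uniform(-30, 30, 3)).ca_trace()
        res = align_structures(moved, trace)
        assert res.tm_by_template == pytest.approx(1.0, abs=1e-3)
        assert res.pairs == [(i, i) for i in range(len(trace))]

    def test_pairs_strictly_increasing(self):
        a = make_ideal_sandwich(IGV, seed=2).ca_trace()
        b = make_ideal_sandwich(IGV, seed=5).ca_trace()[10:95]
        res = align_structures(a, b)
        qs = [p[0] for p in res.pairs]
        ts = [p[1] for p in res.pairs]
        assert qs == sorted(set(qs)) and ts == sorted(set(ts))
        assert 0.0 < res.tm_by_template <= 1.0
        assert 0.0 < res.tm_by_query <= 1.0

    def test_hairpin_shift_matches_exhaustive_seed_search(self):
        """Shifted toy hairpin: the kernel finds the same optimum as refining
        every gapless offset exhaustively."""
        from igstrand.align import AlignParams, _refine, _thread_seeds, _tm_optimal

        rng = np.random.default_rng(4)
        up = np.column_stack([np.zeros(15), np.zeros(15), np.arange(15) * 3.4])
        down = np.column_stack([np.full(15, 4.8), np.zeros(15), (14 - np.arange(15)) * 3.4])
        hairpin = np.vstack([up, down]) + rng.normal(scale=0.05, size=(30, 3))
        shifted = np.roll(hairpin, 5, axis=0)

        params = AlignParams()
        best_tm = -1.0
        for _, seed_pairs in _thread_seeds(shifted, hairpin, k=10**9):
            pairs, _ = _refine(shifted, hairpin, seed_pairs, params)
            if len(pairs) >= 3:
                tm, _ = _tm_optimal(shifted, hairpin, pairs, len(hairpin))
                best_tm = max(best_tm, tm)
        res = align_structures(shifted, hairpin, params)
        assert res.tm_by_template == pytest.approx(best_tm, abs=1e-6)

    def test_too_short_raises(self):
        with pytest.raises(AlignmentError):
            align_structures(np.zeros((10, 3)), np.zeros((30, 3)))


CANNED_TMALIGN = """\
 *********************************************************************
 * TM-align (Version 20190822): protein structure alignment          *
 *********************************************************************

Name of Chain_1: query.pdb
Name of Chain_2: templ.pdb
Length of Chain_1: 6 residues
Length of Chain_2: 6 residues

Aligned length= 5, RMSD= 0.80, Seq_ID=n_identical/n_aligned= 1.000
TM-score= 0.91234 (if normalized by length of Chain_1)
TM-score= 0.90012 (if normalized by length of Chain_2)

(":" denotes residue pairs of d < 5.0 A, "." denotes other aligned residues)
AKLMN-P
:::.:
AKLM-NP
"""


class TestExternalBackend:
    def test_parse_canned_output(self):
        """Synthetic TM-align transcript (not from a real run)."""
        out = parse_tmalign_output(CANNED_TMALIGN)
        assert out["tm_by_query"] == pytest.approx(0.91234)
        assert out["tm_by_template"] == pytest.approx(0.90012)
        assert out["pairs"] == [(0, 0), (1, 1), (2, 2), (3, 3)]

    def test_missing_binary_is_backend_error(self, tmp_path):
        with pytest.raises(BackendError):
            external_backend_align("a.pdb", "b.pdb", executable="/no/such/tmalign")
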