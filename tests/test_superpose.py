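"""Rigid transforms, Kabsch fitting, ensemble superposition, view rotation."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from modelsup.align import build_alignment
from modelsup.divergence import TrimResult, trim
from modelsup.fixtures import EnsembleSpec, make_ensemble
from modelsup.superpose import (RigidTransform, kabsch, rotate_view,
                                superpose_ensemble)

from conftest import make_chain
from oracles import grid_search_rmsd


def _fit_rmsd(tr, P, Q):
    return float(np.sqrt(np.mean(np.sum((tr.apply(Q) - P) ** 2, axis=1))))


class TestRigidTransform:
    def test_rejects_reflection_and_nonorthogonal(self):
        refl = np.diag([1.0, 1.0, -1.0])
        with pytest.raises(ValueError, match="reflection"):
            RigidTransform(refl, np.zeros(3))
        with pytest.raises(ValueError, match="orthonormal"):
            RigidTransform(np.eye(3) * 1.01, np.zeros(3))

    def test_compose_and_inverse(self):
        rng = np.random.default_rng(0)
        a = RigidTransform(Rotation.random(random_state=rng).as_matrix(),
                           rng.normal(size=3))
        b = RigidTransform(Rotation.random(random_state=rng).as_matrix(),
                           rng.normal(size=3))
        x = rng.normal(size=(5, 3))
        np.testing.assert_allclose(a.compose(b).apply(x), a.apply(b.apply(x)),
                                   atol=1e-12)
        np.testing.assert_allclose(a.inverse().apply(a.apply(x)), x,
                                   atol=1e-12)


class TestKabsch:
    def test_identity_on_equal_sets(self):
        rng = np.random.default_rng(1)
        P = rng.normal(size=(6, 3))
        tr = kabsch(P, P)
        assert tr.is_identity(atol=1e-12)
        assert _fit_rmsd(tr, P, P) < 1e-12

    def test_recovers_exact_rotation_translation(self):
        rng = np.random.default_rng(2)
        P = rng.normal(size=(8, 3)) * 3
        R = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        Q = (P - np.array([3.0, 4.0, 5.0])) @ R  # P = R Q + t for some t
        tr = kabsch(P, Q)
        assert _fit_rmsd(tr, P, Q) < 1e-9

    def test_noisy_fit_matches_grid_search(self):
        rng = np.random.default_rng(3)
        P = rng.normal(size=(5, 3)) * 1.5
        R = Rotation.random(random_state=rng).as_matrix()
        Q = (P + rng.normal(scale=0.5, size=P.shape)) @ R.T + rng.normal(size=3)
        tr = kabsch(P, Q)
        ours = _fit_rmsd(tr, P, Q)
        grid = grid_search_rmsd(P, Q, step_deg=2.0)
        assert ours <= grid + 1e-12          # grid cannot beat the optimum
        assert grid <= ours * 1.02           # and lands within 2% of it

    def test_cross_check_scipy_align_vectors(self):
        rng = np.random.default_rng(4)
        P = rng.normal(size=(10, 3)) * 2
        Q = rng.normal(size=(10, 3)) * 2
        tr = kabsch(P, Q)
        rot, _ = Rotation.align_vectors(P - P.mean(0), Q - Q.mean(0))
        np.testing.assert_allclose(tr.rotation, rot.as_matrix(), atol=1e-8)

    def test_weighted_fit_downweights_outlier(self):
        rng = np.random.default_rng(5)
        P = rng.normal(size=(6, 3)) * 3
        Q = P.copy()
        Q[0] += np.array([10.0, 0.0, 0.0])
        w = np.array([0.0, 1, 1, 1, 1, 1.0])
        tr = kabsch(P, Q, weights=w)
        # all points except the outlier map exactly
        np.testing.assert_allclose(tr.apply(Q[1:]), P[1:], atol=1e-9)

    def test_degenerate_sets_rejected(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(ValueError, match="collinear"):
            kabsch(line, line)
        dup = np.ones((4, 3))
        with pytest.raises(ValueError, match="coincident"):
            kabsch(dup, dup)
        with pytest.raises(ValueError, match="at least 3"):
            kabsch(line[:2], line[:2])


def _full_trim(aln):
    return TrimResult(included=frozenset(range(len(aln.columns))),
                      excluded=frozenset(), iterations=0)


class TestSuperposeEnsemble:
    def test_identical_models_zero_rmsd(self, two_identical_models):
        aln = build_alignment(two_identical_models)
        res = superpose_ensemble(two_identical_models, aln, _full_trim(aln))
        assert res.rmsd_included == pytest.approx(0.0, abs=1e-9)
        for tr in res.transforms.values():
            assert _fit_rmsd(tr, two_identical_models[0].ca_coords(),
                             two_identical_models[1].ca_coords()) < 1e-9

    def test_first_model_anchored_bit_identical(self, core_tail_alignment):
        models, _, aln = core_tail_alignment
        trim_result, _ = trim(models, aln)
        res = superpose_ensemble(models, aln, trim_result)
        first = models[0]
        assert res.transforms[first.model_id].is_identity(atol=0.0)
        out = res.superposed_ca(first)
        assert (out == first.ca_coords()).all()

    def test_rigid_premotion_leaves_rmsd_unchanged(self, core_tail_alignment):
        models, _, aln = core_tail_alignment
        trim_result, _ = trim(models, aln)
        base = superpose_ensemble(models, aln, trim_result)
        rng = np.random.default_rng(9)
        moved = list(models)
        m = models[1]
        R = Rotation.random(random_state=rng).as_matrix()
        coords = m.ca_coords() @ R.T + rng.uniform(-15, 15, 3)
        moved[1] = make_chain(m.model_id, coords,
                              start_pos=m.residues[0].seq_pos)
        aln2 = build_alignment(moved)
        res2 = superpose_ensemble(moved, aln2, trim_result)
        assert res2.rmsd_included == pytest.approx(base.rmsd_included, abs=1e-6)
        assert res2.rmsd_all_shared == pytest.approx(base.rmsd_all_shared,
                                                     abs=1e-6)

    def test_included_rmsd_bounded_by_all_shared(self, core_tail_alignment):
        models, _, aln = core_tail_alignment
        trim_result, _ = trim(models, aln)
        res = superpose_ensemble(models, aln, trim_result)
        assert res.rmsd_included <= res.rmsd_all_shared + 1e-9
        assert res.rmsd_included >= 0

    def test_patchwork_coverage_connects_through_overlaps(self):
        spec = EnsembleSpec(n_models=3, core_len=40, tail_len=0,
                            core_noise_sigma=0.1, tail_displacement=0.0,
                            coverage_offsets=((1, 20), (12, 32), (25, 40)),
                            seed=4)
        models, _ = make_ensemble(spec)
        aln = build_alignment(models)
        trim_result, _ = trim(models, aln)
        res = superpose_ensemble(models, aln, trim_result)
        assert res.rmsd_included < 0.5

    def test_disconnected_overlap_rejected(self, helix_coords):
        m1 = make_chain("m1", helix_coords, start_pos=1)
        m2 = make_chain("m2", helix_coords, start_pos=100)
        aln = build_alignment([m1, m2])
        with pytest.raises(ValueError, match="disconnected|covers only"):
            superpose_ensemble([m1, m2], aln, _full_trim(aln))

    def test_pairwise_rmsd_matrix(self, two_identical_models):
        aln = build_alignment(two_identical_models)
        res = superpose_ensemble(two_identical_models, aln, _full_trim(aln))
        assert res.pairwise_rmsd.shape == (2, 2)
        assert res.pairwise_rmsd[0, 1] == pytest.approx(0.0, abs=1e-9)
        assert res.pairwise_rmsd[0, 1] == res.pairwise_rmsd[1, 0]


class TestRotateView:
    def test_zero_and_full_turn_identity(self):
        rng = np.random.default_rng(6)
        coords = {"m": rng.normal(size=(7, 3))}
        np.testing.assert_allclose(rotate_view(coords, (0, 0, 0))["m"],
                                   coords["m"], atol=1e-12)
        np.testing.assert_allclose(rotate_view(coords, (0, 0, 360))["m"],
                                   coords["m"], atol=1e-9)

    def test_composition_matches_single_rotation(self):
        rng = np.random.default_rng(7)
        coords = {"a": rng.normal(size=(5, 3)), "b": rng.normal(size=(4, 3))}
        twice = rotate_view(rotate_view(coords, (0, 0, 90)), (0, 0, 90))
        once = rotate_view(coords, (0, 0, 180))
        for k in coords:
            np.testing.assert_allclose(twice[k], once[k], atol=1e-9)


def test_kabsch_never_beaten_by_grid(subtests=None):
    """Optimality spot-check on several random small instances."""
    rng = np.random.default_rng(11)
    for _ in range(5):
        P = rng.normal(size=(5, 3)) * 1.5
        R = Rotation.random(random_state=rng).as_matrix()
        Q = (P + rng.normal(scale=0.5, size=P.shape)) @ R.T + rng.normal(size=3)
        ours = _fit_rmsd(kabsch(P, Q), P, Q)
        grid = grid_search_rmsd(P, Q, step_deg=6.0)
        assert ours <= grid + 1e-12
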