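"""Map similarity, distribution divergence and weighted dynamics metrics."""

import numpy as np
import pytest

from cryoreweight.density import DensityMap
from cryoreweight.forward import EnsembleSpec, Structure, molmap_sigma, simulate_reference_map
from cryoreweight.metrics import (
    ensemble_js_divergence,
    jensen_shannon,
    kabsch_superpose,
    map_cc,
    overlap_cc,
    rmsd,
    smoc,
    weighted_pca,
    weighted_rmsf,
)
from cryoreweight.synth import make_two_state_ensemble


def _map(values):
    return DensityMap(np.asarray(values, dtype=float), np.zeros(3), 1.0)


class TestMapCC:
    def test_self_correlation_is_one(self, small_map):
        assert map_cc(small_map, small_map) == pytest.approx(1.0)

    def test_negated_map_gives_minus_one(self, small_map):
        flipped = small_map.copy(values=-small_map.values + 3.0)
        assert map_cc(small_map, flipped) == pytest.approx(-1.0)

    def test_hand_computed_pearson(self):
        a = _map(np.array([1.0, 2, 3, 4, 5, 6]).reshape(1, 2, 3))
        b = _map(np.array([2.0, 1, 4, 3, 7, 5]).reshape(1, 2, 3))
        x, y = a.values.ravel(), b.values.ravel()
        expect = np.corrcoef(x, y)[0, 1]
        assert map_cc(a, b) == pytest.approx(expect, abs=1e-12)

    def test_voxel_subset_restriction(self, small_map):
        other = small_map.copy(values=small_map.values**2)
        idx = np.array([0, 5, 17, 40, 80, 100])
        x = small_map.values.ravel()[idx]
        y = other.values.ravel()[idx]
        assert map_cc(small_map, other, idx) == pytest.approx(np.corrcoef(x, y)[0, 1])

    def test_zero_variance_rejected(self, small_map):
        flat = small_map.copy(values=np.ones(small_map.shape))
        with pytest.raises(ValueError, match="variance"):
            map_cc(small_map, flat)

    def test_overlap_variant_is_scale_invariant_about_zero(self, small_map):
        doubled = small_map.copy(values=2.0 * small_map.values)
        assert overlap_cc(small_map, doubled) == pytest.approx(1.0)


class TestSMOC:
    def test_self_map_scores_near_one(self):
        ens = make_two_state_ensemble(M=2, n_residues=12, seed=1)
        s = ens.structures[0]
        res = 8.0
        ref = simulate_reference_map([s], res, voxel_size=1.5)
        track = smoc(ref, s, molmap_sigma(res))
        assert len(track.scores) == 12
        np.testing.assert_allclose(track.scores, 1.0, atol=1e-6)

    def test_zero_reference_zone_scores_zero(self):
        s = Structure(coords=np.array([[0.0, 0, 0]]), elements=["C"])
        ref = DensityMap(np.zeros((9, 9, 9)), origin=-4 * np.ones(3), voxel_size=1.0)
        with pytest.warns(UserWarning, match="zone"):
            track = smoc(ref, s, sigma=1.0, radius=3.0)
        assert track.scores[0] == 0.0

    def test_two_residue_toy_matches_hand_overlap(self):
        # residues sit far apart so the zones are disjoint
        s = Structure(
            coords=np.array([[2.0, 4.0, 4.0], [6.0, 4.0, 4.0]]),
            elements=["C", "C"],
            residue_ids=np.array([1, 2]),
        )
        ref = simulate_reference_map([s], 4.0, voxel_size=1.0, padding=4.0)
        # perturb one residue's density region to break perfect overlap
        vals = ref.values.copy()
        vals[:4] *= 1.7
        vals[:2] += 0.01
        pref = ref.copy(values=vals)
        sigma = molmap_sigma(4.0)
        track = smoc(pref, s, sigma, radius=1.6)
        from cryoreweight.forward import simulate_model_map

        sim = simulate_model_map(s, pref, sigma)
        xs, ys, zs = pref.voxel_coords()
        for k, centre in enumerate(s.coords):
            dist2 = (
                (xs[:, None, None] - centre[0]) ** 2
                + (ys[None, :, None] - centre[1]) ** 2
                + (zs[None, None, :] - centre[2]) ** 2
            )
            zone = dist2 <= 1.6**2
            r = pref.values[zone]
            m = sim.values[zone]
            expect = (r * m).sum() / np.sqrt((r**2).sum() * (m**2).sum())
            assert track.scores[k] == pytest.approx(expect, abs=1e-12)

    def test_scores_bounded_in_unit_interval(self):
        ens = make_two_state_ensemble(M=2, n_residues=10, seed=3)
        ref = simulate_reference_map(ens.structures, 6.0, voxel_size=1.5)
        track = smoc(ref, ens.structures[1], molmap_sigma(6.0))
        assert (track.scores >= 0).all() and (track.scores <= 1 + 1e-12).all()


class TestJensenShannon:
    def test_identical_distributions_give_zero(self):
        p = np.array([0.2, 0.5, 0.3])
        assert jensen_shannon(p, p) == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_support_gives_ln2(self):
        p = np.array([0.5, 0.5, 0.0, 0.0])
        q = np.array([0.0, 0.0, 0.3, 0.7])
        assert jensen_shannon(p, q) == pytest.approx(np.log(2), abs=1e-12)

    def test_matches_average_of_kls_term_by_term(self):
        rng = np.random.default_rng(8)
        p = rng.dirichlet(np.ones(8))
        q = rng.dirichlet(np.ones(8))
        m = 0.5 * (p + q)
        expect = 0.5 * sum(pi * np.log(pi / mi) for pi, mi in zip(p, m)) + 0.5 * sum(
            qi * np.log(qi / mi) for qi, mi in zip(q, m)
        )
        assert jensen_shannon(p, q) == pytest.approx(expect, abs=1e-12)

    def test_symmetry_and_bound(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            p = rng.dirichlet(np.ones(5))
            q = rng.dirichlet(np.ones(5))
            d = jensen_shannon(p, q)
            assert d == pytest.approx(jensen_shannon(q, p), abs=1e-14)
            assert 0.0 <= d <= np.log(2) + 1e-12

    def test_negative_mass_rejected(self):
        with pytest.raises(ValueError):
            jensen_shannon([0.5, 0.5], [-0.1, 1.1])


class TestEnsembleJS:
    def test_identical_ensembles_give_zero(self):
        ens = make_two_state_ensemble(M=6, n_residues=10, seed=4)
        w = np.full(6, 1 / 6)
        assert ensemble_js_divergence(ens, w, ens, w) == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_weighting_reaches_ln2(self):
        ens = make_two_state_ensemble(M=6, n_residues=10, seed=4)
        eps = 1e-9
        wa = np.array([1 - 4 * eps, eps, eps, eps, eps, 0.0])
        wa /= wa.sum()
        wb = np.array([0.0, eps, eps, eps, eps, 1 - 4 * eps])
        wb /= wb.sum()
        # open and closed members occupy different RMSD bins
        d = ensemble_js_divergence(ens, wa, ens, wb, bins=2)
        assert d == pytest.approx(np.log(2), rel=1e-6)

    def test_reweighting_toward_target_reduces_divergence(self):
        ens = make_two_state_ensemble(M=10, seed=5)
        target_w = np.zeros(10)
        target_w[:5] = 0.2  # open state only
        prior_w = np.full(10, 0.1)
        better_w = np.array([0.18] * 5 + [0.02] * 5)
        d_prior = ensemble_js_divergence(ens, prior_w, ens, target_w)
        d_better = ensemble_js_divergence(ens, better_w, ens, target_w)
        assert d_better < d_prior


class TestRMSD:
    def test_translation_and_rotation_removed(self):
        rng = np.random.default_rng(11)
        a = rng.normal(size=(12, 3))
        from scipy.spatial.transform import Rotation

        rot = Rotation.from_rotvec([0.3, -0.2, 0.5]).as_matrix()
        b = a @ rot.T + np.array([5.0, -3.0, 2.0])
        assert rmsd(a, b) == pytest.approx(0.0, abs=1e-9)
        assert rmsd(a, b, superpose=False) > 1.0


class TestWeightedRMSF:
    def _ensemble_with_one_moving_residue(self):
        base = np.zeros((5, 3))
        base[:, 0] = np.arange(5) * 10.0  # residues far apart, superposition-stable
        shifted = base.copy()
        shifted[2, 1] += 2.0
        mk = lambda c, lbl: Structure(
            coords=c, elements=["C"] * 5, atom_names=["CA"] * 5, label=lbl
        )
        return EnsembleSpec([mk(base, "a"), mk(shifted, "b")])

    def test_all_weight_on_one_member_gives_zero(self):
        ens = self._ensemble_with_one_moving_residue()
        eps = 1e-12
        _, r = weighted_rmsf(ens, [1 - eps, eps])
        np.testing.assert_allclose(r, 0.0, atol=1e-5)

    def test_two_conformer_closed_form(self):
        # one residue displaced by 2 A, weights (1/2, 1/2): after mean-centering
        # each conformer sits 1 A away -> RMSF 1.0 for that residue, 0 for the
        # rest (exact on the pre-aligned path; re-superposition would shift a
        # share of the local displacement into the fitted translation)
        ens = self._ensemble_with_one_moving_residue()
        _, r = weighted_rmsf(ens, [0.5, 0.5], superpose=False)
        assert r[2] == pytest.approx(1.0, abs=1e-12)
        assert r[[0, 1, 3, 4]].max() == pytest.approx(0.0, abs=1e-12)
        # the default superposing path spreads some of it but keeps the peak
        _, rs = weighted_rmsf(ens, [0.5, 0.5])
        assert rs.argmax() == 2

    def test_member_permutation_invariance(self):
        ens = make_two_state_ensemble(M=6, n_residues=8, seed=6)
        w = np.array([0.1, 0.3, 0.15, 0.2, 0.05, 0.2])
        _, r1 = weighted_rmsf(ens, w)
        perm = [3, 1, 5, 0, 4, 2]
        ens_p = EnsembleSpec([ens.structures[i] for i in perm])
        _, r2 = weighted_rmsf(ens_p, w[perm])
        np.testing.assert_allclose(r1, r2, atol=1e-8)

    def test_uniform_weights_reduce_to_unweighted_rmsf(self):
        ens = make_two_state_ensemble(M=6, n_residues=8, seed=7)
        w = np.full(6, 1 / 6)
        _, r = weighted_rmsf(ens, w)
        from cryoreweight.metrics import _aligned_representative_stack

        _, coords = _aligned_representative_stack(ens, w)
        mean = coords.mean(axis=0)
        expect = np.sqrt(((coords - mean) ** 2).sum(axis=2).mean(axis=0))
        np.testing.assert_allclose(r, expect, atol=1e-10)

    def test_weight_length_mismatch_rejected(self):
        ens = make_two_state_ensemble(M=4, n_residues=8, seed=8)
        with pytest.raises(ValueError):
            weighted_rmsf(ens, [0.5, 0.5])


class TestWeightedPCA:
    def test_rank_one_displacement_gives_pc1_fraction_one(self):
        base = np.zeros((6, 3))
        base[:, 0] = np.arange(6) * 8.0
        direction = np.zeros((6, 3))
        direction[3, 1] = 1.0
        members = [
            Structure(coords=base + a * direction, elements=["C"] * 6,
                      atom_names=["CA"] * 6, label=str(i))
            for i, a in enumerate([-2.0, -1.0, 1.0, 2.0])
        ]
        ens = EnsembleSpec(members)
        out = weighted_pca(ens, np.full(4, 0.25), n_components=3, superpose=False)
        assert out.variance_fractions[0] == pytest.approx(1.0, abs=1e-9)
        # PC1 is parallel to the displacement direction
        pc1 = out.pcs[0].reshape(6, 3)
        overlap = abs(np.dot(pc1.ravel(), direction.ravel()) / np.linalg.norm(direction))
        assert overlap == pytest.approx(1.0, abs=1e-9)

    def test_uniform_weights_match_unweighted_pca(self):
        ens = make_two_state_ensemble(M=8, n_residues=8, seed=9)
        w = np.full(8, 1 / 8)
        out = weighted_pca(ens, w, n_components=3)
        from cryoreweight.metrics import _aligned_representative_stack

        _, coords = _aligned_representative_stack(ens, w)
        flat = coords.reshape(8, -1)
        centred = flat - flat.mean(axis=0)
        cov = centred.T @ centred / 8
        evals = np.sort(np.linalg.eigvalsh(cov))[::-1]
        np.testing.assert_allclose(
            out.variance_fractions, evals[:3] / evals.sum(), atol=1e-10
        )

    def test_components_match_outer_product_covariance(self):
        ens = make_two_state_ensemble(M=8, n_residues=8, seed=12)
        rng = np.random.default_rng(13)
        w = rng.dirichlet(np.ones(8))
        out = weighted_pca(ens, w, n_components=2)
        from cryoreweight.metrics import _aligned_representative_stack

        _, coords = _aligned_representative_stack(ens, w)
        flat = coords.reshape(8, -1)
        mean = w @ flat
        cov = sum(wi * np.outer(x - mean, x - mean) for wi, x in zip(w, flat))
        evals, evecs = np.linalg.eigh(cov)
        top = evecs[:, np.argsort(evals)[::-1][:2]]
        # subspace overlap >= 0.999
        proj = np.linalg.svd(out.pcs @ top)[1]
        assert proj.min() >= 0.999

    def test_variance_fractions_non_increasing_and_bounded(self):
        ens = make_two_state_ensemble(M=6, n_residues=8, seed=14)
        out = weighted_pca(ens, np.full(6, 1 / 6), n_components=3)
        f = out.variance_fractions
        assert (np.diff(f) <= 1e-12).all()
        assert f.sum() <= 1.0 + 1e-9

    def test_excess_components_rejected(self):
        ens = make_two_state_ensemble(M=4, n_residues=6, seed=15)
        with pytest.raises(ValueError):
            weighted_pca(ens, np.full(4, 0.25), n_components=100)


class TestKabsch:
    def test_superposition_minimises_rmsd(self):
        rng = np.random.default_rng(16)
        a = rng.normal(size=(10, 3))
        b = rng.normal(size=(10, 3))
        fitted = kabsch_superpose(a, b)
        base = np.sqrt(((fitted - b) ** 2).sum(axis=1).mean())
        # any small extra rotation must not improve the fit
        from scipy.spatial.transform import Rotation

        for vec in ([0.05, 0, 0], [0, -0.04, 0.03]):
            rot = Rotation.from_rotvec(vec).as_matrix()
            centred = fitted - fitted.mean(axis=0)
            worse = centred @ rot.T + fitted.mean(axis=0)
            assert np.sqrt(((worse - b) ** 2).sum(axis=1).mean()) >= base - 1e-12
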