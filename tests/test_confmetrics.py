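import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import adjusted_rand_score, calinski_harabasz_score

from conftest import rmsd_matrix_from_frames
from groovedyn import confmetrics as cm
from groovedyn import synthetic_data as sd
from groovedyn.confmetrics import (RamaRegionMap, SurveyRecord,
                                   bound_free_survey, cluster_average,
                                   cluster_select_k, dscore, dscore_profile,
                                   pairwise_rmsd, rama_strain_count)
from groovedyn.geometry import PairingError
from groovedyn.structio import select


class TestDscore:
    def test_endpoints(self):
        assert dscore(10, 20, 10, 20) == pytest.approx(0.0)
        assert dscore(0, 0, 180, 180) == pytest.approx(8.0)
        assert dscore(0, 50, 180, 50) == pytest.approx(4.0)

    def test_circular_difference(self):
        # -170 vs 170 differ by 20 degrees on the circle, not 340
        assert dscore(-170, 0, 170, 0) == pytest.approx(
            2 * (1 - np.cos(np.radians(20))))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.floats(-180, 180), st.floats(-180, 180),
           st.floats(-180, 180), st.floats(-180, 180))
    def test_range_and_symmetry(self, pa, sa, pb, sb):
        d = dscore(pa, sa, pb, sb)
        assert 0.0 <= d <= 8.0 + 1e-12
        assert d == pytest.approx(dscore(pb, sb, pa, sa), abs=1e-12)

    def test_profile_marks_terminal_missing(self):
        a = [(None, 120.0), (-60.0, -45.0), (-60.0, None)]
        b = [(None, 120.0), (-60.0, -45.0), (-60.0, None)]
        out = dscore_profile(a, b)
        assert np.isnan(out[0]) and np.isnan(out[2])
        assert out[1] == pytest.approx(0.0)


class TestRamaStrain:
    def test_alpha_helix_unstrained(self):
        phi = np.full((50, 7), -60.0)
        psi = np.full((50, 7), -45.0)
        _, total = rama_strain_count(phi, psi)
        assert total == 0

    def test_origin_always_strained(self):
        phi = np.zeros((20, 7))
        psi = np.zeros((20, 7))
        per_res, total = rama_strain_count(phi, psi)
        assert total == 20 * 7
        assert np.all(per_res == 20)

    def test_matches_per_frame_lookup(self):
        rng = np.random.default_rng(3)
        phi = rng.uniform(-180, 180, (30, 5))
        psi = rng.uniform(-180, 180, (30, 5))
        m = RamaRegionMap.bundled()
        per_res, total = rama_strain_count(phi, psi, m)
        brute = sum(
            not m.allowed(phi[f, r], psi[f, r])
            for f in range(30) for r in range(5)
        )
        assert total == brute


class TestPairwiseRMSD:
    def test_identical_frames_zero_matrix(self, toy_complex):
        traj = sd.gen_trajectory(toy_complex, [0.0] * 9, n_frames=6, seed=0)
        M = pairwise_rmsd(traj, fit_spec="chain A and name CA",
                          target_spec="chain C and heavy")
        assert np.abs(M.values).max() <= 1e-6

    def test_two_conformer_block_structure(self, toy_complex):
        shifted = toy_complex.with_coord(toy_complex.coord.copy())
        pep = select(toy_complex, "chain C")
        shifted.coord[pep] += [2.0, 0.0, 0.0]
        tA = sd.gen_trajectory(toy_complex, [0.0] * 9, n_frames=10, seed=1)
        tB = sd.gen_trajectory(shifted, [0.0] * 9, n_frames=10, seed=2)
        M = pairwise_rmsd({"A": tA, "B": tB},
                          fit_spec="chain A and name CA",
                          target_spec="chain C and heavy")
        v = M.values
        assert np.abs(v[:10, :10]).max() < 1e-6
        assert np.abs(v[10:, 10:]).max() < 1e-6
        np.testing.assert_allclose(v[:10, 10:], 2.0, atol=1e-3)

    def test_symmetry_and_zero_diagonal(self, toy_complex):
        traj = sd.gen_trajectory(toy_complex, [0.4] * 9, n_frames=20,
                                 seed=3)
        M = pairwise_rmsd(traj, fit_spec="chain A and name CA",
                          target_spec="chain C and heavy")
        assert np.allclose(M.values, M.values.T, atol=1e-9)
        assert np.abs(np.diag(M.values)).max() <= 1e-9

    def test_reference_structures_appended(self, toy_complex):
        traj = sd.gen_trajectory(toy_complex, [0.0] * 9, n_frames=3, seed=4)
        M = pairwise_rmsd(traj, fit_spec="chain A and name CA",
                          target_spec="chain C and heavy",
                          references=[("crystal", toy_complex)])
        assert M.values.shape == (4, 4)
        assert M.labels[-1][0] == "crystal"


class TestClustering:
    def test_two_blobs_recovered(self):
        frames, labels, _ = sd.gen_cluster_ensemble(
            k=2, separation=5.0, spread=0.5, sizes=[30, 30], seed=0)
        res = cluster_select_k(rmsd_matrix_from_frames(frames),
                               k_range=range(2, 6))
        assert res.selected_k == 2
        assert adjusted_rand_score(labels, res.labels) == 1.0

    def test_eight_conformers_selected(self):
        frames, labels, _ = sd.gen_cluster_ensemble(
            k=8, separation=5.0, spread=0.5, sizes=[50] * 8, seed=1)
        res = cluster_select_k(rmsd_matrix_from_frames(frames),
                               k_range=range(2, 13))
        assert res.selected_k == 8
        assert adjusted_rand_score(labels, res.labels) >= 0.99

    def test_restricted_range_matches_exhaustive(self):
        frames, _, _ = sd.gen_cluster_ensemble(
            k=8, separation=5.0, spread=0.5, sizes=[20] * 8, seed=2)
        dist = rmsd_matrix_from_frames(frames)
        res = cluster_select_k(dist, k_range=range(2, 5))
        assert 2 <= res.selected_k <= 4
        # exhaustive evaluation with the same embedding/scorer
        emb = cm._classical_mds(dist)
        from sklearn.cluster import AgglomerativeClustering
        scores = {}
        for k in range(2, 5):
            lab = AgglomerativeClustering(
                n_clusters=k, metric="precomputed", linkage="average",
            ).fit_predict(dist)
            scores[k] = calinski_harabasz_score(emb, lab)
        assert res.selected_k == max(scores, key=lambda k: (scores[k], -k))

    def test_partition_recovery_many_seeds(self):
        hits = 0
        for seed in range(15):
            frames, labels, _ = sd.gen_cluster_ensemble(
                k=4, separation=5.0, spread=0.5, sizes=[25] * 4, seed=seed)
            res = cluster_select_k(rmsd_matrix_from_frames(frames),
                                   k_range=range(2, 9))
            if adjusted_rand_score(labels, res.labels) >= 0.99:
                hits += 1
        assert hits >= 14

    def test_k_range_validation(self):
        with pytest.raises(ValueError):
            cluster_select_k(np.zeros((4, 4)), k_range=range(2, 10))


class TestClusterAverage:
    def test_single_cluster_mean(self):
        rng = np.random.default_rng(0)
        frames = rng.normal(size=(10, 5, 3))
        avg, frac = cluster_average(frames, np.ones(10, dtype=int))
        np.testing.assert_allclose(avg[0], frames.mean(0), atol=1e-12)
        assert frac[0] == 1.0

    def test_population_fractions_exact(self):
        frames, labels, _ = sd.gen_cluster_ensemble(
            k=2, separation=5.0, spread=0.3, sizes=[23, 77], seed=3)
        _, frac = cluster_average(frames, labels)
        assert sorted(np.round(frac, 9)) == [0.23, 0.77]

    def test_planted_centers_recovered_within_clt(self):
        frames, labels, centers = sd.gen_cluster_ensemble(
            k=3, separation=6.0, spread=0.5, sizes=[200] * 3, seed=4)
        avg, _ = cluster_average(frames, labels)
        for c in range(3):
            err = np.sqrt(((avg[c] - centers[c]) ** 2).sum(1).mean())
            # per-atom sd is spread/sqrt(3) per axis; mean of 200 frames
            assert err < 5 * 0.5 / np.sqrt(200)

    def test_empty_label_rejected(self):
        with pytest.raises(ValueError):
            cluster_average(np.zeros((4, 2, 3)), [1, 1, 3, 3])


class TestSurvey:
    def _pair(self, toy, pair_id, group, shift=None, flip_chi=False):
        bound = toy.with_coord(toy.coord.copy())
        if shift is not None:
            pep = select(toy, "chain C and heavy")
            bound.coord[pep] += shift
        if flip_chi:
            side = select(toy, "chain C and resid 6 and sidechain and "
                               "not name CB")
            bound.coord[side] += [0.0, 1.5, 0.0]
        return {"pair_id": pair_id, "group": group, "free": toy,
                "bound": bound, "peptide_spec": "chain C and heavy",
                "fit_spec": "chain A and name CA"}

    def test_identical_pair_zero(self, toy_complex):
        rec, = bound_free_survey([self._pair(toy_complex, "p1", "g1")])
        assert rec.ca_rmsd == pytest.approx(0.0, abs=1e-6)
        assert rec.all_atom_rmsd == pytest.approx(0.0, abs=1e-6)
        assert rec.peptide_length == 9

    def test_side_chain_flip_raises_all_atom_only(self, toy_complex):
        rec, = bound_free_survey(
            [self._pair(toy_complex, "p1", "g1", flip_chi=True)])
        assert rec.all_atom_rmsd > rec.ca_rmsd
        assert rec.ca_rmsd == pytest.approx(0.0, abs=1e-6)

    def test_replicate_rule_keeps_largest(self, toy_complex):
        pairs = [
            self._pair(toy_complex, "small", "g", shift=[0.5, 0, 0]),
            self._pair(toy_complex, "large", "g", shift=[0.9, 0, 0]),
        ]
        recs = bound_free_survey(pairs)
        assert len(recs) == 1
        assert recs[0].pair_id == "large"
        assert recs[0].replicate_rule_applied

    def test_order_invariance(self, toy_complex):
        pairs = [
            self._pair(toy_complex, "a", "g1", shift=[0.3, 0, 0]),
            self._pair(toy_complex, "b", "g2", shift=[0.6, 0, 0]),
        ]
        r1 = bound_free_survey(pairs)
        r2 = bound_free_survey(pairs[::-1])
        assert [(r.pair_id, r.ca_rmsd) for r in r1] == \
            [(r.pair_id, r.ca_rmsd) for r in r2]

    def test_sequence_mismatch_rejected(self, toy_complex):
        other = sd.gen_toy_complex(seed=1, anchor2="HIS")
        pair = self._pair(toy_complex, "x", "g")
        pair["bound"] = other
        with pytest.raises(PairingError, match="position"):
            bound_free_survey([pair])
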