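"""Dissimilarity, force-scheme projection, KDE, and local signatures."""

import numpy as np
import pytest

from rnalandscape import (
    DissimilarityMatrix,
    Region,
    datasets,
    dissimilarity_matrix,
    force_scheme,
    kde_density,
    local_signature,
    morph_ensemble,
    native_contacts,
    qw_dissimilarity,
)
from rnalandscape.elvim import drmsd_matrix, region_from_density, sigma_ij

from conftest import random_rotation


class TestQwDissimilarity:
    def test_identical_frames_give_zero(self, hairpin):
        cg, _ = hairpin
        assert qw_dissimilarity(cg.xyz, cg.xyz, cg.bead_residues) == 0.0

    def test_single_pair_hand_value(self):
        # one bead on residue 5, one on residue 6: sigma = 3 * 1^0.15 = 3 A;
        # distances 10 and 13 A -> q_w = exp(-9/18), delta = 1 - exp(-0.5)
        fk = np.array([[0.0, 0, 0], [10.0, 0, 0]])
        fl = np.array([[0.0, 0, 0], [13.0, 0, 0]])
        delta = qw_dissimilarity(fk, fl, bead_residues=[5, 6])
        assert delta == pytest.approx(1.0 - np.exp(-0.5), abs=1e-12)

    def test_sigma_rule_hand_values(self):
        assert sigma_ij(1) == pytest.approx(3.0, abs=1e-9)
        assert sigma_ij(2) == pytest.approx(3.0 * 2**0.15, abs=1e-9)
        assert sigma_ij(32) == pytest.approx(3.0 * 32**0.15, abs=1e-9)
        assert sigma_ij(32) == pytest.approx(5.05, abs=0.01)

    def test_rigid_motion_invariance(self, hairpin, rng):
        cg, _ = hairpin
        other = cg.xyz + rng.normal(scale=1.5, size=cg.xyz.shape)
        base = qw_dissimilarity(cg.xyz, other, cg.bead_residues)
        R = random_rotation(rng)
        moved = other @ R.T + [7.0, -3.0, 1.0]
        assert qw_dissimilarity(cg.xyz, moved, cg.bead_residues) == pytest.approx(
            base, abs=1e-9
        )

    def test_intra_residue_pairs_are_excluded(self):
        # beads all on one residue: the pair set is empty and that is an error
        with pytest.raises(ValueError, match="pair set"):
            qw_dissimilarity(np.zeros((3, 3)), np.ones((3, 3)),
                             bead_residues=[1, 1, 1])


class TestDissimilarityMatrix:
    def test_identical_frames_give_zero_matrix(self, hairpin):
        cg, _ = hairpin
        frames = np.repeat(cg.xyz[None], 3, axis=0)
        D = dissimilarity_matrix(frames, cg.bead_residues)
        np.testing.assert_allclose(D.values, 0.0, atol=1e-12)

    def test_matches_per_pair_calls(self, hairpin, rng):
        cg, _ = hairpin
        frames = cg.xyz + rng.normal(scale=1.0, size=(12,) + cg.xyz.shape)
        D = dissimilarity_matrix(frames, cg.bead_residues)
        for k in range(12):
            for l in range(k + 1, 12):
                expect = qw_dissimilarity(frames[k], frames[l],
                                          cg.bead_residues)
                assert D.values[k, l] == pytest.approx(expect, abs=1e-12)

    def test_entries_bounded_and_symmetric(self, riboswitch, rng):
        cg, _ = riboswitch
        traj = morph_ensemble(cg, 30, unfold_fraction=1.0, noise=0.5, seed=1)
        D = dissimilarity_matrix(traj.rna, cg.bead_residues)
        assert D.values.max() <= 1.0
        assert D.values.min() >= 0.0
        np.testing.assert_allclose(D.values, D.values.T)
        np.testing.assert_allclose(np.diag(D.values), 0.0)

    def test_inconsistent_bead_counts_rejected(self, hairpin):
        cg, _ = hairpin
        with pytest.raises(ValueError):
            dissimilarity_matrix(np.zeros((3, 5, 3)), cg.bead_residues)

    def test_binary_roundtrip(self, hairpin, rng, tmp_path):
        cg, _ = hairpin
        frames = cg.xyz + rng.normal(scale=1.0, size=(5,) + cg.xyz.shape)
        D = dissimilarity_matrix(frames, cg.bead_residues)
        D.save(tmp_path / "d.npz")
        again = DissimilarityMatrix.load(tmp_path / "d.npz")
        np.testing.assert_array_equal(again.values, D.values)
        assert again.sigma0 == D.sigma0


class TestRegionIO:
    def test_polygon_tsv_roundtrip_and_selection(self, rng):
        from rnalandscape.elvim import (Embedding, read_polygon,
                                        region_from_polygon, write_polygon)

        poly = np.array([[0.0, 0.0], [4.0, 0.0], [4.0, 4.0], [0.0, 4.0]])
        again = read_polygon(write_polygon(poly))
        np.testing.assert_allclose(again, poly)
        pts = np.array([[2.0, 2.0], [5.0, 5.0], [1.0, 3.0]])
        emb = Embedding(points=pts, stress=0.0, stress_history=np.zeros(1),
                        n_iter=1, seed=0)
        region = region_from_polygon(emb, again, label="basin")
        assert sorted(region.indices) == [0, 2]


def _equilateral_matrix() -> DissimilarityMatrix:
    v = np.array([[0.0, 0.5, 0.5], [0.5, 0.0, 0.5], [0.5, 0.5, 0.0]])
    return DissimilarityMatrix(values=v)


class TestForceScheme:
    def test_equilateral_triangle_is_recovered(self):
        emb = force_scheme(_equilateral_matrix(), n_iter=300, seed=0)
        d = [
            np.linalg.norm(emb.points[a] - emb.points[b])
            for a, b in ((0, 1), (0, 2), (1, 2))
        ]
        assert (max(d) - min(d)) / np.mean(d) < 0.02

    def test_all_zero_dissimilarity_collapses_points(self):
        D = DissimilarityMatrix(values=np.zeros((5, 5)))
        emb = force_scheme(D, n_iter=100, seed=3)
        spread = np.linalg.norm(emb.points - emb.points.mean(axis=0), axis=1)
        assert spread.max() < 1e-3

    @pytest.mark.parametrize("seed", range(20))
    def test_stress_decreases_on_random_matrices(self, seed):
        rng = np.random.default_rng(1000 + seed)
        raw = rng.uniform(0.05, 1.0, size=(50, 50))
        sym = np.triu(raw, 1)
        D = DissimilarityMatrix(values=sym + sym.T)
        emb = force_scheme(D, n_iter=100, seed=seed)
        assert emb.stress_history[-1] <= emb.stress_history[0]

    def test_deterministic_given_seed(self):
        D = _equilateral_matrix()
        e1 = force_scheme(D, n_iter=50, seed=5)
        e2 = force_scheme(D, n_iter=50, seed=5)
        assert np.array_equal(e1.points, e2.points)

    def test_embedding_correlates_with_dissimilarity(self, riboswitch):
        cg, _ = riboswitch
        traj = morph_ensemble(cg, 200, unfold_fraction=1.0, noise=0.4, seed=5)
        D = dissimilarity_matrix(traj.rna, cg.bead_residues)
        emb = force_scheme(D, n_iter=60, seed=2)
        from scipy.spatial.distance import pdist, squareform
        from scipy.stats import pearsonr

        iu = np.triu_indices(len(D), k=1)
        d_emb = squareform(pdist(emb.points))[iu]
        r, _ = pearsonr(d_emb, D.values[iu])
        assert r > 0.7

    def test_morph_path_projects_to_connected_filament(self, riboswitch):
        cg, _ = riboswitch
        traj = morph_ensemble(cg, 150, unfold_fraction=1.0, noise=0.2, seed=9)
        D = dissimilarity_matrix(traj.rna, cg.bead_residues)
        emb = force_scheme(D, n_iter=80, seed=4)
        from scipy.spatial.distance import pdist, squareform

        dm = squareform(pdist(emb.points))
        np.fill_diagonal(dm, np.inf)
        nn = dm.min(axis=1)
        consecutive = np.linalg.norm(np.diff(emb.points, axis=0), axis=1)
        assert np.all(consecutive < np.quantile(nn, 0.95) * 5)


class TestKde:
    def test_two_clusters_denser_than_gap(self, rng):
        # two compact (disk-supported) clusters far apart: every sampled
        # point must be denser than the empty midpoint between them
        def disk(n, center, r=0.5):
            th = rng.uniform(0, 2 * np.pi, n)
            rad = r * np.sqrt(rng.uniform(0, 1, n))
            return np.column_stack([rad * np.cos(th), rad * np.sin(th)]) + center

        pts = np.vstack([disk(1000, [0.0, 0.0]), disk(1000, [12.0, 0.0])])
        from rnalandscape.elvim import Embedding

        emb = Embedding(points=pts, stress=0.0,
                        stress_history=np.zeros(1), n_iter=1, seed=0)
        dens = kde_density(emb)
        from scipy.stats import gaussian_kde

        gap = gaussian_kde(pts.T)([[6.0], [0.0]])[0]
        assert dens.min() > gap

    def test_uniform_grid_density_is_flat_in_the_bulk(self):
        from rnalandscape.elvim import Embedding

        xs, ys = np.meshgrid(np.arange(20.0), np.arange(20.0))
        pts = np.column_stack([xs.ravel(), ys.ravel()])
        emb = Embedding(points=pts, stress=0.0, stress_history=np.zeros(1),
                        n_iter=1, seed=0)
        dens = kde_density(emb)
        interior = dens[
            (pts[:, 0] > 4) & (pts[:, 0] < 15) & (pts[:, 1] > 4) & (pts[:, 1] < 15)
        ]
        assert interior.std() / interior.mean() < 0.1

    def test_density_normalizes_over_covering_grid(self, rng):
        from rnalandscape.elvim import Embedding
        from scipy.stats import gaussian_kde

        pts = rng.normal(size=(150, 2))
        emb = Embedding(points=pts, stress=0.0, stress_history=np.zeros(1),
                        n_iter=1, seed=0)
        kde_density(emb)
        kde = gaussian_kde(pts.T)
        g = np.linspace(-8, 8, 200)
        xs, ys = np.meshgrid(g, g)
        vals = kde(np.vstack([xs.ravel(), ys.ravel()]))
        integral = vals.sum() * (g[1] - g[0]) ** 2
        assert integral == pytest.approx(1.0, abs=0.01)
        assert emb.density.min() >= 0.0

    def test_degenerate_point_set_is_an_error(self):
        from rnalandscape.elvim import Embedding

        emb = Embedding(points=np.zeros((10, 2)), stress=0.0,
                        stress_history=np.zeros(1), n_iter=1, seed=0)
        with pytest.raises(ValueError, match="degenerate"):
            kde_density(emb)


class TestLocalSignature:
    def test_identical_frames_zero_mean_drmsd(self, hairpin):
        cg, _ = hairpin
        frames = np.repeat(cg.xyz[None], 3, axis=0)
        sig = local_signature(Region(indices=[0, 1, 2]), frames)
        assert sig.mean_drmsd == 0.0

    def test_majority_frame_is_centroid(self, hairpin):
        cg, _ = hairpin
        a = cg.xyz
        b = datasets.extended_chain(cg)
        frames = np.stack([a, a, b])
        sig = local_signature(Region(indices=[0, 1, 2]), frames)
        assert sig.centroid_index == 0        # frame A, lowest index on tie

    def test_matches_brute_force_centroid(self, rng):
        frames = rng.normal(size=(20, 9, 3)) * 4.0
        region = Region(indices=np.arange(20))
        sig = local_signature(region, frames)
        from rnalandscape import drmsd

        means = [
            np.mean([drmsd(frames[i], frames[j]) for j in range(20) if j != i])
            for i in range(20)
        ]
        assert sig.centroid_index == int(np.argmin(means))
        assert sig.mean_drmsd == pytest.approx(min(means), abs=1e-9)

    def test_single_frame_region(self, hairpin):
        cg, _ = hairpin
        sig = local_signature(Region(indices=[4]), np.repeat(cg.xyz[None], 6, 0))
        assert sig.centroid_index == 4
        assert len(sig.neighbor_indices) == 0

    def test_drmsd_matrix_matches_pairwise_calls(self, rng):
        from rnalandscape import drmsd

        frames = rng.normal(size=(6, 7, 3))
        M = drmsd_matrix(frames)
        for i in range(6):
            for j in range(6):
                assert M[i, j] == pytest.approx(drmsd(frames[i], frames[j]),
                                                abs=1e-9)

    def test_density_region_contains_dense_core(self, rng):
        from rnalandscape.elvim import Embedding

        core = rng.normal(scale=0.1, size=(80, 2))
        halo = rng.normal(scale=4.0, size=(40, 2))
        emb = Embedding(points=np.vstack([core, halo]), stress=0.0,
                        stress_history=np.zeros(1), n_iter=1, seed=0)
        region = region_from_density(emb, quantile=0.3)
        assert np.isin(np.arange(80), region.indices).mean() > 0.9
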