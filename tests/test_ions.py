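"""Ion-coordination analytics: RDF, occupancy, bridging, excess ions."""

import numpy as np
import pytest

from rnalandscape import (
    BridgeSpec,
    Trajectory,
    bridging_map,
    datasets,
    morph_ensemble,
    native_contacts,
    occupancy,
    occupancy_vs_q,
    q_series,
    rdf_mg_phosphate,
)
from rnalandscape.ions import excess_ions


def _static_traj(rna_frames, ion_frames, box=150.0):
    n = len(rna_frames)
    return Trajectory(
        rna=np.asarray(rna_frames, dtype=float),
        ions=np.asarray(ion_frames, dtype=float),
        box_edge=box,
        steps=np.arange(n),
    )


@pytest.fixture(scope="module")
def still_hairpin():
    cg, _ = datasets.toy_hairpin()
    xyz = cg.xyz - cg.xyz.mean(axis=0) + 75.0   # centered in a 150 A box
    return cg, xyz


class TestRdf:
    def test_uniform_random_ions_give_flat_g(self, still_hairpin, rng):
        cg, xyz = still_hairpin
        n_frames, n_ions, box = 1500, 100, 150.0
        ions = rng.uniform(0, box, size=(n_frames, n_ions, 3))
        traj = _static_traj(np.repeat(xyz[None], n_frames, 0), ions, box)
        rdf = rdf_mg_phosphate(traj, bin_width=1.0, r_max=40.0)
        bulk = rdf.g[(rdf.r > 15) & (rdf.r < 35)]
        assert np.all(np.abs(bulk - 1.0) < 0.1)
        assert np.abs(bulk.mean() - 1.0) < 0.02

    def test_frozen_shell_gives_single_spike(self):
        # a single-nucleotide "chain" so the only phosphate is the reference
        xyz = np.array([[75.0, 75.0, 75.0], [79.0, 75.0, 75.0],
                        [83.0, 75.0, 75.0]])
        from rnalandscape.rna_model import CGStructure

        ion = xyz[0] + [5.0, 0.0, 0.0]
        traj = _static_traj(xyz[None], ion[None, None])
        rdf = rdf_mg_phosphate(traj, bin_width=0.5, r_max=12.0)
        nonzero = np.flatnonzero(rdf.g)
        assert len(nonzero) == 1
        assert rdf.r[nonzero[0]] == pytest.approx(5.25)   # bin [5.0, 5.5)

    def test_doubling_frames_leaves_g_unchanged(self, still_hairpin, rng):
        cg, xyz = still_hairpin
        box = 150.0
        ions = rng.uniform(0, box, size=(80, 30, 3))
        t1 = _static_traj(np.repeat(xyz[None], 80, 0), ions, box)
        t2 = _static_traj(np.repeat(xyz[None], 160, 0),
                          np.concatenate([ions, ions]), box)
        r1 = rdf_mg_phosphate(t1, bin_width=1.0, r_max=40.0)
        r2 = rdf_mg_phosphate(t2, bin_width=1.0, r_max=40.0)
        np.testing.assert_allclose(r1.g, r2.g, atol=1e-12)

    def test_no_ions_is_an_error(self, still_hairpin):
        cg, xyz = still_hairpin
        traj = _static_traj(xyz[None], np.zeros((1, 0, 3)))
        with pytest.raises(ValueError, match="no ions"):
            rdf_mg_phosphate(traj)


class TestOccupancy:
    def test_single_ion_counted_at_the_right_phosphate(self, still_hairpin):
        cg, xyz = still_hairpin
        ion = xyz[3 * 6] + [5.0, 0.0, 0.0]      # 5 A from P of residue 7
        traj = _static_traj(xyz[None], ion[None, None])
        counts = occupancy(traj, cutoff=8.0)
        assert counts[0, 6] == 1
        # no other phosphate within 8 A of the ion
        assert counts.sum() == (np.linalg.norm(
            xyz[0::3] - ion, axis=1) < 8.0).sum()

    def test_boundary_is_strict(self, still_hairpin):
        cg, xyz = still_hairpin
        ion = xyz[0] + [8.1, 0.0, 0.0]
        traj = _static_traj(xyz[None], ion[None, None])
        assert occupancy(traj, cutoff=8.0)[0, 0] == 0
        exact = _static_traj(xyz[None], (xyz[0] + [8.0, 0, 0])[None, None])
        assert occupancy(exact, cutoff=8.0)[0, 0] == 0

    def test_matches_brute_force_oracle(self, still_hairpin, rng):
        cg, xyz = still_hairpin
        box = 150.0
        frames = xyz + rng.normal(scale=1.0, size=(5,) + xyz.shape)
        ions = rng.uniform(0, box, size=(5, 12, 3))
        traj = _static_traj(frames, ions, box)
        counts = occupancy(traj, cutoff=8.0)
        for f in range(5):
            for p in range(cg.n_residues):
                expected = 0
                for ion in ions[f]:
                    d = frames[f, 3 * p] - ion
                    d -= box * np.round(d / box)
                    if np.linalg.norm(d) < 8.0:
                        expected += 1
                assert counts[f, p] == expected

    def test_double_counting_semantics(self, still_hairpin):
        # one ion within the cutoff of two phosphates counts toward both
        cg, xyz = still_hairpin
        p1, p2 = xyz[0::3][1], xyz[0::3][10]
        mid = 0.5 * (p1 + p2)
        sep = np.linalg.norm(p1 - p2)
        traj = _static_traj(xyz[None], mid[None, None])
        counts = occupancy(traj, cutoff=sep / 2 + 1.0)
        assert counts[0, 1] == 1 and counts[0, 10] == 1


class TestOccupancyVsQ:
    def test_single_bin_equals_plain_mean(self, still_hairpin, rng):
        cg, xyz = still_hairpin
        ions = rng.uniform(0, 150.0, size=(20, 6, 3))
        traj = _static_traj(np.repeat(xyz[None], 20, 0), ions)
        counts = occupancy(traj, cutoff=8.0)
        heat = occupancy_vs_q(counts, np.full(20, 0.62), bin_width=1.0)
        assert heat.matrix.shape[0] == 1
        np.testing.assert_allclose(heat.matrix[0], counts.mean(axis=0))

    def test_row_count_is_ceil_inverse_bin_width(self, still_hairpin):
        cg, xyz = still_hairpin
        traj = _static_traj(xyz[None], np.zeros((1, 0, 3)))
        counts = occupancy(traj, cutoff=8.0)
        heat = occupancy_vs_q(counts, np.array([0.5]), bin_width=0.05)
        assert heat.matrix.shape[0] == 20
        heat3 = occupancy_vs_q(counts, np.array([0.5]), bin_width=0.3)
        assert heat3.matrix.shape[0] == 4

    def test_empty_bins_are_nan_not_zero(self, still_hairpin):
        cg, xyz = still_hairpin
        traj = _static_traj(np.repeat(xyz[None], 4, 0), np.zeros((4, 0, 3)))
        counts = occupancy(traj, cutoff=8.0)
        heat = occupancy_vs_q(counts, np.array([0.1, 0.1, 0.9, 0.9]), 0.05)
        assert np.isnan(heat.matrix[10]).all()
        assert not np.isnan(heat.matrix[2]).any()

    def test_designed_high_q_ions_dominate_high_q_rows(self, riboswitch,
                                                       riboswitch_contacts,
                                                       rng):
        # ions scripted near residues 5-7 only when Q > 0.5
        cg, _ = riboswitch
        traj = morph_ensemble(cg, 200, unfold_fraction=1.0, noise=0.2, seed=6,
                              n_background_ions=0)
        q = q_series(traj.rna, riboswitch_contacts)
        ions = np.full((200, 3, 3), 10.0)
        for f in range(200):
            if q[f] > 0.5:
                for k, res in enumerate((5, 6, 7)):
                    ions[f, k] = traj.rna[f, 3 * (res - 1)] + rng.normal(
                        scale=1.0, size=3)
        traj2 = Trajectory(rna=traj.rna, ions=ions, box_edge=traj.box_edge,
                           steps=traj.steps)
        counts = occupancy(traj2, cutoff=8.0)
        heat = occupancy_vs_q(counts, q, bin_width=0.25)
        target = heat.matrix[3, [4, 5, 6]]     # residues 5-7 in Q in [0.75,1]
        others = np.delete(heat.matrix[3], [4, 5, 6])
        assert np.nanmin(target) > np.nanmax(others)

    def test_mismatched_lengths_rejected(self, still_hairpin):
        cg, xyz = still_hairpin
        traj = _static_traj(xyz[None], np.zeros((1, 0, 3)))
        counts = occupancy(traj, cutoff=8.0)
        with pytest.raises(ValueError, match="aligned"):
            occupancy_vs_q(counts, np.array([0.5, 0.6]), 0.05)


class TestBridgingMap:
    def test_scripted_bridge_probability(self, riboswitch):
        cg, _ = riboswitch
        traj = morph_ensemble(cg, 10, unfold_fraction=0.0, noise=0.0, seed=2,
                              n_background_ions=0,
                              bridge=BridgeSpec(28, 38, fraction=0.7, jitter=0.0))
        bmap = bridging_map(traj, cutoff=8.0, min_sep=4)
        assert bmap.matrix[27, 37] == pytest.approx(0.7, abs=1e-12)
        assert bmap.top_pair()[:2] == (28, 38)

    def test_no_ions_gives_zero_matrix(self, still_hairpin):
        cg, xyz = still_hairpin
        traj = _static_traj(np.repeat(xyz[None], 5, 0), np.zeros((5, 0, 3)))
        bmap = bridging_map(traj)
        assert bmap.matrix.sum() == 0.0

    def test_symmetry_and_near_diagonal_band(self, riboswitch):
        cg, _ = riboswitch
        traj = morph_ensemble(cg, 50, unfold_fraction=0.5, noise=0.5, seed=4,
                              bridge=BridgeSpec(28, 38, 0.5))
        bmap = bridging_map(traj, cutoff=8.0, min_sep=4)
        np.testing.assert_allclose(bmap.matrix, bmap.matrix.T)
        n = len(bmap.matrix)
        ri = np.arange(n)
        band = np.abs(ri[:, None] - ri[None, :]) < 4
        assert bmap.matrix[band].sum() == 0.0

    def test_probabilities_converge_with_frame_count(self, riboswitch):
        cg, _ = riboswitch
        small = morph_ensemble(cg, 100, unfold_fraction=0.0, noise=0.3, seed=7,
                               n_background_ions=0,
                               bridge=BridgeSpec(28, 38, 0.7))
        large = morph_ensemble(cg, 400, unfold_fraction=0.0, noise=0.3, seed=7,
                               n_background_ions=0,
                               bridge=BridgeSpec(28, 38, 0.7))
        p_small = bridging_map(small, 8.0, 4).matrix[27, 37]
        p_large = bridging_map(large, 8.0, 4).matrix[27, 37]
        assert abs(p_large - 0.7) <= abs(p_small - 0.7) + 2 / np.sqrt(400)


class TestExcessIons:
    def test_scripted_condensation_shows_positive_folded_excess(
        self, riboswitch, riboswitch_contacts
    ):
        cg, _ = riboswitch
        traj = morph_ensemble(cg, 120, unfold_fraction=1.0, noise=0.2, seed=8,
                              n_background_ions=2)
        q = q_series(traj.rna, riboswitch_contacts)
        # park two extra ions next to phosphates in folded frames only
        ions = traj.ions.copy()
        extra = np.full((120, 2, 3), 140.0)
        for f in range(120):
            if q[f] >= 0.85:
                extra[f, 0] = traj.rna[f, 3 * 27] + [3.0, 0, 0]
                extra[f, 1] = traj.rna[f, 3 * 37] + [3.0, 0, 0]
        traj2 = Trajectory(rna=traj.rna, ions=np.concatenate([ions, extra], 1),
                           box_edge=traj.box_edge, steps=traj.steps)
        result = excess_ions(traj2, q, cutoff=8.0)
        assert result["folded"] > result["unfolded"]
        assert result["folded"] > 1.0
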