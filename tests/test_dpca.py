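"""Dihedral featurization, circular embedding, weighted PCA, FES, RMSF."""

import numpy as np
import pytest

import lhcquench as lq
from lhcquench.dpca import DihedralFeatureMatrix
from lhcquench.geometry import rotation_about_axis, wrap_angle


def test_dihedrals_invariant_to_rigid_motion(two_basin):
    ensemble, _ = two_basin
    quads = lq.standard_dihedral_quadruples(ensemble)
    base = lq.compute_dihedrals(ensemble, quads).angles
    rot = rotation_about_axis(np.array([1.0, 1.0, 0.2]), 0.9)
    moved = lq.ConformationalEnsemble(
        coordinates=ensemble.coordinates @ rot.T + np.array([3.0, -7.0, 1.0]),
        topology=ensemble.topology,
    )
    after = lq.compute_dihedrals(moved, quads).angles
    assert np.nanmax(np.abs(wrap_angle(after - base))) < 1e-8


def test_embed_decode_identity(rng):
    angles = rng.uniform(-np.pi, np.pi, size=(50, 7))
    feats = DihedralFeatureMatrix(angles, tuple((i, "phi") for i in range(7)))
    emb = lq.circular_embed(feats)
    decoded = np.arctan2(emb[:, 1::2], emb[:, 0::2])
    assert np.allclose(wrap_angle(decoded - angles), 0.0, atol=1e-12)


@pytest.mark.parametrize("theta,expected", [(0.0, (1.0, 0.0)), (np.pi, (-1.0, 0.0))])
def test_embed_cardinal_angles(theta, expected):
    emb = lq.circular_embed(np.array([[theta]]))
    assert emb[0] == pytest.approx(expected, abs=1e-15)


class TestFitPCA:
    def test_identical_frames_zero_eigenvalues(self):
        x = np.tile(np.arange(6.0), (10, 1))
        model = lq.fit_pca(x)
        assert np.all(np.abs(model.eigenvalues) < 1e-12)

    def test_line_gives_one_nonzero_eigenvalue(self, rng):
        t = rng.normal(size=40)
        direction = np.array([1.0, -2.0, 0.5, 3.0])
        x = np.outer(t, direction) + rng.normal(size=4)  # fixed offset
        model = lq.fit_pca(x)
        assert model.eigenvalues[0] > 1e-3
        assert np.all(model.eigenvalues[1:] < 1e-10 * model.eigenvalues[0])

    def test_matches_sklearn_uniform_weights(self, rng):
        """Uniform-weight path agrees with scikit-learn's PCA oracle."""
        from sklearn.decomposition import PCA

        x = rng.normal(size=(60, 8))
        model = lq.fit_pca(x)
        sk = PCA().fit(x)
        # sklearn uses ddof=1; ours is ddof=0
        assert np.allclose(model.eigenvalues, sk.explained_variance_ * (59 / 60),
                           rtol=1e-8)
        for ours, theirs in zip(model.components, sk.components_):
            dot = abs(float(ours @ theirs))
            assert dot == pytest.approx(1.0, abs=1e-8)

    def test_components_orthonormal(self, rng):
        x = rng.normal(size=(50, 6))
        model = lq.fit_pca(x, frame_weights=rng.uniform(0.5, 2.0, size=50))
        gram = model.components @ model.components.T
        assert np.allclose(gram, np.eye(6), atol=1e-8)
        assert np.all(np.diff(model.eigenvalues) <= 1e-12)

    def test_sign_convention_deterministic(self, rng):
        x = rng.normal(size=(30, 5))
        m1, m2 = lq.fit_pca(x), lq.fit_pca(x[::-1].copy())
        for c1, c2 in zip(m1.components[:3], m2.components[:3]):
            assert np.allclose(c1, c2, atol=1e-8)

    def test_planted_two_basins_dominate_pc1(self, two_basin_features):
        emb = lq.circular_embed(two_basin_features)
        model = lq.fit_pca(emb)
        explained = model.eigenvalues / model.eigenvalues.sum()
        assert explained[0] >= 5 * explained[1]


class TestProjection:
    def test_scores_variance_equals_eigenvalues(self, rng):
        x = rng.normal(size=(80, 6)) @ np.diag([3, 2, 1, 0.5, 0.2, 0.1])
        model = lq.fit_pca(x)
        proj = lq.project(model, x)
        var = proj.scores.var(axis=0, ddof=0)
        assert np.allclose(var, model.eigenvalues, rtol=1e-6, atol=1e-12)

    def test_mean_projects_to_zero(self, rng):
        x = rng.normal(size=(20, 4))
        model = lq.fit_pca(x)
        proj = lq.project(model, model.mean)
        assert np.allclose(proj.scores, 0.0, atol=1e-10)

    def test_reconstruction_with_all_components(self, rng):
        x = rng.normal(size=(25, 5))
        model = lq.fit_pca(x)
        scores = lq.project(model, x).scores
        recon = scores @ model.components + model.mean
        assert np.allclose(recon, x, atol=1e-8)

    def test_pc1_only_shift_changes_only_column1(self, rng):
        x = rng.normal(size=(30, 5))
        model = lq.fit_pca(x)
        base = model.mean.copy()
        shifted = base + 2.5 * model.components[0]
        diff = lq.project(model, np.vstack([base, shifted])).scores
        delta = diff[1] - diff[0]
        assert delta[0] == pytest.approx(2.5, abs=1e-8)
        assert np.all(np.abs(delta[1:]) < 1e-8)

    def test_dimension_mismatch(self, rng):
        model = lq.fit_pca(rng.normal(size=(10, 4)))
        with pytest.raises(ValueError):
            lq.project(model, rng.normal(size=(10, 5)))


class TestFreeEnergySurface:
    def test_two_bin_ratio_one_kT(self):
        """Occupancy ratio 1 : e gives a free-energy gap of exactly 1 kT."""
        n_hi, n_lo = 2000, int(round(2000 / np.e))
        xy = np.concatenate([
            np.tile([[0.25, 0.5]], (n_hi, 1)),
            np.tile([[0.75, 0.5]], (n_lo, 1)),
        ])
        fes = lq.free_energy_surface(xy, bins=2, range_=[[0, 1], [0, 1]])
        finite = fes.free_energy[np.isfinite(fes.free_energy)]
        assert finite.min() == 0.0
        gap = finite.max() - finite.min()
        assert gap == pytest.approx(-np.log(n_lo / n_hi), abs=1e-12)

    def test_flat_density_flat_surface(self, rng):
        n, bins = 200_000, 5
        xy = rng.uniform(0, 1, size=(n, 2))
        fes = lq.free_energy_surface(xy, bins=bins, range_=[[0, 1], [0, 1]])
        bound = 3.0 / np.sqrt(n / bins**2)
        assert np.nanmax(np.abs(fes.free_energy)) < 2 * bound + 0.05

    def test_weight_scaling_invariance(self, rng):
        xy = rng.normal(size=(500, 2))
        w = rng.uniform(0.1, 1.0, size=500)
        f1 = lq.free_energy_surface(xy, w, bins=10)
        f2 = lq.free_energy_surface(xy, w * 37.5, bins=10)
        finite = np.isfinite(f1.free_energy)
        assert np.array_equal(finite, np.isfinite(f2.free_energy))
        assert np.allclose(f1.free_energy[finite], f2.free_energy[finite], atol=1e-12)

    def test_double_well_gap_recovered(self, rng):
        """Two-Gaussian density with a planted 2 kT basin gap."""
        n = 100_000
        w2 = np.exp(-2.0)
        n2 = int(round(n * w2 / (1 + w2)))
        n1 = n - n2
        pts = np.concatenate([
            rng.normal([-2.0, 0.0], 0.5, size=(n1, 2)),
            rng.normal([2.0, 0.0], 0.5, size=(n2, 2)),
        ])
        fes = lq.free_energy_surface(pts, bins=40, range_=[[-4, 4], [-2, 2]])
        nx = fes.free_energy.shape[0]
        left = np.nanmin(np.where(np.isfinite(fes.free_energy[: nx // 2]),
                                  fes.free_energy[: nx // 2], np.inf))
        right = np.nanmin(np.where(np.isfinite(fes.free_energy[nx // 2:]),
                                   fes.free_energy[nx // 2:], np.inf))
        assert abs((right - left) - 2.0) < 0.2


class TestResidueFluctuations:
    def test_identical_frames_zero(self, rng):
        spec = lq.make_basin_spec(n_frames=1, n_residues=8,
                                  planted_residues=(3, 5, 7), seed=0)
        ens, _ = lq.generate_ensemble(spec)
        coords = np.tile(ens.coordinates, (5, 1, 1))
        dup = lq.ConformationalEnsemble(coordinates=coords, topology=ens.topology)
        out = lq.residue_fluctuations(dup)
        assert np.allclose(out["rmsf_A"], 0.0, atol=1e-10)

    def test_rigid_rotations_removed(self, rng):
        spec = lq.make_basin_spec(n_frames=1, n_residues=8,
                                  planted_residues=(3, 5, 7), seed=1)
        ens, _ = lq.generate_ensemble(spec)
        base = ens.coordinates[0]
        frames = []
        for k in range(6):
            rot = rotation_about_axis(rng.normal(size=3) + 0.1, rng.uniform(0, np.pi))
            frames.append(base @ rot.T + rng.normal(size=3) * 4)
        moved = lq.ConformationalEnsemble(
            coordinates=np.stack(frames), topology=ens.topology)
        out = lq.residue_fluctuations(moved)
        assert np.allclose(out["rmsf_A"], 0.0, atol=1e-6)

    def test_jittered_residue_rmsf_matches_noise_model(self, rng):
        """One residue jittered with isotropic sigma=0.5 A: its RMSF
        approaches sigma*sqrt(3) (Monte Carlo of the stated model)."""
        spec = lq.make_basin_spec(n_frames=1, n_residues=10,
                                  planted_residues=(3, 5, 7), seed=2)
        ens, _ = lq.generate_ensemble(spec)
        base = ens.coordinates[0]
        n_frames, sigma = 2000, 0.5
        coords = np.tile(base, (n_frames, 1, 1))
        target = ens.topology["res_id"].to_numpy() == 5
        coords[:, target] += rng.normal(0, sigma, size=(n_frames, target.sum(), 3))
        jit = lq.ConformationalEnsemble(coordinates=coords, topology=ens.topology)
        out = lq.residue_fluctuations(jit)
        got = float(out.loc[out["res_id"] == 5, "rmsf_A"].iloc[0])
        assert got == pytest.approx(sigma * np.sqrt(3), rel=0.1)
        others = out.loc[out["res_id"] != 5, "rmsf_A"]
        assert np.all(others < 0.1)

    def test_single_frame_errors(self):
        spec = lq.make_basin_spec(n_frames=1, n_residues=8,
                                  planted_residues=(3, 5, 7), seed=0)
        ens, _ = lq.generate_ensemble(spec)
        with pytest.raises(ValueError):
            lq.residue_fluctuations(ens)
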