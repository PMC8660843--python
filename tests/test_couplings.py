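"""TrEsp Coulomb couplings and the rigid-sphere overlap parameter."""

import numpy as np
import pytest

import lhcquench as lq
from lhcquench.geometry import rotation_about_axis
from lhcquench.couplings import sphere_intersection_volume

# CODATA 2022 printed values, assembled independently of the package
HARTREE_CM1 = 2.1947463136314e7 / 100.0
BOHR_A = 0.529177210544
K_ORACLE = HARTREE_CM1 * BOHR_A


def _naive_coupling(ca, qa, cb, qb):
    v = 0.0
    for i in range(len(ca)):
        for j in range(len(cb)):
            v += qa[i] * qb[j] / np.linalg.norm(ca[i] - cb[j])
    return K_ORACLE * v


class TestCoulomb:
    def test_zero_charges_exact_zero(self, rng):
        ca, cb = rng.normal(size=(5, 3)), rng.normal(size=(5, 3)) + 10
        assert lq.coulomb_coupling(ca, np.zeros(5), cb, rng.normal(size=5)) == 0.0

    def test_constant_assembly_spot_value(self):
        """q = +0.1 e and -0.2 e at 4.0 A: V = K * (-0.005) cm^-1 with K
        assembled from CODATA before the build."""
        v = lq.coulomb_coupling([[0, 0, 0]], [0.1], [[0, 0, 4.0]], [-0.2])
        assert v == pytest.approx(K_ORACLE * (-0.005), rel=1e-10)

    def test_linearity_in_charges(self, rng):
        ca, cb = rng.normal(size=(6, 3)), rng.normal(size=(4, 3)) + 8
        qa, qb = rng.normal(size=6) * 0.1, rng.normal(size=4) * 0.1
        v1 = lq.coulomb_coupling(ca, qa, cb, qb)
        v2 = lq.coulomb_coupling(ca, 2 * qa, cb, qb)
        assert v2 == pytest.approx(2 * v1, rel=1e-14)

    def test_matches_naive_double_loop(self, rng):
        for _ in range(5):
            ca = rng.normal(scale=3, size=(50, 3))
            cb = rng.normal(scale=3, size=(50, 3)) + np.array([12.0, 0, 0])
            qa, qb = rng.normal(size=50) * 0.05, rng.normal(size=50) * 0.05
            fast = lq.coulomb_coupling(ca, qa, cb, qb)
            slow = _naive_coupling(ca, qa, cb, qb)
            assert fast == pytest.approx(slow, rel=1e-12)

    def test_coincident_atoms_rejected(self):
        with pytest.raises(ValueError):
            lq.coulomb_coupling([[0, 0, 0]], [0.1], [[0, 0, 0]], [0.1])

    def test_joint_rigid_motion_invariance(self, rng):
        ca = rng.normal(size=(8, 3))
        cb = rng.normal(size=(8, 3)) + np.array([6.0, 0, 0])
        qa, qb = rng.normal(size=8) * 0.1, rng.normal(size=8) * 0.1
        base = lq.coulomb_coupling(ca, qa, cb, qb)
        rot = rotation_about_axis(np.array([1.0, -0.5, 2.0]), 1.1)
        shift = np.array([3.0, 4.0, -5.0])
        after = lq.coulomb_coupling(ca @ rot.T + shift, qa, cb @ rot.T + shift, qb)
        assert abs(after - base) / abs(base) < 1e-10

    def test_far_field_dipole_scaling(self):
        """Charge-neutral pigments: log-log slope of |V| vs r is -3 +- 0.05
        over r in [50, 500] A."""
        rs = np.geomspace(50, 500, 12)
        vs = []
        for r in rs:
            pair = lq.generate_pigment_pair(r)
            vs.append(abs(lq.coulomb_coupling(
                pair.coords_a, pair.charges_a.charges_e,
                pair.coords_b, pair.charges_b.charges_e)))
        slope = np.polyfit(np.log(rs), np.log(vs), 1)[0]
        assert slope == pytest.approx(-3.0, abs=0.05)


class TestOverlap:
    def test_full_containment_limit(self):
        r = 1.7
        vol = sphere_intersection_volume(np.array([0.0]), r, r)[0]
        assert vol == pytest.approx(4 / 3 * np.pi * r**3, rel=1e-12)

    def test_lens_formula_spot_value(self):
        """Equal radii R = r = 1.7 A: (pi/12)(4R+r)(2R-r)^2 = 6.4305 A^3."""
        vol = sphere_intersection_volume(np.array([1.7]), 1.7, 1.7)[0]
        assert vol == pytest.approx(np.pi / 12 * (4 * 1.7 + 1.7) * (2 * 1.7 - 1.7) ** 2,
                                    rel=1e-12)
        assert vol == pytest.approx(6.4305, abs=1e-3)

    def test_no_contact_zero(self):
        vol = sphere_intersection_volume(np.array([3.5, 10.0]), 1.7, 1.7)
        assert np.all(vol == 0.0)

    def test_unequal_radii_containment(self):
        small, big = 1.0, 3.0
        vol = sphere_intersection_volume(np.array([1.5]), small, big)[0]
        assert vol == pytest.approx(4 / 3 * np.pi * small**3, rel=1e-12)

    def test_monotone_under_separation(self, rng):
        ca = rng.normal(size=(6, 3))
        cb = rng.normal(size=(6, 3))
        els = ["C"] * 6
        prev = np.inf
        for shift in np.linspace(0, 8, 25):
            o = lq.overlap_parameter(ca, els, cb + np.array([shift, 0, 0]), els)
            assert o <= prev + 1e-10
            prev = o
        assert prev == 0.0

    def test_hydrogens_excluded_by_default(self):
        ca = np.zeros((1, 3))
        cb = np.array([[1.0, 0, 0]])
        with_h = lq.overlap_parameter(ca, ["H"], cb, ["C"])
        assert with_h == 0.0
        incl = lq.overlap_parameter(ca, ["H"], cb, ["C"],
                                    lq.SphereModel(include_hydrogens=True))
        assert incl > 0.0

    def test_sphere_scale_grows_overlap(self):
        ca, cb = np.zeros((1, 3)), np.array([[3.0, 0, 0]])
        o1 = lq.overlap_parameter(ca, ["C"], cb, ["C"], lq.SphereModel(scale=1.0))
        o2 = lq.overlap_parameter(ca, ["C"], cb, ["C"], lq.SphereModel(scale=1.2))
        assert o2 > o1


class TestEnsembleTable:
    def _ensemble_from_pair(self, pair, n_frames=4, drift=0.0):
        import pandas as pd

        def topo(chain, names):
            return pd.DataFrame({
                "chain_id": [chain] * len(names), "res_id": [1] * len(names),
                "res_name": ["PIG"] * len(names), "atom_name": list(names),
                "element": ["C"] * len(names)})

        topology = pd.concat(
            [topo("P", pair.charges_a.atom_names), topo("Q", pair.charges_b.atom_names)],
            ignore_index=True)
        frames = []
        for f in range(n_frames):
            shift = np.array([0.0, 0.0, drift * f])
            frames.append(np.concatenate([pair.coords_a, pair.coords_b + shift]))
        return lq.ConformationalEnsemble(np.stack(frames), topology)

    def _specs(self, pair, swap=False):
        a = ("P", pair.charges_a)
        b = ("Q", pair.charges_b)
        if swap:
            a, b = b, a
        return [lq.PairSpec(
            name="toy",
            selection_a=lq.AtomSelection(chain_id=a[0]), charges_a=a[1],
            selection_b=lq.AtomSelection(chain_id=b[0]), charges_b=b[1])]

    def test_identical_frames_constant_columns(self):
        pair = lq.generate_pigment_pair(5.0)
        ens = self._ensemble_from_pair(pair, n_frames=3, drift=0.0)
        table = lq.pair_couplings_over_ensemble(ens, self._specs(pair))
        assert table["V_coulomb_cm1"].nunique() == 1
        assert table["overlap_A3"].nunique() == 1

    def test_separating_frames_decrease_v_overlap_zero_first(self):
        pair = lq.generate_pigment_pair(3.2)
        ens = self._ensemble_from_pair(pair, n_frames=10, drift=1.5)
        table = lq.pair_couplings_over_ensemble(ens, self._specs(pair))
        v = table["V_coulomb_cm1"].abs().to_numpy()
        o = table["overlap_A3"].to_numpy()
        assert np.all(np.diff(v) < 0)
        assert np.all(np.diff(o) <= 1e-12)
        assert o[-1] == 0.0 and v[-1] > 0.0
        # brute-force oracle per frame
        for f in range(10):
            expected = _naive_coupling(
                ens.coordinates[f, :4], pair.charges_a.charges_e,
                ens.coordinates[f, 4:], pair.charges_b.charges_e)
            assert table["V_coulomb_cm1"].iloc[f] == pytest.approx(expected, rel=1e-10)

    def test_pair_order_symmetry(self):
        pair = lq.generate_pigment_pair(4.1, rotation=33.0)
        ens = self._ensemble_from_pair(pair, n_frames=2, drift=0.4)
        t1 = lq.pair_couplings_over_ensemble(ens, self._specs(pair))
        t2 = lq.pair_couplings_over_ensemble(ens, self._specs(pair, swap=True))
        assert np.allclose(t1["V_coulomb_cm1"], t2["V_coulomb_cm1"], rtol=1e-14)
        assert np.allclose(t1["overlap_A3"], t2["overlap_A3"], rtol=1e-14)
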