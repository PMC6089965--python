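"""H-bond criterion, tilt angles and order parameters on chain trajectories."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation
from scipy.stats import spearmanr

from zeptoassay import traj_analysis as ta
from zeptoassay.synthetic_data import GeneratorConfig, gen_chain_trajectory


def _triplet(da: float, angle_deg: float):
    """Donor at origin, H at 1 Å along x; acceptor at distance ``da`` from the
    donor positioned so the D–H–A angle equals ``angle_deg``."""
    d = np.array([0.0, 0.0, 0.0])
    h = np.array([1.0, 0.0, 0.0])
    # place A by rotating the H->D direction by (180 - angle) about z at H
    theta = np.radians(180.0 - angle_deg)
    direction = np.array([np.cos(theta), np.sin(theta), 0.0])
    # solve |h + r*direction - d| = da for r > 0
    b = 2 * np.dot(h - d, direction)
    c = np.dot(h - d, h - d) - da**2
    r = (-b + np.sqrt(b**2 - 4 * c)) / 2
    a = h + r * direction
    return d, h, a


class TestHBondPresent:
    @pytest.mark.parametrize(
        "da, angle, expected",
        [
            (2.9, 165.0, True),
            (3.2, 179.0, False),  # distance fails
            (3.0, 180.0, True),  # inclusive boundary
            (2.5, 150.0, True),  # inclusive angle boundary
            (2.5, 140.0, False),  # angle fails
        ],
    )
    def test_criterion(self, da, angle, expected):
        d, h, a = _triplet(da, angle)
        assert ta.hbond_present(d, h, a) is expected

    def test_rigid_motion_invariance(self, rng):
        """Criterion is unchanged by 100 random rotations + translations."""
        d, h, a = _triplet(2.95, 155.0)
        base = ta.hbond_present(d, h, a)
        pts = np.stack([d, h, a])
        for _ in range(100):
            rot = Rotation.random(rng=rng).as_matrix()
            shift = rng.normal(0, 50, 3)
            moved = pts @ rot.T + shift
            assert ta.hbond_present(*moved) is base

    def test_coincident_hydrogen_rejected(self):
        p = np.zeros(3)
        with pytest.raises(ValueError):
            ta.hbond_present(p, p, np.array([1.0, 0, 0]))


class TestChainTilt:
    @pytest.mark.parametrize(
        "v, expected",
        [((0, 0, 1), 0.0), ((1, 0, 0), 90.0), ((1, 0, 1), 45.0)],
    )
    def test_angles(self, v, expected):
        assert ta.chain_tilt_theta(np.zeros(3), np.array(v, float)) == pytest.approx(expected)

    def test_antipodal_sum(self, rng):
        for _ in range(20):
            v = rng.normal(size=3)
            t1 = ta.chain_tilt_theta(np.zeros(3), v)
            t2 = ta.chain_tilt_theta(np.zeros(3), -v)
            assert t1 + t2 == pytest.approx(180.0, abs=1e-9)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            ta.chain_tilt_theta(np.ones(3), np.ones(3))


def _traj_from_units(u):
    """Trajectory whose chain vectors are the given unit vectors (frames, chains, 3)."""
    u = np.asarray(u, float)
    s = np.zeros_like(u)
    ids = tuple(f"c{i}" for i in range(u.shape[1]))
    return ta.ChainTrajectory(sulfur=s, oxygen=u, chain_ids=ids)


class TestOrderParameters:
    def test_aligned_gives_one(self):
        u = np.tile(np.array([0.0, 0.0, 1.0]), (5, 8, 1))
        traj = _traj_from_units(u)
        assert ta.nematic_p2(traj, "z") == pytest.approx(1.0)
        assert ta.nematic_p2(traj, "director") == pytest.approx(1.0)
        assert ta.dynamic_s(traj) == pytest.approx(1.0)

    def test_perpendicular_gives_minus_half(self, rng):
        phi = rng.uniform(0, 2 * np.pi, (4, 50))
        u = np.stack([np.cos(phi), np.sin(phi), np.zeros_like(phi)], axis=-1)
        traj = _traj_from_units(u)
        assert ta.nematic_p2(traj, "z") == pytest.approx(-0.5, abs=1e-12)
        assert ta.dynamic_s(traj) == pytest.approx(-0.5, abs=1e-12)

    def test_isotropic_bounds(self, rng):
        """1e4 isotropic orientations: director P2 <= 0.03, |S| <= 0.03."""
        u = rng.normal(size=(100, 100, 3))
        u /= np.linalg.norm(u, axis=-1, keepdims=True)
        traj = _traj_from_units(u)
        assert ta.nematic_p2(traj, "director") <= 0.03
        assert abs(ta.nematic_p2(traj, "z")) <= 0.03
        assert abs(ta.dynamic_s(traj)) <= 0.03

    def test_director_dominates_fixed_axis(self, rng):
        """The director maximizes the projection, so director P2 >= fixed-axis P2."""
        for seed in range(5):
            cfg = GeneratorConfig(seed=seed, trajectory=(25, 20, 2.0, 0.5))
            traj = gen_chain_trajectory(cfg)
            assert ta.nematic_p2(traj, "director") >= ta.nematic_p2(traj, "z") - 1e-12

    def test_wobble_vs_frozen_tilt_separated_by_s(self, rng):
        """S distinguishes stably tilted chains (S < 0 past the magic angle)
        from isotropically wobbling ones (S ~ 0); fixed-axis P2 alone cannot."""
        theta = np.radians(75.0)
        phi = rng.uniform(0, 2 * np.pi, (200, 40))
        tilted = np.stack(
            [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi),
             np.full_like(phi, np.cos(theta))], axis=-1)
        s_tilted = ta.dynamic_s(_traj_from_units(tilted))
        assert s_tilted < -0.2

        wobble = rng.normal(size=(200, 40, 3))
        wobble /= np.linalg.norm(wobble, axis=-1, keepdims=True)
        assert abs(ta.dynamic_s(_traj_from_units(wobble))) < 0.05

    def test_single_frame_dynamic_s_rejected(self):
        traj = _traj_from_units(np.tile([0.0, 0.0, 1.0], (1, 4, 1)))
        with pytest.raises(ValueError):
            ta.dynamic_s(traj)

    def test_order_params_summary(self):
        cfg = GeneratorConfig(seed=0, trajectory=(16, 30, 5.0, 0.5))
        op = ta.order_params(gen_chain_trajectory(cfg))
        assert -0.5 <= op.p2 <= op.p2_director <= 1.0
        assert 0.0 <= op.mean_theta <= 90.0


class TestOccupancy:
    def test_always_bonded(self):
        cfg = GeneratorConfig(seed=1, trajectory=(4, 50, 1.0, 1.0))
        traj = gen_chain_trajectory(cfg)
        for pair in traj.hbond_pairs:
            assert ta.hbond_occupancy(traj, pair) == 100.0

    def test_half_bonded_exact(self):
        cfg = GeneratorConfig(seed=1, trajectory=(3, 100, 1.0, 1.0))
        traj = gen_chain_trajectory(cfg)
        # break the bond in the last 50 frames of the first pair
        acceptor = traj.hbond_acceptor.copy()
        acceptor[50:, 0] = traj.hbond_donor[50:, 0] + np.array([3.8, 0, 0])
        broken = ta.ChainTrajectory(
            sulfur=traj.sulfur, oxygen=traj.oxygen, chain_ids=traj.chain_ids,
            hbond_donor=traj.hbond_donor, hbond_hydrogen=traj.hbond_hydrogen,
            hbond_acceptor=acceptor, hbond_pairs=traj.hbond_pairs,
        )
        assert ta.hbond_occupancy(broken, traj.hbond_pairs[0]) == pytest.approx(50.0)

    def test_bernoulli_recovery(self):
        """Requested 70% occupancy over 1e4 frame-pairs recovered within 1.5%."""
        cfg = GeneratorConfig(seed=3, trajectory=(101, 100, 1.0, 0.7))
        traj = gen_chain_trajectory(cfg)
        occ = ta.occupancy_table(traj)["occupancy_pct"]
        assert occ.mean() == pytest.approx(70.0, abs=1.5)

    def test_unknown_pair(self):
        cfg = GeneratorConfig(seed=1, trajectory=(4, 10, 1.0, 0.5))
        traj = gen_chain_trajectory(cfg)
        with pytest.raises(KeyError):
            ta.hbond_occupancy(traj, ("nope", "nada"))


class TestTrajectoryValidation:
    def test_wrapped_triplet_rejected(self):
        n_f, n_c = 2, 2
        s = np.zeros((n_f, n_c, 3))
        o = s + np.array([0, 0, 4.0])
        d = np.zeros((n_f, 1, 3))
        h = d + np.array([1.0, 0, 0])
        a = d + np.array([150.0, 0, 0])  # absurd span: wrapped coordinates
        with pytest.raises(ValueError, match="wrapped"):
            ta.ChainTrajectory(
                sulfur=s, oxygen=o, chain_ids=("a", "b"),
                hbond_donor=d, hbond_hydrogen=h, hbond_acceptor=a,
                hbond_pairs=(("a", "b"),),
            )

    def test_noncovalent_hydrogen_rejected(self):
        n_f, n_c = 2, 2
        s = np.zeros((n_f, n_c, 3))
        o = s + np.array([0, 0, 4.0])
        d = np.zeros((n_f, 1, 3))
        h = d + np.array([2.0, 0, 0])  # H too far from its donor
        a = d + np.array([2.9, 0, 0])
        with pytest.raises(ValueError, match="covalent"):
            ta.ChainTrajectory(
                sulfur=s, oxygen=o, chain_ids=("a", "b"),
                hbond_donor=d, hbond_hydrogen=h, hbond_acceptor=a,
                hbond_pairs=(("a", "b"),),
            )


def test_generated_order_monotone_in_concentration():
    """Measured P2 increases monotonically with the generator's order
    parameter (Spearman rho = 1 across 10 levels)."""
    levels = np.linspace(0.0, 18.0, 10)
    p2 = []
    for a in levels:
        cfg = GeneratorConfig(seed=11, trajectory=(60, 60, float(a), 0.5))
        p2.append(ta.nematic_p2(gen_chain_trajectory(cfg), "z"))
    rho, _ = spearmanr(levels, p2)
    assert rho == pytest.approx(1.0)
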