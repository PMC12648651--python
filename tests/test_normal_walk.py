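"""Kabsch RMSD against a brute-force rotational search, walk-step
arithmetic, ensemble statistics, and the similarity-reduction walk."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from peas.chem_core import Conformer, Ensemble, synth_ensemble
from peas.normal_walk import (
    ensemble_rmsd_stats,
    normal_walk_reduce,
    svd_rmsd,
    walk_steps,
)


def _direct_rmsd(P, Q, rot):
    d = P @ rot.T - Q
    return float(np.sqrt((d * d).sum() / len(P)))


@pytest.fixture(scope="module")
def euler_grid():
    """2°-spaced zyz Euler grid over SO(3), as stacked rotation matrices."""
    a = np.deg2rad(np.arange(0, 360, 2.0))
    b = np.deg2rad(np.arange(0, 182, 2.0))
    g = np.deg2rad(np.arange(0, 360, 2.0))
    angles = np.stack(np.meshgrid(a, b, g, indexing="ij"), axis=-1).reshape(-1, 3)
    return Rotation.from_euler("zyz", angles).as_matrix()


def brute_force_rmsd(P, Q, grid):
    """Independent oracle: scan every grid rotation for the smallest direct
    RMSD between the centered point sets, then polish the best candidate
    with a local rotation-vector minimization of the direct RMSD."""
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    # RMSD^2 = (|P|^2 + |Q|^2 - 2 tr(R C)) / N with C the cross-covariance:
    # scanning tr(R C) scans the direct RMSD over the whole grid at once
    C = Qc.T @ Pc
    traces = np.einsum("nij,ji->n", grid, C)
    best = grid[np.argmax(traces)]

    def objective(w):
        return _direct_rmsd(Pc, Qc, Rotation.from_rotvec(w).as_matrix() @ best)

    res = minimize(
        objective,
        np.zeros(3),
        method="Nelder-Mead",
        options={"xatol": 1e-12, "fatol": 1e-16, "maxiter": 4000},
    )
    return float(res.fun)


class TestSvdRmsd:
    def test_identity(self, glycine):
        assert svd_rmsd(glycine.coords, glycine.coords) < 1e-12

    def test_rigid_transform_gives_zero(self, glycine):
        rng = np.random.default_rng(1)
        rot = Rotation.random(rng=rng).as_matrix()
        moved = glycine.coords @ rot.T + rng.normal(0, 5, 3)
        assert svd_rmsd(glycine.coords, moved) < 1e-9

    def test_symmetric(self, glycine):
        rng = np.random.default_rng(2)
        other = glycine.coords + rng.normal(0, 0.3, glycine.coords.shape)
        assert svd_rmsd(glycine.coords, other) == pytest.approx(
            svd_rmsd(other, glycine.coords), abs=1e-12
        )

    def test_invariant_to_common_rigid_transform(self, glycine):
        rng = np.random.default_rng(3)
        other = glycine.coords + rng.normal(0, 0.3, glycine.coords.shape)
        rot = Rotation.random(rng=rng).as_matrix()
        shift = rng.normal(0, 4, 3)
        before = svd_rmsd(glycine.coords, other)
        after = svd_rmsd(glycine.coords @ rot.T + shift, other @ rot.T + shift)
        assert after == pytest.approx(before, abs=1e-9)

    def test_atom_count_mismatch_rejected(self):
        with pytest.raises(ValueError):
            svd_rmsd(np.zeros((3, 3)), np.zeros((4, 3)))

    def test_matches_rotation_grid_oracle_on_displaced_fixture(self, euler_grid):
        """4-atom pair with one atom displaced 0.5 Å: Kabsch equals the
        brute-force rotational search to 1e-6 Å."""
        P = np.array([[0.0, 0, 0], [1.5, 0, 0], [0, 1.5, 0], [0, 0, 1.5]])
        Q = P.copy()
        Q[3, 2] += 0.5
        assert svd_rmsd(P, Q) == pytest.approx(brute_force_rmsd(P, Q, euler_grid), abs=1e-6)

    def test_matches_rotation_grid_oracle_on_random_pairs(self, euler_grid):
        """>= 20 random 4-8 atom pairs: Kabsch agrees with the brute-force
        2°-grid search (plus local polish) within 1e-6 Å."""
        rng = np.random.default_rng(42)
        for _ in range(20):
            n = int(rng.integers(4, 9))
            P = rng.normal(0, 2.0, (n, 3))
            Q = P + rng.normal(0, 0.4, (n, 3))
            rot = Rotation.random(rng=rng).as_matrix()
            Q = Q @ rot.T + rng.normal(0, 3, 3)
            assert svd_rmsd(P, Q) == pytest.approx(
                brute_force_rmsd(P, Q, euler_grid), abs=1e-6
            )


class TestWalkSteps:
    @pytest.mark.parametrize("rot, expected", [(1, 20), (5, 100), (0, 1), (6, 120)])
    def test_step_count(self, rot, expected):
        assert walk_steps(rot) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            walk_steps(-1)


class TestEnsembleStats:
    def test_identical_conformers_all_zero(self, glycine):
        ens = synth_ensemble(glycine, n=5, noise_sd=0.0, seed=1)
        rep = ensemble_rmsd_stats(ens)
        for v in (rep.mean, rep.sd, rep.rmsd_min, rep.rmsd_max):
            assert v == pytest.approx(0.0, abs=1e-9)

    def test_hand_placed_rmsds_arithmetic(self, butane):
        """Two members at RMSD 0.2 and 0.6 from the reference: mean 0.4,
        population sd 0.2, min 0.2, max 0.6."""
        base = butane.coords
        # build geometries with exact RMSD by scaling a fixed distortion
        rng = np.random.default_rng(7)
        direction = rng.normal(0, 1.0, base.shape)

        def with_rmsd(target):
            lo, hi = 0.0, 10.0
            for _ in range(80):
                mid = 0.5 * (lo + hi)
                if svd_rmsd(base + mid * direction, base) < target:
                    lo = mid
                else:
                    hi = mid
            return base + 0.5 * (lo + hi) * direction

        confs = [
            Conformer("ref", base, energy=0.0),
            Conformer("a", with_rmsd(0.2), energy=1.0),
            Conformer("b", with_rmsd(0.6), energy=2.0),
        ]
        rep = ensemble_rmsd_stats(Ensemble(molecule=butane, conformers=confs))
        assert rep.reference_id == "ref"
        assert rep.mean == pytest.approx(0.4, abs=1e-6)
        assert rep.sd == pytest.approx(0.2, abs=1e-6)
        assert rep.rmsd_min == pytest.approx(0.2, abs=1e-6)
        assert rep.rmsd_max == pytest.approx(0.6, abs=1e-6)

    def test_reference_is_lowest_energy(self, glycine):
        ens = synth_ensemble(glycine, n=6, noise_sd=0.3, seed=2)
        rep = ensemble_rmsd_stats(ens)
        energies = [c.energy for c in ens]
        assert rep.reference_index == int(np.argmin(energies))
        assert rep.rmsds[rep.reference_index] == 0.0

    def test_too_small_ensemble_rejected(self, glycine):
        ens = synth_ensemble(glycine, n=1, noise_sd=0.1, seed=3)
        with pytest.raises(ValueError):
            ensemble_rmsd_stats(ens)


class TestNormalWalkReduce:
    def test_small_ensemble_bypasses(self, glycine):
        ens = synth_ensemble(glycine, n=40, noise_sd=0.2, seed=4)
        assert normal_walk_reduce(ens, size_threshold=50) is ens

    def test_identical_conformers_collapse_to_reference(self, alkanes):
        mol = alkanes[2]
        ens = synth_ensemble(mol, n=200, noise_sd=0.0, seed=5)
        reduced = normal_walk_reduce(ens, size_threshold=50)
        energies = [c.energy for c in ens]
        ref_id = ens.conformers[int(np.argmin(energies))].conf_id
        assert [c.conf_id for c in reduced] == [ref_id] or len(reduced) == 1

    def test_binned_walk_matches_interval_oracle(self, alkanes):
        """ROT=2 -> 40 steps; each occupied interval keeps exactly its
        lowest-energy member, checked by an exhaustive per-interval scan."""
        mol = alkanes[2]
        ens = synth_ensemble(mol, n=200, noise_sd=0.35, seed=6)
        reduced = normal_walk_reduce(ens, size_threshold=50)
        assert len(reduced) <= 41

        rep = ensemble_rmsd_stats(ens)
        edges = np.linspace(rep.rmsd_min, rep.rmsd_max, rep.steps + 1)
        expected = {rep.reference_index}
        for b in range(rep.steps):
            members = [
                i
                for i in range(len(ens))
                if i != rep.reference_index
                and (
                    edges[b] <= rep.rmsds[i] < edges[b + 1]
                    or (b == rep.steps - 1 and rep.rmsds[i] == edges[-1])
                    or (b == 0 and rep.rmsds[i] < edges[0])
                )
            ]
            if members:
                expected.add(min(members, key=lambda i: (ens.conformers[i].energy, i)))
        got = {c.conf_id for c in reduced}
        assert got == {ens.conformers[i].conf_id for i in expected}

    @pytest.mark.parametrize("variant", ["binned", "quantile"])
    def test_invariants_both_variants(self, alkanes, variant):
        mol = alkanes[3]
        ens = synth_ensemble(mol, n=120, noise_sd=0.3, seed=7)
        reduced = normal_walk_reduce(ens, size_threshold=50, variant=variant)
        ids_in = [c.conf_id for c in ens]
        ids_out = [c.conf_id for c in reduced]
        assert set(ids_out) <= set(ids_in)
        assert ids_out == [i for i in ids_in if i in set(ids_out)]  # order preserved
        assert len(reduced) <= 20 * 3 + 1
        emin_id = min(ens.conformers, key=lambda c: c.energy).conf_id
        assert emin_id in ids_out

    def test_deterministic_and_idempotent(self, alkanes):
        ens = synth_ensemble(alkanes[1], n=150, noise_sd=0.3, seed=8)
        r1 = normal_walk_reduce(ens, size_threshold=50)
        r2 = normal_walk_reduce(ens, size_threshold=50)
        assert [c.conf_id for c in r1] == [c.conf_id for c in r2]
        assert len(r1) <= 21
        again = normal_walk_reduce(r1, size_threshold=50)
        assert again is r1  # already below threshold

    def test_survivors_monotone_in_rot(self, glycine, monkeypatch):
        """On one fixed ensemble, more rotatable bonds mean nested finer
        walk bins, so the survivor count never decreases."""
        import peas.normal_walk as nw

        ens = synth_ensemble(glycine, n=180, noise_sd=0.3, seed=9)
        counts = []
        for rot in (1, 2, 4):  # steps 20/40/80 nest exactly
            monkeypatch.setattr(nw, "rotatable_bond_count", lambda mol, r=rot: r)
            counts.append(len(normal_walk_reduce(ens, size_threshold=50)))
        assert counts == sorted(counts)

    def test_unknown_variant_rejected(self, glycine):
        ens = synth_ensemble(glycine, n=60, noise_sd=0.2, seed=10)
        with pytest.raises(ValueError):
            normal_walk_reduce(ens, variant="spiral")
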