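import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from memnmr import conformers
from memnmr.conformers import (
    FilterConfig,
    ModelPool,
    build_backbone,
    filter_energy_percentile,
    filter_membrane_contact,
    filter_receptor_distance,
    measure_torsions,
    read_pool,
    write_pool,
)
from memnmr.synthetic_data import PoolRecipe, gen_pool


def _uniform_torsions(n, phi, psi, omega=180.0):
    return np.tile([phi, psi, omega], (n, 1))


class TestBuildBackbone:
    def test_bond_lengths_ideal(self):
        coords = build_backbone(_uniform_torsions(2, -60.0, 140.0))
        for i in range(2):
            assert np.linalg.norm(coords[i, 1] - coords[i, 0]) == pytest.approx(1.458, abs=1e-9)
            assert np.linalg.norm(coords[i, 2] - coords[i, 1]) == pytest.approx(1.525, abs=1e-9)
        assert np.linalg.norm(coords[1, 0] - coords[0, 2]) == pytest.approx(1.329, abs=1e-9)

    def test_alpha_helix_i_i4_distance(self):
        # Independent geometric expectation for an ideal alpha helix:
        # rise 1.5 A/res, radius ~2.3 A -> CA(i)-CA(i+4) about 6.2 A.
        coords = build_backbone(_uniform_torsions(10, -57.0, -47.0))
        ca = coords[:, 1, :]
        d = [np.linalg.norm(ca[i + 4] - ca[i]) for i in range(6)]
        assert np.mean(d) == pytest.approx(6.2, abs=0.3)

    def test_extended_chain_ca_ca(self):
        coords = build_backbone(_uniform_torsions(5, 180.0, 180.0))
        ca = coords[:, 1, :]
        for i in range(4):
            assert np.linalg.norm(ca[i + 1] - ca[i]) == pytest.approx(3.8, abs=0.1)

    def test_nonfinite_torsion_rejected(self):
        torsions = _uniform_torsions(4, -60.0, 140.0)
        torsions[2, 0] = math.nan
        with pytest.raises(ValueError, match="non-finite"):
            build_backbone(torsions)

    def test_first_residue_at_origin(self):
        coords = build_backbone(_uniform_torsions(3, -60.0, 140.0))
        assert np.allclose(coords[0, 0], 0.0)

    @settings(max_examples=25, deadline=None)
    @given(
        phi=st.floats(-179.0, 179.0),
        psi=st.floats(-179.0, 179.0),
        omega=st.floats(150.0, 179.0),
    )
    def test_torsion_round_trip(self, phi, psi, omega):
        torsions = _uniform_torsions(6, phi, psi, omega)
        measured = measure_torsions(build_backbone(torsions))
        assert np.nanmax(np.abs(measured[1:, 0] - phi)) < 1e-3
        assert np.nanmax(np.abs(measured[:-1, 1] - psi)) < 1e-3
        assert np.nanmax(np.abs(measured[1:, 2] - omega)) < 1e-3


class TestMembraneFilter:
    def _pool_at_z(self, zs):
        base = gen_pool(PoolRecipe(n_models=len(zs), seed=0, sequence="GSSF"))
        for m, z in zip(base.models, zs):
            m.coords[:, :, 2] += z - m.coords[2, 1, 2]  # anchor residue 3 CA at z
        return base

    def test_interior_point_kept(self):
        pool = self._pool_at_z([15.0])
        assert len(filter_membrane_contact(pool, FilterConfig())) == 1

    def test_bilayer_center_removed(self):
        pool = self._pool_at_z([0.0])
        assert len(filter_membrane_contact(pool, FilterConfig())) == 0

    def test_negative_leaflet_symmetric(self):
        pool = self._pool_at_z([-15.0])
        assert len(filter_membrane_contact(pool, FilterConfig())) == 1

    def test_against_bruteforce(self, rng):
        zs = rng.uniform(0.0, 30.0, size=200)
        pool = self._pool_at_z(list(zs))
        cfg = FilterConfig(slab_zmin=12.0, slab_zmax=18.0)
        kept = filter_membrane_contact(pool, cfg)
        expect = {
            m.model_id
            for m in pool.models
            if 12.0 <= abs(m.coords[2, 1, 2]) <= 18.0
        }
        assert {m.model_id for m in kept.models} == expect


class TestReceptorFilter:
    def test_far_receptor_keeps_all(self, small_pool):
        receptor = np.array([[1000.0, 0.0, 0.0]])
        kept = filter_receptor_distance(small_pool, receptor, FilterConfig())
        assert len(kept) == len(small_pool)

    def test_boundary_violation_removed(self, small_pool):
        m = small_pool.models[0]
        clash = m.coords[0, 0] + np.array([4.9, 0.0, 0.0])
        kept = filter_receptor_distance(small_pool, clash[None, :], FilterConfig())
        assert m.model_id not in {k.model_id for k in kept.models}

    def test_empty_receptor_errors(self, small_pool):
        with pytest.raises(ValueError, match="empty"):
            filter_receptor_distance(small_pool, np.empty((0, 3)), FilterConfig())

    def test_against_allpairs_bruteforce(self, medium_pool, rng):
        receptor = rng.uniform(-40.0, 40.0, size=(25, 3))
        cfg = FilterConfig(receptor_min_distance=5.0)
        kept = filter_receptor_distance(medium_pool, receptor, cfg)
        expect = set()
        for m in medium_pool.models:
            dmin = min(
                float(np.linalg.norm(a - r))
                for a in m.coords.reshape(-1, 3)
                for r in receptor
            )
            if dmin >= 5.0:
                expect.add(m.model_id)
        assert {m.model_id for m in kept.models} == expect


class TestEnergyFilter:
    def _pool_with_energies(self, energies):
        pool = gen_pool(PoolRecipe(n_models=len(energies), seed=5, sequence="GSSF"))
        for m, e in zip(pool.models, energies):
            m.energy = float(e)
        return pool

    def test_lowest_ten_percent(self):
        pool = self._pool_with_energies(range(1, 101))
        kept = filter_energy_percentile(pool, FilterConfig(energy_fraction=0.10))
        assert sorted(m.energy for m in kept.models) == list(map(float, range(1, 11)))

    def test_full_fraction_keeps_all(self):
        pool = self._pool_with_energies(range(10))
        kept = filter_energy_percentile(pool, FilterConfig(energy_fraction=1.0))
        assert len(kept) == len(pool)

    def test_all_ties_kept(self):
        pool = self._pool_with_energies([7.0] * 30)
        kept = filter_energy_percentile(pool, FilterConfig(energy_fraction=0.10))
        assert len(kept) == 30

    def test_reference_pool_threshold(self):
        reference = self._pool_with_energies(range(1, 101))
        sub = reference.subset(reference.models[:50], "first half")
        kept = filter_energy_percentile(sub, FilterConfig(energy_fraction=0.10), reference)
        # threshold from the full pool (energy <= 10), applied to the subset
        assert sorted(m.energy for m in kept.models) == list(map(float, range(1, 11)))

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            filter_energy_percentile(
                self._pool_with_energies([1.0] * 5), FilterConfig(energy_fraction=0.0)
            )


class TestFilterCommutation:
    def test_three_filters_commute(self, medium_pool, rng):
        receptor = rng.uniform(-30.0, 30.0, size=(10, 3))
        cfg = FilterConfig(slab_zmin=5.0, slab_zmax=25.0, energy_fraction=0.3)
        full = medium_pool

        def mem(p):
            return filter_membrane_contact(p, cfg)

        def rec(p):
            return filter_receptor_distance(p, receptor, cfg)

        def ene(p):
            return filter_energy_percentile(p, cfg, reference_pool=full)

        import itertools

        results = []
        for order in itertools.permutations([mem, rec, ene]):
            p = full
            for f in order:
                p = f(p)
            results.append(frozenset(m.model_id for m in p.models))
        assert len(set(results)) == 1

    def test_output_always_subset(self, medium_pool):
        cfg = FilterConfig(slab_zmin=5.0, slab_zmax=25.0)
        kept = filter_membrane_contact(medium_pool, cfg)
        ids = {m.model_id for m in medium_pool.models}
        assert {m.model_id for m in kept.models} <= ids


class TestPoolIO:
    def test_round_trip(self, small_pool, tmp_path):
        pdb = tmp_path / "pool.pdb"
        tsv = tmp_path / "energies.tsv"
        csvp = tmp_path / "shifts.csv"
        write_pool(small_pool, pdb, tsv, csvp)
        again = read_pool(pdb, tsv, csvp)
        assert again.sequence == small_pool.sequence
        assert len(again) == len(small_pool)
        for a, b in zip(again.models, small_pool.models):
            assert a.model_id == b.model_id
            assert a.energy == pytest.approx(b.energy)
            assert np.allclose(a.coords, b.coords, atol=1.5e-3)
            assert a.predicted_shifts == b.predicted_shifts

    def test_unique_model_ids_enforced(self, small_pool):
        models = [small_pool.models[0], small_pool.models[0]]
        with pytest.raises(ValueError, match="unique"):
            ModelPool(models, small_pool.sequence)

    def test_sequence_length_enforced(self, small_pool):
        with pytest.raises(ValueError):
            ModelPool(small_pool.models, small_pool.sequence + "A")
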