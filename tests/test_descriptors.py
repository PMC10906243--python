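"""ASO/AEIF grid fields, feature assembly, and dimensionality reduction."""

import numpy as np
import pytest

from pepcat import conformers as conf
from pepcat import descriptors as desc
from pepcat.errors import ConfigurationError, ValidationError
from tests.conftest import random_toy_ensemble


def brute_force_fields(ensemble, grid, charges, radii=None):
    """Triple-loop per-point evaluation of both fields (the test oracle)."""
    radii = radii or desc.BONDI_RADII
    r = [radii[s] for s in ensemble.symbols]
    pts = grid.points()
    aso = np.zeros(len(pts))
    aeif = np.zeros(len(pts))
    for g, point in enumerate(pts):
        for c in range(ensemble.n_conf):
            best_dist, best_atom = np.inf, None
            for a in range(ensemble.n_atoms):
                d = np.linalg.norm(ensemble.coords[c, a] - point)
                if d <= r[a] and d < best_dist:
                    best_dist, best_atom = d, a
            if best_atom is not None:
                aso[g] += 1.0
                aeif[g] += charges[best_atom]
    return aso / ensemble.n_conf, aeif / ensemble.n_conf


@pytest.fixture
def simple_grid():
    return desc.Grid(origin=(-2.0, -2.0, -2.0), spacing=1.0, dims=(5, 5, 5))


class TestStericField:
    def test_single_atom_indicator(self, simple_grid):
        ensemble = conf.ConformerEnsemble(
            symbols=("C",), coords=np.zeros((1, 1, 3)), energies=np.zeros(1)
        )
        aso = desc.compute_aso(ensemble, simple_grid)
        dists = np.linalg.norm(simple_grid.points(), axis=1)
        np.testing.assert_array_equal(aso, (dists <= desc.BONDI_RADII["C"]) * 1.0)

    def test_half_occupancy_when_one_of_two_conformers_covers(self, simple_grid):
        coords = np.array([[[0.0, 0.0, 0.0]], [[50.0, 50.0, 50.0]]])
        ensemble = conf.ConformerEnsemble(
            symbols=("C",), coords=coords, energies=np.zeros(2)
        )
        aso = desc.compute_aso(ensemble, simple_grid)
        origin_index = np.flatnonzero(
            (simple_grid.points() == 0.0).all(axis=1)
        )[0]
        assert aso[origin_index] == 0.5

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_oracle(self, seed, simple_grid):
        rng = np.random.default_rng(seed)
        ensemble = random_toy_ensemble(rng, n_atoms=5, n_conf=4)
        charges = rng.uniform(-0.5, 0.5, size=5)
        aso = desc.compute_aso(ensemble, simple_grid)
        aeif = desc.compute_aeif(ensemble, simple_grid, charges)
        expected_aso, expected_aeif = brute_force_fields(ensemble, simple_grid, charges)
        np.testing.assert_allclose(aso, expected_aso, atol=1e-12)
        np.testing.assert_allclose(aeif, expected_aeif, atol=1e-12)

    def test_bounds_and_duplicate_conformer_idempotence(self, simple_grid):
        rng = np.random.default_rng(3)
        ensemble = random_toy_ensemble(rng, n_atoms=4, n_conf=3)
        aso = desc.compute_aso(ensemble, simple_grid)
        assert np.all((aso >= 0) & (aso <= 1))
        doubled = conf.ConformerEnsemble(
            symbols=ensemble.symbols,
            coords=np.concatenate([ensemble.coords, ensemble.coords]),
            energies=np.concatenate([ensemble.energies, ensemble.energies]),
        )
        np.testing.assert_allclose(desc.compute_aso(doubled, simple_grid), aso, atol=1e-12)

    def test_missing_radius_names_element(self, simple_grid):
        ensemble = conf.ConformerEnsemble(
            symbols=("Xe",), coords=np.zeros((1, 1, 3)), energies=np.zeros(1)
        )
        with pytest.raises(ConfigurationError, match="Xe"):
            desc.compute_aso(ensemble, simple_grid)


class TestElectronicField:
    def test_zero_charges_give_zero_field(self, simple_grid):
        rng = np.random.default_rng(0)
        ensemble = random_toy_ensemble(rng, n_atoms=4, n_conf=2)
        aeif = desc.compute_aeif(ensemble, simple_grid, np.zeros(4))
        np.testing.assert_array_equal(aeif, 0.0)

    def test_single_covering_atom_reports_its_charge(self, simple_grid):
        ensemble = conf.ConformerEnsemble(
            symbols=("N",), coords=np.zeros((1, 1, 3)), energies=np.zeros(1)
        )
        aeif = desc.compute_aeif(ensemble, simple_grid, np.array([0.37]))
        origin_index = np.flatnonzero((simple_grid.points() == 0.0).all(axis=1))[0]
        assert aeif[origin_index] == 0.37
        assert np.max(np.abs(aeif)) <= 0.37

    def test_charge_length_mismatch_rejected(self, simple_grid):
        rng = np.random.default_rng(1)
        ensemble = random_toy_ensemble(rng, n_atoms=4, n_conf=2)
        with pytest.raises(ValidationError):
            desc.compute_aeif(ensemble, simple_grid, np.zeros(3))


class TestRigidMotionInvariance:
    def test_fields_invariant_to_prealignment_transform(self, peptide_ensemble):
        from scipy.spatial.transform import Rotation

        reference = conf.core_geometry(peptide_ensemble)
        aligned = conf.align_to_core(peptide_ensemble, reference_coords=reference)
        grid = desc.Grid.from_ensembles([aligned], spacing=1.5, margin=2.0)
        charges = desc.gasteiger_charges(aligned.mol)
        aso0 = desc.compute_aso(aligned, grid)
        aeif0 = desc.compute_aeif(aligned, grid, charges)

        rot = Rotation.random(random_state=42).as_matrix()
        moved = conf.ConformerEnsemble(
            symbols=aligned.symbols,
            coords=aligned.coords @ rot.T + np.array([3.0, -7.0, 1.0]),
            energies=aligned.energies,
            mol=aligned.mol,
        )
        realigned = conf.align_to_core(moved, reference_coords=reference)
        assert np.max(np.abs(desc.compute_aso(realigned, grid) - aso0)) < 1e-9
        assert np.max(np.abs(desc.compute_aeif(realigned, grid, charges) - aeif0)) < 1e-9


def _toy_fields(rng, grid, n_catalysts):
    fields = []
    for i in range(n_catalysts):
        aso = rng.uniform(0, 1, size=grid.n_points)
        aeif = rng.uniform(-0.4, 0.4, size=grid.n_points)
        fields.append(desc.CatalystFields(f"cat{i}", grid, aso, aeif))
    return fields


class TestFeatureMatrix:
    def test_dimension_bookkeeping(self):
        grid = desc.Grid(origin=(0, 0, 0), spacing=1.0, dims=(2, 2, 2))
        rng = np.random.default_rng(0)
        matrix = desc.assemble_feature_matrix(_toy_fields(rng, grid, 2))
        assert matrix.values.shape == (2, 16)
        assert matrix.column_provenance[0] == ("aso", 0)
        assert matrix.column_provenance[8] == ("aeif", 0)

    def test_scaling_contract(self):
        grid = desc.Grid(origin=(0, 0, 0), spacing=1.0, dims=(3, 2, 2))
        rng = np.random.default_rng(1)
        matrix = desc.assemble_feature_matrix(_toy_fields(rng, grid, 8))
        assert np.max(np.abs(matrix.values.mean(axis=0))) < 1e-9
        assert np.max(np.abs(matrix.values.var(axis=0) - 1.0)) < 1e-9

    def test_stored_scaling_round_trips_bit_for_bit(self):
        grid = desc.Grid(origin=(0, 0, 0), spacing=1.0, dims=(2, 2, 2))
        rng = np.random.default_rng(2)
        fields = _toy_fields(rng, grid, 5)
        matrix = desc.assemble_feature_matrix(fields)
        raw = np.stack([np.concatenate([f.aso, f.aeif]) for f in fields])
        np.testing.assert_array_equal(matrix.transform(raw), matrix.values)

    def test_grid_mismatch_rejected(self):
        rng = np.random.default_rng(3)
        g1 = desc.Grid(origin=(0, 0, 0), spacing=1.0, dims=(2, 2, 2))
        g2 = desc.Grid(origin=(0, 0, 0), spacing=2.0, dims=(2, 2, 2))
        fields = _toy_fields(rng, g1, 1) + _toy_fields(rng, g2, 1)
        with pytest.raises(ValidationError, match="grid"):
            desc.assemble_feature_matrix(fields)


class TestReduceFeatures:
    def _matrix(self, values):
        values = np.asarray(values, float)
        n, m = values.shape
        return desc.FeatureMatrix(
            values=values,
            labels=tuple(f"cat{i}" for i in range(n)),
            column_provenance=tuple(("aso", j) for j in range(m)),
            means=np.zeros(m),
            scales=np.ones(m),
        )

    def test_constant_column_dropped(self):
        rng = np.random.default_rng(0)
        values = rng.normal(size=(10, 4))
        values[:, 2] = 7.0
        reduced = desc.reduce_features(self._matrix(values), n_pc=2)
        assert 2 not in reduced.retained_columns

    def test_duplicate_column_pruned_keeping_earlier(self):
        rng = np.random.default_rng(1)
        values = rng.normal(size=(12, 4))
        values[:, 3] = values[:, 1]
        reduced = desc.reduce_features(self._matrix(values), n_pc=2)
        assert 1 in reduced.retained_columns
        assert 3 not in reduced.retained_columns

    def test_component_variances_match_eigendecomposition(self):
        rng = np.random.default_rng(2)
        values = rng.normal(size=(20, 30))
        reduced = desc.reduce_features(
            self._matrix(values), corr_threshold=1.1, n_pc=10
        )
        pruned = values[:, reduced.retained_columns]
        cov = np.cov(pruned, rowvar=False)
        eigvals = np.sort(np.linalg.eigvalsh(cov))[::-1]
        component_var = reduced.coordinates.var(axis=0, ddof=1)
        np.testing.assert_allclose(component_var, eigvals[:10], atol=1e-8)

    def test_explained_variance_ratios_non_increasing(self):
        rng = np.random.default_rng(3)
        reduced = desc.reduce_features(
            self._matrix(rng.normal(size=(15, 12))), corr_threshold=1.1, n_pc=6
        )
        ratios = reduced.explained_variance_ratio
        assert np.all(np.diff(ratios) <= 1e-12)
        assert ratios.sum() <= 1.0 + 1e-12

    def test_excessive_component_request_rejected(self):
        rng = np.random.default_rng(4)
        with pytest.raises(ValidationError, match="n_pc"):
            desc.reduce_features(self._matrix(rng.normal(size=(5, 3))), n_pc=10)
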