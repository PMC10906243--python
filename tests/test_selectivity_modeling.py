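"""Free-energy transforms, catalyst-out splits, and PLS selectivity models."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pepcat import selectivity_modeling as sm
from pepcat.errors import ValidationError


class TestEnergyTransforms:
    def test_zero_ee_maps_to_zero_energy(self):
        assert sm.ee_to_ddg(0.0, 300.0) == 0.0

    def test_antisymmetry(self):
        for ee in (0.1, 0.5, 0.9, 0.99):
            assert sm.ee_to_ddg(-ee) == pytest.approx(-sm.ee_to_ddg(ee), rel=1e-12)
        assert sm.dr_to_ddg(98, 2) == pytest.approx(-sm.dr_to_ddg(2, 98), rel=1e-12)

    def test_hand_computed_values(self):
        # independent closed-form evaluation with math.log
        expected_ee = 1.987e-3 * 293.15 * math.log(1.97 / 0.03)
        assert sm.ee_to_ddg(0.97, 293.15) == pytest.approx(expected_ee, rel=1e-12)
        assert expected_ee == pytest.approx(2.44, abs=0.01)
        expected_dr = 1.987e-3 * 293.15 * math.log(58.0 / 42.0)
        assert sm.dr_to_ddg(58, 42, 293.15) == pytest.approx(expected_dr, rel=1e-12)

    def test_round_trip_identity_on_grid(self):
        for ee in np.linspace(-0.999, 0.999, 201):
            assert sm.ddg_to_ee(sm.ee_to_ddg(ee)) == pytest.approx(ee, abs=1e-12)

    def test_strict_monotonicity(self):
        ee_grid = np.linspace(-0.99, 0.99, 50)
        ddg = [sm.ee_to_ddg(e) for e in ee_grid]
        assert np.all(np.diff(ddg) > 0)
        syn_grid = np.linspace(0.1, 0.9, 30)
        dr_vals = [sm.dr_to_ddg(s, 1 - s) for s in syn_grid]
        assert np.all(np.diff(dr_vals) > 0)

    def test_unit_dr_is_zero(self):
        assert sm.dr_to_ddg(50, 50) == 0.0

    @settings(derandomize=True, max_examples=200)
    @given(
        ee=st.floats(min_value=-0.998, max_value=0.998),
        temperature=st.floats(min_value=150.0, max_value=400.0),
    )
    def test_round_trip_and_sign_properties(self, ee, temperature):
        ddg = sm.ee_to_ddg(ee, temperature)
        assert sm.ddg_to_ee(ddg, temperature) == pytest.approx(ee, abs=1e-9)
        assert (ddg > 0) == (ee > 0) or ee == 0
        assert sm.ee_to_ddg(-ee, temperature) == pytest.approx(-ddg, abs=1e-12)

    @pytest.mark.parametrize("bad_ee", [1.0, -1.0, 1.5])
    def test_ee_domain_errors(self, bad_ee):
        with pytest.raises(ValidationError):
            sm.ee_to_ddg(bad_ee)

    def test_dr_domain_errors(self):
        with pytest.raises(ValidationError):
            sm.dr_to_ddg(0.0, 50.0)


def _records(n_catalysts, n_reactions=2, seed=0):
    rng = np.random.default_rng(seed)
    return [
        sm.SelectivityRecord(
            catalyst_label=f"cat{c:03d}",
            reaction_id=f"rxn{r}",
            conversion_pct=float(rng.uniform(5, 95)),
            ee=float(rng.uniform(-0.9, 0.9)),
            dr=(float(rng.uniform(55, 95)), float(rng.uniform(5, 45))),
        )
        for c in range(n_catalysts)
        for r in range(n_reactions)
    ]


class TestCatalystSplit:
    def test_nine_random_plus_pinned_top_performer(self):
        records = _records(50)
        split = sm.make_catalyst_split(records, 9, pinned=["cat007"], seed=1)
        assert len(split.held_out_catalysts) == 10
        assert len(split.train_catalysts) == 40
        assert "cat007" in split.held_out_catalysts
        assert not set(split.held_out_catalysts) & set(split.train_catalysts)

    def test_degenerate_split_keeps_everything_in_train(self):
        split = sm.make_catalyst_split(_records(10), 0, seed=0)
        assert split.held_out_catalysts == ()
        assert len(split.train_catalysts) == 10

    def test_same_seed_reproduces_plan(self):
        records = _records(30)
        assert sm.make_catalyst_split(records, 5, seed=9) == sm.make_catalyst_split(
            records, 5, seed=9
        )

    def test_unknown_pin_rejected(self):
        with pytest.raises(ValidationError, match="nope"):
            sm.make_catalyst_split(_records(5), 1, pinned=["nope"])


class TestFitPLS:
    def test_noiseless_linear_map_recovered_exactly(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 1))
        y = 2.5 * X[:, 0]
        model = sm.fit_pls(X, y, n_latent=1)
        assert np.mean(np.abs(model.predict(X) - y)) < 1e-8

    def test_single_feature_matches_least_squares(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 1))
        y = 1.3 * X[:, 0] - 0.2 + 0.05 * rng.normal(size=40)
        model = sm.fit_pls(X, y, n_latent=1)
        slope, intercept = np.polyfit(X[:, 0], y, 1)
        np.testing.assert_allclose(
            model.predict(X), slope * X[:, 0] + intercept, atol=1e-8
        )

    def test_component_count_beyond_rank_rejected(self):
        rng = np.random.default_rng(2)
        with pytest.raises(ValidationError):
            sm.fit_pls(rng.normal(size=(5, 2)), rng.normal(size=5), n_latent=4)

    def test_cv_selection_recovers_low_noise_signal(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(60, 8))
        w = rng.normal(size=8)
        y = X @ w + 0.05 * rng.normal(size=60)
        model = sm.fit_pls(X, y)
        assert np.mean(np.abs(model.predict(X) - y)) < 0.1
        cosine = np.dot(model.coef_, w) / (
            np.linalg.norm(model.coef_) * np.linalg.norm(w)
        )
        assert cosine > 0.99


class TestEvaluate:
    def _setup(self, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        records = _records(20, n_reactions=2, seed=seed)
        catalysts = sorted({r.catalyst_label for r in records})
        lookup = {c: rng.normal(size=4) for c in catalysts}
        return records, lookup

    def test_perfect_predictor_gives_zero_mae(self):
        records, lookup = self._setup()
        split = sm.make_catalyst_split(records, 4, seed=0)
        train_rows = [r for r in records if r.catalyst_label in split.train_catalysts]
        X, reaction_ids = sm.build_design_matrix(train_rows, lookup)

        class Oracle:
            train_labels = split.train_catalysts
            n_latent = 0

            def predict(self, features):
                # invert the design matrix rows back to the stored targets
                return np.array(
                    [self._lookup[tuple(np.round(row, 9))] for row in np.atleast_2d(features)]
                )

        oracle = Oracle()
        oracle._lookup = {}
        for r in records:
            row, _ = sm.build_design_matrix([r], lookup, reaction_ids)
            oracle._lookup[tuple(np.round(row[0], 9))] = r.ddg_ee
        report = sm.evaluate(oracle, split, records, lookup, reaction_ids=reaction_ids)
        assert report.mae_train == pytest.approx(0.0, abs=1e-12)
        assert report.mae_test == pytest.approx(0.0, abs=1e-12)

    def test_constant_predictor_matches_direct_formula(self):
        records, lookup = self._setup()
        split = sm.make_catalyst_split(records, 4, seed=1)

        class Constant:
            train_labels = split.train_catalysts
            n_latent = 0

            def predict(self, features):
                return np.full(np.atleast_2d(features).shape[0], 0.7)

        report = sm.evaluate(Constant(), split, records, lookup)
        test_rows = [r for r in records if r.catalyst_label in split.held_out_catalysts]
        expected = np.mean([abs(0.7 - r.ddg_ee) for r in test_rows])
        assert report.mae_test == pytest.approx(expected, rel=1e-12)

    def test_leakage_detected(self):
        records, lookup = self._setup()
        split = sm.make_catalyst_split(records, 4, seed=2)

        class Leaky:
            train_labels = tuple(split.held_out_catalysts[:1])
            n_latent = 0

            def predict(self, features):
                return np.zeros(np.atleast_2d(features).shape[0])

        with pytest.raises(ValidationError, match="train"):
            sm.evaluate(Leaky(), split, records, lookup)

    def test_shuffled_targets_degrade_test_error(self):
        rng = np.random.default_rng(4)
        catalysts = [f"cat{c:03d}" for c in range(40)]
        lookup = {c: rng.normal(size=6) for c in catalysts}
        w = rng.normal(size=6)
        records = []
        for c in catalysts:
            ddg = float(lookup[c] @ w) * 0.3
            records.append(
                sm.SelectivityRecord(c, "rxn0", 50.0, sm.ddg_to_ee(ddg), (60.0, 40.0))
            )
        split = sm.make_catalyst_split(records, 10, seed=4)
        train_rows = [r for r in records if r.catalyst_label in split.train_catalysts]
        X, rids = sm.build_design_matrix(train_rows, lookup)
        y = np.array([r.ddg_ee for r in train_rows])
        true_model = sm.fit_pls(X, y, n_latent=3, train_labels=split.train_catalysts)
        shuffled = y.copy()
        rng.shuffle(shuffled)
        null_model = sm.fit_pls(X, shuffled, n_latent=3, train_labels=split.train_catalysts)
        true_report = sm.evaluate(true_model, split, records, lookup, reaction_ids=rids)
        null_report = sm.evaluate(null_model, split, records, lookup, reaction_ids=rids)
        assert true_report.mae_test < 0.5 * null_report.mae_test


class TestCsvRoundTrip:
    def test_write_then_load_preserves_records(self, tmp_path):
        records = _records(5, seed=7)
        path = tmp_path / "selectivity.csv"
        sm.write_selectivity_csv(path, records)
        loaded = sm.load_selectivity_csv(path)
        assert len(loaded) == len(records)
        for orig, back in zip(records, loaded):
            assert back.catalyst_label == orig.catalyst_label
            assert back.ee == pytest.approx(orig.ee, abs=1e-6)
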