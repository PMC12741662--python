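import numpy as np
import pytest

from xylemscale import stats
from xylemscale.pneumatron import fit_lambda
from xylemscale.synthetic import (
    TreeGenParams,
    generate_tree,
    read_fixtures,
    simulate_pneumatron,
    simulate_vessel_diameters,
    tree_tables,
    true_diameter,
    write_fixtures,
)


class TestGenerateTree:
    def test_deterministic_under_seed(self):
        p = TreeGenParams(seed=42)
        t1, t2 = generate_tree(p), generate_tree(p)
        assert t1.true_mean_diameter == t2.true_mean_diameter
        sid = t1.segments[5].segment_id
        assert t1.pneumatron_tables[sid].gas_conductivity == t2.pneumatron_tables[sid].gas_conductivity
        assert [v.lumen_area for v in t1.vessel_tables[sid]] == [
            v.lumen_area for v in t2.vessel_tables[sid]
        ]

    def test_segment_budget_and_orders(self, noisy_tree):
        assert len(noisy_tree.segments) == 58
        orders = {m.branch_order for m in noisy_tree.segments}
        assert orders == {0, 1, 2}
        n_branches = len({m.segment_id[:3] for m in noisy_tree.segments})
        assert n_branches == 21  # main stem + 20 laterals

    def test_zero_widening_exponent_gives_constant_diameter(self):
        tree = generate_tree(TreeGenParams(seed=1, widening_exponent=0.0))
        d = set(np.round(list(tree.true_mean_diameter.values()), 15))
        assert len(d) == 1

    def test_widening_ratio_matches_closed_form(self):
        p = TreeGenParams(seed=1, widening_exponent=0.2)
        ratio = true_diameter(2.75, p) / true_diameter(0.05, p)
        expected = ((1 + 2.75 / 0.01) / (1 + 0.05 / 0.01)) ** 0.2
        assert ratio == pytest.approx(expected, rel=1e-12)

    def test_vessel_counts_in_range(self, noisy_tree):
        counts = [len(v) for v in noisy_tree.vessel_tables.values()]
        assert min(counts) >= 333 and max(counts) <= 1000

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            TreeGenParams(diameter_cv=1.5)
        with pytest.raises(ValueError):
            TreeGenParams(tip_diameter=0.0)


class TestSimulatePneumatron:
    def test_noise_free_round_trip(self):
        series = simulate_pneumatron(0.08, np.linspace(0.4, 0.05, 8), 0.0, seed=0)
        fit = fit_lambda(series)
        assert fit.lambda_v == pytest.approx(-25.0, abs=1e-9)

    def test_replicate_mean_within_two_percent(self):
        fitted = [
            fit_lambda(
                simulate_pneumatron(0.08, np.linspace(0.4, 0.05, 8), 0.05, seed)
            ).mean_vessel_length
            for seed in range(500)
        ]
        assert np.mean(fitted) == pytest.approx(0.08, rel=0.02)

    def test_different_seeds_same_trend(self):
        trims = np.linspace(0.4, 0.05, 8)
        s1 = simulate_pneumatron(0.08, trims, 0.05, seed=1)
        s2 = simulate_pneumatron(0.08, trims, 0.05, seed=2)
        assert s1.gas_conductivity != s2.gas_conductivity
        l1 = fit_lambda(s1).mean_vessel_length
        l2 = fit_lambda(s2).mean_vessel_length
        assert l1 == pytest.approx(l2, rel=0.25)

    def test_nonpositive_lengths_rejected(self):
        with pytest.raises(ValueError):
            simulate_pneumatron(0.08, [0.4, 0.2, 0.0], 0.0, seed=0)


class TestSimulateVesselDiameters:
    def test_cv_zero_all_equal(self):
        vessels = simulate_vessel_diameters(50, 20e-6, 0.0, seed=0)
        assert {v.equivalent_diameter for v in vessels} == {20e-6}

    def test_law_of_large_numbers(self):
        vessels = simulate_vessel_diameters(100_000, 20e-6, 0.3, seed=0)
        mean = np.mean([v.equivalent_diameter for v in vessels])
        assert mean == pytest.approx(20e-6, rel=0.01)

    def test_area_diameter_round_trip(self):
        from xylemscale.anatomy import equivalent_diameter

        vessels = simulate_vessel_diameters(100, 20e-6, 0.3, seed=1)
        for v in vessels[:10]:
            assert equivalent_diameter(v.lumen_area) == pytest.approx(
                v.equivalent_diameter, rel=1e-12
            )

    def test_n_zero_rejected(self):
        with pytest.raises(ValueError):
            simulate_vessel_diameters(0, 20e-6, 0.3, seed=0)


class TestFixtures:
    def test_write_read_round_trip(self, noisy_tree, tmp_path):
        write_fixtures(noisy_tree, tmp_path)
        back = read_fixtures(tmp_path)
        original = tree_tables(noisy_tree)
        for name, df in original.items():
            assert len(back[name]) == len(df)
            np.testing.assert_allclose(
                back[name].select_dtypes("number").to_numpy(),
                df.select_dtypes("number").to_numpy(),
                rtol=1e-12,
            )

    def test_row_counts_consistent(self, noisy_tree, tmp_path):
        paths = write_fixtures(noisy_tree, tmp_path)
        assert set(paths) == {"segments", "pneumatron", "vessels", "pitfields"}
        tables = read_fixtures(tmp_path)
        assert len(tables["segments"]) == 58
        assert len(tables["pneumatron"]) == 58 * noisy_tree.params.pneumatron_points
        assert len(tables["vessels"]) == sum(
            len(v) for v in noisy_tree.vessel_tables.values()
        )

    def test_empty_tree_rejected(self, noisy_tree, tmp_path):
        import dataclasses

        empty = dataclasses.replace(noisy_tree, segments=[])
        with pytest.raises(ValueError, match="no segments"):
            write_fixtures(empty, tmp_path)


class TestParameterRecovery:
    def test_widening_exponent_ci_coverage(self):
        """Log-log pairwise-slope CI covers the true widening exponent in >=90%."""
        covered = 0
        n_rep = 100
        for seed in range(n_rep):
            tree = generate_tree(TreeGenParams(seed=seed))
            p = tree.params
            dist = np.array([m.distance_to_tip for m in tree.segments])
            measured_d = np.array(
                [
                    np.mean([v.equivalent_diameter for v in tree.vessel_tables[m.segment_id]])
                    for m in tree.segments
                ]
            )
            fit = stats.theil_sen(
                np.log10(1 + dist / p.widening_ref_distance), np.log10(measured_d)
            )
            covered += fit.ci_low <= p.widening_exponent <= fit.ci_high
        assert covered / n_rep >= 0.90
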