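"""Standardization plumbing, restarts, interval tables and the CLI."""

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

import refmix.cli as cli
from refmix.data import (
    LabeledDataset,
    StandardizationConstants,
    destandardize_surface,
    standardize,
)
from refmix.evaluation import detect_location_crossing
from refmix.mixture import MixtureParameterSurface, component_quantile
from refmix.model import MixtureDensityNetwork, TanhMixtureEM, reference_intervals
from refmix.simulate import DGPConfig, simulate


class TestStandardize:
    def test_two_point_sample_uses_n_minus_one(self):
        data = LabeledDataset(np.array([1.0, 2.0]), np.array([0.0, 2.0]))
        std, consts = standardize(data)
        np.testing.assert_allclose(std.outcome, [-0.7071, 0.7071], atol=1e-4)
        assert consts.y_sd == pytest.approx(np.sqrt(2.0))

    def test_round_trip_identity(self, rng):
        data = LabeledDataset(rng.uniform(0, 9, 50), rng.normal(5, 3, 50))
        std, consts = standardize(data)
        np.testing.assert_allclose(
            consts.destandardize_y(std.outcome), data.outcome, atol=1e-12
        )
        np.testing.assert_allclose(
            consts.destandardize_x(std.covariate), data.covariate, atol=1e-12
        )

    def test_constants_match_two_pass_recomputation(self, rng):
        y = rng.normal(2, 4, 200)
        x = rng.uniform(size=200)
        _, consts = standardize(LabeledDataset(x, y))
        assert consts.y_mean == pytest.approx(sum(y) / 200)
        assert consts.y_sd == pytest.approx(
            np.sqrt(sum((v - consts.y_mean) ** 2 for v in y) / 199)
        )

    def test_standardized_moments(self, rng):
        data = LabeledDataset(rng.uniform(0, 1, 100), rng.normal(9, 2, 100))
        std, _ = standardize(data)
        assert abs(std.outcome.mean()) < 1e-10
        assert std.outcome.std(ddof=1) == pytest.approx(1.0, abs=1e-10)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            standardize(LabeledDataset(np.ones(5), np.arange(5.0)))


class TestDestandardizeSurface:
    def surface(self, rng):
        w = rng.uniform(0.2, 0.8, (10, 1))
        weights = np.hstack([w, 1 - w])
        return MixtureParameterSurface(
            weights, rng.normal(size=(10, 2)), rng.uniform(0.5, 2, (10, 2))
        )

    def test_identity_constants_are_noop(self, rng):
        s = self.surface(rng)
        out = destandardize_surface(s, StandardizationConstants.identity())
        np.testing.assert_array_equal(out.means, s.means)
        np.testing.assert_array_equal(out.scales, s.scales)

    def test_weights_bitwise_unchanged(self, rng):
        s = self.surface(rng)
        out = destandardize_surface(s, StandardizationConstants(1, 2, 3, 4))
        np.testing.assert_array_equal(out.weights, s.weights)

    def test_quantiles_affinely_equivariant(self, rng):
        s = self.surface(rng)
        consts = StandardizationConstants(0.0, 1.0, 3.0, 4.0)
        q_after = component_quantile(destandardize_surface(s, consts), 0, 0.9)
        q_before = component_quantile(s, 0, 0.9) * consts.y_sd + consts.y_mean
        np.testing.assert_allclose(q_after, q_before, atol=1e-12)


class TestFitWithRestarts:
    def test_single_restart_equals_single_fit(self):
        data = simulate(DGPConfig(n=600, seed=4))
        model = TanhMixtureEM(data.outcome, data.covariate)
        multi = model.fit_with_restarts(restarts=1, seed=9, init_kind="custom")
        assert multi.restart_losses.shape == (1,)
        assert multi.loss == multi.restart_losses[0]

    def test_returns_minimum_loss_clean_run(self):
        data = simulate(DGPConfig(n=800, seed=5))
        model = MixtureDensityNetwork(data.outcome, data.covariate)
        best = model.fit_with_restarts(
            restarts=4, seed=0, method="bfgs", init_kind="random"
        )
        assert best.loss <= best.restart_losses.min() + 1e-9

    def test_min_loss_restart_has_no_crossing_on_separated_data(self):
        data = simulate(DGPConfig(setting="independent", n=1500, seed=6))
        model = MixtureDensityNetwork(data.outcome, data.covariate)
        best = model.fit_with_restarts(
            restarts=6, seed=1, method="bfgs", init_kind="random"
        )
        relabeled = best.relabel_main()
        assert not detect_location_crossing(
            relabeled.fitted, np.linspace(0.01, 0.99, 101)
        )

    def test_invalid_restart_count_rejected(self):
        data = simulate(DGPConfig(n=300, seed=7))
        with pytest.raises(ValueError):
            TanhMixtureEM(data.outcome, data.covariate).fit_with_restarts(restarts=0)


@pytest.fixture(scope="module")
def fitted():
    data = simulate(DGPConfig(setting="independent", n=1500, seed=8))
    return TanhMixtureEM(data.outcome, data.covariate).fit(init_kind="custom")


class TestReferenceIntervals:
    def test_median_column_is_the_mean_curve(self, fitted):
        grid = np.linspace(0.05, 0.95, 31)
        table = fitted.reference_intervals(grid, probabilities=(0.25, 0.5, 0.975))
        relabeled = fitted.relabel_main()
        surf = relabeled.predict(grid)
        np.testing.assert_allclose(
            table.quantiles[:, 1], surf.means[:, 0], atol=1e-10
        )

    def test_columns_nondecreasing_in_p(self, fitted):
        table = fitted.reference_intervals()
        assert np.all(np.diff(table.quantiles, axis=1) >= 0)

    def test_unrelabeled_model_rejected(self, fitted):
        with pytest.raises(ValueError, match="relabel"):
            reference_intervals(fitted.fitted, np.linspace(0, 1, 11))

    def test_two_path_equality_with_manual_destandardization(self, fitted):
        grid = np.linspace(0.1, 0.9, 17)
        relabeled = fitted.relabel_main()
        table = relabeled.reference_intervals(grid, probabilities=(0.95,))
        manual = component_quantile(relabeled.predict(grid), 0, 0.95)
        np.testing.assert_allclose(table.quantiles[:, 0], manual, atol=1e-10)

    def test_affine_consistency_of_fitted_intervals(self):
        data = simulate(DGPConfig(setting="independent", n=1200, seed=12))
        grid = np.linspace(0.1, 0.9, 21)
        base = TanhMixtureEM(data.outcome, data.covariate).fit(init_kind="custom")
        scaled = TanhMixtureEM(3.0 * data.outcome + 7.0, data.covariate).fit(
            init_kind="custom"
        )
        ta = base.reference_intervals(grid, probabilities=(0.05, 0.95))
        tb = scaled.reference_intervals(grid, probabilities=(0.05, 0.95))
        # the two standardized problems are identical up to float rounding,
        # so agreement holds to optimizer tolerance, not machine precision
        np.testing.assert_allclose(3.0 * ta.quantiles + 7.0, tb.quantiles, rtol=1e-3)
        np.testing.assert_allclose(ta.alpha1, tb.alpha1, atol=1e-3)


class TestCli:
    def test_simulate_then_fit_produces_interval_table(self, tmp_path):
        runner = CliRunner()
        csv = tmp_path / "data.csv"
        out = tmp_path / "intervals.csv"
        r1 = runner.invoke(
            cli.main,
            ["simulate", "-n", "600", "--seed", "3", "--out", str(csv)],
        )
        assert r1.exit_code == 0, r1.output
        assert (tmp_path / "data.csv.config.json").exists()
        r2 = runner.invoke(
            cli.main,
            ["fit", str(csv), "--method", "em", "--restarts", "1",
             "--seed", "1", "--grid-size", "41", "--out", str(out)],
        )
        assert r2.exit_code == 0, r2.output
        table = pd.read_csv(out)
        assert len(table) == 41
        assert list(table.columns[:2]) == ["grid", "alpha1"]
        assert table.filter(like="q").shape[1] == 8

    def test_fit_is_bitwise_deterministic(self, tmp_path):
        runner = CliRunner()
        csv = tmp_path / "data.csv"
        runner.invoke(cli.main, ["simulate", "-n", "500", "--seed", "5",
                                 "--out", str(csv)])
        outs = []
        for name in ("a.csv", "b.csv"):
            out = tmp_path / name
            r = runner.invoke(
                cli.main,
                ["fit", str(csv), "--method", "em", "--seed", "2",
                 "--grid-size", "21", "--out", str(out)],
            )
            assert r.exit_code == 0, r.output
            outs.append(out.read_bytes())
        assert outs[0] == outs[1]

    def test_malformed_input_fails_cleanly(self, tmp_path):
        bad = tmp_path / "bad.csv"
        bad.write_text("a,b\n1,2\n")
        runner = CliRunner()
        r = runner.invoke(cli.main, ["fit", str(bad), "--out", "x.csv"])
        assert r.exit_code != 0
        assert "column" in r.output

    def test_study_wiring_writes_run_and_summary_csvs(self, tmp_path, monkeypatch):
        def tiny_study(settings, replications, seed):
            from refmix.evaluation import run_study as real

            return real(
                algorithms=[("em", "custom")],
                settings=[DGPConfig(setting="dependent", n=400)],
                replications=replications,
                seed=seed,
            )

        monkeypatch.setattr(cli, "run_study", tiny_study)
        runner = CliRunner()
        with runner.isolated_filesystem(temp_dir=tmp_path):
            r = runner.invoke(cli.main, ["study", "--reduced", "-R", "2",
                                         "--seed", "1", "--out-prefix", "s"])
            assert r.exit_code == 0, r.output
            runs = pd.read_csv("s_runs.csv")
            summary = pd.read_csv("s_summary.csv")
        assert len(runs) == 2
        assert summary["crossing"].iloc[0] == runs["crossing"].sum()
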