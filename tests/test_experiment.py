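"""Grid runner: accounting, determinism, aggregation shapes, I/O, CLI."""

import numpy as np
import pandas as pd
import pytest

from subgroupsim import (
    ExperimentGrid,
    SimulationDesign,
    load_grid,
    report,
    run_grid,
    simulate_pair,
    summarize,
)
from subgroupsim.experiment import child_seed


def tiny_grid(**kwargs):
    defaults = dict(
        n_groups=3,
        total_ns=(150,),
        nratios=("equal",),
        sratios=("equal",),
        deltas=(0.5,),
        overlaps=(0.1,),
        methods=("lda", "cart"),
        replicates=2,
        master_seed=424242,
    )
    defaults.update(kwargs)
    return ExperimentGrid(**defaults)


class TestGridValidation:
    def test_unknown_method_rejected_before_any_simulation(self):
        with pytest.raises(ValueError, match="unknown method"):
            tiny_grid(methods=("lda", "svm"))

    def test_empty_factor_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            tiny_grid(overlaps=())

    def test_default_sample_sizes_follow_group_count(self):
        assert ExperimentGrid(n_groups=3).total_ns == (150, 300, 750)
        assert ExperimentGrid(n_groups=2).total_ns == (100, 200, 500)

    def test_grid_size_is_product_of_levels(self):
        grid = ExperimentGrid(n_groups=3)
        assert len(grid.cells) == 3 * 2 * 2 * 3 * 5


class TestRunGrid:
    def test_row_accounting(self):
        results = run_grid(tiny_grid())
        # 1 cell x 2 replicates x 2 methods x 2 roles
        assert len(results) == 8
        assert set(results["role"]) == {"train", "cv"}
        assert set(results["method"]) == {"lda", "cart"}

    def test_same_master_seed_is_bit_identical(self, tmp_path):
        a = run_grid(tiny_grid())
        b = run_grid(tiny_grid())
        pd.testing.assert_frame_equal(a, b)
        pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
        a.to_csv(pa, index=False)
        b.to_csv(pb, index=False)
        assert pa.read_bytes() == pb.read_bytes()
        c = run_grid(tiny_grid(master_seed=7))
        assert not a["overall"].equals(c["overall"])

    def test_weighted_identity_on_every_replicate(self):
        results = run_grid(tiny_grid(replicates=3))
        sizes = results[[f"n_g{g}" for g in (1, 2, 3)]].to_numpy()
        rates = results[[f"rate_g{g}" for g in (1, 2, 3)]].to_numpy()
        recombined = (sizes * rates).sum(axis=1) / sizes.sum(axis=1)
        assert np.allclose(recombined, results["overall"], atol=1e-12)

    def test_zero_overlap_cell_equals_homogeneous_simulation(self):
        grid = tiny_grid(overlaps=(0.0,))
        cell = grid.cells[0]
        seed = child_seed(grid.master_seed, 0, 0)
        train, _ = simulate_pair(grid.design_for(cell), seed)
        # independently coded homogeneous-group design: no subgroup structure
        homogeneous = SimulationDesign(
            n_groups=3,
            total_n=150,
            group_separation_delta=0.5,
            subgroup_separation=0.0,
        )
        train_h, _ = simulate_pair(homogeneous, seed)
        assert np.array_equal(train.X, train_h.X)
        assert np.array_equal(train.y_group, train_h.y_group)

    def test_child_seeds_distinct_across_cells_and_replicates(self):
        seeds = {child_seed(1, c, r) for c in range(50) for r in range(50)}
        assert len(seeds) == 2500

    def test_failing_method_recorded_as_missing(self):
        # MIXDA with more subclasses than the smallest class size must
        # fail on every replicate and be recorded as NaN, not raised
        grid = tiny_grid(methods=("lda", "mixda"))
        grid.method_config.mixda.subclasses_per_class = 60
        results = run_grid(grid)
        mix = results[results["method"] == "mixda"]
        assert mix["overall"].isna().all()
        lda = results[results["method"] == "lda"]
        assert lda["overall"].notna().all()


@pytest.fixture(scope="module")
def results():
    return run_grid(
        tiny_grid(
            overlaps=(0.0, 0.05, 0.10, 0.15, 0.20),
            sratios=("equal", "unequal"),
            methods=("lda", "lr", "mixda", "cart", "gam"),
            replicates=2,
        )
    )


class TestBayesRate:
    def test_floor_is_deterministic_and_in_range(self, design3):
        from subgroupsim import population_bayes_rate

        a = population_bayes_rate(design3, n=20_000, seed=1)
        assert a == population_bayes_rate(design3, n=20_000, seed=1)
        assert 0.0 < a < 1.0

    def test_no_fitted_method_beats_the_floor_meaningfully(self, design3):
        from subgroupsim import population_bayes_rate
        from subgroupsim.classifiers import FITTERS

        floor = population_bayes_rate(design3, n=50_000, seed=2)
        train, cv = simulate_pair(design3.replace(total_n=750), 9)
        import warnings

        for name, fit in FITTERS.items():
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = fit(train)
            err = np.mean(model.predict(cv.X) != cv.y_group)
            # a single CV draw of 750 rows: allow a few SE of slack
            assert err > floor - 0.06, name

    def test_floor_shrinks_with_group_separation(self):
        from subgroupsim import population_bayes_rate

        easy = SimulationDesign(n_groups=3, group_separation_delta=0.8)
        hard = SimulationDesign(n_groups=3, group_separation_delta=0.2)
        assert population_bayes_rate(easy, n=30_000, seed=3) < population_bayes_rate(
            hard, n=30_000, seed=3
        )


class TestSummarize:

    def test_overlap_table_shape(self, results):
        summary = summarize(results, by=("overlap",))
        assert summary.pivot().shape == (5, 5)

    def test_sratio_block_shape(self, results):
        summary = summarize(results, by=("sratio", "overlap"))
        assert summary.pivot().shape == (10, 5)

    def test_cell_means_lie_within_replicate_range(self, results):
        summary = summarize(results, by=("sratio", "overlap"))
        sub = results[results["role"] == "cv"]
        for _, row in summary.table.iterrows():
            reps = sub[
                (sub["sratio"] == row["sratio"])
                & (sub["overlap"] == row["overlap"])
                & (sub["method"] == row["method"])
            ]["overall"]
            assert reps.min() - 1e-12 <= row["rate"] <= reps.max() + 1e-12

    def test_marginal_statistics_present_per_method(self, results):
        summary = summarize(results, by=("overlap",))
        marg = summary.marginals.set_index("method")
        assert set(marg.index) == {"lda", "lr", "mixda", "cart", "gam"}
        assert {"min", "max", "median", "mean", "iqr"} <= set(marg.columns)
        assert (marg["min"] <= marg["median"]).all()
        assert (marg["median"] <= marg["max"]).all()

    def test_two_rate_values_aggregate_as_expected(self):
        results = run_grid(tiny_grid(replicates=2, methods=("lda",)))
        summary = summarize(results, by=("overlap",))
        cv = results[(results["role"] == "cv")]["overall"]
        assert summary.table["rate"].iloc[0] == pytest.approx(cv.mean())

    def test_mean_rate_by_group_column(self, results):
        summary = summarize(results, by=("overlap",), value="rate_g2")
        assert len(summary.table) == 25

    def test_empty_results_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            summarize(pd.DataFrame())


class TestReportAndConfig:
    def test_report_round_trip(self, tmp_path):
        results = run_grid(tiny_grid())
        summary = summarize(results, by=("overlap",))
        paths = report(summary, tmp_path, "tbl", text=True)
        table = pd.read_csv(paths[0])
        pd.testing.assert_frame_equal(table, summary.table)
        assert paths[2].read_text().strip()

    def test_yaml_config_round_trip(self, tmp_path):
        cfg = tmp_path / "grid.yaml"
        cfg.write_text(
            "n_groups: 2\n"
            "total_ns: [100, 200]\n"
            "nratios: [equal]\n"
            "sratios: [equal, unequal]\n"
            "deltas: [0.2, 0.8]\n"
            "overlaps: [0.0, 0.2]\n"
            "methods: [lda, cart]\n"
            "replicates: 3\n"
            "master_seed: 5\n"
            "method_config:\n"
            "  cart: {min_node_size: 12}\n"
            "  mixda: {subclasses_per_class: 3}\n"
        )
        grid = load_grid(cfg)
        assert grid.n_groups == 2
        assert grid.total_ns == (100, 200)
        assert grid.method_config.cart.min_node_size == 12
        assert grid.method_config.mixda.subclasses_per_class == 3
        assert len(grid.cells) == 2 * 1 * 2 * 2 * 2

    def test_json_config(self, tmp_path):
        cfg = tmp_path / "grid.json"
        cfg.write_text('{"n_groups": 3, "replicates": 2, "methods": ["lda"]}')
        grid = load_grid(cfg)
        assert grid.replicates == 2
        assert grid.methods == ("lda",)


class TestCLI:
    def test_simulate_run_summarize_pipeline(self, tmp_path):
        from click.testing import CliRunner

        from subgroupsim.cli import main

        runner = CliRunner()
        sim_out = tmp_path / "pair.csv"
        res = runner.invoke(
            main, ["simulate", "--n", "60", "--seed", "3", "--out", str(sim_out)]
        )
        assert res.exit_code == 0, res.output
        df = pd.read_csv(sim_out)
        assert len(df) == 120 and set(df["role"]) == {"train", "cv"}

        run_out = tmp_path / "results.csv"
        cfg = tmp_path / "grid.yaml"
        cfg.write_text(
            "n_groups: 3\ntotal_ns: [150]\nnratios: [equal]\n"
            "sratios: [equal, unequal]\ndeltas: [0.5]\noverlaps: [0.0, 0.1]\n"
            "methods: [lda, cart]\nreplicates: 2\nmaster_seed: 1\n"
        )
        res = runner.invoke(main, ["run", "--config", str(cfg), "--out", str(run_out)])
        assert res.exit_code == 0, res.output
        results = pd.read_csv(run_out)
        assert len(results) == 4 * 2 * 2 * 2  # cells x reps x methods x roles

        sum_dir = tmp_path / "tables"
        res = runner.invoke(
            main, ["summarize", "--results", str(run_out), "--out", str(sum_dir), "--text"]
        )
        assert res.exit_code == 0, res.output
        assert (sum_dir / "overall_by_overlap_table.csv").exists()
        assert (sum_dir / "sratio_increase_overall.csv").exists()
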