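import numpy as np
import pytest
from numpy.testing import assert_allclose
from scipy import stats

from nichepack.adaptive_dynamics import ADConfig
from nichepack.ecology import Community
from nichepack.ibm import IBMConfig, PopulationOfIndividuals
from nichepack.kernels import ModelParams
from nichepack import workbench
from nichepack.workbench import (
    ConfigError,
    RunConfig,
    config_from_entries,
    dump_config,
    fixture_configs,
    load_config,
    seed_initial_community,
    sweep,
    write_config,
)


class TestSeedInitialCommunity:
    def test_single_founder(self, rng):
        comm = seed_initial_community(1, (-2, 2), rng)
        assert isinstance(comm, Community)
        assert comm.size == 1

    def test_hundred_distinct_in_box(self, rng):
        comm = seed_initial_community(100, (-2, 2), rng)
        assert comm.size == 100
        assert np.all(comm.phenotypes >= -2) and np.all(comm.phenotypes <= 2)
        assert len(np.unique(comm.phenotypes, axis=0)) == 100

    def test_ibm_variant(self, rng):
        pop = seed_initial_community(10, (-2, 2), rng, kind="ibm")
        assert isinstance(pop, PopulationOfIndividuals)
        assert pop.size == 10

    def test_per_axis_uniformity(self, rng):
        comm = seed_initial_community(10_000, (-2, 2), rng)
        for axis in range(2):
            stat = stats.kstest(comm.phenotypes[:, axis], stats.uniform(-2, 4).cdf)
            assert stat.pvalue > 0.001

    def test_rejects_zero(self, rng):
        with pytest.raises(ValueError):
            seed_initial_community(0, (-2, 2), rng)


class TestConfigRoundTrip:
    def test_default_fixture_reproduces_fig2_scenario(self, tmp_path):
        cfg = fixture_configs()["fig2-quartic-symmetric"]
        assert cfg.model.carrying_kind == "quartic"
        assert cfg.model.sigma_alpha == 0.5
        assert cfg.model.symmetric
        path = tmp_path / "fig2.cfg"
        write_config(cfg, path)
        back = load_config(path)
        assert back.model == cfg.model
        assert back.ad == cfg.ad

    def test_malformed_file_named_diagnostic(self, tmp_path):
        path = tmp_path / "bad.cfg"
        path.write_text("framework = ad\nmodel.sigmaalpha = 0.5\n")
        with pytest.raises(ConfigError, match="model.sigmaalpha"):
            load_config(path)

    def test_missing_framework(self, tmp_path):
        path = tmp_path / "bad.cfg"
        path.write_text("model.sigma_alpha = 0.5\n")
        with pytest.raises(ConfigError, match="framework"):
            load_config(path)

    def test_duplicate_key(self, tmp_path):
        path = tmp_path / "bad.cfg"
        path.write_text("framework = ad\nseed = 1\nseed = 2\n")
        with pytest.raises(ConfigError, match="duplicate"):
            load_config(path)

    def test_round_trip_random_configs(self, tmp_path, rng):
        for i in range(20):
            framework = ["ad", "ibm", "pde"][int(rng.integers(3))]
            b = rng.normal(size=(2, 2)) if rng.random() < 0.5 else None
            model = ModelParams(
                carrying_kind=["quartic", "radial"][int(rng.integers(2))],
                sigma_alpha=float(rng.uniform(0.2, 0.9)),
                b=b,
                r=float(rng.uniform(0.5, 2.0)),
            )
            kw = {}
            if framework == "ad":
                kw["ad"] = ADConfig(
                    eps_mut=float(rng.uniform(0.01, 0.05)),
                    n_attempts=int(rng.integers(10, 1000)),
                    initial_n=int(rng.integers(1, 100)),
                )
            if framework == "ibm":
                kw["ibm"] = IBMConfig(
                    k_max=float(rng.integers(50, 500)),
                    sigma_mut_ibm=float(rng.uniform(0.001, 0.05)),
                )
            cfg = RunConfig(framework=framework, model=model, seed=int(rng.integers(100)), **kw)
            path = tmp_path / f"cfg{i}.cfg"
            write_config(cfg, path)
            back = load_config(path)
            assert back.framework == cfg.framework
            assert back.seed == cfg.seed
            assert back.model.carrying_kind == cfg.model.carrying_kind
            assert back.model.sigma_alpha == cfg.model.sigma_alpha
            assert_allclose(np.asarray(back.model.b), np.asarray(cfg.model.b))
            if framework == "ad":
                assert back.ad == ADConfig(**{**cfg.ad.__dict__, "seed": cfg.seed})
            if framework == "ibm":
                assert back.ibm == IBMConfig(**{**cfg.ibm.__dict__, "seed": cfg.seed})

    def test_all_fixture_configs_round_trip(self, tmp_path):
        for name, cfg in fixture_configs().items():
            path = tmp_path / f"{name}.cfg"
            write_config(cfg, path)
            back = load_config(path)
            assert back.framework == cfg.framework
            assert dump_config(back) == dump_config(cfg)


class TestSweep:
    def _tiny_ad_config(self, seed, initial_n=1):
        model = ModelParams(carrying_kind="quartic", sigma_alpha=0.5)
        return RunConfig(
            "ad",
            model,
            ad=ADConfig(n_attempts=40, initial_n=initial_n, snapshot_every=10),
            seed=seed,
        )

    def test_single_point_equals_direct_run(self):
        from nichepack.adaptive_dynamics import run_ad
        from nichepack.analysis import DEFAULT_AD_DELTA, cluster_species

        cfg = self._tiny_ad_config(seed=5)
        table = sweep([cfg])
        direct = run_ad(cfg.model, cfg.ad.__class__(**{**cfg.ad.__dict__, "seed": 5}))
        expected = cluster_species(direct.final.phenotypes, DEFAULT_AD_DELTA).count
        assert table["final_count"].iloc[0] == expected

    def test_order_independence(self):
        configs = [self._tiny_ad_config(seed=s, initial_n=n) for s, n in [(1, 1), (2, 5), (3, 20)]]
        t_fwd = sweep(configs, axis_values=[1, 5, 20])
        t_rev = sweep(configs[::-1], axis_values=[20, 5, 1])
        fwd = set(map(tuple, t_fwd[["axis", "seed", "final_count"]].itertuples(index=False)))
        rev = set(map(tuple, t_rev[["axis", "seed", "final_count"]].itertuples(index=False)))
        assert fwd == rev

    def test_failure_recorded_not_raised(self):
        bad = RunConfig(
            "pde",
            ModelParams(carrying_kind="quartic"),
            pde_n=4,  # too coarse: blob normalisation fine but run is trivial
            pde_t_end=0.1,
            seed=0,
        )
        good = self._tiny_ad_config(seed=1)
        table = sweep([good, bad])
        assert len(table) == 2
        assert table["error"].iloc[0] == ""

    def test_empty_sweep_rejected(self):
        with pytest.raises(ValueError):
            sweep([])


class TestOutputs:
    def test_ad_outputs_written(self, tmp_path):
        from nichepack.adaptive_dynamics import run_ad

        cfg = RunConfig(
            "ad",
            ModelParams(carrying_kind="quartic", sigma_alpha=0.5),
            ad=ADConfig(n_attempts=30, snapshot_every=10),
            seed=2,
        )
        traj = workbench.run(cfg)
        workbench.write_outputs(traj, tmp_path / "run", config=cfg)
        assert (tmp_path / "run" / "trajectory.tsv").exists()
        assert (tmp_path / "run" / "events.tsv").exists()
        meta = (tmp_path / "run" / "metadata.json").read_text()
        assert "seed" in meta

    def test_metadata_reproduces_run(self, tmp_path):
        import json

        cfg = RunConfig(
            "ad",
            ModelParams(carrying_kind="quartic", sigma_alpha=0.5),
            ad=ADConfig(n_attempts=25, snapshot_every=5),
            seed=9,
        )
        traj = workbench.run(cfg)
        workbench.write_outputs(traj, tmp_path / "run", config=cfg)
        meta = json.loads((tmp_path / "run" / "metadata.json").read_text())
        cfg_path = tmp_path / "rerun.cfg"
        cfg_path.write_text(meta["config"])
        cfg2 = load_config(cfg_path)
        traj2 = workbench.run(cfg2)
        assert_allclose(traj.final.phenotypes, traj2.final.phenotypes, rtol=0, atol=0)
        assert_allclose(traj.final.abundances, traj2.final.abundances, rtol=0, atol=0)
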