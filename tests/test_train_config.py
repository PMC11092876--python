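import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from molflow.cli import main
from molflow.config import RunConfig, build_prior_spec, run_ablation_grid
from molflow.fixtures import FixtureGrammar, generate_molecules
from molflow.network import FlowNet, ModelConfig
from molflow.priors import marginal_prior_spec
from molflow.schedules import ScheduleSet
from molflow.train import TrainConfig, dirichlet_interpolate, make_pair, train
from molflow.flows import ConditionalPair
from molflow.simplex import assert_on_simplex

TINY_MODEL = {"n_blocks": 1, "scalar_dim": 12, "vector_dim": 2, "edge_dim": 6}


@pytest.fixture(scope="module")
def small_set():
    return generate_molecules(FixtureGrammar(max_heavy=2), 8, seed=0)


class TestRunConfigValidation:
    def test_dirichlet_requires_uniform(self):
        with pytest.raises(ValueError):
            RunConfig(flow_type="dirichlet", categorical_prior="barycenter")
        RunConfig(flow_type="dirichlet", categorical_prior="uniform-simplex")

    def test_unknown_flow_type(self):
        with pytest.raises(ValueError):
            RunConfig(flow_type="diffusion")

    def test_simplex_flow_flag(self):
        assert RunConfig(flow_type="endpoint", categorical_prior="barycenter").is_simplex_flow
        assert not RunConfig(categorical_prior="gaussian").is_simplex_flow

    def test_hash_stable(self):
        a, b = RunConfig(), RunConfig()
        assert a.config_hash() == b.config_hash()
        assert a.config_hash() != RunConfig(blur_sigma=0.2).config_hash()

    def test_from_yaml(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text("flow_type: endpoint\ncategorical_prior: barycenter\nseeds: [0, 1]\n")
        cfg = RunConfig.from_yaml(p)
        assert cfg.categorical_prior == "barycenter"
        assert cfg.seeds == (0, 1)


class TestTraining:
    def test_loss_decreases(self, small_set):
        """Frozen-evaluation check: the average endpoint loss on a fixed set of
        (pair, t) couples goes down after training. Uses the numpy-side
        training_loss as an independent route onto the model's predictions."""
        from molflow.flows import interpolate, training_loss

        cb = small_set[0].codebook
        model = FlowNet(ModelConfig(**TINY_MODEL, seed=0), cb)
        priors = marginal_prior_spec(small_set, cb)
        sch = ScheduleSet.from_nus()
        eval_rng = np.random.default_rng(99)
        eval_pairs = [make_pair(g, priors, eval_rng, ot=False) for g in small_set]
        eval_t = eval_rng.uniform(0.1, 0.9, size=len(eval_pairs))

        def frozen_loss():
            preds = []
            for pair, t in zip(eval_pairs, eval_t):
                hat = model.predict_endpoint(interpolate(pair, sch, float(t)), float(t))
                preds.append({"x": hat.positions, "a": hat.atom_types,
                              "c": hat.charges, "e": hat.bonds})
            return training_loss(eval_pairs, preds, sch, eval_t, "endpoint")

        before = frozen_loss()
        train(model, small_set, priors, sch,
              TrainConfig(n_steps=60, batch_size=4, seed=0, ot_align=False))
        assert frozen_loss() < before

    def test_objective_mode_mismatch(self, small_set):
        cb = small_set[0].codebook
        model = FlowNet(ModelConfig(**TINY_MODEL, seed=0), cb)
        priors = marginal_prior_spec(small_set, cb)
        with pytest.raises(ValueError):
            train(model, small_set, priors, ScheduleSet.from_nus(),
                  TrainConfig(n_steps=1, objective="vector_field"))

    def test_vector_field_training_runs(self, small_set):
        cb = small_set[0].codebook
        model = FlowNet(ModelConfig(**TINY_MODEL, mode="vector_field", seed=0), cb)
        priors = marginal_prior_spec(small_set, cb)
        hist = train(model, small_set, priors, ScheduleSet.from_nus(),
                     TrainConfig(n_steps=5, batch_size=2, seed=0,
                                 objective="vector_field", ot_align=False))
        assert len(hist) == 5 and np.isfinite(hist).all()

    def test_dirichlet_interpolate_on_simplex(self, small_set, rng):
        cb = small_set[0].codebook
        priors = marginal_prior_spec(small_set, cb, blur_sigma=0.0)
        pair = make_pair(small_set[0], priors, rng, ot=False)
        g_t = dirichlet_interpolate(pair, ScheduleSet.from_nus(), 0.5, 100.0, rng)
        assert assert_on_simplex(g_t.atom_types)
        assert assert_on_simplex(g_t.bonds)

    def test_make_pair_ot_reduces_cost(self, small_set, rng):
        g1 = small_set[0]
        priors = marginal_prior_spec(small_set, g1.codebook)
        pair_no = make_pair(g1, priors, np.random.default_rng(5), ot=False)
        pair_ot = make_pair(g1, priors, np.random.default_rng(5), ot=True)
        cost_no = ((pair_no.g0.positions - pair_no.g1.positions) ** 2).sum()
        cost_ot = ((pair_ot.g0.positions - pair_ot.g1.positions) ** 2).sum()
        assert cost_ot <= cost_no + 1e-9


class TestAblationGrid:
    def _tiny(self, **kw):
        return RunConfig(model=TINY_MODEL, train_steps=3, batch_size=2,
                         n_sample=2, sample_steps=4, **kw)

    def test_two_configs_two_seeds(self, small_set):
        cfgs = [
            self._tiny(categorical_prior="gaussian", seeds=(0, 1)),
            self._tiny(categorical_prior="barycenter", seeds=(0, 1)),
        ]
        table = run_ablation_grid(cfgs, dataset=small_set)
        assert isinstance(table, pd.DataFrame)
        assert len(table) == 2
        assert list(table["n_seeds"]) == [2, 2]

    def test_rerun_identical(self, small_set):
        cfgs = [self._tiny(categorical_prior="gaussian", seeds=(0,))]
        t1 = run_ablation_grid(cfgs, dataset=small_set)
        t2 = run_ablation_grid(cfgs, dataset=small_set)
        pd.testing.assert_frame_equal(t1, t2)


class TestBuildPriorSpec:
    def test_marginal(self, small_set):
        cfg = RunConfig(categorical_prior="marginal-simplex")
        spec = build_prior_spec(cfg, small_set, small_set[0].codebook)
        assert spec.atom_type.family == "marginal-simplex"
        assert spec.joint_ac is not None

    def test_gaussian_no_blur(self, small_set):
        spec = build_prior_spec(RunConfig(), small_set, small_set[0].codebook)
        assert spec.atom_type.family == "gaussian"
        assert spec.atom_type.blur_sigma == 0.0


class TestCLI:
    def test_full_pipeline(self, tmp_path):
        runner = CliRunner()
        fix = tmp_path / "fix.sdf"
        ckpt = tmp_path / "model.json"
        gen = tmp_path / "gen.sdf"
        rep = tmp_path / "report.json"
        cfg = tmp_path / "cfg.yaml"
        cfg.write_text(
            "categorical_prior: marginal-simplex\n"
            "model: {n_blocks: 1, scalar_dim: 12, vector_dim: 2, edge_dim: 6}\n"
            "train_steps: 3\nbatch_size: 2\n"
        )
        r = runner.invoke(main, ["make-fixtures", "--n", "6", "--seed", "1",
                                 "--max-heavy", "2", "--out", str(fix)])
        assert r.exit_code == 0, r.output
        r = runner.invoke(main, ["train", "--data", str(fix), "--config", str(cfg),
                                 "--out", str(ckpt)])
        assert r.exit_code == 0, r.output
        r = runner.invoke(main, ["sample", "--checkpoint", str(ckpt), "--n", "3",
                                 "--steps", "4", "--out", str(gen)])
        assert r.exit_code == 0, r.output
        r = runner.invoke(main, ["evaluate", "--generated", str(gen),
                                 "--reference", str(fix), "--report", str(rep)])
        assert r.exit_code == 0, r.output
        import json

        report = json.loads(rep.read_text())
        assert set(report) >= {"atoms_stable_pct", "mols_stable_pct", "mols_valid_pct"}

    def test_ablate_rejects_bad_combo(self, tmp_path):
        runner = CliRunner()
        cfgs = tmp_path / "grid.yaml"
        cfgs.write_text("- {flow_type: dirichlet, categorical_prior: barycenter}\n")
        r = runner.invoke(main, ["ablate", "--configs", str(cfgs), "--out",
                                 str(tmp_path / "t.csv")])
        assert r.exit_code != 0
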