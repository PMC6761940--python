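"""Evidence-lower-bound estimators: bound property against quadrature,
tightness in the conjugate linear-Gaussian case, label-marginalization
algebra, structural reductions, gradient correctness and training
determinism."""

import json

import numpy as np
import pytest

from drvae.gaussian import NumericalError, ValidationError
from drvae.models import (
    Batch,
    ModelConfig,
    draw_noise,
    elbo_pair,
    elbo_singleton,
    fit,
    init_params,
    mc_elbo_pair,
    mc_elbo_singleton,
    total_objective,
    _objective_core,
)
from drvae.synthetic import SyntheticConfig, generate
from oracles import (
    conjugate_linear_gaussian,
    quad_log_evidence_pair,
    quad_log_evidence_singleton,
)

N_DRAWS = 10_000


@pytest.fixture(scope="module")
def toy():
    """1 gene, 1-dim latents, random small networks."""
    cfg = ModelConfig(n_genes=1, latent_dim=1, z3_dim=1,
                      enc_hidden=3, aux_hidden=3)
    params = init_params(cfg, seed=7)
    x1, x2 = np.array([0.4]), np.array([-0.3])
    return params, x1, x2


class TestBoundProperty:
    """Every ELBO variant lower-bounds the quadrature log evidence."""

    @pytest.mark.parametrize("y", [0, 1, None])
    def test_pair_elbo_below_log_evidence(self, toy, y):
        params, x1, x2 = toy
        est, se = mc_elbo_pair(x1, x2, y, params, N_DRAWS, seed=42)
        log_z = quad_log_evidence_pair(params, x1, x2, y)
        assert est <= log_z + 3 * se

    @pytest.mark.parametrize("y", [0, 1, None])
    def test_singleton_elbo_below_log_evidence(self, toy, y):
        params, x1, _ = toy
        est, se = mc_elbo_singleton(x1, y, params, N_DRAWS, seed=43)
        log_z = quad_log_evidence_singleton(params, x1, y)
        assert est <= log_z + 3 * se

    def test_tight_in_conjugate_linear_gaussian_case(self):
        """When the variational family contains the true posterior the
        labeled-singleton bound is an equality (within MC error)."""
        params, x1, log_z = conjugate_linear_gaussian()
        for y in (0, 1):
            est, se = mc_elbo_singleton(x1, y, params, 20_000, seed=5)
            assert abs(est - log_z) < 3 * se

    def test_quadrature_oracle_agrees_with_closed_form(self):
        params, x1, log_z = conjugate_linear_gaussian()
        assert quad_log_evidence_singleton(params, x1, 1) == pytest.approx(
            log_z, abs=1e-6)


class TestMarginalizationAlgebra:
    def test_uniform_classifier_unlabeled_is_mean_labeled_plus_ln2(self, toy):
        """With q(y|z1,z2) == 0.5 the unlabeled pair ELBO equals the average
        of the two labeled ELBOs plus ln 2, for the same noise draws."""
        params, x1, x2 = toy
        params = params.copy()
        params.nets["clf_W"] = np.zeros_like(params.nets["clf_W"])
        params.nets["clf_b"] = np.zeros_like(params.nets["clf_b"])
        eps = draw_noise(np.random.default_rng(0), 1, params.config)
        l0 = elbo_pair(x1, x2, 0, params, eps)
        l1 = elbo_pair(x1, x2, 1, params, eps)
        lu = elbo_pair(x1, x2, None, params, eps)
        assert lu == pytest.approx(0.5 * (l0 + l1) + np.log(2.0), rel=1e-10)

    def test_gene_permutation_invariance(self):
        """Permuting gene order in the data and in all gene-indexed weights
        leaves the ELBO unchanged."""
        cfg = ModelConfig(n_genes=6, latent_dim=2, z3_dim=2,
                          enc_hidden=4, aux_hidden=3)
        params = init_params(cfg, seed=3)
        rng = np.random.default_rng(1)
        x1, x2 = rng.standard_normal(6), rng.standard_normal(6)
        eps = draw_noise(np.random.default_rng(9), 1, cfg)
        base = elbo_pair(x1, x2, 1, params, eps)

        perm = rng.permutation(6)
        permuted = params.copy()
        permuted.nets["enc"]["W1"] = params.nets["enc"]["W1"][perm]
        permuted.nets["dec"]["Wm"] = params.nets["dec"]["Wm"][:, perm]
        permuted.nets["dec"]["bm"] = params.nets["dec"]["bm"][perm]
        permuted.nets["x_log_var"] = params.nets["x_log_var"][perm]
        assert elbo_pair(x1[perm], x2[perm], 1, permuted, eps) == pytest.approx(
            base, rel=1e-10)

    def test_labeled_singletons_differ_only_through_label_branch(self):
        """If the z3 encoder and z1 prior net ignore their inputs, the
        labeled singleton ELBO is identical for y=0 and y=1 (the uniform
        label prior contributes the same log p(y))."""
        cfg = ModelConfig(n_genes=2, latent_dim=1, z3_dim=1,
                          enc_hidden=2, aux_hidden=2)
        params = init_params(cfg, seed=2)
        for net in ("z3_enc", "z1_prior"):
            for k in ("W1", "Wm", "Wv"):
                params.nets[net][k] = np.zeros_like(params.nets[net][k])
        x1 = np.array([0.5, -1.0])
        eps = draw_noise(np.random.default_rng(4), 1, cfg)
        assert elbo_singleton(x1, 0, params, eps) == pytest.approx(
            elbo_singleton(x1, 1, params, eps), rel=1e-12)


class TestObjectiveAlgebra:
    def _eps_for(self, batch, cfg, seed=0):
        r = np.random.default_rng(seed)
        return (draw_noise(r, batch.n_pairs, cfg), draw_noise(r, batch.n_singles, cfg))

    def test_unlabeled_singletons_ignore_class_weight(self, rng):
        cfg = ModelConfig(n_genes=4, latent_dim=2, z3_dim=2,
                          enc_hidden=3, aux_hidden=3)
        params = init_params(cfg, seed=0)
        batch = Batch.from_lists(
            singletons=[(rng.standard_normal(4), None) for _ in range(5)])
        eps = self._eps_for(batch, cfg)
        params.class_loss_weight = 0.0
        base = total_objective(batch, params, eps)
        params.class_loss_weight = 37.0
        assert total_objective(batch, params, eps) == pytest.approx(base)

    def test_zero_class_weight_is_pure_negative_elbo(self, rng):
        cfg = ModelConfig(n_genes=4, latent_dim=2, z3_dim=2,
                          enc_hidden=3, aux_hidden=3)
        params = init_params(cfg, seed=1)
        params.class_loss_weight = 0.0
        pairs = [(rng.standard_normal(4), rng.standard_normal(4), 1)]
        singles = [(rng.standard_normal(4), 0), (rng.standard_normal(4), None)]
        batch = Batch.from_lists(pairs=pairs, singletons=singles)
        eps_p, eps_s = self._eps_for(batch, cfg)
        obj = total_objective(batch, params, (eps_p, eps_s))
        manual = elbo_pair(pairs[0][0], pairs[0][1], 1, params,
                           {k: v[:1] for k, v in eps_p.items()})
        for i, (x, y) in enumerate(singles):
            manual += elbo_singleton(x, y, params,
                                     {k: v[i:i + 1] for k, v in eps_s.items()})
        assert obj == pytest.approx(-manual, rel=1e-10)

    def test_doubling_batch_doubles_objective(self, rng):
        cfg = ModelConfig(n_genes=4, latent_dim=2, z3_dim=2,
                          enc_hidden=3, aux_hidden=3)
        params = init_params(cfg, seed=2)
        x = [rng.standard_normal(4) for _ in range(4)]
        batch = Batch.from_lists(pairs=[(x[0], x[1], 1)], singletons=[(x[2], 0)])
        doubled = Batch.from_lists(pairs=[(x[0], x[1], 1)] * 2,
                                   singletons=[(x[2], 0)] * 2)
        eps_p, eps_s = self._eps_for(batch, cfg)
        eps2 = ({k: np.tile(v, (2, 1)) for k, v in eps_p.items()},
                {k: np.tile(v, (2, 1)) for k, v in eps_s.items()})
        assert total_objective(doubled, params, eps2) == pytest.approx(
            2 * total_objective(batch, params, (eps_p, eps_s)), rel=1e-10)

    def test_empty_batch_raises(self):
        cfg = ModelConfig(n_genes=4, latent_dim=2, z3_dim=2,
                          enc_hidden=3, aux_hidden=3)
        params = init_params(cfg, seed=0)
        empty = Batch.from_lists(n_genes=4)
        with pytest.raises(ValidationError):
            total_objective(empty, params, np.random.default_rng(0))

    def test_ssvae_reduction_difference_block_inert(self, rng):
        """With no pair data and an identity perturbation, the classifier's
        z2 - z1 input block is identically zero, so its weights cannot
        affect the objective — the model reduces to an SSVAE."""
        cfg = ModelConfig(n_genes=4, latent_dim=2, z3_dim=2,
                          enc_hidden=3, aux_hidden=3)
        params = init_params(cfg, seed=5)
        params.nets["pert_W"] = np.zeros((2, 2))
        params.nets["pert_b"] = np.zeros(2)
        params.nets["clf_W"] = rng.standard_normal((4, 2))
        batch = Batch.from_lists(
            singletons=[(rng.standard_normal(4), y) for y in (0, 1, None, None)])
        eps = self._eps_for(batch, cfg)
        base = total_objective(batch, params, eps)
        params.nets["clf_W"][2:] = rng.standard_normal((2, 2))
        assert total_objective(batch, params, eps) == pytest.approx(base, rel=1e-12)

    def test_pertvae_ignores_labels(self, rng):
        cfg = ModelConfig(n_genes=4, latent_dim=2, z3_dim=2,
                          enc_hidden=3, aux_hidden=3, kind="pertvae")
        params = init_params(cfg, seed=6)
        pairs = [(rng.standard_normal(4), rng.standard_normal(4), 1)]
        singles = [(rng.standard_normal(4), 0)]
        labeled = Batch.from_lists(pairs=pairs, singletons=singles)
        eps = self._eps_for(labeled, cfg)
        assert total_objective(labeled, params, eps) == pytest.approx(
            total_objective(labeled.without_labels(), params, eps), rel=1e-12)


class TestGradients:
    def test_objective_gradient_matches_finite_differences(self, rng):
        """Central finite differences vs the backpropagated gradient of the
        total objective, relative tolerance 1e-3, fixed noise."""
        from autograd import grad as ag_grad
        from autograd.misc import flatten as ag_flatten

        cfg = ModelConfig(n_genes=3, latent_dim=2, z3_dim=2,
                          enc_hidden=3, aux_hidden=2)
        params = init_params(cfg, seed=8)
        params.class_loss_weight = 2.0
        batch = Batch.from_lists(
            pairs=[(rng.standard_normal(3), rng.standard_normal(3), 1),
                   (rng.standard_normal(3), rng.standard_normal(3), None)],
            singletons=[(rng.standard_normal(3), 0),
                        (rng.standard_normal(3), None)])
        r = np.random.default_rng(11)
        eps = (draw_noise(r, 2, cfg), draw_noise(r, 2, cfg))

        flat, unflatten = ag_flatten(params.nets)

        def f(v):
            return _objective_core(unflatten(v), batch, eps[0], eps[1],
                                   "drvae", params.class_loss_weight)

        auto = ag_grad(f)(flat)
        h = 1e-5
        idx = np.random.default_rng(3).choice(flat.size, size=60, replace=False)
        for i in idx:
            e = np.zeros_like(flat)
            e[i] = h
            fd = (f(flat + e) - f(flat - e)) / (2 * h)
            assert auto[i] == pytest.approx(fd, rel=1e-3, abs=1e-7)


class TestTraining:
    def test_zero_epochs_returns_near_identity_initialization(self):
        cfg = ModelConfig(n_genes=5, latent_dim=2, z3_dim=2, enc_hidden=3,
                          aux_hidden=3, max_epochs=0, pert_init_sd=1e-4)
        batch = Batch.from_lists(
            singletons=[(np.zeros(5), None)])
        params, log = fit(batch, None, cfg, seed=0)
        assert log["epochs_run"] == 0
        assert np.linalg.norm(params.nets["pert_W"]) <= 1e-2
        assert np.linalg.norm(params.nets["pert_b"]) <= 1e-2

    @pytest.mark.filterwarnings("ignore:empty validation")
    def test_objective_descends_on_synthetic_fixture(self):
        """200 singletons + 40 pairs, latent dim 4: the training objective
        after 50 epochs is below its value at initialization."""
        ds = generate(SyntheticConfig(
            n_genes=10, latent_dim_true=2, n_cell_lines_pairs=20,
            pairs_per_cell_line=2, n_singletons=200, seed=21))
        batch = ds.to_batch()
        cfg = ModelConfig(n_genes=10, latent_dim=4, z3_dim=4, enc_hidden=8,
                          aux_hidden=6, max_epochs=50, patience=50,
                          class_weight_grid=(1.0,), batch_size=64)
        params, log = fit(batch, None, cfg, seed=5)
        obj = log["candidates"][0]["train_objective"]
        assert obj[-1] < obj[0]

    def test_same_seed_same_training_log(self, small_batch, small_config):
        from dataclasses import replace
        cfg = replace(small_config, max_epochs=8)
        _, log_a = fit(small_batch, small_batch, cfg, seed=77)
        _, log_b = fit(small_batch, small_batch, cfg, seed=77)
        assert json.dumps(log_a, default=float) == json.dumps(log_b, default=float)

    def test_empty_validation_warns_and_trains_fixed_epochs(self, small_batch):
        cfg = ModelConfig(n_genes=20, latent_dim=2, z3_dim=2, enc_hidden=4,
                          aux_hidden=3, max_epochs=3, class_weight_grid=(1.0,))
        with pytest.warns(UserWarning, match="empty validation"):
            _, log = fit(small_batch, None, cfg, seed=0)
        assert log["candidates"][0]["epochs_run"] == 3
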