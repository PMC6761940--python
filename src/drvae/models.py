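"""The DrVAE model family.

DrVAE is a semi-supervised deep generative model of drug response.  It
jointly models pre-treatment gene expression ``x1``, post-treatment
expression ``x2``, their latent embeddings ``z1, z2``, a class-independent
latent ``z3`` and a binary response label ``y``:

    p(x1, x2, z1, z2, z3, y)
        = p(x1|z1) p(x2|z2) p(z2|z1) p(z1|z3, y) p(z3) p(y)

All conditionals are diagonal Gaussians parametrized by neural networks
(one ELU hidden layer by default), except:

* the perturbation mean is constrained to be linear, ``z1 + W z1 + b``,
  with ``W, b`` initialized near zero so it starts as the identity;
* ``p(z3)`` is a fixed standard normal and ``p(y)`` a uniform Bernoulli;
* the response classifier ``q(y|z1, z2)`` is a linear softmax over two
  units reading the concatenation ``[z1, z2 - z1]``.

The encoder ``q(z|x)`` and decoder ``p(x|z)`` are shared between the pre-
and post-treatment roles so that both live in one latent space.

Training maximizes the sum of four evidence lower bounds — labeled pairs,
unlabeled pairs, labeled singletons, unlabeled singletons — plus a weighted
cross-entropy term that trains the classifier on labeled data.  Gradients
flow through single-sample reparameterized estimates; Gaussian-Gaussian KL
sub-terms are computed in closed form.  Optimization is plain Adam on
minibatches, with early stopping and classification-loss-weight selection
on a validation fold.

Two ablations are provided: SSVAE (no perturbation modeling; pairs are
flattened to their pre-treatment member) and PertVAE (the unsupervised
perturbation sub-model, used as an embedding).  ``set_identity_perturbation``
produces the "DrVAE w/I" ablation by zeroing ``W, b`` in a trained model
without retraining.
"""

from __future__ import annotations

import copy
import json
import warnings
from dataclasses import dataclass, field, asdict, replace
from itertools import zip_longest
from typing import Optional, Sequence

import autograd.numpy as anp
import numpy as np
from autograd import value_and_grad as ag_value_and_grad
from autograd.misc import flatten as ag_flatten

from .gaussian import (
    BCE_EPS,
    DimensionError,
    GaussianParams,
    LatentSample,
    NumericalError,
    ValidationError,
    bce_batch,
    kl_batch,
    log_density_batch,
    reparameterize_batch,
)

LOG_HALF = float(np.log(0.5))


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class ModelConfig:
    """Hyperparameters of a DrVAE-family model.

    ``latent_dim`` = 100 matches the reduced representation used for the
    downstream analyses; hidden widths are free choices exposed here.
    ``enc_hidden`` / ``aux_hidden`` of 0 make the corresponding networks
    affine (used by the linear-Gaussian test constructions).
    """

    n_genes: int
    latent_dim: int = 100
    z3_dim: int = 100
    enc_hidden: int = 512       # data encoder/decoder hidden width
    aux_hidden: int = 256       # z3 encoder / z1 prior-net hidden width
    kind: str = "drvae"         # drvae | ssvae | pertvae
    learning_rate: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 300
    patience: int = 20
    class_weight_grid: tuple = (0.1, 1.0, 10.0, 100.0)
    pert_init_sd: float = 1e-4
    grad_clip: float = 1e4

    def __post_init__(self) -> None:
        if self.kind not in ("drvae", "ssvae", "pertvae"):
            raise ValidationError(f"unknown model kind {self.kind!r}")
        if min(self.n_genes, self.latent_dim, self.z3_dim) < 1:
            raise ValidationError("dimensions must be positive")


@dataclass
class DrVAEParams:
    """All generative and variational parameters of one model instance.

    ``nets`` maps tensor names to numpy arrays:

    - ``enc``/``dec``: data encoder/decoder MLPs (decoder variance is the
      free per-gene vector ``x_log_var``),
    - ``pert_W``, ``pert_b``, ``pert_log_var``: the linear latent
      perturbation,
    - ``z3_enc``: q(z3 | z1, y); ``z1_prior``: p(z1 | z3, y),
    - ``clf_W``, ``clf_b``: the linear response classifier.
    """

    nets: dict
    config: ModelConfig
    class_loss_weight: float = 1.0

    def copy(self) -> "DrVAEParams":
        return DrVAEParams(
            nets=copy.deepcopy(self.nets),
            config=replace(self.config),
            class_loss_weight=self.class_loss_weight,
        )


# ---------------------------------------------------------------------------
# data container
# ---------------------------------------------------------------------------

def _as_label_array(labels, n: int) -> np.ndarray:
    """Labels as a float array with NaN marking 'unlabeled'."""
    if labels is None:
        return np.full(n, np.nan)
    out = np.asarray([np.nan if v is None else float(v) for v in labels], dtype=float)
    ok = np.isnan(out) | (out == 0.0) | (out == 1.0)
    if not ok.all():
        raise ValidationError("labels must be 0, 1 or None")
    return out


@dataclass
class Batch:
    """Perturbation pairs and pre-treatment singletons, labels optional.

    ``pairs_y`` / ``singles_y`` are float arrays where NaN means the label
    is unobserved; the four training regimes (labeled/unlabeled x
    pair/singleton) are recovered by masking.
    """

    pairs_x1: np.ndarray
    pairs_x2: np.ndarray
    pairs_y: np.ndarray
    singles_x1: np.ndarray
    singles_y: np.ndarray

    @classmethod
    def from_lists(cls, pairs=(), singletons=(), n_genes: Optional[int] = None) -> "Batch":
        """Build from ``[(x1, x2, y-or-None), ...]`` and ``[(x1, y-or-None), ...]``."""
        px1 = [np.asarray(p[0], dtype=float) for p in pairs]
        px2 = [np.asarray(p[1], dtype=float) for p in pairs]
        py = [p[2] if len(p) > 2 else None for p in pairs]
        sx1 = [np.asarray(s[0], dtype=float) for s in singletons]
        sy = [s[1] if len(s) > 1 else None for s in singletons]
        if n_genes is None:
            probe = px1 + sx1
            if not probe:
                raise ValidationError("empty batch and no n_genes given")
            n_genes = probe[0].shape[0]
        G = n_genes
        b = cls(
            pairs_x1=np.asarray(px1, dtype=float).reshape(len(px1), G),
            pairs_x2=np.asarray(px2, dtype=float).reshape(len(px2), G),
            pairs_y=_as_label_array(py, len(px1)),
            singles_x1=np.asarray(sx1, dtype=float).reshape(len(sx1), G),
            singles_y=_as_label_array(sy, len(sx1)),
        )
        b.validate()
        return b

    def validate(self) -> "Batch":
        if self.pairs_x1.shape != self.pairs_x2.shape:
            raise DimensionError("pairs_x1 and pairs_x2 shapes differ")
        if self.n_pairs and self.n_singles and self.pairs_x1.shape[1] != self.singles_x1.shape[1]:
            raise DimensionError("pair and singleton gene counts differ")
        return self

    @property
    def n_pairs(self) -> int:
        return self.pairs_x1.shape[0]

    @property
    def n_singles(self) -> int:
        return self.singles_x1.shape[0]

    @property
    def n_genes(self) -> int:
        return (self.pairs_x1 if self.n_pairs else self.singles_x1).shape[1]

    def is_empty(self) -> bool:
        return self.n_pairs == 0 and self.n_singles == 0

    def labeled_x1(self):
        """All labeled pre-treatment profiles (pairs first), with labels."""
        xs, ys = [], []
        m = ~np.isnan(self.pairs_y)
        if m.any():
            xs.append(self.pairs_x1[m]); ys.append(self.pairs_y[m])
        m = ~np.isnan(self.singles_y)
        if m.any():
            xs.append(self.singles_x1[m]); ys.append(self.singles_y[m])
        if not xs:
            G = self.n_genes if not self.is_empty() else 0
            return np.zeros((0, G)), np.zeros(0)
        return np.vstack(xs), np.concatenate(ys)

    def subset(self, pair_idx, single_idx) -> "Batch":
        return Batch(
            pairs_x1=self.pairs_x1[pair_idx],
            pairs_x2=self.pairs_x2[pair_idx],
            pairs_y=self.pairs_y[pair_idx],
            singles_x1=self.singles_x1[single_idx],
            singles_y=self.singles_y[single_idx],
        )

    def flatten_pairs(self) -> "Batch":
        """Drop x2: every pair becomes a pre-treatment singleton (SSVAE view)."""
        empty = np.zeros((0, self.n_genes))
        return Batch(
            pairs_x1=empty, pairs_x2=empty.copy(), pairs_y=np.zeros(0),
            singles_x1=np.vstack([self.pairs_x1, self.singles_x1]),
            singles_y=np.concatenate([self.pairs_y, self.singles_y]),
        )

    def without_labels(self) -> "Batch":
        return Batch(
            pairs_x1=self.pairs_x1, pairs_x2=self.pairs_x2,
            pairs_y=np.full(self.n_pairs, np.nan),
            singles_x1=self.singles_x1,
            singles_y=np.full(self.n_singles, np.nan),
        )


@dataclass
class ResponsePrediction:
    """Deterministic (mean-propagated) response prediction for one sample."""

    prob_sensitive: float
    z1_mean: np.ndarray
    z2_mean: np.ndarray


# ---------------------------------------------------------------------------
# parameter initialization and network forward passes
# ---------------------------------------------------------------------------

def _glorot(rng, fan_in, fan_out):
    sd = np.sqrt(2.0 / (fan_in + fan_out))
    return rng.normal(0.0, sd, size=(fan_in, fan_out))


def _init_gauss_net(rng, d_in, d_hidden, d_out) -> dict:
    """MLP with one ELU hidden layer (or affine if d_hidden == 0) emitting
    a mean head and a log-variance head."""
    net = {}
    width = d_hidden if d_hidden > 0 else d_in
    if d_hidden > 0:
        net["W1"] = _glorot(rng, d_in, d_hidden)
        net["b1"] = np.zeros(d_hidden)
    net["Wm"] = _glorot(rng, width, d_out)
    net["bm"] = np.zeros(d_out)
    net["Wv"] = _glorot(rng, width, d_out) * 0.1
    net["bv"] = np.zeros(d_out)
    return net


def init_params(config: ModelConfig, seed: int = 0) -> DrVAEParams:
    """Fresh parameters; the perturbation starts within ``pert_init_sd`` of
    the identity map."""
    rng = np.random.default_rng(seed)
    G, d, d3 = config.n_genes, config.latent_dim, config.z3_dim
    nets = {
        "enc": _init_gauss_net(rng, G, config.enc_hidden, d),
        "dec": _init_gauss_net(rng, d, config.enc_hidden, G),
        "x_log_var": np.zeros(G),
        "pert_W": rng.normal(0.0, config.pert_init_sd, size=(d, d)),
        "pert_b": rng.normal(0.0, config.pert_init_sd, size=d),
        "pert_log_var": np.zeros(d),
        "z3_enc": _init_gauss_net(rng, d + 1, config.aux_hidden, d3),
        "z1_prior": _init_gauss_net(rng, d3 + 1, config.aux_hidden, d),
        "clf_W": np.zeros((2 * d, 2)),
        "clf_b": np.zeros(2),
    }
    # decoder variance is a free per-gene parameter, not an input-dependent head
    nets["dec"].pop("Wv"); nets["dec"].pop("bv")
    return DrVAEParams(nets=nets, config=config)


def _elu(x):
    return anp.where(x > 0, x, anp.exp(anp.minimum(x, 0.0)) - 1.0)


def _gauss_net_forward(net: dict, x):
    h = x
    if "W1" in net:
        h = _elu(anp.dot(h, net["W1"]) + net["b1"])
    mean = anp.dot(h, net["Wm"]) + net["bm"]
    if "Wv" in net:
        log_var = anp.dot(h, net["Wv"]) + net["bv"]
    else:
        log_var = None
    return mean, log_var


def _encode(nets: dict, x):
    return _gauss_net_forward(nets["enc"], x)


def _decode(nets: dict, z):
    mean, _ = _gauss_net_forward(nets["dec"], z)
    log_var = 0.0 * mean + nets["x_log_var"]   # broadcast, autograd-safe
    return mean, log_var


def _perturb(nets: dict, z1):
    mean = z1 + anp.dot(z1, nets["pert_W"].T) + nets["pert_b"]
    log_var = 0.0 * mean + nets["pert_log_var"]   # broadcast, autograd-safe
    return mean, log_var


def _with_label(z, y):
    """Append the label as an extra input coordinate."""
    y_col = anp.reshape(y * anp.ones(anp.shape(z)[:-1]), anp.shape(z)[:-1] + (1,))
    return anp.concatenate([z, y_col], axis=-1)


def _infer_z3(nets: dict, z1, y):
    return _gauss_net_forward(nets["z3_enc"], _with_label(z1, y))


def _prior_z1(nets: dict, z3, y):
    return _gauss_net_forward(nets["z1_prior"], _with_label(z3, y))


def _sigmoid(t):
    return 0.5 * (anp.tanh(0.5 * t) + 1.0)


def _classify(nets: dict, z1, z2):
    feats = anp.concatenate([z1, z2 - z1], axis=-1)
    logits = anp.dot(feats, nets["clf_W"]) + nets["clf_b"]
    return _sigmoid(logits[..., 1] - logits[..., 0])


# ---------------------------------------------------------------------------
# public single-sample operations
# ---------------------------------------------------------------------------

def _check_vec(x, length, name):
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.shape[0] != length:
        raise DimensionError(f"{name} must have length {length}, got shape {x.shape}")
    return x


def encode(x, params: DrVAEParams) -> GaussianParams:
    """q(z|x); the same encoder serves pre- and post-treatment profiles."""
    x = _check_vec(x, params.config.n_genes, "x")
    mean, log_var = _encode(params.nets, x)
    return GaussianParams(mean=mean, log_var=log_var)


def decode(z, params: DrVAEParams) -> GaussianParams:
    """p(x|z), a diagonal Gaussian over genes with free per-gene variance."""
    zv = z.value if isinstance(z, LatentSample) else z
    zv = _check_vec(zv, params.config.latent_dim, "z")
    mean, log_var = _decode(params.nets, zv)
    return GaussianParams(mean=mean, log_var=log_var)


def perturb(z1, params: DrVAEParams) -> GaussianParams:
    """p(z2|z1) with linear mean z1 + W z1 + b and state-independent variance."""
    zv = z1.value if isinstance(z1, LatentSample) else z1
    zv = _check_vec(zv, params.config.latent_dim, "z1")
    mean, log_var = _perturb(params.nets, zv)
    return GaussianParams(mean=mean, log_var=np.array(log_var))


def classify(z1, z2, params: DrVAEParams) -> float:
    """q(y=1 | z1, z2): linear softmax on [z1, z2 - z1]."""
    z1v = z1.value if isinstance(z1, LatentSample) else z1
    z2v = z2.value if isinstance(z2, LatentSample) else z2
    d = params.config.latent_dim
    z1v = _check_vec(z1v, d, "z1")
    z2v = _check_vec(z2v, d, "z2")
    return float(_classify(params.nets, z1v, z2v))


def infer_z3(z1, y, params: DrVAEParams) -> GaussianParams:
    """q(z3 | z1, y)."""
    zv = z1.value if isinstance(z1, LatentSample) else z1
    zv = _check_vec(zv, params.config.latent_dim, "z1")
    mean, log_var = _infer_z3(params.nets, zv, float(y))
    return GaussianParams(mean=mean, log_var=log_var)


def prior_z1(z3, y, params: DrVAEParams) -> GaussianParams:
    """p(z1 | z3, y); p(z3) is a unit Gaussian and p(y) uniform."""
    zv = z3.value if isinstance(z3, LatentSample) else z3
    zv = _check_vec(zv, params.config.z3_dim, "z3")
    mean, log_var = _prior_z1(params.nets, zv, float(y))
    return GaussianParams(mean=mean, log_var=log_var)


# ---------------------------------------------------------------------------
# ELBOs — batched cores
# ---------------------------------------------------------------------------
# Single-sample reparameterized estimators; Gaussian-Gaussian KLs in closed
# form.  ``eps`` carries the standard-normal noise for (z1, z2, z3) so that
# the same draws can be reused across the two label branches when the label
# is marginalized (common random numbers), and so gradient tests can hold
# the noise fixed.

def draw_noise(rng: np.random.Generator, n: int, config: ModelConfig) -> dict:
    d, d3 = config.latent_dim, config.z3_dim
    return {
        "z1": rng.standard_normal((n, d)),
        "z2": rng.standard_normal((n, d)),
        "z3": rng.standard_normal((n, d3)),
    }


def _labeled_branch(nets, q1_mean, q1_lv, z1, y, eps_z3):
    """Label-dependent ELBO terms:
    log p(z1|z3,y) - log q(z1|x1) - KL(q(z3|z1,y) || p(z3)) + log p(y).

    The z1-prior term stays a sampled log-ratio: q(z3|z1,y) conditions on
    the sampled z1, so swapping it for a closed-form KL would bias the
    estimator and can break the lower-bound property.  The z3-prior KL is a
    valid conditional Rao-Blackwellization and is analytic."""
    q3_mean, q3_lv = _infer_z3(nets, z1, y)
    z3 = reparameterize_batch(q3_mean, q3_lv, eps_z3)
    p1_mean, p1_lv = _prior_z1(nets, z3, y)
    log_ratio_z1 = (log_density_batch(z1, p1_mean, p1_lv)
                    - log_density_batch(z1, q1_mean, q1_lv))
    kl_z3 = kl_batch(q3_mean, q3_lv, anp.zeros_like(q3_mean), anp.zeros_like(q3_lv))
    return log_ratio_z1 - kl_z3 + LOG_HALF


def _bernoulli_entropy(q):
    qc = anp.clip(q, BCE_EPS, 1.0 - BCE_EPS)
    return -(qc * anp.log(qc) + (1.0 - qc) * anp.log(1.0 - qc))


def _elbo_pair_batch(nets, x1, x2, y, eps):
    """Per-pair ELBO values, shape (n,).

    ``y`` is a float array with NaN marking unlabeled pairs; for those the
    label is marginalized under q(y|z1,z2) and the classifier entropy added.
    Returns ``(elbo, q_y)`` where q_y holds the classifier output on the
    sampled latents (used by the cross-entropy loss).
    """
    q1_mean, q1_lv = _encode(nets, x1)
    q2_mean, q2_lv = _encode(nets, x2)
    z1 = reparameterize_batch(q1_mean, q1_lv, eps["z1"])
    z2 = reparameterize_batch(q2_mean, q2_lv, eps["z2"])
    rec1 = log_density_batch(x1, *_decode(nets, z1))
    rec2 = log_density_batch(x2, *_decode(nets, z2))
    p2_mean, p2_lv = _perturb(nets, z1)
    kl_z2 = kl_batch(q2_mean, q2_lv, p2_mean, p2_lv)
    shared = rec1 + rec2 - kl_z2

    branch0 = _labeled_branch(nets, q1_mean, q1_lv, z1, 0.0, eps["z3"])
    branch1 = _labeled_branch(nets, q1_mean, q1_lv, z1, 1.0, eps["z3"])
    q_y = _classify(nets, z1, z2)

    y = anp.asarray(y, dtype=float)
    labeled = ~np.isnan(np.asarray(y))
    y_filled = anp.where(labeled, anp.nan_to_num(y), 0.0)
    lab_branch = anp.where(y_filled > 0.5, branch1, branch0)
    marg_branch = (1.0 - q_y) * branch0 + q_y * branch1 + _bernoulli_entropy(q_y)
    elbo = shared + anp.where(labeled, lab_branch, marg_branch)
    return elbo, q_y


def _elbo_singleton_batch(nets, x1, y, eps):
    """Per-singleton ELBO values; when the label is marginalized the
    classifier reads z2 = mean of p(z2|z1) for the sampled z1."""
    q1_mean, q1_lv = _encode(nets, x1)
    z1 = reparameterize_batch(q1_mean, q1_lv, eps["z1"])
    rec1 = log_density_batch(x1, *_decode(nets, z1))

    branch0 = _labeled_branch(nets, q1_mean, q1_lv, z1, 0.0, eps["z3"])
    branch1 = _labeled_branch(nets, q1_mean, q1_lv, z1, 1.0, eps["z3"])
    z2_mean, _ = _perturb(nets, z1)
    q_y = _classify(nets, z1, z2_mean)

    y = anp.asarray(y, dtype=float)
    labeled = ~np.isnan(np.asarray(y))
    y_filled = anp.where(labeled, anp.nan_to_num(y), 0.0)
    lab_branch = anp.where(y_filled > 0.5, branch1, branch0)
    marg_branch = (1.0 - q_y) * branch0 + q_y * branch1 + _bernoulli_entropy(q_y)
    elbo = rec1 + anp.where(labeled, lab_branch, marg_branch)
    return elbo, q_y


def _elbo_pertvae_pair_batch(nets, x1, x2, eps):
    """PertVAE pair ELBO: the label/z3 branch is replaced by the fixed
    standard-normal prior on z1."""
    q1_mean, q1_lv = _encode(nets, x1)
    q2_mean, q2_lv = _encode(nets, x2)
    z1 = reparameterize_batch(q1_mean, q1_lv, eps["z1"])
    z2 = reparameterize_batch(q2_mean, q2_lv, eps["z2"])
    rec1 = log_density_batch(x1, *_decode(nets, z1))
    rec2 = log_density_batch(x2, *_decode(nets, z2))
    p2_mean, p2_lv = _perturb(nets, z1)
    kl_z2 = kl_batch(q2_mean, q2_lv, p2_mean, p2_lv)
    kl_z1 = kl_batch(q1_mean, q1_lv, anp.zeros_like(q1_mean), anp.zeros_like(q1_lv))
    return rec1 + rec2 - kl_z2 - kl_z1


def _elbo_pertvae_single_batch(nets, x1, eps):
    q1_mean, q1_lv = _encode(nets, x1)
    z1 = reparameterize_batch(q1_mean, q1_lv, eps["z1"])
    rec1 = log_density_batch(x1, *_decode(nets, z1))
    kl_z1 = kl_batch(q1_mean, q1_lv, anp.zeros_like(q1_mean), anp.zeros_like(q1_lv))
    return rec1 - kl_z1


# ---------------------------------------------------------------------------
# public ELBO / objective
# ---------------------------------------------------------------------------

def _noise_for(x, config, noise_source):
    n = 1
    if isinstance(noise_source, np.random.Generator):
        return draw_noise(noise_source, n, config)
    return noise_source  # already a dict of arrays


def elbo_pair(x1, x2, y, params: DrVAEParams, noise_source) -> float:
    """Single-sample ELBO estimate for one perturbation pair.

    ``y`` may be 0, 1 or None (unlabeled: the label is summed out under the
    classifier posterior, plus its entropy).  ``noise_source`` is a seeded
    ``numpy.random.Generator`` or an explicit noise dict from
    :func:`draw_noise`.
    """
    G = params.config.n_genes
    x1 = _check_vec(x1, G, "x1")[None, :]
    x2 = _check_vec(x2, G, "x2")[None, :]
    eps = _noise_for(x1, params.config, noise_source)
    yv = np.array([np.nan if y is None else float(y)])
    elbo, _ = _elbo_pair_batch(params.nets, x1, x2, yv, eps)
    out = float(elbo[0])
    if not np.isfinite(out):
        raise NumericalError("non-finite pair ELBO")
    return out


def elbo_singleton(x1, y, params: DrVAEParams, noise_source) -> float:
    """Single-sample ELBO estimate for one pre-treatment singleton."""
    G = params.config.n_genes
    x1 = _check_vec(x1, G, "x1")[None, :]
    eps = _noise_for(x1, params.config, noise_source)
    yv = np.array([np.nan if y is None else float(y)])
    elbo, _ = _elbo_singleton_batch(params.nets, x1, yv, eps)
    out = float(elbo[0])
    if not np.isfinite(out):
        raise NumericalError("non-finite singleton ELBO")
    return out


def _objective_core(nets, batch: Batch, eps_pairs, eps_singles, kind: str,
                    class_loss_weight: float):
    """Negative summed ELBO (+ weighted classifier cross-entropy).

    Returns the scalar the optimizer minimizes.  Under ``kind='pertvae'``
    labels are ignored and the z3/classifier machinery never enters.
    """
    total = 0.0
    ce = 0.0
    if batch.n_pairs:
        if kind == "pertvae":
            elbo_p = _elbo_pertvae_pair_batch(nets, batch.pairs_x1, batch.pairs_x2, eps_pairs)
        else:
            elbo_p, q_y = _elbo_pair_batch(
                nets, batch.pairs_x1, batch.pairs_x2, batch.pairs_y, eps_pairs)
            lab = ~np.isnan(batch.pairs_y)
            if lab.any():
                ce = ce + anp.sum(bce_batch(q_y[lab], batch.pairs_y[lab]))
        total = total + anp.sum(elbo_p)
    if batch.n_singles:
        if kind == "pertvae":
            elbo_s = _elbo_pertvae_single_batch(nets, batch.singles_x1, eps_singles)
        else:
            elbo_s, q_y = _elbo_singleton_batch(
                nets, batch.singles_x1, batch.singles_y, eps_singles)
            lab = ~np.isnan(batch.singles_y)
            if lab.any():
                ce = ce + anp.sum(bce_batch(q_y[lab], batch.singles_y[lab]))
        total = total + anp.sum(elbo_s)
    return -total + class_loss_weight * ce


def total_objective(batch: Batch, params: DrVAEParams, noise_source) -> float:
    """The minimized quantity: −(sum of the four regime ELBOs) plus
    ``class_loss_weight`` × summed classifier cross-entropy on labeled items.
    """
    if batch.is_empty():
        raise ValidationError("total_objective of an empty batch")
    if isinstance(noise_source, np.random.Generator):
        eps_p = draw_noise(noise_source, batch.n_pairs, params.config)
        eps_s = draw_noise(noise_source, batch.n_singles, params.config)
    else:
        eps_p, eps_s = noise_source
    val = _objective_core(params.nets, batch, eps_p, eps_s,
                          params.config.kind, params.class_loss_weight)
    val = float(val)
    if not np.isfinite(val):
        # re-evaluate term-wise to name the offender
        for name, fn in _diagnostic_terms(params, batch, eps_p, eps_s):
            if not np.isfinite(fn()):
                raise NumericalError(f"non-finite objective term: {name}")
        raise NumericalError("non-finite objective")
    return val


def _diagnostic_terms(params, batch, eps_p, eps_s):
    nets, kind = params.nets, params.config.kind
    terms = []
    if batch.n_pairs:
        if kind == "pertvae":
            terms.append(("pair ELBO", lambda: float(anp.sum(
                _elbo_pertvae_pair_batch(nets, batch.pairs_x1, batch.pairs_x2, eps_p)))))
        else:
            terms.append(("pair ELBO", lambda: float(anp.sum(
                _elbo_pair_batch(nets, batch.pairs_x1, batch.pairs_x2, batch.pairs_y, eps_p)[0]))))
    if batch.n_singles:
        if kind == "pertvae":
            terms.append(("singleton ELBO", lambda: float(anp.sum(
                _elbo_pertvae_single_batch(nets, batch.singles_x1, eps_s)))))
        else:
            terms.append(("singleton ELBO", lambda: float(anp.sum(
                _elbo_singleton_batch(nets, batch.singles_x1, batch.singles_y, eps_s)[0]))))
    return terms


def mc_elbo_pair(x1, x2, y, params: DrVAEParams, n_draws: int, seed: int = 0):
    """Monte-Carlo average of the pair ELBO over ``n_draws`` noise draws.

    Returns ``(mean, standard_error)``; used to compare the bound against
    independently computed log evidence."""
    G = params.config.n_genes
    x1 = np.tile(_check_vec(x1, G, "x1"), (n_draws, 1))
    x2 = np.tile(_check_vec(x2, G, "x2"), (n_draws, 1))
    eps = draw_noise(np.random.default_rng(seed), n_draws, params.config)
    yv = np.full(n_draws, np.nan if y is None else float(y))
    vals, _ = _elbo_pair_batch(params.nets, x1, x2, yv, eps)
    vals = np.asarray(vals)
    return float(vals.mean()), float(vals.std(ddof=1) / np.sqrt(n_draws))


def mc_elbo_singleton(x1, y, params: DrVAEParams, n_draws: int, seed: int = 0):
    """Monte-Carlo average of the singleton ELBO; see :func:`mc_elbo_pair`."""
    G = params.config.n_genes
    x1 = np.tile(_check_vec(x1, G, "x1"), (n_draws, 1))
    eps = draw_noise(np.random.default_rng(seed), n_draws, params.config)
    yv = np.full(n_draws, np.nan if y is None else float(y))
    vals, _ = _elbo_singleton_batch(params.nets, x1, yv, eps)
    vals = np.asarray(vals)
    return float(vals.mean()), float(vals.std(ddof=1) / np.sqrt(n_draws))


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

def predict_response_batch(x1: np.ndarray, params: DrVAEParams):
    """Mean-propagated predictions for an (n, G) matrix.

    Returns ``(prob, z1_mean, z2_mean)``.  No sampling: z1 is the posterior
    mean of q(z1|x1), z2 the mean of p(z2|z1), and the probability the
    classifier output on those means.
    """
    x1 = np.atleast_2d(np.asarray(x1, dtype=float))
    if x1.shape[1] != params.config.n_genes:
        raise DimensionError(
            f"expected {params.config.n_genes} genes, got {x1.shape[1]}")
    z1_mean, _ = _encode(params.nets, x1)
    z2_mean, _ = _perturb(params.nets, z1_mean)
    prob = _classify(params.nets, z1_mean, z2_mean)
    return np.asarray(prob), np.asarray(z1_mean), np.asarray(z2_mean)


def predict_response(x1, params: DrVAEParams) -> ResponsePrediction:
    """Response probability from pre-treatment expression alone."""
    x1 = _check_vec(x1, params.config.n_genes, "x1")
    prob, z1m, z2m = predict_response_batch(x1[None, :], params)
    return ResponsePrediction(
        prob_sensitive=float(prob[0]), z1_mean=z1m[0], z2_mean=z2m[0])


def predict_posttreatment(x1, params: DrVAEParams) -> np.ndarray:
    """Decoder mean of the predicted post-treatment state.

    With W = b = 0 this is the plain autoencoding reconstruction of x1
    (the "DrVAE w/I" predictor)."""
    single = np.asarray(x1).ndim == 1
    x1 = np.atleast_2d(np.asarray(x1, dtype=float))
    _, _, z2_mean = predict_response_batch(x1, params)
    x2_mean, _ = _decode(params.nets, z2_mean)
    x2_mean = np.asarray(x2_mean)
    return x2_mean[0] if single else x2_mean


def embed(x, params: DrVAEParams) -> np.ndarray:
    """Posterior mean of q(z1|x): the reduced representation used when a
    PertVAE feeds a downstream classifier."""
    single = np.asarray(x).ndim == 1
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[1] != params.config.n_genes:
        raise DimensionError(f"expected {params.config.n_genes} genes")
    mean, _ = _encode(params.nets, x)
    mean = np.asarray(mean)
    return mean[0] if single else mean


def set_identity_perturbation(params: DrVAEParams) -> DrVAEParams:
    """The "DrVAE w/I" ablation: W = 0, b = 0, nothing else touched."""
    out = params.copy()
    out.nets["pert_W"] = np.zeros_like(out.nets["pert_W"])
    out.nets["pert_b"] = np.zeros_like(out.nets["pert_b"])
    return out


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

class _Adam:
    """Plain Adam on a flat parameter vector."""

    def __init__(self, n, lr=1e-3, b1=0.9, b2=0.999, eps=1e-8):
        self.m = np.zeros(n)
        self.v = np.zeros(n)
        self.t = 0
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps

    def step(self, x, g):
        self.t += 1
        self.m = self.b1 * self.m + (1 - self.b1) * g
        self.v = self.b2 * self.v + (1 - self.b2) * g * g
        mhat = self.m / (1 - self.b1 ** self.t)
        vhat = self.v / (1 - self.b2 ** self.t)
        return x - self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _minibatches(batch: Batch, batch_size: int, rng: np.random.Generator):
    """Index chunks over pairs and singletons, shuffled each epoch."""
    p_order = rng.permutation(batch.n_pairs)
    s_order = rng.permutation(batch.n_singles)
    p_chunks = [p_order[i:i + batch_size] for i in range(0, len(p_order), batch_size)]
    s_chunks = [s_order[i:i + batch_size] for i in range(0, len(s_order), batch_size)]
    empty = np.zeros(0, dtype=int)
    for pc, sc in zip_longest(p_chunks, s_chunks, fillvalue=empty):
        yield pc, sc


_FROZEN = {"ssvae": ("pert_W", "pert_b", "pert_log_var")}


def _auroc_or_nan(scores, labels):
    labels = np.asarray(labels)
    if len(labels) == 0 or len(np.unique(labels)) < 2:
        return float("nan")
    from .evaluation import auroc
    return auroc(scores, labels)


def _train_one(train: Batch, val: Optional[Batch], config: ModelConfig,
               class_loss_weight: float, seed_seq: np.random.SeedSequence):
    """Train one candidate (one class-loss weight) with early stopping."""
    s_init, s_noise, s_shuffle, s_val = (
        np.random.default_rng(c) for c in seed_seq.spawn(4))
    params = init_params(config, seed=int(s_init.integers(2 ** 31)))
    params.class_loss_weight = class_loss_weight
    flat, unflatten = ag_flatten(params.nets)
    opt = _Adam(flat.size, lr=config.learning_rate)
    frozen = _FROZEN.get(config.kind, ())

    have_val = val is not None and not val.is_empty()
    if have_val:
        val_eps = (draw_noise(s_val, val.n_pairs, config),
                   draw_noise(s_val, val.n_singles, config))
        val_x, val_y = val.labeled_x1()
    else:
        warnings.warn("empty validation set: training for max_epochs with no early stopping")

    log = {"class_loss_weight": class_loss_weight, "train_objective": [],
           "val_objective": [], "val_auroc": []}
    best = {"val": np.inf, "flat": flat.copy(), "epoch": -1}
    since_best = 0

    def batch_loss(nets_dict, sub: Batch, eps_p, eps_s):
        return _objective_core(nets_dict, sub, eps_p, eps_s,
                               config.kind, class_loss_weight)

    loss_and_grad = ag_value_and_grad(batch_loss)

    for epoch in range(config.max_epochs):
        epoch_obj = 0.0
        for p_idx, s_idx in _minibatches(train, config.batch_size, s_shuffle):
            sub = train.subset(p_idx, s_idx)
            if sub.is_empty():
                continue
            eps_p = draw_noise(s_noise, sub.n_pairs, config)
            eps_s = draw_noise(s_noise, sub.n_singles, config)
            nets = unflatten(flat)
            loss_val, g = loss_and_grad(nets, sub, eps_p, eps_s)
            for name in frozen:
                g[name] = np.zeros_like(g[name])
            gflat, _ = ag_flatten(g)
            if not np.all(np.isfinite(gflat)):
                raise NumericalError(f"non-finite gradient at epoch {epoch}")
            gflat = np.clip(gflat, -config.grad_clip, config.grad_clip)
            epoch_obj += float(loss_val)
            flat = opt.step(flat, gflat)
        if not np.isfinite(epoch_obj):
            raise NumericalError(f"non-finite training objective at epoch {epoch}")
        log["train_objective"].append(epoch_obj)

        if have_val:
            nets = unflatten(flat)
            v = float(_objective_core(nets, val, val_eps[0], val_eps[1],
                                      config.kind, class_loss_weight))
            log["val_objective"].append(v)
            if config.kind != "pertvae" and len(val_y):
                p = DrVAEParams(nets=nets, config=config,
                                class_loss_weight=class_loss_weight)
                scores, _, _ = predict_response_batch(val_x, p)
                log["val_auroc"].append(_auroc_or_nan(scores, val_y))
            else:
                log["val_auroc"].append(float("nan"))
            if v < best["val"] - 1e-12:
                best = {"val": v, "flat": flat.copy(), "epoch": epoch}
                since_best = 0
            else:
                since_best += 1
                if since_best >= config.patience:
                    break
        else:
            log["val_objective"].append(float("nan"))
            log["val_auroc"].append(float("nan"))

    if have_val and best["epoch"] >= 0:
        flat = best["flat"]
        log["best_epoch"] = best["epoch"]
    else:
        log["best_epoch"] = len(log["train_objective"]) - 1
    log["epochs_run"] = len(log["train_objective"])

    out = DrVAEParams(nets=unflatten(flat), config=config,
                      class_loss_weight=class_loss_weight)
    return out, log


def fit(train: Batch, val: Optional[Batch], config: ModelConfig, seed: int = 0):
    """Train a DrVAE-family model.

    For each candidate classification-loss weight in
    ``config.class_weight_grid`` the model is trained with Adam and early
    stopping (patience epochs without validation-objective improvement);
    the candidate with the best validation AUROC wins (falling back to the
    validation objective when AUROC is undefined, e.g. for PertVAE or
    unlabeled validation data).  Fully reproducible given ``seed``.

    Returns ``(DrVAEParams, training_log)``.
    """
    if train.is_empty():
        raise ValidationError("empty training batch")
    if config.max_epochs == 0:
        params = init_params(config, seed=seed)
        return params, {"candidates": [], "selected_weight": None,
                        "criterion": "none", "epochs_run": 0}

    grid = list(config.class_weight_grid)
    if config.kind == "pertvae":
        grid = [0.0]
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(grid))

    candidates = []
    for w, child in zip(grid, children):
        params, log = _train_one(train, val, config, w, child)
        candidates.append((params, log))

    def score(entry):
        _, log = entry
        be = log["best_epoch"]
        auc = log["val_auroc"][be] if log["val_auroc"] else float("nan")
        if np.isfinite(auc):
            return ("auroc", auc)
        vo = log["val_objective"][be] if log["val_objective"] else float("nan")
        return ("objective", -vo if np.isfinite(vo) else -np.inf)

    kinds = {score(c)[0] for c in candidates}
    criterion = "auroc" if kinds == {"auroc"} else "objective"
    best = max(candidates, key=lambda c: score(c)[1])
    full_log = {
        "candidates": [c[1] for c in candidates],
        "selected_weight": best[0].class_loss_weight,
        "criterion": criterion,
    }
    return best[0], full_log


def ssvae_variant(train: Batch, val: Optional[Batch], config: ModelConfig,
                  seed: int = 0):
    """Train the SSVAE ablation: pairs are flattened to their pre-treatment
    member, the perturbation is frozen at the identity, so the classifier
    effectively reads z1 alone.  Returns ``(params, log, predict_fn)``."""
    cfg = replace(config, kind="ssvae")
    tr = train.flatten_pairs()
    vl = val.flatten_pairs() if val is not None else None
    params, log = fit(tr, vl, cfg, seed=seed)
    params.nets["pert_W"] = np.zeros_like(params.nets["pert_W"])
    params.nets["pert_b"] = np.zeros_like(params.nets["pert_b"])

    def predict_fn(x):
        return predict_response_batch(x, params)[0]

    return params, log, predict_fn


def pertvae_variant(train: Batch, val: Optional[Batch], config: ModelConfig,
                    seed: int = 0):
    """Train the unsupervised PertVAE sub-model (labels ignored).

    Returns ``(params, log, embed_fn)`` where ``embed_fn(x)`` is the mean
    of q(z1|x), the reduced representation for downstream classifiers."""
    cfg = replace(config, kind="pertvae")
    params, log = fit(train.without_labels(),
                      val.without_labels() if val is not None else None,
                      cfg, seed=seed)

    def embed_fn(x):
        return embed(x, params)

    return params, log, embed_fn


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

CHECKPOINT_FORMAT_VERSION = 1


def _flatten_nets(nets, prefix=""):
    out = {}
    for k, v in nets.items():
        if isinstance(v, dict):
            out.update(_flatten_nets(v, prefix + k + "."))
        else:
            out[prefix + k] = np.asarray(v)
    return out


def save_checkpoint(path, params: DrVAEParams, log: Optional[dict] = None) -> None:
    """Write a single portable .npz archive: format version, config, all
    parameter tensors by name, and the training log."""
    tensors = _flatten_nets(params.nets)
    meta = {
        "format_version": CHECKPOINT_FORMAT_VERSION,
        "config": asdict(params.config),
        "class_loss_weight": params.class_loss_weight,
        "log": log or {},
    }
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta, default=float).encode(), dtype=np.uint8), **tensors)


def load_checkpoint(path) -> tuple:
    """Read a checkpoint; returns ``(DrVAEParams, training_log)``."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        if meta.get("format_version") != CHECKPOINT_FORMAT_VERSION:
            raise ValidationError(
                f"unsupported checkpoint format {meta.get('format_version')!r}")
        cfg = ModelConfig(**{k: tuple(v) if isinstance(v, list) else v
                             for k, v in meta["config"].items()})
        nets: dict = {}
        for name in data.files:
            if name == "__meta__":
                continue
            parts = name.split(".")
            node = nets
            for p in parts[:-1]:
                node = node.setdefault(p, {})
            node[parts[-1]] = data[name]
    params = DrVAEParams(nets=nets, config=cfg,
                         class_loss_weight=meta["class_loss_weight"])
    return params, meta["log"]
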