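"""Diagonal-Gaussian primitives shared by every model in the package.

All latent and observed conditionals in the DrVAE model family are factorized
(diagonal-covariance) Gaussians.  Variances are carried in log-space
throughout for numerical stability; the helpers here are written against
``autograd.numpy`` so that every quantity is differentiable with respect to
the Gaussian parameters.

Scalar/vector public entry points validate their inputs and operate on a
single vector; the ``*_batch`` helpers accept ``(n, d)`` arrays and are what
the model code calls in its inner loop (no validation, autograd-safe).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import autograd.numpy as anp
import numpy as np

LOG_2PI = float(np.log(2.0 * np.pi))

#: probabilities are clamped to [BCE_EPS, 1 - BCE_EPS] before taking logs
BCE_EPS = 1e-7


class DimensionError(ValueError):
    """Operands have incompatible lengths/shapes."""


class ValidationError(ValueError):
    """An input violates a documented precondition."""


class NumericalError(ArithmeticError):
    """A non-finite value appeared where a finite one is required."""


@dataclass
class GaussianParams:
    """Mean and diagonal log-variance of a factorized Gaussian.

    Parameters may be 1-d (a single distribution over ``d`` coordinates) or
    2-d ``(n, d)`` (a batch of ``n`` independent distributions).
    """

    mean: np.ndarray
    log_var: np.ndarray

    def __post_init__(self) -> None:
        self.mean = anp.asarray(self.mean, dtype=float) if not hasattr(self.mean, "_value") else self.mean
        self.log_var = anp.asarray(self.log_var, dtype=float) if not hasattr(self.log_var, "_value") else self.log_var
        if anp.shape(self.mean) != anp.shape(self.log_var):
            raise DimensionError(
                f"mean shape {anp.shape(self.mean)} != log_var shape {anp.shape(self.log_var)}"
            )

    @property
    def dim(self) -> int:
        return int(anp.shape(self.mean)[-1])

    def sd(self) -> np.ndarray:
        """Standard deviation, exp(log_var / 2)."""
        return anp.exp(0.5 * self.log_var)

    def validate_finite(self) -> "GaussianParams":
        if not (np.all(np.isfinite(self.mean)) and np.all(np.isfinite(self.log_var))):
            raise ValidationError("GaussianParams contain non-finite entries")
        return self


@dataclass
class LatentSample:
    """A realization of one latent variable (z1, z2 or z3)."""

    value: np.ndarray
    source: str = "z1"

    def __post_init__(self) -> None:
        if self.source not in ("z1", "z2", "z3"):
            raise ValidationError(f"unknown latent source {self.source!r}")


# ---------------------------------------------------------------------------
# batched cores (autograd-safe, no validation)
# ---------------------------------------------------------------------------

def log_density_batch(x, mean, log_var):
    """Row-wise diagonal-Gaussian log density; sums over the last axis."""
    return anp.sum(
        -0.5 * LOG_2PI - 0.5 * log_var - (x - mean) ** 2 / (2.0 * anp.exp(log_var)),
        axis=-1,
    )


def kl_batch(q_mean, q_log_var, p_mean, p_log_var):
    """Row-wise closed-form KL(q || p) between diagonal Gaussians."""
    var_ratio = anp.exp(q_log_var - p_log_var)
    t = (q_mean - p_mean) ** 2 / anp.exp(p_log_var)
    return 0.5 * anp.sum(var_ratio + t - 1.0 - (q_log_var - p_log_var), axis=-1)


def reparameterize_batch(mean, log_var, noise):
    """mean + exp(log_var / 2) * noise — the reparameterization trick."""
    return mean + anp.exp(0.5 * log_var) * noise


def bce_batch(prob_positive, label):
    """Elementwise binary cross-entropy with probability clamping."""
    p = anp.clip(prob_positive, BCE_EPS, 1.0 - BCE_EPS)
    return -(label * anp.log(p) + (1.0 - label) * anp.log(1.0 - p))


# ---------------------------------------------------------------------------
# validated single-vector operations
# ---------------------------------------------------------------------------

def _check_lengths(x, g: GaussianParams, name: str = "x") -> np.ndarray:
    x = anp.asarray(x, dtype=float)
    if anp.shape(x) != anp.shape(g.mean):
        raise DimensionError(f"{name} shape {anp.shape(x)} != Gaussian shape {anp.shape(g.mean)}")
    return x


def diag_gaussian_log_density(x, g: GaussianParams) -> float:
    """Log density of ``x`` under the diagonal Gaussian ``g``.

    Returns sum_i [ -log(2*pi)/2 - log_var_i/2 - (x_i - mean_i)^2 / (2 var_i) ].
    """
    x = _check_lengths(x, g)
    if not np.all(np.isfinite(np.asarray(x, dtype=float))):
        raise ValidationError("x contains non-finite entries")
    g.validate_finite()
    return float(log_density_batch(x, g.mean, g.log_var))


def diag_gaussian_kl(q: GaussianParams, p: GaussianParams) -> float:
    """Exact KL(q || p) for diagonal Gaussians; nonnegative, 0 iff q == p.

    The closed form is mathematically nonnegative; the result is clipped at
    zero to absorb float rounding for nearly identical distributions."""
    if anp.shape(q.mean) != anp.shape(p.mean):
        raise DimensionError(
            f"q dim {anp.shape(q.mean)} != p dim {anp.shape(p.mean)}"
        )
    return max(float(kl_batch(q.mean, q.log_var, p.mean, p.log_var)), 0.0)


def reparameterize(g: GaussianParams, noise, source: str = "z1") -> LatentSample:
    """Draw ``mean + sd * noise``; differentiable in the Gaussian parameters."""
    noise = _check_lengths(noise, g, name="noise")
    return LatentSample(value=reparameterize_batch(g.mean, g.log_var, noise), source=source)


def binary_cross_entropy(prob_positive: float, label) -> float:
    """-[y log p + (1 - y) log(1 - p)] with p clamped away from {0, 1}."""
    if label not in (0, 1, 0.0, 1.0):
        raise ValidationError(f"label must be 0 or 1, got {label!r}")
    return float(bce_batch(float(prob_positive), float(label)))
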