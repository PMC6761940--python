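"""Independent reference computations used by the tests.

These deliberately avoid the package's own code paths wherever possible:
scalar normal densities come from scipy.stats, integrals from trapezoid
quadrature on wide grids, AUROC from exhaustive pair counting, Wilcoxon
p-values from full sign enumeration, and the waterfall cutoff from a
brute-force distance-to-chord search.
"""

from __future__ import annotations

from itertools import product

import numpy as np
from scipy import stats
from scipy.integrate import trapezoid

from drvae.models import _decode, _encode, _perturb, _prior_z1


def scalar_normal_logpdf_sum(x, mean, log_var):
    """Sum of scalar normal log-densities via scipy (oracle for the
    package's own vectorized formula)."""
    x, mean, log_var = map(np.atleast_1d, (x, mean, log_var))
    return float(sum(stats.norm.logpdf(xi, mi, np.exp(0.5 * lvi))
                     for xi, mi, lvi in zip(x, mean, log_var)))


def mc_kl_estimate(q_mean, q_lv, p_mean, p_lv, n, seed):
    """Monte-Carlo E_q[log q - log p] with standard error."""
    rng = np.random.default_rng(seed)
    d = len(q_mean)
    z = q_mean + np.exp(0.5 * np.asarray(q_lv)) * rng.standard_normal((n, d))
    lq = np.sum(stats.norm.logpdf(z, q_mean, np.exp(0.5 * np.asarray(q_lv))), axis=1)
    lp = np.sum(stats.norm.logpdf(z, p_mean, np.exp(0.5 * np.asarray(p_lv))), axis=1)
    diff = lq - lp
    return diff.mean(), diff.std(ddof=1) / np.sqrt(n)


# ---------------------------------------------------------------------------
# quadrature log-evidence for 1-latent-dim toy models
# ---------------------------------------------------------------------------

def _norm_pdf(x, mean, var):
    return np.exp(-0.5 * (x - mean) ** 2 / var) / np.sqrt(2 * np.pi * var)


def _x_lik(nets, x, z_grid):
    """p(x|z) for each z in the grid; x is a length-G vector."""
    mean, log_var = _decode(nets, z_grid[:, None])
    var = np.exp(np.asarray(log_var))
    dens = _norm_pdf(np.asarray(x)[None, :], np.asarray(mean), var)
    return np.prod(dens, axis=1)


def _z1_prior_marginal(nets, z1_grid, y, z3_grid):
    """integral over z3 of p(z1|z3,y) p(z3), on the z1 grid."""
    p1_mean, p1_lv = _prior_z1(nets, z3_grid[:, None], float(y))
    p1_mean = np.asarray(p1_mean)[:, 0]
    p1_var = np.exp(np.asarray(p1_lv))[:, 0]
    dens = _norm_pdf(z1_grid[None, :], p1_mean[:, None], p1_var[:, None])
    prior_z3 = _norm_pdf(z3_grid, 0.0, 1.0)
    return trapezoid(dens * prior_z3[:, None], z3_grid, axis=0)


def quad_log_evidence_singleton(params, x1, y, span=14.0, n_grid=1201):
    """log p(x1, y) (or log p(x1) when y is None) by quadrature; requires
    latent_dim == z3_dim == 1."""
    nets = params.nets
    z1 = np.linspace(-span, span, n_grid)
    z3 = np.linspace(-span, span, n_grid)
    lik = _x_lik(nets, np.atleast_1d(x1), z1)
    ys = [0, 1] if y is None else [y]
    total = 0.0
    for yy in ys:
        marg = _z1_prior_marginal(nets, z1, yy, z3)
        total += 0.5 * trapezoid(lik * marg, z1)
    return float(np.log(total))


def quad_log_evidence_pair(params, x1, x2, y, span=14.0, n_grid=1201):
    """log p(x1, x2[, y]) by quadrature over (z1, z2, z3), latent dims 1."""
    nets = params.nets
    z1 = np.linspace(-span, span, n_grid)
    z2 = np.linspace(-span, span, n_grid)
    z3 = np.linspace(-span, span, n_grid)
    lik1 = _x_lik(nets, np.atleast_1d(x1), z1)
    lik2 = _x_lik(nets, np.atleast_1d(x2), z2)
    p2_mean, p2_lv = _perturb(nets, z1[:, None])
    p2_mean = np.asarray(p2_mean)[:, 0]
    p2_var = np.exp(np.asarray(p2_lv))[:, 0]
    # f(z1) = int p(x2|z2) p(z2|z1) dz2
    trans = _norm_pdf(z2[None, :], p2_mean[:, None], p2_var[:, None])
    f = trapezoid(trans * lik2[None, :], z2, axis=1)
    ys = [0, 1] if y is None else [y]
    total = 0.0
    for yy in ys:
        marg = _z1_prior_marginal(nets, z1, yy, z3)
        total += 0.5 * trapezoid(lik1 * f * marg, z1)
    return float(np.log(total))


# ---------------------------------------------------------------------------
# metric oracles
# ---------------------------------------------------------------------------

def auroc_pair_counting(scores, labels):
    """Fraction of (positive, negative) pairs correctly ordered, ties 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            wins += 1.0 if p > q else (0.5 if p == q else 0.0)
    return wins / (len(pos) * len(neg))


def aupr_threshold_enumeration(scores, labels):
    """Average precision by explicit threshold sweep (step-wise convention):
    sum over ranked positives of precision-at-that-rank weighted by the
    recall increment."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    order = np.argsort(-scores, kind="stable")
    y = labels[order]
    tp = np.cumsum(y)
    precision = tp / np.arange(1, len(y) + 1)
    n_pos = labels.sum()
    return float(np.sum(precision * y) / n_pos)


def wilcoxon_exact_enumeration(diffs, alternative="greater"):
    """Exact one-sided signed-rank p-value by enumerating all 2^n sign
    assignments (n <= 12; no zero differences, no tied magnitudes)."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    ranks = stats.rankdata(np.abs(d))
    w_obs = float(np.sum(ranks[d > 0]))
    count = 0
    for signs in product([0, 1], repeat=n):
        w = float(np.sum(ranks[np.array(signs, dtype=bool)]))
        if alternative == "greater":
            count += w >= w_obs
        else:
            count += w <= w_obs
    return count / 2 ** n


def waterfall_cutoff_bruteforce(aac_values):
    """Elbow AAC by exhaustive perpendicular-distance-to-chord search."""
    a = np.sort(np.asarray(aac_values, dtype=float))[::-1]
    n = len(a)
    x0, y0 = 0.0, a[0]
    x1, y1 = float(n - 1), a[-1]
    best, best_d = 0, -1.0
    for i in range(n):
        num = abs((y1 - y0) * i - (x1 - x0) * a[i] + x1 * y0 - y1 * x0)
        den = np.hypot(y1 - y0, x1 - x0)
        d = num / den
        if d > best_d:
            best, best_d = i, d
    return float(a[best])


def conjugate_linear_gaussian(x1_value=0.9):
    """An all-affine model whose variational family contains the true
    posterior, with the closed-form log evidence.

    Generative chain (all scalars): z3 ~ N(0,1); z1 | z3 ~ N(a z3 + g0, s1sq);
    x1 | z1 ~ N(c z1 + d, sxsq).  The prior-net label coefficient is zero so
    the posterior over z1 is label-independent, matching an encoder that
    conditions on x1 alone.  Encoder and z3-posterior parameters are set to
    the exact Gaussian conditionals.  Returns ``(params, x1, log_evidence)``
    where the evidence is for the labeled case (either label).
    """
    from drvae.models import ModelConfig, init_params

    a, g0, s1sq = 0.7, -0.2, 0.3
    c, d, sxsq = 1.3, 0.1, 0.4
    cfg = ModelConfig(n_genes=1, latent_dim=1, z3_dim=1,
                      enc_hidden=0, aux_hidden=0)
    params = init_params(cfg, seed=0)
    n = params.nets
    n["z1_prior"] = {"Wm": np.array([[a], [0.0]]), "bm": np.array([g0]),
                     "Wv": np.zeros((2, 1)), "bv": np.array([np.log(s1sq)])}
    n["dec"] = {"Wm": np.array([[c]]), "bm": np.array([d])}
    n["x_log_var"] = np.array([np.log(sxsq)])

    v1 = a * a + s1sq                       # marginal var of z1
    prec1 = 1 / v1 + c * c / sxsq           # posterior precision of z1 | x1
    n["enc"] = {"Wm": np.array([[(c / sxsq) / prec1]]),
                "bm": np.array([(g0 / v1 - c * d / sxsq) / prec1]),
                "Wv": np.zeros((1, 1)), "bv": np.array([np.log(1 / prec1)])}
    prec3 = 1 + a * a / s1sq                # posterior precision of z3 | z1
    n["z3_enc"] = {"Wm": np.array([[(a / s1sq) / prec3], [0.0]]),
                   "bm": np.array([(-a * g0 / s1sq) / prec3]),
                   "Wv": np.zeros((2, 1)), "bv": np.array([np.log(1 / prec3)])}

    x1 = np.array([float(x1_value)])
    log_evidence = float(
        stats.norm.logpdf(x1[0], c * g0 + d, np.sqrt(c * c * v1 + sxsq))
        + np.log(0.5))
    return params, x1, log_evidence
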