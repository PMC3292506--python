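"""Bayesian mixture model for marker effects with a polygenic term.

Each marker effect comes from a two-component normal mixture: with prior
probability π a small-variance component, otherwise a large-variance
component (variance ratio configurable) — most markers contribute little
while a few may carry moderate or large effects. A polygenic breeding
value with covariance proportional to the sire-pedigree relationship
matrix absorbs genetic variance the markers miss. Variance components
are treated as known inputs (they come from the trait specification);
the Gibbs sampler draws the intercept, per-marker mixture indicators and
effects, and the polygenic vector.

The marker sweep is the hot loop (markers × iterations single-site
updates with weighted residuals) and is JIT-compiled with numba; the
polygenic block is sampled jointly per iteration from its multivariate
normal full conditional using one Cholesky factorization, which is valid
because the variances — hence the conditional precision matrix — are
fixed across iterations.
"""

from __future__ import annotations

import logging

import numpy as np
import scipy.linalg
from numba import njit

from .datamodel import FitResult, GenotypeMatrix, ModelConfig
from .pedigree import sire_relationship_inverse

logger = logging.getLogger("gpcombine")

__all__ = ["fit_bayes_mixture"]


@njit(cache=True)
def _marker_sweep(X, Xw, xtwx, e, a, comp, sigma_e2, v_small, v_large,
                  log_pi_small, log_pi_large, unif, norm):
    """One Gibbs pass over all markers, updating residuals in place.

    For marker j the component indicator is drawn from its marginal
    posterior (effect integrated out), then the effect from its normal
    full conditional. ``e`` is the current residual y − μ − Xa − u.
    """
    m = X.shape[1]
    for j in range(m):
        old = a[j]
        # right-hand side with marker j removed from the residual
        rhs = 0.0
        for i in range(X.shape[0]):
            rhs += Xw[i, j] * (e[i] + X[i, j] * old)
        rhs /= sigma_e2
        prec_s = xtwx[j] / sigma_e2 + 1.0 / v_small
        prec_l = xtwx[j] / sigma_e2 + 1.0 / v_large
        log_ms = log_pi_small - 0.5 * np.log(v_small * prec_s) + 0.5 * rhs * rhs / prec_s
        log_ml = log_pi_large - 0.5 * np.log(v_large * prec_l) + 0.5 * rhs * rhs / prec_l
        p_large = 1.0 / (1.0 + np.exp(log_ms - log_ml))
        if unif[j] < p_large:
            comp[j] = 1
            prec = prec_l
        else:
            comp[j] = 0
            prec = prec_s
        new = rhs / prec + norm[j] / np.sqrt(prec)
        a[j] = new
        diff = old - new
        for i in range(X.shape[0]):
            e[i] += X[i, j] * diff
    return


def fit_bayes_mixture(
    genotypes: GenotypeMatrix,
    ref_ids,
    drp,
    weights,
    pedigree,
    sigma_g2: float,
    config: ModelConfig,
    seed: int | None = None,
    groups=None,
) -> FitResult:
    """Gibbs sampler for the mixture model; returns posterior-mean DGV.

    ``pedigree`` maps bull_id → sire_id (or None) for every genotyped
    bull; the polygenic vector spans all genotyped bulls so candidates
    outside the reference receive a pedigree-propagated polygenic part in
    their DGV. ``groups`` (e.g. population labels) give each group its
    own fixed mean, as in the linear models. Posterior means average
    post-burn-in retained samples only. Identical seeds give identical
    chains.
    """
    if config.kind != "bayes_mixture":
        raise ValueError("config.kind must be 'bayes_mixture'")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    y = np.asarray(drp, dtype=float)
    w = np.asarray(weights, dtype=float)
    ref_rows = genotypes.rows(ref_ids)
    X = genotypes.centered(ref_ids)
    n, m = X.shape
    if not (y.shape[0] == w.shape[0] == n):
        raise ValueError("drp, weights and reference genotypes must align")

    sigma_e2 = sigma_g2
    denom = float(np.sum(2.0 * genotypes.allele_freq * (1.0 - genotypes.allele_freq)))
    # mixture prior calibrated so total marker variance is the configured share
    mix_mean = config.pi + (1.0 - config.pi) * config.variance_ratio
    v_small = config.marker_variance_fraction * sigma_g2 / (denom * mix_mean)
    v_large = config.variance_ratio * v_small
    log_pi_small = np.log(config.pi) if config.pi > 0 else -np.inf
    log_pi_large = np.log(1.0 - config.pi)

    use_poly = config.polygenic_fraction > 0.0
    n_all = genotypes.n_bulls
    if use_poly:
        sigma_u2 = config.polygenic_fraction * sigma_g2
        sires = [pedigree[b] for b in genotypes.bull_ids]
        Ainv = sire_relationship_inverse(genotypes.bull_ids, sires)
        C = Ainv / sigma_u2
        C[ref_rows, ref_rows] += w / sigma_e2
        chol = scipy.linalg.cho_factor(C, lower=True)
        L = np.tril(chol[0])
    u = np.zeros(n_all)

    # Fortran order: the sweep walks markers, so columns must be contiguous
    X = np.asfortranarray(X)
    Xw = np.asfortranarray(X * w[:, None])
    xtwx = np.einsum("ij,ij->j", X, Xw)
    a = np.zeros(m)
    comp = np.zeros(m, dtype=np.int8)

    # fixed means: one per group (single overall mean without groups)
    if groups is None:
        gi = np.zeros(n, dtype=int)
        n_groups = 1
    else:
        labels = np.asarray(groups, dtype=object)
        levels = sorted(set(labels))
        gi = np.array([levels.index(x) for x in labels])
        n_groups = len(levels)
    sw_g = np.bincount(gi, weights=w, minlength=n_groups)
    if (sw_g <= 0).any():
        raise ValueError("every group needs positive total weight")
    mu = np.zeros(n_groups)
    for k in range(n_groups):
        mu[k] = np.average(y[gi == k], weights=w[gi == k])
    e = y - mu[gi] - u[ref_rows]

    sum_a = np.zeros(m)
    sum_u = np.zeros(n_all)
    sum_mu = np.zeros(n_groups)
    incl = np.zeros(m)
    kept = 0

    for it in range(config.chain_length):
        # fixed group means
        e += mu[gi]
        wy = np.bincount(gi, weights=w * e, minlength=n_groups)
        mu = wy / sw_g + rng.standard_normal(n_groups) * np.sqrt(sigma_e2 / sw_g)
        e -= mu[gi]
        # markers
        _marker_sweep(
            X, Xw, xtwx, e, a, comp, sigma_e2, v_small, v_large,
            log_pi_small, log_pi_large, rng.random(m), rng.standard_normal(m),
        )
        # polygenic block, one joint draw from the full conditional
        if use_poly:
            e += u[ref_rows]
            rhs = np.bincount(ref_rows, weights=w * e / sigma_e2, minlength=n_all)
            mean = scipy.linalg.cho_solve(chol, rhs, check_finite=False)
            z = rng.standard_normal(n_all)
            u = mean + scipy.linalg.solve_triangular(
                L, z, lower=True, trans="T", check_finite=False
            )
            e -= u[ref_rows]
        if not np.isfinite(e).all():
            raise FloatingPointError(f"non-finite residual at iteration {it}")
        if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
            sum_a += a
            sum_u += u
            sum_mu += mu
            incl += comp
            kept += 1

    a_mean = sum_a / kept
    u_mean = sum_u / kept
    dgv = genotypes.centered() @ a_mean + (u_mean if use_poly else 0.0)
    return FitResult(
        bull_ids=genotypes.bull_ids.copy(),
        dgv=dgv,
        intercept=float(sum_mu[0] / kept),
        marker_effects=a_mean,
        polygenic_effects=u_mean if use_poly else None,
        kind="bayes_mixture",
        meta={
            "kept_samples": kept,
            "inclusion_large": incl / kept,
            "v_small": v_small,
            "v_large": v_large,
        },
    )
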