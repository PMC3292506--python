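"""Genomic prediction engines.

Three model families cover the evaluation systems being emulated:

* weighted SNP-BLUP — a mixed linear model with random regression on
  centered SNP dosages, equal prior variance across markers, and
  per-bull residual weights w = r²/(1 − r²);
* GBLUP — the mathematically equivalent animal-model reformulation via
  the genomic relationship matrix, used here mainly as an independent
  oracle for the SNP-BLUP solution and for relationship projection;
* a Bayesian mixture model (see :mod:`gpcombine.bayes`) with a
  polygenic term, for systems that let a few markers carry large
  effects.

All solvers are exact direct factorizations: at desk scale (a few
thousand bulls, a few thousand markers) iterative solving buys nothing
and direct solves are easier to test.
"""

from __future__ import annotations

import logging

import numpy as np
import scipy.linalg

from .datamodel import FitResult, GenotypeMatrix, ModelConfig

logger = logging.getLogger("gpcombine")

__all__ = [
    "compute_weights",
    "standardize_weights",
    "marker_prior_variance",
    "fit_snp_blup",
    "build_grm",
    "fit_gblup",
    "blend_gebv",
]


def compute_weights(rel_drp) -> np.ndarray:
    """Residual weights w = r²/(1 − r²) from DRP reliabilities.

    A reliability of 1 would mean an infinite weight (a proof with no
    residual) and is rejected; zero reliability gives weight 0 with a
    warning, since such a record carries no information.
    """
    r2 = np.asarray(rel_drp, dtype=float)
    if ((r2 < 0) | (r2 > 1)).any():
        raise ValueError("reliabilities must lie in [0, 1]")
    if (r2 == 1.0).any():
        raise ValueError("reliability of 1 implies an infinite weight")
    if (r2 == 0.0).any():
        logger.warning("%d record(s) with zero reliability get weight 0", int((r2 == 0).sum()))
    return r2 / (1.0 - r2)


def standardize_weights(weights) -> np.ndarray:
    """Rescale weights so their arithmetic mean is exactly 1."""
    w = np.asarray(weights, dtype=float)
    if (w < 0).any():
        raise ValueError("weights must be nonnegative")
    mean = w.mean()
    if mean <= 0:
        raise ValueError("weights sum to zero; nothing to standardize")
    return w / mean


def marker_prior_variance(sigma_g2: float, fraction: float, allele_freq: np.ndarray) -> float:
    """Equal-variance marker prior: σ²_a = f·σ_g² / Σ_j 2 p_j(1 − p_j)."""
    if sigma_g2 <= 0:
        raise ValueError("genetic variance must be positive")
    if not (0.0 < fraction <= 1.0):
        raise ValueError("marker variance fraction must lie in (0, 1]")
    denom = float(np.sum(2.0 * allele_freq * (1.0 - allele_freq)))
    if denom <= 0:
        raise ValueError("no polymorphic markers")
    return fraction * sigma_g2 / denom


def group_design(groups, n: int) -> tuple[np.ndarray, list]:
    """Fixed-effect design: one intercept column per group.

    ``groups=None`` gives the usual single overall mean. Combined
    multi-population references pass population labels so each
    population gets its own mean — otherwise drift-induced level
    differences between populations leak into the marker effects.
    """
    if groups is None:
        return np.ones((n, 1)), ["mu"]
    groups = np.asarray(groups, dtype=object)
    if groups.shape[0] != n:
        raise ValueError("groups must align with the reference records")
    levels = sorted(set(groups))
    F = np.zeros((n, len(levels)))
    for k, lev in enumerate(levels):
        F[groups == lev, k] = 1.0
    return F, levels


def fit_snp_blup(
    genotypes: GenotypeMatrix,
    ref_ids,
    drp,
    weights,
    sigma_g2: float,
    config: ModelConfig | None = None,
    groups=None,
) -> FitResult:
    """Weighted SNP-BLUP via a direct solve of the mixed-model equations.

    Model: y_i = μ_{g(i)} + Σ_j x_ij a_j + e_i with x centered at 2p,
    prior a_j ~ N(0, σ²_a) equal across markers, residual variance
    σ_g²/w_i, and one fixed mean per group (a single overall mean when
    ``groups`` is None). The shrinkage λ_s = σ_e²/σ²_a is strictly
    positive, so the system is never singular. DGV are returned for
    every genotyped bull and contain the marker part only.
    """
    config = config or ModelConfig(kind="snp_blup")
    y = np.asarray(drp, dtype=float)
    w = np.asarray(weights, dtype=float)
    X = genotypes.centered(ref_ids)
    n, m = X.shape
    if not (y.shape[0] == w.shape[0] == n):
        raise ValueError("drp, weights and reference genotypes must align")
    sigma_a2 = marker_prior_variance(sigma_g2, config.marker_variance_fraction, genotypes.allele_freq)
    sigma_e2 = sigma_g2
    lam = sigma_e2 / sigma_a2
    if lam <= 0:
        raise ValueError("shrinkage must be positive")

    F, levels = group_design(groups, n)
    g = F.shape[1]
    Xw = X * w[:, None]
    Fw = F * w[:, None]
    lhs = np.empty((g + m, g + m))
    lhs[:g, :g] = F.T @ Fw
    lhs[:g, g:] = Fw.T @ X
    lhs[g:, :g] = lhs[:g, g:].T
    lhs[g:, g:] = X.T @ Xw
    lhs[g:, g:][np.diag_indices(m)] += lam
    rhs = np.concatenate((Fw.T @ y, Xw.T @ y))
    sol = scipy.linalg.solve(lhs, rhs, assume_a="pos")
    mu, a = sol[:g], sol[g:]
    dgv = genotypes.centered() @ a
    return FitResult(
        bull_ids=genotypes.bull_ids.copy(),
        dgv=dgv,
        intercept=float(mu[0]),
        marker_effects=a,
        kind="snp_blup",
        meta={"lambda": lam, "sigma_a2": sigma_a2,
              "group_means": dict(zip(map(str, levels), mu))},
    )


def build_grm(genotypes: GenotypeMatrix) -> np.ndarray:
    """Genomic relationship matrix G = MM' / 2Σ p_j(1 − p_j), M = dosages − 2p."""
    p = genotypes.allele_freq
    if ((p <= 0) | (p >= 1)).any():
        raise ValueError("monomorphic markers must be dropped before building G")
    M = genotypes.centered()
    denom = float(np.sum(2.0 * p * (1.0 - p)))
    return (M @ M.T) / denom


def fit_gblup(
    grm: np.ndarray,
    genotypes: GenotypeMatrix,
    ref_ids,
    drp,
    weights,
    sigma_g2: float,
    config: ModelConfig | None = None,
    groups=None,
) -> FitResult:
    """Weighted GBLUP on the animal scale, equivalent to SNP-BLUP.

    Var(g) = G·f·σ_g² with the same residual weights as the paired
    SNP-BLUP. The mixed-model equations are solved on the transformed
    scale g = G_ref,ref α (left-multiplying the animal block by G), which
    avoids inverting G: [F'WF, F'WG; GWF, GWG + λ_g G][β; α] = [F'Wy; GWy].
    DGV for every genotyped bull follow as G_all,ref α (the genomic
    relationship projection). A singular transformed system gets a
    configurable ridge on the reference GRM diagonal (logged).
    """
    config = config or ModelConfig(kind="gblup")
    y = np.asarray(drp, dtype=float)
    w = np.asarray(weights, dtype=float)
    ref_rows = genotypes.rows(ref_ids)
    n = ref_rows.shape[0]
    if not (y.shape[0] == w.shape[0] == n):
        raise ValueError("drp, weights and reference ids must align")
    sigma_gm2 = config.marker_variance_fraction * sigma_g2
    sigma_e2 = sigma_g2
    lam_g = sigma_e2 / sigma_gm2
    G_rr = grm[np.ix_(ref_rows, ref_rows)]

    F, levels = group_design(groups, n)
    g = F.shape[1]
    Fw = F * w[:, None]
    GW = G_rr * w[None, :]

    def assemble(G_block):
        lhs = np.empty((g + n, g + n))
        lhs[:g, :g] = F.T @ Fw
        lhs[:g, g:] = Fw.T @ G_block
        lhs[g:, :g] = lhs[:g, g:].T
        lhs[g:, g:] = GW @ G_block + lam_g * G_block
        rhs = np.concatenate((Fw.T @ y, G_block @ (w * y)))
        return lhs, rhs

    # when n_ref exceeds the marker count G is rank-deficient and the
    # transformed system is singular but consistent: any solution gives
    # the same g = Gα, so the conditioning warning is expected noise
    import warnings

    lhs, rhs = assemble(G_rr)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", scipy.linalg.LinAlgWarning)
            sol = scipy.linalg.solve(lhs, rhs, assume_a="sym")
    except np.linalg.LinAlgError:
        logger.info("singular reference GRM; adding ridge %.1e", config.ridge)
        lhs, rhs = assemble(G_rr + config.ridge * np.eye(n))
        sol = scipy.linalg.solve(lhs, rhs, assume_a="sym")
    mu, alpha = sol[:g], sol[g:]
    dgv = grm[:, ref_rows] @ alpha
    return FitResult(
        bull_ids=genotypes.bull_ids.copy(),
        dgv=dgv,
        intercept=float(mu[0]),
        kind="gblup",
        meta={"lambda_g": lam_g,
              "group_means": dict(zip(map(str, levels), mu))},
    )


def blend_gebv(dgv, pi, rel_dgv: float, rel_pi: float, cov: float | None = None):
    """Blend a genomic prediction with a pedigree index by selection index.

    The two sources are combined with weights solving the 2×2 index
    equations P b = g, where (in genetic-variance units) P holds the
    source variances (their reliabilities) and their covariance, and g
    the covariances with the true breeding value (again the
    reliabilities). The default covariance is min(rel_dgv, rel_pi) — the
    pedigree information is assumed fully contained in the genomic
    prediction when the latter is stronger, which reduces the blend to
    DGV alone in that case, and to PI alone when rel_dgv = 0.

    Returns ``(gebv, blended_reliability)``.
    """
    for name, v in (("rel_dgv", rel_dgv), ("rel_pi", rel_pi)):
        if not (0.0 <= v < 1.0):
            raise ValueError(f"{name} must lie in [0, 1), got {v}")
    dgv = np.asarray(dgv, dtype=float)
    pi = np.asarray(pi, dtype=float)
    if rel_dgv == 0.0 and rel_pi == 0.0:
        logger.warning("both information sources have zero reliability; GEBV = 0")
        return np.zeros_like(dgv), 0.0
    if cov is None:
        cov = min(rel_dgv, rel_pi)
    P = np.array([[rel_dgv, cov], [cov, rel_pi]])
    g = np.array([rel_dgv, rel_pi])
    b = np.linalg.pinv(P) @ g
    gebv = b[0] * dgv + b[1] * pi
    rel = float(b @ g)
    return gebv, rel
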