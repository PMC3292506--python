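"""Reference/validation construction and cross-validation statistics.

The design mirrors progeny-test validation of genomic predictions: bulls
born before a cut-off year with an effective daughter contribution of at
least 20 form the reference; the youngest bulls whose sires are in the
reference form the validation set. Reliability of a prediction is
measured as the squared weighted correlation with the DRP divided by the
weighted mean DRP reliability, and unbiasedness as the weighted
regression of DRP on the prediction (slope 1, intercept 0 when
unbiased).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .datamodel import ReferenceSet, SplitSpec
from .gp_models import standardize_weights
from .simpop import SimulatedStudy, _cutoff_year

logger = logging.getLogger("gpcombine")

__all__ = [
    "make_eval_frame",
    "choose_cutoff_years",
    "build_reference",
    "build_validation",
    "parent_average_pi",
    "weighted_corr_reliability",
    "weighted_bias_regression",
    "genomic_gain",
]


def make_eval_frame(study: SimulatedStudy, trait_name: str, target_population: str) -> pd.DataFrame:
    """Per-bull evaluation view for one trait on one country scale.

    Columns: bull_id, population, birth_year, sire_id, drp, edc, rel —
    DRP and reliability as evaluated on the target population's scale
    (foreign bulls carry the rg²-discounted reliability).
    """
    trait = next(t for t in study.config.traits if t.name == trait_name)
    j = trait.pop_index(target_population)
    frame = study.bulls[["bull_id", "population", "birth_year", "sire_id"]].copy()
    frame["drp"] = study.drp[trait_name][:, j]
    frame["edc"] = study.edc[trait_name]
    frame["rel"] = study.rel[trait_name][:, j]
    return frame


def choose_cutoff_years(bulls: pd.DataFrame, fraction: float = 0.25) -> dict:
    """Per-population cut-off birth year leaving ~fraction in validation."""
    return {
        pop: _cutoff_year(grp["birth_year"].to_numpy(), fraction)
        for pop, grp in bulls.groupby("population")
    }


def build_reference(
    frame: pd.DataFrame,
    split: SplitSpec,
    scope: str,
    target_population: str,
    trait_name: str = "",
) -> ReferenceSet:
    """Reference bulls: born before the cut-off, EDC ≥ min_edc, usable DRP.

    National scope keeps domestic bulls only; combined scope pools every
    population. Provenance (domestic/foreign) is flagged per member.
    """
    if scope not in ("national", "combined"):
        raise ValueError("scope must be 'national' or 'combined'")
    cutoffs = frame["population"].map(split.cutoff_year)
    keep = (
        (frame["birth_year"] < cutoffs)
        & (frame["edc"] >= split.min_edc)
        & frame["drp"].notna()
    )
    if scope == "national":
        keep &= frame["population"] == target_population
    sub = frame[keep]
    if len(sub) == 0:
        raise ValueError(
            f"empty reference for {target_population} (scope={scope}, "
            f"min_edc={split.min_edc})"
        )
    return ReferenceSet(
        bull_ids=sub["bull_id"].to_numpy(),
        target_population=target_population,
        trait=trait_name,
        domestic=(sub["population"] == target_population).to_numpy(),
    )


def build_validation(
    frame: pd.DataFrame,
    split: SplitSpec,
    reference: ReferenceSet,
    target_population: str,
) -> pd.DataFrame:
    """Validation bulls: post-cut-off domestic bulls with sires in scope.

    The sire scope is 'national' (sire among the domestic reference
    members — the comparability rule) or 'combined' (sire anywhere in
    the reference — the enlarged-validation exception used where the
    national rule leaves too few bulls). Always disjoint from the
    reference.
    """
    if split.sire_scope == "national":
        sire_pool = set(reference.bull_ids[reference.domestic])
    else:
        sire_pool = set(reference.bull_ids)
    ref_members = set(reference.bull_ids)
    cutoff = split.cutoff_year[target_population]
    keep = (
        (frame["population"] == target_population)
        & (frame["birth_year"] >= cutoff)
        & frame["sire_id"].isin(sire_pool)
        & ~frame["bull_id"].isin(ref_members)
        & frame["drp"].notna()
    )
    sub = frame[keep]
    if len(sub) == 0:
        raise ValueError(
            f"empty validation set for {target_population}: filters were "
            f"birth_year ≥ {cutoff}, sire scope {split.sire_scope!r}, "
            "DRP present"
        )
    return sub.reset_index(drop=True)


def parent_average_pi(validation: pd.DataFrame, reference: pd.DataFrame):
    """Pedigree index of each validation bull from his sire's reference data.

    The sire's estimate is his shrunken proof û = r²·DRP (reliability
    r²); with dams unknown, PI = û/2 and rel_PI = r²_sire/4. Bulls whose
    sire has no reference estimate get NaN and are dropped from PI-based
    statistics by the caller (with a warning here).
    """
    sire_est = {
        row.bull_id: (row.rel * row.drp, row.rel)
        for row in reference.itertuples()
    }
    pi = np.full(len(validation), np.nan)
    rel_pi = np.full(len(validation), np.nan)
    for i, sire in enumerate(validation["sire_id"]):
        est = sire_est.get(sire)
        if est is not None:
            pi[i] = 0.5 * est[0]
            rel_pi[i] = 0.25 * est[1]
    n_miss = int(np.isnan(pi).sum())
    if n_miss:
        logger.warning("%d validation bull(s) lack a sire estimate; PI undefined", n_miss)
    return pi, rel_pi


def _weighted_moments(x, y, w):
    mx = np.average(x, weights=w)
    my = np.average(y, weights=w)
    cov = np.average((x - mx) * (y - my), weights=w)
    vx = np.average((x - mx) ** 2, weights=w)
    vy = np.average((y - my) ** 2, weights=w)
    return cov, vx, vy


def weighted_corr_reliability(gbv, drp, weights, rel_drp) -> float:
    """Validation reliability: squared weighted correlation of the
    prediction with DRP, divided by the weighted mean DRP reliability.

    The ratio corrects the attenuation caused by DRP being themselves
    noisy measurements of the true breeding value; it is a ratio of noisy
    quantities and may slightly exceed 1, which is reported, not clipped.
    """
    gbv = np.asarray(gbv, dtype=float)
    drp = np.asarray(drp, dtype=float)
    rel = np.asarray(rel_drp, dtype=float)
    if gbv.shape[0] < 3:
        raise ValueError("need at least 3 validation bulls")
    w = standardize_weights(weights)
    cov, vx, vy = _weighted_moments(gbv, drp, w)
    if vx <= 0 or vy <= 0:
        raise ValueError("zero variance in prediction or DRP; reliability undefined")
    corr2 = cov**2 / (vx * vy)
    mean_rel = np.average(rel, weights=w)
    if mean_rel <= 0:
        raise ValueError("weighted mean DRP reliability is zero")
    out = corr2 / mean_rel
    if out > 1.0:
        logger.info("estimated reliability %.3f exceeds 1 (noisy ratio)", out)
    return float(out)


def weighted_bias_regression(drp, gbv, weights, sigma_g: float):
    """Weighted least squares of DRP on the prediction.

    Returns ``(b0, b0/σ_g, b1)``; (0, ·, 1) signals unbiased predictions.
    """
    gbv = np.asarray(gbv, dtype=float)
    drp = np.asarray(drp, dtype=float)
    if np.var(gbv) == 0:
        raise ValueError("degenerate regressor: prediction has zero variance")
    w = standardize_weights(weights)
    res = sm.WLS(drp, sm.add_constant(gbv), weights=w).fit()
    b0, b1 = float(res.params[0]), float(res.params[1])
    return b0, b0 / float(sigma_g), b1


def genomic_gain(rel_gbv: float, rel_pi: float) -> float:
    """Gain attributed to genomic information: REL_GBV − REL_PI.

    May be negative on noisy validation sets; reported as-is.
    """
    return float(rel_gbv) - float(rel_pi)
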