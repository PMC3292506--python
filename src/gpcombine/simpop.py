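"""Synthetic multi-country bull populations.

The generator emulates the statistical structure of a set of closely
related Holstein reference populations: a few thousand progeny-tested
bulls per country, sires recorded within the population, deregressed
proofs (DRP) whose reliability follows the effective daughter
contribution (EDC), and true breeding values whose between-country
correlation is imposed at the QTL-effect level. It is not a
coalescent-accurate cattle genome: allele-frequency divergence between
populations is a single Fst-like parameter, recombination follows a
uniform Haldane map, and dams are unobserved (a maternal gamete is drawn
from the population allele frequencies).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import GenotypeMatrix, TraitSpec

logger = logging.getLogger("gpcombine")

__all__ = [
    "PopulationConfig",
    "SimConfig",
    "SimulatedStudy",
    "simulate_genomes",
    "sample_qtl_effects",
    "true_breeding_values",
    "simulate_drp",
    "sample_edc",
    "assign_validation_candidates",
    "simulate_study",
]


@dataclass
class PopulationConfig:
    """One country's bull cohort: sizes, birth-year layout, EDC scale."""

    name: str
    n_reference: int = 500
    n_validation: int = 125
    year_range: tuple = (1990, 2005)
    edc_mean: float = 117.0  # mean daughters per bull; country-specific
    edc_log_sd: float = 1.0  # long right tail: some bulls have >1000 daughters

    def __post_init__(self) -> None:
        if self.n_reference <= 0 or self.n_validation <= 0:
            raise ValueError("population sizes must be positive")
        if self.year_range[1] <= self.year_range[0]:
            raise ValueError("year_range must span at least two years")
        if self.edc_mean <= 0 or self.edc_log_sd <= 0:
            raise ValueError("EDC distribution parameters must be positive")

    @property
    def n_total(self) -> int:
        return self.n_reference + self.n_validation


@dataclass
class SimConfig:
    """Full simulation design: populations, genome, traits, selection."""

    populations: list
    traits: list
    m_markers: int = 2000
    n_qtl: int = 200
    n_chromosomes: int = 10
    chrom_length_morgans: float = 1.0
    fst: float = 0.02  # closely related populations
    sire_age_gap: int = 4
    select_on_pi: bool = False
    validation_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.populations:
            raise ValueError("at least one population is required")
        if self.n_qtl > self.m_markers:
            raise ValueError("n_qtl cannot exceed m_markers")
        if self.m_markers <= 0 or self.n_chromosomes <= 0:
            raise ValueError("genome sizes must be positive")
        if self.chrom_length_morgans < 0:
            raise ValueError("map length cannot be negative")
        if not (0.0 <= self.fst < 1.0):
            raise ValueError("fst must lie in [0, 1)")
        if not (0.0 < self.validation_fraction < 1.0):
            raise ValueError("validation_fraction must lie in (0, 1)")
        names = [p.name for p in self.populations]
        if len(set(names)) != len(names):
            raise ValueError("population names must be unique")

    @property
    def population_names(self) -> list:
        return [p.name for p in self.populations]


@dataclass
class SimulatedStudy:
    """Everything downstream stages need, truth kept separate from data.

    ``u[trait]`` is n_bulls × C true breeding values (one column per
    country scale); ``drp``/``rel`` have the same layout: column c is the
    bull's proof as evaluated on country c's scale (foreign proofs carry
    the rg²-discounted reliability, emulating across-country conversion).
    """

    config: SimConfig
    genotypes: GenotypeMatrix
    bulls: pd.DataFrame  # bull_id, population, birth_year, sire_id
    u: dict = field(default_factory=dict)
    drp: dict = field(default_factory=dict)
    rel: dict = field(default_factory=dict)
    edc: dict = field(default_factory=dict)
    qtl_indices: np.ndarray | None = None
    qtl_effects: dict = field(default_factory=dict)
    validation_candidate: np.ndarray | None = None

    @property
    def trait_names(self) -> list:
        return [t.name for t in self.config.traits]


def _meiosis(haps: np.ndarray, positions: np.ndarray, chrom: np.ndarray,
             chrom_length: float, rng: np.random.Generator) -> np.ndarray:
    """One gamete from a pair of haplotypes, Haldane crossovers."""
    m = haps.shape[1]
    phase = np.empty(m, dtype=np.int8)
    for c in np.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        start = rng.integers(0, 2)
        if chrom_length > 0:
            n_xo = rng.poisson(chrom_length)
        else:
            n_xo = 0
        if n_xo == 0:
            phase[idx] = start
        else:
            xo = np.sort(rng.uniform(0.0, chrom_length, size=n_xo))
            crossings = np.searchsorted(xo, positions[idx])
            phase[idx] = (start + crossings) % 2
    return haps[phase, np.arange(m)]


def simulate_genomes(config: SimConfig, rng: np.random.Generator):
    """Genomes plus pedigree for every population.

    Founder haplotypes are drawn from population allele frequencies that
    diverge from a shared ancestral frequency by a Balding–Nichols
    Fst-like model; each later bull receives a recombined paternal gamete
    from a recorded sire at least ``sire_age_gap`` years older and a
    maternal gamete drawn from the population frequencies (dams unknown).

    Returns ``(dosages, marker_positions, pedigree)`` with dosages kept
    raw (monomorphic markers are filtered by the caller).
    """
    m = config.m_markers
    per_chrom = np.array_split(np.arange(m), config.n_chromosomes)
    chrom = np.empty(m, dtype=int)
    positions = np.empty(m, dtype=float)
    for c, idx in enumerate(per_chrom):
        chrom[idx] = c
        if len(idx):
            positions[idx] = np.linspace(
                0.0, config.chrom_length_morgans, len(idx), endpoint=False
            )

    p0 = rng.uniform(0.05, 0.95, size=m)
    pop_freq = {}
    for pop in config.populations:
        if config.fst > 0:
            a = p0 * (1.0 - config.fst) / config.fst
            b = (1.0 - p0) * (1.0 - config.fst) / config.fst
            pop_freq[pop.name] = np.clip(rng.beta(a, b), 1e-4, 1.0 - 1e-4)
        else:
            pop_freq[pop.name] = p0

    rows, dosage_rows = [], []
    for pop in config.populations:
        n = pop.n_total
        y0, y1 = pop.year_range
        years = np.sort(np.resize(np.arange(y0, y1 + 1), n))
        freq = pop_freq[pop.name]
        haps = np.empty((n, 2, m), dtype=np.int8)
        ids = [f"{pop.name}_{i:05d}" for i in range(n)]
        sires: list = []
        for i in range(n):
            eligible = np.flatnonzero(years[: i] <= years[i] - config.sire_age_gap)
            if eligible.size == 0:
                # founder: both gametes from the population gene pool
                haps[i] = rng.random((2, m)) < freq
                sires.append(None)
            else:
                s = int(rng.choice(eligible))
                haps[i, 0] = _meiosis(
                    haps[s], positions, chrom, config.chrom_length_morgans, rng
                )
                haps[i, 1] = rng.random(m) < freq
                sires.append(ids[s])
        dosage_rows.append(haps.sum(axis=1))
        rows.append(
            pd.DataFrame(
                {
                    "bull_id": ids,
                    "population": pop.name,
                    "birth_year": years,
                    "sire_id": sires,
                }
            )
        )
    pedigree = pd.concat(rows, ignore_index=True)
    dosages = np.vstack(dosage_rows)
    return dosages, positions, pedigree


def sample_qtl_effects(trait: TraitSpec, n_qtl: int, rng: np.random.Generator) -> np.ndarray:
    """Per-QTL effect vectors across countries, correlation imposed by rg.

    Each QTL's C-vector is zero-mean multivariate normal with correlation
    matrix rg, so the realized between-country correlation of true
    breeding values converges to rg as the number of QTL grows.
    """
    w, v = np.linalg.eigh(trait.rg)
    if w.min() < -1e-8:
        raise ValueError(
            f"rg for trait {trait.name!r} is not PSD (eigenvalue {w.min():.3g})"
        )
    root = v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    z = rng.standard_normal((n_qtl, len(trait.populations)))
    return z @ root.T


def true_breeding_values(
    geno: GenotypeMatrix, qtl_indices: np.ndarray, effects: np.ndarray, trait: TraitSpec
):
    """True breeding values per bull × country, scaled to σ_g per country.

    u_·c is the centered QTL dosage combination; after scaling, the
    empirical SD of u on every country scale equals that country's σ_g
    (scaling per country leaves between-country correlations intact).

    Returns ``(u, scaled_effects)``.
    """
    z = geno.centered()[:, qtl_indices]
    u = z @ effects
    sd = u.std(axis=0, ddof=0)
    if (sd == 0).any():
        raise ValueError("degenerate true-breeding-value variance; too few QTL?")
    scale = trait.sigma_g / sd
    return u * scale, effects * scale


def sample_edc(pop: PopulationConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    """Effective daughter contributions: log-normal with the configured
    mean, long right tail (a few bulls with very many daughters)."""
    mu = np.log(pop.edc_mean) - 0.5 * pop.edc_log_sd**2
    return rng.lognormal(mu, pop.edc_log_sd, size=n)


def simulate_drp(
    u: np.ndarray,
    edc: np.ndarray,
    trait: TraitSpec,
    target_population: str,
    bull_populations: np.ndarray,
    rng: np.random.Generator,
):
    """DRP and reliability for every bull on one country scale.

    Reliability on the bull's own scale is r² = EDC/(EDC + λ) with
    λ = (4 − h²)/h². The proof is the bull's own-scale true value plus
    progeny-test noise with variance σ_g²(1 − r²)/r², converted to the
    target scale's units. A foreign bull's effective reliability on the
    target scale is rg² · r², which is exactly the squared correlation of
    his converted proof with the target-scale true value — the mechanism
    behind combined reference data carrying less information per record
    than national data whenever rg < 1.

    Bulls with EDC = 0 get rel 0 and an undefined (NaN) DRP; callers
    exclude them.
    """
    edc = np.asarray(edc, dtype=float)
    if (edc < 0).any():
        raise ValueError("EDC must be nonnegative")
    lam = trait.lambda_drp
    rel_own = edc / (edc + lam)
    tgt = trait.pop_index(target_population)
    own = np.array([trait.pop_index(p) for p in bull_populations])
    rel_target = trait.rg[own, tgt] ** 2 * rel_own

    drp = np.full(u.shape[0], np.nan)
    ok = rel_own > 0
    if (~ok).any():
        logger.warning("%d bull(s) with EDC=0 have undefined DRP", int((~ok).sum()))
    sd_noise = np.zeros_like(rel_own)
    sd_noise[ok] = trait.sigma_g[own[ok]] * np.sqrt((1.0 - rel_own[ok]) / rel_own[ok])
    noise = rng.standard_normal(u.shape[0]) * sd_noise
    unit = trait.sigma_g[tgt] / trait.sigma_g[own]
    drp[ok] = (u[np.arange(u.shape[0]), own][ok] + noise[ok]) * unit[ok]
    return drp, rel_target


def assign_validation_candidates(
    bulls: pd.DataFrame,
    fraction: float = 0.25,
    selected: bool = False,
    pi: np.ndarray | None = None,
) -> np.ndarray:
    """Label the youngest ~fraction per population as validation candidates.

    The cut-off year is the smallest year placing at least the target
    fraction in validation; ties at the boundary all go to validation.
    With ``selected``, candidates are instead the top half by pedigree
    index among the youngest 2×fraction — emulating the practice of
    genotyping only bulls pre-selected on parent average.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must lie in (0, 1)")
    if selected and pi is None:
        raise ValueError("selection on PI requires a pi array")
    labels = np.zeros(len(bulls), dtype=bool)
    for pop, grp in bulls.groupby("population"):
        idx = grp.index.to_numpy()
        years = grp["birth_year"].to_numpy()
        f = min(2.0 * fraction, 0.9) if selected else fraction
        cutoff = _cutoff_year(years, f)
        young = idx[years >= cutoff]
        if selected:
            k = int(np.ceil(len(young) / 2.0))
            order = np.argsort(-np.asarray(pi)[young], kind="stable")
            young = young[order[:k]]
        labels[young] = True
    return labels


def _cutoff_year(years: np.ndarray, fraction: float) -> int:
    """Latest birth year whose tail still holds ≥ the target fraction.

    Bulls born in or after the cut-off year go to validation, so ties at
    the boundary all land on the validation side.
    """
    target = fraction * len(years)
    cutoff = int(years.min())
    for y in np.sort(np.unique(years)):
        if (years >= y).sum() >= target:
            cutoff = int(y)
    return cutoff


def simulate_study(config: SimConfig, seed: int | None = None) -> SimulatedStudy:
    """Run the full generator: genomes, pedigree, QTL, EDC, DRP, truth.

    Every random draw flows from one seed sequence, so identical configs
    and seeds give bit-identical studies.
    """
    ss = np.random.SeedSequence(config.seed if seed is None else seed)
    rng_geno, rng_qtl, rng_edc, rng_drp = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )
    dosages, _positions, pedigree = simulate_genomes(config, rng_geno)

    freq = dosages.mean(axis=0) / 2.0
    poly = (freq > 0.0) & (freq < 1.0)
    n_mono = int((~poly).sum())
    if n_mono:
        logger.info("dropped %d monomorphic marker(s) after simulation", n_mono)
    if poly.sum() < config.n_qtl:
        raise ValueError("fewer polymorphic markers than requested QTL")
    geno = GenotypeMatrix(
        bull_ids=pedigree["bull_id"].to_numpy(),
        dosages=dosages[:, poly],
    )

    study = SimulatedStudy(config=config, genotypes=geno, bulls=pedigree)
    study.qtl_indices = np.sort(
        rng_qtl.choice(geno.n_markers, size=config.n_qtl, replace=False)
    )
    pops = pedigree["population"].to_numpy()
    pop_cfg = {p.name: p for p in config.populations}

    for trait in config.traits:
        effects = sample_qtl_effects(trait, config.n_qtl, rng_qtl)
        u, scaled = true_breeding_values(geno, study.qtl_indices, effects, trait)
        study.u[trait.name] = u
        study.qtl_effects[trait.name] = scaled
        edc = np.empty(len(pedigree))
        for name, cfg in pop_cfg.items():
            mask = pops == name
            edc[mask] = sample_edc(cfg, int(mask.sum()), rng_edc)
        study.edc[trait.name] = edc
        n, c = len(pedigree), len(trait.populations)
        drp = np.empty((n, c))
        rel = np.empty((n, c))
        for j, target in enumerate(trait.populations):
            drp[:, j], rel[:, j] = simulate_drp(u, edc, trait, target, pops, rng_drp)
        study.drp[trait.name] = drp
        study.rel[trait.name] = rel

    pi = None
    if config.select_on_pi:
        pi = _pi_proxy(study, config.traits[0].name)
    study.validation_candidate = assign_validation_candidates(
        pedigree, config.validation_fraction, config.select_on_pi, pi
    )
    return study


def _pi_proxy(study: SimulatedStudy, trait_name: str) -> np.ndarray:
    """Parent-average proxy used only to emulate selective genotyping:
    half the sire's shrunken own-scale proof (0 for founders' sons)."""
    bulls = study.bulls
    trait = next(t for t in study.config.traits if t.name == trait_name)
    idx = {b: i for i, b in enumerate(bulls["bull_id"])}
    pops = bulls["population"].to_numpy()
    own = np.array([trait.pop_index(p) for p in pops])
    drp_own = study.drp[trait_name][np.arange(len(bulls)), own]
    lam = trait.lambda_drp
    rel_own = study.edc[trait_name] / (study.edc[trait_name] + lam)
    pi = np.zeros(len(bulls))
    for i, sire in enumerate(bulls["sire_id"]):
        if sire is not None and sire in idx:
            s = idx[sire]
            pi[i] = 0.5 * rel_own[s] * drp_own[s]
    return pi
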