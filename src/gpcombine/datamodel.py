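"""Domain types shared by every stage of the pipeline.

The vocabulary follows dairy-cattle genomic evaluation: bulls carry
deregressed proofs (DRP) with an effective daughter contribution (EDC)
and a reliability r²; genotypes are biallelic SNP dosages; traits carry a
heritability and a between-country genetic-correlation matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger("gpcombine")

__all__ = [
    "TraitObservation",
    "BullRecord",
    "GenotypeMatrix",
    "TraitSpec",
    "ReferenceSet",
    "ModelConfig",
    "SplitSpec",
    "FitResult",
    "ValidationReport",
]


@dataclass
class TraitObservation:
    """One bull's proof for one trait, on the scale of his own evaluation."""

    drp: float
    edc: float
    rel_drp: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.rel_drp <= 1.0):
            raise ValueError(f"rel_drp must lie in [0, 1], got {self.rel_drp}")
        if self.edc < 0:
            raise ValueError(f"edc must be nonnegative, got {self.edc}")


@dataclass
class BullRecord:
    """A progeny-tested bull: identity, population, pedigree link, proofs."""

    bull_id: str
    population: str
    birth_year: int
    sire_id: str | None = None
    traits: dict[str, TraitObservation] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sire_id is not None and self.sire_id == self.bull_id:
            raise ValueError(f"bull {self.bull_id} is recorded as his own sire")


class GenotypeMatrix:
    """Bulls × biallelic markers, allele-dosage coded (0/1/2).

    Dosages count copies of an arbitrary but fixed reference allele.
    Centering happens inside the models, never here, so the files stay
    human-checkable. Monomorphic markers must be dropped before
    construction: every retained marker needs 0 < p < 1.
    """

    def __init__(
        self,
        bull_ids,
        dosages: np.ndarray,
        marker_ids=None,
        allele_freq: np.ndarray | None = None,
    ) -> None:
        dosages = np.asarray(dosages)
        if dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D bulls × markers array")
        if np.isnan(dosages.astype(float)).any():
            raise ValueError("missing dosages are not allowed (imputation is out of scope)")
        if not np.isin(dosages, (0, 1, 2)).all():
            raise ValueError("dosages must be coded 0/1/2")
        self.bull_ids = np.asarray(bull_ids, dtype=object)
        if self.bull_ids.shape[0] != dosages.shape[0]:
            raise ValueError("bull_ids length must match dosage rows")
        self.dosages = dosages.astype(np.int8)
        if marker_ids is None:
            marker_ids = [f"m{j}" for j in range(dosages.shape[1])]
        self.marker_ids = np.asarray(marker_ids, dtype=object)
        if self.marker_ids.shape[0] != dosages.shape[1]:
            raise ValueError("marker_ids length must match dosage columns")
        if allele_freq is None:
            allele_freq = dosages.mean(axis=0) / 2.0
        self.allele_freq = np.asarray(allele_freq, dtype=float)
        if self.allele_freq.shape[0] != dosages.shape[1]:
            raise ValueError("allele_freq length must match dosage columns")
        if ((self.allele_freq <= 0.0) | (self.allele_freq >= 1.0)).any():
            bad = int(np.sum((self.allele_freq <= 0) | (self.allele_freq >= 1)))
            raise ValueError(
                f"{bad} marker(s) have allele frequency outside (0, 1); "
                "drop monomorphic markers before constructing a GenotypeMatrix"
            )
        self._index = {b: i for i, b in enumerate(self.bull_ids)}

    @property
    def n_bulls(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    def rows(self, bull_ids) -> np.ndarray:
        """Row indices for the given bulls, in the given order."""
        try:
            return np.array([self._index[b] for b in bull_ids], dtype=int)
        except KeyError as e:  # pragma: no cover - defensive
            raise KeyError(f"bull {e.args[0]!r} has no genotype") from None

    def centered(self, bull_ids=None) -> np.ndarray:
        """Dosages minus 2p, as float64 (the model design matrix)."""
        d = self.dosages if bull_ids is None else self.dosages[self.rows(bull_ids)]
        return d.astype(np.float64) - 2.0 * self.allele_freq


class TraitSpec:
    """Heritability, genetic SD and between-country genetic correlations.

    ``rg`` is a C × C symmetric positive-semidefinite matrix with unit
    diagonal; off-diagonals below 1 encode genotype-by-environment
    interaction and trait-definition differences between countries.
    """

    def __init__(self, name, h2, sigma_g, rg, populations) -> None:
        if not (0.0 < h2 <= 1.0):
            raise ValueError(f"h2 must lie in (0, 1], got {h2}")
        self.name = str(name)
        self.h2 = float(h2)
        self.populations = list(populations)
        c = len(self.populations)
        sigma_g = np.broadcast_to(np.asarray(sigma_g, dtype=float), (c,)).copy()
        if (sigma_g <= 0).any():
            raise ValueError("sigma_g must be positive")
        self.sigma_g = sigma_g
        rg = np.asarray(rg, dtype=float)
        if rg.shape != (c, c):
            raise ValueError(f"rg must be {c}×{c}")
        if not np.allclose(rg, rg.T, atol=1e-10):
            raise ValueError("rg must be symmetric")
        if not np.allclose(np.diag(rg), 1.0, atol=1e-10):
            raise ValueError("rg must have unit diagonal")
        w = np.linalg.eigvalsh(rg)
        if w.min() < -1e-8:
            raise ValueError(f"rg is not positive semidefinite (min eigenvalue {w.min():.3g})")
        self.rg = rg

    @property
    def lambda_drp(self) -> float:
        """EDC→reliability shrinkage constant λ = (4 − h²)/h²."""
        return (4.0 - self.h2) / self.h2

    def pop_index(self, population: str) -> int:
        return self.populations.index(population)


@dataclass
class ReferenceSet:
    """Bulls used to estimate marker effects for one target population/trait.

    ``domestic`` flags provenance; every member passed the EDC filter and
    the set is disjoint from the paired validation set by construction.
    """

    bull_ids: np.ndarray
    target_population: str
    trait: str
    domestic: np.ndarray

    def __post_init__(self) -> None:
        self.bull_ids = np.asarray(self.bull_ids, dtype=object)
        self.domestic = np.asarray(self.domestic, dtype=bool)
        if self.bull_ids.shape != self.domestic.shape:
            raise ValueError("provenance flags must align with bull_ids")

    @property
    def n(self) -> int:
        return self.bull_ids.shape[0]


@dataclass
class ModelConfig:
    """Prediction-model configuration.

    marker_variance_fraction is the share of σ_g² assigned to markers
    (the remainder, for mixture models, goes to the polygenic term).
    ``pi`` is the prior proportion of markers in the small-variance
    mixture class; ``variance_ratio`` the large:small effect-variance
    ratio. The 40%-polygenic preset mirrors evaluation systems that
    assign 40% of the genetic variance to polygenes and 60% to markers.
    """

    kind: str = "snp_blup"
    marker_variance_fraction: float = 1.0
    polygenic_fraction: float = 0.0
    pi: float = 0.95
    variance_ratio: float = 100.0
    chain_length: int = 1000
    burn_in: int = 200
    thin: int = 1
    seed: int = 0
    ridge: float = 1e-6

    def __post_init__(self) -> None:
        if self.kind not in ("snp_blup", "gblup", "bayes_mixture"):
            raise ValueError(f"unknown model kind {self.kind!r}")
        if not (0.0 < self.marker_variance_fraction <= 1.0):
            raise ValueError("marker_variance_fraction must lie in (0, 1]")
        if not (0.0 <= self.polygenic_fraction < 1.0):
            raise ValueError("polygenic_fraction must lie in [0, 1)")
        if not (0.0 <= self.pi < 1.0):
            raise ValueError("pi must lie in [0, 1)")
        if self.variance_ratio <= 0:
            raise ValueError("variance_ratio must be positive")
        if not (self.chain_length > self.burn_in >= 0):
            raise ValueError("chain length must exceed burn-in (burn-in ≥ 0)")
        if self.thin < 1:
            raise ValueError("thin must be ≥ 1")

    @classmethod
    def forty_percent_polygenic(cls, **kw) -> "ModelConfig":
        """Mixture preset with a 40% polygenic / 60% marker variance split."""
        kw.setdefault("kind", "bayes_mixture")
        kw.setdefault("polygenic_fraction", 0.40)
        kw.setdefault("marker_variance_fraction", 0.60)
        return cls(**kw)


@dataclass
class SplitSpec:
    """Reference/validation split: cut-off birth year per population,
    minimum EDC for reference membership, and the sire scope of the
    validation filter (national or combined)."""

    cutoff_year: dict
    min_edc: float = 20.0
    sire_scope: str = "national"

    def __post_init__(self) -> None:
        if self.min_edc < 0:
            raise ValueError("min_edc must be nonnegative")
        if self.sire_scope not in ("national", "combined"):
            raise ValueError("sire_scope must be 'national' or 'combined'")


@dataclass
class FitResult:
    """Output of a genomic prediction fit on one reference set.

    ``dgv`` covers every genotyped bull (reference and candidates alike);
    for models with a polygenic term it already includes that part, so it
    plays the role of a GEBV-like prediction.
    """

    bull_ids: np.ndarray
    dgv: np.ndarray
    intercept: float
    marker_effects: np.ndarray | None = None
    polygenic_effects: np.ndarray | None = None
    kind: str = "snp_blup"
    meta: dict = field(default_factory=dict)

    def dgv_for(self, bull_ids) -> np.ndarray:
        index = {b: i for i, b in enumerate(self.bull_ids)}
        return self.dgv[[index[b] for b in bull_ids]]


class ValidationReport:
    """Per trait × reference-set validation statistics.

    Columns mirror standard cross-validation summaries: reference and
    validation counts, REL_PI, REL_GBV, regression intercept (raw and in
    genetic-SD units), slope, and the genomic gain REL_GBV − REL_PI.
    """

    COLUMNS = [
        "trait",
        "reference_set",
        "n_ref",
        "n_valid",
        "rel_pi",
        "rel_gbv",
        "b0",
        "b0_sigma",
        "b1",
        "gain",
    ]

    def __init__(self) -> None:
        self.rows: list[dict] = []

    def add(self, **row) -> None:
        missing = set(self.COLUMNS) - set(row)
        if missing:
            raise ValueError(f"report row missing fields: {sorted(missing)}")
        rel_cols = [row["rel_pi"], row["rel_gbv"]]
        for v in rel_cols:
            if not (-0.01 <= v <= 1.05):
                logger.warning("reliability %.3f outside [0, 1.05]", v)
        if row["n_valid"] <= 0:
            raise ValueError("n_valid must be positive")
        self.rows.append({c: row[c] for c in self.COLUMNS})

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.rows, columns=self.COLUMNS)

    def __len__(self) -> int:
        return len(self.rows)
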