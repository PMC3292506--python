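"""Deterministic expected reliability of genomic prediction.

The engine is the information-accumulation approximation

    r² = T / (T + M_e),   T = Σ_k N_k · rg_k² · rel_k,

where each source population k contributes N_k reference bulls whose
proofs have mean reliability rel_k on the target scale, discounted by
the squared genetic correlation rg_k with the target country (1 for
domestic records), and M_e is the effective number of independently
segregating chromosome segments that limits deterministic accuracy.
At rg = 1 and a single source this reduces to the standard
single-population deterministic accuracy formula, and it exposes exactly
the factors that drive the gain from combining reference populations:
their sizes, proof reliabilities and relatedness. It is an approximation
chosen for those properties, not a transcription of any one published
derivation. M_e is never hard-coded: it is user input or calibrated from
an observed national reliability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Source",
    "ExpectedGainInputs",
    "expected_reliability",
    "calibrate_me",
    "expected_gain",
]


@dataclass
class Source:
    """One contributing reference population."""

    n: float
    rel_drp: float
    rg: float = 1.0

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("reference size must be nonnegative")
        if not (0.0 <= self.rel_drp <= 1.0):
            raise ValueError("rel_drp must lie in [0, 1]")
        if not (0.0 <= self.rg <= 1.0):
            raise ValueError("rg must lie in [0, 1]")

    @property
    def information(self) -> float:
        return self.n * self.rg**2 * self.rel_drp


@dataclass
class ExpectedGainInputs:
    """Sources feeding one target country's reference, plus h² for context."""

    sources: list = field(default_factory=list)
    h2: float | None = None

    def total_information(self) -> float:
        return float(sum(s.information for s in self.sources))


def expected_reliability(inputs: ExpectedGainInputs, me: float) -> float:
    """Deterministic reliability r² = T/(T + M_e); strictly below 1.

    Monotone increasing in every source's size, rg and proof
    reliability; a source with rg = 0 contributes nothing.
    """
    if me <= 0:
        raise ValueError("M_e must be positive")
    t = inputs.total_information()
    return t / (t + me)


def calibrate_me(observed_rel: float, inputs: ExpectedGainInputs) -> float:
    """Solve T/(T + M_e) = observed r² for M_e (exact inverse).

    Anchors the deterministic expectation to a realized national result,
    the workflow used to predict combined-reference gains.
    """
    if not (0.0 < observed_rel < 1.0):
        raise ValueError("observed reliability must lie in (0, 1)")
    t = inputs.total_information()
    if t <= 0:
        raise ValueError("no information in the calibration sources")
    return t * (1.0 - observed_rel) / observed_rel


def expected_gain(
    national: ExpectedGainInputs, combined: ExpectedGainInputs, me: float
) -> float:
    """Δr² from enlarging the reference; ≥ 0 whenever combined ⊇ national."""
    return expected_reliability(combined, me) - expected_reliability(national, me)
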