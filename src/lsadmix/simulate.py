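"""Synthetic genotype generator for the admixture model.

The generative model: population allele frequencies iid Uniform(0, 1) (or
a user-supplied frequency panel), admixture columns iid Dirichlet, and
genotypes drawn entrywise as ``g_li ~ Binomial(2, (PQ)_li)``.  One seeded
random stream is consumed in the documented order P, then Q, then G, so
the pieces are individually reproducible.  No missing data is generated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import compute_m
from .theory import DirichletSpec

__all__ = [
    "SimScenario",
    "sample_frequencies",
    "sample_admixture",
    "sample_genotypes",
    "simulate",
]


def _as_rng(seed: int | np.random.Generator) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


@dataclass(frozen=True)
class SimScenario:
    """One simulation condition: sizes, admixture prior, optional panel."""

    M: int
    N: int
    K: int
    dirichlet: DirichletSpec
    panel: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.M < 1 or self.N < 1 or self.K < 1:
            raise ValueError(f"M, N, K must be >= 1, got ({self.M}, {self.N}, {self.K})")
        if self.dirichlet.K != self.K:
            raise ValueError(f"Dirichlet spec has K={self.dirichlet.K}, scenario has K={self.K}")
        if self.panel is not None:
            panel = np.asarray(self.panel, dtype=np.float64)
            if panel.shape != (self.M, self.K):
                raise ValueError(f"panel shape {panel.shape} != ({self.M}, {self.K})")
            if panel.min() < 0 or panel.max() > 1:
                raise ValueError("panel frequencies must lie in [0, 1]")


def sample_frequencies(M: int, K: int, seed: int | np.random.Generator) -> np.ndarray:
    """M x K allele frequencies, iid Uniform(0, 1)."""
    return _as_rng(seed).random((M, K))


def sample_admixture(N: int, spec: DirichletSpec, seed: int | np.random.Generator) -> np.ndarray:
    """K x N admixture proportions with iid Dirichlet columns.

    Sampled as normalised independent Gamma deviates (the standard
    construction); columns are renormalised so they sum to one exactly.
    """
    rng = _as_rng(seed)
    Q = rng.dirichlet(spec.alphas, size=N).T
    return Q / Q.sum(axis=0, keepdims=True)


def sample_genotypes(
    P: np.ndarray, Q: np.ndarray, seed: int | np.random.Generator
) -> np.ndarray:
    """Genotypes ``g_li ~ Binomial(2, m_li)`` with ``m = P Q``."""
    m = compute_m(P, Q)
    if m.min() < -1e-12 or m.max() > 1.0 + 1e-12:
        raise ValueError(
            f"success probabilities outside [0, 1] (range [{m.min()}, {m.max()}]); "
            "invalid P or Q"
        )
    rng = _as_rng(seed)
    return rng.binomial(2, np.clip(m, 0.0, 1.0)).astype(np.int8)


def simulate(scenario: SimScenario) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw (P, Q, G) for one scenario from a single seeded stream."""
    rng = np.random.default_rng(scenario.seed)
    if scenario.panel is not None:
        P = np.asarray(scenario.panel, dtype=np.float64)
    else:
        P = sample_frequencies(scenario.M, scenario.K, rng)
    Q = sample_admixture(scenario.N, scenario.dirichlet, rng)
    G = sample_genotypes(P, Q, rng)
    return P, Q, G
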