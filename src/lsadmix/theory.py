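"""Closed-form expectations and variance bounds for the partial problems.

When one factor is known, the least-squares estimate of the other is
unbiased over the binomial genotype distribution, and the trace of its
covariance ("total variance") admits simple bounds:

* known Q:  ``trace(cov p-hat) <= trace((Q Q')^{-1}) / 8`` per locus, and
  asymptotically (iid Dirichlet columns) ``K^2 (1 + (K-1) alpha) / (8N)``,
  which for K = 2 reduces to ``(alpha + 1) / (2N)``;
* known P:  ``trace(cov q-hat) <= trace((P'P)^{-1}) / 8`` per individual,
  decreasing like 1/M for iid rows of P.

These bounds double as independent test oracles for the estimators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DirichletSpec",
    "BoundReport",
    "genotype_variance_bound",
    "empirical_p_variance_bound",
    "empirical_q_variance_bound",
    "dirichlet_second_moment",
    "asymptotic_p_variance_bound",
    "effective_alpha",
]


@dataclass(frozen=True)
class DirichletSpec:
    """Shape parameters of a Dirichlet distribution on the K-simplex."""

    alphas: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "alphas", tuple(float(a) for a in self.alphas))
        if len(self.alphas) < 1 or any(a <= 0 for a in self.alphas):
            raise ValueError(f"all Dirichlet shapes must be > 0, got {self.alphas}")

    @classmethod
    def symmetric(cls, K: int, alpha: float) -> "DirichletSpec":
        return cls((alpha,) * K)

    @property
    def K(self) -> int:
        return len(self.alphas)

    @property
    def alpha0(self) -> float:
        return float(sum(self.alphas))

    @property
    def is_symmetric(self) -> bool:
        return len(set(self.alphas)) == 1


@dataclass(frozen=True)
class BoundReport:
    """Empirical and asymptotic total-variance bounds for an estimator."""

    empirical_bound: float
    asymptotic_bound: float
    n_used: int


def genotype_variance_bound() -> float:
    """Worst-case variance of a genotype count: max over m of 2m(1-m) = 1/2."""
    return 0.5


def empirical_p_variance_bound(Q: np.ndarray) -> float:
    """``trace((Q Q')^{-1}) / 8`` — total-variance bound for p-hat, known Q."""
    Q = np.asarray(Q, dtype=np.float64)
    QQt = Q @ Q.T
    try:
        inv = np.linalg.inv(QQt)
    except np.linalg.LinAlgError as exc:
        raise ValueError("Q Q' is singular") from exc
    return float(np.trace(inv)) / 8.0


def empirical_q_variance_bound(P: np.ndarray) -> float:
    """``trace((P'P)^{-1}) / 8`` — total-variance bound for q-hat, known P."""
    P = np.asarray(P, dtype=np.float64)
    PtP = P.T @ P
    try:
        inv = np.linalg.inv(PtP)
    except np.linalg.LinAlgError as exc:
        raise ValueError("P'P is singular") from exc
    return float(np.trace(inv)) / 8.0


def dirichlet_second_moment(spec: DirichletSpec) -> np.ndarray:
    """Second-moment matrix ``E[q q']`` of a Dirichlet draw.

    Diagonal ``a_k (a_k + 1) / (a_0 (a_0 + 1))``, off-diagonal
    ``a_k a_j / (a_0 (a_0 + 1))``.  For the symmetric K = 2 case this is
    ``[[alpha+1, alpha], [alpha, alpha+1]] / (4 alpha + 2)``.
    """
    a = np.asarray(spec.alphas)
    a0 = spec.alpha0
    M = np.outer(a, a) / (a0 * (a0 + 1.0))
    M[np.diag_indices_from(M)] = a * (a + 1.0) / (a0 * (a0 + 1.0))
    return M


def asymptotic_p_variance_bound(N: int, alpha: float, K: int = 2) -> float:
    """Large-N total-variance bound for p-hat under iid Dirichlet admixture.

    ``(1/(8N)) trace(E[qq']^{-1}) = K^2 (1 + (K-1) alpha) / (8N)`` for the
    symmetric Dirichlet; K = 2 gives ``(alpha + 1) / (2N)``.
    """
    if N < 1:
        raise ValueError(f"N must be >= 1, got {N}")
    if alpha <= 0:
        raise ValueError(f"alpha must be > 0, got {alpha}")
    return K * K * (1.0 + (K - 1.0) * alpha) / (8.0 * N)


def effective_alpha(spec: DirichletSpec) -> float:
    """Symmetric shape with the same total variance as a general Dirichlet.

    The total variance of Dirichlet(a_1..a_K) is
    ``v = sum_k a_k (a_0 - a_k) / (a_0^2 (a_0 + 1))``; the symmetric shape
    matching it is ``alpha = (K-1) / (K^2 v) - 1/K``.  For symmetric input
    this returns the common shape exactly.
    """
    if spec.K < 2:
        raise ValueError("effective alpha requires K >= 2")
    a = np.asarray(spec.alphas)
    a0 = spec.alpha0
    v = float(np.sum(a * (a0 - a)) / (a0 * a0 * (a0 + 1.0)))
    if v <= 0:
        raise ValueError("degenerate Dirichlet: total variance is zero")
    K = spec.K
    return (K - 1.0) / (K * K * v) - 1.0 / K
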