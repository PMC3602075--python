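"""Data model and scalar objective functions.

Matrices are plain ``numpy`` arrays in the conventional orientation:

* ``G`` — genotypes, M loci x N individuals, integer counts in {0, 1, 2};
* ``P`` — allele frequencies, M loci x K populations, entries in [0, 1];
* ``Q`` — admixture proportions, K populations x N individuals, columns on
  the probability simplex.

Validation helpers enforce these invariants; the objective functions assume
conformable shapes and raise :class:`ValueError` naming both shapes when
they are not.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "FitConfig",
    "validate_genotypes",
    "validate_frequencies",
    "validate_admixture",
    "compute_m",
    "ls_objective",
    "penalized_objective",
    "binom_loglik",
]

#: absolute tolerance on the sum-to-one constraint for columns of Q
SIMPLEX_ATOL = 1e-9


@dataclass(frozen=True)
class FitConfig:
    """Run parameters for the alternating least-squares fit.

    Parameters
    ----------
    K : int
        Number of ancestral populations.
    alpha : float
        Degree of admixture (symmetric Dirichlet shape).  ``alpha = 1`` is
        the uninformative prior and reduces the criterion to plain least
        squares; ``alpha < 1`` favours sparse (nearly pure) individuals,
        ``alpha > 1`` favours even mixtures.
    epsilon : float or None
        Absolute convergence tolerance on the penalised criterion between
        consecutive outer iterations.  ``None`` selects the size-dependent
        default ``M * N * 1e-10``.
    max_iter : int
        Cap on outer (P, Q) sweeps.
    seed : int
        Seed for the random simplex initialisation of ``Q``.
    clip_likelihood : float
        Probability floor used when evaluating the monitoring binomial
        log-likelihood (the criterion itself never needs it).
    """

    K: int
    alpha: float = 1.0
    epsilon: float | None = None
    max_iter: int = 2000
    seed: int = 0
    clip_likelihood: float = 1e-10

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError(f"K must be >= 1, got {self.K}")
        if self.alpha <= 0:
            raise ValueError(f"alpha must be > 0, got {self.alpha}")
        if self.epsilon is not None and self.epsilon <= 0:
            raise ValueError(f"epsilon must be > 0, got {self.epsilon}")
        if self.max_iter < 1:
            raise ValueError(f"max_iter must be >= 1, got {self.max_iter}")
        if not 0 < self.clip_likelihood < 0.5:
            raise ValueError(f"clip_likelihood must be in (0, 0.5), got {self.clip_likelihood}")

    def resolve_epsilon(self, M: int, N: int) -> float:
        """Return the convergence tolerance for an M x N problem."""
        return self.epsilon if self.epsilon is not None else M * N * 1e-10


def validate_genotypes(G: np.ndarray) -> np.ndarray:
    """Validate a genotype matrix and return it as a small-integer array.

    Entries must lie in {0, 1, 2}; missing values are not representable
    here (see :mod:`lsadmix.io` for missing-data policies on read).
    """
    G = np.asarray(G)
    if G.ndim != 2 or G.shape[0] < 1 or G.shape[1] < 1:
        raise ValueError(f"genotype matrix must be 2-D and non-empty, got shape {G.shape}")
    if not np.issubdtype(G.dtype, np.integer):
        rounded = np.rint(G)
        if not np.array_equal(rounded, G):
            raise ValueError("genotype matrix contains non-integer entries")
        G = rounded
    if G.min() < 0 or G.max() > 2:
        bad = G[(G < 0) | (G > 2)].ravel()[0]
        raise ValueError(f"genotype entries must be in {{0, 1, 2}}, found {bad}")
    return G.astype(np.int8, copy=False)


def validate_frequencies(P: np.ndarray, *, atol: float = 0.0) -> np.ndarray:
    """Validate an allele-frequency matrix (entries in [0, 1])."""
    P = np.asarray(P, dtype=np.float64)
    if P.ndim != 2 or P.shape[1] < 1:
        raise ValueError(f"frequency matrix must be 2-D with K >= 1 columns, got shape {P.shape}")
    if P.min() < -atol or P.max() > 1 + atol:
        raise ValueError("frequency entries must lie in [0, 1]")
    return np.clip(P, 0.0, 1.0) if atol else P


def validate_admixture(Q: np.ndarray, *, atol: float = SIMPLEX_ATOL) -> np.ndarray:
    """Validate an admixture matrix (nonnegative, columns sum to one)."""
    Q = np.asarray(Q, dtype=np.float64)
    if Q.ndim != 2 or Q.shape[0] < 1 or Q.shape[1] < 1:
        raise ValueError(f"admixture matrix must be 2-D and non-empty, got shape {Q.shape}")
    if Q.min() < -atol:
        raise ValueError(f"admixture entries must be nonnegative, min is {Q.min()}")
    colsums = Q.sum(axis=0)
    worst = np.abs(colsums - 1.0).max()
    if worst > atol:
        raise ValueError(f"admixture columns must sum to 1 (worst deviation {worst:.3e})")
    return Q


def _check_conformable(P: np.ndarray, Q: np.ndarray, G: np.ndarray | None = None) -> None:
    if P.shape[1] != Q.shape[0]:
        raise ValueError(
            f"P has {P.shape[1]} populations (shape {P.shape}) but Q has "
            f"{Q.shape[0]} (shape {Q.shape})"
        )
    if G is not None and (G.shape[0] != P.shape[0] or G.shape[1] != Q.shape[1]):
        raise ValueError(
            f"genotype shape {G.shape} does not match P {P.shape} x Q {Q.shape}"
        )


def compute_m(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Per-allele reference probabilities ``m = P Q``.

    Entry ``(l, i)`` is the chance that one allele copy of individual ``i``
    at locus ``l`` is the reference allele, ``sum_k p_lk q_ki``.  With
    ``P`` in [0, 1] and simplex columns in ``Q`` every entry lies in
    [0, 1].
    """
    P = np.asarray(P, dtype=np.float64)
    Q = np.asarray(Q, dtype=np.float64)
    _check_conformable(P, Q)
    return P @ Q


def ls_objective(P: np.ndarray, Q: np.ndarray, G: np.ndarray) -> float:
    """Least-squares criterion ``||2 P Q - G||_F^2``."""
    P = np.asarray(P, dtype=np.float64)
    Q = np.asarray(Q, dtype=np.float64)
    G = np.asarray(G)
    _check_conformable(P, Q, G)
    R = 2.0 * (P @ Q) - G
    return float(np.einsum("ij,ij->", R, R))


def penalized_objective(P: np.ndarray, Q: np.ndarray, G: np.ndarray, alpha: float) -> float:
    """Least-squares criterion plus the degree-of-admixture penalty.

    The penalty ``K^2 (alpha - 1) * ||Q - 1/K||_F^2`` is the first-order
    approximation of the negative log of a symmetric Dirichlet prior on
    the columns of ``Q`` around the barycentre ``q_k = 1/K``.  For
    ``alpha = 1`` it vanishes; for ``alpha < 1`` it is a (negative) reward
    for sparse columns.
    """
    if alpha <= 0:
        raise ValueError(f"alpha must be > 0, got {alpha}")
    base = ls_objective(P, Q, G)
    if alpha == 1.0:
        return base
    Q = np.asarray(Q, dtype=np.float64)
    K = Q.shape[0]
    dev = Q - 1.0 / K
    return base + K * K * (alpha - 1.0) * float(np.einsum("ij,ij->", dev, dev))


def binom_loglik(P: np.ndarray, Q: np.ndarray, G: np.ndarray, floor: float = 1e-10) -> float:
    """Binomial log-likelihood of (P, Q) given G, up to an additive constant.

    ``sum_li [ g_li ln(m_li) + (2 - g_li) ln(1 - m_li) ]`` with ``m``
    clamped to ``[floor, 1 - floor]`` so the value is always finite.  Used
    for monitoring only; the optimiser never touches it.
    """
    if not 0 < floor < 0.5:
        raise ValueError(f"floor must be in (0, 0.5), got {floor}")
    G = np.asarray(G, dtype=np.float64)
    m = compute_m(P, Q)
    _check_conformable(np.asarray(P, dtype=np.float64), np.asarray(Q, dtype=np.float64), G)
    m = np.clip(m, floor, 1.0 - floor)
    return float(np.sum(G * np.log(m) + (2.0 - G) * np.log1p(-m)))
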