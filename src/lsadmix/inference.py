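"""Alternating least-squares driver and partial-problem estimators.

The full problem minimises ``||2 P Q - G||^2`` (plus the degree-of-admixture
penalty) over box-constrained ``P`` and simplex-constrained ``Q`` by exact
two-block coordinate descent: each block subproblem is convex and solved to
its global optimum, so the penalised criterion never increases.

The single-step estimators (:func:`estimate_p_known_Q`,
:func:`estimate_q_known_P`, :func:`ml_estimate_p_known_Q`) are the
"best-case" updates applied once with one factor fixed at truth; they are
what the theoretical mean/variance results describe.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .model import FitConfig, penalized_objective, validate_genotypes
from .solvers import build_normal_equations, bvls_multirhs, simplex_ls_multirhs

__all__ = [
    "FitResult",
    "init_Q",
    "update_P",
    "update_Q",
    "fit",
    "estimate_p_known_Q",
    "estimate_q_known_P",
    "ml_estimate_p_known_Q",
]


@dataclass
class FitResult:
    """Outcome of an alternating least-squares run.

    ``objective_trace`` holds the penalised criterion after each outer
    (P, Q) sweep and is non-increasing; ``converged`` means the last two
    entries differ by less than the configured tolerance.
    """

    P: np.ndarray
    Q: np.ndarray
    objective_trace: list[float] = field(default_factory=list)
    n_iter: int = 0
    converged: bool = False
    seed: int = 0


def init_Q(K: int, N: int, seed: int) -> np.ndarray:
    """Random simplex initialisation: K iid uniforms per column, normalised."""
    if K < 1 or N < 1:
        raise ValueError(f"need K >= 1 and N >= 1, got K={K}, N={N}")
    rng = np.random.default_rng(seed)
    X = rng.random((K, N))
    return X / X.sum(axis=0, keepdims=True)


def update_P(Q: np.ndarray, G: np.ndarray) -> np.ndarray:
    """Exact minimiser of the criterion over ``P`` with ``Q`` fixed.

    Row ``l`` of ``P`` solves ``min ||2 Q' p - g_l||^2`` over the box
    [0, 1]; all M loci share the design ``2 Q'`` and are solved together.
    """
    Q = np.asarray(Q, dtype=np.float64)
    G = np.asarray(G, dtype=np.float64)
    return bvls_multirhs(2.0 * Q.T, G.T, 0.0, 1.0).T


def update_Q(P: np.ndarray, G: np.ndarray, alpha: float = 1.0) -> np.ndarray:
    """Exact minimiser over simplex-constrained ``Q`` with ``P`` fixed."""
    return simplex_ls_multirhs(build_normal_equations(P, G, alpha))


def fit(G: np.ndarray, config: FitConfig) -> FitResult:
    """Estimate ``P`` and ``Q`` from genotypes by block coordinate descent.

    Starts from a random simplex ``Q`` (seeded), then alternates
    :func:`update_P` and :func:`update_Q` until the absolute change in the
    penalised criterion over one sweep drops below the tolerance or the
    iteration cap is reached.  Non-convergence at the cap is reported via
    ``converged=False``, not raised.
    """
    G = validate_genotypes(G)
    M, N = G.shape
    K = config.K
    if N < K:
        raise ValueError(f"need at least K={K} individuals, got N={N}")
    if M < K:
        raise ValueError(f"need at least K={K} loci, got M={M}")
    eps = config.resolve_epsilon(M, N)

    Q = init_Q(K, N, config.seed)
    Gf = G.astype(np.float64)
    trace: list[float] = []
    P = np.zeros((M, K))
    converged = False
    for it in range(1, config.max_iter + 1):
        try:
            P = update_P(Q, Gf)
            Q = update_Q(P, Gf, config.alpha)
        except (ValueError, RuntimeError) as exc:
            raise RuntimeError(f"solver failure at outer iteration {it}: {exc}") from exc
        trace.append(penalized_objective(P, Q, Gf, config.alpha))
        if len(trace) >= 2 and abs(trace[-1] - trace[-2]) < eps:
            converged = True
            break
    return FitResult(P=P, Q=Q, objective_trace=trace, n_iter=len(trace), converged=converged, seed=config.seed)


def estimate_p_known_Q(G: np.ndarray, Q: np.ndarray, clamp: bool = False) -> np.ndarray:
    """Unconstrained least-squares frequencies given the true admixture.

    ``P-hat = (1/2) G Q' (Q Q')^{-1}`` — the normal-equations solution per
    locus.  Entries may fall outside [0, 1]; pass ``clamp=True`` to clip.
    This estimator is unbiased over the binomial genotype distribution and
    its total variance is bounded by ``trace((QQ')^{-1}) / 8``.
    """
    G = np.asarray(G, dtype=np.float64)
    Q = np.asarray(Q, dtype=np.float64)
    QQt = Q @ Q.T
    try:
        P = 0.5 * np.linalg.solve(QQt, Q @ G.T).T
    except np.linalg.LinAlgError as exc:
        raise ValueError("Q Q' is singular; admixture rows are collinear") from exc
    return np.clip(P, 0.0, 1.0) if clamp else P


def estimate_q_known_P(G: np.ndarray, P: np.ndarray, alpha: float = 1.0) -> np.ndarray:
    """One-shot simplex-constrained admixture given the true frequencies."""
    return update_Q(P, np.asarray(G, dtype=np.float64), alpha)


def _neg_loglik_one_locus(p: np.ndarray, Q: np.ndarray, g: np.ndarray, floor: float):
    m = p @ Q
    mc = np.clip(m, floor, 1.0 - floor)
    nll = -float(np.sum(g * np.log(mc) + (2.0 - g) * np.log1p(-mc)))
    grad = -(Q @ ((g - 2.0 * mc) / (mc * (1.0 - mc))))
    return nll, grad


def ml_estimate_p_known_Q(
    G: np.ndarray,
    Q: np.ndarray,
    row: int,
    floor: float = 1e-10,
) -> np.ndarray:
    """Binomial maximum-likelihood frequencies for one locus, ``p in [0,1]^K``.

    Maximises the exact binomial log-likelihood over the box by L-BFGS-B,
    started from the box-clipped least-squares estimate, so the returned
    likelihood is never below the starting point's.
    """
    G = np.asarray(G, dtype=np.float64)
    Q = np.asarray(Q, dtype=np.float64)
    g = G[row]
    p0 = estimate_p_known_Q(g[None, :], Q, clamp=True)[0]
    res = minimize(
        _neg_loglik_one_locus,
        p0,
        args=(Q, g, floor),
        jac=True,
        method="L-BFGS-B",
        bounds=[(0.0, 1.0)] * Q.shape[0],
    )
    if not np.all(np.isfinite(res.x)):
        raise RuntimeError(f"likelihood maximisation failed at locus {row}: {res.message}")
    return np.clip(res.x, 0.0, 1.0)
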