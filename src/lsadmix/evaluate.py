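"""Evaluation utilities and simulation-study harnesses.

Provides label alignment (admixture estimates are identifiable only up to
a permutation of population labels), percent RMSE, and three experiment
drivers:

* :func:`run_empirical_cov` — replicate the known-Q estimator to check its
  unbiasedness and compare the covariance trace against the bounds;
* :func:`run_bestcase_P` — aggregate RMSE of the known-Q estimate of a
  two-population frequency vector over a 10 x 10 grid of targets, with
  either the least-squares or the binomial maximum-likelihood estimator;
* :func:`run_factorial` — the full-inference study over a grid of
  (K, N, alpha) conditions, reporting permutation-aligned percent RMSE
  for both factors.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

from .inference import estimate_p_known_Q, fit, ml_estimate_p_known_Q
from .model import FitConfig
from .simulate import SimScenario, sample_admixture, simulate
from .theory import (
    BoundReport,
    DirichletSpec,
    asymptotic_p_variance_bound,
    empirical_p_variance_bound,
)

__all__ = [
    "ExperimentResult",
    "align_populations",
    "rmse_percent",
    "run_empirical_cov",
    "run_bestcase_P",
    "run_factorial",
]

logger = logging.getLogger(__name__)

#: maximum K for exhaustive permutation alignment (K! subproblems)
MAX_ALIGN_K = 8


@dataclass
class ExperimentResult:
    """Aggregate percent RMSE for one factorial condition."""

    K: int
    N: int
    M: int
    alpha: float
    estimator: str
    rmse_P_percent: float
    rmse_Q_percent: float
    per_trial: list[dict] = field(default_factory=list)
    n_trials: int = 0
    seed: int = 0


def align_populations(Q_est: np.ndarray, Q_true: np.ndarray) -> tuple[int, ...]:
    """Best relabelling of estimated populations against the truth.

    Returns the permutation ``perm`` minimising ``||Q_est[perm] -
    Q_true||^2`` by exhaustive search over all K! orderings (ties broken
    by the lexicographically smallest permutation).
    """
    Q_est = np.asarray(Q_est, dtype=np.float64)
    Q_true = np.asarray(Q_true, dtype=np.float64)
    if Q_est.shape != Q_true.shape:
        raise ValueError(f"shape mismatch: {Q_est.shape} vs {Q_true.shape}")
    K = Q_est.shape[0]
    if K > MAX_ALIGN_K:
        raise ValueError(
            f"exhaustive alignment supports K <= {MAX_ALIGN_K} (got K={K}); "
            "use an assignment-problem solver for larger K"
        )
    # cross-residuals: cost[a, b] = ||Q_est[a] - Q_true[b]||^2
    cost = (
        np.sum(Q_est**2, axis=1)[:, None]
        + np.sum(Q_true**2, axis=1)[None, :]
        - 2.0 * Q_est @ Q_true.T
    )
    best_perm = tuple(range(K))
    best = np.inf
    for perm in itertools.permutations(range(K)):
        total = cost[list(perm), range(K)].sum()
        if total < best:
            best = total
            best_perm = perm
    return best_perm


def rmse_percent(X_est: np.ndarray, X_true: np.ndarray) -> float:
    """Root mean squared error over all entries, in percent."""
    X_est = np.asarray(X_est, dtype=np.float64)
    X_true = np.asarray(X_true, dtype=np.float64)
    if X_est.shape != X_true.shape:
        raise ValueError(f"shape mismatch: {X_est.shape} vs {X_true.shape}")
    return 100.0 * float(np.sqrt(np.mean((X_est - X_true) ** 2)))


def run_empirical_cov(
    p_true: np.ndarray,
    N: int,
    alpha: float,
    n_trials: int,
    seed: int,
) -> tuple[np.ndarray, np.ndarray, float, BoundReport]:
    """Replicate the known-Q estimator at one locus and summarise its error.

    Draws a single admixture matrix Q (Dirichlet columns), then
    ``n_trials`` independent single-locus genotype rows from
    ``Binomial(2, p'q_i)`` and estimates p each time.  Returns the sample
    mean, sample covariance, its trace, and the empirical/asymptotic
    total-variance bounds for the drawn Q.
    """
    if n_trials < 100:
        raise ValueError(f"need n_trials >= 100, got {n_trials}")
    p_true = np.asarray(p_true, dtype=np.float64)
    K = p_true.size
    rng = np.random.default_rng(seed)
    Q = sample_admixture(N, DirichletSpec.symmetric(K, alpha), rng)
    m = p_true @ Q
    if m.min() < 0 or m.max() > 1:
        raise ValueError("p'Q left [0, 1]; p_true must be a valid frequency vector")
    G = rng.binomial(2, np.broadcast_to(m, (n_trials, N)))
    estimates = estimate_p_known_Q(G, Q)  # one row per trial
    mean = estimates.mean(axis=0)
    cov = np.cov(estimates, rowvar=False).reshape(K, K)
    report = BoundReport(
        empirical_bound=empirical_p_variance_bound(Q),
        asymptotic_bound=asymptotic_p_variance_bound(N, alpha, K),
        n_used=N,
    )
    return mean, cov, float(np.trace(cov)), report


def _bestcase_draws(p: np.ndarray, N: int, alpha: float, n_trials: int, rng):
    """Per-trial admixture matrices and one genotype row each, vectorised."""
    Q = rng.dirichlet((alpha, alpha), size=(n_trials, N))  # (T, N, 2)
    Q = np.swapaxes(Q, 1, 2)  # (T, 2, N)
    m = np.einsum("k,tkn->tn", p, Q)
    G = rng.binomial(2, m)
    return Q, G


def run_bestcase_P(
    N: int,
    alpha: float,
    n_trials: int,
    seed: int,
    estimator: str = "ls",
) -> float:
    """Aggregate percent RMSE of the known-Q estimate of p on a 10 x 10 grid.

    For every target ``p = (p1, p2)`` with each coordinate in
    {0.05, 0.15, ..., 0.95} and each of ``n_trials`` replicates: draw a
    fresh K = 2 admixture matrix (Dirichlet-``alpha`` columns, N
    individuals), draw one genotype row, and estimate p — by the
    unconstrained least-squares formula (``estimator="ls"``) or by
    box-constrained maximisation of the binomial likelihood
    (``estimator="ml"``).  Squared errors are pooled over the whole grid.
    """
    if estimator not in ("ls", "ml"):
        raise ValueError(f"estimator must be 'ls' or 'ml', got {estimator!r}")
    rng = np.random.default_rng(seed)
    grid = np.arange(0.05, 1.0, 0.1)
    sse = 0.0
    count = 0
    for p1 in grid:
        for p2 in grid:
            p = np.array([p1, p2])
            Q, G = _bestcase_draws(p, N, alpha, n_trials, rng)
            if estimator == "ls":
                QQt = np.einsum("tkn,tln->tkl", Q, Q)
                Qg = np.einsum("tkn,tn->tk", Q, G.astype(np.float64))
                est = 0.5 * np.linalg.solve(QQt, Qg[..., None])[..., 0]
            else:
                est = np.empty((n_trials, 2))
                for t in range(n_trials):
                    est[t] = ml_estimate_p_known_Q(G[t][None, :], Q[t], 0)
            sse += float(np.sum((est - p) ** 2))
            count += est.size
    return 100.0 * float(np.sqrt(sse / count))


def run_factorial(
    Ks: list[int],
    Ns: list[int],
    alphas: list[float],
    M: int = 10000,
    n_trials: int = 50,
    seed: int = 0,
    use_known_alpha: bool = False,
    epsilon: float | None = None,
    max_iter: int = 2000,
) -> list[ExperimentResult]:
    """Full-inference simulation study over a grid of conditions.

    For each (K, N, alpha) condition and trial: simulate (P, Q, G) from
    the generative model, run the alternating least-squares fit (with the
    uninformative prior ``alpha=1``, or the true alpha when
    ``use_known_alpha``), align population labels on Q by best
    permutation, and record percent RMSE for Q and for P (sharing the
    permutation).  Per-trial failures are recorded in the result rather
    than raised.

    ``epsilon=None`` selects the size-scaled default stopping threshold
    ``M * N * 1e-10``; pass an explicit value to override.
    """
    if M < max(Ks):
        raise ValueError(f"M={M} is smaller than the largest K {max(Ks)}")
    master = np.random.default_rng(seed)
    results: list[ExperimentResult] = []
    label = "LSa" if use_known_alpha else "LS1"
    for K in Ks:
        for N in Ns:
            for alpha in alphas:
                per_trial: list[dict] = []
                for t in range(n_trials):
                    sim_seed = int(master.integers(2**31))
                    fit_seed = int(master.integers(2**31))
                    record: dict = {"trial": t, "sim_seed": sim_seed, "fit_seed": fit_seed}
                    try:
                        P, Q, G = simulate(
                            SimScenario(M, N, K, DirichletSpec.symmetric(K, alpha), seed=sim_seed)
                        )
                        cfg = FitConfig(
                            K=K,
                            alpha=alpha if use_known_alpha else 1.0,
                            epsilon=epsilon,
                            max_iter=max_iter,
                            seed=fit_seed,
                        )
                        res = fit(G, cfg)
                        perm = align_populations(res.Q, Q)
                        record["rmse_Q"] = rmse_percent(res.Q[list(perm)], Q)
                        record["rmse_P"] = rmse_percent(res.P[:, list(perm)], P)
                        record["n_iter"] = res.n_iter
                        record["converged"] = res.converged
                    except (ValueError, RuntimeError) as exc:  # pragma: no cover
                        logger.warning("trial %d failed for (K=%d, N=%d, alpha=%g): %s", t, K, N, alpha, exc)
                        record["error"] = str(exc)
                    per_trial.append(record)
                ok = [r for r in per_trial if "error" not in r]
                results.append(
                    ExperimentResult(
                        K=K,
                        N=N,
                        M=M,
                        alpha=alpha,
                        estimator=label,
                        rmse_P_percent=float(np.mean([r["rmse_P"] for r in ok])) if ok else float("nan"),
                        rmse_Q_percent=float(np.mean([r["rmse_Q"] for r in ok])) if ok else float("nan"),
                        per_trial=per_trial,
                        n_trials=n_trials,
                        seed=seed,
                    )
                )
    return results
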