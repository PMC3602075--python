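"""Constrained least-squares kernels.

Two solvers shared by the block updates:

* :func:`bvls_multirhs` — bounded-variable least squares for many
  right-hand sides sharing one design matrix, used for the allele
  frequencies (one RHS per locus, box constraint [0, 1]).  It follows the
  fast combinatorial active/passive-set strategy for multiple right-hand
  sides, extended with a second active set for the upper bound: columns
  whose active/passive partitions coincide are solved in one grouped
  linear solve against the shared Gram matrix.

* :func:`simplex_ls_multirhs` — least squares under nonnegativity and a
  sum-to-one constraint, used for the admixture proportions (one RHS per
  individual).  The equality constraint is handled in closed form with a
  Lagrange multiplier on each passive set; nonnegativity by the same
  active-set exchange.

Both use full exchange (move every violating variable at once, release
every variable whose gradient points inward) with a fallback to
single-variable exchange if the objective stalls twice, which guarantees
termination.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve

__all__ = ["NormalEquations", "bvls_multirhs", "build_normal_equations", "simplex_ls_multirhs"]

#: absolute KKT / feasibility tolerance (double precision, modest condition)
KKT_TOL = 1e-8


def _group_columns(codes: np.ndarray, cols: np.ndarray):
    """Yield (pattern, member column indices) for each unique code column."""
    pats, inverse = np.unique(codes[:, cols], axis=1, return_inverse=True)
    for g in range(pats.shape[1]):
        yield pats[:, g], cols[inverse == g]


def bvls_multirhs(
    A: np.ndarray,
    B: np.ndarray,
    lower: float = 0.0,
    upper: float = 1.0,
    *,
    tol: float = KKT_TOL,
    max_iter: int | None = None,
) -> np.ndarray:
    """Minimise ``||A x - b_r||^2`` s.t. ``lower <= x <= upper`` per column.

    Parameters
    ----------
    A : (n, K) ndarray
        Shared design matrix, full column rank.
    B : (n, R) ndarray
        Right-hand sides, one problem per column.
    lower, upper : float
        Box bounds; either may be infinite.  ``lower < upper`` required.
    tol : float
        Absolute KKT tolerance: passive gradients within ``tol`` of zero,
        gradients at the lower (upper) bound above ``-tol`` (below
        ``tol``).
    max_iter : int, optional
        Inner-loop cap per column; default ``30 * K``.

    Returns
    -------
    (K, R) ndarray of solutions.
    """
    A = np.asarray(A, dtype=np.float64)
    B = np.asarray(B, dtype=np.float64)
    if B.ndim == 1:
        B = B[:, None]
    n, K = A.shape
    R = B.shape[1]
    if B.shape[0] != n:
        raise ValueError(f"A has {n} rows but B has {B.shape[0]}")
    if not lower < upper:
        raise ValueError(f"need lower < upper, got [{lower}, {upper}]")
    AtA = A.T @ A
    eig = np.linalg.eigvalsh(AtA)
    if eig[0] <= eig[-1] * 1e-12:
        raise ValueError(
            f"design matrix is rank deficient ({n} rows, {K} columns); "
            "add individuals or reduce the number of populations K"
        )
    chol = cho_factor(AtA)
    AtB = A.T @ B
    cap = max_iter if max_iter is not None else 30 * K

    # unconstrained start; clamp violators (ties at a bound count as clamped)
    X = cho_solve(chol, AtB)
    codes = np.zeros((K, R), dtype=np.int8)  # 0 passive, 1 at lower, 2 at upper
    codes[X <= lower] = 1
    codes[X >= upper] = 2
    if np.isfinite(lower):
        X[codes == 1] = lower
    if np.isfinite(upper):
        X[codes == 2] = upper

    active = (codes != 0).any(axis=0)
    iters = np.zeros(R, dtype=np.int64)
    single_mode = np.zeros(R, dtype=bool)
    stall = np.zeros(R, dtype=np.int8)
    f_prev = np.full(R, np.inf)

    while active.any():
        cols = np.flatnonzero(active)
        iters[cols] += 1
        if (iters[cols] > cap).any():
            bad = cols[iters[cols] > cap][0]
            raise RuntimeError(
                f"bounded LS did not terminate within {cap} exchanges for column "
                f"{bad} (K={K}, pattern={codes[:, bad].tolist()})"
            )

        # grouped equality-constrained solve per unique partition
        for pat, gcols in _group_columns(codes, cols):
            pm, lm, um = pat == 0, pat == 1, pat == 2
            x = np.zeros((K, gcols.size))
            if lm.any():
                x[lm] = lower
            if um.any():
                x[um] = upper
            if pm.any():
                rhs = AtB[np.ix_(pm, gcols)].copy()
                if lm.any():
                    rhs -= lower * AtA[np.ix_(pm, lm)].sum(axis=1, keepdims=True)
                if um.any():
                    rhs -= upper * AtA[np.ix_(pm, um)].sum(axis=1, keepdims=True)
                x[pm] = np.linalg.solve(AtA[np.ix_(pm, pm)], rhs)
            X[:, gcols] = x

        Xc = X[:, cols]
        cc = codes[:, cols]
        passive = cc == 0
        lo_viol = passive & (Xc < lower)
        up_viol = passive & (Xc > upper)
        any_viol = (lo_viol | up_viol).any(axis=0)

        # objective trace for cycling detection
        GX = AtA @ Xc
        f = np.einsum("kj,kj->j", Xc, GX) - 2.0 * np.einsum("kj,kj->j", AtB[:, cols], Xc)
        prev = f_prev[cols]
        slack = 1e-12 * np.maximum(1.0, np.abs(np.where(np.isfinite(prev), prev, 0.0)))
        stalled = f >= prev - slack
        stall[cols] = np.where(stalled, stall[cols] + 1, 0)
        single_mode[cols] |= stall[cols] >= 2
        f_prev[cols] = f

        for jj, col in enumerate(cols):
            if any_viol[jj]:
                lo_j = np.flatnonzero(lo_viol[:, jj])
                up_j = np.flatnonzero(up_viol[:, jj])
                if single_mode[col]:
                    # clamp only the worst violator
                    dist = np.zeros(K)
                    dist[lo_j] = lower - Xc[lo_j, jj]
                    dist[up_j] = Xc[up_j, jj] - upper
                    worst = int(np.argmax(dist))
                    codes[worst, col] = 1 if dist[worst] == lower - Xc[worst, jj] else 2
                    X[worst, col] = lower if codes[worst, col] == 1 else upper
                else:
                    codes[lo_j, col] = 1
                    codes[up_j, col] = 2
                    X[lo_j, col] = lower
                    X[up_j, col] = upper
                continue

            # feasible: check KKT release conditions; w is half the gradient
            w = GX[:, jj] - AtB[:, col]
            rel_lo = np.flatnonzero((cc[:, jj] == 1) & (w < -tol))
            rel_up = np.flatnonzero((cc[:, jj] == 2) & (w > tol))
            if rel_lo.size == 0 and rel_up.size == 0:
                active[col] = False
                continue
            if single_mode[col]:
                cand = np.concatenate([rel_lo, rel_up])
                mag = np.abs(w[cand])
                codes[cand[int(np.argmax(mag))], col] = 0
            else:
                codes[rel_lo, col] = 0
                codes[rel_up, col] = 0

    return X


@dataclass(frozen=True)
class NormalEquations:
    """Normal equations of the penalised admixture subproblem.

    For fixed frequencies ``P``, the criterion for one individual is
    ``q' gram q - 2 rhs_i' q + const`` with ``gram = 4 P'P +
    K^2 (alpha - 1) I`` and ``rhs = 2 P'G + K (alpha - 1) 1``.  ``U``,
    ``a``, ``j`` and ``J`` are the pieces of the Lagrange closed form for
    the sum-to-one constraint: ``q = a U j + (U - a U J U) rhs``.
    """

    gram: np.ndarray
    rhs: np.ndarray
    U: np.ndarray
    a: float
    j: np.ndarray
    J: np.ndarray
    alpha: float

    @property
    def K(self) -> int:
        return self.gram.shape[0]


def build_normal_equations(P: np.ndarray, G: np.ndarray, alpha: float) -> NormalEquations:
    """Assemble :class:`NormalEquations` from frequencies and genotypes.

    Raises if the penalised Gram matrix is not positive definite — either
    ``P`` is rank deficient, or a sparsity prior ``alpha < 1`` is strong
    enough to overwhelm ``4 P'P`` (possible only for very small M).
    """
    P = np.asarray(P, dtype=np.float64)
    G = np.asarray(G, dtype=np.float64)
    if alpha <= 0:
        raise ValueError(f"alpha must be > 0, got {alpha}")
    if P.shape[0] != G.shape[0]:
        raise ValueError(f"P has {P.shape[0]} loci but G has {G.shape[0]}")
    K = P.shape[1]
    gram = 4.0 * (P.T @ P)
    if alpha != 1.0:
        gram = gram + (K * K * (alpha - 1.0)) * np.eye(K)
    eig = np.linalg.eigvalsh(gram)
    if eig[0] <= max(eig[-1], 1.0) * 1e-12:
        if alpha < 1.0:
            raise ValueError(
                f"sparsity prior alpha={alpha} is too strong for this data size: "
                "the penalised Gram matrix is not positive definite"
            )
        raise ValueError(
            "frequency matrix is rank deficient; populations are collinear "
            f"(K={K}, M={P.shape[0]})"
        )
    chol = cho_factor(gram)
    rhs = 2.0 * (P.T @ G)
    if alpha != 1.0:
        rhs = rhs + K * (alpha - 1.0)
    U = cho_solve(chol, np.eye(K))
    j = np.ones(K)
    return NormalEquations(
        gram=gram,
        rhs=rhs,
        U=U,
        a=1.0 / float(U.sum()),
        j=j,
        J=np.outer(j, j),
        alpha=alpha,
    )


def _simplex_solve_support(gram: np.ndarray, rhs_block: np.ndarray) -> np.ndarray:
    """Equality-constrained minimiser of q'Gq - 2 rhs'q with sum(q) = 1.

    Closed form via a Lagrange multiplier on the sum constraint:
    ``q = a U j + (U - a (Uj)(Uj)') rhs`` with ``U = G^{-1}`` and
    ``a = 1 / (j'Uj)``; every returned column sums to one identically.
    """
    U = np.linalg.inv(gram)
    u = U.sum(axis=1)  # U j
    a = 1.0 / float(u.sum())
    return a * u[:, None] + (U - a * np.outer(u, u)) @ rhs_block


def simplex_ls_multirhs(
    ne: NormalEquations,
    *,
    tol: float = KKT_TOL,
    max_iter: int | None = None,
) -> np.ndarray:
    """Solve the simplex-constrained problem for every individual.

    Each column ``q_i`` minimises ``q' gram q - 2 rhs_i' q`` subject to
    ``q >= 0`` and ``sum_k q_k = 1``.  Variables clamped at zero drop out
    of both the objective and the constraint, so each passive set is
    solved with the Lagrange closed form on its Gram submatrix; negative
    entries are exchanged into the active set until the KKT multipliers
    of all clamped entries are nonnegative.

    Returns the (K, N) admixture matrix; columns sum to one exactly (up
    to the closed form's floating arithmetic, well below 1e-12).
    """
    K, R = ne.rhs.shape
    if K == 1:
        return np.ones((1, R))
    cap = max_iter if max_iter is not None else 30 * K

    codes = np.zeros((K, R), dtype=np.int8)  # 0 passive, 1 clamped at zero
    X = _simplex_solve_support(ne.gram, ne.rhs)
    active = (X < 0).any(axis=0)

    iters = np.zeros(R, dtype=np.int64)
    single_mode = np.zeros(R, dtype=bool)
    stall = np.zeros(R, dtype=np.int8)
    f_prev = np.full(R, np.inf)
    first = True

    while active.any():
        cols = np.flatnonzero(active)
        iters[cols] += 1
        if (iters[cols] > cap).any():
            bad = cols[iters[cols] > cap][0]
            raise RuntimeError(
                f"simplex LS did not terminate within {cap} exchanges for "
                f"individual {bad} (support={np.flatnonzero(codes[:, bad] == 0).tolist()})"
            )

        if not first:
            for pat, gcols in _group_columns(codes, cols):
                sup = np.flatnonzero(pat == 0)
                x = np.zeros((K, gcols.size))
                x[np.ix_(sup, np.arange(gcols.size))] = _simplex_solve_support(
                    ne.gram[np.ix_(sup, sup)], ne.rhs[np.ix_(sup, gcols)]
                )
                X[:, gcols] = x
        first = False

        Xc = X[:, cols]
        cc = codes[:, cols]
        viol = (cc == 0) & (Xc < 0.0)
        any_viol = viol.any(axis=0)

        GX = ne.gram @ Xc
        f = np.einsum("kj,kj->j", Xc, GX) - 2.0 * np.einsum("kj,kj->j", ne.rhs[:, cols], Xc)
        prev = f_prev[cols]
        slack = 1e-12 * np.maximum(1.0, np.abs(np.where(np.isfinite(prev), prev, 0.0)))
        stalled = f >= prev - slack
        stall[cols] = np.where(stalled, stall[cols] + 1, 0)
        single_mode[cols] |= stall[cols] >= 2
        f_prev[cols] = f

        for jj, col in enumerate(cols):
            if any_viol[jj]:
                neg = np.flatnonzero(viol[:, jj])
                if single_mode[col]:
                    neg = neg[[int(np.argmin(Xc[neg, jj]))]]
                codes[neg, col] = 1
                X[neg, col] = 0.0
                continue
            # feasible: KKT.  Half-gradient w = gram q - rhs equals the
            # multiplier lambda on every passive entry; clamped entries
            # need w_k - lambda >= 0 to stay clamped.
            w = GX[:, jj] - ne.rhs[:, col]
            sup = cc[:, jj] == 0
            lam = float(w[sup].mean())
            clamped = np.flatnonzero(cc[:, jj] == 1)
            mu = w[clamped] - lam
            rel = clamped[mu < -tol]
            if rel.size == 0:
                active[col] = False
                continue
            if single_mode[col]:
                rel = rel[[int(np.argmin(mu[mu < -tol]))]]
            codes[rel, col] = 0

    return X
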