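"""Constrained sparse-group-lasso solver for log-contrast regression.

The estimator minimizes

    (1/2n) ||y - Z b - Z~ b~||_2^2
        + lam * ( ||b||_1 + ||b~||_1 + sum_v ||b* o M_v||_2 / ||M_v||_1 )

subject to sum(b) = 0 and (when knockoffs are present) sum(b~) = 0, where
b* stacks (b, b~) and the groups M_v come from the taxonomic tree.  With
no knockoff block it is the tree lasso; with no groups it is the
compositional (constrained) lasso; with neither, a plain constrained
lasso with knockoffs.

The optimizer is a two-block ADMM: one block solves the smooth quadratic
under the zero-sum equality constraints (a KKT linear system, factorized
once per penalty level), the other applies the penalty's proximal
operator.  Because tree groups are laminar, the prox of (L1 + sum of
group norms) is computed *exactly* by composing group soft-thresholding
from leaves to root.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import lu_factor, lu_solve

from .tree_groups import GroupStructure

__all__ = [
    "PenaltySpec",
    "TcvsFit",
    "objective",
    "hierarchical_prox",
    "fit",
    "lambda_max",
    "constrained_ols_refit",
]

ZERO_TOL = 1e-8  # coefficients below this magnitude are reported as exact zeros


@dataclass
class PenaltySpec:
    """Penalty level, tree groups, and zero-sum constraint blocks.

    ``constraint_blocks`` lists disjoint index sets over the penalized
    coefficients, each required to sum to zero; ``None`` means they are
    derived from the design (one block per original/knockoff half).
    ``weight_mode`` selects the group-norm divisor: the group size
    (as the objective is stated) or its square root.
    """

    lam: float
    groups: GroupStructure | None = None
    constraint_blocks: list[np.ndarray] | None = None
    weight_mode: str = "size"

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lambda must be non-negative")
        if self.weight_mode not in ("size", "sqrt_size"):
            raise ValueError("weight_mode must be 'size' or 'sqrt_size'")
        if self.constraint_blocks is not None:
            seen: set[int] = set()
            for blk in self.constraint_blocks:
                b = set(np.asarray(blk).tolist())
                if b & seen:
                    raise ValueError("constraint blocks must be disjoint")
                seen |= b


@dataclass
class TcvsFit:
    """Solution of one penalized fit."""

    beta: np.ndarray
    beta_tilde: np.ndarray | None
    intercept: float
    lam: float
    objective_trace: np.ndarray
    converged: bool
    constraint_violation: float
    n_iter: int
    covariate_coefs: np.ndarray | None = None
    rss: float = field(default=np.nan)


def _group_threshold(weight: int, weight_mode: str) -> float:
    return float(weight) if weight_mode == "size" else float(np.sqrt(weight))


def penalty_value(coeffs: np.ndarray, spec: PenaltySpec,
                  l1_mask: np.ndarray | None = None) -> float:
    """lam * (L1 + weighted group norms) for a coefficient vector."""
    c = np.asarray(coeffs, dtype=float)
    mask = np.ones(c.shape, dtype=bool) if l1_mask is None else l1_mask
    val = float(np.abs(c[mask]).sum())
    if spec.groups is not None:
        idx_list = spec.groups.member_indices()
        for g, idx in zip(spec.groups.groups, idx_list):
            sub = c[idx]
            val += float(np.sqrt(sub @ sub)) / _group_threshold(g.weight, spec.weight_mode)
    return spec.lam * val


def objective(y: np.ndarray, design: np.ndarray, coeffs: np.ndarray,
              spec: PenaltySpec, l1_mask: np.ndarray | None = None) -> float:
    """(1/2n)||y - D c||^2 plus the penalty; dimensions must agree."""
    y = np.asarray(y, dtype=float).ravel()
    D = np.asarray(design, dtype=float)
    c = np.asarray(coeffs, dtype=float).ravel()
    if D.shape != (y.size, c.size):
        raise ValueError(
            f"design {D.shape} inconsistent with y ({y.size}) and coeffs ({c.size})"
        )
    r = y - D @ c
    return float(r @ r) / (2 * y.size) + penalty_value(c, spec, l1_mask)


def hierarchical_prox(u: np.ndarray, groups: GroupStructure | None, tau: float,
                      l1_mask: np.ndarray | None = None,
                      weight_mode: str = "size") -> np.ndarray:
    """Exact prox of tau*(||.||_1 + sum_v ||. o m_v||_2 / w_v) for laminar groups.

    Valid because tree-nested (laminar) group structures admit the prox
    as a composition of per-group soft-thresholdings applied leaf-to-root;
    the L1 term is the singleton-leaf level and goes first.
    """
    b = np.asarray(u, dtype=float).copy()
    if tau < 0:
        raise ValueError("tau must be non-negative")
    mask = np.ones(b.shape, dtype=bool) if l1_mask is None else l1_mask
    b[mask] = np.sign(b[mask]) * np.maximum(np.abs(b[mask]) - tau, 0.0)
    if groups is not None:
        if b.shape[0] < groups.p:
            raise ValueError("coefficient dimension smaller than group dimension")
        # ascending subtree size == leaf-to-root for a laminar family
        order = sorted(range(len(groups.groups)), key=lambda i: groups.groups[i].weight)
        idx_list = groups.member_indices()
        for i in order:
            g = groups.groups[i]
            idx = idx_list[i]
            thr = tau / _group_threshold(g.weight, weight_mode)
            sub = b[idx]
            nrm = float(np.sqrt(sub @ sub))
            b[idx] = 0.0 if nrm <= thr else sub * (1.0 - thr / nrm)
    return b


def lambda_max(y: np.ndarray, design: np.ndarray,
               l1_mask: np.ndarray | None = None) -> float:
    """Smallest penalty level at which the all-zero model is stationary.

    Computed from the centered data's gradient at zero; an upper bound in
    the presence of the zero-sum constraint (whose multiplier can only
    loosen it), so the null model is guaranteed at this level.
    """
    y = np.asarray(y, dtype=float).ravel()
    D = np.asarray(design, dtype=float)
    yc = y - y.mean()
    Dc = D - D.mean(axis=0)
    grad = np.abs(Dc.T @ yc) / y.size
    if l1_mask is not None:
        grad = grad[l1_mask]
    return float(grad.max())


class _KktSolver:
    """Factorized KKT system for the smooth + equality-constraint block."""

    def __init__(self, DtD_over_n: np.ndarray, Dty_over_n: np.ndarray,
                 blocks: list[np.ndarray]):
        self.Q = DtD_over_n
        self.b0 = Dty_over_n
        m = DtD_over_n.shape[0]
        k = len(blocks)
        A = np.zeros((k, m))
        for i, blk in enumerate(blocks):
            A[i, blk] = 1.0
        self.A = A
        self.m, self.k = m, k
        self.rho = None
        self._lu = None

    def set_rho(self, rho: float) -> None:
        if self.rho == rho and self._lu is not None:
            return
        K = np.zeros((self.m + self.k, self.m + self.k))
        K[: self.m, : self.m] = self.Q + rho * np.eye(self.m)
        K[: self.m, self.m :] = self.A.T
        K[self.m :, : self.m] = self.A
        self._lu = lu_factor(K)
        self.rho = rho

    def solve(self, v: np.ndarray, rho: float) -> np.ndarray:
        """argmin (1/2) x'Qx - b0'x + (rho/2)||x - v||^2  s.t.  A x = 0."""
        self.set_rho(rho)
        rhs = np.concatenate([self.b0 + rho * v, np.zeros(self.k)])
        return lu_solve(self._lu, rhs)[: self.m]


def fit(
    y: np.ndarray,
    Z: np.ndarray,
    Z_tilde: np.ndarray | None = None,
    spec: PenaltySpec | None = None,
    covariates: np.ndarray | None = None,
    *,
    rho: float = 1.0,
    max_iter: int = 10000,
    eps_rel: float = 1e-6,
    eps_abs: float = 1e-9,
    over_relax: float = 1.7,
    warm_start: np.ndarray | None = None,
) -> TcvsFit:
    """Solve the constrained penalized regression by two-block ADMM.

    The intercept is handled by centering y and all design columns and is
    never penalized or constrained.  Covariate columns are appended
    unpenalized and excluded from constraint blocks and groups.  Returns
    a fit whose constraint blocks are satisfied to 1e-6 at convergence;
    non-convergence is reported via ``converged=False`` with a warning.
    """
    if spec is None:
        raise ValueError("a PenaltySpec is required")
    y = np.asarray(y, dtype=float).ravel()
    Z = np.asarray(Z, dtype=float)
    n, p = Z.shape
    parts = [Z]
    if Z_tilde is not None:
        Z_tilde = np.asarray(Z_tilde, dtype=float)
        if Z_tilde.shape != Z.shape:
            raise ValueError("Z_tilde must match the shape of Z")
        parts.append(Z_tilde)
    n_pen = sum(part.shape[1] for part in parts)
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        parts.append(C)
    D = np.hstack(parts)
    m = D.shape[1]

    if spec.groups is not None and spec.groups.p != n_pen:
        raise ValueError(
            f"group structure spans {spec.groups.p} coefficients but the "
            f"penalized design has {n_pen}"
        )

    l1_mask = np.zeros(m, dtype=bool)
    l1_mask[:n_pen] = True
    if spec.constraint_blocks is not None:
        blocks = [np.asarray(b, dtype=int) for b in spec.constraint_blocks]
    else:
        blocks = [np.arange(p)]
        if Z_tilde is not None:
            blocks.append(np.arange(p, 2 * p))

    ybar = y.mean()
    yc = y - ybar
    col_means = D.mean(axis=0)
    Dc = D - col_means

    kkt = _KktSolver(Dc.T @ Dc / n, Dc.T @ yc / n, blocks)
    z = np.zeros(m) if warm_start is None else np.asarray(warm_start, dtype=float).copy()
    u = np.zeros(m)
    tau_base = spec.lam
    sqrt_m = np.sqrt(m)

    def obj(c: np.ndarray) -> float:
        r = yc - Dc @ c
        return float(r @ r) / (2 * n) + penalty_value(c, spec, l1_mask)

    trace = [obj(z)]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        x = kkt.solve(z - u, rho)
        x_hat = over_relax * x + (1 - over_relax) * z
        z_prev = z
        z = hierarchical_prox(x_hat + u, spec.groups, tau_base / rho,
                              l1_mask=l1_mask, weight_mode=spec.weight_mode)
        u = u + x_hat - z
        trace.append(min(trace[-1], obj(z)))

        r_norm = float(np.linalg.norm(x - z))
        s_norm = float(rho * np.linalg.norm(z - z_prev))
        eps_pri = sqrt_m * eps_abs + eps_rel * max(np.linalg.norm(x), np.linalg.norm(z))
        eps_dual = sqrt_m * eps_abs + eps_rel * rho * float(np.linalg.norm(u))
        viol = max((abs(float(z[blk].sum())) for blk in blocks), default=0.0)
        if r_norm <= eps_pri and s_norm <= eps_dual and viol <= 1e-6:
            converged = True
            break
        if it % 10 == 0:  # residual balancing keeps both residuals comparable
            if r_norm > 10 * s_norm:
                rho *= 2.0
                u /= 2.0
            elif s_norm > 10 * r_norm:
                rho /= 2.0
                u *= 2.0

    if not converged:
        warnings.warn(f"ADMM did not converge in {max_iter} iterations (lam={spec.lam:g})")

    coeffs = z.copy()
    coeffs[np.abs(coeffs) < ZERO_TOL] = 0.0
    viol = max((abs(float(coeffs[blk].sum())) for blk in blocks), default=0.0)
    beta = coeffs[:p]
    beta_tilde = coeffs[p : 2 * p] if Z_tilde is not None else None
    cov_coefs = coeffs[n_pen:] if covariates is not None else None
    resid = yc - Dc @ coeffs
    intercept = float(ybar - col_means @ coeffs)
    return TcvsFit(
        beta=beta,
        beta_tilde=beta_tilde,
        intercept=intercept,
        lam=spec.lam,
        objective_trace=np.asarray(trace),
        converged=converged,
        constraint_violation=viol,
        n_iter=it,
        covariate_coefs=cov_coefs,
        rss=float(resid @ resid),
    )


def constrained_ols_refit(y: np.ndarray, Z_S: np.ndarray,
                          ridge: float = 0.0) -> np.ndarray:
    """Least squares on the selected columns under sum(beta) = 0 (KKT closed form).

    With one or zero columns the constraint forces beta = 0 (warned); a
    singular KKT system is ridge-stabilized with 1e-8 and warned about.
    """
    y = np.asarray(y, dtype=float).ravel()
    Z_S = np.asarray(Z_S, dtype=float)
    if Z_S.ndim == 1:
        Z_S = Z_S[:, None]
    n, k = Z_S.shape
    if k <= 1:
        warnings.warn("fewer than two selected taxa: zero-sum constraint forces beta = 0")
        return np.zeros(k)
    K = np.zeros((k + 1, k + 1))
    K[:k, :k] = Z_S.T @ Z_S / n + ridge * np.eye(k)
    K[:k, k] = 1.0
    K[k, :k] = 1.0
    rhs = np.concatenate([Z_S.T @ y / n, [0.0]])
    try:
        sol = np.linalg.solve(K, rhs)
    except np.linalg.LinAlgError:
        sol = None
    if sol is None or not np.all(np.isfinite(sol)):
        warnings.warn("singular KKT system in constrained refit; ridge-stabilizing")
        K[:k, :k] += 1e-8 * np.eye(k)
        sol = np.linalg.solve(K, rhs)
    beta = sol[:k]
    return beta - beta.mean()  # exact constraint up to machine precision
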