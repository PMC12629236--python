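"""Independent convex-programming oracles used only by the test suite.

Two deliberately different algorithms from the package's ADMM +
leaf-to-root composed prox:

* ``oracle_prox`` solves the proximal problem of the (L1 + weighted
  group-norm) penalty by consensus ADMM with one duplicated variable per
  group — no laminar ordering is used, so it is valid for arbitrary
  (including overlapping) groups and serves as ground truth for the
  hierarchical composition.
* ``oracle_fit_objective`` solves the full constrained sparse-group-lasso
  program with scipy's SLSQP on a smooth reformulation: positive/negative
  coefficient splits make the L1 term linear, group norms are smoothed by
  sqrt(||.||^2 + eps^2) with negligible eps, and the zero-sum constraints
  enter as exact linear equalities.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize


def oracle_prox(
    u: np.ndarray,
    group_indices: list[np.ndarray],
    group_weights: list[float],
    tau: float,
    l1_mask: np.ndarray | None = None,
    max_iter: int = 200_000,
    tol: float = 1e-13,
) -> np.ndarray:
    """argmin_b 0.5||b-u||^2 + tau(||b_mask||_1 + sum_g ||b_g||/w_g).

    Consensus ADMM with duplicated per-group variables; the quadratic
    coupling term is strongly convex so convergence is linear and the
    returned point is accurate to roughly the stopping tolerance.
    """
    u = np.asarray(u, dtype=float)
    m = u.size
    mask = np.ones(m, dtype=bool) if l1_mask is None else np.asarray(l1_mask, bool)
    # treat the L1 term as singleton groups with weight 1
    idx_all = [np.array([k]) for k in range(m) if mask[k]]
    w_all = [1.0] * len(idx_all)
    idx_all += [np.asarray(g, dtype=int) for g in group_indices]
    w_all += [float(w) for w in group_weights]
    counts = np.zeros(m)
    for g in idx_all:
        counts[g] += 1.0

    rho = 1.0
    c = [u[g].copy() for g in idx_all]  # one duplicated variable per group
    dual = [np.zeros(len(g)) for g in idx_all]
    b = u.copy()
    denom = 1.0 + rho * counts
    for _ in range(max_iter):
        acc = u.copy()
        for g, cg, lg in zip(idx_all, c, dual):
            acc[g] += rho * cg - lg
        b = acc / denom
        max_change = 0.0
        for i, g in enumerate(idx_all):
            v = b[g] + dual[i] / rho
            thr = tau / (w_all[i] * rho)
            nrm = float(np.linalg.norm(v))
            cg_new = np.zeros_like(v) if nrm <= thr else v * (1.0 - thr / nrm)
            dual[i] = dual[i] + rho * (b[g] - cg_new)
            max_change = max(max_change, float(np.max(np.abs(cg_new - c[i]))),
                             float(np.max(np.abs(b[g] - cg_new))))
            c[i] = cg_new
        if max_change < tol:
            break
    return b


def prox_objective(b, u, group_indices, group_weights, tau, l1_mask=None):
    b = np.asarray(b, float)
    mask = np.ones(b.size, dtype=bool) if l1_mask is None else l1_mask
    val = 0.5 * float(np.sum((b - u) ** 2)) + tau * float(np.abs(b[mask]).sum())
    for g, w in zip(group_indices, group_weights):
        val += tau * float(np.linalg.norm(b[g])) / w
    return val


def oracle_fit_objective(
    y: np.ndarray,
    D: np.ndarray,
    lam: float,
    group_indices: list[np.ndarray],
    group_weights: list[float],
    constraint_blocks: list[np.ndarray],
    eps: float = 1e-10,
    maxiter: int = 2000,
) -> tuple[float, np.ndarray]:
    """Solve the centered constrained sparse-group lasso with SLSQP.

    Returns (objective value at the solution, coefficient vector), where
    the objective is evaluated exactly (unsmoothed).  Inputs are assumed
    already centered.
    """
    y = np.asarray(y, float).ravel()
    D = np.asarray(D, float)
    n, m = D.shape

    def split_obj(xz):
        bp, bn = xz[:m], xz[m:]
        b = bp - bn
        r = y - D @ b
        val = float(r @ r) / (2 * n) + lam * float(np.sum(bp) + np.sum(bn))
        grad_b = -D.T @ r / n
        gp = grad_b + lam
        gn = -grad_b + lam
        for g, w in zip(group_indices, group_weights):
            sub = b[g]
            nrm = np.sqrt(float(sub @ sub) + eps * eps)
            val += lam * nrm / w
            gsub = lam * sub / (nrm * w)
            gp[g] += gsub
            gn[g] -= gsub
        return val, np.concatenate([gp, gn])

    A = np.zeros((len(constraint_blocks), 2 * m))
    for i, blk in enumerate(constraint_blocks):
        A[i, blk] = 1.0
        A[i, np.asarray(blk) + m] = -1.0
    x0 = np.zeros(2 * m)
    res = minimize(
        split_obj, x0, jac=True, method="SLSQP",
        bounds=[(0, None)] * (2 * m),
        constraints=[{"type": "eq", "fun": lambda x: A @ x, "jac": lambda x: A}]
        if len(constraint_blocks) else [],
        options={"maxiter": maxiter, "ftol": 1e-14},
    )
    b = res.x[:m] - res.x[m:]
    # exact (unsmoothed) objective at the oracle solution
    r = y - D @ b
    val = float(r @ r) / (2 * n) + lam * float(np.abs(b).sum())
    for g, w in zip(group_indices, group_weights):
        val += lam * float(np.linalg.norm(b[g])) / w
    return val, b
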