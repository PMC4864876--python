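"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: pruning is verified by
exhaustive subset enumeration, REML by direct 2-parameter likelihood
maximization without the eigendecomposition trick.
"""

import numpy as np
from scipy import optimize


def pairwise_r2_matrix(dosages: np.ndarray) -> np.ndarray:
    """Dense r^2 matrix by direct per-pair Pearson correlation."""
    m = dosages.shape[1]
    r2 = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            r = np.corrcoef(dosages[:, i], dosages[:, j])[0, 1]
            r2[i, j] = r2[j, i] = r * r
    return r2


def exhaustive_prune(r2: np.ndarray, order: list[int], window: int, r2_max: float):
    """Lexicographically-first (in visiting order) maximal admissible variant
    set, by enumeration of all subsets.

    A set is admissible when every within-window pair has r^2 <= r2_max;
    maximal when no variant can be added.  For a conflict-graph independence
    system the greedy scan returns exactly this set, so it serves as the
    oracle for the clumping implementation.
    """
    m = r2.shape[0]
    conflict = np.zeros(m, dtype=int)
    for i in range(m):
        for j in range(m):
            if i != j and abs(i - j) <= window and r2[i, j] > r2_max:
                conflict[i] |= 1 << j
    admissible = []
    for mask in range(1 << m):
        ok = True
        mm = mask
        while mm:
            i = (mm & -mm).bit_length() - 1
            if conflict[i] & mask:
                ok = False
                break
            mm &= mm - 1
        if ok:
            admissible.append(mask)
    adm = set(admissible)
    rank = {v: k for k, v in enumerate(order)}
    best = None
    for mask in admissible:
        # maximal: no single variant can be added
        if any(
            not (mask >> v & 1) and (mask | (1 << v)) in adm for v in range(m)
        ):
            continue
        key = tuple(sorted(rank[v] for v in range(m) if mask >> v & 1))
        if best is None or key < best[0]:
            best = (key, mask)
    return sorted(v for v in range(m) if best[1] >> v & 1)


def direct_reml(y: np.ndarray, X: np.ndarray, A: np.ndarray):
    """2-parameter REML by Nelder-Mead on (log sigma2_g, log sigma2_e),
    with explicit determinants and solves (no eigen-rotation)."""
    n, p = X.shape

    def nll(theta):
        sg, se = np.exp(theta)
        V = sg * A + se * np.eye(n)
        sign, logdetV = np.linalg.slogdet(V)
        Vi = np.linalg.inv(V)
        XtViX = X.T @ Vi @ X
        b = np.linalg.solve(XtViX, X.T @ Vi @ y)
        r = y - X @ b
        return 0.5 * (logdetV + np.linalg.slogdet(XtViX)[1] + r @ Vi @ r)

    res = optimize.minimize(
        nll, [np.log(np.var(y) / 2 + 1e-3)] * 2, method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 4000},
    )
    sg, se = np.exp(res.x)
    return float(sg), float(se)


def sibship_matrix(n_families: int, family_size: int) -> np.ndarray:
    """Block-diagonal full-sib relationship matrix."""
    n = n_families * family_size
    A = np.zeros((n, n))
    for f in range(n_families):
        s = slice(f * family_size, (f + 1) * family_size)
        A[s, s] = 0.5
    np.fill_diagonal(A, 1.0)
    return A
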