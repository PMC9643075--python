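"""Independent brute-force oracles used to validate the estimators.

Every function here deliberately recomputes a quantity by a different
route than the package (direct density evaluation, nested grid zoom,
path enumeration, hand-rolled normal equations, Newton on the Bernoulli
likelihood) so that agreement is evidence of correctness rather than of
shared code.
"""

import numpy as np
from scipy.special import expit


def mvn_loglik_direct(y, mu, sigma2, V):
    """Direct multivariate-normal log-density via slogdet and inv."""
    n = len(y)
    S = sigma2 * V
    sign, logdet = np.linalg.slogdet(S)
    if sign <= 0:
        return -np.inf
    r = y - mu
    return float(-0.5 * (n * np.log(2 * np.pi) + logdet
                         + r @ np.linalg.inv(S) @ r))


def gridsearch_mvn_loglik(y, V, rounds=8, width=41):
    """Max over (μ, σ²) of the MVN log-density by iterative grid zoom.

    Independent of the closed-form GLS profile: searches a 2-D grid for
    the optimum, zooming in around the best point each round.
    """
    y = np.asarray(y, float)
    mu_lo, mu_hi = y.min() - 3 * y.std(), y.max() + 3 * y.std()
    s2_lo, s2_hi = 1e-6 * y.var(), 10 * y.var()
    best = (-np.inf, None, None)
    for _ in range(rounds):
        mus = np.linspace(mu_lo, mu_hi, width)
        s2s = np.linspace(s2_lo, s2_hi, width)
        for m in mus:
            for s2 in s2s:
                ll = mvn_loglik_direct(y, m, s2, V)
                if ll > best[0]:
                    best = (ll, m, s2)
        dm = (mu_hi - mu_lo) / (width - 1)
        ds = (s2_hi - s2_lo) / (width - 1)
        mu_lo, mu_hi = best[1] - 2 * dm, best[1] + 2 * dm
        s2_lo, s2_hi = max(best[2] - 2 * ds, 1e-12), best[2] + 2 * ds
    return best


def covariance_by_path_enumeration(tree):
    """C[i,j] as the summed edge lengths shared by the two root-to-tip
    paths, enumerated tip pair by tip pair."""
    leaves = list(tree.leaf_node_iter())
    labels = [lf.taxon.label for lf in leaves]
    n = len(leaves)

    def root_path(node):
        path = []
        while node is not None:
            path.append(node)
            node = node.parent_node
        return path[::-1]  # root first

    paths = [root_path(lf) for lf in leaves]
    C = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            shared = 0.0
            for a, b in zip(paths[i], paths[j]):
                if a is not b:
                    break
                shared += a.edge.length or 0.0
            C[i, j] = shared
    return labels, C


def binary_logistic_newton(X, y, tol=1e-12, max_iter=100):
    """Newton–Raphson MLE for P(y=1) = logistic(c + Xb).

    Returns the parameter vector (c, b).  This is the K = 2 oracle: the
    proportional-odds model with one threshold satisfies b = β and
    c = −ζ₁.
    """
    X = np.column_stack((np.ones(len(y)), np.asarray(X, float)))
    y = np.asarray(y, float)
    theta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        p = expit(X @ theta)
        g = X.T @ (y - p)
        W = p * (1 - p)
        H = X.T @ (X * W[:, None])
        step = np.linalg.solve(H, g)
        theta = theta + step
        if np.max(np.abs(step)) < tol:
            break
    return theta


def ols_residuals_normal_equations(x, y):
    """Hand-rolled simple-regression residuals via the 2×2 normal
    equations solved in closed form."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    sx, sy = x.sum(), y.sum()
    sxx, sxy = (x * x).sum(), (x * y).sum()
    det = n * sxx - sx * sx
    b0 = (sxx * sy - sx * sxy) / det
    b1 = (n * sxy - sx * sy) / det
    return y - (b0 + b1 * x)


def greedy_vif_elimination(X, threshold):
    """Independent greedy collinearity screen.

    Uses a different VIF route than the package: VIF_j is read off the
    diagonal of the inverse correlation matrix of the retained columns.
    """
    cols = list(X.columns)
    Xv = X.astype(float)
    while len(cols) >= 2:
        R = np.corrcoef(Xv[cols].to_numpy(), rowvar=False)
        A = np.abs(R - np.eye(len(cols)))
        i, j = np.unravel_index(np.argmax(A), A.shape)
        if A[i, j] < threshold:
            break
        vif = np.diag(np.linalg.inv(R))
        if vif[i] > vif[j]:
            drop = i
        elif vif[j] > vif[i]:
            drop = j
        else:
            drop = max(i, j)
        cols.pop(drop)
    return cols


def proximal_by_sorting(wing_mask, body_mask, fraction):
    """Brute-force proximal-wing selection: explicit per-pixel distances
    to every body pixel, sorted, per connected component (BFS labelling)."""
    import collections
    H, W = wing_mask.shape
    body_px = np.argwhere(body_mask)
    seen = np.zeros_like(wing_mask)
    out = np.zeros_like(wing_mask)
    for r0 in range(H):
        for c0 in range(W):
            if not wing_mask[r0, c0] or seen[r0, c0]:
                continue
            comp = []
            q = collections.deque([(r0, c0)])
            seen[r0, c0] = True
            while q:
                r, c = q.popleft()
                comp.append((r, c))
                for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    rr, cc = r + dr, c + dc
                    if (0 <= rr < H and 0 <= cc < W and wing_mask[rr, cc]
                            and not seen[rr, cc]):
                        seen[rr, cc] = True
                        q.append((rr, cc))
            dists = []
            for (r, c) in comp:
                d = np.sqrt(((body_px[:, 0] - r) ** 2
                             + (body_px[:, 1] - c) ** 2)).min()
                dists.append((d, r * W + c, (r, c)))
            dists.sort()
            keep = int(np.ceil(fraction * len(comp)))
            for _, _, (r, c) in dists[:keep]:
                out[r, c] = True
    return out
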