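"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (explicit loops, exhaustive search)
and shares no code with the package.
"""

import math

import numpy as np


def skld_bruteforce(w, d, epsilon=1e-12):
    """Definitional KL(p||q) + KL(q||p) with explicit python loops."""
    w = [float(x) for x in w]
    d = [float(x) for x in d]
    p = [x / sum(w) for x in w]
    q = [x / sum(d) for x in d]
    p = [max(x, epsilon) for x in p]
    q = [max(x, epsilon) for x in q]
    p = [x / sum(p) for x in p]
    q = [x / sum(q) for x in q]
    kl_pq = sum(pi * math.log(pi / qi) for pi, qi in zip(p, q))
    kl_qp = sum(qi * math.log(qi / pi) for pi, qi in zip(p, q))
    return kl_pq + kl_qp


def assign_bruteforce(panel_values, labels, W, epsilon=1e-12):
    """Exhaustive (reference, factor) SKLD table with independent argmin
    logic.  Returns (winner index per label, chosen columns, column labels)."""
    n_ref = panel_values.shape[1]
    n_col = W.shape[1]
    D = [
        [skld_bruteforce(panel_values[:, i], W[:, j], epsilon) for j in range(n_col)]
        for i in range(n_ref)
    ]
    winners = {}
    for i, lab in enumerate(labels):
        best_j, best_d = 0, D[i][0]
        for j in range(1, n_col):
            if D[i][j] < best_d:
                best_j, best_d = j, D[i][j]
        winners[lab] = best_j
    chosen = sorted(set(winners.values()))
    col_labels = []
    for j in chosen:
        claim = [(D[i][j], i) for i, lab in enumerate(labels) if winners[lab] == j]
        col_labels.append(labels[min(claim)[1]])
    return winners, chosen, col_labels


def nnls_grid_search(G, y, resolution=1e-3, points=21):
    """Convex objective minimized by iteratively refined exhaustive grids.

    The initial box [0, 2||y||/||g_i||] provably contains every optimum of
    min_{c>=0} ||y - Gc|| for non-negative G; each pass shrinks the box
    around the incumbent until the spacing reaches ``resolution``.
    """
    G = np.asarray(G, float)
    y = np.asarray(y, float)
    k = G.shape[1]
    hi = 2.0 * np.linalg.norm(y) / np.linalg.norm(G, axis=0)
    lo = np.zeros(k)
    while True:
        axes = [np.linspace(lo[i], max(hi[i], lo[i] + 1e-12), points) for i in range(k)]
        mesh = np.stack(np.meshgrid(*axes, indexing="ij"), -1).reshape(-1, k)
        resid = mesh @ G.T - y
        best = mesh[np.argmin(np.einsum("ij,ij->i", resid, resid))]
        spacing = np.array([a[1] - a[0] for a in axes])
        if spacing.max() <= resolution:
            return best
        lo = np.maximum(best - 1.5 * spacing, 0.0)
        hi = best + 1.5 * spacing
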