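"""Independent brute-force oracles used by the test suite.

Each routine deliberately avoids the implementation path it checks: the
mixture likelihood is maximized by coordinate grid refinement, stress
centrality by explicit all-pairs path enumeration, and Fisher's exact test
by direct hypergeometric tail summation.
"""

import itertools
from math import comb

import numpy as np
from scipy import stats


def grid_mixture_loglik(y, probs, n_mu=25, n_sigma=14, n_refine=8):
    """Maximum of the 3-component common-sigma mixture log-likelihood by
    dense grid search with iterative refinement."""
    y = np.asarray(y, dtype=float)

    def ll_batch(mus, sig):
        d = probs[None, :, :] * stats.norm.pdf(y[None, :, None],
                                               loc=mus[:, None, :], scale=sig)
        return np.log(d.sum(axis=2)).sum(axis=1)

    lo, hi = y.min() - 1.0, y.max() + 1.0
    gm = np.linspace(lo, hi, n_mu)
    gs = np.linspace(0.25 * y.std(), 1.5 * y.std(), n_sigma)
    M = np.array(np.meshgrid(gm, gm, gm)).reshape(3, -1).T
    best, bp = -np.inf, None
    for s in gs:
        v = ll_batch(M, s)
        i = int(v.argmax())
        if v[i] > best:
            best, bp = float(v[i]), (M[i].copy(), float(s))
    wm, ws = gm[1] - gm[0], gs[1] - gs[0]
    for _ in range(n_refine):
        m, s = bp
        local = [np.linspace(m[j] - wm, m[j] + wm, 7) for j in range(3)]
        M2 = np.array(np.meshgrid(*local)).reshape(3, -1).T
        for ss in np.linspace(max(s - ws, 1e-3), s + ws, 7):
            v = ll_batch(M2, ss)
            i = int(v.argmax())
            if v[i] > best:
                best, bp = float(v[i]), (M2[i].copy(), float(ss))
        wm /= 3.0
        ws /= 3.0
    return best


def brute_force_stress(graph):
    """Stress centrality by enumerating every shortest path between every
    node pair (exponential; n <= ~12 only)."""
    nodes = list(graph.nodes)
    stress = {v: 0 for v in nodes}
    adj = {v: set(graph.neighbors(v)) for v in nodes}

    def all_shortest_paths(s, t):
        # BFS layer by layer, collecting complete paths
        paths = [[s]]
        found = []
        seen_depth = {s: 0}
        while paths and not found:
            nxt = []
            for p in paths:
                for w in adj[p[-1]]:
                    if w in p:
                        continue
                    d = seen_depth.get(w)
                    if d is not None and d < len(p):
                        continue
                    seen_depth[w] = len(p)
                    q = p + [w]
                    if w == t:
                        found.append(q)
                    else:
                        nxt.append(q)
            paths = nxt
        return found

    for i, s in enumerate(nodes):
        for t in nodes[i + 1:]:
            for path in all_shortest_paths(s, t):
                for v in path[1:-1]:
                    stress[v] += 1
    return stress


def hypergeometric_tail(a, b, c, d):
    """One-sided Fisher p for table [[a, b], [c, d]] by direct tail
    summation of the hypergeometric pmf."""
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    denom = comb(n, col1)
    p = 0.0
    for k in range(a, min(row1, col1) + 1):
        if col1 - k > n - row1:
            continue
        p += comb(row1, k) * comb(n - row1, col1 - k) / denom
    return p
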