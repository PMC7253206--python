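"""Independent brute-force oracles shared across test modules.

These deliberately avoid the package's own fitting/centrality code paths:
likelihood maxima come from dense-grid search over the GLM coefficients and
betweenness from exhaustive shortest-path enumeration.
"""

import itertools

import networkx as nx
import numpy as np
from scipy import stats


def grid_max_loglik_two_group(y, is_w, sf, phi, half_width=4.0, n=161):
    """Brute-force max NB2 log-likelihood for mu = sf*exp(b0 + b1*x)."""
    y = np.asarray(y, float)
    x = np.asarray(is_w, float)
    b0c = np.log(max(np.mean(y / sf), 0.5))
    r = 1.0 / phi

    def ll_grid(b0s, b1s):
        eta = (
            b0s[:, None, None]
            + b1s[None, :, None] * x[None, None, :]
            + np.log(sf)[None, None, :]
        )
        mu = np.exp(eta)
        return stats.nbinom.logpmf(y[None, None, :], r, r / (r + mu)).sum(axis=2)

    b0s = np.linspace(b0c - half_width, b0c + half_width, n)
    b1s = np.linspace(-8.0, 8.0, n)
    ll = ll_grid(b0s, b1s)
    i, j = np.unravel_index(np.argmax(ll), ll.shape)
    for _ in range(2):
        w0 = (b0s[1] - b0s[0]) * 2
        w1 = (b1s[1] - b1s[0]) * 2
        b0s = np.linspace(b0s[i] - w0, b0s[i] + w0, n)
        b1s = np.linspace(b1s[j] - w1, b1s[j] + w1, n)
        ll = ll_grid(b0s, b1s)
        i, j = np.unravel_index(np.argmax(ll), ll.shape)
    return float(ll[i, j])


def grid_max_loglik_intercept(y, sf, phi, n=4001):
    """Brute-force max NB2 log-likelihood for the intercept-only model."""
    y = np.asarray(y, float)
    b0c = np.log(max(np.mean(y / sf), 0.5))
    b0s = np.linspace(b0c - 4.0, b0c + 4.0, n)
    r = 1.0 / phi
    mu = np.exp(b0s[:, None] + np.log(sf)[None, :])
    ll = stats.nbinom.logpmf(y[None, :], r, r / (r + mu)).sum(axis=1)
    return float(ll.max())


def brute_force_betweenness(g):
    """Betweenness by enumerating all shortest paths, per component."""
    out = dict.fromkeys(g.nodes, 0.0)
    for comp in nx.connected_components(g):
        nodes = sorted(comp)
        n = len(nodes)
        for s, t in itertools.combinations(nodes, 2):
            paths = list(nx.all_shortest_paths(g, s, t))
            for node in comp:
                if node in (s, t):
                    continue
                out[node] += sum(node in p for p in paths) / len(paths)
        norm = (n - 1) * (n - 2) / 2.0
        for node in nodes:
            out[node] = out[node] / norm if norm > 0 else 0.0
    return out
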