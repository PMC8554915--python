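"""Independent brute-force oracles shared by the unit and acceptance tests.

Each oracle implements a layer's update rule as a literal per-node Python
loop, independent of the vectorised implementation it checks.
"""

import numpy as np

from graphfae.mpnn import (featgraphconv_layer, gcn_mp_layer,
                           graphconv_layer, sage_layer)


def neighbors(g, i):
    return [j for j in range(g.n_nodes) if g.has_edge(i, j)]


def oracle_layer(kind, h, g, weights):
    n, _ = h.shape
    if kind == "gcn":
        (w,) = weights
        deg = np.array([len(neighbors(g, i)) + 1 for i in range(n)])
        out = np.zeros((n, w.shape[1]))
        for i in range(n):
            for j in neighbors(g, i) + [i]:
                out[i] += (w.T @ h[j]) / (np.sqrt(deg[i]) * np.sqrt(deg[j]))
        return out
    if kind == "sage":
        w1, w2 = weights
        out = np.zeros((n, w1.shape[1]))
        for i in range(n):
            closed = neighbors(g, i) + [i]
            mean = np.mean([h[j] for j in closed], axis=0)
            out[i] = w1.T @ h[i] + w2.T @ mean
        return out
    if kind == "graphconv":
        w1, w2 = weights
        out = np.zeros((n, w1.shape[1]))
        for i in range(n):
            out[i] = w1.T @ h[i]
            for j in neighbors(g, i):
                out[i] += w2.T @ h[j]
        return out
    if kind == "featgraphconv":
        w1, w2 = weights
        msg = np.array([w1.T @ h[i] for i in range(n)])
        out = np.zeros((n, w2.shape[1]))
        for i in range(n):
            closed = neighbors(g, i) + [i]
            pooled = np.mean([msg[j] for j in closed], axis=0)
            out[i] = w2.T @ np.concatenate([msg[i], pooled])
        return out
    raise ValueError(kind)


LAYER_FNS = {
    "gcn": lambda h, g, ws: gcn_mp_layer(h, g, *ws),
    "sage": lambda h, g, ws: sage_layer(h, g, *ws),
    "graphconv": lambda h, g, ws: graphconv_layer(h, g, *ws),
    "featgraphconv": lambda h, g, ws: featgraphconv_layer(h, g, *ws),
}


def make_weights(kind, rng, d_in, d_out):
    if kind == "gcn":
        return (rng.standard_normal((d_in, d_out)),)
    if kind == "featgraphconv":
        return (rng.standard_normal((d_in, d_out)),
                rng.standard_normal((2 * d_out, d_out)))
    return (rng.standard_normal((d_in, d_out)),
            rng.standard_normal((d_in, d_out)))
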