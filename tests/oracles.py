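"""Independent scalar-loop oracles for the model and losses.

Everything here is written with explicit Python loops over indices — no
vectorized shortcuts shared with the implementation — so agreement with the
package is a genuine cross-check.
"""

import math


def mat_vec(W, x):
    return [sum(W[r][c] * x[c] for c in range(len(x))) for r in range(len(W))]


def oracle_project(Z, W1):
    return [mat_vec(W1, z) for z in Z]


def oracle_softmax(xs):
    m = max(xs)
    es = [math.exp(x - m) for x in xs]
    s = sum(es)
    return [e / s for e in es]


def oracle_attention(h_rows, Va, Ua, Wa_i):
    """Gated attention distribution over instances, term by term."""
    logits = []
    for h in h_rows:
        v = mat_vec(Va, h)
        u = mat_vec(Ua, h)
        gate = [math.tanh(vj) * (1.0 / (1.0 + math.exp(-uj))) for vj, uj in zip(v, u)]
        logits.append(sum(w * g for w, g in zip(Wa_i, gate)))
    return oracle_softmax(logits)


def oracle_pool(h_rows, a_row):
    dim = len(h_rows[0])
    return [sum(a_row[k] * h_rows[k][j] for k in range(len(h_rows))) for j in range(dim)]


def oracle_forward(Z, params):
    """Full end-to-end forward: returns (a per class, h_slide, s, probs, p_inst)."""
    W1 = params.W1.tolist()
    Va = params.Va.tolist()
    Ua = params.Ua.tolist()
    Wa = params.Wa.tolist()
    Wc = params.Wc.tolist()
    Winst = params.Winst.tolist()
    h_rows = oracle_project(Z.tolist(), W1)
    n = len(Wa)
    a, h_slide, s = [], [], []
    for i in range(n):
        ai = oracle_attention(h_rows, Va, Ua, Wa[i])
        hi = oracle_pool(h_rows, ai)
        a.append(ai)
        h_slide.append(hi)
        s.append(sum(Wc[i][j] * hi[j] for j in range(len(hi))))
    probs = oracle_softmax(s)
    p_inst = [[mat_vec(Winst[i], h) for h in h_rows] for i in range(n)]
    return a, h_slide, s, probs, p_inst


def oracle_hinge(s, y, alpha):
    worst = max(s[j] + alpha for j in range(len(s)) if j != y)
    return max(worst - s[y], 0.0)


def oracle_smooth(s, y, alpha, tau):
    terms = [
        (alpha * (1 if j != y else 0) + s[j] - s[y]) / tau for j in range(len(s))
    ]
    m = max(terms)
    return tau * (m + math.log(sum(math.exp(t - m) for t in terms)))


def oracle_cross_entropy(s, y):
    return -math.log(oracle_softmax(list(s))[y])
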