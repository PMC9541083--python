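"""Independent brute-force oracles used to validate the implementation.

Everything here recomputes quantities by direct enumeration, staying
independent of the code paths under test.
"""

from fractions import Fraction
from itertools import combinations
from math import comb, sqrt


def edge_list(net):
    return [(u, v, w) for u, v, w in net.edges()]


def brute_cluster_terms(C, net):
    """(cohesiveness, density, awm) by direct edge enumeration."""
    C = set(C)
    w_in = w_out = 0.0
    n_in = n_border = 0
    for u, v, w in edge_list(net):
        inside = (u in C) + (v in C)
        if inside == 2:
            w_in += w
            n_in += 1
        elif inside == 1:
            w_out += w
            n_border += 1
    coh = w_in / (w_in + w_out) if w_in + w_out > 0 else 0.0
    n = len(C)
    dens = 2 * w_in / (n * (n - 1)) if n >= 2 else 0.0
    aiew = w_in / n_in if n_in else 0.0
    abew = w_out / n_border if n_border else 0.0
    a = aiew / (aiew + abew) if aiew + abew > 0 else 0.0
    return coh, dens, a


def brute_fitness(C, net):
    return sum(brute_cluster_terms(C, net))


def brute_wcc(p, net):
    ln = net.neighbors(p) | {p}
    if len(ln) < 2:
        return 0.0
    total = sum(w for u, v, w in edge_list(net) if u in ln and v in ln)
    return 2 * total / (sqrt(len(ln)) * (len(ln) - 1))


def exact_hypergeom_upper(k, n_universe, n_group, n_draw):
    """P(X >= k) with exact rational arithmetic."""
    if k <= 0:
        return 1.0
    total = Fraction(0)
    denom = comb(n_universe, n_draw)
    for i in range(k):
        if n_draw - i <= n_universe - n_group and i <= n_group:
            total += Fraction(comb(n_group, i) * comb(n_universe - n_group, n_draw - i), denom)
    return float(1 - total)


# -- metric oracles (direct loops over complex pairs) -----------------------

def na(a, b):
    inter = len(set(a) & set(b))
    return inter * inter / (len(a) * len(b))


def brute_f_measure(S, D, omega=0.2):
    n_sm = sum(1 for s in S if any(na(s, d) >= omega for d in D))
    n_im = sum(1 for d in D if any(na(d, s) >= omega for s in S))
    recall = n_sm / len(S)
    precision = n_im / len(D)
    if precision + recall == 0:
        return precision, recall, 0.0
    return precision, recall, 2 * precision * recall / (precision + recall)


def brute_acc(S, D):
    sn_num = sum(max(len(set(s) & set(d)) for d in D) for s in S)
    sn_den = sum(len(s) for s in S)
    ppv_num = sum(max(len(set(s) & set(d)) for s in S) for d in D)
    ppv_den = sum(len(set(s) & set(d)) for s in S for d in D)
    sn = sn_num / sn_den if sn_den else 0.0
    ppv = ppv_num / ppv_den if ppv_den else 0.0
    return sn, ppv, sqrt(sn * ppv)


def brute_mmr(S, D):
    return sum(max(na(s, d) for d in D) for s in S) / len(S)


def brute_frac(S, D, omega=0.25):
    return sum(1 for s in S if any(na(s, d) >= omega for d in D)) / len(S)


def brute_jaccard(S, D):
    def jac(a, b):
        a, b = set(a), set(b)
        return len(a & b) / len(a | b)

    jd = sum(len(d) * max(jac(d, s) for s in S) for d in D) / sum(len(d) for d in D)
    js = sum(len(s) * max(jac(s, d) for d in D) for s in S) / sum(len(s) for s in S)
    if jd + js == 0:
        return 0.0
    return 2 * jd * js / (jd + js)
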