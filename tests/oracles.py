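"""Independent brute-force references for the screening mathematics.

Everything here is deliberately written in plain Python (lists, loops,
math module) with no reliance on the package's vectorised code paths, so
agreement between the two is evidence, not tautology.
"""

from __future__ import annotations

import math


def cos(u, v):
    nu = math.sqrt(sum(x * x for x in u))
    nv = math.sqrt(sum(x * x for x in v))
    if nu == 0.0 or nv == 0.0:
        return -1.0
    return sum(a * b for a, b in zip(u, v)) / (nu * nv)


def mean(vectors):
    n = len(vectors)
    return [sum(v[i] for v in vectors) / n for i in range(len(vectors[0]))]


def euclid(u, v):
    return math.sqrt(sum((a - b) ** 2 for a, b in zip(u, v)))


def sq_dist(u, v):
    return sum((a - b) ** 2 for a, b in zip(u, v))


def normalised_mean(vectors):
    kept = []
    for v in vectors:
        n = math.sqrt(sum(x * x for x in v))
        if n > 0.0:
            kept.append([x / n for x in v])
    return mean(kept)


def ss_kmeans(P, U, tol=1e-6, max_iter=100):
    """Step-by-step semi-supervised 2-means; returns (lp_flags, iters, conv)."""
    c1, c2 = mean(P), mean(U)
    lp = [cos(u, c1) > cos(u, c2) for u in U]
    iters, converged = 1, False
    for _ in range(max_iter - 1):
        members_p = [u for u, f in zip(U, lp) if f]
        members_n = [u for u, f in zip(U, lp) if not f]
        l1 = mean(members_p) if members_p else c1
        l2 = mean(members_n) if members_n else c2
        movement = max(euclid(l1, c1), euclid(l2, c2))
        c1, c2 = l1, l2
        if movement <= tol:
            converged = True
            break
        new_lp = [sq_dist(u, c1) < sq_dist(u, c2) for u in U]
        iters += 1
        if new_lp == lp:
            lp = new_lp
            converged = True
            break
        lp = new_lp
    return lp, iters, converged


def rocchio_prototypes(pos, neg, alpha, beta):
    mp, mn = normalised_mean(pos), normalised_mean(neg)
    c_pos = [alpha * a - beta * b for a, b in zip(mp, mn)]
    c_neg = [alpha * b - beta * a for a, b in zip(mp, mn)]
    return c_pos, c_neg


def rocchio_round1(P, LN1, alpha, beta):
    """Per-sample cosine comparison; True = reliable negative (LN2)."""
    c_pos, c_neg = rocchio_prototypes(P, LN1, alpha, beta)
    return [cos(x, c_pos) < cos(x, c_neg) for x in LN1]


def rocchio_round2(P, LN2, subsets, alpha, beta, rule="nearest"):
    """Local prototype screen given a fixed partition of LN2.

    ``subsets`` is a list of index lists into LN2. True = final reliable
    negative under the chosen acceptance rule.
    """
    pairs = []
    member_of = [0] * len(LN2)
    for j, idx in enumerate(subsets):
        for i in idx:
            member_of[i] = j
        n_j, p_j = rocchio_prototypes([LN2[i] for i in idx], P, alpha, beta)
        pairs.append((n_j, p_j))
    out = []
    for i, x in enumerate(LN2):
        wins = [cos(x, n_j) > cos(x, p_j) for n_j, p_j in pairs]
        if rule == "all":
            ok = all(wins)
        elif rule == "any":
            ok = any(wins)
        else:
            ok = wins[member_of[i]]
        if all(v == 0.0 for v in x):
            ok = False
        out.append(ok)
    return out


def auc_by_pair_counting(labels, scores):
    """AUC as the fraction of correctly ranked (pos, neg) pairs."""
    pos = [s for l, s in zip(labels, scores) if l == 1]
    neg = [s for l, s in zip(labels, scores) if l == 0]
    total, good = 0, 0.0
    for p in pos:
        for q in neg:
            total += 1
            if p > q:
                good += 1.0
            elif p == q:
                good += 0.5
    return good / total
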