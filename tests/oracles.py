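"""Independent brute-force reference implementations used only by tests.

Everything here is written as plain double loops over points (O(n^2) or
worse) with no shared code with the package, so agreement is meaningful.
"""

from __future__ import annotations

import math
from collections import Counter

import numpy as np


def dist(p, q) -> float:
    return math.sqrt(sum((a - b) ** 2 for a, b in zip(p, q)))


def brute_knn(points, k):
    points = np.asarray(points, dtype=float)
    n = len(points)
    out = []
    for i in range(n):
        cand = [(dist(points[i], points[j]), j) for j in range(n) if j != i]
        cand.sort()  # ties broken by ascending index via the tuple
        out.append([j for _, j in cand[:k]])
    return np.array(out)


def brute_knn_accuracy(points, labels, k):
    neigh = brute_knn(points, k)
    labels = list(labels)
    correct = 0
    for i, nbrs in enumerate(neigh):
        votes = Counter(labels[j] for j in nbrs)
        top = max(votes.values())
        winners = [lab for lab, v in votes.items() if v == top]
        pred = winners[0] if len(winners) == 1 else labels[nbrs[0]]
        correct += pred == labels[i]
    return correct / len(labels)


def brute_knn_recall(hd, emb, k):
    nh = brute_knn(hd, k)
    ne = brute_knn(emb, k)
    return float(np.mean([len(set(a) & set(b)) / k for a, b in zip(nh, ne)]))


def brute_silhouette(points, labels):
    points = np.asarray(points, dtype=float)
    labels = list(labels)
    n = len(labels)
    classes = sorted(set(labels))
    s_vals = []
    for i in range(n):
        same = [j for j in range(n) if j != i and labels[j] == labels[i]]
        if not same:
            s_vals.append(0.0)
            continue
        a = sum(dist(points[i], points[j]) for j in same) / len(same)
        b = math.inf
        for c in classes:
            if c == labels[i]:
                continue
            other = [j for j in range(n) if labels[j] == c]
            b = min(b, sum(dist(points[i], points[j]) for j in other) / len(other))
        denom = max(a, b)
        s_vals.append(0.0 if denom == 0 else (b - a) / denom)
    return float(np.mean(s_vals))


def brute_emi(table) -> float:
    """Exact E[MI]: hypergeometric enumeration with integer combinatorics."""
    table = np.asarray(table, dtype=int)
    ai = table.sum(axis=1)
    bj = table.sum(axis=0)
    n = int(table.sum())
    emi = 0.0
    for a in ai:
        for b in bj:
            for nij in range(max(1, a + b - n), min(a, b) + 1):
                p = (
                    math.comb(a, nij)
                    * math.comb(n - a, b - nij)
                    / math.comb(n, b)
                )
                emi += p * (nij / n) * math.log(n * nij / (a * b))
    return emi


def brute_ami(labels_a, labels_b) -> float:
    la = list(labels_a)
    lb = list(labels_b)
    cats_a = sorted(set(la), key=str)
    cats_b = sorted(set(lb), key=str)
    table = np.zeros((len(cats_a), len(cats_b)), dtype=int)
    for x, y in zip(la, lb):
        table[cats_a.index(x), cats_b.index(y)] += 1
    n = table.sum()

    def entropy(marg):
        return -sum(m / n * math.log(m / n) for m in marg if m > 0)

    h_a = entropy(table.sum(axis=1))
    h_b = entropy(table.sum(axis=0))
    mi = 0.0
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            nij = table[i, j]
            if nij > 0:
                mi += nij / n * math.log(n * nij / (table[i].sum() * table[:, j].sum()))
    emi = brute_emi(table)
    denom = 0.5 * (h_a + h_b) - emi
    if abs(denom) < 1e-15:
        return 0.0
    return (mi - emi) / denom


def brute_interclass_corr(hd, emb, labels):
    hd = np.asarray(hd, dtype=float)
    emb = np.asarray(emb, dtype=float)
    labels = list(labels)
    classes = sorted(set(labels))
    cen_h = {c: hd[[i for i, l in enumerate(labels) if l == c]].mean(axis=0) for c in classes}
    cen_e = {c: emb[[i for i, l in enumerate(labels) if l == c]].mean(axis=0) for c in classes}
    dh, de = [], []
    for i, c1 in enumerate(classes):
        for c2 in classes[i + 1 :]:
            dh.append(dist(cen_h[c1], cen_h[c2]))
            de.append(dist(cen_e[c1], cen_e[c2]))
    return pearson(dh, de)


def brute_intraclass_corr(hd, emb, labels):
    hd = np.asarray(hd, dtype=float)
    emb = np.asarray(emb, dtype=float)
    labels = list(labels)
    classes = sorted(set(labels))

    def var(x, members):
        cen = x[members].mean(axis=0)
        return float(np.mean([dist(x[i], cen) ** 2 for i in members]))

    vh, ve = [], []
    for c in classes:
        members = [i for i, l in enumerate(labels) if l == c]
        vh.append(var(hd, members))
        ve.append(var(emb, members))
    return pearson(vh, ve)


def pearson(u, v) -> float:
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    uc = u - u.mean()
    vc = v - v.mean()
    return float((uc * vc).sum() / math.sqrt((uc**2).sum() * (vc**2).sum()))
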