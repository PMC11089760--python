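"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive -- plain set loops, explicit
enumeration, direct pair counting -- and shares no code with the package
paths it checks.
"""

from __future__ import annotations

from itertools import product
from math import comb

import numpy as np

from lncda.graph import TripartiteGraph


def naive_ngh_score(g: TripartiteGraph, l: str, d: str, alpha: float) -> float:
    """Direct transcription of the neighborhood score with no caching."""
    ml = set(g.mirna_profile_lncrna(l))
    md = set(g.mirna_profile_disease(d))
    neighbors = []
    for other in g.lncrnas:
        if other == l:
            continue
        if set(g.mirna_profile_lncrna(other)) & ml:
            neighbors.append(other)
    inter_u: set = set()
    union_u: set = set()
    for x in neighbors:
        mx = set(g.mirna_profile_lncrna(x))
        inter_u |= mx & md
        union_u |= mx | md
    s = 0.0
    if ml | md:
        s += alpha * len(ml & md) / len(ml | md)
    if union_u:
        s += (1 - alpha) * len(inter_u) / len(union_u)
    return s


def exact_hypergeom_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) by full enumeration of the hypergeometric pmf."""
    denom = comb(N, n)
    total = 0
    for x in range(k, min(K, n) + 1):
        total += comb(K, x) * comb(N - K, n - x)
    return total / denom


def mann_whitney_auc(scores, labels) -> float:
    """Tie-corrected concordant-pair statistic (0.5 credit for score ties)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos = scores[labels]
    neg = scores[~labels]
    wins = 0.0
    for p in pos:
        wins += np.sum(p > neg) + 0.5 * np.sum(p == neg)
    return wins / (len(pos) * len(neg))


def random_graph(rng, n_lnc=8, n_mir=12, n_dis=5, p=0.25) -> TripartiteGraph:
    """Small random tripartite fixture built edge by edge (no library path)."""
    lncs = [f"l{i}" for i in range(n_lnc)]
    mirs = [f"m{i}" for i in range(n_mir)]
    diss = [f"d{i}" for i in range(n_dis)]
    lmi = {(l, m) for l, m in product(lncs, mirs) if rng.random() < p}
    mda = {(m, d) for m, d in product(mirs, diss) if rng.random() < p}
    return TripartiteGraph(lmi, mda, lncrnas=lncs, mirnas=mirs, diseases=diss)
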