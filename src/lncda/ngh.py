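"""NGH: neighborhood-based prediction of lncRNA-disease associations.

The prediction score for a pair (l, d) combines two intersection-over-union
terms on miRNA profiles::

    s(l, d) = alpha * |M_l & M_d| / |M_l | M_d|
            + (1 - alpha) * |U_x (M_x & M_d)| / |U_x (M_x | M_d)|

where M_l is the miRNA profile of the lncRNA, M_d the miRNA profile of the
disease, and x ranges over the *neighbors* of l (lncRNAs sharing at least
one miRNA with l).  ``alpha`` in [0, 1] balances the direct against the
neighborhood evidence.  Any ratio whose denominator is zero contributes 0
(no evidence, no score), which keeps s in [0, 1].

Scores are normalised by their grand total over all |L| x |D| pairs before
being written out or handed to the collaborative-filtering booster; the
normalisation is a positive global scaling and never changes the ranking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .graph import TripartiteGraph

logger = logging.getLogger(__name__)

__all__ = [
    "ScoreBreakdown",
    "ngh_score",
    "ngh_score_all",
    "normalize_scores",
    "rank_predictions",
    "write_rank",
    "NGH",
    "NGHResults",
]


@dataclass(frozen=True)
class ScoreBreakdown:
    """Per-pair decomposition of the prediction score."""

    alpha: float
    direct_inter: int
    direct_union: int
    nbr_inter: int
    nbr_union: int
    s: float


def _check_alpha(alpha: float) -> float:
    alpha = float(alpha)
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    return alpha


def ngh_score(g: TripartiteGraph, l: str, d: str, alpha: float = 0.5) -> ScoreBreakdown:
    """Neighborhood prediction score of the pair ``(l, d)`` with its breakdown."""
    alpha = _check_alpha(alpha)
    ml = g.mirna_profile_lncrna(l)
    md = g.mirna_profile_disease(d)
    di, du = len(ml & md), len(ml | md)
    nbrs = g.neighbors(l)
    if nbrs:
        union_profiles: set[str] = set()
        for x in nbrs:
            union_profiles |= g.mirna_profile_lncrna(x)
        # U_x (M_x & M_d) == (U_x M_x) & M_d and U_x (M_x | M_d) == (U_x M_x) | M_d
        ni, nu = len(union_profiles & md), len(union_profiles | md)
    else:
        ni = nu = 0
    s = 0.0
    if du:
        s += alpha * di / du
    if nu:
        s += (1.0 - alpha) * ni / nu
    return ScoreBreakdown(alpha, di, du, ni, nu, s)


def ngh_score_all(g: TripartiteGraph, alpha: float = 0.5) -> pd.DataFrame:
    """Raw prediction scores for every (lncRNA, disease) pair.

    Returns a DataFrame with sorted lncRNA ids as index and sorted disease
    ids as columns.
    """
    alpha = _check_alpha(alpha)
    if not g.lncrnas or not g.diseases:
        raise ValueError("cannot score: graph has no lncRNAs or no diseases")
    lncs = sorted(g.lncrnas)
    diss = sorted(g.diseases)
    out = np.zeros((len(lncs), len(diss)))
    dis_prof = [g.mirna_profile_disease(d) for d in diss]
    for i, l in enumerate(lncs):
        ml = g.mirna_profile_lncrna(l)
        nbrs = g.neighbors(l)
        nbr_union: set[str] = set()
        for x in nbrs:
            nbr_union |= g.mirna_profile_lncrna(x)
        for j, md in enumerate(dis_prof):
            s = 0.0
            du = len(ml | md)
            if du:
                s += alpha * len(ml & md) / du
            if nbrs:
                nu = len(nbr_union | md)
                if nu:
                    s += (1.0 - alpha) * len(nbr_union & md) / nu
            out[i, j] = s
    return pd.DataFrame(out, index=lncs, columns=diss)


def normalize_scores(raw: pd.DataFrame) -> pd.DataFrame:
    """Divide every score by the grand total so the table sums to 1.

    An all-zero table is returned unchanged with a logged warning (there is
    nothing to normalise).  Negative inputs are rejected.
    """
    vals = raw.to_numpy(dtype=float)
    if (vals < 0).any():
        raise ValueError("scores must be non-negative")
    total = vals.sum()
    if total == 0:
        logger.warning("all scores are zero; normalisation is a no-op")
        return raw.copy()
    return raw / total


def rank_predictions(scores: pd.DataFrame) -> pd.DataFrame:
    """Flatten a score table into a rank of (lncrna, disease, score) triplets.

    Sorted by score descending; ties broken by (lncrna, disease)
    lexicographic order, so the rank is deterministic across runs.
    """
    long = scores.stack().rename("score").reset_index()
    long.columns = ["lncrna", "disease", "score"]
    long = long.sort_values(
        ["score", "lncrna", "disease"],
        ascending=[False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    return long


def write_rank(rank: pd.DataFrame, path) -> None:
    """Write a rank as TSV with header, scores at 6 significant digits."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("lncRNA\tdisease\tscore\n")
        for row in rank.itertuples(index=False):
            fh.write(f"{row.lncrna}\t{row.disease}\t{row.score:.6g}\n")


class NGH:
    """Neighborhood-score association model.

    Parameters
    ----------
    graph : TripartiteGraph
        The lncRNA-miRNA-disease graph.
    alpha : float, default 0.5
        Weight of the direct-overlap term versus the neighborhood term.
    """

    def __init__(self, graph: TripartiteGraph, alpha: float = 0.5) -> None:
        self.graph = graph
        self.alpha = _check_alpha(alpha)

    def fit(self) -> "NGHResults":
        raw = ngh_score_all(self.graph, self.alpha)
        return NGHResults(self, raw, normalize_scores(raw))


class NGHResults:
    """Fitted NGH scores: raw and normalised tables plus the ranked triplets."""

    method = "NGH"

    def __init__(self, model: NGH, raw_scores: pd.DataFrame, scores: pd.DataFrame):
        self.model = model
        self.raw_scores = raw_scores
        self.scores = scores
        self.rank = rank_predictions(scores)

    def breakdown(self, l: str, d: str) -> ScoreBreakdown:
        """Score decomposition (direct and neighborhood terms) for one pair."""
        return ngh_score(self.model.graph, l, d, self.model.alpha)

    def summary(self, top: int = 10) -> str:
        g = self.model.graph
        lines = [
            f"{self.method} association model",
            f"  graph: |L|={len(g.lncrnas)} |M|={len(g.mirnas)} "
            f"|D|={len(g.diseases)} |I|={g.n_lmi} |A|={g.n_mda}",
            f"  alpha: {self.model.alpha}",
            f"  pairs ranked: {len(self.rank)}",
            f"  top {top} predictions:",
        ]
        for row in self.rank.head(top).itertuples(index=False):
            lines.append(f"    {row.lncrna}\t{row.disease}\t{row.score:.6g}")
        return "\n".join(lines)
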