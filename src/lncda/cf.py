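"""Collaborative filtering on the lncRNA x disease relationship matrix.

Two filling criteria produce the relationship matrix R:

* **CF** -- ``r_ij = 1`` when lncRNA i and disease j share at least one
  miRNA, 0 otherwise;
* **NGH-CF** -- ``r_ij`` is the normalised neighborhood prediction score of
  the pair, so the factorisation acts as a booster of the NGH rank.

R is factorised as ``R ~ L^T D`` in a joint latent space of dimension ``f``
by alternating least squares (ALS): only the nonzero index set ``chi``
enters the loss (zeros are treated as unobserved, not as negatives), and a
ridge penalty ``reg * (sum ||l_i||^2 + sum ||d_j||^2)`` keeps the per-block
normal equations well conditioned.  The final prediction for every pair --
observed or not -- is the inner product of its two factor vectors; the
imputation of unobserved pairs is the point of the method.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .graph import TripartiteGraph
from .ngh import ngh_score_all, normalize_scores, rank_predictions

logger = logging.getLogger(__name__)

__all__ = [
    "RelationshipMatrix",
    "FactorModel",
    "fill_cf_binary",
    "fill_nghcf",
    "als_fit",
    "predict_scores",
    "cf_rank",
    "nghcf_rank",
    "CF",
    "NGHCF",
    "ALSResults",
]


@dataclass(frozen=True)
class RelationshipMatrix:
    """lncRNA x disease matrix R with its nonzero index set chi."""

    values: pd.DataFrame

    @property
    def chi(self) -> list[tuple[int, int]]:
        """Positional (row, col) indices of the nonzero entries."""
        rows, cols = np.nonzero(self.values.to_numpy())
        return list(zip(rows.tolist(), cols.tolist()))

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def __post_init__(self) -> None:
        vals = self.values.to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            raise ValueError("relationship matrix entries must be finite")
        if (vals < 0).any():
            raise ValueError("relationship matrix entries must be >= 0")


def fill_cf_binary(g: TripartiteGraph) -> RelationshipMatrix:
    """Binary relationship matrix: 1 iff the pair shares >= 1 miRNA."""
    if not g.lncrnas or not g.diseases:
        raise ValueError("cannot build relationship matrix: empty lncRNA or disease set")
    lncs, diss = sorted(g.lncrnas), sorted(g.diseases)
    vals = np.zeros((len(lncs), len(diss)))
    for i, l in enumerate(lncs):
        ml = g.mirna_profile_lncrna(l)
        for j, d in enumerate(diss):
            if ml & g.mirna_profile_disease(d):
                vals[i, j] = 1.0
    return RelationshipMatrix(pd.DataFrame(vals, index=lncs, columns=diss))


def fill_nghcf(g: TripartiteGraph, alpha: float = 0.5) -> RelationshipMatrix:
    """Relationship matrix filled with normalised neighborhood scores."""
    norm = normalize_scores(ngh_score_all(g, alpha))
    if norm.to_numpy().sum() == 0:
        raise ValueError(
            "all neighborhood scores are zero: nothing to factorize "
            "(the graph carries no lncRNA-disease signal)"
        )
    return RelationshipMatrix(norm)


@dataclass
class FactorModel:
    """Result of an ALS factorisation of a relationship matrix."""

    lnc_factors: pd.DataFrame  # h x f, indexed by lncRNA id
    dis_factors: pd.DataFrame  # k x f, indexed by disease id
    f: int
    reg: float
    seed: int
    objective_trace: list[float] = field(default_factory=list)
    n_iter: int = 0
    converged: bool = False


def als_fit(
    R: RelationshipMatrix,
    f: int = 10,
    reg: float = 0.1,
    max_iter: int = 50,
    tol: float = 1e-4,
    seed: int = 42,
) -> FactorModel:
    """Alternating least squares on the nonzero entries of R.

    Alternates exact block solves: with disease factors fixed, each lncRNA
    factor is the ridge solution on its observed row entries, and vice
    versa.  The objective

        sum_{(i,j) in chi} (r_ij - l_i . d_j)^2
        + reg * (sum_i ||l_i||^2 + sum_j ||d_j||^2)

    is recorded after every half-iteration and is non-increasing across full
    alternations.  The default ridge weight 0.1 is deliberately firm: with a
    weak penalty and a moderate latent dimension the factorization memorises
    the observed entries and the out-of-sample inner products -- the
    predictions the method exists for -- degenerate to noise.  Stops at ``max_iter`` or when the relative decrease over
    one full alternation drops below ``tol``.  Deterministic for a given
    seed: disease factors start from seeded standard normals scaled by
    1/sqrt(f), and lncRNA factors are solved first.
    """
    if f < 1:
        raise ValueError("latent dimension f must be >= 1")
    if reg < 0:
        raise ValueError("reg must be >= 0")
    vals = R.values.to_numpy(dtype=float)
    h, k = vals.shape
    mask = vals != 0
    if not mask.any():
        raise ValueError("chi is empty: relationship matrix has no nonzero entries")
    if f > min(h, k):
        warnings.warn(
            f"latent dimension f={f} exceeds min(h, k)={min(h, k)}; "
            "the factorization is over-parameterized",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    D = rng.standard_normal((k, f)) / np.sqrt(f)
    L = np.zeros((h, f))
    rows_obs = [np.flatnonzero(mask[i]) for i in range(h)]
    cols_obs = [np.flatnonzero(mask[:, j]) for j in range(k)]
    eye = np.eye(f)

    def objective() -> float:
        resid = vals - L @ D.T
        return float((resid[mask] ** 2).sum() + reg * ((L**2).sum() + (D**2).sum()))

    def solve_block(fixed: np.ndarray, obs: list[np.ndarray], target_rows: np.ndarray):
        out = np.zeros((len(obs), f))
        for i, idx in enumerate(obs):
            if idx.size == 0:
                continue  # unobserved row/col: ridge minimizer is the zero vector
            F = fixed[idx]
            y = target_rows[i][idx]
            if reg > 0:
                out[i] = np.linalg.solve(F.T @ F + reg * eye, F.T @ y)
            else:
                out[i] = np.linalg.lstsq(F, y, rcond=None)[0]
        return out

    trace: list[float] = []
    prev: float | None = None
    n_iter = 0
    converged = False
    for it in range(max_iter):
        L = solve_block(D, rows_obs, vals)
        trace.append(objective())
        D = solve_block(L, cols_obs, vals.T)
        obj = objective()
        trace.append(obj)
        n_iter = it + 1
        if not np.isfinite(obj):
            raise FloatingPointError(
                "ALS objective is not finite; the normal equations are "
                "rank-deficient -- use reg > 0"
            )
        if prev is not None and prev - obj <= tol * max(abs(prev), 1e-30):
            converged = True
            break
        prev = obj
    return FactorModel(
        lnc_factors=pd.DataFrame(L, index=R.values.index),
        dis_factors=pd.DataFrame(D, index=R.values.columns),
        f=f,
        reg=reg,
        seed=seed,
        objective_trace=trace,
        n_iter=n_iter,
        converged=converged,
    )


def predict_scores(model: FactorModel) -> pd.DataFrame:
    """Inner-product scores for all h x k pairs, including unobserved ones."""
    vals = model.lnc_factors.to_numpy() @ model.dis_factors.to_numpy().T
    return pd.DataFrame(
        vals, index=model.lnc_factors.index, columns=model.dis_factors.index
    )


def dump_factors(model: FactorModel, path) -> None:
    """Plain-text dump of both factor matrices and the fit parameters."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            f"# ALS factors: f={model.f} reg={model.reg} seed={model.seed} "
            f"n_iter={model.n_iter} converged={model.converged}\n"
        )
        fh.write("# lncRNA factors\n")
        model.lnc_factors.to_csv(fh, sep="\t", header=False)
        fh.write("# disease factors\n")
        model.dis_factors.to_csv(fh, sep="\t", header=False)


def _fit_rank(R, f, reg, max_iter, tol, seed):
    model = als_fit(R, f=f, reg=reg, max_iter=max_iter, tol=tol, seed=seed)
    return model, rank_predictions(predict_scores(model))


def cf_rank(
    g: TripartiteGraph,
    f: int = 10,
    reg: float = 0.1,
    max_iter: int = 50,
    tol: float = 1e-4,
    seed: int = 42,
) -> pd.DataFrame:
    """CF pipeline: binary fill -> ALS -> inner-product scores -> rank."""
    return _fit_rank(fill_cf_binary(g), f, reg, max_iter, tol, seed)[1]


def nghcf_rank(
    g: TripartiteGraph,
    alpha: float = 0.5,
    f: int = 10,
    reg: float = 0.1,
    max_iter: int = 50,
    tol: float = 1e-4,
    seed: int = 42,
    rescale: bool = True,
) -> pd.DataFrame:
    """NGH-CF pipeline: normalised-score fill -> ALS -> scores -> rank."""
    R = fill_nghcf(g, alpha)
    if rescale:
        R = _rescale(R)
    return _fit_rank(R, f, reg, max_iter, tol, seed)[1]


def _rescale(R: RelationshipMatrix) -> RelationshipMatrix:
    # normalised scores sum to 1 over h*k entries, so their magnitude shrinks
    # with matrix size; dividing by the maximum gives reg a size-independent
    # meaning and, being a positive scaling, cannot reorder anything
    m = R.values.to_numpy().max()
    return RelationshipMatrix(R.values / m) if m > 0 else R


class _ALSModelBase:
    method = "CF"

    def __init__(self, graph, f=10, reg=0.1, max_iter=50, tol=1e-4):
        if reg < 0:
            raise ValueError("reg must be >= 0")
        self.graph = graph
        self.f = int(f)
        self.reg = float(reg)
        self.max_iter = int(max_iter)
        self.tol = float(tol)

    def _matrix(self) -> RelationshipMatrix:
        raise NotImplementedError

    def fit(self, seed: int = 42) -> "ALSResults":
        R = self._matrix()
        model, rank = _fit_rank(R, self.f, self.reg, self.max_iter, self.tol, seed)
        return ALSResults(self, R, model, rank)


class CF(_ALSModelBase):
    """Collaborative-filtering model on the binary relationship matrix.

    Parameters
    ----------
    graph : TripartiteGraph
    f : int, default 10
        Latent dimension of the joint factor space.
    reg : float, default 0.1
        Ridge weight on both factor blocks; firm enough that moderate latent
        dimensions cannot memorise the observed entries.
    max_iter, tol
        ALS stopping rule (relative objective decrease per alternation).
    """

    method = "CF"

    def _matrix(self) -> RelationshipMatrix:
        return fill_cf_binary(self.graph)


class NGHCF(_ALSModelBase):
    """NGH boosted by collaborative filtering: ALS on the normalised
    neighborhood-score matrix.

    ``rescale`` (default True) divides the matrix by its maximum before the
    fit so the ridge weight is comparable across matrix sizes.
    """

    method = "NGH-CF"

    def __init__(self, graph, alpha=0.5, f=10, reg=0.1, max_iter=50, tol=1e-4,
                 rescale=True):
        super().__init__(graph, f=f, reg=reg, max_iter=max_iter, tol=tol)
        self.alpha = float(alpha)
        self.rescale = bool(rescale)

    def _matrix(self) -> RelationshipMatrix:
        R = fill_nghcf(self.graph, self.alpha)
        return _rescale(R) if self.rescale else R


class ALSResults:
    """Fitted ALS factorisation: factors, objective trace, predicted rank."""

    def __init__(self, model, R: RelationshipMatrix, factors: FactorModel,
                 rank: pd.DataFrame):
        self.model = model
        self.method = model.method
        self.relationship_matrix = R
        self.factors = factors
        self.scores = predict_scores(factors)
        self.rank = rank

    @property
    def objective_trace(self) -> list[float]:
        return self.factors.objective_trace

    @property
    def converged(self) -> bool:
        return self.factors.converged

    def summary(self, top: int = 10) -> str:
        g = self.model.graph
        m = self.factors
        lines = [
            f"{self.method} association model (ALS factorization)",
            f"  graph: |L|={len(g.lncrnas)} |M|={len(g.mirnas)} "
            f"|D|={len(g.diseases)} |I|={g.n_lmi} |A|={g.n_mda}",
            f"  f={m.f} reg={m.reg} seed={m.seed} "
            f"iterations={m.n_iter} converged={m.converged}",
            f"  |chi|={len(self.relationship_matrix.chi)} "
            f"final objective={m.objective_trace[-1]:.6g}",
            f"  top {top} predictions:",
        ]
        for row in self.rank.head(top).itertuples(index=False):
            lines.append(f"    {row.lncrna}\t{row.disease}\t{row.score:.6g}")
        return "\n".join(lines)
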