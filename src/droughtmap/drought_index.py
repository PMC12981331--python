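"""Composite drought-resistance evaluation (the D-value).

The pipeline is: fuzzy membership normalization of per-trait adverse
changes, PCA of the normalized trait table, variance-contribution weights,
and a weighted sum of component scores:

    Y_ij = (Xj_max - X_ij) / (Xj_max - Xj_min)          membership
    F_ij = sum_t a_tj * Y_it                            component scores
    W_j  = P_j / sum_j P_j                              contribution weights
    D_i  = sum_j F_ij * W_j                             composite index

The membership function above is the *reversed* min-max form: the accession
with the largest adverse change in a trait scores 0 and the smallest scores
1, so a higher D means stronger drought resistance.  ``membership="standard"``
gives the ordinary (X - min)/(max - min) form instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .physiology import TraitChangeTable, trait_changes


@dataclass
class MembershipMatrix:
    """Accessions x traits membership values in [0, 1], plus column extremes."""

    values: pd.DataFrame
    col_min: pd.Series
    col_max: pd.Series
    mode: str = "as_printed"


@dataclass
class TraitPCAModel:
    """PCA of the membership table on the trait correlation (or covariance) matrix.

    ``loadings`` are unit-norm eigenvectors (traits x retained components);
    ``contributions`` are percent variance explained, non-increasing;
    ``scores`` are the component scores of each accession.
    """

    loadings: pd.DataFrame
    contributions: np.ndarray
    scores: pd.DataFrame
    n_retained: int
    all_contributions: np.ndarray = field(default=None, repr=False)


@dataclass
class DValueResult:
    weights: np.ndarray
    d: pd.Series
    ranking: list[str]
    membership: MembershipMatrix | None = None
    pca: TraitPCAModel | None = None


def membership_normalize(
    X: TraitChangeTable | pd.DataFrame, mode: str = "as_printed"
) -> MembershipMatrix:
    """Min-max membership normalization of the adverse-change table.

    ``as_printed`` (default) maps the column maximum to 0 and the minimum
    to 1 — the largest adverse change scores lowest.  ``standard`` is the
    ordinary ascending form.  A constant column has no usable range and is
    rejected by name.
    """
    df = X.values if isinstance(X, TraitChangeTable) else X
    cmin, cmax = df.min(axis=0), df.max(axis=0)
    flat = cmax <= cmin
    if flat.any():
        bad = ", ".join(df.columns[flat])
        raise ValueError(f"constant trait column(s) cannot be normalized: {bad}")
    if mode == "as_printed":
        Y = (cmax - df) / (cmax - cmin)
    elif mode == "standard":
        Y = (df - cmin) / (cmax - cmin)
    else:
        raise ValueError(f"unknown membership mode {mode!r}")
    return MembershipMatrix(values=Y, col_min=cmin, col_max=cmax, mode=mode)


def fit_trait_pca(
    Y: MembershipMatrix | pd.DataFrame,
    retain_rule: str = "cum:0.75",
    matrix: str = "correlation",
) -> TraitPCAModel:
    """Eigen-decomposition of the trait table for component scores and weights.

    Columns are z-standardized and the correlation matrix decomposed
    (``matrix="covariance"`` skips the variance scaling).  Retention rules:
    ``cum:<frac>`` keeps the smallest k whose cumulative contribution reaches
    the fraction; ``eigen:1`` keeps eigenvalues > 1; ``fixed:<k>`` keeps k.
    Eigenvector sign is fixed so each column of loadings sums positive
    (falling back to the largest-magnitude entry when the sum is ~0), which
    orients the dominant component with overall trait membership.
    """
    df = Y.values if isinstance(Y, MembershipMatrix) else Y
    n, t = df.shape
    if n < 2 or t < 2:
        raise ValueError("need at least 2 accessions and 2 traits")
    Z = df.to_numpy(dtype=float)
    Z = Z - Z.mean(axis=0)
    if matrix == "correlation":
        sd = Z.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise ValueError("zero-variance column after membership normalization")
        Z = Z / sd
    elif matrix != "covariance":
        raise ValueError(f"unknown matrix mode {matrix!r}")
    C = (Z.T @ Z) / (n - 1)
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals, evecs = np.maximum(evals[order], 0.0), evecs[:, order]
    # deterministic sign: loadings column sums positive
    for j in range(evecs.shape[1]):
        s = evecs[:, j].sum()
        if abs(s) < 1e-12:
            s = evecs[np.argmax(np.abs(evecs[:, j])), j]
        if s < 0:
            evecs[:, j] = -evecs[:, j]
    total = evals.sum()
    contrib = 100.0 * evals / total

    kind, _, arg = retain_rule.partition(":")
    if kind == "cum":
        target = 100.0 * float(arg or 0.75)
        k = int(np.searchsorted(np.cumsum(contrib), target - 1e-12) + 1)
    elif kind == "eigen":
        k = max(1, int((evals > float(arg or 1.0)).sum()))
    elif kind == "fixed":
        k = int(arg)
    else:
        raise ValueError(f"unknown retain rule {retain_rule!r}")
    rank = int((evals > 1e-10 * evals[0]).sum())
    if k > rank:
        warnings.warn(
            f"requested {k} components but rank is {rank}; truncating", stacklevel=2
        )
        k = rank
    k = min(k, t)

    scores = Z @ evecs[:, :k]
    comp_names = [f"PC{j + 1}" for j in range(k)]
    return TraitPCAModel(
        loadings=pd.DataFrame(evecs[:, :k], index=df.columns, columns=comp_names),
        contributions=contrib[:k],
        scores=pd.DataFrame(scores, index=df.index, columns=comp_names),
        n_retained=k,
        all_contributions=contrib,
    )


def component_weights(P: np.ndarray) -> np.ndarray:
    """Weights W_j = P_j / sum(P_j) over the retained contributions."""
    P = np.asarray(P, dtype=float)
    if P.size == 0 or np.any(P <= 0):
        raise ValueError("contributions must be positive")
    return P / P.sum()


def d_value(model: TraitPCAModel, weights: np.ndarray) -> DValueResult:
    """Composite index D_i = sum_j F_ij * W_j, ranked descending.

    A higher D indicates stronger drought resistance (smaller membership-
    reversed adverse changes along the dominant components).
    """
    W = np.asarray(weights, dtype=float)
    if W.shape[0] != model.scores.shape[1]:
        raise ValueError(
            f"{W.shape[0]} weights vs {model.scores.shape[1]} score components"
        )
    d = pd.Series(model.scores.to_numpy() @ W, index=model.scores.index, name="D")
    ranking = list(d.sort_values(ascending=False, kind="mergesort").index)
    return DValueResult(weights=W, d=d, ranking=ranking, pca=model)


def evaluate_drought_resistance(
    panel: pd.DataFrame,
    directions: dict[str, int] | None = None,
    retain_rule: str = "cum:0.75",
    membership: str = "as_printed",
    matrix: str = "correlation",
) -> DValueResult:
    """Full pipeline: pre/post panel -> adverse changes -> membership -> PCA -> D.

    Returns the result with full provenance (membership matrix, loadings,
    contributions) attached.
    """
    changes = trait_changes(panel, directions=directions)
    Y = membership_normalize(changes, mode=membership)
    model = fit_trait_pca(Y, retain_rule=retain_rule, matrix=matrix)
    W = component_weights(model.contributions)
    res = d_value(model, W)
    res.membership = Y
    return res


def spearman(a, b) -> float:
    """Spearman rank correlation (convenience for recovery checks)."""
    ra, rb = rankdata(a), rankdata(b)
    return float(np.corrcoef(ra, rb)[0, 1])
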