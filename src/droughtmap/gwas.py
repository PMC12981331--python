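"""Mixed-linear-model association scan.

The model per SNP is

    y = W a + x b + u + e,   u ~ N(0, sg^2 K),   e ~ N(0, se^2 I)

with W the covariates (intercept plus structure covariates), K the kinship
matrix and b the tested allele-dosage effect.  The variance-component ratio
delta = se^2/sg^2 is estimated by restricted maximum likelihood after a
single eigendecomposition of K; the default scan reuses the null-model
delta for every SNP (the P3D/EMMAX shortcut), while ``mode="exact"``
re-optimizes delta per SNP.  Significance follows Bonferroni correction on
the number of valid SNPs: genome-wide 0.05/N and suggestive 0.1/N.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import chi2

from .io_formats import GenotypeMatrix
from .popgen import KinshipMatrix

_CHI2_MEDIAN_1DF = float(chi2.ppf(0.5, 1))  # 0.4549...


@dataclass
class ThresholdSet:
    """Bonferroni thresholds derived from the valid-SNP count."""

    n_valid_snps: int
    alpha_genomewide: float = 0.05
    alpha_suggestive: float = 0.1

    @property
    def p_genomewide(self) -> float:
        return self.alpha_genomewide / self.n_valid_snps

    @property
    def p_suggestive(self) -> float:
        return self.alpha_suggestive / self.n_valid_snps

    @property
    def neg_log10_genomewide(self) -> float:
        return float(-np.log10(self.p_genomewide))

    @property
    def neg_log10_suggestive(self) -> float:
        return float(-np.log10(self.p_suggestive))


@dataclass
class NullModel:
    delta: float          # se^2 / sg^2
    sigma_g2: float
    sigma_e2: float
    reml_loglik: float
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray


@dataclass
class GWASResult:
    table: pd.DataFrame   # chrom, pos, maf, beta, se, wald_p, neg_log10_p
    thresholds: ThresholdSet
    null: NullModel
    lambda_gc: float
    n_skipped_monomorphic: int = 0
    mode: str = "p3d"


def significance_thresholds(n_valid_snps: int) -> ThresholdSet:
    """Bonferroni thresholds: genome-wide 0.05/N, suggestive 0.1/N."""
    if n_valid_snps < 1:
        raise ValueError("n_valid_snps must be >= 1")
    return ThresholdSet(n_valid_snps=int(n_valid_snps))


def _reml_neg_loglik(log_delta: float, lam: np.ndarray, yr: np.ndarray,
                     Wr: np.ndarray) -> float:
    """Negative restricted log-likelihood at a given log(delta).

    Works in the eigenbasis of K: weights d_i = lambda_i + delta.
    """
    delta = np.exp(log_delta)
    d = lam + delta
    n, c = Wr.shape
    WtDW = Wr.T @ (Wr / d[:, None])
    WtDy = Wr.T @ (yr / d)
    try:
        alpha = np.linalg.solve(WtDW, WtDy)
    except np.linalg.LinAlgError:
        return np.inf
    resid = yr - Wr @ alpha
    rss = float(resid @ (resid / d))
    if rss <= 0:
        return np.inf
    nf = n - c
    sign1, logdet_WtDW = np.linalg.slogdet(WtDW)
    sign2, logdet_WtW = np.linalg.slogdet(Wr.T @ Wr)
    if sign1 <= 0 or sign2 <= 0:
        return np.inf
    ll = -0.5 * (
        nf * np.log(2.0 * np.pi * rss / nf)
        + nf
        + np.sum(np.log(d))
        + logdet_WtDW
        - logdet_WtW
    )
    return -ll


def null_reml(
    y: np.ndarray,
    K: KinshipMatrix | np.ndarray,
    covariates: np.ndarray | None = None,
) -> NullModel:
    """Estimate the variance-component ratio under the null (no SNP) model.

    Eigendecomposes K once, rotates y and the covariates, and maximizes the
    restricted likelihood over log(delta) in [-10, 10] by bounded scalar
    minimization.  With K = I every (sg^2, se^2) split of the same total is
    likelihood-equivalent; the reported split then simply reflects the
    optimizer's delta and only the total is meaningful.
    """
    Kv = K.values if isinstance(K, KinshipMatrix) else np.asarray(K)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if not np.all(np.isfinite(y)):
        raise ValueError("phenotype contains non-finite values")
    W = np.ones((n, 1)) if covariates is None else np.column_stack(
        [np.ones(n), covariates]
    )
    if np.linalg.matrix_rank(W) < W.shape[1]:
        raise ValueError("covariates are rank deficient after adding intercept")
    lam, U = np.linalg.eigh(Kv)
    lam = np.maximum(lam, 0.0)
    yr, Wr = U.T @ y, U.T @ W
    res = minimize_scalar(
        _reml_neg_loglik, bounds=(-10.0, 10.0), args=(lam, yr, Wr),
        method="bounded", options={"xatol": 1e-6},
    )
    if not np.isfinite(res.fun):
        raise RuntimeError("restricted likelihood not finite; check K and y")
    delta = float(np.exp(res.x))
    d = lam + delta
    WtDW = Wr.T @ (Wr / d[:, None])
    alpha = np.linalg.solve(WtDW, Wr.T @ (yr / d))
    resid = yr - Wr @ alpha
    nf = n - W.shape[1]
    sg2 = float(resid @ (resid / d)) / nf
    return NullModel(
        delta=delta, sigma_g2=sg2, sigma_e2=delta * sg2,
        reml_loglik=float(-res.fun), eigenvalues=lam, eigenvectors=U,
    )


def lmm_scan(
    y: np.ndarray,
    gm: GenotypeMatrix,
    K: KinshipMatrix | np.ndarray,
    covariates: np.ndarray | None = None,
    mode: str = "p3d",
    maf_min: float = 0.05,
    max_missing: float = 0.2,
) -> GWASResult:
    """Per-SNP Wald tests under the mixed model.

    ``p3d`` fixes delta at its null estimate and runs generalized least
    squares per SNP in the rotated space; ``exact`` re-optimizes delta for
    every SNP.  The residual variance of each SNP model is re-estimated, so
    with K = I the Wald statistic reduces to the squared OLS t statistic.
    Monomorphic SNPs (and SNPs failing the MAF or missingness filters) are
    skipped and counted; the Bonferroni thresholds use the tested count.
    """
    if mode not in ("p3d", "exact"):
        raise ValueError(f"unknown scan mode {mode!r}")
    y = np.asarray(y, dtype=float)
    if len(y) != gm.n_samples:
        raise ValueError("phenotype length does not match genotype samples")
    null = null_reml(y, K, covariates)
    lam, U = null.eigenvalues, null.eigenvectors
    n = len(y)
    W = np.ones((n, 1)) if covariates is None else np.column_stack(
        [np.ones(n), covariates]
    )
    yr, Wr = U.T @ y, U.T @ W

    X = gm.imputed()
    p_alt = X.mean(axis=0) / 2.0
    maf = np.minimum(p_alt, 1.0 - p_alt)
    miss_frac = (gm.dosages == -1).mean(axis=0)
    valid = (maf >= maf_min) & (X.std(axis=0) > 0) & (miss_frac <= max_missing)
    n_skip = int((~valid).sum())
    cols = np.where(valid)[0]
    Xr = U.T @ X[:, cols]

    c = W.shape[1]
    betas = np.empty(len(cols))
    ses = np.empty(len(cols))
    pvals = np.empty(len(cols))
    for t, j in enumerate(cols):
        xr = Xr[:, t]
        if mode == "exact":
            res = minimize_scalar(
                _reml_neg_loglik, bounds=(-10.0, 10.0),
                args=(lam, yr, np.column_stack([Wr, xr])),
                method="bounded", options={"xatol": 1e-6},
            )
            delta = float(np.exp(res.x))
        else:
            delta = null.delta
        d = lam + delta
        M = np.column_stack([Wr, xr])
        MtDM = M.T @ (M / d[:, None])
        MtDy = M.T @ (yr / d)
        try:
            MtDM_inv = np.linalg.inv(MtDM)
        except np.linalg.LinAlgError:
            betas[t], ses[t], pvals[t] = np.nan, np.nan, 1.0
            continue
        coef = MtDM_inv @ MtDy
        resid = yr - M @ coef
        sigma2 = float(resid @ (resid / d)) / (n - c - 1)
        beta = float(coef[-1])
        se = float(np.sqrt(sigma2 * MtDM_inv[-1, -1]))
        stat = (beta / se) ** 2 if se > 0 else 0.0
        betas[t], ses[t] = beta, se
        pvals[t] = float(chi2.sf(stat, 1))
    pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)
    table = pd.DataFrame({
        "chrom": gm.chrom[cols],
        "pos": gm.pos[cols],
        "maf": maf[cols],
        "beta": betas,
        "se": ses,
        "wald_p": pvals,
        "neg_log10_p": -np.log10(pvals),
    })
    thresholds = significance_thresholds(len(cols))
    lam_gc = genomic_inflation(pvals)
    return GWASResult(
        table=table, thresholds=thresholds, null=null, lambda_gc=lam_gc,
        n_skipped_monomorphic=n_skip, mode=mode,
    )


def genomic_inflation(pvals: np.ndarray) -> float:
    """lambda_GC = median observed 1-df chi-square over its null median."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value array")
    stats = chi2.ppf(1.0 - p, 1)
    return float(np.median(stats) / _CHI2_MEDIAN_1DF)


def qq_table(pvals: np.ndarray) -> pd.DataFrame:
    """Expected vs observed -log10 p quantile pairs for a Q-Q plot."""
    p = np.sort(np.asarray(pvals, dtype=float))
    if p.size == 0:
        raise ValueError("empty p-value array")
    n = p.size
    expected = -np.log10((np.arange(1, n + 1) - 0.5) / n)
    observed = -np.log10(np.clip(p, np.finfo(float).tiny, 1.0))
    return pd.DataFrame({"expected": expected, "observed": observed})


def manhattan_table(result: GWASResult) -> pd.DataFrame:
    """Scan table with a cumulative genome coordinate for plotting."""
    t = result.table.copy()
    offset = 0
    cum = np.empty(len(t), dtype=np.int64)
    for c in pd.unique(t["chrom"]):
        mask = (t["chrom"] == c).to_numpy()
        cum[mask] = t.loc[mask, "pos"].to_numpy() + offset
        offset = int(cum[mask].max()) if mask.any() else offset
    t["cum_pos"] = cum
    return t
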