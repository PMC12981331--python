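"""Population structure and linkage disequilibrium.

Kinship and PCA work on mean-imputed centered dosages; the admixture model
is a binomial-likelihood EM over ancestry proportions Q and subpopulation
allele frequencies F (the model behind ADMIXTURE/frappe), with a masked-
entry cross-validation scheme for choosing K; trees come from allele-sharing
distances and neighbour joining; LD decay is genotype (composite) r^2
binned by physical distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .io_formats import MISSING, GenotypeMatrix


@dataclass
class KinshipMatrix:
    """Realized-relationship matrix K = Xc Xc' / m from centered dosages."""

    values: np.ndarray
    sample_ids: list[str]
    method: str = "centered"


@dataclass
class StructureResult:
    """Admixture proportions Q, subpopulation frequencies F, and EM diagnostics."""

    Q: np.ndarray             # n x K, rows sum to 1
    allele_freqs: np.ndarray  # K x m
    loglik_trace: np.ndarray
    converged: bool
    K: int


@dataclass
class LDDecayCurve:
    bin_edges: np.ndarray      # bp
    mean_r2: np.ndarray        # per bin (NaN where empty)
    n_pairs: np.ndarray
    max_mean_r2: float
    half_decay_distance: float | None


def kinship_centered(gm: GenotypeMatrix) -> KinshipMatrix:
    """K = Xc Xc' / m with per-SNP mean imputation and centering."""
    X = gm.imputed()
    poly = X.std(axis=0) > 0
    if not poly.any():
        raise ValueError("all SNPs monomorphic; kinship undefined")
    Xc = X[:, poly] - X[:, poly].mean(axis=0)
    K = Xc @ Xc.T / Xc.shape[1]
    return KinshipMatrix(values=K, sample_ids=list(gm.sample_ids))


def genotype_pca(
    gm: GenotypeMatrix, n_components: int = 10, scale: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Principal components of the sample-by-SNP dosage matrix.

    Mean-centered (optionally 1/sqrt(2p(1-p))-scaled) dosages, decomposed by
    SVD.  Returns (coordinates n x k, explained-variance fractions).
    """
    X = gm.imputed()
    p = X.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    Xc = X[:, poly] - X[:, poly].mean(axis=0)
    if scale:
        Xc = Xc / np.sqrt(2.0 * p[poly] * (1.0 - p[poly]))
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    var = s**2
    rank = int((s > 1e-9 * s[0]).sum()) if len(s) else 0
    if n_components > rank:
        warnings.warn(
            f"requested {n_components} PCs but rank is {rank}; truncating",
            stacklevel=2,
        )
        n_components = rank
    coords = U[:, :n_components] * s[:n_components]
    explained = var[:n_components] / var.sum()
    return coords, explained


# ---------------------------------------------------------------------------
# Admixture EM
# ---------------------------------------------------------------------------

_EPS = 1e-9


def admixture_em(
    gm: GenotypeMatrix,
    K: int,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> StructureResult:
    """Maximum-likelihood admixture proportions by EM.

    Model: dosage g_ij ~ Binomial(2, pi_ij) with pi_ij = sum_k q_ik f_kj.
    The EM updates split each observed allele count between ancestries by
    responsibility; missing genotypes are excluded from the likelihood.
    The log-likelihood trace is non-decreasing; non-convergence within
    ``max_iter`` is flagged, not raised.  Output columns are ordered by
    descending mean ancestry for label stability.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    n, m = gm.n_samples, gm.n_snps
    G = gm.dosages.astype(float)
    obs = G != MISSING
    G = np.where(obs, G, 0.0)
    rng = np.random.default_rng(seed)

    if K == 1:
        denom = 2.0 * obs.sum(axis=0)
        f = np.divide(G.sum(axis=0), denom, out=np.full(m, 0.5), where=denom > 0)
        f = np.clip(f, _EPS, 1 - _EPS)
        ll = float((obs * (G * np.log(f) + (2 - G) * np.log(1 - f))).sum())
        return StructureResult(
            Q=np.ones((n, 1)), allele_freqs=f[None, :],
            loglik_trace=np.array([ll]), converged=True, K=1,
        )

    Q = rng.dirichlet(np.ones(K), size=n)
    base = np.divide(G.sum(axis=0), 2.0 * np.maximum(obs.sum(axis=0), 1))
    F = np.clip(base[None, :] + rng.normal(0, 0.05, size=(K, m)), 0.05, 0.95)

    trace = []
    converged = False
    for it in range(max_iter):
        P = np.clip(Q @ F, _EPS, 1 - _EPS)            # n x m
        ll = float((obs * (G * np.log(P) + (2 - G) * np.log(1 - P))).sum())
        trace.append(ll)
        if it > 0 and abs(trace[-1] - trace[-2]) < tol:
            converged = True
            break
        # responsibilities: alt alleles -> A, ref alleles -> B (at old Q, F)
        A = (obs * G) / P                              # n x m
        B = (obs * (2 - G)) / (1 - P)
        EA = Q * (A @ F.T)                             # n x K expected alt counts
        EB = Q * (B @ (1 - F).T)
        num = ((A.T @ Q).T) * F                        # K x m: sum_i A_ij q_ik f_kj
        den = num + ((B.T @ Q).T) * (1 - F)
        Q = (EA + EB) / np.maximum((EA + EB).sum(axis=1, keepdims=True), _EPS)
        F = np.clip(np.divide(num, np.maximum(den, _EPS)), _EPS, 1 - _EPS)

    order = np.argsort(Q.mean(axis=0))[::-1]
    return StructureResult(
        Q=Q[:, order], allele_freqs=F[order], loglik_trace=np.asarray(trace),
        converged=converged, K=K,
    )


def select_k_cv(
    gm: GenotypeMatrix,
    K_range: list[int],
    fold_mask: float = 0.1,
    seed: int = 0,
    max_iter: int = 300,
) -> dict[int, float]:
    """Cross-validation error per K by masked-entry prediction.

    A random ``fold_mask`` fraction of genotype entries is hidden, the
    admixture EM is fitted on the rest, and the CV error is the mean squared
    difference between hidden dosages and their fitted expectation
    2 * sum_k q_ik f_kj.  The K with the lowest error is the supported model;
    a flat curve indicates weak structure and is warned about.
    """
    if not K_range:
        raise ValueError("K_range is empty")
    if not (0.0 < fold_mask < 1.0):
        raise ValueError("fold_mask must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    obs = gm.dosages != MISSING
    mask = (rng.random(gm.dosages.shape) < fold_mask) & obs
    train = gm.dosages.copy()
    train[mask] = MISSING
    gm_train = GenotypeMatrix(
        sample_ids=list(gm.sample_ids), chrom=gm.chrom, pos=gm.pos,
        ref=gm.ref, alt=gm.alt, dosages=train,
    )
    errors: dict[int, float] = {}
    for K in K_range:
        res = admixture_em(gm_train, K, seed=seed + K, max_iter=max_iter)
        pred = 2.0 * res.Q @ res.allele_freqs
        errors[K] = float(np.mean((gm.dosages[mask] - pred[mask]) ** 2))
    # weak structure: no K improves meaningfully on the simplest model tried
    baseline = errors[min(errors)]
    if min(errors.values()) >= baseline * (1.0 - 0.02):
        warnings.warn("CV curve is flat: weak or no population structure",
                      stacklevel=2)
    return errors


# ---------------------------------------------------------------------------
# Distances and trees
# ---------------------------------------------------------------------------

def allele_sharing_distance(gm: GenotypeMatrix) -> np.ndarray:
    """d_ij = 1 - mean identity-by-state over sites typed in both samples."""
    D = gm.dosages.astype(float)
    obs = D != MISSING
    n = gm.n_samples
    dist = np.zeros((n, n))
    for i in range(n):
        both = obs[i] & obs
        diff = np.abs(D[i] - D)
        ibs = 1.0 - diff / 2.0
        with np.errstate(invalid="ignore"):
            mean_ibs = np.where(both, ibs, 0.0).sum(axis=1) / np.maximum(both.sum(axis=1), 1)
        dist[i] = 1.0 - mean_ibs
    dist = (dist + dist.T) / 2.0
    np.fill_diagonal(dist, 0.0)
    return dist


def nj_tree(dist: np.ndarray, ids: list[str]) -> TreeNode:
    """Neighbour-joining tree from a distance matrix.

    Negative branch lengths (possible on non-additive inputs) are clamped
    to zero.  For fewer than 3 taxa a trivially joined tree is returned.
    """
    n = len(ids)
    if dist.shape != (n, n):
        raise ValueError("distance matrix does not match id list")
    if n < 3:
        root = TreeNode(name=None)
        for i, name in enumerate(ids):
            length = float(dist[0, 1] / 2.0) if n == 2 else 0.0
            root.append(TreeNode(name=name, length=length))
        return root
    dm = DistanceMatrix(dist, ids)
    return nj(dm, neg_as_zero=True)


def hudson_fst(gm: GenotypeMatrix, labels: np.ndarray) -> float:
    """Hudson's Fst (ratio-of-averages) between two labelled groups."""
    groups = np.unique(labels)
    if len(groups) != 2:
        raise ValueError("hudson_fst requires exactly two groups")
    num_sum = den_sum = 0.0
    d = np.ma.masked_equal(gm.dosages, MISSING)
    for j in range(gm.n_snps):
        col = d[:, j]
        g1, g2 = col[labels == groups[0]], col[labels == groups[1]]
        n1, n2 = 2 * g1.count(), 2 * g2.count()
        if n1 < 4 or n2 < 4:
            continue
        p1, p2 = g1.sum() / n1, g2.sum() / n2
        num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
        den = p1 * (1 - p2) + p2 * (1 - p1)
        num_sum += num
        den_sum += den
    if den_sum == 0:
        return 0.0
    return float(num_sum / den_sum)


# ---------------------------------------------------------------------------
# LD decay
# ---------------------------------------------------------------------------

def ld_decay(
    gm: GenotypeMatrix,
    max_dist_bp: int = 10_000,
    bin_width: int = 100,
) -> LDDecayCurve:
    """Genotype r^2 versus physical distance, binned.

    r^2 is the squared Pearson correlation of dosages (composite LD —
    appropriate for unphased data) over same-chromosome pairs within
    ``max_dist_bp``.  The half-decay distance is where the binned mean first
    falls to half the maximum binned mean, linearly interpolated between bin
    midpoints.
    """
    X = gm.imputed()
    sd = X.std(axis=0)
    edges = np.arange(0, max_dist_bp + bin_width, bin_width)
    nbins = len(edges) - 1
    sums = np.zeros(nbins)
    counts = np.zeros(nbins, dtype=np.int64)
    for c in np.unique(gm.chrom):
        idx = np.where(gm.chrom == c)[0]
        pos = gm.pos[idx]
        order = np.argsort(pos)
        idx, pos = idx[order], pos[order]
        Z = X[:, idx]
        mu = Z.mean(axis=0)
        for a in range(len(idx)):
            hi = np.searchsorted(pos, pos[a] + max_dist_bp, side="right")
            if hi <= a + 1:
                continue
            js = np.arange(a + 1, hi)
            d = pos[js] - pos[a]
            usable = sd[idx[js]] > 0
            if sd[idx[a]] == 0 or not usable.any():
                continue
            js, d = js[usable], d[usable]
            za = Z[:, a] - mu[a]
            zb = Z[:, js] - mu[js]
            cov = za @ zb / Z.shape[0]
            r2 = (cov / (sd[idx[a]] * sd[idx[js]])) ** 2
            b = np.minimum((d - 1) // bin_width, nbins - 1).astype(int)
            np.add.at(sums, b, r2)
            np.add.at(counts, b, 1)
    if counts.sum() == 0:
        raise ValueError("no SNP pairs within max_dist_bp")
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    valid = ~np.isnan(means)
    max_r2 = float(np.nanmax(means))
    half = max_r2 / 2.0
    mids = (edges[:-1] + edges[1:]) / 2.0
    half_dist: float | None = None
    vm, vx = means[valid], mids[valid]
    start = int(np.nanargmax(means[valid]))
    for k in range(start, len(vm)):
        if vm[k] <= half:
            if k == 0:
                half_dist = float(vx[0])
            else:
                x0, x1, y0, y1 = vx[k - 1], vx[k], vm[k - 1], vm[k]
                half_dist = float(x0 + (y0 - half) * (x1 - x0) / (y0 - y1))
            break
    return LDDecayCurve(
        bin_edges=edges, mean_r2=means, n_pairs=counts,
        max_mean_r2=max_r2, half_decay_distance=half_dist,
    )
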