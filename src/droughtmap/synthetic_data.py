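"""Synthetic genotype / phenotype / KASP-plate generator.

Emulates the statistical structure the downstream analyses assume, so that
every stage of the pipeline is testable without real sequencing data:

* an admixed diploid population with K subpopulations whose allele
  frequencies follow the Balding-Nichols model (Beta around an ancestral
  frequency with variance Fst * p * (1-p));
* linkage disequilibrium from a two-state copy/switch haplotype chain:
  along a chromosome each haplotype either copies its previous allele state
  or, with probability 1 - exp(-recomb_switch * distance), draws a fresh
  allele from its current subpopulation frequency, so pairwise r^2 decays
  roughly as exp(-2 * recomb_switch * d) with half-decay ~ ln(2) /
  (2 * recomb_switch);
* 11 correlated pre/post physiological traits driven by 2-3 latent factors,
  the first proportional to minus a latent drought-tolerance score that
  carries planted QTL effects plus a kinship-structured polygenic term;
* two-channel endpoint-fluorescence (FAM/HEX) genotyping plates with one
  Gaussian cluster per genotype class and no-template controls near the
  origin.

Everything is driven by a single seed: a fixed config reproduces bit-
identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import GenotypeMatrix, GeneModel
from .physiology import TRAITS

#: Pre-stress baseline mean, baseline SD, adverse-change mean and SD per
#: trait, in the units of the trait panel.  Magnitudes are desk-realistic
#: for a diverse tea germplasm panel under moderate drought.
TRAIT_PROFILES: dict[str, tuple[float, float, float, float]] = {
    #            base    base_sd  change  change_sd
    "Pn":      (8.0,    1.2,     3.0,   1.0),
    "Trmmol":  (2.5,    0.4,     1.2,   0.4),
    "Cond":    (0.15,   0.03,    0.06,  0.02),
    "WUE":     (3.2,    0.5,     0.8,   0.3),
    "FvFm":    (0.80,   0.02,    0.07,  0.03),
    "MDA":     (5.0,    1.0,     7.0,   2.0),
    "RWC":     (85.0,   3.0,     6.5,   2.0),
    "Chla":    (1.20,   0.15,    0.20,  0.08),
    "Chlb":    (0.50,   0.08,    0.10,  0.04),
    "Chl":     (1.70,   0.20,    0.30,  0.11),
    "Car":     (0.35,   0.05,    0.06,  0.025),
}

#: Default loadings of the 11 adverse-change traits on 3 latent factors.
#: Factor 1 is minus the latent tolerance (photosynthesis, water status and
#: pigment traits), factor 2 captures stomatal traits, factor 3 WUE/MDA —
#: mirroring the factor structure such panels show.
DEFAULT_FACTOR_LOADINGS: dict[str, tuple[float, float, float]] = {
    "Pn":     (0.80, 0.15, 0.0),
    "Trmmol": (0.20, 0.80, 0.0),
    "Cond":   (0.20, 0.80, 0.0),
    "WUE":    (0.10, 0.0,  0.80),
    "FvFm":   (0.75, 0.0,  0.0),
    "MDA":    (0.30, 0.0,  0.70),
    "RWC":    (0.80, 0.0,  0.0),
    "Chla":   (0.85, 0.0,  0.0),
    "Chlb":   (0.80, 0.0,  0.0),
    "Chl":    (0.85, 0.0,  0.0),
    "Car":    (0.75, 0.0,  0.0),
}


@dataclass
class SimulationConfig:
    """Knobs of the population/phenotype simulator.

    ``recomb_switch`` is the per-bp rate of the copy/switch chain; with the
    default 3.2e-4 the r^2 half-decay sits near 1.1 kb, the scale reported
    for diverse outcrossing tea germplasm.  ``admixture_alpha`` is the
    symmetric Dirichlet concentration of individual ancestry (None draws
    each individual entirely from one subpopulation, useful for clean
    differentiation checks).
    """

    n_samples: int = 200
    n_snps: int = 2000
    K_true: int = 4
    fst: float = 0.15
    recomb_switch: float = 3.2e-4
    n_chrom: int = 2
    chrom_length: int = 1_000_000
    n_qtl: int = 3
    qtl_h2: float = 0.3
    polygenic_h2: float = 0.3
    n_traits: int = 11
    factor_loadings: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_FACTOR_LOADINGS)
    )
    noise_sd: float = 0.45
    admixture_alpha: float | None = 0.5
    maf_floor: float = 0.05
    missing_rate: float = 0.0
    n_replicates: int = 3
    replicate_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.fst < 1.0):
            raise ValueError(f"fst must lie in [0, 1), got {self.fst}")
        for name in ("qtl_h2", "polygenic_h2"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.qtl_h2 + self.polygenic_h2 > 1.0:
            raise ValueError("qtl_h2 + polygenic_h2 exceeds 1")


@dataclass
class SimulationTruth:
    """Ground truth of a simulated panel."""

    Q_true: np.ndarray                  # n x K admixture proportions
    subpop_freqs: np.ndarray            # K x m allele frequencies
    causal_ids: list[tuple[str, int]]   # (chrom, pos) of planted QTLs
    causal_index: np.ndarray            # column indices of planted QTLs
    effect_sizes: np.ndarray
    tolerance: np.ndarray | None = None # latent drought-tolerance score


def _balding_nichols(rng: np.random.Generator, p_anc: np.ndarray, fst: float,
                     K: int) -> np.ndarray:
    """K x m subpopulation frequencies with E=p, Var=fst*p*(1-p)."""
    if fst == 0.0:
        return np.tile(p_anc, (K, 1))
    scale = (1.0 - fst) / fst
    a = p_anc * scale
    b = (1.0 - p_anc) * scale
    return rng.beta(a[None, :], b[None, :], size=(K, len(p_anc)))


def _positions(rng: np.random.Generator, cfg: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    """Sorted random positions split across chromosomes."""
    per = np.full(cfg.n_chrom, cfg.n_snps // cfg.n_chrom)
    per[: cfg.n_snps % cfg.n_chrom] += 1
    chroms, poss = [], []
    for c, m_c in enumerate(per, start=1):
        p = np.sort(rng.choice(cfg.chrom_length, size=m_c, replace=False)) + 1
        chroms.append(np.full(m_c, f"chr{c}", dtype=object))
        poss.append(p)
    return np.concatenate(chroms), np.concatenate(poss).astype(np.int64)


def _copy_haplotypes(rng: np.random.Generator, freqs_by_anc: np.ndarray,
                     pos: np.ndarray, chrom: np.ndarray,
                     switch_rate: float) -> np.ndarray:
    """Haplotypes for one ancestry layer via the copy/switch chain.

    ``freqs_by_anc``: n_hap x m per-haplotype site frequencies (already
    resolved to each haplotype's ancestry at each site).
    """
    n_hap, m = freqs_by_anc.shape
    H = np.empty((n_hap, m), dtype=np.int8)
    H[:, 0] = rng.random(n_hap) < freqs_by_anc[:, 0]
    for j in range(1, m):
        if chrom[j] != chrom[j - 1]:
            p_copy = 0.0
        else:
            p_copy = np.exp(-switch_rate * (pos[j] - pos[j - 1]))
        copy = rng.random(n_hap) < p_copy
        fresh = rng.random(n_hap) < freqs_by_anc[:, j]
        H[:, j] = np.where(copy, H[:, j - 1], fresh)
    return H


def simulate_population(cfg: SimulationConfig) -> tuple[GenotypeMatrix, SimulationTruth]:
    """Simulate an admixed diploid panel with tunable differentiation and LD.

    Ancestral frequencies are Uniform(0.05, 0.95); subpopulation frequencies
    follow Balding-Nichols at the configured Fst; individual ancestry is
    Dirichlet(admixture_alpha); each of the two haplotypes per individual
    draws a single ancestry per chromosome from the individual's proportions
    and then runs the copy/switch chain against that subpopulation's
    frequencies.  Sites ending below the MAF floor have their frequencies
    redrawn from a common-allele band and are regenerated (without LD, which
    only perturbs a small minority of sites).
    """
    rng = np.random.default_rng(cfg.seed)
    n, m, K = cfg.n_samples, cfg.n_snps, cfg.K_true
    chrom, pos = _positions(rng, cfg)
    p_anc = rng.uniform(0.05, 0.95, size=m)
    F = _balding_nichols(rng, p_anc, cfg.fst, K)

    if cfg.admixture_alpha is None:
        labels = rng.integers(0, K, size=n)
        Q = np.zeros((n, K))
        Q[np.arange(n), labels] = 1.0
    else:
        Q = rng.dirichlet(np.full(K, cfg.admixture_alpha), size=n)

    # one ancestry draw per haplotype per chromosome
    chrom_ids = pd.unique(chrom)
    dosages = np.zeros((n, m), dtype=np.int8)
    for hap in range(2):
        anc = np.empty((n, m), dtype=np.int64)
        for c in chrom_ids:
            mask = chrom == c
            draw = np.array([rng.choice(K, p=Q[i]) for i in range(n)])
            anc[:, mask] = draw[:, None]
        freqs = F[anc, np.arange(m)[None, :]]
        dosages += _copy_haplotypes(rng, freqs, pos, chrom, cfg.recomb_switch)

    # MAF floor: resample rare/monomorphic sites as common unstructured sites
    if cfg.maf_floor > 0:
        p_obs = dosages.mean(axis=0) / 2.0
        bad = np.minimum(p_obs, 1 - p_obs) < cfg.maf_floor
        if bad.any():
            p_new = rng.uniform(0.2, 0.8, size=int(bad.sum()))
            dosages[:, bad] = rng.binomial(2, p_new[None, :], size=(n, int(bad.sum()))).astype(np.int8)

    if cfg.missing_rate > 0:
        miss = rng.random(dosages.shape) < cfg.missing_rate
        dosages[miss] = -1

    # plant QTLs on reasonably common sites for identifiable effects
    maf = np.minimum(dosages.mean(axis=0) / 2.0, 1 - dosages.mean(axis=0) / 2.0)
    eligible = np.where(maf >= 0.2)[0]
    if len(eligible) < cfg.n_qtl:
        eligible = np.argsort(maf)[::-1][: max(cfg.n_qtl, 1)]
    causal = np.sort(rng.choice(eligible, size=cfg.n_qtl, replace=False)) if cfg.n_qtl else np.array([], dtype=int)
    betas = rng.normal(0.0, 1.0, size=cfg.n_qtl)

    sample_ids = [f"ACC{i + 1:04d}" for i in range(n)]
    ref = rng.choice(list("ACGT"), size=m).astype(object)
    alt = np.array([rng.choice([b for b in "ACGT" if b != r]) for r in ref], dtype=object)
    gm = GenotypeMatrix(
        sample_ids=sample_ids, chrom=chrom, pos=pos, ref=ref, alt=alt, dosages=dosages,
    )
    truth = SimulationTruth(
        Q_true=Q,
        subpop_freqs=F,
        causal_ids=[(str(chrom[j]), int(pos[j])) for j in causal],
        causal_index=causal,
        effect_sizes=betas,
    )
    return gm, truth


def _scale_to_var(x: np.ndarray, target_var: float) -> np.ndarray:
    v = x.var()
    if v <= 0 or target_var <= 0:
        return np.zeros_like(x)
    return x * np.sqrt(target_var / v)


def simulate_phenotypes(
    gm: GenotypeMatrix,
    truth: SimulationTruth,
    cfg: SimulationConfig,
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Latent tolerance plus a factor-structured pre/post trait panel.

    tolerance = QTL term + polygenic term (multivariate normal with
    covariance proportional to the genotype kinship) + noise, with variance
    fractions qtl_h2 / polygenic_h2 / remainder.  Adverse trait changes mix
    2-3 latent factors (factor 1 = minus the standardized tolerance) through
    the configured loadings plus per-trait noise, then shift/scale to trait-
    typical magnitudes.  Post-stress values are pre -/+ the change depending
    on the trait's adverse direction (MDA rises, the rest fall).

    Returns a long-format replicate panel (accession, replicate, phase,
    11 traits) and the truth object with ``tolerance`` filled in.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    n = gm.n_samples
    if any(j >= gm.n_snps for j in truth.causal_index):
        raise ValueError("causal SNP index outside genotype matrix")

    X = gm.imputed()
    qtl = np.zeros(n)
    if len(truth.causal_index):
        G_c = X[:, truth.causal_index]
        qtl = (G_c - G_c.mean(axis=0)) @ truth.effect_sizes
    Xc = X - X.mean(axis=0)
    Kmat = Xc @ Xc.T / gm.n_snps
    # polygenic draw ~ N(0, K): scale an isotropic draw through chol(K + eps)
    L = np.linalg.cholesky(Kmat + 1e-6 * np.eye(n))
    poly = L @ rng.normal(size=n)
    noise = rng.normal(size=n)
    tol = (
        _scale_to_var(qtl, cfg.qtl_h2)
        + _scale_to_var(poly, cfg.polygenic_h2)
        + _scale_to_var(noise, 1.0 - cfg.qtl_h2 - cfg.polygenic_h2)
    )
    tol = (tol - tol.mean()) / (tol.std() if tol.std() > 0 else 1.0)
    truth.tolerance = tol

    traits = TRAITS[: cfg.n_traits]
    n_factors = len(next(iter(cfg.factor_loadings.values())))
    factors = np.vstack([-tol] + [rng.normal(size=n) for _ in range(n_factors - 1)])
    change = {}
    for t in traits:
        lam = np.asarray(cfg.factor_loadings[t])
        z = lam @ factors + cfg.noise_sd * rng.normal(size=n)
        base, base_sd, ch_mean, ch_sd = TRAIT_PROFILES[t]
        change[t] = ch_mean + ch_sd * z / np.sqrt(lam @ lam + cfg.noise_sd**2)
    # total chlorophyll is the sum of its parts, as in a real assay
    if "Chl" in traits and "Chla" in traits and "Chlb" in traits:
        change["Chl"] = change["Chla"] + change["Chlb"]

    rows = []
    for i, acc in enumerate(gm.sample_ids):
        pre_means = {}
        for t_name in traits:
            base, base_sd, _, _ = TRAIT_PROFILES[t_name]
            pre_means[t_name] = base + base_sd * rng.normal()
        for phase in ("pre", "post"):
            for rep in range(1, cfg.n_replicates + 1):
                row = {"accession": acc, "replicate": rep, "phase": phase}
                for t_name in traits:
                    base, base_sd, _, ch_sd = TRAIT_PROFILES[t_name]
                    val = pre_means[t_name]
                    if phase == "post":
                        sign = +1.0 if t_name == "MDA" else -1.0
                        val = val + sign * change[t_name][i]
                    val += cfg.replicate_sd * ch_sd * rng.normal()
                    if t_name == "FvFm":
                        val = float(np.clip(val, 0.01, 0.99))
                    elif t_name == "RWC":
                        val = float(np.clip(val, 1.0, 99.9))
                    row[t_name] = val
                rows.append(row)
    panel = pd.DataFrame(rows)
    return panel, truth


def place_genes_near_causal(
    gm: GenotypeMatrix, truth: SimulationTruth, gene_length: int = 3000,
    promoter_length: int = 2000,
) -> list[GeneModel]:
    """Single-exon gene models centred on each planted QTL (for window tests)."""
    models = []
    for g, (c, p) in enumerate(truth.causal_ids, start=1):
        start = max(1, p - gene_length // 2)
        end = start + gene_length - 1
        models.append(
            GeneModel(
                gene_id=f"GENE{g:03d}",
                chrom=c,
                strand="+" if g % 2 else "-",
                gene_span=(start, end),
                cds_segments=[(start, start + (gene_length // 3) * 3 - 1)],
                promoter_length=promoter_length,
            )
        )
    return models


# ---------------------------------------------------------------------------
# KASP plates
# ---------------------------------------------------------------------------

#: Mean (FAM, HEX) endpoint signal per class, arbitrary units after
#: baseline subtraction.  NTC sits near the origin.
KASP_CENTERS = {
    "hom1": (2.0, 0.35),
    "het": (1.2, 1.2),
    "hom2": (0.35, 2.0),
    "ntc": (0.08, 0.08),
}


def simulate_kasp_plate(
    n_per_genotype: int | dict[str, int] = 10,
    noise_sd: float = 0.10,
    n_ntc: int = 2,
    seed: int = 0,
    marker: str = "chr10:206216541:C:T",
) -> tuple[pd.DataFrame, pd.Series]:
    """Simulate endpoint FAM/HEX fluorescence wells for one SNP marker.

    Each genotype class is an isotropic Gaussian cluster around its
    characteristic signal; no-template controls sit near the origin with
    magnitude well below any genotype cluster.  Returns the plate table
    (well, sample, FAM, HEX, is_ntc) and the truth labels per sample.
    """
    rng = np.random.default_rng(seed)
    if isinstance(n_per_genotype, int):
        if n_per_genotype < 1:
            raise ValueError("n_per_genotype must be >= 1")
        counts = {g: n_per_genotype for g in ("hom1", "het", "hom2")}
    else:
        counts = dict(n_per_genotype)
        if any(v < 0 for v in counts.values()) or sum(counts.values()) < 1:
            raise ValueError("invalid per-genotype well counts")
    rows, labels = [], {}
    w = 0
    for cls in ("hom1", "het", "hom2"):
        cx, cy = KASP_CENTERS[cls]
        for _ in range(counts.get(cls, 0)):
            w += 1
            sample = f"S{w:03d}"
            fam = max(0.0, cx + noise_sd * rng.normal())
            hex_ = max(0.0, cy + noise_sd * rng.normal())
            rows.append({"well": f"W{w:03d}", "sample": sample,
                         "FAM": fam, "HEX": hex_, "is_ntc": False})
            labels[sample] = cls
    cx, cy = KASP_CENTERS["ntc"]
    for k in range(n_ntc):
        w += 1
        rows.append({"well": f"W{w:03d}", "sample": f"NTC{k + 1}",
                     "FAM": max(0.0, cx + 0.3 * noise_sd * rng.normal()),
                     "HEX": max(0.0, cy + 0.3 * noise_sd * rng.normal()),
                     "is_ntc": True})
    plate = pd.DataFrame(rows)
    plate.attrs["marker"] = marker
    return plate, pd.Series(labels, name="genotype")
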