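# Methods

`droughtmap` implements the analysis chain used to dissect drought
tolerance in a diverse diploid germplasm panel (the motivating system is
tea, *Camellia sinensis*, but nothing is species-specific): physiological
assay arithmetic, a composite drought-resistance index, population
structure and LD description, a mixed-linear-model genome scan, candidate-
gene and haplotype analysis, and endpoint-fluorescence (KASP) genotype
calling. A seeded synthetic-data module generates panels with the
statistical structure these methods assume, so every stage is testable
without sequencing data.

## Physiological indices

Assays are evaluated exactly as printed on instrument readouts:

- MDA (nmol/g FW) = 51.6 · (A532 − A600) / W — thiobarbituric-acid adduct
  absorbance corrected for turbidity, per gram fresh weight.
- RWC (%) = (W₀ − Wd)/W₀ · 100 from fresh and dry leaf weight.
- Chl a (mg/L) = 13.95·A665 − 6.88·A649; Chl b = 24.96·A649 − 7.32·A665;
  Car = (1000·A470 − 2.05·Ca − 114.8·Cb)/245; tissue content (mg/g FW) =
  C·V/(1000·W). The linear forms can go negative for pathological
  absorbance combinations; values are kept but warned about.
- WUE = Pn/Trmmol; qPCR relative expression by 2^−ΔCt or 2^−ΔΔCt.

Eleven indicators form the panel: Pn, Trmmol, Cond, WUE, Fv/Fm, MDA, RWC,
Chl a, Chl b, total Chl, Car. Per accession, replicates are averaged
(mean by default, median available) within phase before differencing. The
adverse change is X_ij = s_j·(mean_pre − mean_post) with s_j = +1 for
traits whose decline is adverse and −1 for MDA. The direction table is
data, not logic: pigments rise under stress in most accessions of a
diverse panel, and whether that is scored adverse is a configuration
choice.

## Composite drought-resistance index (D-value)

1. **Membership normalization** Y_ij = (Xj_max − X_ij)/(Xj_max − Xj_min).
   This is deliberately the *reversed* min–max form: the accession with the
   largest adverse change scores 0, the smallest scores 1, so larger D
   means stronger resistance. `membership="standard"` restores the
   ascending form; a constant column is rejected by name.
2. **PCA** of the column-standardized membership matrix via
   eigendecomposition of the trait correlation matrix (covariance mode
   available). Loadings are unit-norm eigenvectors; each column's sign is
   fixed so its loadings sum positive, which orients the dominant
   component with overall membership (and hence with tolerance) and makes
   results reproducible across BLAS implementations. Retention default is
   the smallest k with cumulative contribution ≥ 75% (alternatives:
   eigenvalue > 1, fixed k). On the default synthetic panel this retains 3
   of 11 components at ~84% cumulative contribution.
3. **Weights** W_j = P_j/ΣP_j over retained contributions; **D_i = Σ_j
   F_ij·W_j** with F the raw component scores. Accessions are ranked by
   descending D.

D is invariant to positive affine rescaling of any raw trait (the
membership step removes location and scale) — a property test asserts this
to 1e-10. Scores are raw PC scores; no second membership transform is
applied to F.

## Synthetic panels

`simulate_population` draws ancestral allele frequencies from
Uniform(0.05, 0.95) and subpopulation frequencies from the Balding–Nichols
Beta model (mean p, variance Fst·p(1−p)). Individual ancestry is
Dirichlet(α = 0.5) across K subpopulations (α configurable; `None` makes
each individual single-origin, which clean differentiation and admixture-
recovery checks need). Haplotypes follow a two-state copy/switch chain
along each chromosome: with probability exp(−c·d) over a gap of d bp the
previous allele state is copied, otherwise a fresh allele is drawn from
the current subpopulation frequency. This gives pairwise r² ≈ exp(−2c·d),
so the expected half-decay distance is ln 2/(2c); the default
c = 3.2·10⁻⁴/bp puts half-decay near 1.1 kb, the scale typical of diverse
outcrossing tea germplasm. Sites below the 0.05 MAF floor are resampled
as unstructured common sites so downstream fixtures are well conditioned.

The latent drought tolerance of each accession is a sum of planted-QTL
effects, a kinship-structured polygenic term, and noise, with variance
fractions qtl_h2/polygenic_h2/remainder. Trait changes mix three latent
factors — factor 1 is minus the standardized tolerance; factors 2 and 3
are independent — through a loadings table that mirrors the factor
structure such panels show (photosynthesis/water-status/pigment traits on
factor 1, stomatal traits on factor 2, WUE and MDA on factor 3), then are
shifted and scaled to trait-typical magnitudes (e.g. mean Fv/Fm decline
0.07, RWC decline 6.5%, MDA rise 7 nmol/g). Total chlorophyll change is
the sum of the Chl a and b changes, reproducing the near-unity correlation
of pigment indicators in real panels. What the generator does **not**
emulate: genotype-by-environment interaction, measurement batch effects,
selection or demography beyond island-model differentiation, and sequence-
level realism — passing tests therefore demonstrate the estimators'
correctness under their assumed model, not robustness to every field
artifact.

KASP plates place one isotropic Gaussian cluster per genotype class in
(FAM, HEX) space — allele-1 homozygotes FAM-high, allele-2 homozygotes
HEX-high, heterozygotes on the diagonal — with no-template controls near
the origin at well under a quarter of any cluster magnitude.

## Population structure and LD

- **Kinship**: K = X_c X_cᵀ/m from per-SNP mean-imputed, mean-centered
  dosages; positive semidefinite by construction.
- **PCA**: SVD of the centered (optionally 1/√(2p(1−p))-scaled) dosage
  matrix.
- **Admixture**: binomial-likelihood EM over ancestry proportions Q and
  subpopulation frequencies F (g_ij ~ Binomial(2, Σ_k q_ik f_kj)), missing
  genotypes excluded from the likelihood; the trace is monotone
  non-decreasing and non-convergence within the iteration cap (default
  2000, Δloglik < 10⁻⁶) is flagged rather than raised. K is chosen by
  masked-entry cross-validation: 10% of entries are hidden, the model is
  fitted on the rest, and the CV error is the MSE of the hidden dosages
  against 2·Σ_k q_ik f_kj. A curve whose best K does not improve on the
  smallest K tried by more than 2% is reported with a weak-structure
  warning.
- **Trees**: allele-sharing distance d = 1 − IBS, neighbour joining
  (scikit-bio's Saitou–Nei implementation; negative branch lengths clamped
  to zero). Tests verify NJ against exhaustive least-squares topology
  search on additive matrices.
- **LD decay**: genotype (composite) r² — the squared Pearson correlation
  of unphased dosages — for same-chromosome pairs within a window, binned
  by distance; the half-decay distance is where the binned mean first
  falls to half its maximum, linearly interpolated between bin midpoints.

Missing-data policy: mean imputation for PCA/kinship/GWAS (simple and
adequate at the low missingness the generator produces), likelihood
exclusion for the EM. MAF filter default 0.05 before structure/LD/GWAS.

## Mixed-model GWAS

Per SNP, y = Wα + xβ + u + ε with u ~ N(0, σ_g²K) and ε ~ N(0, σ_e²I);
W is an intercept plus structure covariates (default: top-3 genotype PCs;
admixture Q columns can be substituted). K is eigendecomposed once and the
restricted likelihood maximized over log δ ∈ [−10, 10] (δ = σ_e²/σ_g²) by
bounded scalar minimization. The default scan (`p3d`) reuses the null δ̂
for every SNP and performs GLS in the rotated space; `exact` re-optimizes
δ per SNP (the two agree within 0.2 −log10 units on moderate-heritability
fixtures). The Wald statistic (β̂/se)² is referred to χ²₁, with the
residual variance re-estimated per SNP model — this makes the K = I case
collapse exactly to the squared OLS t statistic, which the tests exploit
as an independent oracle. With K = I only the total variance is
identified; the null fit then reports an arbitrary split of the same
total, documented in the API.

Significance is Bonferroni on the number of SNPs actually tested:
genome-wide 0.05/N, suggestive 0.1/N. At N = 28,383,000 these evaluate to
1.76·10⁻⁹ (−log10 = 8.75) and 3.52·10⁻⁹ (−log10 = 8.45). Diagnostics:
λ_GC = median(χ²_obs)/χ²₁(0.5), QQ pairs at expected −log10((i−0.5)/n),
and a Manhattan table with cumulative genome coordinates.

## Candidate genes and haplotypes

Significant SNPs define closed-interval windows ±50 kb (clipped at
position 1); a gene is a candidate iff its span intersects the window.
Variant effects are annotated at codon level against a reference sequence
(strand-aware spliced CDS, standard genetic code; synonymous/missense/
nonsense with labels like Thr93Ala). Promoter windows default to 2 kb
upstream of the TSS (configurable) — a convention, since upstream
regulatory extents are rarely known.

Haplotypes are genotype-haplotypes: phase is unavailable, so the default
policy keeps the heterozygous state as its own per-site symbol (0/H/2); an
alternative drops accessions heterozygous anywhere in the region. Classes
are ordered by descending carrier count (ties broken lexicographically),
named Hap-P1…/Hap-C1… by region, and classes with fewer than five carriers
(configurable) are rare and excluded, their members marked unassigned.
The class network is a minimum spanning tree over Hamming distances with
fully deterministic tie-breaking — an MST rather than a median-joining
network because it needs no inferred intermediate states and is verifiable
against an exhaustive oracle. Class phenotypes are compared by one-way
ANOVA plus pairwise Welch t-tests with Holm adjustment; all-identical
values make F undefined and are flagged rather than propagated.

## KASP calling

Wells are normalized by subtracting the NTC centroid (floored at zero).
Wells whose magnitude falls below τ = 0.25 of the median non-NTC magnitude
are no-calls. The rest are clustered by k-means (k = 3, 20 seeded
restarts) on (angle, magnitude/median) — polar coordinates make the
procedure invariant to any common positive scale factor, since the axes'
gains are instrument-dependent. Clusters whose mean angles lie within
0.2 rad are merged (a plate missing a genotype class would otherwise have
a true cluster split in two), and surviving clusters are labelled by the
nearest reference angle: 0 → allele-1 homozygote (FAM), π/4 → heterozygote,
π/2 → allele-2 homozygote (HEX). Confidence is one minus the ratio of the
nearest to second-nearest cluster-angle distance. Concordance against an
expected map reports call rate, agreement over called wells, and a
confusion table.

## Pipeline, determinism and problem sizes

`run_all` executes simulate → trait changes → D-value → structure/tree/LD
→ GWAS → candidate windows → haplotypes → KASP, honouring stage toggles
(disabling GWAS skips candidates with a warning), and writes a JSON
manifest listing every output file with its SHA-256 plus the full
parameter set. All randomness funnels through one master seed; a rerun
with the same config is byte-identical, which the tests assert via
manifest hashes.

Default study conditions follow the motivating design where stated
(11 traits, 3 retained components, rare-haplotype cutoff 5, ±50 kb flanks,
Bonferroni thresholds) and desk-realistic choices elsewhere: panels of
80–300 accessions and 500–5000 SNPs in tests, which are the smallest sizes
at which the stochastic recovery targets (Fst ± 0.05, mean |ΔQ| < 0.15,
half-decay ± 30%, QTL top-hit recovery) are comfortably identifiable.
Numerical tolerances: PSD checks at −10⁻⁸, EM convergence 10⁻⁶, REML
bracket log δ ∈ [−10, 10] with 10⁻⁶ tolerance, D-value reproducibility
10⁻¹⁰.

## Known limitations

- The admixture EM is a desk-scale reimplementation; it is not
  block-relaxation accelerated and can hit the iteration cap on large
  panels (flagged, not fatal).
- LD r² uses composite genotype correlation, not haplotype r²; the two
  differ under strong inbreeding.
- The variance-component ratio is weakly identified when K ≈ I (near-
  unstructured panels with many markers); only the total variance is then
  meaningful.
- Effect annotation handles SNPs only (no indels/splice sites) and one
  transcript per gene.
- The KASP caller assumes one biallelic marker per plate and FAM =
  allele 1; marker metadata can flip the mapping but multi-marker plates
  must be split upstream.
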