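"""End-to-end orchestration: simulate or load inputs, then run the stages
in dependency order (traits -> D-value -> structure -> GWAS -> candidate
windows -> haplotypes -> KASP), writing every output file plus a JSON run
manifest with input hashes and parameters.  All randomness derives from one
master seed, so a rerun with the same config is byte-identical."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .drought_index import evaluate_drought_resistance
from .genehap import build_haplotypes, candidate_windows, haplotype_network_mst
from .gwas import lmm_scan, manhattan_table
from .io_formats import write_gff3, write_newick, write_vcf
from .kasp import call_genotypes, concordance
from .popgen import (
    admixture_em,
    allele_sharing_distance,
    genotype_pca,
    kinship_centered,
    ld_decay,
    nj_tree,
)
from .synthetic_data import (
    SimulationConfig,
    place_genes_near_causal,
    simulate_kasp_plate,
    simulate_phenotypes,
    simulate_population,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    out_dir: str = "pipeline_out"
    seed: int = 0
    # simulation scale
    n_samples: int = 200
    n_snps: int = 2000
    K_true: int = 3
    fst: float = 0.15
    n_qtl: int = 3
    qtl_h2: float = 0.3
    polygenic_h2: float = 0.3
    # stage toggles
    run_structure: bool = True
    run_tree: bool = True
    run_ld: bool = True
    run_gwas: bool = True
    run_candidates: bool = True
    run_haplotypes: bool = True
    run_kasp: bool = True
    # stage parameters
    retain_rule: str = "cum:0.75"
    maf_min: float = 0.05
    gwas_mode: str = "p3d"
    n_pcs: int = 3
    admixture_max_iter: int = 300
    flank: int = 50_000
    min_carriers: int = 5
    tau: float = 0.25
    ld_max_dist: int = 10_000
    ld_bin_width: int = 200

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        flat: dict = {}
        for key, val in raw.items():
            if isinstance(val, dict):
                flat.update(val)
            else:
                flat[key] = val
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(flat) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**flat)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(config: PipelineConfig) -> dict:
    """Execute all enabled stages and return the run manifest.

    Stage order respects data dependencies; disabling a stage disables its
    dependents with an explicit warning.  Every written file is listed in
    ``manifest.json`` with its SHA-256, alongside the full parameter set.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def save_df(df: pd.DataFrame, name: str, index: bool = False) -> Path:
        p = out / name
        df.to_csv(p, sep="\t", index=index, float_format="%.10g")
        written.append(p)
        return p

    manifest: dict = {
        "package_version": __version__,
        "parameters": dataclasses.asdict(config),
        "stages": [],
        "files": {},
    }

    # --- stage: simulate -------------------------------------------------
    sim_cfg = SimulationConfig(
        n_samples=config.n_samples, n_snps=config.n_snps, K_true=config.K_true,
        fst=config.fst, n_qtl=config.n_qtl, qtl_h2=config.qtl_h2,
        polygenic_h2=config.polygenic_h2, seed=config.seed,
    )
    gm, truth = simulate_population(sim_cfg)
    panel, truth = simulate_phenotypes(gm, truth, sim_cfg)
    logger.info("simulated %d samples x %d SNPs", gm.n_samples, gm.n_snps)
    vcf_path = out / "genotypes.vcf"
    write_vcf(gm, vcf_path)
    written.append(vcf_path)
    save_df(panel, "phenotypes.tsv")
    genes = place_genes_near_causal(gm, truth)
    gff_path = out / "genes.gff3"
    write_gff3(genes, gff_path)
    written.append(gff_path)
    truth_path = out / "truth.json"
    truth_path.write_text(json.dumps({
        "causal_ids": [[c, p] for c, p in truth.causal_ids],
        "effect_sizes": list(map(float, truth.effect_sizes)),
        "tolerance": list(map(float, truth.tolerance)),
    }, indent=1))
    written.append(truth_path)
    manifest["stages"].append("simulate")

    # --- stage: drought index -------------------------------------------
    dres = evaluate_drought_resistance(panel, retain_rule=config.retain_rule)
    dvalue_df = pd.DataFrame({
        "accession": dres.d.index,
        "D": dres.d.to_numpy(),
        "rank": [dres.ranking.index(a) + 1 for a in dres.d.index],
    })
    save_df(dvalue_df, "dvalue.tsv")
    save_df(dres.pca.loadings, "pca_loadings.tsv", index=True)
    manifest["stages"].append("drought_index")

    # --- stage: structure -------------------------------------------------
    kin = kinship_centered(gm)
    covariates = None
    if config.run_structure:
        coords, explained = genotype_pca(gm, n_components=max(config.n_pcs, 2))
        covariates = coords[:, : config.n_pcs]
        pca_df = pd.DataFrame(
            coords, columns=[f"PC{i + 1}" for i in range(coords.shape[1])]
        )
        pca_df.insert(0, "accession", gm.sample_ids)
        save_df(pca_df, "genotype_pca.tsv")
        struct = admixture_em(
            gm, K=config.K_true, seed=config.seed + 11,
            max_iter=config.admixture_max_iter,
        )
        q_df = pd.DataFrame(
            struct.Q, columns=[f"Q{k + 1}" for k in range(struct.K)]
        )
        q_df.insert(0, "accession", gm.sample_ids)
        save_df(q_df, "admixture_Q.tsv")
        manifest["stages"].append("structure")
    if config.run_tree:
        dist = allele_sharing_distance(gm)
        tree = nj_tree(dist, gm.sample_ids)
        tree_path = out / "nj_tree.nwk"
        tree_path.write_text(write_newick(tree) + "\n")
        written.append(tree_path)
        manifest["stages"].append("tree")
    if config.run_ld:
        curve = ld_decay(gm, max_dist_bp=config.ld_max_dist,
                         bin_width=config.ld_bin_width)
        ld_df = pd.DataFrame({
            "bin_start": curve.bin_edges[:-1],
            "bin_end": curve.bin_edges[1:],
            "mean_r2": curve.mean_r2,
            "n_pairs": curve.n_pairs,
        })
        save_df(ld_df, "ld_decay.tsv")
        manifest["ld_half_decay_bp"] = curve.half_decay_distance
        manifest["stages"].append("ld")

    # --- stage: GWAS ------------------------------------------------------
    gwas_res = None
    if config.run_gwas:
        d_by_sample = dres.d.reindex(gm.sample_ids).to_numpy()
        gwas_res = lmm_scan(
            d_by_sample, gm, kin, covariates=covariates,
            mode=config.gwas_mode, maf_min=config.maf_min,
        )
        save_df(manhattan_table(gwas_res), "gwas_D.tsv")
        th = gwas_res.thresholds
        thr_path = out / "thresholds.json"
        thr_path.write_text(json.dumps({
            "n_valid_snps": th.n_valid_snps,
            "p_genomewide": th.p_genomewide,
            "p_suggestive": th.p_suggestive,
            "neg_log10_genomewide": round(th.neg_log10_genomewide, 2),
            "neg_log10_suggestive": round(th.neg_log10_suggestive, 2),
            "lambda_gc": gwas_res.lambda_gc,
        }, indent=1))
        written.append(thr_path)
        manifest["stages"].append("gwas")

    # --- stage: candidate windows ----------------------------------------
    if config.run_candidates:
        if gwas_res is None:
            warnings.warn("GWAS stage disabled; skipping candidate windows",
                          stacklevel=2)
        else:
            t = gwas_res.table
            top = t.nsmallest(max(config.n_qtl, 1), "wald_p")
            snps = [(str(r.chrom), int(r.pos)) for r in top.itertuples()]
            wins = candidate_windows(snps, genes, flank=config.flank)
            win_df = pd.DataFrame([
                {"chrom": w.chrom, "pos": w.pos, "start": w.span[0],
                 "end": w.span[1], "genes": ",".join(w.gene_ids)}
                for w in wins
            ])
            save_df(win_df, "candidate_windows.tsv")
            manifest["stages"].append("candidates")

    # --- stage: haplotypes -------------------------------------------------
    if config.run_haplotypes and genes:
        g0 = genes[0]
        for label, span in (("promoter", g0.promoter_span),
                            ("coding", (g0.gene_span[0], g0.gene_span[1]))):
            try:
                tab = build_haplotypes(
                    gm, span, g0.chrom, region_label=label,
                    min_carriers=config.min_carriers,
                )
            except ValueError:
                continue
            save_df(tab.classes, f"haplotypes_{label}.tsv")
            assign = tab.assignments.rename_axis("accession").reset_index()
            save_df(assign, f"haplotype_assignments_{label}.tsv")
            net = haplotype_network_mst(tab)
            net_df = pd.DataFrame(net, columns=["class_a", "class_b", "distance"])
            save_df(net_df, f"haplotype_network_{label}.tsv")
        manifest["stages"].append("haplotypes")

    # --- stage: KASP -------------------------------------------------------
    if config.run_kasp:
        plate, labels = simulate_kasp_plate(seed=config.seed + 23)
        calls = call_genotypes(plate, seed=config.seed + 23, tau=config.tau)
        save_df(plate, "kasp_plate.tsv")
        calls_df = calls.calls.rename_axis("sample").reset_index()
        save_df(calls_df, "kasp_calls.tsv")
        conc = concordance(calls, labels)
        manifest["kasp_concordance"] = {
            "n": conc["n"], "call_rate": conc["call_rate"],
            "agreement": conc["agreement"],
        }
        manifest["stages"].append("kasp")

    manifest["files"] = {p.name: _sha256(p) for p in written}
    man_path = out / "manifest.json"
    man_path.write_text(json.dumps(manifest, indent=1, default=str))
    return manifest
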