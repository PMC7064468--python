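"""End-to-end orchestration: simulate, adjust, stability, blocks, GWAS,
epistasis, prediction and model comparison, with input validation and a
reproducible run manifest.

A single global seed fans out to every stochastic stage through named
SeedSequence substreams, so inserting or toggling a stage never perturbs
the randomness of the others.  The manifest records the package version,
per-stage seeds, input hashes and the files each stage wrote; reruns with
the same seed produce identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io as hio
from .assoc import (bonferroni_threshold, classify_groups, mlm_scan_hap,
                    mlm_scan_snp, pca_covariates, vanraden_kinship)
from .epistasis import epistatic_variance_summary, interaction_scan
from .gblup import (ChainSettings, ModelSpec, compare_models, cross_validate,
                    kernel_additive, kernel_gaussian, kernel_haplotype)
from .ldblocks import build_blocks, call_haplotypes, filter_snps
from .pheno import adjust_gy_block_effects, broad_sense_h2
from .simdata import SimConfig, simulate_genotypes, simulate_trials
from .stability import stability_results, stability_vs_mean

STAGES = ("simulate", "adjust", "stability", "blocks", "gwas",
          "epistasis", "predict", "compare")


@dataclass
class PipelineConfig:
    out_dir: Path
    seed: int = 0
    stages: tuple = STAGES
    sim: dict = field(default_factory=dict)
    maf_min: float = 0.15
    max_missing: float = 0.40
    hap_freq_min: float = 0.05
    p_threshold: str | float = "bonferroni"
    epi_p_cut: float = 0.001
    cv_repeats: int = 20
    cv_test_frac: float = 0.10
    models: tuple = (1, 2, 3, 4)
    backend: str = "reml"
    chain: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw["out_dir"] = Path(raw.get("out_dir", "haplogp_run"))
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _stage_seed(seed: int, stage: str) -> int:
    ss = np.random.SeedSequence([seed, STAGES.index(stage)])
    return int(ss.generate_state(1)[0] % (2 ** 31 - 1))


def _hash_file(path: Path) -> str:
    return hashlib.sha1(path.read_bytes()).hexdigest()[:16]


def validate_inputs(paths: dict[str, str | Path]) -> list[str]:
    """Schema checks for pipeline inputs; returns an itemized issue list."""
    issues: list[str] = []
    vcf = paths.get("vcf")
    if vcf is not None:
        try:
            geno = hio.read_vcf(vcf)
            for c in pd.unique(geno.chrom):
                p = geno.pos[geno.chrom == c]
                bad = np.where(np.diff(p) < 0)[0]
                if bad.size:
                    issues.append(
                        f"VCF not sorted: {c}:{p[bad[0] + 1]} after {c}:{p[bad[0]]}"
                    )
                    break
        except Exception as exc:  # malformed file
            issues.append(f"VCF unreadable: {exc}")
    pheno = paths.get("pheno")
    if pheno is not None:
        try:
            rec = hio.read_pheno_csv(pheno)
            for (eyt, env), tdf in rec.groupby(["eyt", "env"]):
                n_checks = tdf.loc[tdf["is_check"], "line"].nunique()
                if n_checks < 2:
                    issues.append(
                        f"trial ({eyt}, {env}) has {n_checks} distinct check "
                        "line(s); at least 2 required"
                    )
        except Exception as exc:
            issues.append(f"phenotype CSV invalid: {exc}")
    for name, p in paths.items():
        if p is not None and not Path(p).exists():
            issues.append(f"{name} file not found: {p}")
    return issues


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the configured stages in dependency order; return the manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": cfg.seed, "stages": {}}

    def record(stage: str, files: list[Path], extra: dict | None = None):
        manifest["stages"][stage] = {
            "seed": _stage_seed(cfg.seed, stage),
            "outputs": {str(f.name): _hash_file(f) for f in files},
            **(extra or {}),
        }

    try:
        sim_cfg = SimConfig(seed=_stage_seed(cfg.seed, "simulate"), **cfg.sim)
        geno = simulate_genotypes(sim_cfg)
        records, truth = simulate_trials(geno, sim_cfg)
        vcf_p, pheno_p, truth_p = out / "geno.vcf", out / "pheno.csv", out / "truth.json"
        hio.write_vcf(geno, vcf_p)
        hio.write_pheno_csv(records, pheno_p)
        hio.write_truth_json(truth, truth_p)
        record("simulate", [vcf_p, pheno_p, truth_p])

        adj = adjust_gy_block_effects(records)
        h2 = broad_sense_h2(records)
        adj_p, h2_p = out / "adj_means.csv", out / "heritability.csv"
        hio.write_adjmeans_csv(adj.values, adj_p)
        h2.to_csv(h2_p)
        record("adjust", [adj_p, h2_p], {"h2": h2.to_dict()})

        stab_frames = []
        for eyt in sim_cfg.eyt_names:
            st = stability_results(adj, eyt)
            st.insert(0, "line", st.index)
            stab_frames.append(st)
        stab = pd.concat(stab_frames, ignore_index=True)
        stab_p = out / "stability.csv"
        stab.to_csv(stab_p, index=False)
        record("stability", [stab_p],
               {"corr": stability_vs_mean(stab_frames[0]).to_dict()})

        filt = filter_snps(geno, cfg.max_missing, cfg.maf_min)
        blocks = build_blocks(filt)
        H = call_haplotypes(filt, blocks, cfg.hap_freq_min)
        blocks_p = out / "blocks.tsv"
        hio.write_blocks(blocks, blocks_p, out / "blocks.blocks")
        hio.write_hapmatrix(H, out / "hapmatrix.tsv")
        record("blocks", [blocks_p, out / "blocks.blocks", out / "hapmatrix.tsv"],
               {"n_blocks": len(blocks)})

        K = vanraden_kinship(filt)
        scans = []
        for eyt, env in adj.trials:
            yv = adj.values[(eyt, env)]
            pcs, k = pca_covariates(filt, yv)
            covars = pcs.iloc[:, :k] if k else None
            snp_res = mlm_scan_snp(yv, filt, K, covars, trial=(eyt, env))
            hap_res = mlm_scan_hap(yv, H, K, covars, trial=(eyt, env))
            scans.append(("snp", snp_res))
            scans.append(("hap", hap_res))
        snp_all = pd.concat([d for t, d in scans if t == "snp"], ignore_index=True)
        hap_all = pd.concat([d for t, d in scans if t == "hap"], ignore_index=True)
        thr_snp = (bonferroni_threshold(filt.n_snps)
                   if cfg.p_threshold == "bonferroni" else float(cfg.p_threshold))
        thr_hap = (bonferroni_threshold(max(len(blocks), 1))
                   if cfg.p_threshold == "bonferroni" else float(cfg.p_threshold))
        groups = classify_groups(hap_all, thr_hap) if not hap_all.empty else pd.DataFrame()
        gwas_p = out / "gwas_snp.tsv"
        hap_p = out / "gwas_hap.tsv"
        snp_all.to_csv(gwas_p, sep="\t", index=False)
        hap_all.to_csv(hap_p, sep="\t", index=False)
        groups.to_csv(out / "gwas_groups.tsv", sep="\t", index=False)
        record("gwas", [gwas_p, hap_p, out / "gwas_groups.tsv"],
               {"n_snp_hits": int((snp_all["p_value"] <= thr_snp).sum())
                if not snp_all.empty else 0,
                "n_hap_hits": int((hap_all["p_value"] <= thr_hap).sum())
                if not hap_all.empty else 0})

        eyt0 = sim_cfg.eyt_names[0]
        y0 = adj.values[[c for c in adj.values.columns if c[0] == eyt0]]
        y0 = y0.droplevel(0, axis=1)
        loci = np.nan_to_num(filt.codes, nan=np.nan)
        top = (snp_all[snp_all["eyt"] == eyt0]
               .sort_values("p_value").drop_duplicates("locus").head(10)
               if "eyt" in snp_all else snp_all.head(10))
        sel = [filt.snp_ids.index(l) for l in top["locus"]]
        epi = interaction_scan(
            y0.mean(axis=1).to_numpy(), loci[:, sel],
            locus_names=[filt.snp_ids[i] for i in sel],
            order=2, p_cut=cfg.epi_p_cut, report_all=True,
        )
        epi_p = out / "epistasis.tsv"
        epi.to_csv(epi_p, sep="\t", index=False)
        summary = epistatic_variance_summary(epi[epi["p_value"] < cfg.epi_p_cut])
        record("epistasis", [epi_p],
               {"n_significant": int((epi["p_value"] < cfg.epi_p_cut).sum()),
                "summary": summary.to_dict("records")})

        kernels = {
            "G_M": kernel_additive(filt),
            "G_H": kernel_haplotype(H),
            "G_MG": kernel_gaussian(filt),
            "G_HG": kernel_gaussian(H),
        }
        fixed_marker = fixed_hap = None
        if not top.empty:
            fm = pd.DataFrame(
                {l: np.nan_to_num(filt.codes[:, filt.snp_ids.index(l)], nan=0.0)
                 for l in top["locus"].head(3)},
                index=filt.line_ids,
            )
            fixed_marker = fm
        if not groups.empty:
            best_blocks = groups["locus"].head(3).tolist()
            cols = [i for i, b in enumerate(H.columns["block"]) if b in best_blocks]
            if cols:
                fixed_hap = pd.DataFrame(
                    H.incidence[:, cols], index=H.line_ids,
                    columns=[f"{H.columns['block'][i]}:{H.columns['allele'][i]}"
                             for i in cols],
                )
        cv_results = []
        chain = ChainSettings(**cfg.chain) if cfg.chain else ChainSettings()
        for mid in cfg.models:
            spec = ModelSpec.from_id(mid, epistasis=False)
            fixed = {"markers": fixed_marker, "haplotypes": fixed_hap}.get(
                spec.fixed_loci_kind
            )
            res = cross_validate(
                spec, y0, [kernels[spec.kernel_kind]], fixed_loci=fixed,
                repeats=cfg.cv_repeats, test_frac=cfg.cv_test_frac,
                seed=_stage_seed(cfg.seed, "predict"), backend=cfg.backend,
                chain=chain,
            )
            cv_results.append(res)
        cv_p = out / "cv_results.csv"
        pd.DataFrame(
            {f"model{r.model_id}": r.accuracies for r in cv_results}
        ).to_csv(cv_p, index=False)
        record("predict", [cv_p],
               {f"model{r.model_id}_mean": r.mean for r in cv_results})

        comp = compare_models(cv_results)
        comp_p = out / "model_comparison.tsv"
        comp.to_csv(comp_p, sep="\t", index=False)
        record("compare", [comp_p])
    except Exception as exc:
        stage = STAGES[len(manifest["stages"])] if len(manifest["stages"]) < len(STAGES) else "?"
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    manifest_p = out / "manifest.json"
    manifest_p.write_text(json.dumps(manifest, indent=1, default=str))
    return manifest
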