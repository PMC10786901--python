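"""Stage orchestration: one resolved config in, a reproducible report tree out.

Every stage writes TSV/CSV with floats at six significant digits, so two
runs with the same inputs and config produce byte-identical reports.  The
resolved configuration (defaults merged), package version and seed are
dumped into the output directory.
"""

from __future__ import annotations

import copy
import json
import logging
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from . import gwas, haplotypes, phenostats, superior, validation
from .panel import (
    read_gene_models,
    read_labels,
    read_phenotypes,
    read_q_matrix,
    read_vcf,
)

log = logging.getLogger("haplopheno")

FLOAT_FMT = "%.6g"

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "inputs": {
        "vcf": None,
        "phenotypes": None,
        "q_matrix": None,
        "labels": None,
        "genes_bed": None,
        "genes_coding": None,
    },
    "haplotypes": {
        "region_mode": "FULL_GENE",
        "het_policy": "EXCLUDE_ACCESSION",
        "min_carriers": 3,
        "flank_bp": 2000,
    },
    "phenostats": {"condition": "STRESS", "selection_intensity_k": 2.06},
    "gwas": {
        "threshold": 0.005,
        "window_bp": 50000,
        "models": ["MLM", "CMLM", "MLMM"],
        "kinship": "VANRADEN",
        "cmlm_groups": None,
        "mlmm_max_steps": 5,
    },
    "haplopheno": {"min_n": 3, "alpha": 0.05, "policy": "TOP_SEPARATED", "donors_k": 3},
    "validate": {
        "vcf": None,
        "min_depth": 10,
        "min_call_rate": 0.90,
        "tolerance_labels": {},
    },
}


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


def merge_config(user: Mapping[str, Any] | None) -> dict[str, Any]:
    cfg = copy.deepcopy(DEFAULT_CONFIG)

    def merge(dst: dict, src: Mapping) -> None:
        for k, v in src.items():
            if isinstance(v, Mapping) and isinstance(dst.get(k), dict):
                merge(dst[k], v)
            else:
                dst[k] = v

    if user:
        merge(cfg, user)
    return cfg


def load_config(path: str | Path) -> dict[str, Any]:
    with open(path) as fh:
        return merge_config(yaml.safe_load(fh) or {})


def _write_df(df: pd.DataFrame, path: Path, sep: str = "\t", index: bool = False) -> None:
    df.to_csv(path, sep=sep, index=index, float_format=FLOAT_FMT)


def run_pipeline(
    config: Mapping[str, Any], outdir: str | Path, stages: tuple[str, ...] = ("all",)
) -> Path:
    """Run the requested stages; returns the output directory.

    Stage order: haplotypes -> phenostats -> gwas -> haplopheno -> validate.
    Later stages read the earlier stages' in-memory results, so ``all`` (or a
    prefix of the order) is the usual invocation.
    """
    cfg = merge_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    resolved = dict(cfg)
    resolved["software_version"] = __version__
    (outdir / "resolved_config.yaml").write_text(yaml.safe_dump(resolved, sort_keys=True))

    want = set(stages)
    run_all = "all" in want

    def active(name: str) -> bool:
        return run_all or name in want

    state: dict[str, Any] = {}
    inputs = cfg["inputs"]

    def require(key: str, stage: str) -> Path:
        p = inputs.get(key)
        if p is None or not Path(p).exists():
            raise StageError(stage, FileNotFoundError(f"missing input '{key}': {p}"))
        return Path(p)

    if active("haplotypes") or active("gwas") or active("haplopheno"):
        try:
            panel = read_vcf(require("vcf", "haplotypes"))
            genes = read_gene_models(
                require("genes_bed", "haplotypes"), inputs.get("genes_coding")
            )
            state["panel"], state["genes"] = panel, genes
        except StageError:
            raise
        except Exception as exc:
            raise StageError("haplotypes", exc) from exc

    if active("haplotypes"):
        try:
            hcfg = cfg["haplotypes"]
            catalogs = []
            for g in state["genes"]:
                sub = haplotypes.extract_gene_snps(
                    state["panel"], g, hcfg["region_mode"], flank_bp=hcfg["flank_bp"]
                )
                catalogs.append(
                    haplotypes.build_haplotypes(
                        sub,
                        gene_id=g.gene_id,
                        het_policy=hcfg["het_policy"],
                        min_carriers=hcfg["min_carriers"],
                    )
                )
            state["catalogs"] = catalogs
            d = outdir / "haplotypes"
            d.mkdir(exist_ok=True)
            haplotypes.write_catalogs(catalogs, d / "catalogs.tsv", d / "loci.json")
            _write_df(haplotypes.diversity_summary(catalogs).per_gene, d / "diversity.tsv")
            if inputs.get("labels"):
                labels = read_labels(inputs["labels"])
                dist = pd.concat(
                    {c.gene_id: haplotypes.subpop_distribution(c, labels) for c in catalogs},
                    names=["gene_id"],
                )
                _write_df(dist.reset_index(), d / "subpop_distribution.tsv")
        except StageError:
            raise
        except Exception as exc:
            raise StageError("haplotypes", exc) from exc

    if active("phenostats") or active("gwas") or active("haplopheno"):
        try:
            pheno = read_phenotypes(require("phenotypes", "phenostats"))
            pcfg = cfg["phenostats"]
            seasons = sorted(pheno.df["season"].unique())
            conditions = sorted(pheno.df["condition"].unique())
            vc_rows, blup_frames = [], []
            blups_by = {}
            for cond in conditions:
                per_season = {}
                for s in seasons:
                    vc, blups = phenostats.fit_reml(pheno, s, cond)
                    stats = phenostats.variability_stats(vc, k=pcfg["selection_intensity_k"])
                    vc_rows.append(
                        {
                            "season": s, "condition": cond,
                            "sigma2_g": vc.sigma2_g, "sigma2_e": vc.sigma2_e,
                            "grand_mean": vc.grand_mean, "n_reps": vc.n_reps,
                            "gcv_pct": stats.gcv_pct,
                            "repeatability_pct": stats.repeatability_pct,
                            "gam_pct": stats.gam_pct,
                        }
                    )
                    per_season[s] = blups
                    blup_frames.append(
                        blups.rename("blup").reset_index().assign(season=s, condition=cond)
                    )
                blups_by[cond] = phenostats.combine_blups(per_season)
            state["pheno"] = pheno
            state["blups_by_condition"] = blups_by
            d = outdir / "phenostats"
            d.mkdir(exist_ok=True)
            _write_df(pd.DataFrame(vc_rows), d / "variance_components.tsv")
            _write_df(pd.concat(blup_frames, ignore_index=True), d / "blups.tsv")
            for cond, combined in blups_by.items():
                _write_df(combined.reset_index(), d / f"combined_blups_{cond}.tsv")
            if {"STRESS", "NONSTRESS"} <= set(blups_by):
                dsi = phenostats.dsi(
                    blups_by["STRESS"]["combined_blup"], blups_by["NONSTRESS"]["combined_blup"]
                )
                _write_df(dsi.reset_index(), d / "dsi.tsv")
        except StageError:
            raise
        except Exception as exc:
            raise StageError("phenostats", exc) from exc

    if active("gwas"):
        try:
            gcfg = cfg["gwas"]
            cond = cfg["phenostats"]["condition"]
            y = state["blups_by_condition"][cond]["combined_blup"]
            panel = state["panel"]
            K = gwas.kinship(panel, method=gcfg["kinship"])
            q = None
            if inputs.get("q_matrix"):
                q = read_q_matrix(inputs["q_matrix"], panel.accession_ids)
            results = []
            for model in gcfg["models"]:
                if model == "MLM":
                    results.append(gwas.mlm_scan(y, panel, K, covariates=q))
                elif model == "CMLM":
                    results.append(
                        gwas.cmlm_scan(y, panel, K, covariates=q, n_groups=gcfg["cmlm_groups"])
                    )
                elif model == "MLMM":
                    results.append(
                        gwas.mlmm_scan(
                            y, panel, K, covariates=q,
                            max_steps=gcfg["mlmm_max_steps"],
                            add_threshold=gcfg["threshold"],
                        )
                    )
                else:
                    raise ValueError(f"unknown model {model}")
            mtas = gwas.select_mtas(results, threshold=gcfg["threshold"])
            mtas = gwas.annotate_candidates(mtas, state["genes"], window_bp=gcfg["window_bp"])
            state["mtas"] = mtas
            d = outdir / "gwas"
            d.mkdir(exist_ok=True)
            _write_df(pd.concat(results, ignore_index=True), d / "associations.tsv")
            _write_df(mtas.table, d / "mtas.tsv")
            _write_df(
                mtas.chromosome_tally().rename("n_mtas").reset_index(), d / "mta_tally.tsv"
            )
        except StageError:
            raise
        except Exception as exc:
            raise StageError("gwas", exc) from exc

    if active("haplopheno"):
        try:
            scfg = cfg["haplopheno"]
            cond = cfg["phenostats"]["condition"]
            y = state["blups_by_condition"][cond]["combined_blup"]
            res_rows, donor_rows = [], []
            sh_alleles: dict[str, str] = {}
            for cat in state["catalogs"]:
                table, result = superior.analyze_gene(
                    cat, y, min_n=scfg["min_n"], alpha=scfg["alpha"], policy=scfg["policy"]
                )
                for g in table.groups:
                    res_rows.append(
                        {
                            "gene_id": cat.gene_id, "hap_id": g.hap_id, "n": g.n,
                            "mean": g.mean, "sd": g.sd,
                            "letters": result.letters.get(g.hap_id, ""),
                            "is_sh": int(g.hap_id == result.superior_haplotype),
                        }
                    )
                if result.superior_haplotype is not None:
                    sh = result.superior_haplotype
                    sh_alleles[cat.gene_id] = cat.by_id(sh).alleles
                    adv = superior.yield_advantage(table, sh)
                    adv.insert(0, "gene_id", cat.gene_id)
                    donors = superior.find_donors(table, sh, k=scfg["donors_k"])
                    for rank, (acc, val) in enumerate(donors, 1):
                        donor_rows.append(
                            {
                                "gene_id": cat.gene_id, "rank": rank,
                                "accession_id": acc, "blup": val,
                            }
                        )
                    state.setdefault("advantages", []).append(adv)
            state["sh_alleles"] = sh_alleles
            d = outdir / "haplopheno"
            d.mkdir(exist_ok=True)
            _write_df(pd.DataFrame(res_rows), d / "groups.tsv")
            _write_df(pd.DataFrame(donor_rows), d / "donors.tsv")
            if state.get("advantages"):
                _write_df(pd.concat(state["advantages"], ignore_index=True), d / "advantages.tsv")
            combos = superior.sh_combinations(state["catalogs"], sh_alleles)
            _write_df(combos, d / "combinations.tsv")
        except StageError:
            raise
        except Exception as exc:
            raise StageError("haplopheno", exc) from exc

    if active("validate") and cfg["validate"]["vcf"]:
        try:
            vcfg = cfg["validate"]
            vpanel = read_vcf(vcfg["vcf"], with_depth=True)
            vpanel = validation.filter_variants(
                vpanel, min_depth=vcfg["min_depth"], min_call_rate=vcfg["min_call_rate"]
            )
            assignments = [
                validation.assign_haplotype(vpanel, variety, cat)
                for variety in vpanel.accession_ids
                for cat in state["catalogs"]
            ]
            sh_ids = {}
            for gene_id, allele in state.get("sh_alleles", {}).items():
                for cat in state["catalogs"]:
                    if cat.gene_id == gene_id:
                        hap = cat.by_alleles(allele)
                        if hap:
                            sh_ids[gene_id] = hap.hap_id
            report = validation.presence_matrix(
                assignments, sh_ids, tolerance_labels=vcfg["tolerance_labels"]
            )
            d = outdir / "validate"
            d.mkdir(exist_ok=True)
            _write_df(report, d / "presence.tsv")
        except StageError:
            raise
        except Exception as exc:
            raise StageError("validate", exc) from exc

    (outdir / "run.json").write_text(
        json.dumps({"version": __version__, "seed": cfg["seed"], "stages": sorted(want)}, indent=1)
    )
    return outdir
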