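"""End-to-end pipeline driver: preprocess -> scans -> blocks -> triads -> causal.

The pipeline mirrors the analysis scheme: filter SNPs (MAF/missingness) and
low-variability CpGs and genes; run the three cis scans (mQTL, eQTL, eQTM)
with Bonferroni thresholds; collapse correlated features into r^2 blocks and
count independent QTLs; assemble SNP-CpG-gene triads; classify each triad's
causal model by Bayesian-network hill climbing; optionally run annotation
and GWAS-catalog enrichment.  Everything is deterministic given the config.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from trimeqtl import io
from trimeqtl.causal import classify_triads
from trimeqtl.enrichment import fisher_enrichment, adjust_bonferroni, gwas_overlap, load_gwas_catalog
from trimeqtl.independence import correlation_blocks, collapse_to_independent
from trimeqtl.preprocess import beta_to_m, filter_snps, sd_mixture_filter, sd_threshold_filter
from trimeqtl.qtl_scan import scan
from trimeqtl.triads import assemble_meqtls, count_independent_meqtls

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "run_pipeline_frames"]


@dataclass
class PipelineConfig:
    """Paths and parameters for :func:`run_pipeline`."""

    dosage: str = ""
    methylation: str = ""
    expression: str = ""
    snp_features: str = ""
    cpg_features: str = ""
    gene_features: str = ""
    covariates: str = ""
    annotations: str = ""        # optional long-format TSV: snp_id, annotation, family
    background_snps: str = ""    # optional one-id-per-line background for enrichment
    gwas_catalog: str = ""       # optional TSV: snp_id, trait, p
    window_bp: int = 1_000_000
    alpha: float = 0.05
    r2_threshold: float = 0.3
    maf_min: float = 0.05
    missing_max: float = 0.10
    meth_sd_cutoff: float = 0.05
    meth_sd_method: str = "mixture"
    expr_sd_cutoff: float = 0.1
    covariates_mqtl: list = field(default_factory=lambda: ["age", "site", "sex"])
    covariates_eqtl: list = field(default_factory=lambda: ["age", "site", "sex"])
    covariates_eqtm: list = field(default_factory=lambda: ["age", "site", "tissue_type", "sex"])
    residualize_causal: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _select_covariates(covariates: pd.DataFrame | None, names: list) -> pd.DataFrame | None:
    if covariates is None or not names:
        return None
    missing = [n for n in names if n not in covariates.columns]
    if missing:
        raise KeyError(f"covariate columns missing: {missing}")
    return covariates[names]


def run_pipeline_frames(
    dosages: pd.DataFrame,
    betas: pd.DataFrame,
    expression: pd.DataFrame,
    snp_features: pd.DataFrame,
    cpg_features: pd.DataFrame,
    gene_features: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    config: PipelineConfig | None = None,
    out_dir=None,
    annotations: pd.DataFrame | None = None,
    background_snps=None,
    gwas_catalog: pd.DataFrame | None = None,
):
    """Run the pipeline on in-memory DataFrames; see :func:`run_pipeline`.

    Returns the run report dict; when ``out_dir`` is given, all stage
    outputs and the report JSON are written there.
    """
    cfg = config or PipelineConfig()
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    report = {"config": {k: v for k, v in asdict(cfg).items()}, "stages": {}, "timing_s": {}}

    def _stage(name):
        logger.info("pipeline stage: %s", name)
        return time.perf_counter()

    try:
        # ---- preprocess -------------------------------------------------
        t0 = _stage("preprocess")
        dosages_f, snp_report = filter_snps(dosages, cfg.maf_min, cfg.missing_max)
        snp_features_f = snp_features[snp_features["id"].isin(dosages_f.columns)].reset_index(drop=True)
        kept_cpgs, _mix = sd_mixture_filter(
            betas, sd_cutoff=cfg.meth_sd_cutoff, method=cfg.meth_sd_method, random_state=cfg.seed
        )
        betas_f = betas[kept_cpgs]
        m_values = pd.DataFrame(
            beta_to_m(betas_f.to_numpy()), index=betas_f.index, columns=betas_f.columns
        )
        cpg_features_f = cpg_features[cpg_features["id"].isin(kept_cpgs)].reset_index(drop=True)
        kept_genes, _ = sd_threshold_filter(expression, cfg.expr_sd_cutoff)
        expression_f = expression[kept_genes]
        gene_features_f = gene_features[gene_features["id"].isin(kept_genes)].reset_index(drop=True)
        report["stages"]["preprocess"] = {
            "snps": snp_report,
            "cpgs": {"n_input": int(betas.shape[1]), "n_kept": int(betas_f.shape[1])},
            "genes": {"n_input": int(expression.shape[1]), "n_kept": int(expression_f.shape[1])},
        }
        report["timing_s"]["preprocess"] = round(time.perf_counter() - t0, 3)

        # ---- three cis scans -------------------------------------------
        scans = {}
        for mode, cov_names in (
            ("mQTL", cfg.covariates_mqtl),
            ("eQTL", cfg.covariates_eqtl),
            ("eQTM", cfg.covariates_eqtm),
        ):
            t0 = _stage(f"scan:{mode}")
            res = scan(
                mode,
                dosages=dosages_f,
                m_values=m_values,
                expression=expression_f,
                snp_features=snp_features_f,
                cpg_features=cpg_features_f,
                gene_features=gene_features_f,
                covariates=_select_covariates(covariates, cov_names),
                window_bp=cfg.window_bp,
                alpha=cfg.alpha,
            )
            scans[mode] = res
            report["stages"][f"scan_{mode.lower()}"] = {
                "n_significant": res.n_significant,
                "threshold": res.threshold,
                "n_targets": res.n_targets,
                "median_cis": res.median_cis,
                "n_pairs_tested": res.n_pairs_tested,
            }
            report["timing_s"][f"scan_{mode.lower()}"] = round(time.perf_counter() - t0, 3)
            if out is not None:
                io.write_scan_result(res, out / f"scan_{mode.lower()}")

        # ---- independence (per scan) -----------------------------------
        t0 = _stage("independence")
        independent = {}
        for mode, res in scans.items():
            assoc = res.associations
            if assoc.empty:
                independent[mode] = {"n_source_blocks": 0, "n_target_blocks": 0, "n_independent": 0}
                continue
            src_matrix = dosages_f if mode in ("mQTL", "eQTL") else m_values
            src_feat = snp_features_f if mode in ("mQTL", "eQTL") else cpg_features_f
            sblocks = correlation_blocks(
                assoc["source_id"].unique(), src_matrix, src_feat,
                cfg.r2_threshold, cfg.window_bp,
                kind="snp" if mode in ("mQTL", "eQTL") else "cpg",
            )
            if mode == "mQTL":
                tblocks = correlation_blocks(
                    assoc["target_id"].unique(), m_values, cpg_features_f,
                    cfg.r2_threshold, cfg.window_bp, kind="cpg",
                )
            else:
                tblocks = None  # gene targets are not blocked
            reps = collapse_to_independent(assoc, sblocks, tblocks)
            independent[mode] = {
                "n_source_blocks": len(sblocks),
                "n_target_blocks": len(tblocks) if tblocks is not None else int(assoc["target_id"].nunique()),
                "n_independent": len(reps),
            }
            if out is not None:
                reps.to_csv(out / f"independent_{mode.lower()}.tsv", sep="\t", index=False,
                            float_format="%.10g")
        report["stages"]["independence"] = independent
        report["timing_s"]["independence"] = round(time.perf_counter() - t0, 3)

        # ---- triads -----------------------------------------------------
        t0 = _stage("triads")
        triads = assemble_meqtls(scans["mQTL"], scans["eQTL"], scans["eQTM"])
        if not triads.empty:
            cpg_blocks = correlation_blocks(
                triads["cpg_id"].unique(), m_values, cpg_features_f,
                cfg.r2_threshold, cfg.window_bp, kind="cpg",
            )
            snp_blocks = correlation_blocks(
                triads["snp_id"].unique(), dosages_f, snp_features_f,
                cfg.r2_threshold, cfg.window_bp, kind="snp",
            )
            _per_gene, meqtl_summary = count_independent_meqtls(triads, cpg_blocks, snp_blocks)
        else:
            meqtl_summary = {
                "n_triads": 0, "n_snps": 0, "n_cpgs": 0, "n_genes": 0,
                "n_snp_blocks": 0, "n_cpg_blocks": 0, "n_independent_meqtls": 0,
            }
        report["stages"]["triads"] = meqtl_summary
        report["timing_s"]["triads"] = round(time.perf_counter() - t0, 3)
        if out is not None:
            triads.to_csv(out / "triads.tsv", sep="\t", index=False, float_format="%.10g")

        # ---- causal classification -------------------------------------
        t0 = _stage("causal")
        if not triads.empty:
            calls, freq = classify_triads(
                triads, dosages_f, m_values, expression_f,
                covariates=covariates, residualize=cfg.residualize_causal,
            )
            report["stages"]["causal"] = {
                "n_classified": len(calls),
                "model_frequencies": freq.to_dict(orient="records"),
            }
            if out is not None:
                calls.to_csv(out / "causal_calls.tsv", sep="\t", index=False, float_format="%.10g")
                freq.to_csv(out / "model_frequencies.tsv", sep="\t", index=False)
        else:
            report["stages"]["causal"] = {"n_classified": 0, "model_frequencies": []}
        report["timing_s"]["causal"] = round(time.perf_counter() - t0, 3)

        # ---- enrichment (optional) --------------------------------------
        if annotations is not None and background_snps is not None and not triads.empty:
            t0 = _stage("enrichment")
            rows = fisher_enrichment(triads["snp_id"].unique(), background_snps, annotations)
            rows = adjust_bonferroni(rows)
            report["stages"]["enrichment"] = {"n_annotations": len(rows)}
            if out is not None:
                rows.to_csv(out / "enrichment.tsv", sep="\t", index=False, float_format="%.10g")
            report["timing_s"]["enrichment"] = round(time.perf_counter() - t0, 3)
        if gwas_catalog is not None and not triads.empty:
            overlap = gwas_overlap(triads["snp_id"].unique(), load_gwas_catalog(gwas_catalog))
            report["stages"]["gwas_overlap"] = {"n_traits": len(overlap)}
            if out is not None:
                overlap.to_csv(out / "gwas_overlap.tsv", sep="\t", index=False)
    except Exception as exc:
        report["failed"] = f"{type(exc).__name__}: {exc}"
        if out is not None:
            (out / "FAILED").write_text(report["failed"] + "\n")
            io.write_json(report, out / "run_report.json")
        raise

    if out is not None:
        io.write_json(report, out / "run_report.json")
    return report


def run_pipeline(config: PipelineConfig, out_dir=None):
    """Run the full pipeline from files named in ``config``.

    Reads the matrices, feature tables and covariates, executes every stage,
    writes stage outputs and the run report under ``out_dir`` and returns
    the report dict.  Any stage error aborts with the stage context; partial
    outputs are kept alongside a ``FAILED`` marker file.
    """
    dosages, vcf_features = io.read_dosage(config.dosage)
    betas = io.read_matrix(config.methylation)
    expression = io.read_matrix(config.expression)
    snp_features = io.read_features(config.snp_features) if config.snp_features else vcf_features
    if snp_features is None:
        raise ValueError("snp_features required for TSV dosage input")
    cpg_features = io.read_features(config.cpg_features)
    gene_features = io.read_features(config.gene_features)
    covariates = io.read_covariates(config.covariates) if config.covariates else None
    annotations = pd.read_csv(config.annotations, sep="\t") if config.annotations else None
    background = (
        [line.strip() for line in open(config.background_snps) if line.strip()]
        if config.background_snps else None
    )
    catalog = pd.read_csv(config.gwas_catalog, sep="\t") if config.gwas_catalog else None
    return run_pipeline_frames(
        dosages, betas, expression, snp_features, cpg_features, gene_features,
        covariates=covariates, config=config, out_dir=out_dir,
        annotations=annotations, background_snps=background, gwas_catalog=catalog,
    )
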