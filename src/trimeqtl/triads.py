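"""Assemble SNP-CpG-gene triads (meQTLs) from the three scan results.

A triad is a (SNP, CpG, gene) triple whose three pairwise associations are
all significant: SNP-CpG (mQTL), SNP-gene (eQTL) and CpG-gene (eQTM).  The
triad table keeps all three p-values and slopes so downstream stages never
re-scan.  Independent meQTLs are counted per gene as distinct
(CpG block, SNP block) pairs.
"""

from __future__ import annotations

import pandas as pd

from trimeqtl.independence import Block, block_map
from trimeqtl.qtl_scan import ScanResult

__all__ = ["assemble_meqtls", "count_independent_meqtls", "TRIAD_COLUMNS"]

TRIAD_COLUMNS = [
    "snp_id", "cpg_id", "gene_id", "chrom", "snp_pos", "cpg_pos", "gene_pos",
    "p_mqtl", "p_eqtl", "p_eqtm", "slope_mqtl", "slope_eqtl", "slope_eqtm",
]


def _assoc_frame(result) -> pd.DataFrame:
    if isinstance(result, ScanResult):
        return result.associations
    return result


def assemble_meqtls(mqtls, eqtls, eqtms) -> pd.DataFrame:
    """Join the three significant-association lists into triads.

    Accepts :class:`~trimeqtl.qtl_scan.ScanResult` objects or bare
    association DataFrames.  Joins on exact feature ids (common SNPs between
    mQTLs and eQTLs, then overlapping eQTMs on the CpG-gene pair).  The
    result is sorted by (chrom, SNP position, CpG position, gene id).
    """
    m = _assoc_frame(mqtls).rename(columns={
        "source_id": "snp_id", "target_id": "cpg_id",
        "source_pos": "snp_pos", "target_pos": "cpg_pos",
        "p_value": "p_mqtl", "slope": "slope_mqtl",
    })[["snp_id", "cpg_id", "chrom", "snp_pos", "cpg_pos", "p_mqtl", "slope_mqtl"]]
    e = _assoc_frame(eqtls).rename(columns={
        "source_id": "snp_id", "target_id": "gene_id",
        "target_pos": "gene_pos", "p_value": "p_eqtl", "slope": "slope_eqtl",
    })[["snp_id", "gene_id", "gene_pos", "p_eqtl", "slope_eqtl"]]
    q = _assoc_frame(eqtms).rename(columns={
        "source_id": "cpg_id", "target_id": "gene_id",
        "p_value": "p_eqtm", "slope": "slope_eqtm",
    })[["cpg_id", "gene_id", "p_eqtm", "slope_eqtm"]]
    if len(m) == 0 or len(e) == 0 or len(q) == 0:
        return pd.DataFrame(columns=TRIAD_COLUMNS)
    t = m.merge(e, on="snp_id").merge(q, on=["cpg_id", "gene_id"])
    t = t[TRIAD_COLUMNS]
    t = t.sort_values(
        ["chrom", "snp_pos", "cpg_pos", "gene_id", "snp_id", "cpg_id"], kind="stable"
    ).reset_index(drop=True)
    return t


def count_independent_meqtls(
    triads: pd.DataFrame,
    cpg_blocks: list[Block],
    snp_blocks: list[Block],
):
    """Per-gene distinct (CpG block, SNP block) pairs, plus summary counts.

    Returns ``(per_gene, summary)`` where ``per_gene`` maps each gene to its
    number of independent meQTLs and ``summary`` reports totals in the style
    of a per-trait count table: triads, unique SNPs/CpGs/genes, SNP and CpG
    blocks involved, and the total number of independent meQTLs.
    """
    if triads.empty:
        empty = pd.Series(dtype=int, name="n_independent")
        return empty, {
            "n_triads": 0, "n_snps": 0, "n_cpgs": 0, "n_genes": 0,
            "n_snp_blocks": 0, "n_cpg_blocks": 0, "n_independent_meqtls": 0,
        }
    cmap = block_map(cpg_blocks)
    smap = block_map(snp_blocks)
    df = triads.copy()
    try:
        df["cpg_block"] = df["cpg_id"].map(lambda i: cmap[i])
        df["snp_block"] = df["snp_id"].map(lambda i: smap[i])
    except KeyError as exc:
        raise KeyError(f"triad references feature absent from blocks: {exc}") from exc
    per_gene = (
        df.groupby("gene_id")[["cpg_block", "snp_block"]]
        .apply(lambda g: len(g.drop_duplicates()))
        .rename("n_independent")
    )
    summary = {
        "n_triads": int(len(df)),
        "n_snps": int(df["snp_id"].nunique()),
        "n_cpgs": int(df["cpg_id"].nunique()),
        "n_genes": int(df["gene_id"].nunique()),
        "n_snp_blocks": int(df["snp_block"].nunique()),
        "n_cpg_blocks": int(df["cpg_block"].nunique()),
        "n_independent_meqtls": int(per_gene.sum()),
    }
    return per_gene, summary
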