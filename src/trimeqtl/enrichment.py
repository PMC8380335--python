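"""Annotation enrichment and GWAS-catalog overlap for meQTL SNPs.

meQTL SNPs are compared against a background of random cis-SNPs with a
two-sided Fisher exact test per annotation (chromatin states, histone
marks, conservation, eQTL evidence), with Bonferroni adjustment applied
separately within each annotation family.  GWAS-catalog overlap counts, per
trait, how many genome-wide-significant catalog SNPs (p <= 5e-8) fall in
the query set.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "fisher_enrichment",
    "adjust_bonferroni",
    "gwas_overlap",
    "load_gwas_catalog",
    "GWAS_P_MAX",
]

GWAS_P_MAX = 5e-8

ENRICHMENT_COLUMNS = [
    "annotation", "family", "count_target", "n_target",
    "count_background", "n_background", "odds_ratio", "zero_cell", "p_value",
]


def fisher_enrichment(
    target_ids,
    background_ids,
    annotations: pd.DataFrame,
) -> pd.DataFrame:
    """Per-annotation two-sided Fisher exact test of target vs background.

    Parameters
    ----------
    target_ids, background_ids : sequences of SNP ids
        Ids present in the background that also appear in the target set are
        removed from the background before testing.
    annotations : pd.DataFrame
        Long format with columns ``snp_id, annotation, family``; a SNP
        absent from the table simply carries no annotations.

    Returns
    -------
    pd.DataFrame
        One row per annotation with the 2x2 counts, the cross-product odds
        ratio (Haldane 0.5 correction applied, and flagged, only when a cell
        is zero) and the two-sided p-value.
    """
    target = set(target_ids)
    if not target:
        raise ValueError("empty target set")
    background = set(background_ids) - target
    n_t, n_b = len(target), len(background)

    ann = annotations[["snp_id", "annotation", "family"]]
    families = ann.drop_duplicates("annotation").set_index("annotation")["family"]
    rows = []
    grouped = ann.groupby("annotation")["snp_id"]
    for annotation in families.index:
        members = set(grouped.get_group(annotation))
        a = len(target & members)
        c = len(background & members)
        b, d = n_t - a, n_b - c
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        zero = (a == 0) or (b == 0) or (c == 0) or (d == 0)
        if zero:
            orr = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        else:
            orr = (a * d) / (b * c)
        rows.append({
            "annotation": annotation,
            "family": families[annotation],
            "count_target": a,
            "n_target": n_t,
            "count_background": c,
            "n_background": n_b,
            "odds_ratio": float(orr),
            "zero_cell": bool(zero),
            "p_value": float(p),
        })
    return pd.DataFrame(rows, columns=ENRICHMENT_COLUMNS)


def adjust_bonferroni(rows: pd.DataFrame, family_column: str = "family") -> pd.DataFrame:
    """Bonferroni adjustment within each annotation family.

    ``p_adjusted = min(1, p * m_family)`` where ``m_family`` is the number
    of annotations in the row's family.  Never lowers a p-value.
    """
    out = rows.copy()
    m = out.groupby(family_column)["annotation"].transform("count")
    out["p_adjusted"] = np.minimum(1.0, out["p_value"] * m)
    return out


def load_gwas_catalog(source, p_max: float = GWAS_P_MAX) -> pd.DataFrame:
    """Load a GWAS-catalog export (TSV path or DataFrame) and apply the
    genome-wide significance filter: rows with p > ``p_max`` are dropped."""
    cat = pd.read_csv(source, sep="\t") if not isinstance(source, pd.DataFrame) else source.copy()
    required = {"snp_id", "trait", "p"}
    if not required.issubset(cat.columns):
        raise ValueError(f"catalog needs columns {sorted(required)}")
    return cat[cat["p"] <= p_max].reset_index(drop=True)


def gwas_overlap(snp_ids, catalog: pd.DataFrame, suppress_zero: bool = False) -> pd.DataFrame:
    """Per-trait overlap of a SNP set with the (pre-filtered) GWAS catalog.

    Returns per trait the number of catalog SNPs, the number also present in
    ``snp_ids`` and the percentage (100 * overlap / catalog count, rounded
    half-up to an integer).
    """
    query = set(snp_ids)
    rows = []
    for trait, grp in catalog.groupby("trait", sort=True):
        members = set(grp["snp_id"])
        n_cat = len(members)
        n_ov = len(members & query)
        pct = int(np.floor(100.0 * n_ov / n_cat + 0.5)) if n_cat else 0
        rows.append({"trait": trait, "n_catalog": n_cat, "n_overlap": n_ov, "percent": pct})
    out = pd.DataFrame(rows, columns=["trait", "n_catalog", "n_overlap", "percent"])
    if suppress_zero:
        out = out[out["n_overlap"] > 0].reset_index(drop=True)
    return out
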