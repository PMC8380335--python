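"""File formats: TSV matrices, feature tables, VCF dosages, JSON reports.

Conventions
-----------
* Matrix TSVs store features as rows and samples as columns; in memory all
  matrices are samples x features DataFrames indexed by sample id.
* Feature tables (``.ftsv``) are BED-like TSVs with a 1-based ``pos``
  column (not BED's 0-based start): ``chrom, pos, id[, strand]``; gene
  tables use ``tss`` in place of ``pos``.
* Dosages can also be read from VCF with a ``DS`` FORMAT field (via cyvcf2)
  and written as a minimal such VCF.
* All genomic coordinates are 1-based inclusive throughout.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "read_matrix", "write_matrix",
    "read_features", "write_features",
    "read_dosage", "write_dosage_vcf",
    "read_covariates", "write_covariates",
    "read_truth", "write_truth",
    "write_scan_result", "read_associations",
    "write_json", "read_json",
]


def write_matrix(matrix: pd.DataFrame, path) -> None:
    """Write a samples x features matrix as a features-by-samples TSV."""
    out = matrix.T.rename_axis(index="id")
    out.to_csv(path, sep="\t", float_format="%.10g")


def read_matrix(path) -> pd.DataFrame:
    """Read a features-by-samples TSV into a samples x features DataFrame."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    out = df.T
    out.index.name = "sample_id"
    out.columns.name = None
    return out


def write_features(features: pd.DataFrame, path) -> None:
    features.to_csv(path, sep="\t", index=False)


def read_features(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str, "id": str})


def write_covariates(covariates: pd.DataFrame, path) -> None:
    out = covariates.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def read_covariates(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")


def read_dosage(path, fmt: str | None = None, sample_order=None, tol: float = 1e-6):
    """Read a dosage matrix from TSV or VCF (``DS`` FORMAT field).

    ``fmt`` defaults from the file extension.  Values outside [0, 2] beyond
    ``tol`` raise a parse error with the offending line.  When
    ``sample_order`` is given, columns (samples) are aligned to that order.

    Returns ``(dosages, features)``.
    """
    path = Path(path)
    if fmt is None:
        fmt = "vcf" if path.suffix in (".vcf",) or str(path).endswith(".vcf.gz") else "tsv"
    if fmt == "tsv":
        dosages = read_matrix(path).astype(float)
        values = dosages.to_numpy(dtype=float)
        if values.size:
            with np.errstate(invalid="ignore"):
                low = np.nanmin(values, axis=0) < -tol
                high = np.nanmax(values, axis=0) > 2.0 + tol
            offenders = np.flatnonzero(low | high)
            if offenders.size:
                names = [dosages.columns[i] for i in offenders[:5]]
                # matrix TSVs are feature-per-row: line = feature index + header
                raise ValueError(
                    f"dosage outside [0, 2] for SNP(s) {names} (TSV line {offenders[0] + 2})"
                )
        features = None
    elif fmt == "vcf":
        dosages, features = _read_dosage_vcf(path)
    else:
        raise ValueError(f"unknown dosage format {fmt!r}")
    if sample_order is not None:
        missing = [s for s in sample_order if s not in dosages.index]
        if missing:
            raise KeyError(f"samples missing from dosage file: {missing[:5]}")
        dosages = dosages.loc[list(sample_order)]
    return dosages, features


def _read_dosage_vcf(path):
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("reading VCF dosages requires cyvcf2") from exc
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids, chroms, poss, cols = [], [], [], []
    for i, variant in enumerate(vcf):
        ds = variant.format("DS")
        if ds is None:
            raise ValueError(f"VCF record {i + 1} ({variant.CHROM}:{variant.POS}) has no DS field")
        vals = np.asarray(ds, dtype=float).ravel()
        if np.any(vals < -1e-6) or np.any(vals > 2.0 + 1e-6):
            raise ValueError(f"dosage outside [0, 2] at {variant.CHROM}:{variant.POS}")
        ids.append(variant.ID or f"{variant.CHROM}:{variant.POS}")
        chroms.append(variant.CHROM)
        poss.append(variant.POS)
        cols.append(vals)
    dosages = pd.DataFrame(
        np.column_stack(cols) if cols else np.empty((len(samples), 0)),
        index=pd.Index(samples, name="sample_id"),
        columns=ids,
    )
    features = pd.DataFrame({"id": ids, "chrom": chroms, "pos": poss})
    return dosages, features


def write_dosage_vcf(dosages: pd.DataFrame, features: pd.DataFrame, path) -> None:
    """Write dosages as a minimal VCF with a DS FORMAT field."""
    feat = features.set_index("id")
    samples = list(dosages.index)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Allelic dosage">\n')
        for chrom in pd.unique(features["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(str(s) for s in samples) + "\n")
        for snp_id in dosages.columns:
            chrom = feat.loc[snp_id, "chrom"]
            pos = int(feat.loc[snp_id, "pos"])
            vals = dosages[snp_id].to_numpy(dtype=float)
            fields = "\t".join(f"./.:{v:.6g}" for v in vals)
            fh.write(f"{chrom}\t{pos}\t{snp_id}\tA\tG\t.\tPASS\t.\tGT:DS\t{fields}\n")


def write_truth(truth: list, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1)


def read_truth(path) -> list:
    with open(path) as fh:
        return json.load(fh)


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, default=_json_default)


def read_json(path):
    with open(path) as fh:
        return json.load(fh)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_scan_result(result, prefix) -> None:
    """Write a ScanResult as ``<prefix>.tsv`` plus ``<prefix>.meta.json``."""
    prefix = Path(prefix)
    df = result.associations.copy()
    df.insert(0, "mode", result.mode)
    df.to_csv(f"{prefix}.tsv", sep="\t", index=False, float_format="%.10g")
    meta = {
        "mode": result.mode,
        "threshold": result.threshold,
        "alpha": result.alpha,
        "window_bp": result.window_bp,
        "n_targets": result.n_targets,
        "n_sources": result.n_sources,
        "n_pairs_tested": result.n_pairs_tested,
        "median_cis": result.median_cis,
        "n_significant": result.n_significant,
        "n_samples": result.n_samples,
        "covariates": result.covariates,
    }
    write_json(meta, f"{prefix}.meta.json")


def read_associations(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
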