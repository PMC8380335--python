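"""Cis association scanning: mQTL, eQTL and eQTM modes.

Each scan regresses a molecular trait on a cis feature in a linear additive
model with covariate adjustment:

* mQTL: CpG M-value ~ SNP dosage + covariates
* eQTL: log2 expression ~ SNP dosage + covariates
* eQTM: log2 expression ~ CpG M-value + covariates

Candidate pairs are restricted to a +/- 1 Mb window around the target anchor
(CpG position for mQTLs, gene TSS for eQTLs/eQTMs; boundary inclusive).  The
significance threshold is a Bonferroni correction for an effective number of
tests: alpha / (number of targets x median cis partner count per target).

:class:`CisScan` is the model object; :meth:`CisScan.fit` returns a
:class:`ScanResult` carrying the significant associations, the threshold and
the scan metadata.  Mass fitting uses Frisch-Waugh residualization: x and y
are projected off the covariate design once, after which every pair reduces
to a simple regression with the full model's residual degrees of freedom.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "cis_pairs",
    "median_cis_count",
    "bonferroni_threshold",
    "fit_additive_linear",
    "CisScan",
    "ScanResult",
    "scan",
    "target_anchor",
    "encode_covariates",
    "SampleAlignmentError",
]

MODES = ("mQTL", "eQTL", "eQTM")

ASSOCIATION_COLUMNS = [
    "source_id", "target_id", "chrom", "source_pos", "target_pos",
    "distance", "slope", "se", "t_stat", "p_value",
]


class SampleAlignmentError(ValueError):
    """Raised when matrices or covariates do not share the sample axis."""


def target_anchor(features: pd.DataFrame) -> pd.Series:
    """Anchor position of a feature table: ``tss`` column if present, else ``pos``."""
    if "tss" in features.columns:
        return features["tss"]
    return features["pos"]


def gene_tss(features: pd.DataFrame) -> pd.Series:
    """TSS of gene features: explicit ``tss`` column, or start on '+' / end on '-'."""
    if "tss" in features.columns:
        return features["tss"]
    if {"start", "end", "strand"}.issubset(features.columns):
        return features["start"].where(features["strand"] == "+", features["end"])
    raise ValueError("gene features need a 'tss' column or start/end/strand")


def cis_pairs(
    sources: pd.DataFrame,
    targets: pd.DataFrame,
    window_bp: int = 1_000_000,
) -> pd.DataFrame:
    """All (source, target) pairs on the same chromosome within the cis window.

    ``sources`` and ``targets`` are feature tables with columns
    ``id, chrom, pos`` (and optionally ``tss`` for genes, which then anchors
    the window).  The window is inclusive: ``|source.pos - anchor| <=
    window_bp``.  ``distance`` is signed, anchor(target) - source position.
    """
    out = {k: [] for k in ("source_id", "target_id", "chrom", "source_pos", "target_pos")}
    t_anchor = target_anchor(targets).to_numpy()
    for chrom in pd.unique(targets["chrom"]):
        src = sources[sources["chrom"] == chrom]
        if src.empty:
            continue
        order = np.argsort(src["pos"].to_numpy(), kind="stable")
        spos = src["pos"].to_numpy()[order]
        sid = src["id"].to_numpy()[order]
        tmask = (targets["chrom"] == chrom).to_numpy()
        for tid, anchor in zip(targets["id"].to_numpy()[tmask], t_anchor[tmask]):
            lo = np.searchsorted(spos, anchor - window_bp, side="left")
            hi = np.searchsorted(spos, anchor + window_bp, side="right")
            if hi == lo:
                continue
            k = hi - lo
            out["source_id"].extend(sid[lo:hi])
            out["target_id"].extend([tid] * k)
            out["chrom"].extend([chrom] * k)
            out["source_pos"].extend(spos[lo:hi])
            out["target_pos"].extend([anchor] * k)
    pairs = pd.DataFrame(out)
    if pairs.empty:
        pairs = pd.DataFrame(
            columns=["source_id", "target_id", "chrom", "source_pos", "target_pos", "distance"]
        )
        return pairs
    pairs["distance"] = pairs["target_pos"].astype(np.int64) - pairs["source_pos"].astype(np.int64)
    return pairs


def median_cis_count(pairs: pd.DataFrame, targets: pd.DataFrame) -> int:
    """Median number of cis partners per target, over *all* targets.

    Targets with no cis partner count as 0.  For an even number of targets
    the median of the middle two is rounded half-up to an integer, matching
    the integer counts used in the threshold formula.
    """
    if len(targets) == 0:
        return 0
    counts = (
        pairs.groupby("target_id").size().reindex(targets["id"], fill_value=0)
        if len(pairs)
        else pd.Series(0, index=targets["id"])
    )
    med = float(np.median(counts.to_numpy()))
    return int(np.floor(med + 0.5))


def bonferroni_threshold(alpha: float = 0.05, n_targets: int = 1, median_cis: int = 1) -> float:
    """Bonferroni p-value threshold ``alpha / (n_targets * median_cis)``."""
    if n_targets < 1 or median_cis < 1:
        raise ValueError("n_targets and median_cis must be >= 1")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    return alpha / (n_targets * median_cis)


def encode_covariates(covariates: pd.DataFrame | None) -> np.ndarray | None:
    """Numeric design columns for covariates: numerics as-is, others 0/1 dummies."""
    if covariates is None or covariates.shape[1] == 0:
        return None
    cols = []
    for name in covariates.columns:
        col = covariates[name]
        if pd.api.types.is_numeric_dtype(col):
            cols.append(col.to_numpy(dtype=float))
        else:
            dummies = pd.get_dummies(col, drop_first=True)
            for dname in dummies.columns:
                cols.append(dummies[dname].to_numpy(dtype=float))
    return np.column_stack(cols) if cols else None


def fit_additive_linear(y, x, covariates=None):
    """Ordinary least squares of ``y`` on ``[1, x, covariates]``.

    Returns a dict with the slope on ``x``, its standard error, t statistic,
    two-sided p-value from the t distribution with ``n - k`` degrees of
    freedom, and a ``flag`` describing degenerate cases:

    * constant ``x`` (or singular design): slope/se/p are NaN, flag
      ``"constant_x"``, and a warning is logged;
    * zero residual variance (perfect fit): p is reported as 0.0 with flag
      ``"zero_residual"`` rather than NaN.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    n = len(y)
    if len(x) != n:
        raise ValueError("x and y must have the same length")
    if covariates is not None:
        C = encode_covariates(covariates) if isinstance(covariates, pd.DataFrame) else np.asarray(covariates, float)
    else:
        C = None
    ncov = 0 if C is None else C.shape[1]
    k = 2 + ncov
    if n < k + 2:
        raise ValueError(f"need at least {k + 2} samples for {k} parameters")
    if np.ptp(x) == 0:
        logger.warning("fit_additive_linear: constant predictor; association flagged")
        return {"slope": np.nan, "se": np.nan, "t_stat": np.nan, "p_value": np.nan,
                "df": n - k, "flag": "constant_x"}
    design = np.column_stack([np.ones(n), x] + ([] if C is None else [C]))
    beta, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < design.shape[1]:
        logger.warning("fit_additive_linear: singular design; association flagged")
        return {"slope": np.nan, "se": np.nan, "t_stat": np.nan, "p_value": np.nan,
                "df": n - k, "flag": "singular"}
    resid = y - design @ beta
    rss = float(resid @ resid)
    df = n - k
    xtx_inv = np.linalg.inv(design.T @ design)
    slope = float(beta[1])
    scale = float(xtx_inv[1, 1])
    tss = float(np.sum((y - y.mean()) ** 2))
    if rss <= max(tss, 1.0) * 1e-14:
        logger.warning("fit_additive_linear: zero residual variance; p reported as 0")
        return {"slope": slope, "se": 0.0, "t_stat": np.inf, "p_value": 0.0,
                "df": df, "flag": "zero_residual"}
    sigma2 = rss / df
    se = float(np.sqrt(sigma2 * scale))
    t_stat = slope / se
    p = 2.0 * float(stats.t.sf(abs(t_stat), df))
    return {"slope": slope, "se": se, "t_stat": t_stat, "p_value": p, "df": df, "flag": "ok"}


@dataclass
class ScanResult:
    """Results of a cis scan: significant associations plus scan metadata."""

    mode: str
    threshold: float
    alpha: float
    window_bp: int
    n_targets: int
    n_sources: int
    n_pairs_tested: int
    median_cis: int
    covariates: list
    associations: pd.DataFrame
    full: pd.DataFrame | None = None
    n_samples: int = 0

    @property
    def n_significant(self) -> int:
        return len(self.associations)

    def summary(self) -> str:
        lines = [
            f"Cis {self.mode} scan",
            "=" * 30,
            f"samples:            {self.n_samples}",
            f"sources:            {self.n_sources}",
            f"targets:            {self.n_targets}",
            f"cis pairs tested:   {self.n_pairs_tested}",
            f"median cis count:   {self.median_cis}",
            f"alpha:              {self.alpha}",
            f"Bonferroni thresh.: {self.threshold:.3e}",
            f"significant:        {self.n_significant}",
            f"covariates:         {', '.join(self.covariates) if self.covariates else '(none)'}",
        ]
        return "\n".join(lines)


class CisScan:
    """Cis-QTL scan model over aligned sample x feature matrices.

    Parameters
    ----------
    mode : {"mQTL", "eQTL", "eQTM"}
        Determines the roles of the inputs (see module docstring).
    x_matrix, y_matrix : pd.DataFrame
        Samples x features; predictors (dosages or M-values) and targets
        (M-values or expression).  Must share the sample index.
    source_features, target_features : pd.DataFrame
        Feature tables with ``id, chrom, pos`` (genes also ``tss``/``strand``).
    covariates : pd.DataFrame, optional
        Samples x covariates; categorical columns become 0/1 indicators.
    """

    def __init__(
        self,
        mode: str,
        x_matrix: pd.DataFrame,
        y_matrix: pd.DataFrame,
        source_features: pd.DataFrame,
        target_features: pd.DataFrame,
        covariates: pd.DataFrame | None = None,
        window_bp: int = 1_000_000,
        alpha: float = 0.05,
        keep_all: bool = False,
    ):
        if mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        self.mode = mode
        self.window_bp = int(window_bp)
        self.alpha = float(alpha)
        self.keep_all = keep_all
        self.x_matrix = x_matrix
        self.y_matrix = self._align(y_matrix, x_matrix.index, "y_matrix")
        self.covariates = (
            None if covariates is None else self._align(covariates, x_matrix.index, "covariates")
        )
        self.source_features = source_features.reset_index(drop=True)
        self.target_features = target_features.reset_index(drop=True)

    @staticmethod
    def _align(df: pd.DataFrame, index: pd.Index, name: str) -> pd.DataFrame:
        if df.index.equals(index):
            return df
        missing = index.difference(df.index)
        extra = df.index.difference(index)
        if len(missing) or len(extra):
            raise SampleAlignmentError(
                f"{name}: sample mismatch; missing={list(missing)[:5]} extra={list(extra)[:5]}"
            )
        return df.loc[index]

    def fit(self) -> ScanResult:
        pairs = cis_pairs(self.source_features, self.target_features, self.window_bp)
        med = median_cis_count(pairs, self.target_features)
        n_targets = len(self.target_features)
        threshold = bonferroni_threshold(self.alpha, n_targets, max(med, 1))

        n = len(self.x_matrix)
        C = encode_covariates(self.covariates)
        design_c = np.ones((n, 1)) if C is None else np.column_stack([np.ones(n), C])
        k = design_c.shape[1] + 1  # + slope column
        df_resid = n - k
        if df_resid < 2:
            raise ValueError("not enough residual degrees of freedom")
        Q, _ = np.linalg.qr(design_c)

        table = pairs.copy()
        if len(pairs):
            src_ids = pd.Index(self.x_matrix.columns)
            tgt_ids = pd.Index(self.y_matrix.columns)
            si = src_ids.get_indexer(pairs["source_id"])
            ti = tgt_ids.get_indexer(pairs["target_id"])
            if np.any(si < 0) or np.any(ti < 0):
                raise KeyError("cis pair references a feature missing from its matrix")
            X = self.x_matrix.to_numpy(dtype=float)
            Y = self.y_matrix.to_numpy(dtype=float)
            Xr = X - Q @ (Q.T @ X)
            Yr = Y - Q @ (Q.T @ Y)
            slopes = np.empty(len(pairs))
            ses = np.empty(len(pairs))
            tstats = np.empty(len(pairs))
            pvals = np.empty(len(pairs))
            chunk = 200_000
            for start in range(0, len(pairs), chunk):
                sl = slice(start, min(start + chunk, len(pairs)))
                sx = Xr[:, si[sl]]
                sy = Yr[:, ti[sl]]
                sxx = np.einsum("ij,ij->j", sx, sx)
                sxy = np.einsum("ij,ij->j", sx, sy)
                syy = np.einsum("ij,ij->j", sy, sy)
                with np.errstate(divide="ignore", invalid="ignore"):
                    slope = sxy / sxx
                    rss = syy - sxy * slope
                    rss = np.maximum(rss, 0.0)
                    sigma2 = rss / df_resid
                    se = np.sqrt(sigma2 / sxx)
                    t = slope / se
                p = 2.0 * stats.t.sf(np.abs(t), df_resid)
                # degenerate predictors -> flagged with missing p
                const_x = sxx <= 1e-12 * n
                slope[const_x] = np.nan
                se[const_x] = np.nan
                t[const_x] = np.nan
                p[const_x] = np.nan
                # perfect fits -> p = 0, not NaN
                perfect = (~const_x) & (rss <= np.maximum(syy, 1.0) * 1e-14)
                p[perfect] = 0.0
                t[perfect] = np.inf
                se[perfect] = 0.0
                slopes[sl], ses[sl], tstats[sl], pvals[sl] = slope, se, t, p
            if np.any(np.isnan(pvals)):
                logger.warning(
                    "%s scan: %d pairs with degenerate predictor flagged (p missing)",
                    self.mode, int(np.sum(np.isnan(pvals))),
                )
            table["slope"] = slopes
            table["se"] = ses
            table["t_stat"] = tstats
            table["p_value"] = pvals
        else:
            for col in ("slope", "se", "t_stat", "p_value"):
                table[col] = pd.Series(dtype=float)
        table = table[ASSOCIATION_COLUMNS]
        table = table.sort_values(
            ["chrom", "target_pos", "source_pos", "source_id", "target_id"],
            kind="stable",
        ).reset_index(drop=True)
        significant = table[table["p_value"] < threshold].reset_index(drop=True)
        cov_names = [] if self.covariates is None else list(self.covariates.columns)
        return ScanResult(
            mode=self.mode,
            threshold=threshold,
            alpha=self.alpha,
            window_bp=self.window_bp,
            n_targets=n_targets,
            n_sources=len(self.source_features),
            n_pairs_tested=len(pairs),
            median_cis=med,
            covariates=cov_names,
            associations=significant,
            full=table if self.keep_all else None,
            n_samples=n,
        )


def scan(
    mode: str,
    dosages: pd.DataFrame | None = None,
    m_values: pd.DataFrame | None = None,
    expression: pd.DataFrame | None = None,
    snp_features: pd.DataFrame | None = None,
    cpg_features: pd.DataFrame | None = None,
    gene_features: pd.DataFrame | None = None,
    covariates: pd.DataFrame | None = None,
    window_bp: int = 1_000_000,
    alpha: float = 0.05,
    keep_all: bool = False,
) -> ScanResult:
    """Convenience wrapper selecting matrices and features by scan mode."""
    if mode == "mQTL":
        x, y, sf, tf = dosages, m_values, snp_features, cpg_features
    elif mode == "eQTL":
        x, y, sf, tf = dosages, expression, snp_features, gene_features
    elif mode == "eQTM":
        x, y, sf, tf = m_values, expression, cpg_features, gene_features
    else:
        raise ValueError(f"mode must be one of {MODES}")
    if x is None or y is None or sf is None or tf is None:
        raise ValueError(f"mode {mode} requires its two matrices and two feature tables")
    model = CisScan(mode, x, y, sf, tf, covariates=covariates,
                    window_bp=window_bp, alpha=alpha, keep_all=keep_all)
    return model.fit()
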