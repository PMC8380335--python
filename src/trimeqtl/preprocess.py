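"""Value transforms and feature filters applied before cis scanning.

Methylation is measured as beta-values (methylated / total signal, in (0,1))
but modelled on the M-value scale, m = log2(beta / (1 - beta)), which
stabilises the variance at the extremes.  Variability filtering, however, is
done on the beta scale: per-CpG standard deviations are clustered with a 1-D
Gaussian mixture and CpGs falling in low-variability components (mean SD
below the cutoff) are dropped.  SNP dosages are filtered on coded-allele
frequency and missingness, with remaining missing entries mean-imputed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

logger = logging.getLogger(__name__)

__all__ = [
    "beta_to_m",
    "m_to_beta",
    "filter_snps",
    "sd_mixture_filter",
    "sd_threshold_filter",
    "MixtureFit",
]


def beta_to_m(beta):
    """Logit (base 2) transform of methylation beta-values.

    Parameters
    ----------
    beta : float or array-like
        Beta-values strictly inside (0, 1).

    Returns
    -------
    float or ndarray
        ``log2(beta / (1 - beta))``.

    Raises
    ------
    ValueError
        If any value lies outside the open interval (0, 1).  No clipping is
        applied; callers that want clipping must do it explicitly.
    """
    arr = np.asarray(beta, dtype=float)
    if np.any(~np.isfinite(arr)) or np.any(arr <= 0.0) or np.any(arr >= 1.0):
        raise ValueError("beta-values must lie strictly in (0, 1)")
    out = np.log2(arr) - np.log2(1.0 - arr)
    return out if out.ndim else float(out)


def m_to_beta(m):
    """Inverse of :func:`beta_to_m`: ``2**m / (1 + 2**m)``, always in (0, 1)."""
    arr = np.asarray(m, dtype=float)
    # logistic in base 2, evaluated stably for large |m|
    out = np.empty_like(arr, dtype=float)
    pos = arr >= 0
    out[pos] = 1.0 / (1.0 + np.exp2(-arr[pos]))
    e = np.exp2(arr[~pos])
    out[~pos] = e / (1.0 + e)
    return out if out.ndim else float(out)


def filter_snps(
    dosages: pd.DataFrame,
    maf_min: float = 0.05,
    missing_max: float = 0.10,
    impute: str = "mean",
):
    """Filter a samples x SNPs dosage matrix on allele frequency and missingness.

    A SNP is kept when its coded-allele frequency (mean dosage / 2, ignoring
    missing entries) lies in ``[maf_min, 1 - maf_min]`` (bounds inclusive) and
    its missing fraction is at most ``missing_max`` ("more than 10% missing"
    is removed, exactly 10% is kept).  Missing entries of kept SNPs are then
    mean-imputed per SNP (``impute="mean"``) or the samples dropped
    (``impute="drop"``).

    Returns
    -------
    (pd.DataFrame, dict)
        The filtered (and imputed) matrix and a report with counts removed
        per rule.
    """
    if not 0 < maf_min < 0.5:
        raise ValueError("maf_min must be in (0, 0.5)")
    if dosages.shape[1] == 0:
        logger.warning("filter_snps: empty input matrix")
        return dosages.copy(), {
            "n_input": 0, "n_removed_maf": 0, "n_removed_missing": 0, "n_kept": 0,
        }
    values = dosages.to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        freq = np.nanmean(values, axis=0) / 2.0
    missing_frac = np.mean(np.isnan(values), axis=0)
    ok_maf = (freq >= maf_min) & (freq <= 1.0 - maf_min)
    ok_missing = missing_frac <= missing_max
    keep = ok_maf & ok_missing
    report = {
        "n_input": int(dosages.shape[1]),
        "n_removed_maf": int(np.sum(~ok_maf)),
        "n_removed_missing": int(np.sum(~ok_missing)),
        "n_kept": int(np.sum(keep)),
    }
    out = dosages.loc[:, keep].copy()
    if impute == "mean":
        col_means = out.mean(axis=0, skipna=True)
        out = out.fillna(col_means)
    elif impute == "drop":
        out = out.dropna(axis=0, how="any")
    else:
        raise ValueError(f"unknown imputation mode {impute!r}")
    return out, report


@dataclass
class MixtureFit:
    """Summary of the Gaussian-mixture fit used by :func:`sd_mixture_filter`."""

    method: str
    n_components: int = 0
    means: list = field(default_factory=list)
    weights: list = field(default_factory=list)
    bic: dict = field(default_factory=dict)
    low_components: list = field(default_factory=list)


def sd_threshold_filter(matrix: pd.DataFrame, sd_cutoff: float = 0.05):
    """Keep features whose per-feature SD (ddof=1) is >= ``sd_cutoff``."""
    sds = matrix.std(axis=0, ddof=1)
    kept = list(sds.index[sds >= sd_cutoff])
    return kept, MixtureFit(method="threshold")


def sd_mixture_filter(
    matrix: pd.DataFrame,
    sd_cutoff: float = 0.05,
    max_components: int = 4,
    method: str = "mixture",
    random_state: int = 0,
):
    """Drop low-variability features by clustering their standard deviations.

    Per-feature standard deviations (of beta-values, for methylation) are fit
    with 1-D Gaussian mixtures for K = 1..``max_components``; K is chosen by
    BIC.  Features assigned to components whose mean SD is below ``sd_cutoff``
    are excluded.  ``method="threshold"`` skips the mixture and keeps exactly
    the features with SD >= cutoff.

    Returns
    -------
    (list, MixtureFit)
        Kept feature ids (in input column order) and the fit summary.
    """
    if matrix.shape[0] < 2:
        raise ValueError("need at least 2 samples to compute SDs")
    if method == "threshold":
        return sd_threshold_filter(matrix, sd_cutoff)
    if method != "mixture":
        raise ValueError(f"unknown method {method!r}")

    sds = matrix.std(axis=0, ddof=1)
    X = sds.to_numpy(dtype=float).reshape(-1, 1)
    try:
        bics = {}
        fits = {}
        kmax = min(max_components, max(1, len(sds)))
        for k in range(1, kmax + 1):
            gm = GaussianMixture(
                n_components=k, n_init=3, random_state=random_state, reg_covar=1e-10
            )
            gm.fit(X)
            if not gm.converged_:
                continue
            bics[k] = float(gm.bic(X))
            fits[k] = gm
        if not fits:
            raise RuntimeError("no mixture fit converged")
        best_k = min(bics, key=bics.get)
        gm = fits[best_k]
    except Exception as exc:  # degenerate component / EM failure
        logger.warning("sd_mixture_filter: EM failed (%s); falling back to plain threshold", exc)
        kept, _ = sd_threshold_filter(matrix, sd_cutoff)
        return kept, MixtureFit(method="threshold-fallback")

    means = gm.means_.ravel()
    labels = gm.predict(X)
    low = np.flatnonzero(means < sd_cutoff)
    keep_mask = ~np.isin(labels, low)
    kept = list(sds.index[keep_mask])
    fit = MixtureFit(
        method="mixture",
        n_components=int(gm.n_components),
        means=[float(v) for v in means],
        weights=[float(v) for v in gm.weights_.ravel()],
        bic={int(k): v for k, v in bics.items()},
        low_components=[int(i) for i in low],
    )
    return kept, fit
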