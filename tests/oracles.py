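"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (enumeration, O(n^2)/O(n^3) loops,
exact rational arithmetic) and shares no code with the package paths it
checks.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np


def ols_slope_oracle(y, x, covariates=None):
    """Slope, SE, t and p for y ~ 1 + x + covariates via statsmodels."""
    import statsmodels.api as sm

    X = np.column_stack([np.asarray(x, float)] + (
        [np.asarray(covariates, float)] if covariates is not None else []))
    model = sm.OLS(np.asarray(y, float), sm.add_constant(X))
    fit = model.fit()
    return {
        "slope": fit.params[1], "se": fit.bse[1],
        "t_stat": fit.tvalues[1], "p_value": fit.pvalues[1],
    }


def connected_components_oracle(n_nodes, edges):
    """Connected components by depth-first search over an explicit edge list."""
    adj = {i: set() for i in range(n_nodes)}
    for i, j in edges:
        adj[i].add(j)
        adj[j].add(i)
    seen, comps = set(), []
    for start in range(n_nodes):
        if start in seen:
            continue
        stack, comp = [start], set()
        while stack:
            v = stack.pop()
            if v in comp:
                continue
            comp.add(v)
            stack.extend(adj[v] - comp)
        seen |= comp
        comps.append(frozenset(comp))
    return set(comps)


def fisher_two_sided_oracle(a, b, c, d):
    """Two-sided Fisher exact p by full hypergeometric enumeration.

    Exact rational arithmetic: sums P(table) over all tables with the same
    margins whose probability is <= that of the observed table (with the
    conventional tiny relative slack for ties).
    """
    r1, r2 = a + b, c + d
    n = r1 + r2
    c1 = a + c
    denom = comb(n, c1)
    def prob(k):
        return Fraction(comb(r1, k) * comb(r2, c1 - k), denom)
    p_obs = prob(a)
    cutoff = p_obs + p_obs / 10**7  # relative tie tolerance
    lo, hi = max(0, c1 - r2), min(r1, c1)
    total = sum(prob(k) for k in range(lo, hi + 1) if prob(k) <= cutoff)
    return float(total)


def fisher_pvalues_for_margins(r1, r2, c1):
    """Two-sided Fisher p for every table with margins (r1, r2, c1).

    Returns dict a -> p over the support, by the same enumeration rule as
    :func:`fisher_two_sided_oracle` but computed once per margin class.
    """
    n = r1 + r2
    denom = comb(n, c1)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    probs = {k: Fraction(comb(r1, k) * comb(r2, c1 - k), denom) for k in range(lo, hi + 1)}
    out = {}
    for a, p_obs in probs.items():
        cutoff = p_obs + p_obs / 10**7
        out[a] = float(sum(p for p in probs.values() if p <= cutoff))
    return out


def partial_corr_oracle(x, y, z):
    """Partial Pearson correlation of x and y given z, via explicit residuals."""
    x, y, z = (np.asarray(v, float) for v in (x, y, z))
    Z = np.column_stack([np.ones_like(z), z])
    bx, *_ = np.linalg.lstsq(Z, x, rcond=None)
    by, *_ = np.linalg.lstsq(Z, y, rcond=None)
    rx, ry = x - Z @ bx, y - Z @ by
    return float(np.corrcoef(rx, ry)[0, 1])


def triads_triple_loop(mqtl_pairs, eqtl_pairs, eqtm_pairs):
    """All (snp, cpg, gene) with every pairwise association present; O(n^3)."""
    out = set()
    for s1, cpg in mqtl_pairs:
        for s2, gene in eqtl_pairs:
            if s2 != s1:
                continue
            for c2, g2 in eqtm_pairs:
                if c2 == cpg and g2 == gene:
                    out.add((s1, cpg, gene))
    return out


def cis_pairs_brute_force(sources, targets, window_bp):
    """All-pairs O(n^2) cis filter over two feature tables."""
    anchor_col = "tss" if "tss" in targets.columns else "pos"
    out = set()
    for s in sources.itertuples(index=False):
        for t in targets.itertuples(index=False):
            if s.chrom == t.chrom and abs(getattr(t, anchor_col) - s.pos) <= window_bp:
                out.add((s.id, t.id))
    return out


def univariate_gaussian_bic_oracle(v):
    """Closed-form single-node Gaussian BIC: ML loglik minus (2/2) log n."""
    v = np.asarray(v, float)
    n = len(v)
    sigma2 = np.mean((v - v.mean()) ** 2)
    loglik = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)
    return loglik - 0.5 * 2 * np.log(n)
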