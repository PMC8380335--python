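"""Synthetic genotype-methylation-expression studies with known causal truth.

The generator emulates the statistical structure of a colon-tissue cohort:
allelic dosages in [0, 2] drawn under Hardy-Weinberg with local LD partner
SNPs, CpG beta-values in (0, 1) obtained from linear-Gaussian M-value
models with correlated cis-CpG partners, log2-scale Gaussian expression,
and covariates (age, sex, colon site, tissue type).  Each simulated triad
follows one of the five structural causal models (or a global null):

========  =========================================================
label      structural equations (standardized G; eps Gaussian noise)
========  =========================================================
GMeE_GE    Me = a*G + eps1;           E = b*Me + c*G + eps2
GE_GMe     Me = a*G + eps1;           E = c*G + eps2
GMeE       Me = a*G + eps1;           E = b*Me + eps2
GEMe       E  = c*G + eps2;           Me = d*E + eps1
GEMe_GMe   E  = c*G + eps2;           Me = d*E + a*G + eps1
NULL       Me = eps1;                 E = eps2
========  =========================================================

All triads live on one synthetic chromosome, spaced 3 Mb apart so their
cis windows (+/- 1 Mb) never overlap; within a triad all SNPs lie within
1 Mb of the CpG and the gene TSS.  Every stochastic step flows from a
single seeded generator, so a fixed config yields byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from trimeqtl.preprocess import m_to_beta

__all__ = ["CAUSAL_MODELS", "SimulationConfig", "SyntheticStudy",
           "simulate_genotypes", "simulate_triads"]

CAUSAL_MODELS = ("GMeE_GE", "GE_GMe", "GMeE", "GEMe", "GEMe_GMe", "NULL")

TRIAD_SPACING_BP = 3_000_000


@dataclass
class SimulationConfig:
    """Study-design parameters for :func:`simulate_triads`.

    Effect sizes are standardized structural slopes on the M-value / log2
    scales: ``effect_g_me`` (a, G->Me), ``effect_me_e`` (b, Me->E),
    ``effect_g_e`` (c, G->E) and ``effect_e_me`` (d, E->Me).  The sample
    size default of 132 matches a cohort of 37 healthy plus 95
    tumor-adjacent normal samples.
    """

    n_samples: int = 132
    n_triads: int = 20
    causal_model: object = "GMeE_GE"  # one label or a per-triad list
    maf_range: tuple = (0.1, 0.5)
    effect_g_me: float = 1.0
    effect_me_e: float = 0.4
    effect_g_e: float = 1.0
    effect_e_me: float = 0.4
    noise_sd_me: float = 1.0
    noise_sd_e: float = 1.0
    n_ld_partners: int = 9
    ld_r2: float = 0.8
    n_cpg_partners: int = 0
    confound_me: float = 0.0
    confound_e: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 10:
            raise ValueError("n_samples must be >= 10")
        if self.n_triads < 0:
            raise ValueError("n_triads must be >= 0")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("maf_range must lie within (0, 1)")
        if self.noise_sd_me <= 0 or self.noise_sd_e <= 0:
            raise ValueError("noise SDs must be positive")
        if not 0.0 <= self.ld_r2 <= 1.0:
            raise ValueError("ld_r2 must be in [0, 1]")
        if self.n_ld_partners < 0 or self.n_cpg_partners < 0:
            raise ValueError("partner counts must be >= 0")
        for m in self.models():
            if m not in CAUSAL_MODELS:
                raise ValueError(f"unknown causal model {m!r}; choose from {CAUSAL_MODELS}")

    def models(self) -> list:
        """Per-triad causal-model labels."""
        if isinstance(self.causal_model, str):
            return [self.causal_model] * self.n_triads
        models = list(self.causal_model)
        if len(models) != self.n_triads:
            raise ValueError("per-triad causal_model list must have length n_triads")
        return models


@dataclass
class SyntheticStudy:
    """A complete simulated study with per-triad generating truth."""

    dosages: pd.DataFrame
    betas: pd.DataFrame
    expression: pd.DataFrame
    covariates: pd.DataFrame
    snp_features: pd.DataFrame
    cpg_features: pd.DataFrame
    gene_features: pd.DataFrame
    truth: list = field(default_factory=list)

    def __post_init__(self):
        idx = self.dosages.index
        for name in ("betas", "expression", "covariates"):
            if not getattr(self, name).index.equals(idx):
                raise ValueError(f"{name} does not share the sample axis with dosages")
        b = self.betas.to_numpy()
        if b.size and (b.min() <= 0.0 or b.max() >= 1.0):
            raise ValueError("beta-values must lie strictly in (0, 1)")


def _hw_haplotypes(rng, n_samples, freqs):
    """Two Bernoulli(freq) allele draws per sample per locus."""
    return rng.random((n_samples, 2, len(freqs))) < freqs


def _ld_partner(rng, hap, ld_r2):
    """Copy haplotypes, flipping each allele with probability (1-sqrt(r2))/2.

    For an allele frequency q the correlation between original and copy is
    (1 - 2f) * sqrt(q(1-q) / (q'(1-q'))) with q' the flipped frequency; at
    f = (1 - sqrt(r2))/2 the expected squared correlation is approximately
    ld_r2 (exact at q = 0.5).
    """
    f_flip = 0.5 * (1.0 - np.sqrt(ld_r2))
    if f_flip == 0.0:
        return hap.copy()
    flips = rng.random(hap.shape) < f_flip
    return hap ^ flips


def simulate_genotypes(
    n_samples: int,
    n_snps: int,
    maf_range: tuple = (0.05, 0.95),
    ld_r2: float = 0.0,
    n_ld_partners: int = 0,
    seed: int = 0,
    chrom: str = "1",
    start_pos: int = 1,
    spacing: int = 1_000,
    id_prefix: str = "snp",
):
    """Hardy-Weinberg dosages with optional LD partner columns.

    Each of ``n_snps`` causal loci gets an allele frequency uniform in
    ``maf_range`` and ``n_ld_partners`` partner SNPs built by copying its
    haplotypes with per-allele flips targeting ``ld_r2``.  Positions are
    1-based on one synthetic chromosome, ``spacing`` bp apart.

    Returns ``(dosages, features)``: a samples x SNPs DataFrame with values
    in [0, 2] and a feature table (``id, chrom, pos``).
    """
    lo, hi = maf_range
    if not (0.0 < lo <= hi < 1.0):
        raise ValueError("maf_range must lie within (0, 1)")
    rng = np.random.default_rng(seed)
    sample_ids = [f"sample{i:04d}" for i in range(n_samples)]
    if n_snps == 0:
        empty = pd.DataFrame(index=pd.Index(sample_ids, name="sample_id"))
        return empty, pd.DataFrame(columns=["id", "chrom", "pos"])
    freqs = rng.uniform(lo, hi, n_snps)
    hap = _hw_haplotypes(rng, n_samples, freqs)
    cols, ids = [hap.sum(axis=1)], [[f"{id_prefix}{j:05d}" for j in range(n_snps)]]
    for p in range(n_ld_partners):
        cols.append(_ld_partner(rng, hap, ld_r2).sum(axis=1))
        ids.append([f"{id_prefix}{j:05d}_ld{p + 1}" for j in range(n_snps)])
    # interleave: causal SNP then its partners, so positions are local
    values = np.empty((n_samples, n_snps * (1 + n_ld_partners)), dtype=float)
    all_ids = []
    k = 0
    for j in range(n_snps):
        for block, idlist in zip(cols, ids):
            values[:, k] = block[:, j]
            all_ids.append(idlist[j])
            k += 1
    dosages = pd.DataFrame(values, index=pd.Index(sample_ids, name="sample_id"), columns=all_ids)
    features = pd.DataFrame({
        "id": all_ids,
        "chrom": chrom,
        "pos": start_pos + spacing * np.arange(len(all_ids), dtype=np.int64),
    })
    return dosages, features


def _covariates(rng, n_samples) -> pd.DataFrame:
    n_healthy = int(round(n_samples * 37 / 132))
    tissue = np.array([0] * n_healthy + [1] * (n_samples - n_healthy))
    return pd.DataFrame({
        "age": np.round(rng.normal(67.0, 8.0, n_samples), 1),
        "sex": rng.integers(0, 2, n_samples),
        "site": rng.integers(0, 2, n_samples),
        "tissue_type": tissue,
    })


def simulate_triads(config: SimulationConfig) -> SyntheticStudy:
    """Generate a complete study under the configured causal models.

    M-values come from the structural equations, are shifted by a per-CpG
    baseline and mapped to beta-values via the inverse logit2 transform;
    expression gets a per-gene log2 baseline.  When ``confound_me`` /
    ``confound_e`` are non-zero, standardized age and sex enter both traits
    with those coefficients, creating covariate confounding.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    sample_ids = pd.Index([f"sample{i:04d}" for i in range(n)], name="sample_id")
    covariates = _covariates(rng, n).set_index(sample_ids)
    age_std = (covariates["age"].to_numpy() - covariates["age"].mean()) / max(covariates["age"].std(), 1e-9)
    sex = covariates["sex"].to_numpy(dtype=float)
    confound = None
    if config.confound_me or config.confound_e:
        confound = age_std + sex - sex.mean()

    models = config.models()
    a, b, c, d = (config.effect_g_me, config.effect_me_e,
                  config.effect_g_e, config.effect_e_me)

    dos_cols, dos_ids, snp_rows = [], [], []
    m_cols, m_ids, cpg_rows = [], [], []
    e_cols, e_ids, gene_rows = [], [], []
    truth = []
    n_snps_per_triad = 1 + config.n_ld_partners

    for t, model in enumerate(models):
        base = t * TRIAD_SPACING_BP + 1_500_000
        # --- genotypes: one causal SNP plus LD partners, within 1 Mb of CpG/TSS
        q = rng.uniform(*config.maf_range)
        hap = _hw_haplotypes(rng, n, np.array([q]))
        g = hap.sum(axis=1)[:, 0].astype(float)
        snp_id = f"snp_t{t:04d}"
        snp_block_ids = [snp_id] + [f"{snp_id}_ld{p + 1}" for p in range(config.n_ld_partners)]
        snp_pos = base - 500_000 + 1_000 * np.arange(n_snps_per_triad, dtype=np.int64)
        dos_cols.append(g)
        for p in range(config.n_ld_partners):
            dos_cols.append(_ld_partner(rng, hap, config.ld_r2).sum(axis=1)[:, 0].astype(float))
        dos_ids.extend(snp_block_ids)
        for sid, spos in zip(snp_block_ids, snp_pos):
            snp_rows.append((sid, "1", int(spos)))

        g_std = (g - 2.0 * q) / np.sqrt(2.0 * q * (1.0 - q))
        eps1 = rng.normal(0.0, config.noise_sd_me, n)
        eps2 = rng.normal(0.0, config.noise_sd_e, n)
        if model == "GMeE_GE":
            me = a * g_std + eps1
            e = b * me + c * g_std + eps2
        elif model == "GE_GMe":
            me = a * g_std + eps1
            e = c * g_std + eps2
        elif model == "GMeE":
            me = a * g_std + eps1
            e = b * me + eps2
        elif model == "GEMe":
            e = c * g_std + eps2
            me = d * e + eps1
        elif model == "GEMe_GMe":
            e = c * g_std + eps2
            me = d * e + a * g_std + eps1
        else:  # NULL
            me = eps1
            e = eps2
        if confound is not None:
            me = me + config.confound_me * confound
            e = e + config.confound_e * confound

        cpg_id = f"cpg_t{t:04d}"
        me_baseline = rng.uniform(-2.5, 2.5)
        cpg_block = [(cpg_id, me + me_baseline)]
        sd_me = max(float(np.std(me)), 1e-9)
        for p in range(config.n_cpg_partners):
            partner = me + rng.normal(0.0, 0.5 * sd_me, n)
            cpg_block.append((f"{cpg_id}_co{p + 1}", partner + me_baseline))
        for j, (cid, mvals) in enumerate(cpg_block):
            m_cols.append(mvals)
            m_ids.append(cid)
            cpg_rows.append((cid, "1", int(base + 200 * j)))

        gene_id = f"gene_t{t:04d}"
        e_baseline = rng.uniform(6.0, 10.0)
        e_cols.append(e + e_baseline)
        e_ids.append(gene_id)
        gene_rows.append((gene_id, "1", int(base + 100_000), "+"))

        truth.append({
            "snp_id": snp_id,
            "cpg_id": cpg_id,
            "gene_id": gene_id,
            "causal_model": model,
            "effect_g_me": a if model in ("GMeE_GE", "GE_GMe", "GMeE", "GEMe_GMe") else 0.0,
            "effect_me_e": b if model in ("GMeE_GE", "GMeE") else 0.0,
            "effect_g_e": c if model in ("GMeE_GE", "GE_GMe", "GEMe", "GEMe_GMe") else 0.0,
            "effect_e_me": d if model in ("GEMe", "GEMe_GMe") else 0.0,
            "maf": float(q),
        })

    def _frame(cols, ids):
        if not cols:
            return pd.DataFrame(index=sample_ids)
        return pd.DataFrame(np.column_stack(cols), index=sample_ids, columns=ids)

    m_matrix = _frame(m_cols, m_ids)
    betas = pd.DataFrame(m_to_beta(m_matrix.to_numpy()), index=sample_ids, columns=m_ids) \
        if m_cols else pd.DataFrame(index=sample_ids)
    return SyntheticStudy(
        dosages=_frame(dos_cols, dos_ids),
        betas=betas,
        expression=_frame(e_cols, e_ids),
        covariates=covariates,
        snp_features=pd.DataFrame(snp_rows, columns=["id", "chrom", "pos"]),
        cpg_features=pd.DataFrame(cpg_rows, columns=["id", "chrom", "pos"]),
        gene_features=pd.DataFrame(gene_rows, columns=["id", "chrom", "tss", "strand"]),
        truth=truth,
    )
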