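import numpy as np
import pandas as pd
import pytest

from oracles import cis_pairs_brute_force, ols_slope_oracle
from conftest import m_matrix
from trimeqtl.qtl_scan import (
    CisScan,
    SampleAlignmentError,
    bonferroni_threshold,
    cis_pairs,
    fit_additive_linear,
    median_cis_count,
    scan,
)
from trimeqtl.synthetic_data import SimulationConfig, simulate_triads


class TestCisPairs:
    def test_window_boundary_inclusive(self):
        sources = pd.DataFrame({
            "id": ["at", "edge", "out"],
            "chrom": "1",
            "pos": [5_000_000, 4_000_000, 3_999_999],
        })
        targets = pd.DataFrame({"id": ["t"], "chrom": ["1"], "pos": [5_000_000]})
        pairs = cis_pairs(sources, targets, window_bp=1_000_000)
        assert set(pairs["source_id"]) == {"at", "edge"}
        # signed distance: anchor - source position
        d = pairs.set_index("source_id")["distance"]
        assert d["at"] == 0 and d["edge"] == 1_000_000

    def test_matches_brute_force_oracle(self, features_toy):
        snps, cpgs = features_toy
        pairs = cis_pairs(snps, cpgs, window_bp=1_000_000)
        got = set(zip(pairs["source_id"], pairs["target_id"]))
        assert got == cis_pairs_brute_force(snps, cpgs, 1_000_000)

    def test_gene_targets_anchor_at_tss(self):
        snps = pd.DataFrame({"id": ["s"], "chrom": ["1"], "pos": [1_000]})
        genes = pd.DataFrame({"id": ["g"], "chrom": ["1"], "tss": [900_000],
                              "strand": ["+"]})
        pairs = cis_pairs(snps, genes)
        assert len(pairs) == 1 and pairs["distance"].iloc[0] == 899_000


class TestMedianCisCount:
    @pytest.mark.parametrize("counts,expected", [
        ({"a": 3, "b": 3, "c": 3}, 3),
        ({"a": 1, "b": 2, "c": 3, "d": 4}, 3),   # mean(2,3)=2.5 rounds half-up
        ({"a": 7}, 7),
    ])
    def test_examples(self, counts, expected):
        pairs = pd.DataFrame({
            "source_id": [f"{t}_{i}" for t, k in counts.items() for i in range(k)],
            "target_id": [t for t, k in counts.items() for i in range(k)],
        })
        targets = pd.DataFrame({"id": list(counts)})
        assert median_cis_count(pairs, targets) == expected

    def test_zero_partner_targets_counted(self):
        pairs = pd.DataFrame({"source_id": ["s"] * 4, "target_id": ["a"] * 4})
        targets = pd.DataFrame({"id": ["a", "b", "c"]})  # b, c have 0 partners
        assert median_cis_count(pairs, targets) == 0


class TestBonferroniThreshold:
    @pytest.mark.parametrize("n_targets,median_cis,printed", [
        (211_268, 4_817, 4.9e-11),
        (14_654, 5_000, 6.8e-10),
        (14_654, 201, 1.7e-08),
    ])
    def test_printed_thresholds_to_two_significant_figures(self, n_targets, median_cis, printed):
        value = bonferroni_threshold(0.05, n_targets, median_cis)
        assert float(f"{value:.1e}") == pytest.approx(printed)

    def test_identity(self):
        assert bonferroni_threshold(0.05, 1, 1) == 0.05

    def test_zero_counts_error(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0, 10)

    def test_monotone_in_counts(self):
        base = bonferroni_threshold(0.05, 100, 10)
        assert bonferroni_threshold(0.05, 101, 10) < base
        assert bonferroni_threshold(0.05, 100, 11) < base


class TestFitAdditiveLinear:
    def test_matches_statsmodels_oracle(self, rng):
        n = 80
        x = rng.normal(size=n)
        C = rng.normal(size=(n, 2))
        y = 2 + 3 * x + C @ [0.5, -1.0] + rng.normal(size=n)
        got = fit_additive_linear(y, x, C)
        want = ols_slope_oracle(y, x, C)
        for key in ("slope", "se", "t_stat", "p_value"):
            assert got[key] == pytest.approx(want[key], rel=1e-8)

    def test_near_noiseless_slope_recovery(self, rng):
        x = rng.normal(size=50)
        y = 2 + 3 * x + rng.normal(0, 1e-6, 50)
        fit = fit_additive_linear(y, x)
        assert fit["slope"] == pytest.approx(3.0, abs=0.01)

    def test_type_one_error_calibration(self, rng):
        n, reps = 40, 4000
        X = rng.normal(size=(reps, n))
        Y = rng.normal(size=(reps, n))
        hits = sum(fit_additive_linear(Y[i], X[i])["p_value"] < 0.05 for i in range(reps))
        assert hits / reps == pytest.approx(0.05, abs=0.012)

    def test_perfect_fit_reports_zero_p(self, rng):
        x = rng.normal(size=30)
        fit = fit_additive_linear(x.copy(), x)
        assert fit["p_value"] == 0.0 and np.isinf(fit["t_stat"])
        assert fit["flag"] == "zero_residual"

    def test_constant_predictor_flagged(self, rng):
        fit = fit_additive_linear(rng.normal(size=30), np.ones(30))
        assert np.isnan(fit["p_value"]) and fit["flag"] == "constant_x"


def _default_scan(study, mode="mQTL", **kwargs):
    return scan(
        mode,
        dosages=study.dosages,
        m_values=m_matrix(study.betas),
        expression=study.expression,
        snp_features=study.snp_features,
        cpg_features=study.cpg_features,
        gene_features=study.gene_features,
        covariates=study.covariates[["age", "site", "sex"]],
        **kwargs,
    )


class TestScan:
    def test_planted_mqtls_found_and_consistent(self, small_study):
        res = _default_scan(small_study, keep_all=True)
        assert res.n_significant > 0
        assert (res.associations["p_value"] < res.threshold).all()
        planted = {(t["snp_id"], t["cpg_id"]) for t in small_study.truth}
        found = set(zip(res.associations["source_id"], res.associations["target_id"]))
        assert planted <= found

    def test_scan_p_matches_per_pair_oracle(self, small_study):
        res = _default_scan(small_study, keep_all=True)
        covs = small_study.covariates[["age", "site", "sex"]].to_numpy(dtype=float)
        mvals = m_matrix(small_study.betas)
        for row in res.associations.head(8).itertuples(index=False):
            want = ols_slope_oracle(
                mvals[row.target_id].to_numpy(),
                small_study.dosages[row.source_id].to_numpy(),
                covs,
            )
            assert row.p_value == pytest.approx(want["p_value"], rel=1e-8)
            assert row.slope == pytest.approx(want["slope"], rel=1e-8)

    def test_invariant_to_sample_and_feature_order(self, small_study, rng):
        res = _default_scan(small_study)
        perm = rng.permutation(small_study.dosages.index)
        shuffled = scan(
            "mQTL",
            dosages=small_study.dosages.loc[perm, ::-1],
            m_values=m_matrix(small_study.betas).loc[perm],
            snp_features=small_study.snp_features.iloc[::-1],
            cpg_features=small_study.cpg_features,
            covariates=small_study.covariates.loc[perm, ["age", "site", "sex"]],
        )
        a = res.associations.sort_values(["source_id", "target_id"]).reset_index(drop=True)
        b = shuffled.associations.sort_values(["source_id", "target_id"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b, check_like=True, atol=1e-10)

    def test_sample_mismatch_raises_with_names(self, small_study):
        bad = m_matrix(small_study.betas).iloc[:-3]
        with pytest.raises(SampleAlignmentError, match="sample"):
            CisScan(
                "mQTL", small_study.dosages, bad,
                small_study.snp_features, small_study.cpg_features,
            )

    def test_eqtm_without_signal_yields_nothing(self):
        # under GE_GMe, Me and E are associated only through G; given enough
        # stringency the eQTM scan on a NULL study must stay empty
        cfg = SimulationConfig(n_triads=30, causal_model="NULL", seed=9)
        study = simulate_triads(cfg)
        res = scan(
            "eQTM",
            m_values=m_matrix(study.betas),
            expression=study.expression,
            cpg_features=study.cpg_features,
            gene_features=study.gene_features,
            covariates=study.covariates[["age", "site", "tissue_type", "sex"]],
        )
        assert res.n_significant == 0
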