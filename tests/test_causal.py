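import collections

import numpy as np
import pytest

from conftest import m_matrix
from oracles import univariate_gaussian_bic_oracle
from trimeqtl.causal import (
    DEFAULT_BLACKLIST,
    DegenerateDataError,
    TriadCausalModel,
    TriadData,
    classify_dag,
    classify_triads,
    enumerate_dags,
    equivalence_class,
    gaussian_bic_score,
    hill_climb,
)
from trimeqtl.synthetic_data import SimulationConfig, simulate_triads


def _triad_vectors(study, truth):
    m = m_matrix(study.betas)
    return (study.dosages[truth["snp_id"]].to_numpy(),
            m[truth["cpg_id"]].to_numpy(),
            study.expression[truth["gene_id"]].to_numpy())


class TestEnumerateDags:
    def test_twelve_legal_dags(self):
        dags = enumerate_dags()
        assert len(dags) == 12
        assert len(set(dags)) == 12

    def test_empty_graph_included_and_blacklist_respected(self):
        dags = enumerate_dags()
        assert frozenset() in dags
        for dag in dags:
            assert not any(arc in DEFAULT_BLACKLIST for arc in dag)
            assert not ({("Me", "E"), ("E", "Me")} <= dag)


class TestGaussianBicScore:
    def test_complete_dags_score_identically(self, rng):
        d = TriadData(rng.normal(size=300), rng.normal(size=300), rng.normal(size=300))
        c1 = frozenset({("G", "Me"), ("G", "E"), ("Me", "E")})
        c2 = frozenset({("G", "Me"), ("G", "E"), ("E", "Me")})
        s1, s2 = gaussian_bic_score(c1, d), gaussian_bic_score(c2, d)
        assert s1 == pytest.approx(s2, abs=1e-8)

    def test_empty_dag_equals_univariate_closed_form(self, rng):
        g, me, e = rng.normal(size=200), rng.normal(size=200), rng.normal(size=200)
        d = TriadData(g, me, e)
        expected = sum(univariate_gaussian_bic_oracle(v) for v in (g, me, e))
        assert gaussian_bic_score(frozenset(), d) == pytest.approx(expected, rel=1e-10)

    def test_independent_data_prefers_empty_dag(self):
        wins = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            d = TriadData(r.normal(size=5000), r.normal(size=5000), r.normal(size=5000))
            cache = {}
            scores = {g: gaussian_bic_score(g, d, cache) for g in enumerate_dags()}
            wins += max(scores, key=scores.get) == frozenset()
        assert wins >= 19

    def test_illegal_dag_rejected(self, rng):
        d = TriadData(rng.normal(size=50), rng.normal(size=50), rng.normal(size=50))
        with pytest.raises(ValueError):
            gaussian_bic_score(frozenset({("Me", "G")}), d)


class TestHillClimb:
    def test_no_signal_returns_empty_dag(self):
        hits = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            d = TriadData(r.normal(size=5000), r.normal(size=5000), r.normal(size=5000))
            dag, _ = hill_climb(d)
            hits += dag == frozenset()
        assert hits >= 19

    def test_equals_exhaustive_max_on_mixed_models(self):
        agree = total = 0
        for model in ("GMeE_GE", "GE_GMe", "GMeE", "GEMe", "GEMe_GMe"):
            cfg = SimulationConfig(n_triads=40, causal_model=model, seed=21, n_ld_partners=0)
            study = simulate_triads(cfg)
            for truth in study.truth:
                d = TriadData(*_triad_vectors(study, truth))
                cache = {}
                dag, score = hill_climb(d, cache=cache)
                best = max(gaussian_bic_score(g, d, cache) for g in enumerate_dags())
                agree += score >= best - 1e-9
                total += 1
        assert agree / total >= 0.99

    def test_chain_structure_recovery_at_large_n(self):
        hits = 0
        for seed in range(60):
            cfg = SimulationConfig(n_samples=1000, n_triads=1, causal_model="GMeE",
                                   effect_g_me=0.8, effect_me_e=0.8, seed=seed,
                                   n_ld_partners=0)
            study = simulate_triads(cfg)
            d = TriadData(*_triad_vectors(study, study.truth[0]))
            dag, _ = hill_climb(d)
            hits += dag == frozenset({("G", "Me"), ("Me", "E")})
        assert hits >= 54  # >= 90%


class TestClassifyDag:
    @pytest.mark.parametrize("arcs,label", [
        ({("G", "Me"), ("Me", "E"), ("G", "E")}, "GMeE_GE"),
        ({("G", "Me"), ("G", "E")}, "GE_GMe"),
        ({("G", "Me"), ("Me", "E")}, "GMeE"),
        ({("G", "E"), ("E", "Me")}, "GEMe"),
        ({("G", "E"), ("E", "Me"), ("G", "Me")}, "GEMe_GMe"),
        (set(), "OTHER"),
        ({("Me", "E")}, "OTHER"),
    ])
    def test_label_mapping(self, arcs, label):
        assert classify_dag(frozenset(arcs)) == label

    def test_total_on_all_twelve_dags(self):
        labels = [classify_dag(d) for d in enumerate_dags()]
        counts = collections.Counter(labels)
        assert counts["OTHER"] == 7
        assert sum(v for k, v in counts.items() if k != "OTHER") == 5

    def test_equivalence_class_pools_complete_dags(self):
        assert equivalence_class(frozenset({("G", "Me"), ("Me", "E"), ("G", "E")})) == "COMPLETE"
        assert equivalence_class(frozenset({("G", "E"), ("E", "Me"), ("G", "Me")})) == "COMPLETE"
        assert equivalence_class(frozenset({("G", "Me"), ("Me", "E")})) == "GMeE"


class TestClassifyTriads:
    def test_recovery_under_ge_gme(self):
        cfg = SimulationConfig(n_triads=150, causal_model="GE_GMe", seed=33, n_ld_partners=0)
        study = simulate_triads(cfg)
        triads = _truth_triads(study)
        calls, freq = classify_triads(triads, study.dosages, m_matrix(study.betas),
                                      study.expression)
        frac = (calls["model"] == "GE_GMe").mean()
        assert frac >= 0.85

    def test_null_triads_mostly_other(self):
        cfg = SimulationConfig(n_triads=150, causal_model="NULL", seed=34, n_ld_partners=0)
        study = simulate_triads(cfg)
        calls, _ = classify_triads(_truth_triads(study), study.dosages,
                                   m_matrix(study.betas), study.expression)
        assert (calls["model"] == "OTHER").mean() >= 0.90

    def test_missing_feature_raises(self, small_study):
        triads = _truth_triads(small_study)
        triads.loc[0, "snp_id"] = "absent_snp"
        with pytest.raises(KeyError, match="absent_snp"):
            classify_triads(triads, small_study.dosages, m_matrix(small_study.betas),
                            small_study.expression)


class TestTriadData:
    def test_rejects_short_or_constant_vectors(self, rng):
        with pytest.raises(ValueError):
            TriadData([1, 2, 3], [1, 2, 3], [1, 2, 3])
        with pytest.raises(DegenerateDataError):
            TriadData(np.ones(20), rng.normal(size=20), rng.normal(size=20))

    def test_model_object_summary_reports_fit(self, rng):
        cfg = SimulationConfig(n_triads=1, causal_model="GMeE", seed=2, n_ld_partners=0)
        study = simulate_triads(cfg)
        model = TriadCausalModel(*_triad_vectors(study, study.truth[0]))
        fit = model.fit(score_table=True)
        assert len(fit.score_table) == 12
        assert fit.score == pytest.approx(max(fit.score_table.values()), abs=1e-9)
        assert fit.model in fit.summary()


def _truth_triads(study):
    import pandas as pd

    return pd.DataFrame([
        {"snp_id": t["snp_id"], "cpg_id": t["cpg_id"], "gene_id": t["gene_id"]}
        for t in study.truth])
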