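"""Causal-model classification of meQTL triads by Bayesian-network learning.

For each triad the three variables G (SNP dosage, treated as continuous),
Me (CpG M-value) and E (log2 expression) form the nodes of a 3-node
Bayesian network.  Structure is learned by score-based hill climbing with a
Gaussian BIC score, under a blacklist forbidding any arc *into* G — neither
methylation nor expression can explain germline genotype.  The legal arc
set is therefore {G->Me, G->E, Me->E, E->Me}, giving 12 legal DAGs
(2 x 2 x 3 choices).  The learned DAG is classified into one of five named
causal models, or OTHER:

======== =======================  =========================================
label     arcs                    interpretation
======== =======================  =========================================
GMeE_GE   G->Me, Me->E, G->E      direct G effect on E plus mediation by Me
GE_GMe    G->Me, G->E             independent G effects; Me passive
GMeE      G->Me, Me->E            full mediation; Me active
GEMe      G->E,  E->Me            expression drives methylation
GEMe_GMe  G->E,  E->Me, G->Me     reverse mediation plus direct G->Me
======== =======================  =========================================

The two complete DAGs (GMeE_GE and GEMe_GMe) are Markov equivalent and score
identically; which one the search returns is decided by the documented,
deterministic move order, so results also carry the equivalence-class label.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "NODES", "ARC_ORDER", "MODEL_LABELS",
    "TriadData", "DegenerateDataError",
    "enumerate_dags", "gaussian_bic_score", "hill_climb",
    "classify_dag", "equivalence_class",
    "TriadCausalModel", "CausalFit", "classify_triads", "model_frequency_table",
]

NODES = ("G", "Me", "E")

# fixed arc order used for deterministic tie-breaking in the search
ARC_ORDER = (("G", "Me"), ("G", "E"), ("Me", "E"), ("E", "Me"))

# arcs into the genotype node are forbidden: Me or E cannot explain germline G
DEFAULT_BLACKLIST = frozenset({("Me", "G"), ("E", "G")})

MODEL_LABELS = {
    frozenset({("G", "Me"), ("Me", "E"), ("G", "E")}): "GMeE_GE",
    frozenset({("G", "Me"), ("G", "E")}): "GE_GMe",
    frozenset({("G", "Me"), ("Me", "E")}): "GMeE",
    frozenset({("G", "E"), ("E", "Me")}): "GEMe",
    frozenset({("G", "E"), ("E", "Me"), ("G", "Me")}): "GEMe_GMe",
}

_COMPLETE_DAGS = (
    frozenset({("G", "Me"), ("G", "E"), ("Me", "E")}),
    frozenset({("G", "Me"), ("G", "E"), ("E", "Me")}),
)


class DegenerateDataError(ValueError):
    """Raised when a triad's data cannot support a Gaussian regression."""


@dataclass
class TriadData:
    """Aligned per-triad sample vectors for the three network nodes."""

    g: np.ndarray
    me: np.ndarray
    e: np.ndarray

    def __post_init__(self):
        self.g = np.asarray(self.g, dtype=float)
        self.me = np.asarray(self.me, dtype=float)
        self.e = np.asarray(self.e, dtype=float)
        n = len(self.g)
        if len(self.me) != n or len(self.e) != n:
            raise ValueError("g, me, e must have equal length")
        if n < 10:
            raise ValueError("need at least 10 samples per triad")
        for name, v in (("g", self.g), ("me", self.me), ("e", self.e)):
            if np.ptp(v) == 0:
                raise DegenerateDataError(f"{name} is constant")

    @property
    def n(self) -> int:
        return len(self.g)

    def node(self, name: str) -> np.ndarray:
        return {"G": self.g, "Me": self.me, "E": self.e}[name]


def _is_legal(dag: frozenset, blacklist=DEFAULT_BLACKLIST) -> bool:
    if any(arc in blacklist for arc in dag):
        return False
    if ("Me", "E") in dag and ("E", "Me") in dag:  # the only possible cycle
        return False
    return all(arc in ARC_ORDER or arc[::-1] in ARC_ORDER for arc in dag)


def enumerate_dags(blacklist=DEFAULT_BLACKLIST) -> list[frozenset]:
    """All legal DAGs over (G, Me, E) respecting the blacklist; 12 by default.

    Enumerated as 2 choices for G->Me x 2 for G->E x 3 for the Me-E arc
    (absent, Me->E, E->Me), in a fixed deterministic order.
    """
    dags = []
    for g_me in (False, True):
        for g_e in (False, True):
            for me_arc in (None, ("Me", "E"), ("E", "Me")):
                arcs = set()
                if g_me:
                    arcs.add(("G", "Me"))
                if g_e:
                    arcs.add(("G", "E"))
                if me_arc is not None:
                    arcs.add(me_arc)
                dag = frozenset(arcs)
                if _is_legal(dag, blacklist):
                    dags.append(dag)
    return dags


def _node_score(child: str, parents: tuple, data: TriadData, cache: dict | None) -> float:
    """Gaussian BIC contribution of one node given its parents.

    Maximized log-likelihood of the linear-Gaussian regression of the child
    on its parents (ML variance rss/n) minus (k/2) log n, with
    k = |parents| + 2 for the intercept and the residual variance.
    """
    key = (child, parents)
    if cache is not None and key in cache:
        return cache[key]
    y = data.node(child)
    n = data.n
    if parents:
        X = np.column_stack([np.ones(n)] + [data.node(p) for p in parents])
        beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        if rank < X.shape[1]:
            raise DegenerateDataError(f"singular regression for node {child} on {parents}")
        resid = y - X @ beta
        rss = float(resid @ resid)
    else:
        rss = float(np.sum((y - y.mean()) ** 2))
    if rss <= 0:
        raise DegenerateDataError(f"zero residual variance for node {child}")
    sigma2 = rss / n
    loglik = -0.5 * n * (math.log(2.0 * math.pi * sigma2) + 1.0)
    k = len(parents) + 2
    score = loglik - 0.5 * k * math.log(n)
    if cache is not None:
        cache[key] = score
    return score


def _parents(dag: frozenset, node: str) -> tuple:
    # canonical parent order follows NODES, so cache keys are stable
    return tuple(p for p in NODES if (p, node) in dag)


def gaussian_bic_score(dag: frozenset, data: TriadData, cache: dict | None = None) -> float:
    """Decomposable Gaussian BIC of a DAG: sum of per-node scores.

    Higher is better.  Score-equivalent: Markov-equivalent DAGs (e.g. the
    two complete graphs) receive identical scores up to floating point.
    """
    if not _is_legal(dag):
        raise ValueError(f"illegal dag: {sorted(dag)}")
    return sum(_node_score(node, _parents(dag, node), data, cache) for node in NODES)


def _neighbors(dag: frozenset, blacklist) -> list:
    """Single-arc moves in deterministic order: adds, deletes, reverses."""
    moves = []
    for arc in ARC_ORDER:
        if arc not in dag:
            cand = frozenset(dag | {arc})
            if _is_legal(cand, blacklist):
                moves.append(cand)
    for arc in ARC_ORDER:
        if arc in dag:
            moves.append(frozenset(dag - {arc}))
    for arc in ARC_ORDER:
        if arc in dag:
            rev = (arc[1], arc[0])
            cand = frozenset((dag - {arc}) | {rev})
            if _is_legal(cand, blacklist):
                moves.append(cand)
    return moves


def hill_climb(
    data: TriadData,
    blacklist=DEFAULT_BLACKLIST,
    cache: dict | None = None,
    tol: float = 1e-9,
):
    """Greedy score-based structure search from the empty DAG.

    At each step the single-arc move (add, delete or reverse) with the
    largest score improvement is applied; on ties the first move in the
    documented order (add < delete < reverse, arcs ordered G->Me, G->E,
    Me->E, E->Me) wins.  Stops when no move improves the score by more than
    ``tol``.  Deterministic given the data.

    Returns ``(dag, score)``.
    """
    if cache is None:
        cache = {}
    current = frozenset()
    current_score = gaussian_bic_score(current, data, cache)
    while True:
        best_dag = None
        best_score = current_score
        for cand in _neighbors(current, blacklist):
            s = gaussian_bic_score(cand, data, cache)
            if s > best_score + tol:  # strict: ties keep the earlier move
                best_dag, best_score = cand, s
        if best_dag is None:
            break
        current, current_score = best_dag, best_score
    return current, current_score


def classify_dag(dag: frozenset) -> str:
    """Map a legal DAG's arc set to its causal-model label (or OTHER)."""
    if not _is_legal(dag):
        raise ValueError(f"illegal dag: {sorted(dag)}")
    return MODEL_LABELS.get(frozenset(dag), "OTHER")


def equivalence_class(dag: frozenset) -> str:
    """Model label pooled over Markov equivalence: the two complete DAGs
    (GMeE_GE, GEMe_GMe) collapse to ``COMPLETE``; others keep their label."""
    if frozenset(dag) in _COMPLETE_DAGS:
        return "COMPLETE"
    return classify_dag(dag)


@dataclass
class CausalFit:
    """Fit result for one triad: learned DAG, label and score table."""

    dag: frozenset
    model: str
    model_class: str
    score: float
    score_table: dict = field(default_factory=dict)

    def summary(self) -> str:
        arcs = ";".join(f"{a}->{b}" for a, b in sorted(self.dag)) or "(empty)"
        lines = [
            "Triad causal model fit",
            "=" * 30,
            f"arcs:        {arcs}",
            f"model:       {self.model}",
            f"class:       {self.model_class}",
            f"BIC score:   {self.score:.4f}",
        ]
        if self.score_table:
            lines.append("score table (all legal DAGs):")
            for dag, s in sorted(self.score_table.items(), key=lambda kv: -kv[1]):
                arcs = ";".join(f"{a}->{b}" for a, b in sorted(dag)) or "(empty)"
                lines.append(f"  {s:12.4f}  {arcs}")
        return "\n".join(lines)


class TriadCausalModel:
    """Bayesian-network model for one SNP-CpG-gene triad.

    Parameters
    ----------
    g, me, e : array-like
        Sample vectors: SNP dosage, CpG M-value, log2 expression.
    blacklist : frozenset of arcs
        Forbidden arcs; defaults to every arc into G.
    """

    def __init__(self, g, me, e, blacklist=DEFAULT_BLACKLIST):
        self.data = TriadData(g, me, e)
        self.blacklist = blacklist

    def fit(self, method: str = "hill_climb", score_table: bool = False) -> CausalFit:
        """Learn the structure; ``method`` is ``"hill_climb"`` or ``"exhaustive"``."""
        cache: dict = {}
        table = {}
        if method == "exhaustive" or score_table:
            table = {d: gaussian_bic_score(d, self.data, cache) for d in enumerate_dags(self.blacklist)}
        if method == "hill_climb":
            dag, score = hill_climb(self.data, self.blacklist, cache)
        elif method == "exhaustive":
            # deterministic: first DAG in enumeration order among maxima
            best = max(table.values())
            dag = next(d for d in enumerate_dags(self.blacklist) if table[d] >= best - 1e-12)
            score = table[dag]
        else:
            raise ValueError(f"unknown method {method!r}")
        return CausalFit(
            dag=dag,
            model=classify_dag(dag),
            model_class=equivalence_class(dag),
            score=score,
            score_table=table if score_table else {},
        )


def _residualize(v: np.ndarray, C: np.ndarray) -> np.ndarray:
    Q, _ = np.linalg.qr(C)
    return v - Q @ (Q.T @ v)


def classify_triads(
    triads: pd.DataFrame,
    dosages: pd.DataFrame,
    m_values: pd.DataFrame,
    expression: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    residualize: bool = False,
    method: str = "hill_climb",
):
    """Classify every triad and tabulate model frequencies.

    Returns ``(calls, freq)``: a per-triad DataFrame with the learned arcs,
    model label, equivalence-class label and score, and a frequency table
    with count and percentage per model.  ``residualize=True`` first regresses
    each of g, me, e on the covariates and classifies the residuals.
    """
    from trimeqtl.qtl_scan import encode_covariates  # avoid cycle at import time

    missing = [
        i for i in triads["snp_id"] if i not in dosages.columns
    ] + [
        i for i in triads["cpg_id"] if i not in m_values.columns
    ] + [
        i for i in triads["gene_id"] if i not in expression.columns
    ]
    if missing:
        raise KeyError(f"triad features missing from matrices: {sorted(set(missing))[:10]}")

    C = None
    if residualize:
        if covariates is None:
            raise ValueError("residualize=True requires covariates")
        enc = encode_covariates(covariates)
        n = len(dosages)
        C = np.column_stack([np.ones(n)] + ([] if enc is None else [enc]))

    rows = []
    for t in triads.itertuples(index=False):
        g = dosages[t.snp_id].to_numpy(dtype=float)
        me = m_values[t.cpg_id].to_numpy(dtype=float)
        e = expression[t.gene_id].to_numpy(dtype=float)
        if C is not None:
            g, me, e = (_residualize(v, C) for v in (g, me, e))
        fit = TriadCausalModel(g, me, e).fit(method=method)
        rows.append({
            "snp_id": t.snp_id,
            "cpg_id": t.cpg_id,
            "gene_id": t.gene_id,
            "arcs": ";".join(f"{a}->{b}" for a, b in sorted(fit.dag)),
            "model": fit.model,
            "model_class": fit.model_class,
            "score": fit.score,
        })
    calls = pd.DataFrame(rows)
    freq = model_frequency_table(calls["model"] if len(calls) else [])
    return calls, freq


def model_frequency_table(labels) -> pd.DataFrame:
    """Count and percentage per causal-model label.

    Accepts a sequence of labels or a mapping/Series label -> count.
    Percentages are over the total, rounded to one decimal place.
    """
    if isinstance(labels, dict):
        counts = pd.Series(labels, dtype=int)
    elif isinstance(labels, pd.Series) and labels.dtype != object:
        counts = labels.astype(int)
    else:
        counts = pd.Series(list(labels), dtype=object).value_counts()
    order = ["GMeE_GE", "GE_GMe", "GMeE", "GEMe", "GEMe_GMe", "OTHER"]
    counts = counts.reindex([m for m in order if m in counts.index] +
                            [m for m in counts.index if m not in order]).dropna().astype(int)
    total = int(counts.sum())
    freq = pd.DataFrame({
        "model": counts.index,
        "count": counts.to_numpy(),
        "percent": np.round(100.0 * counts.to_numpy() / total, 1) if total else 0.0,
    })
    return freq.reset_index(drop=True)
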