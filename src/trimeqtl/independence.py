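"""Collapse correlated cis features into blocks of independent signals.

Nearby SNPs (through linkage disequilibrium) and nearby CpGs (through
co-methylation) are highly correlated, so counting raw significant
associations overstates the number of independent signals.  Features are
grouped into blocks: edges connect features on the same chromosome within
the cis window whose squared Pearson correlation exceeds the threshold
(default r^2 > 0.3), and blocks are the connected components of that graph.
Each (source block, target block) pair of a scan collapses to one
independent QTL, represented by its minimum-p association.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["Block", "correlation_blocks", "block_map", "collapse_to_independent"]


@dataclass
class Block:
    """A set of mutually reachable correlated features of one kind."""

    block_id: str
    kind: str
    chrom: object
    members: list
    span: tuple

    def __len__(self):
        return len(self.members)


def correlation_blocks(
    ids,
    values: pd.DataFrame,
    positions: pd.DataFrame,
    r2_threshold: float = 0.3,
    window_bp: int = 1_000_000,
    kind: str = "feature",
) -> list[Block]:
    """Partition ``ids`` into connected components of the r^2 graph.

    Parameters
    ----------
    ids : sequence
        Feature ids to block; each must be a column of ``values`` and a row
        of ``positions`` (a feature table with ``id, chrom, pos``).
    values : pd.DataFrame
        Samples x features matrix on which Pearson correlation is computed
        (dosages for SNPs, M-values for CpGs).
    r2_threshold : float
        Edge rule is strict: squared correlation > threshold.
    window_bp : int
        Edges also require |pos_i - pos_j| <= window_bp and equal chromosome.

    Zero-variance features get no edges (correlation undefined) and end up as
    singleton blocks, with a warning.
    """
    ids = list(dict.fromkeys(ids))  # dedupe, keep order
    if not ids:
        return []
    feat = positions.set_index("id")
    missing = [i for i in ids if i not in feat.index or i not in values.columns]
    if missing:
        raise KeyError(f"features absent from matrix or position table: {missing[:5]}")
    chroms = feat.loc[ids, "chrom"].to_numpy()
    pos = feat.loc[ids, "pos"].to_numpy(dtype=np.int64)

    graph = nx.Graph()
    graph.add_nodes_from(ids)
    for chrom in pd.unique(chroms):
        sel = np.flatnonzero(chroms == chrom)
        if len(sel) < 2:
            continue
        sub_ids = [ids[i] for i in sel]
        sub_pos = pos[sel]
        X = values[sub_ids].to_numpy(dtype=float)
        sd = X.std(axis=0)
        degenerate = sd == 0
        if degenerate.any():
            logger.warning(
                "correlation_blocks: %d zero-variance feature(s) become singletons",
                int(degenerate.sum()),
            )
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.corrcoef(X, rowvar=False)
        r2 = corr ** 2
        r2[~np.isfinite(r2)] = 0.0
        close = np.abs(sub_pos[:, None] - sub_pos[None, :]) <= window_bp
        adj = (r2 > r2_threshold) & close
        np.fill_diagonal(adj, False)
        ii, jj = np.nonzero(np.triu(adj))
        graph.add_edges_from((sub_ids[i], sub_ids[j]) for i, j in zip(ii, jj))

    pos_of = dict(zip(ids, pos))
    chrom_of = dict(zip(ids, chroms))
    components = [sorted(c, key=lambda i: (pos_of[i], str(i))) for c in nx.connected_components(graph)]
    components.sort(key=lambda c: (str(chrom_of[c[0]]), pos_of[c[0]], str(c[0])))
    blocks = []
    for i, members in enumerate(components):
        p = [pos_of[m] for m in members]
        blocks.append(
            Block(
                block_id=f"{kind}_block_{i:05d}",
                kind=kind,
                chrom=chrom_of[members[0]],
                members=members,
                span=(int(min(p)), int(max(p))),
            )
        )
    return blocks


def block_map(blocks: list[Block]) -> dict:
    """Mapping feature id -> block id."""
    out = {}
    for b in blocks:
        for m in b.members:
            out[m] = b.block_id
    return out


def collapse_to_independent(
    associations: pd.DataFrame,
    source_blocks: list[Block],
    target_blocks: list[Block] | None = None,
) -> pd.DataFrame:
    """One representative association per distinct (source block, target block).

    ``associations`` is a significant-association table (columns as produced
    by the scan).  When ``target_blocks`` is None the raw target id is the
    target "block" (eQTL/eQTM case where genes are not blocked).  The
    representative is the member with minimum p; ties break on smaller
    absolute distance, then lexicographic (source_id, target_id).

    Raises ``KeyError`` if an association references a feature missing from
    the blocks.
    """
    smap = block_map(source_blocks)
    tmap = block_map(target_blocks) if target_blocks is not None else None
    df = associations.copy()
    try:
        df["source_block"] = df["source_id"].map(lambda i: smap[i])
        if tmap is not None:
            df["target_block"] = df["target_id"].map(lambda i: tmap[i])
        else:
            df["target_block"] = df["target_id"]
    except KeyError as exc:
        raise KeyError(f"association references feature absent from blocks: {exc}") from exc
    if df.empty:
        return df
    df["_absdist"] = df["distance"].abs()
    df = df.sort_values(
        ["p_value", "_absdist", "source_id", "target_id"], kind="stable"
    )
    reps = df.groupby(["source_block", "target_block"], sort=True).head(1)
    reps = reps.drop(columns=["_absdist"]).sort_values(
        ["chrom", "target_pos", "source_pos"], kind="stable"
    ).reset_index(drop=True)
    return reps
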