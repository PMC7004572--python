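"""Bootstrap orchestration, rank combination, and network output.

Per-gene regression produces a non-negative edge-score matrix per bootstrap
resample (and per task).  Scores are converted to ranks (average rank on
ties, highest score = highest rank), summed across bootstraps within a task
and then across tasks, and min-max normalized into a combined confidence in
[0, 1] — making the combination invariant to any strictly monotone transform
of an input.  The global ranked list is cut at the longest prefix whose
precision against a prior/gold standard stays at or above a target (0.5 by
default), measured over the standard's gene x TF universe.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .priors import PriorMatrix


@dataclass
class EdgeScores:
    """Per-(bootstrap, task) regression output: scores >= 0 and signed betas."""

    scores: pd.DataFrame  # genes x TFs, non-negative
    betas: pd.DataFrame  # genes x TFs, signed coefficients

    def __post_init__(self) -> None:
        v = self.scores.to_numpy()
        if v.size and (not np.all(np.isfinite(v)) or np.any(v < 0)):
            raise ValueError("edge scores must be finite and non-negative")


@dataclass
class RankedNetwork:
    """Ordered TF->gene edges with combined confidences and annotations."""

    edges: pd.DataFrame  # regulator, target, combined_confidence, sign, in_prior, task_*

    def __post_init__(self) -> None:
        if self.edges.duplicated(subset=["regulator", "target"]).any():
            raise ValueError("duplicate (regulator, target) pairs")

    def __len__(self) -> int:
        return len(self.edges)

    @property
    def task_columns(self) -> list[str]:
        return [c for c in self.edges.columns if c.startswith("task_")]


def bootstrap_indices(n: int, n_boot: int, seed: int) -> list[np.ndarray]:
    """Resample ``n`` sample indices with replacement, ``n_boot`` times."""
    if n < 1:
        raise ValueError("need at least one sample")
    out = []
    for b in range(n_boot):
        rng = np.random.default_rng([int(seed) % 2**31, b])
        out.append(rng.integers(0, n, size=n))
    return out


def combine_ranks(scores: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Rank-combine score matrices into confidences in [0, 1]."""
    if not scores:
        raise ValueError("no score matrices given")
    first = scores[0]
    total = np.zeros(first.size)
    for m in scores:
        if not (m.index.equals(first.index) and m.columns.equals(first.columns)):
            raise ValueError("score matrices have mismatched axes")
        total += rankdata(m.to_numpy().ravel())
    span = total.max() - total.min()
    if span == 0:
        conf = np.full_like(total, 0.5)
    else:
        conf = (total - total.min()) / span
    return pd.DataFrame(conf.reshape(first.shape), index=first.index, columns=first.columns)


def combine_tasks(per_task_confidences: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Rank-combine task-level confidence matrices into a global matrix."""
    return combine_ranks(per_task_confidences)


def build_ranked_network(
    confidence: pd.DataFrame,
    signs: pd.DataFrame,
    prior: PriorMatrix | None = None,
    task_presence: Mapping[str, pd.DataFrame] | None = None,
    keep_mask: pd.DataFrame | None = None,
) -> RankedNetwork:
    """Flatten a confidence matrix into an ordered edge list.

    Edges whose score was zero in every underlying fit (``keep_mask`` False)
    are treated as absent.  Ordering is by confidence descending, ties broken
    by (tf_id, gene_id) lexicographically.
    """
    genes, tfs = confidence.index, confidence.columns
    rows = {
        "regulator": np.repeat(np.asarray(tfs, dtype=object), len(genes)),
        "target": np.tile(np.asarray(genes, dtype=object), len(tfs)),
        "combined_confidence": confidence.to_numpy().T.ravel(),
        "sign": signs.reindex(index=genes, columns=tfs).fillna(0).to_numpy().T.ravel(),
    }
    if prior is not None:
        inp = (prior.data.reindex(index=genes, columns=tfs).fillna(0) != 0).to_numpy()
        rows["in_prior"] = inp.T.ravel()
    else:
        rows["in_prior"] = np.zeros(len(genes) * len(tfs), dtype=bool)
    if task_presence:
        for name, present in task_presence.items():
            rows[f"task_{name}"] = (
                present.reindex(index=genes, columns=tfs).fillna(False).to_numpy().T.ravel()
            )
    df = pd.DataFrame(rows)
    if keep_mask is not None:
        df = df[keep_mask.to_numpy().T.ravel()]
    df = df.sort_values(
        by=["combined_confidence", "regulator", "target"],
        ascending=[False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    return RankedNetwork(df)


def threshold_by_precision(
    net: RankedNetwork,
    standard: PriorMatrix,
    target_precision: float = 0.5,
) -> RankedNetwork:
    """Keep the longest ranked prefix with precision >= target.

    Precision is measured over the standard's gene x TF universe only (as
    determined by recovery of the standard's interactions); edges outside
    that universe are retained when ranked above the cutoff.
    """
    edges = net.edges
    gene_set = set(standard.gene_ids)
    tf_set = set(standard.tf_ids)
    in_universe = edges["target"].isin(gene_set) & edges["regulator"].isin(tf_set)
    if not in_universe.any():
        raise ValueError("no ranked edge lies in the standard's universe")
    gi, ti = np.nonzero(standard.values != 0.0)
    positives = {(standard.tf_ids[t], standard.gene_ids[g]) for g, t in zip(gi, ti)}
    uni = edges[in_universe]
    hits = np.fromiter(
        ((r, t) in positives for r, t in zip(uni["regulator"], uni["target"])),
        dtype=bool,
        count=len(uni),
    )
    precision = np.cumsum(hits) / np.arange(1, len(uni) + 1)
    ok = np.nonzero(precision >= target_precision)[0]
    if ok.size == 0:
        return RankedNetwork(edges.iloc[0:0].copy())
    cutoff_pos = uni.index[ok[-1]]  # position in the full ranked list
    return RankedNetwork(edges.loc[:cutoff_pos].reset_index(drop=True))


def write_network(net: RankedNetwork, path: str | Path, fmt: str = "tsv") -> None:
    path = Path(path)
    if fmt == "tsv":
        net.edges.to_csv(path, sep="\t", index=False)
    elif fmt == "gexf":
        g = nx.DiGraph()
        for row in net.edges.itertuples(index=False):
            g.add_edge(
                str(row.regulator),
                str(row.target),
                combined_confidence=float(row.combined_confidence),
                sign=int(row.sign),
                in_prior=bool(row.in_prior),
            )
        nx.write_gexf(g, path)
    else:
        raise ValueError(f"unknown network format {fmt!r}")


def read_network(path: str | Path) -> RankedNetwork:
    df = pd.read_csv(path, sep="\t")
    if df.empty and "regulator" not in df.columns:
        raise ValueError(f"{path} lacks a network header")
    for col in ("in_prior",):
        if col in df.columns:
            df[col] = df[col].astype(bool)
    for col in df.columns:
        if col.startswith("task_"):
            df[col] = df[col].astype(bool)
    return RankedNetwork(df)


def mean_sign(betas: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Sign of the mean coefficient across bootstraps/tasks."""
    if not betas:
        raise ValueError("no coefficient matrices")
    stack = sum(b.to_numpy() for b in betas) / len(betas)
    return pd.DataFrame(
        np.sign(stack), index=betas[0].index, columns=betas[0].columns
    )
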