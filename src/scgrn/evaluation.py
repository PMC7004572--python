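"""Precision-recall benchmarking, cross-validation, and negative controls.

Networks are scored by recovery of a held-out gold standard: the ranked edge
list is restricted to the standard's gene x TF universe, edges that were
available as priors during fitting are excluded from both the list and the
positive set, and precision/recall are accumulated down the list.  AUPR is
the average-precision summation (precision at each positive-recovering rank,
divided by total positives), whose expectation under a uniformly random
ranking of the full universe is the universe's positive fraction.

The cross-validation harness repeats the paper-style protocol: split the
gold standard's genes in half, fit with one half as priors, score recovery
of the other half.  Negative controls rerun the identical pipeline with
shuffled priors (random classifier baseline) and with null-sampled counts in
which only sampling noise remains (circular recovery baseline).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .amusr import run_amusr
from .assembly import (
    RankedNetwork,
    build_ranked_network,
    combine_ranks,
    combine_tasks,
    mean_sign,
    threshold_by_precision,
)
from .bbsr import run_bbsr_task
from .config import InferenceConfig
from .matrices import (
    CellMetadata,
    CountMatrix,
    ExpressionMatrix,
    Task,
    TaskSet,
    filter_zero_variance,
    log_transform,
    split_tasks,
)
from .priors import GoldStandard, PriorMatrix, cv_split_gold_standard, shuffle_prior
from .synthetic import null_count_sampler
from .tfa import estimate_tfa


@dataclass
class PRCurve:
    """Cumulative precision/recall down a ranked edge list."""

    precision: np.ndarray
    recall: np.ndarray
    hits: np.ndarray  # bool per rank
    n_positives: int


def precision_recall(
    net: RankedNetwork,
    gs: GoldStandard,
    exclude: PriorMatrix | None = None,
) -> PRCurve:
    """Score a ranked network against a gold standard.

    Evaluation is restricted to the standard's gene x TF universe; edges
    present in ``exclude`` (the fitting priors) are removed from the ranked
    list and from the positive set.
    """
    gene_set, tf_set = set(gs.gene_ids), set(gs.tf_ids)
    gi, ti = np.nonzero(gs.values != 0.0)
    positives = {(gs.tf_ids[t], gs.gene_ids[g]) for g, t in zip(gi, ti)}
    excluded = set()
    if exclude is not None:
        gi, ti = np.nonzero(exclude.values != 0.0)
        excluded = {(exclude.tf_ids[t], exclude.gene_ids[g]) for g, t in zip(gi, ti)}
    positives -= excluded
    if not positives:
        raise ValueError("no positives remain after exclusion")
    edges = net.edges
    keep = edges["target"].isin(gene_set) & edges["regulator"].isin(tf_set)
    pairs = list(zip(edges.loc[keep, "regulator"], edges.loc[keep, "target"]))
    pairs = [pr for pr in pairs if pr not in excluded]
    hits = np.fromiter((pr in positives for pr in pairs), dtype=bool, count=len(pairs))
    ranks = np.arange(1, len(pairs) + 1)
    cum = np.cumsum(hits)
    precision = cum / ranks if len(pairs) else np.empty(0)
    recall = cum / len(positives) if len(pairs) else np.empty(0)
    return PRCurve(precision, recall, hits, len(positives))


def aupr(pr: PRCurve) -> float:
    """Average precision over the ranked list, in [0, 1]."""
    if pr.n_positives < 1:
        raise ValueError("PR curve has no positives")
    if pr.hits.size == 0:
        return 0.0
    return float(pr.precision[pr.hits].sum() / pr.n_positives)


def edge_count_summaries(
    net: RankedNetwork,
    standard: PriorMatrix,
    precision_cutoff: float = 0.5,
    confidence_cutoff: float = 0.95,
) -> tuple[int, int]:
    """(edges kept at the precision cutoff, edges above the confidence cutoff)."""
    n_conf = int((net.edges["combined_confidence"] > confidence_cutoff).sum())
    if len(net) == 0:
        return 0, 0
    try:
        kept = threshold_by_precision(net, standard, precision_cutoff)
    except ValueError:
        return 0, n_conf
    return len(kept), n_conf


def infer_network(
    x: ExpressionMatrix,
    meta: CellMetadata | None,
    prior: PriorMatrix,
    config: InferenceConfig,
    seed: int,
    cells_per_task: int | None = None,
) -> RankedNetwork:
    """Run the full inference pipeline on preprocessed expression.

    TF activities are estimated once from the prior (per-cell solves are
    independent, so estimating before task splitting is equivalent), tasks
    are fit by the configured method over bootstraps, and confidences are
    rank combined within and then across tasks.
    """
    activities = estimate_tfa(x, prior)
    if config.method == "bbsr":
        tasks = TaskSet([Task("all", x)])
    elif config.method in ("bbsr-by-task", "amusr"):
        if meta is None:
            raise ValueError(f"method {config.method!r} needs per-cell conditions")
        tasks = split_tasks(x, meta)
    else:
        raise ValueError(f"unknown method {config.method!r}")
    if cells_per_task is not None:
        sub = []
        for ti, task in enumerate(tasks):
            rng = np.random.default_rng([int(seed) % 2**31, 0xD5, ti])
            n = min(cells_per_task, task.n_cells)
            cells = np.asarray(task.expression.cell_ids)[
                np.sort(rng.choice(task.n_cells, size=n, replace=False))
            ]
            sub.append(
                type(task)(task.name, ExpressionMatrix(task.expression.data.loc[cells]))
            )
        tasks = TaskSet(sub)
    if config.method == "amusr":
        per_task = run_amusr(tasks, activities, prior, config, seed)
    else:
        per_task = {}
        for ti, task in enumerate(tasks):
            per_task[task.name] = run_bbsr_task(
                task.expression,
                activities,
                prior,
                config,
                (int(seed) * 1000003 + ti) % 2**31,
            )
    task_confs, all_scores, all_betas, presence = [], [], [], {}
    for name in tasks.names:
        boots = per_task[name]
        task_confs.append(combine_ranks([es.scores for es in boots]))
        all_scores.extend(es.scores for es in boots)
        all_betas.extend(es.betas for es in boots)
        any_nz = sum((es.scores > 0).astype(int) for es in boots) > 0
        presence[name] = any_nz
    global_conf = combine_tasks(task_confs)
    signs = mean_sign(all_betas)
    keep = sum((s > 0).astype(int) for s in all_scores) > 0
    return build_ranked_network(global_conf, signs, prior, presence, keep)


def _preprocess(counts: CountMatrix) -> ExpressionMatrix:
    return log_transform(filter_zero_variance(counts))


def _cv_repeat(
    x: ExpressionMatrix,
    meta: CellMetadata | None,
    gs: GoldStandard,
    p: PriorMatrix,
    config: InferenceConfig,
    seed: int,
    shuffle: bool = False,
    cells_per_task: int | None = None,
) -> dict:
    prior_part, eval_part = cv_split_gold_standard(gs, p, fraction=0.5, seed=seed)
    if shuffle:
        prior_part = shuffle_prior(prior_part, seed)
    net = infer_network(x, meta, prior_part, config, seed, cells_per_task)
    pr = precision_recall(net, eval_part, exclude=prior_part)
    n_prec, n_conf = edge_count_summaries(net, eval_part)
    return {
        "aupr": aupr(pr),
        "n_precision_edges": n_prec,
        "n_confidence_edges": n_conf,
    }


def crossvalidate(
    counts: CountMatrix,
    meta: CellMetadata | None,
    gs: GoldStandard,
    p: PriorMatrix,
    config: InferenceConfig,
    n_repeats: int = 10,
    seed: int = 0,
    shuffle_priors: bool = False,
    cells_per_task: int | None = None,
) -> pd.DataFrame:
    """Repeated half-split cross-validation; one row of metrics per repeat."""
    x = _preprocess(counts)
    rows = []
    for r in range(n_repeats):
        rep_seed = (int(seed) * 7919 + r) % 2**31
        res = _cv_repeat(
            x, meta, gs, p, config, rep_seed, shuffle_priors, cells_per_task
        )
        res["repeat"] = r
        rows.append(res)
    df = pd.DataFrame(rows).set_index("repeat")
    return df


def negative_controls(
    counts: CountMatrix,
    meta: CellMetadata | None,
    gs: GoldStandard,
    p: PriorMatrix,
    config: InferenceConfig,
    n_repeats: int = 10,
    seed: int = 0,
) -> dict[str, pd.DataFrame]:
    """Shuffled-prior and null-sampled-count control runs of the CV harness.

    The null control keeps metadata and each cell's UMI total, redrawing only
    the individual gene counts from the dataset-wide gene frequency
    distribution.
    """
    shuffled = crossvalidate(
        counts, meta, gs, p, config, n_repeats, seed, shuffle_priors=True
    )
    totals = counts.values.sum(axis=1)
    gene_tot = counts.values.sum(axis=0).astype(float)
    probs = gene_tot / gene_tot.sum()
    null_counts = null_count_sampler(
        probs, totals, seed, gene_ids=counts.gene_ids, cell_ids=counts.cell_ids
    )
    simulated = crossvalidate(null_counts, meta, gs, p, config, n_repeats, seed)
    return {"shuffled": shuffled, "simulated": simulated}
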