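"""Single-task best-subset regression (BBSR).

Each gene's expression is modeled as a linear combination of the activities
of a small regulator set: candidates are the ten TFs with the highest CLR
score plus any a-priori known regulator, then ordinary least squares is fit
to every subset of the candidates and the subset with the lowest BIC,
``n*ln(RSS/n) + q*ln(n)``, is selected.  Data are centered per fit; no
intercept.  A Zellner g-prior hook exists but no predictor bias is applied
by default.  The edge score for a chosen regulator is the fraction of
residual variance it explains: the relative increase in RSS when it is
dropped from the chosen model (refit by OLS), clamped to [0, 1].
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd

from .assembly import EdgeScores, bootstrap_indices
from .clr import clr_matrix, mutual_information_matrix
from .config import InferenceConfig
from .matrices import ExpressionMatrix
from .priors import PriorMatrix
from .tfa import ActivityMatrix


@dataclass
class GeneModel:
    """Chosen regulators and coefficients for one gene."""

    gene_id: str
    regulators: list[str]
    coefficients: pd.Series  # over regulators
    explained_variance: pd.Series  # over regulators, in [0, 1]
    bic: float
    r_squared: float = 0.0


@lru_cache(maxsize=64)
def _subsets_by_size(k: int) -> tuple[np.ndarray, ...]:
    """All index subsets of range(k), grouped by size, lexicographic within."""
    return tuple(
        np.array(list(itertools.combinations(range(k), q)), dtype=np.int64).reshape(
            -1, max(q, 0)
        )
        if q > 0
        else np.zeros((1, 0), dtype=np.int64)
        for q in range(k + 1)
    )


def _ols_rss(G: np.ndarray, c: np.ndarray, yy: float, idx: np.ndarray) -> float:
    """RSS of OLS restricted to predictor indices ``idx`` (centered data)."""
    if idx.size == 0:
        return yy
    Gs = G[np.ix_(idx, idx)]
    ridge = 1e-10 * np.trace(Gs) / idx.size
    coef = np.linalg.solve(Gs + ridge * np.eye(idx.size), c[idx])
    rss = yy - 2 * coef @ c[idx] + coef @ Gs @ coef
    return max(float(rss), 0.0)


def best_subset_regression(
    y: np.ndarray,
    a: np.ndarray,
    tf_ids: list[str],
    gene_id: str = "",
    config: InferenceConfig | None = None,
) -> GeneModel:
    """Exhaustive subset OLS over candidate regulators, scored by BIC.

    ``y`` is the response over samples, ``a`` the samples x candidates
    activity matrix (columns ordered as ``tf_ids``).  All 2^k subsets are
    enumerated (size ascending, lexicographic within size); ties in BIC keep
    the earliest subset, i.e. the smaller then lexicographically first one.
    """
    config = config or InferenceConfig()
    y = np.asarray(y, dtype=float)
    a = np.asarray(a, dtype=float)
    n, k = a.shape
    if n < 2:
        raise ValueError("need at least 2 samples")
    if k != len(tf_ids):
        raise ValueError("tf_ids must match predictor columns")
    if k > config.enumeration_cap:
        raise ValueError(
            f"{k} candidates exceed the enumeration cap "
            f"({config.enumeration_cap}); reduce candidates upstream"
        )
    yc = y - y.mean()
    ac = a - a.mean(axis=0)
    yy = float(yc @ yc)
    empty = GeneModel(gene_id, [], pd.Series(dtype=float), pd.Series(dtype=float), np.nan)
    if yy == 0.0 or k == 0:
        with np.errstate(divide="ignore"):
            empty.bic = float(n * np.log(yy / n)) if yy > 0 else -np.inf
        return empty
    G = ac.T @ ac
    c = ac.T @ yc
    ridge = 1e-10 * float(np.trace(G)) / max(k, 1)
    log_n = np.log(n)
    groups = _subsets_by_size(k)
    best_bic = np.inf
    best_idx = np.empty(0, dtype=np.int64)
    best_rss = yy
    for q, subs in enumerate(groups):
        if q == 0:
            rss = np.array([yy])
        else:
            Gs = G[subs[:, :, None], subs[:, None, :]]
            cs = c[subs]
            eye = ridge * np.eye(q)
            coef = np.linalg.solve(Gs + eye, cs[..., None])[..., 0]
            rss = yy - 2 * np.einsum("cq,cq->c", coef, cs) + np.einsum(
                "cq,cqr,cr->c", coef, Gs, coef
            )
            rss = np.maximum(rss, 0.0)
        with np.errstate(divide="ignore"):
            bic = n * np.log(rss / n) + q * log_n
        j = int(np.argmin(bic))
        if bic[j] < best_bic:
            best_bic = float(bic[j])
            best_idx = groups[q][j]
            best_rss = float(rss[j])
    if best_idx.size == 0:
        empty.bic = best_bic
        return empty
    idx = best_idx
    Gs = G[np.ix_(idx, idx)]
    coef = np.linalg.solve(Gs + ridge * np.eye(idx.size), c[idx])
    r2 = max(0.0, 1.0 - best_rss / yy)
    ev = np.zeros(idx.size)
    for pos in range(idx.size):
        reduced = np.delete(idx, pos)
        rss_wo = _ols_rss(G, c, yy, reduced)
        if rss_wo > 0:
            ev[pos] = np.clip(1.0 - best_rss / rss_wo, 0.0, 1.0)
    regs = [tf_ids[i] for i in idx]
    return GeneModel(
        gene_id,
        regs,
        pd.Series(coef, index=regs),
        pd.Series(ev, index=regs),
        best_bic,
        r2,
    )


def select_regulators(
    z_row: pd.Series,
    prior_row: pd.Series | None = None,
    k: int = 10,
    cap: int = 14,
    exclude: str | None = None,
) -> list[str]:
    """Candidate regulators: top-k TFs by CLR plus prior regulators.

    Ties in CLR break by TF id; the gene's own TF (``exclude``) is never a
    candidate; if the union exceeds ``cap``, priors are kept and the rest
    filled by CLR rank.  Returned sorted by TF id (the enumeration order).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    order = sorted(z_row.index, key=lambda t: (-float(z_row[t]), t))
    order = [t for t in order if t != exclude]
    top = order[:k]
    prior_tfs = []
    if prior_row is not None:
        prior_tfs = [t for t in order if t in prior_row.index and prior_row[t] != 0]
    chosen = list(dict.fromkeys(top + prior_tfs))
    if len(chosen) > cap:
        kept = list(dict.fromkeys(prior_tfs))[:cap]
        for t in order:
            if len(kept) >= cap:
                break
            if t not in kept:
                kept.append(t)
        chosen = kept[:cap]
    return sorted(chosen)


def run_bbsr_task(
    expression: ExpressionMatrix,
    activities: ActivityMatrix,
    prior: PriorMatrix | None,
    config: InferenceConfig,
    seed: int,
) -> list[EdgeScores]:
    """Fit BBSR gene models on each bootstrap resample of one task.

    Returns one :class:`EdgeScores` (genes x TFs explained-variance scores
    plus signed coefficients) per bootstrap.
    """
    cells = expression.cell_ids
    act = activities.data.loc[:, cells]
    tf_ids = list(act.index)
    genes = expression.gene_ids
    X = expression.values
    A = act.to_numpy().T  # cells x TFs
    n = len(cells)
    prior_aligned = None
    if prior is not None:
        prior_aligned = prior.data.reindex(index=genes, columns=tf_ids).fillna(0.0)
    out: list[EdgeScores] = []
    for idx in bootstrap_indices(n, config.n_bootstraps, seed):
        Xb, Ab = X[idx], A[idx]
        mi = mutual_information_matrix(Ab, Xb, config.n_bins)
        z = clr_matrix(mi)
        scores = np.zeros((len(genes), len(tf_ids)))
        betas = np.zeros_like(scores)
        col = {t: j for j, t in enumerate(tf_ids)}
        for i, gene in enumerate(genes):
            z_row = pd.Series(z[:, i], index=tf_ids)
            prior_row = prior_aligned.loc[gene] if prior_aligned is not None else None
            cands = select_regulators(
                z_row,
                prior_row,
                k=config.n_top_regulators,
                cap=config.enumeration_cap,
                exclude=gene,
            )
            if not cands or Xb[:, i].var() == 0:
                continue
            model = best_subset_regression(
                Xb[:, i], Ab[:, [col[t] for t in cands]], cands, gene, config
            )
            for t in model.regulators:
                s = float(model.explained_variance[t])
                if config.score_scaled_by_model_r2:
                    s *= model.r_squared
                scores[i, col[t]] = s
                betas[i, col[t]] = float(model.coefficients[t])
        out.append(
            EdgeScores(
                pd.DataFrame(scores, index=genes, columns=tf_ids),
                pd.DataFrame(betas, index=genes, columns=tf_ids),
            )
        )
    return out
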