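"""Latent transcription-factor activity (TFA) estimation.

Expression is modeled as a linear combination of the activities of each
gene's a-priori known regulators: ``X = P A`` with X genes x cells, P the
genes x TFs prior connectivity, and A the TFs x cells activity matrix.  The
system is overdetermined, so A is approximated by the least-squares
minimizer of ``||P A - X||^2``; the minimum-norm solution is used when P is
rank-deficient (e.g. duplicated TF target profiles), which the pseudoinverse
handles without failure.  A TF with no prior targets falls back to its own
expression as a proxy for activity (zeros when the TF gene is absent).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .matrices import ExpressionMatrix, MatrixValidationError, _check_unique
from .priors import PriorMatrix


@dataclass
class ActivityMatrix:
    """TFs x cells latent activities (relative, unitless)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "TF")
        _check_unique(self.data.columns, "cell")
        if self.data.size and not np.all(np.isfinite(self.data.to_numpy())):
            raise MatrixValidationError("activities must be finite")

    @property
    def tf_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def cell_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def subset_cells(self, cells) -> "ActivityMatrix":
        return ActivityMatrix(self.data.loc[:, cells].copy())

    def write_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index_label="tf_id")


def estimate_tfa(x: ExpressionMatrix, p: PriorMatrix) -> ActivityMatrix:
    """Estimate TF activities from expression and prior connectivity.

    Genes are aligned by identifier (intersection, in prior order); TFs with
    at least one prior target over the shared genes enter the least-squares
    solve, the rest use their own expression row.
    """
    shared = [g for g in p.gene_ids if g in set(x.gene_ids)]
    if not shared:
        raise MatrixValidationError("no genes shared between expression and prior")
    P = p.data.loc[shared].to_numpy()  # genes x TFs
    X = x.data[shared].to_numpy().T  # genes x cells
    tf_ids = p.tf_ids
    has_targets = (P != 0).any(axis=0)
    A = np.zeros((len(tf_ids), X.shape[1]))
    if has_targets.any():
        sol, *_ = np.linalg.lstsq(P[:, has_targets], X, rcond=None)
        A[has_targets] = sol
    gene_pos = {g: i for i, g in enumerate(x.gene_ids)}
    xv = x.values
    for j, tf in enumerate(tf_ids):
        if not has_targets[j] and tf in gene_pos:
            A[j] = xv[:, gene_pos[tf]]
    return ActivityMatrix(pd.DataFrame(A, index=tf_ids, columns=x.cell_ids))
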