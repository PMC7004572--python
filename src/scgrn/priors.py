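"""Prior and gold-standard connectivity matrices, CV splitting, shuffling.

A prior matrix records known or putative TF->gene interactions (genes in
rows, TFs in columns).  Signs carry activation (+) / repression (-); zero
means no known interaction.  Gold standards are restricted to {-1, 0, +1}.
Cross-validation splits the gold standard *by gene*: half of its genes are
retained as priors for fitting, the held-out half becomes the evaluation
standard, and the held-out genes' rows are removed from the fitting prior to
prevent circular recovery.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .matrices import MatrixValidationError, _check_unique


@dataclass
class PriorMatrix:
    """Genes x TFs signed connectivity."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "gene")
        _check_unique(self.data.columns, "TF")
        values = self.data.to_numpy(dtype=float)
        if values.size and not np.all(np.isfinite(values)):
            raise MatrixValidationError("prior entries must be finite")
        self.data = self.data.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def tf_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_interactions(self) -> int:
        return int((self.data.to_numpy() != 0).sum())

    def binarized(self, threshold: float = 0.0) -> "PriorMatrix":
        """Signed connectivity with |value| > threshold mapped to +/-1.

        Real-valued affinity priors are reduced to connectivity this way
        before latent-activity estimation.
        """
        v = self.data.to_numpy()
        out = np.sign(v) * (np.abs(v) > threshold)
        return PriorMatrix(pd.DataFrame(out, index=self.data.index, columns=self.data.columns))

    def write_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index_label="gene_id")


@dataclass
class GoldStandard(PriorMatrix):
    """Prior matrix whose entries are exactly {-1, 0, +1}."""

    def __post_init__(self) -> None:
        super().__post_init__()
        values = self.data.to_numpy()
        if values.size and not np.isin(values, (-1.0, 0.0, 1.0)).all():
            bad = values[~np.isin(values, (-1.0, 0.0, 1.0))]
            raise MatrixValidationError(
                f"gold standard entries must be in {{-1,0,1}}; found {bad[:3]}"
            )


def read_network_matrix(path: str | Path, gold_standard: bool = False) -> PriorMatrix:
    """Read a genes x TFs adjacency TSV (first column gene ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    cls = GoldStandard if gold_standard else PriorMatrix
    return cls(df)


def shuffle_prior(p: PriorMatrix, seed: int) -> PriorMatrix:
    """Negative control: randomly reassign gene names in the prior.

    Rows (target-gene profiles) are permuted uniformly while the gene labels
    stay in place; TF labels and values are untouched, so per-TF column sums
    and the global edge count are preserved exactly.
    """
    if len(p.data) < 2:
        raise ValueError("need at least 2 genes to shuffle")
    rng = np.random.default_rng([int(seed) % 2**31, 0x5F])
    perm = rng.permutation(len(p.data))
    shuffled = pd.DataFrame(
        p.data.to_numpy()[perm], index=p.data.index, columns=p.data.columns
    )
    return type(p)(shuffled)


def cv_split_gold_standard(
    gs: GoldStandard,
    p: PriorMatrix,
    fraction: float = 0.5,
    seed: int = 0,
) -> tuple[PriorMatrix, GoldStandard]:
    """Split gold-standard genes into a fitting prior and an evaluation half.

    ``fraction`` of the gold standard's genes (ceil, default half) are
    retained; the rest are held out.  The returned prior is ``p`` with every
    held-out gene's row removed, and the returned evaluation standard is
    ``gs`` restricted to the held-out genes.  The two gene sets are disjoint.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must be in (0, 1)")
    genes = np.asarray(gs.gene_ids)
    if genes.size == 0:
        raise ValueError("gold standard is empty")
    rng = np.random.default_rng([int(seed) % 2**31, 0xC5])
    perm = rng.permutation(genes.size)
    n_keep = int(np.ceil(genes.size * fraction))
    retained = set(genes[perm[:n_keep]])
    held_out = [g for g in gs.gene_ids if g not in retained]
    eval_part = GoldStandard(gs.data.loc[held_out].copy())
    keep_rows = [g for g in p.gene_ids if g not in set(held_out)]
    prior_part = PriorMatrix(p.data.loc[keep_rows].copy())
    return prior_part, eval_part
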