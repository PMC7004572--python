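"""Genotype assignment from transcribed strain barcodes and doublet handling.

Pooled strains carry unique transcriptional barcodes; droplets containing two
cells ("doublets") are detected when UMIs support more than one strain
barcode.  With ``n`` equally abundant barcoded strains, two independently
drawn cells carry the same barcode with probability ``1/n``, so the expected
removal rate is ``(n - 1)/n`` — 71/72 (about 98.6%) for a 72-strain pool.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

DOUBLET = "DOUBLET"
UNASSIGNED = "UNASSIGNED"


@dataclass
class BarcodeTable:
    """Per-cell UMI support for each strain barcode (cells x barcodes)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        values = self.data.to_numpy()
        if values.size and np.any(values < 0):
            raise ValueError("barcode UMI counts must be non-negative")

    @classmethod
    def from_long(cls, df: pd.DataFrame) -> "BarcodeTable":
        """Build from long-form records (cell_id, replicate_barcode, umi_count)."""
        wide = df.pivot_table(
            index="cell_id",
            columns="replicate_barcode",
            values="umi_count",
            aggfunc="sum",
            fill_value=0,
        )
        return cls(wide)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "BarcodeTable":
        return cls.from_long(pd.read_csv(path, sep="\t"))


def assign_genotypes(
    table: BarcodeTable,
    strain_map: Mapping[str, str],
    min_umi: int = 1,
) -> pd.Series:
    """Label each cell with its strain's genotype, DOUBLET, or UNASSIGNED.

    A cell with >= ``min_umi`` UMIs supporting exactly one barcode receives
    that barcode's genotype; support for two or more barcodes flags a doublet
    (to be excluded downstream); no supported barcode leaves the cell
    unassigned.
    """
    if min_umi < 1:
        raise ValueError("min_umi must be >= 1")
    unknown = [b for b in table.data.columns if b not in strain_map]
    if unknown:
        raise KeyError(f"barcode(s) not in strain table: {unknown[:5]}")
    counts = table.data.to_numpy()
    supported = counts >= min_umi
    n_supported = supported.sum(axis=1)
    barcodes = np.asarray(table.data.columns)
    labels = np.full(len(table.data), UNASSIGNED, dtype=object)
    single = n_supported == 1
    if single.any():
        best = supported[single].argmax(axis=1)
        labels[single] = [strain_map[barcodes[j]] for j in best]
    labels[n_supported >= 2] = DOUBLET
    return pd.Series(labels, index=table.data.index, name="genotype")


def expected_doublet_removal(n_barcodes: int) -> float:
    """Probability two uniform independent barcode draws differ: (n-1)/n."""
    if n_barcodes < 1:
        raise ValueError("n_barcodes must be >= 1")
    return (n_barcodes - 1) / n_barcodes


def simulate_doublets(n_barcodes: int, n_droplets: int, seed: int) -> float:
    """Fraction of simulated two-cell droplets flagged as doublets.

    Each droplet receives two cells whose barcodes are drawn independently
    and uniformly from the strain pool; the droplet's pooled barcode counts
    are passed through :func:`assign_genotypes`.
    """
    if n_droplets < 1:
        raise ValueError("n_droplets must be >= 1")
    rng = np.random.default_rng([int(seed) % 2**31, 0x0DB])
    a = rng.integers(0, n_barcodes, size=n_droplets)
    b = rng.integers(0, n_barcodes, size=n_droplets)
    counts = np.zeros((n_droplets, n_barcodes), dtype=np.int64)
    rows = np.arange(n_droplets)
    np.add.at(counts, (rows, a), 1)
    np.add.at(counts, (rows, b), 1)
    barcodes = [f"bc{j:03d}" for j in range(n_barcodes)]
    table = BarcodeTable(
        pd.DataFrame(counts, index=[f"drop{i}" for i in range(n_droplets)], columns=barcodes)
    )
    strain_map = {bc: f"strain_{bc}" for bc in barcodes}
    labels = assign_genotypes(table, strain_map, min_umi=1)
    return float((labels == DOUBLET).mean())
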