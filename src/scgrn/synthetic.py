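"""Synthetic benchmarks for the inference pipeline.

Two generators are provided.  The *null* sampler reproduces the
sampling-noise negative control: per-cell totals are kept and gene counts
are redrawn multinomially from a fixed transcriptome-wide probability
distribution, so any structure recovered from it is circular.  The
*positive-control* benchmark emulates a pooled multi-condition experiment: a
sparse signed TF->gene truth network drives condition-specific latent TF
activities, latent log2 expression is a linear function of those activities
plus gene base levels and Gaussian noise, and observed UMI counts are
multinomial downsamples of the per-cell rate vector at sequencing depths
drawn log-normally around condition-specific medians (anchored at a
rich-media median of 2250 UMIs per cell).

The defaults define the study conditions used throughout the test suite:
200 genes, 20 TFs with ~14 targets each (the curated yeast gold standard's
out-degree), 3 conditions x 300 cells.  TF genes are latent (not part of
the measured gene panel); cell-cycle structure, doublet transcript mixing
and genotype effects are not simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrices import CellMetadata, CountMatrix
from .priors import GoldStandard, PriorMatrix, cv_split_gold_standard


@dataclass
class SyntheticTruth:
    """Ground truth for the positive-control benchmark."""

    network: pd.DataFrame  # genes x TFs signed weights
    activity_means: pd.DataFrame  # conditions x TFs
    base_rates: np.ndarray  # probability simplex over genes
    depth_medians: np.ndarray  # per-condition median UMI totals
    depth_sigma: float
    seed: int

    @property
    def gene_ids(self) -> list[str]:
        return list(self.network.index)

    @property
    def tf_ids(self) -> list[str]:
        return list(self.network.columns)

    def gold_standard(self) -> GoldStandard:
        return GoldStandard(np.sign(self.network))


@dataclass
class BenchmarkConfig:
    n_genes: int = 200
    n_tfs: int = 20
    n_conditions: int = 3
    cells_per_condition: int = 300
    targets_per_tf: int = 14
    activator_fraction: float = 0.75
    weight_lo: float = 0.5
    weight_hi: float = 2.0
    activity_between_sd: float = 1.0  # spread of condition mean activities
    activity_within_sd: float = 0.5  # cell-to-cell activity fluctuation
    noise_sd: float = 0.25  # latent log2 expression noise
    depth_median: float = 2250.0  # rich-media median UMIs per cell
    depth_sigma: float = 0.35  # lognormal sigma of per-cell depth
    condition_depth_sigma: float = 0.3  # lognormal spread of condition medians
    base_rate_sigma: float = 1.5  # lognormal sigma of gene base rates
    prior_fraction: float = 0.5  # truth genes retained as priors


@dataclass
class BenchmarkBundle:
    counts: CountMatrix
    metadata: CellMetadata
    prior_part: PriorMatrix
    eval_part: GoldStandard
    truth: SyntheticTruth


def null_count_sampler(
    gene_probs: np.ndarray,
    per_cell_totals: np.ndarray,
    seed: int,
    gene_ids: list[str] | None = None,
    cell_ids: list[str] | None = None,
) -> CountMatrix:
    """Redraw gene counts multinomially, preserving each cell's UMI total."""
    probs = np.asarray(gene_probs, dtype=float)
    totals = np.asarray(per_cell_totals)
    if np.any(probs < 0):
        raise ValueError("gene probabilities must be non-negative")
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("gene probabilities must sum to 1")
    if np.any(totals < 0):
        raise ValueError("per-cell totals must be >= 0")
    rng = np.random.default_rng([int(seed) % 2**31, 0x4E])
    counts = rng.multinomial(totals.astype(np.int64), probs)
    gene_ids = gene_ids or [f"G{j:04d}" for j in range(len(probs))]
    cell_ids = cell_ids or [f"cell{i:05d}" for i in range(len(totals))]
    return CountMatrix(pd.DataFrame(counts, index=cell_ids, columns=gene_ids))


def generate_truth(
    n_genes: int,
    n_tfs: int,
    targets_per_tf: int,
    activator_fraction: float,
    seed: int,
    n_conditions: int = 3,
    config: BenchmarkConfig | None = None,
) -> SyntheticTruth:
    """Draw a sparse signed truth network and its condition activity profiles."""
    if targets_per_tf < 1:
        raise ValueError("targets_per_tf must be >= 1")
    if not 0.0 <= activator_fraction <= 1.0:
        raise ValueError("activator_fraction must lie in [0, 1]")
    cfg = config or BenchmarkConfig()
    rng = np.random.default_rng([int(seed) % 2**31, 0x7A])
    gene_ids = [f"G{j:04d}" for j in range(n_genes)]
    tf_ids = [f"TF{k:03d}" for k in range(n_tfs)]
    net = np.zeros((n_genes, n_tfs))
    for k in range(n_tfs):
        targets = rng.choice(n_genes, size=min(targets_per_tf, n_genes), replace=False)
        mags = rng.uniform(cfg.weight_lo, cfg.weight_hi, size=len(targets))
        signs = np.where(rng.random(len(targets)) < activator_fraction, 1.0, -1.0)
        net[targets, k] = mags * signs
    means = rng.normal(0.0, cfg.activity_between_sd, size=(n_conditions, n_tfs))
    base = rng.lognormal(0.0, cfg.base_rate_sigma, size=n_genes)
    base_rates = base / base.sum()
    depth_medians = cfg.depth_median * rng.lognormal(
        0.0, cfg.condition_depth_sigma, size=n_conditions
    )
    return SyntheticTruth(
        pd.DataFrame(net, index=gene_ids, columns=tf_ids),
        pd.DataFrame(
            means,
            index=[f"cond{c}" for c in range(n_conditions)],
            columns=tf_ids,
        ),
        base_rates,
        depth_medians,
        cfg.depth_sigma,
        int(seed),
    )


def simulate_expression(
    truth: SyntheticTruth,
    n_conditions: int,
    cells_per_condition: int,
    noise_sd: float,
    seed: int,
    config: BenchmarkConfig | None = None,
) -> tuple[CountMatrix, CellMetadata]:
    """Simulate UMI counts from the truth network.

    Per cell: TF activity = condition mean + within-condition fluctuation;
    latent log2 expression = network @ activity + base level + noise; rates
    are the per-cell-normalized 2^latent, downsampled multinomially to a
    depth drawn log-normally around the condition's median.
    """
    cfg = config or BenchmarkConfig()
    if n_conditions > len(truth.activity_means):
        raise ValueError("truth has fewer condition profiles than requested")
    rng = np.random.default_rng([int(seed) % 2**31, 0x51])
    W = truth.network.to_numpy()
    n_genes = W.shape[0]
    base_log2 = np.log2(truth.base_rates * n_genes + 1e-12)
    rows, cells, conds = [], [], []
    for ci in range(n_conditions):
        mu = truth.activity_means.iloc[ci].to_numpy()
        act = mu[None, :] + rng.normal(
            0.0, cfg.activity_within_sd, size=(cells_per_condition, len(mu))
        )
        latent = (
            base_log2[None, :]
            + act @ W.T
            + rng.normal(0.0, noise_sd, size=(cells_per_condition, n_genes))
        )
        rates = np.exp2(latent)
        rates /= rates.sum(axis=1, keepdims=True)
        depths = np.maximum(
            rng.lognormal(np.log(truth.depth_medians[ci]), truth.depth_sigma,
                          size=cells_per_condition).astype(np.int64),
            1,
        )
        rows.append(rng.multinomial(depths, rates))
        cells.extend(f"cond{ci}_cell{i:05d}" for i in range(cells_per_condition))
        conds.extend([f"cond{ci}"] * cells_per_condition)
    counts = pd.DataFrame(np.vstack(rows), index=cells, columns=truth.gene_ids)
    meta = CellMetadata(pd.DataFrame({"condition": conds}, index=cells))
    return CountMatrix(counts), meta


def make_benchmark(config: BenchmarkConfig | None = None, seed: int = 0) -> BenchmarkBundle:
    """Compose truth, CV split of the truth, and simulated counts."""
    cfg = config or BenchmarkConfig()
    truth = generate_truth(
        cfg.n_genes,
        cfg.n_tfs,
        cfg.targets_per_tf,
        cfg.activator_fraction,
        seed,
        n_conditions=cfg.n_conditions,
        config=cfg,
    )
    gs = truth.gold_standard()
    prior_part, eval_part = cv_split_gold_standard(
        gs, gs, fraction=cfg.prior_fraction, seed=seed
    )
    counts, meta = simulate_expression(
        truth, cfg.n_conditions, cfg.cells_per_condition, cfg.noise_sd, seed, cfg
    )
    return BenchmarkBundle(counts, meta, prior_part, eval_part, truth)
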