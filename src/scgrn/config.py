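"""Shared inference configuration."""

from __future__ import annotations

from dataclasses import dataclass


@dataclass
class InferenceConfig:
    """Knobs shared by the single-task and multitask regression stages.

    method: "bbsr" (all cells as one task), "bbsr-by-task" (one BBSR fit per
        condition, then rank combination), or "amusr" (joint multitask fit).
    n_bootstraps: resamples of the cell axis per task; confidences are rank
        combined across them.
    n_top_regulators: CLR preselection keeps this many TFs per gene, plus any
        prior regulator.
    n_bins: equal-width bins per variable for the MI estimator.
    enumeration_cap: largest candidate set enumerated exhaustively by best
        subset regression (2^cap fits per gene at the cap).
    score_scaled_by_model_r2: multiply per-regulator explained variance by
        the chosen model's total R^2 when scoring edges.
    ebic_gamma: extended-BIC dimensional penalty weight for AMuSR.
    lambda_b_formula: "sqrt" for c_b*sqrt(d*ln(p)/n), "linear_d" for
        c_b*d*sqrt(ln(p)/n).
    g_prior_weight: Zellner g-prior hook; None (default) applies no bias to
        predictor choice.
    """

    method: str = "amusr"
    n_bootstraps: int = 20
    n_top_regulators: int = 10
    n_bins: int = 10
    enumeration_cap: int = 14
    score_scaled_by_model_r2: bool = False
    ebic_gamma: float = 1.0
    lambda_b_formula: str = "sqrt"
    g_prior_weight: float | None = None
    amusr_tol: float = 1e-2
    amusr_max_iter: int = 1000
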