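"""Precision/recall/F-score and Jaccard metrics, plus the replicate benchmark.

The benchmark harness crosses simulated replicates with experimental
conditions (no-batch / batch / each corrector applied to the batch-affected
matrix) and feature-selection methods, emitting one tidy metrics row per
cell — the long table behind the usual condition-by-method boxplots.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .correction import combat, linear_scale, quantile_normalize
from .datamodel import ComplexSet, ExpressionMatrix, SampleMetadata
from .pseudocomplexes import make_pseudocomplex_set
from .selection import (
    RbnaConfig,
    SelectionResult,
    he_select,
    proteins_from_complexes,
    rbna_select,
    sp_select,
)
from .simulator import SimulationConfig, simulate_dataset

__all__ = [
    "EvalMetrics",
    "precision_recall_f",
    "jaccard",
    "complex_level_eval",
    "BenchmarkConfig",
    "run_benchmark",
]


@dataclass
class EvalMetrics:
    """Precision, recall and F-score over a feature set vs. its truth.

    With zero selected features precision is reported as 1.0 (there are no
    false positives) with ``n_selected=0`` flagging the degenerate case;
    recall and F are then 0.
    """

    precision: float
    recall: float
    f_score: float
    n_selected: int
    n_truth: int
    level: str = "protein"

    def rounded(self, digits: int = 2) -> tuple[float, float, float]:
        return (
            round(self.precision, digits),
            round(self.recall, digits),
            round(self.f_score, digits),
        )


def precision_recall_f(
    selected: set[str], truth: set[str], level: str = "protein"
) -> EvalMetrics:
    if not truth:
        raise ValueError("empty truth set")
    tp = len(set(selected) & truth)
    precision = tp / len(selected) if selected else 1.0
    recall = tp / len(truth)
    f = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
    return EvalMetrics(precision, recall, f, len(selected), len(truth), level)


def jaccard(a: set[str], b: set[str]) -> float:
    union = set(a) | set(b)
    if not union:
        raise ValueError("both sets empty")
    return len(set(a) & set(b)) / len(union)


def complex_level_eval(sel: SelectionResult, complexes: ComplexSet) -> EvalMetrics:
    """Score a complex-level selection against TP/TN pseudo-complex labels."""
    if sel.level != "complex":
        raise ValueError("expected a complex-level selection result")
    labels = {c.complex_id: c.truth_label for c in complexes}
    unlabelled = [f for f in sel.selected if labels.get(f, "unknown") == "unknown"]
    if unlabelled:
        raise ValueError(f"selected complexes without truth labels: {unlabelled[:3]}")
    truth = {c.complex_id for c in complexes if c.truth_label == "TP"}
    return precision_recall_f(sel.selected, truth, level="complex")


@dataclass
class BenchmarkConfig:
    replicates: int = 20
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    methods: tuple[str, ...] = ("sp", "sp_fdr", "he", "snet", "fsnet")
    conditions: tuple[str, ...] = ("no_batch", "batch", "combat", "quantile", "linear")
    purities: tuple[float, ...] = (1.0,)
    n_pseudocomplexes: int = 101
    rbna: RbnaConfig = field(default_factory=RbnaConfig)
    seed: int = 0


_CORRECTORS = {
    "combat": lambda x, meta: combat(x, meta),
    "quantile": lambda x, meta: quantile_normalize(x),
    "linear": lambda x, meta: linear_scale(x),
}


def _condition_matrix(
    condition: str, clean: ExpressionMatrix, noisy: ExpressionMatrix, meta: SampleMetadata
) -> ExpressionMatrix:
    if condition == "no_batch":
        return clean
    if condition == "batch":
        return noisy
    try:
        return _CORRECTORS[condition](noisy, meta)
    except KeyError:
        raise ValueError(f"unknown condition {condition!r}") from None


def _evaluate_method(
    method: str,
    x: ExpressionMatrix,
    meta: SampleMetadata,
    complexes: ComplexSet,
    truth_proteins: set[str],
    rbna: RbnaConfig,
    rng: np.random.Generator,
) -> list[dict]:
    """One method on one matrix: protein-level row, plus complex-level row
    for complex-based methods."""
    rows = []
    if method in ("sp", "sp_fdr"):
        sel = sp_select(x, meta, fdr=0.05 if method == "sp_fdr" else None)
        m = precision_recall_f(sel.selected, truth_proteins)
        rows.append(dict(method=method, level="protein", metrics=m))
        return rows
    if method == "he":
        # post-hoc enrichment of the raw-p t-test set; with ~2-member
        # pseudo-complexes a BH-corrected hypergeometric has no power, so
        # selection is at raw alpha, mirroring the uncorrected t-test row
        sp_raw = sp_select(x, meta, fdr=None)
        sel = he_select(sp_raw.selected, complexes, set(x.protein_ids), fdr=False)
    elif method in ("snet", "fsnet"):
        sel = rbna_select(x, meta, complexes, rbna, fuzzy=(method == "fsnet"), seed=rng)
    else:
        raise ValueError(f"unknown method {method!r}")
    mc = complex_level_eval(sel, complexes)
    rows.append(dict(method=method, level="complex", metrics=mc))
    prot = proteins_from_complexes(sel, complexes)
    mp = precision_recall_f(prot, truth_proteins)
    rows.append(dict(method=method, level="protein", metrics=mp))
    return rows


def run_benchmark(config: BenchmarkConfig) -> pd.DataFrame:
    """Replicate x condition x method x purity benchmark.

    Returns a long-format DataFrame with one row per (replicate, condition,
    method, purity, level) carrying precision/recall/F. Deterministic given
    ``config.seed``: replicate datasets, pseudo-complex draws and permutation
    nulls all derive from it.
    """
    master = np.random.SeedSequence(config.seed)
    rep_seeds = master.spawn(config.replicates)
    rows = []
    for rep in range(config.replicates):
        rep_ss = rep_seeds[rep]
        sim_seed = int(rep_ss.generate_state(1)[0] % (2**31))
        sim_config = SimulationConfig(
            **{**config.simulation.__dict__, "seed": sim_seed}
        )
        ds = simulate_dataset(sim_config)
        truth_proteins = ds.truth.differential_proteins
        pc_rng, method_rng = (np.random.default_rng(s) for s in rep_ss.spawn(2))
        needs_complexes = any(m not in ("sp", "sp_fdr") for m in config.methods)
        for purity in config.purities:
            complexes = (
                make_pseudocomplex_set(
                    ds.clean, ds.truth, config.n_pseudocomplexes, purity, pc_rng
                )
                if needs_complexes
                else ComplexSet([])
            )
            for condition in config.conditions:
                x = _condition_matrix(condition, ds.clean, ds.noisy, ds.meta)
                for method in config.methods:
                    for r in _evaluate_method(
                        method, x, ds.meta, complexes, truth_proteins,
                        config.rbna, method_rng,
                    ):
                        m: EvalMetrics = r["metrics"]
                        rows.append(
                            dict(
                                replicate=rep,
                                condition=condition,
                                method=r["method"],
                                purity=purity,
                                level=r["level"],
                                precision=m.precision,
                                recall=m.recall,
                                f_score=m.f_score,
                                n_selected=m.n_selected,
                                n_truth=m.n_truth,
                            )
                        )
    return pd.DataFrame(rows)
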