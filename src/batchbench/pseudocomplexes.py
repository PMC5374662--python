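"""Pseudo-complex generation for complex-level benchmarking.

Real complex catalogues carry no ground truth for simulated data, so
labelled pseudo-complexes are built from the spike-in itself: the known
differential proteins are clustered by expression similarity (Euclidean
distance, Ward linkage), reordered by dendrogram leaf order so co-expressed
proteins sit next to each other, and the ordered list is split into 101
contiguous true-positive complexes. An equal number of non-differential
proteins, reordered by expression correlation, yields the matched
true-negative complexes.

Purity — the fraction of genuinely differential members per TP complex — is
lowered by randomly swapping members out for non-differential proteins,
mimicking the realistic situation where only part of a complex responds.
"""

from __future__ import annotations

import numpy as np
import scipy.cluster.hierarchy
import scipy.spatial.distance

from .datamodel import ComplexSet, ExpressionMatrix, GroundTruth, ProteinComplex

__all__ = [
    "make_tp_pseudocomplexes",
    "make_tn_pseudocomplexes",
    "adjust_purity",
    "make_pseudocomplex_set",
]


def _leaf_order(values: np.ndarray, metric: str) -> np.ndarray:
    """Ward dendrogram leaf order for rows of ``values``.

    metric "euclidean" or "correlation" (1 - Pearson). Standard left-to-right
    leaf order; no optimal-leaf-ordering refinement, so the result is
    deterministic.
    """
    if metric == "euclidean":
        d = scipy.spatial.distance.pdist(values, metric="euclidean")
    elif metric == "correlation":
        d = scipy.spatial.distance.pdist(values, metric="correlation")
        d = np.nan_to_num(d, nan=1.0)  # zero-variance rows have no correlation
    else:
        raise ValueError(f"unknown metric {metric!r}")
    z = scipy.cluster.hierarchy.linkage(d, method="ward")
    return scipy.cluster.hierarchy.leaves_list(z)


def _split_blocks(ordered: list[str], n: int) -> list[list[str]]:
    """Split into n contiguous blocks of near-equal size, larger blocks first."""
    size, remainder = divmod(len(ordered), n)
    blocks = []
    start = 0
    for i in range(n):
        width = size + (1 if i < remainder else 0)
        blocks.append(ordered[start : start + width])
        start += width
    return blocks


def make_tp_pseudocomplexes(
    x: ExpressionMatrix, truth: GroundTruth, n: int = 101
) -> ComplexSet:
    """Cluster the differential proteins and split into n TP complexes."""
    diff = sorted(truth.differential_proteins)
    if len(diff) < 2 * n:
        raise ValueError(
            f"{len(diff)} differential proteins cannot fill {n} complexes of >= 2; "
            "use a smaller n"
        )
    truth.validate_against(x)
    sub = x.subset_proteins(diff)
    order = _leaf_order(sub.values, "euclidean")
    ordered = [diff[i] for i in order]
    complexes = [
        ProteinComplex(f"TP{i + 1:03d}", f"tp_pseudocomplex_{i + 1}", block, "TP")
        for i, block in enumerate(_split_blocks(ordered, n))
    ]
    return ComplexSet(complexes)


def make_tn_pseudocomplexes(
    x: ExpressionMatrix,
    truth: GroundTruth,
    n: int = 101,
    seed: int | np.random.Generator = 0,
) -> ComplexSet:
    """Sample non-differential proteins and split into n TN complexes.

    The TN protein count matches the TP count (all differential proteins);
    reordering uses 1 - Pearson correlation distance.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n_needed = len(truth.differential_proteins)
    pool = sorted(set(x.protein_ids) - truth.differential_proteins)
    if len(pool) < n_needed:
        raise ValueError(
            f"only {len(pool)} non-differential proteins for {n_needed} TN slots"
        )
    chosen = sorted(rng.choice(len(pool), size=n_needed, replace=False))
    picked = [pool[i] for i in chosen]
    sub = x.subset_proteins(picked)
    order = _leaf_order(sub.values, "correlation")
    ordered = [picked[i] for i in order]
    complexes = [
        ProteinComplex(f"TN{i + 1:03d}", f"tn_pseudocomplex_{i + 1}", block, "TN")
        for i, block in enumerate(_split_blocks(ordered, n))
    ]
    return ComplexSet(complexes)


def adjust_purity(
    tp: ComplexSet,
    truth: GroundTruth,
    nontruth_pool: set[str],
    purity: float,
    seed: int | np.random.Generator = 0,
) -> ComplexSet:
    """Replace round((1 - purity) x size) members per TP complex with
    non-differential proteins.

    Replacements are drawn without replacement from ``nontruth_pool`` across
    the whole set, so complexes stay mutually disjoint. Complex count and
    sizes are preserved exactly.
    """
    if not 0 < purity <= 1:
        raise ValueError("purity must be in (0, 1]")
    if purity == 1.0:
        return ComplexSet([ProteinComplex(c.complex_id, c.name, list(c.members), c.truth_label) for c in tp])
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    pool = sorted(set(nontruth_pool) - truth.differential_proteins)
    total_needed = sum(round((1 - purity) * len(c.members)) for c in tp)
    if total_needed > len(pool):
        raise ValueError(
            f"purity {purity} needs {total_needed} replacement proteins, pool has {len(pool)}"
        )
    replacements = [pool[i] for i in rng.choice(len(pool), size=total_needed, replace=False)]
    out = []
    cursor = 0
    for c in tp:
        n_replace = round((1 - purity) * len(c.members))
        members = list(c.members)
        replace_at = rng.choice(len(members), size=n_replace, replace=False)
        for k, pos in enumerate(sorted(replace_at)):
            members[pos] = replacements[cursor + k]
        cursor += n_replace
        out.append(ProteinComplex(c.complex_id, c.name, members, c.truth_label))
    return ComplexSet(out)


def make_pseudocomplex_set(
    x: ExpressionMatrix,
    truth: GroundTruth,
    n: int = 101,
    purity: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> ComplexSet:
    """TP (at the requested purity) + TN complexes as one labelled set."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    tp = make_tp_pseudocomplexes(x, truth, n)
    tn = make_tn_pseudocomplexes(x, truth, n, rng)
    if purity < 1.0:
        pool = set(x.protein_ids) - truth.differential_proteins - tn.member_union()
        tp = adjust_purity(tp, truth, pool, purity, rng)
    return ComplexSet(list(tp) + list(tn))
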