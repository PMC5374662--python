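"""Feature selection: single-protein t-test, hypergeometric enrichment, and
rank-based network algorithms (SNET / FSNET).

The two rank-based network algorithms score protein complexes from
within-sample protein ranks rather than raw abundances:

1. per sample, proteins are ranked by descending abundance and converted to a
   membership score — binary top-``alpha_top`` membership for SNET, a fuzzy
   ramp (1 down to 0 between ``alpha_top`` and ``alpha_lo``) for FSNET;
2. the class weight ``w_C(g)`` of protein g is its mean membership score over
   the samples of class C — the (fuzzy) fraction of class-C samples where g
   is highly ranked;
3. a complex S is scored for sample s against class C by summing
   ``score(g, s) * w_C(g)`` over members with ``w_C(g) >= beta``;
4. each complex's test statistic contrasts, between the two sample classes,
   the per-sample difference of its D-referenced and D*-referenced scores;
   significance comes from a class-label permutation null.

Because step 1 depends only on within-sample ranks, every downstream quantity
is invariant under strictly monotone per-sample transforms — the mechanism of
batch-effect resistance when a batch distortion preserves within-sample
ordering.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.special
import scipy.stats

from .datamodel import ComplexSet, ExpressionMatrix, SampleMetadata

__all__ = [
    "RbnaConfig",
    "SelectionResult",
    "benjamini_hochberg",
    "sp_select",
    "he_select",
    "rank_scores",
    "rbna_select",
    "proteins_from_complexes",
]


@dataclass
class RbnaConfig:
    """Knobs of the rank-based network algorithms.

    alpha_top — percentile defining "highly ranked" (SNET cutoff; FSNET
    full-membership cutoff); alpha_lo — percentile where FSNET membership
    reaches 0; beta — minimum class weight for a member to contribute to a
    complex score; n_permutations / alpha_sig — permutation-null size and
    significance level.
    """

    alpha_top: float = 0.10
    alpha_lo: float = 0.20
    beta: float = 0.5
    n_permutations: int = 1000
    alpha_sig: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.alpha_top <= self.alpha_lo < 1:
            raise ValueError("need 0 < alpha_top <= alpha_lo < 1")
        if not 0 <= self.beta <= 1:
            raise ValueError("beta must be in [0, 1]")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be positive")


@dataclass
class SelectionResult:
    """Ranked features with statistics and selection flags.

    ``level`` is "protein" or "complex"; ``table`` has columns feature,
    statistic, p_value, p_adjusted (NaN when no multiple-testing correction
    was applied), selected. For complex-level RBNA results ``score_matrix``
    holds the per-sample class-referenced complex scores.
    """

    level: str
    table: pd.DataFrame
    score_matrix: pd.DataFrame | None = None

    @property
    def selected(self) -> set[str]:
        return set(self.table.loc[self.table["selected"], "feature"])


def benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, p[i] * m / rank)
        adjusted[i] = running_min
    return adjusted


def sp_select(
    x: ExpressionMatrix,
    meta: SampleMetadata,
    fdr: float | None = 0.05,
    equal_var: bool = True,
) -> SelectionResult:
    """Single-protein two-sample t-test between the two classes.

    The classical pooled-variance Student's t by default (``equal_var=False``
    switches to Welch); at the usual 4-per-class design the pooled test is
    both the textbook choice and correctly calibrated on over-dispersed
    counts, where Welch is noticeably conservative. With ``fdr`` set,
    selection is BH-adjusted p <= fdr; with ``fdr=None``, raw p <= 0.05.
    Proteins with zero variance in both classes get p = 1.
    """
    meta.validate_against(x)
    cls = meta.class_vector(x.sample_ids)
    classes = sorted(set(cls))
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {classes}")
    a = x.values[:, cls == classes[0]]
    b = x.values[:, cls == classes[1]]
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("need >= 2 samples per class")
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = scipy.stats.ttest_ind(a, b, axis=1, equal_var=equal_var)
    degenerate = np.isnan(p)
    t = np.nan_to_num(t, nan=0.0)
    p = np.where(degenerate, 1.0, p)
    if fdr is not None:
        p_adj = benjamini_hochberg(p)
        selected = p_adj <= fdr
    else:
        p_adj = np.full_like(p, np.nan)
        selected = p <= 0.05
    table = pd.DataFrame(
        dict(feature=x.protein_ids, statistic=t, p_value=p, p_adjusted=p_adj, selected=selected)
    ).sort_values("p_value", kind="stable", ignore_index=True)
    return SelectionResult("protein", table)


def he_select(
    diff_proteins: set[str],
    complexes: ComplexSet,
    background: set[str],
    alpha_sig: float = 0.05,
    fdr: bool = True,
) -> SelectionResult:
    """Hypergeometric over-representation of differential proteins in complexes.

    Upper-tail test of the overlap between ``diff_proteins`` and each
    complex's members (both intersected with ``background``), BH-adjusted by
    default.
    """
    if not background:
        raise ValueError("empty background")
    if not set(diff_proteins) <= set(background):
        raise ValueError("diff_proteins must be a subset of background")
    n_bg = len(background)
    n_diff = len(diff_proteins)
    rows = []
    for c in complexes:
        members = set(c.members) & background
        k = len(members & diff_proteins)
        n_mem = len(members)
        if n_mem == 0:
            p = 1.0
        else:
            # P(overlap >= k) drawing n_mem from n_bg with n_diff successes
            p = float(scipy.stats.hypergeom.sf(k - 1, n_bg, n_diff, n_mem))
        rows.append(dict(feature=c.complex_id, statistic=float(k), p_value=min(p, 1.0)))
    table = pd.DataFrame(rows)
    if fdr:
        table["p_adjusted"] = benjamini_hochberg(table["p_value"].to_numpy())
        table["selected"] = table["p_adjusted"] <= alpha_sig
    else:
        table["p_adjusted"] = np.nan
        table["selected"] = table["p_value"] <= alpha_sig
    table = table.sort_values("p_value", kind="stable", ignore_index=True)
    return SelectionResult("complex", table)


def rank_scores(
    x: ExpressionMatrix,
    config: RbnaConfig = RbnaConfig(),
    fuzzy: bool = False,
) -> np.ndarray:
    """Per-sample rank-percentile membership scores in [0, 1].

    Within each sample, proteins are ranked by descending abundance;
    percentile = rank / n, with ties sharing the mean percentile of their
    run. SNET (``fuzzy=False``): 1 if percentile <= alpha_top else 0. FSNET
    (``fuzzy=True``): 1 below alpha_top, 0 above alpha_lo, linear ramp in
    between. Returns a proteins x samples array.
    """
    n = x.n_proteins
    # descending ranks: highest abundance gets rank 1
    ranks = scipy.stats.rankdata(-x.values, axis=0, method="average")
    pct = ranks / n
    if not fuzzy:
        return (pct <= config.alpha_top).astype(float)
    scores = (config.alpha_lo - pct) / (config.alpha_lo - config.alpha_top)
    return np.clip(scores, 0.0, 1.0)


def _class_permutations(
    cls: np.ndarray, n_permutations: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Class-label permutations: exhaustive when few, sampled otherwise."""
    classes = sorted(set(cls))
    idx_a = [i for i, c in enumerate(cls) if c == classes[0]]
    n, n_a = len(cls), len(idx_a)
    n_exhaustive = scipy.special.comb(n, n_a, exact=True)
    if n_exhaustive <= n_permutations:
        perms = []
        for combo in combinations(range(n), n_a):
            lab = np.array([classes[0] if i in combo else classes[1] for i in range(n)])
            perms.append(lab)
        return perms
    out = []
    for _ in range(n_permutations):
        out.append(rng.permutation(cls))
    return out


def _complex_stat(
    scores: np.ndarray,
    membership: np.ndarray,
    cls: np.ndarray,
    classes: list[str],
    beta: float,
) -> np.ndarray:
    """Per-complex t-statistic on the paired class-referenced score difference.

    scores: proteins x samples membership scores; membership: complexes x
    proteins indicator. For each complex, score(s | C) sums member scores
    weighted by the class weight w_C, restricted to members with w_C >= beta;
    the statistic is the Welch t between classes of the per-sample difference
    score(s | D) - score(s | D*).
    """
    in_a = cls == classes[0]
    in_b = ~in_a
    w_a = scores[:, in_a].mean(axis=1)
    w_b = scores[:, in_b].mean(axis=1)
    u_a = np.where(w_a >= beta, w_a, 0.0)
    u_b = np.where(w_b >= beta, w_b, 0.0)
    s_vs_a = membership @ (u_a[:, None] * scores)  # complexes x samples
    s_vs_b = membership @ (u_b[:, None] * scores)
    d = s_vs_a - s_vs_b
    da, db = d[:, in_a], d[:, in_b]
    na, nb = da.shape[1], db.shape[1]
    ma, mb = da.mean(axis=1), db.mean(axis=1)
    va, vb = da.var(axis=1, ddof=1), db.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / np.sqrt(va / na + vb / nb)
    return np.nan_to_num(t, nan=0.0, posinf=0.0, neginf=0.0)


def rbna_select(
    x: ExpressionMatrix,
    meta: SampleMetadata,
    complexes: ComplexSet,
    config: RbnaConfig = RbnaConfig(),
    fuzzy: bool = False,
    seed: int | np.random.Generator = 0,
) -> SelectionResult:
    """SNET (``fuzzy=False``) / FSNET (``fuzzy=True``) complex selection.

    Permutation p-values use (1 + #{|T_perm| >= |T_obs|}) / (1 + n_perm);
    when the number of distinct class splits is small the null is enumerated
    exhaustively instead of sampled. A complex with no contributing member in
    either class gets statistic 0 and p = 1.
    """
    meta.validate_against(x)
    if len(complexes) == 0:
        raise ValueError("empty complex set")
    cls = meta.class_vector(x.sample_ids)
    classes = sorted(set(cls))
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {classes}")
    for c in classes:
        if (cls == c).sum() < 2:
            raise ValueError(f"class {c!r} has fewer than 2 samples")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    scores = rank_scores(x, config, fuzzy=fuzzy)
    pindex = {pid: i for i, pid in enumerate(x.protein_ids)}
    membership = np.zeros((len(complexes), x.n_proteins))
    for ci, c in enumerate(complexes):
        for m in c.members:
            if m in pindex:
                membership[ci, pindex[m]] = 1.0

    t_obs = _complex_stat(scores, membership, cls, classes, config.beta)
    perms = _class_permutations(cls, config.n_permutations, rng)
    exhaustive = len(perms) < config.n_permutations
    exceed = np.zeros(len(complexes))
    for lab in perms:
        t_perm = _complex_stat(scores, membership, lab, classes, config.beta)
        exceed += np.abs(t_perm) >= np.abs(t_obs) - 1e-12
    if exhaustive:
        # the identity permutation is part of the enumerated null
        p = exceed / len(perms)
    else:
        p = (1.0 + exceed) / (1.0 + len(perms))
    p = np.minimum(p, 1.0)
    p = np.where(t_obs == 0.0, 1.0, p)

    in_a = cls == classes[0]
    w_a = scores[:, in_a].mean(axis=1)
    w_b = scores[:, ~in_a].mean(axis=1)
    u_a = np.where(w_a >= config.beta, w_a, 0.0)
    u_b = np.where(w_b >= config.beta, w_b, 0.0)
    score_rows = {}
    for ref, u in ((classes[0], u_a), (classes[1], u_b)):
        m = membership @ (u[:, None] * scores)
        for ci, c in enumerate(complexes):
            score_rows[(c.complex_id, ref)] = m[ci]
    score_matrix = pd.DataFrame.from_dict(score_rows, orient="index", columns=x.sample_ids)
    score_matrix.index = pd.MultiIndex.from_tuples(score_matrix.index, names=["complex", "ref_class"])

    table = pd.DataFrame(
        dict(
            feature=complexes.ids(),
            statistic=t_obs,
            p_value=p,
            p_adjusted=np.nan,
            selected=p <= config.alpha_sig,
        )
    ).sort_values("p_value", kind="stable", ignore_index=True)
    return SelectionResult("complex", table, score_matrix)


def proteins_from_complexes(sel: SelectionResult, complexes: ComplexSet) -> set[str]:
    """Union of member proteins of the selected complexes."""
    if sel.level != "complex":
        raise ValueError("expected a complex-level selection result")
    return complexes.member_union(sel.selected)
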