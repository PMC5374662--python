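"""Batch-effect correction and normalization.

Three correctors are provided:

* :func:`quantile_normalize` — forces every sample onto the common
  across-sample mean quantile distribution; a generic normalizer, not a
  batch-aware method.
* :func:`linear_scale` — rescales each sample so all sample totals equal the
  global mean total.
* :func:`combat_fit` / :func:`combat_apply` — the parametric empirical-Bayes
  location/scale batch adjustment (ComBat). Per-protein batch effects are
  estimated on standardized data and shrunk toward batch-level priors
  (normal prior on the additive effect, inverse-gamma on the scale), with
  method-of-moments hyperpriors and a fixed-point iteration.

ComBat's location/scale model is additive, so by default the count-scale
input is log2(x+1)-transformed before fitting and back-transformed after
adjustment; set ``log2=False`` to operate on the raw scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import ExpressionMatrix, SampleMetadata

__all__ = [
    "quantile_normalize",
    "linear_scale",
    "CombatFit",
    "combat_fit",
    "combat_apply",
    "combat",
]


def quantile_normalize(x: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalize samples (columns).

    After normalization every sample's sorted value vector equals the
    across-sample mean of sorted vectors; within-sample ranks are preserved
    and tied values share the mean of the quantile targets they span.
    """
    if x.n_samples < 2:
        raise ValueError("quantile normalization needs >= 2 samples")
    v = x.values
    reference = np.sort(v, axis=0).mean(axis=1)
    out = np.empty_like(v, dtype=float)
    for j in range(v.shape[1]):
        col = v[:, j]
        order = np.argsort(col, kind="stable")
        # tie runs share the mean of the quantile targets they span
        _, inv = np.unique(col, return_inverse=True)
        group_of_sorted = inv[order]
        sums = np.bincount(group_of_sorted, weights=reference)
        counts = np.bincount(group_of_sorted)
        out[:, j] = (sums / counts)[inv]
    return ExpressionMatrix(out, list(x.protein_ids), list(x.sample_ids))


def linear_scale(x: ExpressionMatrix) -> ExpressionMatrix:
    """Scale each sample so all sample totals equal the global mean total."""
    totals = x.values.sum(axis=0)
    if np.any(totals <= 0):
        j = int(np.argmax(totals <= 0))
        raise ValueError(f"sample {x.sample_ids[j]!r} has non-positive total")
    factors = totals.mean() / totals
    return ExpressionMatrix(
        x.values * factors[None, :], list(x.protein_ids), list(x.sample_ids)
    )


@dataclass
class CombatFit:
    """Fitted parametric empirical-Bayes batch model.

    Attributes are on the (possibly log2) modelling scale. ``gamma_star`` and
    ``delta_star`` are the shrunken per-batch per-protein location and scale
    adjustments (n_batches x n_proteins); ``stand_mean`` is the batch-free
    fitted mean for each cell, and ``var_pooled`` the per-protein pooled
    variance used for standardization.
    """

    batches: list[str]
    protein_ids: list[str]
    sample_ids: list[str]
    gamma_star: np.ndarray
    delta_star: np.ndarray
    stand_mean: np.ndarray  # n_proteins x n_samples
    var_pooled: np.ndarray  # n_proteins
    gamma_bar: np.ndarray  # per-batch prior mean of gamma
    tau2: np.ndarray  # per-batch prior variance of gamma
    a_prior: np.ndarray  # per-batch inverse-gamma shape for delta^2
    b_prior: np.ndarray  # per-batch inverse-gamma scale for delta^2
    log2: bool

    def __post_init__(self) -> None:
        if np.any(self.var_pooled <= 0):
            raise ValueError("pooled variance must be positive")
        if np.any(self.delta_star <= 0):
            raise ValueError("delta* must be positive")


def _design_matrix(
    meta: SampleMetadata, sample_ids: list[str], covariate: bool
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    batches = sorted(set(meta.batch_vector(sample_ids)))
    batch_design = np.column_stack(
        [
            np.array([meta.batch_of(s) == b for s in sample_ids], dtype=float)
            for b in batches
        ]
    )
    design = batch_design
    if covariate:
        classes = sorted(set(meta.class_vector(sample_ids)))
        for c in classes[1:]:  # reference-coded class factor
            design = np.column_stack(
                [design, np.array([meta.class_of(s) == c for s in sample_ids], dtype=float)]
            )
    return design, batch_design, batches


def _aprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (2 * s2 + m**2) / s2


def _bprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (m * s2 + m**3) / s2


def _postmean(g_hat, g_bar, n, d_star, t2):
    return (t2 * n * g_hat + d_star * g_bar) / (t2 * n + d_star)


def _postvar(sum2, n, a, b):
    return (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)


def _it_sol(z_batch, g_hat, d_hat, g_bar, t2, a, b, conv=1e-6, max_iter=500):
    """Fixed-point iteration for the EB posterior location/scale estimates.

    Convergence is judged on the largest elementwise relative change of the
    location and scale vectors between successive iterates.
    """
    n = np.full(g_hat.shape, z_batch.shape[1], dtype=float)
    g_old, d_old = g_hat.copy(), d_hat.copy()
    for _ in range(max_iter):
        g_new = _postmean(g_hat, g_bar, n, d_old, t2)
        sum2 = ((z_batch - g_new[:, None]) ** 2).sum(axis=1)
        d_new = _postvar(sum2, n, a, b)
        with np.errstate(divide="ignore", invalid="ignore"):
            change = max(
                np.nanmax(np.abs(g_new - g_old) / np.abs(g_old)),
                np.nanmax(np.abs(d_new - d_old) / np.abs(d_old)),
            )
        g_old, d_old = g_new, d_new
        if change < conv:
            break
    return g_old, d_old


def combat_fit(
    x: ExpressionMatrix,
    meta: SampleMetadata,
    covariate: bool = True,
    log2: bool = True,
    conv: float = 1e-6,
    max_iter: int = 500,
) -> CombatFit:
    """Fit the parametric EB batch model.

    ``covariate=True`` protects class effects by including the class label in
    the standardization model. Errors if class is perfectly confounded with
    batch (the design is then singular and batch effects are unidentifiable).
    """
    meta.validate_against(x)
    sample_ids = list(x.sample_ids)
    batches_present = sorted(set(meta.batch_vector(sample_ids)))
    if len(batches_present) < 2:
        raise ValueError("ComBat needs >= 2 batches")
    for b in batches_present:
        n_b = sum(meta.batch_of(s) == b for s in sample_ids)
        if n_b < 2:
            raise ValueError(f"batch {b!r} has {n_b} sample(s); need >= 2 per batch")
    design, batch_design, batches = _design_matrix(meta, sample_ids, covariate)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError(
            "singular design: class labels are confounded with batch labels "
            f"(batches {batches}); ComBat cannot separate the two"
        )

    v = np.log2(x.values + 1.0) if log2 else x.values.astype(float)
    n_samples = v.shape[1]
    n_batches = len(batches)
    batch_counts = batch_design.sum(axis=0)

    # per-protein OLS of the full model; batch coefficients come first
    b_hat = np.linalg.solve(design.T @ design, design.T @ v.T)  # p_design x G
    grand_mean = (batch_counts / n_samples) @ b_hat[:n_batches, :]
    resid = v - (design @ b_hat).T
    var_pooled = (resid**2).mean(axis=1)
    var_pooled = np.where(var_pooled <= 0, 1e-8, var_pooled)

    stand_mean = grand_mean[:, None] + (design[:, n_batches:] @ b_hat[n_batches:, :]).T
    z = (v - stand_mean) / np.sqrt(var_pooled)[:, None]

    gamma_hat = np.linalg.solve(
        batch_design.T @ batch_design, batch_design.T @ z.T
    )  # n_batches x G
    delta_hat = np.vstack(
        [z[:, batch_design[:, i] == 1].var(axis=1, ddof=1) for i in range(n_batches)]
    )

    gamma_bar = gamma_hat.mean(axis=1)
    tau2 = gamma_hat.var(axis=1, ddof=1)
    a_prior = np.array([_aprior(delta_hat[i]) for i in range(n_batches)])
    b_prior = np.array([_bprior(delta_hat[i]) for i in range(n_batches)])

    gamma_star = np.empty_like(gamma_hat)
    delta_star = np.empty_like(delta_hat)
    for i in range(n_batches):
        g, d = _it_sol(
            z[:, batch_design[:, i] == 1],
            gamma_hat[i],
            delta_hat[i],
            gamma_bar[i],
            tau2[i],
            a_prior[i],
            b_prior[i],
            conv=conv,
            max_iter=max_iter,
        )
        gamma_star[i], delta_star[i] = g, d

    return CombatFit(
        batches=batches,
        protein_ids=list(x.protein_ids),
        sample_ids=sample_ids,
        gamma_star=gamma_star,
        delta_star=delta_star,
        stand_mean=stand_mean,
        var_pooled=var_pooled,
        gamma_bar=gamma_bar,
        tau2=tau2,
        a_prior=a_prior,
        b_prior=b_prior,
        log2=log2,
    )


def combat_apply(
    x: ExpressionMatrix, meta: SampleMetadata, fit: CombatFit
) -> ExpressionMatrix:
    """Adjust a matrix with a fitted batch model.

    adjusted = sqrt(var_pooled) / delta* x (standardized - gamma*) + fitted
    mean, back-transformed to the input scale. On the count scale the output
    is clipped at zero (a large negative batch shift can push low counts
    below the representable range of the log transform).
    """
    if x.protein_ids != fit.protein_ids:
        raise ValueError("protein ids do not match the fitted model")
    if x.sample_ids != fit.sample_ids:
        raise ValueError("sample ids do not match the fitted model")
    v = np.log2(x.values + 1.0) if fit.log2 else x.values.astype(float)
    z = (v - fit.stand_mean) / np.sqrt(fit.var_pooled)[:, None]
    adjusted = z.copy()
    for i, b in enumerate(fit.batches):
        cols = np.array([meta.batch_of(s) == b for s in x.sample_ids])
        adjusted[:, cols] = (
            z[:, cols] - fit.gamma_star[i][:, None]
        ) / np.sqrt(fit.delta_star[i])[:, None]
    out = adjusted * np.sqrt(fit.var_pooled)[:, None] + fit.stand_mean
    if fit.log2:
        out = np.maximum(np.exp2(out) - 1.0, 0.0)
    else:
        out = np.maximum(out, 0.0)
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("non-finite adjusted values")
    return ExpressionMatrix(out, list(x.protein_ids), list(x.sample_ids))


def combat(
    x: ExpressionMatrix,
    meta: SampleMetadata,
    covariate: bool = True,
    log2: bool = True,
) -> ExpressionMatrix:
    """Fit-and-apply convenience wrapper."""
    return combat_apply(x, meta, combat_fit(x, meta, covariate=covariate, log2=log2))
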