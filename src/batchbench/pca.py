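"""PCA-based batch diagnostics, PC removal, clustering and protein traceback.

The workflow: rank proteins by across-sample variance and keep the top 20%;
run PCA with samples as observations; test each component's scores for
association with class and with batch (paired boxplot logic made explicit);
drop the batch-dominated components and use the remaining scores as features
for clustering or class prediction; and, when proteins rather than components
are wanted, trace a component back to the proteins that load strongly and
exclusively on it.

Components are numbered from 1 (PC1 = largest variance) throughout the
public API.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy
import scipy.stats

from .datamodel import ExpressionMatrix, SampleMetadata

__all__ = [
    "PCAResult",
    "PCAssociation",
    "variance_preselect",
    "run_pca",
    "pc_association",
    "remove_pcs",
    "cluster_samples",
    "predict_labels_by_coclustering",
    "traceback_proteins",
    "minus_pc1_features",
    "top_n_by_tstat",
]


@dataclass
class PCAResult:
    """SVD of the per-protein-centered matrix, samples as observations.

    ``scores`` (samples x components) and ``loadings`` (proteins x
    components, unit columns) satisfy ``scores @ loadings.T`` = centered
    data; ``variance_explained`` is the per-component fraction of total
    variance, non-increasing.
    """

    scores: np.ndarray
    loadings: np.ndarray
    variance_explained: np.ndarray
    sample_ids: list[str]
    retained_protein_ids: list[str]

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


@dataclass
class PCAssociation:
    """Per-component class and batch association, from two-group t-tests.

    ``table`` has one row per component with the test statistics and the
    dominant factor; ``long_table`` is a boxplot-ready long format
    (component, sample, score, class, batch).
    """

    table: pd.DataFrame
    long_table: pd.DataFrame

    def dominant(self, component: int) -> str:
        return str(
            self.table.loc[self.table["component"] == component, "dominant_factor"].iloc[0]
        )

    def p_class(self, component: int) -> float:
        return float(self.table.loc[self.table["component"] == component, "p_class"].iloc[0])

    def p_batch(self, component: int) -> float:
        return float(self.table.loc[self.table["component"] == component, "p_batch"].iloc[0])

    def batch_dominant_components(self, first: int = 5) -> list[int]:
        sub = self.table[self.table["component"] <= first]
        return [int(c) for c in sub.loc[sub["dominant_factor"] == "batch", "component"]]


def variance_preselect(x: ExpressionMatrix, fraction: float = 0.20) -> ExpressionMatrix:
    """Keep the ceil(fraction * n) proteins with highest across-sample variance.

    Input row order is preserved; variance ties at the cutoff are broken by
    lexicographic protein id.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    n_keep = int(np.ceil(fraction * x.n_proteins))
    variances = x.values.var(axis=1, ddof=1)
    order = sorted(
        range(x.n_proteins), key=lambda i: (-variances[i], x.protein_ids[i])
    )
    keep = sorted(order[:n_keep])
    return ExpressionMatrix(
        x.values[keep, :],
        [x.protein_ids[i] for i in keep],
        list(x.sample_ids),
    )


def run_pca(
    x: ExpressionMatrix, center: bool = True, scale: bool = False, log2: bool = True
) -> PCAResult:
    """PCA via SVD of the per-protein-centered matrix.

    Proteins are variables, samples observations. Values are log2(x+1)
    transformed by default: the spike-in effects (and most proteomics batch
    distortions) are multiplicative, hence additive — and visible as clean
    score shifts — on the log scale. No unit-variance scaling by default —
    the variance-based preselection upstream deliberately encodes magnitude.
    Loading signs are fixed so each component's largest-magnitude loading is
    positive, making results order- and platform-deterministic.
    """
    if x.n_samples < 2:
        raise ValueError("PCA needs >= 2 samples")
    data = x.values.T.astype(float)  # samples x proteins
    if log2:
        data = np.log2(data + 1.0)
    if center:
        data = data - data.mean(axis=0, keepdims=True)
    if scale:
        sd = data.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        data = data / sd
    total_var = (data**2).sum()
    if total_var <= 0:
        raise ValueError("constant matrix: no variance to decompose")
    u, s, vt = np.linalg.svd(data, full_matrices=False)
    # deterministic sign: largest |loading| per component is positive
    for k in range(vt.shape[0]):
        i = np.argmax(np.abs(vt[k]))
        if vt[k, i] < 0:
            vt[k] *= -1.0
            u[:, k] *= -1.0
    scores = u * s
    return PCAResult(
        scores=scores,
        loadings=vt.T,
        variance_explained=s**2 / total_var,
        sample_ids=list(x.sample_ids),
        retained_protein_ids=list(x.protein_ids),
    )


def _two_group_p(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Welch t (2 groups) or one-way ANOVA (>2 groups) on one PC's scores."""
    groups = [scores[labels == g] for g in np.unique(labels)]
    if len(groups) < 2:
        raise ValueError("association test needs >= 2 groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("association test needs >= 2 samples per group")
    if all(np.allclose(g, g[0]) for g in groups) and np.ptp(scores) == 0:
        return 0.0, 1.0
    if len(groups) == 2:
        stat, p = scipy.stats.ttest_ind(groups[0], groups[1], equal_var=False)
    else:
        stat, p = scipy.stats.f_oneway(*groups)
    if np.isnan(p):
        return 0.0, 1.0
    return float(stat), float(p)


def pc_association(
    p: PCAResult,
    meta: SampleMetadata,
    n_components: int | None = None,
    alpha: float = 0.01,
) -> PCAssociation:
    """Class and batch association for the first ``n_components`` components.

    dominant_factor: the factor with p < alpha while the other's p >= alpha;
    "both" when both beat alpha, "neither" otherwise.
    """
    if n_components is None:
        n_components = min(5, p.n_components)
    n_components = min(n_components, p.n_components)
    cls = meta.class_vector(p.sample_ids)
    batch = meta.batch_vector(p.sample_ids)
    rows = []
    long_rows = []
    for k in range(n_components):
        sc = p.scores[:, k]
        t_c, p_c = _two_group_p(sc, cls)
        t_b, p_b = _two_group_p(sc, batch)
        if p_c < alpha and p_b >= alpha:
            dom = "class"
        elif p_b < alpha and p_c >= alpha:
            dom = "batch"
        elif p_c < alpha and p_b < alpha:
            dom = "both"
        else:
            dom = "neither"
        rows.append(
            dict(
                component=k + 1,
                stat_class=t_c,
                p_class=p_c,
                stat_batch=t_b,
                p_batch=p_b,
                variance_explained=float(p.variance_explained[k]),
                dominant_factor=dom,
            )
        )
        for j, s in enumerate(p.sample_ids):
            long_rows.append(
                dict(component=k + 1, sample=s, score=float(sc[j]), **{"class": cls[j]}, batch=batch[j])
            )
    return PCAssociation(pd.DataFrame(rows), pd.DataFrame(long_rows))


def remove_pcs(p: PCAResult, drop: list[int]) -> pd.DataFrame:
    """Drop components (1-based) and return the remaining scores as features.

    The result is a samples x components DataFrame whose ``attrs`` record
    which components were dropped and their variance share.
    """
    for d in drop:
        if not 1 <= d <= p.n_components:
            raise ValueError(f"component {d} out of range 1..{p.n_components}")
    keep = [k for k in range(p.n_components) if (k + 1) not in set(drop)]
    if not keep:
        raise ValueError("cannot drop every component")
    df = pd.DataFrame(
        p.scores[:, keep],
        index=p.sample_ids,
        columns=[f"PC{k + 1}" for k in keep],
    )
    df.attrs["dropped"] = sorted(set(drop))
    df.attrs["dropped_variance_share"] = float(
        sum(p.variance_explained[d - 1] for d in set(drop))
    )
    return df


def batch_removed_features(p: PCAResult, assoc: PCAssociation) -> pd.DataFrame:
    """Cluster-ready PC features after boxplot-guided batch-PC removal.

    Drops every batch-dominant component (always at least PC1 when it is
    batch-dominant, falling back to PC1 if the diagnostic flags nothing) and,
    when any remaining component is class-associated ("class" or "both"),
    restricts to those: trailing components that associate with neither
    factor carry sampling noise that dilutes the class signal in a Euclidean
    clustering.
    """
    drop = assoc.batch_dominant_components() or [1]
    table = assoc.table
    classy = [
        int(c)
        for c in table.loc[table["dominant_factor"].isin(["class", "both"]), "component"]
        if int(c) not in drop
    ]
    feats = remove_pcs(p, drop)
    if classy:
        feats = feats[[f"PC{c}" for c in classy]]
        feats.attrs["dropped"] = drop
    return feats


def cluster_samples(
    features: pd.DataFrame | np.ndarray, k: int = 2, linkage: str = "ward"
) -> tuple[np.ndarray, np.ndarray]:
    """Agglomerative clustering on Euclidean distances.

    Returns (labels in 1..k, scipy linkage matrix). Deterministic given the
    input values; sample order does not affect the partition.
    """
    values = features.to_numpy() if isinstance(features, pd.DataFrame) else np.asarray(features)
    if k > values.shape[0]:
        raise ValueError(f"k={k} exceeds {values.shape[0]} samples")
    z = scipy.cluster.hierarchy.linkage(values, method=linkage)
    labels = scipy.cluster.hierarchy.fcluster(z, t=k, criterion="maxclust")
    return labels, z


def predict_labels_by_coclustering(
    known: ExpressionMatrix,
    known_meta: SampleMetadata,
    unknown: ExpressionMatrix,
    unknown_batch: str = "new",
    preselect_fraction: float = 0.20,
    drop: list[int] | str = "auto",
    k: int | None = None,
) -> dict[str, str]:
    """Predict class labels for unlabelled samples by co-clustering.

    Pools known and unknown samples, preselects by variance, runs PCA, drops
    the batch-dominated components (``drop="auto"``: every batch-dominant
    component among the first five, always including PC1 when it is
    batch-dominant; or an explicit list), clusters the remaining scores, and
    assigns each unknown sample the majority class of the known samples in
    its cluster. A cluster with no known member yields ``"unresolved"``.
    """
    if unknown.n_samples == 0:
        return {}
    if known.protein_ids != unknown.protein_ids:
        raise ValueError("known and unknown matrices must share protein space")
    overlap = set(known.sample_ids) & set(unknown.sample_ids)
    if overlap:
        raise ValueError(f"sample ids shared between known and unknown: {sorted(overlap)[:3]}")
    pooled = ExpressionMatrix(
        np.hstack([known.values, unknown.values]),
        list(known.protein_ids),
        list(known.sample_ids) + list(unknown.sample_ids),
    )
    cls = {s: known_meta.class_of(s) for s in known.sample_ids}
    batch = {s: f"known_{known_meta.batch_of(s)}" for s in known.sample_ids}
    for s in unknown.sample_ids:
        cls[s] = "?"
        batch[s] = unknown_batch
    pre = variance_preselect(pooled, preselect_fraction)
    pca = run_pca(pre)
    if drop == "auto":
        # class association is judged on known samples only; batch on all
        known_idx = [j for j, s in enumerate(pca.sample_ids) if cls[s] != "?"]
        batch_vec = np.array([batch[s] for s in pca.sample_ids])
        cls_known = np.array([cls[pca.sample_ids[j]] for j in known_idx])
        drop_list: list[int] = []
        classy: list[int] = []
        for kcomp in range(min(5, pca.n_components)):
            sc = pca.scores[:, kcomp]
            _, p_b = _two_group_p(sc, batch_vec)
            _, p_c = _two_group_p(sc[known_idx], cls_known)
            if p_b < 0.01 and p_c >= 0.01:
                drop_list.append(kcomp + 1)
            elif p_c < 0.01:
                classy.append(kcomp + 1)
        if not drop_list:
            drop_list = [1]
        feats = remove_pcs(pca, drop_list)
        classy = [c for c in classy if c not in drop_list]
        if classy:
            feats = feats[[f"PC{c}" for c in classy]]
    else:
        drop_list = list(drop)
        feats = remove_pcs(pca, drop_list)
    classes = sorted(set(known_meta.class_vector(known.sample_ids)))
    if k is None:
        k = len(classes)
    labels, _ = cluster_samples(feats, k=k)
    out: dict[str, str] = {}
    for s in unknown.sample_ids:
        j = pca.sample_ids.index(s)
        members = [
            pca.sample_ids[i]
            for i in range(len(labels))
            if labels[i] == labels[j] and cls[pca.sample_ids[i]] != "?"
        ]
        if not members:
            out[s] = "unresolved"
            continue
        counts = pd.Series([cls[m] for m in members]).value_counts()
        out[s] = str(counts.index[0])
    return out


def traceback_proteins(
    p: PCAResult,
    component: int = 1,
    strength_sd: float = 2.0,
    exclusivity_first: int = 5,
) -> set[str]:
    """Proteins loading strongly and exclusively on one component.

    Strength: |loading| above mean(|loadings|) + ``strength_sd`` x SD on the
    component. Exclusivity: the component is the protein's largest-|loading|
    component among the first ``min(exclusivity_first, n_components)``.
    """
    if not 1 <= component <= p.n_components:
        raise ValueError(f"component {component} out of range")
    k = component - 1
    load = np.abs(p.loadings[:, k])
    threshold = load.mean() + strength_sd * load.std(ddof=0)
    first = min(exclusivity_first, p.n_components)
    argmax = np.argmax(np.abs(p.loadings[:, :first]), axis=1)
    selected = (load > threshold) & (argmax == k)
    return {p.retained_protein_ids[i] for i in np.nonzero(selected)[0]}


def minus_pc1_features(
    x: ExpressionMatrix,
    strength_sd: float = 2.0,
    exclusivity_first: int = 5,
) -> tuple[set[str], set[str]]:
    """The "-PC1" feature set: PC1 proteins after removing original-PC1 proteins.

    Runs PCA, traces the proteins strongly associated with PC1 (typically the
    batch-driven set), removes them from the matrix, reruns PCA on the
    reduced data, and traces the new PC1. Returns
    ``(pc1_set, minus_pc1_set)``: the original-PC1 proteins and the
    second-pass set.
    """
    pca1 = run_pca(x)
    pc1_set = traceback_proteins(pca1, 1, strength_sd, exclusivity_first)
    remaining = [pid for pid in x.protein_ids if pid not in pc1_set]
    if len(remaining) < 3:
        raise ValueError("fewer than 3 proteins survive PC1-protein removal")
    reduced = x.subset_proteins(remaining)
    pca2 = run_pca(reduced)
    minus_set = traceback_proteins(pca2, 1, strength_sd, exclusivity_first)
    return pc1_set, minus_set


def top_n_by_tstat(
    x: ExpressionMatrix, meta: SampleMetadata, n: int
) -> set[str]:
    """Top-n proteins by |pooled t| between the two classes; ties by id."""
    if n > x.n_proteins:
        raise ValueError(f"n={n} exceeds {x.n_proteins} proteins")
    cls = meta.class_vector(x.sample_ids)
    classes = sorted(set(cls))
    if len(classes) != 2:
        raise ValueError("t-statistic ranking needs exactly 2 classes")
    a = x.values[:, cls == classes[0]]
    b = x.values[:, cls == classes[1]]
    with np.errstate(divide="ignore", invalid="ignore"):
        t, _ = scipy.stats.ttest_ind(a, b, axis=1, equal_var=True)
    t = np.nan_to_num(t, nan=0.0)
    order = sorted(
        range(x.n_proteins), key=lambda i: (-abs(t[i]), x.protein_ids[i])
    )
    return {x.protein_ids[i] for i in order[:n]}
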