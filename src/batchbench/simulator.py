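"""Benchmark-data simulator: spectral-count base data plus class and batch effects.

The generator follows a two-stage spike-in design. Starting from a
single-class over-dispersed count matrix, class effects are inserted into a
random 20% of proteins in the disease-class (D*) samples, with multiplicative
effect sizes drawn uniformly from a five-level menu. Batch effects are then
applied on top: each class is split evenly into two batches and, in the
affected batch, EVERY protein is multiplied by an independently drawn level
from the (by default identical) menu. Because batch effects touch all
variables while class effects touch only 20%, batch effects dominate total
variance — the regime in which the toolkit's diagnostics and resistant
selectors are meant to operate.

The clean matrix (class effects only) and the noisy matrix (class + batch)
share protein ids, sample ids and ground truth, so any selector can be scored
on both sides of the same spike-in.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datamodel import (
    CLASS_D,
    CLASS_DSTAR,
    ExpressionMatrix,
    GroundTruth,
    SampleMetadata,
)

__all__ = [
    "EffectMenu",
    "MENU_DEFAULT",
    "MENU_ALTERNATE",
    "SimulationConfig",
    "SimulatedDataset",
    "generate_base_matrix",
    "insert_class_effects",
    "insert_batch_effects",
    "simulate_dataset",
    "combine_datasets",
]


@dataclass(frozen=True)
class EffectMenu:
    """Five multiplicative increase levels, as percentage increases.

    A level of 100 means the affected values are doubled (multiplier 2.0).
    """

    levels_percent: tuple[float, float, float, float, float]

    def __post_init__(self) -> None:
        if len(self.levels_percent) != 5:
            raise ValueError("an effect menu has exactly five levels")
        if any(lv <= 0 for lv in self.levels_percent):
            raise ValueError("all menu levels must be positive percentages")

    @property
    def multipliers(self) -> np.ndarray:
        return 1.0 + np.asarray(self.levels_percent, dtype=float) / 100.0

    def sample_multipliers(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.choice(self.multipliers, size=n, replace=True)


#: Menu used for both class and batch effects by default: +20/50/80/100/200%.
MENU_DEFAULT = EffectMenu((20.0, 50.0, 80.0, 100.0, 200.0))
#: Alternate (milder) batch-effect menu used in the combined-dataset experiment.
MENU_ALTERNATE = EffectMenu((10.0, 30.0, 50.0, 70.0, 90.0))


@dataclass
class SimulationConfig:
    n_proteins: int = 1100
    samples_per_class: int = 4
    diff_fraction: float = 0.20
    class_menu: EffectMenu = MENU_DEFAULT
    batch_menu: EffectMenu = MENU_DEFAULT
    affected_batch: str = "2"
    seed: int = 0
    # base-matrix generating distribution (negative binomial)
    mean_range: tuple[float, float] = (5.0, 500.0)
    dispersion: float = 0.2

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be positive")
        if self.samples_per_class < 2:
            raise ValueError(
                "samples_per_class must be >= 2 (two batches need at least "
                "one sample per class per batch)"
            )
        if not 0 < self.diff_fraction < 1:
            raise ValueError("diff_fraction must be in (0, 1)")


@dataclass
class SimulatedDataset:
    """A clean/noisy matrix pair sharing metadata and ground truth.

    ``clean`` carries class effects only; ``noisy`` additionally carries
    batch effects in the affected batch. Samples of the unaffected batch are
    identical between the two matrices.
    """

    clean: ExpressionMatrix
    noisy: ExpressionMatrix
    meta: SampleMetadata
    truth: GroundTruth
    batch_multipliers: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.clean.protein_ids != self.noisy.protein_ids:
            raise ValueError("clean and noisy matrices must share protein ids")
        if self.clean.sample_ids != self.noisy.sample_ids:
            raise ValueError("clean and noisy matrices must share sample ids")


def generate_base_matrix(
    n_proteins: int,
    n_samples: int,
    seed: int | np.random.Generator,
    mean_range: tuple[float, float] = (5.0, 500.0),
    dispersion: float = 0.2,
) -> ExpressionMatrix:
    """Draw a single-class spectral-count matrix.

    Each protein gets a mean abundance drawn log-uniformly from
    ``mean_range``; its counts across samples are i.i.d. negative binomial
    with that mean and quadratic over-dispersion ``var = mu + dispersion *
    mu**2``. All samples are exchangeable — any class or batch structure is
    inserted afterwards.
    """
    if n_proteins < 1 or n_samples < 1:
        raise ValueError("matrix dimensions must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    lo, hi = mean_range
    means = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_proteins))
    # NB with var = mu + phi mu^2  <=>  r = 1/phi, p = r / (r + mu)
    r = 1.0 / dispersion
    p = r / (r + means)
    counts = rng.negative_binomial(r, p[:, None], size=(n_proteins, n_samples))
    protein_ids = [f"P{i:05d}" for i in range(1, n_proteins + 1)]
    sample_ids = [f"S{j:02d}" for j in range(1, n_samples + 1)]
    return ExpressionMatrix(counts.astype(float), protein_ids, sample_ids)


def default_metadata(
    sample_ids: list[str], samples_per_class: int
) -> SampleMetadata:
    """Assign classes and an even two-batch split.

    The first ``samples_per_class`` samples are class D, the rest D*; within
    each class the first half is batch 1 and the second half batch 2.
    """
    if len(sample_ids) != 2 * samples_per_class:
        raise ValueError("expected two equal classes")
    cls: dict[str, str] = {}
    batch: dict[str, str] = {}
    half = samples_per_class // 2
    for k, s in enumerate(sample_ids):
        cls[s] = CLASS_D if k < samples_per_class else CLASS_DSTAR
        within = k % samples_per_class
        batch[s] = "1" if within < half else "2"
    return SampleMetadata(cls, batch)


def insert_class_effects(
    base: ExpressionMatrix,
    meta: SampleMetadata,
    diff_fraction: float = 0.20,
    menu: EffectMenu = MENU_DEFAULT,
    seed: int | np.random.Generator = 0,
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Multiply a random 20% (by default) of proteins in D* samples.

    Exactly ``round(diff_fraction * n_proteins)`` proteins are selected
    uniformly at random; each receives one menu level, applied
    multiplicatively to its values in every D* sample. Class-D samples are
    untouched. The returned ground truth records the selected proteins and
    their multipliers.
    """
    meta.validate_against(base)
    classes = set(meta.class_vector(base.sample_ids))
    if not {CLASS_D, CLASS_DSTAR} <= classes:
        raise ValueError(f"both classes {CLASS_D!r} and {CLASS_DSTAR!r} required, got {sorted(classes)}")
    n_diff = round(diff_fraction * base.n_proteins)
    if n_diff < 1:
        raise ValueError(
            f"diff_fraction {diff_fraction} selects no proteins out of {base.n_proteins}"
        )
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    chosen = rng.choice(base.n_proteins, size=n_diff, replace=False)
    multipliers = menu.sample_multipliers(n_diff, rng)
    out = base.values.copy()
    dstar_cols = np.array(
        [j for j, s in enumerate(base.sample_ids) if meta.class_of(s) == CLASS_DSTAR]
    )
    out[np.ix_(chosen, dstar_cols)] *= multipliers[:, None]
    truth = GroundTruth(
        {base.protein_ids[i]: float(m) for i, m in zip(chosen, multipliers)}
    )
    return (
        ExpressionMatrix(out, list(base.protein_ids), list(base.sample_ids)),
        truth,
    )


def insert_batch_effects(
    data: ExpressionMatrix,
    meta: SampleMetadata,
    menu: EffectMenu = MENU_DEFAULT,
    affected_batch: str = "2",
    seed: int | np.random.Generator = 0,
) -> tuple[ExpressionMatrix, np.ndarray]:
    """Apply batch effects to all proteins of one batch.

    For every protein one menu level is drawn independently; values of that
    protein in every affected-batch sample are multiplied by it. Batch
    effects are deliberately uneven across proteins so that global
    normalization cannot undo them. Returns the modified matrix and the
    per-protein multiplier vector.
    """
    meta.validate_against(data)
    batches = set(meta.batch_vector(data.sample_ids))
    if len(batches) < 2:
        raise ValueError(f"batch-effect insertion needs >= 2 batches, got {sorted(batches)}")
    if affected_batch not in batches:
        raise ValueError(f"affected batch {affected_batch!r} not among {sorted(batches)}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    multipliers = menu.sample_multipliers(data.n_proteins, rng)
    out = data.values.copy()
    cols = np.array(
        [j for j, s in enumerate(data.sample_ids) if meta.batch_of(s) == affected_batch]
    )
    out[:, cols] *= multipliers[:, None]
    return (
        ExpressionMatrix(out, list(data.protein_ids), list(data.sample_ids)),
        multipliers,
    )


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate a clean/noisy benchmark pair with known ground truth.

    Composition: base matrix -> class effects (clean) -> batch effects
    (noisy). Each class is split evenly between batches 1 and 2. Per-stage
    random streams are spawned from the config seed so stages are individually
    reproducible.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_base, rng_class, rng_batch = (np.random.default_rng(s) for s in ss.spawn(3))
    base = generate_base_matrix(
        config.n_proteins,
        2 * config.samples_per_class,
        rng_base,
        config.mean_range,
        config.dispersion,
    )
    meta = default_metadata(base.sample_ids, config.samples_per_class)
    clean, truth = insert_class_effects(
        base, meta, config.diff_fraction, config.class_menu, rng_class
    )
    noisy, batch_mult = insert_batch_effects(
        clean, meta, config.batch_menu, config.affected_batch, rng_batch
    )
    return SimulatedDataset(clean, noisy, meta, truth, batch_mult)


def combine_datasets(
    a: SimulatedDataset,
    b: SimulatedDataset,
    tags: tuple[str, str] = ("A", "B"),
    use: str = "noisy",
) -> tuple[ExpressionMatrix, SampleMetadata]:
    """Column-concatenate two datasets with the same truth, distinct batches.

    Emulates pooling two cohorts that carry the same differential signal but
    different technical structure: sample ids gain a dataset tag and batch
    labels become dataset-qualified (A1, A2, B1, B2).
    """
    if a.clean.protein_ids != b.clean.protein_ids:
        raise ValueError("datasets must share protein ids")
    if a.truth.effect_sizes != b.truth.effect_sizes:
        raise ValueError("datasets must share ground truth")
    xa = getattr(a, use)
    xb = getattr(b, use)
    values = np.hstack([xa.values, xb.values])
    sample_ids = [f"{tags[0]}_{s}" for s in xa.sample_ids] + [
        f"{tags[1]}_{s}" for s in xb.sample_ids
    ]
    cls: dict[str, str] = {}
    batch: dict[str, str] = {}
    for tag, ds, x in ((tags[0], a, xa), (tags[1], b, xb)):
        for s in x.sample_ids:
            cls[f"{tag}_{s}"] = ds.meta.class_of(s)
            batch[f"{tag}_{s}"] = f"{tag}{ds.meta.batch_of(s)}"
    return (
        ExpressionMatrix(values, list(xa.protein_ids), sample_ids),
        SampleMetadata(cls, batch),
    )
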