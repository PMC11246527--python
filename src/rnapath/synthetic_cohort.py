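"""Synthetic tile-embedding cohorts with known ground truth.

Emulates, at desk scale, the statistical structure the downstream stages
assume about a real histology cohort:

* spatially coherent tissue substructures — a Voronoi tessellation of random
  seed points on the base tile grid, each region carrying one substructure /
  pathology class;
* class-conditional tile embeddings — isotropic Gaussians whose means sit on
  a regular simplex scaled so every pair of class means is ``class_sep``
  within-class standard deviations apart (one knob controls kNN difficulty);
* bulk expression generated by the same model the MIL regressor fits
  (per-gene linear tile scorer, ReLU, mean-pool) plus Gaussian noise
  truncated at zero, so the noiseless cohort lies exactly inside the
  hypothesis class and parameter recovery is a meaningful test;
* donor structure (several samples per donor) so donor-disjoint splits are
  exercised, and donor-level covariates/genotypes with optional planted
  effects for calibrating the association stages.

Every generator draws from a stream keyed on ``(spec.seed, stage,
sample_index)`` so outputs are reproducible independently of generation
order.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .tile_bags import CohortManifest, TileBag, write_bag, write_manifest
from .segmentation import AnnotationSet

__all__ = [
    "SyntheticSpec",
    "PlantedEffects",
    "SyntheticCohort",
    "class_means",
    "default_gene_params",
    "generate_tissue_map",
    "generate_bag",
    "generate_overlapping_bag",
    "generate_expression",
    "generate_annotations",
    "generate_covariates_and_genotypes",
    "apply_proportion_effects",
    "apply_interaction_effects",
    "generate_cohort",
    "write_cohort",
]

# stage ids for the per-(seed, stage, sample) random streams
_STAGE_MAP, _STAGE_EMB, _STAGE_EXPR, _STAGE_ANN, _STAGE_COV, _STAGE_GENES, _STAGE_OVL = range(7)


def _rng(seed: int, stage: int, index: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stage, index)))


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic cohort.

    Defaults are the desk-scale study conditions used throughout the test
    suite: 200 samples of 100 tiles (10x10 base grid), 32-dim embeddings,
    50 genes, class separation 8 within-class sd (an "easy" fixture where
    tile classes are essentially noiseless), and expression noise at 5% of
    each gene's across-sample signal sd.
    """

    n_samples: int = 200
    grid_rows: int = 10
    grid_cols: int = 10
    n_classes: int = 4
    n_region_seeds: int = 6
    embed_dim: int = 32
    class_sep: float = 8.0
    embed_sd: float = 1.0
    n_genes: int = 50
    gene_model: str = "tile_affine"  # or "proportion_linear"
    true_W: Optional[np.ndarray] = None
    true_b: Optional[np.ndarray] = None
    expr_noise_sd: float = 0.05
    expr_noise_mode: str = "relative"  # "relative": sd = expr_noise_sd * per-gene signal sd
    n_donors: int = 100
    tile_size_px: int = 128
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_samples", "grid_rows", "grid_cols", "n_classes", "n_region_seeds",
                     "embed_dim", "n_genes", "n_donors", "tile_size_px"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.class_sep < 0:
            raise ValueError("class_sep must be >= 0")
        if self.embed_sd < 0:
            raise ValueError("embed_sd must be >= 0")
        if self.gene_model not in ("tile_affine", "proportion_linear"):
            raise ValueError(f"unknown gene_model: {self.gene_model}")
        if self.embed_dim < self.n_classes:
            raise ValueError("embed_dim must be >= n_classes (simplex class means)")
        if self.expr_noise_mode not in ("relative", "absolute"):
            raise ValueError(f"unknown expr_noise_mode: {self.expr_noise_mode}")

    @property
    def class_names(self) -> List[str]:
        return [f"class_{i}" for i in range(self.n_classes)]

    @property
    def gene_names(self) -> List[str]:
        return [f"gene_{i}" for i in range(self.n_genes)]


def class_means(spec: SyntheticSpec) -> np.ndarray:
    """Class mean embeddings: vertices of a centred regular simplex.

    Returns ``(n_classes, embed_dim)``; every pair of means is exactly
    ``class_sep * embed_sd`` apart, so the difficulty of separating classes
    is uniform across pairs and controlled by a single knob.
    """
    c = spec.n_classes
    verts = np.eye(c) - 1.0 / c  # centred, pairwise distance sqrt(2)
    sep = spec.class_sep * spec.embed_sd
    verts *= sep / np.sqrt(2.0)
    mus = np.zeros((c, spec.embed_dim))
    mus[:, :c] = verts
    return mus


def generate_tissue_map(spec: SyntheticSpec, sample_index: int) -> np.ndarray:
    """Voronoi tissue map: an integer label grid of shape (grid_rows, grid_cols).

    ``n_region_seeds`` points are placed uniformly on the grid, each assigned
    a class uniformly at random; every cell takes the class of its nearest
    seed (Euclidean distance on cell centres, first-index tie-break).
    """
    rng = _rng(spec.seed, _STAGE_MAP, sample_index)
    seeds = rng.uniform(low=0.0, high=[spec.grid_rows, spec.grid_cols], size=(spec.n_region_seeds, 2))
    seed_classes = rng.integers(0, spec.n_classes, size=spec.n_region_seeds)
    rr, cc = np.meshgrid(np.arange(spec.grid_rows) + 0.5, np.arange(spec.grid_cols) + 0.5, indexing="ij")
    cells = np.stack([rr.ravel(), cc.ravel()], axis=1)  # (cells, 2)
    d2 = ((cells[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2)
    nearest = np.argmin(d2, axis=1)
    return seed_classes[nearest].reshape(spec.grid_rows, spec.grid_cols)


def generate_bag(
    label_grid: np.ndarray,
    spec: SyntheticSpec,
    sample_id: str,
    donor_id: str,
    sample_index: int,
) -> Tuple[TileBag, np.ndarray]:
    """One tile per grid cell with a class-conditional Gaussian embedding.

    Tiles are laid out row-major at coords ``(col*tile_size, row*tile_size)``.
    Returns the bag and the flat (row-major) true label per tile.
    """
    rng = _rng(spec.seed, _STAGE_EMB, sample_index)
    mus = class_means(spec)
    labels = np.asarray(label_grid).ravel()
    noise = rng.standard_normal((labels.size, spec.embed_dim)) * spec.embed_sd
    emb = mus[labels] + noise
    rows, cols = np.divmod(np.arange(labels.size), label_grid.shape[1])
    coords = np.stack([cols * spec.tile_size_px, rows * spec.tile_size_px], axis=1).astype(np.int64)
    bag = TileBag(
        sample_id=sample_id,
        donor_id=donor_id,
        tissue="synthetic",
        embeddings=emb,
        coords=coords,
        tile_size_px=spec.tile_size_px,
        stride_px=spec.tile_size_px,
        mpp=0.494,
    )
    return bag, labels


def generate_overlapping_bag(
    label_grid: np.ndarray,
    spec: SyntheticSpec,
    sample_id: str,
    donor_id: str,
    sample_index: int,
    stride_divisor: int = 4,
) -> Tuple[TileBag, np.ndarray]:
    """Overlap-tiled variant of :func:`generate_bag` (default 75% overlap).

    Tile origins step by ``tile_size_px / stride_divisor``; each tile's class
    (and hence embedding distribution) is that of the grid cell containing
    its centre.  Used for majority-vote segmentation and fine-grained
    heatmaps.
    """
    if spec.tile_size_px % stride_divisor != 0:
        raise ValueError("stride_divisor must divide tile_size_px")
    stride = spec.tile_size_px // stride_divisor
    rng = _rng(spec.seed, _STAGE_OVL, sample_index)
    mus = class_means(spec)
    rows, cols = label_grid.shape
    xs = np.arange(0, (cols - 1) * spec.tile_size_px + 1, stride)
    ys = np.arange(0, (rows - 1) * spec.tile_size_px + 1, stride)
    gx, gy = np.meshgrid(xs, ys, indexing="xy")
    coords = np.stack([gx.ravel(), gy.ravel()], axis=1).astype(np.int64)
    centre_col = np.clip((coords[:, 0] + spec.tile_size_px // 2) // spec.tile_size_px, 0, cols - 1)
    centre_row = np.clip((coords[:, 1] + spec.tile_size_px // 2) // spec.tile_size_px, 0, rows - 1)
    labels = np.asarray(label_grid)[centre_row, centre_col]
    emb = mus[labels] + rng.standard_normal((labels.size, spec.embed_dim)) * spec.embed_sd
    bag = TileBag(
        sample_id=sample_id,
        donor_id=donor_id,
        tissue="synthetic",
        embeddings=emb,
        coords=coords,
        tile_size_px=spec.tile_size_px,
        stride_px=stride,
        mpp=0.494,
    )
    return bag, labels


def default_gene_params(spec: SyntheticSpec) -> Tuple[np.ndarray, np.ndarray]:
    """Default true (W, b) for the tile-affine expression model.

    The first ``n_classes`` genes are planted class markers: gene ``g`` scores
    high only on tiles of class ``g`` (its weight vector points at that class
    mean, bias 0, so the ReLU silences all other classes).  These are the
    ground-truth "ROI-specific" genes for enrichment and heatmap tests.
    Remaining genes get random dense weights and a positive bias, giving
    smoothly composition-dependent bulk values.
    """
    rng = _rng(spec.seed, _STAGE_GENES)
    d, g = spec.embed_dim, spec.n_genes
    W = rng.normal(0.0, 0.4 / np.sqrt(d), size=(d, g))
    b = rng.uniform(0.5, 2.0, size=g)
    mus = class_means(spec)
    centroid = mus.mean(axis=0)
    for j in range(min(spec.n_classes, g)):
        direction = mus[j] - centroid
        nrm = np.linalg.norm(direction)
        if nrm > 0:
            W[:, j] = 2.0 * direction / nrm
            b[j] = 0.0
    return W, b


def _tile_affine_scores(X: np.ndarray, W: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.maximum(X @ W + b, 0.0)


def generate_expression(
    embeddings: Sequence[np.ndarray],
    spec: SyntheticSpec,
    sample_ids: Sequence[str],
    compositions: Optional[np.ndarray] = None,
) -> Tuple[pd.DataFrame, List[np.ndarray]]:
    """Bulk expression on a TPM-like (non-negative) scale, plus true tile scores.

    ``tile_affine``: per sample, gene value = mean over tiles of
    ``ReLU(w_g . x + b_g)`` plus Gaussian noise, truncated at 0 — exactly the
    generative form the MIL regressor assumes.  ``proportion_linear``: value =
    linear function of the sample's class-proportion vector plus noise,
    truncated at 0 (``compositions`` required).  In ``relative`` noise mode
    the per-gene noise sd is ``expr_noise_sd`` times the across-sample sd of
    the noiseless values.

    Returns ``(genes x samples DataFrame, list of per-sample K x G true tile
    score matrices)`` (the list is empty for ``proportion_linear``).
    """
    rng = _rng(spec.seed, _STAGE_EXPR)
    n = len(embeddings) if spec.gene_model == "tile_affine" else len(sample_ids)
    if spec.gene_model == "tile_affine":
        W = spec.true_W if spec.true_W is not None else default_gene_params(spec)[0]
        b = spec.true_b if spec.true_b is not None else default_gene_params(spec)[1]
        W = np.asarray(W, dtype=float)
        b = np.asarray(b, dtype=float)
        if W.shape != (spec.embed_dim, spec.n_genes) or b.shape != (spec.n_genes,):
            raise ValueError(
                f"true_W must be ({spec.embed_dim}, {spec.n_genes}) and true_b ({spec.n_genes},); "
                f"got {W.shape} and {b.shape}"
            )
        tile_scores = [_tile_affine_scores(np.asarray(X, dtype=float), W, b) for X in embeddings]
        clean = np.stack([s.mean(axis=0) for s in tile_scores], axis=0)  # (samples, genes)
    else:
        if compositions is None:
            raise ValueError("gene_model='proportion_linear' requires compositions")
        comps = np.asarray(compositions, dtype=float)
        if comps.shape != (n, spec.n_classes):
            raise ValueError(f"compositions must be ({n}, {spec.n_classes}), got {comps.shape}")
        coef = _rng(spec.seed, _STAGE_GENES, 1).uniform(1.0, 5.0, size=(spec.n_classes, spec.n_genes))
        clean = comps @ coef
        tile_scores = []
    if spec.expr_noise_mode == "relative":
        sd = spec.expr_noise_sd * clean.std(axis=0, ddof=0)
    else:
        sd = np.full(spec.n_genes, spec.expr_noise_sd)
    noisy = np.maximum(clean + rng.standard_normal(clean.shape) * sd, 0.0)
    expr = pd.DataFrame(noisy.T, index=spec.gene_names, columns=list(sample_ids))
    return expr, tile_scores


def generate_annotations(
    bags: Sequence[TileBag],
    true_labels: Sequence[np.ndarray],
    class_names: Sequence[str],
    tiles_per_class: int,
    seed: int,
) -> Tuple[AnnotationSet, pd.DataFrame]:
    """Balanced labelled reference set sampled without replacement cohort-wide.

    Returns the annotation set and a provenance table
    ``(sample_id, tile_index, class)``.  Raises if any class has fewer than
    ``tiles_per_class`` tiles in the cohort, naming the class.
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(_STAGE_ANN,)))
    all_labels = np.concatenate([np.asarray(l) for l in true_labels])
    owner = np.concatenate([np.full(len(l), i) for i, l in enumerate(true_labels)])
    within = np.concatenate([np.arange(len(l)) for l in true_labels])
    chosen = []
    for c in range(len(class_names)):
        idx = np.flatnonzero(all_labels == c)
        if idx.size < tiles_per_class:
            raise ValueError(
                f"class '{class_names[c]}' has only {idx.size} tiles in the cohort, "
                f"need {tiles_per_class}"
            )
        chosen.append(rng.choice(idx, size=tiles_per_class, replace=False))
    chosen = np.concatenate(chosen)
    emb = np.concatenate([np.asarray(b.embeddings) for b in bags], axis=0)[chosen]
    labels = all_labels[chosen]
    prov = pd.DataFrame(
        {
            "sample_id": [bags[owner[i]].sample_id for i in chosen],
            "tile_index": within[chosen],
            "class": [class_names[c] for c in labels],
        }
    )
    ann = AnnotationSet(
        embeddings=emb, labels=labels, class_names=list(class_names), tissue="synthetic"
    )
    return ann, prov


@dataclass
class PlantedEffects:
    """Ground-truth effects to inject into a synthetic cohort.

    ``proportion_effects``: (covariate_name, class_index, beta) — the class's
    proportion shifts by beta per unit covariate before renormalisation.
    ``interaction_effects``: (variant_name, gene_name, beta3) — expression of
    the gene shifts by beta3 * dosage * phenotype (genotype-by-phenotype
    interaction).
    """

    proportion_effects: List[Tuple[str, int, float]] = field(default_factory=list)
    interaction_effects: List[Tuple[str, str, float]] = field(default_factory=list)
    allele_freq: float = 0.3
    n_variants: int = 1

    def __post_init__(self) -> None:
        if not 0.0 < self.allele_freq < 1.0:
            raise ValueError(f"allele_freq must be in (0, 1), got {self.allele_freq}")


def generate_covariates_and_genotypes(
    spec: SyntheticSpec,
    effects: Optional[PlantedEffects] = None,
    donors: Optional[Sequence[str]] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Donor-level covariates and genotype dosages.

    Covariates mimic a post-mortem tissue cohort: age (uniform 20-70 years),
    sex (0/1), BMI (normal, mean 27 sd 4), ischemic time (minutes, normal
    mean 600 sd 200, floored at 0) and five genotype PCs (standard normal).
    Dosages are Binomial(2, allele_freq) — Hardy-Weinberg at the stated
    allele frequency.  Returns (covariates indexed by donor, variants x
    donors dosage table).
    """
    effects = effects or PlantedEffects()
    rng = _rng(spec.seed, _STAGE_COV)
    if donors is None:
        donors = [f"donor_{i}" for i in range(spec.n_donors)]
    n = len(donors)
    cov = pd.DataFrame(
        {
            "age": rng.uniform(20.0, 70.0, n),
            "sex": rng.integers(0, 2, n).astype(float),
            "bmi": rng.normal(27.0, 4.0, n),
            "ischemic_time": np.maximum(rng.normal(600.0, 200.0, n), 0.0),
            **{f"pc{i+1}": rng.standard_normal(n) for i in range(5)},
        },
        index=pd.Index(donors, name="donor_id"),
    )
    dosages = pd.DataFrame(
        rng.binomial(2, effects.allele_freq, size=(effects.n_variants, n)).astype(float),
        index=[f"variant_{i}" for i in range(effects.n_variants)],
        columns=donors,
    )
    return cov, dosages


def apply_proportion_effects(
    compositions: pd.DataFrame,
    covariates: pd.DataFrame,
    effects: PlantedEffects,
) -> pd.DataFrame:
    """Inject covariate effects into class proportions, then renormalise.

    ``compositions`` is samples x classes; rows of ``covariates`` are aligned
    by index.  Each planted (covariate, class, beta) adds ``beta * covariate``
    to that class's part; parts are clipped at a small positive floor and
    renormalised to sum to 1.
    """
    out = compositions.to_numpy(dtype=float).copy()
    for cov_name, class_idx, beta in effects.proportion_effects:
        out[:, class_idx] += beta * covariates.loc[compositions.index, cov_name].to_numpy()
    out = np.clip(out, 1e-12, None)
    out /= out.sum(axis=1, keepdims=True)
    return pd.DataFrame(out, index=compositions.index, columns=compositions.columns)


def apply_interaction_effects(
    expression: pd.DataFrame,
    dosage_by_sample: pd.Series,
    phenotype: pd.Series,
    effects: PlantedEffects,
) -> pd.DataFrame:
    """Inject genotype-by-phenotype interaction effects into expression.

    For each planted (variant, gene, beta3), adds ``beta3 * G * P`` to that
    gene's row (G = per-sample dosage, P = per-sample phenotype).  The variant
    name selects nothing here — the caller passes the matching dosage series —
    but is recorded in the ground truth for bookkeeping.
    """
    out = expression.copy()
    g = dosage_by_sample.loc[out.columns].to_numpy(dtype=float)
    p = phenotype.loc[out.columns].to_numpy(dtype=float)
    for _variant, gene, beta3 in effects.interaction_effects:
        out.loc[gene] = out.loc[gene].to_numpy() + beta3 * g * p
    return out


@dataclass
class SyntheticCohort:
    """A fully generated cohort with its ground truth."""

    spec: SyntheticSpec
    bags: List[TileBag]
    label_grids: List[np.ndarray]
    true_labels: List[np.ndarray]
    expression: pd.DataFrame  # genes x samples, TPM-like scale
    true_tile_scores: List[np.ndarray]  # per-sample K x G (tile_affine only)
    compositions: pd.DataFrame  # samples x classes, ground-truth proportions
    donor_of: Dict[str, str]
    true_W: Optional[np.ndarray]
    true_b: Optional[np.ndarray]

    @property
    def sample_ids(self) -> List[str]:
        return [b.sample_id for b in self.bags]


def generate_cohort(spec: SyntheticSpec) -> SyntheticCohort:
    """Generate a complete cohort: maps, bags, expression and ground truth.

    Samples are assigned to donors round-robin (every donor contributes
    ``n_samples / n_donors`` samples on average), which exercises
    donor-disjoint splitting downstream.
    """
    bags, grids, labels = [], [], []
    comps = np.zeros((spec.n_samples, spec.n_classes))
    for i in range(spec.n_samples):
        grid = generate_tissue_map(spec, i)
        sid = f"sample_{i:04d}"
        did = f"donor_{i % spec.n_donors}"
        bag, lab = generate_bag(grid, spec, sid, did, i)
        bags.append(bag)
        grids.append(grid)
        labels.append(lab)
        comps[i] = np.bincount(lab, minlength=spec.n_classes) / lab.size
    if spec.gene_model == "tile_affine":
        if spec.true_W is None:
            spec.true_W, spec.true_b = default_gene_params(spec)
        expr, scores = generate_expression([b.embeddings for b in bags], spec, [b.sample_id for b in bags])
    else:
        expr, scores = generate_expression([], spec, [b.sample_id for b in bags], compositions=comps)
    comp_df = pd.DataFrame(comps, index=[b.sample_id for b in bags], columns=spec.class_names)
    return SyntheticCohort(
        spec=spec,
        bags=bags,
        label_grids=grids,
        true_labels=labels,
        expression=expr,
        true_tile_scores=scores,
        compositions=comp_df,
        donor_of={b.sample_id: b.donor_id for b in bags},
        true_W=spec.true_W,
        true_b=spec.true_b,
    )


def write_cohort(cohort: SyntheticCohort, outdir: str, tiles_per_class: int = 50) -> CohortManifest:
    """Write a cohort to disk: bag HDF5s, manifest, annotations, expression,
    covariates, genotypes and a ground-truth JSON sidecar."""
    os.makedirs(os.path.join(outdir, "bags"), exist_ok=True)
    rows = []
    for bag in cohort.bags:
        rel = os.path.join("bags", f"{bag.sample_id}.h5")
        write_bag(bag, os.path.join(outdir, rel))
        rows.append((bag.sample_id, bag.donor_id, bag.tissue, rel))
    manifest = CohortManifest(
        table=pd.DataFrame(rows, columns=["sample_id", "donor_id", "tissue", "bag_path"]),
        root=outdir,
    )
    write_manifest(manifest, os.path.join(outdir, "manifest.tsv"))
    _, prov = generate_annotations(
        cohort.bags, cohort.true_labels, cohort.spec.class_names, tiles_per_class, cohort.spec.seed
    )
    prov.to_csv(os.path.join(outdir, "annotations.tsv"), sep="\t", index=False)
    cohort.expression.to_csv(os.path.join(outdir, "expression.tsv"), sep="\t")
    cov, dosages = generate_covariates_and_genotypes(cohort.spec)
    cov.to_csv(os.path.join(outdir, "covariates.tsv"), sep="\t")
    dosages.to_csv(os.path.join(outdir, "genotypes.tsv"), sep="\t")
    truth = {
        "class_names": cohort.spec.class_names,
        "true_labels": {b.sample_id: l.tolist() for b, l in zip(cohort.bags, cohort.true_labels)},
        "true_W": None if cohort.true_W is None else np.asarray(cohort.true_W).tolist(),
        "true_b": None if cohort.true_b is None else np.asarray(cohort.true_b).tolist(),
        "compositions": cohort.compositions.to_dict(orient="index"),
        "seed": cohort.spec.seed,
    }
    with open(os.path.join(outdir, "ground_truth.json"), "w") as f:
        json.dump(truth, f)
    return manifest
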