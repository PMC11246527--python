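"""Weakly supervised tissue segmentation by kNN tile classification.

Each unannotated tile is assigned the plurality class of its k nearest
neighbours (k = 200 by default, matching the bulk-cohort setting; k = 50 is
the documented choice at higher magnification) in a small annotated
reference set of tile embeddings — no parametric classifier is trained.
Bags tiled with overlap are fused onto the non-overlapping base grid by
majority voting across the tiles covering each cell, which smooths
uncertainty at substructure boundaries.  Class proportions per sample
(tile counts normalised by total classified tiles) are the image-derived
phenotypes consumed by the compositional statistics.

Tie-breaking is deterministic throughout: plurality vote count, then summed
inverse distance (per-tile) or summed vote fraction (per-cell), then lowest
class index.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.model_selection import StratifiedShuffleSplit
from sklearn.neighbors import NearestNeighbors

from .tile_bags import BagValidationError, TileBag, base_grid_index

__all__ = [
    "AnnotationSet",
    "SegmentationResult",
    "classify_tiles",
    "segment_with_overlap",
    "composition_from_map",
    "holdout_accuracy",
    "presence_call",
    "UNCLASSIFIED",
]

UNCLASSIFIED = -1


@dataclass
class AnnotationSet:
    """Labelled reference tile embeddings for one tissue.

    ``embeddings`` is A x D; ``labels[i]`` indexes ``class_names``.
    """

    embeddings: np.ndarray
    labels: np.ndarray
    class_names: List[str]
    tissue: str = ""

    def __post_init__(self) -> None:
        self.embeddings = np.asarray(self.embeddings, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.embeddings.ndim != 2 or self.embeddings.shape[0] < 1:
            raise BagValidationError("annotation embeddings must be a non-empty A x D matrix")
        if self.labels.shape != (self.embeddings.shape[0],):
            raise BagValidationError("labels must have one entry per annotated tile")
        if self.labels.min() < 0 or self.labels.max() >= len(self.class_names):
            raise BagValidationError("labels must index class_names")

    @property
    def n_annotations(self) -> int:
        return self.embeddings.shape[0]

    @property
    def n_classes(self) -> int:
        return len(self.class_names)


@dataclass
class SegmentationResult:
    """Per-tile class calls fused onto the base grid.

    ``grid_classes`` holds a class index per base cell, ``UNCLASSIFIED`` (-1)
    where no tile covers the cell; such cells are excluded from composition
    denominators.
    """

    tile_classes: np.ndarray
    tile_vote_fractions: np.ndarray
    grid_classes: np.ndarray
    grid_vote_fractions: np.ndarray
    class_names: List[str]

    @property
    def composition(self) -> "Composition":
        return composition_from_map(self)


def _tile_embeddings(bag_or_embeddings) -> np.ndarray:
    if isinstance(bag_or_embeddings, TileBag):
        return np.asarray(bag_or_embeddings.embeddings, dtype=float)
    return np.asarray(bag_or_embeddings, dtype=float)


def classify_tiles(
    bag, ann: AnnotationSet, k: int = 200, metric: str = "euclidean"
) -> Tuple[np.ndarray, np.ndarray]:
    """Assign each tile the plurality class among its k nearest annotations.

    Parameters
    ----------
    bag
        A :class:`~rnapath.tile_bags.TileBag` or a plain ``K x D`` embedding
        matrix.
    ann
        The annotated reference set fitted by the (non-parametric) kNN model.
    k
        Number of neighbours; must not exceed the number of annotations.
    metric
        ``euclidean`` (default) or ``cosine``.

    Returns
    -------
    (classes, vote_fractions)
        Per-tile winning class index and the winning class's share of the k
        votes.  Vote ties break by summed inverse neighbour distance, then by
        lowest class index.
    """
    X = _tile_embeddings(bag)
    if k < 1 or k > ann.n_annotations:
        raise ValueError(f"k must be in [1, {ann.n_annotations}], got {k}")
    if X.shape[1] != ann.embeddings.shape[1]:
        raise BagValidationError(
            f"embedding dimension mismatch: tiles have D={X.shape[1]}, "
            f"annotations have D={ann.embeddings.shape[1]}"
        )
    if metric not in ("euclidean", "cosine"):
        raise ValueError(f"unsupported metric: {metric}")
    nn = NearestNeighbors(n_neighbors=k, metric=metric, algorithm="brute")
    nn.fit(ann.embeddings)
    dist, idx = nn.kneighbors(X)
    neigh_labels = ann.labels[idx]  # (K, k)
    C = ann.n_classes
    onehot = neigh_labels[:, :, None] == np.arange(C)[None, None, :]
    votes = onehot.sum(axis=1)  # (K, C)
    inv_d = 1.0 / np.maximum(dist, 1e-12)
    inv_mass = (onehot * inv_d[:, :, None]).sum(axis=1)  # (K, C)
    # lexicographic argmax: votes, then inverse-distance mass, then lowest index
    order = np.lexsort((np.arange(C)[None, :].repeat(X.shape[0], 0), -inv_mass, -votes), axis=1)
    winners = order[:, 0]
    vote_fractions = votes[np.arange(X.shape[0]), winners] / k
    return winners, vote_fractions


def _covering_cells(coords: np.ndarray, tile_size: int) -> List[np.ndarray]:
    """Base-grid cells overlapped by each tile (a tile spans [x, x+T) x [y, y+T))."""
    out = []
    t = tile_size
    for x, y in coords:
        c0, c1 = x // t, (x + t - 1) // t
        r0, r1 = y // t, (y + t - 1) // t
        cells = [(r, c) for r in range(r0, r1 + 1) for c in range(c0, c1 + 1)]
        out.append(np.asarray(cells))
    return out


def segment_with_overlap(
    bag: TileBag, ann: AnnotationSet, k: int = 200, metric: str = "euclidean"
) -> SegmentationResult:
    """Classify an (optionally overlap-tiled) bag and fuse onto the base grid.

    Every base cell aggregates the class calls of all tiles whose footprint
    covers it; the cell takes the majority class (tie-break: summed vote
    fraction, then lowest class index).  With stride = tile size this reduces
    exactly to :func:`classify_tiles` rasterised onto the grid.  Cells covered
    by no tile are marked ``UNCLASSIFIED``.
    """
    classes, fracs = classify_tiles(bag, ann, k=k, metric=metric)
    t = bag.tile_size_px
    covers = _covering_cells(bag.coords, t)
    max_r = max(int(c[:, 0].max()) for c in covers)
    max_c = max(int(c[:, 1].max()) for c in covers)
    C = ann.n_classes
    counts = np.zeros((max_r + 1, max_c + 1, C), dtype=np.int64)
    masses = np.zeros((max_r + 1, max_c + 1, C), dtype=float)
    for cells, cls, frac in zip(covers, classes, fracs):
        counts[cells[:, 0], cells[:, 1], cls] += 1
        masses[cells[:, 0], cells[:, 1], cls] += frac
    covered = counts.sum(axis=2) > 0
    flat_counts = counts.reshape(-1, C)
    flat_masses = masses.reshape(-1, C)
    n_cells = flat_counts.shape[0]
    order = np.lexsort(
        (np.arange(C)[None, :].repeat(n_cells, 0), -flat_masses, -flat_counts), axis=1
    )
    grid = order[:, 0].reshape(covered.shape)
    win_counts = np.take_along_axis(flat_counts, order[:, :1], axis=1).reshape(covered.shape)
    total = counts.sum(axis=2)
    grid_frac = np.divide(win_counts, total, out=np.zeros_like(masses[:, :, 0]), where=covered)
    grid[~covered] = UNCLASSIFIED
    return SegmentationResult(
        tile_classes=classes,
        tile_vote_fractions=fracs,
        grid_classes=grid,
        grid_vote_fractions=grid_frac,
        class_names=list(ann.class_names),
    )


def composition_from_map(result: SegmentationResult) -> "Composition":
    """Class proportions over classified base cells (counts / total classified)."""
    from .composition_stats import Composition  # local import to avoid a cycle

    grid = result.grid_classes
    classified = grid[grid != UNCLASSIFIED]
    if classified.size == 0:
        raise ValueError("no classified cells: composition is undefined")
    counts = np.bincount(classified, minlength=len(result.class_names))
    return Composition(parts=counts / classified.size, names=list(result.class_names))


def holdout_accuracy(
    ann: AnnotationSet,
    k: int = 200,
    holdout_frac: float = 0.10,
    n_folds: int = 10,
    seed: int = 0,
    metric: str = "euclidean",
) -> Dict:
    """Held-out accuracy of the kNN tile classifier on the annotation set.

    For each of ``n_folds`` folds, a stratified ``holdout_frac`` of each
    class is held out of the kNN reference and classified against the rest.
    Reports per-fold overall accuracy, per-class accuracy, and the median and
    sd across folds (defaults 10% x 10 folds).
    """
    counts = np.bincount(ann.labels, minlength=ann.n_classes)
    min_needed = int(np.ceil(1.0 / holdout_frac))
    for c, n in enumerate(counts):
        if 0 < n < min_needed:
            raise ValueError(
                f"class '{ann.class_names[c]}' has {n} tiles, needs >= {min_needed} "
                f"for a {holdout_frac:.0%} holdout"
            )
    splitter = StratifiedShuffleSplit(
        n_splits=n_folds, test_size=holdout_frac, random_state=seed
    )
    fold_acc, per_class = [], []
    for train_idx, test_idx in splitter.split(ann.embeddings, ann.labels):
        ref = AnnotationSet(
            embeddings=ann.embeddings[train_idx],
            labels=ann.labels[train_idx],
            class_names=ann.class_names,
            tissue=ann.tissue,
        )
        k_eff = min(k, ref.n_annotations)
        pred, _ = classify_tiles(ann.embeddings[test_idx], ref, k=k_eff, metric=metric)
        truth = ann.labels[test_idx]
        fold_acc.append(float(np.mean(pred == truth)))
        pc = np.full(ann.n_classes, np.nan)
        for c in range(ann.n_classes):
            m = truth == c
            if m.any():
                pc[c] = float(np.mean(pred[m] == truth[m]))
        per_class.append(pc)
    per_class = np.asarray(per_class)
    return {
        "fold_accuracy": fold_acc,
        "median_accuracy": float(np.median(fold_acc)),
        "sd_accuracy": float(np.std(fold_acc, ddof=1)) if n_folds > 1 else 0.0,
        "per_class_accuracy": {
            name: float(np.nanmedian(per_class[:, c])) for c, name in enumerate(ann.class_names)
        },
        "n_folds": n_folds,
        "holdout_frac": holdout_frac,
        "k": k,
    }


def presence_call(composition, class_name: str, threshold: float = 0.05) -> bool:
    """True iff the class's proportion strictly exceeds ``threshold``.

    The 5% default mirrors the pathology-presence rule used for flagging
    e.g. calcification occupying more than 5% of the tissue in a slide.
    """
    if class_name not in composition.names:
        raise KeyError(f"class '{class_name}' not in composition: {composition.names}")
    part = composition.parts[composition.names.index(class_name)]
    return bool(part > threshold)
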