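"""Per-sample tile-embedding bags and cohort manifests.

A whole-slide image is represented as a *bag*: a ``K x D`` matrix of tile
embeddings together with the upper-left pixel coordinate of each tile in the
source slide.  Bags are stored one-per-sample in HDF5 files with fixed dataset
names (``embeddings`` float32, ``coords`` int64 in (x, y) order) and scalar
metadata as root attributes, so that bags written by any tool following this
layout are interchangeable.

Coordinates are 0-based pixel units with x = column and y = row, upper-left
origin.  The *base grid* is the non-overlapping tiling at ``tile_size_px``;
``base_grid_index`` maps each tile onto it by floor division and is the
common spatial frame for segmentation maps, heatmaps and Moran's I adjacency.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "TileBag",
    "CohortManifest",
    "BagValidationError",
    "BagFormatError",
    "write_bag",
    "read_bag",
    "base_grid_index",
    "read_manifest",
    "write_manifest",
]


class BagValidationError(ValueError):
    """A bag or manifest violates a structural invariant."""


class BagFormatError(ValueError):
    """An on-disk bag file is missing datasets or malformed."""


@dataclass
class TileBag:
    """A bag of tile embeddings for one histology sample.

    Parameters
    ----------
    sample_id, donor_id, tissue
        Identifiers; ``donor_id`` drives split hygiene downstream.
    embeddings
        ``(K, D)`` float array of tile feature vectors.
    coords
        ``(K, 2)`` integer array of upper-left tile coordinates, columns
        ``(x, y)`` in pixels.
    tile_size_px
        Side length of each square tile in pixels.
    stride_px
        Offset between consecutive tile origins; ``stride_px < tile_size_px``
        means the bag was tiled with overlap.
    mpp
        Microns per pixel of the source scan, if known.
    """

    sample_id: str
    donor_id: str
    tissue: str
    embeddings: np.ndarray
    coords: np.ndarray
    tile_size_px: int
    stride_px: int
    mpp: Optional[float] = None

    def __post_init__(self) -> None:
        self.embeddings = np.asarray(self.embeddings)
        self.coords = np.asarray(self.coords)
        self.validate()

    @property
    def n_tiles(self) -> int:
        return self.embeddings.shape[0]

    @property
    def embed_dim(self) -> int:
        return self.embeddings.shape[1]

    def validate(self) -> None:
        if self.embeddings.ndim != 2 or self.embeddings.shape[0] < 1 or self.embeddings.shape[1] < 1:
            raise BagValidationError(
                f"embeddings must be a K x D matrix with K,D >= 1, got shape {self.embeddings.shape}"
            )
        if self.coords.ndim != 2 or self.coords.shape != (self.embeddings.shape[0], 2):
            raise BagValidationError(
                f"coords must have shape ({self.embeddings.shape[0]}, 2), got {self.coords.shape}"
            )
        if not np.issubdtype(self.coords.dtype, np.integer):
            raise BagValidationError(f"coords must be integer-typed, got dtype {self.coords.dtype}")
        if (self.coords < 0).any():
            raise BagValidationError("coords entries must be >= 0")
        if len(np.unique(self.coords, axis=0)) != self.coords.shape[0]:
            raise BagValidationError("coords rows must be distinct (duplicate tile origin found)")
        if not (isinstance(self.tile_size_px, (int, np.integer)) and self.tile_size_px > 0):
            raise BagValidationError(f"tile_size_px must be a positive integer, got {self.tile_size_px}")
        if not (isinstance(self.stride_px, (int, np.integer)) and self.stride_px > 0):
            raise BagValidationError(f"stride_px must be a positive integer, got {self.stride_px}")
        if self.stride_px > self.tile_size_px:
            raise BagValidationError(
                f"stride_px ({self.stride_px}) must not exceed tile_size_px ({self.tile_size_px})"
            )
        if self.mpp is not None and not self.mpp > 0:
            raise BagValidationError(f"mpp must be positive, got {self.mpp}")


def write_bag(bag: TileBag, path: str) -> None:
    """Write a bag to an HDF5 file; ``read_bag(path)`` reproduces it bit-exactly.

    Embeddings are stored float32 (the canonical encoder output precision);
    callers that need float64 round-tripping should keep their own copy.
    """
    bag.validate()
    with h5py.File(path, "w") as f:
        f.create_dataset("embeddings", data=bag.embeddings.astype(np.float32, copy=False))
        f.create_dataset("coords", data=bag.coords.astype(np.int64, copy=False))
        f.attrs["sample_id"] = bag.sample_id
        f.attrs["donor_id"] = bag.donor_id
        f.attrs["tissue"] = bag.tissue
        f.attrs["tile_size_px"] = int(bag.tile_size_px)
        f.attrs["stride_px"] = int(bag.stride_px)
        if bag.mpp is not None:
            f.attrs["mpp"] = float(bag.mpp)


def read_bag(path: str) -> TileBag:
    """Read a bag written by :func:`write_bag`."""
    if not os.path.exists(path):
        raise BagFormatError(f"bag file does not exist: {path}")
    try:
        f = h5py.File(path, "r")
    except OSError as exc:
        raise BagFormatError(f"not a readable HDF5 bag file: {path} ({exc})") from exc
    with f:
        for name in ("embeddings", "coords"):
            if name not in f:
                raise BagFormatError(f"bag file {path} is missing the '{name}' dataset")
        for attr in ("sample_id", "donor_id", "tissue", "tile_size_px", "stride_px"):
            if attr not in f.attrs:
                raise BagFormatError(f"bag file {path} is missing the '{attr}' attribute")
        emb = np.asarray(f["embeddings"])
        coords = np.asarray(f["coords"])
        if emb.ndim != 2:
            raise BagFormatError(f"'embeddings' must be 2-D, got shape {emb.shape}")
        if coords.ndim != 2 or coords.shape != (emb.shape[0], 2):
            raise BagFormatError(
                f"'coords' must have shape ({emb.shape[0]}, 2), got {coords.shape}"
            )
        mpp = float(f.attrs["mpp"]) if "mpp" in f.attrs else None
        return TileBag(
            sample_id=str(f.attrs["sample_id"]),
            donor_id=str(f.attrs["donor_id"]),
            tissue=str(f.attrs["tissue"]),
            embeddings=emb,
            coords=coords,
            tile_size_px=int(f.attrs["tile_size_px"]),
            stride_px=int(f.attrs["stride_px"]),
            mpp=mpp,
        )


def base_grid_index(bag: TileBag) -> np.ndarray:
    """Map each tile onto the non-overlapping base grid.

    Returns a ``(K, 2)`` integer array of ``(row, col)`` cells where
    ``row = y // tile_size_px`` and ``col = x // tile_size_px``.  Pure
    function of ``coords`` and ``tile_size_px``: permuting tiles permutes
    rows identically.
    """
    t = bag.tile_size_px
    cols = bag.coords[:, 0] // t
    rows = bag.coords[:, 1] // t
    return np.stack([rows, cols], axis=1)


MANIFEST_COLUMNS = ["sample_id", "donor_id", "tissue", "bag_path"]


@dataclass
class CohortManifest:
    """Index of the bags making up a cohort.

    ``table`` has columns ``sample_id donor_id tissue bag_path`` and an
    optional ``split`` column.  ``validate`` enforces unique sample ids,
    existing bag files, a constant embedding dimension across the cohort and
    donor-disjoint splits.
    """

    table: pd.DataFrame
    root: str = "."
    _embed_dim: Optional[int] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in MANIFEST_COLUMNS if c not in self.table.columns]
        if missing:
            raise BagValidationError(f"manifest is missing columns: {missing}")
        if self.table["sample_id"].duplicated().any():
            dups = self.table.loc[self.table["sample_id"].duplicated(), "sample_id"].tolist()
            raise BagValidationError(f"duplicate sample_id in manifest: {dups}")
        if "split" in self.table.columns:
            per_donor = self.table.groupby("donor_id")["split"].nunique()
            bad = per_donor[per_donor > 1].index.tolist()
            if bad:
                raise BagValidationError(
                    f"donors appear under more than one split label: {bad}"
                )

    def bag_path(self, sample_id: str) -> str:
        row = self.table.loc[self.table["sample_id"] == sample_id]
        if row.empty:
            raise KeyError(f"sample_id not in manifest: {sample_id}")
        return os.path.join(self.root, row["bag_path"].iloc[0])

    def load_bag(self, sample_id: str) -> TileBag:
        bag = read_bag(self.bag_path(sample_id))
        if self._embed_dim is None:
            self._embed_dim = bag.embed_dim
        elif bag.embed_dim != self._embed_dim:
            raise BagValidationError(
                f"mixed embedding dimensions in cohort: sample {sample_id} has D={bag.embed_dim}, "
                f"expected D={self._embed_dim}"
            )
        return bag

    def validate(self, check_dims: bool = True) -> None:
        for _, row in self.table.iterrows():
            path = os.path.join(self.root, row["bag_path"])
            if not os.path.exists(path):
                raise BagValidationError(f"bag file missing for sample {row['sample_id']}: {path}")
        if check_dims:
            dims = set()
            for sid in self.table["sample_id"]:
                with h5py.File(self.bag_path(sid), "r") as f:
                    if "embeddings" not in f:
                        raise BagFormatError(f"bag for sample {sid} missing 'embeddings'")
                    dims.add(int(f["embeddings"].shape[1]))
            if len(dims) > 1:
                raise BagValidationError(f"mixed embedding dimensions in cohort: {sorted(dims)}")
            if dims:
                self._embed_dim = dims.pop()


def read_manifest(path: str, root: Optional[str] = None) -> CohortManifest:
    """Read a cohort manifest TSV. Relative ``bag_path`` entries resolve against
    ``root`` (default: the manifest's directory)."""
    table = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "donor_id": str})
    return CohortManifest(table=table, root=root if root is not None else os.path.dirname(path) or ".")


def write_manifest(manifest: CohortManifest, path: str) -> None:
    manifest.table.to_csv(path, sep="\t", index=False)
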