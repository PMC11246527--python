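"""RNAPath: multiple-instance regression of bulk gene expression from tile
embeddings, with spatial expression heatmaps.

The model is deliberately minimal so that tile-level predictions are
identifiable and interpretable: for a tile embedding ``x`` (D-dim) the score
of gene g is

    y_hat(p, g) = ReLU(w_g . x_p + b_g)                    (tile level)
    Y_hat(g)    = mean over tiles p of y_hat(p, g)         (sample level)

— a single linear layer, a ReLU to keep tile scores non-negative, and mean
pooling over the bag.  No hidden layers or nonlinearities precede the tile
score.  Training minimises the MSE between ``Y_hat`` and log2(TPM+1) bulk
expression with Adam, batch size 1, a decaying learning rate (start 1e-4),
bag dropout (keep a uniform-random 70-100% of tiles per visit), feature
dropout (p = 0.10, inverted scaling), genes processed in groups of at most
500 with gradients accumulated across groups and one update per sample, and
donor-disjoint 80:10:10 splits.  Because the model is a linear layer + ReLU
+ mean, its gradients have closed form and the trainer is plain NumPy:

    dL/dW[:,g] = dL/dY_hat(g) * (1/K) * X^T m_g,   m_g = 1[w_g.x + b_g > 0]

The returned model is the epoch checkpoint with minimum validation MSE.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .tile_bags import BagValidationError, TileBag, base_grid_index

__all__ = [
    "RNAPathModel",
    "TrainConfig",
    "SpatialPrediction",
    "preprocess_expression",
    "predict_tiles",
    "predict_sample",
    "split_by_donor",
    "train",
    "evaluate",
    "heatmap",
    "render_heatmap",
    "save_model",
    "load_model",
]


def preprocess_expression(tpm: pd.DataFrame, min_tpm: float = 10.0, min_frac: float = 0.05) -> pd.DataFrame:
    """Filter and log-transform a genes x samples TPM matrix.

    A gene is kept iff its TPM strictly exceeds ``min_tpm`` in at least
    ``ceil(min_frac * n_samples)`` samples; kept values become
    ``log2(TPM + 1)``.
    """
    values = tpm.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("TPM values must be non-negative")
    n = tpm.shape[1]
    need = math.ceil(min_frac * n)
    keep = (values > min_tpm).sum(axis=1) >= need
    return pd.DataFrame(
        np.log2(values[keep] + 1.0), index=tpm.index[keep], columns=tpm.columns
    )


@dataclass
class RNAPathModel:
    """Per-gene linear tile scorers: weights ``W`` (D x G) and biases ``b`` (G)."""

    W: np.ndarray
    b: np.ndarray
    gene_names: List[str]
    tissue: str = ""

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.W.ndim != 2 or self.b.shape != (self.W.shape[1],):
            raise ValueError(f"W must be D x G and b length G; got {self.W.shape}, {self.b.shape}")
        if len(self.gene_names) != self.W.shape[1]:
            raise ValueError("gene_names must have one entry per model gene")

    @property
    def embed_dim(self) -> int:
        return self.W.shape[0]

    @property
    def n_genes(self) -> int:
        return self.W.shape[1]


def _bag_embeddings(bag) -> np.ndarray:
    if isinstance(bag, TileBag):
        return np.asarray(bag.embeddings, dtype=float)
    return np.asarray(bag, dtype=float)


def predict_tiles(model: RNAPathModel, bag) -> np.ndarray:
    """Tile-level scores ``ReLU(X W + b)``: a K x G non-negative matrix."""
    X = _bag_embeddings(bag)
    if X.ndim != 2 or X.shape[1] != model.embed_dim:
        raise BagValidationError(
            f"bag embedding dimension {X.shape[1] if X.ndim == 2 else '?'} does not match "
            f"model D={model.embed_dim}"
        )
    return np.maximum(X @ model.W + model.b, 0.0)


def predict_sample(model: RNAPathModel, bag) -> np.ndarray:
    """Sample-level prediction: the arithmetic mean of tile scores (G-vector)."""
    scores = predict_tiles(model, bag)
    if scores.shape[0] < 1:
        raise ValueError("cannot predict from an empty bag")
    return scores.mean(axis=0)


@dataclass
class TrainConfig:
    """Training regime for the MIL regressor.

    ``lr_final_factor`` sets how far the exponential learning-rate schedule
    decays by ``max_epochs`` (default: to 10% of ``lr0``).
    """

    lr0: float = 1e-4
    scheduler: str = "exponential"
    lr_final_factor: float = 0.1
    max_epochs: int = 200
    batch_size: int = 1
    bag_keep_range: Tuple[float, float] = (0.70, 1.00)
    feature_dropout_p: float = 0.10
    gene_group_size: int = 500
    split_fracs: Tuple[float, float, float] = (0.8, 0.1, 0.1)
    seed: int = 0
    checkpoint_rule: str = "best_val"  # or "last"
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8

    def __post_init__(self) -> None:
        lo, hi = self.bag_keep_range
        if not 0.0 < lo <= hi <= 1.0:
            raise ValueError(f"bag_keep_range must satisfy 0 < lo <= hi <= 1, got {self.bag_keep_range}")
        if self.gene_group_size < 1:
            raise ValueError("gene_group_size must be >= 1")
        if not 0.0 <= self.feature_dropout_p < 1.0:
            raise ValueError("feature_dropout_p must be in [0, 1)")
        if abs(sum(self.split_fracs) - 1.0) > 1e-9:
            raise ValueError("split_fracs must sum to 1")
        if self.scheduler not in ("exponential", "constant"):
            raise ValueError(f"unknown scheduler: {self.scheduler}")
        if self.checkpoint_rule not in ("best_val", "last"):
            raise ValueError(f"unknown checkpoint_rule: {self.checkpoint_rule}")

    def lr_at(self, epoch: int) -> float:
        if self.scheduler == "constant":
            return self.lr0
        gamma = self.lr_final_factor ** (1.0 / max(self.max_epochs - 1, 1))
        return self.lr0 * gamma**epoch


def split_by_donor(
    donor_of: Dict[str, str],
    fracs: Tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> Dict[str, List[str]]:
    """Partition samples into donor-disjoint train/val/test splits.

    Donors are shuffled and cut at the cumulative fractions; every sample of
    a donor follows its donor, so no individual appears in two splits (bulk
    expression shares germline genetic effects across samples of one donor,
    which would otherwise leak between splits).
    """
    donors = sorted(set(donor_of.values()))
    rng = np.random.default_rng(seed)
    rng.shuffle(donors)
    n = len(donors)
    n_train = int(round(fracs[0] * n))
    n_val = int(round(fracs[1] * n))
    groups = {
        "train": set(donors[:n_train]),
        "val": set(donors[n_train : n_train + n_val]),
        "test": set(donors[n_train + n_val :]),
    }
    out = {name: [] for name in groups}
    for sid in sorted(donor_of):
        for name, ds in groups.items():
            if donor_of[sid] in ds:
                out[name].append(sid)
    assert_donor_disjoint(out, donor_of)
    return out


def assert_donor_disjoint(splits: Dict[str, List[str]], donor_of: Dict[str, str]) -> None:
    seen: Dict[str, str] = {}
    for name, sids in splits.items():
        for sid in sids:
            d = donor_of[sid]
            if d in seen and seen[d] != name:
                raise ValueError(f"donor {d} appears in splits '{seen[d]}' and '{name}'")
            seen[d] = name


def _sample_mse(model_W, model_b, X, y) -> float:
    pred = np.maximum(X @ model_W + model_b, 0.0).mean(axis=0)
    return float(np.mean((y - pred) ** 2))


def train(
    bags: Dict[str, np.ndarray],
    expression: pd.DataFrame,
    donor_of: Dict[str, str],
    config: Optional[TrainConfig] = None,
    gene_names: Optional[Sequence[str]] = None,
    splits: Optional[Dict[str, List[str]]] = None,
    tissue: str = "",
    verbose: bool = False,
) -> Tuple[RNAPathModel, Dict]:
    """Train the MIL regressor.

    Parameters
    ----------
    bags
        Mapping sample_id -> K x D embedding matrix (or TileBag).
    expression
        genes x samples matrix of log2(TPM+1) targets; every training sample
        must have a value for every model gene.
    donor_of
        sample_id -> donor_id, for split hygiene.
    config
        Training regime; defaults to the standard one (see
        :class:`TrainConfig`).
    splits
        Optional precomputed {"train": [...], "val": [...], "test": [...]};
        donor-disjointness is asserted either way.

    Returns
    -------
    (model, history)
        The checkpoint selected by ``config.checkpoint_rule`` and a history
        dict with per-epoch train/val MSE, the splits and the lr schedule.

    Notes
    -----
    Weights start at zero with biases at the per-gene mean of the training
    targets, so initial tile scores are positive and the ReLU passes
    gradients everywhere from the first step.
    """
    config = config or TrainConfig()
    X_of = {sid: _bag_embeddings(b) for sid, b in bags.items()}
    gene_names = list(gene_names) if gene_names is not None else list(expression.index)
    missing = [g for g in gene_names if g not in expression.index]
    if missing:
        raise ValueError(f"genes missing from expression: {missing[:5]}")
    if splits is None:
        splits = split_by_donor(
            {sid: donor_of[sid] for sid in X_of}, config.split_fracs, seed=config.seed
        )
    else:
        assert_donor_disjoint(splits, donor_of)
    for name in ("train", "val", "test"):
        for sid in splits.get(name, []):
            if sid not in expression.columns:
                raise ValueError(f"sample {sid} has no expression column")
    train_ids = splits["train"]
    val_ids = splits.get("val", [])
    if not train_ids:
        raise ValueError("empty training split")
    Y = expression.loc[gene_names]
    d = next(iter(X_of.values())).shape[1]
    g = len(gene_names)

    W = np.zeros((d, g))
    b = Y[train_ids].mean(axis=1).to_numpy(dtype=float).copy()
    mW = np.zeros_like(W)
    vW = np.zeros_like(W)
    mb = np.zeros_like(b)
    vb = np.zeros_like(b)
    t_step = 0
    rng = np.random.default_rng(config.seed)
    groups = [
        slice(s, min(s + config.gene_group_size, g)) for s in range(0, g, config.gene_group_size)
    ]

    def full_mse(ids: Sequence[str], Wc, bc) -> float:
        if not ids:
            return float("nan")
        return float(
            np.mean([_sample_mse(Wc, bc, X_of[sid], Y[sid].to_numpy(dtype=float)) for sid in ids])
        )

    history = {"train_mse": [], "val_mse": [], "lr": [], "splits": splits}
    best_val = np.inf
    best = (W.copy(), b.copy())
    keep_lo, keep_hi = config.bag_keep_range
    p_drop = config.feature_dropout_p

    for epoch in range(config.max_epochs):
        lr = config.lr_at(epoch)
        order = rng.permutation(len(train_ids))
        for si in order:
            sid = train_ids[si]
            X = X_of[sid]
            k = X.shape[0]
            # bag dropout: keep a uniform-random fraction of tiles per visit
            keep = max(1, int(round(rng.uniform(keep_lo, keep_hi) * k)))
            idx = rng.choice(k, size=keep, replace=False) if keep < k else np.arange(k)
            Xs = X[idx]
            if p_drop > 0:
                mask = rng.random(Xs.shape) >= p_drop
                Xs = Xs * mask / (1.0 - p_drop)  # inverted scaling keeps E[X] fixed
            y = Y[sid].to_numpy(dtype=float)
            gW = np.zeros_like(W)
            gb = np.zeros_like(b)
            # gene groups: accumulate gradients, one optimiser update per sample.
            # Each group contributes its genes' share of the full-MSE gradient
            # (2/G per gene), so grouping is purely a memory detail: any group
            # size reproduces the ungrouped gradient exactly.
            for grp in groups:
                S = Xs @ W[:, grp] + b[grp]
                relu_mask = S > 0
                pred = np.where(relu_mask, S, 0.0).mean(axis=0)
                err = pred - y[grp]
                dpred = (2.0 / g) * err
                dS = relu_mask * (dpred[None, :] / Xs.shape[0])
                gW[:, grp] = Xs.T @ dS
                gb[grp] = dS.sum(axis=0)
            t_step += 1
            b1, b2, eps = config.adam_beta1, config.adam_beta2, config.adam_eps
            mW = b1 * mW + (1 - b1) * gW
            vW = b2 * vW + (1 - b2) * gW**2
            mb = b1 * mb + (1 - b1) * gb
            vb = b2 * vb + (1 - b2) * gb**2
            bc1 = 1 - b1**t_step
            bc2 = 1 - b2**t_step
            W -= lr * (mW / bc1) / (np.sqrt(vW / bc2) + eps)
            b -= lr * (mb / bc1) / (np.sqrt(vb / bc2) + eps)
        tr = full_mse(train_ids, W, b)
        va = full_mse(val_ids, W, b)
        history["train_mse"].append(tr)
        history["val_mse"].append(va)
        history["lr"].append(lr)
        if verbose:
            import sys

            print(f"epoch {epoch + 1}/{config.max_epochs} train_mse={tr:.6f} val_mse={va:.6f}", file=sys.stderr)
        if val_ids and va < best_val:
            best_val = va
            best = (W.copy(), b.copy())
    if config.checkpoint_rule == "best_val" and val_ids:
        W, b = best
    model = RNAPathModel(W=W, b=b, gene_names=gene_names, tissue=tissue)
    history["best_val_mse"] = best_val if val_ids else None
    return model, history


def evaluate(
    model: RNAPathModel,
    bags: Dict[str, np.ndarray],
    expression: pd.DataFrame,
    sample_ids: Sequence[str],
) -> pd.DataFrame:
    """Per-gene Pearson r between predicted and measured expression.

    Needs at least 3 samples.  Genes whose predictions (or targets) have zero
    variance across samples get ``r = NaN`` with ``defined = False`` rather
    than a silent 0.  The summary median is over defined genes;
    ``result.attrs["median_r"]``.
    """
    sample_ids = list(sample_ids)
    if len(sample_ids) < 3:
        raise ValueError(f"need >= 3 samples to evaluate, got {len(sample_ids)}")
    preds = np.stack([predict_sample(model, bags[sid]) for sid in sample_ids], axis=1)  # G x n
    truth = expression.loc[model.gene_names, sample_ids].to_numpy(dtype=float)
    pv = preds.var(axis=1)
    tv = truth.var(axis=1)
    defined = (pv > 0) & (tv > 0)
    pc = preds - preds.mean(axis=1, keepdims=True)
    tc = truth - truth.mean(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (pc * tc).sum(axis=1) / np.sqrt((pc**2).sum(axis=1) * (tc**2).sum(axis=1))
    r = np.where(defined, r, np.nan)
    out = pd.DataFrame({"r": r, "defined": defined}, index=model.gene_names)
    out.attrs["median_r"] = float(np.nanmedian(r)) if defined.any() else float("nan")
    out.attrs["n_samples"] = len(sample_ids)
    return out


@dataclass
class SpatialPrediction:
    """A gene's tile scores rasterised onto the base grid.

    ``values[r, c]`` is the mean post-ReLU tile score of all tiles covering
    the cell (NaN where coverage is 0); ``coverage`` counts covering tiles.
    """

    values: np.ndarray
    coverage: np.ndarray
    gene: str
    sample_id: str = ""


def heatmap(model: RNAPathModel, bag: TileBag, gene: str) -> SpatialPrediction:
    """Fine-grained spatial expression map for one gene.

    Designed for bags tiled with overlap (stride = tile_size/4 gives the
    standard 75% overlap); every base-grid cell averages the tile scores of
    all overlapping tiles whose footprint covers it.  With a non-overlapping
    bag this reduces to the tile scores laid out on the grid.
    """
    if gene not in model.gene_names:
        raise KeyError(f"gene '{gene}' not in model")
    gi = model.gene_names.index(gene)
    scores = predict_tiles(model, bag)[:, gi]
    t = bag.tile_size_px
    x, y = bag.coords[:, 0], bag.coords[:, 1]
    r0, r1 = y // t, (y + t - 1) // t
    c0, c1 = x // t, (x + t - 1) // t
    rows = int(r1.max()) + 1
    cols = int(c1.max()) + 1
    total = np.zeros((rows, cols))
    count = np.zeros((rows, cols), dtype=np.int64)
    for i in range(scores.size):
        total[r0[i] : r1[i] + 1, c0[i] : c1[i] + 1] += scores[i]
        count[r0[i] : r1[i] + 1, c0[i] : c1[i] + 1] += 1
    with np.errstate(invalid="ignore"):
        values = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    return SpatialPrediction(values=values, coverage=count, gene=gene, sample_id=bag.sample_id)


def render_heatmap(sp: SpatialPrediction, path: str, dpi: int = 150) -> None:
    """Render a spatial prediction to an image (high = red, low = blue)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    im = ax.imshow(sp.values, cmap="RdBu_r", interpolation="nearest")
    fig.colorbar(im, ax=ax, label=f"predicted score: {sp.gene}")
    ax.set_title(sp.sample_id or sp.gene)
    ax.set_xlabel("base-grid column")
    ax.set_ylabel("base-grid row")
    fig.savefig(path, dpi=dpi, bbox_inches="tight")
    plt.close(fig)


def save_model(model: RNAPathModel, path: str) -> None:
    """Save a model to a single ``.npz`` archive."""
    np.savez(
        path,
        W=model.W,
        b=model.b,
        meta=json.dumps({"gene_names": model.gene_names, "tissue": model.tissue}),
    )


def load_model(path: str) -> RNAPathModel:
    with np.load(path, allow_pickle=False) as f:
        meta = json.loads(str(f["meta"]))
        return RNAPathModel(W=f["W"], b=f["b"], gene_names=meta["gene_names"], tissue=meta["tissue"])
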