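"""Compositional phenotype statistics.

Substructure and pathology proportions per sample sum to one, so they live
on the simplex and cannot be analysed with ordinary linear models directly.
This module provides the pivot-coordinate (a specific orthonormal isometric
log-ratio) transform whose first coordinate carries one chosen part's
relative dominance, multiplicative zero replacement, covariate association
with Bonferroni adjustment, per-gene differential expression against a
pivot-coordinate phenotype with Benjamini-Hochberg FDR control, and the
single-gene genotype-by-phenotype interaction model

    Y = I + b1*G + b2*P + b3*P*G + eps

where G is genotype dosage, P the (pivot-coordinate) phenotype and b3 the
interaction effect of interest.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "Composition",
    "InteractionResult",
    "zero_replace",
    "pivot_coordinates",
    "pivot_phenotype",
    "associate_covariates",
    "differential_expression",
    "interaction_eqtl",
]


@dataclass
class Composition:
    """A vector of named parts on the simplex (sums to 1)."""

    parts: np.ndarray
    names: List[str]

    def __post_init__(self) -> None:
        self.parts = np.asarray(self.parts, dtype=float)
        if self.parts.ndim != 1 or self.parts.size < 2:
            raise ValueError("a composition needs at least 2 parts")
        if len(self.names) != self.parts.size:
            raise ValueError("names must match parts")
        if (self.parts < 0).any() or (self.parts > 1).any():
            raise ValueError("parts must lie in [0, 1]")
        if abs(self.parts.sum() - 1.0) > 1e-9:
            raise ValueError(f"parts must sum to 1 (got {self.parts.sum():.12f})")


def zero_replace(c: Composition, delta: float) -> Composition:
    """Multiplicative zero replacement.

    Zero parts are set to ``delta``; nonzero parts are scaled by
    ``1 - z*delta`` (z = number of zeros), preserving their ratios and the
    unit sum.  ``delta`` must be below the smallest nonzero part; a sensible
    default for tile-count compositions is ``0.65 / total_tiles`` (below the
    smallest observable nonzero proportion).
    """
    parts = c.parts
    zero = parts == 0.0
    if not zero.any():
        return Composition(parts=parts.copy(), names=list(c.names))
    if not 0.0 < delta < parts[~zero].min():
        raise ValueError(
            f"delta must lie in (0, min nonzero part = {parts[~zero].min():.6g}), got {delta}"
        )
    z = int(zero.sum())
    out = parts * (1.0 - z * delta)
    out[zero] = delta
    return Composition(parts=out, names=list(c.names))


def pivot_coordinates(c, pivot_part: int = 0) -> np.ndarray:
    """Pivot (isometric log-ratio) coordinates with the chosen part first.

    The parts are cyclically rotated so ``pivot_part`` sits in position 1;
    coordinate j (1-based, D parts) is

        z_j = sqrt((D-j)/(D-j+1)) * ln( x_j / gmean(x_{j+1}, ..., x_D) )

    The first coordinate isolates the pivot part's dominance relative to the
    geometric mean of everything else and is the standard univariate
    phenotype for that part.  Requires strictly positive parts (apply
    :func:`zero_replace` first).  The map is an isometry: the Euclidean norm
    of the coordinates equals the norm of the centred-log-ratio vector.
    """
    parts = c.parts if isinstance(c, Composition) else np.asarray(c, dtype=float)
    d = parts.size
    if not 0 <= pivot_part < d:
        raise IndexError(f"pivot_part must index the {d} parts, got {pivot_part}")
    if (parts <= 0).any():
        raise ValueError("pivot coordinates need strictly positive parts; use zero_replace first")
    x = np.roll(parts, -pivot_part)
    logx = np.log(x)
    z = np.empty(d - 1)
    for j in range(1, d):
        tail_gmean_log = logx[j:].mean()
        z[j - 1] = np.sqrt((d - j) / (d - j + 1.0)) * (logx[j - 1] - tail_gmean_log)
    return z


def pivot_phenotype(
    compositions: pd.DataFrame,
    part: str,
    total_tiles: Optional[pd.Series] = None,
    delta: Optional[float] = None,
) -> pd.Series:
    """First pivot coordinate of ``part`` for every sample.

    ``compositions`` is samples x parts (rows sum to 1).  Zeros are handled
    by multiplicative replacement with ``delta = 0.65 / total_tiles`` per
    sample (or a fixed ``delta``); samples with no ``total_tiles`` entry fall
    back to 0.65 / (number of parts * 1000).
    """
    if part not in compositions.columns:
        raise KeyError(f"part '{part}' not in composition columns: {list(compositions.columns)}")
    pivot_idx = list(compositions.columns).index(part)
    names = list(compositions.columns)
    out = {}
    for sid, row in compositions.iterrows():
        comp = Composition(parts=row.to_numpy(dtype=float), names=names)
        if (comp.parts == 0).any():
            if delta is not None:
                d = delta
            elif total_tiles is not None:
                d = 0.65 / float(total_tiles.loc[sid])
            else:
                d = 0.65 / (len(names) * 1000.0)
            comp = zero_replace(comp, d)
        out[sid] = pivot_coordinates(comp, pivot_part=pivot_idx)[0]
    return pd.Series(out, name=f"pivot[{part}]")


def _check_full_rank(X: np.ndarray, names: Sequence[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify columns involved in the deficiency by greedy elimination
        keep, dropped = [], []
        for j in range(X.shape[1]):
            trial = X[:, keep + [j]]
            if np.linalg.matrix_rank(trial) == len(keep) + 1:
                keep.append(j)
            else:
                dropped.append(names[j])
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]}); "
            f"collinear columns: {dropped}"
        )


def associate_covariates(
    phenotype: pd.Series,
    covariates: pd.DataFrame,
    targets: Optional[Sequence[str]] = None,
    adjust: str = "bonferroni",
    n_tests: Optional[int] = None,
) -> pd.DataFrame:
    """OLS of a phenotype on covariates, with multiplicity adjustment.

    Fits ``phenotype ~ 1 + covariates`` once; for each target covariate
    reports its coefficient conditional on all others, its standard error,
    the two-sided t-test p-value, and the adjusted p-value (Bonferroni by
    default, across ``n_tests`` tests — default: the number of targets).

    Returns a DataFrame with columns ``target beta se p p_adj`` and the
    adjustment method in ``.attrs["adjust"]``.
    """
    common = phenotype.index.intersection(covariates.index)
    if len(common) != len(phenotype) or len(common) != len(covariates):
        phenotype = phenotype.loc[common]
        covariates = covariates.loc[common]
    n = len(phenotype)
    if n <= covariates.shape[1] + 2:
        raise ValueError(f"need n > n_covariates + 2 (n={n}, covariates={covariates.shape[1]})")
    X = sm.add_constant(covariates.astype(float), has_constant="add")
    _check_full_rank(X.to_numpy(), list(X.columns))
    fit = sm.OLS(phenotype.astype(float), X).fit()
    targets = list(targets) if targets is not None else list(covariates.columns)
    m = n_tests if n_tests is not None else len(targets)
    rows = []
    for t in targets:
        if t not in X.columns:
            raise KeyError(f"target covariate '{t}' not in design")
        p = float(fit.pvalues[t])
        if adjust == "bonferroni":
            p_adj = min(1.0, p * m)
        elif adjust == "none":
            p_adj = p
        else:
            raise ValueError(f"unsupported adjustment: {adjust}")
        rows.append((t, float(fit.params[t]), float(fit.bse[t]), p, p_adj))
    out = pd.DataFrame(rows, columns=["target", "beta", "se", "p", "p_adj"])
    out.attrs["adjust"] = adjust
    out.attrs["n_tests"] = m
    return out


def differential_expression(
    expression: pd.DataFrame,
    phenotype: pd.Series,
    covariates: Optional[pd.DataFrame] = None,
    fdr_level: float = 0.01,
) -> pd.DataFrame:
    """Per-gene OLS of log-scale expression on a compositional phenotype.

    ``expression`` is genes x samples on the log2(x+1) scale; for every gene
    an OLS fit ``expr ~ 1 + phenotype + covariates`` is computed (all genes
    share one design matrix, so the fits are vectorised through the normal
    equations) and the phenotype coefficient is tested two-sided.
    Benjamini-Hochberg step-up controls the FDR at ``fdr_level`` (1% by
    default).

    Returns a DataFrame indexed by gene with columns
    ``beta se p p_adj significant``, sorted by p.
    """
    samples = list(expression.columns)
    if not phenotype.index.isin(samples).all() or len(phenotype) != len(samples):
        raise ValueError("phenotype samples do not match expression columns")
    cols = [np.ones(len(samples)), phenotype.loc[samples].to_numpy(dtype=float)]
    names = ["const", "phenotype"]
    if covariates is not None:
        if not covariates.index.isin(samples).all() or len(covariates) != len(samples):
            raise ValueError("covariate samples do not match expression columns")
        cov = covariates.loc[samples].astype(float)
        cols.extend(cov[c].to_numpy() for c in cov.columns)
        names.extend(cov.columns)
    X = np.column_stack(cols)
    _check_full_rank(X, names)
    Y = expression.to_numpy(dtype=float).T  # samples x genes
    n, p = X.shape
    xtx_inv = np.linalg.inv(X.T @ X)
    beta_all = xtx_inv @ X.T @ Y  # p x genes
    resid = Y - X @ beta_all
    dof = n - p
    sigma2 = (resid**2).sum(axis=0) / dof
    se_pheno = np.sqrt(sigma2 * xtx_inv[1, 1])
    beta = beta_all[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = beta / se_pheno
    pvals = 2.0 * stats.t.sf(np.abs(tval), dof)
    pvals = np.where(np.isfinite(pvals), pvals, 1.0)
    reject, p_adj, _, _ = multipletests(pvals, alpha=fdr_level, method="fdr_bh")
    out = pd.DataFrame(
        {"beta": beta, "se": se_pheno, "p": pvals, "p_adj": p_adj, "significant": reject},
        index=expression.index,
    ).sort_values("p")
    out.attrs["adjust"] = "fdr_bh"
    out.attrs["fdr_level"] = fdr_level
    return out


@dataclass
class InteractionResult:
    """Fit of the genotype-by-phenotype interaction model."""

    intercept: float
    beta1: float  # genotype main effect
    beta2: float  # phenotype main effect
    beta3: float  # interaction (the eQTL-by-phenotype effect of interest)
    se: pd.Series  # for const, G, P, GxP
    pvalues: pd.Series
    residuals: np.ndarray
    n: int


def interaction_eqtl(
    y: pd.Series,
    genotype: pd.Series,
    phenotype: pd.Series,
    covariates: Optional[pd.DataFrame] = None,
    center: bool = False,
) -> InteractionResult:
    """Fit ``Y = I + b1*G + b2*P + b3*P*G (+ covariates) + eps`` by OLS.

    ``b3`` and its two-sided p-value are the interaction-eQTL result.  With
    ``center=True`` G and P are mean-centred before forming the product term
    (the model as written uses raw G and P).
    """
    common = y.index.intersection(genotype.index).intersection(phenotype.index)
    if covariates is not None:
        common = common.intersection(covariates.index)
    if len(common) == 0:
        raise ValueError(
            "expression, genotype and phenotype share no sample ids; "
            "map donor-level dosages to samples first"
        )
    y = y.loc[common].astype(float)
    g = genotype.loc[common].astype(float)
    p = phenotype.loc[common].astype(float)
    if g.nunique() < 2:
        raise np.linalg.LinAlgError("genotype is constant: design is rank deficient")
    if p.nunique() < 2:
        raise np.linalg.LinAlgError("phenotype is constant: design is rank deficient")
    if center:
        g = g - g.mean()
        p = p - p.mean()
    data = {"G": g, "P": p, "GxP": g * p}
    if covariates is not None:
        for c in covariates.columns:
            data[c] = covariates.loc[common, c].astype(float)
    X = sm.add_constant(pd.DataFrame(data), has_constant="add")
    _check_full_rank(X.to_numpy(), list(X.columns))
    fit = sm.OLS(y, X).fit()
    return InteractionResult(
        intercept=float(fit.params["const"]),
        beta1=float(fit.params["G"]),
        beta2=float(fit.params["P"]),
        beta3=float(fit.params["GxP"]),
        se=fit.bse[["const", "G", "P", "GxP"]],
        pvalues=fit.pvalues[["const", "G", "P", "GxP"]],
        residuals=np.asarray(fit.resid),
        n=len(y),
    )
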