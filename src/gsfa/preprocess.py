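"""UMI counts -> model input Y: deviance residuals, gene selection, covariate
regression and per-gene scaling.

The transformation treats each gene's counts as binomial draws out of the
cell's total, under a null of constant expression proportion pooled across
cells.  The signed square root of each cell/gene deviance contribution is a
variance-stabilized, z-score-like quantity suited to factor analysis of
sparse counts; the per-gene total deviance doubles as a feature-selection
statistic.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .io import CountMatrix, DataError

__all__ = [
    "ResidualMatrix",
    "deviance_residuals",
    "deviance_statistic",
    "select_top_genes",
    "regress_out",
    "center_scale",
    "preprocess_counts",
]


@dataclass
class ResidualMatrix:
    """Cells x genes real matrix carrying transform metadata."""

    Y: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    null_proportion: np.ndarray | None = None  # per-gene pooled pi-hat
    cell_totals: np.ndarray | None = None
    history: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=float)
        if not np.all(np.isfinite(self.Y)):
            raise DataError("residual matrix contains non-finite entries")
        if self.Y.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise DataError("residual matrix shape inconsistent with ids")

    @property
    def shape(self) -> tuple[int, int]:
        return self.Y.shape

    def _replace(self, Y: np.ndarray, step: str, gene_idx=None) -> "ResidualMatrix":
        genes = (
            list(self.gene_ids)
            if gene_idx is None
            else [self.gene_ids[j] for j in gene_idx]
        )
        pi = self.null_proportion
        if pi is not None and gene_idx is not None:
            pi = pi[gene_idx]
        return ResidualMatrix(
            Y,
            genes,
            list(self.cell_ids),
            null_proportion=pi,
            cell_totals=self.cell_totals,
            history=self.history + [step],
        )


def _binomial_deviance(y: np.ndarray, n: np.ndarray, pi: np.ndarray) -> np.ndarray:
    """Per-entry binomial deviance 2y log(y/npi) + 2(n-y) log((n-y)/(n-npi)).

    Uses the 0*log(0/x) == 0 convention and a log1p form for the (n-y) term,
    which stays accurate when counts are a tiny fraction of the cell total.
    """
    y = y.astype(float)
    mu = n * pi  # expected counts, cells x genes
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(y > 0, 2.0 * y * np.log(np.where(y > 0, y, 1.0) / mu), 0.0)
    n_minus = n - y
    denom = n - mu
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = (mu - y) / denom
        t2 = np.where(n_minus > 0, 2.0 * n_minus * np.log1p(ratio), 0.0)
    d = t1 + t2
    d = np.where(mu == 0, 0.0, d)  # all-zero gene: pi-hat = 0 -> deviance 0
    return np.maximum(d, 0.0)  # clamp roundoff


def deviance_residuals(counts: CountMatrix) -> ResidualMatrix:
    """Signed square-root binomial deviance residuals of UMI counts.

    r_ij = sign(y_ij - n_i pi_j) sqrt(d_ij), with n_i the cell total and
    pi_j the pooled expression proportion of gene j.
    """
    y = counts.counts
    n = y.sum(axis=1, keepdims=True).astype(float)
    if np.any(n == 0):
        bad = [counts.cell_ids[i] for i in np.flatnonzero(n[:, 0] == 0)[:5]]
        raise DataError(f"cells with zero total count: {bad}")
    pi = y.sum(axis=0, keepdims=True) / n.sum()
    d = _binomial_deviance(y, n, pi)
    r = np.sign(y - n * pi) * np.sqrt(d)
    return ResidualMatrix(
        r,
        list(counts.gene_ids),
        list(counts.cell_ids),
        null_proportion=pi.ravel(),
        cell_totals=n.ravel(),
        history=["deviance_residuals"],
    )


def deviance_statistic(counts: CountMatrix) -> np.ndarray:
    """Per-gene total binomial deviance (the gene-ranking score)."""
    r = deviance_residuals(counts)
    return np.einsum("ij,ij->j", r.Y, r.Y)


def select_top_genes(
    residuals: ResidualMatrix, stats: np.ndarray, n_top: int
) -> ResidualMatrix:
    """Keep the n_top genes with the highest deviance statistic.

    Ties broken by input gene order (stable sort).
    """
    if n_top <= 0:
        raise ValueError("n_top must be positive")
    if n_top > residuals.Y.shape[1]:
        raise ValueError("n_top exceeds the number of genes")
    order = np.argsort(-np.asarray(stats), kind="stable")[:n_top]
    keep = np.sort(order)  # preserve original column order
    return residuals._replace(residuals.Y[:, keep], f"top_{n_top}", gene_idx=keep)


def regress_out(residuals: ResidualMatrix, covariates: np.ndarray) -> ResidualMatrix:
    """Replace each gene column by its OLS residual against [1, covariates]."""
    C = np.atleast_2d(np.asarray(covariates, dtype=float))
    if C.shape[0] != residuals.Y.shape[0]:
        raise DataError("covariate rows do not match cell count")
    X = np.column_stack([np.ones(C.shape[0]), C])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, _, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
        dropped = sorted(piv[rank:])
        names = ["intercept"] + [f"covariate {j}" for j in range(C.shape[1])]
        raise DataError(
            "collinear covariate design; redundant columns: "
            + ", ".join(names[j] for j in dropped)
        )
    coef, *_ = np.linalg.lstsq(X, residuals.Y, rcond=None)
    return residuals._replace(residuals.Y - X @ coef, "regress_out")


def center_scale(residuals: ResidualMatrix) -> ResidualMatrix:
    """Center each gene to mean 0 and scale to sample variance 1."""
    Y = residuals.Y
    mu = Y.mean(axis=0)
    sd = Y.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise DataError(
            "zero-variance genes (drop them before scaling): "
            + ", ".join(residuals.gene_ids[j] for j in zero[:10])
        )
    return residuals._replace((Y - mu) / sd, "center_scale")


def preprocess_counts(
    counts: CountMatrix,
    n_top_genes: int | None = None,
    covariates: np.ndarray | None = None,
) -> ResidualMatrix:
    """Full chain: deviance residuals -> top genes -> covariates -> scaling.

    Genes whose residual column is constant (e.g. all-zero genes) are dropped
    before scaling.
    """
    res = deviance_residuals(counts)
    stats = np.einsum("ij,ij->j", res.Y, res.Y)
    if n_top_genes is not None:
        res = select_top_genes(res, stats, n_top_genes)
    if covariates is not None:
        res = regress_out(res, covariates)
    sd = res.Y.std(axis=0, ddof=1)
    keep = np.flatnonzero(sd > 0)
    if keep.size < res.Y.shape[1]:
        res = res._replace(res.Y[:, keep], "drop_constant", gene_idx=keep)
    return center_scale(res)
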