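"""Guided sparse factor model: a two-layer Bayesian model linking genetic
perturbations to latent gene modules and, through them, to genes.

The model class follows the data-in / fit / results-out convention: build a
:class:`GuidedSparseFactorModel` from a preprocessed expression matrix and a
binary perturbation matrix, call :meth:`~GuidedSparseFactorModel.fit` to run
the Gibbs sampler, and work with the returned :class:`~gsfa.results.GSFAResults`.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import _gibbs
from ._gibbs import GibbsState, Hyperpriors
from .io import CountMatrix, PerturbationMatrix, CellMetadata, DataError
from .preprocess import preprocess_counts

logger = logging.getLogger(__name__)

__all__ = ["ModelConfig", "GuidedSparseFactorModel", "scan_num_factors"]


@dataclass
class ModelConfig:
    """Sampler and prior configuration.

    Parameters
    ----------
    n_factors
        Number of latent factors K (1 <= K < min(N, P)).
    prior_type
        Loading prior: ``normal_mixture`` (default; background component is a
        narrow normal) or ``spike_slab`` (background is a point mass at 0).
    c
        Foreground/background scale ratio c_k of the normal-mixture prior,
        fixed in (0, 1).
    pi_beta, p_beta
        Beta hyperprior (a, b) on the per-factor loading density pi_k and the
        per-perturbation effect density p_m; ``None`` defaults to (1, K).
    sigma2_ig, d2_ig, psi_ig
        Inverse-gamma (shape, rate) hyperpriors on the loading slab variance,
        effect slab variance and residual variances.
    """

    n_factors: int
    prior_type: str = "normal_mixture"
    c: float = 0.25
    pi_beta: tuple[float, float] | None = None
    p_beta: tuple[float, float] | None = None
    sigma2_ig: tuple[float, float] = (2.0, 1.0)
    d2_ig: tuple[float, float] = (2.0, 1.0)
    psi_ig: tuple[float, float] = (2.0, 1.0)

    def __post_init__(self) -> None:
        if self.n_factors < 1:
            raise ValueError("n_factors must be >= 1")
        if not 0.0 < self.c < 1.0:
            raise ValueError("c must be in (0, 1)")
        if self.prior_type not in ("normal_mixture", "spike_slab"):
            raise ValueError(f"unknown prior_type {self.prior_type!r}")

    def hyperpriors(self) -> Hyperpriors:
        K = self.n_factors
        return Hyperpriors(
            pi_beta=self.pi_beta or (1.0, float(K)),
            p_beta=self.p_beta or (1.0, float(K)),
            sigma2_ig=self.sigma2_ig,
            d2_ig=self.d2_ig,
            psi_ig=self.psi_ig,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["pi_beta"] = self.pi_beta or (1.0, float(self.n_factors))
        d["p_beta"] = self.p_beta or (1.0, float(self.n_factors))
        return d


class GuidedSparseFactorModel:
    """Two-layer Bayesian sparse factor model for perturbation screens.

    Y = Z W' + E with gene-specific residual variances, and Z = G beta + Phi,
    so the perturbations act as a prior that guides the factors.  Sparsity on
    the loadings W uses a two-component normal mixture (or spike-and-slab);
    sparsity on the perturbation effects beta uses a spike-and-slab.

    Parameters
    ----------
    Y
        Cells x genes real matrix, each gene centered and scaled to unit
        variance (see :func:`gsfa.preprocess.preprocess_counts`).
    G
        Cells x perturbations binary matrix (or :class:`PerturbationMatrix`).
    n_factors
        Number of latent factors K.
    groups
        Optional per-cell binary labels; when given, perturbation effects are
        estimated separately within each group (shared factors and loadings).
    """

    def __init__(
        self,
        Y: np.ndarray,
        G: np.ndarray | PerturbationMatrix,
        n_factors: int,
        *,
        groups: np.ndarray | None = None,
        perturbation_names: list[str] | None = None,
        gene_ids: list[str] | None = None,
        negative_control: int | str | None = None,
        config: ModelConfig | None = None,
        **config_kwargs,
    ) -> None:
        if isinstance(G, PerturbationMatrix):
            perturbation_names = perturbation_names or list(G.perturbation_names)
            if negative_control is None and G.negative_control_index is not None:
                negative_control = G.negative_control_index
            G = G.G
        self.Y = np.asarray(Y, dtype=float)
        self.G = np.asarray(G)
        if self.Y.ndim != 2 or self.G.ndim != 2:
            raise DataError("Y and G must be 2-dimensional")
        if self.Y.shape[0] != self.G.shape[0]:
            raise DataError("Y and G disagree on the number of cells")
        if not np.all(np.isfinite(self.Y)):
            raise DataError("Y contains NaN or infinite entries")
        if not np.isin(self.G, (0, 1)).all():
            raise DataError("G must be binary")
        N, P = self.Y.shape
        if config is None:
            config = ModelConfig(n_factors=n_factors, **config_kwargs)
        if not config.n_factors < min(N, P):
            raise ValueError("n_factors must be < min(n_cells, n_genes)")
        self.config = config
        self.n_cells, self.n_genes = N, P
        self.n_perturbations = self.G.shape[1]
        self.perturbation_names = perturbation_names or [
            f"perturbation_{m}" for m in range(self.n_perturbations)
        ]
        self.gene_ids = gene_ids or [f"gene_{j}" for j in range(P)]
        if isinstance(negative_control, str):
            negative_control = self.perturbation_names.index(negative_control)
        self.negative_control_index = negative_control
        if groups is not None:
            groups = np.asarray(groups)
            if groups.shape[0] != N:
                raise DataError("groups length does not match the cell count")
            if not np.isin(groups, (0, 1)).all():
                raise DataError("groups must be binary labels")
        self.groups = groups

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_counts(
        cls,
        counts: CountMatrix,
        guides: PerturbationMatrix,
        n_factors: int,
        *,
        meta: CellMetadata | None = None,
        n_top_genes: int | None = None,
        **kwargs,
    ) -> "GuidedSparseFactorModel":
        """Build the model from raw UMI counts via the deviance-residual chain."""
        from .io import align

        counts, guides, meta = align(counts, guides, meta)
        guides.check_fittable()
        covariates = meta.covariates if meta is not None else None
        res = preprocess_counts(counts, n_top_genes=n_top_genes, covariates=covariates)
        groups = meta.group if meta is not None else None
        return cls(
            res.Y,
            guides,
            n_factors,
            groups=groups,
            gene_ids=list(res.gene_ids),
            **kwargs,
        )

    # -- initialization -----------------------------------------------------

    @property
    def _group_rows(self) -> list[np.ndarray]:
        if self.groups is None:
            return [np.arange(self.n_cells)]
        return [np.flatnonzero(self.groups == g) for g in (0, 1)]

    @property
    def n_groups(self) -> int:
        return 1 if self.groups is None else 2

    def init_state(self, seed: int = 0) -> GibbsState:
        """Deterministic initial state from a rank-K truncated SVD of Y.

        Z = U_K S_K and W = V_K, indicators at 1, beta from least squares of
        Z on G, psi = 1 and hyperparameters at their prior means.
        """
        K = self.config.n_factors
        U, s, Vt = np.linalg.svd(self.Y, full_matrices=False)
        Z = U[:, :K] * s[:K]
        W = Vt[:K].T.copy()
        M = self.n_perturbations
        beta = np.zeros((self.n_groups, M, K))
        for g, rows in enumerate(self._group_rows):
            if rows.size:
                beta[g], *_ = np.linalg.lstsq(
                    self.G[rows].astype(float), Z[rows], rcond=None
                )
        hp = self.config.hyperpriors()
        pi0 = hp.pi_beta[0] / sum(hp.pi_beta)
        p0 = hp.p_beta[0] / sum(hp.p_beta)
        ig_mean = lambda ab: ab[1] / max(ab[0] - 1.0, 0.5)
        return GibbsState(
            Z=Z,
            W=W,
            F=np.ones((self.n_genes, K), dtype=np.int8),
            beta=beta,
            gamma=np.ones((self.n_groups, M, K), dtype=np.int8),
            psi=np.ones(self.n_genes),
            pi=np.full(K, pi0),
            sigma2=np.full(K, ig_mean(self.config.sigma2_ig)),
            p=np.full((self.n_groups, M), p0),
            d2=np.full((self.n_groups, M), ig_mean(self.config.d2_ig)),
        )

    # -- fitting ------------------------------------------------------------

    def fit(
        self,
        n_iter: int = 3000,
        n_use: int = 1000,
        seed: int = 0,
        *,
        guided: bool = True,
        store_z: bool = False,
        callback=None,
    ):
        """Run the Gibbs chain and summarize the trailing draws.

        Parameters
        ----------
        n_iter, n_use
            Total iterations and the number of trailing iterations retained
            for posterior summaries (0 < n_use <= n_iter).
        seed
            Seed of the chain's random generator; identical inputs and seed
            give bit-identical chains.
        guided
            With ``False`` the perturbation layer is switched off (beta is
            clamped at 0), giving an unguided sparse factor analysis — used
            by the two-step baseline.
        store_z
            Also store per-draw factor matrices (memory-heavy).

        Returns
        -------
        GSFAResults
        """
        from .results import GSFAResults, PosteriorSamples

        if not 0 < n_use <= n_iter:
            raise ValueError("need 0 < n_use <= n_iter")
        cfg = self.config
        hp = cfg.hyperpriors()
        rng = np.random.default_rng(seed)
        state = self.init_state(seed)
        group_rows = self._group_rows
        K, P, M = cfg.n_factors, self.n_genes, self.n_perturbations
        T = n_use
        draws = {
            "beta": np.empty((T, self.n_groups, M, K)),
            "gamma": np.empty((T, self.n_groups, M, K), dtype=np.int8),
            "W": np.empty((T, P, K)),
            "F": np.empty((T, P, K), dtype=np.int8),
        }
        if store_z:
            draws["Z"] = np.empty((T, self.n_cells, K))
        z_sum = np.zeros((self.n_cells, K))
        psi_sum = np.zeros(P)
        log_joint_trace = np.empty(n_iter)
        for it in range(n_iter):
            _gibbs.gibbs_step(
                rng, state, self.Y, self.G, group_rows, hp, cfg.c, cfg.prior_type,
                guided=guided,
            )
            log_joint_trace[it] = state.log_joint
            t = it - (n_iter - n_use)
            if t >= 0:
                draws["beta"][t] = state.beta
                draws["gamma"][t] = state.gamma
                draws["W"][t] = state.W
                draws["F"][t] = state.F
                if store_z:
                    draws["Z"][t] = state.Z
                z_sum += state.Z
                psi_sum += state.psi
            if callback is not None:
                callback(it, state)
        samples = PosteriorSamples(
            beta=draws["beta"],
            gamma=draws["gamma"],
            W=draws["W"],
            F=draws["F"],
            Z=draws.get("Z"),
            z_mean=z_sum / n_use,
            psi_mean=psi_sum / n_use,
            log_joint_trace=log_joint_trace,
            config=cfg.to_dict()
            | {
                "n_iter": n_iter,
                "n_use": n_use,
                "seed": seed,
                "guided": guided,
                "n_groups": self.n_groups,
            },
        )
        return GSFAResults(
            samples,
            perturbation_names=list(self.perturbation_names),
            gene_ids=list(self.gene_ids),
            negative_control_index=self.negative_control_index,
            Y=self.Y,
        )


def scan_num_factors(
    Y: np.ndarray,
    G: np.ndarray,
    k_grid,
    n_iter: int = 500,
    n_use: int = 100,
    seed: int = 0,
    **model_kwargs,
) -> pd.DataFrame:
    """Fit short chains over a grid of K and report explained variance.

    The percent variance explained is 1 - ||Y - Zbar Wbar'||_F^2 / ||Y||_F^2
    on posterior means; the user picks the elbow.  A K = 0 row (0 percent)
    anchors the curve.
    """
    k_grid = sorted(set(int(k) for k in k_grid))
    if len(k_grid) < 2:
        raise ValueError("provide at least two K values")
    rows = [{"K": 0, "pct_var_explained": 0.0}]
    for k in k_grid:
        model = GuidedSparseFactorModel(Y, G, n_factors=k, **model_kwargs)
        res = model.fit(n_iter=n_iter, n_use=n_use, seed=seed)
        rows.append({"K": k, "pct_var_explained": 100.0 * res.explained_variance})
    return pd.DataFrame(rows)
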