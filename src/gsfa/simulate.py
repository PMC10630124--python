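"""Synthetic CRISPR-screen data under the model's own generative process.

The defaults reproduce the study conditions of the simulation protocol:
guides hit ~5% of cells per perturbation, six perturbations each act on a
distinct factor with effects 0.1-0.6, ten factors with loading density
pi in {0.05, 0.1, 0.2} and N(0, 0.5)-variance foreground loadings, unit
normal factor and expression noise.  The count layer draws per-cell library
sizes L_i ~ N(5e5, sd 1e5) and Poisson counts with rate
L_i * exp(1/5e5 + y_ij) * count_rate_scale; the additive 1/5e5 offset and
the default scale of 1 follow the protocol as printed (``count_rate_scale``
of 1/5e5 yields UMI-scale counts instead).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import CountMatrix, PerturbationMatrix

__all__ = [
    "SimConfig",
    "SimTruth",
    "default_effect_matrix",
    "make_scenario_beta",
    "simulate_normal",
    "simulate_counts",
    "spike_in_real_data",
]

SCENARIOS = ("default", "negative_control", "multi_factor")


def default_effect_matrix(M: int = 6, K: int = 10) -> np.ndarray:
    """Diagonal effect matrix: perturbation m hits factor m with 0.1 * (m+1)."""
    beta = np.zeros((M, K))
    for m in range(M):
        beta[m, m % K] = 0.1 * (m + 1)
    return beta


def make_scenario_beta(
    scenario: str,
    M: int = 6,
    K: int = 10,
    effect: float = 0.4,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Effect matrices of the simulation scenarios.

    ``default``: the diagonal 0.1-0.6 matrix.  ``negative_control``: M target
    rows plus one non-targeting control row, all sharing a nonspecific effect
    of ``effect`` on factor 5 (index 4).  ``multi_factor``: each perturbation
    hits 3 seeded-random factors with a common effect of ``effect``.
    """
    if scenario == "default":
        return default_effect_matrix(M, K)
    if scenario == "negative_control":
        beta = np.zeros((M + 1, K))
        beta[:M] = default_effect_matrix(M, K)
        beta[:, min(4, K - 1)] += effect  # shared nonspecific effect, factor 5
        return beta
    if scenario == "multi_factor":
        rng = rng or np.random.default_rng(0)
        beta = np.zeros((M, K))
        for m in range(M):
            beta[m, rng.choice(K, size=min(3, K), replace=False)] = effect
        return beta
    raise ValueError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")


@dataclass
class SimConfig:
    """Generator settings; defaults are the protocol's study conditions
    (scale the dimensions down for quick runs, not the rates or effects)."""

    n_cells: int = 4000
    n_genes: int = 6000
    n_perturbations: int = 6
    n_factors: int = 10
    guide_prob: float = 0.05
    factor_density: float = 0.1
    loading_var: float = 0.5
    effect_matrix: np.ndarray | None = None  # M x K; default diagonal 0.1-0.6
    library_mean: float = 5e5
    library_sd: float = 1e5
    count_offset: float = 1.0 / 5e5
    count_rate_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.guide_prob < 1:
            raise ValueError("guide_prob must be in (0, 1)")
        if not 0 < self.factor_density < 1:
            raise ValueError("factor_density must be in (0, 1)")
        if min(self.n_cells, self.n_genes, self.n_perturbations, self.n_factors) < 1:
            raise ValueError("dimensions must be positive")
        if self.effect_matrix is None:
            self.effect_matrix = default_effect_matrix(
                self.n_perturbations, self.n_factors
            )
        self.effect_matrix = np.asarray(self.effect_matrix, dtype=float)
        if self.effect_matrix.shape != (self.n_perturbations, self.n_factors):
            raise ValueError("effect_matrix shape must be (M, K)")


@dataclass
class SimTruth:
    """Ground truth exported with every simulated dataset."""

    Z: np.ndarray
    W: np.ndarray
    F: np.ndarray  # nonzero-loading indicator
    beta: np.ndarray
    G: np.ndarray
    target_genes: dict[int, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.target_genes:
            self.target_genes = {
                m: np.flatnonzero(
                    (self.F[:, self.beta[m] != 0] != 0).any(axis=1)
                )
                for m in range(self.beta.shape[0])
            }


def _draw_guides(rng: np.random.Generator, N: int, M: int, prob: float) -> np.ndarray:
    G = (rng.random((N, M)) < prob).astype(np.int8)
    for m in range(M):  # a carrier-free column is unusable downstream; redraw
        while G[:, m].sum() == 0:
            G[:, m] = (rng.random(N) < prob).astype(np.int8)
    return G


def simulate_normal(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray, SimTruth]:
    """Continuous-expression scenario.

    G_im ~ Bern(guide_prob); Z = G beta + Phi with unit normal Phi;
    W_jk ~ pi N(0, loading_var) + (1 - pi) delta_0; Y = Z W' + E with unit
    normal E.
    """
    rng = rng or np.random.default_rng(config.seed)
    N, P = config.n_cells, config.n_genes
    M, K = config.n_perturbations, config.n_factors
    G = _draw_guides(rng, N, M, config.guide_prob)
    Z = G @ config.effect_matrix + rng.standard_normal((N, K))
    F = (rng.random((P, K)) < config.factor_density).astype(np.int8)
    W = F * rng.normal(0.0, np.sqrt(config.loading_var), size=(P, K))
    Y = Z @ W.T + rng.standard_normal((N, P))
    return Y, G, SimTruth(Z=Z, W=W, F=F, beta=config.effect_matrix.copy(), G=G)


def simulate_counts(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[CountMatrix, np.ndarray, SimTruth]:
    """Count scenario: the normal draw pushed through a Poisson layer.

    L_i ~ N(library_mean, library_sd) with negative draws redrawn, then
    c_ij ~ Poisson(L_i exp(count_offset + y_ij) * count_rate_scale).
    """
    rng = rng or np.random.default_rng(config.seed)
    Y, G, truth = simulate_normal(config, rng)
    N = config.n_cells
    L = rng.normal(config.library_mean, config.library_sd, size=N)
    bad = L <= 0
    while bad.any():
        L[bad] = rng.normal(config.library_mean, config.library_sd, size=int(bad.sum()))
        bad = L <= 0
    rate = L[:, None] * np.exp(config.count_offset + Y) * config.count_rate_scale
    counts = rng.poisson(rate)
    cm = CountMatrix(
        counts,
        [f"cell_{i}" for i in range(N)],
        [f"gene_{j}" for j in range(config.n_genes)],
    )
    return cm, G, truth


def spike_in_real_data(
    counts: CountMatrix,
    n_perturbations: int = 6,
    n_targets_per_perturbation: int = 20,
    guide_prob: float = 0.05,
    effect: float = 0.5,
    rng: np.random.Generator | None = None,
) -> tuple[CountMatrix, PerturbationMatrix, SimTruth]:
    """Spike synthetic perturbations into a background count matrix.

    Guides are assigned at random and the counts of randomly chosen target
    genes in perturbed cells are multiplied by ``effect`` (fold change;
    1 leaves the data unchanged).  No latent factors are introduced; the
    exported truth carries the target lists.
    """
    import logging

    rng = rng or np.random.default_rng(0)
    N, P = counts.shape
    G = _draw_guides(rng, N, n_perturbations, guide_prob)
    new = counts.counts.astype(float).copy()
    target_genes: dict[int, np.ndarray] = {}
    for m in range(n_perturbations):
        targets = np.sort(rng.choice(P, size=n_targets_per_perturbation, replace=False))
        target_genes[m] = targets
        zero_expr = [j for j in targets if counts.counts[:, j].sum() == 0]
        if zero_expr and effect != 1.0:
            logging.getLogger(__name__).warning(
                "perturbation %d targets %d genes with zero expression", m, len(zero_expr)
            )
        carriers = np.flatnonzero(G[:, m] == 1)
        block = new[np.ix_(carriers, targets)] * effect
        new[np.ix_(carriers, targets)] = np.round(block)
    cm = CountMatrix(new.astype(np.int64), list(counts.cell_ids), list(counts.gene_ids))
    pm = PerturbationMatrix(
        G,
        [f"perturbation_{m}" for m in range(n_perturbations)],
        cell_ids=list(counts.cell_ids),
    )
    K = 1  # no factor structure; placeholder truth matrices
    truth = SimTruth(
        Z=np.zeros((N, K)),
        W=np.zeros((P, K)),
        F=np.zeros((P, K), dtype=np.int8),
        beta=np.zeros((n_perturbations, K)),
        G=G,
        target_genes=target_genes,
    )
    return cm, pm, truth
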