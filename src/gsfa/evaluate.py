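"""Scoring against simulation ground truth, comparison baselines and
permutation calibration.

Inferred factors are only identified up to sign and permutation, so every
truth-referenced metric first maps each true factor to the inferred factor
with the maximal absolute Pearson correlation (many-to-one allowed).
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import auc, roc_curve
from statsmodels.stats.multitest import multipletests

from .model import GuidedSparseFactorModel
from .results import GSFAResults
from .simulate import SimConfig, SimTruth, simulate_counts

logger = logging.getLogger(__name__)

__all__ = [
    "match_factors",
    "fdp_power",
    "roc",
    "welch_t_test",
    "clustering_two_step",
    "two_step_factor_baseline",
    "permutation_calibration",
    "loading_fdp",
    "effect_fdp",
    "deg_fdp",
    "count_scenario_benchmark",
]


# ---------------------------------------------------------------------------
# elementary metrics


def match_factors(
    Z_true: np.ndarray, Z_inferred: np.ndarray
) -> dict[int, tuple[int, float]]:
    """Map each true factor to the inferred factor of maximal |Pearson r|.

    Many-to-one mappings are allowed; ties break to the lower inferred index.
    Zero-variance columns (on either side) are excluded with a warning.

    Returns ``{true_k: (inferred_k, abs_r)}``.
    """
    if Z_true.shape[0] != Z_inferred.shape[0]:
        raise ValueError("factor matrices disagree on the cell count")
    sd_t = Z_true.std(axis=0)
    sd_i = Z_inferred.std(axis=0)
    if (sd_t == 0).any() or (sd_i == 0).any():
        warnings.warn("zero-variance factor columns excluded from matching")
    zt = (Z_true - Z_true.mean(axis=0)) / np.where(sd_t == 0, np.inf, sd_t)
    zi = (Z_inferred - Z_inferred.mean(axis=0)) / np.where(sd_i == 0, np.inf, sd_i)
    corr = np.abs(zt.T @ zi) / Z_true.shape[0]
    out: dict[int, tuple[int, float]] = {}
    for k in range(Z_true.shape[1]):
        if sd_t[k] == 0:
            continue
        j = int(np.argmax(corr[k]))  # argmax takes the first (lowest) index on ties
        out[k] = (j, float(corr[k, j]))
    return out


def fdp_power(calls: set, truth: set, universe: set) -> tuple[float, float | None]:
    """False discovery proportion and power of a call set.

    fdp = |calls \\ truth| / max(|calls|, 1) (0 for empty calls);
    power = |calls & truth| / |truth|, ``None`` when the truth set is empty.
    """
    calls, truth, universe = set(calls), set(truth), set(universe)
    if not calls <= universe or not truth <= universe:
        raise ValueError("calls and truth must be subsets of the universe")
    fdp = len(calls - truth) / max(len(calls), 1)
    power = None if not truth else len(calls & truth) / len(truth)
    return fdp, power


def roc(scores: np.ndarray, truth: np.ndarray):
    """TPR/FPR sweep and trapezoidal area for a ranking score.

    Returns ``(fpr, tpr, area)``; ``(None, None, None)`` when the truth has a
    single class.  Ties follow the Mann-Whitney convention.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth).astype(bool)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    if truth.all() or not truth.any():
        return None, None, None
    fpr, tpr, _ = roc_curve(truth.astype(int), scores)
    return fpr, tpr, float(auc(fpr, tpr))


def welch_t_test(Y: np.ndarray, G: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided Welch's t-test per gene and perturbation (carriers vs rest).

    Returns (p-values, BH-adjusted q-values), each M x P; genes in a
    degenerate comparison (either group < 2 cells) get NaN.
    """
    Y = np.asarray(Y, dtype=float)
    G = np.asarray(G)
    M = G.shape[1]
    P = Y.shape[1]
    pvals = np.full((M, P), np.nan)
    qvals = np.full((M, P), np.nan)
    for m in range(M):
        carriers = G[:, m] == 1
        if carriers.sum() < 2 or (~carriers).sum() < 2:
            continue
        with np.errstate(invalid="ignore", divide="ignore"):
            res = scipy.stats.ttest_ind(
                Y[carriers], Y[~carriers], equal_var=False, axis=0
            )
        pvals[m] = res.pvalue
        ok = np.isfinite(pvals[m])
        if ok.any():
            qvals[m, ok] = multipletests(pvals[m, ok], method="fdr_bh")[1]
    return pvals, qvals


# ---------------------------------------------------------------------------
# baselines


def clustering_two_step(
    Y: np.ndarray,
    G: np.ndarray,
    n_clusters: int = 10,
    n_pcs: int = 10,
    assoc_fdr: float = 0.05,
    deg_fdr: float = 0.05,
    seed: int = 0,
) -> dict[int, set[int]]:
    """Two-step clustering baseline for candidate target genes.

    Cluster cells (k-means on the top principal components), associate each
    perturbation with clusters by Fisher's exact test (BH-FDR < assoc_fdr),
    take cluster-vs-rest Welch DEGs (BH-FDR < deg_fdr) and union them over a
    perturbation's associated clusters.
    """
    if n_clusters < 2:
        raise ValueError("n_clusters must be >= 2")
    N = Y.shape[0]
    pcs = PCA(n_components=min(n_pcs, min(Y.shape) - 1), random_state=seed).fit_transform(Y)
    for attempt in range(2):
        km = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed + attempt)
        labels = km.fit_predict(pcs)
        sizes = np.bincount(labels, minlength=n_clusters)
        if (sizes > 0).all():
            break
    else:
        raise RuntimeError("k-means produced an empty cluster twice")
    # cluster-vs-rest DEG sets, computed once per cluster
    cluster_degs: dict[int, set[int]] = {}
    for c in range(n_clusters):
        in_c = labels == c
        _, qv = welch_t_test(Y, in_c[:, None].astype(int))
        cluster_degs[c] = set(np.flatnonzero(qv[0] < deg_fdr))
    out: dict[int, set[int]] = {}
    for m in range(G.shape[1]):
        carriers = G[:, m] == 1
        pvals = []
        for c in range(n_clusters):
            in_c = labels == c
            table = [
                [int(np.sum(carriers & in_c)), int(np.sum(carriers & ~in_c))],
                [int(np.sum(~carriers & in_c)), int(np.sum(~carriers & ~in_c))],
            ]
            pvals.append(scipy.stats.fisher_exact(table)[1])
        qv = multipletests(pvals, method="fdr_bh")[1]
        associated = np.flatnonzero(qv < assoc_fdr)
        genes: set[int] = set()
        for c in associated:
            genes |= cluster_degs[c]
        out[m] = genes
    return out


def two_step_factor_baseline(
    Y: np.ndarray,
    G: np.ndarray,
    n_factors: int = 10,
    n_iter: int = 1200,
    n_use: int = 400,
    seed: int = 0,
    assoc_fdr: float = 0.05,
    pip_threshold: float = 0.95,
    **model_kwargs,
) -> dict[int, set[int]]:
    """Unguided factor analysis followed by perturbation-factor association.

    Factors come from the same sampler with the perturbation layer switched
    off; each perturbation is associated with factors via Welch's t-test on
    the posterior-mean factor scores (BH-FDR < assoc_fdr), and its candidate
    genes are the union of loadings with PIP > pip_threshold on associated
    factors.
    """
    model = GuidedSparseFactorModel(Y, G, n_factors=n_factors, **model_kwargs)
    res = model.fit(n_iter=n_iter, n_use=n_use, seed=seed, guided=False)
    zbar = res.z_mean
    pvals, _ = welch_t_test(zbar, G)  # M x K
    pip = res.pip_w
    out: dict[int, set[int]] = {}
    for m in range(G.shape[1]):
        ok = np.isfinite(pvals[m])
        qv = np.full(pvals.shape[1], np.nan)
        if ok.any():
            qv[ok] = multipletests(pvals[m, ok], method="fdr_bh")[1]
        associated = np.flatnonzero(qv < assoc_fdr)
        genes: set[int] = set()
        for k in associated:
            genes |= set(np.flatnonzero(pip[:, k] > pip_threshold))
        out[m] = genes
    return out


# ---------------------------------------------------------------------------
# calibration


def permutation_calibration(
    Y: np.ndarray,
    G: np.ndarray,
    n_perm: int = 3,
    n_factors: int = 10,
    n_iter: int = 600,
    n_use: int = 200,
    seed: int = 0,
    groups: np.ndarray | None = None,
    permutations: list[np.ndarray] | None = None,
    **model_kwargs,
) -> pd.DataFrame:
    """Refit on guide matrices shuffled relative to the expression rows.

    Each permutation shuffles the rows of G (within each group when a group
    label is supplied), breaking any true association while preserving both
    marginals; PIPs should then concentrate near 0 and LFSRs near 1.

    Returns one row per permutation with the PIP(beta) distribution summary,
    the LFSR median, and the smallest empirical perturbation-factor
    correlation p-value.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for r in range(n_perm):
        if permutations is not None:
            perm = np.asarray(permutations[r])
        elif groups is None:
            perm = rng.permutation(G.shape[0])
        else:
            perm = np.arange(G.shape[0])
            for g in np.unique(groups):
                idx = np.flatnonzero(groups == g)
                perm[idx] = idx[rng.permutation(idx.size)]
        Gp = G[perm]
        model = GuidedSparseFactorModel(
            Y, Gp, n_factors=n_factors, groups=groups, **model_kwargs
        )
        res = model.fit(n_iter=n_iter, n_use=n_use, seed=seed + r)
        pip = np.asarray(res.pip_beta).ravel()
        lf = res.lfsr(group=0 if res.n_groups > 1 else None)
        corr_p = [
            scipy.stats.pearsonr(Gp[:, m], res.z_mean[:, k]).pvalue
            for m in range(Gp.shape[1])
            for k in range(res.z_mean.shape[1])
        ]
        rows.append(
            {
                "permutation": r,
                "pip_beta_max": float(pip.max()),
                "pip_beta_mean": float(pip.mean()),
                "frac_pip_above_0.95": float(np.mean(pip > 0.95)),
                "lfsr_median": float(np.median(lf)),
                "min_corr_pvalue": float(min(corr_p)),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# truth-referenced FDP metrics


def loading_fdp(
    results: GSFAResults,
    truth: SimTruth,
    pip_threshold: float = 0.95,
) -> tuple[float, float | None, int]:
    """FDP/power of gene-factor loading selection at PIP > pip_threshold.

    True factors are matched to inferred factors by |Pearson r| of the factor
    scores; selected loadings on a matched inferred factor are scored against
    the matched true factor's nonzero-loading support, pooled over factors.
    """
    fmap = match_factors(truth.Z, results.z_mean)
    pip = results.pip_w
    n_sel = n_false = n_true_total = n_hit = 0
    for k_true, (k_inf, _) in fmap.items():
        sel = pip[:, k_inf] > pip_threshold
        support = truth.F[:, k_true] != 0
        n_sel += int(sel.sum())
        n_false += int((sel & ~support).sum())
        n_true_total += int(support.sum())
        n_hit += int((sel & support).sum())
    fdp = n_false / max(n_sel, 1)
    power = None if n_true_total == 0 else n_hit / n_true_total
    return fdp, power, n_sel


def effect_fdp(
    results: GSFAResults,
    truth: SimTruth,
    pip_threshold: float = 0.95,
) -> tuple[float, float | None, int]:
    """FDP/power of perturbation-to-factor effect selection at PIP > threshold,
    on matched factors."""
    fmap = match_factors(truth.Z, results.z_mean)
    pip = np.asarray(results.pip_beta)
    M = truth.beta.shape[0]
    n_sel = n_false = n_true_total = n_hit = 0
    for k_true, (k_inf, _) in fmap.items():
        for m in range(M):
            sel = pip[m, k_inf] > pip_threshold
            is_true = truth.beta[m, k_true] != 0
            n_sel += int(sel)
            n_false += int(sel and not is_true)
            n_true_total += int(is_true)
            n_hit += int(sel and is_true)
    fdp = n_false / max(n_sel, 1)
    power = None if n_true_total == 0 else n_hit / n_true_total
    return fdp, power, n_sel


def deg_fdp(
    results: GSFAResults,
    truth: SimTruth,
    lfsr_threshold: float = 0.05,
) -> tuple[float, float | None, int]:
    """FDP/power of DEG calls at LFSR < threshold, pooled over perturbations.

    Truth: genes with nonzero loading on any factor the perturbation acts on.
    """
    lf = results.lfsr()
    M = truth.beta.shape[0]
    n_sel = n_false = n_true_total = n_hit = 0
    for m in range(M):
        calls = set(np.flatnonzero(lf[m] < lfsr_threshold))
        true_set = set(truth.target_genes[m].tolist())
        n_sel += len(calls)
        n_false += len(calls - true_set)
        n_true_total += len(true_set)
        n_hit += len(calls & true_set)
    fdp = n_false / max(n_sel, 1)
    power = None if n_true_total == 0 else n_hit / n_true_total
    return fdp, power, n_sel


def baseline_fpr(
    candidates: dict[int, set[int]], truth: SimTruth
) -> float | None:
    """Mean fraction of false candidates over perturbations with nonempty
    candidate sets; ``None`` when every set is empty."""
    rates = []
    for m, genes in candidates.items():
        if not genes:
            continue
        true_set = set(truth.target_genes[m].tolist())
        rates.append(len(genes - true_set) / len(genes))
    return None if not rates else float(np.mean(rates))


# ---------------------------------------------------------------------------
# simulation -> fit -> score loop (shared by the acceptance harness)


@dataclass
class BenchmarkRecord:
    replicate: int
    factor_density: float
    loading_fdp: float
    loading_power: float | None
    n_loadings_selected: int
    effect_fdp: float
    effect_power: float | None
    n_effects_selected: int
    deg_fdp: float
    deg_power: float | None
    n_degs: int
    mean_matched_abs_r: float
    clustering_fpr: float | None
    welch_deg_fdp: float | None


def count_scenario_benchmark(
    factor_densities=(0.05, 0.1),
    replicates_per_density: int = 5,
    n_cells: int = 800,
    n_genes: int = 1000,
    n_iter: int = 1200,
    n_use: int = 400,
    seed: int = 1,
    run_clustering_baseline: bool = True,
    run_welch: bool = False,
    **sim_overrides,
) -> pd.DataFrame:
    """Simulate count-scenario datasets, fit the model and score everything.

    One row per replicate with loading/effect/DEG FDP and power, the mean
    matched-factor |Pearson r|, and (optionally) the clustering baseline's
    false positive rate on the identical data.
    """
    from .preprocess import preprocess_counts

    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in
                   ss.spawn(len(factor_densities) * replicates_per_density)]
    rows = []
    idx = 0
    for density in factor_densities:
        for r in range(replicates_per_density):
            rep_seed = child_seeds[idx]
            idx += 1
            cfg = SimConfig(
                n_cells=n_cells,
                n_genes=n_genes,
                factor_density=density,
                seed=rep_seed,
                **sim_overrides,
            )
            counts, G, truth = simulate_counts(cfg)
            res_mat = preprocess_counts(counts)
            kept = np.array([int(g.split("_")[1]) for g in res_mat.gene_ids])
            truth_kept = SimTruth(
                Z=truth.Z,
                W=truth.W[kept],
                F=truth.F[kept],
                beta=truth.beta,
                G=truth.G,
            )
            model = GuidedSparseFactorModel(
                res_mat.Y, G, n_factors=cfg.n_factors, gene_ids=list(res_mat.gene_ids)
            )
            fit = model.fit(n_iter=n_iter, n_use=n_use, seed=rep_seed)
            l_fdp, l_pow, l_n = loading_fdp(fit, truth_kept)
            e_fdp, e_pow, e_n = effect_fdp(fit, truth_kept)
            d_fdp, d_pow, d_n = deg_fdp(fit, truth_kept)
            fmap = match_factors(truth_kept.Z, fit.z_mean)
            mean_r = float(np.mean([r_ for _, r_ in fmap.values()]))
            clus_fpr = None
            if run_clustering_baseline:
                cand = clustering_two_step(
                    res_mat.Y, G, n_clusters=cfg.n_factors, seed=rep_seed
                )
                clus_fpr = baseline_fpr(cand, truth_kept)
            welch_fdp_val = None
            if run_welch:
                _, qv = welch_t_test(res_mat.Y, G)
                n_sel = n_false = 0
                for m in range(G.shape[1]):
                    calls = set(np.flatnonzero(qv[m] < 0.05))
                    true_set = set(truth_kept.target_genes[m].tolist())
                    n_sel += len(calls)
                    n_false += len(calls - true_set)
                welch_fdp_val = n_false / max(n_sel, 1)
            rows.append(
                BenchmarkRecord(
                    replicate=idx - 1,
                    factor_density=density,
                    loading_fdp=l_fdp,
                    loading_power=l_pow,
                    n_loadings_selected=l_n,
                    effect_fdp=e_fdp,
                    effect_power=e_pow,
                    n_effects_selected=e_n,
                    deg_fdp=d_fdp,
                    deg_power=d_pow,
                    n_degs=d_n,
                    mean_matched_abs_r=mean_r,
                    clustering_fpr=clus_fpr,
                    welch_deg_fdp=welch_fdp_val,
                ).__dict__
            )
            logger.info("benchmark replicate %d done (density %.2f)", idx - 1, density)
    return pd.DataFrame(rows)
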