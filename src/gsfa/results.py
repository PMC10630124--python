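"""Posterior summaries: PIPs, total perturbation-to-gene effects, local false
sign rates, DEG calls and negative-control adjustment.

The total effect of perturbation m on gene j sums the factor-mediated paths
per posterior draw, theta_mj^(t) = sum_k beta_mk^(t) W_jk^(t) F_jk^(t); the
foreground indicator F masks background-component loadings.  Significance is
summarized by the local false sign rate,
LFSR(theta_mj) = min{Pr(theta >= 0 | data), Pr(theta <= 0 | data)},
with non-strict inequalities on both sides so an identically-zero effect has
LFSR exactly 1.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

FORMAT_VERSION = 1

__all__ = [
    "PosteriorSamples",
    "GSFAResults",
    "IncompatibleArtifactError",
    "pip_beta",
    "pip_w",
    "total_effects",
    "lfsr",
    "call_degs",
    "adjust_negative_control",
]


class IncompatibleArtifactError(RuntimeError):
    """A stored fit cannot be read by this package version."""


@dataclass
class PosteriorSamples:
    """Trailing Gibbs draws plus chain-level summaries.

    Draw arrays are indexed (draw, [group,] ...); ``beta`` and ``gamma``
    carry an explicit group axis even for the single-group model.
    """

    beta: np.ndarray  # T x n_groups x M x K
    gamma: np.ndarray  # T x n_groups x M x K
    W: np.ndarray  # T x P x K
    F: np.ndarray  # T x P x K
    z_mean: np.ndarray  # N x K
    psi_mean: np.ndarray  # P
    log_joint_trace: np.ndarray
    config: dict = field(default_factory=dict)
    Z: np.ndarray | None = None  # T x N x K, optional

    def __post_init__(self) -> None:
        T = self.beta.shape[0]
        for name in ("gamma", "W", "F"):
            if getattr(self, name).shape[0] != T:
                raise ValueError(f"draw-count mismatch between beta and {name}")
        if not np.all(np.isfinite(self.beta)) or not np.all(np.isfinite(self.W)):
            raise ValueError("posterior draws contain non-finite values")

    @property
    def n_draws(self) -> int:
        return self.beta.shape[0]

    @property
    def n_groups(self) -> int:
        return self.beta.shape[1]


def _squeeze_group(arr: np.ndarray, n_groups: int, group: int | None):
    if group is not None:
        return arr[:, group]
    return arr[:, 0] if n_groups == 1 else arr


def pip_beta(samples: PosteriorSamples, group: int | None = None) -> np.ndarray:
    """PIP(beta_mk) = Pr(gamma_mk = 1 | data): mean of gamma over draws."""
    g = _squeeze_group(samples.gamma, samples.n_groups, group)
    return g.mean(axis=0)


def mean_beta(samples: PosteriorSamples, group: int | None = None) -> np.ndarray:
    b = _squeeze_group(samples.beta, samples.n_groups, group)
    return b.mean(axis=0)


def pip_w(samples: PosteriorSamples) -> np.ndarray:
    """PIP(W_jk) = Pr(F_jk = 1 | data): mean of F over draws."""
    return samples.F.mean(axis=0)


def total_effects(
    samples: PosteriorSamples,
    group: int | None = None,
    gene_block_size: int | None = None,
) -> np.ndarray:
    """Per-draw total effects theta^(t) = beta^(t) (W^(t) o F^(t))'.

    Returns a (draws x M x P) array.  ``gene_block_size`` computes the same
    result in gene blocks to bound peak memory.
    """
    beta = _squeeze_group(samples.beta, samples.n_groups, group)
    if beta.ndim != 3:
        raise ValueError("specify group= for a two-group fit")
    WF = samples.W * samples.F
    P = WF.shape[1]
    if gene_block_size is None or gene_block_size >= P:
        return np.einsum("tmk,tjk->tmj", beta, WF)
    out = np.empty((beta.shape[0], beta.shape[1], P))
    for lo in range(0, P, gene_block_size):
        hi = min(lo + gene_block_size, P)
        out[:, :, lo:hi] = np.einsum("tmk,tjk->tmj", beta, WF[:, lo:hi])
    return out


def lfsr(theta_draws: np.ndarray) -> np.ndarray:
    """LFSR = min of the two non-strict empirical sign-tail probabilities."""
    if theta_draws.shape[0] < 1:
        raise ValueError("need at least one draw")
    p_nonneg = (theta_draws >= 0).mean(axis=0)
    p_nonpos = (theta_draws <= 0).mean(axis=0)
    return np.minimum(p_nonneg, p_nonpos)


def call_degs(
    lfsr_matrix: np.ndarray,
    gene_ids: list[str],
    perturbation_names: list[str],
    threshold: float = 0.05,
) -> dict[str, list[str]]:
    """Gene j is a DEG for perturbation m iff lfsr(m, j) < threshold (strict).

    LFSR is already a posterior error measure, so no further multiplicity
    correction is applied.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    return {
        name: [gene_ids[j] for j in np.flatnonzero(lfsr_matrix[m] < threshold)]
        for m, name in enumerate(perturbation_names)
    }


def adjust_negative_control(
    samples: PosteriorSamples, nc_index: int
) -> PosteriorSamples:
    """Subtract the negative-control effect row per draw: beta' = beta - beta_0.

    Removes nonspecific guide effects shared with the non-targeting control.
    The control row itself is kept unadjusted for diagnostics; the foreground
    masks (gamma, F) are left untouched.
    """
    M = samples.beta.shape[2]
    if not 0 <= nc_index < M:
        raise ValueError(f"negative-control index {nc_index} out of range")
    beta = samples.beta.copy()
    nc = beta[:, :, nc_index : nc_index + 1, :]
    adjusted = beta - nc
    adjusted[:, :, nc_index, :] = beta[:, :, nc_index, :]
    return PosteriorSamples(
        beta=adjusted,
        gamma=samples.gamma,
        W=samples.W,
        F=samples.F,
        z_mean=samples.z_mean,
        psi_mean=samples.psi_mean,
        log_joint_trace=samples.log_joint_trace,
        config=dict(samples.config) | {"negative_control_adjusted": nc_index},
        Z=samples.Z,
    )


class GSFAResults:
    """Fitted-model results: estimates, uncertainties and diagnostics.

    Wraps the stored posterior draws with labelled accessors, DEG calling,
    negative-control adjustment, plotting and HDF5 round-tripping.
    """

    def __init__(
        self,
        samples: PosteriorSamples,
        perturbation_names: list[str],
        gene_ids: list[str],
        negative_control_index: int | None = None,
        Y: np.ndarray | None = None,
    ) -> None:
        self.samples = samples
        self.perturbation_names = list(perturbation_names)
        self.gene_ids = list(gene_ids)
        self.negative_control_index = negative_control_index
        self.Y = Y

    # -- point summaries ----------------------------------------------------

    @property
    def n_draws(self) -> int:
        return self.samples.n_draws

    @property
    def n_groups(self) -> int:
        return self.samples.n_groups

    @property
    def pip_beta(self) -> np.ndarray:
        return pip_beta(self.samples)

    @property
    def mean_beta(self) -> np.ndarray:
        return mean_beta(self.samples)

    def sd_beta(self, group: int | None = None) -> np.ndarray:
        b = _squeeze_group(self.samples.beta, self.n_groups, group)
        return b.std(axis=0, ddof=1)

    @property
    def pip_w(self) -> np.ndarray:
        return pip_w(self.samples)

    @property
    def mean_w(self) -> np.ndarray:
        return self.samples.W.mean(axis=0)

    @property
    def z_mean(self) -> np.ndarray:
        return self.samples.z_mean

    @property
    def log_joint_trace(self) -> np.ndarray:
        return self.samples.log_joint_trace

    @property
    def explained_variance(self) -> float:
        """1 - ||Y - Zbar Wbar'||_F^2 / ||Y||_F^2 on posterior means."""
        if self.Y is None:
            raise ValueError("expression matrix was not stored with this fit")
        resid = self.Y - self.samples.z_mean @ self.mean_w.T
        return 1.0 - float(np.sum(resid**2)) / float(np.sum(self.Y**2))

    # -- gene-level effects --------------------------------------------------

    def _maybe_adjusted(self, adjust_nc: bool) -> PosteriorSamples:
        if not adjust_nc:
            return self.samples
        if self.negative_control_index is None:
            raise ValueError("no negative-control perturbation was designated")
        return adjust_negative_control(self.samples, self.negative_control_index)

    def total_effects(
        self,
        group: int | None = None,
        adjust_nc: bool = False,
        gene_block_size: int | None = None,
    ) -> np.ndarray:
        return total_effects(
            self._maybe_adjusted(adjust_nc), group=group,
            gene_block_size=gene_block_size,
        )

    def lfsr(self, group: int | None = None, adjust_nc: bool = False) -> np.ndarray:
        return lfsr(self.total_effects(group=group, adjust_nc=adjust_nc))

    def call_degs(
        self,
        threshold: float = 0.05,
        group: int | None = None,
        adjust_nc: bool = False,
    ) -> dict[str, list[str]]:
        return call_degs(
            self.lfsr(group=group, adjust_nc=adjust_nc),
            self.gene_ids,
            self.perturbation_names,
            threshold,
        )

    # -- presentation --------------------------------------------------------

    def effect_table(self, group: int | None = None) -> pd.DataFrame:
        """Long table of perturbation-to-factor effects with PIPs."""
        pip = pip_beta(self.samples, group=group)
        mb = mean_beta(self.samples, group=group)
        sd = self.sd_beta(group=group)
        if pip.ndim == 3:
            raise ValueError("specify group= for a two-group fit")
        M, K = pip.shape
        rows = [
            {
                "perturbation": self.perturbation_names[m],
                "factor": k,
                "pip": pip[m, k],
                "mean": mb[m, k],
                "sd": sd[m, k],
            }
            for m in range(M)
            for k in range(K)
        ]
        return pd.DataFrame(rows)

    def summary(
        self, pip_threshold: float = 0.95, lfsr_threshold: float = 0.05
    ) -> str:
        """Human-readable fit summary."""
        cfg = self.samples.config
        lines = [
            "Guided sparse factor model fit",
            "=" * 34,
            f"cells x genes:      {self.samples.z_mean.shape[0]} x {len(self.gene_ids)}",
            f"factors (K):        {cfg.get('n_factors')}",
            f"perturbations:      {len(self.perturbation_names)}",
            f"loading prior:      {cfg.get('prior_type')}",
            f"iterations:         {cfg.get('n_iter')} (last {cfg.get('n_use')} used)",
            f"seed:               {cfg.get('seed')}",
        ]
        if self.Y is not None:
            lines.append(f"variance explained: {100 * self.explained_variance:.1f}%")
        degs = self.call_degs(threshold=lfsr_threshold, group=0 if self.n_groups > 1 else None)
        pip = pip_beta(self.samples, group=0 if self.n_groups > 1 else None)
        lines.append("")
        lines.append(
            f"{'perturbation':<20}{'factors PIP>' + format(pip_threshold, '.2f'):<18}"
            f"DEGs (LFSR<{lfsr_threshold:g})"
        )
        for m, name in enumerate(self.perturbation_names):
            hits = np.flatnonzero(pip[m] > pip_threshold)
            lines.append(
                f"{name:<20}{','.join(map(str, hits)) or '-':<18}{len(degs[name])}"
            )
        return "\n".join(lines)

    def plot_effects(self, group: int | None = None, ax=None):
        """Heatmap of posterior-mean perturbation-to-factor effects (PIP-masked)."""
        import matplotlib.pyplot as plt

        pip = pip_beta(self.samples, group=group)
        mb = mean_beta(self.samples, group=group)
        if ax is None:
            _, ax = plt.subplots(figsize=(0.5 * mb.shape[1] + 2, 0.4 * mb.shape[0] + 1.5))
        vmax = max(np.abs(mb).max(), 1e-6)
        im = ax.imshow(mb * (pip > 0.5), cmap="RdBu_r", vmin=-vmax, vmax=vmax)
        ax.set_xlabel("factor")
        ax.set_ylabel("perturbation")
        ax.set_yticks(range(len(self.perturbation_names)), self.perturbation_names)
        ax.figure.colorbar(im, ax=ax, label="posterior mean effect")
        return ax

    def plot_trace(self, ax=None):
        """Log-joint trace over Gibbs iterations (mixing diagnostic)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.samples.log_joint_trace)
        ax.set_xlabel("iteration")
        ax.set_ylabel("log joint density")
        return ax

    # -- persistence ---------------------------------------------------------

    def save(self, path, store_y: bool = True) -> None:
        """Write the fit to an HDF5 artifact (lossless round-trip)."""
        import h5py

        with h5py.File(path, "w") as f:
            f.attrs["format_version"] = FORMAT_VERSION
            f.attrs["package"] = "gsfa"
            f.attrs["config"] = json.dumps(self.samples.config)
            f.attrs["perturbation_names"] = json.dumps(self.perturbation_names)
            f.attrs["gene_ids"] = json.dumps(self.gene_ids)
            f.attrs["negative_control_index"] = (
                -1 if self.negative_control_index is None else self.negative_control_index
            )
            for name in ("beta", "gamma", "W", "F", "z_mean", "psi_mean",
                         "log_joint_trace"):
                f.create_dataset(name, data=getattr(self.samples, name))
            if self.samples.Z is not None:
                f.create_dataset("Z", data=self.samples.Z)
            if store_y and self.Y is not None:
                f.create_dataset("Y", data=self.Y)

    @classmethod
    def load(cls, path) -> "GSFAResults":
        import h5py

        try:
            f = h5py.File(path, "r")
        except OSError as exc:
            raise IncompatibleArtifactError(f"cannot open fit artifact: {exc}") from exc
        with f:
            version = f.attrs.get("format_version")
            if version != FORMAT_VERSION:
                raise IncompatibleArtifactError(
                    f"fit artifact format {version!r} not supported "
                    f"(expected {FORMAT_VERSION})"
                )
            samples = PosteriorSamples(
                beta=f["beta"][...],
                gamma=f["gamma"][...],
                W=f["W"][...],
                F=f["F"][...],
                z_mean=f["z_mean"][...],
                psi_mean=f["psi_mean"][...],
                log_joint_trace=f["log_joint_trace"][...],
                config=json.loads(f.attrs["config"]),
                Z=f["Z"][...] if "Z" in f else None,
            )
            nc = int(f.attrs["negative_control_index"])
            return cls(
                samples,
                perturbation_names=json.loads(f.attrs["perturbation_names"]),
                gene_ids=json.loads(f.attrs["gene_ids"]),
                negative_control_index=None if nc < 0 else nc,
                Y=f["Y"][...] if "Y" in f else None,
            )
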