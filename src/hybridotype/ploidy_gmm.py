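"""Ploidy inference from allele-balance distributions via Gaussian mixtures.

At heterozygous-like biallelic sites the alt-allele balance (alt depth over
total depth) clusters around k/p for allelic dosage k of ploidy p: a single
mode at 1/2 in diploids, modes at 1/3 and 2/3 in triploids, at 1/4, 1/2 and
3/4 in tetraploids. Ploidy is inferred by fitting a *free* Gaussian mixture
(three free means and weights, common variance) and three *fixed* mixtures
whose means are pinned to the canonical diploid/triploid/tetraploid
positions with uniform component weights and a free common variance. Each
fixed model is a point in the free model's parameter space, so the free
log-likelihood dominates each fixed one; the ploidy whose fixed model loses
the least likelihood relative to the free model is selected. Weights are
held uniform in the fixed models because freeing them makes the hypotheses
nest one another (a tetraploid mixture with free weights can collapse onto
the diploid one and absorb stray tail density), which would bias
smallest-loss selection toward the highest ploidy on perfectly clean data. A uniform-background "denoising" mixture is
fitted first and downstream fits weight each site by its posterior
probability of not being background noise.

The EM machinery here is purpose-built: the fixed-mean, shared-variance,
site-weighted parameterization is the method itself, not a generic mixture
fit.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import logsumexp
from scipy.stats import norm

from .vcf_io import VariantTable

logger = logging.getLogger(__name__)

#: Canonical allele-balance means per ploidy hypothesis.
PLOIDY_MEANS = {
    2: np.array([0.5]),
    3: np.array([1 / 3, 2 / 3]),
    4: np.array([0.25, 0.5, 0.75]),
}

VAR_FLOOR = 1e-4  # variance floor (sigma >= 0.01) against degenerate fits


@dataclass
class FittedMixture:
    """Gaussian mixture with common variance: sum_k w_k N(mu_k, var)."""

    means: np.ndarray
    weights: np.ndarray
    var: float
    loglik: float

    def log_density(self, x: np.ndarray) -> np.ndarray:
        lp = (
            np.log(self.weights)[None, :]
            + norm.logpdf(x[:, None], self.means[None, :], np.sqrt(self.var))
        )
        return logsumexp(lp, axis=1)

    def density(self, x: np.ndarray) -> np.ndarray:
        return np.exp(self.log_density(x))

    def bin_masses(self, edges: np.ndarray) -> np.ndarray:
        """Probability mass of the mixture in each histogram bin."""
        sd = np.sqrt(self.var)
        cdf = norm.cdf(edges[:, None], self.means[None, :], sd) @ self.weights
        return np.diff(cdf)


@dataclass
class PloidyFit:
    sample_id: str
    n_sites: int
    loglik_free: float
    loglik_fixed: dict[int, float]
    delta: dict[int, float]
    best_ploidy: int
    r_squared: float
    noise_fraction: float
    models: dict[object, FittedMixture] = field(default_factory=dict)
    values: np.ndarray | None = None
    site_weights: np.ndarray | None = None


def select_sites(
    table: VariantTable,
    sample_id: str,
    min_depth: int = 20,
    ratio_bounds: tuple[float, float] = (0.1, 0.9),
    min_gq: int = 20,
    min_sites: int = 100,
) -> np.ndarray:
    """Alt-allele balances at heterozygous-like sites for one sample.

    Uses all biallelic SNPs (not only diagnostic loci): a site enters when
    its summed ref+alt depth is >= ``min_depth``, its genotype quality is
    >= ``min_gq`` and its balance lies strictly inside ``ratio_bounds``
    (excluding the homozygous clusters at 0 and 1).
    """
    si = table.sample_index(sample_id)
    lo, hi = ratio_bounds
    vals: list[float] = []
    for rec in table.records:
        if not (rec.is_snp and rec.is_biallelic):
            continue
        ad = rec.allele_depths[si]
        if ad[0] < 0 or ad[1] < 0:
            continue
        if min_gq > 0 and 0 <= rec.gqs[si] < min_gq:
            continue
        total = int(ad[0]) + int(ad[1])
        if total < min_depth:
            continue
        bal = int(ad[1]) / total
        if lo < bal < hi:
            vals.append(bal)
    if len(vals) < min_sites:
        raise ValueError(
            f"sample {sample_id!r}: only {len(vals)} usable heterozygous-like "
            f"sites, need >= {min_sites}"
        )
    return np.asarray(vals)


def _em_gmm(
    x: np.ndarray,
    w: np.ndarray,
    means: np.ndarray,
    fix_means: bool,
    fix_weights: bool = False,
    var: float = 0.01,
    pis0: np.ndarray | None = None,
    max_iter: int = 500,
    tol: float = 1e-8,
) -> FittedMixture:
    """Weighted EM for a common-variance Gaussian mixture.

    Maximizes  sum_i w_i log sum_k pi_k N(x_i; mu_k, var).  Means stay at
    their initial values when ``fix_means`` is set and component weights
    stay uniform when ``fix_weights`` is set; the shared variance is always
    free. Monotone in the weighted log-likelihood.
    """
    k = len(means)
    means = means.astype(float).copy()
    pis = np.full(k, 1.0 / k) if pis0 is None else np.asarray(pis0, dtype=float)
    var = max(var, VAR_FLOOR)
    wsum = w.sum()
    prev = -np.inf
    for _ in range(max_iter):
        logp = np.log(pis)[None, :] + norm.logpdf(
            x[:, None], means[None, :], np.sqrt(var)
        )
        lse = logsumexp(logp, axis=1)
        loglik = float(np.dot(w, lse))
        resp = np.exp(logp - lse[:, None])  # (n, k)
        wr = w[:, None] * resp
        nk = wr.sum(axis=0)
        if not fix_weights:
            pis = np.maximum(nk / wsum, 1e-12)
            pis /= pis.sum()
        if not fix_means:
            means = (wr * x[:, None]).sum(axis=0) / np.maximum(nk, 1e-12)
        var = float((wr * (x[:, None] - means[None, :]) ** 2).sum() / wsum)
        if var < VAR_FLOOR:
            warnings.warn("mixture variance hit the floor; clamping", stacklevel=2)
            var = VAR_FLOOR
        if loglik - prev < tol and np.isfinite(prev):
            break
        prev = loglik
    logp = np.log(pis)[None, :] + norm.logpdf(x[:, None], means[None, :], np.sqrt(var))
    loglik = float(np.dot(w, logsumexp(logp, axis=1)))
    return FittedMixture(means=means, weights=pis, var=var, loglik=loglik)


def denoise(
    values: np.ndarray,
    min_sites: int = 100,
    max_iter: int = 1000,
    seed: int = 0,
) -> tuple[np.ndarray, float]:
    """Down-weight sites that look like uniform background noise.

    Fits, by EM, a mixture of a Uniform(0, 1) component and a free
    three-component Gaussian mixture (common variance). Returns the
    per-site posterior weight of the Gaussian (signal) part and the
    estimated uniform mixing proportion.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < min_sites:
        raise ValueError(f"denoise needs >= {min_sites} values, got {len(x)}")
    means = np.array([0.25, 0.5, 0.75])
    pis = np.array([0.75 / 3, 0.75 / 3, 0.75 / 3])
    pi_noise = 0.25
    var = 0.01
    prev = -np.inf
    converged = False
    for _ in range(max_iter):
        log_g = np.log(pis)[None, :] + norm.logpdf(
            x[:, None], means[None, :], np.sqrt(var)
        )
        log_noise = np.full(len(x), np.log(max(pi_noise, 1e-300)))  # U(0,1) pdf = 1
        log_all = np.column_stack([log_noise, log_g])
        lse = logsumexp(log_all, axis=1)
        loglik = float(lse.sum())
        resp = np.exp(log_all - lse[:, None])
        nk = resp.sum(axis=0)
        pi_noise = nk[0] / len(x)
        pis = np.maximum(nk[1:] / len(x), 1e-12)
        g_resp = resp[:, 1:]
        ng = np.maximum(g_resp.sum(axis=0), 1e-12)
        means = (g_resp * x[:, None]).sum(axis=0) / ng
        var = max(
            float((g_resp * (x[:, None] - means[None, :]) ** 2).sum() / ng.sum()),
            VAR_FLOOR,
        )
        if abs(loglik - prev) < 1e-6 * max(1.0, abs(loglik)) and np.isfinite(prev):
            converged = True
            break
        prev = loglik
    if not converged:
        warnings.warn("denoise EM did not converge; returning best iterate",
                      stacklevel=2)
    log_g = np.log(pis)[None, :] + norm.logpdf(x[:, None], means[None, :], np.sqrt(var))
    log_noise = np.full(len(x), np.log(max(pi_noise, 1e-300)))
    log_all = np.column_stack([log_noise, log_g])
    signal_w = 1.0 - np.exp(log_noise - logsumexp(log_all, axis=1))
    return signal_w, float(pi_noise)


def fit_ploidy_models(
    values: np.ndarray,
    weights: np.ndarray | None = None,
    sample_id: str = "",
    noise_fraction: float = 0.0,
    n_bins: int = 100,
    seed: int = 0,
    n_restarts: int = 5,
) -> PloidyFit:
    """Fit free and ploidy-fixed mixtures and select the best ploidy.

    The fixed model for ploidy p has component means pinned at k/p for
    k = 1..p-1, uniform component weights and a free common variance. The
    free model (three free means and weights, common variance) is fitted
    from the canonical tetraploid initialization, ``n_restarts`` seeded
    random initializations, and from each converged fixed model's mean
    vector (padded to three components), which guarantees — EM being
    monotone and each fixed model lying in the free parameter space — that
    the free log-likelihood is at least each fixed one. Ploidy is the
    hypothesis with the smallest likelihood loss relative to the free
    model, ties broken toward lower ploidy. ``r_squared`` measures how well
    the selected fixed model reproduces the empirical allele-balance
    histogram (``n_bins`` bins on (0, 1), noise weights applied).
    """
    x = np.asarray(values, dtype=float)
    w = np.ones_like(x) if weights is None else np.asarray(weights, dtype=float)

    fixed: dict[int, FittedMixture] = {}
    for p, mu in PLOIDY_MEANS.items():
        fixed[p] = _em_gmm(x, w, mu, fix_means=True, fix_weights=True)

    inits: list[tuple[np.ndarray, np.ndarray | None, float]] = [
        (PLOIDY_MEANS[4], None, 0.01)
    ]
    rng = np.random.default_rng(seed)
    for _ in range(n_restarts):
        inits.append((np.sort(rng.uniform(0.1, 0.9, size=3)), None, 0.01))
    for p, fit in fixed.items():
        # start one free-model run exactly at each fixed optimum (last mean
        # repeated with its weight split keeps the density identical), so
        # monotone EM guarantees the free likelihood dominates the fixed one
        k = len(fit.means)
        mu0 = np.concatenate([fit.means, np.repeat(fit.means[-1], 3 - k)])
        pis0 = np.full(3, 1.0 / k)
        pis0[k - 1 :] = (1.0 / k) / (3 - k + 1)
        inits.append((mu0, pis0, fit.var))
    free = None
    for mu0, pis0, var0 in inits:
        cand = _em_gmm(x, w, np.asarray(mu0, dtype=float), fix_means=False,
                       pis0=pis0, var=var0)
        if free is None or cand.loglik > free.loglik:
            free = cand
    assert free is not None

    delta = {p: free.loglik - fixed[p].loglik for p in fixed}
    best_ploidy = min(sorted(delta), key=lambda p: (delta[p], p))

    edges = np.linspace(0.0, 1.0, n_bins + 1)
    counts, _ = np.histogram(x, bins=edges, weights=w)
    obs = counts / counts.sum() if counts.sum() > 0 else counts
    pred = fixed[best_ploidy].bin_masses(edges)
    pred = pred / pred.sum() if pred.sum() > 0 else pred
    ss_res = float(((obs - pred) ** 2).sum())
    ss_tot = float(((obs - obs.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    r2 = float(min(max(r2, 0.0), 1.0))

    models: dict[object, FittedMixture] = {"free": free}
    models.update(fixed)
    return PloidyFit(
        sample_id=sample_id,
        n_sites=len(x),
        loglik_free=free.loglik,
        loglik_fixed={p: f.loglik for p, f in fixed.items()},
        delta=delta,
        best_ploidy=best_ploidy,
        r_squared=r2,
        noise_fraction=noise_fraction,
        models=models,
        values=x,
        site_weights=w,
    )


def fit_sample(
    table: VariantTable,
    sample_id: str,
    min_depth: int = 20,
    ratio_bounds: tuple[float, float] = (0.1, 0.9),
    min_gq: int = 20,
    min_sites: int = 100,
    seed: int = 0,
) -> PloidyFit:
    """Site selection, denoising and model fitting for one sample."""
    vals = select_sites(
        table, sample_id, min_depth=min_depth, ratio_bounds=ratio_bounds,
        min_gq=min_gq, min_sites=min_sites,
    )
    sw, noise = denoise(vals, min_sites=min_sites, seed=seed)
    return fit_ploidy_models(
        vals, weights=sw, sample_id=sample_id, noise_fraction=noise, seed=seed
    )


PLOIDY_NAMES = {2: "diploid", 3: "triploid", 4: "tetraploid"}


def write_fits(fits: list[PloidyFit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "sample_id\tn_sites\tnoise_fraction\tdelta_diploid\tdelta_triploid\t"
            "delta_tetraploid\tbest_ploidy\tr_squared\n"
        )
        for f in fits:
            fh.write(
                f"{f.sample_id}\t{f.n_sites}\t{f.noise_fraction:.6f}\t"
                f"{f.delta[2]:.6f}\t{f.delta[3]:.6f}\t{f.delta[4]:.6f}\t"
                f"{f.best_ploidy}\t{f.r_squared:.6f}\n"
            )


def ploidy_report(
    fits: list[PloidyFit],
    out_path: str | Path,
    table_path: str | Path | None = None,
) -> None:
    """Per-sample allele-balance histograms with the best fixed model overlaid."""
    if not fits:
        raise ValueError("no fits to plot")
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(fits)
    ncol = min(4, n)
    nrow = (n + ncol - 1) // ncol
    fig, axes = plt.subplots(
        nrow, ncol, figsize=(3 * ncol, 2.4 * nrow), squeeze=False
    )
    grid = np.linspace(0.01, 0.99, 300)
    for ax, fit in zip(axes.ravel(), fits):
        ax.hist(
            fit.values, bins=40, range=(0, 1), weights=fit.site_weights,
            density=True, color="0.8",
        )
        best = fit.models[fit.best_ploidy]
        ax.plot(grid, best.density(grid), "C3", lw=1.2)
        ax.set_title(
            f"{fit.sample_id}: {PLOIDY_NAMES[fit.best_ploidy]} "
            f"(R²={fit.r_squared:.2f})",
            fontsize=8,
        )
        ax.set_xlim(0, 1)
    for ax in axes.ravel()[n:]:
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    if table_path is not None:
        write_fits(fits, table_path)
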