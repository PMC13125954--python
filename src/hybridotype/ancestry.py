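"""Two-pool ancestry proportions (K = 2) and principal component analysis.

The admixture model: a diploid individual draws each allele from the
lessonae (L) pool with probability q and from the ridibundus (R) pool with
probability 1 - q, so at locus j the L-oriented allele count g_j ~
Binomial(2, f_j) with f_j = q * p_Lj + (1 - q) * p_Rj, where p_Lj and p_Rj
are the pool allele frequencies. With known parental samples the
frequencies are estimated directly and q is fitted per sample by bounded
maximum likelihood (supervised mode); without labels, pool frequencies and
all q values are fitted jointly by EM (unsupervised mode, K fixed at 2).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .panel import DiagnosticPanel
from .vcf_io import GroupLabels, VariantTable

logger = logging.getLogger(__name__)


@dataclass
class AncestryEstimate:
    sample_id: str
    q_l: float  # fraction of ancestry from the L pool
    loglik: float
    n_loci: int
    mode: str  # "supervised" | "unsupervised"


@dataclass
class PcaResult:
    sample_ids: list[str]
    coordinates: np.ndarray  # (n_samples, k)
    variance_fractions: np.ndarray  # (k,), non-increasing


def _biallelic_records(table: VariantTable):
    return [r for r in table.records if r.is_snp and r.is_biallelic]


def _alt_dosage_matrix(table: VariantTable) -> np.ndarray:
    """Alt-allele counts per sample x biallelic locus; -1 for missing."""
    recs = _biallelic_records(table)
    mat = np.full((table.n_samples, len(recs)), -1.0)
    for j, rec in enumerate(recs):
        for i, gt in enumerate(rec.genotypes):
            if gt is not None:
                mat[i, j] = sum(1 for a in gt if a == 1)
    return mat


def _panel_l_dosage(
    table: VariantTable, panel: DiagnosticPanel, sample_id: str
) -> tuple[np.ndarray, np.ndarray]:
    """(L-allele copies, total called copies) per informative panel locus."""
    si = table.sample_index(sample_id)
    loci = panel.locus_map()
    g, m = [], []
    for rec in table.records:
        loc = loci.get((rec.marker_id, rec.pos))
        if loc is None:
            continue
        gt = rec.genotypes[si]
        if gt is None:
            continue
        states = [rec.alleles[a] for a in gt]
        if any(s not in (loc.l_allele, loc.r_allele) for s in states):
            continue
        g.append(sum(s == loc.l_allele for s in states))
        m.append(len(states))
    return np.asarray(g, dtype=float), np.asarray(m, dtype=float)


def estimate_q_supervised(
    table: VariantTable,
    labels: GroupLabels,
    sample_id: str,
    panel: DiagnosticPanel | None = None,
) -> AncestryEstimate:
    """Maximum-likelihood ancestry fraction with known parental pools.

    When a diagnostic ``panel`` is given, the pool frequencies at those
    loci are exactly 1 (L pool) and 0 (R pool) by construction, the
    binomial likelihood is maximized in closed form by the sample's
    L-allele dosage fraction, and that closed form is returned. Otherwise
    pool frequencies are estimated from the L- and R-labelled samples with
    a pseudocount, p_hat = (count + 0.5) / (2n + 1), and q is fitted
    numerically over [0, 1] to tolerance 1e-6.
    """
    if panel is not None:
        g, m = _panel_l_dosage(table, panel, sample_id)
        if len(g) == 0:
            raise ValueError(f"sample {sample_id!r}: no informative loci")
        q = float(g.sum() / m.sum())
        qc = min(max(q, 1e-12), 1 - 1e-12)
        ll = float((g * np.log(qc) + (m - g) * np.log(1 - qc)).sum())
        return AncestryEstimate(sample_id, q, ll, len(g), "supervised")

    labels.validate_against(table)
    recs = _biallelic_records(table)
    l_idx = [table.sample_index(s) for s in labels.samples_in_group("L")]
    r_idx = [table.sample_index(s) for s in labels.samples_in_group("R")]
    if not l_idx or not r_idx:
        raise ValueError("supervised mode needs L and R labelled samples")
    si = table.sample_index(sample_id)
    p_l, p_r, g = [], [], []
    for rec in recs:
        gt = rec.genotypes[si]
        if gt is None:
            continue
        cl = [a for i in l_idx if (x := rec.genotypes[i]) is not None for a in x]
        cr = [a for i in r_idx if (x := rec.genotypes[i]) is not None for a in x]
        if not cl or not cr:
            continue
        # frequency of the ALT allele in each pool, with pseudocount
        p_l.append((sum(cl) + 0.5) / (len(cl) + 1))
        p_r.append((sum(cr) + 0.5) / (len(cr) + 1))
        g.append(sum(1 for a in gt if a == 1))
    if not g:
        raise ValueError(f"sample {sample_id!r}: no informative loci")
    p_l = np.asarray(p_l)
    p_r = np.asarray(p_r)
    g = np.asarray(g, dtype=float)

    def negll(q: float) -> float:
        f = np.clip(q * p_l + (1 - q) * p_r, 1e-12, 1 - 1e-12)
        return -float((g * np.log(f) + (2 - g) * np.log(1 - f)).sum())

    res = minimize_scalar(negll, bounds=(0.0, 1.0), method="bounded",
                          options={"xatol": 1e-6})
    return AncestryEstimate(sample_id, float(res.x), -float(res.fun),
                            len(g), "supervised")


def estimate_q_unsupervised(
    table: VariantTable,
    k: int = 2,
    seed: int = 0,
    n_replicates: int = 25,
    max_iter: int = 2000,
    tol: float = 1e-8,
    labels: GroupLabels | None = None,
) -> list[AncestryEstimate]:
    """Joint EM for pool allele frequencies and per-sample ancestry (K = 2).

    Runs ``n_replicates`` EM replicates from seeded random starts and
    returns the estimates from the replicate with the best log-likelihood.
    Pool 0 is reported as the L pool; when ``labels`` are supplied the two
    pools are aligned to L/R by correlating the fitted frequencies with
    frequencies observed in the labelled parental samples, otherwise the
    orientation is arbitrary (q and 1 - q are interchangeable).
    """
    if k != 2:
        raise ValueError("only K=2 (two parental gene pools) is supported")
    if table.n_samples < 3:
        raise ValueError("unsupervised estimation needs >= 3 samples")
    dos = _alt_dosage_matrix(table)
    if (dos < 0).any():
        raise ValueError("missing genotypes present; filter the table first")
    n, m = dos.shape
    rng = np.random.default_rng(seed)

    best_ll = -np.inf
    best: tuple[np.ndarray, np.ndarray] | None = None
    for _ in range(n_replicates):
        q = rng.uniform(0.05, 0.95, size=n)
        p = np.clip(
            dos.mean(axis=0) / 2 + rng.normal(0, 0.1, size=(2, m)), 0.01, 0.99
        )
        prev = -np.inf
        for _ in range(max_iter):
            # E-step: expected pool-of-origin counts per (sample, locus, allele)
            f = np.clip(q[:, None] * p[0] + (1 - q[:, None]) * p[1], 1e-12, 1 - 1e-12)
            # posterior that a carried ALT (resp. REF) copy came from pool 0
            a_alt = q[:, None] * p[0] / f
            a_ref = q[:, None] * (1 - p[0]) / (1 - f)
            ll = float((dos * np.log(f) + (2 - dos) * np.log(1 - f)).sum())
            e_alt0 = dos * a_alt          # ALT copies from pool 0
            e_ref0 = (2 - dos) * a_ref    # REF copies from pool 0
            q = (e_alt0 + e_ref0).sum(axis=1) / (2 * m)
            q = np.clip(q, 1e-6, 1 - 1e-6)
            denom0 = (e_alt0 + e_ref0).sum(axis=0)
            p0 = e_alt0.sum(axis=0) / np.maximum(denom0, 1e-12)
            e_alt1 = dos - e_alt0
            e_ref1 = (2 - dos) - e_ref0
            denom1 = (e_alt1 + e_ref1).sum(axis=0)
            p1 = e_alt1.sum(axis=0) / np.maximum(denom1, 1e-12)
            p = np.clip(np.vstack([p0, p1]), 1e-6, 1 - 1e-6)
            if abs(ll - prev) < tol and np.isfinite(prev):
                break
            prev = ll
        else:
            warnings.warn("admixture EM did not converge; using best iterate",
                          stacklevel=2)
        if ll > best_ll:
            best_ll = ll
            best = (q.copy(), p.copy())
    assert best is not None
    q, p = best

    if labels is not None:
        l_idx = [table.sample_index(s) for s in labels.samples_in_group("L")
                 if s in table.sample_ids]
        if l_idx and np.mean(q[l_idx]) < 0.5:
            q = 1 - q
            p = p[::-1]

    return [
        AncestryEstimate(s, float(q[i]), best_ll, m, "unsupervised")
        for i, s in enumerate(table.sample_ids)
    ]


def run_pca(table: VariantTable, n_components: int = 2) -> PcaResult:
    """PCA of the variance-standardized alt-allele dosage matrix.

    Columns are centered at twice the mean allele frequency and scaled by
    the binomial standard deviation sqrt(p(1-p)); monomorphic loci carry no
    information and are dropped. Coordinates come from the singular value
    decomposition; variance fractions are relative to the retained matrix.
    """
    if table.n_samples < 2:
        raise ValueError("PCA needs >= 2 samples")
    dos = _alt_dosage_matrix(table)
    if dos.shape[1] < 1:
        raise ValueError("PCA needs >= 1 biallelic locus")
    if (dos < 0).any():
        raise ValueError("missing genotypes present; filter the table first")
    p = dos.mean(axis=0) / 2
    keep = (p > 0) & (p < 1)
    if not keep.any():
        raise ValueError("all loci are monomorphic; PCA undefined")
    x = (dos[:, keep] - 2 * p[keep]) / np.sqrt(p[keep] * (1 - p[keep]))
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    k = min(n_components, len(s))
    coords = u[:, :k] * s[:k]
    total = float((s**2).sum())
    fracs = s[:k] ** 2 / total if total > 0 else np.zeros(k)
    return PcaResult(
        sample_ids=list(table.sample_ids),
        coordinates=coords,
        variance_fractions=fracs,
    )


def write_ancestry(estimates: list[AncestryEstimate], path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tq_l\tmode\tn_loci\n")
        for e in estimates:
            fh.write(f"{e.sample_id}\t{e.q_l:.6f}\t{e.mode}\t{e.n_loci}\n")


def write_pca(result: PcaResult, path) -> None:
    k = result.coordinates.shape[1]
    with open(path, "w") as fh:
        fh.write("sample_id\t" + "\t".join(f"PC{i+1}" for i in range(k)) + "\n")
        for i, s in enumerate(result.sample_ids):
            coords = "\t".join(f"{c:.6f}" for c in result.coordinates[i])
            fh.write(f"{s}\t{coords}\n")


def ancestry_barplot(estimates: list[AncestryEstimate], out_path) -> None:
    """Stacked per-sample ancestry bars (L fraction vs R fraction)."""
    if not estimates:
        raise ValueError("no estimates to plot")
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(max(4, 0.3 * len(estimates)), 3))
    xs = np.arange(len(estimates))
    ql = np.array([e.q_l for e in estimates])
    ax.bar(xs, ql, color="C2", label="lessonae")
    ax.bar(xs, 1 - ql, bottom=ql, color="C0", label="ridibundus")
    ax.set_xticks(xs)
    ax.set_xticklabels([e.sample_id for e in estimates], rotation=90, fontsize=6)
    ax.set_ylabel("ancestry fraction")
    ax.legend(fontsize=7, frameon=False, loc="center left", bbox_to_anchor=(1, 0.5))
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)


def pca_plot(result: PcaResult, out_path, labels: GroupLabels | None = None) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    if labels is not None:
        groups = [labels[s] for s in result.sample_ids]
        for g in sorted(set(groups)):
            sel = [i for i, x in enumerate(groups) if x == g]
            ax.scatter(result.coordinates[sel, 0],
                       result.coordinates[sel, 1] if result.coordinates.shape[1] > 1
                       else np.zeros(len(sel)),
                       label=g, s=25)
        ax.legend(frameon=False)
    else:
        ax.scatter(result.coordinates[:, 0],
                   result.coordinates[:, 1] if result.coordinates.shape[1] > 1
                   else np.zeros(len(result.sample_ids)), s=25)
    ax.set_xlabel(f"PC1 ({100 * result.variance_fractions[0]:.0f}%)")
    if len(result.variance_fractions) > 1:
        ax.set_ylabel(f"PC2 ({100 * result.variance_fractions[1]:.0f}%)")
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
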