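"""Allele-depth-ratio profiling and parental-genome dosage classification.

At a diagnostic locus the fraction of reads supporting the lessonae (L)
allele estimates the L-genome dosage fraction of the individual: a diploid
L/R hybrid averages 0.5, a triploid with two L copies (LLR) 2/3 and a
triploid with two R copies (LRR) 1/3. Ratios are computed from the AD field
irrespective of the called genotype, so they remain informative even where
a diploid caller has miscalled a triploid site.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .panel import DiagnosticPanel
from .vcf_io import VariantTable

#: Canonical mean-ratio centers for each dosage class.
DOSAGE_CENTERS = {
    "diploid": 0.5,
    "triploid_LL_R": 2.0 / 3.0,
    "triploid_L_RR": 1.0 / 3.0,
}


@dataclass
class AlleleRatioProfile:
    """Per-sample L-allele depth ratios across diagnostic loci."""

    sample_id: str
    ratios: np.ndarray
    mean_ratio: float
    hist_edges: np.ndarray
    hist_density: np.ndarray  # normalized: sums to 1
    n_sites: int


@dataclass
class DosageCall:
    sample_id: str
    call: str  # diploid | triploid_LL_R | triploid_L_RR | ambiguous
    mean_ratio: float
    decision_statistic: float  # |mean_ratio - nearest center|
    n_sites: int = 0


def ratio_profile(
    table: VariantTable,
    panel: DiagnosticPanel,
    sample_id: str,
    min_total_depth: int = 1,
    n_bins: int = 40,
) -> AlleleRatioProfile:
    """L-allele depth ratio at every usable panel locus for one sample.

    A locus is usable when the summed depth over the L and R alleles is at
    least ``min_total_depth``. Raises if no locus qualifies.
    """
    si = table.sample_index(sample_id)
    loci = panel.locus_map()
    ratios: list[float] = []
    for rec in table.records:
        loc = loci.get((rec.marker_id, rec.pos))
        if loc is None:
            continue
        alleles = rec.alleles
        try:
            l_idx = alleles.index(loc.l_allele)
            r_idx = alleles.index(loc.r_allele)
        except ValueError:
            continue
        ad = rec.allele_depths[si]
        if ad[l_idx] < 0 or ad[r_idx] < 0:
            continue
        total = int(ad[l_idx]) + int(ad[r_idx])
        if total >= max(min_total_depth, 1):
            ratios.append(int(ad[l_idx]) / total)
    if not ratios:
        raise ValueError(f"sample {sample_id!r}: no panel loci with usable depth")
    arr = np.asarray(ratios)
    counts, edges = np.histogram(arr, bins=n_bins, range=(0.0, 1.0))
    density = counts / counts.sum()
    return AlleleRatioProfile(
        sample_id=sample_id,
        ratios=arr,
        mean_ratio=float(arr.mean()),
        hist_edges=edges,
        hist_density=density,
        n_sites=len(arr),
    )


def classify_dosage(
    profile: AlleleRatioProfile,
    centers: dict[str, float] | None = None,
    margin: float = 0.07,
    min_sites: int = 50,
) -> DosageCall:
    """Nearest-center classification of the mean allele ratio.

    The call is the dosage class whose canonical center (0.5, 2/3 or 1/3)
    lies nearest the sample's mean ratio, provided the distance is within
    ``margin``; otherwise ``ambiguous``. Deterministic stand-in for reading
    peaks off the per-sample ratio histograms; the GMM ploidy module
    provides the likelihood-based test.
    """
    if profile.n_sites < min_sites:
        raise ValueError(
            f"sample {profile.sample_id!r}: {profile.n_sites} usable sites "
            f"< required {min_sites}"
        )
    centers = centers or DOSAGE_CENTERS
    best_call = min(centers, key=lambda c: abs(profile.mean_ratio - centers[c]))
    stat = abs(profile.mean_ratio - centers[best_call])
    call = best_call if stat <= margin else "ambiguous"
    return DosageCall(
        sample_id=profile.sample_id,
        call=call,
        mean_ratio=profile.mean_ratio,
        decision_statistic=stat,
        n_sites=profile.n_sites,
    )


def write_dosage_calls(calls: list[DosageCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tn_sites\tmean_ratio\tcall\tdecision_statistic\n")
        for c in calls:
            fh.write(
                f"{c.sample_id}\t{c.n_sites}\t{c.mean_ratio:.6f}\t{c.call}\t"
                f"{c.decision_statistic:.6f}\n"
            )


def dosage_histogram_plot(
    profiles: list[AlleleRatioProfile], out_path: str | Path
) -> None:
    """Frequency-vs-allele-ratio curves, one per sample, on a shared axis."""
    if not profiles:
        raise ValueError("no profiles to plot")
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for p in profiles:
        mids = 0.5 * (p.hist_edges[:-1] + p.hist_edges[1:])
        ax.plot(mids, p.hist_density, alpha=0.7, lw=1.0, label=p.sample_id)
    for x in (1 / 3, 0.5, 2 / 3):
        ax.axvline(x, color="0.85", lw=0.8, zorder=0)
    ax.set_xlabel("L-allele depth ratio")
    ax.set_ylabel("fraction of SNPs")
    if len(profiles) <= 12:
        ax.legend(fontsize=7, frameon=False)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
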