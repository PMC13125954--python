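"""Hybrid index and interclass heterozygosity on the diagnostic panel.

The hybrid index of a sample is the fraction of its alleles at diagnostic
loci that derive from the ridibundus (R) pool: 0 for a pure lessonae
individual, 1 for a pure ridibundus one, 0.5 for an F1 hybrid. Interclass
heterozygosity is the fraction of diagnostic loci carrying one allele from
each pool: 0 in parentals, 1 in F1s. Together they place each individual in
the classic "triangle plot", whose lower boundary under Hardy-Weinberg
equilibrium is h -> 2*h*(1-h).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .panel import DiagnosticPanel
from .vcf_io import VariantTable


@dataclass
class HybridScore:
    sample_id: str
    hybrid_index: float
    interclass_het: float
    n_loci: int


def score_sample(
    table: VariantTable, panel: DiagnosticPanel, sample_id: str
) -> HybridScore:
    """Score one sample's panel genotypes.

    ``hybrid_index`` = (R alleles carried) / (alleles called at panel loci);
    ``interclass_het`` = (loci with both an L and an R allele) / n_loci.
    Loci missing from the table or with a missing genotype in this sample
    are dropped from ``n_loci``. Genotypes are the (diploid) calls as they
    stand — triploids genotyped by a diploid caller are scored from those
    calls, which is exactly how the bias artifact in such data arises.
    """
    si = table.sample_index(sample_id)
    loci = panel.locus_map()
    n_loci = 0
    r_alleles = 0
    total_alleles = 0
    het_loci = 0
    for rec in table.records:
        loc = loci.get((rec.marker_id, rec.pos))
        if loc is None:
            continue
        gt = rec.genotypes[si]
        if gt is None:
            continue
        alleles = rec.alleles
        states = [alleles[a] for a in gt]
        if any(s not in (loc.l_allele, loc.r_allele) for s in states):
            continue  # third allele at a diagnostic locus: uninformative
        n_loci += 1
        total_alleles += len(states)
        n_r = sum(s == loc.r_allele for s in states)
        r_alleles += n_r
        if 0 < n_r < len(states):
            het_loci += 1
    if n_loci == 0:
        raise ValueError(f"sample {sample_id!r}: no informative panel loci")
    return HybridScore(
        sample_id=sample_id,
        hybrid_index=r_alleles / total_alleles,
        interclass_het=het_loci / n_loci,
        n_loci=n_loci,
    )


def score_cohort(
    table: VariantTable, panel: DiagnosticPanel, sample_ids: list[str] | None = None
) -> list[HybridScore]:
    """Score every sample (or the given subset)."""
    ids = sample_ids if sample_ids is not None else table.sample_ids
    return [score_sample(table, panel, s) for s in ids]


def hwe_boundary(h: float) -> float:
    """Expected heterozygosity 2*h*(1-h) at hybrid index h under HWE.

    Individuals cannot fall below this curve on the triangle plot when
    their loci are in Hardy-Weinberg equilibrium at ancestry fraction h.
    """
    if not 0.0 <= h <= 1.0:
        raise ValueError(f"hybrid index must be in [0, 1], got {h}")
    return 2.0 * h * (1.0 - h)


def write_scores(scores: list[HybridScore], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\thybrid_index\tinterclass_het\tn_loci\n")
        for s in scores:
            fh.write(
                f"{s.sample_id}\t{s.hybrid_index:.6f}\t{s.interclass_het:.6f}\t{s.n_loci}\n"
            )


def triangle_report(
    scores: list[HybridScore],
    out_path: str | Path,
    table_path: str | Path | None = None,
) -> None:
    """Write the triangle scatter plot (and optionally the score table).

    The plot shows interclass heterozygosity against hybrid index with the
    feasible-region triangle and the HWE boundary curve.
    """
    if not scores:
        raise ValueError("no scores to plot")
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import numpy as np

    fig, ax = plt.subplots(figsize=(5, 4.5))
    h = np.linspace(0, 1, 201)
    ax.plot(h, [hwe_boundary(x) for x in h], "k:", label="HWE boundary")
    ax.plot([0, 0.5, 1, 0], [0, 1, 0, 0], color="0.7", lw=0.8)
    ax.scatter(
        [s.hybrid_index for s in scores],
        [s.interclass_het for s in scores],
        s=25,
        alpha=0.8,
        zorder=3,
    )
    ax.set_xlabel("hybrid index (0 = lessonae, 1 = ridibundus)")
    ax.set_ylabel("interclass heterozygosity")
    ax.set_xlim(-0.02, 1.02)
    ax.set_ylim(-0.02, 1.05)
    ax.legend(loc="upper right", frameon=False)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    if table_path is not None:
        write_scores(scores, table_path)
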