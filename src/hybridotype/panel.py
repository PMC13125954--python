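"""Ascertainment of species-diagnostic SNPs between two parental gene pools.

A locus is *100% diagnostic* when every called allele in all lessonae (L)
samples is one state and every called allele in all ridibundus (R) samples
is the other state. Any allele at such a locus then identifies its parental
origin unambiguously, which is what the hybrid-index, dosage and ancestry
analyses rely on. Hybrid (E) and unknown (U) samples play no part in
ascertainment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

from .vcf_io import GroupLabels, VariantRecord, VariantTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PanelLocus:
    marker_id: str
    pos: int
    l_allele: str
    r_allele: str


@dataclass
class DiagnosticPanel:
    """Loci fixed for alternate alleles between the L and R pools."""

    loci: list[PanelLocus]
    n_l_samples: int
    n_r_samples: int

    def __len__(self) -> int:
        return len(self.loci)

    def locus_map(self) -> dict[tuple[str, int], PanelLocus]:
        return {(loc.marker_id, loc.pos): loc for loc in self.loci}


def _fixed_allele(rec: VariantRecord, indices: list[int]) -> int | None:
    """Allele index fixed across the given samples, or None."""
    allele: int | None = None
    for i in indices:
        gt = rec.genotypes[i]
        if gt is None:
            return None
        for a in gt:
            if allele is None:
                allele = a
            elif a != allele:
                return None
    return allele


def ascertain_panel(table: VariantTable, labels: GroupLabels) -> DiagnosticPanel:
    """Find all loci with fixed allelic differences between L and R samples.

    Requires at least one sample labelled L and one labelled R. Loci where
    either parental group contains a heterozygote, a missing genotype, or
    where the two groups share their fixed allele are excluded. An empty
    panel is returned (with a warning) when no locus qualifies.
    """
    labels.validate_against(table)
    l_idx = [table.sample_index(s) for s in labels.samples_in_group("L")
             if s in table.sample_ids]
    r_idx = [table.sample_index(s) for s in labels.samples_in_group("R")
             if s in table.sample_ids]
    if not l_idx or not r_idx:
        raise ValueError(
            f"panel ascertainment needs >=1 L and >=1 R sample "
            f"(got {len(l_idx)} L, {len(r_idx)} R)"
        )
    loci: list[PanelLocus] = []
    for rec in table.records:
        if not (rec.is_snp and rec.is_biallelic):
            continue
        a_l = _fixed_allele(rec, l_idx)
        a_r = _fixed_allele(rec, r_idx)
        if a_l is None or a_r is None or a_l == a_r:
            continue
        alleles = rec.alleles
        loci.append(
            PanelLocus(rec.marker_id, rec.pos, alleles[a_l], alleles[a_r])
        )
    if not loci:
        logger.warning("no diagnostic loci found between L and R samples")
    return DiagnosticPanel(loci=loci, n_l_samples=len(l_idx), n_r_samples=len(r_idx))


def write_panel(panel: DiagnosticPanel, path: str | Path) -> None:
    """Serialize as TSV: marker_id, pos, l_allele, r_allele."""
    with open(path, "w") as fh:
        fh.write("marker_id\tpos\tl_allele\tr_allele\n")
        for loc in panel.loci:
            fh.write(f"{loc.marker_id}\t{loc.pos}\t{loc.l_allele}\t{loc.r_allele}\n")


def read_panel(path: str | Path, n_l_samples: int = 0, n_r_samples: int = 0) -> DiagnosticPanel:
    loci = []
    lines = Path(path).read_text().splitlines()
    for line in lines[1:]:
        if not line.strip():
            continue
        marker, pos, la, ra = line.split("\t")
        loci.append(PanelLocus(marker, int(pos), la, ra))
    return DiagnosticPanel(loci=loci, n_l_samples=n_l_samples, n_r_samples=n_r_samples)
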