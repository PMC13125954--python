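"""Builders for small hand-constructed variant tables used across tests."""

from __future__ import annotations

import numpy as np

from hybridotype.vcf_io import VariantRecord, VariantTable


def make_record(
    marker_id: str,
    pos: int,
    ref: str,
    alts: tuple[str, ...],
    genotypes: list[tuple[int, ...] | None],
    ads: list[tuple[int, ...]] | None = None,
    dps: list[int] | None = None,
    gqs: list[int] | None = None,
) -> VariantRecord:
    n = len(genotypes)
    n_alleles = 1 + len(alts)
    if ads is None:
        ads = [tuple([25] * n_alleles) for _ in range(n)]
    if dps is None:
        dps = [sum(max(v, 0) for v in ad) for ad in ads]
    if gqs is None:
        gqs = [99] * n
    return VariantRecord(
        marker_id=marker_id,
        pos=pos,
        ref=ref,
        alts=alts,
        genotypes=list(genotypes),
        allele_depths=np.array(ads, dtype=int),
        depths=np.array(dps, dtype=int),
        gqs=np.array(gqs, dtype=int),
    )


def make_table(sample_ids: list[str], records: list[VariantRecord]) -> VariantTable:
    return VariantTable(sample_ids=sample_ids, records=records)


def diagnostic_table(
    sample_ids: list[str],
    genotype_rows: list[list[tuple[int, ...]]],
    ref: str = "A",
    alt: str = "G",
) -> VariantTable:
    """One marker per row; REF is the L-allele, ALT the R-allele."""
    records = [
        make_record(f"m{j:04d}", 10, ref, (alt,), row)
        for j, row in enumerate(genotype_rows, 1)
    ]
    return make_table(sample_ids, records)
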