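"""Multi-sample VCF input/output and the hard genotype filter chain.

The in-memory container is :class:`VariantTable`, a thin ordered list of
:class:`VariantRecord` objects carrying, per sample, the genotype call (GT),
per-allele read depths (AD), total depth (DP) and genotype quality (GQ) —
the four FORMAT fields every downstream analysis in this package consumes.

Filtering follows the hard-filter chain typically applied to jointly
genotyped target-capture data before hybrid-zone analyses: indels and
multi-allelic sites are removed, then any site with a missing genotype, a
per-sample depth below ``dp_min`` or a genotype quality below ``gq_min`` in
*any* individual, and finally sites with a minor allele frequency below
``maf_min``. A thinning step keeps one SNP per reference marker.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import pysam

logger = logging.getLogger(__name__)

_BASES = frozenset("ACGT")

#: Valid sample group codes: lessonae, ridibundus, esculentus, unknown.
GROUP_CODES = ("L", "R", "E", "U")


class VcfFormatError(ValueError):
    """Raised when a VCF lacks a FORMAT field required downstream."""


@dataclass
class VariantRecord:
    """A single variant site with per-sample calls.

    ``genotypes[i]`` is a tuple of allele indices for sample *i* (length =
    call ploidy) or ``None`` when the genotype is missing.  ``allele_depths``
    has one row per sample and one column per allele (REF first); missing AD
    is stored as ``-1``.  ``depths`` and ``gqs`` use ``-1`` for missing.
    """

    marker_id: str
    pos: int  # 1-based, as in the VCF
    ref: str
    alts: tuple[str, ...]
    genotypes: list[tuple[int, ...] | None]
    allele_depths: np.ndarray
    depths: np.ndarray
    gqs: np.ndarray

    @property
    def n_alleles(self) -> int:
        return 1 + len(self.alts)

    @property
    def alleles(self) -> tuple[str, ...]:
        return (self.ref,) + self.alts

    @property
    def is_snp(self) -> bool:
        return len(self.ref) == 1 and all(
            len(a) == 1 and a in _BASES for a in self.alts
        )

    @property
    def is_biallelic(self) -> bool:
        return len(self.alts) == 1

    def called_allele_counts(self) -> np.ndarray:
        """Counts of each allele over all non-missing genotype calls."""
        counts = np.zeros(self.n_alleles, dtype=int)
        for gt in self.genotypes:
            if gt is None:
                continue
            for a in gt:
                counts[a] += 1
        return counts

    def minor_allele_frequency(self) -> float:
        """MAF over called alleles; NaN when nothing is called."""
        counts = self.called_allele_counts()
        total = counts.sum()
        if total == 0:
            return float("nan")
        freqs = counts / total
        return float(np.sort(freqs)[:-1].sum()) if self.n_alleles > 1 else 0.0


@dataclass
class VariantTable:
    """Ordered collection of variant records over a fixed sample panel."""

    sample_ids: list[str]
    records: list[VariantRecord] = field(default_factory=list)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def __len__(self) -> int:
        return len(self.records)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"sample {sample_id!r} not in table") from None

    def marker_ids(self) -> list[str]:
        """Distinct marker ids in order of first appearance."""
        seen: dict[str, None] = {}
        for rec in self.records:
            seen.setdefault(rec.marker_id, None)
        return list(seen)


@dataclass
class GroupLabels:
    """Mapping sample_id -> group code (L, R, E or U)."""

    labels: dict[str, str]

    def __post_init__(self) -> None:
        bad = {s: g for s, g in self.labels.items() if g not in GROUP_CODES}
        if bad:
            raise ValueError(f"invalid group codes: {bad}; expected {GROUP_CODES}")

    def __getitem__(self, sample_id: str) -> str:
        return self.labels[sample_id]

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s, g in self.labels.items() if g == group]

    def validate_against(self, table: VariantTable) -> None:
        missing = [s for s in table.sample_ids if s not in self.labels]
        if missing:
            raise ValueError(f"samples without a group label: {missing}")


def read_labels(path: str | Path) -> GroupLabels:
    """Read a two-column tab-separated ``sample_id<TAB>group`` file."""
    labels: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
        labels[parts[0]] = parts[1]
    return GroupLabels(labels)


def write_labels(labels: GroupLabels, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sample, group in labels.labels.items():
            fh.write(f"{sample}\t{group}\n")


def read_vcf(path: str | Path) -> VariantTable:
    """Read a VCF (v4.x) with GT, AD, DP and GQ FORMAT fields.

    Multi-allelic records and indels are retained (the filter chain rejects
    them); missing genotypes are represented explicitly as ``None``.

    Raises
    ------
    VcfFormatError
        If the AD FORMAT field is absent (allele depths are required by the
        dosage and ploidy analyses).
    """
    path = str(path)
    with pysam.VariantFile(path) as vcf:
        if "AD" not in vcf.header.formats:
            raise VcfFormatError(
                f"{path}: FORMAT field AD (per-allele depths) is missing; "
                "it is required by the allele-ratio analyses"
            )
        samples = list(vcf.header.samples)
        records: list[VariantRecord] = []
        for rec in vcf:
            n_alleles = len(rec.alleles)
            gts: list[tuple[int, ...] | None] = []
            ads = np.full((len(samples), n_alleles), -1, dtype=int)
            dps = np.full(len(samples), -1, dtype=int)
            gqs = np.full(len(samples), -1, dtype=int)
            for i, s in enumerate(samples):
                call = rec.samples[s]
                gt = call.get("GT")
                if gt is None or any(a is None for a in gt):
                    gts.append(None)
                else:
                    gts.append(tuple(int(a) for a in gt))
                ad = call.get("AD")
                if ad is not None and not any(v is None for v in ad):
                    ads[i, : len(ad)] = ad
                dp = call.get("DP")
                if dp is not None:
                    dps[i] = dp
                gq = call.get("GQ")
                if gq is not None:
                    gqs[i] = gq
            records.append(
                VariantRecord(
                    marker_id=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alts=tuple(rec.alts or ()),
                    genotypes=gts,
                    allele_depths=ads,
                    depths=dps,
                    gqs=gqs,
                )
            )
    return VariantTable(sample_ids=samples, records=records)


def write_vcf(table: VariantTable, path: str | Path) -> None:
    """Write a VariantTable as a plain-text VCF v4.2 file.

    Round-trips bit-exactly through :func:`read_vcf` on the GT/AD/DP/GQ
    fields, including triploid genotype calls and missing values.
    """
    header = pysam.VariantHeader()
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("AD", "R", "Integer", "Allelic depths (REF first)")
    header.formats.add("DP", 1, "Integer", "Total read depth")
    header.formats.add("GQ", 1, "Integer", "Genotype quality")
    for marker in table.marker_ids():
        header.contigs.add(marker)
    for s in table.sample_ids:
        header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for rec in table.records:
            vrec = out.new_record(
                contig=rec.marker_id,
                start=rec.pos - 1,
                alleles=rec.alleles,
            )
            for i, s in enumerate(table.sample_ids):
                call = vrec.samples[s]
                gt = rec.genotypes[i]
                call["GT"] = gt if gt is not None else (None,)
                ad = rec.allele_depths[i]
                if (ad >= 0).all():
                    call["AD"] = tuple(int(v) for v in ad)
                else:
                    call["AD"] = tuple(None for _ in range(rec.n_alleles))
                if rec.depths[i] >= 0:
                    call["DP"] = int(rec.depths[i])
                if rec.gqs[i] >= 0:
                    call["GQ"] = int(rec.gqs[i])
            out.write(vrec)


def _record_failure_reason(
    rec: VariantRecord, maf_min: float, dp_min: int, gq_min: int
) -> str | None:
    """First filter rule violated by the record, or None if it passes."""
    if not rec.is_snp:
        return "indel"
    if not rec.is_biallelic:
        return "multiallelic"
    if any(gt is None for gt in rec.genotypes):
        return "missing_genotype"
    if (rec.depths < dp_min).any():
        return f"depth<{dp_min}"
    if (rec.gqs < gq_min).any():
        return f"gq<{gq_min}"
    if maf_min > 0 and rec.minor_allele_frequency() < maf_min:
        return f"maf<{maf_min}"
    return None


def filter_chain(
    table: VariantTable,
    maf_min: float = 0.1,
    dp_min: int = 10,
    gq_min: int = 20,
    log: list[tuple[str, int, str]] | None = None,
) -> VariantTable:
    """Apply the hard genotype filters and return the surviving records.

    A record survives only if it is a biallelic SNP, every sample has a
    called genotype with DP >= ``dp_min`` and GQ >= ``gq_min``, and the
    minor allele frequency over called alleles is >= ``maf_min``
    (``maf_min=0`` disables the MAF rule). Idempotent by construction.

    Parameters
    ----------
    log
        Optional list collecting ``(marker_id, pos, reason)`` for every
        removed record; reasons are also emitted at DEBUG level.
    """
    kept: list[VariantRecord] = []
    for rec in table.records:
        reason = _record_failure_reason(rec, maf_min, dp_min, gq_min)
        if reason is None:
            kept.append(rec)
        else:
            if log is not None:
                log.append((rec.marker_id, rec.pos, reason))
            logger.debug("filtered %s:%d (%s)", rec.marker_id, rec.pos, reason)
    logger.info("filter_chain: %d of %d records pass", len(kept), len(table))
    return replace(table, records=kept)


def thin_one_per_marker(table: VariantTable) -> VariantTable:
    """Keep the first SNP (lowest position) of each reference marker.

    Deterministic replacement for distance-based thinning: target-capture
    markers are short reference sequences, so one SNP per marker removes
    within-marker linkage regardless of the distance parameter.
    """
    best: dict[str, VariantRecord] = {}
    for rec in table.records:
        cur = best.get(rec.marker_id)
        if cur is None or rec.pos < cur.pos:
            best[rec.marker_id] = rec
    kept = [best[m] for m in table.marker_ids()]
    return replace(table, records=kept)
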