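"""Synthetic hybridogenetic-population generator.

Emulates the genotype data of a mixed water-frog population: two fixed
parental gene pools (lessonae "L" and ridibundus "R"), diploid F1-like
hybrids carrying one genome of each (E2), and triploid hybrids carrying an
extra copy of one parental genome (E3_LLR: two L copies, one R; E3_LRR: one
L, two R). A configurable fraction of loci are generated as fixed allelic
differences between the pools (the diagnostic loci); the rest are shared
polymorphisms with Beta-distributed allele frequencies.

Sequencing is modelled per site and sample: total depth is Poisson (or
negative-binomial) around a mean, the count of reads supporting the
L-lineage allele is Binomial(depth, f*(1-eps) + (1-f)*eps) where f is the
true L-allele dosage fraction of the individual and eps the per-read error
rate. Genotypes are then *called as diploid* — the maximum-likelihood call
among hom-ref/het/hom-alt under the binomial read model — regardless of the
individual's true ploidy, reproducing the analysis conditions in which
triploid heterozygous sites are occasionally miscalled homozygous for the
double-dose parent. Genotype quality is the Phred-scaled likelihood ratio
of the best to the second-best diploid genotype, capped at 99.

Every draw flows from a single seed, so fixtures are reproducible
byte-for-byte.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .covwin import DepthTrack, write_depth_tsv
from .panel import DiagnosticPanel, PanelLocus
from .vcf_io import GroupLabels, VariantRecord, VariantTable, write_labels, write_vcf

_BASES = np.array(list("ACGT"))

#: (copies from L pool, copies from R pool) per cohort group.
GROUP_DOSAGE = {
    "L": (2, 0),
    "R": (0, 2),
    "E2": (1, 1),
    "E3_LLR": (2, 1),
    "E3_LRR": (1, 2),
}

#: Group code used in the labels file for each cohort group.
GROUP_LABEL = {"L": "L", "R": "R", "E2": "E", "E3_LLR": "E", "E3_LRR": "E"}


@dataclass
class SimConfig:
    """Full parameterization of the synthetic population and sequencing model.

    Defaults mirror the study conditions this generator emulates: a cohort
    of 11 lessonae, 12 ridibundus, 13 diploid and 9 triploid hybrids (8
    with doubled L genome, 1 with doubled R genome); target-capture-scale
    mean depth of 40x; and roughly a third of markers capturing poorly.
    """

    n_markers: int = 300
    snps_per_marker: int = 1  # or (lo, hi) range sampled per marker
    prop_diagnostic: float = 0.3
    beta_a: float = 2.0  # shared-polymorphism frequency prior Beta(a, b)
    beta_b: float = 2.0
    n_l: int = 11
    n_r: int = 12
    n_e2: int = 13
    n_e3_llr: int = 8
    n_e3_lrr: int = 1
    mean_depth: float = 40.0
    depth_model: str = "poisson"  # "poisson" | "negbin"
    nb_dispersion: float = 5.0  # negbin size parameter (smaller = more spread)
    epsilon: float = 0.005  # per-read error rate
    emit_true_ploidy_gt: bool = False  # true GT (incl. 3-allele) instead of calls
    # depth-track (coverage fixture) parameters
    marker_len_range: tuple[int, int] = (120, 600)
    depth_autocorr_window: int = 25
    prop_poor_markers: float = 0.3
    track_noise: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("prop_diagnostic", "prop_poor_markers"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 <= self.epsilon < 0.5:
            raise ValueError(f"epsilon must be in [0, 0.5), got {self.epsilon}")
        for name in ("n_markers", "n_l", "n_r", "n_e2", "n_e3_llr", "n_e3_lrr"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.depth_model not in ("poisson", "negbin"):
            raise ValueError(f"unknown depth_model {self.depth_model!r}")
        if self.seed is None:
            raise ValueError("seed is mandatory")


@dataclass
class GroundTruth:
    """Per-locus and per-sample generative truth matching the emitted VCF."""

    loci: pd.DataFrame  # marker_id, pos, is_diagnostic, l_allele, r_allele, p_l, p_r
    samples: pd.DataFrame  # sample_id, group, ploidy, dosage, true_q_l

    def diagnostic_panel(self) -> DiagnosticPanel:
        """The true diagnostic panel (loci generated as fixed differences)."""
        sel = self.loci[self.loci["is_diagnostic"]]
        loci = [
            PanelLocus(r.marker_id, int(r.pos), r.l_allele, r.r_allele)
            for r in sel.itertuples()
        ]
        n_l = int((self.samples["group"] == "L").sum())
        n_r = int((self.samples["group"] == "R").sum())
        return DiagnosticPanel(loci=loci, n_l_samples=n_l, n_r_samples=n_r)


def _sample_names(config: SimConfig) -> list[tuple[str, str]]:
    names = []
    for group, n in (
        ("L", config.n_l),
        ("R", config.n_r),
        ("E2", config.n_e2),
        ("E3_LLR", config.n_e3_llr),
        ("E3_LRR", config.n_e3_lrr),
    ):
        for i in range(n):
            names.append((f"{group}_{i + 1:02d}", group))
    return names


def _call_diploid(
    n_a: int, depth: int, a_idx: int, epsilon: float
) -> tuple[tuple[int, int] | None, int]:
    """ML diploid genotype from A-supporting read count; returns (GT, GQ).

    Genotype hypotheses carry 2, 1 or 0 copies of allele A with expected
    A-read fractions 1-eps, 1/2 and eps. GT is expressed in ref/alt allele
    indices given ``a_idx`` (index of allele A).
    """
    if depth == 0:
        return None, 0
    eps = max(epsilon, 1e-6)
    probs = np.array([1.0 - eps, 0.5, eps])  # A copies: 2, 1, 0
    ll = n_a * np.log(probs) + (depth - n_a) * np.log(1.0 - probs)
    order = np.argsort(ll)[::-1]
    gq = int(min(99, round(10.0 * (ll[order[0]] - ll[order[1]]) / np.log(10.0))))
    n_copies_a = 2 - int(order[0])
    b_idx = 1 - a_idx
    gt = tuple(sorted([a_idx] * n_copies_a + [b_idx] * (2 - n_copies_a)))
    return gt, gq  # type: ignore[return-value]


def _draw_depth(rng: np.random.Generator, config: SimConfig) -> int:
    if config.depth_model == "poisson":
        return int(rng.poisson(config.mean_depth))
    size = config.nb_dispersion
    p = size / (size + config.mean_depth)
    return int(rng.negative_binomial(size, p))


def simulate_cohort(
    config: SimConfig,
) -> tuple[VariantTable, GroupLabels, GroundTruth]:
    """Simulate genotype data for the configured cohort.

    Returns the variant table (with diploid-called genotypes unless
    ``emit_true_ploidy_gt`` is set), the sample group labels and the
    generative ground truth.
    """
    rng = np.random.default_rng(config.seed)
    samples = _sample_names(config)
    sample_ids = [s for s, _ in samples]
    n_samples = len(sample_ids)
    if n_samples == 0:
        raise ValueError("cohort is empty")

    # -- loci layout -------------------------------------------------------
    loci_rows = []
    locus_meta = []  # (marker, pos, a_base, b_base, a_is_ref, diag, p_l, p_r)
    for mi in range(config.n_markers):
        marker = f"m{mi + 1:05d}"
        if isinstance(config.snps_per_marker, int):
            k = config.snps_per_marker
        else:
            lo, hi = config.snps_per_marker
            k = int(rng.integers(lo, hi + 1))
        lo_len, hi_len = config.marker_len_range
        length = int(rng.integers(lo_len, hi_len + 1))
        positions = np.sort(
            rng.choice(np.arange(1, length + 1), size=min(k, length), replace=False)
        )
        for pos in positions:
            a_base, b_base = rng.choice(_BASES, size=2, replace=False)
            a_is_ref = bool(rng.random() < 0.5)
            diag = bool(rng.random() < config.prop_diagnostic)
            if diag:
                p_l, p_r = 1.0, 0.0  # allele A is the L-lineage allele
            else:
                p = float(rng.beta(config.beta_a, config.beta_b))
                p_l = p_r = p
            locus_meta.append(
                (marker, int(pos), a_base, b_base, a_is_ref, diag, p_l, p_r)
            )
            loci_rows.append(
                {
                    "marker_id": marker,
                    "pos": int(pos),
                    "is_diagnostic": diag,
                    "l_allele": a_base,
                    "r_allele": b_base,
                    "p_l": p_l,
                    "p_r": p_r,
                }
            )

    # -- per-sample haplotype dosage and reads ----------------------------
    records: list[VariantRecord] = []
    for marker, pos, a_base, b_base, a_is_ref, diag, p_l, p_r in locus_meta:
        ref, alt = (a_base, b_base) if a_is_ref else (b_base, a_base)
        a_idx = 0 if a_is_ref else 1
        gts: list[tuple[int, ...] | None] = []
        ads = np.zeros((n_samples, 2), dtype=int)
        dps = np.zeros(n_samples, dtype=int)
        gqs = np.zeros(n_samples, dtype=int)
        for i, (_, group) in enumerate(samples):
            c_l, c_r = GROUP_DOSAGE[group]
            m = c_l + c_r
            n_a = int(rng.binomial(c_l, p_l) + rng.binomial(c_r, p_r))
            f = n_a / m
            depth = _draw_depth(rng, config)
            p_read_a = f * (1 - config.epsilon) + (1 - f) * config.epsilon
            reads_a = int(rng.binomial(depth, p_read_a))
            if config.emit_true_ploidy_gt:
                b_copies = m - n_a
                gt = tuple(
                    sorted([a_idx] * n_a + [1 - a_idx] * b_copies)
                )
                _, gq = _call_diploid(reads_a, depth, a_idx, config.epsilon)
                gts.append(gt if depth > 0 else None)
            else:
                gt, gq = _call_diploid(reads_a, depth, a_idx, config.epsilon)
                gts.append(gt)
            ads[i, a_idx] = reads_a
            ads[i, 1 - a_idx] = depth - reads_a
            dps[i] = depth
            gqs[i] = gq
        records.append(
            VariantRecord(
                marker_id=marker,
                pos=pos,
                ref=ref,
                alts=(alt,),
                genotypes=gts,
                allele_depths=ads,
                depths=dps,
                gqs=gqs,
            )
        )

    table = VariantTable(sample_ids=sample_ids, records=records)
    labels = GroupLabels({s: GROUP_LABEL[g] for s, g in samples})
    sample_rows = []
    for s, g in samples:
        c_l, c_r = GROUP_DOSAGE[g]
        sample_rows.append(
            {
                "sample_id": s,
                "group": g,
                "ploidy": c_l + c_r,
                "dosage": "L" * c_l + "R" * c_r,
                "true_q_l": c_l / (c_l + c_r),
            }
        )
    truth = GroundTruth(
        loci=pd.DataFrame(loci_rows), samples=pd.DataFrame(sample_rows)
    )
    return table, labels, truth


def simulate_depth_tracks(
    config: SimConfig,
) -> tuple[dict[str, list[DepthTrack]], pd.DataFrame]:
    """Per-sample autocorrelated depth tracks with per-marker capture efficiency.

    A fraction ``prop_poor_markers`` of markers gets a near-zero capture
    efficiency (emulating baits that fail on the study taxa); the rest draw
    a lognormal efficiency around 1. Depths are Poisson counts around
    ``mean_depth * efficiency`` smoothed by a moving average of width
    ``depth_autocorr_window`` (or exactly constant when ``track_noise`` is
    off). Returns the tracks and a per-marker truth table with the
    efficiencies.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 0x7261CC5]).generate_state(1)[0]
    )
    sample_ids = [s for s, _ in _sample_names(config)]
    lo_len, hi_len = config.marker_len_range
    rows = []
    markers = []
    for mi in range(config.n_markers):
        marker = f"m{mi + 1:05d}"
        length = int(rng.integers(lo_len, hi_len + 1))
        poor = bool(rng.random() < config.prop_poor_markers)
        eff = float(rng.uniform(0.0, 0.05)) if poor else float(
            rng.lognormal(0.0, 0.4)
        )
        markers.append((marker, length, eff))
        rows.append(
            {"marker_id": marker, "length": length, "efficiency": eff,
             "is_poor": poor}
        )
    tracks: dict[str, list[DepthTrack]] = {}
    w = max(1, config.depth_autocorr_window)
    kernel = np.ones(w) / w
    for s in sample_ids:
        ts = []
        for marker, length, eff in markers:
            lam = config.mean_depth * eff
            if config.track_noise:
                raw = rng.poisson(lam, size=length).astype(float)
                smooth = np.convolve(raw, kernel, mode="same")
                depths = np.rint(smooth).astype(int)
            else:
                depths = np.full(length, int(round(lam)), dtype=int)
            ts.append(DepthTrack(marker, depths))
        tracks[s] = ts
    return tracks, pd.DataFrame(rows)


def write_fixture(config: SimConfig, out_dir: str | Path) -> dict[str, Path]:
    """Write a complete, self-consistent fixture set to ``out_dir``.

    Emits the VCF, the labels TSV, the per-locus and per-sample truth
    tables, per-sample depth tracks and a README echoing the configuration.
    Byte-identical across runs with the same config.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table, labels, truth = simulate_cohort(config)
    paths = {
        "vcf": out / "cohort.vcf",
        "labels": out / "labels.tsv",
        "truth_loci": out / "truth_loci.tsv",
        "truth_samples": out / "truth_samples.tsv",
        "readme": out / "README.txt",
    }
    write_vcf(table, paths["vcf"])
    write_labels(labels, paths["labels"])
    truth.loci.to_csv(paths["truth_loci"], sep="\t", index=False)
    truth.samples.to_csv(paths["truth_samples"], sep="\t", index=False)
    depth_dir = out / "depth"
    depth_dir.mkdir(exist_ok=True)
    tracks, track_truth = simulate_depth_tracks(config)
    for s, ts in tracks.items():
        p = depth_dir / f"{s}.depth.tsv"
        write_depth_tsv(ts, p)
        paths[f"depth:{s}"] = p
    track_truth.to_csv(out / "truth_markers.tsv", sep="\t", index=False)
    paths["truth_markers"] = out / "truth_markers.tsv"
    cfg_lines = [
        f"{f.name} = {getattr(config, f.name)!r}"
        for f in dataclasses.fields(config)
    ]
    paths["readme"].write_text(
        "Synthetic hybridogenetic cohort fixture\n"
        "=======================================\n"
        "Generated by hybridotype.simhyb.write_fixture with configuration:\n\n"
        + "\n".join(cfg_lines)
        + "\n"
    )
    return paths
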