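"""End-to-end orchestration: simulate/load -> filter -> panel -> scores.

``run_pipeline`` executes the requested stages in dependency order, writes
one TSV (and, best-effort, one plot) per stage into the output directory,
and finishes with a combined per-sample report that places the triangle
coordinates, the dosage call, the GMM ploidy and the ancestry estimate
side by side. Dosage calls and GMM ploidy are never reconciled: samples
where the two disagree are flagged in the report.

Runs are deterministic given (config, seed): per-sample GMM seeds are
derived from the pipeline seed, and all tables are written with fixed
formatting.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import ancestry, covwin, dosage, ploidy_gmm, triangle
from .panel import DiagnosticPanel, ascertain_panel, write_panel
from .simhyb import SimConfig, simulate_cohort, simulate_depth_tracks
from .vcf_io import (
    GroupLabels,
    VariantTable,
    filter_chain,
    read_labels,
    read_vcf,
    thin_one_per_marker,
    write_vcf,
)

logger = logging.getLogger(__name__)

ALL_STAGES = (
    "filter",
    "panel",
    "triangle",
    "dosage",
    "ploidy",
    "ancestry",
    "coverage",
    "report",
)

#: stage -> stages that must run (or have run) before it
STAGE_DEPS = {
    "filter": (),
    "panel": ("filter",),
    "triangle": ("panel",),
    "dosage": ("panel",),
    "ploidy": ("filter",),
    "ancestry": ("panel",),
    "coverage": (),
    "report": (),
}

#: ploidy implied by each dosage call, for the consistency flag
DOSAGE_PLOIDY = {"diploid": 2, "triploid_LL_R": 3, "triploid_L_RR": 3}


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name prefixes the message."""


@dataclass
class PipelineConfig:
    """Paths, thresholds and stage selection for a full run."""

    out_dir: str | Path = "hybridotype_out"
    vcf: str | Path | None = None
    labels: str | Path | None = None
    depth_dir: str | Path | None = None  # per-sample *.depth.tsv files
    simulate: SimConfig | None = None  # generate inputs instead of loading
    stages: tuple[str, ...] = ALL_STAGES
    # filter thresholds
    maf_min: float = 0.1
    dp_min: int = 10
    gq_min: int = 20
    thin: bool = True
    # dosage
    min_total_depth: int = 1
    dosage_margin: float = 0.07
    dosage_min_sites: int = 50
    # GMM ploidy
    gmm_min_depth: int = 20
    gmm_ratio_bounds: tuple[float, float] = (0.1, 0.9)
    gmm_min_gq: int = 20
    gmm_min_sites: int = 100
    # ancestry
    run_unsupervised: bool = False
    # coverage
    window: int = 100
    cov_hi: int = 100
    cov_lo: int = 10
    make_plots: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if not 0.0 <= self.maf_min <= 0.5:
            raise ValueError("maf_min must be in [0, 0.5]")
        if self.simulate is None and "filter" in self.stages and self.vcf is None:
            raise ValueError("either a VCF path or a simulation config is required")


def _check_deps(stages: tuple[str, ...]) -> None:
    done: set[str] = set()
    for st in ALL_STAGES:
        if st not in stages:
            continue
        missing = [d for d in STAGE_DEPS[st] if d not in done and d not in stages]
        if missing:
            raise StageError(f"{st}: requires stage(s) {missing} to run first")
        done.add(st)


def _plot(config: PipelineConfig, fn, *args) -> None:
    if not config.make_plots:
        return
    try:
        fn(*args)
    except Exception as exc:  # plots are best-effort
        logger.warning("plot %s failed: %s", fn.__name__, exc)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages and return the in-memory result bundle."""
    _check_deps(config.stages)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info(
        "pipeline config: %s",
        {f.name: getattr(config, f.name) for f in dataclasses.fields(config)},
    )
    bundle: dict = {}

    # ------------------------------------------------------------------ input
    tracks_by_sample = None
    if config.simulate is not None:
        table, labels, truth = simulate_cohort(config.simulate)
        bundle["truth"] = truth
        write_vcf(table, out / "simulated.vcf")
        if "coverage" in config.stages:
            tracks_by_sample, track_truth = simulate_depth_tracks(config.simulate)
            bundle["track_truth"] = track_truth
    else:
        table = read_vcf(config.vcf)
        labels = read_labels(config.labels) if config.labels else None
    bundle["input_table"] = table
    bundle["labels"] = labels

    # ----------------------------------------------------------------- filter
    if "filter" in config.stages:
        try:
            filt_log: list = []
            filtered = filter_chain(
                table,
                maf_min=config.maf_min,
                dp_min=config.dp_min,
                gq_min=config.gq_min,
                log=filt_log,
            )
            if config.thin:
                filtered = thin_one_per_marker(filtered)
            write_vcf(filtered, out / "filtered.vcf")
            with open(out / "filter_log.tsv", "w") as fh:
                fh.write("marker_id\tpos\treason\n")
                for marker, pos, reason in filt_log:
                    fh.write(f"{marker}\t{pos}\t{reason}\n")
        except Exception as exc:
            raise StageError(f"filter: {exc}") from exc
        bundle["filtered"] = filtered
    else:
        filtered = table

    # ------------------------------------------------------------------ panel
    panel: DiagnosticPanel | None = None
    if "panel" in config.stages:
        if labels is None:
            raise StageError("panel: group labels are required")
        try:
            panel = ascertain_panel(filtered, labels)
            write_panel(panel, out / "panel.tsv")
        except StageError:
            raise
        except Exception as exc:
            raise StageError(f"panel: {exc}") from exc
        bundle["panel"] = panel

    # --------------------------------------------------------------- triangle
    scores = {}
    if "triangle" in config.stages:
        assert panel is not None
        try:
            score_list = triangle.score_cohort(filtered, panel)
            triangle.write_scores(score_list, out / "triangle_scores.tsv")
            _plot(config, triangle.triangle_report, score_list,
                  out / "triangle.png")
            scores = {s.sample_id: s for s in score_list}
        except Exception as exc:
            raise StageError(f"triangle: {exc}") from exc
        bundle["scores"] = scores

    # ----------------------------------------------------------------- dosage
    calls = {}
    if "dosage" in config.stages:
        assert panel is not None
        try:
            profiles = []
            for s in filtered.sample_ids:
                prof = dosage.ratio_profile(
                    filtered, panel, s, min_total_depth=config.min_total_depth
                )
                profiles.append(prof)
                try:
                    calls[s] = dosage.classify_dosage(
                        prof,
                        margin=config.dosage_margin,
                        min_sites=config.dosage_min_sites,
                    )
                except ValueError as exc:
                    logger.warning("dosage: %s", exc)
            dosage.write_dosage_calls(list(calls.values()),
                                      out / "dosage_calls.tsv")
            _plot(config, dosage.dosage_histogram_plot, profiles,
                  out / "allele_ratios.png")
        except Exception as exc:
            raise StageError(f"dosage: {exc}") from exc
        bundle["dosage_calls"] = calls

    # ----------------------------------------------------------------- ploidy
    fits = {}
    if "ploidy" in config.stages:
        try:
            fit_list = []
            for i, s in enumerate(filtered.sample_ids):
                seed = int(
                    np.random.SeedSequence([config.seed, i]).generate_state(1)[0]
                    % (2**31)
                )
                try:
                    fit = ploidy_gmm.fit_sample(
                        filtered,
                        s,
                        min_depth=config.gmm_min_depth,
                        ratio_bounds=config.gmm_ratio_bounds,
                        min_gq=config.gmm_min_gq,
                        min_sites=config.gmm_min_sites,
                        seed=seed,
                    )
                    fits[s] = fit
                    fit_list.append(fit)
                except ValueError as exc:
                    logger.warning("ploidy: %s", exc)
            ploidy_gmm.write_fits(fit_list, out / "ploidy_fits.tsv")
            if fit_list:
                _plot(config, ploidy_gmm.ploidy_report, fit_list,
                      out / "ploidy.png")
        except Exception as exc:
            raise StageError(f"ploidy: {exc}") from exc
        bundle["ploidy_fits"] = fits

    # --------------------------------------------------------------- ancestry
    q_by_sample = {}
    if "ancestry" in config.stages:
        assert panel is not None and labels is not None
        try:
            estimates = [
                ancestry.estimate_q_supervised(filtered, labels, s, panel=panel)
                for s in filtered.sample_ids
            ]
            q_by_sample = {e.sample_id: e for e in estimates}
            ancestry.write_ancestry(estimates, out / "ancestry_q.tsv")
            _plot(config, ancestry.ancestry_barplot, estimates,
                  out / "ancestry.png")
            if config.run_unsupervised:
                unsup = ancestry.estimate_q_unsupervised(
                    filtered, seed=config.seed, labels=labels
                )
                ancestry.write_ancestry(unsup, out / "ancestry_q_unsupervised.tsv")
                bundle["ancestry_unsupervised"] = unsup
            pca = ancestry.run_pca(filtered)
            ancestry.write_pca(pca, out / "pca.tsv")
            _plot(config, ancestry.pca_plot, pca, out / "pca.png", labels)
            bundle["pca"] = pca
        except Exception as exc:
            raise StageError(f"ancestry: {exc}") from exc
        bundle["ancestry"] = q_by_sample

    # --------------------------------------------------------------- coverage
    if "coverage" in config.stages:
        try:
            if tracks_by_sample is None:
                if config.depth_dir is None:
                    raise ValueError("no depth tables: set depth_dir or simulate")
                tracks_by_sample = {
                    p.name.removesuffix(".depth.tsv"): covwin.read_depth_tsv(p)
                    for p in sorted(Path(config.depth_dir).glob("*.depth.tsv"))
                }
                if not tracks_by_sample:
                    raise ValueError(f"no *.depth.tsv files in {config.depth_dir}")
            summary = covwin.summarize_coverage(
                tracks_by_sample, window=config.window,
                hi=config.cov_hi, lo=config.cov_lo,
            )
            summary.per_marker.to_csv(out / "coverage_per_marker.tsv", sep="\t")
            summary.per_sample.to_csv(out / "coverage_per_sample.tsv", sep="\t")
            _plot(config, covwin.coverage_plot, summary, out / "coverage.png")
            bundle["coverage"] = summary
        except Exception as exc:
            raise StageError(f"coverage: {exc}") from exc

    # ----------------------------------------------------------------- report
    if "report" in config.stages:
        rows = []
        for s in filtered.sample_ids:
            sc = scores.get(s)
            dc = calls.get(s)
            fit = fits.get(s)
            q = q_by_sample.get(s)
            implied = DOSAGE_PLOIDY.get(dc.call) if dc else None
            if implied is None or fit is None:
                consistent = "NA"
            else:
                consistent = "yes" if implied == fit.best_ploidy else "DISAGREE"
            rows.append(
                {
                    "sample_id": s,
                    "group": labels[s] if labels else "NA",
                    "hybrid_index": f"{sc.hybrid_index:.4f}" if sc else "NA",
                    "interclass_het": f"{sc.interclass_het:.4f}" if sc else "NA",
                    "dosage_call": dc.call if dc else "NA",
                    "mean_ratio": f"{dc.mean_ratio:.4f}" if dc else "NA",
                    "gmm_ploidy": fit.best_ploidy if fit else "NA",
                    "q_l": f"{q.q_l:.4f}" if q else "NA",
                    "ploidy_consistent": consistent,
                }
            )
        cols = list(rows[0]) if rows else []
        with open(out / "report.tsv", "w") as fh:
            fh.write("\t".join(cols) + "\n")
            for r in rows:
                fh.write("\t".join(str(r[c]) for c in cols) + "\n")
        bundle["report_rows"] = rows
        n_flag = sum(r["ploidy_consistent"] == "DISAGREE" for r in rows)
        if n_flag:
            logger.warning("%d sample(s) with dosage/GMM ploidy disagreement",
                           n_flag)
    return bundle
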