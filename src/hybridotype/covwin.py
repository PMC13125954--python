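"""Per-marker coverage metric for target-capture data.

The metric is the minimum depth of the best-covered continuous window
(default 100 bp) within each target marker: the largest depth d such that
some window of the given length is covered at >= d everywhere. Unlike mean
depth it is insensitive to the marker's reference length, so markers of
very different sizes are comparable. Markers shorter than the window score
their whole-marker minimum.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class DepthTrack:
    """Per-base depth along one target marker (0-based positions)."""

    marker_id: str
    depths: np.ndarray

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=int)
        if self.depths.size < 1:
            raise ValueError(f"marker {self.marker_id!r}: empty depth track")
        if (self.depths < 0).any():
            raise ValueError(f"marker {self.marker_id!r}: negative depths")


@dataclass
class CoverageSummary:
    #: rows = markers, columns = samples, values = best_window_min_depth
    per_marker_sample: pd.DataFrame
    #: per-marker median across samples plus ranking by summed coverage
    per_marker: pd.DataFrame
    #: per-sample median and total across markers
    per_sample: pd.DataFrame
    n_markers_median_above: int
    n_markers_median_below: int
    hi: int
    lo: int


def best_window_min(track: DepthTrack, window: int = 100) -> int:
    """Max over windows of the within-window minimum depth, O(n).

    Sliding-window minimum via a monotone deque; for markers shorter than
    the window the whole-marker minimum is returned.
    """
    if window < 1:
        raise ValueError(f"window must be >= 1, got {window}")
    d = track.depths
    n = len(d)
    if n <= window:
        return int(d.min())
    dq: deque[int] = deque()  # indices, depths increasing
    best = 0
    for i in range(n):
        while dq and d[dq[-1]] >= d[i]:
            dq.pop()
        dq.append(i)
        if dq[0] <= i - window:
            dq.popleft()
        if i >= window - 1:
            front = int(d[dq[0]])
            if front > best:
                best = front
    return best


def read_depth_tsv(path: str | Path, one_based: bool = False) -> list[DepthTrack]:
    """Read per-base depths from a 3-column TSV (marker_id, pos, depth).

    Accepts samtools-depth output (``one_based=True``). Positions absent
    from the file are filled with depth 0 up to the largest seen position.
    """
    df = pd.read_csv(
        path, sep="\t", header=None, names=["marker_id", "pos", "depth"],
        comment="#",
    )
    offset = 1 if one_based else 0
    tracks = []
    for marker, sub in df.groupby("marker_id", sort=False):
        pos = sub["pos"].to_numpy() - offset
        if (pos < 0).any():
            raise ValueError(f"{path}: negative position for marker {marker!r}")
        depths = np.zeros(int(pos.max()) + 1, dtype=int)
        depths[pos] = sub["depth"].to_numpy()
        tracks.append(DepthTrack(str(marker), depths))
    return tracks


def write_depth_tsv(tracks: list[DepthTrack], path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in tracks:
            for i, d in enumerate(t.depths):
                fh.write(f"{t.marker_id}\t{i}\t{int(d)}\n")


def summarize_coverage(
    tracks_by_sample: dict[str, list[DepthTrack]],
    window: int = 100,
    hi: int = 100,
    lo: int = 10,
) -> CoverageSummary:
    """Cohort coverage summary from per-sample depth tracks.

    Every sample must provide the same marker set. Markers are ranked by
    the sum of their per-sample best-window depths (descending); the
    counts of markers whose cross-sample median exceeds ``hi`` or falls
    below ``lo`` summarize how many targets are well or poorly captured.
    """
    marker_sets = {
        s: tuple(t.marker_id for t in ts) for s, ts in tracks_by_sample.items()
    }
    ref_sample = next(iter(marker_sets))
    ref = set(marker_sets[ref_sample])
    for s, markers in marker_sets.items():
        diff = ref.symmetric_difference(markers)
        if diff:
            raise ValueError(
                f"marker sets differ between {ref_sample!r} and {s!r}: "
                f"{sorted(diff)[:5]}..."
            )
    data = {
        s: {t.marker_id: best_window_min(t, window) for t in ts}
        for s, ts in tracks_by_sample.items()
    }
    df = pd.DataFrame(data)  # rows markers, cols samples
    df = df.loc[list(marker_sets[ref_sample])]

    per_marker = pd.DataFrame(
        {"median": df.median(axis=1), "sum": df.sum(axis=1)}
    )
    per_marker = per_marker.sort_values("sum", ascending=False, kind="stable")
    per_marker["rank"] = np.arange(1, len(per_marker) + 1)
    per_sample = pd.DataFrame(
        {"median": df.median(axis=0), "total": df.sum(axis=0)}
    )
    return CoverageSummary(
        per_marker_sample=df,
        per_marker=per_marker,
        per_sample=per_sample,
        n_markers_median_above=int((per_marker["median"] > hi).sum()),
        n_markers_median_below=int((per_marker["median"] < lo).sum()),
        hi=hi,
        lo=lo,
    )


def coverage_plot(summary: CoverageSummary, out_path: str | Path) -> None:
    """Ranked per-marker coverage curve (markers ordered by summed depth)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 3.5))
    pm = summary.per_marker
    ax.plot(pm["rank"], pm["median"], lw=1.0)
    ax.axhline(summary.lo, color="C3", lw=0.8, ls=":",
               label=f"low coverage (<{summary.lo})")
    ax.axhline(summary.hi, color="C2", lw=0.8, ls=":",
               label=f"high coverage (>{summary.hi})")
    ax.set_xlabel("marker rank (by summed coverage)")
    ax.set_ylabel("median best-window min depth")
    ax.set_yscale("symlog")
    ax.legend(fontsize=7, frameon=False)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
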