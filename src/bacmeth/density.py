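"""Sliding-window motif-density scanning and region calling.

Motif occurrences are counted in overlapping windows (1 kb sliding every
100 bp by default); the genome-wide mean count per window and a dispersion
statistic (SEM by default, SD selectable) define enrichment thresholds:
windows at mean + k*dispersion or above seed enriched regions, mean -
k*dispersion or below seed depleted regions, and overlapping or abutting
same-direction seed windows are merged into maximal regions. Note that with
tens of thousands of windows the SEM is very small and the call is highly
threshold-sensitive; both dispersion modes are first-class.
"""

from __future__ import annotations

from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from .genome import Genome

DISPERSIONS = ("sem", "sd")


class WindowScan(NamedTuple):
    """Per-window counts plus genome-wide context statistics."""

    windows: pd.DataFrame  # contig, start, end, count, truncated
    genome_mean: float
    sem: float
    sd: float

    def dispersion(self, kind: str = "sem") -> float:
        if kind not in DISPERSIONS:
            raise ValueError(f"dispersion must be one of {DISPERSIONS}")
        return self.sem if kind == "sem" else self.sd


def window_counts(
    genome: Genome,
    occurrences: pd.DataFrame,
    size: int = 1000,
    step: int = 100,
) -> WindowScan:
    """Count motif occurrences (by match start) in sliding windows.

    Window starts run 0, step, 2*step, ... up to L - size on each contig; a
    contig shorter than *size* yields a single truncated window
    flagged as such. An occurrence is counted in a window iff its match start
    lies in [win_start, win_start + size).
    """
    if step < 1 or size < 1:
        raise ValueError("size and step must be positive")
    frames = []
    for contig, seq in genome.items():
        L = len(seq)
        starts = np.sort(
            occurrences.loc[occurrences["contig"] == contig, "start"].to_numpy()
        )
        if L < size:
            wstarts = np.array([0])
            wends = np.array([L])
            truncated = np.array([True])
        else:
            wstarts = np.arange(0, L - size + 1, step)
            wends = wstarts + size
            truncated = np.zeros(len(wstarts), dtype=bool)
        counts = np.searchsorted(starts, wends) - np.searchsorted(starts, wstarts)
        frames.append(
            pd.DataFrame(
                {
                    "contig": contig,
                    "start": wstarts,
                    "end": wends,
                    "count": counts,
                    "truncated": truncated,
                }
            )
        )
    windows = pd.concat(frames, ignore_index=True)
    counts = windows["count"].to_numpy(float)
    mean = counts.mean()
    sd = counts.std(ddof=0)
    sem = sd / np.sqrt(len(counts))
    return WindowScan(windows, float(mean), float(sem), float(sd))


def call_regions(
    scan: WindowScan, k: float = 2.0, dispersion: str = "sem"
) -> pd.DataFrame:
    """Merge significant windows into enriched/depleted regions.

    A window seeds an enriched region when count >= mean + k*dispersion and a
    depleted one when count <= mean - k*dispersion. When the dispersion is
    exactly 0 (homogeneous counts) the comparison falls back to strict
    inequality against the mean, so an all-equal scan calls no regions.
    Same-direction seed windows that overlap or abut are merged; region
    bounds are the union of merged windows and the peak count is retained.
    """
    if len(scan.windows) < 2:
        raise ValueError("need at least 2 windows")
    disp = scan.dispersion(dispersion)
    w = scan.windows
    counts = w["count"].to_numpy(float)
    if disp == 0:
        # homogeneous counts: no window deviates from the mean, nothing called
        enriched = counts > scan.genome_mean
        depleted = counts < scan.genome_mean
    else:
        enriched = counts >= scan.genome_mean + k * disp
        depleted = counts <= scan.genome_mean - k * disp
    regions = []
    for mask, direction in ((enriched, "enriched"), (depleted, "depleted")):
        sel = w[mask].sort_values(["contig", "start"])
        cur = None
        for row in sel.itertuples(index=False):
            if (
                cur is not None
                and row.contig == cur["contig"]
                and row.start <= cur["end"]  # overlap or abut
            ):
                cur["end"] = max(cur["end"], row.end)
                cur["peak_count"] = max(cur["peak_count"], row.count)
            else:
                if cur is not None:
                    regions.append(cur)
                cur = {
                    "contig": row.contig,
                    "start": int(row.start),
                    "end": int(row.end),
                    "direction": direction,
                    "peak_count": int(row.count),
                }
        if cur is not None:
            regions.append(cur)
    out = pd.DataFrame(
        regions, columns=["contig", "start", "end", "direction", "peak_count"]
    )
    return out.sort_values(["contig", "start"]).reset_index(drop=True)


def read_catalog_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED4 catalog of labelled genomic regions (core/GI/RGP/P...)."""
    rows = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 4:
            raise ValueError(f"{path}:{ln}: BED4 needs 4 columns")
        start, end = int(fields[1]), int(fields[2])
        if end <= start:
            raise ValueError(f"{path}:{ln}: end <= start")
        rows.append(
            {"contig": fields[0], "start": start, "end": end, "label": fields[3]}
        )
    return pd.DataFrame(rows)


def annotate_regions(
    regions: pd.DataFrame, catalog: pd.DataFrame, default_label: str = "core"
) -> pd.DataFrame:
    """Label each density region by the catalog feature with maximal overlap
    (majority rule); regions overlapping nothing get the default label."""
    out = regions.copy()
    labels = []
    for row in out.itertuples(index=False):
        cat = catalog[catalog["contig"] == row.contig]
        best_label, best_ov = default_label, 0
        for feat in cat.itertuples(index=False):
            ov = min(row.end, feat.end) - max(row.start, feat.start)
            if ov > best_ov:
                best_label, best_ov = feat.label, ov
        labels.append(best_label)
    out["label"] = labels
    return out


def write_bedgraph(scan: WindowScan, path: str | Path) -> None:
    """Per-window counts as bedGraph (0-based half-open; overlapping windows
    are emitted as-is, one line per window)."""
    with open(path, "w") as fh:
        fh.write('track type=bedGraph name="motif_density"\n')
        for row in scan.windows.itertuples(index=False):
            fh.write(f"{row.contig}\t{row.start}\t{row.end}\t{row.count}\n")


def write_regions_bed(regions: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        for row in regions.itertuples(index=False):
            fh.write(
                f"{row.contig}\t{row.start}\t{row.end}\t{row.direction}\t"
                f"{row.peak_count}\t.\n"
            )
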