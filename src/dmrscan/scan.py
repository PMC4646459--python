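"""Genome-wide candidate-DMR scan.

Chromosomes are tiled into non-overlapping 1-kb windows, each window is
annotated and classified by the trained boosted-TAN ensemble, and runs of
at least three exactly-abutting positive windows are merged into candidate
DMRs — single positive windows carry too high a false-positive risk to
report on their own.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping

import numpy as np

from .boosting import BoostedEnsemble
from .features import (FeatureCatalog, GenomeSequence, GenomicWindow,
                       RepeatAnnotation, extract_feature_matrix)

__all__ = [
    "PredictedSite",
    "MergedDMR",
    "make_windows",
    "classify_windows",
    "merge_consecutive",
    "write_sites_bed",
    "write_dmrs_bed",
    "read_bed",
]


@dataclass(frozen=True)
class PredictedSite:
    window: GenomicWindow
    margin: float
    positive: bool


@dataclass(frozen=True)
class MergedDMR:
    chrom: str
    start: int
    end: int
    n_windows: int
    mean_margin: float

    def __len__(self) -> int:
        return self.end - self.start


def make_windows(chromosome_lengths: Mapping[str, int],
                 tile_size: int = 1000) -> list[GenomicWindow]:
    """Non-overlapping tiles per chromosome, in input order.

    A trailing partial window shorter than the tile is dropped so every
    window yields a fixed-length feature vector.
    """
    if tile_size < 1:
        raise ValueError("tile_size must be >= 1")
    windows = []
    for chrom, length in chromosome_lengths.items():
        for start in range(0, length - tile_size + 1, tile_size):
            windows.append(GenomicWindow(chrom, start, start + tile_size))
    return windows


def classify_windows(windows: Iterable[GenomicWindow],
                     genome: GenomeSequence,
                     repeats: RepeatAnnotation,
                     catalog: FeatureCatalog,
                     ensemble: BoostedEnsemble,
                     chunk_size: int = 2000) -> Iterator[PredictedSite]:
    """Stream one PredictedSite per window.

    Windows are annotated and scored in bounded-size chunks so memory does
    not grow with genome size.  ``catalog`` must be the feature subset the
    ensemble was trained on.
    """
    if ensemble.models and ensemble.models[0].n_features != len(catalog):
        raise ValueError("catalog does not match the ensemble's schema")
    buffer: list[GenomicWindow] = []

    def flush(buf):
        X = extract_feature_matrix(buf, genome, repeats, catalog)
        margins = ensemble.decision_margin(X.to_numpy())
        for w, m in zip(buf, margins):
            yield PredictedSite(w, float(m), bool(m > 0))

    for window in windows:
        buffer.append(window)
        if len(buffer) >= chunk_size:
            yield from flush(buffer)
            buffer = []
    if buffer:
        yield from flush(buffer)


def merge_consecutive(predicted_sites: Iterable[PredictedSite],
                      min_run: int = 3) -> list[MergedDMR]:
    """Merge maximal runs of >= min_run exactly-abutting positive windows.

    Adjacency means the next window starts exactly at the previous end on
    the same chromosome; shorter runs are discarded.  Input must be sorted
    by (chrom, start).
    """
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    sites = list(predicted_sites)
    keys = [(s.window.chrom, s.window.start) for s in sites]
    if keys != sorted(keys):
        raise ValueError("predicted sites must be sorted by (chrom, start)")
    merged: list[MergedDMR] = []
    run: list[PredictedSite] = []

    def close(run):
        if len(run) >= min_run:
            merged.append(MergedDMR(
                run[0].window.chrom, run[0].window.start,
                run[-1].window.end, len(run),
                float(np.mean([s.margin for s in run]))))

    for site in sites:
        if not site.positive:
            close(run)
            run = []
            continue
        if (run and site.window.chrom == run[-1].window.chrom
                and site.window.start == run[-1].window.end):
            run.append(site)
        else:
            close(run)
            run = [site]
    close(run)
    return merged


# ---------------------------------------------------------------------------
# BED I/O (0-based half-open, tab-separated)


def write_sites_bed(sites: Iterable[PredictedSite], path,
                    positive_only: bool = True) -> None:
    with open(path, "w") as fh:
        for s in sites:
            if positive_only and not s.positive:
                continue
            fh.write(f"{s.window.chrom}\t{s.window.start}\t{s.window.end}"
                     f"\tsite\t{s.margin:.6g}\n")


def write_dmrs_bed(dmrs: Iterable[MergedDMR], path) -> None:
    with open(path, "w") as fh:
        for k, d in enumerate(dmrs, start=1):
            fh.write(f"{d.chrom}\t{d.start}\t{d.end}\tDMR{k:05d}"
                     f"\t{d.mean_margin:.6g}\n")


def read_bed(path) -> list[GenomicWindow]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            out.append(GenomicWindow(parts[0], int(parts[1]), int(parts[2])))
    return out
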