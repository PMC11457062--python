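"""Chromosome-window variant-density scan with Tukey outlier detection.

Windows are 0-based half-open tiles (default 1 Mbp, last window truncated to
the chromosome end).  The outlier rule uses Tukey hinges (the fivenum
convention of the quoted boxplot machinery, not type-7 quantiles): the
difference matters for small window counts.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from pikescan.io import GenotypeTable


@dataclasses.dataclass(frozen=True)
class Window:
    chrom: str
    start: int  # 0-based half-open
    end: int


@dataclasses.dataclass
class WindowDensity:
    chrom: str
    start: int
    end: int
    n_variants: int


@dataclasses.dataclass(frozen=True)
class OutlierRule:
    q1_hinge: float
    q3_hinge: float
    iqr: float
    threshold: float  # q3 + 1.5 * iqr


def make_windows(chrom_lengths, width: int = 1_000_000) -> list:
    """Tile each chromosome with ceil(length/width) windows."""
    if width <= 0:
        raise ValueError("width must be positive")
    out = []
    for chrom, length in chrom_lengths:
        start = 0
        while start < length:
            out.append(Window(chrom, start, min(start + width, int(length))))
            start += width
    return out


def count_per_window(table: GenotypeTable, windows) -> tuple:
    """Assign each variant to its tiling window.

    A variant at 1-based position p belongs to the window with
    ``p - 1 in [start, end)``.  Variants on chromosomes absent from the
    window set are skipped and counted.
    """
    by_chrom: dict[str, list] = {}
    for w in windows:
        by_chrom.setdefault(w.chrom, []).append(w)
    counts = {id(w): 0 for w in windows}
    n_skipped = 0
    for chrom in dict.fromkeys(table.chrom):
        wins = by_chrom.get(chrom)
        pos0 = table.pos[table.chrom == chrom] - 1  # to 0-based
        if wins is None:
            n_skipped += len(pos0)
            continue
        starts = np.asarray([w.start for w in wins])
        ends = np.asarray([w.end for w in wins])
        idx = np.searchsorted(starts, pos0, side="right") - 1
        for p, i in zip(pos0, idx):
            if i >= 0 and p < ends[i]:
                counts[id(wins[i])] += 1
            else:
                n_skipped += 1
    densities = [WindowDensity(w.chrom, w.start, w.end, counts[id(w)]) for w in windows]
    return densities, n_skipped


def tukey_hinges(values) -> tuple:
    """Lower/upper hinges by the fivenum (median-inclusive halves) rule."""
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    n4 = np.floor((n + 3) / 2) / 2
    idx = np.asarray([n4, n + 1 - n4])
    lo = 0.5 * (x[np.floor(idx).astype(int) - 1] + x[np.ceil(idx).astype(int) - 1])
    return float(lo[0]), float(lo[1])


def outlier_threshold(densities) -> tuple:
    """Tukey boxplot rule: outliers are windows strictly above q3 + 1.5*IQR."""
    if len(densities) < 5:
        raise ValueError("need at least 5 windows for the outlier rule")
    counts = np.asarray([d.n_variants for d in densities], dtype=float)
    q1, q3 = tukey_hinges(counts)
    iqr = q3 - q1
    rule = OutlierRule(q1, q3, iqr, q3 + 1.5 * iqr)
    outliers = [d for d in densities if d.n_variants > rule.threshold]
    return rule, outliers


def per_chrom_density(densities, chrom_lengths) -> dict:
    """Variants per kbp per chromosome; empty chromosomes report 0.0."""
    if not chrom_lengths:
        raise ValueError("chrom_lengths must be non-empty")
    totals: dict[str, int] = {c: 0 for c, _ in chrom_lengths}
    for d in densities:
        if d.chrom in totals:
            totals[d.chrom] += d.n_variants
    return {c: totals[c] / (length / 1000.0) for c, length in chrom_lengths}
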