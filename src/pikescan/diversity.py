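"""Per-individual and per-population diversity statistics.

Covers genotype tallies, observed heterozygosity, private alleles, fixed
differences, windowed Tajima's D, SNP-spacing summaries, and an
identity-by-state distance matrix.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd

from pikescan.io import HET, HOM_ALT, HOM_REF, MISSING, GenotypeTable, SampleSheet


# ---------------------------------------------------------------------------
# tallies and heterozygosity


def genotype_tallies(table: GenotypeTable, sheet: SampleSheet):
    """Per-sample (n_het, n_hom_alt) counts and per-population means.

    Returns ``(per_sample, per_population)`` data frames.  Counts are over
    non-missing genotypes; population means are arithmetic means over the
    population's samples.
    """
    for s in table.samples:
        sheet.population_of(s)  # raises if absent
    n_het = (table.codes == HET).sum(axis=0)
    n_hom_alt = (table.codes == HOM_ALT).sum(axis=0)
    per_sample = pd.DataFrame({
        "sample": table.samples,
        "population": [sheet.population_of(s) for s in table.samples],
        "n_het": n_het,
        "n_hom_alt": n_hom_alt,
    })
    per_pop = (
        per_sample.groupby("population", sort=False)[["n_het", "n_hom_alt"]]
        .mean()
        .rename(columns={"n_het": "mean_het", "n_hom_alt": "mean_hom_alt"})
        .reset_index()
    )
    return per_sample, per_pop


def observed_heterozygosity(table: GenotypeTable, sheet: SampleSheet, population: str) -> float:
    """Mean over loci of (het calls / non-missing calls) within the population.

    Loci with zero non-missing calls in the population are skipped.
    """
    members = sheet.members(population)
    if not members:
        raise ValueError(f"population {population!r} has no samples")
    codes = table.codes[:, table.sample_indices(members)]
    n_called = (codes != MISSING).sum(axis=1)
    n_het = (codes == HET).sum(axis=1)
    usable = n_called > 0
    if not usable.any():
        return float("nan")
    return float(np.mean(n_het[usable] / n_called[usable]))


# ---------------------------------------------------------------------------
# private alleles and fixed differences


def _pop_indicator(table: GenotypeTable, sheet: SampleSheet):
    pops = sheet.populations
    ind = np.zeros((table.n_samples, len(pops)), dtype=np.int64)
    for j, s in enumerate(table.samples):
        ind[j, pops.index(sheet.population_of(s))] = 1
    return pops, ind


def private_alleles(table: GenotypeTable, sheet: SampleSheet, min_count: int = 1) -> dict:
    """Count (locus, allele) pairs private to each population.

    A pair is private to population *p* iff its copy count is positive in
    *p* and zero in every other population; it is counted only when the copy
    count in *p* is at least ``min_count``.
    """
    pops, ind = _pop_indicator(table, sheet)
    if len(pops) < 2:
        raise ValueError("private alleles are undefined with fewer than 2 populations")
    max_allele = max((len(a) for a in table.alts), default=0)
    counts = {p: 0 for p in pops}
    for allele in range(max_allele + 1):
        copies = (table.allele_idx == allele).sum(axis=2) @ ind  # (sites, pops)
        present = copies > 0
        exclusive = present & (present.sum(axis=1, keepdims=True) == 1)
        qualifying = exclusive & (copies >= min_count)
        for k, p in enumerate(pops):
            counts[p] += int(qualifying[:, k].sum())
    return counts


def fixed_difference_matrix(table: GenotypeTable, sheet: SampleSheet):
    """Pairwise fixed-difference counts over biallelic sites.

    ``matrix[A][B]`` counts sites where every non-missing genotype in A is
    homozygous alternate and every non-missing genotype in B is homozygous
    reference (both populations must have at least one call).  Also returns
    per-population fixed-alternate totals and the number of skipped
    non-biallelic sites.
    """
    pops, ind = _pop_indicator(table, sheet)
    bi = table.is_biallelic()
    n_skipped = int((~bi).sum())
    codes = table.codes[bi]
    n_called = (codes != MISSING) @ ind
    n_hom_alt = (codes == HOM_ALT) @ ind
    n_hom_ref = (codes == HOM_REF) @ ind
    fixed_alt = (n_called > 0) & (n_hom_alt == n_called)
    fixed_ref = (n_called > 0) & (n_hom_ref == n_called)
    matrix = pd.DataFrame(0, index=pops, columns=pops, dtype=int)
    for a, pa in enumerate(pops):
        for b, pb in enumerate(pops):
            if a != b:
                matrix.loc[pa, pb] = int((fixed_alt[:, a] & fixed_ref[:, b]).sum())
    totals = {p: int(fixed_alt[:, k].sum()) for k, p in enumerate(pops)}
    return matrix, totals, n_skipped


# ---------------------------------------------------------------------------
# Tajima's D


@dataclasses.dataclass(frozen=True)
class TajimaConstants:
    """Normalising constants of the D statistic for n sequences."""

    n: int
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float

    @classmethod
    def from_n(cls, n: int) -> "TajimaConstants":
        if n < 4:
            raise ValueError("Tajima constants require n >= 4")
        a1 = sum(1.0 / i for i in range(1, n))
        a2 = sum(1.0 / i**2 for i in range(1, n))
        b1 = (n + 1) / (3.0 * (n - 1))
        b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
        c1 = b1 - 1.0 / a1
        c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
        e1 = c1 / a1
        e2 = c2 / (a2 + a1**2)
        assert e1 > 0 and e2 > 0
        return cls(n, a1, a2, b1, b2, c1, c2, e1, e2)


@dataclasses.dataclass
class TajimaWindow:
    chrom: str
    start: int  # 0-based half-open
    end: int
    n: int  # sequences used for the constants (min across sites)
    S: int
    pi: float
    D: float  # NaN when undefined (S == 0)


def tajimas_d_windows(
    table: GenotypeTable,
    sheet: SampleSheet,
    population: str,
    window_bp: int = 10_000,
    chrom_lengths=None,
):
    """Windowed Tajima's D for one population.

    Per window: S is the polymorphic-site count, pi the average pairwise
    difference computed from genotype-derived allele counts
    (``sum over sites of 2 j (n - j) / (n (n - 1))`` with j alt copies and n
    twice the non-missing diploids at the site), and
    ``D = (pi - S/a1) / sqrt(e1 S + e2 S (S - 1))`` with constants from the
    minimum per-site n in the window.  Windows with S = 0 carry D = NaN and
    are excluded from the mean.  Sites with n < 4 or more than one alternate
    allele are skipped (counted).

    Returns ``(windows, mean_D, n_skipped_sites)``.
    """
    members = sheet.members(population)
    if not members:
        raise ValueError(f"population {population!r} has no samples")
    sub = table.codes[:, table.sample_indices(members)]
    n_seq = 2 * (sub != MISSING).sum(axis=1)
    j_alt = np.where(sub == HET, 1, 0).sum(axis=1) + 2 * (sub == HOM_ALT).sum(axis=1)
    usable = (n_seq >= 4) & table.is_biallelic()
    n_skipped = int((~usable).sum())

    windows: list[TajimaWindow] = []
    chroms = list(dict.fromkeys(table.chrom))
    length_of = dict(chrom_lengths) if chrom_lengths else {}
    for chrom in chroms:
        on_chrom = (table.chrom == chrom) & usable
        pos = table.pos[on_chrom]
        ns = n_seq[on_chrom]
        js = j_alt[on_chrom]
        max_end = int(length_of.get(chrom, pos.max() if len(pos) else window_bp))
        for start in range(0, max_end, window_bp):
            end = min(start + window_bp, max_end) if chrom in length_of else start + window_bp
            in_win = (pos > start) & (pos <= end)  # 1-based pos in (start, end]
            if not in_win.any():
                continue
            nw, jw = ns[in_win], js[in_win]
            poly = (jw > 0) & (jw < nw)
            S = int(poly.sum())
            pi = float(np.sum(2.0 * jw * (nw - jw) / (nw * (nw - 1.0))))
            n_min = int(nw.min())
            if S == 0:
                D = float("nan")
            else:
                k = TajimaConstants.from_n(n_min)
                var = k.e1 * S + k.e2 * S * (S - 1)
                D = (pi - S / k.a1) / math.sqrt(var) if var > 0 else float("nan")
            windows.append(TajimaWindow(chrom, start, end, n_min, S, pi, D))
    defined = [w.D for w in windows if not math.isnan(w.D)]
    mean_d = float(np.mean(defined)) if defined else float("nan")
    return windows, mean_d, n_skipped


# ---------------------------------------------------------------------------
# spacing / divergence arithmetic


def snp_spacing(genome_length_bp: float, variant_count: float) -> int:
    """Mean bp between variants, rounded half-up to integer bp."""
    if variant_count <= 0:
        raise ValueError("variant_count must be positive")
    if genome_length_bp <= 0:
        raise ValueError("genome_length_bp must be positive")
    return int(math.floor(genome_length_bp / variant_count + 0.5))


def divergence_percent(genome_length_bp: float, variant_count: float, sig_figs: int = 3) -> float:
    """Percent of the genome differing from the reference, to ``sig_figs``."""
    if genome_length_bp <= 0:
        raise ValueError("genome_length_bp must be positive")
    pct = 100.0 * variant_count / genome_length_bp
    if pct == 0:
        return 0.0
    digits = sig_figs - 1 - int(math.floor(math.log10(abs(pct))))
    return round(pct, digits)


# ---------------------------------------------------------------------------
# identity-by-state distances


def ibs_distance_matrix(table: GenotypeTable):
    """Allele-sharing distance per sample pair.

    ``distance(i, j)`` is the mean over co-called sites of half the allele
    mismatch count (dosage difference), in [0, 1].  Pairs with zero
    co-called sites get NaN and are reported in ``undefined_pairs``.
    """
    if table.n_samples < 2:
        raise ValueError("need at least 2 samples for an IBS matrix")
    dosage = table.alt_dosage()
    n = table.n_samples
    dist = np.zeros((n, n))
    undefined = []
    for i in range(n):
        for j in range(i + 1, n):
            both = ~np.isnan(dosage[:, i]) & ~np.isnan(dosage[:, j])
            if not both.any():
                dist[i, j] = dist[j, i] = np.nan
                undefined.append((table.samples[i], table.samples[j]))
                continue
            d = np.mean(np.abs(dosage[both, i] - dosage[both, j])) / 2.0
            dist[i, j] = dist[j, i] = d
    frame = pd.DataFrame(dist, index=table.samples, columns=table.samples)
    return frame, undefined
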