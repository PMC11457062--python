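"""Sex-linked-region detectors.

Three complementary detectors:

1. a reference-free canonical k-mer filter (sex-specific k-mers per
   population, mapped back to the genome and summarised in 10-kb windows);
2. a genotype-pattern screen (hom-alt prefilter, exact all-male-het /
   all-female-het scan, and a DAPC loading screen with sex as the group);
3. coverage-ratio presence/absence genotyping of a male-only region against
   an autosomal control.

K-mers are held as canonical 2-bit-packed integers (lexicographic min of the
k-mer and its reverse complement), so k must be odd and at most 31.
"""

from __future__ import annotations

import dataclasses
import gzip
import math
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from pikescan.io import HET, HOM_ALT, MISSING, GenotypeTable, SampleSheet
from pikescan.windows import Window, WindowDensity, make_windows

_BASE_TO_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_TO_CODE[_b] = _i
    _BASE_TO_CODE[_b + 32] = _i  # lowercase
_CODE_TO_BASE = "ACGT"


# ---------------------------------------------------------------------------
# k-mer primitives


def encode_kmer(kmer: str) -> int:
    code = 0
    for ch in kmer:
        v = int(_BASE_TO_CODE[ord(ch)])
        if v > 3:
            raise ValueError(f"non-ACGT base in k-mer {kmer!r}")
        code = (code << 2) | v
    return code


def decode_kmer(code: int, k: int) -> str:
    return "".join(_CODE_TO_BASE[(code >> (2 * (k - 1 - i))) & 3] for i in range(k))


def revcomp_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Vectorised reverse complement of 2-bit-packed k-mers.

    Complement is bitwise NOT; base order is reversed by swapping 2-bit
    fields in log2(32) steps, then right-aligning to 2k bits.
    """
    x = ~np.asarray(codes, dtype=np.uint64)
    x = ((x >> np.uint64(2)) & np.uint64(0x3333333333333333)) | \
        ((x & np.uint64(0x3333333333333333)) << np.uint64(2))
    x = ((x >> np.uint64(4)) & np.uint64(0x0F0F0F0F0F0F0F0F)) | \
        ((x & np.uint64(0x0F0F0F0F0F0F0F0F)) << np.uint64(4))
    x = ((x >> np.uint64(8)) & np.uint64(0x00FF00FF00FF00FF)) | \
        ((x & np.uint64(0x00FF00FF00FF00FF)) << np.uint64(8))
    x = ((x >> np.uint64(16)) & np.uint64(0x0000FFFF0000FFFF)) | \
        ((x & np.uint64(0x0000FFFF0000FFFF)) << np.uint64(16))
    x = (x >> np.uint64(32)) | (x << np.uint64(32))
    return x >> np.uint64(64 - 2 * k)


def canonical_codes(codes: np.ndarray, k: int) -> np.ndarray:
    return np.minimum(np.asarray(codes, dtype=np.uint64), revcomp_codes(codes, k))


def _rolling_codes(base_codes: np.ndarray, k: int):
    """All k-windows of a 2-bit code array; windows with codes > 3 are invalid."""
    n = len(base_codes) - k + 1
    if n <= 0:
        return np.empty(0, np.uint64), np.empty(0, bool)
    x = (base_codes & np.uint8(3)).astype(np.uint64)
    codes = np.zeros(n, dtype=np.uint64)
    two = np.uint64(2)
    for j in range(k):
        codes <<= two
        codes |= x[j:j + n]
    bad = (base_codes > 3).astype(np.int32)
    cum = np.concatenate([[0], np.cumsum(bad)])
    valid = (cum[k:] - cum[:-k]) == 0
    return codes, valid


def _read_fastq_codes(path: str | Path) -> np.ndarray:
    """Concatenate all read sequences into one code array, 'N'-separated."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(str(path), "rb") as fh:
        data = fh.read()
    seq_lines = data.split(b"\n")[1::4]
    if not seq_lines or all(not s for s in seq_lines):
        return np.empty(0, dtype=np.uint8)
    joined = b"N".join(s for s in seq_lines if s)
    return _BASE_TO_CODE[np.frombuffer(joined, dtype=np.uint8)]


@dataclasses.dataclass(frozen=True)
class SexKmerRule:
    """Thresholds for sex-specific k-mer retention.

    ``target_sum_min_exclusive`` is a strict bound: the target-sex copy sum
    must be greater than it (the default 7 means sum >= 8).
    """

    opposite_max: int = 2
    target_min: int = 1
    target_sum_min_exclusive: int = 7

    def __post_init__(self) -> None:
        if min(self.opposite_max, self.target_min, self.target_sum_min_exclusive) < 0:
            raise ValueError("rule thresholds must be non-negative")


class KmerCountSet:
    """Per-sample canonical k-mer counts (sorted code arrays)."""

    def __init__(self, k: int, per_sample: dict):
        if k % 2 == 0:
            raise ValueError("k must be odd (canonical form would tie)")
        if k > 31:
            raise ValueError("k must be <= 31 for 2-bit packing")
        self.k = k
        #: sample -> (sorted uint64 codes, int64 counts)
        self.per_sample = per_sample

    @property
    def samples(self) -> list:
        return list(self.per_sample)

    def count_of(self, sample: str, code: int) -> int:
        codes, counts = self.per_sample[sample]
        i = np.searchsorted(codes, np.uint64(code))
        if i < len(codes) and codes[i] == np.uint64(code):
            return int(counts[i])
        return 0

    def lookup(self, sample: str, query: np.ndarray) -> np.ndarray:
        """Counts for an array of canonical codes (0 when absent)."""
        codes, counts = self.per_sample[sample]
        query = np.asarray(query, dtype=np.uint64)
        idx = np.searchsorted(codes, query)
        idx = np.clip(idx, 0, max(len(codes) - 1, 0))
        out = np.zeros(len(query), dtype=np.int64)
        if len(codes):
            hit = codes[idx] == query
            out[hit] = counts[idx[hit]]
        return out

    @classmethod
    def from_fastqs(cls, fastq_by_sample: dict, k: int = 31) -> "KmerCountSet":
        per_sample = {}
        for sample, path in fastq_by_sample.items():
            base_codes = _read_fastq_codes(path)
            if base_codes.size == 0:
                warnings.warn(f"empty FASTQ for {sample}: no k-mers counted")
                per_sample[sample] = (np.empty(0, np.uint64), np.empty(0, np.int64))
                continue
            codes, valid = _rolling_codes(base_codes, k)
            canon = canonical_codes(codes[valid], k)
            uniq, counts = np.unique(canon, return_counts=True)
            per_sample[sample] = (uniq, counts.astype(np.int64))
        return cls(k, per_sample)

    @classmethod
    def from_counts(cls, k: int, counts_by_sample: dict) -> "KmerCountSet":
        """Build from ``{sample: {kmer_string: count}}`` (strings canonicalised)."""
        per_sample = {}
        for sample, mapping in counts_by_sample.items():
            agg: dict[int, int] = {}
            for kmer, count in mapping.items():
                if len(kmer) != k:
                    raise ValueError(f"k-mer {kmer!r} is not length {k}")
                code = int(canonical_codes(np.asarray([encode_kmer(kmer)]), k)[0])
                agg[code] = agg.get(code, 0) + int(count)
            codes = np.asarray(sorted(agg), dtype=np.uint64)
            counts = np.asarray([agg[c] for c in codes], dtype=np.int64)
            per_sample[sample] = (codes, counts)
        return cls(k, per_sample)


def count_kmers(fastq_by_sample: dict, k: int = 31) -> KmerCountSet:
    """Canonical k-mer counts per sample from FASTQ (plain or gzip)."""
    return KmerCountSet.from_fastqs(fastq_by_sample, k=k)


def sex_specific_kmers(
    counts: KmerCountSet,
    sheet: SampleSheet,
    population: str,
    target_sex: str,
    rule: SexKmerRule = SexKmerRule(),
) -> np.ndarray:
    """Canonical codes retained by the within-population sex-specificity rule.

    A k-mer is retained iff every opposite-sex sample has at most
    ``opposite_max`` copies, every target-sex sample has at least
    ``target_min`` copies, and the target-sex copy sum is strictly greater
    than ``target_sum_min_exclusive``.
    """
    opposite_sex = "female" if target_sex == "male" else "male"
    targets = sheet.by_sex(target_sex, population)
    opposites = sheet.by_sex(opposite_sex, population)
    if len(targets) < 3 or len(opposites) < 3:
        raise ValueError(
            "sex-specific k-mer detection requires at least 3 samples of each "
            f"sex in {population!r} (have {len(targets)} {target_sex}, "
            f"{len(opposites)} {opposite_sex})"
        )
    # candidates: k-mers meeting target_min in every target sample
    candidate = None
    for s in targets:
        codes, cnt = counts.per_sample[s]
        mine = codes[cnt >= rule.target_min]
        candidate = mine if candidate is None else candidate[np.isin(candidate, mine)]
        if candidate.size == 0:
            return candidate
    total = np.zeros(len(candidate), dtype=np.int64)
    for s in targets:
        total += counts.lookup(s, candidate)
    keep = total > rule.target_sum_min_exclusive
    candidate, total = candidate[keep], total[keep]
    for s in opposites:
        if candidate.size == 0:
            break
        ok = counts.lookup(s, candidate) <= rule.opposite_max
        candidate = candidate[ok]
    return candidate


def write_kmer_fasta(codes: np.ndarray, k: int, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, code in enumerate(codes, 1):
            fh.write(f">kmer_{i}\n{decode_kmer(int(code), k)}\n")


def _mismatch_variants(query: np.ndarray, k: int) -> tuple:
    """All single-substitution variants of each query, canonicalised.

    Returns ``(variant_codes, owner_index)``; owners map variants back to
    their originating query row.
    """
    query = np.asarray(query, dtype=np.uint64)
    variants = [query]
    owners = [np.arange(len(query))]
    for i in range(k):
        for b in (1, 2, 3):  # XOR flips the base at position i
            variants.append(query ^ (np.uint64(b) << np.uint64(2 * i)))
            owners.append(np.arange(len(query)))
    flat = canonical_codes(np.concatenate(variants), k)
    return flat, np.concatenate(owners)


def map_kmers_to_genome(kmer_codes: np.ndarray, reference, k: int, max_mismatches: int = 0):
    """Hits of canonical k-mers against the reference, both strands.

    ``reference`` is a :class:`pikescan.synth.Reference` (2-bit codes per
    chromosome).  With ``max_mismatches=1``, single-substitution matches are
    also reported (the short-read-aligner behaviour; needed to anchor
    variant-carrying k-mers near their genomic origin).  Returns
    ``(hits, n_unmapped)``; hits has columns kmer_code / chrom / pos
    (1-based start of the matching window).
    """
    if max_mismatches not in (0, 1):
        raise ValueError("max_mismatches must be 0 or 1")
    query = np.unique(np.asarray(kmer_codes, dtype=np.uint64))
    if max_mismatches == 0:
        probes, owner = canonical_codes(query, k), np.arange(len(query))
    else:
        probes, owner = _mismatch_variants(query, k)
    rows = []
    mapped = np.zeros(len(query), dtype=bool)
    for chrom, seq in reference.sequences.items():
        codes, valid = _rolling_codes(seq, k)
        canon = canonical_codes(codes, k)
        canon[~valid] = np.uint64(0xFFFFFFFFFFFFFFFF)
        order = np.argsort(canon, kind="stable")
        sorted_canon = canon[order]
        left = np.searchsorted(sorted_canon, probes, side="left")
        right = np.searchsorted(sorted_canon, probes, side="right")
        hit_rows = np.flatnonzero(right > left)
        for pi in hit_rows:
            qi = owner[pi]
            mapped[qi] = True
            for pos0 in order[left[pi]:right[pi]]:
                rows.append((int(query[qi]), chrom, int(pos0) + 1))
    hits = pd.DataFrame(rows, columns=["kmer_code", "chrom", "pos"]).drop_duplicates()
    return hits, int((~mapped).sum())


def kmer_window_density(hits: pd.DataFrame, windows) -> list:
    """Per-window hit counts (1-based hit position p falls in p-1 in [start,end))."""
    counts = {id(w): 0 for w in windows}
    by_chrom: dict[str, list] = {}
    for w in windows:
        by_chrom.setdefault(w.chrom, []).append(w)
    for chrom, grp in hits.groupby("chrom"):
        wins = by_chrom.get(chrom)
        if not wins:
            continue
        starts = np.asarray([w.start for w in wins])
        ends = np.asarray([w.end for w in wins])
        pos0 = grp["pos"].to_numpy() - 1
        idx = np.searchsorted(starts, pos0, side="right") - 1
        for p, i in zip(pos0, idx):
            if i >= 0 and p < ends[i]:
                counts[id(wins[i])] += 1
    return [WindowDensity(w.chrom, w.start, w.end, counts[id(w)]) for w in windows]


# ---------------------------------------------------------------------------
# genotype-pattern screen


@dataclasses.dataclass(frozen=True)
class SexSnpPattern:
    site_index: int
    chrom: str
    pos: int
    pattern: str  # "male_specific_het" | "female_specific_het"


def prefilter_sex_sites(table: GenotypeTable, group_samples) -> np.ndarray:
    """Mask of sites with no hom-alt genotype in the group.

    Rationale: against a female reference with an XY system, Y-linked
    variation appears only as male heterozygosity, so any hom-alt call in
    the analysed group marks a site as not sex-system related.
    """
    if not list(group_samples):
        raise ValueError("empty group")
    codes = table.codes[:, table.sample_indices(group_samples)]
    return ~(codes == HOM_ALT).any(axis=1)


def exact_pattern_scan(
    table: GenotypeTable,
    sheet: SampleSheet,
    tolerance: int = 0,
    bin_bp: int = 10_000,
):
    """All-male-het / all-female-het site scan with a mismatch tolerance.

    A site is ``male_specific_het`` iff (missing genotypes excluded from
    both tallies) at most ``tolerance`` males are not heterozygous and at
    most ``tolerance`` females are heterozygous, with at least one
    heterozygous male present; symmetric for ``female_specific_het``.
    Returns ``(patterns, histogram)`` where histogram maps chrom ->
    {bin_start: count} over fixed-width bins.
    """
    males = [s for s in table.samples if sheet.sex_of(s) == "male"]
    females = [s for s in table.samples if sheet.sex_of(s) == "female"]
    if not males or not females:
        raise ValueError("need at least one sample of each sex")
    m = table.codes[:, table.sample_indices(males)]
    f = table.codes[:, table.sample_indices(females)]

    def scan(target, opposite):
        t_called = target != MISSING
        t_het = target == HET
        o_het = opposite == HET
        not_het = (t_called & ~t_het).sum(axis=1)
        opp_het = o_het.sum(axis=1)
        return (not_het <= tolerance) & (opp_het <= tolerance) & (t_het.sum(axis=1) >= 1)

    male_mask = scan(m, f)
    female_mask = scan(f, m) & ~male_mask
    patterns = [
        SexSnpPattern(int(i), str(table.chrom[i]), int(table.pos[i]), "male_specific_het")
        for i in np.flatnonzero(male_mask)
    ] + [
        SexSnpPattern(int(i), str(table.chrom[i]), int(table.pos[i]), "female_specific_het")
        for i in np.flatnonzero(female_mask)
    ]
    histogram: dict[str, dict[int, int]] = {}
    for p in patterns:
        bins = histogram.setdefault(p.chrom, {})
        b = ((p.pos - 1) // bin_bp) * bin_bp
        bins[b] = bins.get(b, 0) + 1
    return patterns, histogram


def sex_dapc_screen(
    table: GenotypeTable,
    sheet: SampleSheet,
    n_pc: int = 24,
    tolerance: int = 0,
):
    """DAPC with sex as the group, intersected with the exact pattern scan.

    Expects a table already reduced by :func:`prefilter_sex_sites` and
    restricted to sexed samples.  Candidates are sites in the high-loading
    structural set (any discriminant axis) that also carry an exact
    sex-specific genotype pattern.  Returns ``(candidates, model)``.
    """
    from pikescan import dapc as _dapc

    sexes = [sheet.sex_of(s) for s in table.samples]
    matrix = _dapc.dosage_matrix(table)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pca = _dapc.genotype_pca(matrix, n_pc)
        model = _dapc.lda_fit(pca, sexes, n_df=1)
        structural = set()
        for axis in range(model.variant_loadings.shape[1]):
            structural.update(_dapc.snpzip_select(model.variant_loadings[:, axis]).tolist())
    patterns, _ = exact_pattern_scan(table, sheet, tolerance=tolerance)
    candidates = [p for p in patterns if p.site_index in structural]
    return candidates, model


# ---------------------------------------------------------------------------
# coverage-ratio genotyping


@dataclasses.dataclass(frozen=True)
class CoverageCall:
    sample: str
    target_depth: float
    control_depth: float
    ratio: float
    call: str  # present | absent | ambiguous


def coverage_ratio_genotype(
    depth: pd.DataFrame,
    target_region: str,
    control_region: str,
    present_min: float = 0.25,
    absent_max: float = 0.05,
) -> list:
    """Presence/absence calls from the target/control mean-depth ratio.

    A hemizygous carrier is expected near ratio 0.5; the default thresholds
    call present at >= 0.25 and absent at <= 0.05, ambiguous between.
    """
    calls = []
    for sample, grp in depth.groupby("sample", sort=False):
        vals = dict(zip(grp["region"], grp["mean_depth"]))
        if target_region not in vals or control_region not in vals:
            raise ValueError(f"sample {sample!r} lacks depth for target or control region")
        ctrl = float(vals[control_region])
        if ctrl <= 0:
            raise ValueError(f"sample {sample!r} has zero control depth on {control_region!r}")
        tgt = float(vals[target_region])
        ratio = tgt / ctrl
        if ratio >= present_min:
            call = "present"
        elif ratio <= absent_max:
            call = "absent"
        else:
            call = "ambiguous"
        calls.append(CoverageCall(sample, tgt, ctrl, ratio, call))
    return calls
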