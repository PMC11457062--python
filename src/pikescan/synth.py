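"""Synthetic diploid cohort generator with planted truth.

Produces a reference genome, a multi-population cohort VCF with a
west-to-east-style heterozygosity gradient, population-private alleles, a
planted male-heterozygous region plus a male-only insert contig, per-sample
reads, and a machine-readable truth file for parameter-recovery tests.

Genotypes are drawn site-independently (no linkage); LD-based methods are
not supported downstream.  All outputs are byte-reproducible for a fixed
seed.
"""

from __future__ import annotations

import dataclasses
import gzip
import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from pikescan.io import FEMALE, MALE, SampleSheet

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
COMPLEMENT = np.frombuffer(b"TGCA", dtype=np.uint8)  # indexed by 2-bit code

#: hard-filter / site-filter criteria for which deliberate failures can be planted
FAILABLE_CRITERIA = (
    "QD", "FS", "MQ", "MQRankSum", "ReadPosRankSum",
    "QUAL", "DEPTH_LOW", "DEPTH_HIGH",
)


# ---------------------------------------------------------------------------
# specs and truth


@dataclasses.dataclass
class CohortSpec:
    """Parameters of a synthetic multi-population diploid cohort.

    ``theta_per_pop`` is the expected per-site heterozygosity of each
    population; the expected heterozygous-genotype count per individual is
    ``theta * n_sites`` (before missingness).
    """

    populations: list  # (name, n_males, n_females)
    theta_per_pop: dict
    private_allele_rate: float
    missing_rate: float
    chrom_lengths: list  # (chrom_name, length_bp)
    seed: int
    n_sites: int = 5000
    filter_fail_fractions: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [p[0] for p in self.populations]
        if len(set(names)) != len(names):
            raise ValueError("population names must be unique")
        for _, length in self.chrom_lengths:
            if length <= 0:
                raise ValueError("chromosome lengths must be positive")
        for rate in (self.private_allele_rate, self.missing_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        for pop, theta in self.theta_per_pop.items():
            if theta < 0 or theta >= 0.375:
                # p = x*u with u ~ U(0,1) gives E[2p(1-p)] = x - (2/3)x^2,
                # maximised at 0.375; beyond that no frequency scale exists.
                raise ValueError(
                    f"theta={theta} for {pop} implies an unattainable per-site "
                    "heterozygosity (model bound 0.375)"
                )
        unknown = set(self.theta_per_pop) - set(names)
        if unknown:
            raise ValueError(f"theta given for unknown populations {sorted(unknown)}")

    @property
    def pop_names(self) -> list:
        return [p[0] for p in self.populations]

    def sample_names(self) -> list:
        out = []
        for name, n_m, n_f in self.populations:
            out.extend(f"{name}_M{i + 1}" for i in range(n_m))
            out.extend(f"{name}_F{i + 1}" for i in range(n_f))
        return out

    def sample_sheet(self) -> SampleSheet:
        rows = []
        for name, n_m, n_f in self.populations:
            rows.extend((f"{name}_M{i + 1}", name, MALE) for i in range(n_m))
            rows.extend((f"{name}_F{i + 1}", name, FEMALE) for i in range(n_f))
        return SampleSheet(pd.DataFrame(rows, columns=["sample", "population", "sex"]))


@dataclasses.dataclass
class SexRegionSpec:
    """A planted XY interval plus a male-only insert contig."""

    chrom: str
    start: int  # 1-based inclusive
    end: int
    male_het_snp_count: int
    insert_name: str
    insert_length: int
    carrier_populations: set

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("sex region start must be <= end")
        if self.male_het_snp_count < 0:
            raise ValueError("male_het_snp_count must be >= 0")


@dataclasses.dataclass
class TruthSet:
    """Planted parameters of a synthetic cohort, for recovery tests."""

    true_sex: dict  # sample -> "male"|"female"
    site_class: list  # per VCF site: "neutral" | "private:<pop>" | "male_linked"
    expected_het_count: dict  # pop -> expected per-individual het count (missingness applied)
    theta_per_pop: dict
    carrier: dict  # sample -> bool (carries male-only insert)
    planted_filter_fail: list  # per site: list of criteria the site was built to fail
    sex_region: dict | None = None  # {chrom, start, end}
    insert: dict | None = None  # {name, length}
    pop_freqs: list | None = None  # per site: per-population alt frequency (spec order)

    def to_json(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthSet":
        return cls(**json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# reference


class Reference:
    """Simulated reference: named chromosomes as 2-bit base-code arrays."""

    def __init__(self, sequences: dict):
        self.sequences = {name: np.asarray(seq, dtype=np.uint8) for name, seq in sequences.items()}

    @property
    def chrom_lengths(self) -> list:
        return [(name, len(seq)) for name, seq in self.sequences.items()]

    def base_str(self, chrom: str, pos: int) -> str:
        """Reference base at 1-based position."""
        return chr(BASES[self.sequences[chrom][pos - 1]])

    def write_fasta(self, path: str | Path, width: int = 60) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            for name, seq in self.sequences.items():
                fh.write(f">{name}\n")
                ascii_seq = BASES[seq].tobytes().decode()
                for i in range(0, len(ascii_seq), width):
                    fh.write(ascii_seq[i:i + width] + "\n")
        import pyfaidx

        pyfaidx.Faidx(str(path))  # writes the .fai sidecar
        return path

    @classmethod
    def from_fasta(cls, path: str | Path) -> "Reference":
        import pyfaidx

        fa = pyfaidx.Fasta(str(path))
        seqs = {}
        for name in fa.keys():
            raw = np.frombuffer(str(fa[name][:]).upper().encode(), dtype=np.uint8)
            codes = np.full(raw.shape, 255, dtype=np.uint8)
            for code, base in enumerate(b"ACGT"):
                codes[raw == base] = code
            seqs[name] = codes
        return cls(seqs)


def simulate_reference(chrom_lengths, gc_fraction: float = 0.45, seed: int = 0) -> Reference:
    """Draw i.i.d. bases per chromosome at the requested GC content."""
    for name, length in chrom_lengths:
        if length <= 0:
            raise ValueError(f"chromosome {name} has non-positive length {length}")
    rng = np.random.default_rng(seed)
    at = (1.0 - gc_fraction) / 2.0
    gc = gc_fraction / 2.0
    probs = [at, gc, gc, at]  # A, C, G, T
    seqs = {}
    for name, length in chrom_lengths:
        seqs[name] = rng.choice(4, size=int(length), p=probs).astype(np.uint8)
    return Reference(seqs)


# ---------------------------------------------------------------------------
# cohort


def _freq_scale(theta: float) -> float:
    """Scale x with p = x*u, u~U(0,1), so that E[2p(1-p)] = theta."""
    return 0.75 * (1.0 - math.sqrt(1.0 - 8.0 * theta / 3.0))


class Cohort:
    """In-memory synthetic cohort: sites, genotypes, depths, annotations."""

    def __init__(self, spec: CohortSpec, reference: Reference):
        self.spec = spec
        self.reference = reference
        self.samples = spec.sample_names()
        self.sheet = spec.sample_sheet()
        self.chrom: np.ndarray = np.empty(0, dtype=object)
        self.pos: np.ndarray = np.empty(0, dtype=np.int64)
        self.ref_allele: list = []
        self.alt_allele: list = []
        self.alleles: np.ndarray = np.empty((0, 0, 2), dtype=np.int8)  # -1 missing
        self.depth: np.ndarray = np.empty((0, 0), dtype=np.int32)
        self.qual: np.ndarray = np.empty(0)
        self.info: dict = {}
        self.insert_name: str | None = None
        self.insert_seq: np.ndarray | None = None  # 2-bit codes

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    def write_vcf(self, path: str | Path) -> Path:
        path = Path(path)
        info_keys = ["QD", "FS", "MQ", "MQRankSum", "ReadPosRankSum"]
        lines = [
            "##fileformat=VCFv4.2",
            "##source=pikescan-synth",
        ]
        for name, length in self.reference.chrom_lengths:
            lines.append(f"##contig=<ID={name},length={length}>")
        for key in info_keys:
            lines.append(f'##INFO=<ID={key},Number=1,Type=Float,Description="{key}">')
        lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
        lines.append('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
        lines.append(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(self.samples)
        )
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")
            for i in range(self.n_sites):
                info = ";".join(f"{k}={self.info[k][i]:.2f}" for k in info_keys)
                fields = [
                    str(self.chrom[i]),
                    str(self.pos[i]),
                    ".",
                    self.ref_allele[i],
                    self.alt_allele[i],
                    f"{self.qual[i]:.1f}",
                    ".",
                    info,
                    "GT:DP",
                ]
                row = self.alleles[i]
                for j in range(len(self.samples)):
                    a, b = row[j]
                    gt = "./." if a < 0 else f"{a}/{b}"
                    fields.append(f"{gt}:{self.depth[i, j]}")
                fh.write("\t".join(fields) + "\n")
        return path

    def write_insert_fasta(self, path: str | Path) -> Path | None:
        if self.insert_seq is None:
            return None
        path = Path(path)
        with open(path, "w") as fh:
            fh.write(f">{self.insert_name}\n")
            seq = BASES[self.insert_seq].tobytes().decode()
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")
        return path


def simulate_cohort(spec: CohortSpec, reference: Reference):
    """Draw the cohort VCF substrate and its truth.

    Biallelic SNP sites are placed uniformly across chromosomes.  Neutral
    sites share a per-site frequency shape across populations, scaled per
    population so the expected per-site heterozygosity equals that
    population's theta; private sites segregate in exactly one population at
    founder-drifted (U-shaped Beta) frequencies, so fixed differences arise
    naturally.  Genotypes are Hardy-Weinberg draws; GATK-style INFO fields
    are synthesised with configurable planted failure fractions per
    criterion.  Per-population expected heterozygous counts are recorded in
    the truth from the realised frequencies.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    cohort = Cohort(spec, reference)
    pops = spec.pop_names
    n_sites = spec.n_sites
    n_samples = len(cohort.samples)
    pop_of = np.asarray([pops.index(cohort.sheet.population_of(s)) for s in cohort.samples])

    # site placement: uniform over the genome, unique positions, sorted
    chrom_names = [c for c, _ in reference.chrom_lengths]
    lengths = np.asarray([l for _, l in reference.chrom_lengths], dtype=float)
    per_chrom = rng.multinomial(n_sites, lengths / lengths.sum())
    chroms, positions = [], []
    for (name, length), k in zip(reference.chrom_lengths, per_chrom):
        pos = rng.choice(np.arange(1, length + 1), size=min(k, length), replace=False)
        pos.sort()
        chroms.extend([name] * len(pos))
        positions.append(pos)
    cohort.chrom = np.asarray(chroms, dtype=object)
    cohort.pos = np.concatenate(positions) if positions else np.empty(0, dtype=np.int64)
    n_sites = cohort.n_sites

    # alleles: ref from the reference sequence, alt a different base
    ref_codes = np.asarray(
        [reference.sequences[c][p - 1] for c, p in zip(cohort.chrom, cohort.pos)], dtype=np.uint8
    )
    alt_codes = (ref_codes + rng.integers(1, 4, size=n_sites)) % 4
    cohort.ref_allele = [chr(BASES[c]) for c in ref_codes]
    cohort.alt_allele = [chr(BASES[c]) for c in alt_codes]

    # classification and per-population alternate-allele frequencies
    scales = np.asarray([_freq_scale(spec.theta_per_pop[p]) for p in pops])
    shape = rng.uniform(0.0, 1.0, size=n_sites)
    freqs = shape[:, None] * scales[None, :]
    is_private = rng.random(n_sites) < spec.private_allele_rate
    private_pop = rng.integers(0, len(pops), size=n_sites)
    site_class = np.where(is_private, "private", "neutral").astype(object)
    private_freq = np.clip(rng.beta(0.8, 0.8, size=n_sites), 0.02, 0.98)
    for i in np.flatnonzero(is_private):
        freqs[i, :] = 0.0
        freqs[i, private_pop[i]] = private_freq[i]
        site_class[i] = f"private:{pops[private_pop[i]]}"

    # Hardy-Weinberg genotypes: two Bernoulli gametes per individual
    p_sample = freqs[:, pop_of]  # (n_sites, n_samples)
    hapA = (rng.random((n_sites, n_samples)) < p_sample).astype(np.int8)
    hapB = (rng.random((n_sites, n_samples)) < p_sample).astype(np.int8)
    alleles = np.stack([hapA, hapB], axis=2)
    if spec.missing_rate > 0:
        miss = rng.random((n_sites, n_samples)) < spec.missing_rate
        alleles[miss] = -1
    cohort.alleles = alleles

    # depths and annotations, with planted per-criterion failures
    fail = {c: rng.random(n_sites) < spec.filter_fail_fractions.get(c, 0.0)
            for c in FAILABLE_CRITERIA}
    depth = rng.poisson(30.0, size=(n_sites, n_samples)).astype(np.int32)
    low = np.flatnonzero(fail["DEPTH_LOW"])
    depth[low] = rng.poisson(4.0, size=(len(low), n_samples))
    high = np.flatnonzero(fail["DEPTH_HIGH"] & ~fail["DEPTH_LOW"])
    depth[high] = rng.poisson(90.0, size=(len(high), n_samples))
    cohort.depth = depth

    def draw(pass_lo, pass_hi, fail_lo, fail_hi, mask):
        vals = rng.uniform(pass_lo, pass_hi, size=n_sites)
        vals[mask] = rng.uniform(fail_lo, fail_hi, size=int(mask.sum()))
        return np.round(vals, 2)

    cohort.info = {
        "QD": draw(5, 35, 0.0, 1.9, fail["QD"]),
        "FS": draw(0, 30, 60.5, 200, fail["FS"]),
        "MQ": draw(40, 60, 0, 29.5, fail["MQ"]),
        "MQRankSum": draw(-3, 3, -20, -12.6, fail["MQRankSum"]),
        "ReadPosRankSum": draw(-4, 4, -20, -8.1, fail["ReadPosRankSum"]),
    }
    cohort.qual = np.round(draw(30, 2000, 0, 19.9, fail["QUAL"]), 1)

    planted_fail = [
        [c for c in FAILABLE_CRITERIA if fail[c][i]
         and not (c == "DEPTH_HIGH" and fail["DEPTH_LOW"][i])]
        for i in range(n_sites)
    ]

    expected_het = {}
    for k, pop in enumerate(pops):
        per_site = 2.0 * freqs[:, k] * (1.0 - freqs[:, k])
        expected_het[pop] = float(per_site.sum() * (1.0 - spec.missing_rate))

    truth = TruthSet(
        true_sex={s: cohort.sheet.sex_of(s) for s in cohort.samples},
        site_class=list(site_class),
        expected_het_count=expected_het,
        theta_per_pop=dict(spec.theta_per_pop),
        carrier={s: False for s in cohort.samples},
        planted_filter_fail=planted_fail,
        pop_freqs=[[round(float(v), 5) for v in row] for row in freqs],
    )
    return cohort, truth


def plant_sex_region(cohort: Cohort, truth: TruthSet, region: SexRegionSpec):
    """Insert male-heterozygous-only SNPs and record a male-only insert contig.

    Every male of a carrier population becomes heterozygous at exactly
    ``male_het_snp_count`` new sites inside the region; every female and
    every non-carrier sample is homozygous reference there.  The insert is a
    random sequence absent from the reference, carried on one haplotype of
    carrier males.
    """
    ref = cohort.reference
    if region.chrom not in ref.sequences:
        raise ValueError(f"sex region chromosome {region.chrom!r} not in reference")
    length = len(ref.sequences[region.chrom])
    if region.end > length:
        raise ValueError("sex region extends beyond its chromosome")
    unknown = set(region.carrier_populations) - set(cohort.spec.pop_names)
    if unknown:
        raise ValueError(f"carrier populations {sorted(unknown)} not in cohort")

    rng = np.random.default_rng(np.random.SeedSequence([cohort.spec.seed, 7]))
    taken = set(cohort.pos[cohort.chrom == region.chrom].tolist())
    candidates = np.asarray(
        [p for p in range(region.start, region.end + 1) if p not in taken], dtype=np.int64
    )
    if len(candidates) < region.male_het_snp_count:
        raise ValueError("sex region too small for the requested SNP count")
    new_pos = np.sort(rng.choice(candidates, size=region.male_het_snp_count, replace=False))

    sheet = cohort.sheet
    carrier_males = [
        s for s in cohort.samples
        if sheet.sex_of(s) == MALE and sheet.population_of(s) in region.carrier_populations
    ]
    carrier_idx = cohort.sample_index(carrier_males)

    n_new = len(new_pos)
    n_samples = len(cohort.samples)
    ref_codes = ref.sequences[region.chrom][new_pos - 1]
    alt_codes = (ref_codes + rng.integers(1, 4, size=n_new)) % 4
    alleles = np.zeros((n_new, n_samples, 2), dtype=np.int8)
    alleles[:, carrier_idx, 1] = 1  # het in every carrier male
    depth = rng.poisson(30.0, size=(n_new, n_samples)).astype(np.int32)
    info = {
        "QD": np.round(rng.uniform(5, 35, n_new), 2),
        "FS": np.round(rng.uniform(0, 30, n_new), 2),
        "MQ": np.round(rng.uniform(40, 60, n_new), 2),
        "MQRankSum": np.round(rng.uniform(-3, 3, n_new), 2),
        "ReadPosRankSum": np.round(rng.uniform(-4, 4, n_new), 2),
    }
    qual = np.round(rng.uniform(30, 2000, n_new), 1)

    # merge the new sites in coordinate order
    order_chrom = [c for c, _ in ref.chrom_lengths]
    rank = {c: i for i, c in enumerate(order_chrom)}
    all_chrom = np.concatenate([cohort.chrom, np.asarray([region.chrom] * n_new, dtype=object)])
    all_pos = np.concatenate([cohort.pos, new_pos])
    sort_key = np.lexsort((all_pos, np.asarray([rank[c] for c in all_chrom])))
    is_new = np.concatenate([np.zeros(cohort.n_sites, bool), np.ones(n_new, bool)])

    def merge(old, new):
        return np.concatenate([old, new], axis=0)[sort_key]

    cohort.alleles = merge(cohort.alleles, alleles)
    cohort.depth = merge(cohort.depth, depth)
    cohort.qual = merge(cohort.qual, qual)
    for key in cohort.info:
        cohort.info[key] = merge(cohort.info[key], info[key])
    old_ref, old_alt = cohort.ref_allele, cohort.alt_allele
    merged_ref = list(np.asarray(
        old_ref + [chr(BASES[c]) for c in ref_codes], dtype=object)[sort_key])
    merged_alt = list(np.asarray(
        old_alt + [chr(BASES[c]) for c in alt_codes], dtype=object)[sort_key])
    cohort.ref_allele, cohort.alt_allele = merged_ref, merged_alt
    cohort.chrom = all_chrom[sort_key]
    cohort.pos = all_pos[sort_key]

    classes = np.asarray(truth.site_class + ["male_linked"] * n_new, dtype=object)[sort_key]
    truth.site_class = list(classes)
    fail_list = truth.planted_filter_fail + [[] for _ in range(n_new)]
    truth.planted_filter_fail = [fail_list[i] for i in sort_key]
    if truth.pop_freqs is not None:
        n_pops = len(cohort.spec.pop_names)
        freq_list = truth.pop_freqs + [[0.0] * n_pops for _ in range(n_new)]
        truth.pop_freqs = [freq_list[i] for i in sort_key]
    truth.sex_region = {"chrom": region.chrom, "start": region.start, "end": region.end}
    truth.insert = {"name": region.insert_name, "length": region.insert_length}
    for s in carrier_males:
        truth.carrier[s] = True

    cohort.insert_name = region.insert_name
    cohort.insert_seq = rng.integers(0, 4, size=region.insert_length).astype(np.uint8)
    return cohort, truth


# helper used by plant_sex_region
def _sample_index(self, names):
    lookup = {s: i for i, s in enumerate(self.samples)}
    return np.asarray([lookup[n] for n in names], dtype=np.intp)


Cohort.sample_index = _sample_index


# ---------------------------------------------------------------------------
# reads


def simulate_reads(
    cohort: Cohort,
    truth: TruthSet,
    reference: Reference,
    coverage_x: float,
    read_len: int = 100,
    error_rate: float = 0.0,
    seed: int = 0,
    out_dir: str | Path = ".",
    samples=None,
) -> dict:
    """Sample uniform reads from each individual's two haplotypes.

    Haplotypes are the reference edited by the individual's genotypes;
    carrier males additionally carry the insert contig on one haplotype.
    ``samples`` restricts output to a subset (per-sample random streams are
    independent, so the subset's files match a full run byte for byte).
    Returns ``{sample: fastq_path}``; files are gzip FASTQ.
    """
    if coverage_x <= 0:
        raise ValueError("coverage_x must be positive")
    shortest = min(length for _, length in reference.chrom_lengths)
    if read_len > shortest:
        raise ValueError("read_len exceeds the shortest chromosome")
    if cohort.insert_seq is not None and read_len > len(cohort.insert_seq):
        raise ValueError("read_len exceeds the insert length")

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence([seed, 0x5EED])
    child_seeds = ss.spawn(len(cohort.samples))
    paths = {}
    chrom_names = [c for c, _ in reference.chrom_lengths]
    site_by_chrom = {c: np.flatnonzero(cohort.chrom == c) for c in chrom_names}

    wanted = set(samples) if samples is not None else None
    for j, sample in enumerate(cohort.samples):
        if wanted is not None and sample not in wanted:
            continue
        rng = np.random.default_rng(child_seeds[j])
        templates = []  # (sequence codes, label)
        for c in chrom_names:
            idx = site_by_chrom[c]
            pos = cohort.pos[idx]
            calls = cohort.alleles[idx, j]  # (n, 2)
            alt_code = np.asarray(
                ["ACGT".index(cohort.alt_allele[i]) for i in idx], dtype=np.uint8
            ) if len(idx) else np.empty(0, dtype=np.uint8)
            for hap in (0, 1):
                seq = reference.sequences[c].copy()
                # het alt assigned to haplotype by the stored gamete order
                carry = calls[:, hap] == 1
                seq[pos[carry] - 1] = alt_code[carry]
                templates.append(seq)
        if truth.carrier.get(sample, False) and cohort.insert_seq is not None:
            # embed the insert between shared random flanks so reads can span
            # its edges (a bare contig would leave terminal k-mers uncovered)
            flank_rng = np.random.default_rng(
                np.random.SeedSequence([cohort.spec.seed, 0xF1A]))
            left = flank_rng.integers(0, 4, size=2 * read_len).astype(np.uint8)
            right = flank_rng.integers(0, 4, size=2 * read_len).astype(np.uint8)
            templates.append(np.concatenate([left, cohort.insert_seq, right]))

        reads = []
        for seq in templates:
            n_reads = int(round(len(seq) * coverage_x / 2.0 / read_len))
            if n_reads == 0:
                continue
            starts = rng.integers(0, len(seq) - read_len + 1, size=n_reads)
            block = seq[starts[:, None] + np.arange(read_len)[None, :]]
            if error_rate > 0:
                err = rng.random(block.shape) < error_rate
                shift = rng.integers(1, 4, size=block.shape).astype(np.uint8)
                block = np.where(err, (block + shift) % 4, block)
            rc = rng.random(n_reads) < 0.5
            block[rc] = 3 - block[rc, ::-1]
            reads.append(block)
        path = out_dir / f"{sample}.fastq.gz"
        _write_fastq(path, sample, reads, read_len)
        paths[sample] = path
    return paths


def simulate_depth_table(
    cohort: Cohort,
    truth: TruthSet,
    coverage_x: float,
    control_region: str | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-region mean depths consistent with the planted insert.

    Control region depth is near ``coverage_x`` for everyone; the insert
    region is hemizygous (about half coverage) in carriers and essentially
    zero elsewhere.  Mirrors what an aligner-derived depth table would show.
    """
    if truth.insert is None:
        raise ValueError("no insert planted: nothing to genotype by coverage")
    control = control_region or cohort.reference.chrom_lengths[0][0]
    target = truth.insert["name"]
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xD3]))
    rows = []
    for sample in cohort.samples:
        ctrl = rng.normal(coverage_x, 0.03 * coverage_x)
        if truth.carrier.get(sample, False):
            tgt = rng.normal(coverage_x / 2.0, 0.05 * coverage_x)
        else:
            tgt = abs(rng.normal(0.0, 0.005 * coverage_x))
        rows.append((sample, control, round(max(ctrl, 0.0), 3)))
        rows.append((sample, target, round(max(tgt, 0.0), 3)))
    return pd.DataFrame(rows, columns=["sample", "region", "mean_depth"])


def _write_fastq(path: Path, sample: str, blocks, read_len: int) -> None:
    tail = b"\n+\n" + b"I" * read_len + b"\n"
    prefix = sample.encode()
    with gzip.open(path, "wb", compresslevel=2) as fh:
        n = 0
        for block in blocks:
            buf = BASES[block].tobytes()
            parts = []
            for i in range(block.shape[0]):
                n += 1
                parts.append(b"@%s_%d\n" % (prefix, n))
                parts.append(buf[i * read_len:(i + 1) * read_len])
                parts.append(tail)
            fh.write(b"".join(parts))
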