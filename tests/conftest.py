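"""Shared fixtures: synthetic cohorts and a hand-written VCF builder."""

from __future__ import annotations

from pathlib import Path

import pytest

from pikescan import synth
from pikescan.io import GenotypeTable

CHROMS = [("chr1", 60_000), ("chr2", 40_000)]
SEX_REGION = ("chr1", 10_001, 30_000)
N_PLANTED = 40


def build_cohort(seed=11, missing_rate=0.02, plant=True, n_sites=1500,
                 fail_fractions=None, private_allele_rate=0.2):
    reference = synth.simulate_reference(CHROMS, gc_fraction=0.45, seed=seed)
    spec = synth.CohortSpec(
        populations=[("CHT", 4, 4), ("WHI", 3, 3), ("SLA", 3, 3)],
        theta_per_pop={"CHT": 0.20, "WHI": 0.08, "SLA": 0.05},
        private_allele_rate=private_allele_rate,
        missing_rate=missing_rate,
        chrom_lengths=CHROMS,
        seed=seed,
        n_sites=n_sites,
        filter_fail_fractions=fail_fractions or {},
    )
    cohort, truth = synth.simulate_cohort(spec, reference)
    if plant:
        chrom, start, end = SEX_REGION
        region = synth.SexRegionSpec(chrom, start, end, N_PLANTED,
                                     "male_insert", 2_000, {"CHT"})
        synth.plant_sex_region(cohort, truth, region)
    return reference, cohort, truth


@pytest.fixture(scope="session")
def cohort_bundle(tmp_path_factory):
    """A planted cohort with its VCF, genotype table, and truth."""
    reference, cohort, truth = build_cohort()
    out = tmp_path_factory.mktemp("cohort")
    vcf = cohort.write_vcf(out / "cohort.vcf")
    table = GenotypeTable.from_vcf(vcf)
    return {
        "reference": reference,
        "cohort": cohort,
        "truth": truth,
        "vcf": vcf,
        "table": table,
        "sheet": cohort.sheet,
    }


@pytest.fixture(scope="session")
def null_cohort_bundle(tmp_path_factory):
    """Balanced-sex cohort without any planted sex region (and no missingness)."""
    reference, cohort, truth = build_cohort(seed=23, missing_rate=0.0, plant=False)
    out = tmp_path_factory.mktemp("null_cohort")
    vcf = cohort.write_vcf(out / "cohort.vcf")
    table = GenotypeTable.from_vcf(vcf)
    return {
        "reference": reference,
        "cohort": cohort,
        "truth": truth,
        "vcf": vcf,
        "table": table,
        "sheet": cohort.sheet,
    }


def write_vcf(path: Path, records, samples, with_dp=True) -> Path:
    """Hand-written VCF from row dicts.

    Each record: dict with chrom, pos, ref, alt (comma string), and optional
    qual, info (dict), gts (list like '0/1'), dps (list of ints).
    """
    fmt = "GT:DP" if with_dp else "GT"
    lines = ["##fileformat=VCFv4.2"]
    chroms = list(dict.fromkeys(r["chrom"] for r in records)) or ["chr1"]
    for c in chroms:
        lines.append(f"##contig=<ID={c},length=100000000>")
    for key in ("QD", "FS", "MQ", "MQRankSum", "ReadPosRankSum"):
        lines.append(f'##INFO=<ID={key},Number=1,Type=Float,Description="x">')
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="x">')
    if with_dp:
        lines.append('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="x">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples))
    for r in records:
        info = r.get("info") or {}
        info_str = ";".join(f"{k}={v}" for k, v in info.items()) or "."
        gts = r.get("gts") or ["0/1"] * len(samples)
        dps = r.get("dps") or [30] * len(samples)
        cells = [f"{g}:{d}" if with_dp else g for g, d in zip(gts, dps)]
        lines.append("\t".join([
            r["chrom"], str(r["pos"]), ".", r["ref"], r["alt"],
            str(r.get("qual", 100.0)), ".", info_str, fmt, *cells,
        ]))
    path.write_text("\n".join(lines) + "\n")
    return path
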