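"""Variant-filter cascade with a per-step retention report.

The cascade applies, in order: SNP-only selection, a GATK-style hard filter
on INFO annotations, and VCFtools-style site filters (quality, mean depth,
missing count, minor-allele count, and a heterozygous-genotypes-below-100%
rule).  Each step's retained set is a subset of the previous step's, and the
final set is the intersection of all per-site predicates, so permuting the
steps changes intermediate counts but never the final set.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
from cyvcf2 import VCF, Writer

from pikescan.io import provenance_header


@dataclasses.dataclass
class FilterThresholds:
    qd_min: float = 2.0
    fs_max: float = 60.0
    mq_min: float = 30.0
    mqranksum_min: float = -12.5
    readposranksum_min: float = -8.0
    qual_min: float = 20.0
    mean_depth_min: float = 10.0
    mean_depth_max: float = 60.0
    max_missing_count: int = 10
    mac_min: int = 1
    require_homozygote: bool = True
    drop_all_het: bool = True

    def __post_init__(self) -> None:
        if self.mean_depth_min > self.mean_depth_max:
            raise ValueError("mean_depth_min must be <= mean_depth_max")
        for name in ("qd_min", "fs_max", "mq_min", "mqranksum_min",
                     "readposranksum_min", "qual_min"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"threshold {name} must be finite")


@dataclasses.dataclass
class FilterReport:
    """Ordered (step_name, parameter_value, n_retained) rows."""

    steps: list

    def __post_init__(self) -> None:
        counts = [n for _, _, n in self.steps]
        if any(b > a for a, b in zip(counts, counts[1:])):
            raise ValueError("retention counts must be non-increasing")

    @property
    def n_raw(self) -> int:
        return self.steps[0][2]

    @property
    def n_final(self) -> int:
        return self.steps[-1][2]

    def write_tsv(self, path: str | Path, seed=None) -> None:
        with open(path, "w") as fh:
            fh.write(provenance_header(seed=seed))
            fh.write("step\tparameter\tretained\n")
            for name, param, n in self.steps:
                fh.write(f"{name}\t{param}\t{n}\n")


# ---------------------------------------------------------------------------
# per-site predicate evaluation


class _Site:
    """The per-record facts the cascade needs, decoupled from htslib handles."""

    __slots__ = ("line_no", "chrom", "pos", "is_snp", "info", "qual",
                 "mean_depth", "n_missing", "mac", "n_hom", "n_het", "n_called")

    def __init__(self, var, line_no: int):
        self.line_no = line_no
        self.chrom = var.CHROM
        self.pos = var.POS
        alts = var.ALT
        self.is_snp = (
            len(var.REF) == 1 and len(alts) >= 1
            and all(len(a) == 1 and a in "ACGT" for a in alts)
        )
        self.info = {}
        for key in ("QD", "FS", "MQ", "MQRankSum", "ReadPosRankSum"):
            val = var.INFO.get(key)
            if val is not None:
                try:
                    val = float(val)
                except (TypeError, ValueError):
                    raise ValueError(
                        f"non-numeric {key} at {self.chrom}:{self.pos}"
                    ) from None
            self.info[key] = val
        self.qual = var.QUAL

        allele_counts: dict[int, int] = {}
        n_hom = n_het = n_called = 0
        called_mask = []
        for call in var.genotypes:
            a, b = call[0], call[1]
            if a < 0 or b < 0:
                called_mask.append(False)
                continue
            called_mask.append(True)
            n_called += 1
            allele_counts[a] = allele_counts.get(a, 0) + 1
            allele_counts[b] = allele_counts.get(b, 0) + 1
            if a == b:
                n_hom += 1
            else:
                n_het += 1
        self.n_called = n_called
        self.n_missing = len(var.genotypes) - n_called
        self.n_hom = n_hom
        self.n_het = n_het
        # minor allele copies: least frequent observed allele; monomorphic -> 0
        self.mac = min(allele_counts.values()) if len(allele_counts) > 1 else 0

        try:
            dp = var.format("DP")
        except KeyError:
            dp = None
        if dp is not None:
            dp = np.asarray(dp, dtype=float).reshape(-1)
            dp[dp < 0] = np.nan  # htslib missing sentinel
            dp = dp[np.asarray(called_mask, dtype=bool)]
            with np.errstate(invalid="ignore"):
                self.mean_depth = float(np.nanmean(dp)) if dp.size and not np.all(np.isnan(dp)) else np.nan
        else:
            self.mean_depth = None


def _pred_snp(site: _Site, thr: FilterThresholds) -> bool:
    return site.is_snp


def _pred_hard(site: _Site, thr: FilterThresholds) -> bool:
    # a missing annotation never causes removal (GATK behaviour)
    checks = (
        (site.info["QD"], lambda v: v < thr.qd_min),
        (site.info["FS"], lambda v: v > thr.fs_max),
        (site.info["MQ"], lambda v: v < thr.mq_min),
        (site.info["MQRankSum"], lambda v: v < thr.mqranksum_min),
        (site.info["ReadPosRankSum"], lambda v: v < thr.readposranksum_min),
    )
    return not any(val is not None and fails(val) for val, fails in checks)


def _pred_qual(site: _Site, thr: FilterThresholds) -> bool:
    return site.qual is None or site.qual >= thr.qual_min


def _pred_min_depth(site: _Site, thr: FilterThresholds) -> bool:
    if site.mean_depth is None:
        raise ValueError(
            "VCF has no per-sample DP: the mean-depth step cannot run "
            "(drop it from the thresholds or add DP)"
        )
    return bool(np.isnan(site.mean_depth)) or site.mean_depth >= thr.mean_depth_min


def _pred_max_depth(site: _Site, thr: FilterThresholds) -> bool:
    return bool(np.isnan(site.mean_depth)) or site.mean_depth <= thr.mean_depth_max


def _pred_missing(site: _Site, thr: FilterThresholds) -> bool:
    return site.n_missing <= thr.max_missing_count


def _pred_mac(site: _Site, thr: FilterThresholds) -> bool:
    return site.mac >= thr.mac_min


def _pred_het100(site: _Site, thr: FilterThresholds) -> bool:
    if thr.require_homozygote and site.n_hom < 1:
        return False
    if thr.drop_all_het and site.n_called > 0 and site.n_het == site.n_called:
        return False
    return True


def cascade_steps(thr: FilterThresholds):
    """(name, printed parameter, predicate) in canonical report order."""
    return [
        ("snp_only", "-", _pred_snp),
        ("gatk_hard_filter", "-", _pred_hard),
        ("min_quality", thr.qual_min, _pred_qual),
        ("min_mean_depth", thr.mean_depth_min, _pred_min_depth),
        ("max_mean_depth", thr.mean_depth_max, _pred_max_depth),
        ("max_missing_count", thr.max_missing_count, _pred_missing),
        ("minor_allele_count", thr.mac_min, _pred_mac),
        ("het_genotypes_lt_100pct", "<100%", _pred_het100),
    ]


def _evaluate(vcf_path, thr: FilterThresholds, steps):
    """One streaming pass: per-step cumulative pass mask over all records."""
    vcf = VCF(str(vcf_path))
    n_steps = len(steps)
    keep_rows = []
    n_records = 0
    for line_no, var in enumerate(vcf, start=1):
        try:
            site = _Site(var, line_no)
        except ValueError:
            raise
        except Exception as exc:  # pragma: no cover - defensive
            raise ValueError(f"unreadable VCF record at line {line_no}: {exc}") from exc
        n_records += 1
        row = np.zeros(n_steps, dtype=bool)
        alive = True
        for i, (_, _, pred) in enumerate(steps):
            if alive:
                alive = bool(pred(site, thr))
            row[i] = alive
        keep_rows.append(row)
    vcf.close()
    mask = np.asarray(keep_rows, dtype=bool).reshape(n_records, n_steps)
    return mask


def _write_selected(vcf_path, out_path, keep: np.ndarray) -> None:
    vcf = VCF(str(vcf_path))
    writer = Writer(str(out_path), vcf)
    for i, var in enumerate(vcf):
        if keep[i]:
            writer.write_record(var)
    writer.close()
    vcf.close()


# ---------------------------------------------------------------------------
# public operations


def select_snps(vcf_path, out_path, thresholds: FilterThresholds | None = None) -> int:
    """Keep only sites where REF and every ALT are single bases."""
    thr = thresholds or FilterThresholds()
    steps = [cascade_steps(thr)[0]]
    mask = _evaluate(vcf_path, thr, steps)
    keep = mask[:, 0] if mask.size else np.zeros(0, bool)
    _write_selected(vcf_path, out_path, keep)
    return int(keep.sum())


def hard_filter(vcf_path, out_path, thresholds: FilterThresholds | None = None) -> int:
    """Drop sites failing any GATK-style INFO cutoff; missing annotations pass."""
    thr = thresholds or FilterThresholds()
    steps = [cascade_steps(thr)[1]]
    mask = _evaluate(vcf_path, thr, steps)
    keep = mask[:, 0] if mask.size else np.zeros(0, bool)
    _write_selected(vcf_path, out_path, keep)
    return int(keep.sum())


def site_filters(vcf_path, out_path, thresholds: FilterThresholds | None = None) -> FilterReport:
    """VCFtools-style site filters (quality through the all-het rule)."""
    thr = thresholds or FilterThresholds()
    steps = cascade_steps(thr)[2:]
    mask = _evaluate(vcf_path, thr, steps)
    n_raw = mask.shape[0]
    keep = mask[:, -1] if mask.size else np.zeros(n_raw, bool)
    _write_selected(vcf_path, out_path, keep)
    rows = [("input", "-", n_raw)]
    rows += [(name, param, int(mask[:, i].sum()) if mask.size else 0)
             for i, (name, param, _) in enumerate(steps)]
    return FilterReport(rows)


def run_cascade(vcf_path, out_path, thresholds: FilterThresholds | None = None) -> FilterReport:
    """Full cascade in canonical order with a per-step retention report."""
    thr = thresholds or FilterThresholds()
    steps = cascade_steps(thr)
    mask = _evaluate(vcf_path, thr, steps)
    n_raw = mask.shape[0]
    keep = mask[:, -1] if mask.size else np.zeros(n_raw, bool)
    _write_selected(vcf_path, out_path, keep)
    rows = [("raw", "-", n_raw)]
    rows += [(name, param, int(mask[:, i].sum()) if mask.size else 0)
             for i, (name, param, _) in enumerate(steps)]
    return FilterReport(rows)


def retention_percent(n_raw: int, n_retained: int) -> float:
    """Percentage of sites retained, to one decimal place."""
    if n_raw <= 0:
        raise ValueError("n_raw must be positive")
    if n_retained > n_raw:
        raise ValueError("n_retained cannot exceed n_raw")
    return round(100.0 * n_retained / n_raw, 1)
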