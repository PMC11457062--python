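"""Input/output substrate: sample sheets, genotype tables, depth tables.

The :class:`GenotypeTable` is the central in-memory substrate shared by the
filtering, diversity, window-scan, DAPC, and sex-screen stages.  Genotypes are
stored both as zygosity codes (hom-ref / het / hom-alt / missing) and as
allele-index pairs so that multiallelic sites keep their allele-level calls.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

#: zygosity codes used throughout the package
HOM_REF = 0
HET = 1
HOM_ALT = 2
MISSING = -1

MALE = "male"
FEMALE = "female"


@dataclasses.dataclass(frozen=True)
class SampleSheet:
    """Sample metadata: population membership and phenotypic sex."""

    frame: pd.DataFrame  # columns: sample, population, sex

    def __post_init__(self) -> None:
        required = {"sample", "population", "sex"}
        if not required.issubset(self.frame.columns):
            raise ValueError(f"sample sheet needs columns {sorted(required)}")
        if self.frame["sample"].duplicated().any():
            dupes = self.frame.loc[self.frame["sample"].duplicated(), "sample"]
            raise ValueError(f"duplicate samples in sheet: {list(dupes)}")

    @classmethod
    def read(cls, path: str | Path) -> "SampleSheet":
        frame = pd.read_csv(path, sep="\t", comment="#", dtype=str)
        return cls(frame)

    def write(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    @property
    def samples(self) -> list[str]:
        return list(self.frame["sample"])

    @property
    def populations(self) -> list[str]:
        return list(dict.fromkeys(self.frame["population"]))

    def population_of(self, sample: str) -> str:
        return self._lookup(sample, "population")

    def sex_of(self, sample: str) -> str:
        return self._lookup(sample, "sex")

    def _lookup(self, sample: str, column: str) -> str:
        rows = self.frame.loc[self.frame["sample"] == sample, column]
        if rows.empty:
            raise KeyError(f"sample {sample!r} absent from sample sheet")
        return rows.iloc[0]

    def members(self, population: str) -> list[str]:
        return list(self.frame.loc[self.frame["population"] == population, "sample"])

    def by_sex(self, sex: str, population: str | None = None) -> list[str]:
        mask = self.frame["sex"] == sex
        if population is not None:
            mask &= self.frame["population"] == population
        return list(self.frame.loc[mask, "sample"])


class GenotypeTable:
    """Sites x samples genotype matrix with site annotations.

    Parameters
    ----------
    chrom, pos : site coordinates (pos is 1-based).
    ref, alts : reference allele and tuple of alternate alleles per site.
    codes : ``(n_sites, n_samples)`` int8 matrix of zygosity codes.
    allele_idx : ``(n_sites, n_samples, 2)`` int8 matrix of per-haplotype
        allele indices (0 = ref, 1.. = alts, -1 = missing).
    samples : ordered sample names.
    """

    def __init__(self, chrom, pos, ref, alts, codes, allele_idx, samples):
        self.chrom = np.asarray(chrom, dtype=object)
        self.pos = np.asarray(pos, dtype=np.int64)
        self.ref = list(ref)
        self.alts = [tuple(a) for a in alts]
        self.codes = np.asarray(codes, dtype=np.int8)
        self.allele_idx = np.asarray(allele_idx, dtype=np.int8)
        self.samples = list(samples)
        if self.codes.shape != (len(self.pos), len(self.samples)):
            raise ValueError("codes shape inconsistent with sites x samples")
        self._check_sorted()

    def _check_sorted(self) -> None:
        for c in dict.fromkeys(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) < 0):
                raise ValueError(f"positions not sorted on {c}")

    # -- construction -------------------------------------------------

    @classmethod
    def from_vcf(cls, path: str | Path) -> "GenotypeTable":
        from cyvcf2 import VCF

        vcf = VCF(str(path), gts012=True)
        samples = list(vcf.samples)
        chrom, pos, ref, alts, codes, aidx = [], [], [], [], [], []
        for var in vcf:
            chrom.append(var.CHROM)
            pos.append(var.POS)
            ref.append(var.REF)
            alts.append(tuple(var.ALT))
            # gts012: 0=hom-ref 1=het 2=hom-alt 3=unknown
            gt = np.asarray(var.gt_types, dtype=np.int8)
            gt[gt == 3] = MISSING
            codes.append(gt)
            pair = np.full((len(samples), 2), MISSING, dtype=np.int8)
            for i, call in enumerate(var.genotypes):
                a, b = call[0], call[1]
                if a >= 0 and b >= 0:
                    pair[i, 0], pair[i, 1] = a, b
            aidx.append(pair)
        vcf.close()
        n = len(pos)
        return cls(
            chrom,
            pos,
            ref,
            alts,
            np.asarray(codes, dtype=np.int8).reshape(n, len(samples)),
            np.asarray(aidx, dtype=np.int8).reshape(n, len(samples), 2),
            samples,
        )

    # -- views ---------------------------------------------------------

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_indices(self, names) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.asarray([lookup[n] for n in names], dtype=np.intp)
        except KeyError as exc:
            raise KeyError(f"sample {exc.args[0]!r} absent from genotype table") from None

    def is_biallelic(self) -> np.ndarray:
        return np.asarray([len(a) == 1 for a in self.alts], dtype=bool)

    def alt_dosage(self) -> np.ndarray:
        """Alternate-allele dosage (0/1/2) with missing as NaN; any alt counts."""
        d = self.codes.astype(float)
        d[self.codes == MISSING] = np.nan
        return d

    def subset_sites(self, mask) -> "GenotypeTable":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return GenotypeTable(
            self.chrom[idx],
            self.pos[idx],
            [self.ref[i] for i in idx],
            [self.alts[i] for i in idx],
            self.codes[idx],
            self.allele_idx[idx],
            self.samples,
        )

    def subset_samples(self, names) -> "GenotypeTable":
        idx = self.sample_indices(names)
        return GenotypeTable(
            self.chrom, self.pos, self.ref, self.alts,
            self.codes[:, idx], self.allele_idx[:, idx], [self.samples[i] for i in idx],
        )


def read_depth_table(path: str | Path) -> pd.DataFrame:
    """Per-region mean-depth table: columns sample, region, mean_depth."""
    frame = pd.read_csv(path, sep="\t", comment="#")
    required = {"sample", "region", "mean_depth"}
    if not required.issubset(frame.columns):
        raise ValueError(f"depth table needs columns {sorted(required)}")
    return frame


def provenance_header(seed=None, **params) -> str:
    """Comment header recording version, seed, and parameters for output files."""
    from pikescan import __version__

    parts = [f"# pikescan v{__version__}"]
    if seed is not None:
        parts.append(f"seed={seed}")
    parts.extend(f"{k}={v}" for k, v in params.items())
    return " ".join(parts) + "\n"
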