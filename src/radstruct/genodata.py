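"""Core genotype data model and readers/writers.

The central container is :class:`GenotypeMatrix`: samples x loci alternate-allele
dosages (0/1/2) with ``MISSING = -1`` as a distinct sentinel, plus per-locus
coordinates. All downstream statistics treat missing dosages as absent
observations; nothing here ever conflates missing with the reference genotype.

Coordinates are 1-based inclusive throughout (VCF convention). BED input is
converted from 0-based half-open at the reader boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

MISSING: int = -1

SEX_LABELS = ("F", "M", "unknown")

SPECIES_CLASSES = ("pure_A", "pure_B", "admixed", "B_with_A_mtDNA", "unclassified")


class EmptyInputError(ValueError):
    """Raised when an operation would yield or received zero records."""


@dataclass(frozen=True)
class GenomicRegion:
    """A 1-based inclusive genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "start", int(self.start))
        object.__setattr__(self, "end", int(self.end))
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"invalid region {self.chrom}:{self.start}-{self.end} "
                "(need 1 <= start <= end)"
            )

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


@dataclass
class GenotypeMatrix:
    """Samples x loci matrix of alternate-allele dosages.

    Attributes
    ----------
    samples : list of sample ids, row order of ``G``.
    loci : DataFrame with columns chrom, pos, id, ref, alt and optionally
        median_depth and rad_locus; one row per column of ``G``, sorted by
        (chrom, pos).
    G : int8 array of shape (n_samples, n_loci) with entries in {0, 1, 2, -1}.
    """

    samples: list[str]
    loci: pd.DataFrame
    G: np.ndarray

    def __post_init__(self) -> None:
        self.G = np.asarray(self.G, dtype=np.int8)
        if self.G.shape != (len(self.samples), len(self.loci)):
            raise ValueError(
                f"G shape {self.G.shape} does not match "
                f"{len(self.samples)} samples x {len(self.loci)} loci"
            )
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids")
        bad = ~np.isin(self.G, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError(f"{bad.sum()} dosages outside {{0,1,2,MISSING}}")
        self.loci = self.loci.reset_index(drop=True)
        self._check_loci()

    def _check_loci(self) -> None:
        loci = self.loci
        if len(loci) and (loci["pos"] < 1).any():
            raise ValueError("locus positions must be >= 1")
        for _, sub in loci.groupby("chrom", sort=False):
            p = sub["pos"].to_numpy()
            if np.any(np.diff(p) < 0):
                raise ValueError("loci not sorted by position within chromosome")
            if np.any(np.diff(p) == 0):
                raise ValueError("duplicate (chrom, pos)")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def missing_rate_per_sample(self) -> np.ndarray:
        if self.n_loci == 0:
            return np.zeros(self.n_samples)
        return (self.G == MISSING).mean(axis=1)

    def sample_index(self, ids: Iterable[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        return np.array([lookup[s] for s in ids], dtype=int)


def _dosage_from_gt(gt: Sequence[int | None]) -> int:
    alleles = [a for a in gt[:2] if a is not None and a >= 0]
    if len(alleles) < 2:
        return MISSING
    return int(alleles[0] > 0) + int(alleles[1] > 0)


def read_vcf(path: str | Path, min_gq: float | None = None) -> GenotypeMatrix:
    """Read a biallelic-SNP VCF into a GenotypeMatrix.

    Non-biallelic or non-SNP records are skipped (count logged). Dosage is the
    count of alternate alleles in GT; half-calls and ``./.`` become MISSING.
    ``min_gq``, when given, masks genotypes below that GQ.
    """
    from cyvcf2 import VCF

    path = Path(path)
    if not path.exists():
        raise IOError(f"cannot read VCF: {path}")
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows = []
    dosages = []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            n_skipped += 1
            continue
        d = np.array([_dosage_from_gt(gt) for gt in var.genotypes], dtype=np.int8)
        if min_gq is not None:
            gq = var.gt_quals
            if gq is not None:
                d = np.where(gq < min_gq, MISSING, d)
        dp = None
        try:
            fmt_dp = var.format("DP")
        except Exception:
            fmt_dp = None
        if fmt_dp is not None:
            valid = fmt_dp[fmt_dp >= 0]
            dp = float(np.median(valid)) if len(valid) else None
        rows.append(
            {
                "chrom": var.CHROM,
                "pos": var.POS,
                "id": var.ID or f"{var.CHROM}:{var.POS}",
                "ref": var.REF,
                "alt": var.ALT[0],
                "median_depth": dp,
            }
        )
        dosages.append(d)
    vcf.close()
    if n_skipped:
        log.info("read_vcf: skipped %d non-biallelic/non-SNP records", n_skipped)
    if not rows:
        raise EmptyInputError(f"no biallelic SNP records in {path}")
    loci = pd.DataFrame(rows)
    G = np.stack(dosages, axis=1)
    order = np.lexsort((loci["pos"].to_numpy(), loci["chrom"].to_numpy()))
    loci = loci.iloc[order].reset_index(drop=True)
    G = G[:, order]
    if loci["median_depth"].isna().all():
        loci = loci.drop(columns=["median_depth"])
    gm = GenotypeMatrix(samples=samples, loci=loci, G=G)
    gm.n_skipped_records = n_skipped  # type: ignore[attr-defined]
    return gm


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write a GenotypeMatrix as an unphased VCF v4.2 with GT (and DP if present)."""
    path = Path(path)
    has_dp = "median_depth" in gm.loci.columns
    fmt = "GT:DP" if has_dp else "GT"
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=radstruct\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if has_dp:
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        for chrom in pd.unique(gm.loci["chrom"]) if gm.n_loci else []:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples)
            + "\n"
        )
        for j, row in gm.loci.iterrows():
            dp = ""
            if has_dp:
                d = row["median_depth"]
                dp = f":{int(d)}" if pd.notna(d) else ":."
            gts = "\t".join(_GT_STR[int(g)] + dp for g in gm.G[:, j])
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{row['id']}\t{row['ref']}\t"
                f"{row['alt']}\t.\tPASS\t.\t{fmt}\t{gts}\n"
            )


def read_sample_table(path: str | Path) -> pd.DataFrame:
    """Read the sample metadata TSV.

    Expected columns: sample_id, ecoregion, site, sex, plus optional
    ``mtdna_<pos>`` columns holding diagnostic-site base calls. Sex is coerced
    into {F, M, unknown}; blanks map to unknown. Duplicate sample ids raise.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"sample_id", "ecoregion", "site", "sex"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise ValueError(f"sample table missing columns: {sorted(missing_cols)}")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample ids: {dups}")
    df["sex"] = df["sex"].str.strip().str.upper().map(
        {"F": "F", "M": "M", "FEMALE": "F", "MALE": "M"}
    ).fillna("unknown")
    if "species_class" not in df.columns:
        df["species_class"] = "unclassified"
    return df.set_index("sample_id", drop=False)


def write_sample_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_bed(path: str | Path) -> list[GenomicRegion]:
    """Read a 3+ column BED file; 0-based half-open -> 1-based inclusive."""
    regions = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end = line.split("\t")[:3]
            regions.append(GenomicRegion(chrom, int(start) + 1, int(end)))
    return regions


def write_bed(regions: Sequence[GenomicRegion], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\n")


def loci_in_regions(loci: pd.DataFrame, regions: Sequence[GenomicRegion]) -> np.ndarray:
    """Boolean mask over loci rows: position lies inside any region (inclusive)."""
    mask = np.zeros(len(loci), dtype=bool)
    chroms = loci["chrom"].to_numpy()
    pos = loci["pos"].to_numpy()
    for r in regions:
        mask |= (chroms == r.chrom) & (pos >= r.start) & (pos <= r.end)
    return mask


def subset(
    gm: GenotypeMatrix,
    sample_keep: Sequence[str] | None = None,
    locus_keep: np.ndarray | None = None,
    regions: Sequence[GenomicRegion] | None = None,
    invert_regions: bool = False,
) -> GenotypeMatrix:
    """Order-preserving subset by sample ids and/or locus mask and/or regions.

    ``regions`` keeps loci inside the regions; ``invert_regions=True`` drops
    them instead (the removal mode used when excising inversions and
    sex-linked segments).
    """
    G = gm.G
    samples = gm.samples
    if sample_keep is not None:
        idx = gm.sample_index(sample_keep)
        G = G[idx, :]
        samples = [gm.samples[i] for i in idx]
    mask = np.ones(gm.n_loci, dtype=bool)
    if locus_keep is not None:
        mask &= np.asarray(locus_keep, dtype=bool)
    if regions is not None:
        in_reg = loci_in_regions(gm.loci, regions)
        mask &= ~in_reg if invert_regions else in_reg
    loci = gm.loci.loc[mask].reset_index(drop=True)
    G = G[:, mask]
    if len(loci) == 0 or len(samples) == 0:
        raise EmptyInputError(
            f"subset removed everything ({len(samples)} samples, {len(loci)} loci left)"
        )
    return GenotypeMatrix(samples=list(samples), loci=loci, G=G.copy())


def site_allele_stats(gm: GenotypeMatrix) -> pd.DataFrame:
    """Per-locus allele statistics on non-missing calls.

    Returns a DataFrame with p_alt, maf, missing_rate, H_obs (fraction of
    heterozygous calls) and H_exp = 2p(1-p). Loci with zero non-missing calls
    get NaN statistics (missing_rate 1), never an error.
    """
    G = gm.G
    miss = G == MISSING
    n_called = (~miss).sum(axis=0).astype(float)
    alt = np.where(miss, 0, G).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_alt = np.where(n_called > 0, alt / (2.0 * n_called), np.nan)
        h_obs = np.where(n_called > 0, (G == 1).sum(axis=0) / n_called, np.nan)
    maf = np.minimum(p_alt, 1.0 - p_alt)
    h_exp = 2.0 * p_alt * (1.0 - p_alt)
    missing_rate = miss.mean(axis=0) if gm.n_samples else np.ones(gm.n_loci)
    return pd.DataFrame(
        {
            "chrom": gm.loci["chrom"],
            "pos": gm.loci["pos"],
            "p_alt": p_alt,
            "maf": maf,
            "missing_rate": missing_rate,
            "H_obs": h_obs,
            "H_exp": h_exp,
        }
    )


def region_length(region: GenomicRegion) -> dict:
    """Length of a region in bp, Mbp at 1 decimal (half-up), and nearest-integer Mbp."""
    import decimal

    bp = region.length_bp
    mbp = decimal.Decimal(bp) / decimal.Decimal(10**6)
    one_dec = float(mbp.quantize(decimal.Decimal("0.1"), rounding=decimal.ROUND_HALF_UP))
    nearest = int(mbp.quantize(decimal.Decimal("1"), rounding=decimal.ROUND_HALF_UP))
    return {"bp": bp, "mbp_1dp": one_dec, "mbp_int": nearest}
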