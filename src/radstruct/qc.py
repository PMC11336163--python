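"""SNP- and sample-level filtering, kinship screening, and the filter ledger.

The ledger mirrors a staged filtering table: one row per step with the counts
of SNPs and samples surviving that step, so any removal is attributable to
exactly one stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genodata import MISSING, EmptyInputError, GenotypeMatrix, site_allele_stats


@dataclass
class FilterLedger:
    rows: list[dict] = field(default_factory=list)

    def append(self, step: str, gm: GenotypeMatrix) -> None:
        self.rows.append(
            {"step": step, "snps": gm.n_loci, "samples": gm.n_samples}
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["step", "snps", "samples"])

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class KinshipPair:
    sample_i: str
    sample_j: str
    phi: float  # NaN when the denominator is zero
    n_sites: int


def snp_filter(
    gm: GenotypeMatrix,
    maf_min: float = 0.01,
    max_missing_rate: float = 0.10,
    het_max: float = 0.6,
    het_mode: str = "observed",
    depth_range: tuple[float, float] | None = (10.0, 95.0),
    ledger: FilterLedger | None = None,
    step_label: str = "snp_filter",
) -> GenotypeMatrix:
    """Drop loci failing MAF / missingness / heterozygosity / depth thresholds.

    Retains loci with maf > maf_min, missing_rate < max_missing_rate and
    heterozygosity <= het_max (``het_mode`` picks observed or expected). When
    the loci table carries median depth and ``depth_range`` is given, median
    depth must lie inside the closed interval.
    """
    if het_mode not in ("observed", "expected"):
        raise ValueError("het_mode must be 'observed' or 'expected'")
    stats = site_allele_stats(gm)
    het = stats["H_obs"] if het_mode == "observed" else stats["H_exp"]
    keep = (
        (stats["maf"].to_numpy() > maf_min)
        & (stats["missing_rate"].to_numpy() < max_missing_rate)
        & (het.to_numpy() <= het_max)
    )
    keep &= ~stats["maf"].isna().to_numpy()
    if depth_range is not None and "median_depth" in gm.loci.columns:
        d = gm.loci["median_depth"].to_numpy(dtype=float)
        ok = (d >= depth_range[0]) & (d <= depth_range[1])
        keep &= np.where(np.isnan(d), True, ok)
    if not keep.any():
        raise EmptyInputError("snp_filter removed every locus")
    out = GenotypeMatrix(
        samples=list(gm.samples),
        loci=gm.loci.loc[keep].reset_index(drop=True),
        G=gm.G[:, keep].copy(),
    )
    if ledger is not None:
        ledger.append(step_label, out)
    return out


def sample_filter(
    gm: GenotypeMatrix,
    max_missing: float = 0.30,
    ledger: FilterLedger | None = None,
    step_label: str = "sample_filter",
) -> GenotypeMatrix:
    """Drop samples whose genotype missing rate exceeds ``max_missing``."""
    rates = gm.missing_rate_per_sample()
    keep = rates <= max_missing
    if not keep.any():
        raise EmptyInputError("sample_filter removed every sample")
    out = GenotypeMatrix(
        samples=[s for s, k in zip(gm.samples, keep) if k],
        loci=gm.loci.copy(),
        G=gm.G[keep, :].copy(),
    )
    if ledger is not None:
        ledger.append(step_label, out)
    return out


def king_kinship(gm: GenotypeMatrix, min_sites: int = 100) -> list[KinshipPair]:
    """Robust within-pair kinship (the KING estimator used by relatedness2).

    Phi(i,j) = (N_Aa,Aa - 2 N_AA,aa) / (N_Aa,i + N_Aa,j) over jointly
    non-missing sites, where N_Aa,Aa counts sites with both heterozygous,
    N_AA,aa opposite homozygotes, and N_Aa,. each member's heterozygous sites.
    Zero denominator yields phi = NaN, not an error. Pairs sharing fewer than
    ``min_sites`` observations are skipped.
    """
    if gm.n_samples < 2:
        raise ValueError("need at least 2 samples")
    G = gm.G
    n = gm.n_samples
    obs = G != MISSING
    het = G == 1
    hom0 = G == 0
    hom2 = G == 2
    pairs: list[KinshipPair] = []
    for i in range(n):
        for j in range(i + 1, n):
            both = obs[i] & obs[j]
            ns = int(both.sum())
            if ns < min_sites:
                continue
            n_hh = int((het[i] & het[j] & both).sum())
            n_opp = int(((hom0[i] & hom2[j]) | (hom2[i] & hom0[j])).sum())
            n_het_i = int((het[i] & both).sum())
            n_het_j = int((het[j] & both).sum())
            denom = n_het_i + n_het_j
            phi = (n_hh - 2.0 * n_opp) / denom if denom else float("nan")
            pairs.append(KinshipPair(gm.samples[i], gm.samples[j], phi, ns))
    return pairs


def prune_related(
    gm: GenotypeMatrix,
    pairs: list[KinshipPair],
    phi_threshold: float = 0.177,
    ledger: FilterLedger | None = None,
) -> tuple[GenotypeMatrix, list[str]]:
    """Greedy removal of one member per flagged pair (Phi > threshold).

    The member with more missing data goes; ties break on lexicographic id.
    Guarantees no surviving pair above the threshold.
    """
    flagged = [
        p for p in pairs if np.isfinite(p.phi) and p.phi > phi_threshold
    ]
    rates = dict(zip(gm.samples, gm.missing_rate_per_sample()))
    removed: set[str] = set()
    for p in sorted(flagged, key=lambda p: -p.phi):
        if p.sample_i in removed or p.sample_j in removed:
            continue
        a, b = p.sample_i, p.sample_j
        drop = a if (rates[a], a) > (rates[b], b) else b
        removed.add(drop)
    if not removed:
        out = gm
    else:
        keep = [s for s in gm.samples if s not in removed]
        idx = gm.sample_index(keep)
        out = GenotypeMatrix(samples=keep, loci=gm.loci.copy(), G=gm.G[idx].copy())
    if ledger is not None:
        ledger.append("relatedness_prune", out)
    return out, sorted(removed)


def one_snp_per_locus(
    gm: GenotypeMatrix,
    rad_locus: np.ndarray | str = "rad_locus",
    ledger: FilterLedger | None = None,
) -> GenotypeMatrix:
    """Keep only the lowest-position SNP of each RAD locus.

    ``rad_locus`` is either a column name in the loci table or an array of
    locus ids aligned with the loci rows.
    """
    if isinstance(rad_locus, str):
        if rad_locus not in gm.loci.columns:
            raise ValueError(f"loci table has no column {rad_locus!r}")
        ids = gm.loci[rad_locus].to_numpy()
    else:
        ids = np.asarray(rad_locus)
        if len(ids) != gm.n_loci:
            raise ValueError("rad_locus annotation length mismatch")
    if pd.isna(ids).any():
        raise ValueError("missing RAD-locus annotation")
    df = pd.DataFrame({"locus": ids, "pos": gm.loci["pos"].to_numpy()})
    first = df.groupby("locus", sort=False)["pos"].idxmin()
    keep = np.zeros(gm.n_loci, dtype=bool)
    keep[first.to_numpy()] = True
    out = GenotypeMatrix(
        samples=list(gm.samples),
        loci=gm.loci.loc[keep].reset_index(drop=True),
        G=gm.G[:, keep].copy(),
    )
    if ledger is not None:
        ledger.append("one_snp_per_rad_locus", out)
    return out
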