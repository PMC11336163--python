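"""Inversion-region detection and karyotyping.

Large polymorphic inversions show up as (i) highly aggregated PCA allele
loadings and LD spikes over Mbp scales, and (ii) three clusters along PC1 of a
region-restricted PCA — the two homozygous arrangements at the extremes with
low heterozygosity, and the heterozygous arrangement in the middle with high
heterozygosity. Detection flags windows whose aggregate statistic exceeds a
robust z-threshold; karyotyping clusters samples on PC1 and validates the
heterozygosity ordering before confirming a region.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genodata import MISSING, GenomicRegion, GenotypeMatrix, subset
from .structure import pca_genotypes


@dataclass
class KaryotypeCall:
    region: GenomicRegion
    karyotype: pd.Series           # per-sample label in {AA, AB, BB, unassigned}
    cluster_het: dict[str, float]  # mean observed heterozygosity per karyotype
    cluster_pc1_centers: dict[str, float]
    p_inv: float
    confirmed: bool
    n_snps: int


def detect_aggregated_regions(
    track: pd.DataFrame,
    stat_col: str = "stat",
    window_bp: float = 1e6,
    z_threshold: float = 4.0,
    merge_gap_bp: float = 2e6,
    min_windows: int = 10,
) -> list[GenomicRegion]:
    """Flag genome windows with aggregated signal and merge them into regions.

    ``track`` has one row per site or window with columns chrom, pos (or
    start/end) and a statistic. The statistic is summed per fixed window; a
    window is flagged when its sum exceeds median + z_threshold * (1.4826 *
    MAD) computed per chromosome; flagged windows within ``merge_gap_bp`` are
    merged, and region bounds snap to the outermost contributing positions.
    Chromosomes with fewer than ``min_windows`` windows are skipped.
    """
    regions: list[GenomicRegion] = []
    for chrom, sub in track.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy(dtype=float)
        stat = sub[stat_col].to_numpy(dtype=float)
        ok = np.isfinite(stat)
        pos, stat = pos[ok], stat[ok]
        if len(pos) == 0:
            continue
        win = ((pos - 1) // window_bp).astype(int)
        n_windows = win.max() + 1
        if n_windows < min_windows:
            warnings.warn(f"{chrom}: only {n_windows} windows, skipped")
            continue
        sums = np.zeros(n_windows)
        np.add.at(sums, win, stat)
        med = np.median(sums)
        mad = np.median(np.abs(sums - med))
        scale = 1.4826 * mad
        if scale <= 0:
            continue
        flagged = np.where(sums > med + z_threshold * scale)[0]
        if len(flagged) == 0:
            continue
        # merge flagged windows within merge_gap_bp
        groups: list[list[int]] = [[flagged[0]]]
        for w in flagged[1:]:
            if (w - groups[-1][-1]) * window_bp <= merge_gap_bp:
                groups[-1].append(w)
            else:
                groups.append([w])
        for grp in groups:
            in_grp = np.isin(win, grp)
            p = pos[in_grp]
            regions.append(GenomicRegion(chrom, int(p.min()), int(p.max())))
    return regions


def karyotype_region(
    gm: GenotypeMatrix, region: GenomicRegion, seed: int = 0,
    separation_min: float = 0.95,
) -> KaryotypeCall:
    """Karyotype samples as AA/AB/BB from a region-restricted PCA.

    PCA over the region's SNPs, k-means (k=3, multi-restart) on PC1; clusters
    are ordered along PC1 and labelled AA (left), AB (middle), BB (right),
    with AA/BB swapped afterwards if needed so AA is the larger homozygote
    cluster (arrangement polarity is unknowable from genotypes alone). The
    call is ``confirmed`` only if (i) the middle cluster has strictly maximal
    mean observed heterozygosity and (ii) the three clusters are genuinely
    discrete: the cluster means explain at least ``separation_min`` of PC1
    variance. Condition (ii) guards against the unimodal null, where
    heterozygous samples sit centrally on PC1 and would satisfy (i) by
    construction. p_inv = (2 n_BB + n_AB) / (2 n_assigned). Samples farther
    than 3 cluster-SDs from every center are unassigned.
    """
    from sklearn.cluster import KMeans

    sub = subset(gm, regions=[region])
    poly = (np.nanstd(np.where(sub.G == MISSING, np.nan, sub.G), axis=0) > 0)
    if poly.sum() < 10:
        raise ValueError(f"region {region} has {poly.sum()} polymorphic SNPs (<10)")
    if sub.n_samples < 10:
        raise ValueError("need >= 10 samples to karyotype")
    pca = pca_genotypes(sub, n_axes=2)
    pc1 = pca.scores[:, 0]
    km = KMeans(n_clusters=3, n_init=10, random_state=seed).fit(pc1[:, None])
    centers = km.cluster_centers_.ravel()
    order = np.argsort(centers)  # left, middle, right along PC1
    lab_of = {order[0]: "AA", order[1]: "AB", order[2]: "BB"}
    labels = np.array([lab_of[c] for c in km.labels_], dtype=object)

    # unassign outliers: > 3 cluster SDs from every center
    sds = np.array(
        [pc1[km.labels_ == c].std() if (km.labels_ == c).sum() > 1 else np.inf
         for c in range(3)]
    )
    z = np.abs(pc1[:, None] - centers[None, :]) / np.maximum(sds[None, :], 1e-9)
    labels[(z > 3).all(axis=1)] = "unassigned"

    # per-karyotype mean observed heterozygosity over region SNPs
    het_rate = np.where(sub.G == MISSING, np.nan, (sub.G == 1).astype(float))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        per_sample_het = np.nanmean(het_rate, axis=1)
    cluster_het = {}
    pc1_centers = {}
    for lab in ("AA", "AB", "BB"):
        m = labels == lab
        cluster_het[lab] = float(np.nanmean(per_sample_het[m])) if m.sum() else float("nan")
        pc1_centers[lab] = float(pc1[m].mean()) if m.sum() else float("nan")
        if 0 < m.sum() < 2:
            warnings.warn(f"karyotype cluster {lab} has <2 members")

    # AA = larger homozygote cluster (polarity convention)
    if (labels == "BB").sum() > (labels == "AA").sum():
        swap = {"AA": "BB", "BB": "AA", "AB": "AB", "unassigned": "unassigned"}
        labels = np.array([swap[l] for l in labels], dtype=object)
        cluster_het = {swap.get(k, k): v for k, v in cluster_het.items()}
        pc1_centers = {swap.get(k, k): v for k, v in pc1_centers.items()}

    n_assigned = int((labels != "unassigned").sum())
    n_ab = int((labels == "AB").sum())
    n_bb = int((labels == "BB").sum())
    p_inv = (2 * n_bb + n_ab) / (2 * n_assigned) if n_assigned else float("nan")
    wss = float(km.inertia_)
    total_ss = float(((pc1 - pc1.mean()) ** 2).sum())
    separation = 1.0 - wss / total_ss if total_ss > 0 else 0.0
    confirmed = (
        np.isfinite(cluster_het["AB"])
        and cluster_het["AB"] > np.nanmax([cluster_het["AA"], cluster_het["BB"]])
        and separation >= separation_min
    )
    return KaryotypeCall(
        region=region,
        karyotype=pd.Series(labels, index=gm.samples, name="karyotype"),
        cluster_het=cluster_het,
        cluster_pc1_centers=pc1_centers,
        p_inv=float(p_inv),
        confirmed=bool(confirmed),
        n_snps=int(sub.n_loci),
    )
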