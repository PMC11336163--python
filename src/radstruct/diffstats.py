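"""Outlier scans, differentiation and diversity statistics, group tests, and
the species/hybrid classifier.

* PCA-based outlier scan: per-locus z-scores from regressing standardized
  dosages on the leading PCs, robust Mahalanobis distance, genomic-inflation
  correction, chi-square p-values and Benjamini-Hochberg q-values;
* multi-locus Weir & Cockerham (1984) theta with a bootstrap over loci;
* per-individual inbreeding F from observed vs expected homozygosity;
* Kruskal-Wallis + Dunn's post-hoc tests on per-group values;
* a decision-table classifier combining K=2 nuclear ancestry with diagnostic
  mtDNA sites into species / hybrid / mito-nuclear-discordant categories.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genodata import MISSING, GenotypeMatrix
from .structure import _imputed_centered


def round_half_up(x: float, ndigits: int = 1) -> float:
    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(x)).quantize(q, rounding=decimal.ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# PCA-based outlier scan (Mahalanobis on PC-regression z-scores)
# ---------------------------------------------------------------------------

def pcadapt_outliers(
    gm: GenotypeMatrix,
    K: int = 2,
    fdr: float = 0.05,
    robust_scatter: str = "mad_diagonal",
) -> pd.DataFrame:
    """Locus outlier scan against the first K principal components.

    Dosages are standardized (centered, scaled by sqrt(p(1-p))); each locus is
    regressed on the K orthonormal PC score vectors, giving K z-scores per
    locus (coefficient / residual SE). D2 is the Mahalanobis distance of the
    z-vector using a robust location (coordinatewise median) and, by default,
    a MAD-based diagonal scatter. The genomic inflation factor
    lambda = median(D2) / median(chi2_K) rescales D2 before the chi-square
    upper-tail p-value; q-values are Benjamini-Hochberg.
    """
    from statsmodels.stats.multitest import multipletests

    n, L = gm.n_samples, gm.n_loci
    if K >= n:
        raise ValueError("K must be < n samples")
    if L < 50:
        raise ValueError("need >= 50 loci")
    X, center = _imputed_centered(gm)
    p_hat = np.clip(center / 2.0, 1e-6, 1 - 1e-6)
    X = X / np.sqrt(p_hat * (1.0 - p_hat))
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    Uk = U[:, :K]  # orthonormal regressors
    beta = Uk.T @ X                          # K x L (since Uk columns orthonormal)
    resid = X - Uk @ beta
    dof = max(n - K, 1)
    sigma = np.sqrt((resid**2).sum(axis=0) / dof)
    sigma = np.maximum(sigma, 1e-12)
    z = (beta / sigma).T                     # L x K

    mu = np.median(z, axis=0)
    if robust_scatter == "mad_diagonal":
        mad = np.median(np.abs(z - mu), axis=0) * 1.4826
        mad = np.maximum(mad, 1e-12)
        d2 = (((z - mu) / mad) ** 2).sum(axis=1)
    elif robust_scatter == "mcd":
        from sklearn.covariance import MinCovDet

        mcd = MinCovDet(random_state=0).fit(z)
        d2 = mcd.mahalanobis(z)
    else:
        raise ValueError("robust_scatter must be 'mad_diagonal' or 'mcd'")

    lam = float(np.median(d2) / stats.chi2.median(K))
    p = stats.chi2.sf(d2 / lam, df=K)
    _, q, _, _ = multipletests(p, method="fdr_bh")
    out = pd.DataFrame(
        {
            "chrom": gm.loci["chrom"].to_numpy(),
            "pos": gm.loci["pos"].to_numpy(),
            "D2": d2,
            "p_value": p,
            "q_value": q,
            "flag_fdr": q < fdr,
            "flag_bonferroni": p < 0.05 / L,
        }
    )
    for k in range(K):
        out[f"z{k + 1}"] = z[:, k]
    out.attrs["lambda"] = lam
    out.attrs["K"] = K
    return out


def outlier_partition_counts(L_total: int, n_outlier: int) -> dict:
    """Partition arithmetic: outlier/neutral counts and half-up percentages."""
    if n_outlier > L_total:
        raise ValueError("outlier count exceeds total")
    return {
        "n_outlier": int(n_outlier),
        "n_neutral": int(L_total - n_outlier),
        "pct_outlier": round_half_up(100.0 * n_outlier / L_total, 1),
        "pct_neutral": round_half_up(100.0 * (L_total - n_outlier) / L_total, 1),
    }


# ---------------------------------------------------------------------------
# Weir & Cockerham FST
# ---------------------------------------------------------------------------

def _wc_components(
    G: np.ndarray, groups: list[np.ndarray]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus variance components (a, b, c) of Weir & Cockerham (1984)
    for biallelic loci with unequal sample sizes; r = len(groups)."""
    r = len(groups)
    L = G.shape[1]
    n_i = np.zeros((r, L))
    p_i = np.zeros((r, L))
    h_i = np.zeros((r, L))
    for k, idx in enumerate(groups):
        sub = G[idx]
        obs = sub != MISSING
        n = obs.sum(axis=0).astype(float)
        alt = np.where(obs, sub, 0).sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p_i[k] = np.where(n > 0, alt / (2 * n), np.nan)
            h_i[k] = np.where(n > 0, (sub == 1).sum(axis=0) / n, np.nan)
        n_i[k] = n
    valid = (n_i >= 2).all(axis=0)
    nbar = n_i.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n_i**2).sum(axis=0) / (r * nbar)) / (r - 1)
        pbar = (n_i * p_i).sum(axis=0) / (r * nbar)
        s2 = (n_i * (p_i - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n_i * h_i).sum(axis=0) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
    poly = valid & (pbar > 0) & (pbar < 1)
    return a[poly], b[poly], c[poly]


@dataclass
class FstResult:
    groups: list[str]
    theta: pd.DataFrame     # pairwise multi-locus theta
    p_value: pd.DataFrame   # bootstrap one-sided p (theta <= 0)
    ci_low: pd.DataFrame
    ci_high: pd.DataFrame
    n_boot: int


def wc_fst(
    gm: GenotypeMatrix,
    group_labels: pd.Series | dict,
    n_boot: int = 1000,
    seed: int = 0,
) -> FstResult:
    """Pairwise multi-locus Weir-Cockerham theta with a bootstrap over loci.

    theta = sum_l a_l / sum_l (a_l + b_l + c_l); the bootstrap resamples loci
    with replacement, p = fraction of replicates with theta* <= 0 (one-sided
    departure from zero), and the CI is the 2.5-97.5 percentile interval.
    Pairs with no jointly polymorphic usable loci get NaN entries.
    """
    if isinstance(group_labels, dict):
        group_labels = pd.Series(group_labels)
    group_labels = group_labels.reindex(gm.samples)
    names = sorted(group_labels.dropna().unique())
    rng = np.random.default_rng(seed)
    theta = pd.DataFrame(np.nan, index=names, columns=names)
    pval = pd.DataFrame(np.nan, index=names, columns=names)
    lo = pd.DataFrame(np.nan, index=names, columns=names)
    hi = pd.DataFrame(np.nan, index=names, columns=names)
    for i, gi in enumerate(names):
        theta.loc[gi, gi] = 0.0
        for gj in names[i + 1 :]:
            idx_i = np.where((group_labels == gi).to_numpy())[0]
            idx_j = np.where((group_labels == gj).to_numpy())[0]
            a, b, c = _wc_components(gm.G, [idx_i, idx_j])
            denom = a + b + c
            use = np.isfinite(denom) & (denom != 0)
            a, denom = a[use], denom[use]
            if len(a) == 0:
                continue
            t = float(a.sum() / denom.sum())
            boots = np.empty(n_boot)
            idx = rng.integers(0, len(a), size=(n_boot, len(a)))
            boots = a[idx].sum(axis=1) / denom[idx].sum(axis=1)
            p = float((boots <= 0).mean())
            theta.loc[gi, gj] = theta.loc[gj, gi] = t
            pval.loc[gi, gj] = pval.loc[gj, gi] = p
            lo.loc[gi, gj] = lo.loc[gj, gi] = float(np.percentile(boots, 2.5))
            hi.loc[gi, gj] = hi.loc[gj, gi] = float(np.percentile(boots, 97.5))
    return FstResult(names, theta, pval, lo, hi, n_boot)


# ---------------------------------------------------------------------------
# Individual inbreeding
# ---------------------------------------------------------------------------

def individual_inbreeding(gm: GenotypeMatrix, min_sites: int = 50) -> pd.DataFrame:
    """Method-of-moments inbreeding F per individual.

    F = (O_hom - E_hom) / (L - E_hom), with E_hom summed over the sample's
    non-missing loci as 1 - 2 p (1-p) (2n / (2n - 1)), p and n the locus-wise
    sample allele frequency and genotyped count (small-sample corrected).
    """
    G = gm.G
    obs = G != MISSING
    n = obs.sum(axis=0).astype(float)
    alt = np.where(obs, G, 0).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / (2 * n), np.nan)
        e_hom_site = 1.0 - 2.0 * p * (1 - p) * (2 * n / (2 * n - 1))
    rows = []
    for i, sid in enumerate(gm.samples):
        ok = obs[i] & np.isfinite(e_hom_site) & (n >= 2)
        L = int(ok.sum())
        if L < min_sites:
            rows.append({"sample_id": sid, "O_hom": np.nan, "E_hom": np.nan,
                         "L": L, "F": np.nan})
            continue
        o_hom = int(((G[i] == 0) | (G[i] == 2))[ok].sum())
        e_hom = float(e_hom_site[ok].sum())
        denom = L - e_hom
        f = (o_hom - e_hom) / denom if abs(denom) > 1e-12 else np.nan
        rows.append({"sample_id": sid, "O_hom": o_hom, "E_hom": e_hom, "L": L, "F": f})
    return pd.DataFrame(rows).set_index("sample_id", drop=False)


# ---------------------------------------------------------------------------
# Group tests: Kruskal-Wallis + Dunn
# ---------------------------------------------------------------------------

def group_het_tests(
    values: pd.Series | np.ndarray,
    labels: pd.Series | np.ndarray,
    adjust: str = "bonferroni",
) -> dict:
    """Kruskal-Wallis across groups plus Dunn's pairwise post-hoc z tests.

    Dunn's z uses mean ranks from the pooled tie-corrected ranking; pairwise
    p-values are two-sided normal tails, adjusted by Bonferroni (default),
    Benjamini-Hochberg, or left raw.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    ok = np.isfinite(values)
    values, labels = values[ok], labels[ok]
    names = sorted(pd.unique(labels))
    groups = [values[labels == g] for g in names]
    if len(names) < 2 or min(len(g) for g in groups) < 3:
        raise ValueError("need >= 2 groups with >= 3 values each")
    if np.all(values == values[0]):
        return {"H": 0.0, "p": 1.0, "dunn": pd.DataFrame()}
    H, p = stats.kruskal(*groups)

    N = len(values)
    ranks = stats.rankdata(values)
    _, counts = np.unique(values, return_counts=True)
    tie_term = (counts**3 - counts).sum()
    rows = []
    raw_p = []
    for i, gi in enumerate(names):
        for gj in names[i + 1 :]:
            ri = ranks[labels == gi].mean()
            rj = ranks[labels == gj].mean()
            ni, nj = (labels == gi).sum(), (labels == gj).sum()
            se = np.sqrt(
                (N * (N + 1) / 12.0 - tie_term / (12.0 * (N - 1)))
                * (1.0 / ni + 1.0 / nj)
            )
            z = (ri - rj) / se
            pij = 2.0 * stats.norm.sf(abs(z))
            rows.append({"group_i": gi, "group_j": gj, "z": float(z)})
            raw_p.append(pij)
    raw_p = np.array(raw_p)
    if adjust == "bonferroni":
        adj = np.minimum(raw_p * len(raw_p), 1.0)
    elif adjust == "bh":
        from statsmodels.stats.multitest import multipletests

        _, adj, _, _ = multipletests(raw_p, method="fdr_bh")
    elif adjust == "none":
        adj = raw_p
    else:
        raise ValueError("adjust must be bonferroni/bh/none")
    dunn = pd.DataFrame(rows)
    dunn["p_raw"] = raw_p
    dunn["p_adj"] = adj
    return {"H": float(H), "p": float(p), "dunn": dunn}


# ---------------------------------------------------------------------------
# Species / hybrid classifier
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MtdnaDiagnostics:
    """Diagnostic mtDNA sites: position -> (species, diagnostic base)."""

    a_site: tuple[str, str] = ("4894", "G")
    b_site: tuple[str, str] = ("5138", "T")


def classify_species(
    Q: np.ndarray,
    samples: list[str],
    sample_table: pd.DataFrame,
    diagnostics: MtdnaDiagnostics = MtdnaDiagnostics(),
    admix_threshold: float = 0.05,
    a_cluster: int | None = None,
) -> pd.DataFrame:
    """Combine K=2 nuclear ancestry with diagnostic mtDNA sites.

    mtDNA species = A if the A-diagnostic base is present, B if the
    B-diagnostic base is present, unclassified otherwise (both present ->
    unclassified with a warning). Nuclear class: majority cluster when minor
    ancestry < ``admix_threshold``, else admixed. Final decision table:
    nuclear A -> pure_A; nuclear admixed -> admixed; nuclear B with mtDNA A ->
    B_with_A_mtDNA; nuclear B otherwise -> pure_B. ``a_cluster`` names the Q
    column of species A; by default the minority cluster is taken as A.
    """
    import warnings

    Q = np.asarray(Q, dtype=float)
    if Q.shape[1] != 2:
        raise ValueError("classifier expects K=2 ancestry")
    if a_cluster is None:
        a_cluster = int(np.argmin((Q > 0.5).sum(axis=0)))
    col_a = f"mtdna_{diagnostics.a_site[0]}"
    col_b = f"mtdna_{diagnostics.b_site[0]}"
    rows = []
    for i, sid in enumerate(samples):
        meta = sample_table.loc[sid] if sid in sample_table.index else None
        has_a = meta is not None and col_a in meta and meta[col_a] == diagnostics.a_site[1]
        has_b = meta is not None and col_b in meta and meta[col_b] == diagnostics.b_site[1]
        if has_a and has_b:
            warnings.warn(f"{sid}: both diagnostic mtDNA bases present")
            mt = "unclassified"
        elif has_a:
            mt = "A"
        elif has_b:
            mt = "B"
        else:
            mt = "unclassified"
        q_a = Q[i, a_cluster]
        minor = min(q_a, 1.0 - q_a)
        if minor >= admix_threshold:
            cls = "admixed"
        elif q_a > 0.5:
            cls = "pure_A"
        elif mt == "A":
            cls = "B_with_A_mtDNA"
        else:
            cls = "pure_B"
        rows.append(
            {
                "sample_id": sid,
                "q_A": float(q_a),
                "minor_ancestry": float(minor),
                "mtdna_species": mt,
                "species_class": cls,
            }
        )
    return pd.DataFrame(rows).set_index("sample_id", drop=False)


def ecoregion_summary(
    calls: pd.DataFrame, sample_table: pd.DataFrame
) -> pd.DataFrame:
    """Per-ecoregion counts and half-up percentages of each species class."""
    if "ecoregion" in calls.columns:
        merged = calls
    else:
        merged = calls.join(sample_table["ecoregion"], how="left")
    rows = []
    for eco, sub in merged.groupby("ecoregion"):
        n = len(sub)
        row = {"ecoregion": eco, "n": n}
        for cls in ("pure_A", "admixed", "B_with_A_mtDNA", "pure_B"):
            cnt = int((sub["species_class"] == cls).sum())
            row[f"n_{cls}"] = cnt
            row[f"pct_{cls}"] = round_half_up(100.0 * cnt / n, 1) if n else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def summary_percentages(counts: dict[str, int], totals: dict[str, int]) -> dict:
    """Half-up 1-decimal percentages for (count, total) pairs keyed alike."""
    return {
        k: round_half_up(100.0 * counts[k] / totals[k], 1) for k in counts
    }
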