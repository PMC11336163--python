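"""Per-marker association with phenotypic sex.

A genotype-level analog of read-presence sex scans: under an XY system,
male-limited markers (on the Y) are present — non-missing, alt-carrying —
almost exclusively in males, so a 2x2 test of sex x marker presence flags
them. Bonferroni control is applied over the markers actually tested, and a
signed bias statistic (+1 = fully male-biased) gives the direction. A
male-biased significant segment is the XY-like signature (males
heterogametic).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .genodata import MISSING, GenotypeMatrix


def _presence(G: np.ndarray, mode: str) -> np.ndarray:
    if mode == "presence":
        return G != MISSING
    if mode == "dosage":  # alt-carrier status among non-missing calls
        return G >= 1
    raise ValueError("mode must be 'presence' or 'dosage'")


def sex_scan(
    gm: GenotypeMatrix,
    sexes: pd.Series | dict,
    mode: str = "presence",
    min_per_sex: int = 5,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Test each marker for sex-biased presence/carrier status.

    For every marker a 2x2 table of (sex x property) is tested by chi-square
    with continuity correction, falling back to Fisher's exact test when any
    expected cell is < 5. ``bias`` = carrier fraction in males minus in
    females (sign flips exactly under a sex-label swap). Markers with fewer
    than ``min_per_sex`` informative individuals of either sex are reported
    as untested (p NaN), and the Bonferroni threshold uses L = number of
    markers actually tested.
    """
    if isinstance(sexes, dict):
        sexes = pd.Series(sexes)
    sexes = sexes.reindex(gm.samples)
    is_m = (sexes == "M").to_numpy()
    is_f = (sexes == "F").to_numpy()
    if is_m.sum() == 0 or is_f.sum() == 0:
        raise ValueError("need at least one individual of each sex")
    G = gm.G
    prop = _presence(G, mode)
    if mode == "dosage":
        informative = G != MISSING
    else:
        informative = np.ones_like(prop, dtype=bool)

    # vectorized 2x2 tables: [carrier_m, noncarrier_m; carrier_f, noncarrier_f]
    inf_m = informative[is_m]
    inf_f = informative[is_f]
    n_m = inf_m.sum(axis=0).astype(float)
    n_f = inf_f.sum(axis=0).astype(float)
    a = (prop[is_m] & inf_m).sum(axis=0).astype(float)   # male carriers
    c = (prop[is_f] & inf_f).sum(axis=0).astype(float)   # female carriers
    b = n_m - a
    d = n_f - c
    tested = (n_m >= min_per_sex) & (n_f >= min_per_sex)
    with np.errstate(invalid="ignore", divide="ignore"):
        f_m = np.where(n_m > 0, a / n_m, np.nan)
        f_f = np.where(n_f > 0, c / n_f, np.nan)
    bias = f_m - f_f

    N = a + b + c + d
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = (a + b) * (c + d) * (a + c) * (b + d)
        chi2 = np.where(
            denom > 0,
            N * np.maximum(np.abs(a * d - b * c) - N / 2.0, 0.0) ** 2 / denom,
            0.0,
        )
        expected_min = np.minimum.reduce(
            [
                (a + b) * (a + c) / N, (a + b) * (b + d) / N,
                (c + d) * (a + c) / N, (c + d) * (b + d) / N,
            ]
        )
    p = stats.chi2.sf(chi2, df=1)
    p = np.where(bias == 0, 1.0, p)  # exact null symmetry for balanced tables
    # exact test where the chi-square approximation is unsafe: small expected
    # counts, or extreme observed cells (fully sex-limited markers)
    obs_min = np.minimum.reduce([a, b, c, d])
    need_exact = tested & ((expected_min < 5) | (obs_min < 5)) & (bias != 0)
    for j in np.where(need_exact)[0]:
        table = np.array([[a[j], b[j]], [c[j], d[j]]], dtype=int)
        _, p[j] = stats.fisher_exact(table)
    p = np.where(tested, p, np.nan)
    bias = np.where(tested, bias, np.nan)

    df = pd.DataFrame({"p_value": p, "bias": bias, "tested": tested})
    df.insert(0, "pos", gm.loci["pos"].to_numpy())
    df.insert(0, "chrom", gm.loci["chrom"].to_numpy())
    df["mode"] = mode
    n_tested = int(df["tested"].sum())
    threshold = alpha / n_tested if n_tested else np.nan
    df["significant"] = df["tested"] & (df["p_value"] < threshold)
    df.attrs["bonferroni_threshold"] = threshold
    df.attrs["n_tested"] = n_tested
    return df


def significant_span(scan: pd.DataFrame) -> dict | None:
    """Outermost significant markers per chromosome; None when no hits."""
    hits = scan[scan["significant"]]
    if hits.empty:
        return None
    spans = {}
    for chrom, sub in hits.groupby("chrom"):
        spans[chrom] = (int(sub["pos"].min()), int(sub["pos"].max()))
    return spans
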