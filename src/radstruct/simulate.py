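"""Synthetic ddRAD-style SNP dataset generator.

Emulates the statistical structure the downstream analyses assume, so every
stage can be exercised without sequence data:

* two gadid-like species (A, B) with near-fixed nuclear divergence at a
  diagnostic subset of loci and species-diagnostic maternal mtDNA sites;
* F1 and serial-backcross hybrids with pedigree-expected ancestry;
* an island model of >=2 populations within species B, calibrated to a target
  Weir-Cockerham FST through the Balding-Nichols frequency model;
* a minority of outlier loci with inflated differentiation;
* Mbp-scale inversion polymorphisms: two internally near-monomorphic haplotype
  groups, so inversion heterozygotes (AB) are heterozygous at divergent sites
  and homozygotes are not;
* an XY-like sex-linked segment whose male-limited markers are present
  (non-missing, alt-carrying) almost exclusively in males;
* random missingness, a lognormal median-depth model, and optional duplicate /
  parent-offspring sample pairs.

All randomness flows from a single seed through numpy Generators; identical
configs produce identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genodata import (
    MISSING,
    GenomicRegion,
    GenotypeMatrix,
    write_bed,
    write_sample_table,
    write_vcf,
)

# mtDNA diagnostic sites: one site carries the species-A diagnostic base, the
# other the species-B diagnostic base; the non-diagnostic species shows the
# alternative base at that site.
MTDNA_DIAG_A = ("4894", "G", "A")  # (position, diagnostic base, other base)
MTDNA_DIAG_B = ("5138", "T", "C")


@dataclass(frozen=True)
class HybridSpec:
    """``hclass`` is "F1" or "BC<g>" (g >= 1); backcrossing is onto species B
    unless ``backcross_parent`` says "A". ``maternal`` fixes the mtDNA lineage."""

    hclass: str
    count: int
    backcross_parent: str = "B"
    maternal: str = "A"


@dataclass(frozen=True)
class InversionSpec:
    region: GenomicRegion
    p_inv: float = 0.3
    divergent_fraction: float = 0.8
    within_diversity: float = 0.05  # allele freq of the rare allele inside a haplogroup


@dataclass(frozen=True)
class SexSpec:
    region: GenomicRegion
    male_limited_fraction: float = 0.8
    presence_prob_male: float = 0.98
    leakage_prob_female: float = 0.0


@dataclass(frozen=True)
class RelatedSpec:
    relationship: str  # "duplicate" | "parent_offspring"
    count: int = 1


@dataclass
class SimConfig:
    """Full description of one synthetic dataset. The seed fixes everything."""

    seed: int = 0
    n_loci: int = 2000
    chrom_layout: dict[str, int] = field(
        default_factory=lambda: {"chr1": 30_000_000, "chr2": 30_000_000}
    )
    # species divergence: diagnostic loci are near-fixed between species with gap d
    species_divergence: float = 0.96
    diagnostic_fraction: float = 0.5
    n_pure_A: int = 0
    hybrid_spec: list[HybridSpec] = field(default_factory=list)
    # island model within species B
    pop_sizes: dict[str, int] = field(default_factory=lambda: {"pop1": 50})
    fst: float = 0.01
    outlier_fraction: float = 0.0
    outlier_multiplier: float = 10.0
    inversion_spec: list[InversionSpec] = field(default_factory=list)
    sex_spec: SexSpec | None = None
    n_B_with_A_mtdna: int = 0
    missing_rate: float = 0.0
    depth_meanlog: float = 3.4  # median depth ~ lognormal, e^3.4 ~ 30x
    depth_sdlog: float = 0.35
    related_pairs: list[RelatedSpec] = field(default_factory=list)

    def validate(self) -> None:
        for f, name in [
            (self.species_divergence, "species_divergence"),
            (self.diagnostic_fraction, "diagnostic_fraction"),
            (self.fst, "fst"),
            (self.outlier_fraction, "outlier_fraction"),
            (self.missing_rate, "missing_rate"),
        ]:
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"{name}={f} outside [0, 1]")
        if any(n < 0 for n in self.pop_sizes.values()) or self.n_pure_A < 0:
            raise ValueError("negative sample counts")
        regions = [s.region for s in self.inversion_spec]
        if self.sex_spec:
            regions.append(self.sex_spec.region)
        for r in regions:
            if r.chrom not in self.chrom_layout:
                raise ValueError(f"region chromosome {r.chrom} not in layout")
            if r.end > self.chrom_layout[r.chrom]:
                raise ValueError(f"region {r} exceeds chromosome length")


def _balding_nichols(rng, p_anc: np.ndarray, fst: np.ndarray) -> np.ndarray:
    """Deme allele frequencies ~ Beta(p(1-F)/F, (1-p)(1-F)/F)."""
    fst = np.clip(fst, 1e-6, 0.999)
    a = p_anc * (1.0 - fst) / fst
    b = (1.0 - p_anc) * (1.0 - fst) / fst
    return np.clip(rng.beta(a, b), 1e-4, 1.0 - 1e-4)


def _layout_loci(cfg: SimConfig, rng) -> pd.DataFrame:
    chroms = list(cfg.chrom_layout)
    lengths = np.array([cfg.chrom_layout[c] for c in chroms], dtype=float)
    counts = np.maximum(1, np.round(cfg.n_loci * lengths / lengths.sum()).astype(int))
    # adjust to hit n_loci exactly
    while counts.sum() > cfg.n_loci:
        counts[np.argmax(counts)] -= 1
    while counts.sum() < cfg.n_loci:
        counts[np.argmax(lengths)] += 1
    rows = []
    bases = np.array(list("ACGT"))
    for chrom, k in zip(chroms, counts):
        pos = np.sort(rng.choice(cfg.chrom_layout[chrom], size=k, replace=False)) + 1
        for p in pos:
            ref, alt = rng.choice(4, size=2, replace=False)
            rows.append(
                {"chrom": chrom, "pos": int(p), "id": f"{chrom}:{p}",
                 "ref": bases[ref], "alt": bases[alt]}
            )
    return pd.DataFrame(rows)


def simulate_hybrids(
    freq_A: np.ndarray,
    freq_B: np.ndarray,
    hclass: str,
    n: int,
    seed: int | np.random.Generator,
    backcross_parent: str = "B",
) -> tuple[np.ndarray, np.ndarray, float]:
    """Simulate hybrid dosages at the haplotype level with free recombination.

    F1: one haplotype drawn from each species' frequencies. BCg: a gamete from
    the previous-generation hybrid (each locus picks one of its two haplotypes)
    paired with a gamete from the recurrent parent. Returns (dosage block
    n x L, realized minor-parent ancestry per sample over loci, expected minor
    ancestry = 0.5**(g+1) for BCg, 0.5 for F1).
    """
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    if hclass == "F1":
        gen = 0
    elif hclass.startswith("BC") and hclass[2:].isdigit() and int(hclass[2:]) >= 1:
        gen = int(hclass[2:])
    else:
        raise ValueError(f"unknown hybrid class {hclass!r}")
    L = len(freq_A)
    if len(freq_B) != L:
        raise ValueError("parental frequency vectors differ in length")
    recurrent, minor = (freq_B, freq_A) if backcross_parent == "B" else (freq_A, freq_B)

    # h1 is the haplotype carrying minor-parent ancestry (origin flag 1)
    h1 = (rng.random((n, L)) < minor).astype(np.int8)
    h2 = (rng.random((n, L)) < recurrent).astype(np.int8)
    orig1 = np.ones((n, L), dtype=np.int8)
    orig2 = np.zeros((n, L), dtype=np.int8)
    for _ in range(gen):
        pick = rng.random((n, L)) < 0.5
        h1, orig1 = np.where(pick, h1, h2), np.where(pick, orig1, orig2)
        h2 = (rng.random((n, L)) < recurrent).astype(np.int8)
        orig2 = np.zeros((n, L), dtype=np.int8)
    dosage = (h1 + h2).astype(np.int8)
    ancestry = (orig1 + orig2).mean(axis=1) / 2.0
    expected = 0.5 ** (gen + 1)
    return dosage, ancestry, expected


def expected_summaries(cfg: SimConfig) -> dict:
    """Closed-form expectations implied by a config (test oracle)."""
    cfg.validate()
    pops = list(cfg.pop_sizes)
    pairwise_fst = {
        (a, b): (cfg.fst if len(pops) > 1 else 0.0)
        for i, a in enumerate(pops)
        for b in pops[i + 1 :]
    }
    karyo = {}
    for spec in cfg.inversion_spec:
        q = spec.p_inv
        p = 1.0 - q
        karyo[(spec.region.chrom, spec.region.start, spec.region.end)] = (
            p * p, 2 * p * q, q * q,
        )
    ancestry = {}
    for h in cfg.hybrid_spec:
        g = 0 if h.hclass == "F1" else int(h.hclass[2:])
        ancestry[h.hclass] = 0.5 ** (g + 1)
    kinship = {"duplicate": 0.5, "parent_offspring": 0.25}
    return {
        "pairwise_fst": pairwise_fst,
        "karyotype_freqs": karyo,
        "hybrid_minor_ancestry": ancestry,
        "kinship": kinship,
    }


def _mtdna_columns(species: str) -> dict[str, str]:
    posA, baseA, otherA = MTDNA_DIAG_A
    posB, baseB, otherB = MTDNA_DIAG_B
    if species == "A":
        return {f"mtdna_{posA}": baseA, f"mtdna_{posB}": otherB}
    return {f"mtdna_{posA}": otherA, f"mtdna_{posB}": baseB}


def simulate_dataset(cfg: SimConfig) -> tuple[GenotypeMatrix, pd.DataFrame, dict]:
    """Generate (GenotypeMatrix, sample table, truth record) from a config."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    loci = _layout_loci(cfg, rng)
    L = len(loci)
    chroms = loci["chrom"].to_numpy()
    pos = loci["pos"].to_numpy()

    # --- per-locus roles -------------------------------------------------
    label = np.full(L, "neutral", dtype=object)
    inv_idx: list[np.ndarray] = []
    for spec in cfg.inversion_spec:
        m = (chroms == spec.region.chrom) & (pos >= spec.region.start) & (pos <= spec.region.end)
        inv_idx.append(np.where(m)[0])
        label[m] = "inversion_bg"
        div = np.where(m)[0]
        ndiv = int(round(spec.divergent_fraction * len(div)))
        chosen = rng.choice(div, size=ndiv, replace=False) if ndiv else np.array([], int)
        label[chosen] = "inversion"
    sex_ml = np.array([], dtype=int)
    if cfg.sex_spec:
        r = cfg.sex_spec.region
        m = (chroms == r.chrom) & (pos >= r.start) & (pos <= r.end)
        cand = np.where(m & (label == "neutral"))[0]
        nml = int(round(cfg.sex_spec.male_limited_fraction * len(cand)))
        sex_ml = rng.choice(cand, size=nml, replace=False) if nml else sex_ml
        label[sex_ml] = "sex_linked"
    free = np.where(label == "neutral")[0]
    n_out = int(round(cfg.outlier_fraction * len(free)))
    out_idx = rng.choice(free, size=n_out, replace=False) if n_out else np.array([], int)
    label[out_idx] = "outlier"

    # --- allele frequencies ----------------------------------------------
    p_anc = rng.uniform(0.05, 0.95, size=L)
    diag = np.zeros(L, dtype=bool)
    ndiag = int(round(cfg.diagnostic_fraction * len(free)))
    free2 = np.setdiff1d(free, out_idx)
    if ndiag and len(free2):
        diag[rng.choice(free2, size=min(ndiag, len(free2)), replace=False)] = True
    gap = cfg.species_divergence
    side = rng.random(L) < 0.5
    p_B_anc = p_anc.copy()
    p_B_anc[diag] = np.where(side[diag], (1 - gap) / 2, 1 - (1 - gap) / 2)
    freq_A = p_anc.copy()
    freq_A[diag] = 1.0 - p_B_anc[diag]

    pops = list(cfg.pop_sizes)
    fst_loc = np.full(L, max(cfg.fst, 1e-6))
    fst_loc[out_idx] = np.minimum(cfg.fst * cfg.outlier_multiplier, 0.9)
    deme_freqs = {
        pop: _balding_nichols(rng, p_B_anc, fst_loc) for pop in pops
    }

    # --- samples ----------------------------------------------------------
    sample_rows: list[dict] = []
    blocks: list[np.ndarray] = []
    truth_samples: list[dict] = []

    def add_sample(sid, species_class, pop, dosage, mtdna_species, ancestry_minor):
        sex = "M" if rng.random() < 0.5 else "F"
        row = {
            "sample_id": sid,
            "ecoregion": pop if pop else ("speciesA" if species_class == "pure_A" else "hybrid"),
            "site": f"site_{pop}" if pop else "site_x",
            "sex": sex,
        }
        row.update(_mtdna_columns(mtdna_species))
        sample_rows.append(row)
        blocks.append(dosage)
        truth_samples.append(
            {
                "sample_id": sid,
                "species_class": species_class,
                "population": pop,
                "sex": sex,
                "mtdna_species": mtdna_species,
                "minor_ancestry": ancestry_minor,
                "karyotypes": {},
                "relative_of": None,
            }
        )

    discordant_left = cfg.n_B_with_A_mtdna
    for pop in pops:
        f = deme_freqs[pop]
        for i in range(cfg.pop_sizes[pop]):
            dos = rng.binomial(2, f).astype(np.int8)
            mt = "B"
            cls = "pure_B"
            if discordant_left > 0:
                mt = "A"
                cls = "B_with_A_mtDNA"
                discordant_left -= 1
            add_sample(f"{pop}_{i:03d}", cls, pop, dos, mt, 0.0)
    for i in range(cfg.n_pure_A):
        dos = rng.binomial(2, freq_A).astype(np.int8)
        add_sample(f"A_{i:03d}", "pure_A", None, dos, "A", 1.0)
    for spec in cfg.hybrid_spec:
        dos, anc, _exp = simulate_hybrids(
            freq_A, deme_freqs[pops[0]], spec.hclass, spec.count, rng,
            backcross_parent=spec.backcross_parent,
        )
        for i in range(spec.count):
            add_sample(
                f"{spec.hclass}_{i:03d}", "admixed", pops[0], dos[i],
                spec.maternal, float(anc[i]),
            )

    G = np.stack(blocks, axis=0) if blocks else np.zeros((0, L), np.int8)
    n = G.shape[0]

    # --- inversion overrides ----------------------------------------------
    for spec, idx in zip(cfg.inversion_spec, inv_idx):
        div_sites = idx[label[idx] == "inversion"]
        eps = spec.within_diversity
        q = spec.p_inv
        for si, t in enumerate(truth_samples):
            if t["species_class"] == "pure_A":
                k = 0  # species A carries the ancestral arrangement
            else:
                k = rng.binomial(2, q)  # copies of the inverted arrangement
            t["karyotypes"][
                f"{spec.region.chrom}:{spec.region.start}-{spec.region.end}"
            ] = ("AA", "AB", "BB")[k]
            # haplotype groups: ancestral near-monomorphic at eps, inverted at 1-eps
            f1 = 1 - eps if k >= 1 else eps
            f2 = 1 - eps if k == 2 else eps
            d = (rng.random(len(div_sites)) < f1).astype(np.int8) + (
                rng.random(len(div_sites)) < f2
            ).astype(np.int8)
            G[si, div_sites] = d

    # --- sex-linked overrides ----------------------------------------------
    if cfg.sex_spec and len(sex_ml):
        ss = cfg.sex_spec
        for si, t in enumerate(truth_samples):
            if t["sex"] == "M":
                present = rng.random(len(sex_ml)) < ss.presence_prob_male
            else:
                present = rng.random(len(sex_ml)) < ss.leakage_prob_female
            vals = np.where(present, 2, MISSING).astype(np.int8)
            G[si, sex_ml] = vals

    # --- related pairs -----------------------------------------------------
    pure_b = [i for i, t in enumerate(truth_samples) if t["species_class"] == "pure_B"]
    rel_records = []
    k = 0
    for spec in cfg.related_pairs:
        for _ in range(spec.count):
            if not pure_b:
                break
            src = int(rng.choice(pure_b))
            t_src = truth_samples[src]
            sid = f"rel{k}_{spec.relationship}"
            k += 1
            if spec.relationship == "duplicate":
                dos = G[src].copy()
            elif spec.relationship == "parent_offspring":
                f = deme_freqs[t_src["population"] or pops[0]]
                parent_allele = np.where(
                    G[src] == 1, (rng.random(L) < 0.5).astype(np.int8), (G[src] // 2)
                ).astype(np.int8)
                parent_allele = np.where(G[src] == MISSING,
                                         (rng.random(L) < f).astype(np.int8),
                                         parent_allele)
                other = (rng.random(L) < f).astype(np.int8)
                dos = (parent_allele + other).astype(np.int8)
            else:
                raise ValueError(f"unknown relationship {spec.relationship!r}")
            G = np.vstack([G, dos[None, :]])
            row = dict(sample_rows[src])
            row["sample_id"] = sid
            sample_rows.append(row)
            t = dict(t_src)
            t["sample_id"] = sid
            t["relative_of"] = t_src["sample_id"]
            t["karyotypes"] = dict(t_src["karyotypes"])
            truth_samples.append(t)
            rel_records.append(
                {"relationship": spec.relationship, "a": t_src["sample_id"], "b": sid}
            )
    n = G.shape[0]

    # --- missingness and depth ---------------------------------------------
    if cfg.missing_rate > 0 and n:
        mask = rng.random(G.shape) < cfg.missing_rate
        G = np.where(mask, MISSING, G).astype(np.int8)
    loci = loci.copy()
    loci["median_depth"] = np.round(
        rng.lognormal(cfg.depth_meanlog, cfg.depth_sdlog, size=L), 1
    )

    table = pd.DataFrame(sample_rows)
    table["species_class"] = "unclassified"
    table = table.set_index("sample_id", drop=False)
    gm = GenotypeMatrix(
        samples=[r["sample_id"] for r in sample_rows], loci=loci, G=G.astype(np.int8)
    )
    truth = {
        "samples": {t["sample_id"]: t for t in truth_samples},
        "locus_label": label.tolist(),
        "related_pairs": rel_records,
        "deme_ancestral_freq": p_B_anc,
        "species_A_freq": freq_A,
        "config": cfg,
    }
    return gm, table, truth


def write_dataset(
    gm: GenotypeMatrix, table: pd.DataFrame, truth: dict, outdir: str | Path
) -> None:
    """Emit VCF + sample TSV + truth JSON + regions BED into a directory."""
    import json

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_vcf(gm, outdir / "genotypes.vcf")
    write_sample_table(table, outdir / "samples.tsv")
    cfg: SimConfig = truth["config"]
    regions = [s.region for s in cfg.inversion_spec]
    if cfg.sex_spec:
        regions.append(cfg.sex_spec.region)
    write_bed(regions, outdir / "regions.bed")
    serializable = {
        "samples": truth["samples"],
        "locus_label": truth["locus_label"],
        "related_pairs": truth["related_pairs"],
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(serializable, fh, indent=1)
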