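"""Staged analysis pipeline with a reproducible filter ledger.

Stage order mirrors the layered design the statistics assume: QC -> species
screen (remove the other species and admixed individuals; mito-nuclear
discordant conspecifics are retained) -> MAF refilter -> inversion detect /
karyotype -> sex scan -> removal of inversion and sex-linked regions ->
structure (PCA / clusters / ancestry) -> outlier partition -> LD prune ->
final structure on neutral unlinked loci. Every removal appends one ledger
row, so each count change is attributable to exactly one stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .genodata import (
    GenomicRegion,
    GenotypeMatrix,
    read_bed,
    read_sample_table,
    read_vcf,
    subset,
    write_vcf,
)
from .qc import FilterLedger, king_kinship, prune_related, sample_filter, snp_filter
from .structure import (
    admixture_em,
    find_clusters,
    loading_profile,
    pca_genotypes,
)
from .inversion import detect_aggregated_regions, karyotype_region
from .ld import ld_prune, site_mean_r2_profile
from .sexassoc import sex_scan, significant_span
from .diffstats import classify_species, ecoregion_summary, pcadapt_outliers

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    vcf: str | None = None
    sample_table: str | None = None
    regions_bed: str | None = None
    out_dir: str = "radstruct_run"
    seed: int = 0
    # stage toggles
    do_qc: bool = True
    do_species_screen: bool = True
    do_inversion: bool = True
    do_sex_scan: bool = True
    do_outliers: bool = True
    do_ld_prune: bool = True
    # thresholds
    maf_min: float = 0.01
    maf_refilter: float = 0.05
    max_missing_rate: float = 0.10
    max_sample_missing: float = 0.30
    het_max: float = 0.6
    het_mode: str = "observed"
    depth_range: tuple[float, float] | None = (10.0, 95.0)
    kin_threshold: float = 0.177
    kin_min_sites: int = 100
    admix_threshold: float = 0.05
    keep_discordant: bool = True
    inversion_z: float = 4.0
    inversion_window_bp: float = 1e6
    sex_alpha: float = 0.05
    sex_mode: str = "presence"
    outlier_K: int = 2
    outlier_fdr: float = 0.05
    outlier_set: str = "fdr"  # or "bonferroni"
    r2_within: float = 0.05
    ld_window_bp: float = 1e7
    r2_between: float = 0.10
    write_stage_vcfs: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "depth_range" in raw and raw["depth_range"] is not None:
            raw["depth_range"] = tuple(raw["depth_range"])
        return cls(**raw)


def _checksum(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def run_pipeline(
    cfg: RunConfig,
    gm: GenotypeMatrix | None = None,
    table: pd.DataFrame | None = None,
    regions: list[GenomicRegion] | None = None,
) -> dict:
    """Run the staged workflow; returns a result dict and writes a run directory.

    Inputs may be given as paths in the config or directly as objects (the
    in-memory route the synthetic generator uses).
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if gm is None:
        if cfg.vcf is None:
            raise ValueError("no genotype input (vcf path or GenotypeMatrix)")
        gm = read_vcf(cfg.vcf)
    if table is None and cfg.sample_table:
        table = read_sample_table(cfg.sample_table)
    if regions is None and cfg.regions_bed:
        regions = read_bed(cfg.regions_bed)

    gm_raw = gm  # pre-QC matrix: the sex scan's substrate (presence/absence
    # markers are near-monomorphic and half-missing by nature, so they cannot
    # survive MAF/missingness filters; the read-presence scan they stand in
    # for runs upstream of SNP filtering)
    ledger = FilterLedger()
    ledger.append("input", gm)
    results: dict = {"config": dataclasses.asdict(cfg), "stages": []}

    def stage(name):
        results["stages"].append(name)
        log.info("stage: %s", name)

    # --- QC ---------------------------------------------------------------
    if cfg.do_qc:
        stage("qc")
        gm = snp_filter(
            gm, maf_min=cfg.maf_min, max_missing_rate=cfg.max_missing_rate,
            het_max=cfg.het_max, het_mode=cfg.het_mode,
            depth_range=cfg.depth_range, ledger=ledger,
        )
        gm = sample_filter(gm, max_missing=cfg.max_sample_missing, ledger=ledger)
        pairs = king_kinship(gm, min_sites=cfg.kin_min_sites)
        gm, removed = prune_related(gm, pairs, cfg.kin_threshold, ledger=ledger)
        results["related_removed"] = removed

    # --- species screen ----------------------------------------------------
    if cfg.do_species_screen and table is not None:
        stage("species_screen")
        anc = admixture_em(gm, K=2, seed=cfg.seed)
        calls = classify_species(
            anc.Q, gm.samples, table, admix_threshold=cfg.admix_threshold
        )
        results["species_calls"] = calls
        results["ecoregion_summary"] = ecoregion_summary(calls, table)
        keep_classes = {"pure_B"}
        if cfg.keep_discordant:
            keep_classes.add("B_with_A_mtDNA")
        keep = [s for s in gm.samples if calls.loc[s, "species_class"] in keep_classes]
        gm = subset(gm, sample_keep=keep)
        gm = snp_filter(
            gm, maf_min=cfg.maf_refilter, max_missing_rate=1.01,
            het_max=1.0, depth_range=None,
        )
        ledger.append("species_screen+maf_refilter", gm)

    # --- inversion detection / karyotyping ----------------------------------
    detected: list[GenomicRegion] = list(regions or [])
    karyos = []
    if cfg.do_inversion:
        stage("inversion")
        pca = pca_genotypes(gm, n_axes=min(8, gm.n_samples - 1))
        auto: list[GenomicRegion] = []
        for ax in range(pca.scores.shape[1]):
            prof = loading_profile(pca.loadings[:, ax], gm.loci,
                                   window_bp=cfg.inversion_window_bp)
            track = prof.rename(columns={"sq_loading": "stat"})
            auto.extend(
                detect_aggregated_regions(
                    track, stat_col="stat", window_bp=cfg.inversion_window_bp,
                    z_threshold=cfg.inversion_z,
                )
            )
        # deduplicate overlapping candidates
        merged: list[GenomicRegion] = []
        for r in sorted(auto, key=lambda r: (r.chrom, r.start)):
            if merged and merged[-1].chrom == r.chrom and r.start <= merged[-1].end:
                merged[-1] = GenomicRegion(
                    r.chrom, merged[-1].start, max(merged[-1].end, r.end)
                )
            else:
                merged.append(r)
        if not detected:
            detected = merged
        results["inversion_candidates"] = merged
        for r in detected:
            try:
                karyos.append(karyotype_region(gm, r, seed=cfg.seed))
            except ValueError as e:
                log.warning("karyotype %s failed: %s", r, e)
        results["karyotypes"] = karyos

    # --- sex scan ------------------------------------------------------------
    sex_regions: list[GenomicRegion] = []
    if cfg.do_sex_scan and table is not None and "sex" in table.columns:
        stage("sex_scan")
        gm_sex = subset(gm_raw, sample_keep=gm.samples)
        sexes = table["sex"].reindex(gm_sex.samples)
        if (sexes == "M").sum() >= 5 and (sexes == "F").sum() >= 5:
            scan = sex_scan(gm_sex, sexes, mode=cfg.sex_mode, alpha=cfg.sex_alpha)
            results["sex_scan"] = scan
            spans = significant_span(scan)
            if spans:
                sex_regions = [
                    GenomicRegion(c, s, e) for c, (s, e) in spans.items()
                ]
            results["sex_regions"] = sex_regions
        else:
            log.warning("not enough sexed individuals; sex scan skipped")

    # --- remove confirmed inversion + sex regions -----------------------------
    removal = [k.region for k in karyos if k.confirmed] + sex_regions
    if removal:
        stage("region_removal")
        gm = subset(gm, regions=removal, invert_regions=True)
        ledger.append("inversion+sex_region_removal", gm)
    results["removed_regions"] = removal

    # --- structure on the screened dataset ------------------------------------
    stage("structure")
    pca = pca_genotypes(gm, n_axes=min(10, gm.n_samples - 1))
    results["pca"] = pca
    best_k, assign, bic = find_clusters(
        pca.scores, k_max=min(6, gm.n_samples - 1), seed=cfg.seed
    )
    results["clusters"] = {"best_k": best_k, "assignments": assign, "bic": bic}

    # --- outlier partition -----------------------------------------------------
    if cfg.do_outliers and gm.n_loci >= 50:
        stage("outliers")
        ot = pcadapt_outliers(gm, K=cfg.outlier_K, fdr=cfg.outlier_fdr)
        results["outliers"] = ot
        flag = ot["flag_fdr"] if cfg.outlier_set == "fdr" else ot["flag_bonferroni"]
        gm = subset(gm, locus_keep=~flag.to_numpy())
        ledger.append("outlier_removal", gm)

    # --- LD prune --------------------------------------------------------------
    if cfg.do_ld_prune:
        stage("ld_prune")
        gm = ld_prune(
            gm, r2_within=cfg.r2_within, window_bp=cfg.ld_window_bp,
            r2_between=cfg.r2_between,
        )
        ledger.append("ld_prune", gm)

    # --- final structure ---------------------------------------------------------
    stage("final_structure")
    results["final_pca"] = pca_genotypes(gm, n_axes=min(10, gm.n_samples - 1))
    results["final_matrix"] = gm
    results["ledger"] = ledger

    # --- outputs -----------------------------------------------------------------
    ledger.write(out / "ledger.tsv")
    if cfg.write_stage_vcfs:
        write_vcf(gm, out / "final.vcf")
    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "config": dataclasses.asdict(cfg),
        "ledger": ledger.rows,
        "stages": results["stages"],
    }
    manifest["checksum"] = _checksum(manifest)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    results["manifest"] = manifest
    return results
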