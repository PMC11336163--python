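import numpy as np
import pandas as pd
import pytest

import radstruct as rs


def make_gm(G, chrom=None, pos=None, samples=None, **loci_extra):
    """Build a GenotypeMatrix from a raw dosage array (rows = samples)."""
    G = np.asarray(G, dtype=np.int8)
    n, L = G.shape
    if samples is None:
        samples = [f"s{i}" for i in range(n)]
    if chrom is None:
        chrom = ["chr1"] * L
    if pos is None:
        pos = np.arange(1, L + 1) * 1000
    loci = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "id": [f"{c}:{p}" for c, p in zip(chrom, pos)],
            "ref": ["A"] * L,
            "alt": ["G"] * L,
            **loci_extra,
        }
    )
    return rs.GenotypeMatrix(samples=list(samples), loci=loci, G=G)


def random_gm(rng, n=30, L=200, missing=0.05, n_chrom=2, span=10_000_000):
    G = rng.integers(0, 3, size=(n, L)).astype(np.int8)
    if missing:
        G[rng.random(G.shape) < missing] = rs.MISSING
    per = L // n_chrom
    chrom, pos = [], []
    for c in range(n_chrom):
        k = per if c < n_chrom - 1 else L - per * (n_chrom - 1)
        chrom += [f"chr{c + 1}"] * k
        pos += sorted(rng.choice(span, size=k, replace=False) + 1)
    return make_gm(G, chrom=chrom, pos=pos)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260101)


@pytest.fixture(scope="session")
def inversion_dataset():
    """200 samples, one planted inversion (p_inv = 0.3) with 150 region SNPs."""
    region = rs.GenomicRegion("chr2", 5_000_000, 15_000_000)
    cfg = rs.SimConfig(
        seed=11,
        n_loci=450,
        chrom_layout={"chr1": 30_000_000, "chr2": 30_000_000},
        pop_sizes={"p1": 200},
        fst=0.005,
        inversion_spec=[rs.InversionSpec(region, p_inv=0.3)],
        missing_rate=0.02,
    )
    # chr2 gets ~225 loci; the 10-Mbp region covers ~1/3 of chr2 -> ~150 SNPs
    gm, table, truth = rs.simulate_dataset(cfg)
    return gm, table, truth, region


@pytest.fixture(scope="session")
def species_dataset():
    """Two species + hybrids + discordant conspecifics, 3 demes."""
    cfg = rs.SimConfig(
        seed=7,
        n_loci=800,
        pop_sizes={"WA": 40, "EA": 40, "HB": 40},
        fst=0.01,
        n_pure_A=10,
        hybrid_spec=[rs.HybridSpec("F1", 4, maternal="A")],
        n_B_with_A_mtdna=6,
        missing_rate=0.03,
    )
    return rs.simulate_dataset(cfg)
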