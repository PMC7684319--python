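import numpy as np
import pytest

from clipmap.models import (
    ALTERNATIVE,
    CONSTITUTIVE,
    GeneModel,
    GenomicInterval,
    Peak,
)
from clipmap.synthetic import SimulationConfig, simulate_annotation


def make_gene(
    chrom: str = "chrT",
    strand: str = "+",
    n_exons: int = 6,
    exon_len: int = 100,
    intron_len: int = 100,
    start: int = 100,
    gene_id: str = "gT",
    transcript_id: str = "gT.t1",
    biotype: str = "protein_coding",
    alt_index: int | None = None,
    cds_utr: int = 0,
) -> GeneModel:
    """A regular gene: exons of ``exon_len`` separated by ``intron_len``."""
    exons = []
    pos = start
    for _ in range(n_exons):
        exons.append(GenomicInterval(chrom, pos, pos + exon_len, strand))
        pos += exon_len + intron_len
    pos -= intron_len
    labels = [CONSTITUTIVE] * n_exons
    if alt_index is not None:
        labels[alt_index] = ALTERNATIVE
    cds = []
    if cds_utr:
        total = n_exons * exon_len
        lo_t, hi_t = cds_utr, total - cds_utr
        cum = 0
        for e in exons:
            a, b = max(cum, lo_t), min(cum + exon_len, hi_t)
            if a < b:
                cds.append(GenomicInterval(chrom, e.start + a - cum, e.start + b - cum, strand))
            cum += exon_len
    return GeneModel(
        gene_id=gene_id,
        transcript_id=transcript_id,
        biotype=biotype,
        interval=GenomicInterval(chrom, start, pos, strand),
        exons=exons,
        exon_labels=labels,
        cds=cds,
    )


def make_peak(chrom, start, end, strand="+", lib="lib1", p=5.0, fold=8.0, name=""):
    return Peak(
        interval=GenomicInterval(chrom, start, end, strand),
        library_id=lib,
        neg_log10_p=p,
        fold_enrichment=fold,
        name=name,
    )


@pytest.fixture
def six_exon_gene() -> GeneModel:
    """'+' strand gene: exons [100,200) [300,400) ... [1100,1200)."""
    return make_gene()


@pytest.fixture
def six_exon_gene_minus() -> GeneModel:
    return make_gene(strand="-", gene_id="gM", transcript_id="gM.t1")


@pytest.fixture(scope="session")
def sim_small():
    """A small but complete simulated study shared across tests."""
    cfg = SimulationConfig(seed=11, n_genes=40)
    models, genome = simulate_annotation(cfg)
    return cfg, models, genome


def random_peak_libraries(rng: np.random.Generator, n_libs=4, max_peaks=50):
    """Random dense peak instances for merge-oracle comparisons."""
    libs = []
    for li in range(n_libs):
        n = int(rng.integers(0, max_peaks + 1))
        lst = []
        for _ in range(n):
            chrom = f"chr{rng.integers(1, 3)}"
            strand = "+" if rng.random() < 0.5 else "-"
            s = int(rng.integers(0, 1500))
            w = int(rng.integers(10, 80))
            lst.append(make_peak(chrom, s, s + w, strand, lib=f"lib{li + 1}"))
        libs.append(lst)
    return libs
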