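import warnings

import pytest

from clipflow.crosslinks import call_significant_sites
from clipflow.genome import Gene, GenomeAnnotation, Transcript, cotranscribed_region
from clipflow.simulate import SimulationConfig, generate_genome, simulate_iclip


def regions_of(annotation):
    regions = {}
    for gene in annotation.genes:
        regions.setdefault((gene.chrom, gene.strand), []).extend(
            cotranscribed_region(gene)
        )
    return {k: sorted(v) for k, v in sorted(regions.items())}


@pytest.fixture
def toy_annotation():
    """Two genes on one small chromosome, one per strand."""
    seq = "ACGT" * 1000  # 4 kb
    tx1 = Transcript("gA.t1", [(100, 200), (300, 400)], tsl=1, cds=(150, 350))
    gene_a = Gene("gA", "chr1", "+", [tx1])
    tx2 = Transcript("gB.t1", [(1000, 1200), (1500, 1700)], tsl=1)
    gene_b = Gene("gB", "chr1", "-", [tx2], biotype="noncoding")
    ann = GenomeAnnotation({"chr1": seq}, [gene_a, gene_b])
    ann.validate()
    return ann


@pytest.fixture(scope="session")
def default_sim():
    """Default synthetic dataset: genome + truth + iCLIP libraries."""
    cfg = SimulationConfig(seed=1)
    annotation, truth = generate_genome(cfg)
    signal, control = simulate_iclip(annotation, truth, cfg)
    return {
        "config": cfg,
        "annotation": annotation,
        "truth": truth,
        "signal": signal,
        "control": control,
        "regions": regions_of(annotation),
    }


@pytest.fixture(scope="session")
def motif_sim():
    """Denser planting for motif-recovery tests (>= 50 sites)."""
    cfg = SimulationConfig(seed=1, n_planted_sites=60)
    annotation, truth = generate_genome(cfg)
    signal, control = simulate_iclip(annotation, truth, cfg)
    regions = regions_of(annotation)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sites = call_significant_sites(signal, regions, n_rand=100, seed=7)
    return {
        "config": cfg,
        "annotation": annotation,
        "truth": truth,
        "signal": signal,
        "control": control,
        "regions": regions,
        "sites": sites,
    }
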