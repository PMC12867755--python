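import pytest

from ectosrna.synthdata import SimConfig, make_genome, simulate_reads


@pytest.fixture(scope="session")
def study():
    """Full-size simulated study: genome, annotation, truth, total library.

    Seed 7, 10 planted miRNA loci, 200k reads (>= 50 reads per locus).
    """
    cfg = SimConfig(seed=7)
    genome, features, truth = make_genome(cfg)
    total, labels = simulate_reads(genome, features, truth, cfg, "total",
                                   return_labels=True)
    return {"config": cfg, "genome": genome, "features": features,
            "truth": truth, "total": total, "total_labels": labels}


@pytest.fixture(scope="session")
def risc_reads(study):
    cfg = study["config"]
    return simulate_reads(study["genome"], study["features"], study["truth"],
                          cfg, "risc")


@pytest.fixture(scope="session")
def small_study():
    """Small fast study for unit tests: 1 contig, 3 loci, 20k reads."""
    cfg = SimConfig(seed=3, n_contigs=1, contig_len=60_000, n_genes=10,
                    n_tes=5, n_mirnas=3, library_depth=60_000)
    genome, features, truth = make_genome(cfg)
    total, labels = simulate_reads(genome, features, truth, cfg, "total",
                                   return_labels=True)
    return {"config": cfg, "genome": genome, "features": features,
            "truth": truth, "total": total, "total_labels": labels}
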